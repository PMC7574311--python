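import pytest

from proteopipe.contig_db import NucContig


@pytest.fixture
def toy_contigs():
    """Two tiny contigs: one with an internal stop in frame 1, one too short."""
    return [
        NucContig("c1", "ATGCCTGAAGCTAAATAAATGGTTCCTGAAGCT"),
        NucContig("c2", "TTTTT"),
    ]


@pytest.fixture
def contig_fasta(tmp_path, toy_contigs):
    path = tmp_path / "contigs.fasta"
    with open(path, "w") as fh:
        for c in toy_contigs:
            fh.write(f">{c.id}\n{c.seq}\n")
    return path
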