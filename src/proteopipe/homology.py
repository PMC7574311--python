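"""Best-hit homolog annotation of contig-derived candidate proteins.

Candidate entries from the contig peptide database carry no functional
information, so each is annotated with its closest match in a reference
proteome (e.g. *Medicago truncatula*, or the partial curated *M. sativa*
set). "Closest" is the highest Smith-Waterman local-alignment score under
BLOSUM62 with affine gaps (open 11, extend 1) — the standard
protein-search scoring. Ties are broken by higher percent identity, then
by lexicographically smaller accession, so annotation is independent of
reference input order. No E-values are computed; ranking is by raw score.

A confirmation database can then be produced in which every annotated
candidate contig's entries are replaced by the single homolog sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .contig_db import PeptideDatabase, PeptideEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceProtein:
    accession: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"reference {self.accession!r}: empty sequence")


@dataclass(frozen=True)
class Annotation:
    query_id: str
    best_accession: str
    alignment_score: float
    percent_identity: float
    description: str = ""


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> PairwiseAligner:
    """Local aligner with affine gaps: a gap of length L costs
    ``gap_open + L * gap_extend``, the BLAST convention."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _identity_over_columns(alignment) -> float:
    """Percent identity over the aligned columns (gap columns included)."""
    counts = alignment.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    if ncols == 0:
        return 0.0
    return 100.0 * counts.identities / ncols


def best_fit(
    query: str,
    references: Sequence[ReferenceProtein],
    query_id: str = "query",
    aligner: PairwiseAligner | None = None,
) -> Annotation:
    """Return the reference with the highest local-alignment score.

    Sequences containing only residues the substitution matrix cannot
    score are handled by mapping unknown residues to 'X'.
    """
    if not references:
        raise ValueError("reference set is empty")
    if not query:
        raise ValueError("query sequence is empty")
    if aligner is None:
        aligner = make_aligner()
    alphabet = set(str(aligner.substitution_matrix.alphabet))

    def sanitize(s: str) -> str:
        return "".join(c if c in alphabet else "X" for c in s.upper())

    q = sanitize(query)
    best: tuple[float, float, str] | None = None  # (score, identity, accession)
    best_ref: ReferenceProtein | None = None
    for ref in references:
        aln = aligner.align(q, sanitize(ref.seq))
        score = aln.score
        ident = _identity_over_columns(aln[0]) if len(aln) else 0.0
        key = (score, ident, ref.accession)
        if best is None or (key[0], key[1], _neg(key[2])) > (
            best[0],
            best[1],
            _neg(best[2]),
        ):
            best = key
            best_ref = ref
    assert best is not None and best_ref is not None
    return Annotation(
        query_id=query_id,
        best_accession=best_ref.accession,
        alignment_score=float(best[0]),
        percent_identity=best[1],
        description=best_ref.description,
    )


class _neg:
    """Inverts string ordering so 'smaller accession wins' fits a max."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg) and self.s == other.s


def annotate_all(
    queries: Iterable[tuple[str, str]],
    references: Sequence[ReferenceProtein],
    aligner: PairwiseAligner | None = None,
) -> list[Annotation]:
    if aligner is None:
        aligner = make_aligner()
    return [
        best_fit(seq, references, query_id=qid, aligner=aligner)
        for qid, seq in queries
    ]


def replace_with_homologs(
    database: PeptideDatabase,
    mapping: dict[str, ReferenceProtein],
) -> PeptideDatabase:
    """Replace all entries of each mapped base contig by one homolog entry.

    Unmapped entries pass through unchanged. The homolog entry carries the
    reference accession as its id (frame 1, segment 1 by convention). A
    mapping key naming a contig absent from the database is skipped with a
    warning. Idempotent for a fixed mapping.
    """
    present = {e.base_contig for e in database.entries}
    for contig in sorted(set(mapping) - present):
        logger.warning("mapping references absent contig %r; skipped", contig)
    out = PeptideDatabase(params=database.params)
    replaced: set[str] = set()
    for entry in database.entries:
        ref = mapping.get(entry.base_contig)
        if ref is None:
            out.entries.append(entry)
        elif entry.base_contig not in replaced:
            replaced.add(entry.base_contig)
            out.entries.append(
                PeptideEntry(
                    entry_id=ref.accession,
                    base_contig=ref.accession,
                    frame=1,
                    segment=1,
                    seq=ref.seq,
                )
            )
    out.n_source_contigs = len({e.base_contig for e in out.entries})
    return out


def read_references(path) -> list[ReferenceProtein]:
    """Load a reference proteome FASTA; id = first token, rest = description."""
    refs = []
    for rec in SeqIO.parse(path, "fasta"):
        refs.append(
            ReferenceProtein(
                accession=rec.id,
                seq=str(rec.seq),
                description=rec.description.partition(" ")[2],
            )
        )
    return refs
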