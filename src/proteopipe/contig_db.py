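"""Peptide search-database construction from transcriptome contigs.

Assembled transcript contigs of a species without a sequenced proteome
(here: alfalfa, *Medicago sativa*) can serve as a proteomic search space
once translated. Because the reading frame of a contig relative to the
coding sequence is unknown, every contig is translated in the three
forward frames; each frame translation is split at stop codons into
maximal stop-free segments, and segments shorter than a minimum length
(default five residues) are discarded. The surviving segments form the
peptide database used by downstream spectrum-identification engines.

Reverse-complement frames (a full six-frame translation) are available
behind an option but are off by default: assembled transcripts are
normally reported on the sense strand.
"""

from __future__ import annotations

import json
import logging
import re
import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (U is normalized to T on input).
IUPAC_NUC = set("ACGTUNRYSWKMBDHV")

_STANDARD_TABLE = unambiguous_dna_by_id[1]

#: codon -> amino acid for the standard genetic code, stops as '*'.
CODON_TABLE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TABLE[_stop] = "*"

FORWARD_FRAMES = (1, 2, 3)
SIX_FRAMES = (1, 2, 3, 4, 5, 6)

_STOP_RUN = re.compile(r"\*+")


class InputFormatError(ValueError):
    """Malformed input data (bad FASTA, bad sequence characters, duplicate ids)."""


@dataclass(frozen=True)
class NucContig:
    """A nucleotide contig: whitespace-free id plus an IUPAC sequence.

    The sequence is uppercased and U-normalized at construction; a
    character outside the IUPAC nucleotide alphabet raises
    :class:`InputFormatError` naming the contig.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise InputFormatError(f"invalid contig id: {self.id!r}")
        norm = self.seq.upper().replace("U", "T")
        bad = set(norm) - IUPAC_NUC
        if bad:
            raise InputFormatError(
                f"contig {self.id!r}: non-IUPAC nucleotide character(s) "
                f"{sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", norm)


@dataclass(frozen=True)
class PeptideEntry:
    """One stop-free translated segment with its provenance."""

    entry_id: str
    base_contig: str
    frame: int
    segment: int
    seq: str


@dataclass
class DatabaseParams:
    frames: tuple[int, ...] = FORWARD_FRAMES
    min_len: int = 5
    naming: str = "canonical"
    table_id: int = 1


@dataclass
class PeptideDatabase:
    """Ordered collection of peptide entries plus summary counts."""

    entries: list[PeptideEntry] = field(default_factory=list)
    n_source_contigs: int = 0
    params: DatabaseParams = field(default_factory=DatabaseParams)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def summary(self, n_input_contigs: int | None = None) -> dict:
        d = {
            "n_entries": self.n_entries,
            "n_source_contigs": self.n_source_contigs,
            "params": {
                "frames": list(self.params.frames),
                "min_len": self.params.min_len,
                "naming": self.params.naming,
                "genetic_code_table": self.params.table_id,
            },
        }
        if n_input_contigs is not None:
            d = {"n_input_contigs": n_input_contigs, **d}
        return d


def translate_frame(contig: NucContig, frame: int) -> str:
    """Translate one forward frame (1-3) or reverse-complement frame (4-6).

    Translation starts at offset ``frame - 1`` (frames 4-6: same offsets on
    the reverse complement) and proceeds codon by codon under the standard
    genetic code. A trailing partial codon is dropped. A codon containing
    any character outside A/C/G/T translates to ``X`` — an ambiguous codon
    is never treated as evidence of a stop. Stop codons give ``*``.
    """
    if frame not in SIX_FRAMES:
        raise ValueError(f"frame must be in 1..6, got {frame}")
    seq = contig.seq if frame <= 3 else reverse_complement(contig.seq)
    offset = (frame - 1) % 3
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def split_at_stops(frame_translation: str) -> list[str]:
    """Return the maximal ``*``-free substrings, left to right.

    Empty segments arising from leading, trailing, or consecutive stops
    are omitted.
    """
    return [s for s in _STOP_RUN.split(frame_translation) if s]


def name_entries(
    base_contig: str,
    frame: int,
    segments: Sequence[str],
    style: str = "canonical",
) -> list[tuple[str, str]]:
    """Assign entry ids to the stop-split segments of one contig frame.

    ``canonical`` ids are frame-qualified and collision-free:
    ``<base>_f<frame>`` for the first segment, ``<base>_f<frame>_<j>`` for
    segment *j* >= 2. ``paper`` style reproduces the frame-blind convention
    ``<base>``, ``<base>_2``, ...; with more than one frame these ids
    collide across frames, so a warning is emitted by the database builder
    when that happens.
    """
    if style not in ("canonical", "paper"):
        raise ValueError(f"unknown naming style: {style!r}")
    named = []
    for j, seg in enumerate(segments, start=1):
        if style == "canonical":
            eid = f"{base_contig}_f{frame}" if j == 1 else f"{base_contig}_f{frame}_{j}"
        else:
            eid = base_contig if j == 1 else f"{base_contig}_{j}"
        named.append((eid, seg))
    return named


def filter_min_length(
    entries: Iterable[tuple[str, str]], min_len: int = 5
) -> list[tuple[str, str]]:
    """Keep entries with ``len(seq) >= min_len`` (boundary inclusive), order preserved."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return [(eid, seq) for eid, seq in entries if len(seq) >= min_len]


def build_database(
    contigs: Iterable[NucContig],
    frames: Sequence[int] = FORWARD_FRAMES,
    min_len: int = 5,
    naming: str = "canonical",
    progress_every: int = 0,
) -> PeptideDatabase:
    """Translate, stop-split, name and length-filter every contig.

    Output order is deterministic: input contig order, then frame, then
    segment. ``n_source_contigs`` counts contigs that contribute at least
    one surviving entry. Duplicate contig ids raise
    :class:`InputFormatError`; duplicate peptide *sequences* are retained.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    frames = tuple(frames)
    if not frames or any(f not in SIX_FRAMES for f in frames):
        raise ValueError(f"frames must be a non-empty subset of 1..6, got {frames}")
    params = DatabaseParams(frames=frames, min_len=min_len, naming=naming)
    db = PeptideDatabase(params=params)
    seen_ids: set[str] = set()
    seen_entry_ids: set[str] = set()
    collision_warned = False
    n_in = 0
    for contig in contigs:
        n_in += 1
        if contig.id in seen_ids:
            raise InputFormatError(f"duplicate contig id: {contig.id!r}")
        seen_ids.add(contig.id)
        contributed = False
        for frame in frames:
            segments = split_at_stops(translate_frame(contig, frame))
            named = name_entries(contig.id, frame, segments, style=naming)
            # segment numbers refer to the pre-filter split order, so the
            # id suffix stays aligned with the segment field after filtering
            kept = [
                (j, eid, seq)
                for j, (eid, seq) in enumerate(named, start=1)
                if len(seq) >= min_len
            ]
            for j, eid, seq in kept:
                if eid in seen_entry_ids:
                    if not collision_warned:
                        warnings.warn(
                            f"entry id collision under {naming!r} naming "
                            f"(first: {eid!r}); ids are not unique across frames",
                            stacklevel=2,
                        )
                        collision_warned = True
                seen_entry_ids.add(eid)
                db.entries.append(
                    PeptideEntry(
                        entry_id=eid,
                        base_contig=contig.id,
                        frame=frame,
                        segment=j,
                        seq=seq,
                    )
                )
                contributed = True
        if contributed:
            db.n_source_contigs += 1
        if progress_every and n_in % progress_every == 0:
            logger.info("processed %d contigs, %d entries", n_in, db.n_entries)
    if progress_every:
        logger.info(
            "done: %d contigs in, %d entries, %d source contigs",
            n_in,
            db.n_entries,
            db.n_source_contigs,
        )
    return db


# ---------------------------------------------------------------------------
# FASTA I/O

def read_contigs(path_or_handle) -> Iterator[NucContig]:
    """Stream contigs from a (possibly wrapped) nucleotide FASTA.

    The id is the first whitespace-delimited token of the header.
    """
    from Bio import SeqIO

    for rec in SeqIO.parse(path_or_handle, "fasta"):
        yield NucContig(id=rec.id, seq=str(rec.seq))


def write_fasta(
    entries: Iterable[tuple[str, str]], handle: TextIO, width: int = 60
) -> int:
    """Write (id, seq) pairs as wrapped protein FASTA; return record count."""
    n = 0
    for eid, seq in entries:
        handle.write(f">{eid}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")
        n += 1
    return n


def write_database(
    db: PeptideDatabase,
    fasta_path: str,
    summary_path: str | None = None,
    n_input_contigs: int | None = None,
) -> None:
    with open(fasta_path, "w") as fh:
        write_fasta(((e.entry_id, e.seq) for e in db.entries), fh)
    if summary_path:
        with open(summary_path, "w") as fh:
            json.dump(db.summary(n_input_contigs), fh, indent=2)
            fh.write("\n")


def count_entries(database_file: str) -> int:
    """Count records in a protein FASTA by streaming over '>' header lines.

    Constant memory; a sequence line appearing before any header raises
    :class:`InputFormatError` with the offending line number.
    """
    n = 0
    with open(database_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                n += 1
            elif line.strip() and n == 0:
                raise InputFormatError(
                    f"{database_file}: line {lineno}: sequence data before "
                    "first '>' header"
                )
    return n


def _log_progress_to_stderr() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
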