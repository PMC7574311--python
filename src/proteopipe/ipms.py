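"""Per-protein evidence aggregation and candidate filtering for IP-MS.

Immunoprecipitation followed by LC-MS/MS (IP-MS) yields peptide-spectrum
matches (PSMs). Candidate bait interactors are accepted on spectral-count
evidence: a protein (or contig group) qualifies when it carries at least
``min_peptides`` distinct peptide sequences and at least ``min_spectra``
PSMs (defaults 3 and 6, inclusive). Sequence coverage — the percentage of
a protein's residues hit by at least one identified peptide — is reported
when the protein sequence is available. An optional wild-type control
subtraction drops candidates whose control spectral count exceeds a
fraction of their bait count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# canonical ids: <base>_f<k> or <base>_f<k>_<j>
_CANONICAL_RE = re.compile(r"^(?P<base>.+?)_f[1-6](?:_\d+)?$")
# frame-blind ids: segment extensions append one _<j> to a base that, by
# the "contig_<n>" convention, itself ends in _<digits>
_PAPER_RE = re.compile(r"^(?P<base>.*_\d+)_\d+$")


class InputFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match: a spectrum assigned to a peptide that
    maps to one or more proteins, in the bait or the control sample."""

    spectrum_id: str
    peptide: str
    proteins: tuple[str, ...]
    sample: str = "bait"

    def __post_init__(self) -> None:
        if not self.peptide or "*" in self.peptide:
            raise InputFormatError(
                f"spectrum {self.spectrum_id!r}: peptide must be non-empty "
                f"and stop-free, got {self.peptide!r}"
            )
        if not self.proteins:
            raise InputFormatError(
                f"spectrum {self.spectrum_id!r}: empty protein list"
            )


@dataclass(frozen=True)
class ProteinEvidence:
    """Aggregated evidence for one accession in one sample."""

    accession: str
    n_peptides: int
    n_spectra: int
    sample: str = "bait"
    coverage_pct: float | None = None


def base_accession(accession: str) -> str:
    """Strip frame (``_f<k>``) and segment (``_<j>``) suffixes from a
    contig-derived accession, collapsing extensions onto their base contig.

    Frame-qualified (canonical) ids are unambiguous. Frame-blind ids like
    ``contig_7_2`` are collapsed onto ``contig_7`` by removing one trailing
    numeric extension, which requires the base id itself to end in an
    underscore-number (the usual assembler convention); other accessions
    pass through unchanged.
    """
    m = _CANONICAL_RE.match(accession)
    if m:
        return m.group("base")
    m = _PAPER_RE.match(accession)
    if m:
        return m.group("base")
    return accession


def aggregate_psms(
    records: Iterable[PSMRecord],
    group_extensions: bool = False,
    shared_peptide_policy: str = "all",
) -> list[ProteinEvidence]:
    """Aggregate PSMs into per-accession, per-sample evidence records.

    ``n_peptides`` counts distinct peptide strings; ``n_spectra`` counts
    PSMs. Under policy ``all`` a shared peptide/PSM counts for every
    protein it maps to; under ``razor`` only for the protein with the most
    distinct peptides over the whole sample (ties broken by
    lexicographically smallest accession), so every PSM contributes to
    exactly one protein. Output is sorted by (sample, accession).
    """
    if shared_peptide_policy not in ("all", "razor"):
        raise ValueError(f"unknown policy: {shared_peptide_policy!r}")
    records = list(records)
    seen_spectra: set[tuple[str, str]] = set()
    for r in records:
        key = (r.sample, r.spectrum_id)
        if key in seen_spectra:
            raise InputFormatError(
                f"duplicate spectrum_id {r.spectrum_id!r} in sample {r.sample!r}"
            )
        seen_spectra.add(key)

    def accessions(r: PSMRecord) -> list[str]:
        accs = [base_accession(a) for a in r.proteins] if group_extensions else list(r.proteins)
        return sorted(set(accs))

    if shared_peptide_policy == "razor":
        # peptide-level protein ranking per sample: most distinct peptides wins
        pep_sets: dict[tuple[str, str], set[str]] = {}
        for r in records:
            for acc in accessions(r):
                pep_sets.setdefault((r.sample, acc), set()).add(r.peptide)
        def owner(r: PSMRecord) -> list[str]:
            return [
                min(
                    accessions(r),
                    key=lambda a: (-len(pep_sets[(r.sample, a)]), a),
                )
            ]
        assign = owner
    else:
        assign = accessions

    peptides: dict[tuple[str, str], set[str]] = {}
    spectra: dict[tuple[str, str], int] = {}
    for r in records:
        for acc in assign(r):
            key = (r.sample, acc)
            peptides.setdefault(key, set()).add(r.peptide)
            spectra[key] = spectra.get(key, 0) + 1
    return [
        ProteinEvidence(
            accession=acc,
            n_peptides=len(peptides[(sample, acc)]),
            n_spectra=spectra[(sample, acc)],
            sample=sample,
        )
        for sample, acc in sorted(spectra)
    ]


def filter_candidates(
    evidence: Iterable[ProteinEvidence],
    min_peptides: int = 3,
    min_spectra: int = 6,
) -> list[ProteinEvidence]:
    """Keep records with ``n_peptides >= min_peptides`` and
    ``n_spectra >= min_spectra`` (both inclusive); order preserved."""
    if min_peptides < 0 or min_spectra < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        e
        for e in evidence
        if e.n_peptides >= min_peptides and e.n_spectra >= min_spectra
    ]


def subtract_control(
    candidates: Sequence[ProteinEvidence],
    control_evidence: Iterable[ProteinEvidence],
    max_control_fraction: float = 0.5,
) -> list[tuple[ProteinEvidence, bool]]:
    """Flag bait candidates against a wild-type control IP.

    A candidate is dropped (flag ``False``) when the same accession occurs
    in the control with ``control n_spectra > max_control_fraction * bait
    n_spectra`` (strict inequality). Returns (record, kept) pairs; every
    decision is logged.
    """
    if not 0.0 <= max_control_fraction <= 1.0:
        raise ValueError(
            f"max_control_fraction must be in [0, 1], got {max_control_fraction}"
        )
    control = {e.accession: e for e in control_evidence}
    out: list[tuple[ProteinEvidence, bool]] = []
    for cand in candidates:
        ctrl = control.get(cand.accession)
        keep = ctrl is None or ctrl.n_spectra <= max_control_fraction * cand.n_spectra
        if ctrl is None:
            logger.debug("%s: no control evidence, kept", cand.accession)
        else:
            logger.info(
                "%s: control %d vs bait %d spectra (fraction %.2f) -> %s",
                cand.accession,
                ctrl.n_spectra,
                cand.n_spectra,
                max_control_fraction,
                "kept" if keep else "dropped",
            )
        out.append((cand, keep))
    return out


def compute_coverage(
    protein_seq: str,
    peptides: Iterable[str],
    equate_il: bool = False,
) -> float:
    """Sequence coverage in percent: residues hit by >= 1 exact substring
    occurrence of any peptide (all occurrences, overlaps merged) over the
    protein length. ``equate_il`` treats isoleucine and leucine as equal,
    matching some search-engine conventions.
    """
    if not protein_seq:
        raise ValueError("protein sequence must be non-empty")

    def norm(s: str) -> str:
        return s.replace("I", "L") if equate_il else s

    target = norm(protein_seq)
    covered = [False] * len(target)
    for pep in set(peptides):
        p = norm(pep)
        if not p:
            continue
        start = 0
        while True:
            i = target.find(p, start)
            if i < 0:
                break
            for k in range(i, i + len(p)):
                covered[k] = True
            start = i + 1
    return 100.0 * sum(covered) / len(target)


def collect_peptides(
    records: Iterable[PSMRecord], group_extensions: bool = False
) -> dict[tuple[str, str], set[str]]:
    """Map (sample, accession) to the distinct peptide strings observed."""
    out: dict[tuple[str, str], set[str]] = {}
    for r in records:
        accs = (
            {base_accession(a) for a in r.proteins}
            if group_extensions
            else set(r.proteins)
        )
        for acc in accs:
            out.setdefault((r.sample, acc), set()).add(r.peptide)
    return out


def attach_coverage(
    evidence: Sequence[ProteinEvidence],
    peptide_map: dict[tuple[str, str], set[str]],
    sequences: dict[str, str],
    equate_il: bool = False,
) -> list[ProteinEvidence]:
    """Fill ``coverage_pct`` where the accession's sequence is known."""
    out = []
    for e in evidence:
        seq = sequences.get(e.accession)
        if seq:
            cov = compute_coverage(
                seq, peptide_map.get((e.sample, e.accession), set()), equate_il
            )
            out.append(replace(e, coverage_pct=cov))
        else:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# tabular I/O

#: default column mapping for PeptideShaker-style exports
DEFAULT_COLUMNS = {
    "spectrum_id": "spectrum_id",
    "peptide": "peptide",
    "proteins": "proteins",
    "sample": "sample",
}


def read_psm_table(path, columns: dict[str, str] | None = None) -> list[PSMRecord]:
    """Read a tab-separated PSM report with a header row.

    ``columns`` maps the required logical names (spectrum_id, peptide,
    proteins, sample) to the file's column names; extra columns are
    ignored. The proteins field is semicolon-separated.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            PSMRecord(
                spectrum_id=d[cols["spectrum_id"]],
                peptide=d[cols["peptide"]],
                proteins=tuple(
                    a for a in str(d[cols["proteins"]]).split(";") if a
                ),
                sample=d[cols["sample"]],
            )
        )
    return records


def evidence_frame(evidence: Sequence[ProteinEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": e.accession,
                "sample": e.sample,
                "n_peptides": e.n_peptides,
                "n_spectra": e.n_spectra,
                "coverage_pct": e.coverage_pct,
            }
            for e in evidence
        ],
        columns=["accession", "sample", "n_peptides", "n_spectra", "coverage_pct"],
    )


def candidates_frame(
    evidence: Sequence[ProteinEvidence],
    min_peptides: int = 3,
    min_spectra: int = 6,
) -> pd.DataFrame:
    """Evidence table with pass/fail verdicts and the failing reasons."""
    rows = []
    for e in evidence:
        reasons = []
        if e.n_peptides < min_peptides:
            reasons.append(f"n_peptides<{min_peptides}")
        if e.n_spectra < min_spectra:
            reasons.append(f"n_spectra<{min_spectra}")
        rows.append(
            {
                "accession": e.accession,
                "sample": e.sample,
                "n_peptides": e.n_peptides,
                "n_spectra": e.n_spectra,
                "coverage_pct": e.coverage_pct,
                "candidate": not reasons,
                "fail_reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "sample",
            "n_peptides",
            "n_spectra",
            "coverage_pct",
            "candidate",
            "fail_reason",
        ],
    )
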