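"""Differential-expression calling and tissue-specificity classification.

A gene is a DEG when its multiple-testing-corrected p-value is below
``alpha`` (strict, default 0.05) and its absolute log2 fold change is at
least ``log2(min_fold)`` (inclusive, default 2-fold i.e. |log2FC| >= 1).
Direction (increased / decreased) follows the sign of log2FC.

Across leaf, stem and root, each DEG's per-direction membership set
places it in exactly one Venn category: common to all three tissues,
specific to one tissue, or shared by one pair. Increased and decreased
directions are tallied independently, so a gene up in one tissue and
down in another contributes to both tallies. Percentages are relative to
each tissue's total DEG count and rounded to the nearest integer.

Gene-expression plasticity between two genotypes is summarised as the
fold ratio of their DEG counts, either as the ratio of summed totals or
as the mean of per-tissue ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("leaf", "stem", "root")
DIRECTIONS = ("increased", "decreased")


class InputFormatError(ValueError):
    pass


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result in one tissue/contrast.

    ``log2fc`` is positive when expression is higher in the first-named
    condition of the contrast; ``padj`` may be missing (NaN/None), in
    which case the gene is never called a DEG.
    """

    gene_id: str
    log2fc: float
    padj: float | None
    tissue: str
    contrast: str = ""


DEGSets = dict[str, dict[str, set[str]]]  # direction -> tissue -> genes


def call_deg(
    table: Iterable[DERecord],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> DEGSets:
    """Call per-tissue DEG sets split by direction of change.

    A record qualifies iff ``padj < alpha`` (strict) and
    ``|log2fc| >= log2(min_fold)`` (inclusive). Records with missing padj
    are never DEG.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if min_fold <= 1.0:
        raise ValueError(f"min_fold must be > 1, got {min_fold}")
    lfc_cut = math.log2(min_fold)
    sets: DEGSets = {d: {t: set() for t in TISSUES} for d in DIRECTIONS}
    seen: set[tuple[str, str, str]] = set()
    for rec in table:
        if rec.tissue not in TISSUES:
            raise InputFormatError(
                f"gene {rec.gene_id!r}: unknown tissue {rec.tissue!r}"
            )
        key = (rec.gene_id, rec.tissue, rec.contrast)
        if key in seen:
            raise InputFormatError(
                f"duplicate record for gene {rec.gene_id!r} in {rec.tissue}"
            )
        seen.add(key)
        if rec.padj is None or (isinstance(rec.padj, float) and math.isnan(rec.padj)):
            continue
        if rec.padj < alpha and abs(rec.log2fc) >= lfc_cut:
            direction = "increased" if rec.log2fc > 0 else "decreased"
            sets[direction][rec.tissue].add(rec.gene_id)
    return sets


#: Venn categories in reporting order.
CATEGORIES = (
    "common",
    "leaf_specific",
    "stem_specific",
    "root_specific",
    "leaf_stem",
    "leaf_root",
    "stem_root",
)

_MEMBERSHIP_TO_CATEGORY = {
    frozenset(TISSUES): "common",
    frozenset({"leaf"}): "leaf_specific",
    frozenset({"stem"}): "stem_specific",
    frozenset({"root"}): "root_specific",
    frozenset({"leaf", "stem"}): "leaf_stem",
    frozenset({"leaf", "root"}): "leaf_root",
    frozenset({"stem", "root"}): "stem_root",
}


@dataclass
class DEGClassification:
    """Per-direction Venn classification of three tissue DEG sets."""

    #: direction -> gene -> (membership frozenset, category)
    assignments: dict[str, dict[str, tuple[frozenset, str]]]
    #: direction -> category -> count
    counts: dict[str, dict[str, int]]
    #: direction -> tissue -> total DEG in that tissue
    tissue_totals: dict[str, dict[str, int]]
    #: direction -> tissue -> category -> integer percent of tissue total
    percentages: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gene,
                "direction": direction,
                "membership": "+".join(sorted(members, key=TISSUES.index)),
                "category": category,
            }
            for direction, genes in self.assignments.items()
            for gene, (members, category) in sorted(genes.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "direction", "membership", "category"]
        )

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": d, "category": c, "count": self.counts[d][c]}
            for d in DIRECTIONS
            for c in CATEGORIES
        ]
        return pd.DataFrame(rows, columns=["direction", "category", "count"])


def classify_tissue_specificity(
    leaf: Mapping[str, set[str]] | set[str],
    stem: Mapping[str, set[str]] | set[str] | None = None,
    root: Mapping[str, set[str]] | set[str] | None = None,
) -> DEGClassification:
    """Classify direction-aware tissue specificity of DEG sets.

    Accepts either the ``DEGSets`` mapping from :func:`call_deg` (single
    argument) or three per-tissue dicts/sets. Per direction, every gene in
    the union of the three sets is assigned the category determined by its
    membership set; the seven category counts partition the union.
    """
    if stem is None and root is None:
        deg_sets = leaf  # type: ignore[assignment]
        per_dir = {d: {t: set(deg_sets[d][t]) for t in TISSUES} for d in DIRECTIONS}
    else:
        def split(x):
            if isinstance(x, Mapping):
                return {d: set(x.get(d, set())) for d in DIRECTIONS}
            return {"increased": set(x), "decreased": set()}

        by_tissue = {
            "leaf": split(leaf),
            "stem": split(stem),
            "root": split(root),
        }
        per_dir = {
            d: {t: by_tissue[t][d] for t in TISSUES} for d in DIRECTIONS
        }

    assignments: dict[str, dict[str, tuple[frozenset, str]]] = {}
    counts: dict[str, dict[str, int]] = {}
    tissue_totals: dict[str, dict[str, int]] = {}
    percentages: dict[str, dict[str, dict[str, int]]] = {}
    for d in DIRECTIONS:
        sets = per_dir[d]
        union = set().union(*sets.values())
        assignments[d] = {}
        counts[d] = {c: 0 for c in CATEGORIES}
        for gene in union:
            members = frozenset(t for t in TISSUES if gene in sets[t])
            category = _MEMBERSHIP_TO_CATEGORY[members]
            assignments[d][gene] = (members, category)
            counts[d][category] += 1
        tissue_totals[d] = {t: len(sets[t]) for t in TISSUES}
        percentages[d] = {}
        for t in TISSUES:
            total = tissue_totals[d][t]
            percentages[d][t] = {}
            for c in CATEGORIES:
                if t not in _category_tissues(c) or total == 0:
                    continue
                percentages[d][t][c] = int(
                    _round_half_up(100.0 * counts[d][c] / total, 0)
                )
    return DEGClassification(
        assignments=assignments,
        counts=counts,
        tissue_totals=tissue_totals,
        percentages=percentages,
    )


def _category_tissues(category: str) -> frozenset:
    for members, cat in _MEMBERSHIP_TO_CATEGORY.items():
        if cat == category:
            return members
    raise KeyError(category)


def _round_half_up(x: float, ndigits: int) -> float:
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class PlasticitySummary:
    headline: float  # rounded half-up to 1 decimal, from the chosen method
    ratio_of_totals: float
    mean_of_ratios: float
    per_tissue_ratios: tuple[float, ...]
    method: str


def summarize_plasticity(
    genotype_a_counts: Sequence[int],
    genotype_b_counts: Sequence[int],
    method: str = "ratio_of_totals",
) -> PlasticitySummary:
    """Fold ratio of DEG counts between two genotypes over matched tissues.

    ``ratio_of_totals`` is sum(B)/sum(A); ``mean_of_ratios`` averages the
    per-tissue ratios B_i/A_i. Both are computed; the headline value comes
    from ``method``, rounded half-up to one decimal.
    """
    if method not in ("ratio_of_totals", "mean_of_ratios"):
        raise ValueError(f"unknown method: {method!r}")
    a = list(genotype_a_counts)
    b = list(genotype_b_counts)
    if len(a) != len(b) or not a:
        raise ValueError("count vectors must be non-empty and equal length")
    if any(x <= 0 for x in a):
        raise ValueError(f"zero or negative denominator count in {a}: ratio undefined")
    per_tissue = tuple(bi / ai for ai, bi in zip(a, b))
    ratio_of_totals = sum(b) / sum(a)
    mean_of_ratios = sum(per_tissue) / len(per_tissue)
    headline_raw = ratio_of_totals if method == "ratio_of_totals" else mean_of_ratios
    return PlasticitySummary(
        headline=_round_half_up(headline_raw, 1),
        ratio_of_totals=ratio_of_totals,
        mean_of_ratios=mean_of_ratios,
        per_tissue_ratios=per_tissue,
        method=method,
    )


# ---------------------------------------------------------------------------
# tabular I/O

def read_de_table(path, tissue: str, contrast: str = "") -> list[DERecord]:
    """Read a per-tissue DE TSV with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                DERecord(
                    gene_id=str(row.gene_id),
                    log2fc=float(row.log2fc),
                    padj=None if pd.isna(row.padj) else float(row.padj),
                    tissue=tissue,
                    contrast=contrast,
                )
            )
        except (TypeError, ValueError) as exc:
            raise InputFormatError(f"{path}: row {i}: {exc}") from exc
    return records
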