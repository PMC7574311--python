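"""Seeded synthetic inputs with ground truth for every pipeline stage.

The study's primary inputs (raw transcriptome contigs, raw spectra, raw
reads) are not shippable, so each stage is exercised on generated data
whose truth is known by construction:

* :func:`gen_contigs` — random nucleotide contigs with stop codons
  injected at a controlled per-codon density, plus the expected peptide
  database computed by a naive translator/splitter kept deliberately
  independent of :mod:`proteopipe.contig_db` (hard-coded codon table,
  character-by-character splitting) so the two code paths cross-check
  each other.
* :func:`gen_psm_report` — a PSM table with planted bait interactors
  (at least 3 peptides and 6 spectra each) against background proteins
  that fail at least one of those bounds, plus true labels.
* :func:`gen_de_tables` — three per-tissue DE tables with genes planted
  into chosen Venn categories and directions; planted genes get
  significant corrected p-values and above-threshold fold changes in
  exactly their member tissues, everything else stays sub-threshold.

All generators are deterministic given (parameters, seed); regenerated
files are byte-identical. Truth is plain TSV/JSON so tests never depend
on generator internals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

# Hard-coded standard genetic code for the naive oracle — independent of
# the Biopython-backed table used by the main implementation.
_ORACLE_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_STOPS = ("TAA", "TAG", "TGA")


def naive_expected_entries(
    contigs: Sequence[tuple[str, str]],
    frames: Sequence[int] = (1, 2, 3),
    min_len: int = 5,
) -> list[tuple[str, str, int, int, str]]:
    """Brute-force expected database: (entry_id, base, frame, segment, seq).

    Canonical frame-qualified naming. Written without reference to the
    main implementation: explicit codon loop over a literal codon table,
    manual segment accumulation.
    """
    out = []
    for cid, seq in contigs:
        s = seq.upper().replace("U", "T")
        for frame in frames:
            aa = ""
            i = frame - 1
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if all(c in "ACGT" for c in codon):
                    aa += _ORACLE_CODONS[codon]
                else:
                    aa += "X"
                i += 3
            # manual split at '*'
            segments: list[str] = []
            current = ""
            for ch in aa:
                if ch == "*":
                    if current:
                        segments.append(current)
                    current = ""
                else:
                    current += ch
            if current:
                segments.append(current)
            for j, seg in enumerate(segments, start=1):
                if len(seg) < min_len:
                    continue
                eid = f"{cid}_f{frame}" if j == 1 else f"{cid}_f{frame}_{j}"
                out.append((eid, cid, frame, j, seg))
    return out


# ---------------------------------------------------------------------------
# contigs


def gen_contigs(
    n: int,
    length_range: tuple[int, int] = (30, 300),
    stop_density: float = 0.05,
    n_fraction: float = 0.0,
    seed: int = 0,
    min_len: int = 5,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, int, int, str]]]:
    """Generate random contigs and the expected peptide database.

    Contigs are uniform over A/C/G/T; in frame 1, each codon is replaced
    by a random stop codon with probability ``stop_density``; finally each
    position is masked to N with probability ``n_fraction``. Returns
    (contigs, expected entries from the naive oracle).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    lo, hi = length_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    if not 0.0 <= stop_density < 1.0:
        raise ValueError(f"stop_density must be in [0, 1), got {stop_density}")
    if not 0.0 <= n_fraction <= 1.0:
        raise ValueError(f"n_fraction must be in [0, 1], got {n_fraction}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    contigs = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(bases, size=length))
        for i in range(0, length - 2, 3):
            if rng.random() < stop_density:
                stop = _STOPS[int(rng.integers(0, 3))]
                seq[i : i + 3] = list(stop)
        if n_fraction > 0:
            mask = rng.random(length) < n_fraction
            for i in np.flatnonzero(mask):
                seq[i] = "N"
        contigs.append((f"contig_{k + 1}", "".join(seq)))
    truth = naive_expected_entries(contigs, min_len=min_len)
    return contigs, truth


def write_contig_dataset(
    out_dir: str | Path,
    contigs: Sequence[tuple[str, str]],
    truth: Sequence[tuple[str, str, int, int, str]],
    params: dict | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "contigs.fasta"
    with open(fasta, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    truth_path = out / "expected_peptides.tsv"
    with open(truth_path, "w") as fh:
        fh.write("entry_id\tbase_contig\tframe\tsegment\tseq\n")
        for row in truth:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths = {"contigs": fasta, "truth": truth_path}
    if params is not None:
        pp = out / "params.json"
        with open(pp, "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["params"] = pp
    return paths


# ---------------------------------------------------------------------------
# PSM reports

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class PlantedProtein:
    accession: str
    is_interactor: bool
    n_peptides: int
    n_spectra: int


def gen_psm_report(
    n_true: int,
    n_background: int,
    seed: int = 0,
    mode: str = "noiseless",
    true_mean_spectra: float = 10.0,
    background_mean_spectra: float = 2.0,
    nb_dispersion: float = 2.0,
    control_overlap: float = 0.0,
) -> tuple[list[dict], list[PlantedProtein]]:
    """Generate PSM rows and per-protein planted labels.

    ``noiseless`` mode draws true-interactor counts from the acceptance
    region (peptides in [3, 8], spectra in [max(6, peptides), 20]) and
    background counts from its complement (peptides in [1, 2], or 3-4
    peptides with spectra capped at 5), so the evidence filter separates
    the classes perfectly by construction. ``negbin`` mode draws spectral
    counts from a negative binomial around the class means instead; the
    drawn counts, not the labels, then define which proteins clear the
    filter. A ``control_overlap`` fraction of background proteins also
    appears in the control sample.
    """
    if mode not in ("noiseless", "negbin"):
        raise ValueError(f"unknown mode: {mode!r}")
    if not 0.0 <= control_overlap <= 1.0:
        raise ValueError(f"control_overlap must be in [0, 1], got {control_overlap}")
    rng = np.random.default_rng(seed)
    proteins: list[PlantedProtein] = []

    def draw_counts(is_true: bool) -> tuple[int, int]:
        if mode == "noiseless":
            if is_true:
                n_pep = int(rng.integers(3, 9))
                n_spec = int(rng.integers(max(6, n_pep), 21))
            else:
                if rng.random() < 0.5:
                    n_pep = int(rng.integers(1, 3))
                    n_spec = int(rng.integers(n_pep, 6))
                else:
                    n_pep = int(rng.integers(3, 5))
                    n_spec = int(rng.integers(n_pep, 6))
            return n_pep, n_spec
        mean = true_mean_spectra if is_true else background_mean_spectra
        # NB parameterised by mean and dispersion r: p = r / (r + mean)
        p = nb_dispersion / (nb_dispersion + mean)
        n_spec = 1 + int(rng.negative_binomial(nb_dispersion, p))
        n_pep = int(rng.integers(1, n_spec + 1))
        return n_pep, n_spec

    for k in range(n_true):
        n_pep, n_spec = draw_counts(True)
        proteins.append(PlantedProtein(f"true_{k + 1}", True, n_pep, n_spec))
    for k in range(n_background):
        n_pep, n_spec = draw_counts(False)
        proteins.append(PlantedProtein(f"bg_{k + 1}", False, n_pep, n_spec))

    rows: list[dict] = []
    spectrum_counter = 0

    def emit(prot: PlantedProtein, sample: str, n_pep: int, n_spec: int) -> None:
        nonlocal spectrum_counter
        peptides = [
            "".join(rng.choice(_AA, size=int(rng.integers(8, 13))))
            for _ in range(n_pep)
        ]
        # every peptide appears at least once; the remainder re-sample
        choices = list(range(n_pep)) + [
            int(rng.integers(0, n_pep)) for _ in range(n_spec - n_pep)
        ]
        for idx in choices:
            spectrum_counter += 1
            rows.append(
                {
                    "spectrum_id": f"spec_{spectrum_counter:06d}",
                    "peptide": peptides[idx],
                    "proteins": prot.accession,
                    "sample": sample,
                }
            )

    for prot in proteins:
        emit(prot, "bait", prot.n_peptides, prot.n_spectra)
    n_ctrl = int(round(control_overlap * n_background))
    for prot in proteins[n_true : n_true + n_ctrl]:
        n_spec = max(1, prot.n_spectra)
        n_pep = min(prot.n_peptides, n_spec)
        emit(prot, "control", n_pep, n_spec)
    return rows, proteins


def write_psm_dataset(
    out_dir: str | Path,
    rows: Sequence[dict],
    proteins: Sequence[PlantedProtein],
    params: dict | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    psm_path = out / "psms.tsv"
    with open(psm_path, "w") as fh:
        fh.write("spectrum_id\tpeptide\tproteins\tsample\n")
        for r in rows:
            fh.write(
                f"{r['spectrum_id']}\t{r['peptide']}\t{r['proteins']}\t{r['sample']}\n"
            )
    labels_path = out / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("accession\tis_interactor\tn_peptides\tn_spectra\n")
        for p in proteins:
            fh.write(
                f"{p.accession}\t{int(p.is_interactor)}\t{p.n_peptides}\t{p.n_spectra}\n"
            )
    paths = {"psms": psm_path, "labels": labels_path}
    if params is not None:
        pp = out / "params.json"
        with open(pp, "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["params"] = pp
    return paths


# ---------------------------------------------------------------------------
# DE tables

TISSUES = ("leaf", "stem", "root")

_CATEGORY_MEMBERS = {
    "common": ("leaf", "stem", "root"),
    "leaf_specific": ("leaf",),
    "stem_specific": ("stem",),
    "root_specific": ("root",),
    "leaf_stem": ("leaf", "stem"),
    "leaf_root": ("leaf", "root"),
    "stem_root": ("stem", "root"),
}


def gen_de_tables(
    n_genes: int,
    planted: dict[tuple[str, str], int],
    lfc_effect: float = 2.5,
    lfc_sd: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, list[dict]], list[dict]]:
    """Generate three per-tissue DE tables with planted Venn categories.

    ``planted`` maps (category, direction) — e.g. ``("common",
    "increased")`` — to a gene count. Planted genes receive
    ``padj ~ U(0, alpha/10)`` and ``|log2fc| ~ Normal(lfc_effect,
    lfc_sd)`` (signed by direction) in exactly their member tissues;
    everywhere else, and for all unplanted genes, ``padj ~ U(0, 1)`` and
    ``log2fc ~ U(-0.9, 0.9)`` (below the 2-fold threshold, so chance
    significance cannot create a DEG). Returns ({tissue: rows}, truth
    rows). When ``lfc_effect`` is below 1 the planted genes fall under
    the fold threshold and are (by design) not recoverable.
    """
    n_planted = sum(planted.values())
    if n_planted > n_genes:
        raise ValueError(
            f"planted counts ({n_planted}) exceed n_genes ({n_genes})"
        )
    for (cat, direction), cnt in planted.items():
        if cat not in _CATEGORY_MEMBERS:
            raise ValueError(f"unknown category {cat!r}")
        if direction not in ("increased", "decreased"):
            raise ValueError(f"unknown direction {direction!r}")
        if cnt < 0:
            raise ValueError("planted counts must be >= 0")
    rng = np.random.default_rng(seed)
    tables: dict[str, list[dict]] = {t: [] for t in TISSUES}
    truth: list[dict] = []
    gene_no = 0

    def null_row(gene: str) -> dict:
        return {
            "gene_id": gene,
            "log2fc": round(float(rng.uniform(-0.9, 0.9)), 4),
            "padj": round(float(rng.uniform(0.0, 1.0)), 6),
        }

    for (cat, direction), cnt in sorted(planted.items()):
        members = set(_CATEGORY_MEMBERS[cat])
        sign = 1.0 if direction == "increased" else -1.0
        for _ in range(cnt):
            gene_no += 1
            gene = f"gene_{gene_no:05d}"
            truth.append({"gene_id": gene, "category": cat, "direction": direction})
            for t in TISSUES:
                if t in members:
                    lfc = sign * abs(float(rng.normal(lfc_effect, lfc_sd)))
                    tables[t].append(
                        {
                            "gene_id": gene,
                            "log2fc": round(lfc, 4),
                            "padj": round(float(rng.uniform(0.0, alpha / 10.0)), 8),
                        }
                    )
                else:
                    tables[t].append(null_row(gene))
    for _ in range(n_genes - n_planted):
        gene_no += 1
        gene = f"gene_{gene_no:05d}"
        for t in TISSUES:
            tables[t].append(null_row(gene))
    return tables, truth


def write_de_dataset(
    out_dir: str | Path,
    tables: dict[str, list[dict]],
    truth: Sequence[dict],
    params: dict | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tissue, rows in tables.items():
        p = out / f"de_{tissue}.tsv"
        with open(p, "w") as fh:
            fh.write("gene_id\tlog2fc\tpadj\n")
            for r in rows:
                fh.write(f"{r['gene_id']}\t{r['log2fc']}\t{r['padj']}\n")
        paths[tissue] = p
    tp = out / "truth.tsv"
    with open(tp, "w") as fh:
        fh.write("gene_id\tcategory\tdirection\n")
        for r in truth:
            fh.write(f"{r['gene_id']}\t{r['category']}\t{r['direction']}\n")
    paths["truth"] = tp
    if params is not None:
        pp = out / "params.json"
        with open(pp, "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["params"] = pp
    return paths
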