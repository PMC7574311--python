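# proteopipe

Tools for a tissue-resolved proteogenomic/transcriptomic workflow in a
species without a finished proteome (the motivating case is alfalfa,
*Medicago sativa*, under drought stress):

1. **Peptide search-database construction** (`proteopipe.contig_db`) —
   translate assembled transcript contigs in the three forward reading
   frames (optionally six), split each frame translation at stop codons
   into maximal stop-free segments, and drop segments shorter than five
   residues. The surviving entries form the protein FASTA that spectrum
   identification engines search against.
2. **IP-MS interactor evidence** (`proteopipe.ipms`) — aggregate
   peptide-spectrum matches (PSMs) into per-protein evidence (distinct
   peptides, spectral counts, sequence coverage) and accept candidate
   bait interactors with at least 3 distinct peptides **and** at least
   6 spectra; optional wild-type control subtraction.
3. **Homolog annotation** (`proteopipe.homology`) — annotate candidate
   contig proteins by their best Smith–Waterman local-alignment hit
   (BLOSUM62, affine gaps 11/1) in a reference proteome, and build the
   confirmation database in which each candidate contig is replaced by
   its homolog.
4. **DEG tissue-specificity classification** (`proteopipe.deg`) — call
   differentially expressed genes (corrected *p* < 0.05 and ≥ 2-fold
   change, i.e. |log2FC| ≥ 1), classify each gene's direction-aware
   Venn category across leaf/stem/root (common, tissue-specific,
   shared pair), and summarise between-genotype expression plasticity
   as a fold ratio of DEG counts.
5. **Synthetic data** (`proteopipe.synthetic`) — seeded generators for
   contigs, PSM reports and DE tables with serialized ground truth, so
   every stage is testable without external downloads.

## Worked example

Generate 200 random contigs, build the peptide database, and check it:

```sh
$ proteopipe simulate contigs --seed 5 --out sim
$ proteopipe build-db --in sim/contigs.fasta --out peptides.fasta --summary summary.json
1624 entries from 200/200 contigs
$ proteopipe count-entries --in peptides.fasta
1624
```

The 1624 entries are all the ≥5-residue stop-free segments of the three
forward frame translations; `sim/expected_peptides.tsv` holds the same
set computed by an independent naive translator, and the two agree
exactly. Entry ids are frame-qualified: `contig_1_f1` is the first
segment of frame 1, `contig_1_f1_2` the segment after its first stop.

Filter planted bait interactors out of a synthetic PSM report:

```sh
$ proteopipe simulate psms --seed 3 --out psim
$ proteopipe filter-candidates --psm psim/psms.tsv --out cands.tsv
25 candidates of 500 bait proteins
```

The 25 accepted accessions are exactly the 25 planted interactors in
`psim/labels.tsv` (precision = recall = 1): every planted interactor
carries ≥ 3 peptides and ≥ 6 spectra, every background protein fails at
least one bound.

Classify tissue specificity of DE tables with 74 planted
common-increased and 154 common-decreased genes:

```sh
$ proteopipe simulate de --seed 2 --out dsim
$ proteopipe deg-classify --leaf dsim/de_leaf.tsv --stem dsim/de_stem.tsv \
      --root dsim/de_root.tsv --out deg
increased: common 74, totals leaf 74, stem 74, root 74
decreased: common 154, totals leaf 154, stem 154, root 154
```

As a library, the plasticity summary on the study's published per-tissue
DEG totals (silenced genotype vs empty vector):

```pycon
>>> from proteopipe.deg import summarize_plasticity
>>> summarize_plasticity((998, 1195, 587), (5521, 4426, 2607)).headline
4.5
```

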