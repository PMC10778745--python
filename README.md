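# mirnaome

A tested, fully deterministic pipeline for inferring a species' miRNAome
from small-RNA sequencing data, written for researchers who want every step
of a miRNA discovery study — read processing, hairpin curation, naming,
cluster calling, quantification, differential expression, reference-gene
selection, and qPCR analysis — as inspectable, reusable Python instead of a
chain of external tools.

## What it does

Starting from single-end small-RNA FASTQ libraries and a reference genome:

1. **Preprocess** — remove the 3' sequencing adapter
   (`AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC`), keep inserts of 18–25 nt, report
   per-base quality.
2. **Discovery** — exact-map collapsed reads to both genome strands, chain
   overlapping alignments into read stacks, excise each stack with a 70 nt
   flank as a putative hairpin arm, fold the window (maximum base pairing,
   Watson–Crick + G:U, minimum loop 3), and curate candidates with five
   criteria: detection in ≥2 libraries; ≥10 mismatch-free reads on the 5p
   *and* the 3p arm; a 0–4 nt 3' overhang of each mature against the
   opposing arm (the Drosha/Dicer signature); 5' homogeneity (modal 5'
   start > 50% of each arm's reads); and >60% of each mature's bases paired
   with the opposing arm.
3. **Annotation** — Smith–Waterman alignment against a miRBase-like hairpin
   database with Karlin–Altschul E-values (calibrated per database from a
   random-query null); conserved orthologues at E ≤ 1e-5 inherit the hit's
   family, the rest are screened against an other-ncRNA database and
   against the genome (>5 significant loci ⇒ repetitive element) before
   being accepted as novel.  Names follow miRBase conventions (`slu-mir-21-1`,
   `slu-mir-nov2a`), identical matures across gene copies merge
   (`slu-mir-21-1-2-5p`, `slu-mir-7ab-5p`), and arms are labelled
   guide/passenger at a 10× abundance ratio.
4. **Clusters** — genes ≤10 kb apart, same orientation, not separated by an
   opposite-strand transcription unit; homo- vs hetero-clusters by family.
5. **Quantify** — tolerance-bounded read-to-mature assignment (≤1 mismatch,
   5' offset ≤2, 3' offset ≤5), DESeq2-style median-of-ratios
   normalization, top-N relative abundance per group, per-group diversity.
6. **Differential expression** — per-gene negative-binomial Wald tests
   (method-of-moments dispersion), Benjamini–Hochberg correction, and the
   reporting filters ≥30 normalized reads, |log2FC| ≥ 1, padj ≤ 0.05,
   passenger-arm exclusion, on the study's contrasts (early stages vs
   larvae, the two fingerling stages, each adult organ vs the pool of the
   others; liver is never a focal organ).
7. **Reference stability & qPCR** — abundance/RSD prescreen of candidate
   reference miRNAs from sequencing counts; geNorm M, NormFinder,
   BestKeeper and delta-Ct on Cq tables with RefFinder-style geometric-mean
   rank aggregation; efficiency-corrected ΔCq quantification
   (RQ = E^(Cq_cal − Cq)), normalization to the geometric mean of two
   reference assays, Student's t group comparisons, and sequencing–qPCR
   concordance (Pearson r on log10 fold changes).

A first-class **synthetic-data module** builds a toy genome with planted
hairpin genes (duplicated loci, clusters, guide/passenger asymmetry,
group-specific expression) and labelled decoys (repetitive elements, ncRNA
look-alikes), simulates 20 adapter-ligated 75 bp libraries across 10 sample
groups plus qPCR Cq tables, and records everything in a truth manifest —
so the entire pipeline is validated against known ground truth without any
downloads.

## Worked example

```bash
mirnaome simulate --preset tiny --seed 42 --out fixture/
mirnaome run-all --fixture fixture/ --out results/
cat results/report.txt
```

prints (abridged):

```
mirnaome 0.1.0 run summary  [config 4357ec51144a]

[reads | config 4357ec51144a]
  raw 60000, kept 60000 (no adapter 0, length-discarded 0)

[miRNA gene inventory | config 4357ec51144a]
  9 genes (8 conserved + 1 novel), 8 families
  16 unique matures (8 5p / 8 3p)
  discarded candidates: {'criteria': 2, 'ncRNA': 1, 'repetitive': 1}

[clusters | config 4357ec51144a]
  2 clusters (1 homo / 1 hetero), 4 clustered genes

[differential expression | config 4357ec51144a]
  early_vs_larvae: 1 significant matures
  head_kidney_vs_rest: 3 significant matures
  ...

[reference-gene stability | config 4357ec51144a]
  mir-107-3p: geomean rank 1.565
  ...
  mir-unstable: geomean rank 5.000
```

All 9 planted genes (including the duplicated `slu-mir-21-1`/`-2` pair and
the novel `slu-mir-nov1`) are recovered at their loci, both planted
clusters are called, the two decoys are discarded with their correct
reasons ("repetitive", "ncRNA"), and the deliberately unstable qPCR assay
ranks last in every stability method.  Machine-readable tables
(`genes.tsv`, `genes.gff3`, `counts.tsv`, `de_*.tsv`, `stability.tsv`, …)
are written next to the report, each stamped with the configuration hash.

The same stages are importable as a library — `mirnaome.discovery`,
`mirnaome.diffexp`, `mirnaome.refstability`, `mirnaome.qpcr` — with the
pipeline driver in `mirnaome.orchestration`.

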