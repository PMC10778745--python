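# Methods

This note documents the models and procedures behind `mirnaome`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Read processing

Small-RNA libraries ligate a known 3' adapter to every insert; with 75 bp
reads and 18–25 nt matures the adapter is always sequenced.  Trimming keeps
the insert 5' of the left-most adapter occurrence — a full-length match
anywhere in the read, or a ≥8 nt adapter *prefix* flush with the read end —
allowing one mismatch per 8 nt (an `N` never matches).  Reads with no
adapter occurrence are discarded rather than passed through: an untrimmable
read cannot be a genuine short insert.  Length selection keeps 18–25 nt
inclusive.  Per-base quality is summarized (mean Phred per position), not
filtered on: with modern instruments the quality profile is a QC check.
The count identity raw = no-adapter + length-discarded + kept holds exactly
and is asserted in tests.  For full libraries trimming runs vectorized over
byte matrices of equal-length reads; the block path is tested for exact
agreement with the scalar trimmer.

## Candidate discovery and the five curation criteria

Collapsed reads are exact-matched to both genome strands via an 18-mer
seed-and-verify index.  Sequences occurring at more than five genomic loci
are flagged multi-locus and never seed candidates — the same >5 threshold
used later for the repetitive-element screen.  Same-strand alignments whose
starts lie within 25 nt chain into read stacks (minimum 5 reads).  Each
stack is excised twice — as the 5'-proximal or 3'-proximal arm of a
70 nt-flanked window — both windows are folded, and the window whose
structure pairs more stack bases across the loop is retained (ties keep the
5' window).  Arms are the modal read sequences of the two largest read
groups in the retained window; a one-armed stack gets a star arm predicted
from the fold (with zero read support, so it can never satisfy the read
criterion).

The curation criteria, with their numeric thresholds:

1. detected (≥1 mismatch-free read on either arm) in ≥2 libraries;
2. ≥10 mismatch-free reads on the 5p arm **and** ≥10 on the 3p arm, summed
   across libraries (read support per library is retained in the outputs so
   the per-library reading can be audited);
3. each mature's 3' overhang relative to the pairing with the opposing arm
   lies in 0–4 nt;
4. 5' homogeneity: the modal 5' start position carries strictly more than
   half of each read-supported arm's reads;
5. strictly more than 60% of each mature's bases pair with the opposing
   arm.

### Structure: global fold vs duplex register

Two structural computations coexist deliberately.

*Window selection, star prediction, and the reported dot-bracket* use a
Nussinov-style maximum-base-pairing fold (Watson–Crick + G:U, minimum
hairpin loop 3, nested structures only, deterministic traceback that pairs
the 5'-most base with its most distal optimal partner).  Its pair count is
provably optimal — verified against exhaustive enumeration of all nested
structures for sequences up to 18 nt.

*Criteria 3 and 5* are evaluated on the best **gapless duplex register**
between the two read-defined arms: base *i* of the 5p arm faces base
L₃−1−(i+o) of the 3p arm, and the offset *o* (|o| ≤ 6) with the most
complementary pairs wins, ties to the smallest |o|.  The reasons are
twofold.  First, maximum-pairing structures are highly degenerate: an arm
of a genuine hairpin whose stem carries mismatches can be rerouted into
loop or flank partners by an equally- or better-paired global structure,
making overhang and pairing-fraction readings unstable.  Second, any
bulge-tolerant arm-to-arm matching credits two *random* sequences with
roughly 65% "pairing" (the complementary-LCS effect), which would defeat
the 60% threshold as a discriminator.  The gapless register measures
exactly what the criteria describe — the contiguous RNA duplex left by
Drosha/Dicer processing — and separates planted hairpins (~80–90% paired)
from unstructured read stacks (~45–55%) with a wide margin.  The known
limitation: strongly bulged duplexes in real data are undercounted by a
gapless register; the offset bound and the gapless constraint are the
conservative choice for a desk-scale reimplementation.  A thermodynamic
folding engine can replace the built-in folder behind the same interface.

Pairing fraction is counted against the opposing arm (the mature:star
duplex), not against arbitrary window positions: under a maximum-pairing
folder almost every base of a long window pairs *somewhere*, so only
duplex pairing is a meaningful signal.

Candidates from the 5p-seeded and 3p-seeded stacks of one gene excise
near-identical windows; candidates whose precursor intervals overlap by
≥50% on one strand are merged, keeping the better-supported one.

## Annotation

Conservation is decided by affine-gap Smith–Waterman (match +5, mismatch
−4, gap open −8, gap extend −2; Biopython's `PairwiseAligner` as the
engine) against a miRBase-like hairpin database, with Karlin–Altschul
E-values E = K·m·n·e^(−λS) and significance at E ≤ 1e-5.  The textbook
(λ, K) constants are not reliable for this scoring scheme on small
databases, so the pipeline fits them per search space from a random-query
null: score a few dozen random queries against the database (both
strands), fit the extreme-value distribution by moments
(λ = π/(σ√6), u = mean − γ/λ, K = e^(λu)/(m·n)).  For the genome the fit
runs on sampled windows; the size term rescales exactly.  With calibrated
constants, genuine orthologues (even with several substitutions) sit many
orders of magnitude below the threshold while 100/100 random queries are
rejected.

Putative novel precursors are screened first against an other-ncRNA decoy
database (discard reason "ncRNA"), then against the genome with a
BLAST-like seed-and-extend locus count (16-mer seeds, per-locus local
alignment, E against the full genome size): more than 5 significant loci
⇒ "repetitive".

Nomenclature: conserved genes are `prefix-mir-<family>` with numeric copy
suffixes by genomic position when a family has several loci; novel genes
are numbered in positional discovery order with letter tags for identical
duplicated precursors (`nov2a`/`nov2b`) — the letter-vs-number convention
for novel genes is a documented package convention, inferred from common
usage rather than a formal rule.  Matures identical in (sequence, arm)
across gene copies merge their copy suffixes (`-21-1-2-5p`) or letters
(`-7ab-5p`).  Arm dominance: the minor arm is a passenger when
major/minor ≥ 10 (inclusive, since a 10-fold deficit is the exclusion
trigger); a zero-count minor arm is a passenger once the major reaches 10
reads; otherwise the arms are co-dominant.  A merged mature shared by
several genes is labelled passenger only if every parent labels it so.

## Clusters

miRBase definition: ≥2 genes, pairwise adjacent gap ≤10 kb (inclusive,
measured between precursor bounding intervals — precursors are the
annotated units), same orientation, and no opposite-strand transcription
unit wholly between neighbours (vacuously true when no annotation is
supplied).  Implementation is single-linkage chaining along each
contig/strand, tested against a brute-force transitive-closure oracle on
1,000 random layouts.  A cluster is "homo" when all members share one
family *number* (letter variants such as 430a/b/c count as one family).

## Quantification

A read is assigned to a unique mature when it aligns with ≤1 mismatch, a
5' offset ≤2 nt and a 3' offset ≤5 nt — the isomiR envelope of the mature;
ties break by fewest mismatches, then smallest 5' offset, then mature
table order, and each read counts once.  (Near-identical paralog matures
can therefore exchange trimmed read variants deterministically; counts are
exact at the unique-mature level, which is also where the expression
design is validated.)  Normalization is median-of-ratios over
all-positive rows with size factors rescaled to geometric mean 1;
counts-per-million is available behind a flag.  Group diversity calls a
mature detected when its normalized count exceeds a threshold (default 0)
in at least one replicate; the threshold is a parameter because
presence/absence conventions vary.

## Differential expression

For a two-group contrast with normalized group means μ̂_A, μ̂_B and
per-gene NB dispersion α (method of moments on within-group normalized
counts, pooled across the two groups, floored at 1e-8):

    log2FC = log2((μ̂_B + c)/(μ̂_A + c)),   c = 0.5
    Var(ln μ̂_g) ≈ (1/n_g)(1/(μ̂_g + c) + α)
    W = log2FC / SE,  SE = √(V_A + V_B)/ln 2,  p = 2·Φ(−|W|)

No empirical-Bayes dispersion shrinkage and no fold-change shrinkage: the
estimator is deliberately simple, fully specified, and antisymmetric under
group swap.  Benjamini–Hochberg runs per contrast over testable genes only
(all-zero and low-count genes removed first).  Reporting filters: at least
one group mean ≥30 normalized reads ("in the samples compared" read as a
group-mean condition; alternatives are switchable), |log2FC| ≥ 1,
padj ≤ 0.05, passenger arms excluded.  Under a null NB simulation
(2,000 genes, n = 4 vs 4, α = 0.1) the padj ≤ 0.05 fraction stays below
0.05, and planted 4-fold effects at baseMean ≥ 100 are recovered with
sensitivity ≥ 0.9 at empirical FDR ≤ 0.1.

Study contrasts: pooled early stages vs pooled larvae (4 vs 4), fingerling
3 g vs 35 g (2 vs 2), and each adult organ vs the pool of the other three
(2 vs 6).  Liver is never a focal organ (one liver library failed QC in
the emulated design) but remains in the pools — the reading that keeps the
pool at n = 6.

## Reference-gene stability and qPCR

Candidates are prescreened from sequencing: overall mean normalized count
in [2,500, 130,000] and RSD ≤ 0.3 (both inclusive).  Stability operates on
relative quantities q = E^(Cq_min − Cq) (per-assay efficiency, default
2.0):

* geNorm M — mean SD of pairwise log2 ratios; single pass, no iterative
  exclusion (only a handful of candidates are ranked; iterative mode would
  add nothing at n = 4–5).  The pairwise V of the top-2 genes is exposed
  as an *approximation* of a two-gene combined stability value.
* NormFinder — on log2 quantities with the shared per-sample effect
  removed; with groups, ρ = mean |gene-by-group interaction| + mean
  intragroup-variance SE term; without, the square root of the gene
  variance after sample-effect removal.
* BestKeeper — SD and CV of raw Cq plus Pearson r against the per-sample
  mean-Cq index; ranked by SD; a constant index leaves r undefined.
* delta-Ct — mean over partners of the SD of pairwise Cq differences.

Per-method ranks (average on ties) aggregate as the geometric mean,
RefFinder-style.  geNorm M and delta-Ct are invariant to per-sample global
Cq shifts, and a designed unstable candidate (SD 1.5 cycles plus a ±2-cycle
group effect against 0.1-cycle references) ranks last in every method on
100/100 simulated tables.

qPCR: Cq > 30.0 excluded (30.0 retained); efficiency from the OLS
standard-curve slope as E = 10^(−1/slope); RQ = E^(Cq_cal − Cq) with the
calibrator the per-assay minimum Cq across retained samples (the model
leaves the calibrator free; the maximally expressed sample makes all RQs
≤1 and is shift-invariant); NRQ divides by the geometric mean of two
reference-assay RQs, which cancels global Cq shifts exactly; group
comparison is a two-sided pooled-variance Student's t (Welch behind a
flag).  Concordance between platforms is Pearson r on paired log10 fold
changes.

## The synthetic-data generator

The generator emulates a developmental/organ small-RNA survey: 10 sample
groups (eyed egg; larvae at 2, 15, 26 dph; two fingerling stages; liver,
head kidney, spleen, gills) with 2 replicate libraries each, 75 bp
single-end reads, 100,000 reads per library at the default scale.

**Hairpins** are planted as m5 + loop + (revcomp(m5[2:]) + 2 nt), giving a
near-perfect stem with a 2 nt 3' overhang on the 3p arm, plus two central
stem mismatches.  The mismatches matter: a perfect palindromic stem makes
the reverse complement of trimmed 3p-arm reads an exact substring of the
5p arm, which fabricates phantom minus-strand genes at every locus; real
hairpins are not palindromes.  Mature lengths are 22–24 nt, loops
11–16 nt, precursors 55–64 nt — every planted gene passes all five
criteria by construction.  Letter variants of one family (430a/b/c, 7a/7b)
share the 5p mature, with a sibling-specific extra substitution in each 3p
arm so sister matures never collapse to the same read variants.

**The catalog** (default scale) plants 30 genes: 27 conserved across 26
families (including an identical duplicated mir-21 pair), 3 novel (one
single, one identical duplicated pair), arranged with 4 clusters — a homo
mir-430a/b/c triplet, the hetero mir-462/731 pair, the duplicated mir-21
pair, and a hetero mir-17/19a/92a triplet.  The genome layout alternates
strands with unit pitch chosen so consecutive same-strand units are always
>10.5 kb apart: the only clusters in the genome are the planted ones.
Oversized requests raise a sizing error.

**Decoys** are labelled with the screen they must fail: *repetitive*
hairpins planted at 6 loci (each extra copy carries mutations inside both
mature cores so primary-locus reads map uniquely, while the copies stay
alignable for the locus-count screen); *ncRNA* hairpins whose diverged
copies populate the decoy database; and, for unit tests, *structure*
(two unpairable read stacks), *support* (reads in a single library) and
*ragged* (modal 5' fraction 0.35) kinds.

**Reads** are the planted mature with the modal 5' start (per-gene modal
fraction drawn in [0.7, 0.95]; off-modal reads shift +1) and a 3' trim of
0–2 nt, the adapter, and random fill to 75 bp, with uniform quality
strings.  Per-(gene, arm) counts per library are one multinomial draw at
probabilities design-mean/depth — no extra overdispersion — and leftover
probability mass becomes random unmappable background inserts (~40% of
the default libraries), which exercises the unassigned-read path.
Passenger arms are emitted at the designed guide:passenger ratio (15–25×,
two co-dominant families at 1.5×).  Expression design: four uniformly
high stable genes (3,000–6,000/library) that land in the reference
prescreen window; a liver-dominant gene at 25,000 in liver; maternal-style
mir-430 expression in eggs/early larvae; one planted effect per study
contrast; log-uniform baselines (200–1,200) elsewhere.  When a library's
planted mass would exceed the depth (the tiny preset), the whole design
scales down proportionally.

**Cq tables**: Cq = assay base + shared per-sample effect (SD 0.3 cycles,
modelling template-input variation, which stability statistics must
cancel) + assay group effect + Gaussian noise; one candidate is designed
unstable (SD 1.5, alternating ±2-cycle group effect).

All randomness flows from one master seed through per-library
`SeedSequence` spawns; fixtures and pipeline runs are byte-identical
across reruns.

**What passing on this data does not show**: no sequencing errors, UMIs,
quality degradation, isomiR 5'/3' templated/non-templated complexity
beyond the simple jitter model, no bulged hairpin stems, no chimeric or
degradation reads, and genome/database sizes are orders of magnitude below
a real assembly and miRBase.  The synthetic validation demonstrates the
logic and the thresholds, not real-data performance.

## Numerical and determinism notes

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  Ties are specified everywhere: excision keeps the 5' window;
candidate dedup keeps the better-supported then leftmost; read assignment
breaks by mismatches, 5' offset, table order; equal-E reference hits break
to the lower family number; stability ranks average over ties.  All
pipeline thresholds live in one dataclass whose hash is stamped on every
output; `load → dump → load` is the identity.  Folding cost is O(n³) per
window via a per-cell vectorized recurrence, negligible at window sizes
≤200 nt.  The default test suite runs the full study-scale experiment
once (≈2 minutes single-core); simulations in the statistical tests use
2,000 genes and 100 Cq tables, sizes at which the asserted bounds are
stable across seeds.
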