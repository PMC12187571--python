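# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Differential gates

**One-vs-rest expression.** Per gene, the effect is the difference of group
means on the log2 scale (target entity vs the pooled remainder) and the
test is the two-sided Mann-Whitney rank-sum test. When both groups have at
most 8 observations the p-value is exact: all C(n₁+n₂, n₁) label
assignments are enumerated on midranks, and the two-sided p is twice the
smaller tail probability, capped at 1 (so identical groups give p = 1).
Larger groups use the tie-corrected normal approximation with continuity
correction. P-values are adjusted across all genes with Benjamini-Hochberg
(the step-up estimate, delegated to statsmodels and verified against a
literal step-up oracle in the tests). The pass rule is log2FC > 2.5 and
P_adj < 0.01. "Compared with all other entities" is implemented as the
pooled contrast by default; a strict mode additionally requires the
fold-change gate against every entity separately, since cohort-level
descriptions are ambiguous between the two readings.

**Knockdown proteomics.** Replicate-level log2 abundances, Welch's t per
protein and cell line (rank tests are unreliable at n = 4), BH within each
line. Concordance demands |log2FC| > 1.0, P_adj < 0.01 and an identical
sign of regulation in every line. BH rather than a named alternative is a
choice, config-exposed (Bonferroni available through the same interface by
adjusting the gate externally).

## Regulatory genomics

Coordinates follow the BED convention (0-based half-open) throughout; the
TSS of a minus-strand gene is its annotation `end`. Peak-to-gene distance
is measured from the TSS to the nearest peak edge — `start` on the left,
the exclusive `end` on the right — and is 0 when the TSS falls inside the
peak. The assignment window defaults to 100 kb, wide enough to span a
typical promoter–enhancer contact (tens of kb). A peak may serve several
genes and vice versa.

Stitching merges same-chromosome peaks transitively while gaps are at most
12,500 bp — the canonical ROSE constant, kept because the procedure is
otherwise parameter-free and the value is the field's default. A promoter
exclusion (drop peaks fully inside TSS ± w before stitching) is available
but off by default. Super-enhancer calling sorts stitched regions ascending
by total signal, scales rank to x = i/n and signal to y = s/s_max (max
scaling rather than min-max so an all-positive vector maps into (0,1]), and
places the cutoff at argmax(x − y), the point where the scaled curve's
tangent has slope 1; ties break toward the larger index, and regions
strictly above the cutoff signal are super-enhancers. A near-linear curve
(max(x−y) < 0.1) is flagged `weak_elbow` rather than rejected.

## Enrichment scoring

**ssGSEA.** Genes are ranked per sample by value, descending, with a
deterministic tie-break (original index order); member weights are
midrank^α with ascending midranks, so the highest-expressed gene carries
weight ≈ N. The score is the *sum* over the ranked list of the weighted
in-set ECDF minus the out-of-set ECDF — the original single-sample
formulation, not the max-deviation variant — with α = 0.25 by default. At
α = 0 the score depends on ranks only and is invariant under any strictly
monotone transform of the values. A set covering, or missing, the measured
universe is an error. Matrix scoring optionally divides all scores by the
global max−min range.

**Preranked GSEA.** The classic running sum: increments |stat|^p
(normalized to total 1 over members, p = 1 by default) at member genes,
decrement 1/(N−|S|) at non-members, ES the signed maximal deviation. The
implementation evaluates the walk only at member positions (its linear
segments cannot contain an extremum), which the tests check against the
literal walk and against an independent implementation (gseapy) on no-tie
instances. The null is a seeded gene-sampling permutation: random same-size
sets, NES = ES divided by the mean |null ES| of matching sign, p =
(1 + #{null at least as extreme, matching sign}) / (1 + #matching-sign).
The analytic multilevel null of fgsea is deliberately not reproduced; a
permutation null supports the same qualitative claims (sign, significance)
at the cost of a p-value floor of 1/(n_perm+1).

**Signature construction.** The anchor-gene set takes the top-100 Pearson
correlates of the anchor computed *within the target entity's samples
only* (between-entity correlation would be dominated by the group shift);
the anchor itself is excluded. The knockdown signature takes genes
significantly down-regulated upon knockdown in at least `min_support`
experiments (default: all), i.e. fusion-activated genes; the symmetric
up-regulated set is available.

## Methylation

CpGs are selected in [gene start − flank, gene end + flank) with flank
1,500 bp (promoter-inclusive; the window is a declared default, not an
inferred one). The 2-D embedding is PCA on the centered beta submatrix —
a declared substitute for unspecified nonlinear reductions — and the
"distinct clustering" read-out is quantified as the silhouette of target
vs rest on those two coordinates. The hypomethylation call is a two-sided
rank-sum test on per-sample mean beta with the direction reported; beta
values are used raw (no M-value transform) because the test is rank-based.

## IRS diagnostics

IRS = intensity (0–3) × proportion category (0–4), range {0,…,12}. The
banding of percent positive cells follows the classical Remmele–Stegner
scheme — 0 for 0%, 1 for (0,10)%, 2 for [10,50]%, 3 for (50,80]%, 4 for
(80,100]% — with the band edges config-exposed so a modified variant can be
dialed in. The diagnostic curve evaluates "positive iff IRS ≥ c" for every
integer c, giving sensitivity 100·TP/(TP+FN) and specificity
100·TN/(TN+FP); the named operating points are the positivity rule IRS > 1
(equivalently c = 2) and the largest cutoff retaining 100% sensitivity.
The workflow rule is exclusive at the boundary: IRS equal to the cutoff
triggers "reconsider / molecular testing".

## Synthetic-data model

The generator is a scaled-down mirror of a multi-entity tumor cohort,
chosen so the full suite runs in minutes on one CPU: 8 entities × 10
samples, 2,000 genes, with every artifact a deterministic function of one
seed.

* **Bulk expression**: iid Normal(6, 1) on the log2 scale; two planted
  biomarkers shifted +4 in the target entity, the anchor biomarker a
  further +2 so that prioritization between the candidates is decisive
  (mirroring a validation candidate selected for its markedly higher
  expression); a 50-gene module generated as anchor + Normal(0, 0.5), so
  module genes track the anchor everywhere and are themselves
  target-overexpressed.
* **Knockdown proteomics**: 1,000 proteins (identity protein→gene map),
  two cell lines, 4 + 4 replicates. True effects: −2 for the planted
  program (both biomarkers plus 40 module proteins), Normal(0, 0.3)
  background drawn independently per line; replicate noise Normal(0, 0.1),
  a high-precision quantitative-MS regime chosen so the planted program
  clears the within-line FDR gate by construction, as the bundle's
  contract requires.
* **Peaks**: one planted peak 5 kb from each biomarker TSS; 200 decoy
  peaks within ±50 kb of the TSSs of genes *outside* the planted program.
  Genes are spaced 250 kb apart so a decoy reaches exactly one gene.
  Decoys avoid module genes deliberately: module genes legitimately pass
  the expression and proteomics gates, so a decoy there would grow the
  intersection by construction rather than by statistical accident —
  exactly what the false-positive guarantee is meant to measure.
* **Enhancer landscape**: 400 clustered peak groups 50 kb apart (gaps
  within a group ≤ 3 kb, so stitching merges them); total signals
  Exponential(5)+1 with 12 planted regions at Uniform(80, 200). The
  planted regions always exceed the tangent cutoff; the exponential tail
  legitimately contributes additional supers, as on real data.
* **Methylation**: beta = logistic(Normal(0.6, 0.5)); 12 CpGs inside the
  anchor gene, 10 of them shifted −0.3 (clipped to [0,1]) in target
  samples; 288 background CpGs elsewhere. A standalone cohort generator
  mirrors the 24-target vs 192-mimic comparison.
* **Single cell**: negative binomial with dispersion 0.5 (size 2), gene
  means Lognormal(log 0.3, 1), the planted program × 8 in tumor cells;
  200 tumor + 200 normal cells. Scoring consumes log1p counts and drops
  cells with < 200 detected genes (no cell is dropped at these defaults).
* **IHC cohort**: 61 target samples scoring uniformly on {6, 8, 9, 12}
  (the attainable IRS values in [6, 12]), 249 mimics over 18 entities
  scoring 0 (occasionally 1), with a 2% contamination fraction scoring
  2–4. The 2% default mirrors a ~98%-specificity regime and is documented
  as a mirror, not a reproduction.

**What the generator does not emulate**: platform/batch effects, absolute
expression distributions, probe-level methylation artifacts, doublets or
ambient RNA in single-cell data, inter-rater IHC variability. Passing
tests therefore demonstrate correctness of the procedures under a clean
planted model, not performance on real cohorts.

## Numerical conventions and degenerate inputs

Ties use midranks everywhere a rank is taken; running-sum magnitude ties
resolve toward the positive deviation. Readers reject malformed lines by
number, duplicate feature ids by name, and missing expression values
outright (no imputation rule is defined, so none is invented). Degenerate
cases raise rather than guess: identical stitched signals (no cutoff),
constant beta submatrices, zero-variance anchors, gene sets covering the
whole universe. Zero-variance signature scores yield missing correlations
with a warning. Written tables use 17 significant digits so a write/read
cycle is bitwise exact, and all outputs of a fixed config + seed are
byte-identical across runs (timestamps live only in the run log).

## Problem sizes

Defaults were chosen so the default test run and the acceptance script
each finish in well under a few minutes on a single CPU: the bundle at
2,000 genes × 80 samples, enrichment calibration at 200 trials × 1,000
permutations on 1,000-gene universes, methylation at 20 seeds × 216
samples, and the super-enhancer monotonicity property at 1,000 random
vectors.

## Known limitations

* The permutation NES is not numerically comparable to analytic fgsea NES
  values; only sign and significance are.
* The pooled one-vs-rest contrast can admit genes high in the target and
  in one mimic; use the strict per-entity mode when that matters.
* The tangent cutoff assumes a convex rank-signal curve; heavy-but-smooth
  tails move the cutoff into the tail rather than to its start, so the
  super-enhancer count is landscape-dependent.
* The IRS banding implements the classical scheme; a supplementary-variant
  banding can be configured but no attempt is made to infer one.
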