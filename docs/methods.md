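# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of `striatlas`, and what the synthetic-data generator does
and does not emulate.

## Coordinates and containers

All region coordinates are 0-based half-open (BED convention) everywhere in
memory; 1-based inputs are converted at the reader boundary. Chromosome
names are matched by exact string comparison; `chr`-prefix normalization is
an explicit opt-in flag on the readers. Coverage lives in `SignalTrack`
objects: one fixed-width bin vector per chromosome, values in *reads per
bin*. Normalization states are one-way (`raw` → `background_equalized` or
`rpgc_1x`); `rpgc_1x` means the genome-wide mean bin value is 1 ("1×
genome coverage").

## Island calling

The caller follows the classic broad-mark island model. The genome is cut
into windows (default 200 bp). A window is *eligible* when its count is
improbable under a global Poisson background λ (reads per window over the
whole effective genome; or from a library-scaled control track when one is
given): upper-tail P(X ≥ c; λ) < `eligibility_p` (default 0.05). Islands are
maximal runs of eligible windows in which consecutive eligible windows may
be separated by at most `gap_bp` of ineligible ones (per-mark defaults:
1000 bp for H3K27ac, 600 bp for RNAPII, 1400 bp for H3K27me3, at 200-bp
windows). The island score is Σ −ln P(c_w; λ) over eligible member windows.

**E-value control.** Islands are retained if their score exceeds the
threshold at which the expected number of equally high-scoring islands per
genome under the null is ≤ `evalue` (default 0.003). The null is estimated
by seeded Monte-Carlo: `n_shuffles` (default 20) replicate genomes of iid
Poisson(λ) window counts are assembled into islands, pooling their scores.
Two numerical points:

* *Parametric rather than permutation null.* Permuting the observed window
  counts is only equivalent when the signal fraction is negligible; on a
  signal-rich track the shuffle scatters genuinely enriched windows into
  the null and the threshold explodes. The island model's null is iid
  Poisson background, so the default draws counts parametrically
  (`null_method="poisson"`); permutation remains available.
* *Tail extrapolation.* With B shuffles the empirical null resolves
  expected counts only down to 1/B per genome, far above 0.003. The upper
  tail of the null island-score survival curve is therefore modelled as
  exponential (mean-excess estimator over the top ~10% of null scores, at
  least 100) and solved for the configured E-value. Island score tails
  decay at least exponentially here, so the extrapolation errs on the
  conservative side.

High-confidence lists intersect replicate island calls (≥ 1 bp overlap in
every replicate) and merge the retained intervals; universes merge the
per-condition high-confidence sets.

## Differential enrichment

One engine serves every contrast. Counts are normalized by per-sample size
factors computed by *median of ratios over background regions*: for each
background region, the ratio of the sample's count to the region's
geometric-mean count across samples; the per-sample median of these ratios,
rescaled to geometric mean 1. Background regions are sampled outside the
island universe, implementing background equalization.

**NB-Wald mode** (`dispersion="auto"`). Per region, the pooled within-group
variance of normalized counts s² is computed; a genome-wide mean-variance
trend s²(μ) = b₁μ + b₂μ² (the negative-binomial form) is fitted by
iteratively reweighted least squares with weights 1/trend², so high-mean
regions do not dominate; the region's variance is shrunk toward the trend
with `prior_df` (default 20) pseudo-degrees of freedom. The Wald statistic
is the log ratio of the group means (pseudocount 0.5) over its delta-method
standard error, referred to the normal distribution, BH-adjusted across
regions. Working entirely on normalized counts (no per-sample 1/s_j terms)
makes the p-values exactly invariant to rescaling a sample's counts
together with its declared size factor. Calibration, measured on 10,000
null NB regions (dispersion 0.05, 4 vs 4): type-I error 0.049–0.057 at
nominal 0.05.

**Exact mode** (`dispersion=0`). The conditional Poisson test: the group-2
total given the region total is Binomial with success probability equal to
the group-2 share of the size factors; two-sided p by the
minimum-likelihood convention. This is the no-overdispersion model of
classical window-count callers.

**Enhancer catalogue.** The NeuN⁺ (neuronal) vs NeuN⁻ (glial/other)
contrast labels regions neuronal (higher normalized NeuN⁺ signal) or glial
at raw p < 1e-15 by default. The catalogue uses the exact mode: the 1e-15
regime is only reachable under a Poisson-type model — the NB-Wald standard
error is floored by the dispersion term (≈ √(2α/n)), which caps |z| near 6
for a 4-fold change at n = 2 — and the stringent historical cutoff was set
under exactly such a model. Whether the cutoff is raw or adjusted is
configurable (`use_adjusted`, default raw).

Thresholds used downstream: genotype contrasts at BH-adjusted p (1e-5 at
sequencing depth; 0.05 at the desk-scale synthetic depth — an analysis
parameter, `attribution_alpha`), concordance filter at raw p < 0.05 on both
contrasts.

## Integrative statistics

* **Attribution**: a differential region overlapping (≥ 1 bp, configurable)
  only neuronal catalogue entries is Neuronal, only glial entries Glial,
  neither or both Non-specific; the three labels partition the input.
* **Metaprofiles**: coverage is resampled exactly (piecewise-constant
  averaging) onto fixed bin schemes — midpoint-centred windows for regions
  (±2 kb, 100 bp bins) or 2-kb flanks at 100 bp/bin plus 100 length-scaled
  body bins for genes — and strand-flipped so bin 0 is always 5′. Tracks
  should be 1×-normalized; a uniform track yields a flat profile at 1.
* **Clustering**: per-gene profiles for each (mark × fraction) are
  concatenated along columns (a flag could use per-mark matrices; the
  concatenated form is the default) and clustered by seeded k-means
  (k-means++ init, best of `restarts` runs), k = 7 by default, matching the
  seven striatal epigenetic archetypes.
* **Enrichment tests** are two-sided exact binomial tests against the
  composition of the relevant universe (cluster share, chromosome share,
  neuronal share of cell-type-specific genes), Bonferroni-adjusted where a
  family is tested (family = k clusters, or the chromosome count). Top-N
  gene lists are ranked by raw or adjusted p (caller's choice), ties broken
  lexicographically by gene id for determinism. "FC < 1 / FC > 1" is read
  as linear fold change below/above 1, i.e. the sign of log2FC.
* **Concordance**: regions passing p < 0.05 in both the genotype and age
  contrasts are attributed, then summarized as per-label mean log2FCs, the
  sign-concordance fraction, and Spearman's ρ between the two fold-change
  vectors; an optional region × condition signal matrix is z-scored and
  ordered by average-linkage Euclidean hierarchical clustering
  (deterministic, seedless) for the heatmap.
* **Group-wise z-scores**: gene-wise z-scores (sample sd, n−1; constant
  rows map to zeros with a warning) pooled per sample group, compared by
  the standard tie-corrected Kruskal–Wallis chi-square tail ("one-sided KW"
  in some figure legends is nonstandard wording; the standard tail is
  used), pairwise follow-ups BH-adjusted.
* **Nuclear fractions**: NeuN⁺% = NeuN⁺/(NeuN⁺+NeuN⁻)×100; totals under
  30,000 singlet events warn.

## 4C-seq

Fragments are delimited by first-cutter (DpnII, GATC) site starts — the
4-bp site belongs to the downstream fragment, matching a cut 5′ of GATC —
and annotated with internal second-cutter (Csp6I, GTAC) sites; a fragment
without one is *blind*. Bait design applies the printed criteria strictly:
first-to-second cutter distance > 350 bp, fragment length in (500, 1500) bp,
not blind. Figure legends elsewhere say "quartile normalized" where the
methods say quantile; quantile normalization is implemented (rank-average
mapping; ties averaged — exact equality of sorted vectors therefore holds
for tie-free scores). The bait fragment ± 2 fragments are excluded from
scoring (self-ligation and undigested artefacts; configurable). Smoothing
is a centred 21-fragment running mean over the scored fragment order with
shrunken symmetric edge windows.

**Interaction calling.** Per sample, a monotone non-increasing background
in distance from the bait is fitted by isotonic regression separately up-
and downstream of the bait, on the smoothed profile. Exceedance is judged
on *log-ratio* residuals — multiplicative 4C noise makes relative
exceedance approximately homoscedastic, whereas absolute residuals are
dominated by bait-proximal variance. The noise scale σ of the smoothed
profile is estimated robustly from the raw-vs-smoothed fragment scatter
(MAD/√window; the isotonic fit's own residuals underestimate it because
the fit absorbs medium-scale noise). Regions grow by hysteresis: at least
one seed fragment above 3.5σ, extension above 1.5σ, gaps ≤ 2 fragments
merged, minimum 5 fragments. An empirical residual-quantile threshold was
rejected: it forces a fixed candidate rate under the null and caps
candidates below the smeared width of a true contact. A region is reported
only if it reproduces (overlaps) in every sample of the condition.
Differential interactions are two-tailed t-tests (paired across declared
sample pairs, e.g. male/female; a zero-variance paired difference falls
back to the unpaired Welch test with a warning) on per-sample means of
member-fragment normalized scores, BH-adjusted across regions.

## 3D models and insulation

A locus is discretized into beads of 25 fragments each. Per bait, bead
signal (mean of scored member fragments) maps to a target distance by the
inverse-power transform d ∝ s^(−1/α) (α = 1) rescaled affinely per bait onto
[1, 10] model units — distances are arbitrary model units; 4C signal fixes
no physical scale, so only relative geometry is meaningful and all
comparisons use reflection-invariant quantities. Coordinates minimize
Σ w(‖x_b − x_t‖ − d)² plus a harmonic lower wall on consecutive-bead
distances (0.2 units; an upper wall is available but off by default) and a
soft excluded-volume lower wall (0.2 units) on all pairs, by multi-restart
L-BFGS with analytic gradients from seeded random-walk initializations
(deterministic under a fixed seed). This is an objective-minimization
contract, not a trajectory-level reproduction of the original annealing
tool.

The virtual Hi-C is the all-pairs Euclidean distance matrix. Insulation
uses the contact proxy c = 1/(d + ε), ε = 1e-6 × median off-diagonal
distance, which makes "low insulation at boundaries" literally true on
distance models: for scale b ∈ [b_min, b_max] (defaults 4..30, i.e. 40 kb
to 300 kb at 10 kb per bead in the reference locus geometry) the insulation
at position k is the mean contact over the b × b square crossing k, defined
only where the window fits. Per-scale profiles are z-scored (an effectively
constant profile maps to zeros rather than amplifying float noise) and
averaged into the aggregate; boundaries are its local minima with
prominence ≥ 10% of the aggregate range (per-scale profiles are retained
for cumulative heatmaps; minima are called on the aggregate). Boundary sets
from two conditions are matched greedily by proximity (≤ 5 beads) with
signed displacements in beads and bp, plus aggregate-insulation differences
per match; model similarity is the Spearman correlation of
strictly-upper-triangle distances.

## Synthetic data

The generator plants ground truth for every stage: a small genome (default
2 × 5 Mb, 200-bp bins) with non-overlapping genes and enhancers placed
uniformly at random by exact gap allocation (no rejection loops); neuronal,
glial and shared enhancer classes (100 each, 2 kb) with 4-fold active/
inactive fraction separation (20 vs 5 expected reads per bin over a
background of 2); gene-body archetypes for the clustering stage (active
mark high in the matching fraction, repressive mark high in the opposite
one); bulk tracks as mixture-weighted sums of the two nuclear-fraction
expectations (NeuN⁺ fraction 0.6, identical across genotypes, as the sorted
proportions are in the tissue this emulates); genotype effects applied
multiplicatively on the affected class only, −1/+1 log2 at the early age
and −1.5/+1.5 at the late age for neuronal/glial classes, with an age
effect of −0.8/+0.8 of the same sign structure — the "accelerated aging"
configuration in which the mutation amplifies the physiological age trend.
Counts are gamma-Poisson (negative binomial, dispersion 0.05) so the
differential stage's dispersion handling is exercised; `none` and
`poisson` noise modes support exactness and null tests. RNA counts couple
each gene's fold change to its linked enhancer's planted effect (coupling
0.8 by default) plus a neurons-vs-glia table driven by gene class. 4C
profiles derive from explicit bead geometries (s = A·d^(−α), log-normal
noise σ = 0.2, integerized), including a two-domain geometry with
configurable boundary position and separation. Sequences carry planted
GATC/GTAC sites (mean spacings 400/1200 bp) over random background for
fragment-map tests.

All randomness flows through named, CRC-32-hashed child streams of the
config seed, so every product is independently reproducible and the whole
simulation is byte-deterministic.

**What passing tests do and do not show.** The generator omits read-level
artefacts (mappability, GC bias, duplicates), batch/sex structure,
CAG-repeat instability, diploid genotypes, and realistic enhancer-gene
distance coupling; its signal density (~20% of the genome) is higher and
its depth far lower than real striatal data. Recovery results therefore
validate the *statistical machinery* — calibration, thresholds, invariances
and parameter recovery under the stated noise model — not performance on
real sequencing data.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
2 × 5 Mb genome for island statistics (50 null seeds), 10,000 regions for
type-I calibration, 500 regions for power, 100 seeded runs for 4C recovery
and nulls, 40-bead chains with 5 baits and 50 seeded runs for boundary
recovery, and top-60 gene sets against a 300-gene universe in the
enrichment tests (the full-scale analysis uses top-300 against ~37k
transcripts). These sizes give stable Monte-Carlo estimates in seconds to
minutes per stage.

## Known limitations

* The island score null is extrapolated beyond the Monte-Carlo range; for
  E-values below ~1/(B × islands per shuffle × 10) the threshold leans on
  the exponential tail model.
* The NB-Wald engine is mildly anti-conservative (~0.05 → 0.052–0.057) at
  very small replicate numbers; the exact mode ignores biological
  overdispersion entirely and should be read as the historical Poisson-type
  contrast it reproduces.
* The 4C caller's reproducibility rule requires a region in *every* sample
  of a condition; with many replicates this becomes conservative.
* Bead models are identifiable only up to rigid motions and reflection, and
  the per-bait affine distance rescale distorts absolute geometry; distance
  matrices are compared by rank correlation for this reason.
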