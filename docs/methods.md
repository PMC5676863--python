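# Methods

This note documents the models behind each pipeline stage, the defaults and
why, what the synthetic-data generator does and does not emulate, and the
numerical choices that were genuinely open.

## Count model and study design

The package targets paired designs in which the same RNA samples are measured
by two library strategies: conventional random-primed mRNA-seq (read counts)
and 3′-DGE (UMI counts, with read counts as an intermediate). Counts are
modelled as negative binomial with mean μ and variance μ + φμ², the
parameterization the differential-expression stack assumes; φ = 0 is the
Poisson limit.

The default simulated design mirrors a typical drug-treatment benchmarking
experiment: 8 vehicle-control and 4 treated biological replicates per arm,
~22,000 genes, per-sample library sizes log-normal around 3.5 × 10⁶ counts
(CV 0.15), dispersion φ = 0.1 (bulk-replicate scale), and two treatment
archetypes — a "large-effect" treatment with thousands of true fold changes
and a "no-effect" treatment with none — giving a positive and a negative
control for every DE-level analysis.

## Synthetic-data generator

Per gene: baseline abundance ~ LogNormal(0, 1.5) (heavy-tailed, as real
expression profiles are); mean transcript length ~ LogNormal(log 2000, 0.7) bp;
PCR amplification ratio (expected reads per UMI) ~ Uniform(2, 3); DE genes a
uniform random subset with random sign and magnitude
`de_log2fc_mean · LogNormal(−σ²/2, σ)` so the expected absolute log2
fold-change equals `de_log2fc_mean` exactly (σ = `de_log2fc_sd`; σ = 0 gives a
point mass).

Expected conventional read counts are proportional to abundance × transcript
length (random priming yields fragments along the whole transcript); expected
DGE UMI counts are proportional to abundance alone. The DGE sensitivity gap is
modelled as per-gene dropout: genes in the bottom half of baseline abundance
fail reverse transcription in the DGE arm with probability 0.3, zeroing them
in every DGE sample. Those two defaults jointly reproduce a ~15% detection
gap between the arms, and the per-gene (not per-sample) dropout reproduces
the observation that differentially detected genes are consistent across
treatment conditions. DGE read counts are built from the UMI counts by
per-molecule amplification with support ≥ 1 (one guaranteed read plus
Poisson extras with mean amp − 1), so `umi ≤ reads` holds cell-wise by
construction, and the dataset-wide reads/UMI ratio lands inside the
configured amplification interval.

What the generator does **not** emulate: sequence-level effects (alignment,
barcode collisions, UMI saturation), gene–gene correlation, GC/length biases
beyond the linear length factor, and batch structure. Passing tests therefore
validate the *pipeline mechanics and statistics* on NB-world data; they do
not certify behaviour under real-data artifacts the model omits.

## Downsampling

"Remove reads one at a time with probability proportional to current gene
representation" is exactly uniform removal of individual reads, i.e. keeping
`target` reads is one multivariate hypergeometric draw — the default
`hypergeometric` variant, verified against the joint MVH law by chi-square
goodness of fit. The `fixed_probability` variant freezes removal
probabilities at the initial proportions (skipping exhausted genes),
implemented as repeated clipped multinomial rounds; it is equivalent to the
one-at-a-time rule whenever no gene exhausts and very close otherwise.

UMI coupling: removing one uniformly-random read from a gene with c reads and
u UMIs eliminates a distinct UMI with probability u/c; repeating this with
the ratio recomputed is the urn process whose removal total is
Hypergeometric(c, u, r) given r removed reads, drawn directly per gene. This
guarantees 0 ≤ u ≤ c at every depth and E[final u] = u₀·target/total.
A config flag freezes the ratio at u₀/c₀ instead (clipped binomial), since
the one-pass reading of the removal rule is also defensible.

The low-expression pre-filter (< 4 counts) is applied per sample by default,
with a summed-across-samples switch. Replicate variability of stochastic
removal is assessed over 16 independent repetitions by default; the CV of
detected-gene counts at half depth is far below 1%.

## Detection saturation

Detection threshold: ≥ 4 counts. Curves are computed on a log-spaced depth
grid (default 30 points from 10⁴ up to the sample depth — log spacing
resolves the knee near K_m) and fit by unweighted nonlinear least squares to
G(d) = V_max·d/(K_m + d), initialized at V_max⁰ = max observed detection and
K_m⁰ = the smallest grid depth reaching half of it. Fits default to the
across-replicate average curve; per-sample fits are available.
Non-convergence sets a flag rather than raising. Parameter recovery at the
realistic scale (V_max = 12,000 genes, K_m = 50,000 reads) is exact on
noiseless curves and < 5% median relative error under binomial detection
noise. Note the fitted curve is an approximation: with a hard detection
threshold the true expected curve is slightly sigmoidal at very low depth.

## Concordance

"Comparable units" is implemented as per-sample scaling to 10⁶ total
(idempotent projection) followed by log2(x + 1); length normalization divides
conventional counts by mean transcript length in kb and *refuses* UMI
matrices unless forced, because UMI counts are length-independent and the
division would inject a length artifact. That is also why the
length-independent negative control cannot leave r unchanged: dividing by a
realistically varying length (≈ 1 log2 unit of spread) measurably lowers r
(≈ 0.05–0.07 here), an intrinsic property of the transform rather than an
implementation choice.

The bias band follows x = y on the mean-vs-mean log2 plot: residual
d_g = dge − conv, half-width k·SD(d) with k = 2 by default ("typical
variance" operationalized as an SD multiple). Under a no-bias simulation the
flagged fraction matches the two-sided normal tail at k (≈ 4.6% for k = 2).

## Differential expression

The stack re-implements the classic pairwise edgeR procedure from its
published components, self-contained:

- **TMM**: M and A values on library-size-adjusted proportions over genes
  positive in both samples; double trim (30% on M, 5% on A, rank-based);
  factor = 2^(precision-weighted trimmed mean); factors normalized to
  geometric mean 1; reference sample chosen by the closest-to-mean upper
  quartile rule.
- **Equalization**: counts are quantile-adjusted to the geometric-mean
  effective library size by NB quantile matching, using the mid-p percentile
  under the source distribution and linear interpolation on the target CDF
  (a count maps to itself when the two means coincide). Estimation and
  adjustment are alternated once (Poisson-scale start, then at the estimated
  φ).
- **Dispersion**: common φ maximizes the exact conditional NB log-likelihood
  of the equalized counts given group totals (groups of size 1 contribute
  nothing; all-singleton designs are an error). Tagwise φ_g maximizes the
  gene's likelihood plus prior·(genome-average likelihood) on a log grid —
  weighted-likelihood shrinkage with prior weight 10. The shrinkage prior is
  the global average rather than an abundance-local moving average; this is
  the main simplification relative to edgeR and is visible only as slightly
  stronger shrinkage.
- **Exact test**: group sums of equalized counts conditioned on their total;
  sums of n iid NB(μ, φ) are NB with size n/φ; the two-sided p doubles the
  smaller inclusive tail, capped at 1 (so equal group totals with equal group
  sizes give p = 1 exactly, and φ = 0 with totals 3 vs 7 reduces to the exact
  binomial 0.34375). Enumeration over 0..T per gene is vectorized in chunks.
- **BH FDR** via the standard step-up (statsmodels), DEG cutoff 0.1; genes
  with < 4 counts total are excluded before testing (consistent with the
  detection threshold).

Cross-checks against Bioconductor edgeR on identical inputs: TMM factors
agree to ~1%, exact-test p-values correlate > 0.999 in log space with median
absolute difference < 0.01 (edgeR interpolates a continuous pmf), and the
common-dispersion estimates agree to three decimals on simulated data.

Calibration measured at the study scale (10⁴ genes, 8 vs 4, φ = 0.1,
libraries 3.5 × 10⁶): empirical type-I error 0.049 at α = 0.05 and zero DEGs
at FDR < 0.1 under the null. Power at the same scale with 3,000 two-fold
effects: ~73% of true DE genes recovered at FDR < 0.1 with false-discovery
proportion ~6%. This recovery is a property of the conditions, not the
implementation — real edgeR on the identical matrix recovers slightly
*fewer* — because with φ = 0.1 and 8 vs 4 replicates the per-gene power for
a two-fold change tops out near 90% even at infinite depth, and
below-median-depth genes pull the average down.

DEG-vs-depth curves downsample each matrix by its own counts (UMI counts for
the DGE arm, read counts for conventional — matching how each technology's
depth axis is expressed) and re-run the full DE stack per grid depth.

## RRHO

Scores s = sign(log2fc)·(−log10 p); ties broken lexicographically by gene id
for determinism; p = 0 clamped to the smallest positive double before the
log. Grid cutoffs are {step, 2·step, …, N} with N always appended, so the
full-overlap corner exists. Overlaps come from a 2-D cumulative histogram of
rank pairs; each cell is scored by the hypergeometric right tail when the
overlap exceeds x·y/N and the left tail otherwise, stored as signed −log10 p.
No multiple-testing correction is applied across cells (the map is presented
raw). Cell values are verified against full hypergeometric enumeration and
the map against brute-force set intersection.

## GO power

Per process and method, the 2×2 table is (in-process vs out-of-process) ×
(detected vs not): p1 and p2 are the detection fractions inside and outside
the process, and the Monte-Carlo power (default 1,000 simulations, two-sided
Fisher exact test, α = 0.05) measures the ability to detect the process's
*differential detectability*. Note one consequence: a process entirely
missing from a method's detected set is maximally detectable under this
construction (p1 = 0 against a high p2), not undetectable. Per-process seeds
are derived from a CRC of the process id so results are independent of
iteration order. Processes with no members in the universe are skipped with a
log entry. Classification at power 0.8: both_powered / a_only / b_only /
neither.

## Numerical and scale choices

- Simulation sizes in the test suite and acceptance script are scaled to
  desk runtime while preserving per-gene sequencing depth: DE-stack checks
  use 10,000 genes at library mean 3.5 × 10⁶; detection-gap checks 8,000
  genes at 1.5 × 10⁶; concordance 6,000 genes at 10⁶.
- Exact-test enumeration is chunked at ≤ 4 × 10⁶ outcome points to bound
  memory; per-gene log-pmfs are max-stabilized before exponentiation.
- Dispersion optimization is bounded on φ ∈ [10⁻⁶, 20] (log scale); the
  tagwise grid spans [10⁻⁴, 5] with the common value appended.
- All stochastic stages accept either an integer seed or a numpy Generator;
  CLI runs log the seed and all filter counts to `run.log`.

## Known limitations

- The DE stack is not bit-identical to any edgeR release (interpolation in
  the quantile adjustment, global tagwise prior, no abundance-dependent
  trend); differences are small but nonzero.
- The exact test rounds equalized group totals to integers for enumeration.
- Michaelis–Menten is a summary model; its parameters are interpretable but
  the true detection curve is not exactly hyperbolic near zero depth.
- The GO power construction is one defensible operationalization of
  enrichment-power loss; absolute per-process power values depend on it and
  should be compared only within a construction.
- The generator's independence assumptions (no gene–gene correlation) make
  simulated p-value distributions cleaner than real data's.
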