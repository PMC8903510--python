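# Methods

This note documents the models, conventions, and design choices behind
`plexbridge`, in the order data flows through the package.

## Study design assumed

One experiment is a set of TMT plexes (default four 10-plexes) analyzed
together. Each plex carries individual samples of two phenotypes (CTL,
PDR), one aliquot of a pooled *validation* sample (pool 1, controls only,
a cross-plex technical replicate), and one aliquot of a pooled *bridge*
sample (pool 2, a mixture of all individual samples) that serves as the
reference channel. Matrix columns are named `plexID.channelLabel->sampleID`
so they stay globally unique; pool aliquots are tagged by role
(`validation_pool`, `reference`), never by magic sample names.

## PSM quality filtering

Rules, applied per plex in order: (a) no TMT label; (b) missing reference
quantification; (c) precursor purity < 0.5 (strict — purity 0.50 is kept);
contaminant-flagged PSMs; then (d) summed reporter intensity at or below
the 5th percentile of the PSMs surviving the earlier rules. Conventions
that needed a decision:

* The percentile is a linear-interpolation sample quantile, computed per
  plex (not per MS run); the level is configurable.
* Boundary handling for (d) is inclusive (`<=` the percentile value), with
  one guard: a PSM tied with the plex's maximum summed intensity is never
  treated as low-intensity. Without the guard a degenerate plex whose sums
  are all equal would be removed wholesale.
* A relative-percentile rule is contractive, not idempotent: reapplying it
  to its own output trims another 5%. `FilterReport` records the absolute
  threshold used, and passing that threshold back
  (`intensity_threshold=...`) makes re-application a no-op. Rule (d) can be
  disabled outright with `intensity_percentile=None`.
* Redundant PSMs — same (plex, MS run, peptide sequence incl.
  modifications, charge) — collapse to the one with the highest summed
  reporter intensity; ties break on the lexicographically smallest
  spectrum id so results are order-independent.
* Both unique and razor peptide assignments are quantified. An optional
  `min_probability` re-applies the upstream identification-probability cut.

## Normalization

Per PSM and non-reference channel, the ratio is
`log2(I_channel) - log2(I_reference)`. Zero intensities mean non-detection
and become missing observations (never ±inf); a zero reference intensity
skips the whole PSM with a counted warning. Per (entry, sample), ratios are
Tukey-fenced (drop outside `[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`, quartiles by
linear interpolation — centralized in `normalize.quantile` so the
convention can be switched in one place) and the median of the survivors is
the cell value. The per-sample MAD normalization uses the plain median
absolute deviation with **no** 1.4826 consistency constant, and the global
M₀/MAD₀ are medians across **all** samples of all plexes jointly. After
normalization every sample's median equals M₀ and MAD equals MAD₀ exactly;
since MAD₀/MAD_i > 0 the map is strictly increasing and within-sample
ranks are preserved.

Reference intensities: per entry and plex, the up-to-3 PSMs with the
largest MS1 precursor intensity (after redundant collapse) contribute
`ms1 * (reference reporter / summed reporters)`; plexes with no quantified
PSM for the entry are imputed with the global minimum observed REF value
*before* averaging over all plexes (an `impute_global_min=False` flag
averages over observed plexes only). Entries with nonpositive REF are
excluded with an error count. Final abundance is `A = RN + log2(REF_i)`.

A note on the batch-shift invariance: additive per-plex log2 shifts applied
to every channel of a plex (reference included) cancel exactly in ratio
space. When the shift differs per protein, however, it reorders summed
reporter intensities within the plex, so the relative bottom-5% rule may
select different PSMs; the invariance therefore holds exactly with rule (d)
disabled, and up to PSM membership otherwise.

## Differential expression

Two-group moderated t on the trimmed matrix (pool columns removed, only
entries measured in all remaining samples). The empirical-Bayes prior
(d₀, s₀²) is fitted by matching the mean and variance of log sample
variances to a scaled F distribution, with Newton root-finding on the
trigamma inverse; when the observed dispersion of variances falls below
the chi-square sampling floor, d₀ = ∞ and s₀² is the mean variance. The
total df is d₀ + df_residual, capped at the pooled residual df across
entries when the prior was estimated (an externally supplied prior is
taken at face value — that is also what makes the d₀ = 0 and d₀ = ∞
testing hooks exact limit cases). The implementation is cross-checked
against an independent R implementation of the same estimator in the test
suite.

Storey q-values use the fixed-λ estimator π₀ = #{p > λ}/((1−λ)m) at
λ = 0.5 (floored at 1/m, capped at 1), with a cubic-spline smoother over a
λ grid available behind a flag; q-values are the step-up running minima of
π₀·m·p/rank, and with π₀ = 1 they coincide exactly with
Benjamini–Hochberg. Fold changes are PDR minus control; the volcano
classification uses strict inequalities (q < 0.05, linear fold > 1.5).
Tests are two-sided; no fold-change prefilter is applied before testing.

## Effect sizes and power

Hedges' g = J·(mean₁ − mean₂)/s_pooled with J = 1 − 3/(4·df − 1). The 95%
CI inverts the noncentral-t pivot on the Cohen's-d scale (exact coverage
for the population standardized difference; J multiplies the point
estimate only), with a normal approximation beyond df = 200. Zero pooled
dispersion yields a flagged result (`assumption_warning`) rather than an
exception, since such proteins (both groups constant) violate the
estimator's assumptions and deserve explicit skepticism downstream.
scipy's noncentral-t CDF can return NaN in deep tails at large
noncentrality; a normal-approximation fallback covers those regions.

FDR-controlled power solves FDR = π₀α/(π₀α + (1−π₀)·power(α)) for the
per-comparison α by bracketed root-finding (residual < 1e−10). The power
model is the two-sided two-sample t with equal per-group n and
noncentrality g·√(n/2); an unequal-n variant (noncentrality
g·√(n₁n₂/(n₁+n₂))) is available for retrospective checks. Because the t
power underflows at extreme α, the bracket is located on a log-spaced α
grid before refinement; an unattainable FDR (e.g. FDR ≥ π₀) returns power
0 with a flag. π₀ = 0.7 is a user parameter (the planning convention for
this design), not an estimate.

## QC and annotation

Spearman correlations are pairwise-complete with average ranks (pairs
sharing < 3 entries yield missing cells with a warning). PCA uses the
complete-entry submatrix, centered per protein, unscaled — abundances
already share the log2 scale. Ward/Euclidean clustering runs on the same
submatrix, with flags to exclude or restrict to the blood-protein panel.
Dropout classes partition proteins observed anywhere: *complete* (measured
everywhere), *inter-plex* (whole plexes absent, full elsewhere),
*intra-plex* (strict subset within some plex; takes precedence when both
patterns occur). Hemoglobin subphenotype bands (g/dL) are
PDR-L ≤ 1.0e−4, PDR-M ∈ [2.0e−4, 1.7e−3], PDR-H ∈ [4.9e−3, 8.4e−3],
endpoints inclusive; values in the gaps between bands are left
`unclassified` rather than snapped. The default blood-protein panels (23
plasma, 7 erythroid gene symbols; erythroid wins on overlap) are
reconstructions of the classic high-abundance sets, clearly synthetic and
overridable by the caller.

## Synthetic data generator

The generator emulates the assumed study design on the log2 scale:
protein baselines ~ N(16, 2²) (log-normal intensities); a fraction π₀ of
proteins is null, non-null standardized effects ~ N(0, 1.5²) scaled by the
biological SD (0.5) into log2 fold changes; per-sample biological noise
N(0, 0.5²); per-plex per-protein batch shifts N(0, 0.5²) applied to every
channel including the reference; PSM sampling depth N(0, 1²) shared by MS1
and reporters; reporter noise N(0, 0.15²) per channel. Pool channels are
exact linear mixtures of the individual samples' true abundances (pool 1:
controls; pool 2/bridge: all). Plasma-annotated proteins carry no
phenotype effect; erythroid-annotated proteins get a +2 log2 PDR upshift
(hemorrhage contamination). Defaults for the dropout rates (0.34
inter-plex, 0.035 intra-plex) and design (4 plexes, 10 CTL, 22 PDR,
~1200 proteins) reproduce the measured/complete/dropout proportions typical
of this design; the reporter-noise magnitude is a tunable chosen to put
technical-replicate correlations in the high-0.9s band, not an estimate.
PDR hemoglobin is drawn by cycling the three subphenotype bands then
sampling uniformly within the band, so every subphenotype is populated.

Dropout is injected after quantification (whole plexes removed, or a strict
channel subset blanked within one plex). Because the bottom-5% intensity
filter can itself erase a low-abundance protein from a plex, the truth
ledger's `dropout_class` is the *realized* class — the generator reapplies
the filter chain and classifies the surviving presence pattern with its own
straight-line classifier — while the injected class is kept alongside.
Seeding uses explicit `SeedSequence` spawn keys: protein truth depends only
on the protein count and seed; each plex's noise has its own substream; all
normal draws are standard normals scaled afterwards so zeroing a variance
never changes stream consumption. Dropout plex-targeting draws sizes
relative to the plex count and so re-randomizes when plexes are added.

What the generator does **not** emulate: missing-not-at-random mechanisms
beyond the two dropout classes, isotopic impurity cross-talk between
reporter channels, chromatographic or spectral artifacts, and
heteroscedastic per-protein biological variance (all proteins share one
biological SD, which is why the fitted prior df comes out very large on
simulated data). Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
pathology of real LC-MS data.

## Problem sizes used in the test and acceptance runs

The bundled suites run the full pipeline at the study design (4 plexes,
1200 proteins, ≈24k PSMs), a 3000-protein null study for type-I-error
calibration, 2000-protein effect-size recovery, 200k-replicate Monte-Carlo
power checks, and 1000 random ≤5×5 matrices against the straight-line
normalization oracle. These sizes give binomial/Monte-Carlo standard
errors comfortably below the asserted tolerances while keeping a full run
in the minutes range.

## Known limitations

* Gene/protein/peptide levels share one summarization path; phosphosite
  summarization is out of scope.
* The moderated-t implementation fits a constant prior (no mean-variance
  trend); a trend option is a natural extension but is not asserted
  anywhere.
* The Storey smoother is a cubic smoothing spline evaluated at the largest
  λ, a pragmatic variant of the classic natural-spline smoother.
* `fdr_alpha` assumes a common effect size and two-sided t rejection; it
  does not model correlated tests.
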