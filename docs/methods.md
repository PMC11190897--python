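# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
known limitations. Parameter names refer to keyword arguments of the
public functions.

## Bulk differential expression (`bulk_de`)

Counts are modelled per gene as negative binomial with mean μ and
dispersion φ (variance μ + φμ²).

- **Low-count filter.** A gene is kept if its CPM reaches `min_cpm`
  (default 1.0) in at least `min_samples_per_group` (default 2) samples of
  some group. The defaults therefore remove genes expressed in only one
  sample per group. The numeric threshold is a convention, configurable.
- **TMM factors.** Reference sample: upper-quartile CPM closest to the
  mean upper quartile. Per sample, log-ratios M and abundances A over
  genes positive in both sample and reference are doubly trimmed (30 % on
  M, 5 % on A, each tail) and the factor is 2^(weighted mean M) with
  inverse asymptotic-variance weights, rescaled to geometric mean 1.
  Factors agree with the reference Bioconductor implementation to 4
  decimal places on shared input (development cross-check).
- **Dispersion.** Counts are equalized to a common effective library size
  ("pseudocounts", simple rescaling rather than quantile adjustment — a
  deliberate simplification that preserves the conditional-test contract
  at this scale). The common φ maximizes the mean per-gene conditional NB
  log-likelihood given group totals (valid because a sum of iid NB(r, p)
  is NB(nr, p)), searched on a log grid with bounded Brent refinement.
  Tagwise φ_g maximizes l_g(φ) + (prior_df/df_res)·l̄(φ), where l̄ is the
  average per-gene curve; `prior_df` defaults to 10, and φ_g → φ_common as
  prior_df → ∞ by construction.
- **Exact test.** Per gene, group sums of pseudocounts are rounded to
  integers (each group separately, so swapping group labels mirrors the
  conditional distribution exactly); the two-sided p sums the conditional
  probabilities of all splits no more probable than the observed one.
  φ = 0 uses the exact conditional binomial. log₂ fold changes add a
  prior count of 0.125 to each group's mean pseudocount to avoid infinite
  values. BH adjustment runs across the retained genes.
- **Significance convention.** The upstream screen's "upregulated" set
  uses adjusted p ≤ 1e-4 by default (`alpha`, `use_fdr` configurable):
  the disease-biopsy analyses this package models printed a P < 0.0001
  cutoff without stating raw vs adjusted, so both modes exist and neither
  is privileged by the tests.

Calibration measured by the suite: on null NB data (φ = 0.2, 5 vs 5,
2000 genes) the raw p < 0.05 fraction falls in [0.03, 0.07]; with planted
|log₂FC| ≥ 1 at 8 vs 8 the FDR ≤ 0.05 call set recovers ≥ 80 % of planted
genes.

## Enrichment (`enrichment`)

One-sided (enrichment) Fisher exact test per term on the 2×2
query × term table over the background universe; the universe defaults to
the union of term genes and should be widened to the DE-tested genes by
the caller (the CLI does). The odds ratio uses a Haldane 0.5 correction
when any cell is zero. BH runs within the library. The rank z-score is
Monte-Carlo: `n_permutations` (default 1000, seeded) random queries of the
observed size are drawn uniformly from the universe, terms are ranked by p
in each draw, and z = (mean permuted rank − observed rank)/sd, with an sd
floor of 1e-6 — earlier-than-expected terms get z > 0. The combined score
is c = −ln(p_adj)·z with p_adj floored at 1e-300, so enriched terms score
positive; the sign convention resolves the ambiguity of "product of the
log-adjusted p and z" (ln p_adj < 0). Note that BH re-application is *not*
a no-op (the step-up minimum inflates re-adjusted values); the suite
checks the adjustment against an independent step-up recomputation
instead.

## Mediator → receptor screen (`receptor_map`)

"Expressing" means TPM strictly above `tpm_threshold`, default 0 — the
threshold is not standardized in the field, so `coverage_sensitivity`
reports coverage at {0, 1, 5} TPM. Coverage uses ANY-semantics over a
mediator's receptor list, hence is monotone nonincreasing in the threshold
and at least the best single-receptor coverage. Prioritization keeps a
mediator when it is significantly upregulated and coverage ≥
`min_coverage` (default 0.10 — the exclusion rule drops receptors found on
*fewer than* 10 % of neurons, so exactly 10 % is kept). The
mediator → receptor mapping is data (a two-column TSV), not code.

## Ca²⁺ imaging (`calcium`)

Normalization: out(t) = (F(t) − B − F₀)/(F_KCl,max − F₀), with B the
supplied background, F₀ the mean over the 10 s *before* drug onset
(half-open window: the onset frame already carries drug), and F_KCl,max
the KCl-window maximum. The scale is thus 0 at baseline and 1 at the KCl
maximum, and every downstream call is invariant to multiplying the raw
trace and background by any k > 0.

QC: included iff the KCl rise exceeds 5 % of baseline *and* the baseline
is stable. "Stable" is operationalized (the source protocols leave it
qualitative) as |fitted linear slope| × window ≤ `drift_tol` (default 5 %
of F₀) and baseline CV ≤ 10 %; failure reasons are reported.

Responder rule: normalized peak strictly > `threshold` (default 0.1)
within `response_window_s` (default 90 s) after drug onset. The response
window is a package choice — applications last ~30 s with ≥3 min between
drugs, so 90 s captures the transient without bleeding into the next
application; it is configurable because the original criterion does not
fix a window. Cosensitivity tables partition the QC-included universe;
reporter overlap reports the reporter⁺ fraction among responders plus
mean ± SEM soma areas per class. Soma-area histograms use 100 µm² bins
(cosmetic).

## Nerve recording (`nerve`)

- **Spike detection.** The trace is smoothed by a 0.3 ms moving average —
  consistent with the 100–1500 Hz acquisition band-pass — and noise is
  estimated on the smoothed trace as robust RMS (1.4826 × MAD). The
  default threshold is "twice the background noise" with noise read as a
  peak-to-peak proxy: 2 × (4 × robust RMS). Detecting on the smoothed
  trace is what makes a 5× raw-RMS spike clear the threshold while pure
  noise produces < 0.5 false events/s; on the raw trace those two
  requirements are irreconcilable (an 8σ threshold can never pass a 5σ
  peak, and a threshold low enough to pass it drowns in noise crossings).
  Crossing groups separated by `dead_time_ms` (default 2 ms) become one
  event, timestamped at the absolute peak; `threshold_uv` overrides the
  automatic rule.
- **Rates.** 1 s bins, 60 s centered moving average. Baseline = mean
  smoothed rate over the 300 s before drug onset; peak = max smoothed rate
  within 600 s after onset; Δ = peak − baseline, percent = 100·Δ/baseline.
  On a stationary 5 Hz train the max-of-estimate bias stays below
  1 spike/s with these defaults (regression-tested).
- **Concentration–response.** n/mean/SEM per concentration; optional
  3-parameter Hill fit (Emax, EC50, slope), off by default, requiring ≥3
  concentrations.
- **Waveform matching.** 3 ms peak-aligned snippets (re-centered on the
  raw absolute peak within ±0.3 ms), average-linkage agglomeration cut at
  `merge_threshold` (1.5) × the expected same-unit noise distance
  σ√(2m); cluster templates are then merged iteratively while the closest
  pair lies under the same criterion, which heals splits of a single true
  unit that snippet-level linkage keeps apart. The clustering is a
  documented stand-in for the original (uncited) waveform-matching
  procedure.
- **Distension.** 1 s binned rates; responsive iff the supra-threshold
  (default 20 mm Hg) mean rate exceeds the sub-threshold mean by more than
  `k_sd` (2) × SD of sub-threshold bin rates.

## Cell counting (`cellcount`)

The Kittler–Illingworth criterion J(t) = 1 + 2[P₁ln σ₁ + P₂ln σ₂] −
2[P₁ln P₁ + P₂ln P₂] is minimized over all 256 levels (classes with zero
mass or zero variance are skipped). Empty histogram gaps make J flat over
a run of thresholds that induce the identical partition, so ties are
broken to the lowest level within 1e-9 of the minimum — this makes the
result independent of floating-point summation order, and the suite checks
exact integer agreement with an independently coded exhaustive scan. The
original workflow's manual threshold adjustment is not reproducible and is
replaced by an explicit `threshold` override. Watershed: markers are
distance-transform maxima at least `min_distance_px` (7) apart;
components under `min_area_px` (30 px) are discarded as debris. The
neuron fraction is marker-positive count / nuclear-positive count,
reported per image (a pooled figure is a caller-side sum).

## Test selection (`stats`)

Two groups: Shapiro–Wilk per group at `alpha_gate` (0.05); both normal →
F-test on the variance ratio → Student's t (homogeneous) or Welch's t;
otherwise Mann–Whitney U. k groups: all normal and Levene-homogeneous →
one-way ANOVA with Bonferroni-adjusted pairwise t post-tests; otherwise
Kruskal–Wallis with Dunn post-tests (hand-implemented: rank-sum z with tie
correction, Bonferroni-adjusted). Groups under 3 observations force the
nonparametric branch with a warning. The gate α is per comparison. A
one-tailed `alternative` is exposed for the two-group tests.

## Synthetic data (`simulate`)

The generators define the conditions under which the suite's recovery
claims hold; they are intentionally simple:

- **Bulk counts**: gene means lognormal (log-mean 4.0, log-sd 1.5 —
  a realistic bulk dynamic range), NB via gamma–Poisson, library sizes
  uniform in 0.8–1.2 M, planted log₂ fold changes N(0, 2) truncated to
  |lfc| ≥ 0.5 so "true DE" is well defined. No batch effects, GC/length
  bias, or outlier samples.
- **Neuron matrix**: per-gene Bernoulli positivity (optionally conditioned
  on another gene's planted state, which is how marker coexpression is
  planted), lognormal TPM when positive, hard zeros otherwise. No
  dropout-vs-depth coupling, no population structure beyond the labels.
- **Traces**: baseline + difference-of-exponentials transients (1 s rise,
  8 s decay — plausible somatic Ca²⁺ kinetics; the source material shows
  but never parameterizes transient shape) + white Gaussian noise; every
  ROI except a planted "dead" fraction gets a KCl transient; responders
  get a drug transient of normalized amplitude ~N(0.5, 0.1) clipped ≥
  0.15 so truth stays away from the 0.1 decision boundary. Sampling
  2.5 Hz. No bleaching, drift (except when planted), or motion.
- **Recordings**: biphasic difference-of-Gaussians templates (2 ms; the
  repolarization lobe at half amplitude, as in real extracellular
  potentials), homogeneous Poisson event times with a per-unit rate step
  inside the drug window, a one-template-width refractory gap, white
  Gaussian noise at 20 kHz, optional triangular pressure ramp. Truth
  timestamps are template-peak-aligned. No bursting, no electrode drift,
  no overlapping-spike resolution.
- **Micrographs**: uniform disks at rejection-sampled positions (minimum
  separation 2.2 × max radius by default; lower it to plant touching
  objects), foreground 200 on background 20, additive Gaussian noise,
  8-bit. Every neuron-marker disk also carries a nuclear disk. No
  illumination gradients, no intensity texture.

Consequently, passing tests demonstrate correctness of the *computations*
under clean, known-truth conditions — not robustness to the full mess of
real data (ambient RNA, photobleaching, electrode artefacts, uneven
staining). The interfaces accept real data in the same formats.

## Numerical choices and degenerate inputs

- Dispersion search bounded to φ ∈ [1e-8, 10]; estimates ≤ 2e-8 report 0.
- Exact-test p of an all-zero gene is 1; zero control mean in a fold
  change reports +inf with a warning rather than raising.
- Rank-z sd floor 1e-6; single-term libraries return z = 0 with a warning.
- KCl maximum ≤ baseline marks the ROI as QC-failed rather than producing
  an undefined normalization.
- Per-stage seeds derive from the global seed by CRC-hashing the stage
  name, so adding a stage never shifts another stage's stream.

## Limitations

- The exact-test pseudocount rescaling (not quantile-adjusted) and the
  tagwise shrinkage weighting are simplifications of the reference
  count-model machinery; they agree closely in practice (see the
  development cross-check) but are not numerically identical in all
  regimes.
- The Monte-Carlo rank z is an approximation to a precomputed
  expected-rank table; its sampling error (~1/√n_permutations) enters the
  combined score.
- Unit matching is amplitude-dominated Euclidean clustering; units with
  equal amplitude but different shape at low SNR will merge.
- No multi-factor DE designs, no batch covariates, no image-based ROI or
  background extraction, no z-stacks.
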