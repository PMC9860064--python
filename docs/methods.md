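# Methods

## Scope and data model

The package analyses batch co-cultures of *Prochlorococcus* (MED4, MIT9312,
MIT0604 — high-light; NATL2A, MIT9313 — low-light) and *Alteromonas* (HOT1A3,
BS11, ATCC27126, AltDE1, AltDE) in nitrogen-limited medium (Pro99 with
100 μM NH₄⁺). A culture is observed as a bulk chlorophyll-fluorescence time
series in arbitrary units, sampled near daily over ~140 days, plus
flow-cytometry cell counts of both populations at a few sampled days. The
canonical on-disk form is long/tidy CSV; days are real numbers from
inoculation. Fluorescence at or below the detection floor is retained but
flagged, and every log-domain computation excludes flagged points — clamping
them instead would imprint the (arbitrary-unit) floor on fitted shapes.

## Growth-phase extraction

Model: N_t = N₀ e^{μ(t−L)}. The peak (FL_max, t_max) is the maximum observed
fluorescence, ties broken to the earliest day so the decline window starts as
early as possible. The growth window ends at the peak and is found by
shrinking from the first point until the regression of ln FL on t reaches
R² > 0.9 with μ > 0 (minimum 4 points; R² on 3 points is uninformative).

One refinement on top of the threshold rule: window ends are then trimmed
while doing so *strictly* improves R². Without it, a flat lag prefix ahead of
a long clean exponential still passes R² > 0.9 (we measured R² = 0.964 on a
noiseless curve with a 3.3-day lag) and biases μ low by ~20%; and the
observed peak sample typically falls just past the true peak onto the decline
branch when the true peak lies between samples. With the refinement, noiseless
simulated curves are recovered to machine precision (μ and L to ≲1e−10). The
fit is accepted only at R² > 0.9; rejected cultures are kept in the feature
table with a status code rather than dropped silently. The lag is defined
through the intercept — L = (ln FL_first − intercept)/μ, clipped at 0 — the
simplest definition consistent with the growth equation; a threshold-crossing
definition would differ when the first observation is itself noisy, and the
choice is recorded in output metadata.

## Mortality models

The decline phase is τ = t − t_max ≥ 0, y = FL/FL_max, with FL_max fixed at
the observed peak rather than fitted: normalization makes RMSE comparable
across cultures, and y(0) = 1 holds for every model by construction. All four
models use τ (including the harmonic, for consistency of "time since decline
onset"). At least 5 usable points are required.

Fitting follows a robust multi-start recipe: bounded nonlinear least squares
(dogbox trust region) on soft-L1 loss with residual scale 0.1, started from
the all-0.5 parameter vector plus seeded uniform draws within bounds
(rates ∈ [0, 50] d⁻¹, shape n ∈ (0.01, 10], fraction f ∈ [0, 1]; 50 random
starts by default, fewer in the drivers where convergence is easy). The
winning start minimizes the *plain* RMSE — the robust loss shapes the
optimization only, the reported error metric is defined independently. The
bi-exponential is reported with a₁ ≥ a₂ (post-hoc swap) since it is invariant
under (f, a₁) ↔ (1−f, a₂).

Model comparison uses RMSE and Gaussian BIC = m·ln(RSS/m) + k·ln m with
k = 1/3/1/2 free parameters. Two numerical guards: RSS at float-noise level
(RMSE < 1e−12 on the normalized scale) maps to a −∞ sentinel, because below
that the Gaussian likelihood ranks models by rounding error; and −∞ ties
resolve to the most parsimonious model. The Weibull is fitted in rate form
e^{−aτⁿ}; the scale form e^{−(τ/a′)ⁿ} with a′ = a^{−1/n} is available as a
converter, and the decimal reduction time t_d = (ln 10^d / a)^{1/n} is
parameterization-invariant and satisfies y(t_d) = 10^{−d} exactly. Group td₂
statistics are computed per curve and then averaged.

## Nitrogen budget

biomass[μmol N/L] = X[cells/ml] · Q_N[fg/cell] · 10⁻⁶ / MW_N, with quotas at
the lower end of measured values (7 fg N/cell for high-light
*Prochlorococcus*, 10.5 for NATL2A, 14 for MIT9313, 13 for *Alteromonas*,
MW_N = 14 g/mol): larger quotas imply more N in biomass than the 100 μmol/L
supplied, and cells under long-term N stress hold less N than in exponential
growth. A sensitivity grid over quota ranges (up to 20/25 fg N/cell) reports
where feasibility breaks; since biomass is linear in each quota the
feasibility boundary is monotone.

Interactions are called per strain pair and day: log2FC = log₂(mean co /
mean axenic) of a population's biomass against its same-strain axenic
control, tested by a two-sample t-test on log₂ biomass, Bonferroni-corrected
within the strain-pair family. Significant positive → synergistic,
significant negative → competitive, otherwise neutral (with a
`negative_trend` flag so "potentially competitive" cases stay visible).
Fold changes are computed on arm means (replicates are not paired across
arms); the choice is recorded in output metadata.

## Curve-shape analytics

Curves are aligned to peak day 0 and binned on integer days −10..+80
(half-open [d, d+1) bins, multiple observations averaged), linearly
interpolated inside, nearest-value filled at the edges, then z-scored per
day (population SD; constant days are zeroed and flagged). PCA signs are
fixed by forcing each component's largest-|loading| entry positive, making
ordination deterministic across platforms. PERMANOVA computes the adonis
pseudo-F from distance-based sums of squares on Euclidean distances
(SS_total = Σ_{i<j} d²_ij / N; within-group analogue per group), with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) under seeded label permutation —
never exactly zero. Classification is a stratified 10-fold random forest
(folds reduced with a warning if the rarest class is smaller); per-day
importances are averaged over 30 refits of the full matrix.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design — 25 strain combinations plus
axenic controls in triplicate, 140 days of daily sampling with ±0.1-day
jitter, multiplicative lognormal noise (CV 5%), detection floor 1 au — with
a piecewise trajectory per culture: flat at FL_max/100 until the lag,
exponential rise at μ to FL_max, then the strain's mortality law. Phototroph
strains carry two Weibull laws: an axenic one (shape drawn once around 2.1,
SD 0.9, clipped above 1.1; td₂ around 12.6 d) and a co-culture one (shape
around 0.4, SD 0.2, clipped above 0.05; td₂ around 300 d, lognormal spread).
One strain (MIT9313) carries a 10-day co-culture lag penalty, emulating a
delayed-growth phenotype. Heterotroph profiles are dim, slowly-declining
background signals and never modify the phototroph's decline — the designed
asymmetry that the classification analysis should rediscover.

Growth parameters (μ = 0.4 d⁻¹, lag 2.5 d, FL_max 300 au) share one centre
across phototroph strains, with per-culture variation (μ CV 8%, FL_max CV
20%, lag ±1 d, decline-parameter CV 5%): growth under these conditions is
strain-similar, and making growth strain-linked would let a classifier
identify strains from the rise phase, which is not the structure of the
system being emulated.

Counts are generated budget-downward: a latent total N biomass per culture
and day (co-culture heterotroph biomass = axenic mean × 2^log2FC with
strain-level benefit +1.3 for MED4/MIT0604/NATL2A and −0.2 for
MIT9312/MIT9313; heterotroph fraction ≈ 0.76; axenic phototroph ~0.01
μmol N/L; totals decaying over days 60/100/140), capped at 100 μmol N/L and
converted to cells through the same quotas the analysis uses — so
feasibility holds by construction and quota conversion is exact on the way
back. An optional log-space Gaussian bump (off by default) adds the
secondary-growth deviation seen in strongly synergistic co-cultures.

What the generator does *not* emulate: secondary growth phases by default
(hence model-error/biomass correlations here do not reproduce the
positive-RMSE correlation that secondary growth creates in real data),
nutrient-explicit dynamics, transfers/revivals, and any coupling between a
culture's fluorescence trajectory and its own count trajectory beyond
treatment and strain labels. Passing tests therefore demonstrate that the
estimators recover known generating structure under realistic noise — not
that real cultures follow these laws.

## Problem sizes and determinism

Default analyses fit 4 models × ~90 curves with 15 random starts, run
999-permutation PERMANOVA and 10-fold/30-repeat forests; the whole pipeline
completes in about a minute on one CPU. All stochastic stages (multi-start
draws, permutations, forest seeds, the simulator) derive from a single
config seed; stage seeds are deterministic offsets, so identical seeds give
bit-identical reports.

## Known limitations

- Decline onset is anchored at the global fluorescence peak; cultures that
  plateau before declining are fitted from the plateau's highest point.
- With daily sampling the anchoring discretizes the true peak, which limits
  end-to-end recovery of Weibull parameters to ~0.02–0.05 in n even without
  noise (the fitter itself recovers to 1e−4 on exactly-specified phases).
- Weibull shape estimates shrink slightly toward 1 when the observable
  decline spans few decades (detection-floor truncation).
- The axenic *Alteromonas* "curves" carry almost no chlorophyll signal;
  growth features for them are reported as undetected rather than forced.
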