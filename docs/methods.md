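# Methods

`fluxcap` implements an analysis pipeline for extracellular flux assays of
sperm energy metabolism: plate-level oxygen consumption (OCR) and
extracellular acidification (ECAR) kinetics are normalized, summarized
into a bioenergetic parameter panel and modulator responses, and compared
between incubation conditions (non-capacitating, NC, vs capacitating,
CAP) with hierarchical mixed models. A synthetic plate generator with
recorded ground truth stands in for raw instrument data.

## Assay model and cycle windows

A run consists of 24-well plates measured over 9 cycles of 6 min. Cycle 1
is unstable and excluded from every statistic. Cycles 2–4 are the
pre-injection baseline. After cycle 4 each well receives assay medium
(baseline wells) or one modulator — oligomycin (ATP-synthase inhibitor),
FCCP (uncoupler), 2-deoxy-D-glucose (2DOG, hexokinase-level glycolysis
inhibitor) or sodium oxamate (lactate-dehydrogenase inhibitor) — acting
over cycles 5–7. After cycle 7 every well receives antimycin A + rotenone
(A+R), which abolishes mitochondrial electron transport; cycles 8–9
measure the non-mitochondrial OCR floor. The `CycleWindows` object
encodes this partition; all aggregation is by cycle index (time stamps
are carried for plotting only).

Four cell-free wells per plate track the instrument/medium background.
Correction subtracts the per-cycle mean of the same experiment's
background wells; per-sperm normalization then divides by the well's
sperm count and rescales units (1 pmol O2 = 1e6 amol; 1 mpH = 1e6
nano-pH). Correction precedes normalization — the only dimensionally
coherent order, since the background is a per-well instrument signal.
Negative corrected rates are retained; exclusion decisions belong to the
statistics layer (a gamma model needs positive responses, so wells whose
A+R-corrected baseline OCR is ≤ 0 are excluded from percent-response
statistics and counted in the log).

## Parameter panel and responses

With `mean_w` denoting the window mean of a signal:

- basal respiration = mean_baseline(OCR) − mean_AR(OCR)
- proton leak (%) = 100 · (mean_5–7(OCR, oligomycin well) − mean_AR(OCR,
  same well)) / basal; respiratory ATP production (%) = 100 − leak
- maximal respiration (%) = 100 · (max_5–7(OCR, FCCP well) −
  mean_AR(OCR)) / basal; spare capacity (%) = maximal − 100
- basal glycolysis = mean_baseline(ECAR), uncorrected; glycolytic
  reserve (%) = 100 · (max_5–7(ECAR, oligomycin well) − basal gly) /
  basal gly
- OCR/ECAR ratio = per-well ratio of uncorrected baseline means; cohort
  summaries average per-well ratios, never divide cohort means.

The FCCP-OCR and oligomycin-ECAR aggregates use the highest value among
cycles 5–7 (transient peak responses); all other aggregates use means,
in both incubation conditions. Modulator responses are percent of the
well's own baseline; for OCR both numerator and denominator are first
reduced by the well's A+R mean, which makes the response invariant to
any constant additive offset of the OCR trace (a property test). Two
aggregation conventions exist: `mean` (cycles 5–7 mean, both signals)
and `extremum` (ECAR max under oligomycin, min under 2DOG), the latter
used in between-species comparisons.

Panels that need two wells (baseline + oligomycin, baseline + FCCP) pair
each baseline well with every candidate partner of the same experiment
and condition and average the pair results (`pairing="all"`, default;
`"first"` is available). Runs truncated before the A+R window fall back
to the uncorrected baseline mean with a `nonmito_uncorrected` flag
rather than failing the plate.

## Mixed models

The observational unit is the well; the independent experiment enters as
a random intercept, which is what justifies well-level replication.
Two families are supported, both fitted by maximum likelihood (not REML)
so that likelihood-ratio tests between nested fixed-effect structures
are valid:

- **Gaussian on log10**: `log10 y = Xβ + u + e`. For a single random
  intercept the ML problem is profiled to a one-dimensional search over
  the variance ratio; β, both variances and the log-likelihood are then
  closed-form. The boundary (zero between-experiment variance) is
  evaluated explicitly and flagged. This fitter reproduces statsmodels
  `MixedLM(reml=False)` to ~1e-6 on coefficients and is ~100x faster,
  which the calibration simulations rely on.
- **Gamma with inverse link**: `1/μ = Xβ + u`, `y ~ Gamma(k, μ)`. The
  marginal likelihood integrates `u` per group by Laplace approximation:
  the negative log-integrand is strictly convex on the feasible region
  `η > 0` (the link's positivity constraint acts as a natural barrier),
  so a damped Newton search finds the conditional mode; adaptive
  Gauss–Hermite quadrature (≥ 9 nodes, centred at the Laplace mode) is
  available as a verification route. Standard errors come from the
  numeric observed information at the optimum. On a frozen fixture the
  fit agrees with R `glmmTMB` to ~7 significant digits in coefficients
  and log-likelihood.

**Family choice** fits both candidates and keeps the one whose
conditional quantile (Dunn–Smyth) residuals are closer to normal by the
Shapiro–Wilk W statistic, with ties breaking to the Gaussian family.
Quantile residuals — not raw Pearson residuals — are the comparable
diagnostic: Pearson residuals of a correctly specified gamma model are
intrinsically skewed (skewness 2/√k), so judging the gamma fit by their
normality would reject it even on gamma data. Both fits and both W
statistics are returned for audit.

**Inference.** LRT: χ² = 2Δℓ clamped at zero, df = difference in
fixed-effect counts. Post-hoc comparisons use estimated marginal means
on the link scale with equal weights over the other factors; all
pairwise differences are tested with Tukey (studentized-range)
adjustment by default. Denominator df: Satterthwaite for the Gaussian
family (numeric gradient/Hessian of the profiled ML likelihood in the
two variance parameters, clamped to [1, residual df]); normal
approximation for the gamma family. Cohort summaries report mean, SD
(n−1), and two 95% CI half-widths — over wells (t on well-level df) and
over experiment means — because either replication level can be argued.

## Synthetic data generator

Each well's expected per-sperm rate is
`condition mean × exp(experiment effect) × exp(well effect) ×
multiplier(cycle)`, with the multiplier rising from 1 toward the
treatment plateau from cycle 5 by a first-order approach (rate 1.498 per
cycle: 95% of the plateau by the second post-injection cycle) and moving
to the A+R state from cycle 8 with a faster rate (6.0: essentially
complete within one cycle — A+R collapses electron transport regardless
of the preceding treatment; a slow decay would leave FCCP wells' A+R
window above baseline and make corrected baselines negative, which real
traces do not show). OCR's A+R state is a non-mitochondrial floor (5% of
the pre-injection rate); ECAR's is a compensatory rise. Observed values
multiply the expectation by mean-one lognormal cycle noise; raw
(pre-normalization) traces add the plate background and divide by the
per-well sperm count, so generated data exercise the full pipeline.

Defaults encode the steppe-mouse study conditions: basal respiration
315 (NC) / 231 (CAP) amol O2 min⁻¹ sperm⁻¹ and basal glycolysis
18.9 / 25.7 nano-pH min⁻¹ sperm⁻¹; 4 experiments; per condition and
experiment, 2 wells for each of 5 treatments plus 4 background wells
(24-well plates); sperm counts lognormal around 1e7. Because the
pipeline sees the onset transient and the A+R correction, plateau
multipliers are *derived* by closed-form inversion of the window
arithmetic so that the noiseless pipeline output equals the target
cohort responses (OCR: 37.3% oligomycin, 841% FCCP, 153% 2DOG, 42.7%
oxamate of baseline; ECAR: 147%, 72.1%, 63.0%, and a 141% A+R level) —
see `ocr_plateau_for_response`. Noise scales: between-experiment SD 0.35
(log), matching the ≈0.39 across-experiment CV of basal respiration;
well SD 0.08; cycle CV 0.06 for OCR and 0.17 for ECAR — the ECAR value
is implied by the gap between mean-window (+47%) and peak-window
(+67.6%) oligomycin responses, i.e. by how far the within-window peak
sits above the mean. All noise terms are mean-one lognormal so
configured rates are also expected cohort rates.

Species presets differ in the OCR response to 2DOG: the `spicilegus`
preset raises respiration when glycolysis is blocked (two-way metabolic
compensation), the `musculus` preset lowers it to near-oligomycin
levels; both raise ECAR under oligomycin. The musculus preset's absolute
rates are nominal (its source data were collected on a different
instrument), so only signs and relative changes are meaningful for it.

What the generator does not emulate: oxygen-diffusion physics, drift or
edge effects in the background, correlated (AR-type) cycle noise,
buffer-capacity conversion of ECAR to proton efflux, and any feedback
between the two pathways beyond static cross-signal multipliers. Tests
passing on synthetic data therefore validate the arithmetic, the
hierarchy handling and the inferential calibration — not instrument
artifacts.

A known internal tension of the anchoring values: the basal-rate rows
(315/18.9) imply a per-well OCR/ECAR ratio near 16.7, while the
published ratio cohort (a different experiment subset) averages 5.19.
One generator cannot reproduce both; the defaults anchor the basal-rate
rows and report the ratio as computed.

The ATP-assay generator draws per-sample true contents (NC 1242, CAP
701 amol sperm⁻¹, lognormal between-sample SD 0.25), maps them through a
linear luciferase curve (blank 50 RLU, slope 1e-5 RLU/amol) and emits
triplicate readings with 3% CV plus a six-point standards table spanning
1e7–3e9 amol.

## Numerical choices and edge cases

- Window sets are validated disjoint and ordered; requesting a missing
  cycle is a typed error, falling back only where documented (A+R
  truncation).
- Standard curves: least-squares line (log-log power law optional),
  rejected below r² = 0.98; readings below blank clamp to zero ATP with
  a flag; readings beyond the standards are flagged as extrapolated but
  kept (sample sizes are small; hard rejection would drop whole
  conditions).
- GLMM optimization: Nelder–Mead then BFGS polish from a gamma-GLM
  start; infeasible parameter points (any η ≤ 0 at the conditional mode
  search) return a large penalty. Non-convergence is reported on the
  fit, never raised.
- LRT df = 0 (identical models) returns p = 1.
- Ties in window max/min need no tie-breaking: only the value is used.
- Display rounding: integer percentages in narrative report lines, one
  decimal in tables; full precision in CSVs (round-trip to 1e-9).
- Problem sizes in the shipped simulations (2000 null replicates at
  2×4×5 wells; 100 recovery datasets per family at ~200 wells; 8
  replicate cohorts of 6 experiments for cohort summaries) give binomial
  or CLT margins comfortably inside the asserted bands.

## Known limitations

- The gamma GLMM supports a single random intercept (the design's only
  grouping factor); no crossed or random-slope structures.
- Laplace approximation can be biased for very small group counts with
  large random-effect variance; the AGQ route is provided for checking.
- The LRT on fixed effects is asymptotic; with very few experiments the
  type-I error runs slightly above nominal (the calibration suite pins
  it within [0.03, 0.07] at the study's design size).
- ECAR is treated as an opaque acidification rate (nano-pH min⁻¹); no
  buffer-capacity or CO₂-vs-lactate decomposition is attempted, so
  glycolytic interpretation inherits that ambiguity.
- Vendor instrument exports are not parsed; data enter through the
  package's documented CSV dialects.
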