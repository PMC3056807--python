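# Methods

## The problem the pipeline addresses

Hourly cerebral microdialysis (MD) in traumatic brain injury is a panel
of short, strongly autocorrelated time series with large between-patient
level differences. Naively pooling subject-hours makes almost any
MD–pressure association look "significant": subject means leak into the
pooled correlation, and serial dependence wrecks nominal error rates.
Every stage of this package is built around separating three components
of an apparent MD–pressure association: (i) between-subject level
coupling, (ii) genuine within-subject hour-to-hour coupling, and (iii)
pooling artefacts.

## Synthetic cohort generator

Markers are modelled on their variance-stabilised scales (square root
for glucose, lactate, pyruvate; log10 for glycerol) as

    m_ij(t) = alpha_j(location) + a_ij
              + beta_ICP,j (ICP_i(t) - mu_ICP) + beta_CPP,j (CPP_i(t) - mu_CPP)
              + s_ij(t)

with `a_ij ~ N(0, sigma_bj^2)` a patient intercept, `s_ij` stationary
ARMA(1,1), and `ICP_i(t)`, `CPP_i(t)` the mean pressures over the hour
before the vial's membrane time (the same alignment the preprocessing
computes, so couplings are recoverable by construction). Raw
concentrations are obtained by squaring / exponentiating; vial components
go missing independently at `missing_rate`.

Key defaults and their rationale:

- `n_patients = 90`, `frac_pericontusional = 64/90`, `hours_mean = 84`
  *complete* marker sets per patient (vials are drawn
  negative-binomially, dispersion 10, at rate
  `hours_mean / (1 - missing_rate)^4` so the complete-set mean hits the
  target under marker-wise missingness), minimum 5 h. Unbalanced panels
  are deliberate: the pooled estimators must tolerate them.
- Marker ARMA coefficients `phi` of 0.78–0.83 (theta 0) give per-patient
  adjacent-hour correlations around 0.74–0.80; between/within SDs are
  set so subject identity explains roughly half to three quarters of
  marker variance (intraclass correlations 0.52–0.76; `CohortConfig.icc`
  and `with_icc` expose the mapping).
- Pressures: per-patient levels `mu_ICP,i ~ N(14, 4^2)` (truncated
  positive) and `mu_MAP,i ~ N(80, 7^2)`, consistent with clinical
  targets (ICP <= 20, CPP 60–70 mmHg), plus AR(1) deviations at the
  1-minute sampling resolution (phi 0.8 per sample, marginal SD
  3 / 4 mmHg). Hour-means of such a process are nearly serially
  independent within a patient; an optional slow hourly AR(1) level
  (`icp_slow_sd`, `map_slow_sd`, default 0) adds hour-scale persistence
  for sensitivity experiments — see "Known limitations" for why it is
  off by default. MAP is floored at ICP + 5 mmHg so CPP stays defined.
- Default hourly couplings are small (|beta| <= 0.008 per mmHg,
  nonzero for glucose/lactate toward ICP and CPP pericontusionally,
  glucose/lactate/glycerol toward ICP nonpericontusionally), keeping
  pressure-explained marker variance in the low single-digit percents.
  Separate `subject_coupling_*` knobs couple the patient intercept to the
  patient's mean pressure, creating purely between-subject association
  with no temporal alignment — the regime the permutation diagnostics
  are designed to expose.
- GOS: an ordinal-logistic draw on centred mean ICP (weight −0.25/mmHg)
  and mean CPP (+0.08/mmHg), cutpoints chosen for roughly 15% mortality
  and ~55% favourable outcome; epoch scores never exceed the best score
  and the 1-year score equals it. The vegetative level is allowed even
  though rare, so outcome code must handle all five levels. MD does not
  enter the outcome model by default.

What the generator does **not** emulate: waveform-level pressure
dynamics, interventions (CSF drainage, osmotherapy, barbiturates) and
their feedback on pressures, assay chemistry and recovery fractions,
nonstationarity of marker baselines, and heavy-tailed artefact bursts.
Passing tests therefore demonstrate estimator correctness and
calibration under a second-order-realistic panel structure, not clinical
realism of any individual trace.

## Preprocessing

- Transfer-time shift: membrane_time = vial_time − 17 min (configurable).
- Limiters: per-marker closed intervals clamp to the nearer bound, every
  clamp counted. The defaults (glucose 0.1–25, lactate 0.1–30 mM;
  pyruvate 10–1500, glycerol 1–5000 uM) bracket bedside analyzer ranges;
  the denominators' floors keep LP/LG ratios finite and bounded.
- Ratios are computed from raw (limited, untransformed) concentrations,
  LP = lactate·1000/pyruvate (units harmonised), LG = lactate/glucose;
  ratios are reported in natural units unless `transform_ratios` is set.
- Pressure alignment: for membrane time t the window is the half-open
  hour (t − 60 min, t]; CPP is averaged over timestamp-matched MAP−ICP
  pairs (config switch for separate-mean subtraction). Rows with less
  than 50% of the expected samples in the window (expected = window /
  median sampling interval) are dropped with a logged reason, as are
  rows inside user-supplied artifact exclusion intervals.
- Complete sets: only rows with all four markers and both aligned
  pressures survive; per-patient retained/dropped counts are reported.

## Correlograms and the permutation null

Lagged correlations pair `x_t` with `y_{t+lag}` strictly within patient
(positive lag = pressure after the MD sample). Two pooling modes:
`pooled` (one Pearson correlation over all subject-hour pairs — the mode
in which subject-mean structure is visible) and `per_patient`
(pair-count-weighted mean of per-patient correlations). Lags with fewer
than `min_pairs` (default 30) pooled pairs are reported missing, as are
lags undefined for constant series.

The within-subject permutation null re-orders each patient's marker
values uniformly while pressures stay fixed: subject marginals — and
hence all between-subject structure — are preserved exactly, while
temporal alignment is destroyed. In pooled mode the pointwise band at
each lag is the *conditional* permutation null: marker values are
permuted among exactly the rows entering that lag's pairing, so only the
cross-moment varies across replicates. This coincides with the naive
whole-series scramble at lag 0; at long lags the naive construction is
anticonservative, because the observed pairing window holds a contiguous
(autocorrelated, mean-drifting) block of the series while a whole-series
reshuffle fills it with a well-mixed subset. The band is a pointwise
percentile interval (default B = 1000, level 0.95, seed recorded); a
cross-patient full-scramble control (mean of min(B, 100) replicates) is
reported alongside and should sit at zero.

Subject-identity variance is r² of the regression on patient dummies,
computed as 1 − SS_within/SS_total. For strongly autocorrelated series
this estimator exceeds the population intraclass correlation by roughly
`(1 + phi) / ((1 - phi) n)` of the within-share (the variance of a
patient's sample mean), a fraction of a percent to a few percent at the
default series lengths; calibration experiments that target an exact ICC
therefore use moderate autocorrelation (phi = 0.5) and ~84-hour series.

## REML mixed model with ARMA(1,1) residuals

Per patient, `Sigma_i = sigma_b^2 J + sigma^2 R_i` with
`R_i[a,c] = rho(|h_a − h_c|)` evaluated at *observed hour offsets* (gaps
from dropped vials decay correlation by true elapsed time) and

    rho(0) = 1,  rho(k) = gamma phi^(k−1),
    gamma = (1 + phi theta)(phi + theta) / (1 + 2 phi theta + theta^2).

The REML objective profiles beta out by GLS per evaluation (per-patient
Cholesky; identical offset patterns share one factorisation) and is
minimised over (log sigma_b, log sigma, atanh phi, atanh theta) — the
transforms enforce positivity and stationarity — by L-BFGS-B with
numerical gradients from three moment-informed starts (local optima in
phi/theta are the realistic risk). Reported: fixed effects with Wald z
tests (normal reference, appropriate for the large per-patient n and
possibly differing from a t-reference in small panels), variance
components, phi, theta, the implied adjacent-hour residual correlation
rho(1), and the REML log-likelihood (which matches a dense
multivariate-normal evaluation to 1e-8 in the tests). Predictors are
standardised per stratum for optimisation and back-scaled for reporting.
Any covariance parameter can be pinned (e.g. sigma_b = phi = theta = 0
reduces the fit to pooled OLS — a test fixture, not a recommendation).
`effect_size_report` turns coefficients into predicted pressure changes
for stated marker perturbations, the scale on which "extreme marker
excursions predict minor pressure changes" is judged.

## RBF networks under leave-one-patient-out CV

The network is deliberately classical and deterministic: k-means centers
on standardised training predictors, per-center width = mean distance to
the two nearest other centers (pair distance at k = 2, mean point
distance at k = 1), Gaussian activations, and a ridge-regularised linear
output layer with unpenalised bias. Iterative epoch-based training is
re-specified away: capacity enters only through the node count and
ridge, both selected by nested patient-grouped cross-validation inside
each leave-one-patient-out fold (standardisation statistics come from
the training fold only). The pooled Pearson r of true versus predicted
over all held-out rows is reported as mean ± SD over repeated runs
differing only in RNG stream — that spread is what the ± on
cross-validated correlations means here. Negative r is reported as-is:
when held-out patients carry no transferable signal, subject-mean-driven
predictions systematically anti-correlate rather than hover at zero.
The permuted control reruns the identical procedure after shuffling each
patient's marker rows against their own hours; skill that survives it
rests on subject means, not temporal alignment. The representation
search predicts per-patient pressure summaries (whole-period mean;
hours / % of monitoring above or below cutoffs, defaults ICP
{15, 20, 25, 30}, CPP {40, ..., 90} mmHg) from per-patient mean MD
profiles by leave-one-out linear regression, flagging zero-variance
representations.

## Short-term probes and outcome tests

Differences use exact k-hour spacings only (k = 1..4); pairs spanning
dropped hours are excluded rather than bridged, because mixing gap
lengths changes the implied dynamics. Per-subject normalisation rescales
each patient to mean 0, SD 1 (patients with under 3 rows or a constant
variable are dropped). Subject-mean regressions use the patient as the
unit: residual df = n_patients − p − 1, and patients with Cook's
distance > 1 are excluded on a single refit and reported with their
distances. The differenced design grid reports raw model p-values and
Holm-adjusted ones side by side (the grid is wide; readers can choose).
Δ-marker rows are paired with pressure at the later hour t by default
(t − k by flag).

Outcome analysis collapses each patient to whole-period summaries,
including the raised-LP-ratio burden above a configurable threshold
(default 25, a conventional clinical cutoff) in hours and as % of
complete-set hours. Best GOS is the maximum over recorded epochs;
patients with under 12 complete MD hours, or no GOS, are excluded with
logged reasons. Each summary column is tested across GOS groups by
one-way ANOVA and tie-corrected Kruskal–Wallis; a finding counts only
when both agree at alpha = 0.05. Zero within-group variance with
distinct means reports F = inf, p = 0; fully tied data report H = 0,
p = 1.

## Descriptive surfaces

Pressure-binned pooled tables (ICP edges 15/20/25/30; CPP edges
40–90 by 10) report mean ± SD of raw-unit markers and ratios with
per-bin counts that conserve stratum totals. They carry an explicit
repeated-measures caveat, and a `per_patient` weighting variant (each
patient contributes each bin once via their own bin mean) is provided.
Lowess fits are degree-1 local regressions with tricube weights,
default span 2/3 and 2 robustifying iterations (delegated to
statsmodels, which implements exactly this scheme), with an SE band from
the tricube-weighted local residual variance divided by the local
effective sample size. Trend checks fit pooled order-2/3 polynomials on
hour-since-insertion and report both r² and whether removing the trend
shifts marker–pressure correlations by more than 0.02.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations to what the
statistics need rather than to the full clinical scale: calibration
experiments use 20–60 patients with 40–84-hour series and 20 seeds;
permutation bands use B = 500; REML parameter recovery uses 60 patients
x 84 h over 10 seeds; the end-to-end determinism check uses 12 patients.
The acceptance script runs the default 90-patient structure. Collinear
designs are rejected at condition number 1e10 (mixed model) / 1e12
(OLS); REML convergence requires optimizer success and reports the final
gradient norm; k-means uses 4 restarts from the given seed; ridge
default 1e-3 on standardised activations.

## Known limitations

- The whole-series within-subject scramble (retained for `per_patient`
  pooling and the scramble control) is anticonservative as a pointwise
  band at long lags for autocorrelated markers; pooled-mode bands use
  the conditional per-lag construction instead. Either way the band is
  pointwise, not simultaneous: with 71 lags, a few excursions are
  expected under the null.
- When the paired hourly *pressure* series is itself strongly serially
  dependent within patients (e.g. via the optional slow pressure level),
  any per-subject reshuffle null — conditional or not — is again
  anticonservative: with both series persistent, exchangeability fails
  and chance within-subject alignments outrun the permutation spread.
  The default generator keeps hour-mean pressures nearly independent
  within patient, where the band is calibrated (~5% escape); treat bands
  on strongly persistent pressure representations as qualitative.
- The identity-variance r² is a biased-up ICC estimator for short,
  strongly autocorrelated series (quantified above).
- REML standard errors ignore covariance-parameter uncertainty, as
  usual for Wald-type mixed-model inference.
- The RBF permuted control preserves each patient's row multiset, so it
  tests temporal alignment only — it cannot detect leakage of subject
  identity, which is instead excluded structurally by the grouped CV
  (and asserted in tests).
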