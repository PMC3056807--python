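# mdicp

Longitudinal analysis of cerebral microdialysis (MD) against intracranial
pressure (ICP) and cerebral perfusion pressure (CPP) in neurocritical-care
monitoring, for biostatisticians and neuromonitoring researchers who need
the within-subject time-series structure of hourly MD data handled
honestly rather than pooled away.

Patients in a neurointensive care unit are monitored with an implanted MD
catheter sampling brain extracellular fluid hourly (glucose, lactate,
pyruvate, glycerol; plus the lactate:pyruvate and lactate:glucose ratios)
alongside 1–2-minute ICP and mean arterial pressure (MAP) streams, with
CPP = MAP − ICP. The scientific question is how much of the hour-to-hour
MD signal is actually coupled to pressure/perfusion, once you account for
the fact that MD is strongly autocorrelated within a patient and that
patients differ hugely in their long-run marker levels.

## What the package computes

- **Synthetic cohorts** (`mdicp.cohort`): a generative model on the
  markers' modelling scale (square root for glucose/lactate/pyruvate,
  log10 for glycerol),

  `m_ij(t) = α_j(loc) + a_ij + β_ICP·ICP_i(t) + β_CPP·CPP_i(t) + s_ij(t)`,

  with patient random intercepts `a_ij`, stationary ARMA(1,1) deviations
  `s_ij`, minute-resolution AR(1) pressure streams around per-patient
  levels, ordinal-logistic Glasgow Outcome Scale (GOS) scores driven by
  mean pressures, and marker-wise vial missingness. Every downstream
  stage is testable by parameter recovery against this generator.
- **Preprocessing** (`mdicp.preprocess`): membrane-to-vial transfer-time
  shift (default 17 min), assay limiters, ratios from raw concentrations,
  variance-stabilising transforms, pairing of each vial with the mean ICP
  and CPP over the hour before its membrane time, and the complete-set
  filter (all four markers plus pressures present).
- **Correlograms** (`mdicp.correlograms`): pooled and per-patient ACF /
  lagged cross-correlation over unbalanced panels; a within-subject
  permutation null (per-patient reshuffling that preserves each subject's
  marginal distribution) with a pointwise Monte-Carlo percentile band and
  a cross-patient full-scramble control; and the subject-identity
  variance decomposition r² = 1 − SS_within/SS_total.
- **Mixed models** (`mdicp.mixed_effects`): restricted maximum likelihood
  (REML) linear mixed models with patient random intercepts and ARMA(1,1)
  within-patient residual correlation
  ρ(k) = γ·φ^(k−1), γ = (1+φθ)(φ+θ)/(1+2φθ+θ²), written directly from
  the likelihood (profiled GLS for β, Cholesky per patient block) with
  Wald z tests — no mixed-model library underneath.
- **RBF networks** (`mdicp.rbf`): Gaussian radial-basis-function
  regression (k-means centers, ridge output layer) under strict
  leave-one-patient-out cross-validation with nested model selection,
  per-patient permuted controls, and a search over alternative pressure
  representations (hours / % of monitoring above or below cutoffs).
- **Short-term analyses** (`mdicp.short_term`): k-hour differenced
  regressions (k = 1..4, exact spacings only), per-subject
  z-normalisation, and per-subject mean regressions with Cook's distance
  > 1 screening.
- **Outcome** (`mdicp.outcome`): per-patient summaries (including raised
  LP-ratio burden) versus best GOS by one-way ANOVA and tie-corrected
  Kruskal–Wallis, with the <12-monitored-hours exclusion rule.

## Worked example

```python
from mdicp import (CohortConfig, simulate_cohort, preprocess_cohort,
                   identity_variance, acf, fit_reml)

cfg = CohortConfig(n_patients=30, hours_mean=60, seed=5)
frame = preprocess_cohort(simulate_cohort(cfg))
print("complete hourly rows:", len(frame))

iv = identity_variance(frame, ["glucose_t", "lactate_t", "pyruvate_t",
                               "glycerol_t"])
for k, v in iv.r2.items():
    print(f"identity r2 {k}: {v:.2f}")
print("lactate adjacent-hour r:",
      round(acf(frame, "lactate_t", 1, pooling="per_patient")["r"].iloc[1], 2))

fit = fit_reml(frame, "icp_hour", n_starts=2)
print(f"REML rho(1)={fit.rho1:.3f}  sigma_b={fit.sigma_b:.2f}  sigma={fit.sigma:.2f}")
```

prints

```
complete hourly rows: 1788
identity r2 glucose_t: 0.53
identity r2 lactate_t: 0.76
identity r2 pyruvate_t: 0.77
identity r2 glycerol_t: 0.66
lactate adjacent-hour r: 0.8
REML rho(1)=-0.028  sigma_b=4.21  sigma=1.08
```

Read: subject identity alone explains 53–77% of marker variance and
adjacent MD hours correlate at ~0.8 within patients — the markers are
dominated by slow, patient-specific processes — while the mixed model's
between-patient ICP spread (σ_b ≈ 4.2 mmHg) dwarfs anything the markers
explain, and its residual adjacent-hour correlation ρ(1) is what remains
of ICP dynamics once patient identity is absorbed.

The same pipeline is scriptable from the shell:

```sh
mdicp simulate --out cohort --seed 7 --n-patients 8
mdicp preprocess --in cohort --out aligned.csv
mdicp correlogram --in aligned.csv --pair lg_ratio:icp_hour --perms 500 --seed 1
mdicp mixedfit --in aligned.csv --response icp_hour
mdicp rbfcv --in aligned.csv --response icp_hour --nodes 2,4 --seed 2
mdicp outcome --in aligned.csv --gos cohort/patients.csv
```

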