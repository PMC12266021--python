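# inavarmeta

Meta-analysis toolkit for reported midpoints of activation and inactivation
of the cardiac fast sodium current (I_Na, Nav1.5 / *SCN5A*).

Published whole-cell patch-clamp experiments characterize I_Na voltage
dependence with two numbers per gating process: the midpoint of activation
V_a and the midpoint of inactivation V_i, each reported as a mean over
cells (μ_a, μ_i) with a spread (σ or SEM) and a cell count (n_a, n_i).
Across laboratories these reported means differ far more than the
within-experiment cell-to-cell spread would suggest, and the paired means
move together. This package is for electrophysiologists, modellers, and
meta-analysts who need to quantify that structure: how much
between-experiment variability there is, how much of it is *correlated*
(shifting both midpoints equally, as an uncorrected liquid junction
potential would) versus *uncorrelated*, and whether reported experimental
factors (holding potentials, slope factors, peak-current voltage,
solutions) predict the midpoints.

## The model

Steady-state gating follows two-state Boltzmann curves. Peak currents in
the standard step protocols are

    I_peak,a(V_test) = g_max (V_test − E) / (1 + exp((V_a − V_test)/k_a)),   k_a > 0
    I_peak,i(V_pre)  = I_max / (1 + exp((V_pre − V_i)/k_i)),                 k_i < 0

with E the sodium reversal potential (Nernst). Midpoints and slope factors
are obtained by nonlinear least squares, exactly as in the surveyed
experiments (`inavarmeta.boltzmann`).

At the meta-analysis level each experiment e is modelled as

    μ_a,e = β_a + c_e + u_a,e + ε_a,e ,   μ_i,e = β_i + c_e + u_i,e + ε_i,e

where c_e ~ N(0, τ_corr²) is a shared shift affecting both midpoints
equally, u_·,e ~ N(0, τ_unc²) are midpoint-specific shifts, and ε is the
sampling error of a mean over n cells with within-experiment SD σ. The
moment identities Cov(μ_a, μ_i) = τ_corr² and Var(μ_x) = τ_corr² + τ_unc,x²
+ E[σ_x²/n_x] yield a method-of-moments estimator of the components
(`inavarmeta.meta.estimate_components`, bootstrap BCa confidence
intervals). The same structure is visualized by decomposing each paired
mean's displacement from the mean-of-means into components along and
perpendicular to the unweighted OLS best-fit line.

A synthetic-cohort generator (`inavarmeta.cohort`) draws experiments from
this hierarchy, and a mechanistic simulator pushes virtual cells through
full voltage-step protocols with liquid-junction-potential, series-
resistance, drift, and temperature artifacts, so artifact signatures in the
fitted midpoints emerge from circuit physics.

## Worked example

```python
from inavarmeta import MidpointVariability

model = MidpointVariability.simulate(seed=1)   # default: the study conditions
res = model.fit(seed=1)
print(res.summary())
```

```
Midpoint variability meta-analysis
==========================================================
Experiments: 172  (both midpoints: 150, activation only: 7, inactivation only: 15)
----------------------------------------------------------
Activation (V_a)
  mean midpoints mu_a: median   -40.1 mV, range 50.4 mV, 5-95% range 32.6 mV
  within-experiment SD sigma_a: median 3.8 mV (typical 90% cell range 12.5 mV)
  cell counts n_a: median 12, range [3, 81]
----------------------------------------------------------
Inactivation (V_i)
  mean midpoints mu_i: median   -81.2 mV, range 51.1 mV, 5-95% range 29.7 mV
  within-experiment SD sigma_i: median 3.6 mV (typical 90% cell range 11.8 mV)
  cell counts n_i: median 10, range [3, 74]
----------------------------------------------------------
Paired regression (mu_i on mu_a, unweighted OLS)
  slope 0.76 mV/mV (95% CI 0.68 to 0.85), intercept -51.6 mV
  Pearson r = 0.82, r^2 = 0.67, n = 150
  slope-1 line: intercept -42.2 mV (slope 1 rejected at 95%)
  decomposition (ols axis): SD along line 12.8 mV, perpendicular 4.2 mV
----------------------------------------------------------
Variance components (method of moments, bootstrap 95% CI)
  tau_corr (shared shift)   8.61 mV  (7.59 to 9.73)
  tau_unc_a                 4.63 mV  (3.56 to 5.79)
  tau_unc_i                 2.84 mV  (0.00 to 4.22)
```

Reading this: the cohort of 172 simulated experiments reproduces the
configured baselines (medians near −40 and −81 mV) and within-experiment
spreads (medians near 4.0 and 3.6 mV, i.e. ~13 and ~12 mV 90% cell
ranges). The 150 paired means correlate strongly (r = 0.82), and the
component estimator attributes most of the between-experiment variance to
the shared shift (τ_corr ≈ 8.6 mV vs τ_unc ≈ 3–5 mV) — recovering the
generating values τ_corr = 8, τ_unc = 4 within its intervals. The SD along
the best-fit line (12.8 mV) dwarfs the perpendicular SD (4.2 mV): the
correlated component dominates.

The same analysis runs on real data: put an experiment table in the
documented CSV schema (see `inavarmeta.dataset.COLUMNS`) and use
`MidpointVariability.from_csv(path)`, or the CLI:

```sh
inavarmeta simulate --seed 1 --out cohort.csv --truth truth.csv
inavarmeta analyze --data cohort.csv --out report/ --seed 1
inavarmeta fit-curves points.csv --branch activation --e-rev 40
```

`analyze` writes `summary.json` (all statistics, figure-style keys),
`decomposition.csv` (per-experiment components and √(n_a+n_i)), and
`report.md`.

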