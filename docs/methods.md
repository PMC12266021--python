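# Methods

## Scope

The package analyses experiment-level summaries of I_Na voltage
dependence: per-experiment mean midpoints of activation (μ_a) and
inactivation (μ_i), their within-experiment SDs (σ_a, σ_i), cell counts
(n_a, n_i), and reported experimental metadata. It does not model channel
kinetics (time courses, recovery, late current), does not parse source
publications, and does not impute missing metadata.

## Gating model and curve fitting

Steady-state activation and availability are two-state Boltzmann curves
f(V) = 1/(1 + exp((V_half − V)/k)), with k > 0 for activation and k < 0
for inactivation; smaller |k| means steeper voltage dependence. Peak
currents are g_max (V − E) f_a(V) for the activation protocol and
I_max f_i(V_pre) for the inactivation protocol. The typographic ambiguity
of rendered sigmoid formulas is resolved by monotonicity: with these sign
conventions the activation curve increases and the availability curve
decreases with voltage, which is physiologically unambiguous.

Fits use Levenberg–Marquardt nonlinear least squares
(`scipy.optimize.least_squares`, ftol = xtol = gtol = 1e−14, ≤ 500·(p+1)
function evaluations). Initial guesses come from the data: V_half from
the voltage of half-maximal normalized conductance (linear interpolation),
k from the 25–75% span divided by 2·ln 3, g_max/I_max from the extreme
conductance/current. Points at the reversal potential carry no conductance
information and are excluded from the guess construction (not from the
fit). At least five points are required; data that do not bracket the
midpoint trigger an ill-conditioning warning; a fitted slope factor with
the wrong sign for the requested branch is flagged (`branch_violation`)
and warned about, never silently corrected. On noiseless model-generated
data the generating parameters are recovered to below 1e−6 mV.

The reversal potential is supplied by the caller, either measured or from
the Nernst equation (z = 1, physical constants from `scipy.constants`);
the temperature default is 22 °C, the midpoint of the 18–26 °C
room-temperature bracket common to the surveyed experiments. The
peak-current voltage V_peak is located on a grid (default −80…+40 mV in
5 mV steps, a typical protocol resolution), ties breaking to the more
hyperpolarized voltage, with a warning when the optimum sits on the grid
edge.

Units are consistent rather than fixed: voltages in mV throughout;
conductance in nS gives currents in pA, conductance in µS gives nA. The
mechanistic simulator works in nA (g_max in µS) because nA·MΩ = mV makes
the series-resistance product dimensionally direct.

## Hierarchical cohort model

Each experiment e receives a shared shift c_e ~ N(0, τ_corr²) added to
both midpoints, independent shifts u_a,e ~ N(0, τ_unc_a²) and
u_i,e ~ N(0, τ_unc_i²), and each cell an independent deviation
N(0, σ_within²). Reported values are the sample mean, sample SD (ddof 1),
and count over the experiment's cells. A Student-t option
(variance-matched, default 4 df) exists for robustness checks; Normal is
the default since the data provide no distributional information about
the between-experiment shifts.

Defaults describe the surveyed literature: 172 experiments split
150/7/15 (both / activation-only / inactivation-only), baselines
−39.9 / −81.2 mV (the reported medians), σ_within 4.0 / 3.6 mV (reported
median SDs), and cell counts log-normal with median 10 restricted to
[3, 88] (the reported count summary). The log-normal spread parameter is
set so the configured maximum falls at the 99th percentile of the
unrounded law (σ_log = ln(max/median)/2.3263), which reproduces the heavy
right tail of published cell counts with no extra parameter; the rejection
step skews the realized median slightly above 10 for the activation side
in some draws. τ_corr = 8 mV and τ_unc = 4 mV are calibration choices:
by the moment identity r = τ_corr²/√(∏(τ_corr² + τ_unc² + E[σ²/n])) they
imply a population pair correlation of ≈ 0.78, matching the reported
correlation of the paired means. Counts for the two sides are drawn
independently (in reality they are often equal — a feature not emulated,
and irrelevant to the moment structure). Metadata (cell type, α-subunit,
β1, LJP status) are drawn independently of the shifts with frequencies
resembling the literature, so subgroup views on synthetic cohorts are
null by construction.

Randomness is split one stream per experiment via
`SeedSequence([seed, index])`, so cohorts are bit-reproducible and stable
under partial regeneration.

What passing tests on these cohorts show — and do not show: they verify
the estimators recover known generating structure of this form; they
cannot show that real between-experiment variability is Normal, that real
metadata are independent of the shifts, or that the correlated component
in real data is an artifact rather than biology.

## Mechanistic artifact simulator

Each simulated cell runs full step protocols. The true membrane voltage
at a commanded step is v_m = v_cmd − ljp + drift·t + temp_coeff·ΔT, after
which the residual series resistance R_s(1 − compensation) is resolved
self-consistently: v_m = v_adj − I(v_m)·R_s,eff, solved by damped
fixed-point iteration (damping 0.3, step threshold three decades below
the 1e−6 mV tolerance so the step size bounds the true error, ≤ 200
iterations; verified against bisection). Per-cell midpoints and slopes
are then recovered by refitting on the commanded voltages — the analysis
a lab would run.

Sign conventions, fixed and surfaced because the literature statements
conflict:

* **LJP.** With ljp_mV > 0 the membrane sits more negative than
  commanded, so on the command axis both fitted midpoints shift by
  exactly +ljp_mV — *equal* shifts, the correlated-artifact signature
  that matters for the decomposition. The default refit uses the
  apparent (command-axis) reversal potential, as when E is measured from
  the same recording; this makes the equality exact. A `nominal` option
  uses the true E (as when computed from Nernst) and leaves a small
  residual driving-force mismatch.
* **Series resistance.** Inward current across R_s depolarizes the
  membrane relative to the command; the regenerative interaction shifts
  the fitted V_a toward hyperpolarized values and reduces k_a (steeper
  curve) on the command axis. Published descriptions of this effect
  disagree in direction; the simulator follows the self-consistent
  circuit algebra, which produces the leftward (hyperpolarizing) shift
  with increased steepness.
* **Inactivation protocol.** The preconditioning step carries the static
  offsets only: the preconditioning current is at steady state (channels
  inactivated), so its R_s error is negligible and is not modelled; the
  fixed test step scales all points equally and cancels in the fit.

Not modelled at all (no quantitative basis to do so): capacitance
transients, space clamp, endogenous currents, redox drift, culture and
passage effects.

## Meta-analysis stages

* **Summaries** (means, SDs, counts): count, median, min/max, range, and
  the empirical 5th-to-95th percentile range using linear interpolation
  between order statistics (the most common quantile convention;
  documented because the choice moves the range by tenths of mV).
  The "typical 90% cell range" is 2·1.6449·σ (z at four decimals).
* **Paired regression**: unweighted OLS of μ_i on μ_a via statsmodels;
  95% slope CI from the t-distribution with n−2 df; Pearson r and
  r² = r². The fixed-slope-1 line has intercept mean(μ_i − μ_a)
  (least squares under the constraint), reported with whether slope 1
  falls inside the free fit's CI.
* **Decomposition**: displacements from the unweighted mean-of-means
  projected onto the OLS best-fit direction (1, slope)/√(1+slope²) and
  its perpendicular; pc1 positive toward depolarized μ_a, pc2 positive
  toward depolarized μ_i. The OLS direction is used (rather than the PCA
  major axis, which differs slightly) because the decomposition is
  defined relative to the best-fit line; `axis="pca"` exposes the
  eigenvector alternative. Experiments lacking either midpoint are
  excluded, as is their experiment size n_a + n_i from the funnel table.
* **Variance components**: τ_corr² = sample Cov(μ_a, μ_i);
  τ_unc,x² = Var(μ_x) − Cov − mean(σ_x²/n_x); negative estimates
  truncated at zero and flagged. 95% CIs from a seeded nonparametric
  bootstrap over experiments (default 2000 replicates) using the
  bias-corrected accelerated (BCa) construction on the τ (mV) scale:
  variance-type statistics are right-skewed at cohort sizes near 150 and
  plain percentile intervals sit systematically low; the acceleration
  constant uses closed-form leave-one-out updates of the covariance
  moments, keeping the jackknife O(n). Degenerate (constant) bootstrap
  distributions collapse the interval to the point estimate.
* **Factor regressions**: univariate complete-case OLS with the
  complete-case n reported next to r²; no multiple-testing adjustment —
  outputs are descriptive/exploratory, and factor relationships may
  reflect shared design inheritance between studies rather than
  causation. LJP status, being categorical, gets per-category summaries
  instead.

## Pipeline and reproducibility

`report.run_pipeline` runs all stages in fixed order, records skipped
stages with reasons (e.g. fewer than 3 paired records for regression,
fewer than 10 for components), and writes `summary.json` (floats at 6
significant digits), `decomposition.csv`, `report.md`, and a MANIFEST.
The single bootstrap seed is the only stochastic input, so identical
inputs and seed give byte-identical `summary.json`. A checked-in contract
(`report_schema.json`) lists required keys and stage coverage;
`validate_summary` checks a summary against it.

## Problem sizes

Default analyses use the 172-experiment cohort. Asymptotic checks of the
moment estimator use cohorts of 150 / 1 500 / 15 000 experiments;
closed-form-versus-simulation checks use 2 000–5 000 experiments;
coverage of the component CIs is assessed over 100 seeded replications of
150-experiment cohorts at 2 000 bootstrap replicates. Mechanistic
simulations use 3–8 cells with 25-point activation and 14-point
inactivation grids, which suffice because per-cell fits are exact at zero
noise.

## Known limitations

* The moment estimator assumes the shared shift enters both midpoints
  with coefficient exactly 1; a correlated component with a different
  gain would load partly on τ_unc.
* Reported σ values are taken at face value; publication rounding of
  SEMs propagates into the resolved SDs.
* The generator draws each experiment as its own study; within-study
  correlation of repeated control experiments is not emulated, so
  study-level subgroup views on synthetic data are uninformative beyond
  the range bound.
* The LJP magnitude, not its solution-composition origin, is modelled;
  computing junction potentials from solutions is out of scope.
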