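"""Model/Results interface over the midpoint meta-analysis.

:class:`MidpointVariability` is constructed from an experiment table (a
validated DataFrame in the :mod:`~inavarmeta.dataset` schema, a CSV file, or
a simulated cohort); ``fit()`` runs the full analysis and returns a
:class:`MidpointVariabilityResults` carrying the summaries, the paired
regression with its slope CI, the along/perpendicular decomposition, and
the method-of-moments variance components with bootstrap CIs. Plotting and
factor/subgroup views hang off the results object.

Example
-------
>>> from inavarmeta import MidpointVariability
>>> model = MidpointVariability.simulate(seed=1)
>>> res = model.fit(seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dataset, meta
from .cohort import CohortConfig, generate_cohort

__all__ = ["MidpointVariability", "MidpointVariabilityResults"]


class MidpointVariability:
    """Hierarchical variability model of reported I_Na midpoints.

    Parameters
    ----------
    data
        Experiment table in the package schema. Validated (strictness per
        ``strict``) and SD/SEM-resolved on construction.
    strict
        If true (default), any invariant violation raises; otherwise
        offending rows are dropped with a logged warning.
    """

    def __init__(self, data: pd.DataFrame, strict: bool = True):
        self.data = dataset.resolve_sd(dataset.validate(data, strict=strict))
        self.truth: pd.DataFrame | None = None

    @classmethod
    def from_csv(cls, path, strict: bool = True) -> "MidpointVariability":
        """Build the model from an experiment-table CSV."""
        df = dataset.load_dataset(path, strict=strict)
        return cls(df, strict=strict)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, strict: bool = True):
        return cls(df, strict=strict)

    @classmethod
    def simulate(
        cls, config: CohortConfig | None = None, seed: int | None = None
    ) -> "MidpointVariability":
        """Build the model from a synthetic cohort.

        The generator's latent truth table is kept on ``model.truth`` for
        parameter-recovery checks; it never enters the analysis itself.
        """
        config = config or CohortConfig()
        if seed is not None:
            config.seed = seed
        records, truth = generate_cohort(config)
        model = cls(records, strict=False)
        model.truth = truth
        model.config = config
        return model

    def fit(
        self,
        bootstrap: int = 2000,
        seed: int = 0,
        axis: str = "ols",
    ) -> "MidpointVariabilityResults":
        """Run the full analysis.

        Parameters
        ----------
        bootstrap
            Bootstrap replicates for the variance-component CIs.
        seed
            Seed for the bootstrap resampling (the only stochastic stage).
        axis
            ``"ols"`` (best-fit line, default) or ``"pca"`` (covariance
            eigenvector) for the decomposition axis.
        """
        df = self.data
        counts = dataset.midpoint_counts(df)
        summaries = {}
        for side in ("activation", "inactivation"):
            if df[f"mu_{'a' if side == 'activation' else 'i'}"].notna().any():
                summaries[side] = {
                    "means": meta.summarize_means(df, side),
                    "sds": meta.summarize_sds(df, side),
                    "counts": meta.summarize_counts(df, side),
                }
        regression = fixed_slope = decomposition = components = None
        skipped: dict[str, str] = {}
        if counts["both"] >= 3:
            regression = meta.paired_regression(df)
            fixed_slope = meta.fixed_slope_regression(df, slope=1.0)
            decomposition = meta.decompose(df, axis=axis)
        else:
            skipped["regression"] = skipped["decomposition"] = (
                f"only {counts['both']} paired records (< 3)"
            )
        if counts["both"] >= 10:
            components = meta.estimate_components(
                df, n_bootstrap=bootstrap, seed=seed
            )
        else:
            skipped["components"] = (
                f"only {counts['both']} paired records (< 10)"
            )
        return MidpointVariabilityResults(
            model=self,
            counts=counts,
            summaries=summaries,
            regression=regression,
            fixed_slope=fixed_slope,
            decomposition=decomposition,
            components=components,
            skipped=skipped,
            seed=seed,
        )


@dataclass
class MidpointVariabilityResults:
    """Fitted results of :class:`MidpointVariability`."""

    model: MidpointVariability
    counts: dict
    summaries: dict
    regression: meta.RegressionResult | None
    fixed_slope: meta.FixedSlopeResult | None
    decomposition: meta.Decomposition | None
    components: meta.ComponentEstimates | None
    skipped: dict = field(default_factory=dict)
    seed: int = 0

    # -- views -----------------------------------------------------------

    def funnel(self) -> pd.DataFrame:
        if self.decomposition is None:
            raise ValueError("decomposition was skipped: "
                             + self.skipped.get("decomposition", ""))
        return meta.funnel_table(self.decomposition)

    def subgroup(self, key: str):
        """Per-group summaries for a metadata partition (e.g. 'beta1')."""
        return meta.subgroup_summary(self.model.data, key)

    def factor(self, factor: str, response: str):
        """Factor-vs-midpoint regression (or LJP-status group summary)."""
        return meta.factor_regression(self.model.data, factor, response)

    # -- output ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table of the headline statistics."""
        lines = []
        add = lines.append
        c = self.counts
        add("Midpoint variability meta-analysis")
        add("=" * 58)
        add(f"Experiments: {c['total']}  (both midpoints: {c['both']}, "
            f"activation only: {c['activation_only']}, "
            f"inactivation only: {c['inactivation_only']})")
        for side, tag in (("activation", "a"), ("inactivation", "i")):
            if side not in self.summaries:
                continue
            s = self.summaries[side]
            add("-" * 58)
            add(f"{side.capitalize()} (V_{tag})")
            m, sd, n = s["means"], s["sds"], s["counts"]
            add(f"  mean midpoints mu_{tag}: median {m.median:7.1f} mV, "
                f"range {m.range:.1f} mV, 5-95% range {m.p5_p95_range:.1f} mV")
            add(f"  within-experiment SD sigma_{tag}: median {sd.median:.1f} mV "
                f"(typical 90% cell range "
                f"{meta.normal_90_width(sd.median):.1f} mV)")
            add(f"  cell counts n_{tag}: median {n.median:.0f}, "
                f"range [{n.min:.0f}, {n.max:.0f}]")
        if self.regression is not None:
            r = self.regression
            add("-" * 58)
            add("Paired regression (mu_i on mu_a, unweighted OLS)")
            add(f"  slope {r.slope:.2f} mV/mV "
                f"(95% CI {r.slope_ci_low:.2f} to {r.slope_ci_high:.2f}), "
                f"intercept {r.intercept:.1f} mV")
            add(f"  Pearson r = {r.pearson_r:.2f}, r^2 = {r.r_squared:.2f}, "
                f"n = {r.n_points}")
            fs = self.fixed_slope
            verdict = "not rejected" if fs.slope_in_free_ci else "rejected"
            add(f"  slope-1 line: intercept {fs.intercept:.1f} mV "
                f"(slope 1 {verdict} at 95%)")
        if self.decomposition is not None:
            d = self.decomposition
            add(f"  decomposition ({d.axis_kind} axis): SD along line "
                f"{np.std(d.pc1, ddof=1):.1f} mV, perpendicular "
                f"{np.std(d.pc2, ddof=1):.1f} mV")
        if self.components is not None:
            e = self.components
            add("-" * 58)
            add("Variance components (method of moments, bootstrap 95% CI)")
            for name, val in (("tau_corr (shared shift)", e.tau_corr),
                              ("tau_unc_a", e.tau_unc_a),
                              ("tau_unc_i", e.tau_unc_i)):
                key = name.split(" ")[0]
                lo, hi = e.ci[key]
                flag = "  [truncated]" if e.truncated[key] else ""
                add(f"  {name:24s} {val:5.2f} mV  ({lo:.2f} to {hi:.2f}){flag}")
        for stage, reason in self.skipped.items():
            add(f"  [skipped] {stage}: {reason}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready digest of all fitted quantities."""
        out: dict = {"counts": dict(self.counts), "skipped": dict(self.skipped)}
        for side in self.summaries:
            for what, s in self.summaries[side].items():
                out[f"{side}.{what}"] = s.to_dict()
        if self.regression is not None:
            out["regression"] = self.regression.to_dict()
            out["fixed_slope"] = {
                "intercept": self.fixed_slope.intercept,
                "slope_in_free_ci": self.fixed_slope.slope_in_free_ci,
            }
        if self.decomposition is not None:
            d = self.decomposition
            out["decomposition"] = {
                "center_mu_a": d.center[0],
                "center_mu_i": d.center[1],
                "axis": list(d.axis),
                "axis_kind": d.axis_kind,
                "pc1_sd": float(np.std(d.pc1, ddof=1)),
                "pc2_sd": float(np.std(d.pc2, ddof=1)),
            }
        if self.components is not None:
            out["components"] = self.components.to_dict()
        return out

    # -- plotting --------------------------------------------------------

    def plot_pairs(self, ax=None):
        """Scatter of (mu_a, mu_i) with the free and slope-1 fits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        paired = df[df["mu_a"].notna() & df["mu_i"].notna()]
        ax.plot(paired["mu_a"], paired["mu_i"], "o", ms=4, alpha=0.6)
        if self.regression is not None:
            xs = np.linspace(paired["mu_a"].min(), paired["mu_a"].max(), 50)
            r = self.regression
            ax.plot(xs, r.intercept + r.slope * xs, "-", label="best fit")
            fs = self.fixed_slope
            ax.plot(xs, fs.intercept + xs, "--", label="slope 1")
            ax.legend()
        ax.set_xlabel(r"$\mu_a$ (mV)")
        ax.set_ylabel(r"$\mu_i$ (mV)")
        return ax

    def plot_funnel(self, component: str = "pc1", ax=None):
        """sqrt(experiment size) against a decomposition component."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.funnel()
        ax.plot(tab[component], tab["sqrt_size"], "o", ms=4, alpha=0.6)
        ax.set_xlabel(f"{component} (mV)")
        ax.set_ylabel(r"$\sqrt{n_a + n_i}$")
        return ax
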