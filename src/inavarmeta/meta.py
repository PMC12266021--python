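"""Analysis of reported midpoints: summaries, paired regression,
correlated/uncorrelated decomposition, funnel statistics, variance-component
estimation, subgroup views, and experimental-factor correlations.

The central objects are the per-experiment mean midpoints (mu_a, mu_i). The
between-experiment scatter of the paired means is split into a component
along the unweighted OLS best-fit line (the correlated part, affecting both
midpoints almost equally — e.g. an uncorrected liquid junction potential)
and a component perpendicular to it (the uncorrelated part). A
method-of-moments estimator maps the same idea onto explicit variance
components: Cov(mu_a, mu_i) estimates tau_corr^2 (shared shift variance),
and each Var(mu_x) minus that covariance minus the sampling contribution
mean(sigma_x^2 / n_x) estimates the midpoint-specific tau_unc_x^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import dataset
from .exceptions import DatasetError, SchemaError, TruncationWarning

__all__ = [
    "SummaryStats",
    "RegressionResult",
    "FixedSlopeResult",
    "Decomposition",
    "ComponentEstimates",
    "SubgroupSummary",
    "summarize_means",
    "summarize_sds",
    "summarize_counts",
    "normal_90_width",
    "paired_regression",
    "fixed_slope_regression",
    "decompose",
    "funnel_table",
    "estimate_components",
    "subgroup_summary",
    "factor_regression",
    "Z_90",
]

#: z-score of the 95th normal percentile (4-decimal convention), so that
#: mu +/- Z_90 * sigma spans the central 90% of a normal distribution.
Z_90 = 1.6449


@dataclass
class SummaryStats:
    """Five-number-style summary of a set of values (means, SDs, or counts)."""

    count: int
    median: float
    min: float
    max: float
    range: float
    p5_p95_range: float
    units: str = "mV"

    @classmethod
    def from_values(cls, values, units: str = "mV") -> "SummaryStats":
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if len(values) == 0:
            raise DatasetError("no values to summarize")
        # empirical quantiles with linear interpolation between order statistics
        p5, p95 = np.percentile(values, [5, 95])
        return cls(
            count=int(len(values)),
            median=float(np.median(values)),
            min=float(values.min()),
            max=float(values.max()),
            range=float(values.max() - values.min()),
            p5_p95_range=float(p95 - p5),
            units=units,
        )

    def to_dict(self) -> dict:
        return {
            "count": self.count, "median": self.median, "min": self.min,
            "max": self.max, "range": self.range,
            "p5_p95_range": self.p5_p95_range, "units": self.units,
        }


@dataclass
class RegressionResult:
    """Unweighted OLS fit with a t-based 95% CI on the slope."""

    intercept: float
    slope: float
    slope_ci_low: float
    slope_ci_high: float
    pearson_r: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept, "slope": self.slope,
            "slope_ci_low": self.slope_ci_low,
            "slope_ci_high": self.slope_ci_high,
            "pearson_r": self.pearson_r, "r_squared": self.r_squared,
            "n": self.n_points,
        }


@dataclass
class FixedSlopeResult:
    """Least-squares intercept under a fixed slope, plus the CI check."""

    slope: float
    intercept: float
    slope_in_free_ci: bool
    free_fit: RegressionResult


@dataclass
class Decomposition:
    """Per-experiment components along/perpendicular to the best-fit axis.

    ``pc1`` is the displacement (mV) from the mean-of-means along the axis
    (positive toward depolarized mu_a); ``pc2`` the perpendicular component
    (positive toward depolarized mu_i at fixed pc1). ``size`` is
    n_a + n_i, the experiment size.
    """

    center: tuple[float, float]
    axis: np.ndarray
    experiment_id: list[str]
    pc1: np.ndarray
    pc2: np.ndarray
    size: np.ndarray
    axis_kind: str = "ols"
    regression: RegressionResult | None = None

    @property
    def sqrt_size(self) -> np.ndarray:
        return np.sqrt(self.size)


@dataclass
class ComponentEstimates:
    """Method-of-moments variance components with bootstrap 95% CIs (mV)."""

    tau_corr: float
    tau_unc_a: float
    tau_unc_i: float
    ci: dict = field(default_factory=dict)
    truncated: dict = field(default_factory=dict)
    n_experiments: int = 0
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "tau_corr": self.tau_corr,
            "tau_unc_a": self.tau_unc_a,
            "tau_unc_i": self.tau_unc_i,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "truncated": dict(self.truncated),
            "n_experiments": self.n_experiments,
            "n_bootstrap": self.n_bootstrap,
        }


@dataclass
class SubgroupSummary:
    """Per-group statistics produced by :func:`subgroup_summary`."""

    label: str
    n: int
    activation: SummaryStats | None
    inactivation: SummaryStats | None
    regression: RegressionResult | None


def _side_column(side: str, what: str) -> str:
    side = {"activation": "a", "inactivation": "i", "a": "a", "i": "i"}.get(side)
    if side is None:
        raise SchemaError("side must be 'activation' or 'inactivation'")
    return f"{what}_{side}"


def summarize_means(df: pd.DataFrame, side: str) -> SummaryStats:
    """Summary of the reported mean midpoints on one side (mV)."""
    return SummaryStats.from_values(df[_side_column(side, "mu")], units="mV")


def summarize_sds(df: pd.DataFrame, side: str) -> SummaryStats:
    """Summary of the resolved within-experiment sample SDs (mV)."""
    col = _side_column(side, "sd")
    values = df[col]
    if values.isna().all():
        raise DatasetError(
            f"no {col} values; run dataset.resolve_sd first if only SEMs present"
        )
    return SummaryStats.from_values(values, units="mV")


def summarize_counts(df: pd.DataFrame, side: str) -> SummaryStats:
    """Summary of the per-experiment cell counts."""
    return SummaryStats.from_values(df[_side_column(side, "n")], units="cells")


def normal_90_width(sigma: float) -> float:
    """Width of the central 90% of a normal with SD ``sigma``: 2 * 1.6449 * sigma.

    This is the '5th-to-95th percentile range' (approximately mu +/- 1.64
    sigma) used to visualize where individual-cell midpoints likely fell.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 2.0 * Z_90 * sigma


def _paired(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["mu_a"].notna() & df["mu_i"].notna()]


def paired_regression(df: pd.DataFrame) -> RegressionResult:
    """Unweighted OLS of mu_i on mu_a over experiments reporting both.

    The 95% CI on the slope is the two-sided t-interval with n - 2 degrees
    of freedom; Pearson r and r^2 = r^2 are reported alongside.
    """
    paired = _paired(df)
    if len(paired) < 3:
        raise DatasetError(f"need >= 3 paired records, got {len(paired)}")
    x = paired["mu_a"].to_numpy(float)
    y = paired["mu_i"].to_numpy(float)
    if np.ptp(x) == 0:
        raise DatasetError("zero variance in mu_a; regression is singular")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        slope_ci_low=float(ci[1, 0]),
        slope_ci_high=float(ci[1, 1]),
        pearson_r=r,
        r_squared=r * r,
        n_points=len(paired),
    )


def fixed_slope_regression(df: pd.DataFrame, slope: float = 1.0) -> FixedSlopeResult:
    """Least-squares line with the slope held fixed (default 1 mV/mV).

    The intercept is mean(mu_i - slope * mu_a); the result also records
    whether the fixed slope falls inside the free fit's 95% CI (i.e.
    whether it can be statistically rejected).
    """
    paired = _paired(df)
    if len(paired) < 2:
        raise DatasetError("need >= 2 paired records")
    intercept = float((paired["mu_i"] - slope * paired["mu_a"]).mean())
    free = paired_regression(df)
    in_ci = bool(free.slope_ci_low <= slope <= free.slope_ci_high)
    return FixedSlopeResult(
        slope=slope, intercept=intercept, slope_in_free_ci=in_ci, free_fit=free
    )


def decompose(df: pd.DataFrame, axis: str = "ols") -> Decomposition:
    """Split each paired experiment's displacement from the mean-of-means
    into components along and perpendicular to the best-fit axis.

    ``axis="ols"`` (default) uses the unit vector (1, slope)/sqrt(1 +
    slope^2) of the unweighted OLS line — the reading used throughout the
    analysis; ``axis="pca"`` uses the leading covariance eigenvector (the
    textbook principal axis) instead. Experiments lacking either midpoint
    are excluded. The two components are an orthonormal coordinate pair, so
    pc1^2 + pc2^2 reproduces each point's squared distance to the center.
    """
    paired = _paired(df)
    reg = paired_regression(df)
    x = paired["mu_a"].to_numpy(float)
    y = paired["mu_i"].to_numpy(float)
    center = (float(x.mean()), float(y.mean()))
    if axis == "ols":
        u = np.array([1.0, reg.slope])
    elif axis == "pca":
        cov = np.cov(np.vstack([x, y]), ddof=1)
        eigval, eigvec = np.linalg.eigh(cov)
        u = eigvec[:, int(np.argmax(eigval))]
    else:
        raise SchemaError("axis must be 'ols' or 'pca'")
    u = u / np.linalg.norm(u)
    if u[0] < 0:  # pc1 positive toward depolarized mu_a
        u = -u
    perp = np.array([-u[1], u[0]])  # pc2 positive toward depolarized mu_i
    dx, dy = x - center[0], y - center[1]
    size = (paired["n_a"].to_numpy(float) + paired["n_i"].to_numpy(float))
    return Decomposition(
        center=center,
        axis=u,
        experiment_id=list(paired["experiment_id"].astype(str)),
        pc1=dx * u[0] + dy * u[1],
        pc2=dx * perp[0] + dy * perp[1],
        size=size,
        axis_kind=axis,
        regression=reg,
    )


def funnel_table(dec: Decomposition) -> pd.DataFrame:
    """Funnel-plot table: per-experiment pc1, pc2 and sqrt(n_a + n_i)."""
    return pd.DataFrame({
        "experiment_id": dec.experiment_id,
        "pc1": dec.pc1,
        "pc2": dec.pc2,
        "size": dec.size,
        "sqrt_size": dec.sqrt_size,
    })


def estimate_components(
    df: pd.DataFrame,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> ComponentEstimates:
    """Method-of-moments estimates of the variance components, with CIs.

    tau_corr^2 is estimated by the sample covariance of (mu_a, mu_i);
    tau_unc_x^2 by Var(mu_x) - Cov - mean(sigma_x^2 / n_x), truncated at
    zero (and flagged) when negative. 95% CIs come from a nonparametric
    bootstrap over experiments using the bias-corrected accelerated (BCa)
    construction — variance-type statistics are right-skewed at these
    cohort sizes and plain percentile intervals sit systematically low for
    them. Requires at least 10 paired records with resolved SDs and counts.
    """
    paired = _paired(df)
    paired = paired[
        paired["sd_a"].notna() & paired["sd_i"].notna()
        & paired["n_a"].notna() & paired["n_i"].notna()
    ]
    n = len(paired)
    if n < 10:
        raise DatasetError(f"need >= 10 complete paired records, got {n}")
    x = paired["mu_a"].to_numpy(float)
    y = paired["mu_i"].to_numpy(float)
    se2_a = (paired["sd_a"].to_numpy(float) ** 2) / paired["n_a"].to_numpy(float)
    se2_i = (paired["sd_i"].to_numpy(float) ** 2) / paired["n_i"].to_numpy(float)

    def moments(xs, ys, sa, si):
        cov = np.sum(
            (xs - xs.mean(-1, keepdims=True)) * (ys - ys.mean(-1, keepdims=True)),
            axis=-1,
        ) / (xs.shape[-1] - 1)
        var_a = np.var(xs, axis=-1, ddof=1)
        var_i = np.var(ys, axis=-1, ddof=1)
        t_corr2 = cov
        t_unc_a2 = var_a - cov - sa.mean(-1)
        t_unc_i2 = var_i - cov - si.mean(-1)
        return t_corr2, t_unc_a2, t_unc_i2

    t_corr2, t_unc_a2, t_unc_i2 = moments(x, y, se2_a, se2_i)
    truncated = {
        "tau_corr": bool(t_corr2 < 0),
        "tau_unc_a": bool(t_unc_a2 < 0),
        "tau_unc_i": bool(t_unc_i2 < 0),
    }
    if any(truncated.values()):
        names = [k for k, v in truncated.items() if v]
        warnings.warn(
            f"negative moment estimates truncated at zero: {names}",
            TruncationWarning,
        )

    def tau(v):
        return np.sqrt(np.clip(v, 0.0, None))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    boots = moments(x[idx], y[idx], se2_a[idx], se2_i[idx])

    # leave-one-out moments in closed form (for the BCa acceleration):
    # removing j changes the centered cross-product sum by
    # n/(n-1) * (x_j - mx)(y_j - my)
    mx, my = x.mean(), y.mean()
    dxj, dyj = x - mx, y - my
    s_xy, s_xx, s_yy = (dxj * dyj).sum(), (dxj**2).sum(), (dyj**2).sum()
    cov_j = (s_xy - n / (n - 1) * dxj * dyj) / (n - 2)
    var_a_j = (s_xx - n / (n - 1) * dxj**2) / (n - 2)
    var_i_j = (s_yy - n / (n - 1) * dyj**2) / (n - 2)
    mse_a_j = (se2_a.sum() - se2_a) / (n - 1)
    mse_i_j = (se2_i.sum() - se2_i) / (n - 1)
    jacks = (
        cov_j,
        var_a_j - cov_j - mse_a_j,
        var_i_j - cov_j - mse_i_j,
    )

    def _bca_ci(theta2_hat, boots2, jacks2, alpha=0.05):
        """Bias-corrected accelerated percentile interval on the tau scale."""
        from scipy.stats import norm

        theta_hat = tau(theta2_hat)
        tb = tau(boots2)
        if np.ptp(tb) == 0:
            return (float(tb[0]), float(tb[0]))
        prop = np.clip(
            np.mean(tb < theta_hat), 1.0 / (len(tb) + 1), len(tb) / (len(tb) + 1)
        )
        z0 = norm.ppf(prop)
        tj = tau(jacks2)
        d = tj.mean() - tj
        denom = (d**2).sum() ** 1.5
        a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0
        z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
        a_lo = norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
        a_hi = norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
        lo, hi = np.percentile(tb, [100 * a_lo, 100 * a_hi])
        return (float(lo), float(hi))

    ci = {
        name: _bca_ci(point2, boots[comp], jacks[comp])
        for comp, (name, point2) in enumerate(
            (("tau_corr", t_corr2), ("tau_unc_a", t_unc_a2),
             ("tau_unc_i", t_unc_i2))
        )
    }
    return ComponentEstimates(
        tau_corr=float(tau(t_corr2)),
        tau_unc_a=float(tau(t_unc_a2)),
        tau_unc_i=float(tau(t_unc_i2)),
        ci=ci,
        truncated=truncated,
        n_experiments=n,
        n_bootstrap=n_bootstrap,
    )


def subgroup_summary(df: pd.DataFrame, key: str) -> dict[str, SubgroupSummary]:
    """Per-group summaries (and regressions where possible) for a partition
    by ``alpha_subunit``, ``beta1``, ``cell_type``, ``study_id``, or any
    other metadata field. Absent values form the ``"unknown"`` group.
    """
    groups = dataset.partition(df, key)
    out: dict[str, SubgroupSummary] = {}
    for label, group in groups.items():
        act = inact = reg = None
        if group["mu_a"].notna().any():
            act = summarize_means(group, "activation")
        if group["mu_i"].notna().any():
            inact = summarize_means(group, "inactivation")
        if len(_paired(group)) >= 3:
            try:
                reg = paired_regression(group)
            except DatasetError:
                reg = None
        out[label] = SubgroupSummary(
            label=label, n=len(group), activation=act,
            inactivation=inact, regression=reg,
        )
    return out


#: Numeric fields usable as factors in :func:`factor_regression`.
NUMERIC_FACTORS = [
    "v_hold_a", "v_hold_i", "k_a", "v_peak", "temperature_C",
    "na_out_mM", "na_in_mM", "ca_in_uM", "cl_out_mM", "cl_in_mM",
    "mu_a", "mu_i",
]


def factor_regression(df: pd.DataFrame, factor: str, response: str):
    """Correlation of a reported experimental factor with a mean midpoint.

    For numeric factors: complete-case univariate OLS of ``response``
    (``mu_a`` or ``mu_i``) on the factor, returning a
    :class:`RegressionResult` (its ``n_points`` is the complete-case
    count — shrinking denominators are reported, not hidden). For the
    categorical ``ljp_status``: per-category :class:`SummaryStats` of the
    responses over the paired experiments.
    """
    if response not in ("mu_a", "mu_i"):
        raise SchemaError("response must be 'mu_a' or 'mu_i'")
    if factor == "ljp_status":
        paired = _paired(df)
        out = {}
        for label, group in dataset.partition(paired, "ljp_status").items():
            out[label] = SummaryStats.from_values(group[response], units="mV")
        return out
    if factor not in NUMERIC_FACTORS:
        raise SchemaError(f"unknown factor {factor!r}")
    cc = df[df[factor].notna() & df[response].notna()]
    if len(cc) < 3:
        raise DatasetError(
            f"need >= 3 complete cases for {factor} vs {response}, got {len(cc)}"
        )
    x = cc[factor].to_numpy(float)
    y = cc[response].to_numpy(float)
    if np.ptp(x) == 0:
        raise DatasetError(f"zero variance in {factor}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        slope_ci_low=float(ci[1, 0]),
        slope_ci_high=float(ci[1, 1]),
        pearson_r=r,
        r_squared=r * r,
        n_points=len(cc),
    )
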