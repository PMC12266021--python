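"""Synthetic cohorts of midpoint experiments.

Two generators live here. The statistical generator
(:func:`generate_cohort`) draws experiments from the hierarchical
variability structure the analysis assumes: each experiment e receives a
shared shift c_e ~ N(0, tau_corr^2) applied to both midpoints (the
correlated between-experiment component), independent shifts
u_a,e ~ N(0, tau_unc_a^2) and u_i,e ~ N(0, tau_unc_i^2) (uncorrelated
components), and each of its cells an independent within-experiment
deviation N(0, sigma_within^2). Reported values are the per-experiment
sample mean, sample SD, and cell count, exactly the six numbers a
publication provides.

The mechanistic generator (:func:`simulate_experiment_mechanistic`) builds
each cell's data the long way round: simulated activation/inactivation
step protocols with voltage-control artifacts (liquid junction potential,
series resistance, drift, temperature), Boltzmann peak currents, additive
measurement noise, and a per-cell refit — so artifact signatures emerge
from the circuit model rather than being painted on.

Default configuration values describe the surveyed literature: 172
experiments (150 reporting both midpoints, 7 activation only, 15
inactivation only), baseline midpoints -39.9 / -81.2 mV, within-experiment
SDs 4.0 / 3.6 mV, cell counts with median 10 on [3, 88], and between-
experiment components tau_corr = 8 mV, tau_unc = 4 mV, which imply a
population correlation of the paired means of about 0.78.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np
import pandas as pd

from . import dataset
from .boltzmann import (
    BoltzmannParams,
    fit_activation,
    fit_inactivation,
    gating_curve,
)
from .exceptions import ArtifactError, ConfigError

__all__ = [
    "CohortConfig",
    "ArtifactConfig",
    "generate_cohort",
    "simulate_experiment_mechanistic",
    "solve_rs_voltage",
]


@dataclass
class CohortConfig:
    """Variance components, baselines, and sizes for the statistical generator.

    All SDs are in mV. ``tau_corr`` is the SD of the shared (correlated)
    per-experiment shift; ``tau_unc_a``/``tau_unc_i`` the SDs of the
    midpoint-specific shifts; ``sigma_within_*`` the cell-to-cell SDs.
    Cell counts are drawn from a log-normal rounded to integers and
    rejected outside [min, max]; its spread is set so that the configured
    maximum sits at the 99th percentile of the unrounded law.
    """

    n_experiments: int = 172
    fraction_both: float = 150 / 172
    fraction_act_only: float = 7 / 172
    fraction_inact_only: float = 15 / 172
    base_mu_a: float = -39.9
    base_mu_i: float = -81.2
    tau_corr: float = 8.0
    tau_unc_a: float = 4.0
    tau_unc_i: float = 4.0
    sigma_within_a: float = 4.0
    sigma_within_i: float = 3.6
    cell_count_median: float = 10.0
    cell_count_min: int = 3
    cell_count_max: int = 88
    shift_distribution: str = "normal"  # or "student-t" for robustness checks
    student_t_df: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("tau_corr", "tau_unc_a", "tau_unc_i",
                     "sigma_within_a", "sigma_within_i"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        fracs = (self.fraction_both, self.fraction_act_only,
                 self.fraction_inact_only)
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ConfigError("fractions must sum to 1")
        if self.cell_count_min < dataset.MIN_CELL_COUNT:
            raise ConfigError(
                f"cell_count_min must be >= {dataset.MIN_CELL_COUNT}")
        if not (self.cell_count_min <= self.cell_count_median
                <= self.cell_count_max):
            raise ConfigError("cell count law requires min <= median <= max")
        if self.n_experiments < 1:
            raise ConfigError("n_experiments must be >= 1")
        if self.shift_distribution not in ("normal", "student-t"):
            raise ConfigError("shift_distribution must be 'normal' or 'student-t'")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Read a config from JSON or flat ``key = value`` text."""
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"cannot parse config line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                try:
                    d[key] = json.loads(val)
                except json.JSONDecodeError:
                    d[key] = val
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ArtifactConfig:
    """Mechanistic voltage-error settings for the protocol simulator.

    ljp_mV
        Liquid-junction-potential offset: the true membrane potential is
        ``v_cmd - ljp_mV`` (plus the other terms), so a positive value
        leaves the membrane more negative than commanded and the fitted
        (command-axis) midpoints shift by +ljp_mV — identically for
        activation and inactivation, which is the signature that matters.
    rs_MOhm, rs_compensation_fraction
        Series resistance and the compensated fraction; the effective
        residual resistance is ``rs_MOhm * (1 - rs_compensation_fraction)``.
    drift_mV_per_min, minutes_since_rupture
        Linear midpoint drift with time in the whole-cell configuration
        (reported drifts are toward negative potentials, i.e. a negative
        rate of about -0.5 mV/min).
    temperature_shift_mV_per_C, delta_T_C
        Temperature sensitivity of the midpoints (about +0.43 mV per
        degree C for activation) times the deviation from the reference
        temperature.
    """

    ljp_mV: float = 0.0
    rs_MOhm: float = 0.0
    rs_compensation_fraction: float = 0.0
    drift_mV_per_min: float = 0.0
    minutes_since_rupture: float = 0.0
    temperature_shift_mV_per_C: float = 0.0
    delta_T_C: float = 0.0

    def validate(self) -> None:
        if self.rs_MOhm < 0:
            raise ConfigError("rs_MOhm must be >= 0")
        if not (0.0 <= self.rs_compensation_fraction < 1.0):
            raise ConfigError("rs_compensation_fraction must be in [0, 1)")

    @property
    def rs_effective_MOhm(self) -> float:
        return self.rs_MOhm * (1.0 - self.rs_compensation_fraction)

    @property
    def static_offset_mV(self) -> float:
        """Voltage offset applied to every commanded potential (mV)."""
        return (
            -self.ljp_mV
            + self.drift_mV_per_min * self.minutes_since_rupture
            + self.temperature_shift_mV_per_C * self.delta_T_C
        )


def _experiment_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based stream split: one independent stream per experiment
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _draw_cell_count(rng, median, lo, hi) -> int:
    """Log-normal count rounded to an integer, rejected outside [lo, hi]."""
    mu = math.log(median)
    # place the configured max at the 99th percentile of the unrounded law
    sigma = max(math.log(hi / median) / 2.3263, 1e-9)
    for _ in range(1000):
        n = int(round(rng.lognormal(mu, sigma)))
        if lo <= n <= hi:
            return n
    raise ConfigError("cell count law rejected 1000 consecutive draws")


_CELL_TYPES = (["HEK", "CHO"], [0.92, 0.08])
_ALPHAS = (["a*", "b", "unknown", "a", "b*"], [0.40, 0.25, 0.15, 0.12, 0.08])
_BETA1 = (["yes", "no"], [0.6, 0.4])
_LJP = (["corrected", "uncorrected", "unreported"], [0.06, 0.05, 0.89])


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort from the hierarchical variability model.

    Returns ``(records, truth)``: the experiment table in the
    :mod:`~inavarmeta.dataset` schema (means, sample SDs, counts, and
    metadata drawn independently of the shifts), and a truth sidecar keyed
    by ``experiment_id`` with the latent components ``c`` (shared),
    ``u_a``/``u_i`` (uncorrelated) and the noiseless per-experiment means.
    Bit-identical for identical ``(config, config.seed)``.
    """
    config = config or CohortConfig()
    config.validate()
    n = config.n_experiments
    n_both = int(round(config.fraction_both * n))
    n_act = int(round(config.fraction_act_only * n))
    n_act = min(n_act, n - n_both)
    n_inact = n - n_both - n_act

    rows, truth_rows = [], []
    for e in range(n):
        rng = _experiment_rng(config.seed, e)
        if config.shift_distribution == "student-t":
            df_ = config.student_t_df
            scale = math.sqrt((df_ - 2.0) / df_) if df_ > 2 else 1.0
            c = config.tau_corr * scale * rng.standard_t(df_)
            u_a = config.tau_unc_a * scale * rng.standard_t(df_)
            u_i = config.tau_unc_i * scale * rng.standard_t(df_)
        else:
            c = rng.normal(0.0, config.tau_corr)
            u_a = rng.normal(0.0, config.tau_unc_a)
            u_i = rng.normal(0.0, config.tau_unc_i)
        has_a = e < n_both or n_both + n_act > e >= n_both
        has_i = e < n_both or e >= n_both + n_act
        true_mu_a = config.base_mu_a + c + u_a
        true_mu_i = config.base_mu_i + c + u_i

        rec: dict = {
            "study_id": f"SYN{e:03d}",
            "experiment_id": f"E{e:03d}",
            "cell_type": rng.choice(_CELL_TYPES[0], p=_CELL_TYPES[1]),
            "alpha_subunit": rng.choice(_ALPHAS[0], p=_ALPHAS[1]),
            "beta1": rng.choice(_BETA1[0], p=_BETA1[1]),
            "ljp_status": rng.choice(_LJP[0], p=_LJP[1]),
        }
        if rec["ljp_status"] == "corrected":
            rec["ljp_mV"] = round(float(rng.uniform(6.7, 8.0)), 1)
        if has_a:
            n_a = _draw_cell_count(
                rng, config.cell_count_median,
                config.cell_count_min, config.cell_count_max)
            cells = true_mu_a + rng.normal(0.0, config.sigma_within_a, n_a)
            rec.update(
                mu_a=float(np.mean(cells)),
                sd_a=float(np.std(cells, ddof=1)),
                n_a=n_a,
            )
        if has_i:
            n_i = _draw_cell_count(
                rng, config.cell_count_median,
                config.cell_count_min, config.cell_count_max)
            cells = true_mu_i + rng.normal(0.0, config.sigma_within_i, n_i)
            rec.update(
                mu_i=float(np.mean(cells)),
                sd_i=float(np.std(cells, ddof=1)),
                n_i=n_i,
            )
        rows.append(rec)
        truth_rows.append({
            "experiment_id": rec["experiment_id"],
            "c": c, "u_a": u_a, "u_i": u_i,
            "true_mu_a": true_mu_a if has_a else np.nan,
            "true_mu_i": true_mu_i if has_i else np.nan,
        })

    records = pd.DataFrame(rows).reindex(columns=dataset.COLUMNS)
    records = records.astype(object).where(pd.notna(records), np.nan)
    for col in dataset.NUMERIC_COLUMNS:
        records[col] = pd.to_numeric(records[col])
    return records, pd.DataFrame(truth_rows)


def solve_rs_voltage(
    v_cmd: float,
    p: BoltzmannParams,
    rs_eff_MOhm: float,
    damping: float = 0.3,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Membrane voltage under a series-resistance voltage error.

    Solves the scalar circuit equation ``v_m = v_cmd - I(v_m) * rs_eff``
    (current in nA, resistance in MOhm, product in mV) by damped
    fixed-point iteration. With an inward current (I < 0) the membrane sits
    depolarized relative to the command. ``rs_eff_MOhm = 0`` returns
    ``v_cmd`` unchanged.
    """
    if rs_eff_MOhm < 0:
        raise ConfigError("rs_eff_MOhm must be >= 0")
    if rs_eff_MOhm == 0:
        return float(v_cmd)

    def current(v):
        return p.g_max * (v - p.e_rev) * gating_curve(v, p.v_half, p.k)

    v = float(v_cmd)
    for _ in range(max_iter):
        target = v_cmd - current(v) * rs_eff_MOhm
        v_next = (1.0 - damping) * v + damping * target
        # stop three decades below tol so the step size bounds the true error
        if abs(v_next - v) <= 1e-3 * tol:
            return float(v_next)
        v = v_next
    raise ArtifactError(
        f"series-resistance solve did not converge at v_cmd = {v_cmd} mV"
    )


DEFAULT_ACT_GRID = np.arange(-80.0, 45.0, 5.0)
DEFAULT_INACT_GRID = np.arange(-140.0, 0.0, 10.0)


def simulate_experiment_mechanistic(
    act_params: BoltzmannParams,
    inact_params: BoltzmannParams,
    n_cells: int,
    artifacts: ArtifactConfig | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    act_grid=None,
    inact_grid=None,
    experiment_id: str = "MECH000",
    e_rev_mode: str = "measured",
) -> tuple[pd.Series, pd.DataFrame]:
    """Simulate one experiment through full voltage-step protocols.

    For every cell and commanded step the true membrane voltage is
    ``v_cmd + offset`` (offset from LJP, drift, and temperature, see
    :class:`ArtifactConfig`), with the residual series resistance then
    resolved self-consistently via :func:`solve_rs_voltage` in the
    activation protocol. Peak currents (in nA; pass ``g_max`` in uS) get
    additive Gaussian noise of SD ``noise_sd``. Each cell's midpoints and
    slopes are recovered by refitting the Boltzmann models to the
    commanded voltages — the same analysis a lab would run.

    ``e_rev_mode`` controls the reversal potential used in the refit:
    ``"measured"`` (default) uses the apparent, command-axis reversal (as
    when E is determined experimentally from the same recording), which
    makes a pure LJP offset shift both fitted midpoints exactly equally;
    ``"nominal"`` uses the true model value (as when E comes from the
    Nernst equation), leaving a small residual driving-force mismatch.

    During the inactivation protocol the preconditioning step carries the
    static offset only (the preconditioning current is at steady state, so
    its series-resistance error is negligible and is not modelled).

    Returns ``(record, cells)``: the summarized experiment row (means,
    sample SDs, counts) and the per-cell fitted values.
    """
    artifacts = artifacts or ArtifactConfig()
    artifacts.validate()
    if n_cells < dataset.MIN_CELL_COUNT:
        raise ConfigError(f"n_cells must be >= {dataset.MIN_CELL_COUNT}")
    act_grid = DEFAULT_ACT_GRID if act_grid is None else np.asarray(act_grid, float)
    inact_grid = (
        DEFAULT_INACT_GRID if inact_grid is None else np.asarray(inact_grid, float)
    )
    offset = artifacts.static_offset_mV
    rs_eff = artifacts.rs_effective_MOhm
    if e_rev_mode == "measured":
        e_rev_fit = act_params.e_rev - offset
    elif e_rev_mode == "nominal":
        e_rev_fit = act_params.e_rev
    else:
        raise ConfigError("e_rev_mode must be 'measured' or 'nominal'")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    cells = []
    for j in range(n_cells):
        # activation protocol
        i_act = np.empty_like(act_grid)
        for s, v_cmd in enumerate(act_grid):
            v_adj = v_cmd + offset
            try:
                v_m = solve_rs_voltage(v_adj, act_params, rs_eff)
            except ArtifactError as exc:
                raise ArtifactError(f"cell {j}, step {v_cmd} mV: {exc}") from exc
            i_act[s] = act_params.g_max * (v_m - act_params.e_rev) * gating_curve(
                v_m, act_params.v_half, act_params.k
            )
        i_act = i_act + rng.normal(0.0, noise_sd, i_act.shape)
        p_a, _ = fit_activation(act_grid, i_act, e_rev=e_rev_fit)

        # inactivation protocol: availability set by the preconditioning step
        avail = gating_curve(
            inact_grid + offset, inact_params.v_half, inact_params.k
        )
        i_inact = inact_params.i_max * avail
        i_inact = i_inact + rng.normal(0.0, noise_sd, i_inact.shape)
        p_i, _ = fit_inactivation(inact_grid, i_inact)

        cells.append({
            "cell": j,
            "v_a": p_a.v_half, "k_a": p_a.k, "g_max": p_a.g_max,
            "v_i": p_i.v_half, "k_i": p_i.k, "i_max": p_i.i_max,
        })

    cells_df = pd.DataFrame(cells)
    record = pd.Series({c: np.nan for c in dataset.COLUMNS}, dtype=object)
    record["study_id"] = "MECH"
    record["experiment_id"] = experiment_id
    record["mu_a"] = float(cells_df["v_a"].mean())
    record["sd_a"] = float(cells_df["v_a"].std(ddof=1))
    record["n_a"] = n_cells
    record["mu_i"] = float(cells_df["v_i"].mean())
    record["sd_i"] = float(cells_df["v_i"].std(ddof=1))
    record["n_i"] = n_cells
    record["k_a"] = float(cells_df["k_a"].mean())
    record["cell_type"] = "HEK"
    record["alpha_subunit"] = "unknown"
    record["beta1"] = "no"
    record["ljp_status"] = "unreported"
    return record, cells_df
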