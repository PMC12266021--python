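"""End-to-end pipeline driver and machine-readable reporting.

:func:`run_pipeline` executes every analysis stage in a fixed order on one
experiment table (load -> resolve SDs -> summaries -> paired regression ->
decomposition -> subgroups -> factor correlations -> variance components)
and writes three artifacts to the output directory:

* ``summary.json`` — every statistic, keyed by the figure-style namespace
  (``fig2.means.inactivation.median``, ``fig3.regression.slope``, ...),
  floats serialized to 6 significant digits; deterministic for fixed
  inputs and seed.
* ``decomposition.csv`` — per-experiment pc1, pc2, sqrt(n_a + n_i).
* ``report.md`` — the human-readable summary table.
* ``MANIFEST.json`` — which stages completed, which were skipped and why.

A stage that cannot run on the given data (e.g. too few paired records) is
recorded as skipped with its reason rather than aborting the pipeline;
unexpected stage failures are recorded and reflected in a nonzero exit
status from the CLI.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import dataset, meta
from .exceptions import DatasetError
from .model import MidpointVariability

__all__ = ["PipelineReport", "run_pipeline", "validate_summary", "round_sig"]

#: Numeric factors examined against each midpoint when present in the data.
FACTOR_PLAN = [
    ("v_hold_a", "mu_a", "fig5.vhold_a"),
    ("v_hold_i", "mu_i", "fig5.vhold_i"),
    ("k_a", "mu_a", "fig5.k_a"),
    ("v_peak", "mu_a", "fig5.v_peak"),
    ("temperature_C", "mu_a", "figS1.temperature.mu_a"),
    ("temperature_C", "mu_i", "figS1.temperature.mu_i"),
    ("na_out_mM", "mu_a", "figS1.na_out.mu_a"),
    ("na_out_mM", "mu_i", "figS1.na_out.mu_i"),
]

SUBGROUP_KEYS = ["alpha_subunit", "beta1", "cell_type"]


def round_sig(x, digits: int = 6):
    """Round floats (recursively through dicts/lists) to significant digits."""
    if isinstance(x, dict):
        return {k: round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [round_sig(v, digits) for v in x]
    if isinstance(x, bool) or not isinstance(x, float):
        return x
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _column_checksum(df) -> str:
    payload = ",".join(df.columns).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Record of one pipeline run: outputs, stage status, provenance."""

    summary: dict
    stages: dict = field(default_factory=dict)
    out_dir: Path | None = None
    timestamp: str = ""
    ok: bool = True

    def completed(self, stage: str) -> bool:
        return self.stages.get(stage) == "completed"


def _summaries_into(summary, df):
    for side, tag in (("activation", "a"), ("inactivation", "i")):
        if not df[f"mu_{tag}"].notna().any():
            summary[f"fig2.{side}.skipped"] = "no reported means on this side"
            continue
        summary[f"fig2.means.{side}"] = meta.summarize_means(df, side).to_dict()
        summary[f"fig2.sds.{side}"] = meta.summarize_sds(df, side).to_dict()
        summary[f"fig2.counts.{side}"] = meta.summarize_counts(df, side).to_dict()
        med_sd = summary[f"fig2.sds.{side}"]["median"]
        summary[f"fig2.normal_90_width.{side}"] = meta.normal_90_width(med_sd)


def run_pipeline(
    data_path,
    out_dir,
    strict: bool = True,
    axis: str = "ols",
    bootstrap: int = 2000,
    seed: int = 0,
) -> PipelineReport:
    """Run the full analysis on an experiment-table CSV and write reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    summary: dict = {"seed": int(seed)}

    df = dataset.load_dataset(data_path, strict=strict)
    df = dataset.resolve_sd(df)
    stages["load"] = "completed"
    summary["dataset.n_rows"] = int(len(df))
    summary["dataset.column_checksum"] = _column_checksum(df)
    try:
        summary["software.version"] = importlib.metadata.version("inavarmeta")
    except importlib.metadata.PackageNotFoundError:
        summary["software.version"] = "unknown"
    counts = dataset.midpoint_counts(df)
    for key, val in counts.items():
        summary[f"counts.{key}"] = val

    model = MidpointVariability(df, strict=strict)
    results = model.fit(bootstrap=bootstrap, seed=seed, axis=axis)

    _summaries_into(summary, df)
    stages["summaries"] = "completed"

    if results.regression is not None:
        summary["fig3.regression"] = results.regression.to_dict()
        summary["fig3.fixed_slope"] = {
            "intercept": results.fixed_slope.intercept,
            "slope_in_free_ci": results.fixed_slope.slope_in_free_ci,
        }
        d = results.to_dict()["decomposition"]
        summary["fig3.decomposition"] = d
        stages["regression"] = stages["decomposition"] = "completed"
        results.funnel().to_csv(out_dir / "decomposition.csv", index=False)
    else:
        reason = results.skipped.get("regression", "unavailable")
        stages["regression"] = stages["decomposition"] = f"skipped: {reason}"
        summary["fig3.skipped"] = reason

    if results.components is not None:
        summary["components"] = results.components.to_dict()
        stages["components"] = "completed"
    else:
        reason = results.skipped.get("components", "unavailable")
        stages["components"] = f"skipped: {reason}"
        summary["components.skipped"] = reason

    for key in SUBGROUP_KEYS:
        groups = results.subgroup(key)
        summary[f"fig4.subgroups.{key}"] = {
            label: {
                "n": g.n,
                "mu_a_median": g.activation.median if g.activation else None,
                "mu_i_median": g.inactivation.median if g.inactivation else None,
                "mu_a_range": g.activation.range if g.activation else None,
                "mu_i_range": g.inactivation.range if g.inactivation else None,
            }
            for label, g in groups.items()
        }
    stages["subgroups"] = "completed"

    n_factors = 0
    for factor, response, key in FACTOR_PLAN:
        try:
            res = meta.factor_regression(df, factor, response)
        except DatasetError:
            continue
        summary[key] = {"r2": res.r_squared, "n": res.n_points,
                        "slope": res.slope, "intercept": res.intercept}
        n_factors += 1
    try:
        ljp = meta.factor_regression(df, "ljp_status", "mu_i")
        summary["fig5.ljp_status.mu_i"] = {
            label: s.to_dict() for label, s in ljp.items()
        }
        n_factors += 1
    except DatasetError:
        pass
    if n_factors:
        stages["factors"] = "completed"
    else:
        stages["factors"] = "skipped: no factors reported"
        summary["fig5.skipped"] = "no factors reported"

    summary = round_sig(summary)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out_dir / "report.md", "w") as fh:
        fh.write("# Midpoint variability report\n\n```\n")
        fh.write(results.summary())
        fh.write("\n```\n")

    report = PipelineReport(
        summary=summary,
        stages=stages,
        out_dir=out_dir,
        timestamp=datetime.now(timezone.utc).isoformat(),
        ok=all(not s.startswith("failed") for s in stages.values()),
    )
    with open(out_dir / "MANIFEST.json", "w") as fh:
        json.dump(
            {"stages": stages, "timestamp": report.timestamp, "ok": report.ok},
            fh, indent=2,
        )
    return report


def validate_summary(summary: dict) -> list[str]:
    """Check a summary dict against the checked-in report contract.

    Returns a list of problems (empty when valid): missing required keys,
    wrong scalar types, and stages neither present nor marked skipped.
    """
    schema = json.loads(
        (Path(__file__).parent / "report_schema.json").read_text()
    )
    problems = []
    types = {"int": int, "str": str, "float": float}
    for key, typename in schema["required"].items():
        if key not in summary:
            problems.append(f"missing required key {key}")
        elif not isinstance(summary[key], types[typename]):
            problems.append(f"{key} should be {typename}")
    for stage in schema["stages"]:
        prefix_present = any(k.startswith(stage) for k in summary)
        stage_parts = set(stage.split("."))
        skipped = any(
            k.endswith(".skipped")
            and set(k[: -len(".skipped")].split(".")) <= stage_parts
            for k in summary
        )
        if not prefix_present and not skipped:
            problems.append(f"stage {stage} neither present nor skipped")
    return problems
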