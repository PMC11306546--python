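"""Pipeline orchestration, run manifests and human-readable reports.

A run takes a geography input CSV plus a configuration (staffing, service
model, Monte Carlo settings), produces per-geography and aggregate threshold
estimates, and writes three artifacts next to each other: ``results.csv``
(Table-style rates and CI bounds), ``results.json`` (with per-draw
percentile grids) and ``manifest.json`` — a snapshot of everything needed to
reproduce the results bit-for-bit (config, seed, input checksum, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .cost import ServiceModel, StaffingPlan
from .errors import ConfigError, ValidationError
from .io import (
    GeographyInputs,
    load_geography_inputs,
    write_results,
    write_results_json,
)
from .thresholds import ThresholdEstimate
from .uncertainty import SimulationConfig, simulate_aggregate, simulate_many

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration: staffing, service model, simulation, options."""

    plan: StaffingPlan = StaffingPlan.rn()
    svc: ServiceModel = ServiceModel()
    sim: SimulationConfig = SimulationConfig()
    travel_opportunity_in_overhead: bool = False
    use_employment_weights: bool = False
    pooling: str = "mean"

    def snapshot(self) -> dict:
        return {
            "staffing": dataclasses.asdict(self.plan),
            "service": dataclasses.asdict(self.svc),
            "simulation": dataclasses.asdict(self.sim),
            "travel_opportunity_in_overhead": self.travel_opportunity_in_overhead,
            "use_employment_weights": self.use_employment_weights,
            "pooling": self.pooling,
        }


def load_run_config(path: str | Path, sim: SimulationConfig | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognised keys: staffing.supervisor_kind / .ratio / .annual_hours,
    service.panel_size / .enrollment_months / .visit_duration_h /
    .inperson_share / .productive_fraction, travel_opportunity_in_overhead.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    staffing = raw.get("staffing", {})
    kind = staffing.get("supervisor_kind", "RN")
    from .cost import DEFAULT_SUPERVISOR_RATIOS, FULL_TIME_ANNUAL_HOURS

    plan = StaffingPlan(
        supervisor_kind=kind,
        supervisor_ratio=float(staffing.get("ratio", DEFAULT_SUPERVISOR_RATIOS.get(kind, 8.0))),
        annual_hours=float(staffing.get("annual_hours", FULL_TIME_ANNUAL_HOURS)),
    )
    service = raw.get("service", {})
    svc = ServiceModel(
        panel_size=float(service.get("panel_size", 65)),
        enrollment_months=float(service.get("enrollment_months", 6)),
        visit_duration=float(service.get("visit_duration_h", 0.5)),
        inperson_share=float(service.get("inperson_share", 0.25)),
        productive_fraction=float(service.get("productive_fraction", 1.0)),
    )
    return RunConfig(
        plan=plan,
        svc=svc,
        sim=sim or SimulationConfig(),
        travel_opportunity_in_overhead=bool(raw.get("travel_opportunity_in_overhead", False)),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    inputs_path: str | Path,
    config: RunConfig,
    outputs: Sequence[str],
) -> dict:
    manifest = {
        "version": __version__,
        "created_unix": time.time(),
        "inputs": str(inputs_path),
        "inputs_sha256": _sha256(Path(inputs_path)),
        "seed": config.sim.seed,
        "config": config.snapshot(),
        "outputs": list(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def run_pipeline(
    inputs_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[ThresholdEstimate]:
    """End-to-end run: load, simulate, aggregate, write results + manifest.

    Returns the per-geography estimates followed by the NATIONAL, METRO and
    NONMETRO aggregates. Outputs are fully determined by (inputs, config,
    seed).
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    geos = load_geography_inputs(inputs_path)
    logger.info(
        "simulating %d geographies x %d draws (seed %d)",
        len(geos), config.sim.n_draws, config.sim.seed,
    )
    estimates = simulate_many(
        geos, config.plan, config.svc, config.sim,
        travel_opportunity_in_overhead=config.travel_opportunity_in_overhead,
    )

    def agg(sub_geos: list[GeographyInputs], sub_est: list[ThresholdEstimate], label: str):
        weights = (
            [g.employment_weight for g in sub_geos]
            if config.use_employment_weights
            else None
        )
        return simulate_aggregate(
            sub_geos, config.plan, config.svc, config.sim,
            weights=weights, label=label, pooling=config.pooling, estimates=sub_est,
        )

    results = list(estimates)
    results.append(agg(list(geos), estimates, "NATIONAL"))
    for flag, label in ((True, "METRO"), (False, "NONMETRO")):
        sub = [(g, e) for g, e in zip(geos, estimates) if g.metro == flag]
        if sub:
            results.append(agg([g for g, _ in sub], [e for _, e in sub], label))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    json_path = out_dir / "results.json"
    write_results(results, csv_path)
    write_results_json(results, json_path)
    write_manifest(out_dir / "manifest.json", inputs_path, config, [csv_path.name, json_path.name])
    logger.info("run finished in %.2fs; wrote %s", time.perf_counter() - t0, out_dir)
    return results


def render_report(estimates: Sequence[ThresholdEstimate]) -> str:
    """Markdown summary table: label, FFS mean + CI, PMPM mean + CI.

    Rows are sorted by label (aggregates first), so rendering is stable
    under input permutation; currency is formatted to cents.
    """
    if not estimates:
        raise ValidationError("no estimates to report")
    aggregates = {"NATIONAL", "METRO", "NONMETRO"}
    ordered = sorted(estimates, key=lambda e: (e.label not in aggregates, e.label))
    lines = [
        "| Geography | FFS per visit | FFS 95% CI | PMPM | PMPM 95% CI |",
        "|---|---|---|---|---|",
    ]
    for e in ordered:
        lines.append(
            f"| {e.label} | ${e.ffs_rate:.2f} | (${e.ffs_ci_low:.2f}, ${e.ffs_ci_high:.2f}) "
            f"| ${e.pmpm_rate:.2f} | (${e.pmpm_ci_low:.2f}, ${e.pmpm_ci_high:.2f}) |"
        )
    return "\n".join(lines) + "\n"
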