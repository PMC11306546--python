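"""Prespecified sensitivity analyses: supervisor substitution and panel sweep.

Supervisor swap: rerun the full simulation with the RN care-manager plan
(1 supervisor per 8 CHWs) replaced by the MSW plan (1 per 6), reusing the
same seed so every difference in the output is structural, not sampling
noise. Only the supervision wage and ratio change; the overhead ledger is
untouched (supervisor-attributable overhead is assumed folded into the
per-CHW-hour ledger).

Panel sweep: rescale a baseline estimate across panel sizes by the
inverse-panel law, applied per draw so CI bounds move by exactly the same
factor as the point value. Monthly per-CHW cost is held fixed; visit volume
is demand-limited (proportional to panel at fixed per-patient intensity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .cost import ServiceModel, StaffingPlan
from .errors import ValidationError
from .io import GeographyInputs
from .thresholds import ThresholdEstimate, rescale_estimate
from .uncertainty import SimulationConfig, simulate_aggregate, simulate_many

logger = logging.getLogger(__name__)

#: Default panel grid; the endpoints 15 and 100 are the studied extremes.
DEFAULT_PANEL_GRID = (15, 25, 35, 45, 55, 65, 75, 85, 100)


@dataclass(frozen=True)
class SweepResult:
    """Ordered (panel size, estimate) pairs for one sweep scenario."""

    scenario: str
    entries: tuple[tuple[float, ThresholdEstimate], ...]

    def __post_init__(self) -> None:
        panels = [p for p, _ in self.entries]
        if any(b <= a for a, b in zip(panels, panels[1:])):
            raise ValidationError("panel sizes must be strictly increasing")
        ffs = [e.ffs_rate for _, e in self.entries]
        pmpm = [e.pmpm_rate for _, e in self.entries]
        if any(b >= a for a, b in zip(ffs, ffs[1:])) or any(
            b >= a for a, b in zip(pmpm, pmpm[1:])
        ):
            raise ValidationError("threshold rates must be strictly decreasing in panel size")

    def panels(self) -> list[float]:
        return [p for p, _ in self.entries]

    def estimates(self) -> list[ThresholdEstimate]:
        return [e for _, e in self.entries]


@dataclass(frozen=True)
class SupervisorSwapResult:
    """Paired aggregate estimates under RN 1:8 and MSW 1:6 supervision."""

    rn: ThresholdEstimate
    msw: ThresholdEstimate
    rn_per_geo: tuple[ThresholdEstimate, ...] = ()
    msw_per_geo: tuple[ThresholdEstimate, ...] = ()


def supervisor_swap(
    geos: Sequence[GeographyInputs],
    svc: ServiceModel,
    config: SimulationConfig,
    *,
    weights: Sequence[float] | None = None,
    annual_hours: float | None = None,
    pooling: str = "mean",
) -> SupervisorSwapResult:
    """Two full simulation runs differing only in the staffing plan.

    The same master seed drives both runs, so per-draw input realisations
    are identical and the output difference isolates the supervision change.
    """
    plans = (
        StaffingPlan.rn() if annual_hours is None else StaffingPlan.rn(annual_hours),
        StaffingPlan.msw() if annual_hours is None else StaffingPlan.msw(annual_hours),
    )
    results = []
    per_geo = []
    for plan in plans:
        ests = simulate_many(geos, plan, svc, config)
        per_geo.append(tuple(ests))
        results.append(
            simulate_aggregate(
                geos, plan, svc, config,
                weights=weights, label="NATIONAL", pooling=pooling, estimates=ests,
            )
        )
    return SupervisorSwapResult(
        rn=results[0], msw=results[1], rn_per_geo=per_geo[0], msw_per_geo=per_geo[1]
    )


def panel_sweep(
    baseline: ThresholdEstimate,
    panels: Sequence[float] = DEFAULT_PANEL_GRID,
    scenario: str = "panel-sweep",
) -> SweepResult:
    """Rescale a baseline estimate over a grid of panel sizes.

    The baseline's own panel size is the reference; a grid point equal to it
    returns the baseline unchanged. Points and every stored draw rescale by
    reference_panel / panel. A warning is logged for panels above the
    reference, where demand-implied visit volume exceeds the travel-limited
    capacity the baseline was computed from.
    """
    if any(p <= 0 for p in panels):
        raise ValidationError("panel sizes must be > 0")
    entries = []
    for p in sorted(set(float(p) for p in panels)):
        if p > baseline.panel_size:
            logger.warning(
                "panel %g exceeds reference %g: demand-implied visit volume "
                "exceeds baseline capacity", p, baseline.panel_size,
            )
        est = baseline if p == baseline.panel_size else rescale_estimate(baseline, p)
        entries.append((p, est))
    return SweepResult(scenario=scenario, entries=tuple(entries))
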