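"""Per-CHW cost composition and monthly visit capacity.

The cost of supporting one full-time community health worker is the sum of
three pieces, all expressed per year and divided by 12 for the monthly total:

* labor — the CHW's own wage over the annual paid hours;
* supervision — one supervisor's wage allocated across the team, i.e.
  supervisor wage x annual hours / (CHWs per supervisor);
* overhead — five per-work-hour components (equipment, software,
  transportation, space, benefits) scaled by annual hours.

Visit capacity treats each visit as a fixed-duration block; an in-person
visit additionally consumes the full round-trip travel time, virtual visits
none. With an in-person share s, travel time t and visit duration d, the
expected time per visit is d + s*t, and monthly capacity is the productive
monthly hours divided by that.

All arithmetic accepts NumPy arrays in place of scalars so the Monte Carlo
layer can push whole draw vectors through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, ValidationError
from .io import OVERHEAD_COMPONENTS, GeographyInputs, OverheadLedger

#: Default CHWs supervised per supervisor, by supervisor occupation.
DEFAULT_SUPERVISOR_RATIOS = {"RN": 8.0, "MSW": 6.0}

#: Paid hours per year for a full-time CHW.
FULL_TIME_ANNUAL_HOURS = 2080.0


@dataclass(frozen=True)
class StaffingPlan:
    """Supervision structure and paid hours for one CHW position."""

    supervisor_kind: str = "RN"
    supervisor_ratio: float = 8.0
    annual_hours: float = FULL_TIME_ANNUAL_HOURS

    def __post_init__(self) -> None:
        if self.supervisor_kind not in ("RN", "MSW"):
            raise ConfigError(f"unknown supervisor occupation {self.supervisor_kind!r}")
        if not (math.isfinite(self.supervisor_ratio) and self.supervisor_ratio >= 1):
            raise ValidationError(f"supervisor_ratio must be >= 1, got {self.supervisor_ratio!r}")
        if not (math.isfinite(self.annual_hours) and self.annual_hours > 0):
            raise ValidationError(f"annual_hours must be > 0, got {self.annual_hours!r}")

    @classmethod
    def rn(cls, annual_hours: float = FULL_TIME_ANNUAL_HOURS) -> "StaffingPlan":
        """RN care-manager supervision at the typical 1:8 ratio."""
        return cls("RN", DEFAULT_SUPERVISOR_RATIOS["RN"], annual_hours)

    @classmethod
    def msw(cls, annual_hours: float = FULL_TIME_ANNUAL_HOURS) -> "StaffingPlan":
        """Master's-level social worker supervision at the typical 1:6 ratio."""
        return cls("MSW", DEFAULT_SUPERVISOR_RATIOS["MSW"], annual_hours)


@dataclass(frozen=True)
class ServiceModel:
    """Panel and visit-mix assumptions for one CHW.

    Defaults are the base case: a concurrent panel of 65 patients each
    enrolled for a mean of 6 months, 30-minute visits, and a 1:3
    in-person-to-virtual mix (in-person share 0.25). ``productive_fraction``
    is the share of paid hours available for visits plus travel; the default
    of 1.0 is the most generous (lowest-threshold) assumption.
    """

    panel_size: float = 65.0
    enrollment_months: float = 6.0
    visit_duration: float = 0.5
    inperson_share: float = 0.25
    productive_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.panel_size >= 1:
            raise ValidationError(f"panel_size must be >= 1, got {self.panel_size!r}")
        if not 0 < self.inperson_share <= 1:
            raise ValidationError(f"inperson_share must be in (0, 1], got {self.inperson_share!r}")
        if not self.visit_duration > 0:
            raise ValidationError(f"visit_duration must be > 0, got {self.visit_duration!r}")
        if not 0 < self.productive_fraction <= 1:
            raise ValidationError(
                f"productive_fraction must be in (0, 1], got {self.productive_fraction!r}"
            )
        if not self.enrollment_months > 0:
            raise ValidationError(
                f"enrollment_months must be > 0, got {self.enrollment_months!r}"
            )

    @property
    def patients_served_per_year(self) -> float:
        """Panel turnover: concurrent panel x 12 / enrollment duration.

        Reporting only — PMPM revenue depends on concurrent member-months,
        not on turnover.
        """
        return self.panel_size * 12.0 / self.enrollment_months


@dataclass(frozen=True)
class CostBreakdown:
    """Annual and monthly cost of supporting one CHW, decomposed."""

    labor: float
    supervision: float
    overhead_by_component: Mapping[str, float]
    total_annual: float = field(init=False)
    total_monthly: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.labor + self.supervision + sum(self.overhead_by_component.values())
        object.__setattr__(self, "total_annual", total)
        object.__setattr__(self, "total_monthly", total / 12.0)

    @property
    def overhead_total(self) -> float:
        return sum(self.overhead_by_component.values())


def labor_cost(wage, plan: StaffingPlan):
    """Annual CHW wage cost: hourly wage x annual paid hours."""
    if np.any(np.asarray(wage) <= 0):
        raise ValidationError("wage must be > 0")
    return wage * plan.annual_hours


def supervision_cost(sup_wage, plan: StaffingPlan):
    """Per-CHW share of one supervisor's annual wage.

    One supervisor covers ``supervisor_ratio`` CHWs, so each CHW carries
    sup_wage x annual_hours / ratio.
    """
    if np.any(np.asarray(sup_wage) <= 0):
        raise ValidationError("supervisor wage must be > 0")
    return sup_wage * plan.annual_hours / plan.supervisor_ratio


def overhead_cost(ledger: OverheadLedger, plan: StaffingPlan) -> dict[str, float]:
    """Annualise the per-work-hour overhead ledger component by component."""
    return {name: rate * plan.annual_hours for name, rate in ledger.components().items()}


def monthly_visit_capacity(
    svc: ServiceModel,
    travel_time,
    plan: StaffingPlan,
    *,
    travel_opportunity_in_overhead: bool = False,
):
    """Visits one CHW can deliver per month given the visit mix.

    Capacity = productive monthly hours / (visit_duration + inperson_share x
    travel_time). With ``travel_opportunity_in_overhead`` the travel hours
    are costed in the ledger instead (see :func:`total_cost`) and excluded
    here, so capacity uses the visit duration alone.
    """
    t = 0.0 if travel_opportunity_in_overhead else travel_time
    denom = svc.visit_duration + svc.inperson_share * t
    if np.any(np.asarray(denom) <= 0):
        raise ValidationError("visit_duration + inperson_share * travel_time must be > 0")
    monthly_hours = plan.annual_hours / 12.0 * svc.productive_fraction
    return monthly_hours / denom


def total_cost(
    geo: GeographyInputs,
    plan: StaffingPlan,
    *,
    svc: ServiceModel | None = None,
    travel_opportunity_in_overhead: bool = False,
) -> CostBreakdown:
    """Compose the full cost of one CHW position in ``geo``.

    By default travel time is charged only through reduced visit capacity
    (the transportation ledger component covers vehicle and commute dollars).
    With ``travel_opportunity_in_overhead`` the CHW wage for in-person travel
    hours is added to the transportation component instead, and capacity is
    computed travel-free — never both, so no hour is charged twice.
    """
    sup = geo.supervisor_wages.get(plan.supervisor_kind)
    if sup is None:
        raise ConfigError(
            f"{geo.geo_id}: no {plan.supervisor_kind} supervisor wage available"
        )
    labor = labor_cost(geo.chw_wage.mean, plan)
    supervision = supervision_cost(sup.mean, plan)
    overhead = overhead_cost(geo.overhead, plan)
    if travel_opportunity_in_overhead:
        if svc is None:
            raise ConfigError("travel_opportunity_in_overhead requires a ServiceModel")
        visits_per_year = 12.0 * monthly_visit_capacity(
            svc, 0.0, plan, travel_opportunity_in_overhead=True
        )
        travel_hours = svc.inperson_share * geo.travel_time_per_inperson_visit * visits_per_year
        overhead["transportation"] = overhead["transportation"] + geo.chw_wage.mean * travel_hours
    return CostBreakdown(labor=labor, supervision=supervision, overhead_by_component=overhead)
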