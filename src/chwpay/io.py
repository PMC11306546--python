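"""Domain types and CSV input/output for geography cost tables.

The canonical input is a UTF-8 CSV with one row per geography (a state or a
sub-state metropolitan / non-metropolitan area). Monetary columns are dollars
per hour in a single dollar-year; sources quoted in other years are brought to
the common year at load time with a CPI multiplier. Overhead is expressed per
CHW work-hour; annual overhead figures must be divided by annual paid hours
before ingestion.

Schema version "1" header::

    geo_id,state,area_name,metro,chw_wage_mean,chw_wage_sd,rn_wage_mean,
    rn_wage_sd,msw_wage_mean,msw_wage_sd,oh_equipment,oh_software,
    oh_transportation,oh_space,oh_benefits,travel_time_hours,employment_weight

Optional columns ``oh_<component>_sd`` attach within-geography standard
deviations to overhead components (absent sds are treated as 0, i.e. certain).
Unknown extra columns are ignored with a logged warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .errors import OutputError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .thresholds import ThresholdEstimate

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

OVERHEAD_COMPONENTS = ("equipment", "software", "transportation", "space", "benefits")

REQUIRED_COLUMNS = (
    "geo_id",
    "state",
    "area_name",
    "metro",
    "chw_wage_mean",
    "chw_wage_sd",
    "rn_wage_mean",
    "rn_wage_sd",
    "msw_wage_mean",
    "msw_wage_sd",
    "oh_equipment",
    "oh_software",
    "oh_transportation",
    "oh_space",
    "oh_benefits",
    "travel_time_hours",
    "employment_weight",
)

OPTIONAL_COLUMNS = tuple(f"oh_{c}_sd" for c in OVERHEAD_COMPONENTS)

#: Hard ceiling on round-trip travel per in-person visit (hours).
MAX_TRAVEL_TIME_H = 8.0

_TRUTHY = {"1", "true", "t", "yes", "metro"}
_FALSY = {"0", "false", "f", "no", "nonmetro", "non-metro"}


def _require_finite_nonneg(value: float, geo_id: str, name: str) -> float:
    v = float(value)
    if not math.isfinite(v) or v < 0:
        raise ValidationError(f"{geo_id}: {name} must be finite and >= 0, got {value!r}")
    return v


@dataclass(frozen=True)
class WageDistribution:
    """Hourly wage as a mean and standard deviation ($/h), OEWS style."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and self.mean > 0):
            raise ValidationError(f"wage mean must be finite and > 0, got {self.mean!r}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValidationError(f"wage sd must be finite and >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class OverheadLedger:
    """Non-wage cost per CHW work-hour, split into five components ($/h).

    ``sds`` carries optional within-geography standard deviations per
    component; components without an entry are treated as certain.
    """

    equipment: float
    software: float
    transportation: float
    space: float
    benefits: float
    sds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in OVERHEAD_COMPONENTS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"overhead {name} must be finite and >= 0, got {v!r}")
        for name, sd in self.sds.items():
            if name not in OVERHEAD_COMPONENTS:
                raise ValidationError(f"unknown overhead component {name!r} in sds")
            if not (math.isfinite(sd) and sd >= 0):
                raise ValidationError(f"overhead sd for {name} must be finite and >= 0")

    @property
    def total(self) -> float:
        """Total overhead rate, the sum of the five components ($/h)."""
        return sum(getattr(self, name) for name in OVERHEAD_COMPONENTS)

    def components(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in OVERHEAD_COMPONENTS}

    def sd_of(self, name: str) -> float:
        return float(self.sds.get(name, 0.0))


@dataclass(frozen=True)
class DollarYearAdjustment:
    """CPI multiplier taking source-year dollars to the common dollar-year."""

    cpi_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cpi_factor) and self.cpi_factor > 0):
            raise ValidationError(f"cpi_factor must be > 0, got {self.cpi_factor!r}")


@dataclass(frozen=True)
class GeographyInputs:
    """All model inputs for one geography (state or sub-state area)."""

    geo_id: str
    state: str
    area_name: str
    metro: bool
    chw_wage: WageDistribution
    supervisor_wages: Mapping[str, WageDistribution]
    overhead: OverheadLedger
    travel_time_per_inperson_visit: float
    employment_weight: float = 1.0

    def __post_init__(self) -> None:
        t = self.travel_time_per_inperson_visit
        if not (math.isfinite(t) and 0 <= t < MAX_TRAVEL_TIME_H):
            raise ValidationError(
                f"{self.geo_id}: travel_time_per_inperson_visit must be in "
                f"[0, {MAX_TRAVEL_TIME_H}) hours, got {t!r}"
            )
        w = self.employment_weight
        if not (math.isfinite(w) and w >= 0):
            raise ValidationError(f"{self.geo_id}: employment_weight must be >= 0, got {w!r}")
        for kind in self.supervisor_wages:
            if kind not in ("RN", "MSW"):
                raise ValidationError(f"{self.geo_id}: unknown supervisor occupation {kind!r}")


def adjust_to_2023_usd(amount: float, adj: DollarYearAdjustment) -> float:
    """Convert ``amount`` from source-year to common-year (2023) dollars."""
    if not math.isfinite(amount):
        raise ValidationError(f"amount must be finite, got {amount!r}")
    return amount * adj.cpi_factor


def _parse_bool(value: object, geo_id: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"{geo_id}: metro flag {value!r} is not a recognised boolean")


def _row_to_geography(row: Mapping[str, object], adj: DollarYearAdjustment) -> GeographyInputs:
    geo_id = str(row["geo_id"])

    def money(col: str) -> float:
        return adjust_to_2023_usd(
            _require_finite_nonneg(float(row[col]), geo_id, col), adj
        )

    chw = WageDistribution(mean=money("chw_wage_mean"), sd=money("chw_wage_sd"))
    sup = {
        "RN": WageDistribution(mean=money("rn_wage_mean"), sd=money("rn_wage_sd")),
        "MSW": WageDistribution(mean=money("msw_wage_mean"), sd=money("msw_wage_sd")),
    }
    sds = {}
    for comp in OVERHEAD_COMPONENTS:
        col = f"oh_{comp}_sd"
        if col in row and not pd.isna(row[col]):
            sds[comp] = money(col)
    ledger = OverheadLedger(
        equipment=money("oh_equipment"),
        software=money("oh_software"),
        transportation=money("oh_transportation"),
        space=money("oh_space"),
        benefits=money("oh_benefits"),
        sds=sds,
    )
    weight = row.get("employment_weight")
    weight = 1.0 if weight is None or pd.isna(weight) else float(weight)
    return GeographyInputs(
        geo_id=geo_id,
        state=str(row["state"]),
        area_name=str(row["area_name"]),
        metro=_parse_bool(row["metro"], geo_id),
        chw_wage=chw,
        supervisor_wages=sup,
        overhead=ledger,
        travel_time_per_inperson_visit=float(row["travel_time_hours"]),
        employment_weight=weight,
    )


def load_geography_inputs(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    adj: DollarYearAdjustment | None = None,
) -> list[GeographyInputs]:
    """Read and validate a geography input table.

    Every row either yields a valid :class:`GeographyInputs` or contributes a
    located error message; nothing is silently dropped. All row errors are
    collected and raised together.

    Parameters
    ----------
    path:
        CSV file following the schema documented in this module.
    schema_version:
        Expected schema version; only ``"1"`` is defined.
    adj:
        Optional CPI adjustment applied to every monetary column at load.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r} (expected '1')")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    adj = adj or DollarYearAdjustment(1.0)

    frame = pd.read_csv(path, dtype={"geo_id": str, "state": str, "area_name": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra = [c for c in frame.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))

    dupes = frame["geo_id"][frame["geo_id"].duplicated()].unique().tolist()
    problems: list[str] = [f"duplicate geo_id: {g}" for g in dupes]

    geos: list[GeographyInputs] = []
    for _, row in frame.iterrows():
        try:
            geos.append(_row_to_geography(row, adj))
        except (ValidationError, ValueError) as exc:
            problems.append(f"row geo_id={row.get('geo_id')!r}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} problem(s) in {path.name}:\n  " + "\n  ".join(problems)
        )
    logger.info("loaded %d geographies from %s", len(geos), path)
    return geos


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "label",
    "ffs_rate",
    "ffs_ci_low",
    "ffs_ci_high",
    "pmpm_rate",
    "pmpm_ci_low",
    "pmpm_ci_high",
)


def results_frame(estimates: Sequence["ThresholdEstimate"]) -> pd.DataFrame:
    """Tabulate threshold estimates with currency rounded to cents."""
    if not estimates:
        raise ValidationError("no estimates to tabulate")
    rows = [
        {
            "label": e.label,
            "ffs_rate": round(e.ffs_rate, 2),
            "ffs_ci_low": round(e.ffs_ci_low, 2),
            "ffs_ci_high": round(e.ffs_ci_high, 2),
            "pmpm_rate": round(e.pmpm_rate, 2),
            "pmpm_ci_low": round(e.pmpm_ci_low, 2),
            "pmpm_ci_high": round(e.pmpm_ci_high, 2),
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(estimates: Sequence["ThresholdEstimate"], path: str | Path) -> None:
    """Write estimates as CSV, one row per geography or aggregate.

    Currency is rendered to 2 decimals; internal arithmetic keeps full float
    precision, so rounding happens only here.
    """
    frame = results_frame(estimates)
    try:
        frame.to_csv(path, index=False, float_format="%.2f")
    except OSError as exc:
        raise OutputError(f"cannot write results to {path}: {exc}") from exc


def write_results_json(estimates: Sequence["ThresholdEstimate"], path: str | Path) -> None:
    """JSON variant carrying the per-draw percentile grid for each estimate."""
    if not estimates:
        raise ValidationError("no estimates to write")
    payload = [e.to_dict() for e in estimates]
    try:
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    except OSError as exc:
        raise OutputError(f"cannot write results to {path}: {exc}") from exc


def load_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV (for reporting and round-trip checks)."""
    frame = pd.read_csv(path, dtype={"label": str})
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"results file missing column(s): {', '.join(missing)}")
    return frame


def geographies_to_frame(geos: Iterable[GeographyInputs]) -> pd.DataFrame:
    """Serialize geographies back to the input schema (inverse of loading)."""
    rows = []
    for g in geos:
        row: dict[str, object] = {
            "geo_id": g.geo_id,
            "state": g.state,
            "area_name": g.area_name,
            "metro": int(g.metro),
            "chw_wage_mean": g.chw_wage.mean,
            "chw_wage_sd": g.chw_wage.sd,
            "rn_wage_mean": g.supervisor_wages["RN"].mean,
            "rn_wage_sd": g.supervisor_wages["RN"].sd,
            "msw_wage_mean": g.supervisor_wages["MSW"].mean,
            "msw_wage_sd": g.supervisor_wages["MSW"].sd,
        }
        for comp, value in g.overhead.components().items():
            row[f"oh_{comp}"] = value
        row["travel_time_hours"] = g.travel_time_per_inperson_visit
        row["employment_weight"] = g.employment_weight
        for comp in OVERHEAD_COMPONENTS:
            row[f"oh_{comp}_sd"] = g.overhead.sd_of(comp)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_geography_inputs(geos: Iterable[GeographyInputs], path: str | Path) -> None:
    try:
        geographies_to_frame(geos).to_csv(path, index=False)
    except OSError as exc:
        raise OutputError(f"cannot write inputs to {path}: {exc}") from exc
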