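"""Synthetic geography input tables with realistic cross-geography structure.

Real inputs of this kind come from occupation wage surveys (OEWS) and
commercial cost surveys, keyed by state and by sub-state metropolitan /
non-metropolitan area. The generator emulates their statistical shape:

* wage means vary across geographies roughly symmetrically — drawn from
  truncated normals around the national target;
* overhead totals are strongly right-skewed across geographies (a few very
  expensive areas) — drawn log-normally around the national target mean;
* transportation dominates overhead (about 65% on average) with
  geography-level noise, modelled as a Beta-distributed share;
* round-trip travel per in-person visit is longer in non-metropolitan areas.

Default national targets are the study base case: CHW wage $23.51/h, RN
supervisor $39.88/h, MSW $29.37/h, overhead $43.65 per CHW work-hour with a
65.1% transportation share. Travel-time defaults are calibrated so the
capacity-implied national mean FFS threshold lands near $53.24 under default
staffing and service settings; that is a calibration choice, not an observed
quantity. Within-geography sds are not published and default to 25% of the
wage mean and 40% of each overhead component mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import (
    OVERHEAD_COMPONENTS,
    GeographyInputs,
    OverheadLedger,
    WageDistribution,
    write_geography_inputs,
)

logger = logging.getLogger(__name__)

# 50 states + DC + PR, the geography universe of the wage survey.
STATE_CODES = (
    "AL AK AZ AR CA CO CT DE DC FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN "
    "MS MO MT NE NV NH NJ NM NY NC ND OH OK OR PA PR RI SC SD TN TX UT VT VA "
    "WA WV WI WY"
).split()

# Dirichlet weights for the non-transportation overhead split
# (equipment, software, space, benefits): benefits > space > equipment > software.
_REMAINDER_WEIGHTS = np.array([1.0, 0.8, 1.6, 2.0]) * 5.0
_REMAINDER_NAMES = ("equipment", "software", "space", "benefits")


@dataclass(frozen=True)
class SynthConfig:
    """National targets and dispersion knobs for the generator."""

    n_states: int = 52
    areas_per_state: int = 2
    metro_fraction: float = 0.5
    chw_wage_mean: float = 23.51
    chw_wage_cross_sd: float = 3.3
    rn_wage_mean: float = 39.88
    rn_wage_cross_sd: float = 8.0
    msw_wage_mean: float = 29.37
    msw_wage_cross_sd: float = 5.5
    wage_within_sd_frac: float = 0.25
    overhead_mean: float = 43.65
    overhead_log_sd: float = 0.5
    overhead_within_sd_frac: float = 0.40
    transport_share_mean: float = 0.651
    transport_share_concentration: float = 12.0
    travel_time_metro_h: float = 0.85
    travel_time_nonmetro_h: float = 1.05
    travel_time_sd_h: float = 0.15
    wage_floor: float = 10.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not 1 <= self.n_states <= len(STATE_CODES):
            raise ValidationError(f"n_states must be in [1, {len(STATE_CODES)}]")
        if self.areas_per_state < 1:
            raise ValidationError("areas_per_state must be >= 1")
        for name in ("metro_fraction", "transport_share_mean"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v!r}")
        for name in ("chw_wage_mean", "rn_wage_mean", "msw_wage_mean", "overhead_mean"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be > 0, got {v!r}")
        if self.travel_time_metro_h > self.travel_time_nonmetro_h:
            raise ValidationError("metro travel time must not exceed non-metro travel time")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = out < lo
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lo
    return out


def generate(
    config: SynthConfig | None = None,
    out_path: str | Path | None = None,
) -> list[GeographyInputs]:
    """Generate a geography table; optionally write it as input-schema CSV.

    Deterministic for a fixed ``config.seed``: the same config produces the
    same geographies and byte-identical CSV output.
    """
    config = config or SynthConfig()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    n = config.n_states * config.areas_per_state

    chw_means = _truncated_normal(rng, config.chw_wage_mean, config.chw_wage_cross_sd, config.wage_floor, n)
    rn_means = _truncated_normal(rng, config.rn_wage_mean, config.rn_wage_cross_sd, config.wage_floor, n)
    msw_means = _truncated_normal(rng, config.msw_wage_mean, config.msw_wage_cross_sd, config.wage_floor, n)

    # log-normal with the configured arithmetic mean: mu = ln(mean) - s^2/2
    s = config.overhead_log_sd
    mu = math.log(config.overhead_mean) - 0.5 * s * s
    overhead_totals = rng.lognormal(mu, s, n)

    a = config.transport_share_mean * config.transport_share_concentration
    b = (1.0 - config.transport_share_mean) * config.transport_share_concentration
    shares = np.clip(rng.beta(a, b, n), 0.02, 0.98)
    remainder_splits = rng.dirichlet(_REMAINDER_WEIGHTS, n)

    metro_flags = rng.random(n) < config.metro_fraction
    travel_means = np.where(metro_flags, config.travel_time_metro_h, config.travel_time_nonmetro_h)
    travel = np.clip(rng.normal(travel_means, config.travel_time_sd_h), 0.05, 7.9)

    geos: list[GeographyInputs] = []
    k = 0
    for si in range(config.n_states):
        state = STATE_CODES[si]
        for ai in range(config.areas_per_state):
            metro = bool(metro_flags[k])
            kind = "metro" if metro else "nonmetro"
            transportation = shares[k] * overhead_totals[k]
            remainder = (1.0 - shares[k]) * overhead_totals[k]
            comps = {"transportation": float(transportation)}
            for name, frac in zip(_REMAINDER_NAMES, remainder_splits[k]):
                comps[name] = float(frac * remainder)
            sds = {
                name: config.overhead_within_sd_frac * comps[name]
                for name in OVERHEAD_COMPONENTS
            }
            wfrac = config.wage_within_sd_frac
            geos.append(
                GeographyInputs(
                    geo_id=f"{state}-{kind}-{ai + 1}",
                    state=state,
                    area_name=f"{state} {kind} area {ai + 1}",
                    metro=metro,
                    chw_wage=WageDistribution(float(chw_means[k]), wfrac * float(chw_means[k])),
                    supervisor_wages={
                        "RN": WageDistribution(float(rn_means[k]), wfrac * float(rn_means[k])),
                        "MSW": WageDistribution(float(msw_means[k]), wfrac * float(msw_means[k])),
                    },
                    overhead=OverheadLedger(sds=sds, **comps),
                    travel_time_per_inperson_visit=float(travel[k]),
                    employment_weight=1.0,
                )
            )
            k += 1
    if out_path is not None:
        write_geography_inputs(geos, out_path)
        logger.info("wrote %d synthetic geographies to %s", len(geos), out_path)
    return geos


def fixture_national() -> GeographyInputs:
    """Synthetic national-composite geography carrying the base-case means.

    A single stand-in geography (not a real survey area) whose inputs are the
    published national means: CHW $23.51/h, RN $39.88/h, MSW $29.37/h,
    overhead $43.65/h with transportation $28.42 (a 65.1% share), and the
    calibrated default travel time. Useful for worked examples and tests.
    """
    total = 43.65
    transportation = 28.42
    comps = {
        "transportation": transportation,
        "equipment": 2.75,
        "software": 2.28,
        "space": 4.10,
        "benefits": total - transportation - 2.75 - 2.28 - 4.10,
    }
    return GeographyInputs(
        geo_id="US-NATIONAL",
        state="US",
        area_name="synthetic national composite",
        metro=True,
        chw_wage=WageDistribution(23.51, 0.25 * 23.51),
        supervisor_wages={
            "RN": WageDistribution(39.88, 0.25 * 39.88),
            "MSW": WageDistribution(29.37, 0.25 * 29.37),
        },
        overhead=OverheadLedger(
            sds={name: 0.40 * value for name, value in comps.items()}, **comps
        ),
        travel_time_per_inperson_visit=0.95,
        employment_weight=1.0,
    )
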