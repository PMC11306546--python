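"""Monte Carlo propagation of input uncertainty to threshold credible intervals.

Each uncertain input (wages; overhead components with a recorded sd) is
sampled independently from a normal distribution around its geography-level
mean and sd, 10,000 draws by default. Draws below a small positive floor are
resampled — not clipped — so no point mass accumulates at the floor and means
stay unbiased for realistic sds. Cross-input covariation is represented only
through geography-level stratification: each geography carries its own means,
so inputs that move together across locations do so here too, without an
explicit covariance matrix.

Credible intervals are empirical percentiles (2.5/97.5 at the default 95%
level) of the per-draw threshold distribution.

Reproducibility: one master seed; geography i uses the i-th child of
``numpy.random.SeedSequence(seed)`` (PCG64), so results are bit-identical for
a fixed seed and independent of how many draws other geographies consume.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cost import ServiceModel, StaffingPlan, monthly_visit_capacity
from .errors import ConfigError, ValidationError
from .io import OVERHEAD_COMPONENTS, GeographyInputs, OverheadLedger, WageDistribution
from .thresholds import (
    ThresholdEstimate,
    aggregate,
    ffs_threshold,
    pmpm_threshold,
    summarize_draws,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings: draw count, seed, CI level, resampling floor."""

    n_draws: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    truncation_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigError(f"n_draws must be >= 1, got {self.n_draws!r}")
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level!r}")
        if not (math.isfinite(self.truncation_floor) and self.truncation_floor > 0):
            raise ConfigError("truncation_floor must be a positive dollar amount")
        if self.n_draws < 40 and self.ci_level >= 0.95:
            warnings.warn(
                f"n_draws={self.n_draws} is too small for stable {self.ci_level:.0%} "
                "percentile bounds",
                stacklevel=2,
            )

    @property
    def ci_percentiles(self) -> tuple[float, float]:
        alpha = 100.0 * (1.0 - self.ci_level) / 2.0
        return (alpha, 100.0 - alpha)


def geography_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    """Substream for the geography at position ``index`` in the table."""
    child = np.random.SeedSequence(config.seed).spawn(index + 1)[index]
    return np.random.Generator(np.random.PCG64(child))


def sample_truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    floor: float,
    size: int,
) -> np.ndarray:
    """Normal draws with values below ``floor`` replaced by resampling."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out < floor
    # resampling (not clipping) keeps the retained distribution smooth
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < floor
    return out


def draw_inputs(
    geo: GeographyInputs,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GeographyInputs:
    """One Monte Carlo realisation of a geography's uncertain inputs.

    Fields with sd = 0 pass through unchanged; sampled fields keep sd = 0 in
    the returned object (a realisation is certain).
    """
    draws = _draw_matrix(geo, config, rng, 1)
    chw = WageDistribution(mean=float(draws["chw"][0]))
    sup = {
        kind: WageDistribution(mean=float(draws[f"sup_{kind}"][0]))
        for kind in geo.supervisor_wages
    }
    ledger = OverheadLedger(
        **{comp: float(draws[f"oh_{comp}"][0]) for comp in OVERHEAD_COMPONENTS}
    )
    return replace(geo, chw_wage=chw, supervisor_wages=sup, overhead=ledger)


def _draw_matrix(
    geo: GeographyInputs,
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
) -> dict[str, np.ndarray]:
    """Draw vectors for every uncertain monetary input of one geography.

    Sampling order is fixed (CHW wage, supervisors in sorted-key order,
    overhead components in ledger order) so a given seed always yields the
    same realisations.
    """
    floor = config.truncation_floor
    draws = {"chw": sample_truncated_normal(rng, geo.chw_wage.mean, geo.chw_wage.sd, floor, n)}
    for kind in sorted(geo.supervisor_wages):
        w = geo.supervisor_wages[kind]
        draws[f"sup_{kind}"] = sample_truncated_normal(rng, w.mean, w.sd, floor, n)
    for comp, mean in geo.overhead.components().items():
        sd = geo.overhead.sd_of(comp)
        if sd == 0:
            draws[f"oh_{comp}"] = np.full(n, mean)
        else:
            # overhead components may genuinely be 0; floor only applies
            # to strictly positive means
            lo = floor if mean > 0 else 0.0
            draws[f"oh_{comp}"] = sample_truncated_normal(rng, mean, sd, lo, n)
    return draws


def _threshold_draws(
    geo: GeographyInputs,
    plan: StaffingPlan,
    svc: ServiceModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    travel_opportunity_in_overhead: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-draw FFS and PMPM thresholds for one geography."""
    if plan.supervisor_kind not in geo.supervisor_wages:
        raise ConfigError(f"{geo.geo_id}: no {plan.supervisor_kind} supervisor wage available")
    draws = _draw_matrix(geo, config, rng, config.n_draws)
    wage = draws["chw"]
    sup_wage = draws[f"sup_{plan.supervisor_kind}"]
    overhead_rate = sum(draws[f"oh_{comp}"] for comp in OVERHEAD_COMPONENTS)
    capacity = monthly_visit_capacity(
        svc,
        geo.travel_time_per_inperson_visit,
        plan,
        travel_opportunity_in_overhead=travel_opportunity_in_overhead,
    )
    annual = (wage + sup_wage / plan.supervisor_ratio + overhead_rate) * plan.annual_hours
    if travel_opportunity_in_overhead:
        travel_hours = (
            svc.inperson_share * geo.travel_time_per_inperson_visit * 12.0 * capacity
        )
        annual = annual + wage * travel_hours
    monthly = annual / 12.0
    return ffs_threshold(monthly, capacity), pmpm_threshold(monthly, svc.panel_size)


def _summarize(
    label: str,
    ffs: np.ndarray,
    pmpm: np.ndarray,
    svc: ServiceModel,
    config: SimulationConfig,
) -> ThresholdEstimate:
    lo_p, hi_p = config.ci_percentiles
    f_lo, f_hi = np.percentile(ffs, [lo_p, hi_p])
    p_lo, p_hi = np.percentile(pmpm, [lo_p, hi_p])
    f_mean, p_mean = float(ffs.mean()), float(pmpm.mean())
    return ThresholdEstimate(
        label=label,
        ffs_rate=f_mean,
        pmpm_rate=p_mean,
        ffs_ci_low=float(min(f_lo, f_mean)),
        ffs_ci_high=float(max(f_hi, f_mean)),
        pmpm_ci_low=float(min(p_lo, p_mean)),
        pmpm_ci_high=float(max(p_hi, p_mean)),
        panel_size=svc.panel_size,
        n_draws=int(ffs.size),
        draws_summary=summarize_draws(ffs, pmpm),
        ffs_draws=ffs,
        pmpm_draws=pmpm,
    )


def simulate_thresholds(
    geo: GeographyInputs,
    plan: StaffingPlan,
    svc: ServiceModel,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
    travel_opportunity_in_overhead: bool = False,
) -> ThresholdEstimate:
    """Monte Carlo threshold estimate for one geography.

    Point value is the mean of the per-draw thresholds; CI bounds are the
    empirical percentiles at ``config.ci_level``. The break-even identity
    (rate x volume = monthly cost) holds within every draw by construction.
    """
    rng = rng if rng is not None else geography_rng(config, 0)
    ffs, pmpm = _threshold_draws(
        geo, plan, svc, config, rng,
        travel_opportunity_in_overhead=travel_opportunity_in_overhead,
    )
    return _summarize(geo.geo_id, ffs, pmpm, svc, config)


def simulate_many(
    geos: Sequence[GeographyInputs],
    plan: StaffingPlan,
    svc: ServiceModel,
    config: SimulationConfig,
    *,
    travel_opportunity_in_overhead: bool = False,
) -> list[ThresholdEstimate]:
    """Per-geography estimates, each on its own seed substream."""
    if not geos:
        raise ValidationError("no geographies to simulate")
    out = []
    for i, geo in enumerate(geos):
        rng = geography_rng(config, i)
        ffs, pmpm = _threshold_draws(
            geo, plan, svc, config, rng,
            travel_opportunity_in_overhead=travel_opportunity_in_overhead,
        )
        out.append(_summarize(geo.geo_id, ffs, pmpm, svc, config))
    return out


def simulate_aggregate(
    geos: Sequence[GeographyInputs],
    plan: StaffingPlan,
    svc: ServiceModel,
    config: SimulationConfig,
    *,
    weights: Sequence[float] | None = None,
    label: str = "NATIONAL",
    pooling: str = "mean",
    estimates: Sequence[ThresholdEstimate] | None = None,
    travel_opportunity_in_overhead: bool = False,
) -> ThresholdEstimate:
    """Aggregate Monte Carlo estimate across geographies.

    pooling="mean" (default): per draw, take the (weighted) cross-geography
    mean threshold, then summarise those mean-draws — the CI reflects
    uncertainty in the aggregate mean. pooling="pooled": concatenate every
    geography's draws (weights repeat draws proportionally via percentile
    weighting) — the CI reflects the spread across geographies and draws
    combined, which is how wide national intervals arise from narrow
    per-geography ones.
    """
    if estimates is None:
        estimates = simulate_many(
            geos, plan, svc, config,
            travel_opportunity_in_overhead=travel_opportunity_in_overhead,
        )
    if pooling == "mean":
        return replace(aggregate(estimates, weights=weights, label=label), panel_size=svc.panel_size)
    if pooling != "pooled":
        raise ConfigError(f"unknown pooling mode {pooling!r}")
    n = len(estimates)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must match estimates and be non-negative with positive sum")
    ffs_all = np.concatenate([e.ffs_draws for e in estimates])
    pmpm_all = np.concatenate([e.pmpm_draws for e in estimates])
    w_all = np.concatenate([np.full(e.ffs_draws.size, wi / e.ffs_draws.size) for e, wi in zip(estimates, w)])
    w_all = w_all / w_all.sum()
    lo_p, hi_p = config.ci_percentiles
    f_lo, f_hi = _weighted_percentile(ffs_all, w_all, [lo_p, hi_p])
    p_lo, p_hi = _weighted_percentile(pmpm_all, w_all, [lo_p, hi_p])
    f_mean = float(np.dot(w_all, ffs_all))
    p_mean = float(np.dot(w_all, pmpm_all))
    return ThresholdEstimate(
        label=label,
        ffs_rate=f_mean,
        pmpm_rate=p_mean,
        ffs_ci_low=float(min(f_lo, f_mean)),
        ffs_ci_high=float(max(f_hi, f_mean)),
        pmpm_ci_low=float(min(p_lo, p_mean)),
        pmpm_ci_high=float(max(p_hi, p_mean)),
        panel_size=svc.panel_size,
        n_draws=int(ffs_all.size),
        draws_summary=summarize_draws(ffs_all, pmpm_all),
    )


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: Sequence[float]) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    return np.interp(np.asarray(q) / 100.0, cum, v)
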