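"""Break-even payment thresholds: FFS per visit and capitated PMPM.

Both thresholds are minima: the payment rate at which revenue exactly covers
the monthly cost of the CHW position, with no margin.

* FFS: rate per 30-minute visit (billing code 98960) = monthly cost /
  monthly visit volume.
* PMPM: capitated rate per concurrent panel member = monthly cost /
  panel size.

The inverse-panel law drives the panel sensitivity: holding per-CHW monthly
cost fixed, both thresholds scale by (reference panel / new panel) — PMPM
because the cost is spread over the members, FFS because visit volume is
proportional to panel size at fixed per-patient visit intensity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Percentile grid recorded in JSON results alongside the 95% CI.
PERCENTILE_GRID = (1.0, 2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5, 99.0)


@dataclass(frozen=True)
class ThresholdEstimate:
    """FFS and PMPM break-even rates for one geography or aggregate.

    ``ci_low``/``ci_high`` equal the point value in deterministic runs and
    are empirical credible-interval bounds after Monte Carlo. When draw
    vectors are retained (``ffs_draws``/``pmpm_draws``) downstream rescaling
    operates per draw, so CI bounds transform exactly with the point value.
    """

    label: str
    ffs_rate: float
    pmpm_rate: float
    ffs_ci_low: float = math.nan
    ffs_ci_high: float = math.nan
    pmpm_ci_low: float = math.nan
    pmpm_ci_high: float = math.nan
    panel_size: float = 65.0
    n_draws: int = 1
    draws_summary: dict | None = None
    ffs_draws: np.ndarray | None = field(default=None, repr=False, compare=False)
    pmpm_draws: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if math.isnan(self.ffs_ci_low):
            object.__setattr__(self, "ffs_ci_low", self.ffs_rate)
            object.__setattr__(self, "ffs_ci_high", self.ffs_rate)
        if math.isnan(self.pmpm_ci_low):
            object.__setattr__(self, "pmpm_ci_low", self.pmpm_rate)
            object.__setattr__(self, "pmpm_ci_high", self.pmpm_rate)
        if not (self.ffs_rate > 0 and self.pmpm_rate > 0):
            raise ValidationError(f"{self.label}: threshold rates must be > 0")
        tol = 1e-9 * max(1.0, self.ffs_rate, self.pmpm_rate)
        if (
            self.ffs_ci_low > self.ffs_rate + tol
            or self.ffs_ci_high < self.ffs_rate - tol
            or self.pmpm_ci_low > self.pmpm_rate + tol
            or self.pmpm_ci_high < self.pmpm_rate - tol
        ):
            raise ValidationError(f"{self.label}: CI bounds must bracket the point value")

    def to_dict(self) -> dict:
        out = {
            "label": self.label,
            "panel_size": self.panel_size,
            "n_draws": self.n_draws,
            "ffs_rate": self.ffs_rate,
            "ffs_ci_low": self.ffs_ci_low,
            "ffs_ci_high": self.ffs_ci_high,
            "pmpm_rate": self.pmpm_rate,
            "pmpm_ci_low": self.pmpm_ci_low,
            "pmpm_ci_high": self.pmpm_ci_high,
        }
        if self.draws_summary is not None:
            out["draws_summary"] = self.draws_summary
        return out


def summarize_draws(ffs_draws: np.ndarray, pmpm_draws: np.ndarray) -> dict:
    """Percentile grid over the retained draw vectors, for JSON output."""
    return {
        "percentiles": list(PERCENTILE_GRID),
        "ffs": [float(v) for v in np.percentile(ffs_draws, PERCENTILE_GRID)],
        "pmpm": [float(v) for v in np.percentile(pmpm_draws, PERCENTILE_GRID)],
    }


def pmpm_threshold(monthly_cost, panel_size):
    """Minimum capitated rate: monthly cost spread over the concurrent panel."""
    if np.any(np.asarray(panel_size) < 1):
        raise ValidationError("panel_size must be >= 1")
    if np.any(np.asarray(monthly_cost) <= 0):
        raise ValidationError("monthly_cost must be > 0")
    return monthly_cost / panel_size


def ffs_threshold(monthly_cost, monthly_visits):
    """Minimum fee-for-service rate: monthly cost spread over monthly visits."""
    if np.any(np.asarray(monthly_visits) <= 0):
        raise ValidationError("monthly_visits must be > 0")
    if np.any(np.asarray(monthly_cost) <= 0):
        raise ValidationError("monthly_cost must be > 0")
    return monthly_cost / monthly_visits


def rescale_by_panel(baseline_rate, baseline_panel, new_panel):
    """Inverse-panel rescaling of a break-even rate at fixed per-CHW cost.

    rate' = rate x baseline_panel / new_panel, so rate' x new_panel recovers
    the same monthly cost exactly. Applies to both PMPM and FFS (visit volume
    proportional to panel at fixed per-patient visit intensity).
    """
    for name, v in (
        ("baseline_rate", baseline_rate),
        ("baseline_panel", baseline_panel),
        ("new_panel", new_panel),
    ):
        if np.any(np.asarray(v) <= 0):
            raise ValidationError(f"{name} must be > 0")
    return baseline_rate * baseline_panel / new_panel


def rescale_estimate(est: ThresholdEstimate, new_panel: float) -> ThresholdEstimate:
    """Apply :func:`rescale_by_panel` to every stored quantity of an estimate.

    Point values, CI bounds and any retained draws all scale by the same
    factor, so credible intervals transform exactly with the mean.
    """
    factor = est.panel_size / new_panel
    if np.any(np.asarray(new_panel) <= 0):
        raise ValidationError("new_panel must be > 0")
    ffs_draws = None if est.ffs_draws is None else est.ffs_draws * factor
    pmpm_draws = None if est.pmpm_draws is None else est.pmpm_draws * factor
    summary = None
    if ffs_draws is not None and pmpm_draws is not None:
        summary = summarize_draws(ffs_draws, pmpm_draws)
    return replace(
        est,
        ffs_rate=est.ffs_rate * factor,
        ffs_ci_low=est.ffs_ci_low * factor,
        ffs_ci_high=est.ffs_ci_high * factor,
        pmpm_rate=est.pmpm_rate * factor,
        pmpm_ci_low=est.pmpm_ci_low * factor,
        pmpm_ci_high=est.pmpm_ci_high * factor,
        panel_size=new_panel,
        draws_summary=summary,
        ffs_draws=ffs_draws,
        pmpm_draws=pmpm_draws,
    )


def aggregate(
    estimates: Sequence[ThresholdEstimate],
    weights: Sequence[float] | None = None,
    label: str = "AGGREGATE",
) -> ThresholdEstimate:
    """Weighted arithmetic mean of estimates across geographies.

    With no weights (or all-equal weights) this is the unweighted mean. When
    every estimate carries draw vectors of equal length, the draws are
    averaged pointwise and the CI recomputed from the pooled-mean draws;
    otherwise CI bounds are averaged with the same weights.
    """
    if not estimates:
        raise ValidationError("no estimates to aggregate")
    n = len(estimates)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValidationError(f"weights length {w.size} != estimates length {n}")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative with positive sum")
    w = w / w.sum()

    def wmean(values: Sequence[float]) -> float:
        return float(np.dot(w, np.asarray(values, dtype=float)))

    have_draws = all(
        e.ffs_draws is not None
        and e.pmpm_draws is not None
        and e.ffs_draws.shape == estimates[0].ffs_draws.shape
        for e in estimates
    ) and estimates[0].ffs_draws is not None
    if have_draws:
        ffs_draws = np.tensordot(w, np.stack([e.ffs_draws for e in estimates]), axes=1)
        pmpm_draws = np.tensordot(w, np.stack([e.pmpm_draws for e in estimates]), axes=1)
        lo, hi = np.percentile(ffs_draws, [2.5, 97.5])
        plo, phi = np.percentile(pmpm_draws, [2.5, 97.5])
        return ThresholdEstimate(
            label=label,
            ffs_rate=float(ffs_draws.mean()),
            pmpm_rate=float(pmpm_draws.mean()),
            ffs_ci_low=float(min(lo, ffs_draws.mean())),
            ffs_ci_high=float(max(hi, ffs_draws.mean())),
            pmpm_ci_low=float(min(plo, pmpm_draws.mean())),
            pmpm_ci_high=float(max(phi, pmpm_draws.mean())),
            panel_size=estimates[0].panel_size,
            n_draws=int(ffs_draws.size),
            draws_summary=summarize_draws(ffs_draws, pmpm_draws),
            ffs_draws=ffs_draws,
            pmpm_draws=pmpm_draws,
        )
    return ThresholdEstimate(
        label=label,
        ffs_rate=wmean([e.ffs_rate for e in estimates]),
        ffs_ci_low=wmean([e.ffs_ci_low for e in estimates]),
        ffs_ci_high=wmean([e.ffs_ci_high for e in estimates]),
        pmpm_rate=wmean([e.pmpm_rate for e in estimates]),
        pmpm_ci_low=wmean([e.pmpm_ci_low for e in estimates]),
        pmpm_ci_high=wmean([e.pmpm_ci_high for e in estimates]),
        panel_size=estimates[0].panel_size,
        n_draws=max(e.n_draws for e in estimates),
    )
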