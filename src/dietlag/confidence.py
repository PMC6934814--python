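"""Confidence sequencing for the selected precedence periods.

For each nutrient, the full lag-scan grid is regrouped by that nutrient's
lag: fixing the lag at k and pooling the fits over all combinations of the
other nutrients' lags gives, per k, a mean fit statistic (Rmean) and its
spread. Three criteria each nominate a lag — the lag in the globally optimal
vector, the lag maximizing Rmean, and the lag minimizing the SD of Rmean —
and the spread of the three nominations is mapped onto a coarse star scale:
the tighter the agreement, the higher the confidence that the precedence
period is well determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NUTRIENTS
from .lags import OptimizationResult

#: SD-of-criterion-lags ranges (years) and their star labels, half-open
#: lower-inclusive: [0,2) ***, [2,5) **, [5,8) *, [8,inf) none.
STAR_BOUNDS: tuple[tuple[float, str], ...] = (
    (2.0, "***"),
    (5.0, "**"),
    (8.0, "*"),
    (float("inf"), ""),
)


def star_level(sd_precedence: float) -> str:
    """Map the SD of the three criterion lags to a star label."""
    if sd_precedence < 0:
        raise ValueError("sd_precedence must be non-negative")
    for bound, label in STAR_BOUNDS:
        if sd_precedence < bound:
            return label
    return ""


@dataclass(frozen=True)
class LagProfile:
    """Per-lag aggregates of the fit statistic for one nutrient.

    Entry k pools every usable lag vector whose component for this nutrient
    equals k: ``n`` combinations, their mean r (Rmean) and sample SD
    (SD = 0 when only one combination contributes).
    """

    nutrient: str
    r_mean: np.ndarray
    r_sd: np.ndarray
    n: np.ndarray

    @property
    def max_lag(self) -> int:
        return self.r_mean.size - 1


@dataclass(frozen=True)
class ConfidenceSummary:
    """Three criterion lags, their mean and SD, and the star level."""

    nutrient: str
    lag_at_r_optimal: int
    lag_at_max_rmean: int
    lag_at_min_sd: int
    mean_precedence: float
    sd_precedence: float
    stars: str

    @property
    def criterion_lags(self) -> tuple[int, int, int]:
        return (self.lag_at_r_optimal, self.lag_at_max_rmean, self.lag_at_min_sd)

    def to_dict(self) -> dict:
        return {
            "nutrient": self.nutrient,
            "lag_at_r_optimal": int(self.lag_at_r_optimal),
            "lag_at_max_rmean": int(self.lag_at_max_rmean),
            "lag_at_min_sd": int(self.lag_at_min_sd),
            "mean_precedence": float(self.mean_precedence),
            "sd_precedence": float(self.sd_precedence),
            "stars": self.stars,
        }


def lag_profile(result: OptimizationResult, nutrient: str) -> LagProfile:
    """Regroup the scan grid by one nutrient's lag.

    Unusable combinations (NaN in the grid) carry no fit statistic and are
    excluded from the aggregates.
    """
    if nutrient not in NUTRIENTS:
        raise KeyError(f"unknown nutrient {nutrient!r}; known: {list(NUTRIENTS)}")
    axis = NUTRIENTS.index(nutrient)
    L = result.max_lag + 1
    # rows: this nutrient's lag; columns: all combinations of the others
    grid = np.moveaxis(result.r_grid, axis, 0).reshape(L, -1)
    finite = np.isfinite(grid)
    n = finite.sum(axis=1)
    sums = np.where(finite, grid, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, sums / n, np.nan)
        sq = np.where(finite, (grid - mean[:, None]) ** 2, 0.0).sum(axis=1)
        sd = np.where(n > 1, np.sqrt(sq / np.maximum(n - 1, 1)), 0.0)
    sd = np.where(n == 0, np.nan, sd)
    return LagProfile(nutrient=nutrient, r_mean=mean, r_sd=sd, n=n)


def precedence_confidence(profile: LagProfile, optimal_lag: int) -> ConfidenceSummary:
    """Combine the three criterion lags into a mean precedence and stars.

    The criteria are the optimal-vector lag, the argmax of Rmean, and the
    argmin of the SD of Rmean (ties toward the smallest lag; lags with no
    usable combination are ignored). The SD of the three lags is the sample
    (n−1) SD, mapped onto the star scale by :func:`star_level`.
    """
    if not 0 <= optimal_lag <= profile.max_lag:
        raise ValueError(f"optimal_lag {optimal_lag} outside [0, {profile.max_lag}]")
    mean_masked = np.where(np.isfinite(profile.r_mean), profile.r_mean, -np.inf)
    sd_masked = np.where(np.isfinite(profile.r_sd), profile.r_sd, np.inf)
    lag_max_rmean = int(np.argmax(mean_masked))  # first occurrence = smallest lag
    lag_min_sd = int(np.argmin(sd_masked))
    crit = np.array([optimal_lag, lag_max_rmean, lag_min_sd], dtype=float)
    mean_prec = float(crit.mean())
    sd_prec = float(crit.std(ddof=1))
    return ConfidenceSummary(
        nutrient=profile.nutrient,
        lag_at_r_optimal=int(optimal_lag),
        lag_at_max_rmean=lag_max_rmean,
        lag_at_min_sd=lag_min_sd,
        mean_precedence=mean_prec,
        sd_precedence=sd_prec,
        stars=star_level(sd_prec),
    )


def confidence_table(result: OptimizationResult) -> list[ConfidenceSummary]:
    """One :class:`ConfidenceSummary` per nutrient for a completed scan."""
    out = []
    for i, nutrient in enumerate(NUTRIENTS):
        profile = lag_profile(result, nutrient)
        out.append(precedence_confidence(profile, result.optimal_lags[i]))
    return out
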