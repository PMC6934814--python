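"""Diet-composition grid search driven by a fitted calculator equation.

Candidate diets are enumerated on a per-nutrient gram grid, scored with the
linear calculator equation (predicted correlation), and the winner is the
diet that stays energetically closest to the period's historical mean
availability among those whose predicted correlation is within a small
tolerance of the grid minimum. Reported diets are rescaled to a common
energy (2000 kcal by default) so compositions are comparable across periods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import (
    KCAL_PER_GRAM,
    N_NUTRIENTS,
    NUTRIENTS,
    AnalysisConfig,
    DietComposition,
    LifePeriod,
    NutrientSeries,
    ValidationError,
    percent_energy,
    round_half_up,
    scale_to_energy,
)
from .lags import CalculatorFit


@dataclass(frozen=True)
class DietGridSpec:
    """Per-nutrient candidate gram values: low, low+step, ..., ≤ high."""

    low: np.ndarray
    high: np.ndarray
    step: np.ndarray

    def __post_init__(self) -> None:
        low = np.asarray(self.low, dtype=float)
        high = np.asarray(self.high, dtype=float)
        step = np.asarray(self.step, dtype=float)
        for name, arr in (("low", low), ("high", high), ("step", step)):
            if arr.shape != (N_NUTRIENTS,):
                raise ValidationError(f"DietGridSpec: {name} needs {N_NUTRIENTS} values")
        if np.any(low > high):
            raise ValidationError("DietGridSpec: low must not exceed high")
        if np.any(step <= 0):
            raise ValidationError("DietGridSpec: steps must be positive")
        if np.any(low < 0):
            raise ValidationError("DietGridSpec: bounds must be non-negative")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)
        object.__setattr__(self, "step", step)

    def values(self, i: int) -> np.ndarray:
        n = int(np.floor((self.high[i] - self.low[i]) / self.step[i] + 1e-9)) + 1
        return self.low[i] + self.step[i] * np.arange(n)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(self.values(i).size for i in range(N_NUTRIENTS))

    @property
    def grid_size(self) -> int:
        return int(np.prod(self.sizes))


@dataclass(frozen=True)
class SelectionPolicy:
    """Two-stage rule: keep diets within ``r_tolerance`` of the minimum
    predicted correlation, then pick the minimum energy difference."""

    r_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.r_tolerance < 0:
            raise ValidationError("r_tolerance must be non-negative")


@dataclass(frozen=True)
class OptimalDietReport:
    """Selected diet for one period, alongside the historical mean."""

    period: LifePeriod
    predicted: DietComposition
    mean: DietComposition
    r_predicted: float
    energy_difference_kcal: float
    report_kcal: float = 2000.0

    @property
    def predicted_scaled(self) -> DietComposition:
        return scale_to_energy(self.predicted, self.report_kcal)

    @property
    def mean_scaled(self) -> DietComposition:
        return scale_to_energy(self.mean, self.report_kcal)

    def to_dict(self) -> dict:
        return {
            "period": self.period.name,
            "predicted_grams": self.predicted.as_dict(),
            "mean_grams": self.mean.as_dict(),
            "predicted_grams_scaled": self.predicted_scaled.as_dict(),
            "mean_grams_scaled": self.mean_scaled.as_dict(),
            "predicted_percent_energy": dict(
                zip(NUTRIENTS, percent_energy(self.predicted).tolist())
            ),
            "mean_percent_energy": dict(
                zip(NUTRIENTS, percent_energy(self.mean).tolist())
            ),
            "r_predicted": float(self.r_predicted),
            "energy_difference_kcal": float(self.energy_difference_kcal),
            "report_kcal": float(self.report_kcal),
        }


def mean_availability(series: NutrientSeries, period: LifePeriod) -> DietComposition:
    """Arithmetic mean grams over the period's years, with no lag shifting."""
    return DietComposition(grams=series.at(period.years).mean(axis=0))


def rpredicted(fit: CalculatorFit, diet: DietComposition) -> float:
    """Predicted correlation for a diet: alpha + sum_i beta_i · grams_i.

    Deliberately not clamped to [−1, 1]: it is a model extrapolation, and
    clamping would hide how far outside the fitted range a diet sits.
    """
    return float(fit.alpha + diet.grams @ fit.betas)


def energy_difference(
    a: DietComposition, b: DietComposition, mode: str = "absolute"
) -> float:
    """kcal distance between two diets, summed per nutrient.

    "absolute" (default) sums kcal_i·|a_i − b_i| and is a metric on diets;
    "signed" sums kcal_i·(a_i − b_i), letting surpluses cancel deficits.
    """
    delta = a.grams - b.grams
    if mode == "absolute":
        return float(KCAL_PER_GRAM @ np.abs(delta))
    if mode == "signed":
        return float(KCAL_PER_GRAM @ delta)
    raise ValidationError("energy_difference mode must be 'absolute' or 'signed'")


def default_grid(
    series: NutrientSeries,
    period: LifePeriod,
    config: AnalysisConfig | None = None,
) -> DietGridSpec:
    """Grid bounds from the period's observed range, snapped outward.

    Per nutrient the bounds are [0.5·min, 1.5·max] of the grams observed in
    the period, rounded outward to multiples of the step so historical
    values sit on the grid.
    """
    config = config or AnalysisConfig()
    obs = series.at(period.years)
    step = np.asarray(config.grid_steps, dtype=float)
    lo = np.floor(config.grid_range[0] * obs.min(axis=0) / step) * step
    hi = np.ceil(config.grid_range[1] * obs.max(axis=0) / step) * step
    return DietGridSpec(low=np.maximum(lo, 0.0), high=hi, step=step)


def _blocks(values: list[np.ndarray], max_block: int = 1 << 20):
    """Yield the grid in lexicographic order as (prefix_grams, tail_grid).

    ``tail_grid`` is a (B, n_tail) array of trailing-nutrient gram values in
    lexicographic order; the same array object is reused across prefixes.
    """
    sizes = [v.size for v in values]
    split = len(values)
    tail = 1
    while split > 0 and tail * sizes[split - 1] <= max_block:
        tail *= sizes[split - 1]
        split -= 1
    tail_vals = values[split:]
    if tail_vals:
        mesh = np.meshgrid(*tail_vals, indexing="ij")
        tail_grid = np.column_stack([m.ravel() for m in mesh])
    else:
        tail_grid = np.zeros((1, 0))
    for prefix in itertools.product(*values[:split]):
        yield np.asarray(prefix, dtype=float), tail_grid


def optimize_diet(
    fit: CalculatorFit,
    mean_diet: DietComposition,
    grid: DietGridSpec,
    policy: SelectionPolicy | None = None,
    config: AnalysisConfig | None = None,
) -> OptimalDietReport:
    """Scan the diet grid and select the optimal predicted diet.

    Pass 1 finds the grid minimum of the objective (the predicted
    correlation itself, or its absolute value under ``r_objective =
    "absolute"``). Pass 2 keeps diets within ``r_tolerance`` of that minimum
    and selects the one with the smallest energy difference from the
    period's mean diet, ties broken by the lexicographically smallest gram
    vector. Selection happens on raw grams; rescaling to the report energy
    is presentation only.
    """
    config = config or AnalysisConfig()
    policy = policy or SelectionPolicy(r_tolerance=config.r_tolerance)
    if grid.grid_size == 0:
        raise ValidationError("optimize_diet: empty grid")
    values = [grid.values(i) for i in range(N_NUTRIENTS)]
    betas = fit.betas
    signed_obj = config.r_objective == "signed"

    def objective(rp: np.ndarray) -> np.ndarray:
        return rp if signed_obj else np.abs(rp)

    # pass 1: grid minimum of the objective
    best_obj = np.inf
    for prefix, tail in _blocks(values):
        k = prefix.size
        rp = fit.alpha + prefix @ betas[:k] + tail @ betas[k:]
        best_obj = min(best_obj, float(objective(rp).min()))

    # pass 2: minimum energy difference within the tolerance band
    cutoff = best_obj + policy.r_tolerance
    best_ed = np.inf
    best_grams: np.ndarray | None = None
    m = mean_diet.grams
    for prefix, tail in _blocks(values):
        k = prefix.size
        rp = fit.alpha + prefix @ betas[:k] + tail @ betas[k:]
        cand = objective(rp) <= cutoff
        if not np.any(cand):
            continue
        if config.energy_diff_mode == "absolute":
            ed = KCAL_PER_GRAM[:k] @ np.abs(prefix - m[:k]) + np.abs(
                tail - m[k:]
            ) @ KCAL_PER_GRAM[k:]
        else:
            ed = np.abs(
                KCAL_PER_GRAM[:k] @ (prefix - m[:k]) + (tail - m[k:]) @ KCAL_PER_GRAM[k:]
            )
        ed = np.where(cand, ed, np.inf)
        j = int(np.argmin(ed))  # first minimum = lexicographically smallest tail
        if ed[j] < best_ed:
            best_ed = float(ed[j])
            best_grams = np.concatenate([prefix, tail[j]])
    assert best_grams is not None
    chosen = DietComposition(grams=best_grams)
    return OptimalDietReport(
        period=fit.period or LifePeriod("unspecified", 0, 1),
        predicted=chosen,
        mean=mean_diet,
        r_predicted=rpredicted(fit, chosen),
        energy_difference_kcal=energy_difference(chosen, mean_diet, config.energy_diff_mode),
        report_kcal=config.report_kcal,
    )


def build_report(reports: list[OptimalDietReport], rounded: bool = True):
    """Assemble the cross-period comparison table.

    Rows are nutrient × {predicted, mean}; columns are a (measure, period)
    MultiIndex with percent-of-energy shares and grams/day at the common
    report energy. Values are rounded half-up to integers at output only
    (``rounded=False`` returns full precision).
    """
    import pandas as pd

    measures = {}
    for rep in reports:
        for kind, diet in (("predicted", rep.predicted), ("mean", rep.mean)):
            scaled = scale_to_energy(diet, rep.report_kcal)
            measures[("percent", rep.period.name, kind)] = percent_energy(scaled)
            measures[("grams", rep.period.name, kind)] = scaled.grams
    rows = []
    index = []
    for kind in ("predicted", "mean"):
        for i, nutrient in enumerate(NUTRIENTS):
            index.append((kind, nutrient))
            rows.append(
                [
                    measures[(measure, rep.period.name, kind)][i]
                    for measure in ("percent", "grams")
                    for rep in reports
                ]
            )
    cols = pd.MultiIndex.from_tuples(
        [
            (measure, rep.period.name)
            for measure in ("percent", "grams")
            for rep in reports
        ],
        names=["measure", "period"],
    )
    df = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["diet", "nutrient"]), columns=cols
    )
    if rounded:
        df = df.apply(round_half_up).astype(int)
    return df
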