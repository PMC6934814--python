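"""Domain types and energy arithmetic shared by every pipeline stage.

The pipeline relates yearly per-capita macronutrient availability (grams/day)
to a yearly ecological correlation series. Five macronutrients are tracked in
a fixed canonical order: carbohydrates, protein, saturated fat,
monounsaturated fat, polyunsaturated fat. Energy conversion uses the standard
Atwater-style factors 4 kcal/g for carbohydrates and protein and 9 kcal/g for
every fat class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical nutrient order used by every array in the package.
NUTRIENTS: tuple[str, ...] = (
    "carbohydrates",
    "protein",
    "sat_fat",
    "mono_fat",
    "poly_fat",
)

N_NUTRIENTS = len(NUTRIENTS)

#: kcal per gram in canonical nutrient order (carbs 4, protein 4, fats 9).
KCAL_PER_GRAM = np.array([4.0, 4.0, 9.0, 9.0, 9.0])


class ValidationError(ValueError):
    """Input data violates a structural invariant (named cell in message)."""


class InsufficientDataError(ValueError):
    """Too few usable observations to identify the model."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient; offending columns are named."""


@dataclass(frozen=True)
class EnergyConstants:
    """Energy conversion factors, kcal per gram, canonical nutrient order."""

    kcal_per_gram: tuple[float, ...] = (4.0, 4.0, 9.0, 9.0, 9.0)

    def __post_init__(self) -> None:
        if len(self.kcal_per_gram) != N_NUTRIENTS:
            raise ValidationError("kcal_per_gram must have one entry per nutrient")
        if any(k <= 0 for k in self.kcal_per_gram):
            raise ValidationError("kcal_per_gram entries must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.kcal_per_gram, dtype=float)


DEFAULT_ENERGY = EnergyConstants()


def _validate_years(years: np.ndarray, what: str) -> None:
    if years.size == 0:
        raise ValidationError(f"{what}: empty year span")
    diffs = np.diff(years)
    if years.size > 1 and not np.all(diffs == 1):
        bad = int(years[np.argmax(diffs != 1)])
        raise ValidationError(
            f"{what}: years must be contiguous with step 1; gap after year {bad}"
        )


@dataclass(frozen=True)
class NutrientSeries:
    """Yearly availability panel: one row per calendar year, five columns.

    Parameters
    ----------
    years
        Contiguous, strictly increasing integer calendar years.
    values
        Array of shape ``(len(years), 5)`` of non-negative grams/day/capita in
        canonical nutrient order.
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        _validate_years(years, "NutrientSeries")
        if values.shape != (years.size, N_NUTRIENTS):
            raise ValidationError(
                f"NutrientSeries: values shape {values.shape} does not match "
                f"({years.size}, {N_NUTRIENTS})"
            )
        if not np.all(np.isfinite(values)):
            yi, ni = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"NutrientSeries: non-finite value at year {years[yi]}, "
                f"column {NUTRIENTS[ni]}"
            )
        if np.any(values < 0):
            yi, ni = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"NutrientSeries: negative value at year {years[yi]}, "
                f"column {NUTRIENTS[ni]}"
            )

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def __len__(self) -> int:
        return self.years.size

    def column(self, nutrient: str) -> np.ndarray:
        """Values for one nutrient over the whole span."""
        return self.values[:, NUTRIENTS.index(nutrient)]

    def at(self, years: np.ndarray) -> np.ndarray:
        """Rows for the given years (must all be covered)."""
        years = np.asarray(years, dtype=int)
        if years.min() < self.start_year or years.max() > self.end_year:
            raise ValidationError(
                f"NutrientSeries: year span {years.min()}-{years.max()} not "
                f"covered by {self.start_year}-{self.end_year}"
            )
        return self.values[years - self.start_year]


@dataclass(frozen=True)
class RSeries:
    """Yearly correlation series: one value in [-1, 1] per calendar year.

    Each value is the Pearson correlation, across US states, between that
    year's per-capita personal income and a fixed per-state age-adjusted death
    rate — the response the lag calculator is fitted to.
    """

    years: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "r", r)
        _validate_years(years, "RSeries")
        if r.shape != (years.size,):
            raise ValidationError("RSeries: r must have one value per year")
        finite = np.isfinite(r)
        if np.any(np.abs(r[finite]) > 1):
            bad = int(years[finite][np.argmax(np.abs(r[finite]) > 1)])
            raise ValidationError(f"RSeries: |r| > 1 at year {bad}")

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def __len__(self) -> int:
        return self.years.size

    def at(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=int)
        if years.min() < self.start_year or years.max() > self.end_year:
            raise ValidationError(
                f"RSeries: year span {years.min()}-{years.max()} not covered "
                f"by {self.start_year}-{self.end_year}"
            )
        return self.r[years - self.start_year]


@dataclass(frozen=True)
class LifePeriod:
    """A calendar window over which one calculator equation is fitted.

    Boundary years are inclusive at both ends, so adjacent default periods
    share their boundary year (1949 belongs to both youth and early middle
    age).
    """

    name: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValidationError(
                f"LifePeriod {self.name}: start_year must precede end_year"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def __len__(self) -> int:
        return self.end_year - self.start_year + 1


#: The four default life periods, boundary-inclusive.
DEFAULT_PERIODS: tuple[LifePeriod, ...] = (
    LifePeriod("youth", 1929, 1949),
    LifePeriod("early_middle_age", 1949, 1970),
    LifePeriod("late_middle_age", 1970, 1990),
    LifePeriod("late_age", 1990, 2005),
)


def period_by_name(name: str, periods: Sequence[LifePeriod] = DEFAULT_PERIODS) -> LifePeriod:
    for p in periods:
        if p.name == name:
            return p
    raise KeyError(f"unknown life period {name!r}; known: {[p.name for p in periods]}")


@dataclass(frozen=True)
class DietComposition:
    """Grams/day of each macronutrient, with derived energy and shares."""

    grams: np.ndarray
    constants: EnergyConstants = DEFAULT_ENERGY

    def __post_init__(self) -> None:
        grams = np.asarray(self.grams, dtype=float)
        object.__setattr__(self, "grams", grams)
        if grams.shape != (N_NUTRIENTS,):
            raise ValidationError(
                f"DietComposition: expected {N_NUTRIENTS} gram values, got shape {grams.shape}"
            )
        if np.any(grams < 0) or not np.all(np.isfinite(grams)):
            bad = NUTRIENTS[int(np.argmax((grams < 0) | ~np.isfinite(grams)))]
            raise ValidationError(f"DietComposition: invalid grams for {bad}")

    @property
    def energy_kcal(self) -> float:
        return float(self.grams @ self.constants.array)

    @property
    def percent_energy(self) -> np.ndarray:
        return percent_energy(self)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(NUTRIENTS, self.grams.tolist()))


def energy_of(diet: DietComposition, constants: EnergyConstants | None = None) -> float:
    """Total energy of a diet in kcal: 4·CH + 4·P + 9·(SF + MUF + PUF)."""
    constants = constants or diet.constants
    return float(diet.grams @ constants.array)


def scale_to_energy(diet: DietComposition, target_kcal: float) -> DietComposition:
    """Rescale all grams so total energy equals ``target_kcal`` exactly.

    Macronutrient proportions (percent of energy) are unchanged.
    """
    if target_kcal <= 0:
        raise ValidationError("scale_to_energy: target_kcal must be positive")
    e = energy_of(diet)
    if e <= 0:
        raise ValidationError("scale_to_energy: cannot scale a zero-energy diet")
    return replace(diet, grams=diet.grams * (target_kcal / e))


def percent_energy(diet: DietComposition) -> np.ndarray:
    """Percent-of-energy share per nutrient; shares sum to 100."""
    e = energy_of(diet)
    if e <= 0:
        raise ValidationError("percent_energy: undefined for a zero-energy diet")
    return 100.0 * diet.grams * diet.constants.array / e


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer with ties going up (report-time only)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable knobs of the pipeline, with defaults matching the study.

    Attributes
    ----------
    max_lag
        Largest back shift, in whole years, tried per nutrient (default 20,
        giving a 21^5 = 4,084,101 combination grid).
    periods
        Life periods to fit, boundary-inclusive.
    grid_steps
        Gram step of the diet search grid per nutrient; 5 g for all but
        polyunsaturated fat, which uses 1 g because its realistic range is
        narrower than one 5 g step.
    grid_range
        (lo_factor, hi_factor) applied to the period's observed min/max grams
        when deriving default diet-grid bounds.
    r_tolerance
        Width of the predicted-correlation band inside which diets compete on
        energy difference (default 0.01).
    report_kcal
        Common energy scale of reported diets (default 2000 kcal).
    min_rows
        Minimum usable observations per fit; 7 = parameters + 1.
    coverage
        "per_combination": years lacking lagged coverage are dropped per lag
        combination (default). "common_window": every combination is
        restricted to the window usable at max_lag.
    energy_diff_mode
        "absolute" (default) sums per-nutrient |gram difference| in kcal;
        "signed" lets surpluses and deficits cancel.
    r_objective
        "signed" (default) minimizes the predicted correlation itself;
        "absolute" drives it toward zero.
    seed
        Seed for every stochastic component.
    """

    max_lag: int = 20
    periods: tuple[LifePeriod, ...] = DEFAULT_PERIODS
    grid_steps: tuple[float, ...] = (5.0, 5.0, 5.0, 5.0, 1.0)
    grid_range: tuple[float, float] = (0.5, 1.5)
    r_tolerance: float = 0.01
    report_kcal: float = 2000.0
    min_rows: int = 7
    coverage: str = "per_combination"
    energy_diff_mode: str = "absolute"
    r_objective: str = "signed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValidationError("max_lag must be non-negative")
        if any(s <= 0 for s in self.grid_steps):
            raise ValidationError("grid steps must be positive")
        if self.r_tolerance < 0:
            raise ValidationError("r_tolerance must be non-negative")
        if self.report_kcal <= 0:
            raise ValidationError("report_kcal must be positive")
        if self.min_rows < N_NUTRIENTS + 2:
            raise ValidationError("min_rows must exceed the parameter count")
        if self.coverage not in ("per_combination", "common_window"):
            raise ValidationError("coverage must be per_combination or common_window")
        if self.energy_diff_mode not in ("absolute", "signed"):
            raise ValidationError("energy_diff_mode must be absolute or signed")
        if self.r_objective not in ("signed", "absolute"):
            raise ValidationError("r_objective must be signed or absolute")

    def to_dict(self) -> dict:
        return {
            "max_lag": self.max_lag,
            "periods": [
                {"name": p.name, "start_year": p.start_year, "end_year": p.end_year}
                for p in self.periods
            ],
            "grid_steps": list(self.grid_steps),
            "grid_range": list(self.grid_range),
            "r_tolerance": self.r_tolerance,
            "report_kcal": self.report_kcal,
            "min_rows": self.min_rows,
            "coverage": self.coverage,
            "energy_diff_mode": self.energy_diff_mode,
            "r_objective": self.r_objective,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "periods" in d:
            d["periods"] = tuple(
                LifePeriod(p["name"], p["start_year"], p["end_year"])
                for p in d["periods"]
            )
        for key in ("grid_steps", "grid_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
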