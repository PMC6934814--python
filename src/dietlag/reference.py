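"""Published reference diets used as worked-example inputs.

These are the published 2000-kcal-scaled diet compositions for the four
life periods of the US 1929–2005 analysis this package implements: the
predicted optimal diets and the corresponding historical mean availability
diets, in grams/day per capita, canonical nutrient order (carbohydrates,
protein, saturated fat, monounsaturated fat, polyunsaturated fat). The
matching published percent-of-energy shares are included so the energy
arithmetic (4/4/9 kcal per gram, integer rounding at report time) can be
checked against them.
"""

from __future__ import annotations

import numpy as np

PERIOD_NAMES: tuple[str, ...] = (
    "youth",
    "early_middle_age",
    "late_middle_age",
    "late_age",
)

#: Predicted optimal diets, grams/day at the 2000 kcal scale, per period.
PREDICTED_GRAMS: dict[str, np.ndarray] = {
    "youth": np.array([269.0, 57.0, 33.0, 30.0, 14.0]),
    "early_middle_age": np.array([269.0, 34.0, 37.0, 37.0, 14.0]),
    "late_middle_age": np.array([251.0, 31.0, 38.0, 40.0, 19.0]),
    "late_age": np.array([218.0, 84.0, 35.0, 33.0, 19.0]),
}

#: Historical mean availability diets, grams/day at the 2000 kcal scale.
MEAN_GRAMS: dict[str, np.ndarray] = {
    "youth": np.array([275.0, 58.0, 34.0, 31.0, 10.0]),
    "early_middle_age": np.array([254.0, 60.0, 35.0, 35.0, 13.0]),
    "late_middle_age": np.array([241.0, 64.0, 32.0, 37.0, 17.0]),
    "late_age": np.array([247.0, 61.0, 29.0, 38.0, 17.0]),
}

#: Published percent-of-energy shares for the predicted diets.
PREDICTED_PERCENT: dict[str, np.ndarray] = {
    "youth": np.array([54.0, 11.0, 14.0, 14.0, 7.0]),
    "early_middle_age": np.array([54.0, 7.0, 17.0, 16.0, 6.0]),
    "late_middle_age": np.array([50.0, 6.0, 17.0, 18.0, 9.0]),
    "late_age": np.array([43.0, 17.0, 16.0, 15.0, 9.0]),
}

#: Published percent-of-energy shares for the mean diets.
MEAN_PERCENT: dict[str, np.ndarray] = {
    "youth": np.array([55.0, 12.0, 15.0, 14.0, 4.0]),
    "early_middle_age": np.array([51.0, 12.0, 15.0, 16.0, 6.0]),
    "late_middle_age": np.array([48.0, 13.0, 14.0, 17.0, 8.0]),
    "late_age": np.array([50.0, 12.0, 13.0, 17.0, 8.0]),
}
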