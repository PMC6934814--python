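"""CSV and JSON carriers for series and result objects.

File dialect: comma-separated UTF-8 with a header row. Canonical column
names are ``year``, the five nutrient columns (``carbohydrates``,
``protein``, ``sat_fat``, ``mono_fat``, ``poly_fat``) and ``r``. Column
order in the file is irrelevant; on read everything is normalized to the
canonical order. Floats are written with 17 significant digits so a
write-then-read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NUTRIENTS, NutrientSeries, RSeries, ValidationError

_FLOAT_FMT = "%.17g"


def read_nutrient_series(path: str | Path) -> NutrientSeries:
    """Read a yearly availability panel from CSV.

    The file must contain a ``year`` column and one column per nutrient;
    columns may appear in any order. Years must be contiguous and all values
    non-negative, otherwise a :class:`ValidationError` names the offending
    cell.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("year", *NUTRIENTS) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    df = df.sort_values("year")
    return NutrientSeries(
        years=df["year"].to_numpy(dtype=int),
        values=df[list(NUTRIENTS)].to_numpy(dtype=float),
    )


def write_nutrient_series(series: NutrientSeries, path: str | Path) -> None:
    df = pd.DataFrame({"year": series.years})
    for i, name in enumerate(NUTRIENTS):
        df[name] = series.values[:, i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_r_series(path: str | Path) -> RSeries:
    """Read a yearly correlation series (columns ``year``, ``r``) from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("year", "r") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    df = df.sort_values("year")
    return RSeries(
        years=df["year"].to_numpy(dtype=int),
        r=df["r"].to_numpy(dtype=float),
    )


def write_r_series(series: RSeries, path: str | Path) -> None:
    pd.DataFrame({"year": series.years, "r": series.r}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def dump_json(obj: dict, path: str | Path) -> None:
    """Write a result object deterministically (sorted keys, fixed layout)."""
    Path(path).write_text(
        json.dumps(_plain(obj), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj
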