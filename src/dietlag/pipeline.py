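"""End-to-end pipeline: lag scan → confidence → diet optimization → report.

Each stage writes its result to a deterministic JSON/CSV artifact so a run
is fully reproducible and individual stages can be re-examined. A manifest
records the configuration, input digests, package version, and per-stage
timings; everything except the timings is bit-stable across reruns on
identical inputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .confidence import ConfidenceSummary, confidence_table
from .core import AnalysisConfig, NutrientSeries, RSeries
from .diet import (
    OptimalDietReport,
    SelectionPolicy,
    build_report,
    default_grid,
    mean_availability,
    optimize_diet,
)
from .io import dump_json, read_nutrient_series, read_r_series
from .lags import OptimizationResult, global_optimize


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    inputs: dict
    version: str
    timings_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "inputs": self.inputs,
            "version": self.version,
            "timings_s": self.timings_s,
            "outputs": self.outputs,
        }


@dataclass
class PipelineResult:
    """In-memory results of a full run, one entry per life period."""

    optimizations: dict[str, OptimizationResult]
    confidences: dict[str, list[ConfidenceSummary]]
    diets: dict[str, OptimalDietReport]
    manifest: RunManifest

    @property
    def report(self):
        return build_report([self.diets[p] for p in self.diets])


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    series_path: str | Path,
    r_path: str | Path,
    out_dir: str | Path,
    progress: bool = False,
) -> PipelineResult:
    """Run the full calculator on a series/response pair and write artifacts.

    Per life period: exhaustive lag scan, per-nutrient confidence summary,
    historical mean availability, diet-grid optimization. Finishes with the
    cross-period comparison table. Any stage error aborts with the stage
    name and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        inputs={
            "series": {"path": str(series_path), "sha256": _sha256(series_path)},
            "r": {"path": str(r_path), "sha256": _sha256(r_path)},
        },
        version=__version__,
    )

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        return result

    series = _stage("read_series", read_nutrient_series, series_path)
    r = _stage("read_r", read_r_series, r_path)

    optimizations: dict[str, OptimizationResult] = {}
    confidences: dict[str, list[ConfidenceSummary]] = {}
    diets: dict[str, OptimalDietReport] = {}
    for period in config.periods:
        opt = _stage(f"optimize_lags[{period.name}]", global_optimize, series, r, period, config)
        conf = _stage(f"confidence[{period.name}]", confidence_table, opt)
        mean = _stage(f"mean_availability[{period.name}]", mean_availability, series, period)
        grid = default_grid(series, period, config)
        diet = _stage(
            f"optimize_diet[{period.name}]",
            optimize_diet,
            opt.optimal_fit,
            mean,
            grid,
            SelectionPolicy(r_tolerance=config.r_tolerance),
            config,
        )
        optimizations[period.name] = opt
        confidences[period.name] = conf
        diets[period.name] = diet
        if progress:
            print(
                f"[{period.name}] lags={opt.optimal_lags} "
                f"R_optimal={opt.r_optimal:.4f} R_predicted={diet.r_predicted:.4f}"
            )
        _write(out, manifest, f"optimization_{period.name}.json", opt.to_dict())
        _write(
            out,
            manifest,
            f"confidence_{period.name}.json",
            {"period": period.name, "nutrients": [c.to_dict() for c in conf]},
        )
        _write(out, manifest, f"diet_{period.name}.json", diet.to_dict())

    table = build_report([diets[p.name] for p in config.periods])
    table_path = out / "report.csv"
    table.to_csv(table_path)
    manifest.outputs.append(str(table_path))
    dump_json(manifest.to_dict(), out / "manifest.json")
    return PipelineResult(
        optimizations=optimizations,
        confidences=confidences,
        diets=diets,
        manifest=manifest,
    )


def _write(out: Path, manifest: RunManifest, name: str, obj: dict) -> None:
    path = out / name
    dump_json(obj, path)
    manifest.outputs.append(str(path))
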