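"""Configuration, recording IO and the end-to-end analysis pipeline.

The pipeline chains: simulate (or read recordings) -> multilevel maps ->
min-max normalization -> feature assembly -> leave-one-session-out kNN ->
report tables and figures.  Every run writes a manifest echoing all
parameters in effect, library versions, per-stage timings and drop counts,
so a run is reproducible from its output directory alone.

Recordings travel as plain delimited text (CSV) with one sample per row:
``participant, session, point, sample_index, velocity`` (or ``position``,
which is routed through two-point differentiation).  There is no entrenched
eye-tracker export standard, so the column schema is the package's own and
is documented in the README.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .classify import FeatureSpec, accuracy_table, assemble_features, knn_loso_cv
from .measures import ApEnParams, FuzEnParams
from .mlmap import LLEMapParams, MapCollection, VelocitySeries, plot_map
from .synth import SyntheticConfig, differentiate_positions, generate_dataset

logger = logging.getLogger("emmap.pipeline")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_recordings",
    "write_recordings",
    "run_pipeline",
]

RECORDING_COLUMNS = ("participant", "session", "point", "sample_index")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


class SynthSection(BaseModel):
    """Synthetic-dataset block of the pipeline config (see SyntheticConfig)."""

    n_participants: int = 5
    n_sessions: int = 2
    n_points: int = 2
    rate: int = 1000
    duration_ms: int = 1024
    latency_mean_ms: float = 170.0
    latency_sd_ms: float = 25.0
    latency_bounds_ms: tuple[float, float] = (100.0, 250.0)
    measurement_noise_sd: float = 1.0
    excluded_sessions: tuple[tuple[int, int], ...] = ()

    def to_config(self, seed: int) -> SyntheticConfig:
        return SyntheticConfig(seed=seed, **self.model_dump())


class ApEnSection(BaseModel):
    m: int = 2
    r_coef: float = 0.2
    r_scope: Literal["whole_series", "segment"] = "whole_series"

    def to_params(self) -> ApEnParams:
        return ApEnParams(**self.model_dump())


class FuzEnSection(BaseModel):
    m: int = 2
    n: float = 2.0
    r_coef: float = 0.075
    r_scope: Literal["whole_series", "segment"] = "whole_series"

    def to_params(self) -> FuzEnParams:
        return FuzEnParams(**self.model_dump())


class LLESection(BaseModel):
    mode: Literal["paper_average", "rosenstein_slope"] = "paper_average"
    follow_steps: int = 10
    selection: Literal["fnn_mi_auto", "fixed"] = "fnn_mi_auto"
    fixed_m: int = 2
    fixed_tau: int = 1

    def to_params(self) -> LLEMapParams:
        return LLEMapParams(**self.model_dump())


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration.

    An invalid config raises before any stage runs, so no partial outputs
    are produced.
    """

    seed: int = 0
    input_path: str | None = None  # None -> simulate
    input_kind: Literal["velocity", "position"] = "velocity"
    strict_length: bool = True
    truncate: bool = False
    nss: int = 64
    measures: tuple[str, ...] = ("ApEn", "FuzEn", "LLE")
    synth: SynthSection = Field(default_factory=SynthSection)
    apen: ApEnSection = Field(default_factory=ApEnSection)
    fuzen: FuzEnSection = Field(default_factory=FuzEnSection)
    lle: LLESection = Field(default_factory=LLESection)
    specs: tuple[str, ...] = ("set64_ApEn", "set64_128_256_ApEn_FuzEn_LLE")
    k_grid: tuple[int, ...] = (3, 7)
    normalization: Literal["paper", "fold_safe"] = "paper"
    first_n_segments: int = 4
    figures: bool = True
    log_level: str = "INFO"

    @field_validator("measures")
    @classmethod
    def _known_measures(cls, v):
        from .mlmap import MEASURES

        bad = [m for m in v if m not in MEASURES]
        if bad:
            raise ValueError(f"unknown measures {bad}")
        return v

    @field_validator("specs")
    @classmethod
    def _parse_specs(cls, v):
        for name in v:
            FeatureSpec.from_name(name)  # raises on malformed names
        return v

    @field_validator("k_grid")
    @classmethod
    def _positive_k(cls, v):
        if any(k < 1 for k in v):
            raise ValueError("all k must be >= 1")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        return cls(**payload)


def write_recordings(series_list: Sequence[VelocitySeries], path: str | Path) -> None:
    """Write a dataset as one long-format CSV (one sample per row)."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "participant": s.participant_id,
                    "session": s.session_id,
                    "point": s.point_id,
                    "sample_index": np.arange(s.n_samples),
                    "velocity": s.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recordings(
    path: str | Path,
    kind: Literal["velocity", "position"] = "velocity",
    rate: int = 1000,
    expected_samples: int | None = 1024,
    strict: bool = True,
    truncate: bool = False,
) -> list[VelocitySeries]:
    """Read recordings from delimited text, grouped by (participant, session, point).

    Position-format inputs are differentiated into velocity (two-point forward
    difference), which shortens each series by one sample; supply
    ``expected_samples`` accordingly (it applies to the resulting velocity
    series).  Series of the wrong length are truncated when ``truncate`` is
    set, rejected (and counted) in ``strict`` mode, or passed through
    otherwise.  Malformed (non-numeric / missing) rows are dropped with their
    line numbers logged.
    """
    value_col = "position" if kind == "position" else "velocity"
    df = pd.read_csv(path)
    required = set(RECORDING_COLUMNS) | {value_col}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"[read] recording file lacks columns {sorted(missing)}")
    numeric = pd.to_numeric(df[value_col], errors="coerce")
    bad = numeric.isna() & df[value_col].notna() | df[value_col].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 0-base
        logger.warning("dropping %d malformed rows at lines %s", bad.sum(), lines[:20])
        df = df[~bad].copy()
    df[value_col] = pd.to_numeric(df[value_col])

    series_list: list[VelocitySeries] = []
    rejected = 0
    for (participant, session, point), sub in df.groupby(
        ["participant", "session", "point"], sort=True
    ):
        values = sub.sort_values("sample_index")[value_col].to_numpy(dtype=float)
        if kind == "position":
            values = differentiate_positions(values, 1.0 / rate)
        if expected_samples is not None and values.size != expected_samples:
            if truncate and values.size > expected_samples:
                values = values[:expected_samples]
            elif strict:
                rejected += 1
                continue
        series_list.append(
            VelocitySeries(
                samples=values, rate=rate,
                participant_id=participant, session_id=session, point_id=point,
            )
        )
    if rejected:
        logger.warning("rejected %d series with unexpected length", rejected)
    if strict and rejected and not series_list:
        raise PipelineError(f"[read] all {rejected} series rejected by length validation")
    return series_list


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("stage %s finished in %.3fs", name, timings[name])

    return _Timer()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run simulate/read -> maps -> features -> classify -> report.

    Returns the manifest dict; all artifacts (recordings, maps, features,
    reports, figures, manifest) are written under ``outdir``.  Any stage
    failure aborts with a stage-tagged :class:`PipelineError`.
    """
    logging.getLogger("emmap").setLevel(config.log_level.upper())
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest(),
        "versions": _versions(),
        "artifacts": {},
        "drop_counts": {},
    }

    with _stage("input", timings):
        if config.input_path is None:
            dataset = generate_dataset(config.synth.to_config(config.seed))
            write_recordings(dataset, out / "recordings.csv")
            manifest["artifacts"]["recordings"] = "recordings.csv"
        else:
            dataset = read_recordings(
                config.input_path,
                kind=config.input_kind,
                expected_samples=config.synth.duration_ms
                * config.synth.rate // 1000,
                strict=config.strict_length,
                truncate=config.truncate,
            )
        if not dataset:
            raise ValueError("no input series")

    with _stage("maps", timings):
        params = {
            "ApEn": config.apen.to_params(),
            "FuzEn": config.fuzen.to_params(),
            "LLE": config.lle.to_params(),
        }
        collection = MapCollection.from_series(
            dataset, measures=config.measures, params=params, nss=config.nss
        )
        collection.normalize()
        maps_df = collection.to_dataframe()
        maps_df.to_csv(out / "maps.csv", index=False)
        (out / "maps.json").write_text(
            json.dumps(
                {
                    "nss": collection.nss,
                    "nemr": collection.nemr,
                    "n_levels": collection.maps[config.measures[0]][0].n_levels,
                    "measures": list(config.measures),
                    "n_series": len(collection.series_meta),
                    "missing_cells": int(maps_df["value"].isna().sum()),
                },
                indent=2,
            )
        )
        manifest["artifacts"]["maps"] = "maps.csv"
        manifest["drop_counts"]["missing_map_cells"] = int(maps_df["value"].isna().sum())

    with _stage("features", timings):
        feature_sets = {}
        for name in config.specs:
            spec = FeatureSpec.from_name(name, nss=config.nss)
            if not set(spec.measures).issubset(config.measures):
                raise ValueError(f"spec {name} uses measures outside {config.measures}")
            data = assemble_features(collection, spec)
            data.to_dataframe().to_csv(out / f"features_{name}.csv", index=False)
            feature_sets[name] = data
            manifest["drop_counts"][f"dropped_rows_{name}"] = data.n_dropped
        manifest["artifacts"]["features"] = [f"features_{n}.csv" for n in config.specs]

    with _stage("classify", timings):
        reports = []
        for name, data in feature_sets.items():
            for k in config.k_grid:
                reports.append(
                    knn_loso_cv(
                        data, k,
                        fold_safe_normalization=(config.normalization == "fold_safe"),
                    )
                )
        report_df = pd.concat([r.to_dataframe() for r in reports], ignore_index=True)
        report_df.to_csv(out / "reports.csv", index=False)
        confusions = {
            f"{r.spec_name}_k{r.k}": r.confusion.tolist() for r in reports
        }
        (out / "confusions.json").write_text(json.dumps(confusions, indent=2))
        manifest["artifacts"]["reports"] = "reports.csv"

    with _stage("report", timings):
        table = accuracy_table(reports, first_n_segments=config.first_n_segments)
        table.to_csv(out / "accuracy_table.csv", float_format="%.6f")
        manifest["artifacts"]["accuracy_table"] = "accuracy_table.csv"
        if config.figures:
            figures = []
            for measure in config.measures:
                fig_path = out / f"map_{measure}.png"
                plot_map(collection.average(measure), path=str(fig_path))
                figures.append(fig_path.name)
            manifest["artifacts"]["figures"] = figures

    manifest["timings_s"] = timings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "emmap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
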