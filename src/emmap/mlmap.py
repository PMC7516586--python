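"""Dyadic multilevel time-scale maps of nonlinear measures over velocity series.

A *multilevel map* (MM) decomposes a fixed-length recording (default 1024 ms
at 1000 Hz) into a dyadic hierarchy of time segments: level 1 holds the
shortest segments (``nss`` = 64 ms, 16 of them), each higher level merges two
neighbouring segments, up to level 5 covering the whole series.  One measure
(ApEn, FuzEn or LLE) is evaluated independently on every segment, so each
recording yields one map per measure.  Averaged over many recordings, the
maps expose where in the post-stimulus second the eye-movement events
(saccadic latency, saccade, fixation) live: the saccade window shows the
lowest entropies, the latency window positive Lyapunov exponents.

Cell addressing is 1-based ``(level, index)`` to match the usual "3rd segment
of the 1st level" phrasing; segment windows are half-open ``[start, end)`` in
milliseconds, so the two children of a cell tile it exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import measures as _meas
from . import lyapunov as _lyap
from .measures import ApEnParams, FuzEnParams, MeasureError, ParameterError

logger = logging.getLogger("emmap.mlmap")

__all__ = [
    "MEASURES",
    "VelocitySeries",
    "LLEMapParams",
    "MultilevelMap",
    "MapCollection",
    "DegenerateRangeError",
    "StructureError",
    "n_levels",
    "segment_bounds",
    "build_map",
    "average_maps",
    "normalize_level",
    "plot_map",
]

MEASURES = ("ApEn", "FuzEn", "LLE")


class StructureError(ValueError):
    """Maps or series with incompatible dyadic structure."""


class DegenerateRangeError(ValueError):
    """Min-max normalization of an all-equal value population."""


@dataclass(frozen=True)
class VelocitySeries:
    """One eye-movement velocity recording with its identity.

    ``samples`` are velocities in deg/s at ``rate`` Hz; the default geometry
    is 1024 samples = 1024 ms at 1000 Hz.  ``participant_id`` and
    ``session_id`` jointly form the cross-validation group (all recordings of
    one participant-session are held out together).
    """

    samples: np.ndarray
    rate: int = 1000
    participant_id: int | str = 0
    session_id: int | str = 0
    point_id: int | str = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise _meas.DataError(f"samples must be a 1-D series, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise _meas.DataError("velocity series contains NaN or Inf")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if (arr.size * 1000) % self.rate != 0:
            raise StructureError(
                f"{arr.size} samples at {self.rate} Hz is not a whole number of ms"
            )
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> int:
        return self.n_samples * 1000 // self.rate

    @property
    def series_id(self) -> str:
        return f"p{self.participant_id}_s{self.session_id}_pt{self.point_id}"

    @property
    def group(self) -> str:
        """Participant-session identifier used as the CV fold key."""
        return f"p{self.participant_id}_s{self.session_id}"


@dataclass(frozen=True)
class LLEMapParams:
    """How LLE map cells are computed.

    Embedding parameters are selected once per full series (FNN + mutual
    information) and reused for all its segments — 64-sample segments are too
    short for reliable FNN/MI.  Segments too short for the selected embedding
    fall back to ``(fixed_m, fixed_tau)``; if even that leaves too few state
    vectors the cell is marked missing.
    """

    mode: _lyap.LLEMode = "paper_average"
    follow_steps: int = 10
    min_temporal_separation: int | None = None
    selection: str = "fnn_mi_auto"  # or "fixed"
    fixed_m: int = 2
    fixed_tau: int = 1
    max_lag: int = 40
    mi_bins: int = 16
    max_m: int = 6
    min_vectors: int = 10


def n_levels(nemr: int = 1024, nss: int = 64) -> int:
    """Number of map levels: log2(nemr/nss) + 1 (5 at the defaults)."""
    if nss <= 0 or nemr <= 0 or nemr % nss != 0:
        raise StructureError(f"nemr={nemr} must be a positive multiple of nss={nss}")
    ratio = nemr // nss
    if ratio & (ratio - 1):
        raise StructureError(f"nemr/nss={ratio} must be a power of two")
    return int(np.log2(ratio)) + 1


def cells_at_level(level: int, nemr: int = 1024, nss: int = 64) -> int:
    return nemr // (nss * 2 ** (level - 1))


def segment_bounds(
    level: int, index: int, nss: int = 64, nemr: int = 1024
) -> tuple[int, int]:
    """Half-open window ``[start_ms, end_ms)`` of cell ``(level, index)``, 1-based."""
    levels = n_levels(nemr, nss)
    if not 1 <= level <= levels:
        raise StructureError(f"level {level} outside 1..{levels}")
    length = nss * 2 ** (level - 1)
    if not 1 <= index <= nemr // length:
        raise StructureError(f"index {index} outside 1..{nemr // length} at level {level}")
    return (index - 1) * length, index * length


@dataclass
class MultilevelMap:
    """Per-measure dyadic map: ``levels[l-1][s-1]`` is cell (l, s); NaN = missing."""

    measure: str
    nss: int
    nemr: int
    levels: list[np.ndarray]
    series_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        expected = [cells_at_level(l, self.nemr, self.nss) for l in range(1, self.n_levels + 1)]
        got = [len(v) for v in self.levels]
        if got != expected:
            raise StructureError(f"level cell counts {got} do not match {expected}")
        self.levels = [np.asarray(v, dtype=float) for v in self.levels]

    @property
    def n_levels(self) -> int:
        return n_levels(self.nemr, self.nss)

    def cell(self, level: int, index: int) -> float:
        segment_bounds(level, index, self.nss, self.nemr)  # bounds check
        return float(self.levels[level - 1][index - 1])

    @property
    def missing(self) -> list[np.ndarray]:
        return [np.isnan(v) for v in self.levels]

    def same_structure(self, other: "MultilevelMap") -> bool:
        return (self.measure, self.nss, self.nemr) == (other.measure, other.nss, other.nemr)

    def copy_with(self, levels: list[np.ndarray]) -> "MultilevelMap":
        return replace(self, levels=[np.array(v, dtype=float) for v in levels])

    def to_records(self) -> list[dict]:
        rows = []
        for level in range(1, self.n_levels + 1):
            for index in range(1, len(self.levels[level - 1]) + 1):
                start, end = segment_bounds(level, index, self.nss, self.nemr)
                rows.append(
                    {
                        "series_id": self.series_id,
                        "group": self.group,
                        "measure": self.measure,
                        "level": level,
                        "index": index,
                        "start_ms": start,
                        "end_ms": end,
                        "value": self.levels[level - 1][index - 1],
                    }
                )
        return rows


def _series_embedding(u: np.ndarray, params: LLEMapParams) -> _lyap.EmbeddingParams:
    if params.selection == "fixed":
        return _lyap.EmbeddingParams(params.fixed_m, params.fixed_tau, "fixed")
    lag = _lyap.select_lag_mi(u, max_lag=params.max_lag, bins=params.mi_bins)
    tau = params.fixed_tau if lag.fallback else lag.tau
    dim = _lyap.select_dim_fnn(u, tau, max_m=params.max_m)
    m = params.fixed_m if not dim.converged else dim.m
    return _lyap.EmbeddingParams(m, tau, "fnn_mi_auto")


def build_map(
    series: VelocitySeries,
    measure: str,
    params: ApEnParams | FuzEnParams | LLEMapParams | None = None,
    nss: int = 64,
) -> MultilevelMap:
    """Evaluate one measure on every dyadic segment of a series.

    Entropy tolerances default to ``r_coef`` x the population SD of the whole
    parent series (``r_scope='whole_series'``); a constant series has SD 0,
    where both entropies are 0 for any positive tolerance, so a unit
    tolerance is substituted there.  Cells where the measure fails (e.g.
    fuzzy-similarity underflow, too few state vectors) are marked missing
    (NaN) and logged, never silently zeroed.
    """
    if measure not in MEASURES:
        raise ParameterError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if params is None:
        params = {"ApEn": ApEnParams(), "FuzEn": FuzEnParams(), "LLE": LLEMapParams()}[measure]
    nemr = series.duration_ms
    levels_total = n_levels(nemr, nss)
    if (series.rate * nss) % 1000 != 0:
        raise StructureError(f"nss={nss} ms is not a whole number of samples at {series.rate} Hz")
    per_ms = series.rate / 1000.0
    u = series.samples

    whole_sd = float(u.std(ddof=0))
    if measure in ("ApEn", "FuzEn"):
        if params.r_scope == "whole_series":
            # constant parent series: entropies are 0 for any r > 0
            r_whole = params.r_coef * whole_sd if whole_sd > 0 else 1.0
        emb = None
    else:
        emb = _series_embedding(u, params) if whole_sd > 0 else _lyap.EmbeddingParams(
            params.fixed_m, params.fixed_tau, "fixed"
        )

    levels: list[np.ndarray] = []
    for level in range(1, levels_total + 1):
        cells = np.full(cells_at_level(level, nemr, nss), np.nan)
        for index in range(1, cells.size + 1):
            start_ms, end_ms = segment_bounds(level, index, nss, nemr)
            seg = u[int(start_ms * per_ms) : int(end_ms * per_ms)]
            try:
                if measure == "ApEn":
                    r = r_whole if params.r_scope == "whole_series" else _segment_r(seg, params)
                    cells[index - 1] = _meas.approximate_entropy(seg, r, m=params.m)
                elif measure == "FuzEn":
                    r = r_whole if params.r_scope == "whole_series" else _segment_r(seg, params)
                    cells[index - 1] = _meas.fuzzy_entropy(seg, r, m=params.m, n=params.n)
                else:
                    cells[index - 1] = _segment_lle(seg, emb, params, series.rate)
            except (MeasureError, _lyap.DegenerateNeighboursError) as exc:
                logger.warning(
                    "%s cell (%d,%d) of %s marked missing: %s",
                    measure, level, index, series.series_id, exc,
                )
        levels.append(cells)
    return MultilevelMap(
        measure=measure, nss=nss, nemr=nemr, levels=levels,
        series_id=series.series_id, group=series.group,
    )


def _segment_r(seg: np.ndarray, params: ApEnParams | FuzEnParams) -> float:
    seg_sd = float(seg.std(ddof=0))
    return params.r_coef * seg_sd if seg_sd > 0 else 1.0


def _segment_lle(
    seg: np.ndarray, emb: _lyap.EmbeddingParams, params: LLEMapParams, rate: int
) -> float:
    p = _lyap.LLEParams(
        follow_steps=params.follow_steps,
        dt=1.0 / rate,
        min_temporal_separation=params.min_temporal_separation,
        mode=params.mode,
    )

    def feasible(e: _lyap.EmbeddingParams) -> bool:
        n_vec = e.n_vectors(seg.size)
        window = p.min_temporal_separation
        if window is None:
            window = e.m * e.tau
        # need enough vectors to follow divergence AND at least one neighbour
        # candidate outside the temporal-exclusion window
        return (
            n_vec >= max(params.min_vectors, params.follow_steps + 2)
            and n_vec - params.follow_steps > window + 1
        )

    if not feasible(emb):
        emb = _lyap.EmbeddingParams(params.fixed_m, params.fixed_tau, "fixed")
    return _lyap.largest_lyapunov(seg, emb, p)


def average_maps(maps: Sequence[MultilevelMap]) -> MultilevelMap:
    """Cell-wise mean over non-missing values; missing only if missing everywhere."""
    if not maps:
        raise StructureError("cannot average an empty list of maps")
    first = maps[0]
    for other in maps[1:]:
        if not first.same_structure(other):
            raise StructureError("maps differ in measure or dyadic structure")
    averaged = []
    for level_idx in range(first.n_levels):
        stacked = np.vstack([m.levels[level_idx] for m in maps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            averaged.append(np.nanmean(stacked, axis=0))
    return MultilevelMap(
        measure=first.measure, nss=first.nss, nemr=first.nemr, levels=averaged,
        series_id=None, group=None,
    )


def normalize_level(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Min-max rescale a value population to [0, 1] (NaNs pass through)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise DegenerateRangeError("need at least two distinct finite values to min-max rescale")
    lo, hi = finite.min(), finite.max()
    return (arr - lo) / (hi - lo)


@dataclass
class MapCollection:
    """Aligned per-measure maps of a dataset of recordings.

    ``maps[measure][i]`` is the map of series ``series_meta.iloc[i]``.  After
    :meth:`normalize`, ``normalized[measure][i]`` holds the min-max rescaled
    maps, pooled per (measure, level) across all series — the rescaling is
    fitted on the whole dataset before any train/test split (the fold-safe
    alternative lives in the classification layer).
    """

    maps: dict[str, list[MultilevelMap]]
    series_meta: pd.DataFrame
    nss: int = 64
    nemr: int = 1024
    normalized: dict[str, list[MultilevelMap]] | None = None

    @classmethod
    def from_series(
        cls,
        series_list: Sequence[VelocitySeries],
        measures: Sequence[str] = MEASURES,
        params: Mapping[str, object] | None = None,
        nss: int = 64,
    ) -> "MapCollection":
        if not series_list:
            raise StructureError("empty series list")
        params = dict(params or {})
        maps: dict[str, list[MultilevelMap]] = {}
        for measure in measures:
            maps[measure] = [
                build_map(s, measure, params.get(measure), nss=nss) for s in series_list
            ]
        meta = pd.DataFrame(
            {
                "series_id": [s.series_id for s in series_list],
                "participant": [s.participant_id for s in series_list],
                "session": [s.session_id for s in series_list],
                "point": [s.point_id for s in series_list],
                "group": [s.group for s in series_list],
            }
        )
        return cls(maps=maps, series_meta=meta, nss=nss, nemr=series_list[0].duration_ms)

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def normalize(self) -> "MapCollection":
        """Fill ``normalized`` with per-measure, per-level pooled min-max maps."""
        normalized: dict[str, list[MultilevelMap]] = {}
        for measure, maps in self.maps.items():
            levels_norm: list[np.ndarray] = []
            for level_idx in range(maps[0].n_levels):
                pooled = np.vstack([m.levels[level_idx] for m in maps])
                try:
                    scaled = normalize_level(pooled.ravel()).reshape(pooled.shape)
                except DegenerateRangeError:
                    logger.warning(
                        "degenerate value range for %s level %d; cells flagged missing",
                        measure, level_idx + 1,
                    )
                    scaled = np.full(pooled.shape, np.nan)
                levels_norm.append(scaled)
            normalized[measure] = [
                m.copy_with([levels_norm[l][i] for l in range(m.n_levels)])
                for i, m in enumerate(maps)
            ]
        self.normalized = normalized
        return self

    def average(self, measure: str, use_normalized: bool = False) -> MultilevelMap:
        source = self.normalized if use_normalized else self.maps
        if source is None:
            raise StructureError("collection has not been normalized yet")
        return average_maps(source[measure])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table of all cells (one row per series x measure x cell)."""
        frames = []
        for measure, maps in self.maps.items():
            raw = pd.DataFrame([r for m in maps for r in m.to_records()])
            if self.normalized is not None:
                norm = pd.DataFrame(
                    [r for m in self.normalized[measure] for r in m.to_records()]
                )
                raw["normalized_value"] = norm["value"].to_numpy()
            else:
                raw["normalized_value"] = np.nan
            frames.append(raw)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, nss: int | None = None) -> "MapCollection":
        """Rebuild a collection from :meth:`to_dataframe` output (round trip)."""
        required = {"series_id", "measure", "level", "index", "value"}
        if not required.issubset(df.columns):
            raise StructureError(f"map table must contain columns {sorted(required)}")
        nemr = int(df["end_ms"].max())
        if nss is None:
            nss = int((df.loc[df["level"] == 1, "end_ms"] - df.loc[df["level"] == 1, "start_ms"]).iloc[0])
        series_ids = list(dict.fromkeys(df["series_id"]))
        maps: dict[str, list[MultilevelMap]] = {}
        normalized: dict[str, list[MultilevelMap]] = {}
        has_norm = "normalized_value" in df.columns and df["normalized_value"].notna().any()
        for measure in dict.fromkeys(df["measure"]):
            sub_m = df[df["measure"] == measure]
            maps[measure] = []
            normalized[measure] = []
            for sid in series_ids:
                sub = sub_m[sub_m["series_id"] == sid].sort_values(["level", "index"])
                group = sub["group"].iloc[0] if "group" in sub.columns else None
                levels = [
                    sub.loc[sub["level"] == l, "value"].to_numpy()
                    for l in sorted(sub["level"].unique())
                ]
                maps[measure].append(
                    MultilevelMap(measure, nss, nemr, levels, series_id=sid, group=group)
                )
                if has_norm:
                    levels_n = [
                        sub.loc[sub["level"] == l, "normalized_value"].to_numpy()
                        for l in sorted(sub["level"].unique())
                    ]
                    normalized[measure].append(
                        MultilevelMap(measure, nss, nemr, levels_n, series_id=sid, group=group)
                    )
        meta_cols = [c for c in ("series_id", "participant", "session", "point", "group") if c in df.columns]
        meta = df[meta_cols].drop_duplicates("series_id").reset_index(drop=True)
        return cls(
            maps=maps, series_meta=meta, nss=nss, nemr=nemr,
            normalized=normalized if has_norm else None,
        )


def plot_map(mm: MultilevelMap, path: str | None = None, ax=None, cmap: str = "RdYlGn_r"):
    """Heat-map rendering of a multilevel map (each level one row of blocks)."""
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    finite = np.concatenate([v[np.isfinite(v)] for v in mm.levels])
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    for level in range(1, mm.n_levels + 1):
        values = mm.levels[level - 1]
        for index in range(1, values.size + 1):
            start, end = segment_bounds(level, index, mm.nss, mm.nemr)
            value = values[index - 1]
            color = (
                plt.get_cmap(cmap)((value - vmin) / (vmax - vmin or 1.0))
                if np.isfinite(value)
                else (0.8, 0.8, 0.8)
            )
            ax.add_patch(
                plt.Rectangle((start, level - 0.5), end - start, 1.0,
                              facecolor=color, edgecolor="black", linewidth=0.4)
            )
    ax.set_xlim(0, mm.nemr)
    ax.set_ylim(0.5, mm.n_levels + 0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("map level")
    ax.set_title(mm.measure)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
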