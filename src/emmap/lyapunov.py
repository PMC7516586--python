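"""Delay-coordinate embedding and largest Lyapunov exponent (LLE) estimation.

The state of the underlying dynamical system is reconstructed from a scalar
series via Takens delay embedding: ``x_i = (u_i, u_{i+tau}, ..., u_{i+(m-1)tau})``,
giving ``M = N - (m-1)*tau`` state vectors.  The lag ``tau`` is chosen at the
first local minimum of the lagged mutual information, the dimension ``m`` by
the false-nearest-neighbours (FNN) criterion.

The LLE measures the mean exponential rate at which initially close
trajectories separate: ``d_j(i) ~ d_j(0) * exp(lambda * i * dt)``.  Two
estimators are provided:

* ``paper_average`` — for every reference vector, take the log distance ratio
  to its nearest neighbour after a fixed horizon ``i`` and average
  ``ln(d_j(i)/d_j(0)) / (i*dt)`` over references.
* ``rosenstein_slope`` — the least-squares slope of the mean log divergence
  curve ``<ln d_j(i)>`` against ``i*dt`` (Rosenstein et al.'s small-data
  algorithm), generally the more robust estimator.

Positive values indicate divergence (chaos), negative convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .measures import DataError, ParameterError, SeriesLengthError, _validate_series

__all__ = [
    "EmbeddingParams",
    "LLEParams",
    "LagSelection",
    "DimSelection",
    "DegenerateNeighboursError",
    "delay_embed",
    "select_lag_mi",
    "select_dim_fnn",
    "largest_lyapunov",
]

LLEMode = Literal["paper_average", "rosenstein_slope"]


class DegenerateNeighboursError(ArithmeticError):
    """All nearest-neighbour pairs had zero initial separation."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension and lag, plus how they were obtained."""

    m: int
    tau: int
    source: Literal["fnn_mi_auto", "fixed"] = "fixed"

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ParameterError(f"need m >= 1 and tau >= 1, got m={self.m}, tau={self.tau}")

    def n_vectors(self, n_samples: int) -> int:
        return n_samples - (self.m - 1) * self.tau


@dataclass(frozen=True)
class LLEParams:
    """Divergence-tracking parameters for the LLE estimators.

    ``follow_steps`` is the horizon ``i`` (in samples) over which neighbour
    separation is followed; ``dt`` the sampling interval in seconds;
    ``min_temporal_separation`` the Theiler-style exclusion window for
    neighbour search (None -> ``m * tau``).
    """

    follow_steps: int = 10
    dt: float = 0.001
    min_temporal_separation: int | None = None
    mode: LLEMode = "paper_average"

    def __post_init__(self) -> None:
        if self.follow_steps < 1:
            raise ParameterError("follow_steps must be >= 1")
        if not self.dt > 0:
            raise ParameterError("dt must be > 0")
        if self.min_temporal_separation is not None and self.min_temporal_separation < 0:
            raise ParameterError("min_temporal_separation must be >= 0")


@dataclass(frozen=True)
class LagSelection:
    tau: int
    mi: np.ndarray = field(repr=False)  # mi[t] = MI at lag t, t = 0..max_lag
    fallback: bool = False


@dataclass(frozen=True)
class DimSelection:
    m: int
    fnn_fraction: np.ndarray = field(repr=False)  # fraction at m = 1..max_m
    converged: bool = True


def delay_embed(u: Sequence[float] | np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-coordinate vectors, shape ``(M, m)`` with ``M = N - (m-1)*tau``."""
    if m < 1 or tau < 1:
        raise ParameterError(f"need m >= 1 and tau >= 1, got m={m}, tau={tau}")
    arr = _validate_series(u, (m - 1) * tau + 2)
    count = arr.size - (m - 1) * tau
    idx = np.arange(count)[:, None] + np.arange(m)[None, :] * tau
    return arr[idx]


def _histogram_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(px, py)[nz]))))


def select_lag_mi(
    u: Sequence[float] | np.ndarray, max_lag: int = 40, bins: int = 16
) -> LagSelection:
    """Embedding lag from the first local minimum of lagged mutual information.

    MI is histogram-estimated with ``bins`` equal-width bins.  If the lag-1 MI
    is already at the small-sample noise floor (no detectable dependence, e.g.
    white noise), or no local minimum exists within ``max_lag``, the
    MI-minimising lag is returned with ``fallback=True``.
    """
    arr = _validate_series(u, 8)
    if max_lag < 1 or max_lag >= arr.size // 2:
        raise ParameterError(f"need 1 <= max_lag < N/2, got {max_lag} for N={arr.size}")
    if np.ptp(arr) == 0:
        raise DataError("mutual information undefined for a constant series")
    mi = np.empty(max_lag + 1)
    mi[0] = _histogram_mi(arr, arr, bins)
    for lag in range(1, max_lag + 1):
        mi[lag] = _histogram_mi(arr[:-lag], arr[lag:], bins)
    # Miller-Madow-style bias of the histogram MI estimate at independence.
    noise_floor = (bins - 1) ** 2 / (2.0 * (arr.size - max_lag))
    if mi[1] <= 2.0 * noise_floor:
        return LagSelection(tau=int(np.argmin(mi[1:]) + 1), mi=mi, fallback=True)
    # Lightly smooth the curve and ask for a prominent dip: the raw histogram
    # estimate jitters on its plateau, producing shallow spurious minima.
    from scipy.signal import find_peaks

    curve = mi[1:]
    padded = np.r_[curve[0], curve, curve[-1]]
    smooth = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    dips, _ = find_peaks(-smooth, prominence=0.1 * np.ptp(smooth))
    if dips.size:
        return LagSelection(tau=int(dips[0] + 1), mi=mi, fallback=False)
    return LagSelection(tau=int(np.argmin(mi[1:]) + 1), mi=mi, fallback=True)


def select_dim_fnn(
    u: Sequence[float] | np.ndarray,
    tau: int,
    max_m: int = 8,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> DimSelection:
    """Embedding dimension by the Kennel false-nearest-neighbours test.

    A neighbour pair at dimension ``m`` is *false* if adding the next delay
    coordinate increases their separation by more than ``rtol`` relative to
    their distance, or moves them apart by more than ``atol`` series standard
    deviations.  Returns the smallest ``m`` whose false fraction drops below
    ``threshold`` (1% by default); if never reached — as for stochastic data,
    which has no finite embedding — returns ``max_m`` with
    ``converged=False``.
    """
    if max_m < 2:
        raise ParameterError(f"max_m must be >= 2, got {max_m}")
    arr = _validate_series(u, max_m * tau + 2)
    scale = float(arr.std(ddof=0))
    if scale == 0:
        raise DataError("FNN undefined for a constant series")
    fractions = np.full(max_m, np.nan)
    for m in range(1, max_m + 1):
        vectors = delay_embed(arr, m, tau)
        # keep only vectors whose next delay coordinate u[i + m*tau] exists
        usable = arr.size - m * tau
        if usable < 2:
            break
        vectors = vectors[:usable]
        tree = cKDTree(vectors)
        dist, nn = tree.query(vectors, k=2)
        dist, nn = dist[:, 1], nn[:, 1]
        extra = np.abs(arr[np.arange(usable) + m * tau] - arr[nn + m * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_false = np.where(dist > 0, extra / np.where(dist > 0, dist, 1.0) > rtol, extra > 0)
        size_false = np.sqrt(dist**2 + extra**2) / scale > atol
        # pairs separated only at rounding level (exactly periodic data) are
        # true neighbours; the ratio test on them compares rounding noise
        degenerate = np.hypot(dist, extra) < 1e-8 * scale
        fractions[m - 1] = float(np.mean((ratio_false | size_false) & ~degenerate))
        if fractions[m - 1] < threshold:
            return DimSelection(m=m, fnn_fraction=fractions, converged=True)
    return DimSelection(m=max_m, fnn_fraction=fractions, converged=False)


def _divergence_setup(
    u: Sequence[float] | np.ndarray, emb: EmbeddingParams, p: LLEParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference indices, their nearest neighbours, and the embedded vectors."""
    vectors = delay_embed(u, emb.m, emb.tau)
    n_vec = vectors.shape[0]
    last_ref = n_vec - p.follow_steps
    if last_ref < 2:
        raise SeriesLengthError(
            f"only {n_vec} state vectors; cannot follow divergence for {p.follow_steps} steps"
        )
    window = p.min_temporal_separation
    if window is None:
        window = emb.m * emb.tau
    dist = cdist(vectors[:last_ref], vectors[:last_ref])
    idx = np.arange(last_ref)
    dist[np.abs(idx[:, None] - idx[None, :]) <= window] = np.inf
    nn = dist.argmin(axis=1)
    d0 = dist[idx, nn]
    valid = np.isfinite(d0) & (d0 > 0)
    if not np.any(valid):
        raise DegenerateNeighboursError("no neighbour pair with positive initial separation")
    return vectors, idx[valid], nn[valid]


def largest_lyapunov(
    u: Sequence[float] | np.ndarray,
    emb: EmbeddingParams,
    p: LLEParams = LLEParams(),
) -> float:
    """Largest Lyapunov exponent of a scalar series, in 1/seconds (1/``dt`` units).

    Nearest neighbours are found in the embedding space (Euclidean metric)
    excluding temporally close vectors, and their separation is followed for
    ``p.follow_steps`` samples; see the module docstring for the two modes.
    Reference vectors whose pair separation vanishes are skipped.
    """
    vectors, refs, nns = _divergence_setup(u, emb, p)
    d0 = np.linalg.norm(vectors[refs] - vectors[nns], axis=1)
    if p.mode == "paper_average":
        di = np.linalg.norm(
            vectors[refs + p.follow_steps] - vectors[nns + p.follow_steps], axis=1
        )
        ok = di > 0
        if not np.any(ok):
            raise DegenerateNeighboursError("all followed pairs collapsed to zero distance")
        lam = np.log(di[ok] / d0[ok]) / (p.follow_steps * p.dt)
        return float(lam.mean())
    if p.mode == "rosenstein_slope":
        steps = np.arange(1, p.follow_steps + 1)
        mean_log = np.empty(steps.size)
        for j, step in enumerate(steps):
            di = np.linalg.norm(vectors[refs + step] - vectors[nns + step], axis=1)
            ok = di > 0
            if not np.any(ok):
                raise DegenerateNeighboursError("all followed pairs collapsed to zero distance")
            mean_log[j] = np.mean(np.log(di[ok]))
        slope = np.polyfit(steps * p.dt, mean_log, 1)[0]
        return float(slope)
    raise ParameterError(f"unknown LLE mode {p.mode!r}")
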