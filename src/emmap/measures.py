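"""Regularity measures for scalar time series: approximate and fuzzy entropy.

Both statistics quantify how often short patterns of a series repeat.  For a
series u(1), ..., u(N) and pattern length ``m``:

* **Approximate entropy** (ApEn) counts, for each m-point template, the
  fraction of templates whose Chebyshev distance lies within an absolute
  tolerance ``r`` (self-matches included), and returns the difference of the
  average log-counts between pattern lengths ``m`` and ``m + 1``.  Low values
  mean that patterns which match at length ``m`` tend to keep matching at
  ``m + 1`` — a regular signal.

* **Fuzzy entropy** (FuzEn) replaces the hard tolerance with an exponential
  membership function ``exp(-d**n / r)`` evaluated on baseline-removed
  (per-pattern de-meaned) templates, with self-matches excluded.  The soft
  boundary makes the statistic continuous in the data and less dependent on
  the exact tolerance.

Both are reported in nats (natural logarithm throughout).  The absolute
tolerance ``r_abs`` is supplied by the caller; in the eye-movement pipeline it
is ``r_coef`` times the population standard deviation of the *parent*
1024-sample velocity series, not of the individual map segment (see
:class:`ApEnParams.r_scope`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

__all__ = [
    "MeasureError",
    "SeriesLengthError",
    "ParameterError",
    "DataError",
    "DegenerateSimilarityError",
    "ApEnParams",
    "FuzEnParams",
    "sd",
    "approximate_entropy",
    "fuzzy_entropy",
    "fuzen_param_sweep",
]

RScope = Literal["whole_series", "segment"]


class MeasureError(Exception):
    """Base class for measure-evaluation failures."""


class SeriesLengthError(MeasureError, ValueError):
    """Series too short for the requested pattern length / embedding."""


class ParameterError(MeasureError, ValueError):
    """Invalid measure parameter (e.g. non-positive tolerance)."""


class DataError(MeasureError, ValueError):
    """Non-finite samples or otherwise unusable input data."""


class DegenerateSimilarityError(MeasureError, ArithmeticError):
    """Fuzzy similarity sum underflowed to zero; entropy undefined."""


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters.

    ``r_scope`` states which series the tolerance coefficient multiplies:
    the whole parent recording (default) or the individual segment.
    """

    m: int = 2
    r_coef: float = 0.2
    r_scope: RScope = "whole_series"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"pattern length m must be >= 1, got {self.m}")
        if not self.r_coef > 0:
            raise ParameterError(f"r_coef must be > 0, got {self.r_coef}")


@dataclass(frozen=True)
class FuzEnParams:
    """Fuzzy-entropy parameters: ``n`` is the fuzzy-boundary gradient."""

    m: int = 2
    n: float = 2.0
    r_coef: float = 0.075
    r_scope: RScope = "whole_series"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"pattern length m must be >= 1, got {self.m}")
        if not self.n > 0:
            raise ParameterError(f"gradient n must be > 0, got {self.n}")
        if not self.r_coef > 0:
            raise ParameterError(f"r_coef must be > 0, got {self.r_coef}")


def _validate_series(u: Sequence[float] | np.ndarray, min_len: int) -> np.ndarray:
    arr = np.asarray(u, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"expected a 1-D series, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DataError("series contains NaN or Inf samples")
    if arr.size < min_len:
        raise SeriesLengthError(
            f"series of length {arr.size} is too short; need at least {min_len}"
        )
    return arr


def sd(u: Sequence[float] | np.ndarray) -> float:
    """Population standard deviation (divide by N) of a series.

    The population convention is fixed so that the tolerance ``r_coef * sd``
    is reproducible; at N = 1024 the 1/N vs 1/(N-1) difference is negligible.
    A constant series returns 0, which downstream turns into a
    :class:`ParameterError` when used as a tolerance.
    """
    arr = _validate_series(u, 2)
    return float(arr.std(ddof=0))


def approximate_entropy(u: Sequence[float] | np.ndarray, r_abs: float, m: int = 2) -> float:
    """ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r), in nats.

    ``Phi^q(r)`` is the mean over the N-q+1 length-q templates of the log
    fraction of templates within Chebyshev distance ``r_abs`` (``d <= r``,
    self-matches included, so every count is positive).

    Parameters
    ----------
    u : array-like
        Scalar series, length >= m + 2, finite.
    r_abs : float
        Absolute tolerance (> 0); typically ``r_coef`` x SD of the parent
        series.
    m : int
        Pattern length (default 2).
    """
    if m < 1:
        raise ParameterError(f"pattern length m must be >= 1, got {m}")
    if not r_abs > 0:
        raise ParameterError(f"tolerance r_abs must be > 0, got {r_abs}")
    arr = _validate_series(u, m + 2)

    def phi(q: int) -> float:
        templates = sliding_window_view(arr, q)
        dist = cdist(templates, templates, "chebyshev")
        counts = np.count_nonzero(dist <= r_abs, axis=1)
        return float(np.mean(np.log(counts / templates.shape[0])))

    return phi(m) - phi(m + 1)


def _phi_fuzzy(arr: np.ndarray, q: int, n: float, r_abs: float) -> float:
    # i runs over N - q templates (the last available one is dropped),
    # matching the estimator's finite-set definition.
    count = arr.size - q
    templates = sliding_window_view(arr, q)[:count].astype(float)
    templates = templates - templates.mean(axis=1, keepdims=True)
    dist = cdist(templates, templates, "chebyshev")
    sim = np.exp(-(dist ** n) / r_abs)
    np.fill_diagonal(sim, 0.0)
    return float((sim.sum(axis=1) / (count - 1)).mean())


def fuzzy_entropy(
    u: Sequence[float] | np.ndarray, r_abs: float, m: int = 2, n: float = 2.0
) -> float:
    """FuzEn(m, n, r, N) = ln(phi^m) - ln(phi^{m+1}), in nats.

    ``phi^q`` averages the pairwise similarity ``exp(-d**n / r_abs)`` between
    baseline-removed length-q templates, self-pairs excluded; ``d`` is the
    Chebyshev distance.  Requires length >= m + 3 so the (m+1)-level average
    over j != i is non-empty.

    Raises
    ------
    DegenerateSimilarityError
        If ``phi^{m+1}`` underflows to exactly zero (all pairs far apart on
        the scale of ``r_abs``); callers should mark the value as missing.
    """
    if m < 1:
        raise ParameterError(f"pattern length m must be >= 1, got {m}")
    if not n > 0:
        raise ParameterError(f"gradient n must be > 0, got {n}")
    if not r_abs > 0:
        raise ParameterError(f"tolerance r_abs must be > 0, got {r_abs}")
    arr = _validate_series(u, m + 3)
    phi_m = _phi_fuzzy(arr, m, n, r_abs)
    phi_m1 = _phi_fuzzy(arr, m + 1, n, r_abs)
    if phi_m <= 0.0 or phi_m1 <= 0.0:
        raise DegenerateSimilarityError(
            "fuzzy similarity sum underflowed to zero; entropy undefined"
        )
    return float(np.log(phi_m) - np.log(phi_m1))


def fuzen_param_sweep(
    collection: Iterable[Sequence[float] | np.ndarray],
    n_grid: Sequence[float],
    r_coef_grid: Sequence[float],
    m: int = 2,
) -> pd.DataFrame:
    """Across-series spread of FuzEn over an (n, r_coef) grid.

    For every grid pair, FuzEn is evaluated on each series with
    ``r_abs = r_coef * sd(series)`` and the population SD of the resulting
    values is tabulated.  The table is a diagnostic for choosing (n, r):
    the recommended operating point is where the SD starts decreasing only
    slowly; the choice itself is left to the analyst.

    Returns a DataFrame with columns ``n``, ``r_coef``, ``sd_fuzen``,
    ``n_series``, ``n_failed``.  Cells where every series fails carry NaN.
    """
    series_list = [np.asarray(s, dtype=float) for s in collection]
    if not series_list:
        raise DataError("empty series collection")
    if len(n_grid) == 0 or len(r_coef_grid) == 0:
        raise ParameterError("parameter grids must be non-empty")
    sds = [sd(s) for s in series_list]
    rows = []
    for n_val in n_grid:
        for r_coef in r_coef_grid:
            values = []
            failed = 0
            for series, series_sd in zip(series_list, sds):
                try:
                    values.append(
                        fuzzy_entropy(series, r_coef * series_sd, m=m, n=n_val)
                    )
                except MeasureError:
                    failed += 1
            spread = float(np.std(values, ddof=0)) if values else float("nan")
            rows.append(
                {
                    "n": n_val,
                    "r_coef": r_coef,
                    "sd_fuzen": spread,
                    "n_series": len(values),
                    "n_failed": failed,
                }
            )
    return pd.DataFrame(rows)
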