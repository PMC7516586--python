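"""Synthetic eye-movement velocity generator.

Emulates a "jumping point" trial: after stimulus onset the trace shows a
*saccadic latency* period (the oculomotor programming delay, ~100-250 ms of
low-amplitude, weakly divergent fluctuation), then one ballistic *saccade*
(30-80 ms bell-shaped velocity pulse, peaking up to ~500 deg/s), then
*fixation* on the new target with tremor, slow drift and sparse
microsaccades, plus white measurement noise throughout.  At 1000 Hz the
default series is 1024 samples long, so a dyadic multilevel map applies
directly.

Model choices (the real experiment's waveform is not published, so these are
the generator's own assumptions, documented in the methods note):

* fixational micro-movement (tremor) noise is present during *both* the
  latency period (the eye is still fixating the old target) and the final
  fixation, but is suppressed during the ballistic saccade itself — this is
  the main irregularity source of the trace;
* latency dynamics additionally carry a weakly unstable AR(1) component
  (coefficient slightly above 1) so that nearby trajectories genuinely
  diverge, giving the positive Lyapunov exponents characteristic of the
  pre-saccadic interval;
* saccade: raised-cosine velocity pulse; its amplitude follows a saturating
  main-sequence relation of the drawn duration, keeping peak velocities
  physiological (<~ 520 deg/s);
* fixation additionally shows AR(1) low-pass drift + Poisson microsaccades
  (small raised-cosine pulses of either sign);
* measurement noise: small i.i.d. Gaussian velocity noise everywhere,
  standing in for sensor noise after the tracker's onboard filtering.

Every stochastic element is driven by one master seed; a series is uniquely
reproducible from ``(seed, participant, session, point)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .measures import DataError, ParameterError, SeriesLengthError
from .mlmap import VelocitySeries

__all__ = [
    "SyntheticConfig",
    "ConfigError",
    "generate_series",
    "generate_dataset",
    "differentiate_positions",
]


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Distributional description of one synthetic trial.

    Durations in ms, velocities in deg/s.  ``latency_ms`` is truncated-normal
    (mean, SD, bounds); ``saccade_duration_ms`` uniform.  Set the noise
    fields to zero for an exactly piecewise-silent trace.
    """

    rate: int = 1000
    duration_ms: int = 1024
    # saccadic latency
    latency_mean_ms: float = 170.0
    latency_sd_ms: float = 25.0
    latency_bounds_ms: tuple[float, float] = (100.0, 250.0)
    latency_ar: float = 1.002          # weakly unstable: trajectories diverge
    latency_fluct_sd: float = 1.5      # AR innovation, deg/s
    # saccade
    saccade_duration_ms: tuple[float, float] = (30.0, 80.0)
    saccade_vmax: float = 550.0        # main-sequence saturation velocity
    saccade_amp_scale_deg: float = 12.0
    # fixational micro-movements (active during latency and fixation)
    tremor_sd: float = 15.0
    drift_sd: float = 3.0
    drift_ar: float = 0.99
    microsaccade_rate_hz: float = 1.5
    microsaccade_peak: tuple[float, float] = (8.0, 25.0)
    microsaccade_duration_ms: tuple[float, float] = (10.0, 20.0)
    # everywhere
    measurement_noise_sd: float = 1.0
    # dataset geometry
    seed: int = 0
    n_participants: int = 24
    n_sessions: int = 2
    n_points: int = 29
    excluded_sessions: tuple[tuple[int, int], ...] = ()
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration_ms <= 0:
            raise ConfigError("rate and duration_ms must be positive")
        lo, hi = self.latency_bounds_ms
        if not (0 < lo <= hi):
            raise ConfigError("latency bounds must satisfy 0 < lo <= hi")
        if self.saccade_duration_ms[0] > self.saccade_duration_ms[1]:
            raise ConfigError("saccade duration range reversed")
        if lo + self.saccade_duration_ms[0] >= self.duration_ms:
            raise ConfigError("latency + saccade cannot fit in the series duration")
        for name in ("latency_fluct_sd", "tremor_sd", "drift_sd",
                     "microsaccade_rate_hz", "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def _series_rng(config: SyntheticConfig, participant: int, session: int, point: int):
    key = np.random.SeedSequence(
        config.seed, spawn_key=(int(participant), int(session), int(point))
    )
    return np.random.default_rng(key)


def _draw_latency(config: SyntheticConfig, rng) -> float:
    lo, hi = config.latency_bounds_ms
    if config.latency_sd_ms == 0:
        return float(np.clip(config.latency_mean_ms, lo, hi))
    a = (lo - config.latency_mean_ms) / config.latency_sd_ms
    b = (hi - config.latency_mean_ms) / config.latency_sd_ms
    return float(
        truncnorm.rvs(a, b, loc=config.latency_mean_ms, scale=config.latency_sd_ms,
                      random_state=rng)
    )


def _raised_cosine(n: int, peak: float) -> np.ndarray:
    # unimodal pulse, zero at both endpoints
    return peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def generate_series(
    config: SyntheticConfig,
    participant: int = 0,
    session: int = 0,
    point: int = 0,
) -> VelocitySeries:
    """One latency -> saccade -> fixation velocity trace.

    Deterministic in ``(config.seed, participant, session, point)``.  Timing
    draws that do not fit the series are redrawn up to ``config.max_redraws``
    times before raising :class:`ConfigError`.
    """
    rng = _series_rng(config, participant, session, point)
    per_ms = config.rate / 1000.0
    n = int(round(config.duration_ms * per_ms))
    v = np.zeros(n)

    for _ in range(config.max_redraws):
        latency_ms = _draw_latency(config, rng)
        sacc_dur_ms = float(rng.uniform(*config.saccade_duration_ms))
        if latency_ms + sacc_dur_ms < config.duration_ms - 1:
            break
    else:
        raise ConfigError("could not draw a feasible latency + saccade timing")

    i_sacc = int(round(latency_ms * per_ms))
    n_sacc = max(2, int(round(sacc_dur_ms * per_ms)))

    # (a) saccadic latency: fixational tremor + weakly unstable AR(1) component
    if i_sacc > 0:
        if config.tremor_sd > 0:
            v[:i_sacc] += rng.normal(0.0, config.tremor_sd, i_sacc)
        if config.latency_fluct_sd > 0:
            innov = rng.normal(0.0, config.latency_fluct_sd, i_sacc)
            v[:i_sacc] += lfilter([1.0], [1.0, -config.latency_ar], innov)

    # (b) saccade: raised-cosine pulse, main-sequence-like peak velocity
    amp_deg = max(0.5, (sacc_dur_ms - 20.0) / 2.5) * rng.uniform(0.8, 1.2)
    peak = config.saccade_vmax * (1.0 - np.exp(-amp_deg / config.saccade_amp_scale_deg))
    sign = rng.choice((-1.0, 1.0))
    end = min(n, i_sacc + n_sacc)
    v[i_sacc:end] += _raised_cosine(n_sacc, sign * peak)[: end - i_sacc]

    # (c) fixation: tremor + drift + sparse microsaccades
    i_fix = end
    n_fix = n - i_fix
    if n_fix > 0:
        if config.tremor_sd > 0:
            v[i_fix:] += rng.normal(0.0, config.tremor_sd, n_fix)
        if config.drift_sd > 0:
            innov = rng.normal(0.0, 1.0, n_fix)
            drift = lfilter([1.0], [1.0, -config.drift_ar], innov)
            std = drift.std() or 1.0
            v[i_fix:] += config.drift_sd * drift / std
        if config.microsaccade_rate_hz > 0:
            count = rng.poisson(config.microsaccade_rate_hz * n_fix / config.rate)
            for _ in range(count):
                dur = int(round(rng.uniform(*config.microsaccade_duration_ms) * per_ms))
                dur = max(2, dur)
                onset = i_fix + int(rng.integers(0, max(1, n_fix - dur)))
                peak_ms = rng.uniform(*config.microsaccade_peak) * rng.choice((-1.0, 1.0))
                stop = min(n, onset + dur)
                v[onset:stop] += _raised_cosine(dur, peak_ms)[: stop - onset]

    # (d) measurement noise everywhere
    if config.measurement_noise_sd > 0:
        v += rng.normal(0.0, config.measurement_noise_sd, n)

    return VelocitySeries(
        samples=v, rate=config.rate,
        participant_id=participant, session_id=session, point_id=point,
    )


def generate_dataset(config: SyntheticConfig) -> list[VelocitySeries]:
    """Full participants x sessions x points dataset.

    ``excluded_sessions`` lists (participant, session) pairs dropped from the
    output (mirroring recordings lost to acquisition problems), so the series
    count is ``(n_participants * n_sessions - excluded) * n_points``.
    """
    excluded = set(config.excluded_sessions)
    dataset = []
    for participant in range(config.n_participants):
        for session in range(config.n_sessions):
            if (participant, session) in excluded:
                continue
            for point in range(config.n_points):
                dataset.append(generate_series(config, participant, session, point))
    return dataset


def differentiate_positions(
    positions: Sequence[float] | np.ndarray, dt: float, stencil: str = "forward"
) -> np.ndarray:
    """Two-point differentiation of a position trace into velocity.

    ``forward`` (default): v_i = (x_{i+1} - x_i)/dt, length N-1.
    ``central``: v_i = (x_{i+1} - x_{i-1})/(2 dt), length N-2.
    """
    x = np.asarray(positions, dtype=float)
    if x.ndim != 1:
        raise DataError(f"positions must be 1-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataError("positions contain NaN or Inf")
    if not dt > 0:
        raise ParameterError("dt must be > 0")
    if stencil == "forward":
        if x.size < 2:
            raise SeriesLengthError("need at least 2 position samples")
        return np.diff(x) / dt
    if stencil == "central":
        if x.size < 3:
            raise SeriesLengthError("need at least 3 position samples")
        return (x[2:] - x[:-2]) / (2.0 * dt)
    raise ParameterError(f"unknown stencil {stencil!r}")
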