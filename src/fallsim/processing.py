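"""Turn sampled platform-angle and force traces into fit-ready observables.

The measurement pipeline mirrors a motion-capture workflow: angle sampled at
150 Hz, zero-phase low-pass filtering (dual-pass second-order Butterworth,
10 Hz cut-off), finite-difference differentiation, linear interpolation of
the angular velocity at the 70-degree crossing, and threshold detection of
the impact instant on the vertical ground reaction force (first sample
exceeding 10 N).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

__all__ = [
    "SampledSeries",
    "TrialObservables",
    "lowpass_filter",
    "angular_velocity_series",
    "speed_at_angle_empirical",
    "detect_impact",
    "detect_release",
    "extract_observables",
    "DEFAULT_RATE",
    "DEFAULT_CUTOFF",
    "DEFAULT_GRF_THRESHOLD",
]

DEFAULT_RATE = 150.0  # Hz
DEFAULT_CUTOFF = 10.0  # Hz
DEFAULT_FILTER_ORDER = 2
DEFAULT_GRF_THRESHOLD = 10.0  # N
#: angle rise above theta0 that marks perturbation onset, degrees
RELEASE_DELTA_DEG = 0.5


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled scalar time series.

    ``quantity`` labels the physical content: ``angle-deg`` (platform angle,
    degrees), ``omega-rad-s`` (angular velocity, rad/s) or ``grf-N``
    (vertical ground reaction force, N).
    """

    rate: float
    values: np.ndarray
    quantity: str = "angle-deg"

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate


@dataclass(frozen=True)
class TrialObservables:
    """Observables extracted from one trial's raw traces."""

    omega_at_70: float
    impact_index: Optional[int] = None
    release_index: Optional[int] = None

    def __post_init__(self):
        if (
            self.release_index is not None
            and self.impact_index is not None
            and not self.release_index < self.impact_index
        ):
            raise ValueError("release must precede impact")


def lowpass_filter(
    series: SampledSeries,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_FILTER_ORDER,
) -> SampledSeries:
    """Zero-phase (dual-pass) Butterworth low-pass filter.

    The filter is applied forward then backward (``filtfilt``), cancelling
    phase lag and squaring the single-pass magnitude response. DC gain is
    exactly 1. The series must be long enough for the filter's edge padding.
    """
    nyq = series.rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    b, a = signal.butter(order, cutoff / nyq)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(series) <= max(padlen, 4 * order):
        raise ValueError(f"series of length {len(series)} too short for stable dual-pass filtering")
    return replace(series, values=signal.filtfilt(b, a, series.values))


def angular_velocity_series(angle: SampledSeries) -> SampledSeries:
    """Differentiate an angle series (degrees) into angular velocity (rad/s).

    Central differences in the interior (O(dt^2)), one-sided at the ends.
    """
    if len(angle) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / angle.rate
    omega = np.gradient(np.radians(angle.values), dt)
    return SampledSeries(rate=angle.rate, values=omega, quantity="omega-rad-s")


def speed_at_angle_empirical(
    angle: SampledSeries,
    omega: SampledSeries,
    target_deg: float = 70.0,
) -> float:
    """Angular velocity (rad/s) at the upward crossing of ``target_deg``.

    The angle trace must cross the target exactly once while increasing; the
    velocity is linearly interpolated between the bracketing samples (at
    150 Hz consecutive samples are <~0.5 deg apart near impact speeds).
    """
    if len(angle) != len(omega):
        raise ValueError("angle and omega series must have equal length")
    vals = angle.values
    below = vals < target_deg
    crossings = np.nonzero(below[:-1] & ~below[1:])[0]
    if vals[0] >= target_deg:
        raise ValueError(
            f"angle starts at {vals[0]:.2f} deg, already at or above target {target_deg} deg"
        )
    if len(crossings) == 0:
        raise ValueError(f"angle never crosses {target_deg} deg: malformed trial")
    if len(crossings) > 1:
        raise ValueError(f"angle crosses {target_deg} deg {len(crossings)} times: malformed trial")
    i = crossings[0]
    if vals[i + 1] == vals[i]:  # exactly at a sample
        return float(omega.values[i])
    frac = (target_deg - vals[i]) / (vals[i + 1] - vals[i])
    return float(omega.values[i] + frac * (omega.values[i + 1] - omega.values[i]))


def detect_impact(grf: SampledSeries, threshold: float = DEFAULT_GRF_THRESHOLD) -> Optional[int]:
    """Index of the first GRF sample strictly above ``threshold`` (N), or None."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    above = np.nonzero(grf.values > threshold)[0]
    return int(above[0]) if len(above) else None


def detect_release(angle: SampledSeries, delta_deg: float = RELEASE_DELTA_DEG) -> Optional[int]:
    """Perturbation-onset index: first sample where the angle exceeds its
    initial value by ``delta_deg`` degrees."""
    above = np.nonzero(angle.values > angle.values[0] + delta_deg)[0]
    return int(above[0]) if len(above) else None


def extract_observables(
    angle: SampledSeries,
    grf: Optional[SampledSeries] = None,
    target_deg: float = 70.0,
    cutoff: float = DEFAULT_CUTOFF,
    grf_threshold: float = DEFAULT_GRF_THRESHOLD,
) -> TrialObservables:
    """Full per-trial pipeline: filter, differentiate, read out, detect impact."""
    filtered = lowpass_filter(angle, cutoff=cutoff)
    omega = angular_velocity_series(filtered)
    w70 = speed_at_angle_empirical(filtered, omega, target_deg)
    impact = detect_impact(grf, grf_threshold) if grf is not None else None
    release = detect_release(angle)
    return TrialObservables(omega_at_70=w70, impact_index=impact, release_index=release)
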