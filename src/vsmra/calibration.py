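"""Protocol calibration from field-map ROI statistics and flow curves.

Two measurement streams feed the sequence design: (i) B0/B1 values sampled
in arterial and muscle ROIs give the representative field errors that set
the VS pre-compensation parameters, and (ii) phase-contrast time-velocity
curves give the systolic onset and peak times that set the ECG trigger
delays of the SS and VS preparations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .vs_prep import PrecompParams


class InsufficientDataError(ValueError):
    pass


class NoSystoleError(ValueError):
    pass


@dataclass(frozen=True)
class RoiSample:
    """Scalar samples pooled over a region of interest (Hz for B0, a
    dimensionless scale for B1)."""

    values: np.ndarray
    label: str = "artery"
    station: int = 1

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("ROI sample must be non-empty")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class FlowCurve:
    """Velocity versus time after the ECG trigger (uniform sampling)."""

    time: np.ndarray  # ms
    velocity: np.ndarray  # cm/s

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        if t.size < 5 or t.shape != v.shape:
            raise ValueError("flow curve needs >= 5 matched samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "velocity", v)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def at(self, t: float) -> float:
        """Velocity at time ``t`` (ms post-trigger), periodic extension,
        linear interpolation."""
        period = self.time[-1] - self.time[0] + self.dt
        tt = self.time[0] + (t - self.time[0]) % period
        return float(np.interp(tt, self.time, self.velocity))


@dataclass(frozen=True)
class SystoleTiming:
    onset: float  # ms
    peak: float  # ms
    peak_velocity: float  # cm/s

    def __post_init__(self):
        if not self.onset < self.peak:
            raise ValueError("onset must precede peak")


def trimmed_range(values: Sequence[float], trim_fraction: float = 0.05):
    """Range of the values after discarding the 5% most extreme ones.

    ``floor(trim_fraction/2 * n)`` values are removed at each tail
    (symmetric trimming); the extrema of the survivors are returned.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 3:
        raise InsufficientDataError("need at least 3 values to trim")
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must lie in [0, 1)")
    k = int(math.floor(trim_fraction / 2.0 * v.size))
    kept = v[k : v.size - k]
    return float(kept[0]), float(kept[-1])


def trimmed_values(values: Sequence[float], trim_fraction: float = 0.05) -> np.ndarray:
    """The surviving (sorted) values of the symmetric trim."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 3:
        raise InsufficientDataError("need at least 3 values to trim")
    k = int(math.floor(trim_fraction / 2.0 * v.size))
    return v[k : v.size - k]


def derive_precomp(
    b0_roi: RoiSample, b1_roi: RoiSample, trim_fraction: float = 0.05
) -> PrecompParams:
    """Pre-compensation parameters from ROI field statistics: ``A`` is the
    inverse of the median trimmed B1 scale, ``f`` the median trimmed B0
    offset."""
    b1_med = float(np.median(trimmed_values(b1_roi.values, trim_fraction)))
    if b1_med <= 0:
        raise ValueError("median B1 scale must be positive")
    f = float(np.median(trimmed_values(b0_roi.values, trim_fraction)))
    return PrecompParams(A=1.0 / b1_med, f=f)


def detect_systole(
    curve: FlowCurve, onset_threshold: float = 0.10, min_height: float = 1e-6
) -> SystoleTiming:
    """Locate the systolic upstroke in a time-velocity curve.

    The peak is the sample of maximum velocity; the baseline is the
    pre-upstroke minimum (before the peak); the onset is the earliest
    threshold crossing at ``baseline + onset_threshold * height``, linearly
    interpolated between samples.
    """
    t, v = curve.time, curve.velocity
    ipk = int(np.argmax(v))
    if ipk == 0:
        baseline = float(v[0])
    else:
        baseline = float(np.min(v[: ipk + 1]))
    height = float(v[ipk]) - baseline
    if height <= min_height:
        raise NoSystoleError("curve has no systolic upstroke")
    level = baseline + onset_threshold * height
    ibase = int(np.argmin(v[: ipk + 1])) if ipk > 0 else 0
    onset = float(t[ibase])
    for i in range(ibase, ipk):
        if v[i] <= level <= v[i + 1] and v[i + 1] > v[i]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            onset = float(t[i] + frac * (t[i + 1] - t[i]))
            break
    else:
        if v[ibase] > level:
            onset = float(t[ibase])
    return SystoleTiming(onset=onset, peak=float(t[ipk]), peak_velocity=float(v[ipk]))


def _round_half_up(x: float, step: float) -> float:
    return math.floor(x / step + 0.5) * step


def derive_trigger_delays(
    timing: SystoleTiming,
    lead_ss: float = 20.0,
    lead_vs: float = 15.0,
    round_to: float = 10.0,
) -> tuple[float, float]:
    """ECG trigger delays (ms) for the SS and VS preparations.

    The SS inversion leads the systolic onset by ``lead_ss`` and the VS
    saturation leads the systolic peak by ``lead_vs``; both are rounded
    half-up to ``round_to`` and clamped at zero.
    """
    td_ss = _round_half_up(timing.onset - lead_ss, round_to)
    td_vs = _round_half_up(timing.peak - lead_vs, round_to)
    clamped = False
    if td_ss < 0:
        td_ss, clamped = 0.0, True
    if td_vs < 0:
        td_vs, clamped = 0.0, True
    if clamped:
        import warnings

        warnings.warn("trigger delay clamped to 0 ms", stacklevel=2)
    return float(td_ss), float(td_vs)
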