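"""Rotating-frame Bloch simulation under the hard-pulse approximation.

The engine treats every waveform sample as a constant effective field and
applies the exact axis-angle rotation it generates, so the only time-step
errors are (i) the piecewise-constant sampling of continuously modulated RF
and (ii) the frozen spin position within one sample.  Velocity is handled by
advancing the spin position linearly between samples; relaxation, when
enabled, is applied after each rotation (rotate-then-relax operator
splitting, second-order accurate in the time step).

Conventions (inherited by every other module):

* RF samples are complex nutation rates in Hz (``gamma * B1 / 2pi``); the
  complex argument is the RF phase in radians.
* Gradients are in mT/m, positions in mm, velocities in cm/s, times in ms,
  off-resonance in Hz.
* A 90 degree pulse of phase 0 ("about +x") takes (0, 0, 1) to (0, 1, 0).
  With this handedness a spin at off-resonance ``f`` accrues transverse
  phase ``+2*pi*f*t``, so an RF phase ramp ``exp(+1j*2*pi*f*t)`` tracks it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Proton gyromagnetic ratio, gamma / 2 pi, in kHz/mT.  Numerically equal to
#: Hz per (mT/m * mm), the form used when combining gradients and positions.
GAMMA_KHZ_PER_MT = 42.577


class WaveformError(ValueError):
    """Malformed or mismatched RF/gradient waveforms."""


@dataclass(frozen=True)
class RFWaveform:
    """Complex RF waveform on a uniform time grid.

    Parameters
    ----------
    samples:
        Complex nutation rate per sample in Hz; ``abs`` is the instantaneous
        nutation amplitude, ``angle`` the RF phase in radians.
    dt:
        Sample duration in ms.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=complex)
        if samples.ndim != 1:
            raise WaveformError("RF samples must be one-dimensional")
        if not np.all(np.isfinite(samples.view(float))):
            raise WaveformError("RF samples must be finite")
        if not self.dt > 0:
            raise WaveformError("dt must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Total duration in ms."""
        return len(self.samples) * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample-center times in ms."""
        return (np.arange(len(self.samples)) + 0.5) * self.dt


@dataclass(frozen=True)
class GradientWaveform:
    """Gradient waveform in mT/m, sharing the time grid of a paired RF."""

    samples: np.ndarray
    dt: float
    axis: str = "z"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or not np.all(np.isfinite(samples)):
            raise WaveformError("gradient samples must be finite and 1-D")
        if not self.dt > 0:
            raise WaveformError("dt must be positive")
        if self.axis not in ("x", "y", "z"):
            raise WaveformError("axis must be one of x/y/z")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self.samples)) + 0.5) * self.dt

    @property
    def m0(self) -> float:
        """Zeroth moment, sum(G dt), in mT/m * ms."""
        return float(np.sum(self.samples) * self.dt)

    @property
    def m1(self) -> float:
        """First moment, sum(G t dt), in mT/m * ms^2 (sample-center times)."""
        return float(np.sum(self.samples * self.times) * self.dt)


@dataclass
class Isochromat:
    """A single simulated spin: magnetization plus its physical context.

    ``position`` is measured along the gradient axis.  ``T1``/``T2`` may be
    ``math.inf`` to disable the corresponding relaxation channel.
    """

    M: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    position: float = 0.0  # mm
    velocity: float = 0.0  # cm/s, constant during one preparation pulse
    off_resonance: float = 0.0  # Hz
    b1_scale: float = 1.0
    T1: float = math.inf  # ms
    T2: float = math.inf  # ms

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (3,) or not np.all(np.isfinite(self.M)):
            raise ValueError("M must be a finite 3-vector")
        if not self.b1_scale > 0:
            raise ValueError("b1_scale must be positive")
        if not (self.T1 > 0 and self.T2 > 0):
            raise ValueError("T1 and T2 must be positive")


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation about a unit axis with the package's fixed handedness.

    Defined so that ``rotation_matrix([1,0,0], pi/2)`` maps z to y (the
    convention-defining hard-pulse case); equivalently Rodrigues' formula
    evaluated at ``-angle``.
    """
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return c * np.eye(3) - s * K + (1.0 - c) * np.outer(k, k)


def hard_pulse_rotation(flip_deg: float, phase_rad: float, M: Sequence[float]) -> np.ndarray:
    """Instantaneous rotation by ``flip_deg`` about the transverse axis
    (cos(phase), sin(phase), 0).  Total function; no relaxation."""
    axis = np.array([math.cos(phase_rad), math.sin(phase_rad), 0.0])
    return rotation_matrix(axis, math.radians(flip_deg)) @ np.asarray(M, dtype=float)


def _check_pair(rf: RFWaveform, grad: GradientWaveform) -> None:
    if len(rf) != len(grad) or not math.isclose(rf.dt, grad.dt, rel_tol=1e-12):
        raise WaveformError("RF and gradient waveforms must share the time grid")


def simulate_ensemble(
    rf: RFWaveform,
    grad: GradientWaveform,
    position=0.0,
    velocity=0.0,
    off_resonance=0.0,
    b1_scale=1.0,
    M0: Sequence[float] = (0.0, 0.0, 1.0),
    relaxation: bool = False,
    T1: float = math.inf,
    T2: float = math.inf,
    events: Mapping[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Propagate many isochromats through one RF/gradient waveform pair.

    ``position`` (mm), ``velocity`` (cm/s), ``off_resonance`` (Hz) and
    ``b1_scale`` broadcast against each other to define the ensemble.
    ``events`` maps sample indices to instantaneous 3x3 rotation matrices
    applied just before that sample (index ``len(rf)`` means after the last
    sample); they model idealized zero-duration rotations.

    Returns an ``(N, 3)`` array of final magnetization vectors (``(3,)`` if
    every input is scalar).
    """
    _check_pair(rf, grad)
    pos, vel, off, scale = np.broadcast_arrays(
        np.atleast_1d(np.asarray(position, dtype=float)),
        np.atleast_1d(np.asarray(velocity, dtype=float)),
        np.atleast_1d(np.asarray(off_resonance, dtype=float)),
        np.atleast_1d(np.asarray(b1_scale, dtype=float)),
    )
    scalar_input = all(
        np.ndim(a) == 0 for a in (position, velocity, off_resonance, b1_scale)
    )
    n_spins = pos.shape[0]
    M = np.tile(np.asarray(M0, dtype=float), (n_spins, 1))

    dt = rf.dt
    t_mid = rf.times
    v_mm_per_ms = vel * 0.01  # cm/s -> mm/ms
    if relaxation:
        E1 = math.exp(-dt / T1)
        E2 = math.exp(-dt / T2)

    rf_re = rf.samples.real
    rf_im = rf.samples.imag
    g = grad.samples
    events = dict(events or {})

    for i in range(len(rf)):
        if i in events:
            M = M @ np.asarray(events[i], dtype=float).T
        bx = scale * rf_re[i]
        by = scale * rf_im[i]
        x = pos + v_mm_per_ms * t_mid[i]
        bz = -(off + GAMMA_KHZ_PER_MT * g[i] * x)
        bmag = np.sqrt(bx * bx + by * by + bz * bz)
        nonzero = bmag > 0.0
        if np.any(nonzero):
            inv = np.where(nonzero, 1.0 / np.where(nonzero, bmag, 1.0), 0.0)
            kx, ky, kz = bx * inv, by * inv, bz * inv
            theta = 2.0 * math.pi * bmag * dt * 1e-3  # Hz * ms -> rad
            c = np.cos(theta)
            s = np.where(nonzero, np.sin(theta), 0.0)
            c = np.where(nonzero, c, 1.0)
            mx, my, mz = M[:, 0], M[:, 1], M[:, 2]
            kdotm = kx * mx + ky * my + kz * mz
            cx = ky * mz - kz * my
            cy = kz * mx - kx * mz
            cz = kx * my - ky * mx
            omc = 1.0 - c
            M = np.stack(
                (
                    c * mx - s * cx + omc * kdotm * kx,
                    c * my - s * cy + omc * kdotm * ky,
                    c * mz - s * cz + omc * kdotm * kz,
                ),
                axis=1,
            )
        if relaxation:
            M[:, 0] *= E2
            M[:, 1] *= E2
            M[:, 2] = 1.0 + (M[:, 2] - 1.0) * E1
    if len(rf) in events:
        M = M @ np.asarray(events[len(rf)], dtype=float).T
    return M[0] if scalar_input else M


def simulate_piecewise(
    rf: RFWaveform,
    grad: GradientWaveform,
    spin: Isochromat,
    relaxation: bool = False,
    events: Mapping[int, np.ndarray] | None = None,
) -> Isochromat:
    """Propagate a single isochromat through a waveform pair.

    Returns a new :class:`Isochromat` with the final magnetization and the
    position advanced by ``velocity * duration``.
    """
    M = simulate_ensemble(
        rf,
        grad,
        position=spin.position,
        velocity=spin.velocity,
        off_resonance=spin.off_resonance,
        b1_scale=spin.b1_scale,
        M0=spin.M,
        relaxation=relaxation,
        T1=spin.T1,
        T2=spin.T2,
        events=events,
    )
    new_pos = spin.position + spin.velocity * 0.01 * rf.duration
    return replace(spin, M=M, position=new_pos)
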