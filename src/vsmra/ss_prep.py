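"""Slab-selective (SS) adiabatic hyperbolic-secant inversion.

The inversion envelope is ``A(t') = peak_b1 * sech(beta * t')`` with a
frequency sweep ``df(t') = -mu * beta * tanh(beta * t') / (2 pi)`` realized
as phase modulation (single RF channel), ``t'`` symmetric about the pulse
center.  Its inversion band is ``mu * beta / pi`` Hz wide; played under a
constant slab-select gradient the band maps to a spatial slab, sized to
cover the imaging volume plus a superior margin so upstream venous blood is
pre-inverted before it flows into the volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .bloch import GAMMA_KHZ_PER_MT, GradientWaveform, RFWaveform, simulate_ensemble
from .vs_prep import PreparationPulse

#: nutation rate of a 0.5 uT B1 field, Hz — the granularity of the default
#: peak-amplitude search.
B1_STEP_HZ = GAMMA_KHZ_PER_MT * 0.5e-3 * 1e3  # 21.29 Hz


@dataclass(frozen=True)
class HSPulseSpec:
    """Hyperbolic-secant design parameters (defaults: the 30 ms, beta = 300
    rad/s, mu = 14 whole-neck inversion)."""

    duration: float = 30.0  # ms
    beta: float = 300.0  # rad/s
    mu: float = 14.0
    peak_b1: float | None = None  # Hz nutation; None -> smallest adiabatic value
    slab_thickness: float = 264.0  # mm
    dt: float = 0.01  # ms

    def __post_init__(self):
        if not (self.duration > 0 and self.beta > 0 and self.mu > 0 and self.dt > 0):
            raise ValueError("duration, beta, mu and dt must be positive")
        if self.peak_b1 is not None and not self.peak_b1 > 0:
            raise ValueError("peak_b1 must be positive")
        if not self.slab_thickness > 0:
            raise ValueError("slab_thickness must be positive")


@dataclass(frozen=True)
class SlabGeometry:
    """S-I extent of the imaging volume and of the inversion slab (mm
    intervals); the slab overhangs the imaging volume superiorly."""

    imaging_extent: tuple[float, float]
    slab_extent: tuple[float, float]

    @property
    def margin_superior(self) -> float:
        return self.slab_extent[1] - self.imaging_extent[1]

    @property
    def slab_thickness(self) -> float:
        return self.slab_extent[1] - self.slab_extent[0]

    def contains(self, z_mm: float) -> bool:
        return self.slab_extent[0] <= z_mm <= self.slab_extent[1]


def hs_bandwidth(beta: float, mu: float) -> float:
    """Inversion bandwidth ``mu * beta / pi`` in Hz (sech/tanh sweep)."""
    if beta < 0 or mu < 0:
        raise ValueError("beta and mu must be non-negative")
    return mu * beta / math.pi


def _hs_waveforms(spec: HSPulseSpec, peak_b1: float) -> tuple[RFWaveform, GradientWaveform]:
    n = round(spec.duration / spec.dt)
    t_ms = (np.arange(n) + 0.5) * spec.dt - spec.duration / 2.0  # centered
    t_s = t_ms * 1e-3
    amp = peak_b1 / np.cosh(spec.beta * t_s)
    # phase = integral of the sweep: -mu * ln cosh(beta t)
    phase = -spec.mu * np.log(np.cosh(spec.beta * t_s))
    rf = RFWaveform(amp * np.exp(1j * phase), spec.dt)
    grad_amp = hs_bandwidth(spec.beta, spec.mu) / (
        GAMMA_KHZ_PER_MT * spec.slab_thickness
    )
    grad = GradientWaveform(np.full(n, grad_amp), spec.dt)
    return rf, grad


@lru_cache(maxsize=32)
def adiabatic_threshold(
    duration: float, beta: float, mu: float, dt: float, target: float = -0.97
) -> float:
    """Smallest peak nutation (Hz, in 0.5 uT-equivalent steps) for which the
    on-resonance inversion reaches ``Mz < target``."""
    spec = HSPulseSpec(duration=duration, beta=beta, mu=mu, peak_b1=1.0, dt=dt)
    for k in range(1, 200):
        peak = k * B1_STEP_HZ
        rf, _ = _hs_waveforms(spec, peak)
        grad0 = GradientWaveform(np.zeros(len(rf)), dt)
        mz = simulate_ensemble(rf, grad0)[2]
        if mz < target:
            return peak
    raise RuntimeError("no adiabatic amplitude found below 100 uT")


def design_hs_inversion(spec: HSPulseSpec) -> PreparationPulse:
    """Build the sech/tanh inversion with its constant slab-select gradient
    (amplitude = bandwidth / (gamma * slab_thickness))."""
    peak = spec.peak_b1
    if peak is None:
        peak = adiabatic_threshold(spec.duration, spec.beta, spec.mu, spec.dt)
    rf, grad = _hs_waveforms(spec, peak)
    meta = {
        "spec": spec,
        "peak_b1": peak,
        "bandwidth": hs_bandwidth(spec.beta, spec.mu),
        "grad_amp": grad.samples[0],
        "sweep_extent": spec.mu
        * spec.beta
        * math.tanh(spec.beta * spec.duration * 1e-3 / 2.0)
        / (2.0 * math.pi),
    }
    return PreparationPulse(rf, grad, events={}, meta=meta)


def inversion_profile(
    pulse: PreparationPulse, offsets, peak_b1_scale: float = 1.0
) -> np.ndarray:
    """Bloch-simulated final Mz per off-resonance (Hz); equivalently per
    position ``offset / (gamma * grad_amp)`` on the slab gradient."""
    off = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(off)):
        raise ValueError("offset grid must be finite")
    grad0 = GradientWaveform(np.zeros(len(pulse.rf)), pulse.rf.dt)
    M = simulate_ensemble(pulse.rf, grad0, off_resonance=off, b1_scale=peak_b1_scale)
    return M[:, 2]


def inversion_efficiency(
    pulse: PreparationPulse, off_resonance=0.0, b1_scale=1.0
) -> np.ndarray:
    """Longitudinal scaling factor of the inversion (ideally -1) at given
    field errors, assuming transverse spoiling afterwards."""
    off = np.atleast_1d(np.asarray(off_resonance, dtype=float))
    scale = np.atleast_1d(np.asarray(b1_scale, dtype=float))
    off, scale = np.broadcast_arrays(off, scale)
    grad0 = GradientWaveform(np.zeros(len(pulse.rf)), pulse.rf.dt)
    M = simulate_ensemble(pulse.rf, grad0, off_resonance=off, b1_scale=scale)
    out = M[:, 2]
    return out if np.ndim(off_resonance) or np.ndim(b1_scale) else float(out[0])


def slab_geometry(imaging_extent, margin_superior: float) -> SlabGeometry:
    """Slab covering the imaging extent plus a superior margin; inferior
    edges coincide.  ``imaging_extent`` is a thickness (mm) or an
    (inferior, superior) interval."""
    if margin_superior < 0:
        raise ValueError("superior margin must be non-negative")
    if np.isscalar(imaging_extent):
        if not imaging_extent > 0:
            raise ValueError("imaging extent must be positive")
        extent = (0.0, float(imaging_extent))
    else:
        lo, hi = map(float, imaging_extent)
        if not hi > lo:
            raise ValueError("imaging extent must be a non-empty interval")
        extent = (lo, hi)
    return SlabGeometry(extent, (extent[0], extent[1] + float(margin_superior)))
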