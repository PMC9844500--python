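"""Velocity-selective (VS) saturation pulse design and simulation.

The VS preparation is a train of ``n_sub`` hard RF sub-pulses separated by
double-refocused velocity-encoding intervals.  Each interval carries two
90x-180y-90x composite refocusing pulses (each an exact 180 about y on
resonance) and two unipolar gradient lobes, one before the first composite
and one right after it, with the post-lobe gap equal to the end gap so the
interval is a double spin echo: a static spin's gradient and off-resonance
phase cancels exactly, and the pair of 180s composes to the identity, so
the whole interval reduces to a pure z-rotation whose angle is the
velocity-encoding phase ``2*pi*v/fov_v`` (the two lobes act at different
times, so only the motion between them survives the refocusing).  Because
every interval is a plain z-rotation, the phase ramp accumulates linearly
across the train: sub-pulse ``k`` effectively rotates about a transverse
axis at phase ``k * 2*pi*v/fov_v``, which makes the zero-velocity response
a clean rotation by the full flip angle, the velocity response periodic
with period ``fov_v``, and the stop band the Fourier (Dirichlet-kernel)
mainlobe of the uniform sub-pulse train.

Field-error pre-compensation scales the whole RF waveform by ``A`` (the
inverse of the representative B1 scale) and applies a linear phase ramp at
the representative off-resonance ``f``, so the pulse is played "already
rotated" into the frame of the mis-set spins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bloch import (
    GAMMA_KHZ_PER_MT,
    GradientWaveform,
    RFWaveform,
    rotation_matrix,
    simulate_ensemble,
)


class InfeasiblePulseError(ValueError):
    """Requested pulse needs hardware beyond the configured limits."""


@dataclass(frozen=True)
class VSPulseSpec:
    """Design parameters of the VS saturation pulse.

    Defaults are the whole-neck protocol values: nine hard sub-pulses, a
    100 degree total flip and a 70 cm/s velocity field of view.
    """

    n_sub: int = 9
    flip_total: float = 100.0  # degrees
    fov_v: float = 70.0  # cm/s
    sub_pulse_dur: float = 0.5  # ms
    grad_lobe_dur: float = 0.5  # ms
    composite_dur: float = 1.6  # ms (90x is a quarter, 180y a half)
    gap_dur: float = 0.3  # ms echo-balancing gap after the 2nd lobe and at the end
    dt: float = 0.02  # ms simulation raster
    max_grad: float = 40.0  # mT/m hardware cap
    shot_index: int = 0

    def __post_init__(self):
        if self.n_sub < 2:
            raise ValueError("n_sub must be >= 2")
        if not self.fov_v > 0:
            raise ValueError("fov_v must be positive")
        if not 0 < self.flip_total < 180:
            raise ValueError("flip_total must lie in (0, 180) degrees")
        for name in ("sub_pulse_dur", "grad_lobe_dur", "composite_dur", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.gap_dur < 0:
            raise ValueError("gap_dur must be non-negative")


@dataclass(frozen=True)
class PrecompParams:
    """Eq.-style field pre-compensation: amplitude factor ``A`` (inverse of
    the representative B1 scale) and off-resonance ``f`` in Hz."""

    A: float = 1.0
    f: float = 0.0

    def __post_init__(self):
        if not self.A > 0:
            raise ValueError("A must be positive")
        if not math.isfinite(self.f):
            raise ValueError("f must be finite")


@dataclass(frozen=True)
class PreparationPulse:
    """A designed preparation pulse: RF + gradient (+ optional instantaneous
    rotation events) and the metadata of its construction."""

    rf: RFWaveform
    grad: GradientWaveform
    events: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.rf.duration

    def precompensated(self, params: PrecompParams) -> "PreparationPulse":
        return replace(self, rf=precompensate_rf(self.rf, params))


def cutoff_velocity(spec: VSPulseSpec) -> float:
    """Nominal cut-off velocity, ``fov_v / (2 (n_sub + 1))`` cm/s.

    This is the design convention separating the saturated slow band from
    the preserved fast band; :func:`stopband_width` reports the simulated
    counterpart.
    """
    return spec.fov_v / (2.0 * (spec.n_sub + 1))


def _steps(duration: float, dt: float) -> int:
    n = round(duration / dt)
    if n < 1 or abs(n * dt - duration) > 1e-9:
        raise ValueError(f"duration {duration} ms is not a multiple of dt={dt} ms")
    return n


def design_vs_pulse(spec: VSPulseSpec, ideal_refocusing: bool = False) -> PreparationPulse:
    """Construct the double-refocused VS saturation pulse.

    Each encoding interval is laid out as::

        [lobe][composite 1][lobe][gap][composite 2][gap]

    (all lobes unipolar).  The first lobe sits before composite 1 and the
    second right after it; the two equal gaps make the interval a double
    spin echo, so static and off-resonance phase refocus while the
    velocity phase ``2*pi*v/fov_v`` set by the lobe-center separation
    survives.  With ``ideal_refocusing`` the composites are replaced by
    zero-duration exact 180y rotations at the centers of the (silent)
    composite windows; timing and gradients are unchanged.  This isolates
    the encoding-interval contract from composite imperfections in tests.
    """
    dt = spec.dt
    n_sp = _steps(spec.sub_pulse_dur, dt)
    n_lobe = _steps(spec.grad_lobe_dur, dt)
    n_c4 = _steps(spec.composite_dur / 4.0, dt)
    n_gap = _steps(spec.gap_dur, dt) if spec.gap_dur else 0

    # Gradient amplitude from the per-interval first-moment requirement:
    # a spin at v cm/s must gain v/fov_v cycles per encoding interval.
    lobe_sep = spec.grad_lobe_dur + spec.composite_dur  # ms between lobe centers
    grad_amp = 1e5 / (GAMMA_KHZ_PER_MT * spec.grad_lobe_dur * lobe_sep * spec.fov_v)
    if grad_amp > spec.max_grad:
        raise InfeasiblePulseError(
            f"velocity encoding needs {grad_amp:.1f} mT/m > cap {spec.max_grad} mT/m"
        )

    sub_flip = spec.flip_total / spec.n_sub  # degrees
    sub_amp = (sub_flip / 360.0) / (n_sp * dt * 1e-3)  # Hz nutation
    comp_amp = 0.25 / (n_c4 * dt * 1e-3)  # 90 deg over a quarter window

    rf: list[np.ndarray] = []
    gr: list[np.ndarray] = []
    events: dict[int, np.ndarray] = {}
    subpulse_bounds, interval_bounds = [], []
    cursor = 0

    def emit(rf_val: complex, g_val: float, n: int):
        nonlocal cursor
        if n:
            rf.append(np.full(n, rf_val, dtype=complex))
            gr.append(np.full(n, g_val))
            cursor += n

    def composite():
        if ideal_refocusing:
            events[cursor + 2 * n_c4] = rotation_matrix((0.0, 1.0, 0.0), math.pi)
            emit(0.0, 0.0, 4 * n_c4)
        else:
            emit(comp_amp, 0.0, n_c4)
            emit(comp_amp * 1j, 0.0, 2 * n_c4)  # 180 about y
            emit(comp_amp, 0.0, n_c4)

    for k in range(spec.n_sub):
        subpulse_bounds.append((cursor, cursor + n_sp))
        emit(sub_amp, 0.0, n_sp)
        if k == spec.n_sub - 1:
            break
        start = cursor
        emit(0.0, grad_amp, n_lobe)
        composite()
        emit(0.0, grad_amp, n_lobe)
        emit(0.0, 0.0, n_gap)
        composite()
        emit(0.0, 0.0, n_gap)
        interval_bounds.append((start, cursor))

    rf_wave = RFWaveform(np.concatenate(rf), dt)
    grad_wave = GradientWaveform(np.concatenate(gr), dt)
    meta = {
        "spec": spec,
        "grad_amp": grad_amp,
        "subpulse_bounds": subpulse_bounds,
        "interval_bounds": interval_bounds,
        "interval_m0": 2.0 * grad_amp * n_lobe * dt,  # mT/m * ms, unipolar area
        "ideal_refocusing": ideal_refocusing,
    }
    return PreparationPulse(rf_wave, grad_wave, events, meta)


def precompensate_rf(rf: RFWaveform, params: PrecompParams) -> RFWaveform:
    """Scale every sample by ``A`` and apply the linear phase ramp
    ``exp(+1j 2 pi f t)``; the duration is unchanged."""
    if not params.A > 0:
        raise ValueError("A must be positive")
    ramp = np.exp(1j * 2.0 * math.pi * params.f * rf.times * 1e-3)
    return RFWaveform(params.A * rf.samples * ramp, rf.dt)


def velocity_response(
    pulse: PreparationPulse,
    velocities: Sequence[float],
    off_resonance: float = 0.0,
    b1_scale: float = 1.0,
    position: float = 0.0,
) -> np.ndarray:
    """Final Mz per velocity (cm/s), starting from equilibrium, no relaxation."""
    v = np.asarray(velocities, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity grid must be finite")
    M = simulate_ensemble(
        pulse.rf,
        pulse.grad,
        position=position,
        velocity=v,
        off_resonance=off_resonance,
        b1_scale=b1_scale,
        events=pulse.events,
    )
    return M[:, 2]


def spatial_response(
    pulse: PreparationPulse,
    positions: Sequence[float],
    velocity: float = 0.0,
    off_resonance: float = 0.0,
    b1_scale: float = 1.0,
) -> np.ndarray:
    """Final Mz per position (mm); stripes appear when refocusing is
    imperfect (e.g. scaled B1)."""
    x = np.asarray(positions, dtype=float)
    M = simulate_ensemble(
        pulse.rf,
        pulse.grad,
        position=x,
        velocity=velocity,
        off_resonance=off_resonance,
        b1_scale=b1_scale,
        events=pulse.events,
    )
    return M[:, 2]


def stopband_width(pulse: PreparationPulse, grid_step: float = 0.05) -> float:
    """Simulated full width (cm/s) of the saturation band around v = 0.

    Edges are the first crossings of the midpoint between the saturated
    level ``cos(flip_total)`` and the pass-band level 1.
    """
    spec = pulse.meta["spec"]
    vmax = spec.fov_v / 2.0
    v = np.arange(-vmax, vmax + grid_step / 2, grid_step)
    mz = velocity_response(pulse, v)
    level = 0.5 * (math.cos(math.radians(spec.flip_total)) + 1.0)
    below = mz < level
    if not below[np.argmin(np.abs(v))]:
        return 0.0
    idx0 = int(np.argmin(np.abs(v)))
    lo = idx0
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = idx0
    while hi < len(v) - 1 and below[hi + 1]:
        hi += 1
    return float(v[hi] - v[lo])


def stripe_period(pulse: PreparationPulse) -> float:
    """Spatial period (mm) of the residual excitation stripe pattern, set by
    the per-interval unipolar gradient area."""
    m0 = pulse.meta["interval_m0"]  # mT/m * ms
    return 1e3 / (GAMMA_KHZ_PER_MT * m0)


def shift_pulse(pulse: PreparationPulse, shift_mm: float) -> PreparationPulse:
    """Translate the spatial excitation profile by ``shift_mm``.

    Implemented as the gradient-referenced RF phase ramp that is exactly
    equivalent to offsetting the gradient isocenter: the response at
    position x of the shifted pulse equals the original response at
    x + shift_mm, while the velocity response at the isocenter is
    unchanged.
    """
    g = pulse.grad.samples
    dt = pulse.grad.dt
    # cumulative gradient area up to each sample center, mT/m * ms
    a_cum = np.cumsum(g) * dt - 0.5 * g * dt
    phase = -2.0 * math.pi * GAMMA_KHZ_PER_MT * shift_mm * a_cum * 1e-3
    rf = RFWaveform(pulse.rf.samples * np.exp(1j * phase), dt)
    meta = dict(pulse.meta)
    meta["shift_mm"] = meta.get("shift_mm", 0.0) + shift_mm
    return replace(pulse, rf=rf, meta=meta)


def make_shot_set(spec: VSPulseSpec, n_shots: int = 4) -> list[PreparationPulse]:
    """The alternately applied VS pulses with spatially shifted profiles.

    Shot ``k`` is the base design translated by ``k/n_shots`` of one stripe
    period, so averaging over a shot cycle smooths residual stripe
    artifacts while leaving the velocity response untouched.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    base = design_vs_pulse(spec)
    period = stripe_period(base)
    shots = []
    for k in range(n_shots):
        shot = shift_pulse(base, k * period / n_shots) if k else base
        meta = dict(shot.meta)
        meta["spec"] = replace(spec, shot_index=k)
        shots.append(replace(shot, meta=meta))
    return shots
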