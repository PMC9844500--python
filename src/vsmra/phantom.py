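"""Digital neck phantom, synthetic measurements and the ECG-gated protocol
simulator.

The phantom is a labeled voxel volume with per-class relaxation times and
velocity waveforms: two superior-inferior arterial trunks joined by one
horizontal branch (emulating a subclavian artery), two venous tubes, muscle
background and a fat rim.  The protocol simulator replays the gated
preparation chain -- slab-selective inversion at the systolic-onset trigger
delay, velocity-selective saturation near peak systole one R-R later, then
the segmented readout -- and evolves each voxel's longitudinal
magnetization analytically to its periodic steady state.  The synthetic
angiogram is the center-of-k-space signal per voxel, which dominates image
contrast for the center-out view ordering.

Arterial inflow follows the replacement rule: blood arriving from below the
inversion slab between the two triggers carries fresh, uninverted
magnetization, so arterial voxels enter the VS pulse fully relaxed.
Venous blood flows down from inside the slab's superior margin and is
therefore inverted like static tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bloch import simulate_ensemble
from .calibration import FlowCurve
from .ss_prep import HSPulseSpec, design_hs_inversion, inversion_efficiency
from .vs_prep import (
    PrecompParams,
    PreparationPulse,
    VSPulseSpec,
    design_vs_pulse,
)

#: 3T literature relaxation defaults (ms); the protocol paper states none.
BLOOD_T1, BLOOD_T2 = 1650.0, 150.0
MUSCLE_T1, MUSCLE_T2 = 900.0, 50.0
FAT_T1, FAT_T2 = 380.0, 100.0

#: measured station defaults: (artery peak, vein, systole onset, systole peak)
STATION_DEFAULTS = {
    1: {"artery_peak": 66.18, "vein": 9.45, "onset": 58.15, "peak": 126.32},
    2: {"artery_peak": 46.88, "vein": 18.01, "onset": 90.23, "peak": 150.38},
}


class IncompletePhantomError(ValueError):
    pass


@dataclass(frozen=True)
class TissueClass:
    name: str
    T1: float  # ms
    T2: float  # ms
    proton_density: float
    velocity: float | FlowCurve = 0.0  # cm/s or a gated waveform
    fresh_inflow: bool = False  # replaced by un-prepped upstream blood
    suppressed: bool = False  # e.g. fat under ideal fat-sat
    in_slab: bool = True

    def __post_init__(self):
        if not (self.T1 >= self.T2 > 0):
            raise ValueError("need T1 >= T2 > 0")
        if self.proton_density < 0:
            raise ValueError("proton density must be non-negative")

    def velocity_at(self, t_ms: float) -> float:
        if isinstance(self.velocity, FlowCurve):
            return self.velocity.at(t_ms)
        return float(self.velocity)


@dataclass(frozen=True)
class Phantom:
    labels: np.ndarray  # 3D int labels, axes (x, y, z); z is S-I
    voxel_mm: float
    classes: Mapping[int, TissueClass]

    def __post_init__(self):
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.classes):
            raise ValueError("labels outside the class table")
        names = {c.name for c in self.classes.values()}
        if not {"artery", "muscle"} <= names:
            raise ValueError("phantom needs at least one artery and one muscle class")

    def label_of(self, name: str) -> int:
        for lab, cls in self.classes.items():
            if cls.name == name:
                return lab
        raise KeyError(name)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int, int] = (32, 32, 40)
    voxel_mm: float = 2.0
    station: int = 1
    artery_radius_mm: float = 4.0
    vein_radius_mm: float = 4.0
    branch_radius_mm: float = 3.0
    artery_peak_velocity: float | None = None  # cm/s; None -> station default
    vein_velocity: float | None = None

    def __post_init__(self):
        if min(self.artery_radius_mm, self.vein_radius_mm, self.branch_radius_mm) <= 0:
            raise ValueError("tube radii must be positive")
        if self.station not in (1, 2):
            raise ValueError("station must be 1 or 2")


@dataclass(frozen=True)
class ProtocolConfig:
    """ECG-gated timing and readout parameters of one station.

    ``TD_ss``/``TD_vs`` are trigger delays after the first/second R-wave;
    ``TI`` is the delay from the VS saturation to the first (center-out)
    readout view; the sequence repeats every ``repetition_rr`` R-R
    intervals.
    """

    TD_ss: float = 40.0  # ms
    TD_vs: float = 110.0  # ms
    TI: float = 100.0  # ms
    RR: float = 857.0  # ms (70 bpm)
    repetition_rr: int = 3
    readout_flip: float = 14.0  # degrees
    TR: float = 7.6  # ms
    views_per_segment: int = 71
    station: int = 1
    fov_mm: tuple[float, float, float] = (220.0, 220.0, 102.0)
    station_offset_mm: float = -48.5
    slab_margin_mm: float = 162.0
    inversion_duration: float = 30.0  # ms

    def __post_init__(self):
        if min(self.TD_ss, self.TD_vs, self.TI, self.RR, self.TR) < 0:
            raise ValueError("times must be non-negative")
        if self.TD_ss + self.inversion_duration > self.TD_vs + self.RR:
            raise ValueError("SS inversion would overlap the VS preparation")

    @property
    def cycle_ms(self) -> float:
        return self.repetition_rr * self.RR

    @property
    def ss_to_vs_ms(self) -> float:
        """Gap from the SS inversion to the VS saturation (second trigger)."""
        return self.RR + self.TD_vs - self.TD_ss


STATION2_PROTOCOL = ProtocolConfig(
    TD_ss=70.0,
    TD_vs=140.0,
    station=2,
    fov_mm=(220.0, 220.0, 130.0),
    station_offset_mm=65.0,
    slab_margin_mm=115.0,
)


def synth_flow_curve(
    onset: float = 58.15,
    peak: float = 126.32,
    peak_velocity: float = 66.18,
    baseline: float = 5.0,
    period: float = 857.0,
    dt: float = 20.05,
    shape: str = "triangle",
    noise: float = 0.0,
    seed: int | None = None,
) -> FlowCurve:
    """Pulsatile time-velocity curve with stated systolic landmarks.

    ``triangle`` rises linearly from (onset, baseline) to
    (peak, peak_velocity) and falls back over twice the upstroke time;
    ``gamma`` uses a gamma-variate upstroke with its apex at ``peak``.
    The sample nearest the apex is pinned to ``peak_velocity`` so the
    sampled maximum equals the requested peak (a phase-contrast
    measurement reports the frame maximum, not the continuous apex).
    Optional Gaussian noise (cm/s std) is seeded.
    """
    if not (0 <= onset < peak < period):
        raise ValueError("need 0 <= onset < peak < period")
    t = np.arange(0.0, period, dt)
    h = peak_velocity - baseline
    if shape == "triangle":
        down = peak + 2.0 * (peak - onset)
        v = baseline + h * np.interp(t, [0.0, onset, peak, down, period], [0, 0, 1, 0, 0])
    elif shape == "gamma":
        alpha = 3.0
        u = np.clip((t - onset) / (peak - onset), 0.0, None)
        v = baseline + h * u**alpha * np.exp(alpha * (1.0 - u))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    v[int(np.argmin(np.abs(t - peak)))] = peak_velocity
    if noise > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise, size=v.shape)
    return FlowCurve(t, v)


def default_tissue_classes(
    station: int = 1,
    artery_peak_velocity: float | None = None,
    vein_velocity: float | None = None,
) -> dict[int, TissueClass]:
    d = STATION_DEFAULTS[station]
    apk = d["artery_peak"] if artery_peak_velocity is None else artery_peak_velocity
    vv = d["vein"] if vein_velocity is None else vein_velocity
    artery_curve = synth_flow_curve(onset=d["onset"], peak=d["peak"], peak_velocity=apk)
    return {
        0: TissueClass("background", 1.0, 1.0, 0.0),
        1: TissueClass("muscle", MUSCLE_T1, MUSCLE_T2, 1.0),
        2: TissueClass("fat", FAT_T1, FAT_T2, 1.0, suppressed=True),
        3: TissueClass(
            "artery", BLOOD_T1, BLOOD_T2, 1.0, velocity=artery_curve, fresh_inflow=True
        ),
        4: TissueClass("vein", BLOOD_T1, BLOOD_T2, 1.0, velocity=vv),
    }


def make_neck_phantom(params: PhantomParams | None = None, seed: int = 0) -> Phantom:
    """Deterministic labeled neck phantom (label axes are x, y, z; z is S-I).

    Contains two vertical arterial trunks, one horizontal arterial branch,
    two vertical veins, elliptical muscle background and a fat rim; tube
    centers are jittered by up to half a voxel from the seed.
    """
    p = params or PhantomParams()
    nx, ny, nz = p.shape
    rng = np.random.default_rng(seed)
    vox = p.voxel_mm
    x = (np.arange(nx) - nx / 2.0 + 0.5) * vox
    y = (np.arange(ny) - ny / 2.0 + 0.5) * vox
    X, Y = np.meshgrid(x, y, indexing="ij")

    labels = np.zeros(p.shape, dtype=np.int8)
    a, b = 0.46 * nx * vox, 0.46 * ny * vox
    body = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    rim = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0) & ((X / (a - 2 * vox)) ** 2 + (Y / (b - 2 * vox)) ** 2 > 1.0)
    labels[body] = 1
    labels[rim] = 2

    def vertical_tube(cx, cy, radius, label, z_lo=0, z_hi=None):
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
        labels[:, :, slice(z_lo, z_hi)][mask] = label

    jit = lambda: rng.uniform(-0.5, 0.5) * vox
    dx = 0.22 * nx * vox
    vertical_tube(-dx + jit(), -0.15 * ny * vox + jit(), p.artery_radius_mm, 3)
    vertical_tube(+dx + jit(), -0.15 * ny * vox + jit(), p.artery_radius_mm, 3)
    vertical_tube(-dx + jit(), +0.2 * ny * vox + jit(), p.vein_radius_mm, 4)
    vertical_tube(+dx + jit(), +0.2 * ny * vox + jit(), p.vein_radius_mm, 4)

    # horizontal arterial branch (subclavian-like) near the inferior end
    zc = max(2, nz // 6)
    ycb = -0.15 * ny * vox + jit()
    z = (np.arange(nz) - zc) * vox
    Yb, Zb = np.meshgrid(y, z, indexing="ij")
    branch = (Yb - ycb) ** 2 + Zb**2 <= p.branch_radius_mm**2
    for ix in range(nx):
        if abs(x[ix]) <= dx:
            labels[ix][branch] = 3

    classes = default_tissue_classes(
        p.station, p.artery_peak_velocity, p.vein_velocity
    )
    return Phantom(labels=labels, voxel_mm=vox, classes=classes)


def synth_field_maps(
    shape: tuple[int, int, int],
    b0_range: tuple[float, float] = (-145.3, 346.9),
    b1_range: tuple[float, float] = (0.57, 1.17),
    order: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random polynomial B0 (Hz) and B1-scale volumes spanning the
    requested ranges exactly (deterministic per seed)."""
    rng = np.random.default_rng(seed)

    def poly_field(lo: float, hi: float) -> np.ndarray:
        coords = [np.linspace(-1.0, 1.0, n) for n in shape]
        U, V, W = np.meshgrid(*coords, indexing="ij")
        f = np.zeros(shape)
        for i in range(order + 1):
            for j in range(order + 1 - i):
                for k in range(order + 1 - i - j):
                    f += rng.normal() * U**i * V**j * W**k
        if hi == lo:
            return np.full(shape, lo)
        fmin, fmax = f.min(), f.max()
        return lo + (f - fmin) * (hi - lo) / (fmax - fmin)

    return poly_field(*b0_range), poly_field(*b1_range)


def prep_chain_mz(
    T1,
    eps_ss,
    r_vs,
    gap_ss_to_vs: float,
    gap_vs_to_read: float,
    gap_read_to_ss: float,
    fresh_inflow=False,
    tol: float = 1e-6,
    max_cycles: int = 500,
):
    """Steady-state longitudinal magnetization at the readout center.

    One cycle is: SS inversion (Mz -> eps_ss * Mz), T1 recovery for
    ``gap_ss_to_vs``, VS saturation (Mz -> r_vs * Mz), recovery for
    ``gap_vs_to_read``, readout sample, recovery for ``gap_read_to_ss``.
    All arguments broadcast; ``fresh_inflow`` voxels enter the VS pulse
    fully relaxed each cycle (their history is washed out by inflow).
    Iterates the cycle map until the readout Mz changes by < ``tol``.
    """
    T1, eps_ss, r_vs, fresh = np.broadcast_arrays(
        np.atleast_1d(np.asarray(T1, dtype=float)),
        np.atleast_1d(np.asarray(eps_ss, dtype=float)),
        np.atleast_1d(np.asarray(r_vs, dtype=float)),
        np.atleast_1d(np.asarray(fresh_inflow, dtype=bool)),
    )

    def recover(M, t):
        return 1.0 + (M - 1.0) * np.exp(-t / T1)

    M = np.ones_like(T1)
    prev = np.full_like(T1, np.nan)
    for _ in range(max_cycles):
        M_vs = recover(eps_ss * M, gap_ss_to_vs)
        M_vs = np.where(fresh, 1.0, M_vs)
        M_read = recover(r_vs * M_vs, gap_vs_to_read)
        if np.all(np.abs(M_read - prev) < tol):
            break
        prev = M_read
        M = recover(M_read, gap_read_to_ss)
    return M_read if np.ndim(T1) else float(M_read[0])


def _vs_multipliers(
    vs_pulse: PreparationPulse,
    velocities: np.ndarray,
    b0: np.ndarray,
    b1: np.ndarray,
) -> np.ndarray:
    """Per-voxel longitudinal VS scaling via one batched Bloch run over the
    unique (velocity, B0, B1) tuples (fields quantized to 1 Hz / 0.005)."""
    key = np.stack(
        [np.round(velocities, 2), np.round(b0, 0), np.round(b1 / 0.005) * 0.005],
        axis=1,
    )
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    M = simulate_ensemble(
        vs_pulse.rf,
        vs_pulse.grad,
        velocity=uniq[:, 0],
        off_resonance=uniq[:, 1],
        b1_scale=np.clip(uniq[:, 2], 1e-3, None),
        events=vs_pulse.events,
    )
    return M[inverse, 2]


def simulate_protocol(
    phantom: Phantom,
    protocol: ProtocolConfig,
    vs_pulse: PreparationPulse | Sequence[PreparationPulse] | None = None,
    ss_pulse: PreparationPulse | None = None,
    field_maps: tuple[np.ndarray, np.ndarray] | None = None,
    precomp: PrecompParams | None = None,
    use_ss: bool = True,
    use_vs: bool = True,
    inflow: str = "replace",
) -> np.ndarray:
    """Synthetic angiogram volume for one gated station acquisition.

    ``field_maps`` is an optional (B0 Hz, B1 scale) volume pair on the
    phantom grid; ``precomp`` pre-compensates the VS pulse before playing
    it.  ``inflow='none'`` disables the arterial replacement rule (the
    config-selectable alternative bookkeeping).
    """
    if inflow not in ("replace", "none"):
        raise ValueError("inflow must be 'replace' or 'none'")
    if vs_pulse is None:
        vs_pulse = design_vs_pulse(VSPulseSpec())
    elif isinstance(vs_pulse, Sequence):
        vs_pulse = vs_pulse[0]  # shots share the isocenter velocity response
    if precomp is not None:
        vs_pulse = vs_pulse.precompensated(precomp)
    if ss_pulse is None and use_ss:
        ss_pulse = design_hs_inversion(HSPulseSpec())

    labels = phantom.labels
    flat = labels.ravel()
    nvox = flat.size

    T1 = np.ones(nvox)
    pd = np.zeros(nvox)
    vel = np.zeros(nvox)
    fresh = np.zeros(nvox, dtype=bool)
    suppressed = np.zeros(nvox, dtype=bool)
    in_slab = np.ones(nvox, dtype=bool)
    for lab, cls in phantom.classes.items():
        sel = flat == lab
        if not np.any(sel):
            continue
        if cls.proton_density > 0 and cls.velocity is None:
            raise IncompletePhantomError(f"tissue {cls.name} lacks a velocity")
        T1[sel] = cls.T1
        pd[sel] = cls.proton_density
        vel[sel] = cls.velocity_at(protocol.TD_vs)
        fresh[sel] = cls.fresh_inflow and inflow == "replace"
        suppressed[sel] = cls.suppressed
        in_slab[sel] = cls.in_slab

    active = pd > 0
    if field_maps is not None:
        b0 = np.asarray(field_maps[0], dtype=float).ravel()
        b1 = np.asarray(field_maps[1], dtype=float).ravel()
        if b0.size != nvox or b1.size != nvox:
            raise ValueError("field maps must match the phantom grid")
    else:
        b0 = np.zeros(nvox)
        b1 = np.ones(nvox)

    r_vs = np.ones(nvox)
    if use_vs:
        r_vs[active] = _vs_multipliers(
            vs_pulse, vel[active], b0[active], b1[active]
        )

    eps = np.ones(nvox)
    if use_ss and ss_pulse is not None:
        key = np.stack(
            [np.round(b0[active] / 20.0) * 20.0, np.round(b1[active] / 0.02) * 0.02],
            axis=1,
        )
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        eff = inversion_efficiency(
            ss_pulse, off_resonance=uniq[:, 0], b1_scale=np.clip(uniq[:, 1], 1e-3, None)
        )
        eps_active = np.asarray(eff)[inverse]
        eps[active] = np.where(in_slab[active], eps_active, 1.0)

    gap_sv = protocol.ss_to_vs_ms
    gap_vr = protocol.TI
    gap_rest = protocol.cycle_ms - protocol.TD_ss - gap_sv - gap_vr
    mz = np.zeros(nvox)
    mz[active] = prep_chain_mz(
        T1[active],
        eps[active],
        r_vs[active],
        gap_sv,
        gap_vr,
        max(gap_rest, 0.0) + protocol.TD_ss,
        fresh_inflow=fresh[active],
    )

    signal = mz * math.sin(math.radians(protocol.readout_flip)) * pd
    signal[suppressed] = 0.0
    return signal.reshape(labels.shape)


def relative_cr(image: np.ndarray, artery_roi: np.ndarray, muscle_roi: np.ndarray) -> float:
    """Relative contrast ratio (S_A - S_M) / S_A between the mean artery and
    muscle ROI intensities."""
    artery_roi = np.asarray(artery_roi, dtype=bool)
    muscle_roi = np.asarray(muscle_roi, dtype=bool)
    if not artery_roi.any() or not muscle_roi.any():
        raise ValueError("ROIs must be non-empty")
    s_a = float(np.mean(image[artery_roi]))
    s_m = float(np.mean(image[muscle_roi]))
    if s_a <= 0:
        raise ValueError("arterial signal must be positive for a relative CR")
    return (s_a - s_m) / s_a


def slicewise_roi(
    mask: np.ndarray, voxel_mm: float, spacing_mm: float = 1.5, copies: int = 1
) -> np.ndarray:
    """ROI built on axial slices ``spacing_mm`` apart, each copied to its
    ``copies`` neighboring slices on either side (the CR measurement
    convention)."""
    mask = np.asarray(mask, dtype=bool)
    step = max(1, round(spacing_mm / voxel_mm))
    out = np.zeros_like(mask)
    for z in range(0, mask.shape[2], step):
        for dz in range(-copies, copies + 1):
            zz = z + dz
            if 0 <= zz < mask.shape[2]:
                out[:, :, zz] |= mask[:, :, z]
    return out


def mip(image: np.ndarray, axis: int = 1) -> np.ndarray:
    """Maximum intensity projection along an axis."""
    return np.max(image, axis=axis)
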