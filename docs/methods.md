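# Methods

## Bloch engine

Simulation is in the rotating frame under the hard-pulse approximation:
each waveform sample is a constant effective field
(b1_scale·RF_x, b1_scale·RF_y, −(Δf + γ·G·x)) in Hz, applied as the exact
axis-angle rotation it generates over one raster step.  Moving spins
advance linearly, x(t) = x₀ + v·t, with the position frozen at the sample
midpoint within a step.  Relaxation, when enabled, is applied after each
rotation (rotate-then-relax splitting; the error is second order in the
raster step and irrelevant at the default 0.01–0.02 ms rasters).

Conventions, fixed once and inherited by every module:

* a 90° pulse of phase 0 rotates (0,0,1) → (0,1,0);
* with that handedness, a spin at off-resonance f accrues transverse
  phase +2πft, so the pre-compensation ramp e^{+j2πft} tracks it exactly
  (verified numerically by the pre-compensation tests);
* γ/2π = 42.577 kHz/mT, stored as a single constant.

Zero-duration "event" rotations can be attached at sample boundaries.
They exist so tests can replace the composite refocusing pulses with
ideal 180° rotations and probe the encoding-interval contract in
isolation; designed pulses never rely on them.

## VS saturation pulse

The preparation is N hard sub-pulses of flip θ/N (defaults N = 9,
θ = 100°) separated by N−1 velocity-encoding intervals.  Each interval is

    [lobe][composite][lobe][gap][composite][gap]

with two 90x–180y–90x composites and two *unipolar* gradient lobes, the
first before and the second right after the first composite.  The two
equal gaps make the interval a double spin echo, so static and
off-resonance phase refocus exactly, and the two 180s compose to the
identity; what survives is a pure z-rotation by the velocity phase
2π·v/FOV_v, set by the lobe area and the lobe-center separation
(G = 10⁵ / (γ·δ·Δt·FOV_v), with δ the lobe duration and Δt = δ + composite
duration; a configurable hardware cap rejects infeasible specs).  Because
every interval is a plain z-rotation, sub-pulse k effectively rotates
about a transverse axis at phase k·2πv/FOV_v: at v = 0 the flips add to
θ; at v = FOV_v/2 the axes alternate and the net flip collapses to θ/N;
the response is exactly periodic in FOV_v.

The single-composite-per-interval variant was tried first and rejected:
with one refocusing pulse per interval the interval operator is (180y
about y)·Z(ψ), whose square is the identity, so the velocity phase
cancels pairwise across intervals instead of accumulating — the simulated
stop band then swallows the venous velocity range, contradicting both the
stated cut-off and the need for the SS inversion.  The two-composite
layout is also what "double-refocused" names in the VS literature.

The nominal cut-off is reported as FOV_v/(2(N+1)) — the convention that
reproduces 3.5 cm/s for (9, 70) — while `stopband_width` reports the
Bloch-simulated band (edges at the midpoint between cos θ and 1; half
width ≈ 3.3 cm/s for the default design).  Whether the quoted 3.5 cm/s
is a convention or a simulated threshold crossing is not decidable from
the protocol description, so both numbers are exposed.

Sub-pulse amplitudes are uniform (hard pulses, no windowing stated
anywhere); gradient lobes are rectangles, since only their moments enter
the contract.  Timing defaults (0.5 ms sub-pulses, 0.5 ms lobes, 1.6 ms
composites, 0.3 ms gaps) keep peak RF near 625 Hz (≈15 µT) and the
encoding gradient at 32 mT/m under a 40 mT/m cap; total duration 42.9 ms.
T2 decay during the pulse is not applied by default (relaxation off), but
the duration is exposed for such studies.

**Pre-compensation.**  `precompensate_rf` maps every sample B1(t) →
A·B1(t)·e^{j2πft}.  With A = 1/s and f matching a spin's (s, Δf) the
compensation is exact up to the (refocused) off-resonance precession in
the gradient intervals; the corner-case tests show mean response errors
dropping from 0.2–0.9 to < 1e-3 across the measured field-error extremes.

**Shifted shots.**  Shot k of `make_shot_set` translates the spatial
response by k/n of one stripe period (the period 1/(γ·m0) set by the
per-interval unipolar area m0).  The shift is realized as the
gradient-referenced RF phase ramp exp(−j·2πγ·Δx·A_cum(t)), the exact
frame-equivalent of offsetting the gradient isocenter by Δx: spatial
profiles translate to machine precision and the velocity response at the
isocenter is untouched.  A literal extra gradient blip would change the
stripe period rather than translate the pattern, so the phase-ramp form
is used as the faithful mechanism.

## SS adiabatic inversion

Amplitude peak_b1·sech(βt′), sweep −μβ·tanh(βt′)/2π realized as phase
modulation −μ·ln cosh(βt′) (single-channel RF), t′ symmetric over
±duration/2.  Bandwidth μβ/π = 1336.9 Hz for (300 rad/s, 14); the quoted
1338 Hz differs by 0.08% (rounding of unknown origin — both numbers are
reported).  The slab gradient is bandwidth/(γ·thickness).  The default
peak amplitude is the smallest multiple of a 0.5 µT-equivalent step
(21.3 Hz) reaching Mz < −0.97 on resonance — 298 Hz (≈7 µT) for the
default pulse — found by direct simulation and cached.  Slab geometry
aligns the inferior edges and adds the superior margin, so upstream
venous blood is pre-inverted while arterial blood entering from below is
not.

## Calibration

* "5% outliers eliminated" is read as symmetric trimming: ⌊0.025·n⌋
  values dropped per tail before taking extrema (`trimmed_range`).
* The representative statistic mapping ROI values to (A, f) is the median
  of the trimmed values; the protocol never states the statistic or
  whether arterial or pooled ROIs were used, so the choice is anchored to
  reproducing the printed station values (A = 1.15⁻¹, f = 100 Hz;
  A = 0.95⁻¹, f = 53 Hz) and exposed as configuration.
* Systole detection: peak = sample of maximum velocity; baseline =
  pre-peak minimum; onset = earliest crossing of baseline + 10% of the
  upstroke height, linearly interpolated.  The 10% threshold and the
  lead times (SS leads onset by 20 ms, VS leads peak by 15 ms, rounding
  half-up to 10 ms) are the values that reproduce all four printed
  trigger delays from the printed mean timings; all are arguments.

## Sampling

DC-centered integer coordinates with the half-open convention (negative
side gets the extra index for even sizes).  The square spiral starts at
(0,0) toward +ky and walks counter-clockwise rings of non-decreasing
Chebyshev radius (direction is unstated in the source material; fixed for
determinism).  Outside the fully sampled calibration core, every R-th
*visited* point is acquired (uniform 1/R density along the walk); whether
core points advance that counter is exposed as a flag, default off.
Segments are consecutive chunks of `views_per_segment` acquired points,
so the earliest segments always carry the k-space center.

## Phantom and protocol simulator

The phantom is a stated world, not a dial: tube velocities default to the
measured station values (arterial peak 66.18/46.88 cm/s, veins
9.45/18.01 cm/s), arterial flow curves carry the measured systolic
landmarks (onset 58.15/90.23 ms, peak 126.32/150.38 ms, 20.05 ms
sampling), synthetic field maps span the measured B0/B1 ranges, and the
timing defaults are the protocol's (TD_ss 40/70 ms, TD_vs 110/140 ms,
TI 100 ms, 3 R-R repetition at 70 bpm).  T1/T2 are 3T literature values
(blood 1650/150 ms, muscle 900/50 ms, fat 380/100 ms) since the protocol
states none; all are configuration.  The flow-curve generator pins the
sample nearest the apex to the requested peak velocity, because a
phase-contrast "peak velocity" is itself a frame maximum at 20.05 ms
resolution.

Per voxel and cycle the simulator applies: SS inversion (simulated
efficiency at the voxel's B0/B1) if the voxel is in the slab → T1
recovery over RR + TD_vs − TD_ss → VS saturation (simulated Mz multiplier
at the voxel's velocity at TD_vs and its B0/B1) → recovery over TI →
readout sample → recovery over the rest of the 3 R-R cycle; the cycle map
is iterated to a periodic steady state (tolerance 1e-6).  TI is the
VS-to-readout-center delay, per the sequence timing diagram.  Arterial
voxels follow the inflow replacement rule — two systolic inflows between
the triggers wash in blood never touched by the SS inversion, so arteries
enter the VS pulse fully relaxed (`inflow="none"` selects the
alternative, history-keeping bookkeeping).  Veins descend from inside the
superior slab margin and are treated as inverted.  The image value is
Mz·sin(readout flip)·PD at the first, center-of-k-space view — with
center-out ordering that view dominates contrast; echo-train filtering is
out of scope.  Fat is treated as perfectly fat-saturated.  Preparation
pulse durations are neglected in the relaxation bookkeeping (tens of ms
against R-R-scale gaps).

Field quantization for speed: VS multipliers are computed once per unique
(velocity, B0 rounded to 1 Hz, B1 rounded to 0.005) tuple, inversion
efficiencies per (B0/20 Hz, B1/0.02) tuple, then scattered back.

**What a green phantom test establishes.**  The phantom has no coil
noise, no reconstruction (the parallel-imaging solver is out of scope),
no motion, laminar plug flow only, and velocities constant within a
preparation.  Green tests therefore establish the *mechanistic* claims —
vein suppression requires the SS inversion, pre-compensation recovers
arterial response under measured field errors, the schedule is
well-formed — not the in-vivo contrast-ratio values, which depend on
subjects and are deliberately not targeted.

## Numerical choices

* Rasters: 0.02 ms (VS), 0.01 ms (HS); halving the VS raster moves Mz by
  < 1e-4 (rotations are exact per sample; only the frozen-position and
  phase-sampling errors remain).
* Periodicity/symmetry of Mz(v) hold to ~1e-14; tests assert 1e-6.
* Degenerate inputs raise: mismatched waveform grids, non-positive B1
  scale/T1/T2, infeasible gradient amplitude, flat flow curves, empty
  ROIs, non-positive arterial signal in the CR.
* Trigger delays clamp at 0 ms with a warning.

## Known limitations

No SLR/optimal-control VS design, no trapezoid/slew gradient modeling, no
diffusion or acceleration terms, no SAR, no reconstruction, no noise
model.  The simulated stop-band width depends on the chosen edge level;
the nominal cut-off convention is reported alongside it for that reason.
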