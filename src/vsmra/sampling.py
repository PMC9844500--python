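"""Square-spiral ky-kz view ordering and the segmented, under-sampled
acquisition schedule.

The phase/partition-encode plane is traversed center-out along expanding
concentric square rings (Chebyshev radius), so early segments carry the
center of k-space.  The inner calibration core is fully sampled for
self-calibrated parallel imaging; outside it every R-th visited point is
acquired.  The acquired sequence is chunked into consecutive segments of
``views_per_segment`` shots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TrajectorySpec:
    """Grid sizes, acceleration, calibration-core size and segment length.

    Defaults are the station-1 protocol (240 x 71 encodes, R = 3, 24-wide
    calibration core, 71 views per segment).
    """

    ny: int = 240
    nz: int = 71
    R: int = 3
    calib: int = 24
    views_per_segment: int = 71
    #: whether calibration-core points advance the outer decimation counter
    count_calib_in_decimation: bool = False

    def __post_init__(self):
        if self.ny < 1 or self.nz < 1:
            raise ValueError("grid sizes must be >= 1")
        if self.R < 1:
            raise ValueError("acceleration factor must be >= 1")
        if not 0 <= self.calib <= min(self.ny, self.nz):
            raise ValueError("calibration core must fit inside the grid")
        if self.views_per_segment < 1:
            raise ValueError("views_per_segment must be >= 1")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered (ky, kz) samples, their segment indices and the binary mask.

    Coordinates are DC-centered integers; for even sizes the negative side
    carries the extra index (half-open convention), so ``ky`` spans
    ``[-ny//2, ny - ny//2 - 1]``.
    """

    spec: TrajectorySpec
    samples: np.ndarray  # (n, 2) int, (ky, kz) in acquisition order
    segments: np.ndarray  # (n,) int segment index per sample

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros((self.spec.ny, self.spec.nz), dtype=bool)
        iy = self.samples[:, 0] + self.spec.ny // 2
        iz = self.samples[:, 1] + self.spec.nz // 2
        m[iy, iz] = True
        return m

    @property
    def n_segments(self) -> int:
        return int(self.segments.max()) + 1 if len(self.segments) else 0

    def segment(self, i: int) -> np.ndarray:
        return self.samples[self.segments == i]


def _k_range(n: int) -> tuple[int, int]:
    """Inclusive DC-centered index range for a grid of size n."""
    return -(n // 2), n - n // 2 - 1


def square_spiral_order(ny: int, nz: int) -> np.ndarray:
    """Center-out square-spiral visit order of an ny x nz grid.

    Starts at (0, 0), turns counter-clockwise starting toward +ky, visits
    every in-grid point exactly once, and never decreases the Chebyshev
    radius max(|ky|, |kz|).  Rings clipped by an anisotropic grid simply
    skip their out-of-grid points.
    """
    ky_lo, ky_hi = _k_range(ny)
    kz_lo, kz_hi = _k_range(nz)
    rmax = max(-ky_lo, ky_hi, -kz_lo, kz_hi)
    out = [(0, 0)]
    for r in range(1, rmax + 1):
        ring = []
        # enter the ring at (+r, -r+1) moving +kz along the right edge,
        # then -ky along the top, -kz along the left, +ky along the bottom.
        ring += [(r, kz) for kz in range(-r + 1, r + 1)]
        ring += [(ky, r) for ky in range(r - 1, -r - 1, -1)]
        ring += [(-r, kz) for kz in range(r - 1, -r - 1, -1)]
        ring += [(ky, -r) for ky in range(-r + 1, r + 1)]
        out += [
            (ky, kz)
            for ky, kz in ring
            if ky_lo <= ky <= ky_hi and kz_lo <= kz <= kz_hi
        ]
    return np.array(out, dtype=int)


def build_schedule(spec: TrajectorySpec) -> AcquisitionSchedule:
    """Walk the spiral, keep the calibration core fully sampled and every
    R-th outer point, then segment the acquired sequence."""
    order = square_spiral_order(spec.ny, spec.nz)
    cy_lo, cy_hi = _k_range(spec.calib) if spec.calib else (1, 0)
    cz_lo, cz_hi = cy_lo, cy_hi
    acquired = []
    outer_step = 0
    for ky, kz in order:
        in_core = spec.calib > 0 and cy_lo <= ky <= cy_hi and cz_lo <= kz <= cz_hi
        if in_core:
            acquired.append((ky, kz))
            if spec.count_calib_in_decimation:
                outer_step += 1
        else:
            if outer_step % spec.R == 0:
                acquired.append((ky, kz))
            outer_step += 1
    samples = np.array(acquired, dtype=int)
    segments = np.arange(len(samples)) // spec.views_per_segment
    return AcquisitionSchedule(spec=spec, samples=samples, segments=segments)


def acquired_fraction(spec: TrajectorySpec) -> float:
    """Counting identity: (calib^2 + (ny nz - calib^2)/R) / (ny nz)."""
    total = spec.ny * spec.nz
    core = spec.calib**2
    return (core + (total - core) / spec.R) / total
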