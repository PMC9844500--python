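"""File interchange: delimited-text waveforms/curves/schedules and NIfTI
volumes."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bloch import GradientWaveform, RFWaveform
from .calibration import FlowCurve
from .sampling import AcquisitionSchedule

WAVEFORM_COLUMNS = ["time_ms", "rf_real_hz", "rf_imag_hz", "grad_mt_m"]


def save_waveform(path, rf: RFWaveform, grad: GradientWaveform) -> None:
    """Waveform pair as CSV with columns time, RF real/imag (Hz), G (mT/m)."""
    df = pd.DataFrame(
        {
            "time_ms": rf.times,
            "rf_real_hz": rf.samples.real,
            "rf_imag_hz": rf.samples.imag,
            "grad_mt_m": grad.samples,
        }
    )
    df.to_csv(path, index=False)


def load_waveform(path) -> tuple[RFWaveform, GradientWaveform]:
    df = pd.read_csv(path)
    missing = set(WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waveform file lacks columns {sorted(missing)}")
    t = df["time_ms"].to_numpy()
    if len(t) < 2:
        raise ValueError("waveform needs at least two samples")
    dt = float(np.median(np.diff(t)))
    rf = RFWaveform(df["rf_real_hz"].to_numpy() + 1j * df["rf_imag_hz"].to_numpy(), dt)
    grad = GradientWaveform(df["grad_mt_m"].to_numpy(), dt)
    return rf, grad


def save_flow_curve(path, curve: FlowCurve) -> None:
    pd.DataFrame({"time_ms": curve.time, "velocity_cm_s": curve.velocity}).to_csv(
        path, index=False
    )


def load_flow_curve(path) -> FlowCurve:
    df = pd.read_csv(path)
    return FlowCurve(df["time_ms"].to_numpy(), df["velocity_cm_s"].to_numpy())


def save_schedule(path, sched: AcquisitionSchedule) -> None:
    pd.DataFrame(
        {
            "order": np.arange(len(sched.samples)),
            "ky": sched.samples[:, 0],
            "kz": sched.samples[:, 1],
            "segment": sched.segments,
        }
    ).to_csv(path, index=False)


def save_volume(path, volume: np.ndarray, voxel_mm: float = 1.0) -> None:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_protocol_card(path, *objs) -> None:
    """Dump dataclass configs (protocol, pulse specs, derived parameters) as
    a JSON protocol card."""
    card = {}
    for obj in objs:
        if dataclasses.is_dataclass(obj):
            card[type(obj).__name__] = dataclasses.asdict(obj)
        elif isinstance(obj, dict):
            card.update(obj)
        else:
            raise TypeError(f"cannot serialize {type(obj)}")
    Path(path).write_text(json.dumps(card, indent=2, default=float) + "\n")
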