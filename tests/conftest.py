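import numpy as np
import pytest

from vsmra.bloch import GradientWaveform, RFWaveform
from vsmra.phantom import (
    PhantomParams,
    ProtocolConfig,
    STATION2_PROTOCOL,
    make_neck_phantom,
    simulate_protocol,
)
from vsmra.ss_prep import HSPulseSpec, design_hs_inversion
from vsmra.vs_prep import VSPulseSpec, design_vs_pulse


@pytest.fixture(scope="session")
def vs_spec():
    """The whole-neck VS design: 9 sub-pulses, 100 degrees, FOV_v 70 cm/s."""
    return VSPulseSpec()


@pytest.fixture(scope="session")
def vs_pulse(vs_spec):
    return design_vs_pulse(vs_spec)


@pytest.fixture(scope="session")
def hs_pulse():
    return design_hs_inversion(HSPulseSpec())


@pytest.fixture(scope="session")
def neck_phantoms():
    return {
        1: make_neck_phantom(PhantomParams(station=1), seed=11),
        2: make_neck_phantom(PhantomParams(station=2), seed=11),
    }


@pytest.fixture(scope="session")
def station_images(neck_phantoms):
    """Synthetic angiograms per station, with and without the SS inversion."""
    protocols = {1: ProtocolConfig(), 2: STATION2_PROTOCOL}
    out = {}
    for st, ph in neck_phantoms.items():
        out[st] = {
            "ss+vs": simulate_protocol(ph, protocols[st]),
            "vs": simulate_protocol(ph, protocols[st], use_ss=False),
        }
    return out


def interval_segment(pulse):
    """RF/gradient/events restricted to the first velocity-encoding interval."""
    s0, s1 = pulse.meta["interval_bounds"][0]
    rf = RFWaveform(pulse.rf.samples[s0:s1], pulse.rf.dt)
    grad = GradientWaveform(pulse.grad.samples[s0:s1], pulse.grad.dt)
    events = {i - s0: m for i, m in pulse.events.items() if s0 <= i <= s1}
    return rf, grad, events


def random_waveform_pair(rng, n=20, dt=0.1):
    rf = RFWaveform(
        rng.normal(0, 300, n) + 1j * rng.normal(0, 300, n), dt
    )
    grad = GradientWaveform(rng.normal(0, 10, n), dt)
    return rf, grad


def rotation_oracle(rf, grad, position, velocity, off_resonance, b1_scale, M0):
    """Independent propagation: explicit per-sample rotation matrices built
    with scipy, composed by matrix product."""
    from scipy.spatial.transform import Rotation

    from vsmra.bloch import GAMMA_KHZ_PER_MT

    M = np.asarray(M0, dtype=float).copy()
    for i in range(len(rf)):
        t_mid = (i + 0.5) * rf.dt
        x = position + velocity * 0.01 * t_mid
        b = np.array(
            [
                b1_scale * rf.samples[i].real,
                b1_scale * rf.samples[i].imag,
                -(off_resonance + GAMMA_KHZ_PER_MT * grad.samples[i] * x),
            ]
        )
        bmag = np.linalg.norm(b)
        if bmag == 0:
            continue
        theta = 2.0 * np.pi * bmag * rf.dt * 1e-3
        M = Rotation.from_rotvec(-theta * b / bmag).as_matrix() @ M
    return M
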