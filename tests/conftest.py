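import math

import numpy as np
import pytest

from neoflow.containers import IQBlock
from neoflow.params import AcquisitionParams
from neoflow.simulate import VesselSegment, synthesize_iq


@pytest.fixture(scope="session")
def small_params() -> AcquisitionParams:
    """High-frame-rate sequence on a small grid (0.8 s, two cardiac cycles)."""
    return AcquisitionParams(prf=9600, n_angles=3, n_frames=2560, shape=(24, 16))


@pytest.fixture(scope="session")
def pulsatile_block(small_params):
    """One vertical 0.8 mm artery (PSV 10, EDV 4 cm/s) under default
    clutter and noise, with its ground truth."""
    seg = VesselSegment(points=((0.2, 0.8), (2.2, 0.8)), diameter_mm=0.8)
    return synthesize_iq([seg], small_params, seed=1)


def make_tilted_block(angle_deg: float, seed: int = 3, psv: float = 10.0, edv: float = 4.0):
    """Pulsatile vessel tilted ``angle_deg`` away from the beam axis."""
    th = math.radians(angle_deg)
    dz = 2.0
    dx = dz * math.tan(th)
    nx = max(int((dx + 1.0) / 0.1) + 4, 12)
    params = AcquisitionParams(prf=9600, n_angles=3, n_frames=2560, shape=(24, nx))
    seg = VesselSegment(
        points=((0.2, 0.5), (0.2 + dz, 0.5 + dx)), diameter_mm=0.8, psv_cms=psv, edv_cms=edv
    )
    return synthesize_iq([seg], params, seed=seed)


def tone_block(freq_hz: float, params: AcquisitionParams, amplitude: float = 1.0) -> IQBlock:
    """Uniform block whose every pixel is a complex tone at ``freq_hz``."""
    t = np.arange(params.n_frames) / params.frame_rate
    sig = amplitude * np.exp(2j * np.pi * freq_hz * t)
    data = np.broadcast_to(sig, (*params.shape, params.n_frames)).copy()
    return IQBlock(data, params)
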