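"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .params import AcquisitionParams


@dataclass
class IQBlock:
    """Complex beamformed IQ data cube, depth x width x time.

    The slow-time phase rotation of each pixel encodes scatterer motion;
    this is the raw input of the processing chain (beamforming and plane-
    wave compounding happen upstream).
    """

    data: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("IQBlock.data must be 3-D (depth, width, time)")
        if self.data.shape[2] != self.params.n_frames:
            raise ValueError(
                f"time axis ({self.data.shape[2]}) != params.n_frames ({self.params.n_frames})"
            )
        if self.data.shape[:2] != tuple(self.params.shape):
            raise ValueError(
                f"spatial shape {self.data.shape[:2]} != params.shape {tuple(self.params.shape)}"
            )

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]


@dataclass
class PowerDopplerImage:
    """Time-integrated energy of the clutter-filtered blood signal.

    Intensity is proportional to the number of moving red blood cells per
    voxel and is the basis for all vascular morphology.
    """

    intensity: np.ndarray
    pixel_spacing: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if np.any(self.intensity < 0):
            raise ValueError("power Doppler intensity must be non-negative")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape
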