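"""Acquisition parameters of an ultrafast compounded-plane-wave Doppler sequence.

The compounded frame rate is the pulse repetition frequency divided by the
number of tilted plane-wave angles that are coherently compounded into one
frame, and the block duration follows from the number of compounded frames.
Both are derived quantities here so the arithmetic invariants hold by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionParams:
    """Metadata of one ultrafast Doppler acquisition block.

    Parameters
    ----------
    prf : float
        Pulse repetition frequency of plane-wave transmissions, Hz.
    n_angles : int
        Number of compounded plane-wave angles per frame.
    n_frames : int
        Number of compounded frames in the block.
    pulse_frequency : float
        Probe centre frequency, Hz.
    speed_of_sound : float
        Assumed speed of sound in tissue, m/s.
    pixel_spacing : float
        Isotropic pixel pitch of the beamformed grid, mm/pixel.
    shape : tuple of int
        Spatial grid (depth rows, width columns); row 0 is the shallowest
        depth, mm coordinate = index * pixel_spacing.
    """

    prf: float
    n_angles: int
    n_frames: int
    pulse_frequency: float = 6e6
    speed_of_sound: float = 1540.0
    pixel_spacing: float = 0.1
    shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pulse_frequency <= 0 or self.speed_of_sound <= 0:
            raise ValueError("pulse_frequency and speed_of_sound must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if len(self.shape) != 2 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be two positive extents")

    @property
    def frame_rate(self) -> float:
        """Compounded frame rate, Hz (= prf / n_angles)."""
        return self.prf / self.n_angles

    @property
    def duration(self) -> float:
        """Block duration, s (= n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    @property
    def fov(self) -> tuple[float, float]:
        """Field of view extents (depth, width), mm."""
        return (self.shape[0] * self.pixel_spacing, self.shape[1] * self.pixel_spacing)

    def nyquist_velocity(self, theta_rad: float = 0.0) -> float:
        """Largest axial blood speed sampled without aliasing, cm/s.

        The Doppler shift of a scatterer moving at speed V is
        f = 2 V f_pulse cos(theta) / c0; the two-sided spectrum is sampled
        at the frame rate, so |f| <= frame_rate / 2 without de-aliasing.
        """
        import math

        f_max = self.frame_rate / 2.0
        v_ms = f_max * self.speed_of_sound / (2.0 * self.pulse_frequency * math.cos(theta_rad))
        return v_ms * 100.0


#: Sequence favouring non-aliased sampling of high velocities.
HIGH_VELOCITY = AcquisitionParams(prf=9600, n_angles=3, n_frames=2500)

#: Sequence favouring sensitivity to small vessels (more compounded angles).
LOW_VELOCITY = AcquisitionParams(prf=8000, n_angles=5, n_frames=1600)
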