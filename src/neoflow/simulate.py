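"""Ground-truth-annotated synthetic inputs for the resistivity pipeline.

Emulates the statistical and physical structure the pipeline assumes:

* vessel trees rendered as tubes (0.2--2 mm) with top-hat or Gaussian
  cross-lumen intensity profiles on a power-Doppler-like image;
* three-tube calibration phantoms of known diameters;
* pulsatile IQ blocks in which each lumen pixel is a complex phasor whose
  instantaneous Doppler frequency follows f = 2 v(t) f_pulse cos(theta)/c0,
  buried under low-rank, slowly varying tissue clutter and white noise;
* statistical cohorts of per-subject RI-vs-diameter measurement tables.

Every generated object carries a :class:`GroundTruth` so downstream
estimates can be scored against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import IQBlock, PowerDopplerImage
from .params import AcquisitionParams

__all__ = [
    "VesselSegment",
    "GroundTruth",
    "CohortSpec",
    "cardiac_waveform",
    "make_vessel_tree",
    "make_phantom",
    "synthesize_iq",
    "make_cohort",
]

#: Full width at half maximum of the imaging point-spread function, mm.
#: Matches the stated 0.2 mm spatial resolution limit of the method.
DEFAULT_PSF_FWHM_MM = 0.2

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class VesselSegment:
    """A straight or polyline tube segment in image coordinates.

    ``points`` is an (k, 2) array of (depth_mm, width_mm) vertices.  The
    cross-lumen intensity profile is either a top hat of width ``diameter_mm``
    or a Gaussian whose standard deviation equals the tube radius
    (``diameter_mm / 2``), the model underlying Hessian vesselness filters.
    Veins are modelled as non-pulsatile: psv == edv.
    """

    points: tuple[tuple[float, float], ...]
    diameter_mm: float
    profile: str = "top_hat"
    psv_cms: float = 10.0
    edv_cms: float = 4.0
    flow_sign: int = 1
    label: str = "artery"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("points must be a polyline of >= 2 (z, x) mm vertices")
        object.__setattr__(self, "points", tuple(map(tuple, pts)))
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        if self.profile not in ("top_hat", "gaussian"):
            raise ValueError("profile must be 'top_hat' or 'gaussian'")
        if self.label not in ("artery", "vein"):
            raise ValueError("label must be 'artery' or 'vein'")
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be +1 or -1")
        if self.label == "artery":
            if not (self.psv_cms >= self.edv_cms >= 0):
                raise ValueError("arteries require psv >= edv >= 0")
        elif self.psv_cms != self.edv_cms:
            raise ValueError("veins are non-pulsatile: psv must equal edv")

    @property
    def ri(self) -> float:
        """True resistivity index (PSV - EDV) / PSV of the segment."""
        if self.psv_cms <= 0:
            return 0.0
        return (self.psv_cms - self.edv_cms) / self.psv_cms

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass
class GroundTruth:
    """Per-pixel and per-vessel truth accompanying a synthetic object.

    ``blood``, ``clutter`` and ``noise`` are the separable components of a
    synthesized IQ cube; their sum reconstructs the emitted block exactly.
    """

    diameter_map: np.ndarray | None = None
    ri_map: np.ndarray | None = None
    centreline: np.ndarray | None = None
    junction: np.ndarray | None = None
    lumen: np.ndarray | None = None
    segment_lumens: list[np.ndarray] = field(default_factory=list)
    waveforms: list[np.ndarray] = field(default_factory=list)
    blood: np.ndarray | None = None
    clutter: np.ndarray | None = None
    noise: np.ndarray | None = None
    aliased: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic patient cohort.

    Each subject draws a regression slope m_i ~ N(slope_mean, slope_sd) and
    an RI-in-small-vessels ri_i ~ N(ri_small_mean, ri_small_sd); skeleton
    measurements follow ri(d) = m_i (d - 0.2) + ri_i + noise.  Defaults
    emulate the anterior-cerebral-artery branches territory of a very
    preterm cohort: slope 0.08 +/- 0.07 per mm and RI at the 0.2 mm
    resolution limit 0.58 +/- 0.08, n = 74 subjects.
    """

    n_subjects: int = 74
    slope_mean: float = 0.08
    slope_sd: float = 0.07
    ri_small_mean: float = 0.58
    ri_small_sd: float = 0.08
    diameter_range: tuple[float, float] = (0.3, 1.5)
    n_skeleton_points: int = 200
    measurement_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.slope_sd < 0 or self.ri_small_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.diameter_range
        if not (0.2 < lo < hi < 3.0):
            raise ValueError("diameter_range must lie within (0.2, 3.0) mm")
        if self.n_skeleton_points < 2:
            raise ValueError("n_skeleton_points must be >= 2")


def cardiac_waveform(
    psv_cms: float,
    edv_cms: float,
    frame_rate: float,
    n_frames: int,
    cycle_s: float = 0.4,
    phase: float = 0.5,
) -> np.ndarray:
    """Neonatal arterial velocity waveform sampled at the frame rate, cm/s.

    A raised-cosine systolic upstroke and downstroke followed by an
    exponential diastolic decay, repeated every ``cycle_s`` (default 400 ms,
    i.e. 150 bpm).  The waveform is rescaled so its continuous minimum is
    exactly ``edv_cms`` (attained at end-diastole, just before the next
    upstroke) and its maximum exactly ``psv_cms``.  ``phase`` shifts the
    cycle start as a fraction of the cycle so both landmarks fall in the
    interior of a short block.
    """
    if psv_cms < edv_cms:
        raise ValueError("psv must be >= edv")
    t = np.arange(n_frames) / frame_rate
    tc = ((t / cycle_s + phase) % 1.0) * cycle_s

    t_up, t_down, tau = 0.06, 0.09, 0.12
    w_d = 0.15  # normalised velocity at end of systolic downstroke
    w_min = w_d * math.exp(-(cycle_s - t_up - t_down) / tau)

    w = np.empty_like(tc)
    up = tc < t_up
    down = (tc >= t_up) & (tc < t_up + t_down)
    dia = tc >= t_up + t_down
    w[up] = w_min + (1 - w_min) * 0.5 * (1 - np.cos(np.pi * tc[up] / t_up))
    w[down] = w_d + (1 - w_d) * 0.5 * (1 + np.cos(np.pi * (tc[down] - t_up) / t_down))
    w[dia] = w_d * np.exp(-(tc[dia] - t_up - t_down) / tau)

    w = (w - w_min) / (1 - w_min)
    np.clip(w, 0.0, 1.0, out=w)
    return edv_cms + (psv_cms - edv_cms) * w


def _segment_distance_field(seg: VesselSegment, params: AcquisitionParams) -> np.ndarray:
    """Distance (mm) of every pixel centre to the segment polyline."""
    nz, nx = params.shape
    px = params.pixel_spacing
    zz, xx = np.meshgrid(np.arange(nz) * px, np.arange(nx) * px, indexing="ij")
    pts = seg.as_array()
    dist = np.full((nz, nx), np.inf)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dd = np.hypot(zz - p0[0], xx - p0[1])
        else:
            tproj = ((zz - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / L2
            np.clip(tproj, 0.0, 1.0, out=tproj)
            dd = np.hypot(zz - (p0[0] + tproj * d[0]), xx - (p0[1] + tproj * d[1]))
        np.minimum(dist, dd, out=dist)
    return dist


def _render_profile(seg: VesselSegment, dist: np.ndarray) -> np.ndarray:
    r = seg.diameter_mm / 2.0
    if seg.profile == "top_hat":
        return (dist <= r).astype(float)
    # Gaussian intensity across the lumen with std equal to the radius
    return np.exp(-(dist**2) / (2.0 * r**2))


def _check_in_fov(seg: VesselSegment, params: AcquisitionParams, idx: int) -> None:
    fz, fx = params.fov
    for z, x in seg.points:
        if not (0.0 <= z <= fz and 0.0 <= x <= fx):
            raise ValueError(
                f"segment {idx} vertex ({z:.2f}, {x:.2f}) mm outside field of view "
                f"({fz:.2f} x {fx:.2f} mm)"
            )


def make_vessel_tree(
    segments: list[VesselSegment],
    params: AcquisitionParams,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
) -> tuple[PowerDopplerImage, GroundTruth]:
    """Render a vessel tree onto the image grid with ground-truth maps.

    Each segment's lumen is rendered with its intensity profile; the summed
    image is blurred by an isotropic Gaussian point-spread function of the
    given FWHM.  The truth diameter map is populated on the true centreline;
    pixels belonging to two or more lumens are flagged as junctions.
    Diameters below twice the pixel spacing are below the resolvability of
    the grid and raise a warning flag in the truth (not an error).
    """
    if not segments:
        raise ValueError("at least one segment required")
    nz, nx = params.shape
    px = params.pixel_spacing
    truth = GroundTruth(
        diameter_map=np.full((nz, nx), np.nan),
        ri_map=np.full((nz, nx), np.nan),
        centreline=np.zeros((nz, nx), bool),
        junction=np.zeros((nz, nx), bool),
        lumen=np.zeros((nz, nx), bool),
    )
    image = np.zeros((nz, nx))
    membership = np.zeros((nz, nx), dtype=int)
    for i, seg in enumerate(segments):
        _check_in_fov(seg, params, i)
        if seg.diameter_mm < 2 * px:
            truth.warnings.append(
                f"segment {i}: diameter {seg.diameter_mm:.3f} mm below resolvability "
                f"(2 x pixel spacing = {2 * px:.3f} mm)"
            )
        dist = _segment_distance_field(seg, params)
        image += _render_profile(seg, dist)
        lum = dist <= seg.diameter_mm / 2.0
        membership += lum
        truth.lumen |= lum
        truth.segment_lumens.append(lum)
        truth.ri_map[lum] = seg.ri
        centre = dist <= px / 2.0
        truth.centreline |= centre
        truth.diameter_map[centre] = seg.diameter_mm
    truth.junction = membership >= 2
    if psf_fwhm_mm > 0:
        image = gaussian_filter(image, psf_fwhm_mm * _FWHM_TO_SIGMA / px)
    pd_img = PowerDopplerImage(image, px, provenance={"source": "make_vessel_tree"})
    return pd_img, truth


def make_phantom(
    diameters_mm: list[float],
    params: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
    min_separation_mm: float = 3.0,
) -> tuple[PowerDopplerImage, GroundTruth]:
    """Synthetic calibration phantom: parallel vertical tubes of known size.

    Tubes are laid out evenly across the width, top-hat profiles, centre
    separation at least ``min_separation_mm``; overlapping tubes are an
    error.  Additive white noise of standard deviation ``noise_sd`` (in
    image intensity units) is applied after the point-spread function and
    the image is clipped at zero to preserve the non-negativity of a power
    Doppler image.  This replicates the layout of a flow phantom only; no
    acoustic texture is modelled.
    """
    if not diameters_mm:
        raise ValueError("need at least one tube")
    fz, fx = params.fov
    n = len(diameters_mm)
    margin = fx / (n + 1)
    centres = [(i + 1) * margin for i in range(n)]
    for (c0, d0), (c1, d1) in zip(
        zip(centres[:-1], diameters_mm[:-1]), zip(centres[1:], diameters_mm[1:])
    ):
        sep = c1 - c0
        if sep < min_separation_mm:
            raise ValueError(
                f"tube separation {sep:.2f} mm < required {min_separation_mm:.2f} mm"
            )
        if sep <= (d0 + d1) / 2:
            raise ValueError("tubes overlap")
    z0, z1 = 0.05 * fz, 0.95 * fz
    segments = [
        VesselSegment(points=((z0, c), (z1, c)), diameter_mm=d, profile="top_hat")
        for c, d in zip(centres, diameters_mm)
    ]
    image, truth = make_vessel_tree(segments, params, psf_fwhm_mm=psf_fwhm_mm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = image.intensity + rng.normal(0.0, noise_sd, image.intensity.shape)
        np.clip(noisy, 0.0, None, out=noisy)
        image = PowerDopplerImage(
            noisy, image.pixel_spacing, provenance={"source": "make_phantom"}
        )
    return image, truth


def _lowpass_temporal_mode(rng: np.random.Generator, n: int, frame_rate: float,
                           f_max: float = 20.0) -> np.ndarray:
    """Complex temporal signal with spectral support below ``f_max`` Hz."""
    freqs = np.fft.fftfreq(n, d=1.0 / frame_rate)
    spec = np.zeros(n, complex)
    keep = np.abs(freqs) < f_max
    spec[keep] = rng.normal(size=keep.sum()) + 1j * rng.normal(size=keep.sum())
    mode = np.fft.ifft(spec)
    return mode / np.linalg.norm(mode)


def synthesize_iq(
    segments: list[VesselSegment],
    params: AcquisitionParams,
    waveforms: list[np.ndarray] | None = None,
    clutter_rank: int = 5,
    clutter_to_blood_db: float | None = 40.0,
    noise_db: float | None = 20.0,
    seed: int = 0,
    cycle_s: float = 0.4,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
) -> tuple[IQBlock, GroundTruth]:
    """Synthesize a pulsatile IQ block with separable blood/clutter/noise.

    Each lumen pixel of each segment is a complex phasor of amplitude given
    by the segment's intensity profile, with a per-pixel random initial
    phase, whose instantaneous Doppler frequency is

        f(t) = flow_sign * 2 v(t) f_pulse u_z / c0

    where ``u_z`` is the beam-axis (depth) component of the unit flow
    direction, i.e. cos(theta) of the beam-to-flow angle.  Tissue clutter is
    an exact rank-``clutter_rank`` sum of spatially smooth modes times
    slowly varying (< 20 Hz) temporal modes, scaled ``clutter_to_blood_db``
    dB above the blood energy.  ``noise_db`` is the blood-to-noise energy
    ratio in dB (an SNR; ``None`` disables either component).

    Doppler frequencies beyond +/- prf/2 are physically unsamplable and
    raise; frequencies beyond +/- frame_rate/2 but within +/- frame_rate are
    allowed and flag the truth as ``aliased`` (they exercise de-aliasing).
    """
    if not segments:
        raise ValueError("at least one segment required")
    if waveforms is not None and len(waveforms) != len(segments):
        raise ValueError("one waveform per segment required")
    rng = np.random.default_rng(seed)
    nz, nx = params.shape
    nt = params.n_frames
    fr = params.frame_rate

    truth = GroundTruth(
        diameter_map=np.full((nz, nx), np.nan),
        ri_map=np.full((nz, nx), np.nan),
        centreline=np.zeros((nz, nx), bool),
        junction=np.zeros((nz, nx), bool),
        lumen=np.zeros((nz, nx), bool),
    )
    blood = np.zeros((nz, nx, nt), complex)
    membership = np.zeros((nz, nx), dtype=int)
    for i, seg in enumerate(segments):
        _check_in_fov(seg, params, i)
        pts = seg.as_array()
        d = pts[-1] - pts[0]
        u_z = abs(d[0]) / np.linalg.norm(d)  # cos(beam-to-flow angle)
        if waveforms is not None:
            v = np.asarray(waveforms[i], dtype=float)
            if v.shape != (nt,):
                raise ValueError("waveforms must be sampled at the frame rate over the block")
        else:
            v = cardiac_waveform(seg.psv_cms, seg.edv_cms, fr, nt, cycle_s=cycle_s)
        truth.waveforms.append(v)
        f_inst = seg.flow_sign * 2.0 * (v * 1e-2) * params.pulse_frequency * u_z / params.speed_of_sound
        f_peak = float(np.max(np.abs(f_inst)))
        if f_peak > params.prf / 2.0:
            raise ValueError(
                f"segment {i}: Doppler frequency {f_peak:.0f} Hz beyond +/- prf/2 "
                f"({params.prf / 2:.0f} Hz) is physically unsamplable"
            )
        if f_peak > fr / 2.0:
            truth.aliased = True
        phase = 2.0 * np.pi * np.cumsum(f_inst) / fr
        dist = _segment_distance_field(seg, params)
        amp = _render_profile(seg, dist)
        if psf_fwhm_mm > 0:
            # the beamformed grid carries the system point-spread function
            amp = gaussian_filter(amp, psf_fwhm_mm * _FWHM_TO_SIGMA / params.pixel_spacing)
        lum = dist <= seg.diameter_mm / 2.0
        rows, cols = np.nonzero(amp > 1e-3 * amp.max())
        phi0 = rng.uniform(0.0, 2.0 * np.pi, rows.size)
        blood[rows, cols, :] += (
            amp[rows, cols, None] * np.exp(1j * (phi0[:, None] + phase[None, :]))
        )
        membership += lum
        truth.lumen |= lum
        truth.segment_lumens.append(lum)
        truth.ri_map[lum] = seg.ri
        centre = dist <= params.pixel_spacing / 2.0
        truth.centreline |= centre
        truth.diameter_map[centre] = seg.diameter_mm
    truth.junction = membership >= 2

    e_blood = float(np.sum(np.abs(blood) ** 2))
    if e_blood == 0:
        raise ValueError("blood signal has zero energy; check segment geometry")

    clutter = np.zeros_like(blood)
    if clutter_to_blood_db is not None and clutter_rank > 0:
        # tissue moves quasi-rigidly: every clutter mode carries the same
        # magnitude map -- the echogenicity envelope -- and differs only in
        # its phase pattern (harmonics of a smooth displacement-like field,
        # mutually orthogonal by construction).  The shared magnitude is
        # what produces the bright diagonal block in the spatial-similarity
        # matrix that adaptive rank selection relies on; decaying mode
        # energies keep the singular vectors aligned with the modes.
        field = gaussian_filter(rng.normal(size=(nz, nx)), 6.0)
        envelope = np.exp(0.8 * field / (field.std() or 1.0))
        warp = gaussian_filter(rng.normal(size=(nz, nx)), 4.0)
        span = warp.max() - warp.min() or 1.0
        warp = 3.0 * (warp - warp.min()) / span
        for k in range(clutter_rank):
            spatial = envelope * np.exp(2j * np.pi * (k + 1) * warp)
            temporal = _lowpass_temporal_mode(rng, nt, fr)
            clutter += 0.6**k * spatial[:, :, None] * temporal[None, None, :]
        e_c = float(np.sum(np.abs(clutter) ** 2))
        clutter *= math.sqrt(e_blood * 10 ** (clutter_to_blood_db / 10.0) / e_c)

    noise = np.zeros_like(blood)
    if noise_db is not None:
        noise = rng.normal(size=blood.shape) + 1j * rng.normal(size=blood.shape)
        e_n = float(np.sum(np.abs(noise) ** 2))
        noise *= math.sqrt(e_blood * 10 ** (-noise_db / 10.0) / e_n)

    truth.blood, truth.clutter, truth.noise = blood, clutter, noise
    block = IQBlock(blood + clutter + noise, params)
    return block, truth


def make_cohort(spec: CohortSpec) -> list[pd.DataFrame]:
    """Draw per-subject skeleton measurement tables from a cohort spec.

    Returns one DataFrame per subject with columns ``diameter_mm`` and
    ``ri``; the subject's true slope and RI-in-small-vessels are stored in
    ``DataFrame.attrs``.  Bit-reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.diameter_range
    tables: list[pd.DataFrame] = []
    for i in range(spec.n_subjects):
        m = rng.normal(spec.slope_mean, spec.slope_sd)
        r0 = rng.normal(spec.ri_small_mean, spec.ri_small_sd)
        d = rng.uniform(lo, hi, spec.n_skeleton_points)
        ri = m * (d - 0.2) + r0
        if spec.measurement_noise_sd > 0:
            ri = ri + rng.normal(0.0, spec.measurement_noise_sd, d.size)
        df = pd.DataFrame({"diameter_mm": d, "ri": ri})
        df.attrs.update(subject=i, true_slope=m, true_ri_small=r0)
        tables.append(df)
    return tables
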