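"""Per-pixel Doppler spectral analysis: spectrogram to resistivity index.

The slow-time signal of every pixel is turned into a spectrogram (40 ms
Hann windows, 3 ms hop), magnitudes are averaged over a 5 x 5 spatial
neighbourhood, entries below 10 % of the spectrogram maximum are zeroed,
aliasing is corrected under the unidirectional-flow assumption (doubling
the measurable velocity range), and the power-weighted mean Doppler
frequency yields a velocity trace.  Peak systolic (PSV) and end-diastolic
(EDV) velocities are read in 12.5 ms windows centred on image-wide cardiac
landmarks, and the resistivity (Pourcelot) index is

    RI = (PSV - EDV) / PSV

whose PSV/EDV ratio cancels the cos(theta) beam-angle factor, making the
RI angle independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT, find_peaks
from scipy.signal.windows import hann

from .containers import IQBlock
from .morphology import Skeleton
from .params import AcquisitionParams

__all__ = [
    "Spectrogram",
    "VelocityTrace",
    "CardiacLandmarks",
    "NoCardiacSignalError",
    "spectrogram",
    "average_neighbourhood",
    "noise_floor",
    "dealias",
    "mean_frequency",
    "to_velocity",
    "global_landmarks",
    "psv_edv",
    "map_skeleton_ri",
]

WINDOW_S = 0.040
HOP_S = 0.003
LANDMARK_WINDOW_S = 0.0125
AMBIGUITY_RATIO = 1.2


class NoCardiacSignalError(ValueError):
    """Raised when no cardiac cycle can be detected in a velocity trace."""


@dataclass
class Spectrogram:
    """Magnitude time-frequency map of one pixel (or pixel neighbourhood).

    ``freqs`` is centred on zero for a two-sided spectrogram and becomes
    one-sided over a span of one frame rate after de-aliasing.
    """

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    frame_rate: float
    window_s: float = WINDOW_S
    hop_s: float = HOP_S
    dealiased: bool = False
    flow_sign: int = 0
    flags: dict = field(default_factory=dict)

    def copy_with(self, magnitude=None, freqs=None, **kw) -> "Spectrogram":
        return Spectrogram(
            magnitude=self.magnitude if magnitude is None else magnitude,
            freqs=self.freqs if freqs is None else freqs,
            times=self.times,
            frame_rate=self.frame_rate,
            window_s=self.window_s,
            hop_s=self.hop_s,
            dealiased=kw.get("dealiased", self.dealiased),
            flow_sign=kw.get("flow_sign", self.flow_sign),
            flags={**self.flags, **kw.get("flags", {})},
        )


@dataclass
class VelocityTrace:
    """Velocity trace with its cardiac summary values."""

    v: np.ndarray
    times: np.ndarray
    psv: float
    edv: float
    ri: float
    t_psv: float
    t_edv: float
    n_cycles: int
    flags: dict = field(default_factory=dict)


@dataclass
class CardiacLandmarks:
    """Image-averaged PSV/EDV time points, one pair per detected cycle."""

    t_psv: np.ndarray
    t_edv: np.ndarray

    def __post_init__(self) -> None:
        self.t_psv = np.atleast_1d(np.asarray(self.t_psv, float))
        self.t_edv = np.atleast_1d(np.asarray(self.t_edv, float))
        if self.t_psv.size == 0 or self.t_edv.size == 0:
            raise NoCardiacSignalError("no cardiac signal: missing PSV or EDV landmarks")

    @property
    def n_cycles(self) -> int:
        return min(self.t_psv.size, self.t_edv.size)


def _make_stft(frame_rate: float, n_frames: int) -> ShortTimeFFT:
    win_len = round(WINDOW_S * frame_rate)
    hop = max(1, round(HOP_S * frame_rate))
    if n_frames < win_len:
        raise ValueError(
            f"block of {n_frames} frames shorter than one {win_len}-sample window"
        )
    w = hann(win_len, sym=False)
    return ShortTimeFFT(w, hop=hop, fs=frame_rate, fft_mode="centered")


def _stft_magnitude(signals: np.ndarray, frame_rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude STFT along the last axis; returns (mag, freqs, times).

    Only slices whose window lies fully inside the record are kept, so
    zero-padded border columns cannot masquerade as low-velocity samples.
    """
    n = signals.shape[-1]
    sft = _make_stft(frame_rate, n)
    p0 = sft.lower_border_end[1]
    p1 = sft.upper_border_begin(n)[1]
    if p0 >= p1:  # record barely longer than one window: keep everything
        p0, p1 = None, None
    S = sft.stft(signals, p0=p0, p1=p1)
    return np.abs(S), sft.f.copy(), sft.t(n, p0=p0, p1=p1).copy()


def spectrogram(block: IQBlock, pixel: tuple[int, int]) -> Spectrogram:
    """Two-sided magnitude spectrogram of a single pixel's slow-time signal."""
    r, c = pixel
    mag, freqs, times = _stft_magnitude(block.data[r, c, :], block.params.frame_rate)
    return Spectrogram(mag, freqs, times, block.params.frame_rate)


def average_neighbourhood(block: IQBlock, pixel: tuple[int, int], size: int = 5) -> Spectrogram:
    """Mean of per-pixel spectrogram magnitudes over a size x size window.

    The window is centred on ``pixel`` and truncated at image borders.
    Magnitude averaging improves the ridge SNR by roughly sqrt(window
    population) for independent noise.
    """
    r, c = pixel
    half = size // 2
    nz, nx, _ = block.data.shape
    r0, r1 = max(0, r - half), min(nz, r + half + 1)
    c0, c1 = max(0, c - half), min(nx, c + half + 1)
    traces = block.data[r0:r1, c0:c1, :].reshape(-1, block.data.shape[2])
    mag, freqs, times = _stft_magnitude(traces, block.params.frame_rate)
    return Spectrogram(mag.mean(axis=0), freqs, times, block.params.frame_rate)


def noise_floor(spec: Spectrogram, fraction: float = 0.10) -> Spectrogram:
    """Zero spectrogram entries below ``fraction`` of the global maximum.

    The cut is relative to the maximum of this spectrogram (not per time
    column) and the operation is idempotent.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    mag = spec.magnitude.copy()
    mag[mag < fraction * mag.max()] = 0.0
    return spec.copy_with(magnitude=mag)


def dealias(spec: Spectrogram, ambiguity_ratio: float = AMBIGUITY_RATIO) -> Spectrogram:
    """Unwrap aliased Doppler content under the unidirectional-flow assumption.

    The dominant flow sign is taken from the time-integrated signed-
    frequency power; the opposite-sign half of the spectrum is remapped
    onto the extension of the dominant side, so the frequency axis becomes
    one-sided over a span of one frame rate and the maximum measurable
    |Doppler frequency| doubles.  When the two signs carry comparable
    energy (ratio below ``ambiguity_ratio``) the pixel is flagged
    ambiguous and left untouched.
    """
    if spec.dealiased:
        return spec
    w = spec.magnitude**2
    pos = float(w[spec.freqs > 0].sum())
    neg = float(w[spec.freqs < 0].sum())
    dom, opp = (pos, neg) if pos >= neg else (neg, pos)
    if opp > 0 and dom / opp < ambiguity_ratio:
        return spec.copy_with(flags={"ambiguous_flow_sign": True})
    sign = 1 if pos >= neg else -1
    fr = spec.frame_rate
    if sign > 0:
        new_freqs = np.where(spec.freqs < 0, spec.freqs + fr, spec.freqs)
    else:
        new_freqs = np.where(spec.freqs > 0, spec.freqs - fr, spec.freqs)
    order = np.argsort(new_freqs)
    return spec.copy_with(
        magnitude=spec.magnitude[order],
        freqs=new_freqs[order],
        dealiased=True,
        flow_sign=sign,
    )


def mean_frequency(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """Power-weighted frequency centroid per time step.

    Returns (trace in Hz, boolean flag of all-zero columns, which get 0).
    """
    w = spec.magnitude**2
    tot = w.sum(axis=0)
    empty = tot == 0
    tot_safe = np.where(empty, 1.0, tot)
    trace = (spec.freqs[:, None] * w).sum(axis=0) / tot_safe
    trace[empty] = 0.0
    return trace, empty


def to_velocity(f_hz: np.ndarray | float, params: AcquisitionParams, theta: float = 0.0):
    """Doppler frequency to blood speed, cm/s: V = f c0 / (2 f_pulse cos theta).

    Grazing angles (|cos theta| < 0.1) make the absolute velocity
    ill-conditioned and raise; RI computations do not need the angle since
    it cancels in the PSV/EDV ratio.
    """
    c = math.cos(theta)
    if abs(c) < 0.1:
        raise ValueError("grazing angle: |cos(theta)| < 0.1, absolute velocity undefined")
    return np.asarray(f_hz) * params.speed_of_sound / (2.0 * params.pulse_frequency * c) * 100.0


def _speed_trace(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Floored, de-aliased, sign-folded velocity-proportional trace (Hz)."""
    trace, empty = mean_frequency(spec)
    w = spec.magnitude**2
    sign = np.sign((trace * w.sum(axis=0)).sum()) or 1.0
    return sign * trace, empty, spec.times


def global_landmarks(
    block: IQBlock,
    mask: np.ndarray,
    min_separation_s: float = 0.25,
    floor_fraction: float = 0.10,
) -> CardiacLandmarks:
    """Cardiac PSV/EDV time points from the image-averaged spectrogram.

    The spectrogram magnitude is averaged over all mask pixels, floored,
    de-aliased, and reduced to a mean-frequency speed trace; PSV times are
    its per-cycle maxima and EDV times its per-cycle minima (peak detection
    with the given minimum separation).  A trace with relative modulation
    below 10 % has no detectable cardiac signal and raises.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    traces = block.data[mask, :]
    mag, freqs, times = _stft_magnitude(traces, block.params.frame_rate)
    spec = Spectrogram(mag.mean(axis=0), freqs, times, block.params.frame_rate)
    spec = dealias(noise_floor(spec, floor_fraction))
    v, _, times = _speed_trace(spec)
    vmax, vmin = float(v.max()), float(v.min())
    if vmax <= 0 or (vmax - vmin) < 0.10 * vmax:
        raise NoCardiacSignalError("no cardiac signal: velocity modulation below 10%")
    distance = max(1, int(round(min_separation_s / spec.hop_s)))
    prominence = 0.2 * (vmax - vmin)
    peaks, _ = find_peaks(v, distance=distance, prominence=prominence)
    if peaks.size == 0:
        raise NoCardiacSignalError("no cardiac signal: no systolic peak found")
    # end-diastole: the minimum between consecutive systolic peaks, plus the
    # leading segment when it spans at least half an inter-beat interval
    troughs = []
    if peaks[0] >= distance // 2:
        troughs.append(int(np.argmin(v[: peaks[0]])))
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(int(a + np.argmin(v[a:b])))
    if not troughs:
        raise NoCardiacSignalError("no cardiac signal: no end-diastolic minimum found")
    return CardiacLandmarks(times[peaks], times[np.asarray(troughs)])


def psv_edv(
    v: np.ndarray,
    times: np.ndarray,
    landmarks: CardiacLandmarks,
    window_s: float = LANDMARK_WINDOW_S,
) -> VelocityTrace:
    """Per-pixel PSV/EDV/RI from a velocity trace and global landmarks.

    For each cycle, PSV is the maximum of v within +/- window/2 of the
    global PSV time and EDV the minimum around the global EDV time; cycles
    whose window falls off the record are skipped.  PSV and EDV are
    averaged across cycles before forming RI = (PSV - EDV)/PSV.  A
    negative EDV (flow reversal) is flagged, never clamped, so RI may
    exceed 1 there; otherwise RI lies in [0, 1].
    """
    v = np.asarray(v, float)
    half = window_s / 2.0
    flags: dict = {}

    def per_cycle(centres, reduce):
        out, kept = [], []
        for t0 in centres:
            sel = np.abs(times - t0) <= half
            if not sel.any():
                continue
            out.append(reduce(v[sel]))
            kept.append(t0)
        return out, kept

    psvs, t_ps = per_cycle(landmarks.t_psv, np.max)
    edvs, t_es = per_cycle(landmarks.t_edv, np.min)
    n_cycles = min(len(psvs), len(edvs))
    if n_cycles == 0:
        flags["undefined"] = True
        return VelocityTrace(v, times, np.nan, np.nan, np.nan, np.nan, np.nan, 0, flags)
    psv = float(np.mean(psvs))
    edv = float(np.mean(edvs))
    if edv < 0:
        flags["negative_edv"] = True
    if psv <= 0:
        flags["undefined"] = True
        ri = np.nan
    else:
        ri = (psv - edv) / psv
    return VelocityTrace(v, times, psv, edv, ri, float(t_ps[0]), float(t_es[0]), n_cycles, flags)


def map_skeleton_ri(
    block: IQBlock,
    skel: Skeleton,
    landmarks: CardiacLandmarks | None = None,
    mask: np.ndarray | None = None,
    neighbourhood: int = 5,
    floor_fraction: float = 0.10,
) -> Skeleton:
    """Resistivity index at every masked-skeleton pixel.

    Runs the full per-pixel chain (5 x 5 magnitude averaging -> 10 % noise
    floor -> de-aliasing -> mean frequency -> PSV/EDV in landmark windows).
    Pixels with an ambiguous flow sign or no valid cycle are flagged and
    left NaN, never dropped silently.  ``mask`` (default: the skeleton
    itself) is used to derive the image-wide cardiac landmarks when none
    are given.
    """
    if landmarks is None:
        landmarks = global_landmarks(block, skel.mask if mask is None else mask)
    ri = np.full(skel.mask.shape, np.nan)
    psv_map = np.full(skel.mask.shape, np.nan)
    edv_map = np.full(skel.mask.shape, np.nan)
    quality = skel.quality.copy()
    params = block.params
    for r, c in np.argwhere(skel.included):
        spec = average_neighbourhood(block, (r, c), size=neighbourhood)
        spec = dealias(noise_floor(spec, floor_fraction))
        if spec.flags.get("ambiguous_flow_sign"):
            continue
        v_hz, _, times = _speed_trace(spec)
        v = to_velocity(v_hz, params, theta=0.0)
        res = psv_edv(v, times, landmarks)
        if res.flags.get("undefined") or not np.isfinite(res.ri):
            continue
        ri[r, c] = res.ri
        psv_map[r, c] = res.psv
        edv_map[r, c] = res.edv
    out = Skeleton(
        skel.mask,
        skel.pixel_spacing,
        excluded=skel.excluded.copy(),
        theta=skel.theta,
        diameter_mm=skel.diameter_mm,
        ri=ri,
        psv_cms=psv_map,
        edv_cms=edv_map,
        quality=quality,
        meta=dict(skel.meta),
    )
    return out
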