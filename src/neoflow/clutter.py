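"""SVD clutter filtering of ultrafast Doppler IQ data.

Tissue ("clutter") is high-amplitude, spatially coherent and slowly varying,
so it concentrates in the leading singular components of the Casorati matrix
(space flattened x time).  Removing those components separates the blood
signal; integrating its energy over the block yields the power Doppler
image.

The adaptive rank selection follows the similarity-matrix idea: spatial
singular vectors of tissue share the echogenicity envelope, so the matrix
C(i, j) = |<|U_i|, |U_j|>| of magnitude-normalised spatial vectors shows a
bright diagonal block over the clutter subspace.  The selected rank is where
the diagonal-band similarity first falls below the midpoint of its initial
plateau and its floor.  A slow-time guard additionally requires candidate
clutter components to be temporally slow, so blocks without tissue clutter
(where the leading component is blood) yield rank 0, i.e. an identity
filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import IQBlock, PowerDopplerImage

__all__ = [
    "SVDDecomposition",
    "svd_decompose",
    "adaptive_rank_threshold",
    "svd_clutter_filter",
    "power_doppler",
]


@dataclass
class SVDDecomposition:
    """Thin SVD of the Casorati matrix of an IQ block.

    ``U`` holds spatial singular vectors (space x components, depth-major
    flattening), ``s`` the non-increasing singular values and ``V`` the
    temporal singular vectors (time x components).  Components
    ``1..selected_rank`` are considered clutter once a rank is selected.
    """

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray
    spatial_shape: tuple[int, int]
    frame_rate: float
    selected_rank: int | None = None

    @property
    def n_components(self) -> int:
        return self.s.size


def svd_decompose(block: IQBlock) -> SVDDecomposition:
    """Exact thin SVD of the block's Casorati matrix.

    The cube is flattened depth-major to (space, time).  Requires at least
    two frames and finite data; NaN/Inf values are reported with their
    indices.
    """
    data = block.data
    if data.shape[2] < 2:
        raise ValueError("need at least 2 frames for an SVD clutter filter")
    bad = ~np.isfinite(data)
    if bad.any():
        idx = np.argwhere(bad)[:5]
        raise ValueError(f"non-finite IQ samples at (z, x, t) indices {idx.tolist()} ...")
    nz, nx, nt = data.shape
    X = data.reshape(nz * nx, nt)
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    return SVDDecomposition(
        U=U,
        s=s,
        V=Vh.conj().T,
        spatial_shape=(nz, nx),
        frame_rate=block.params.frame_rate,
    )


def _temporal_mean_abs_frequency(decomp: SVDDecomposition, k: int) -> float:
    """Power-weighted mean |frequency| (Hz) of temporal singular vector k."""
    v = decomp.V[:, k]
    spec = np.abs(np.fft.fft(v)) ** 2
    freqs = np.abs(np.fft.fftfreq(v.size, d=1.0 / decomp.frame_rate))
    tot = spec.sum()
    if tot == 0:
        return 0.0
    return float((freqs * spec).sum() / tot)


def adaptive_rank_threshold(
    decomp: SVDDecomposition,
    band_halfwidth: int = 5,
    plateau_len: int = 5,
    floor_fraction: float = 0.2,
    slow_freq_hz: float = 50.0,
) -> int:
    """Select the clutter rank from the spatial-similarity diagonal profile.

    ``d(k)`` is the mean of the similarity matrix over the (2w+1)-wide
    diagonal band at index k; the rank is the first k where d(k) drops below
    the midpoint of the initial plateau (mean of the first ``plateau_len``
    values) and the floor (mean over the trailing ``floor_fraction``).  The
    slow-time guard caps the rank at the first component whose temporal mean
    |frequency| exceeds ``slow_freq_hz``: tissue is slow, blood is not, so a
    clutter-free block returns 0 (identity filter).  Degenerate profiles
    (no contrast between plateau and floor) fall back to a fixed-fraction
    rank with a warning.
    """
    n = decomp.n_components
    if n < 10:
        raise ValueError("adaptive thresholding requires >= 10 components")
    # centred magnitude similarity: tissue singular vectors share the
    # echogenicity envelope (similarity near 1) while blood/noise vectors
    # decorrelate to ~0 once the mean magnitude level is removed
    A = np.abs(decomp.U)
    A = A - A.mean(axis=0)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    A = A / norms
    C = np.abs(A.T @ A)

    # backward diagonal band: mean similarity of component k to its w
    # predecessors; drops sharply at the first component outside the
    # clutter block
    w = band_halfwidth
    d = np.empty(n)
    for k in range(1, n):
        lo = max(0, k - w)
        d[k] = C[k, lo:k].mean()
    d[0] = d[1]

    d_max = d[:plateau_len].mean()
    n_floor = max(1, int(np.ceil(floor_fraction * n)))
    d_floor = d[-n_floor:].mean()

    if d_max - d_floor < 0.02:
        warnings.warn(
            "degenerate similarity profile: no clutter plateau; "
            "falling back to fixed-fraction rank",
            RuntimeWarning,
            stacklevel=2,
        )
        rank = max(1, n // 20)
    else:
        thr = 0.5 * (d_max + d_floor)
        below = np.nonzero(d < thr)[0]
        rank = int(below[0]) if below.size else n - 1

    # slow-time guard: clutter components must be temporally slow
    guard = 0
    while guard < rank and _temporal_mean_abs_frequency(decomp, guard) < slow_freq_hz:
        guard += 1
    rank = min(rank, guard)
    return int(np.clip(rank, 0, n - 1))


def svd_clutter_filter(block: IQBlock, rank: int | str = "adaptive") -> IQBlock:
    """Remove the rank-truncated clutter reconstruction from the block.

    ``rank`` may be an explicit component count (0 is the identity) or
    ``"adaptive"`` to use :func:`adaptive_rank_threshold`.  The output keeps
    the shape and metadata of the input and is linear in it for fixed rank.
    """
    decomp = svd_decompose(block)
    if rank == "adaptive":
        r = adaptive_rank_threshold(decomp)
    else:
        r = int(rank)
    if r >= decomp.n_components:
        raise ValueError(f"rank {r} >= number of components {decomp.n_components}")
    if r < 0:
        raise ValueError("rank must be >= 0")
    decomp.selected_rank = r
    nz, nx = decomp.spatial_shape
    if r == 0:
        return IQBlock(block.data.copy(), block.params)
    clutter = (decomp.U[:, :r] * decomp.s[:r]) @ decomp.V[:, :r].conj().T
    filtered = block.data.reshape(nz * nx, -1) - clutter
    return IQBlock(filtered.reshape(block.data.shape), block.params)


def power_doppler(filtered: IQBlock) -> PowerDopplerImage:
    """Integrate the energy of the (clutter-filtered) signal per voxel.

    intensity(z, x) = sum_t |data(z, x, t)|^2 — proportional to the moving
    scatterer content of the voxel.  The input is expected to be clutter
    filtered already (not enforced).
    """
    intensity = np.sum(np.abs(filtered.data) ** 2, axis=2)
    return PowerDopplerImage(
        intensity,
        filtered.params.pixel_spacing,
        provenance={"source": "power_doppler", "n_frames": filtered.params.n_frames},
    )
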