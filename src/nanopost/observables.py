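"""Structural observables of a chain in (or out of) a post array.

Implements the axial span, the gyration radius and its longitudinal /
lateral decomposition, the interstitial occupation number, the
orientation-averaged single-chain structure factor (Debye sum), the
tangent-tangent orientation correlation function, and the short-range
exponential fit yielding the persistence length.

All per-frame quantities are reported as block-averaged means with
standard errors (>= 10 blocks by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import PostArrayGeometry, cell_index

__all__ = [
    "ObservableSeries",
    "StructureFactorResult",
    "OrientationCorrelation",
    "block_stats",
    "span",
    "gyration_components",
    "occupation_number",
    "structure_factor",
    "structure_factor_histogram",
    "orientation_correlation",
    "estimate_persistence_length",
    "local_loglog_slope",
    "default_q_grid",
]


def block_stats(values: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and block-averaged standard error of a correlated series."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    n_blocks = min(n_blocks, values.size)
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    sem = means.std(ddof=1) / math.sqrt(n_blocks) if n_blocks > 1 else math.nan
    return float(values.mean()), float(sem)


@dataclass
class ObservableSeries:
    """Per-frame values of one observable with block-averaged statistics."""

    name: str
    values: np.ndarray
    n_blocks: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean, self.sem = block_stats(self.values, self.n_blocks)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StructureFactorResult:
    """Single-chain structure factor S(q) on a wavevector grid."""

    q: np.ndarray
    S: np.ndarray
    N: int

    @property
    def length_scale(self) -> np.ndarray:
        """Real-space scale Omega = 2*pi/q probed by each wavevector."""
        return 2.0 * np.pi / self.q


@dataclass
class OrientationCorrelation:
    """Tangent-tangent correlations C(n_s) = <u_i . u_{i+n_s}>."""

    n_s: np.ndarray
    C: np.ndarray
    topology: str


def _as_frames(frames) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, N, 3) or (N, 3)")
    return frames


def span(frames) -> np.ndarray:
    """Per-frame axial span max(x_i) - min(x_i) along the post axes."""
    frames = _as_frames(frames)
    x = frames[:, :, 0]
    return x.max(axis=1) - x.min(axis=1)


def gyration_components(frames) -> dict[str, np.ndarray]:
    """Per-frame R_g and its longitudinal / lateral components.

    R_gx is the component along the post axes; the lateral component is
    R_gyz = sqrt((R_gy^2 + R_gz^2)/2), so R_g^2 = R_gx^2 + 2 R_gyz^2.
    """
    frames = _as_frames(frames)
    if frames.shape[1] < 2:
        raise ValueError("gyration requires at least 2 beads")
    d = frames - frames.mean(axis=1, keepdims=True)
    second = (d**2).mean(axis=1)  # (F, 3) diagonal of gyration tensor
    rgx2 = second[:, 0]
    rgyz2 = 0.5 * (second[:, 1] + second[:, 2])
    return {
        "R_g": np.sqrt(second.sum(axis=1)),
        "R_gx": np.sqrt(rgx2),
        "R_gyz": np.sqrt(rgyz2),
    }


def occupation_number(frame, array: PostArrayGeometry) -> int:
    """Number of distinct interstitial cells visited by the beads of a frame.

    A bead in a passage aperture counts toward the cell that contains it
    (the yz plane is fully tiled by the cells).
    """
    frame = np.asarray(frame, dtype=float)
    oy, oz = array.origin
    iy = np.floor((frame[:, 1] - oy) / array.S_p).astype(int)
    iz = np.floor((frame[:, 2] - oz) / array.S_p).astype(int)
    return len(set(zip(iy.tolist(), iz.tolist())))


def occupation_series(frames, array: PostArrayGeometry) -> np.ndarray:
    frames = _as_frames(frames)
    return np.array([occupation_number(f, array) for f in frames], dtype=float)


def default_q_grid(frames, l: float = 0.97, n_points: int = 200) -> np.ndarray:
    """Logarithmic q grid from twice the largest span down to half a bond."""
    smax = max(float(span(frames).max()), l)
    return np.geomspace(2.0 * np.pi / (2.0 * smax), 2.0 * np.pi / (0.5 * l), n_points)


def structure_factor(frames, q) -> StructureFactorResult:
    """Orientation-averaged Debye sum S(q) = <sum_ij sinc(q r_ij)> / N^2.

    Direct O(N^2) evaluation over all bead pairs, averaged over frames.
    This is the reference path; see :func:`structure_factor_histogram`
    for the binned acceleration.
    """
    frames = _as_frames(frames)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q grid must be positive")
    n_frames, N, _ = frames.shape
    S = np.zeros_like(q)
    for f in frames:
        d = np.linalg.norm(f[:, None, :] - f[None, :, :], axis=2)
        qr = q[:, None] * d.ravel()[None, :]
        S += np.sinc(qr / np.pi).sum(axis=1)
    S /= n_frames * N * N
    return StructureFactorResult(q=q, S=S, N=N)


def structure_factor_histogram(
    frames, q, n_bins: int = 2000
) -> StructureFactorResult:
    """Debye sum accelerated through a pair-distance histogram.

    Distances are binned and sinc evaluated at bin centers; accuracy is
    controlled by the bin width (error ~ (q*dr)^2/6 per pair).
    """
    frames = _as_frames(frames)
    q = np.asarray(q, dtype=float)
    n_frames, N, _ = frames.shape
    iu = np.triu_indices(N, k=1)
    dists = np.concatenate(
        [np.linalg.norm(f[iu[0]] - f[iu[1]], axis=1) for f in frames]
    )
    rmax = dists.max() * (1 + 1e-9) if dists.size else 1.0
    counts, edges = np.histogram(dists, bins=n_bins, range=(0.0, rmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonzero = counts > 0
    qr = q[:, None] * centers[nonzero][None, :]
    pair_sum = (np.sinc(qr / np.pi) * counts[nonzero][None, :]).sum(axis=1)
    # diagonal (i == j) terms contribute N per frame; off-diagonal twice
    S = (N * n_frames + 2.0 * pair_sum) / (n_frames * N * N)
    return StructureFactorResult(q=q, S=S, N=N)


def orientation_correlation(frames, topology: str) -> OrientationCorrelation:
    """Average tangent-tangent correlation over frames and chain fragments.

    Linear chains average over all bond pairs (i, i+n_s) within range;
    circular chains wrap indices modulo the bond count, which makes
    C(n_s) = C(N_bonds - n_s) exactly (ring inversion symmetry).
    """
    frames = _as_frames(frames)
    circular = topology == "circular"
    if circular:
        bonds = np.roll(frames, -1, axis=1) - frames
    else:
        bonds = np.diff(frames, axis=1)
    nb = bonds.shape[1]
    if nb < 2:
        raise ValueError("orientation correlation requires at least 2 bonds")
    u = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
    if circular:
        n_s = np.arange(nb + 1)
        C = np.empty(nb + 1)
        for ns in n_s:
            C[ns] = np.mean(np.sum(u * np.roll(u, -ns, axis=1), axis=2))
    else:
        n_s = np.arange(nb)
        C = np.empty(nb)
        for ns in n_s:
            C[ns] = np.mean(np.sum(u[:, : nb - ns] * u[:, ns:], axis=2))
    return OrientationCorrelation(n_s=n_s, C=C, topology=topology)


def estimate_persistence_length(
    corr: OrientationCorrelation,
    l: float = 0.97,
    c_min: float = math.exp(-0.5),
) -> tuple[float, float]:
    """Persistence length from the short-range exponential decay.

    Fits ln C(n_s) = -n_s l / P by least squares over the window of
    separations n_s >= 1 with C(n_s) >= c_min.  The default window
    (c_min = e^(-1/2), separations up to about half a persistence length)
    stays inside the regime where the decay of a self-avoiding chain is
    still exponential; beyond it, excluded-volume swelling makes the
    correlations decay slower than exponential and the fit is biased
    upward.  Returns (P, standard error).
    """
    mask = (corr.n_s >= 1) & (corr.C >= max(c_min, 0.0)) & (corr.C > 0)
    # the window must be contiguous from n_s = 1: stop at the first miss
    order = np.argsort(corr.n_s[mask])
    ns = corr.n_s[mask][order]
    C = corr.C[mask][order]
    keep = ns <= (np.arange(ns.size) + 1)  # contiguous prefix 1,2,3,...
    ns, C = ns[keep], C[keep]
    if ns.size < 3:
        raise ValueError(
            "fewer than 3 usable points in the persistence-length fit window"
        )
    fit = stats.linregress(ns, np.log(C))
    if fit.slope >= 0:
        raise ValueError("non-decaying correlations: cannot fit persistence length")
    P = -l / fit.slope
    P_err = l * fit.stderr / fit.slope**2
    return float(P), float(abs(P_err))


def local_loglog_slope(q: np.ndarray, S: np.ndarray, window: int = 7) -> np.ndarray:
    """Running log-log slope of S(q), a reporting aid for regime reading.

    The onsets of structure-factor humps (near 2*pi/S_p or 2*pi/d_c) and
    the characteristic slopes (-1 rod, -2 extended de Gennes, -5/3 classic
    de Gennes) can be read off this curve; no automated classification is
    attempted.
    """
    lq, lS = np.log(q), np.log(S)
    half = window // 2
    out = np.full_like(lq, np.nan)
    for i in range(half, lq.size - half):
        sl = slice(i - half, i + half + 1)
        out[i] = stats.linregress(lq[sl], lS[sl]).slope
    return out
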