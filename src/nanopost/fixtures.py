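"""Deterministic synthetic conformations for testing analysis operations.

Every observable in the package can be exercised without running any
dynamics: rods and rings have closed-form observables, the ideal
wormlike-chain sampler plants a known persistence length, and
``planted_cells`` plants a known occupation number.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .chain import ChainState
from .constants import BOND_LENGTH
from .geometry import PostArrayGeometry

__all__ = [
    "rod",
    "rectangle_ring",
    "regular_polygon_ring",
    "ideal_wlc",
    "planted_cells",
    "two_bead",
    "generate_fixture",
]


def rod(N: int, l: float = BOND_LENGTH, axis: int = 0) -> np.ndarray:
    """Straight rod of N beads at spacing l along the given axis."""
    pos = np.zeros((N, 3))
    pos[:, axis] = np.arange(N) * l
    return pos


def rectangle_ring(N: int, l: float = BOND_LENGTH) -> np.ndarray:
    """Fully prolonged rectangular loop: two strands of ~L/2 separated by l."""
    if N % 2:
        raise ValueError("rectangle ring requires an even number of beads")
    half = N // 2
    pos = np.zeros((N, 3))
    pos[:half, 0] = np.arange(half) * l
    pos[half:, 0] = (half - 1) * l - np.arange(half) * l
    pos[half:, 1] = l
    return pos


def regular_polygon_ring(N: int, l: float = BOND_LENGTH) -> np.ndarray:
    """Planar regular N-gon with side length l (in the xy plane).

    Its tangent correlations are exactly C(n_s) = cos(2 pi n_s / N).
    """
    if N < 3:
        raise ValueError("polygon ring requires at least 3 beads")
    R = l / (2.0 * math.sin(math.pi / N))
    ang = 2.0 * math.pi * np.arange(N) / N
    pos = np.zeros((N, 3))
    pos[:, 0] = R * np.cos(ang)
    pos[:, 1] = R * np.sin(ang)
    return pos


def _stiffness_for_persistence(P: float, l: float) -> float:
    """Stiffness b whose mean bond-angle cosine gives decay length P.

    For the discrete WLC the bond-angle cosine is distributed as
    p(x) ~ exp(b x) on [-1, 1], so <cos> = coth(b) - 1/b and
    C(n) = <cos>^n = exp(-n l / P) with P = -l / ln<cos>.
    """
    target = math.exp(-l / P)

    def mean_cos(b: float) -> float:
        # coth(b) - 1/b, stable for small b
        if b < 1e-4:
            return b / 3.0
        return 1.0 / math.tanh(b) - 1.0 / b

    return brentq(lambda b: mean_cos(b) - target, 1e-6, 1e5)


def ideal_wlc(
    N: int,
    seed: int,
    P: float | None = None,
    b: float | None = None,
    l: float = BOND_LENGTH,
    n_frames: int = 1,
) -> np.ndarray:
    """Ideal (no excluded volume) discrete wormlike chains.

    Bond directions are sampled from the Boltzmann distribution of the
    discrete bending energy, p(cos theta') ~ exp(b cos theta'), giving
    exactly exponential tangent correlations.  Specify either the
    stiffness ``b`` or the target persistence length ``P`` (the matching
    b is solved from <cos> = exp(-l/P)).

    Returns frames of shape (n_frames, N, 3).
    """
    if (P is None) == (b is None):
        raise ValueError("specify exactly one of P or b")
    if P is not None:
        b = _stiffness_for_persistence(P, l)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, N, 3))
    for f in range(n_frames):
        u = np.empty((N - 1, 3))
        u[0] = _random_unit(rng)
        for i in range(1, N - 1):
            u[i] = _propagate(u[i - 1], b, rng)
        pos = np.zeros((N, 3))
        pos[1:] = np.cumsum(l * u, axis=0)
        frames[f] = pos
    return frames


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _propagate(u_prev: np.ndarray, b: float, rng: np.random.Generator) -> np.ndarray:
    # sample cos(theta') from p(x) ~ exp(b x) on [-1, 1] by inverse CDF
    xi = rng.random()
    if b < 1e-8:
        c = 2.0 * xi - 1.0
    else:
        c = 1.0 + math.log(xi + (1.0 - xi) * math.exp(-2.0 * b)) / b
    c = min(1.0, max(-1.0, c))
    s = math.sqrt(max(0.0, 1.0 - c * c))
    phi = 2.0 * math.pi * rng.random()
    # orthonormal frame around u_prev
    a = np.array([1.0, 0.0, 0.0])
    if abs(u_prev[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u_prev, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u_prev, e1)
    return c * u_prev + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def planted_cells(
    cells: list[tuple[int, int]],
    array: PostArrayGeometry,
    beads_per_cell: int = 1,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Beads placed at (optionally jittered) centers of the given cells.

    The occupation number of the resulting frame equals the number of
    distinct cells as long as the jitter stays below S_p/2.
    """
    rng = np.random.default_rng(seed)
    pos = []
    for x_offset, (i, j) in enumerate(cells):
        center = array.cell_center(i, j)
        for k in range(beads_per_cell):
            dy, dz = (rng.uniform(-jitter, jitter, 2) if jitter else (0.0, 0.0))
            pos.append([x_offset * 0.5 + 0.1 * k, center[0] + dy, center[1] + dz])
    return np.asarray(pos, dtype=float)


def two_bead(r: float) -> np.ndarray:
    """Two beads separated by r along x (closed-form structure factor)."""
    return np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])


_KINDS = {
    "rod": rod,
    "rectangle_ring": rectangle_ring,
    "regular_polygon_ring": regular_polygon_ring,
    "ideal_wlc": ideal_wlc,
    "planted_cells": planted_cells,
    "two_bead": two_bead,
}


def generate_fixture(kind: str, seed: int = 0, **params):
    """Dispatch to one of the named fixture generators.

    Kinds: rod, rectangle_ring, regular_polygon_ring, ideal_wlc,
    planted_cells, two_bead.  ``seed`` is forwarded to the stochastic
    generators and ignored by the deterministic ones.
    """
    try:
        fn = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    if kind == "ideal_wlc":
        return fn(seed=seed, **params)
    if kind == "planted_cells":
        return fn(seed=seed, **params)
    return fn(**params)


def as_chain(positions: np.ndarray, topology: str = "linear") -> ChainState:
    """Wrap a fixture frame in a ChainState (validity not enforced)."""
    return ChainState(topology=topology, positions=np.asarray(positions, float))
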