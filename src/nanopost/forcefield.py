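"""Potential energy terms of the bead-spring wormlike chain model.

The chain is a touching-bead model: beads of diameter sigma interact
through the purely repulsive WCA potential, consecutive beads are bonded
by a FENE spring plus the WCA term, and chain stiffness enters through a
discretized wormlike-chain bending energy ``(B/l)(1 + cos theta)`` where
``theta`` is the valence angle between consecutive bonds.  Posts repel
beads through the same WCA form shifted radially by the bare post radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .chain import ChainState
from .constants import BOND_LENGTH, EPSILON, FENE_KAPPA, FENE_R0, R_CUT, SIGMA
from .geometry import PostArrayGeometry

__all__ = [
    "ForceFieldParams",
    "wca_bead_bead",
    "wca_bead_post",
    "fene_bond",
    "bending",
    "total_energy_forces",
]


class OverstretchedBondError(ValueError):
    """A bond reached the maximal FENE extension R_o."""


class BeadInsidePostError(ValueError):
    """A bead center entered a post core (r <= D_p/2)."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants in reduced units.

    ``b`` is the dimensionless stiffness B/(l*k_B*T): 0 for a flexible
    chain, 20 for the semiflexible chain mapping to double-stranded DNA
    (persistence length ~ 50 nm at a bead size of ~ 2.5 nm).
    """

    epsilon: float = EPSILON
    sigma: float = SIGMA
    kappa: float = FENE_KAPPA
    R_o: float = FENE_R0
    b: float = 0.0
    l: float = BOND_LENGTH  # nominal bond length entering B = b*l*kT

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("FENE spring constant must be positive")
        if self.R_o <= self.sigma:
            raise ValueError("maximal bond length R_o must exceed sigma")
        if self.b < 0:
            raise ValueError("stiffness b must be non-negative")

    @property
    def r_c(self) -> float:
        """WCA cutoff 2^(1/6) sigma."""
        return R_CUT * self.sigma

    @property
    def B(self) -> float:
        """Bending modulus B = b * l * k_B T (k_B T = epsilon)."""
        return self.b * self.l * self.epsilon

    @property
    def bend_k(self) -> float:
        """Prefactor B/l = b * k_B T of the discrete bending energy."""
        return self.b * self.epsilon


def wca_bead_bead(r, epsilon: float = EPSILON, sigma: float = SIGMA):
    """Purely repulsive WCA pair energy, zero at and beyond 2^(1/6) sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bead-bead distance must be positive")
    with np.errstate(over="raise"):
        sr6 = (sigma / r) ** 6
        e = np.where(r < R_CUT * sigma, 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon, 0.0)
    return e if e.ndim else float(e)


def wca_bead_post(r, D_p: float, epsilon: float = EPSILON, sigma: float = SIGMA):
    """Bead-post energy: WCA evaluated at the surface distance r - D_p/2."""
    r = np.asarray(r, dtype=float)
    s = r - D_p / 2.0
    if np.any(s <= 0):
        raise BeadInsidePostError(
            "bead center inside post core (r <= D_p/2); broken configuration "
            "or too large a timestep"
        )
    return wca_bead_bead(s, epsilon, sigma)


def fene_bond(l_ij, kappa: float = FENE_KAPPA, R_o: float = FENE_R0):
    """FENE bond energy -(kappa/2) R_o^2 ln[1 - (l/R_o)^2].

    The full bonded interaction of the model is this term plus
    ``wca_bead_bead(l_ij)``.
    """
    l_ij = np.asarray(l_ij, dtype=float)
    if np.any(l_ij < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(l_ij >= R_o):
        raise OverstretchedBondError(
            f"bond length >= maximal allowable extension R_o={R_o}"
        )
    return -0.5 * kappa * R_o**2 * np.log(1.0 - (l_ij / R_o) ** 2)


def bending(theta, b: float, kT: float = 1.0):
    """Bending energy (B/l)(1 + cos theta) = b*kT*(1 + cos theta).

    ``theta`` is the valence angle between consecutive bonds (pi for a
    straight chain, where the energy vanishes).  Equivalently
    ``b*kT*(1 - u_i . u_{i+1})`` in terms of bond unit vectors.
    """
    theta = np.asarray(theta, dtype=float)
    return b * kT * (1.0 + np.cos(theta))


def total_energy_forces(
    chain: ChainState,
    array: PostArrayGeometry | None = None,
    ff: ForceFieldParams | None = None,
) -> tuple[float, np.ndarray]:
    """Total potential energy and exact per-bead forces.

    WCA acts between every bead pair (bonded neighbors included, once);
    FENE on every bond; bending on every consecutive bond pair (wrapping
    for circular topology); bead-post WCA against the four cell-vertex
    posts.  Forces are the analytic negative gradients of the energy.
    """
    if ff is None:
        ff = ForceFieldParams()
    pos = np.ascontiguousarray(chain.positions, dtype=np.float64)
    n = pos.shape[0]
    # all pairs: exact reference path (no neighbor-list truncation)
    pairs = np.empty((n * (n - 1) // 2, 2), np.int64)
    n_pairs = _kernels.build_pairs(pos, math.inf, pairs)
    forces = np.empty_like(pos)
    if array is not None:
        has_array, S_p, Dp_half = True, array.S_p, array.D_p / 2.0
        oy, oz = array.origin
    else:
        has_array, S_p, Dp_half, oy, oz = False, 1.0, 0.0, 0.0, 0.0
    energy, status = _kernels.energy_forces(
        pos, forces, pairs, n_pairs, chain.circular, ff.bend_k, ff.kappa,
        ff.R_o, has_array, S_p, Dp_half, oy, oz,
    )
    if status == _kernels.OVERSTRETCH:
        raise OverstretchedBondError("bond at or beyond maximal FENE extension")
    if status == _kernels.INSIDE_POST:
        raise BeadInsidePostError("bead center inside a post core")
    if status == _kernels.NAN:
        raise FloatingPointError("non-finite energy")
    return float(energy), forces
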