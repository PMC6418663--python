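"""Chain state container for linear and circular bead-spring polymers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOND_LENGTH, FENE_R0

__all__ = ["ChainState"]


@dataclass
class ChainState:
    """Positions and velocities of a bead-spring chain.

    A linear chain of N beads has N-1 bonds; a circular chain closes the
    bond N -> 1 and has N bonds.  The contour length is the number of bonds
    times the nominal bond length.
    """

    topology: str  # "linear" | "circular"
    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.N < 3:
            raise ValueError("a chain needs at least 3 beads")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    @property
    def n_bonds(self) -> int:
        return self.N if self.circular else self.N - 1

    @property
    def contour_length(self) -> float:
        return self.n_bonds * BOND_LENGTH

    def bond_vectors(self) -> np.ndarray:
        """(n_bonds, 3) array of bond vectors r_{i+1} - r_i (wrapping for rings)."""
        if self.circular:
            return np.roll(self.positions, -1, axis=0) - self.positions
        return np.diff(self.positions, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def bond_unit_vectors(self) -> np.ndarray:
        b = self.bond_vectors()
        return b / np.linalg.norm(b, axis=1, keepdims=True)

    def validate(self) -> None:
        """Raise if any bond exceeds the maximal FENE extension."""
        lmax = float(self.bond_lengths().max())
        if lmax >= FENE_R0:
            raise ValueError(
                f"bond length {lmax:.4f} exceeds maximal extension R_o={FENE_R0}"
            )

    def copy(self) -> "ChainState":
        return ChainState(
            topology=self.topology,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
        )
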