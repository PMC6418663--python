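"""Initial conformations and thermostatted leap-frog dynamics.

The equations of motion are integrated with the leap-frog scheme in the
NVT ensemble using a Nose-Hoover thermostat (relaxation time 0.1 tau by
default), matching the simulation protocol of the underlying model.  A
Langevin thermostat is available as an alternative for small systems, and
a plain NVE mode exists for integrator validation (energy conservation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .chain import ChainState
from .constants import BOND_LENGTH
from .forcefield import (
    BeadInsidePostError,
    ForceFieldParams,
    OverstretchedBondError,
)
from .geometry import PostArrayGeometry

__all__ = [
    "SimulationParams",
    "Trajectory",
    "build_chain",
    "maxwell_velocities",
    "integrate",
    "equilibrate_then_sample",
    "SampleResult",
]

_THERMOSTATS = {"none": 0, "nose_hoover": 1, "langevin": 2}


class PlacementError(ValueError):
    """Requested initial conformation does not fit into the post array."""


class IntegrationError(RuntimeError):
    """Integration failed (overstretched bond, bead inside post, or NaN)."""

    def __init__(self, message: str, step: int):
        super().__init__(f"{message} at step {step}")
        self.step = step


@dataclass(frozen=True)
class SimulationParams:
    """Integrator and thermostat settings (reduced units).

    dt = 0.005 tau and a Nose-Hoover relaxation time of 0.1 tau are the
    reference values of the model; n_* are step counts, with observables
    sampled every ``sample_every`` steps.
    """

    dt: float = 0.005
    T: float = 1.0
    thermostat: str = "nose_hoover"
    relaxation: float = 0.1  # Nose-Hoover time constant (tau)
    friction: float = 1.0  # Langevin gamma (1/tau)
    seed: int = 0
    n_equil: int = 100_000
    n_prod: int = 1_000_000
    sample_every: int = 1000
    skin: float = 0.3  # Verlet-list skin (sigma)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.thermostat not in _THERMOSTATS:
            raise ValueError(
                f"unknown thermostat {self.thermostat!r}; "
                f"choose from {sorted(_THERMOSTATS)}"
            )


@dataclass
class Trajectory:
    """Sampled frames plus energy bookkeeping from one integration run."""

    frames: np.ndarray  # (n_frames, N, 3)
    potential_energy: np.ndarray
    kinetic_energy: np.ndarray
    steps: np.ndarray
    final_state: ChainState
    topology: str
    dt: float
    seed: int

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential_energy + self.kinetic_energy

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def build_chain(
    topology: str,
    N: int,
    orientation: str = "parallel",
    array: PostArrayGeometry | None = None,
    l: float = BOND_LENGTH,
) -> ChainState:
    """Straightened initial conformation.

    Linear chains start as a fully straightened backbone at bond length
    ``l``; circular chains as a completely prolonged rectangular loop with
    side lengths ~L/2 and ``l``.  The principal axis is placed parallel or
    perpendicular to the post axes; inside an array the chain is laid
    through interstitial cell centers, and a perpendicular placement that
    cannot avoid the post cores raises :class:`PlacementError`.
    """
    if N < 3:
        raise ValueError("N must be at least 3")
    if orientation not in ("parallel", "perpendicular"):
        raise ValueError("orientation must be 'parallel' or 'perpendicular'")
    if topology == "linear":
        t = np.arange(N) * l
        t -= t.mean()
        long_axis = t
        lat = np.zeros(N)
    elif topology == "circular":
        if N % 2:
            raise ValueError("circular chains require an even number of beads")
        half = N // 2
        t = np.empty(N)
        lat = np.empty(N)
        t[:half] = np.arange(half) * l
        lat[:half] = 0.0
        t[half:] = t[half - 1] - np.arange(half) * l
        lat[half:] = l
        t -= t[:half].mean()
        long_axis = t
    else:
        raise ValueError(f"unknown topology {topology!r}")

    pos = np.zeros((N, 3))
    if array is not None:
        center = array.cell_center(0, 0)
        if orientation == "parallel":
            pos[:, 0] = long_axis
            pos[:, 1] = center[0]
            pos[:, 2] = center[1] + lat - lat.mean()
        else:
            # principal axis along y, running across cells through passages
            span = long_axis.max() - long_axis.min()
            if array.w_p < array.w and span > array.S_p:
                raise PlacementError(
                    "perpendicular placement spans several cells but the "
                    f"passage width w_p={array.w_p:.3g} is impassable"
                )
            pos[:, 1] = center[0] + long_axis
            pos[:, 2] = center[1] + lat - lat.mean()
        _check_post_clearance(pos, array)
    else:
        axis = 0 if orientation == "parallel" else 1
        pos[:, axis] = long_axis
        pos[:, 2] = lat - lat.mean()
    state = ChainState(topology=topology, positions=pos)
    state.validate()
    return state


def _check_post_clearance(pos: np.ndarray, array: PostArrayGeometry) -> None:
    oy, oz = array.origin
    y = pos[:, 1] - oy
    z = pos[:, 2] - oz
    fy = np.abs(y / array.S_p - np.round(y / array.S_p)) * array.S_p
    fz = np.abs(z / array.S_p - np.round(z / array.S_p)) * array.S_p
    r = np.hypot(fy, fz)
    if np.any(r <= array.D_p / 2.0):
        raise PlacementError("initial conformation places a bead inside a post core")


def maxwell_velocities(
    N: int, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at temperature T with zero total momentum."""
    v = rng.normal(0.0, math.sqrt(T), size=(N, 3))
    v -= v.mean(axis=0)
    return v


def integrate(
    chain: ChainState,
    array: PostArrayGeometry | None,
    ff: ForceFieldParams,
    sim: SimulationParams,
    n_steps: int | None = None,
    chi0: float = 0.0,
) -> Trajectory:
    """Advance the chain ``n_steps`` (default ``sim.n_prod``) leap-frog steps.

    The chain state is advanced in place (positions and half-step
    velocities); the returned trajectory holds frames sampled every
    ``sim.sample_every`` steps with matching potential and kinetic
    energies.  Deterministic given (seed, thermostat, step counts).
    """
    if n_steps is None:
        n_steps = sim.n_prod
    chain.validate()
    pos = np.ascontiguousarray(chain.positions)
    vel = np.ascontiguousarray(chain.velocities)
    if array is not None:
        has_array, S_p, Dp_half = True, array.S_p, array.D_p / 2.0
        oy, oz = array.origin
    else:
        has_array, S_p, Dp_half, oy, oz = False, 1.0, 0.0, 0.0, 0.0
    frames, pe, ke, chi, status, fail_step = _kernels.run_md(
        pos,
        vel,
        chain.circular,
        ff.bend_k,
        ff.kappa,
        ff.R_o,
        has_array,
        S_p,
        Dp_half,
        oy,
        oz,
        sim.dt,
        sim.T,
        _THERMOSTATS[sim.thermostat],
        sim.relaxation,
        sim.friction,
        n_steps,
        sim.sample_every,
        sim.seed % 2**31,
        sim.skin,
        chi0,
    )
    if status == _kernels.OVERSTRETCH:
        raise IntegrationError("overstretched bond", fail_step)
    if status == _kernels.INSIDE_POST:
        raise IntegrationError("bead inside post core", fail_step)
    if status == _kernels.NAN:
        raise IntegrationError("non-finite energy", fail_step)
    if status == _kernels.PAIR_OVERFLOW:
        raise IntegrationError("neighbor list overflow", fail_step)
    final = ChainState(topology=chain.topology, positions=pos, velocities=vel)
    steps = np.arange(frames.shape[0]) * sim.sample_every
    return Trajectory(
        frames=frames,
        potential_energy=pe,
        kinetic_energy=ke,
        steps=steps,
        final_state=final,
        topology=chain.topology,
        dt=sim.dt,
        seed=sim.seed,
    )


@dataclass
class SampleResult:
    """Production-phase frames and convergence metadata."""

    trajectory: Trajectory
    converged: bool
    equil_rg: np.ndarray = field(default=None)  # type: ignore[assignment]


def _radius_of_gyration(frames: np.ndarray) -> np.ndarray:
    com = frames.mean(axis=1, keepdims=True)
    return np.sqrt(((frames - com) ** 2).sum(axis=2).mean(axis=1))


def equilibrate_then_sample(
    chain: ChainState,
    array: PostArrayGeometry | None,
    ff: ForceFieldParams,
    sim: SimulationParams,
    rtol: float = 0.05,
    n_chunks: int = 8,
) -> SampleResult:
    """Equilibrate with a block-stationarity check, then run production.

    Equilibration proceeds in ``n_chunks`` chunks of ``sim.n_equil /
    n_chunks`` steps; it is considered converged once the chunk means of
    both the radius of gyration and the potential energy change by less
    than ``rtol`` (relative) between two consecutive chunks.  If the check
    never passes the full ``sim.n_equil`` steps are still run and the
    result is flagged ``converged=False``.
    """
    rng = np.random.default_rng(sim.seed)
    if not chain.velocities.any():
        chain.velocities = maxwell_velocities(chain.N, sim.T, rng)

    chunk = max(sim.n_equil // n_chunks, 1)
    prev_rg = prev_pe = None
    converged = False
    rg_means = []
    for k in range(n_chunks):
        sub = replace(sim, seed=int(rng.integers(2**31)))
        traj = integrate(chain, array, ff, sub, n_steps=chunk)
        chain = traj.final_state
        rg = float(_radius_of_gyration(traj.frames).mean())
        pe = float(traj.potential_energy.mean())
        rg_means.append(rg)
        if prev_rg is not None and not converged:
            drg = abs(rg - prev_rg) / max(abs(prev_rg), 1e-12)
            dpe = abs(pe - prev_pe) / max(abs(prev_pe), 1e-12)
            if drg < rtol and dpe < rtol:
                converged = True
        prev_rg, prev_pe = rg, pe
        if converged and k >= 1:
            break

    prod = replace(sim, seed=int(rng.integers(2**31)))
    traj = integrate(chain, array, ff, prod, n_steps=sim.n_prod)
    return SampleResult(
        trajectory=traj, converged=converged, equil_rg=np.array(rg_means)
    )
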