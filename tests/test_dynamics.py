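"""Initial conformations and leap-frog integration (NVE, NH, Langevin)."""

import numpy as np
import pytest
from scipy import stats

from nanopost.chain import ChainState
from nanopost.dynamics import (
    PlacementError,
    SimulationParams,
    build_chain,
    integrate,
    equilibrate_then_sample,
    maxwell_velocities,
)
from nanopost.forcefield import ForceFieldParams
from nanopost.geometry import PostArrayGeometry


class TestBuildChain:
    def test_linear_end_to_end(self):
        chain = build_chain("linear", 100)
        r = chain.positions[-1] - chain.positions[0]
        assert np.linalg.norm(r) == pytest.approx(99 * 0.97)
        assert chain.n_bonds == 99

    def test_circular_rectangle(self):
        chain = build_chain("circular", 100)
        assert chain.n_bonds == 100
        x = chain.positions[:, 0]
        assert x.max() - x.min() == pytest.approx(49 * 0.97)
        # two strands separated by one bond length
        z = chain.positions[:, 2]
        assert np.ptp(z) == pytest.approx(0.97)
        np.testing.assert_allclose(chain.bond_lengths(), 0.97, rtol=1e-12)

    def test_built_chains_are_valid(self, ff_semiflexible):
        from nanopost.forcefield import total_energy_forces

        for topology in ("linear", "circular"):
            chain = build_chain(topology, 50)
            assert chain.bond_lengths().max() < 1.5
            e, _ = total_energy_forces(chain, None, ff_semiflexible)
            assert np.isfinite(e)

    def test_in_array_placement_avoids_post_cores(self, array12):
        chain = build_chain("linear", 60, "parallel", array12)
        # yz distance of every bead to every nearby post center > D_p/2
        from nanopost.geometry import post_surface_distances

        for p in chain.positions:
            dists = [r for _, r in post_surface_distances(p[1:], array12)]
            assert min(dists) > array12.D_p / 2.0

    def test_perpendicular_impassable_raises(self):
        array = PostArrayGeometry(S_p=12.0, d_p=11.9)  # w_p = 0.1 < w
        with pytest.raises(PlacementError):
            build_chain("linear", 100, "perpendicular", array)

    def test_odd_circular_rejected(self):
        with pytest.raises(ValueError):
            build_chain("circular", 101)


def _nve_energy_metrics(dt, n_steps=10_000, N=50, seed=4):
    """Secular drift fraction and RMS fluctuation of NVE total energy."""
    ff = ForceFieldParams(b=20.0)
    chain = build_chain("linear", N)
    chain.velocities = maxwell_velocities(N, 1.0, np.random.default_rng(seed))
    # brief thermostatted relaxation, then NVE
    warm = SimulationParams(thermostat="nose_hoover", seed=seed, sample_every=500)
    integrate(chain, None, ff, warm, n_steps=20_000)
    sim = SimulationParams(dt=dt, thermostat="none", seed=seed, sample_every=10)
    traj = integrate(chain, None, ff, sim, n_steps=n_steps)
    E = traj.total_energy
    fit = stats.linregress(traj.steps.astype(float), E)
    drift = abs(fit.slope) * n_steps / abs(E.mean())
    rms = float(np.std(E - fit.intercept - fit.slope * traj.steps) / abs(E.mean()))
    return drift, rms


class TestIntegration:
    def test_nve_energy_conservation(self):
        """Leap-frog conserves energy: relative drift < 1e-4 over 1e4 steps."""
        drift, _ = _nve_energy_metrics(dt=0.005)
        assert drift < 1e-4

    def test_nve_second_order_dt_scaling(self):
        """Energy fluctuations shrink ~4x when the timestep is halved."""
        _, rms1 = _nve_energy_metrics(dt=0.005)
        _, rms2 = _nve_energy_metrics(dt=0.0025)
        assert 2.5 < rms1 / rms2 < 6.5

    def test_nve_conserves_axial_momentum_in_array(self, array12, ff_flexible):
        """Posts exert no force along their axes."""
        chain = build_chain("linear", 30, "parallel", array12)
        chain.velocities = maxwell_velocities(30, 1.0, np.random.default_rng(5))
        chain.velocities[:, 0] += 0.1  # nonzero axial momentum
        px0 = chain.velocities[:, 0].sum()
        sim = SimulationParams(thermostat="none", seed=5, sample_every=1000)
        traj = integrate(chain, array12, ff_flexible, sim, n_steps=5_000)
        assert traj.final_state.velocities[:, 0].sum() == pytest.approx(px0, abs=1e-9)

    @pytest.mark.parametrize("thermostat", ["nose_hoover", "langevin"])
    def test_kinetic_temperature(self, thermostat):
        """Time-averaged kinetic temperature equals the set point within 3 SE."""
        N = 50
        ff = ForceFieldParams(b=0.0)
        chain = build_chain("linear", N)
        chain.velocities = maxwell_velocities(N, 1.0, np.random.default_rng(6))
        sim = SimulationParams(thermostat=thermostat, seed=6, sample_every=100)
        integrate(chain, None, ff, sim, n_steps=20_000)
        traj = integrate(chain, None, ff, sim, n_steps=200_000)
        # NH conserves the (zero) COM momentum: 3N-3 DOF; Langevin noise
        # thermalizes the COM as well: 3N DOF.
        dof = 3 * N - 3 if thermostat == "nose_hoover" else 3 * N
        T = 2.0 * traj.kinetic_energy / dof
        from nanopost.observables import block_stats

        mean, sem = block_stats(T)
        assert abs(mean - 1.0) < 3 * sem + 0.01

    def test_determinism_same_seed(self, ff_flexible):
        runs = []
        for _ in range(2):
            chain = build_chain("linear", 20)
            chain.velocities = maxwell_velocities(20, 1.0, np.random.default_rng(7))
            sim = SimulationParams(seed=7, sample_every=100)
            traj = integrate(chain, None, ff_flexible, sim, n_steps=2_000)
            runs.append(traj.frames.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_chain_in_array_never_enters_post_core(self, ff_flexible):
        array = PostArrayGeometry(S_p=12.0, d_p=4.9)
        chain = build_chain("linear", 40, "parallel", array)
        chain.velocities = maxwell_velocities(40, 1.0, np.random.default_rng(8))
        sim = SimulationParams(seed=8, sample_every=200)
        traj = integrate(chain, array, ff_flexible, sim, n_steps=50_000)
        # min yz distance of any sampled bead to the nearest post center
        yz = traj.frames[:, :, 1:]
        frac = yz / array.S_p
        near = np.abs(frac - np.round(frac)) * array.S_p
        rmin = np.hypot(near[..., 0], near[..., 1]).min()
        assert rmin > array.D_p / 2.0

    def test_circular_topology_integrates(self, ff_semiflexible):
        chain = build_chain("circular", 40)
        chain.velocities = maxwell_velocities(40, 1.0, np.random.default_rng(9))
        sim = SimulationParams(seed=9, sample_every=500)
        traj = integrate(chain, None, ff_semiflexible, sim, n_steps=10_000)
        assert traj.final_state.bond_lengths().max() < 1.5
        assert traj.final_state.n_bonds == 40


class TestEquilibrateThenSample:
    def test_flexible_free_chain_bond_length(self):
        """<l> ~ 0.97 for the FENE + WCA bond at T = 1 (short check run)."""
        chain = build_chain("linear", 50)
        ff = ForceFieldParams(b=0.0)
        sim = SimulationParams(
            seed=10, n_equil=40_000, n_prod=200_000, sample_every=500
        )
        result = equilibrate_then_sample(chain, None, ff, sim)
        lengths = np.array(
            [
                np.linalg.norm(np.diff(f, axis=0), axis=1).mean()
                for f in result.trajectory.frames
            ]
        )
        assert lengths.mean() == pytest.approx(0.97, abs=0.01)

    def test_two_orientations_agree(self):
        """Parallel and perpendicular starts give consistent span."""
        from nanopost.observables import block_stats, span

        array = PostArrayGeometry(S_p=12.0, d_p=4.9)
        ff = ForceFieldParams(b=0.0)
        results = []
        for orientation in ("parallel", "perpendicular"):
            chain = build_chain("linear", 40, orientation, array)
            sim = SimulationParams(
                seed=11, n_equil=100_000, n_prod=200_000, sample_every=500
            )
            res = equilibrate_then_sample(chain, array, ff, sim)
            results.append(block_stats(span(res.trajectory.frames)))
        (m1, s1), (m2, s2) = results
        assert abs(m1 - m2) < 3.0 * np.hypot(s1, s2) + 0.5
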