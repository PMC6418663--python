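"""Span, gyration, occupation, structure factor, orientation correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopost.fixtures import (
    ideal_wlc,
    planted_cells,
    rectangle_ring,
    regular_polygon_ring,
    rod,
    two_bead,
)
from nanopost.geometry import PostArrayGeometry
from nanopost.observables import (
    OrientationCorrelation,
    block_stats,
    estimate_persistence_length,
    gyration_components,
    occupation_number,
    occupation_series,
    orientation_correlation,
    span,
    structure_factor,
    structure_factor_histogram,
)


class TestSpan:
    def test_rod_along_x(self):
        assert span(rod(100, l=0.97, axis=0))[0] == pytest.approx(99 * 0.97)

    def test_rod_along_y_has_zero_axial_span(self):
        assert span(rod(100, l=0.97, axis=1))[0] == pytest.approx(0.0)

    def test_two_frames_average(self):
        frames = np.stack([rod(10, l=1.0), rod(10, l=0.5)])
        a, b = span(frames)
        assert (a + b) / 2 == pytest.approx((9.0 + 4.5) / 2)

    def test_stretched_chain_span_approaches_end_to_end(self):
        # mild transverse wiggle on a strongly x-stretched chain
        pos = rod(50, l=0.97)
        pos[:, 1] = 0.1 * np.sin(np.arange(50))
        e2e = np.linalg.norm(pos[-1] - pos[0])
        assert span(pos)[0] == pytest.approx(e2e, rel=1e-3)


class TestGyration:
    def test_three_collinear_beads(self):
        g = gyration_components(np.array([[-1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]]))
        assert g["R_g"][0] ** 2 == pytest.approx(2.0 / 3.0)
        assert g["R_gyz"][0] == pytest.approx(0.0)

    def test_isotropic_cloud_components(self, rng):
        pts = rng.normal(size=(1, 30000, 3))
        g = gyration_components(pts)
        # R_gx ~ R_gyz ~ R_g / sqrt(3) for an isotropic cloud
        assert g["R_gx"][0] == pytest.approx(g["R_g"][0] / math.sqrt(3), rel=0.03)
        assert g["R_gyz"][0] == pytest.approx(g["R_g"][0] / math.sqrt(3), rel=0.03)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_decomposition_identity(self, seed):
        """R_gx^2 + 2 R_gyz^2 = R_g^2 for any frame."""
        pts = np.random.default_rng(seed).normal(size=(5, 3)) * 3.0
        g = gyration_components(pts)
        assert g["R_gx"][0] ** 2 + 2 * g["R_gyz"][0] ** 2 == pytest.approx(
            g["R_g"][0] ** 2, rel=1e-12
        )


class TestOccupation:
    def test_single_cell(self, array12):
        frame = planted_cells([(0, 0)], array12, beads_per_cell=5)
        assert occupation_number(frame, array12) == 1

    def test_two_adjacent_cells(self, array12):
        frame = planted_cells([(0, 0), (1, 0)], array12)
        assert occupation_number(frame, array12) == 2

    def test_planted_2x2_block(self, array12):
        cells = [(0, 0), (1, 0), (0, 1), (1, 1)]
        frame = planted_cells(cells, array12, beads_per_cell=3, jitter=2.0, seed=3)
        assert occupation_number(frame, array12) == 4

    def test_passage_bead_counts_toward_containing_cell(self, array12):
        # bead in the passage between cells (0,0) and (1,0), on the (1,0) side
        y = 1.0 * array12.S_p + 0.01
        frame = np.array([[0.0, y, array12.S_p / 2.0]])
        assert occupation_number(frame, array12) == 1
        assert occupation_number(
            np.vstack([frame, np.asarray([[0, *array12.cell_center(0, 0)]])]),
            array12,
        ) == 2

    def test_invariance_under_relabeling_and_lattice_translation(self, rng, array12):
        frame = planted_cells([(0, 0), (2, 1), (1, 1)], array12, 4, jitter=4.0, seed=5)
        n0 = occupation_number(frame, array12)
        perm = rng.permutation(frame.shape[0])
        assert occupation_number(frame[perm], array12) == n0
        shifted = frame + np.array([0.0, 3 * array12.S_p, -2 * array12.S_p])
        assert occupation_number(shifted, array12) == n0

    def test_series(self, array12):
        frames = np.stack(
            [
                planted_cells([(0, 0)], array12, 2),
                planted_cells([(0, 0), (1, 0)], array12),
            ]
        )
        np.testing.assert_array_equal(occupation_series(frames, array12), [1.0, 2.0])


class TestStructureFactor:
    def test_low_q_normalization(self, rng):
        frame = rng.normal(size=(25, 3))
        res = structure_factor(frame, np.array([1e-6]))
        assert res.S[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_beads_closed_form(self):
        # S(q) = (1 + sinc(q r))/2; at q r = pi the sinc vanishes
        r = 2.0
        q = np.array([math.pi / r, 1.3, 0.7])
        res = structure_factor(two_bead(r), q)
        expected = 0.5 * (1.0 + np.sinc(q * r / math.pi))
        np.testing.assert_allclose(res.S, expected, rtol=1e-12)
        assert res.S[0] == pytest.approx(0.5)

    def test_histogram_path_matches_direct_sum(self, rng):
        frame = rng.normal(size=(20, 3)) * 2.0
        q = np.geomspace(0.1, 10.0, 50)
        direct = structure_factor(frame, q)
        binned = structure_factor_histogram(frame, q, n_bins=20000)
        np.testing.assert_allclose(binned.S, direct.S, atol=1e-3)

    def test_bounds(self, rng):
        frames = rng.normal(size=(3, 15, 3))
        q = np.geomspace(0.05, 20.0, 60)
        res = structure_factor(frames, q)
        assert np.all(res.S > 0.0) and np.all(res.S <= 1.0 + 1e-12)

    def test_rejects_nonpositive_q(self, rng):
        with pytest.raises(ValueError):
            structure_factor(rng.normal(size=(5, 3)), np.array([0.0, 1.0]))


class TestOrientationCorrelation:
    def test_straight_rod_fully_correlated(self):
        corr = orientation_correlation(rod(20), "linear")
        np.testing.assert_allclose(corr.C, 1.0, atol=1e-12)

    @pytest.mark.parametrize("N", [4, 7, 12])
    def test_regular_polygon_closed_form(self, N):
        corr = orientation_correlation(regular_polygon_ring(N), "circular")
        expected = np.cos(2 * math.pi * corr.n_s / N)
        np.testing.assert_allclose(corr.C, expected, atol=1e-10)

    def test_square_ring_values(self):
        corr = orientation_correlation(regular_polygon_ring(4), "circular")
        assert corr.C[1] == pytest.approx(0.0, abs=1e-12)
        assert corr.C[2] == pytest.approx(-1.0)

    def test_ring_inversion_symmetry(self, rng):
        # noisy ring: wrap-around averaging makes C(n) = C(N-n) exactly
        pos = regular_polygon_ring(16) + rng.normal(0, 0.05, (16, 3))
        corr = orientation_correlation(pos, "circular")
        nb = 16
        for ns in range(nb + 1):
            assert corr.C[ns] == pytest.approx(corr.C[nb - ns], rel=1e-12)

    def test_rectangle_ring_has_antiparallel_strands(self):
        corr = orientation_correlation(rectangle_ring(40), "circular")
        assert corr.C[20] == pytest.approx(-0.9, abs=0.1)  # opposite strand


class TestPersistenceLength:
    def test_exact_exponential_recovered(self):
        ns = np.arange(0, 30)
        P_true, l = 19.7, 0.97
        corr = OrientationCorrelation(
            n_s=ns, C=np.exp(-l * ns / P_true), topology="linear"
        )
        P, err = estimate_persistence_length(corr, l=l)
        assert P == pytest.approx(P_true, rel=1e-10)
        assert err < 1e-8

    def test_ideal_wlc_parameter_recovery(self):
        """Planted persistence length recovered from sampled conformations."""
        frames = ideal_wlc(N=500, seed=42, P=10.0, l=0.97, n_frames=60)
        corr = orientation_correlation(frames, "linear")
        P, err = estimate_persistence_length(corr, l=0.97)
        assert P == pytest.approx(10.0, rel=0.05)

    def test_too_few_points_raises(self):
        corr = OrientationCorrelation(
            n_s=np.arange(5), C=np.array([1.0, 0.3, 0.1, 0.05, 0.01]),
            topology="linear",
        )
        with pytest.raises(ValueError):
            estimate_persistence_length(corr)


class TestBlockStats:
    def test_constant_series(self):
        mean, sem = block_stats(np.full(100, 3.5))
        assert mean == 3.5 and sem == 0.0

    def test_sem_scale_on_iid_data(self, rng):
        x = rng.normal(size=10000)
        mean, sem = block_stats(x, n_blocks=10)
        assert sem == pytest.approx(x.std() / 100.0, rel=0.8)
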