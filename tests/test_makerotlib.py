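"""Rotamer-library generation: grids, minimization, clustering, probabilities."""

import numpy as np
import pytest

from rotlib import fixtures
from rotlib.energy import DipeptideScorer
from rotlib.makerotlib import (
    KT_ROOM,
    MakeRotLibConfig,
    build_bin,
    build_library,
    chi_vector_distance,
    distinct_minima_count,
    energies_to_probabilities,
    estimate_chi_sd,
    kmeans_chi,
    minimize_chi,
    phi_psi_grid,
    probability_to_energy,
    seed_chi_grid,
    select_rotamers,
)


class TestGrids:
    @pytest.mark.parametrize("spacing,expected", [(10.0, 1296), (180.0, 4), (90.0, 16)])
    def test_bin_counts(self, spacing, expected):
        bins = phi_psi_grid(spacing)
        assert len(bins) == expected
        assert len(set(bins)) == expected
        for p, s in bins:
            assert -180 < p <= 180 and -180 < s <= 180

    def test_non_divisor_spacing_rejected(self):
        with pytest.raises(ValueError):
            phi_psi_grid(7.0)

    def test_seed_grid_counts(self, toy1, toy2):
        assert seed_chi_grid(toy1[0], 5.0).shape == (72, 1)
        assert seed_chi_grid(toy2[0], 5.0).shape == (72 * 72, 2)

    def test_symmetric_chi_seed_grid(self):
        text = fixtures.FIXTURE_TOPOLOGIES["TOY1"].replace(
            "chi_periods: [360]", "chi_periods: [180]")
        top = fixtures.parse_topology(text)
        assert seed_chi_grid(top, 5.0).shape == (36, 1)

    def test_zero_chi_topology_yields_single_seed(self):
        top = fixtures.load_topology("ALA")
        assert seed_chi_grid(top, 5.0).shape == (1, 0)


class TestMinimizeChi:
    def test_exact_minimum_does_not_move(self, toy1):
        top, prm = toy1
        sc = DipeptideScorer(top, prm, -60, -40)
        x, e = minimize_chi(sc, np.array([60.0]))
        assert x[0] == pytest.approx(60.0, abs=1e-9)

    def test_converges_to_nearest_minimum(self, toy1):
        top, prm = toy1
        sc = DipeptideScorer(top, prm, -60, -40)
        x, _ = minimize_chi(sc, np.array([50.0]))
        assert x[0] == pytest.approx(60.0, abs=0.1)  # not 180

    def test_descent_property(self, val):
        top, prm = val
        sc = DipeptideScorer(top, prm, -110, 130)
        seeds = np.arange(-180.0, 180.0, 20.0)[:, None]
        e0 = sc.energy(seeds)
        prev = np.asarray(e0, float)
        x = seeds
        for _ in range(25):
            x, e = minimize_chi(sc, x, steps=1)
            assert np.all(e <= prev + 1e-9)
            prev = e


class TestKmeans:
    def test_single_point_single_seed(self):
        labels, cent, _ = kmeans_chi([[42.0]], [[0.0]], [360])
        assert labels.tolist() == [0]
        assert cent[0][0] == pytest.approx(42.0)

    def test_wraparound_circular_mean(self):
        labels, cent, _ = kmeans_chi([[179.0], [-179.0]], [[170.0]], [360])
        assert abs(cent[0][0]) == pytest.approx(180.0, abs=1e-9)

    def test_three_well_synthetic_matches_nearest_center_oracle(self, rng):
        centers = np.array([-60.0, 60.0, 180.0])
        pts = np.concatenate([
            rng.normal(c, 5.0, size=40) for c in centers
        ])[:, None]
        labels, cent, _ = kmeans_chi(pts, centers[:, None], [360])
        # oracle: nearest true center under circular distance
        d = np.abs(((pts - centers[None, :] + 180) % 360) - 180)
        oracle = np.argmin(d, axis=1)
        assert np.array_equal(labels, oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kmeans_chi(np.zeros((0, 1)), [[0.0]], [360])

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError):
            kmeans_chi([[1.0]], [[0.0], [0.0]], [360])


class TestSelectRotamers:
    def test_singleton_cluster(self):
        out = select_rotamers([[10.0]], [3.0], np.array([0]), 1)
        assert out[0][1] == 3.0

    def test_lowest_energy_member_wins(self):
        pts = [[1.0], [2.0], [3.0]]
        out = select_rotamers(pts, [3.0, 1.0, 2.0], np.array([0, 0, 0]), 1)
        assert out[0][0][0] == 2.0 and out[0][1] == 1.0

    def test_ties_break_by_smallest_chi(self):
        pts = [[30.0, 5.0], [-10.0, 99.0], [-10.0, 50.0]]
        out = select_rotamers(pts, [1.0, 1.0, 1.0], np.array([0, 0, 0]), 1)
        assert out[0][0].tolist() == [-10.0, 50.0]


class TestChiSd:
    def test_harmonic_closed_form(self):
        a = 0.005  # kcal/mol/deg^2

        class Harmonic:
            def energy(self, chis):
                chis = np.atleast_2d(np.asarray(chis, float))
                return (a * chis[:, 0] ** 2)

        sds, flat = estimate_chi_sd(Harmonic(), np.array([0.0]), rise=0.5)
        assert sds[0] == pytest.approx(np.sqrt(0.5 / a), abs=0.05)  # 10 deg
        assert not flat

    def test_threefold_torsion_matches_analytic_inversion(self, toy1):
        top, prm = toy1
        sc = DipeptideScorer(top, prm, -60, -40)
        sds, flat = estimate_chi_sd(sc, np.array([60.0]), rise=0.5)
        # K(1 - cos(3 delta)) = 0.5 with K = 1 -> delta = arccos(0.5)/3
        expected = np.degrees(np.arccos(0.5)) / 3.0
        assert sds[0] == pytest.approx(expected, abs=0.05)
        assert not flat

    def test_symmetric_well_equal_directions(self, toy1):
        top, prm = toy1
        sc = DipeptideScorer(top, prm, -60, -40)
        sds_plus, _ = estimate_chi_sd(sc, np.array([60.0]))
        sds_minus, _ = estimate_chi_sd(sc, np.array([-60.0]))
        assert sds_plus[0] == pytest.approx(sds_minus[0], abs=1e-6)

    def test_flat_direction_returns_cap_with_flag(self):
        class Flat:
            def energy(self, chis):
                chis = np.atleast_2d(np.asarray(chis, float))
                return np.zeros(len(chis))

        sds, flat = estimate_chi_sd(Flat(), np.array([0.0]), rise=0.5, cap=60.0)
        assert sds[0] == 60.0 and flat


class TestProbabilities:
    def test_equal_energies_uniform(self):
        p = energies_to_probabilities([2.0, 2.0, 2.0])
        np.testing.assert_allclose(p, 1 / 3, atol=1e-12)

    def test_kT_ln2_gap_gives_two_thirds(self):
        p = energies_to_probabilities([0.0, KT_ROOM * np.log(2.0)])
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_normalization(self, rng):
        p = energies_to_probabilities(rng.uniform(0, 10, size=17))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probability_one_maps_to_zero_energy(self):
        assert probability_to_energy(1.0) == 0.0

    def test_round_trip_preserves_energy_differences(self, rng):
        e = rng.uniform(0, 5, size=6)
        p = energies_to_probabilities(e)
        back = probability_to_energy(p)
        diff = (back - back[0]) - (e - e[0])
        np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    def test_halving_probability_costs_kT_ln2(self):
        e1 = probability_to_energy(0.5, p_ref=1.0)
        e2 = probability_to_energy(0.25, p_ref=1.0)
        assert e2 - e1 == pytest.approx(KT_ROOM * np.log(2.0), abs=1e-12)


class TestBuildLibrary:
    def test_toy1_analytic_wells(self, toy1):
        top, prm = toy1
        lib = build_library(top, prm, MakeRotLibConfig(phi_psi_spacing=180.0))
        assert len(lib.bins) == 4
        for b in lib.bins.values():
            chis = sorted(float(r.chi_means[0]) for r in b.rotamers)
            assert chis == pytest.approx([-60.0, 60.0, 180.0], abs=0.5)
            for r in b.rotamers:
                assert r.probability == pytest.approx(1 / 3, abs=1e-9)
            assert b.check_normalized()

    def test_equal_rotamer_count_across_bins(self, toy2):
        top, prm = toy2
        lib = build_library(top, prm, MakeRotLibConfig(phi_psi_spacing=180.0))
        assert lib.n_rotamers() == 9

    def test_deterministic(self, toy1):
        top, prm = toy1
        cfg = MakeRotLibConfig(phi_psi_spacing=180.0)
        a = build_library(top, prm, cfg)
        b = build_library(top, prm, cfg)
        for key in a.bins:
            for ra, rb in zip(a.bins[key].rotamers, b.bins[key].rotamers):
                np.testing.assert_array_equal(ra.chi_means, rb.chi_means)
                assert ra.probability == rb.probability

    def test_selection_optimality(self, val):
        """Every reported rotamer energy is the minimum of its cluster."""
        top, prm = val
        sc = DipeptideScorer(top, prm, -60, -40)
        seeds = seed_chi_grid(top, 10.0)
        minimized, energies = minimize_chi(sc, seeds)
        labels, _, _ = kmeans_chi(minimized, np.array([[-60.0], [60.0], [180.0]]),
                                  top.chi_periods)
        for chi, e, size in select_rotamers(minimized, energies, labels, 3):
            members = energies[labels == labels[np.argmin(
                chi_vector_distance(minimized, chi, np.array([360.0])))]]
            assert e <= members.min() + 1e-12


class TestDistinctMinima:
    def test_toy1_three_wells(self, toy1):
        assert distinct_minima_count(*toy1, -60, -40) == 3

    def test_toy2_nine_wells(self, toy2):
        assert distinct_minima_count(*toy2, -60, -40, grid_spacing=10.0) == 9

    def test_valine_matches_dense_grid_basin_oracle(self, val):
        top, prm = val
        phi, psi = -110.0, 130.0
        n = distinct_minima_count(top, prm, phi, psi)
        # oracle: 1-degree scan, count strict local minima of the periodic curve
        sc = DipeptideScorer(top, prm, phi, psi)
        grid = np.arange(-180.0, 180.0, 1.0)[:, None]
        e = sc.energy(grid)
        m = len(grid)
        basins = sum(
            1 for i in range(m)
            if e[i] < e[(i - 1) % m] and e[i] < e[(i + 1) % m]
        )
        assert n == basins == 3
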