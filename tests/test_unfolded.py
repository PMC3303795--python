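"""Unfolded-state estimation: ensemble sampling, chains, term averages."""

import numpy as np
import pytest

from rotlib import fixtures
from rotlib.chem import measure_dihedral
from rotlib.energy import EnergyBreakdown, WeightSet, total_energy
from rotlib.makerotlib import MakeRotLibConfig, build_library
from rotlib.unfolded import (
    ChainScorer,
    FragmentEnsembleSpec,
    UnfoldedEnergyTable,
    build_chain,
    estimate_unfolded,
    generate_fragment_ensemble,
    unfolded_energy,
)


class TestEnsemble:
    def test_seeded_determinism(self):
        spec = FragmentEnsembleSpec(n_fragments=1, seed=42)
        a = generate_fragment_ensemble(spec)
        b = generate_fragment_ensemble(spec)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (1, 5, 2)

    def test_mixture_weights_recovered_at_large_n(self):
        spec = FragmentEnsembleSpec(n_fragments=2000, seed=0)
        ens = generate_fragment_ensemble(spec)
        phis = ens[..., 0].ravel()
        # residues within 3 sigma of the alpha mean and not plausibly beta
        alpha_frac = np.mean(np.abs(phis - (-63.0)) < 30.0)
        # alpha weight 0.4 plus the uniform component's mass in that window
        expected = 0.40 + 0.20 * (60.0 / 360.0)
        assert alpha_frac == pytest.approx(expected, abs=0.02)

    def test_degenerate_all_alpha_mixture(self):
        spec = FragmentEnsembleSpec(n_fragments=200, seed=1,
                                    alpha=(1.0, -63.0, -43.0, 10.0),
                                    beta=(0.0, -120.0, 130.0, 15.0))
        ens = generate_fragment_ensemble(spec)
        z = np.abs(ens[..., 0] - (-63.0)) / 10.0
        assert np.max(z) < 5.0
        assert np.mean(z < 3.0) > 0.99

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            FragmentEnsembleSpec(alpha=(0.9, -63, -43, 10),
                                 beta=(0.4, -120, 130, 15))


class TestChain:
    def test_backbone_torsions_round_trip(self):
        ala = fixtures.load_topology("ALA")
        val = fixtures.load_topology("VAL")
        phis = np.array([-63.0, -110.0, -70.0])
        psis = np.array([-43.0, 130.0, -35.0])
        chain = build_chain([ala, val, ala], phis, psis,
                            [np.zeros(0), np.array([175.0]), np.zeros(0)])
        pos = {k: c for k, c in zip(chain.atom_names, chain.coords)}
        # interior residue phi/psi measured from the built coordinates
        phi1 = measure_dihedral(pos[(0, "C")], pos[(1, "N")], pos[(1, "CA")],
                                pos[(1, "C")])
        psi1 = measure_dihedral(pos[(1, "N")], pos[(1, "CA")], pos[(1, "C")],
                                pos[(2, "N")])
        omega = measure_dihedral(pos[(0, "CA")], pos[(0, "C")], pos[(1, "N")],
                                 pos[(1, "CA")])
        assert phi1 == pytest.approx(-110.0, abs=1e-6)
        assert psi1 == pytest.approx(130.0, abs=1e-6)
        assert abs(omega) == pytest.approx(180.0, abs=1e-6)
        chi1 = measure_dihedral(pos[(1, "N")], pos[(1, "CA")], pos[(1, "CB")],
                                pos[(1, "CG1")])
        assert chi1 == pytest.approx(175.0, abs=1e-6)

    def test_residue_breakdowns_sum_to_chain_total(self):
        ala = fixtures.load_topology("ALA")
        val = fixtures.load_topology("VAL")
        prm = fixtures.params_for("VAL")
        chain = build_chain([ala, val, ala], [-63, -80, -70], [-43, 60, -35],
                            [np.zeros(0), np.array([-60.0]), np.zeros(0)])
        scorer = ChainScorer(chain, prm)
        total = scorer.total(chain.coords)
        by_residue = sum(
            sum(scorer.residue_breakdown(chain.coords, r).as_dict().values())
            for r in range(3)
        )
        assert by_residue == pytest.approx(total, abs=1e-9)


@pytest.fixture(scope="module")
def val_lib():
    top = fixtures.load_topology("VAL")
    prm = fixtures.params_for("VAL")
    return build_library(top, prm, MakeRotLibConfig(phi_psi_spacing=90.0, chi_seed_spacing=15.0))


class TestEstimate:
    def test_identical_fragments_average_to_single_value(self, val_lib):
        top = fixtures.load_topology("VAL")
        prm = fixtures.params_for("VAL")
        frag = np.tile(np.array([[-63.0, -43.0]]), (5, 1))[None, :, :]
        ens3 = np.repeat(frag, 3, axis=0)
        one = estimate_unfolded(top, frag, prm, val_lib, seed=0)
        three = estimate_unfolded(top, ens3, prm, val_lib, seed=0)
        for term in one:
            if term == "n":
                continue
            assert three[term] == pytest.approx(one[term], abs=1e-9)

    def test_term_set_matches_energy_breakdown(self, val_lib):
        top = fixtures.load_topology("VAL")
        prm = fixtures.params_for("VAL")
        ens = generate_fragment_ensemble(FragmentEnsembleSpec(n_fragments=2, seed=3))
        entry = estimate_unfolded(top, ens, prm, val_lib, seed=0)
        expected = {t for t in EnergyBreakdown.TERMS if t != "unfolded"}
        assert set(entry) - {"n"} == expected

    def test_weighted_unfolded_equals_total_energy_identity(self, val_lib):
        top = fixtures.load_topology("VAL")
        prm = fixtures.params_for("VAL")
        ens = generate_fragment_ensemble(FragmentEnsembleSpec(n_fragments=2, seed=5))
        entry = estimate_unfolded(top, ens, prm, val_lib, seed=0)
        table = UnfoldedEnergyTable(entries={"VAL": entry}, ensemble_size=2, seed=5)
        weights = WeightSet()
        direct = unfolded_energy("VAL", table, weights)
        bd = EnergyBreakdown(**{t: entry[t] for t in EnergyBreakdown.TERMS
                                if t != "unfolded"})
        assert direct == pytest.approx(total_energy(bd, weights), abs=1e-12)

    def test_missing_residue_lookup_error(self):
        table = UnfoldedEnergyTable(entries={})
        with pytest.raises(KeyError):
            unfolded_energy("LEU", table, WeightSet())

    def test_ring_residue_has_larger_intra_repulsion_than_acyclic(self):
        """Fused-ring side chains carry 1-4/1-5 ring repulsion that acyclic
        side chains of comparable size do not."""
        ige = fixtures.load_topology("IGE")
        leu = fixtures.load_topology("LEU")
        prm = fixtures.params_for("IGE")
        frag = np.tile(np.array([[-63.0, -43.0]]), (5, 1))[None, :, :]
        cfg = MakeRotLibConfig(chi_seed_spacing=30.0)
        lib_ige = build_library(ige, prm, cfg, bins=[(-60.0, -40.0)])
        lib_leu = build_library(leu, prm, cfg, bins=[(-60.0, -40.0)])
        rep_ring = estimate_unfolded(ige, frag, prm, lib_ige, seed=0)["mm_lj_intra_rep"]
        rep_acyc = estimate_unfolded(leu, frag, prm, lib_leu, seed=0)["mm_lj_intra_rep"]
        assert rep_ring > rep_acyc
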