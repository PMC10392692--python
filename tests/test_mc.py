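"""Constant-pH MC engine: energies, moves, titration and determinism."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from asynsalt.mc import (
    build_slit_system,
    debye_length,
    pair_energy,
    run,
    single_free_bead_system,
    single_titratable_bead_system,
    total_energy,
)
from asynsalt.sequences import ProteinSequence


class TestDebyeLength:
    def test_inverse_square_root_scaling(self):
        assert debye_length(0.04) == pytest.approx(debye_length(0.01) / 2.0)

    def test_value_at_100_mM(self):
        # direct evaluation of (8 pi l_B N_A c)^(-1/2) at l_B = 7 A
        assert debye_length(0.1, bjerrum=7.0) == pytest.approx(9.72, abs=0.01)

    def test_zero_salt_unscreened(self):
        assert math.isinf(debye_length(0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            debye_length(-0.1)


class TestPairEnergy:
    def test_neutral_at_sigma_is_lj_zero_crossing(self):
        assert pair_energy(4.0, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_far_neutral_pair_vanishes(self):
        assert pair_energy(1e6, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_like_charges_at_debye_length(self):
        # l_B e^-1 / lambda_D with point-like beads
        u = pair_energy(9.6, 1, 1, sigma1=0.01, sigma2=0.01, debye=9.6)
        assert u == pytest.approx(7.0 * math.exp(-1) / 9.6, rel=1e-3)
        assert u == pytest.approx(0.268, abs=0.002)

    def test_overlap_sentinel(self):
        assert math.isinf(pair_energy(0.0, 1, -1))


MINI_TAIL = ProteinSequence("GKNEEGAP", "mini_tail")
MINI_FREE = ProteinSequence("MDKFMGLSNEGG", "mini_free", has_free_cterm=True)


def mini_system(n_grafted=4, area=900.0, c_salt=0.02, rng_seed=2, **kw):
    return build_slit_system(MINI_TAIL, MINI_FREE, n_grafted=n_grafted,
                             area_per_tail=area, c_salt=c_salt,
                             rng_seed=rng_seed, **kw)


class TestSystemGeometry:
    def test_grafting_density_is_configured_density(self, ctail, asyn):
        for n in (32, 50):
            s = build_slit_system(ctail, asyn, n_grafted=n, rng_seed=0)
            assert s.grafting_density == pytest.approx(1.0 / 1200.0)
            assert s.n_grafted == n
            assert s.L_z == s.L_xy  # cubic slit

    def test_slit_too_small_for_tail_rejected(self, ctail, asyn):
        with pytest.raises(ValueError, match="slit height"):
            build_slit_system(ctail, asyn, n_grafted=8, rng_seed=0)

    def test_beads_inside_slit_and_anchors_on_plane(self, ctail, asyn):
        s = build_slit_system(ctail, asyn, n_grafted=32, rng_seed=0)
        assert np.all(s.pos[~s.anchored, 2] > 0)
        assert np.all(s.pos[:, 2] < s.L_z)
        assert np.all(s.pos[s.anchored, 2] == 0.0)
        # one anchor per grafted chain, at the tail's N-terminal bead
        assert s.anchored.sum() == s.n_grafted

    def test_grafted_nterm_not_titratable(self):
        s = mini_system()
        anchor_beads = set(np.nonzero(s.anchored)[0])
        assert anchor_beads.isdisjoint(set(s.site_bead))


class TestTotalEnergy:
    def test_two_bead_chain_at_equilibrium_is_zero(self):
        seq = ProteinSequence("GG", "gg", has_free_nterm=False,
                              has_free_cterm=False)
        s = build_slit_system(seq, None, n_grafted=1, area_per_tail=1e4,
                              rng_seed=0)
        s.pos[1] = s.pos[0] + [0.0, 0.0, s.bond_req]
        # beads 4.1 A apart are bonded neighbours: only the bond term counts
        assert total_energy(s) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_is_harmonic(self):
        seq = ProteinSequence("GG", "gg", has_free_nterm=False,
                              has_free_cterm=False)
        s = build_slit_system(seq, None, n_grafted=1, area_per_tail=1e4,
                              rng_seed=0)
        s.pos[1] = s.pos[0] + [0.0, 0.0, s.bond_req + 1.0]
        assert total_energy(s) == pytest.approx(0.5 * s.bond_k, abs=1e-12)


class TestMoves:
    def test_ideal_bead_samples_uniform_z(self):
        """Non-interacting bead in the slit: ideal-gas density profile."""
        s = single_free_bead_system(box=100.0)
        res = run(s, n_equil_sweeps=100, n_prod_sweeps=50000, sample_every=1,
                  rng_seed=5)
        # thin to ~independent samples: the bead decorrelates across the box
        # in ~(L/step)^2 ~ 16 sweeps
        thin = res.z_cm[::20]
        hist, _ = np.histogram(thin, bins=10, range=(0.0, 100.0))
        stat, p = chisquare(hist)
        assert p > 0.01
        assert np.all(res.z_cm > 0) and np.all(res.z_cm < 100.0)

    def test_energy_bookkeeping_matches_recomputation(self):
        s = mini_system()
        res = run(s, n_equil_sweeps=100, n_prod_sweeps=200, rng_seed=3)
        assert res.stats.drift_per_1e4_moves < 1e-6

    def test_acceptance_rates_are_rates(self):
        s = mini_system()
        res = run(s, n_equil_sweeps=100, n_prod_sweeps=100, rng_seed=3)
        for kind in ("bead", "chain", "pivot", "titration"):
            assert 0.0 <= res.stats.acceptance(kind) <= 1.0
            assert res.stats.attempts[kind] > 0

    def test_anchors_never_move(self):
        s = mini_system()
        before = s.pos[s.anchored].copy()
        res = run(s, n_equil_sweeps=50, n_prod_sweeps=50, rng_seed=3)
        after = res.system.pos[res.system.anchored]
        assert np.array_equal(before, after)

    def test_fixed_seed_bitwise_reproducible(self):
        s = mini_system()
        r1 = run(s, n_equil_sweeps=50, n_prod_sweeps=100, rng_seed=11)
        r2 = run(s, n_equil_sweeps=50, n_prod_sweeps=100, rng_seed=11)
        assert np.array_equal(r1.z_cm, r2.z_cm)
        assert np.array_equal(r1.dipole, r2.dipole)
        assert np.array_equal(r1.energy, r2.energy)
        r3 = run(s, n_equil_sweeps=50, n_prod_sweeps=100, rng_seed=12)
        assert not np.array_equal(r1.z_cm, r3.z_cm)


class TestTitration:
    @pytest.mark.parametrize("delta", [-2, -1, 0, 1, 2])
    def test_isolated_acid_matches_henderson_hasselbalch(self, delta):
        """Swap moves on a lone site reproduce HH occupancy exactly."""
        pka = 4.4  # glutamate
        s = single_titratable_bead_system("E", pH=pka + delta)
        n = 20000
        res = run(s, n_equil_sweeps=200, n_prod_sweeps=n, sample_every=1,
                  rng_seed=delta + 10)
        deprot = 1.0 - res.site_protonated_fraction[0]
        expected = 1.0 / (1.0 + 10.0 ** (-delta))
        se = math.sqrt(max(expected * (1 - expected), 1e-4) / (n / 10))
        assert deprot == pytest.approx(expected, abs=3 * se)

    def test_isolated_base_discharges_at_high_ph(self):
        s = single_titratable_bead_system("K", pH=13.0)
        res = run(s, n_equil_sweeps=100, n_prod_sweeps=5000, sample_every=1,
                  rng_seed=1)
        assert res.site_protonated_fraction[0] < 0.01  # mean charge -> 0

    def test_mean_charge_from_protonation_acid(self):
        s = single_titratable_bead_system("E", pH=4.4)
        res = run(s, n_equil_sweeps=100, n_prod_sweeps=20000, sample_every=1,
                  rng_seed=2)
        mean_q = -(1.0 - res.site_protonated_fraction[0])
        assert mean_q == pytest.approx(-0.5, abs=0.03)
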