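"""The softened 8-6 potentials and the E_86 binding energy."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

import opepdock as od
from opepdock import forcefield as ff
from opepdock.cgmodel import AtomRecord, coarse_grain
from opepdock.exceptions import PartnerError
from opepdock.residues import N_TYPES, TYPE_INDEX, is_salt_bridge_pair
from opepdock.softscore import (
    SOFT_DEPTH_RATIO,
    SOFT_SIGMA_RATIO,
    bin_energies_by_irmsd,
    ess86_pair,
    score_e86,
    soften_parameters,
)


def _single_pair_table(sigma=4.0, eps=1.0, attractive=True):
    r0 = (sigma + 0.3992) / 1.0729
    eps_m = np.full((N_TYPES, N_TYPES), eps)
    att = np.full((N_TYPES, N_TYPES), attractive)
    r0_m = np.full((N_TYPES, N_TYPES), r0)
    return ff.PairParameterTable(eps=eps_m, attractive=att, r0=r0_m)


class TestSoftenParameters:
    def test_sigma_prime_factor(self):
        soft = soften_parameters(_single_pair_table(sigma=4.0))
        # printed factor 0.866; exact construction sqrt(3)/2
        assert soft.sigma_prime[0, 0] == pytest.approx(3.4640, abs=2e-4)
        assert soft.sigma_prime[0, 0] / 4.0 == pytest.approx(SOFT_SIGMA_RATIO)

    def test_depth_scaling_factor(self):
        soft = soften_parameters(_single_pair_table(eps=1.0))
        assert soft.eps_prime[0, 0] == pytest.approx(9.481, abs=1e-3)
        assert SOFT_DEPTH_RATIO == pytest.approx(9.481, abs=1e-3)

    def test_repulsive_entries_untouched(self, config):
        t = config.pair_table
        soft = soften_parameters(t, config)
        rep = ~t.attractive
        assert np.array_equal(soft.sigma_prime[rep], t.sigma[rep])
        assert np.array_equal(soft.eps_prime[rep], t.eps[rep])


class TestEss86:
    def test_minimum_matches_unsoftened(self):
        t = _single_pair_table(sigma=5.5, eps=2.0)
        soft = soften_parameters(t)
        assert ess86_pair(5.5, 0, 0, soft) == pytest.approx(-2.0, abs=1e-6)

    def test_argmin_at_sigma(self):
        t = _single_pair_table(sigma=5.5, eps=2.0)
        soft = soften_parameters(t)
        res = minimize_scalar(lambda r: ess86_pair(r, 0, 0, soft),
                              bounds=(3.0, 10.0), method="bounded",
                              options={"xatol": 1e-9})
        assert res.x == pytest.approx(5.5, abs=1e-4)
        assert soft.sigma_prime[0, 0] / res.x == pytest.approx(0.866, abs=1e-3)

    def test_broader_well_than_unsoftened(self, config):
        t = config.pair_table
        soft = soften_parameters(t, config)
        for i, j in [(0, 0), (9, 13), (17, 17)]:
            if not t.attractive[i, j]:
                continue
            sigma = t.sigma[i, j]
            r = np.linspace(sigma * 1.001, 2 * sigma, 200)
            assert np.all(ess86_pair(r, i, j, soft) <=
                          ff.ess_pair(r, i, j, t) + 1e-12)

    def test_repulsive_delegates(self, config):
        t = config.pair_table
        soft = soften_parameters(t, config)
        rep = np.argwhere(~t.attractive)
        i, j = next((a, b) for a, b in rep if not is_salt_bridge_pair(a, b))
        r = 3.7
        assert ess86_pair(r, int(i), int(j), soft) == \
            ff.ess_pair(r, int(i), int(j), t)

    def test_table_wide_matching_construction(self, config):
        """E_SS86(sigma) = E_SS(sigma) for every attractive pair in the
        shipped table, to 1e-6 kcal/mol."""
        t = config.pair_table
        soft = soften_parameters(t, config)
        worst = 0.0
        for i in range(N_TYPES):
            for j in range(i, N_TYPES):
                if not t.attractive[i, j] or is_salt_bridge_pair(i, j):
                    continue
                s = t.sigma[i, j]
                worst = max(worst, abs(ess86_pair(s, i, j, soft) -
                                       ff.ess_pair(s, i, j, t)))
        assert worst < 1e-6


def _phe_dipeptide(sc_distance):
    """Two PHE residues on different chains with SC beads exactly
    sc_distance apart (backbones far off to the sides)."""
    recs = []
    for chain, x_sc in (("A", 0.0), ("B", sc_distance)):
        shift = -12.0 if chain == "A" else 12.0
        o = np.array([x_sc + shift, 0.0, 0.0])
        recs += [
            AtomRecord(chain, 1, "", "PHE", "N", "N", o + (0, 3, 0)),
            AtomRecord(chain, 1, "", "PHE", "CA", "C", o + (1.4, 3, 0)),
            AtomRecord(chain, 1, "", "PHE", "C", "C", o + (2, 4.2, 0)),
            AtomRecord(chain, 1, "", "PHE", "O", "O", o + (1.5, 5.3, 0)),
            AtomRecord(chain, 1, "", "PHE", "CB", "C",
                       np.array([x_sc, 0.0, 0.0])),
        ]
    cg = coarse_grain(recs)
    return od.assign_partners(cg, {"A"}, {"B"})


class TestScoreE86:
    def test_separated_partners_zero(self, toy_native, soft, config):
        moved = toy_native.copy()
        lig = moved.partner_bead_indices(1)
        moved.bead_pos[lig] += 200.0
        bd = score_e86(moved, soft, config)
        assert bd.total == 0.0
        assert bd.n_pairs_evaluated == 0

    def test_unassigned_partners_rejected(self, tiny_pdb, soft, config):
        cg = coarse_grain(od.parse_pdb(tiny_pdb))
        with pytest.raises(PartnerError):
            score_e86(cg, soft, config)

    def test_single_phe_pair_at_sigma(self, config_nocut):
        i = TYPE_INDEX["PHE"]
        t = config_nocut.pair_table
        sigma = t.sigma[i, i]
        cg = _phe_dipeptide(sigma)
        soft_nc = soften_parameters(t, config_nocut)
        bd = score_e86(cg, soft_nc, config_nocut)
        assert bd.e_ss86 == pytest.approx(ff.ess_pair(sigma, i, i, t), abs=1e-9)

    def test_partner_swap_symmetric(self, toy_native, soft, config):
        bd = score_e86(toy_native, soft, config)
        swapped = od.assign_partners(toy_native, {"B"}, {"A"})
        bd2 = score_e86(swapped, soft, config)
        assert bd2.e_ss86 == pytest.approx(bd.e_ss86, abs=1e-9)
        assert bd2.total == pytest.approx(bd.total, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_native, soft, config):
        bd = score_e86(toy_native, soft, config)
        rot = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        moved = toy_native.transformed(rot, np.array([3.0, -7.0, 1.0]))
        bd2 = score_e86(moved, soft, config)
        assert bd2.total == pytest.approx(bd.total, abs=1e-8)

    def test_one_partner_motion_changes_energy(self, toy_native, soft, config):
        bd = score_e86(toy_native, soft, config)
        moved = toy_native.copy()
        lig = moved.partner_bead_indices(1)
        moved.bead_pos[lig] += np.array([1.0, 0.0, 0.0])
        bd2 = score_e86(moved, soft, config)
        assert bd2.total != pytest.approx(bd.total, abs=1e-6)

    def test_total_is_sum_of_terms(self, toy_native, soft, config):
        bd = score_e86(toy_native, soft, config)
        assert bd.total == pytest.approx(
            bd.e_vdw86 + bd.e_ss86 + bd.e_hb + bd.e_sb, abs=1e-9)

    def test_brute_force_oracle(self, toy_native, config_nocut):
        """Naive double loop over all bead pairs reproduces the cutoff-free
        total to 1e-9 (independent routing implementation)."""
        from opepdock.cgmodel import BACKBONE_ROLES, ROLE_H, ROLE_PRO_HEAVY
        from opepdock.residues import RESIDUE_TYPES, salt_bridge_id

        cfg = config_nocut
        soft_nc = soften_parameters(cfg.pair_table, cfg)
        cg = toy_native
        bd = score_e86(cg, soft_nc, cfg)

        bp = cg.bead_partner()
        center = cg.is_center()
        total_ss = total_sb = total_vdw = 0.0
        for a in range(cg.n_beads):
            for b in range(cg.n_beads):
                if bp[a] != 0 or bp[b] != 1:
                    continue
                r = float(np.linalg.norm(cg.bead_pos[a] - cg.bead_pos[b]))
                ra, rb = int(cg.bead_role[a]), int(cg.bead_role[b])
                ta = int(cg.residue_type[cg.bead_residue[a]])
                tb = int(cg.residue_type[cg.bead_residue[b]])
                if center[a] and center[b]:
                    sb = salt_bridge_id(RESIDUE_TYPES[ta], RESIDUE_TYPES[tb])
                    if sb:
                        total_sb += ff.esb_pair(r, sb, cfg.sb_profiles)
                    else:
                        total_ss += ess86_pair(r, ta, tb, soft_nc)
                elif (ra in BACKBONE_ROLES or rb in BACKBONE_ROLES) and \
                        ROLE_H not in (ra, rb) and ROLE_PRO_HEAVY not in (ra, rb):
                    from opepdock.softscore import evdw86_pair
                    total_vdw += evdw86_pair(r, ra, rb, soft_nc)
        assert bd.e_ss86 == pytest.approx(total_ss, abs=1e-9)
        assert bd.e_sb == pytest.approx(total_sb, abs=1e-9)
        assert bd.e_vdw86 == pytest.approx(total_vdw, abs=1e-9)


class TestBinEnergies:
    def _bd(self, e):
        from opepdock.softscore import EnergyBreakdown
        return EnergyBreakdown(0.0, e, 0.0, 0.0, 1)

    def test_single_bin_mean(self):
        out = bin_energies_by_irmsd([2.1, 2.7, 2.9],
                                    [self._bd(x) for x in (-1.0, -2.0, -3.0)])
        assert list(out.index) == [2]
        assert out.loc[2, "e_ss86_mean"] == pytest.approx(-2.0)

    def test_two_singleton_bins(self):
        out = bin_energies_by_irmsd([0.5, 1.5], [self._bd(-1), self._bd(-2)])
        assert list(out.index) == [0, 1]
        assert out.loc[0, "e_ss86_count"] == 1

    def test_empty_bins_absent(self):
        out = bin_energies_by_irmsd([0.5, 10.5], [self._bd(-1), self._bd(-2)])
        assert 5 not in out.index

    def test_planted_signal_lower_near_native(self, config, soft):
        from opepdock.synthetic import make_recovery_benchmark

        ds = make_recovery_benchmark(n_targets=1, n_decoys=150, seed=2)[0]
        bds = [score_e86(ds.decoy_complex(i), soft, config)
               for i in range(ds.n_decoys)]
        out = bin_energies_by_irmsd(ds.irmsd, bds)
        near_bins = [b for b in out.index if b < 4]
        far_bins = [b for b in out.index if 10 <= b < 20]
        assert near_bins and far_bins
        near_mean = out.loc[near_bins, "e_ss86_mean"].mean()
        far_mean = out.loc[far_bins, "e_ss86_mean"].mean()
        assert near_mean < far_mean
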