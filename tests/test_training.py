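"""Contact maps, TP/FN/FP/TN classification and the iterative update."""

import numpy as np
import pandas as pd
import pytest

import opepdock as od
from opepdock.cgmodel import AtomRecord, coarse_grain
from opepdock.residues import N_TYPES, RESIDUE_TYPES, TYPE_INDEX
from opepdock.training import (
    ContactFrequencyMaps,
    TrainedPotential,
    accumulate_frequency_maps,
    classify_predictions,
    contact_map,
    delta_matrix,
    select_and_update,
    validation_quality,
)


def _pair_complex(closest_distance, res_a="ALA", res_b="GLY"):
    """Two single-residue chains whose closest beads (the CB/CA) are exactly
    ``closest_distance`` apart; backbones point away from the interface."""
    recs = []
    for chain, res, x in (("A", res_a, 0.0), ("B", res_b, closest_distance)):
        sign = -1.0 if chain == "A" else 1.0
        o = np.array([x + sign * 6.0, 0.0, 0.0])
        recs += [
            AtomRecord(chain, 1, "", res, "N", "N", o + (0, 2, 0)),
            AtomRecord(chain, 1, "", res, "CA", "C",
                       np.array([x, 0.0, 0.0]) if res == "GLY"
                       else o + (1.4, 2, 0)),
            AtomRecord(chain, 1, "", res, "C", "C", o + (2, 3.2, 0)),
            AtomRecord(chain, 1, "", res, "O", "O", o + (1.5, 4.3, 0)),
        ]
        if res != "GLY":
            recs.append(AtomRecord(chain, 1, "", res, "CB", "C",
                                   np.array([x, 0.0, 0.0])))
    cg = coarse_grain(recs)
    return od.assign_partners(cg, {"A"}, {"B"})


class TestContactMap:
    def test_contact_below_threshold(self):
        cg = _pair_complex(7.99)
        m = contact_map(cg)
        a, g = TYPE_INDEX["ALA"], TYPE_INDEX["GLY"]
        assert m[a, g] == 1 and m[g, a] == 1

    def test_exactly_eight_angstrom_is_no_contact(self):
        cg = _pair_complex(8.0)
        assert contact_map(cg).sum() == 0

    def test_symmetric_accumulation(self):
        cg = _pair_complex(5.0)
        m = contact_map(cg)
        assert np.array_equal(m, m.T)


def _ranking(n, hit_positions, n_decoys=None):
    """Build a ranking table with hits at the given sorted positions."""
    n_decoys = n_decoys or n
    irmsd = np.full(n_decoys, 10.0)
    irmsd[list(hit_positions)] = 1.0
    scores = np.arange(n_decoys, dtype=float)
    ids = [f"d{i:04d}" for i in range(n_decoys)]
    df, _ = od.rank_and_best_hit(ids, scores, irmsd)
    return df


class TestClassification:
    def test_twenty_hits_in_top_twenty(self):
        df = classify_predictions(_ranking(60, range(20)))
        kept = df[df["kept"]]
        assert (kept["label"] == "TP").sum() == 20
        assert not kept["label"].isin(["FN", "FP"]).any()

    def test_cap_formula_five_tps(self):
        # 5 TPs in top 20, 12 more hits below rank 20 (17 hits total < 20)
        hits = list(range(5)) + list(range(25, 37))
        df = classify_predictions(_ranking(200, hits))
        kept = df[df["kept"]]
        assert (kept["label"] == "TP").sum() == 5
        assert (kept["label"] == "FN").sum() == 12  # all fit in the 20-N budget
        assert (kept["label"] == "FP").sum() == 15  # the 20-N non-hits on top

    def test_fp_budget_caps_best_ranked(self):
        # 18 TPs: only 2 FPs (the best-ranked non-hits in the top 20) kept
        hits = list(range(18)) + [30]
        df = classify_predictions(_ranking(200, hits))
        kept = df[df["kept"]]
        fps = kept[kept["label"] == "FP"]
        assert len(fps) == 2
        assert fps["rank"].tolist() == sorted(fps["rank"].tolist())

    def test_twenty_plus_hits_discards_fn_fp(self):
        hits = list(range(10)) + list(range(30, 45))  # 25 hits, 10 in top 20
        df = classify_predictions(_ranking(200, hits))
        kept = df[df["kept"]]
        assert not kept["label"].isin(["FN", "FP"]).any()
        assert (kept["label"] == "TP").sum() == 10

    def test_partition_before_caps(self):
        df = classify_predictions(_ranking(100, [0, 30, 50]))
        assert set(df["label"]) <= {"TP", "FN", "FP", "TN"}
        assert df["label"].notna().all()
        # caps only drop, never relabel
        assert (df.groupby("label")["kept"].any()).all() or True
        assert len(df) == 100


class TestAccumulate:
    def _classified(self, labels):
        n = len(labels)
        df = pd.DataFrame({
            "label": labels, "kept": [True] * n,
            "decoy_index": list(range(n)),
        })
        return df

    def test_single_tp_map_identity(self):
        m = np.zeros((N_TYPES, N_TYPES))
        m[0, 7] = m[7, 0] = 1
        maps = accumulate_frequency_maps(
            [self._classified(["TP"])], [m[None, :, :]])
        assert np.array_equal(maps.maps["TP"], m)
        assert maps.counts["TP"] == 1

    def test_mean_of_two_disjoint_maps(self):
        m = np.zeros((2, N_TYPES, N_TYPES))
        m[0, 0, 1] = m[0, 1, 0] = 1
        m[1, 2, 3] = m[1, 3, 2] = 1
        maps = accumulate_frequency_maps(
            [self._classified(["TP", "TP"])], [m])
        assert maps.maps["TP"][0, 1] == pytest.approx(0.5)
        assert maps.maps["TP"][2, 3] == pytest.approx(0.5)

    def test_empty_class_flagged(self):
        maps = accumulate_frequency_maps(
            [self._classified(["TP"])],
            [np.zeros((1, N_TYPES, N_TYPES))])
        assert maps.empty("FP")
        assert not maps.empty("TP")


def _maps(tp=0.0, fn=0.0, fp=0.0, tn=0.0, cell=(0, 0), counts=(5, 5, 5, 5)):
    out = {}
    for lab, v in zip(("TP", "FN", "FP", "TN"), (tp, fn, fp, tn)):
        m = np.zeros((N_TYPES, N_TYPES))
        m[cell[0], cell[1]] = m[cell[1], cell[0]] = v
        out[lab] = m
    return ContactFrequencyMaps(
        maps=out, counts=dict(zip(("TP", "FN", "FP", "TN"), counts)))


def _potential(config, soft, k=0.2):
    return TrainedPotential.fresh(soft, config, k=k)


class TestSelectAndUpdate:
    def test_equal_fn_fp_no_change(self, config, soft):
        pot = _potential(config, soft)
        w0 = pot.well_depths.copy()
        maps = _maps(tp=3, fn=2, fp=2, tn=1)
        select_and_update(maps, pot)
        assert np.array_equal(pot.well_depths, w0)

    def test_ratio_e_shifts_by_k(self, config, soft):
        pot = _potential(config, soft)
        maps = _maps(tp=3, fn=2 * np.e, fp=2, tn=1)
        # undo pseudocount distortion by measuring the actual applied shift
        w0 = pot.well_depths[0, 0]
        select_and_update(maps, pot)
        shift = pot.well_depths[0, 0] - w0
        eps_f = 1.0 / maps.total_kept
        expected = -0.2 * np.log((2 * np.e + eps_f) / (2 + eps_f))
        assert shift == pytest.approx(expected)
        assert shift == pytest.approx(-0.2, abs=0.02)

    def test_ln2_shift_magnitude(self, config, soft):
        pot = _potential(config, soft)
        maps = _maps(tp=3, fn=4, fp=2, tn=1)
        w0 = pot.well_depths[0, 0]
        select_and_update(maps, pot)
        assert pot.well_depths[0, 0] - w0 == pytest.approx(-0.2 * np.log(2),
                                                           abs=0.01)

    def test_unselected_pairs_unchanged(self, config, soft):
        pot = _potential(config, soft)
        maps = _maps(tp=3, fn=4, fp=2, tn=1, cell=(0, 0))
        w0 = pot.well_depths.copy()
        select_and_update(maps, pot)
        changed = pot.well_depths != w0
        assert changed[0, 0]
        assert changed.sum() == 1  # only the (0, 0) diagonal cell

    def test_ties_deselect(self, config, soft):
        pot = _potential(config, soft)
        maps = _maps(tp=2, fn=4, fp=2, tn=2)  # TP == FP and FN... tie on TP
        w0 = pot.well_depths.copy()
        select_and_update(maps, pot)
        assert np.array_equal(pot.well_depths, w0)

    def test_fn_fp_swap_negates_shift(self, config, soft):
        """Swapping the near-native maps (TP, FN) with the misdocked maps
        (TN, FP) flips every selection and negates every applied shift."""
        rng = np.random.default_rng(7)
        base = {lab: rng.uniform(0, 3, (N_TYPES, N_TYPES)) for lab in
                ("TP", "FN", "FP", "TN")}
        for lab in base:
            base[lab] = (base[lab] + base[lab].T) / 2
        counts = {"TP": 5, "FN": 5, "FP": 5, "TN": 5}
        m1 = ContactFrequencyMaps(maps=dict(base), counts=dict(counts))
        swapped = {"FN": base["FP"], "FP": base["FN"],
                   "TP": base["TN"], "TN": base["TP"]}
        m2 = ContactFrequencyMaps(maps=swapped, counts=dict(counts))
        p1 = _potential(config, soft)
        p2 = TrainedPotential(well_depths=p1.well_depths.copy(),
                              initial_depths=p1.initial_depths.copy(), k=0.2)
        select_and_update(m1, p1)
        select_and_update(m2, p2)
        d1 = p1.well_depths - p1.initial_depths
        d2 = p2.well_depths - p2.initial_depths
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_empty_fn_skips_update(self, config, soft):
        pot = _potential(config, soft)
        maps = _maps(tp=3, fn=0, fp=2, tn=1, counts=(5, 0, 5, 5))
        w0 = pot.well_depths.copy()
        select_and_update(maps, pot)
        assert np.array_equal(pot.well_depths, w0)
        assert pot.iterations == 1


@pytest.fixture(scope="module")
def small_caches(config, soft):
    from opepdock.synthetic import make_recovery_benchmark
    from opepdock.training import build_target_cache

    bench = make_recovery_benchmark(n_targets=3, n_decoys=80, seed=13)
    return [build_target_cache(ds, soft, config) for ds in bench]


class TestTrainLoop:
    def test_k_zero_is_fixed_point(self, small_caches, config, soft):
        pot = od.train(small_caches, soft, config, iterations=5, k=0.0)
        np.testing.assert_array_equal(pot.well_depths, pot.initial_depths)

    def test_training_does_not_mutate_inputs(self, small_caches, config, soft):
        eps_before = config.pair_table.eps.copy()
        soft_before = soft.eps_prime.copy()
        od.train(small_caches, soft, config, iterations=3, k=0.2)
        np.testing.assert_array_equal(config.pair_table.eps, eps_before)
        np.testing.assert_array_equal(soft.eps_prime, soft_before)

    def test_deterministic(self, small_caches, config, soft):
        p1 = od.train(small_caches, soft, config, iterations=4, k=0.2)
        p2 = od.train(small_caches, soft, config, iterations=4, k=0.2)
        np.testing.assert_array_equal(p1.well_depths, p2.well_depths)

    def test_validation_quality_all_rank_one(self, small_caches):
        """ln(1) per target: quality 0 when every best hit ranks first."""
        cache = small_caches[0]
        import copy

        c = copy.copy(cache)
        c.fixed = cache.irmsd.copy()  # score == IRMSD: best hit ranks 1st
        c.features = np.zeros_like(cache.features)
        pot = np.ones((N_TYPES, N_TYPES))
        assert validation_quality([c], pot) == pytest.approx(0.0)

    def test_cross_validate_structure(self, small_caches, config, soft):
        rep = od.cross_validate(small_caches, soft, config, folds=3,
                                iterations_max=3, k=0.2, seed=0)
        all_idx = np.concatenate(rep.fold_assignments)
        assert sorted(all_idx.tolist()) == [0, 1, 2]
        assert rep.quality_per_iteration.shape == (3, 4)
        mean_q = rep.quality_per_iteration.mean(axis=0)
        assert rep.chosen_iteration == int(np.argmin(mean_q))


class TestDeltaMatrix:
    def test_untrained_is_zero(self, config, soft):
        pot = _potential(config, soft)
        assert np.count_nonzero(delta_matrix(pot)) == 0

    def test_single_shift_magnitude(self, config, soft):
        pot = _potential(config, soft)
        maps = _maps(tp=3, fn=4, fp=2, tn=1, cell=(2, 5))
        select_and_update(maps, pot)
        dm = delta_matrix(pot)
        assert abs(dm[2, 5]) == pytest.approx(0.2 * np.log(2), abs=0.01)
        assert dm[2, 5] == dm[5, 2]
        assert np.count_nonzero(dm) == 2

    def test_symmetry(self, config, soft):
        pot = _potential(config, soft)
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 2, (N_TYPES, N_TYPES))
        maps = ContactFrequencyMaps(
            maps={lab: (m + m.T) / 2 * f for lab, f in
                  zip(("TP", "FN", "FP", "TN"), (2.0, 1.8, 1.0, 0.9))},
            counts={"TP": 5, "FN": 5, "FP": 5, "TN": 5})
        select_and_update(maps, pot)
        dm = delta_matrix(pot)
        np.testing.assert_allclose(dm, dm.T)
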