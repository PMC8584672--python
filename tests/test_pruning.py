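"""Mask edits, dead-unit cascades, budget matching, and the prune loop."""

import numpy as np
import pytest

from prunebm import pruning
from prunebm.core_bm import BoltzmannNet, init_dbm, init_rbm
from prunebm.pruning import (
    PruneConfig,
    PruneRunReport,
    match_unit_budget,
    remove_dead_units,
    threshold_prune,
    zero_importance_prune,
)


def _count_live(mask):
    return int(np.asarray(mask).sum())


class TestThresholdPrune:
    def test_halving_910_leaves_455(self):
        rng = np.random.default_rng(0)
        mask = np.ones((13, 70), dtype=np.uint8)
        imp = rng.random((13, 70))
        new = threshold_prune(mask, imp, 50.0)
        assert _count_live(new) == 455

    def test_iterated_halving_matches_floor_sequence(self):
        rng = np.random.default_rng(1)
        mask = np.ones((13, 70), dtype=np.uint8)
        counts = []
        for _ in range(3):
            imp = np.where(mask == 1, rng.random(mask.shape), np.nan)
            mask = threshold_prune(mask, imp, 50.0)
            counts.append(_count_live(mask))
        assert counts == [455, 227, 113]

    def test_percentile_zero_changes_nothing(self):
        mask = np.ones((4, 4), dtype=np.uint8)
        new = threshold_prune(mask, np.arange(16.0).reshape(4, 4), 0.0)
        assert np.array_equal(new, mask)

    def test_tie_break_removes_lowest_indices_first(self):
        mask = np.ones((2, 4), dtype=np.uint8)
        new = threshold_prune(mask, np.zeros((2, 4)), 50.0)
        assert _count_live(new) == 4
        # row-major lowest indices go first
        assert new[0].tolist() == [0, 0, 0, 0]
        assert new[1].tolist() == [1, 1, 1, 1]

    def test_survivor_values_untouched(self):
        net = init_rbm(3, 3, weight_sd=1.0, seed=0)
        w_before = net.weights[0].copy()
        imp = np.abs(net.weights[0])
        net.masks[0] = threshold_prune(net.masks[0], imp, 40.0)
        net.apply_masks()
        live = net.masks[0] == 1
        assert np.array_equal(net.weights[0][live], w_before[live])

    def test_percentile_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_prune(np.ones((2, 2), dtype=np.uint8), np.ones((2, 2)), 120)

    def test_missing_live_importance_rejected(self):
        mask = np.ones((2, 2), dtype=np.uint8)
        vals = np.array([[np.nan, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            threshold_prune(mask, vals, 50.0)


class TestZeroImportancePrune:
    def test_zero_fraction_above_percentile_removes_all_zeros(self):
        mask = np.ones((10, 10), dtype=np.uint8)
        vals = np.ones((10, 10))
        vals[:3, :] = 0.0  # 30% zeros with a 25th-percentile config
        new = zero_importance_prune(mask, vals, 25.0)
        assert _count_live(new) == 70
        assert not new[:3].any()

    def test_no_zeros_falls_back_to_threshold(self):
        rng = np.random.default_rng(2)
        mask = np.ones((6, 6), dtype=np.uint8)
        vals = rng.random((6, 6)) + 0.1
        assert np.array_equal(
            zero_importance_prune(mask, vals, 50.0),
            threshold_prune(mask, vals, 50.0),
        )

    def test_strictly_positive_importance_equivalent_to_threshold(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((8, 8)) < 0.8).astype(np.uint8)
        vals = np.where(mask == 1, rng.random((8, 8)) + 1e-3, np.nan)
        assert np.array_equal(
            zero_importance_prune(mask, vals, 30.0),
            threshold_prune(mask, vals, 30.0),
        )


class TestRemoveDeadUnits:
    def test_all_zero_hidden_column_removes_unit(self):
        net = init_rbm(4, 3, weight_sd=0.5, seed=0)
        net.masks[0][:, 1] = 0
        net.apply_masks()
        new, rep = remove_dead_units(net)
        assert new.layer_sizes == [4, 2]
        assert rep["removed_per_layer"] == [0, 1]

    def test_dbm_middle_unit_dead_from_outgoing_side(self):
        net = init_dbm([3, 3, 2], weight_sd=0.5, seed=1)
        net.masks[1][0, :] = 0  # all outgoing weights of h1 unit 0 pruned
        net.apply_masks()
        n_live_before = net.n_live_weights()
        new, rep = remove_dead_units(net)
        assert new.layer_sizes == [3, 2, 2]
        # its live incoming weights were dropped too
        assert new.n_live_weights() < n_live_before

    def test_cascade_reaches_fixpoint(self):
        """Removing one unit strands another; brute-force recount confirms
        the cascade ran to completion."""
        net = init_dbm([2, 3, 2], weight_sd=0.5, seed=2)
        # h2 unit 0 connected only through h1 unit 0; h1 unit 0 has no
        # visible input, so both must go
        net.masks[0][:, 0] = 0
        net.masks[1][:] = 0
        net.masks[1][0, 0] = 1
        net.masks[1][1, 1] = 1
        net.masks[1][2, 1] = 1
        net.apply_masks()
        new, rep = remove_dead_units(net)
        for l in range(1, new.n_layers):
            assert np.all(new.masks[l - 1].sum(axis=0) > 0)
            if l < new.n_layers - 1:
                assert np.all(new.masks[l].sum(axis=1) > 0)
        assert new.layer_sizes == [2, 2, 1]

    def test_disconnected_visible_units_flagged_not_deleted(self):
        net = init_rbm(4, 2, weight_sd=0.5, seed=3)
        net.masks[0][2, :] = 0
        net.apply_masks()
        new, rep = remove_dead_units(net)
        assert new.layer_sizes[0] == 4
        assert rep["disconnected_visible"] == [2]


class TestMatchUnitBudget:
    @pytest.mark.parametrize("budget,expected", [(455, 35), (227, 18), (113, 9)])
    def test_table_budgets(self, budget, expected):
        assert match_unit_budget(70, 13, budget) == expected

    def test_full_budget_returns_all_units(self):
        assert match_unit_budget(70, 13, 910) == 70

    def test_overflow_budget_capped(self):
        assert match_unit_budget(70, 13, 2000) == 70

    def test_smallest_count_reaching_budget(self):
        assert match_unit_budget(18, 13, 113) == 9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            match_unit_budget(0, 13, 10)


@pytest.fixture(scope="module")
def small_run():
    from prunebm import synthetic_data as sd, training

    data = sd.generate_mixture(
        sd.patch_mixture_spec(n_units=13, n_samples=1500, seed=11)
    )
    tcfg = training.TrainConfig(epochs=1, seed=11)
    net = init_rbm(13, 20, weight_sd=0.1, bias_h=-2.0, seed=11)
    training.train_rbm(net, data, tcfg)
    return net, data, tcfg


class TestPruneLoop:

    def test_random_weight_criterion_is_deterministic(self, small_run):
        net, data, tcfg = small_run
        cfgs = [PruneConfig(criterion="random_weight", percentile=50,
                            n_iterations=2, retrain_epochs=1, seed=5)
                for _ in range(2)]
        masks = []
        for cfg in cfgs:
            pruned, _ = pruning.prune_loop(net.copy(), data, cfg, tcfg)
            masks.append(pruned.masks[0])
        assert np.array_equal(masks[0], masks[1])

    def test_weight_counts_are_exact_live_entries(self, small_run):
        net, data, tcfg = small_run
        cfg = PruneConfig(criterion="weight_magnitude", percentile=50,
                          n_iterations=3, retrain_epochs=1, seed=6)
        pruned, report = pruning.prune_loop(net.copy(), data, cfg, tcfg)
        last = report.records[-1]
        assert last["n_weights_total"] == pruned.n_live_weights()
        counts = [r["n_weights_total"] for r in report.records]
        assert counts == sorted(counts, reverse=True)

    def test_anti_fi_and_variance_fi_removals_are_complementary(self, small_run):
        """At 50% with no ties, the sets removed by the two criteria
        partition the live weights."""
        from prunebm import fisher

        net, data, _ = small_run
        stats = fisher.collect_stats(net, mode="clamped", data=data,
                                     estimator="expectation", seed=0)
        ests = pruning.compute_importance(net, "variance_fi", stats=stats)
        vals = ests[0].values
        assert np.unique(vals).size == vals.size  # no ties in this fixture
        low = threshold_prune(net.masks[0], vals, 50.0)
        high = threshold_prune(net.masks[0], -vals, 50.0)
        removed_low = (net.masks[0] == 1) & (low == 0)
        removed_high = (net.masks[0] == 1) & (high == 0)
        assert not (removed_low & removed_high).any()
        assert (removed_low | removed_high).sum() == net.n_live_weights()

    def test_mask_monotonicity_across_iterations(self, small_run):
        net, data, tcfg = small_run
        cfg = PruneConfig(criterion="variance_fi", percentile=40,
                          n_iterations=3, retrain_epochs=1, seed=8)
        # instrument: record masks after each iteration via the evaluator hook
        seen = []
        pruned, _ = pruning.prune_loop(
            net.copy(), data, cfg, tcfg,
            evaluate=lambda m: (seen.append(m.masks[0].copy()), {})[1],
        )
        # within surviving units, earlier live counts can only shrink
        for a, b in zip(seen[::2], seen[2::2]):
            assert b.sum() <= a.sum()

    def test_random_unit_control_matches_budget(self, small_run):
        net, data, tcfg = small_run
        cfg = PruneConfig(criterion="random_unit", percentile=50,
                          n_iterations=1, retrain_epochs=1, seed=9)
        pruned, report = pruning.prune_loop(net.copy(), data, cfg, tcfg)
        budget = 20 * 13 // 2
        n_keep = match_unit_budget(20, 13, budget)
        assert report.records[0]["n_units"][1] == n_keep

    def test_report_rejects_increasing_weight_counts(self):
        rep = PruneRunReport(criterion="random_weight", seed=0)
        rep.append({"n_weights_total": 100})
        with pytest.raises(ValueError):
            rep.append({"n_weights_total": 120})


class TestDbmPruneLoop:
    def test_dbm_loop_prunes_both_pairs_and_keeps_books(self):
        """Two-hidden-layer loop: mixed statistics, per-pair percentiles,
        dead-unit cascade, PCD retraining."""
        from prunebm import synthetic_data as sd, training

        data = sd.generate_mixture(
            sd.patch_mixture_spec(n_units=10, n_pairs=3, n_samples=400, seed=13)
        )
        tcfg = training.TrainConfig(epochs=1, batch_size=10,
                                    n_persistent_chains=20, weight_norm_cap=6.0,
                                    seed=13)
        net = training.pretrain_stack(data, (8, 6), (tcfg, tcfg), seed=13)
        cfg = PruneConfig(criterion="variance_fi", percentile=(10.0, 25.0),
                          n_iterations=2, retrain_epochs=1, seed=13,
                          stat_mode="mixed", stat_samples=400, stat_thin=5)
        pruned, report = pruning.prune_loop(net, data, cfg, tcfg)
        assert pruned.n_pairs == 2
        last = report.records[-1]
        assert last["n_weights_total"] == pruned.n_live_weights()
        assert last["n_units"] == pruned.layer_sizes
        counts = [r["n_weights_total"] for r in report.records]
        assert counts == sorted(counts, reverse=True)
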