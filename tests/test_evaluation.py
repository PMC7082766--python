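from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorextent import (
    BinaryMask,
    VoxelGeometry,
    ablation_importance,
    addition_order_analysis,
    confusion,
    evaluate,
    interobserver_metrics,
    jaccard_pair,
    occult_rim_analysis,
    region_histology_summary,
    report,
    youden_index,
)
from tumorextent.delineation import AbnormalityChannelSet
from tumorextent.evaluation import ConfusionCounts

GEOM = VoxelGeometry(0.5, 1.0, (2, 3, 1))


def _arr(cells, shape=(2, 3, 1)):
    out = np.zeros(shape, bool)
    for c in cells:
        out[c] = True
    return out


def _channel_set(grids, geometry=None):
    g = geometry or VoxelGeometry(0.5, 1.0, next(iter(grids.values())).shape)
    return AbnormalityChannelSet(
        channels={k: np.asarray(v, bool) for k, v in grids.items()},
        threshold_multiplier=1.0, reference=None, geometry=g,
    )


class TestConfusionAndReport:
    def test_enumeration_example(self):
        # cells a..f; pred {a,b,c,d}, gold {b,c,e}, valid all six
        cells = [(i, j, 0) for i in range(2) for j in range(3)]
        a, b, c, d, e, f = cells
        counts = confusion(_arr([a, b, c, d]), _arr([b, c, e]), _arr(cells))
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 2, 1, 1)

    def test_perfect_prediction(self):
        gold = _arr([(0, 0, 0), (1, 2, 0)])
        counts = confusion(gold, gold, np.ones((2, 3, 1), bool))
        rep = report(counts)
        assert counts.fp == counts.fn == 0
        assert rep.sensitivity == rep.specificity == rep.accuracy == rep.jaccard == 1.0
        assert rep.youden == pytest.approx(1.0)

    def test_empty_prediction(self):
        counts = confusion(_arr([]), _arr([(0, 0, 0)]), np.ones((2, 3, 1), bool))
        assert counts.tp == counts.fp == 0

    def test_empty_valid_mask_rejected(self):
        with pytest.raises(ValueError):
            confusion(_arr([]), _arr([]), _arr([]))

    def test_voxels_outside_valid_ignored(self):
        pred = _arr([(0, 0, 0), (0, 1, 0)])
        gold = _arr([(0, 0, 0)])
        valid = _arr([(0, 0, 0)])
        counts = confusion(pred, gold, valid)
        assert counts.total == 1 and counts.tp == 1 and counts.fp == 0

    @pytest.mark.parametrize(
        "sens,spec,expected", [(0.82, 0.86, 0.68), (0.61, 0.98, 0.59)]
    )
    def test_youden_worked_examples(self, sens, spec, expected):
        assert youden_index(sens, spec) == pytest.approx(expected)

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_youden_identity_holds(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        rep = report(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if np.isnan(rep.sensitivity) or np.isnan(rep.specificity):
            assert np.isnan(rep.youden)
        else:
            assert rep.youden == pytest.approx(rep.sensitivity + rep.specificity - 1)

    def test_zero_denominators_give_nan(self):
        rep = report(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(rep.sensitivity) and np.isnan(rep.jaccard)
        assert rep.specificity == 1.0

    def test_volumes_from_geometry(self):
        rep = report(ConfusionCounts(tp=3, fp=1, tn=1, fn=1), GEOM)
        assert rep.volume_pred_ul == pytest.approx(4 * 0.25)
        assert rep.volume_gold_ul == pytest.approx(4 * 0.25)


class TestJaccard:
    def test_identity_disjoint_and_half(self):
        a = _arr([(0, 0, 0), (0, 1, 0), (1, 0, 0)])
        b = _arr([(0, 1, 0), (1, 0, 0), (1, 1, 0)])
        assert jaccard_pair(a, a) == 1.0
        assert jaccard_pair(a, _arr([(1, 2, 0)])) == 0.0
        assert jaccard_pair(a, b) == 0.5

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            jaccard_pair(_arr([]), _arr([]))

    @given(st.integers(0, 2**18 - 1), st.integers(0, 2**18 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_size_bound(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(18)], bool).reshape(2, 3, 3)
        b = np.array([(bbits >> i) & 1 for i in range(18)], bool).reshape(2, 3, 3)
        if not (a.any() or b.any()):
            return
        j = jaccard_pair(a, b)
        assert j == jaccard_pair(b, a)
        na, nb = a.sum(), b.sum()
        if min(na, nb) > 0:
            assert j <= min(na, nb) / max(na, nb)


class TestInterobserver:
    def _mask(self, n_voxels, geom):
        arr = np.zeros(geom.grid_shape, bool)
        arr.ravel()[:n_voxels] = True
        return BinaryMask(arr, geom, "obs")

    def test_pair_volume_error_formula(self):
        geom = VoxelGeometry(0.5, 1.0, (20, 20, 2))
        res = interobserver_metrics([self._mask(360, geom), self._mask(440, geom)])
        # volumes 90 and 110 uL -> |20| / 100 * 100 = 20%
        assert res.volume_error_pct.iloc[0, 1] == pytest.approx(20.0)

    def test_identical_observers(self):
        geom = VoxelGeometry(0.5, 1.0, (4, 4, 2))
        masks = [self._mask(5, geom) for _ in range(3)]
        res = interobserver_metrics(masks)
        assert (res.jaccard.values == 1.0).all()
        assert res.summary["volume_error_pct_mean"] == 0.0

    def test_four_observers_six_pairs(self, light_phantom):
        res = interobserver_metrics(light_phantom.observer_masks)
        assert res.summary["n_pairs"] == 6
        assert res.jaccard.shape == (4, 4)


def _brute_force_multimodal(flat_channels, min_count):
    return flat_channels.sum(axis=0) >= min_count


def _brute_force_scores(mask, gold):
    tp = int((mask & gold).sum()); fn = int((~mask & gold).sum())
    fp = int((mask & ~gold).sum()); tn = int((~mask & ~gold).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec, (tp + tn) / mask.size


class TestAblation:
    def test_duplicate_channel_contributes_nothing_under_union_rule(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6, 2)) > 0.5
        grids = {"postgd_high": a, "t1_high": a.copy(), "t2_low": rng.random((6, 6, 2)) > 0.5}
        gold = rng.random((6, 6, 2)) > 0.7
        valid = np.ones((6, 6, 2), bool)
        # min_count 1: the mask is the channel union, so a duplicated
        # channel is fully redundant and removing either changes nothing
        df = ablation_importance(_channel_set(grids), gold, valid, min_count=1)
        assert df.loc["postgd_high", "delta_accuracy"] == 0.0
        assert df.loc["t1_high", "delta_accuracy"] == 0.0
        assert df.loc["postgd_high", "contribution"] == 0.0
        assert df["rank"].sort_values().tolist() == [1, 2, 3]

    def test_essential_channel_removal_kills_sensitivity(self):
        z = np.zeros((4, 4, 1), bool)
        tumor = z.copy(); tumor[1:3, 1:3, 0] = True
        grids = {"postgd_high": tumor.copy(), "adc_high": tumor.copy(), "cbf_low": z.copy()}
        df = ablation_importance(
            _channel_set(grids), tumor, np.ones_like(tumor), min_count=2
        )
        # removing postgd_high (or adc_high) leaves <2 channels on the tumor
        assert df.loc["postgd_high", "delta_sensitivity"] == pytest.approx(1.0)
        assert df.loc["adc_high", "delta_sensitivity"] == pytest.approx(1.0)
        assert df.loc["cbf_low", "contribution"] == 0.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(17)
        shape = (8, 8, 4)
        names = ["postgd_high", "t1_high", "t2_low", "cbv_low", "adc_low"]
        for _ in range(5):
            grids = {n: rng.random(shape) > 0.6 for n in names}
            gold = rng.random(shape) > 0.7
            valid = rng.random(shape) > 0.2
            df = ablation_importance(_channel_set(grids), gold, valid, 2)
            flat = np.stack([grids[n][valid] for n in names])
            g = gold[valid]
            full = _brute_force_multimodal(flat, 2)
            s_f, p_f, a_f = _brute_force_scores(full, g)
            for i, n in enumerate(names):
                rest = np.delete(flat, i, axis=0)
                red = _brute_force_multimodal(rest, 2)
                s, p, a = _brute_force_scores(red, g)
                assert df.loc[n, "delta_accuracy"] == pytest.approx(a_f - a, abs=1e-12)
                assert df.loc[n, "delta_sensitivity"] == pytest.approx(s_f - s, abs=1e-12)
                # removal monotonicity: sensitivity drops, specificity rises
                assert df.loc[n, "delta_sensitivity"] >= -1e-12
                assert df.loc[n, "delta_specificity"] <= 1e-12

    def test_contributions_sum_to_one_when_any_positive(self):
        rng = np.random.default_rng(2)
        shape = (8, 8, 2)
        grids = {n: rng.random(shape) > 0.5 for n in ["postgd_high", "t1_high", "adc_high"]}
        gold = grids["postgd_high"] & grids["t1_high"]
        df = ablation_importance(_channel_set(grids), gold, np.ones(shape, bool), 2)
        if (df["contribution"] > 0).any():
            assert df["contribution"].sum() == pytest.approx(1.0)
        assert (df["contribution"] >= 0).all()


class TestAdditionOrder:
    def _random_setup(self, seed, n_channels=4, shape=(8, 8, 2)):
        rng = np.random.default_rng(seed)
        names = ["postgd_high", "t1_high", "t2_low", "cbv_low", "cbf_low"][:n_channels]
        grids = {n: rng.random(shape) > 0.55 for n in names}
        gold = rng.random(shape) > 0.7
        valid = rng.random(shape) > 0.1
        return grids, gold, valid

    def test_deltas_telescope(self):
        grids, gold, valid = self._random_setup(3)
        res = addition_order_analysis(_channel_set(grids), gold, valid, 2)
        final = res.deltas[res.deltas["position"] == len(grids)]["accuracy"]
        for oi, sub in res.deltas.groupby("order"):
            assert sub["delta"].sum() == pytest.approx(
                final.iloc[0] - res.baseline_accuracy, abs=1e-12
            )

    def test_first_addition_has_zero_delta_under_counting_rule(self):
        grids, gold, valid = self._random_setup(4)
        res = addition_order_analysis(_channel_set(grids), gold, valid, 2)
        first = res.deltas[res.deltas["position"] == 1]
        assert (first["delta"].abs() < 1e-15).all()

    def test_matches_naive_per_order_loop(self):
        grids, gold, valid = self._random_setup(7, n_channels=4)
        names = list(grids)
        cs = _channel_set(grids)
        res = addition_order_analysis(cs, gold, valid, 2)
        g = gold[valid]
        flat = {n: grids[n][valid] for n in names}
        expected_rows = {}
        for order in permutations(names):
            prev = float((np.zeros_like(g) == g).mean())
            for pos, ch in enumerate(order, start=1):
                counts = np.sum([flat[c] for c in order[:pos]], axis=0)
                acc = float(((counts >= 2) == g).mean())
                expected_rows[(order, pos)] = acc - prev
                prev = acc
        agg = res.deltas.set_index(["order", "position"])
        impl_orders = res.deltas.groupby("order")["channel"].apply(tuple)
        for oi, order in impl_orders.items():
            for pos in range(1, len(names) + 1):
                assert agg.loc[(oi, pos), "delta"] == pytest.approx(
                    expected_rows[(order, pos)], abs=1e-12
                )

    def test_sampled_orders_reproducible_with_seed(self):
        grids, gold, valid = self._random_setup(11, n_channels=5)
        cs = _channel_set(grids)
        r1 = addition_order_analysis(cs, gold, valid, 2, orders=20, rng=np.random.default_rng(4))
        r2 = addition_order_analysis(cs, gold, valid, 2, orders=20, rng=np.random.default_rng(4))
        pd.testing.assert_frame_equal(r1.deltas, r2.deltas)
        assert r1.n_orders == 20


class TestOccultRim:
    def test_consensus_covering_gold_flags_empty_rim(self):
        shape = (4, 4, 1)
        gold = np.zeros(shape, bool); gold[1, 1, 0] = True
        consensus = gold.copy()
        cs = _channel_set({"postgd_high": gold.copy(), "t2_low": gold.copy()})
        res = occult_rim_analysis(gold, consensus, cs, np.ones(shape, bool))
        assert res.empty and res.ablation is None

    def test_empty_consensus_rim_equals_gold(self):
        shape = (4, 4, 1)
        gold = np.zeros(shape, bool); gold[1:3, 1:3, 0] = True
        cs = _channel_set({"postgd_high": gold.copy(), "t2_low": gold.copy()})
        res = occult_rim_analysis(gold, np.zeros(shape, bool), cs, np.ones(shape, bool))
        np.testing.assert_array_equal(res.rim.values, gold)

    def test_rim_specific_channels_top_ranking(self):
        shape = (10, 10, 2)
        core = np.zeros(shape, bool); core[3:7, 3:7, :] = True
        rim = np.zeros(shape, bool); rim[2:8, 2:8, :] = True
        rim &= ~core
        gold = core | rim
        # core detected by postgd+t1; rim abnormal only on adc_high and t2_low
        grids = {
            "postgd_high": core.copy(),
            "t1_high": core.copy(),
            "t2_low": rim.copy(),
            "adc_high": rim.copy(),
        }
        res = occult_rim_analysis(gold, core, _channel_set(grids), np.ones(shape, bool))
        top2 = set(res.ablation.sort_values("rank").index[:2])
        assert top2 == {"t2_low", "adc_high"}
        assert res.report.sensitivity == pytest.approx(1.0)


class TestRegionSummary:
    def test_constant_region(self):
        vals = np.full((4, 4, 1), 7.0)
        regions = {"core": _arr([(0, 0, 0)], (4, 4, 1)), "rim": _arr([(1, 1, 0)], (4, 4, 1))}
        df = region_histology_summary({"pimo": vals}, regions)
        row = df[(df.region == "core") & (df.parameter == "pimo")].iloc[0]
        assert row["mean"] == 7.0 and row["sd"] == 0.0 and row["n_voxels"] == 1

    def test_pooled_mean_matches_hand_computation(self):
        vals = np.zeros((2, 3, 1))
        vals[0, 0, 0] = vals[0, 1, 0] = 4.0
        vals[1, 0, 0] = 10.0
        region = _arr([(0, 0, 0), (0, 1, 0), (1, 0, 0)])
        df = region_histology_summary({"x": vals}, {"r": region})
        assert df.iloc[0]["mean"] == pytest.approx(6.0)
        assert df.iloc[0]["n_voxels"] == 3

    def test_overlapping_regions_rejected(self):
        a = _arr([(0, 0, 0)])
        with pytest.raises(ValueError):
            region_histology_summary({"x": np.zeros((2, 3, 1))}, {"a": a, "b": a})

    def test_uncovered_region_reported_missing(self):
        vals = np.full((2, 3, 1), np.nan)
        df = region_histology_summary({"x": vals}, {"r": _arr([(0, 0, 0)])})
        assert np.isnan(df.iloc[0]["mean"]) and df.iloc[0]["n_voxels"] == 0


def test_evaluate_convenience_equals_manual_composition(light_phantom):
    ph = light_phantom
    pred = ph.core_mask.values
    gold = ph.truth_mask.values
    valid = ph.brain_mask.values
    rep = evaluate(pred, gold, valid, ph.geometry)
    rep2 = report(confusion(pred, gold, valid), ph.geometry)
    assert rep.to_dict() == rep2.to_dict()
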