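"""Metrics, grid search, model training, routing, CV and evaluation."""

import math

import numpy as np
import pytest

from glycmotif.classifier import (
    ModelBundle,
    SVMParams,
    compute_metrics,
    cross_validate,
    evaluate_independent,
    grid_search,
    predict,
    train_mdd_clustered,
    train_second_layer,
    train_single,
)
from glycmotif.mdd import MDDConfig, mdd_cluster, route_fragment
from glycmotif.seqdata import ProteinRecord, SiteRecord


def _separable_toy(frag_factory, n=30):
    """Windows trivially separable by the residue at offset -5."""
    pos = [frag_factory("WAAAASAAAAA", f"POS{i}", 6, "positive") for i in range(n)]
    neg = [frag_factory("DAAAASAAAAA", f"NEG{i}", 6, "negative") for i in range(n)]
    return pos, neg


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(tp=10, fp=0, tn=10, fn=0)
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_balanced_design_accuracy(self):
        # Sn=0.76 and Sp=0.80 on a balanced 375/375 design
        m = compute_metrics(tp=285, fn=90, tn=300, fp=75)
        assert m.sn == pytest.approx(0.76)
        assert m.sp == pytest.approx(0.80)
        assert m.acc == pytest.approx(0.78)

    def test_mcc_against_direct_arithmetic(self):
        tp, fn, tn, fp = 285, 90, 300, 75
        m = compute_metrics(tp=tp, fp=fp, tn=tn, fn=fn)
        expected = (tp * tn - fn * fp) / math.sqrt(
            (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
        )
        assert m.mcc == pytest.approx(expected, abs=1e-12)

    def test_random_confusions_match_formulas(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 500, 4))
            m = compute_metrics(tp, fp, tn, fn)
            assert m.sn == pytest.approx(tp / (tp + fn))
            assert m.sp == pytest.approx(tn / (tn + fp))
            assert m.acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert -1.0 <= m.mcc <= 1.0
            assert m.acc * m.total == pytest.approx(tp + tn)

    def test_undefined_metric_is_nan_not_zero(self):
        m = compute_metrics(tp=0, fp=0, tn=5, fn=0)
        assert math.isnan(m.sn) and math.isnan(m.mcc)
        assert m.sp == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    def test_presentation_rounding(self):
        m = compute_metrics(tp=285, fn=90, tn=300, fp=75)
        assert m.format_row() == "0.76 0.80 0.78 0.56"


class TestGridSearch:
    def test_separable_reaches_perfect_balanced_accuracy(self, frag_factory):
        from glycmotif.encoders import encode_fragments

        pos, neg = _separable_toy(frag_factory, 15)
        Xp = encode_fragments(pos, "binary")
        Xn = encode_fragments(neg, "binary")
        params = grid_search(Xp, Xn, [SVMParams(1, 0.01), SVMParams(8, 0.1)], seed=0)
        assert params.C > 0

    def test_returned_point_beats_grid_by_exhaustive_recheck(self, bench_data):
        from glycmotif.encoders import encode_fragments
        from glycmotif.sampling import random_subsample

        pos = bench_data.pos_fragments[:60]
        neg = random_subsample(bench_data.neg_fragments, 60, seed=0)
        Xp = encode_fragments(pos, "binary")
        Xn = encode_fragments(neg, "binary")
        grid = [SVMParams(C=c, gamma=g) for c in (0.5, 4, 32) for g in (0.004, 0.06, 0.5)]

        def objective(p):
            from sklearn.model_selection import StratifiedKFold
            from glycmotif.classifier import _fit_svc, _proba_positive

            X = np.vstack([Xp, Xn])
            y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xn), int)])
            skf = StratifiedKFold(3, shuffle=True, random_state=0)
            tp = fp = tn = fn = 0
            for tr, te in skf.split(X, y):
                clf = _fit_svc(X[tr], y[tr], p, 0)
                pred = (_proba_positive(clf, X[te]) >= 0.5).astype(int)
                tp += int(np.sum((pred == 1) & (y[te] == 1)))
                fp += int(np.sum((pred == 1) & (y[te] == 0)))
                tn += int(np.sum((pred == 0) & (y[te] == 0)))
                fn += int(np.sum((pred == 0) & (y[te] == 1)))
            return (tp / (tp + fn) + tn / (tn + fp)) / 2

        best = grid_search(Xp, Xn, grid, k=3, seed=0)
        best_obj = objective(best)
        assert all(objective(p) <= best_obj + 1e-12 for p in grid)

    def test_deterministic(self, frag_factory):
        from glycmotif.encoders import encode_fragments

        pos, neg = _separable_toy(frag_factory, 12)
        Xp, Xn = encode_fragments(pos, "binary"), encode_fragments(neg, "binary")
        grid = [SVMParams(1, 0.01), SVMParams(2, 0.02)]
        assert grid_search(Xp, Xn, grid, seed=5) == grid_search(Xp, Xn, grid, seed=5)


class TestTrainSingle:
    def test_overfit_sanity_on_separable_toy(self, frag_factory):
        pos, neg = _separable_toy(frag_factory)
        bundle = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        metrics = evaluate_independent(bundle, pos + neg)
        assert metrics.acc > 0.95

    def test_single_class_rejected(self, frag_factory):
        pos, _ = _separable_toy(frag_factory, 5)
        with pytest.raises(ValueError):
            train_single(pos, [], "binary", SVMParams())

    def test_serialization_roundtrip_bit_identical(self, frag_factory, tmp_path):
        pos, neg = _separable_toy(frag_factory)
        bundle = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        path = tmp_path / "model.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        from glycmotif.classifier import _score_fragments

        p1, _ = _score_fragments(bundle, pos + neg)
        p2, _ = _score_fragments(loaded, pos + neg)
        assert np.array_equal(p1, p2)


class TestTrainClustered:
    def test_single_leaf_equivalent_to_single(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 20)
        # min_cluster_size above the data size forces a root-only tree
        cfg = MDDConfig(min_cluster_size=150)
        clustered = train_mdd_clustered(
            pos, neg, cfg, "binary", SVMParams(8, 0.05), seed=0
        )
        assert clustered.tree.is_leaf
        single = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        from glycmotif.classifier import _score_fragments

        pc, _ = _score_fragments(clustered, pos + neg)
        ps, _ = _score_fragments(single, pos + neg)
        assert np.allclose(pc, ps)

    def test_every_leaf_has_a_model(self, bench_data):
        from glycmotif.sampling import random_subsample

        negs = random_subsample(bench_data.neg_fragments, 375, seed=0)
        bundle = train_mdd_clustered(
            bench_data.pos_fragments, negs, MDDConfig(), "binary",
            SVMParams(8, 0.05), seed=0,
        )
        leaf_ids = {leaf.leaf_id for leaf in bundle.tree.leaves()}
        assert set(bundle.models) == leaf_ids
        assert set(bundle.leaf_params) == leaf_ids

    def test_routing_is_total(self, bench_data, random_windows):
        tree = mdd_cluster(bench_data.pos_fragments)
        leaf_ids = {leaf.leaf_id for leaf in tree.leaves()}
        assert all(route_fragment(tree, f) in leaf_ids for f in random_windows)


class TestPredict:
    def test_probability_half_is_positive(self, frag_factory):
        # boundary rule: probability >= 0.5 counts as positive
        pos, neg = _separable_toy(frag_factory)
        bundle = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        proteins = {"Q1": ProteinRecord("Q1", "WAAAASAAAAA")}
        rows = predict(bundle, proteins, sites=[SiteRecord("Q1", 6, "S", "unknown")])
        assert rows[0]["label"] == ("positive" if rows[0]["probability"] >= 0.5 else "negative")

    def test_row_per_st_site(self, frag_factory):
        pos, neg = _separable_toy(frag_factory)
        bundle = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        proteins = {"Q1": ProteinRecord("Q1", "STACKSSTACK")}
        rows = predict(bundle, proteins)
        n_st = sum(1 for ch in "STACKSSTACK" if ch in "ST")
        assert len(rows) == n_st

    def test_heldout_auc_on_benchmark(self, bench_data):
        """Held-out positives score above held-out negatives (AUC > 0.9
        would be optimistic at this signal level; require clear ranking)."""
        from glycmotif.sampling import random_subsample

        pos = bench_data.pos_fragments
        negs = random_subsample(bench_data.neg_fragments, 375, seed=1)
        bundle = train_mdd_clustered(
            pos[:300], negs[:300], MDDConfig(), "binary", SVMParams(8, 2**-6), seed=0
        )
        from glycmotif.classifier import _score_fragments

        pp, _ = _score_fragments(bundle, pos[300:])
        pn, _ = _score_fragments(bundle, negs[300:])
        # probability of a random positive outranking a random negative
        auc = np.mean([p > n for p in pp for n in pn]) + 0.5 * np.mean(
            [p == n for p in pp for n in pn]
        )
        assert auc > 0.7
        assert pp.mean() > pn.mean()


class TestSecondLayer:
    def test_stacking_input_dimension_is_leaf_count(self, bench_data):
        from glycmotif.sampling import random_subsample
        from glycmotif.classifier import _stacking_features, _score_fragments
        from glycmotif.encoders import encode_fragments

        negs = random_subsample(bench_data.neg_fragments, 375, seed=0)
        bundle = train_mdd_clustered(
            bench_data.pos_fragments, negs, MDDConfig(), "binary",
            SVMParams(8, 2**-6), seed=0,
        )
        bundle = train_second_layer(bundle, bench_data.pos_fragments[:50], negs[:50])
        X = encode_fragments(bench_data.pos_fragments[:5], "binary")
        stacked = _stacking_features(bundle, X)
        assert stacked.shape == (5, len(bundle.models))
        # enabling the layer changes the scoring path but stays valid
        bundle.use_second_layer = True
        probs, _ = _score_fragments(bundle, bench_data.pos_fragments[:5])
        assert np.all((probs >= 0) & (probs <= 1))


class TestCrossValidate:
    def test_pooled_counts_sum_to_data_size(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 20)
        m = cross_validate(pos, neg, k=5, params=SVMParams(8, 0.05), seed=0)
        assert m.total == 40

    def test_leave_one_out_degenerate(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 6)
        m = cross_validate(pos, neg, k=6, params=SVMParams(8, 0.05), seed=0)
        assert m.total == 12

    def test_separable_toy_near_perfect(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 20)
        m = cross_validate(pos, neg, k=5, params=SVMParams(8, 0.05), seed=0)
        assert m.acc > 0.9

    def test_deterministic_given_seed(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 15)
        m1 = cross_validate(pos, neg, k=3, params=SVMParams(2, 0.05), seed=4)
        m2 = cross_validate(pos, neg, k=3, params=SVMParams(2, 0.05), seed=4)
        assert m1 == m2

    def test_k_below_two_rejected(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 5)
        with pytest.raises(ValueError):
            cross_validate(pos, neg, k=1)


class TestEvaluateIndependent:
    def test_metrics_equal_manual_recount(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 15)
        bundle = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        test = pos[:10] + neg[:10]
        m = evaluate_independent(bundle, test)
        from glycmotif.classifier import _score_fragments

        probs, _ = _score_fragments(bundle, test)
        pred = probs >= 0.5
        truth = np.array([f.label == "positive" for f in test])
        assert m.tp == int(np.sum(pred & truth))
        assert m.tn == int(np.sum(~pred & ~truth))
        assert m.fp == int(np.sum(pred & ~truth))
        assert m.fn == int(np.sum(~pred & truth))

    def test_imbalanced_test_specificity_dominates_accuracy(self, bench_data):
        """At a ~1:8 class ratio Acc tracks Sp much closer than Sn."""
        from glycmotif.sampling import random_subsample

        pos = bench_data.pos_fragments
        negs = random_subsample(bench_data.neg_fragments, 375, seed=3)
        bundle = train_mdd_clustered(
            pos[:300], negs[:300], MDDConfig(), "binary", SVMParams(8, 2**-6), seed=0
        )
        test = pos[300:] + [
            f for f in bench_data.neg_fragments if f not in set(negs[:300])
        ][:600]
        m = evaluate_independent(bundle, test)
        assert abs(m.acc - m.sp) < abs(m.acc - m.sn)

    def test_empty_test_rejected(self, frag_factory):
        pos, neg = _separable_toy(frag_factory, 5)
        bundle = train_single(pos, neg, "binary", SVMParams(8, 0.05), seed=0)
        with pytest.raises(ValueError):
            evaluate_independent(bundle, [])
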