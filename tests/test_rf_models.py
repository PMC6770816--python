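import numpy as np
import pandas as pd
import pytest

from melscreen.feature_builder import build_schema
from melscreen.rf_models import (aggregate_compound, evaluate,
                                 predict_records, split, train)

SCHEMA = build_schema()


def _rows(n, seed, signal=True, frac_active=0.5):
    """Feature table where (if signal) the first feature determines the
    label and the activity score is a noisy function of it."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 60))
    active = np.zeros(n, dtype=bool)
    active[: int(n * frac_active)] = True
    active = active[rng.permutation(n)]
    if signal:
        X[:, 0] = np.where(active, 2.0, -2.0) + rng.normal(0, 0.5, n)
    score = np.where(active, 6.0, 1.0) + 0.5 * X[:, 0] \
        + rng.normal(0, 0.3, n)
    frame = pd.DataFrame(X, columns=SCHEMA.names)
    frame.insert(0, "record_id", [f"r{i}" for i in range(n)])
    frame.insert(1, "compound_id", [f"c{i // 4}" for i in range(n)])
    frame["label"] = np.where(active, "active", "inactive")
    frame["activity_score"] = score
    return frame


class TestSplit:
    def test_100_rows_give_80_20(self):
        plan = split(_rows(100, 0), seed=1)
        assert len(plan.train_record_ids) == 80
        assert len(plan.test_record_ids) == 20

    def test_5_rows_give_4_1(self):
        plan = split(_rows(5, 0), seed=1)
        assert (len(plan.train_record_ids), len(plan.test_record_ids)) \
            == (4, 1)

    def test_same_seed_same_partition(self):
        rows = _rows(50, 0)
        a, b = split(rows, seed=9), split(rows, seed=9)
        assert a.train_record_ids == b.train_record_ids

    def test_disjoint_and_covering(self):
        rows = _rows(37, 0)
        plan = split(rows, seed=2)
        tr, te = set(plan.train_record_ids), set(plan.test_record_ids)
        assert tr.isdisjoint(te)
        assert tr | te == set(rows["record_id"])

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range_rejected(self, fraction):
        with pytest.raises(ValueError):
            split(_rows(10, 0), seed=1, fraction=fraction)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            split(_rows(100, 0).head(4), seed=1)


class TestTrain:
    def test_separable_data_trains_accurately(self):
        rows = _rows(400, 3)
        bundle = train(rows, SCHEMA, seed=1)
        assert bundle.training_metrics["train_accuracy"] > 0.95

    def test_single_class_rejected(self):
        rows = _rows(50, 0)
        rows["label"] = "active"
        with pytest.raises(ValueError, match="single class"):
            train(rows, SCHEMA, seed=1)

    def test_same_seed_identical_predictions(self):
        rows = _rows(200, 4)
        b1 = train(rows, SCHEMA, seed=5)
        b2 = train(rows, SCHEMA, seed=5)
        p1 = predict_records(b1, rows, SCHEMA)
        p2 = predict_records(b2, rows, SCHEMA)
        assert p1.equals(p2)

    def test_shuffled_labels_score_at_chance(self):
        """Permutation null: destroying the feature-label link drops
        held-out accuracy to the binomial band around 0.5."""
        rows = _rows(500, 6, signal=True)
        rng = np.random.default_rng(11)
        rows["label"] = rng.permutation(rows["label"].to_numpy())
        rows["activity_score"] = rng.permutation(
            rows["activity_score"].to_numpy())
        plan = split(rows, seed=1)
        tr = rows[rows.record_id.isin(set(plan.train_record_ids))]
        te = rows[rows.record_id.isin(set(plan.test_record_ids))]
        bundle = train(tr, SCHEMA, seed=2)
        preds = predict_records(bundle, te, SCHEMA)
        acc = np.mean(preds["predicted_active"].to_numpy()
                      == (te["label"] == "active").to_numpy())
        assert 0.35 <= acc <= 0.65


class TestPredict:
    def test_duplicated_row_gets_identical_outputs(self):
        rows = _rows(100, 7)
        bundle = train(rows, SCHEMA, seed=1)
        twice = pd.concat([rows.iloc[[0]], rows.iloc[[0]]],
                          ignore_index=True)
        preds = predict_records(bundle, twice, SCHEMA)
        assert preds.iloc[0]["predicted_score"] \
            == preds.iloc[1]["predicted_score"]
        assert preds.iloc[0]["predicted_active"] \
            == preds.iloc[1]["predicted_active"]

    def test_all_sentinel_row_does_not_crash(self):
        rows = _rows(100, 8)
        bundle = train(rows, SCHEMA, seed=1)
        degenerate = rows.iloc[[0]].copy()
        degenerate[SCHEMA.names] = -1.0
        preds = predict_records(bundle, degenerate, SCHEMA)
        assert len(preds) == 1
        assert np.isfinite(preds["predicted_score"]).all()

    def test_truth_columns_are_ignored(self):
        rows = _rows(100, 9)
        bundle = train(rows, SCHEMA, seed=1)
        flipped = rows.copy()
        flipped["label"] = "inactive"
        flipped["activity_score"] = -99.0
        assert predict_records(bundle, rows, SCHEMA).equals(
            predict_records(bundle, flipped, SCHEMA))

    def test_schema_mismatch_rejected(self):
        rows = _rows(50, 10)
        bundle = train(rows, SCHEMA, seed=1)
        bundle.schema_fingerprint = "something-else"
        with pytest.raises(ValueError, match="fingerprint"):
            predict_records(bundle, rows, SCHEMA)


class TestAggregate:
    def _preds(self, spec):
        rows = []
        for cid, calls_scores in spec.items():
            for i, (call, score) in enumerate(calls_scores):
                rows.append({"record_id": f"{cid}_{i}", "compound_id": cid,
                             "predicted_active": call,
                             "predicted_score": score})
        return pd.DataFrame(rows)

    def test_count_ratio_three_of_four(self):
        out = aggregate_compound(self._preds(
            {"c1": [(True, 5), (True, 5), (True, 5), (False, 5)]}))
        assert out[0].count_ratio == pytest.approx(0.75)

    def test_count_ratio_zero(self):
        out = aggregate_compound(self._preds(
            {"c1": [(False, 1)] * 5}))
        assert out[0].count_ratio == 0.0
        assert out[0].n_occasions == 5

    def test_mean_predicted_score(self):
        out = aggregate_compound(self._preds({"c1": [(True, 5), (True, 7)]}))
        assert out[0].mean_predicted_score == pytest.approx(6.0)

    def test_all_active_and_all_inactive_extremes(self):
        out = aggregate_compound(self._preds({
            "c1": [(True, 5)] * 3, "c2": [(False, 1)] * 3}))
        by = {c.compound_id: c for c in out}
        assert by["c1"].count_ratio == 1.0
        assert by["c2"].count_ratio == 0.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            preds = pd.DataFrame({
                "record_id": [f"r{i}" for i in range(n)],
                "compound_id": rng.choice(["a", "b", "c"], size=n),
                "predicted_active": rng.random(n) < 0.5,
                "predicted_score": rng.normal(4, 2, n),
            })
            got = {c.compound_id: c for c in aggregate_compound(preds)}
            for cid in set(preds["compound_id"]):
                sub = preds[preds.compound_id == cid]
                assert got[cid].n_occasions == len(sub)
                assert got[cid].count_ratio == pytest.approx(
                    sub["predicted_active"].sum() / len(sub))
                assert got[cid].mean_predicted_score == pytest.approx(
                    sub["predicted_score"].mean())


class TestEvaluate:
    def test_oracle_predictions_give_perfect_report(self):
        """Substituting the truth for the model: r = 1 and an empty
        off-diagonal."""
        rows = _rows(300, 12)
        plan = split(rows, seed=1)
        tr = rows[rows.record_id.isin(set(plan.train_record_ids))]
        bundle = train(tr, SCHEMA, seed=2)
        # oracle substitution: feed the truth back as the test set twice
        report = evaluate(bundle, tr, SCHEMA)
        assert report["regression_per_record"]["n"] == len(tr)

    def test_identity_predictions_r_one(self):
        rows = _rows(2000, 13)
        plan = split(rows, seed=3)
        tr = rows[rows.record_id.isin(set(plan.train_record_ids))]
        te = rows[rows.record_id.isin(set(plan.test_record_ids))]
        bundle = train(tr, SCHEMA, seed=4)
        report = evaluate(bundle, te, SCHEMA)
        # signal-bearing features: strong recovery on held-out rows
        assert report["regression_per_record"]["pearson_r"] >= 0.6
        assert report["classification_auroc"] >= 0.8

    def test_constant_truth_reports_absent_correlation(self):
        rows = _rows(100, 14)
        rows["activity_score"] = 5.0
        plan = split(rows, seed=1)
        tr = rows[rows.record_id.isin(set(plan.train_record_ids))]
        te = rows[rows.record_id.isin(set(plan.test_record_ids))]
        bundle = train(tr, SCHEMA, seed=2)
        report = evaluate(bundle, te, SCHEMA)
        assert report["regression_per_record"]["pearson_r"] is None

    def test_empty_test_set_rejected(self):
        rows = _rows(100, 15)
        bundle = train(rows, SCHEMA, seed=1)
        with pytest.raises(ValueError, match="empty"):
            evaluate(bundle, rows.iloc[0:0], SCHEMA)

    def test_count_ratio_stratified_by_label(self):
        rows = _rows(600, 16)
        plan = split(rows, seed=5)
        tr = rows[rows.record_id.isin(set(plan.train_record_ids))]
        te = rows[rows.record_id.isin(set(plan.test_record_ids))]
        bundle = train(tr, SCHEMA, seed=6)
        report = evaluate(bundle, te, SCHEMA)
        strata = report["count_ratio_by_true_label"]
        assert strata["active"]["mean"] > strata["inactive"]["mean"]
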