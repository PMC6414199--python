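"""Apoptosis scoring: classifier, manual flags, death curves, colocalization."""

import numpy as np
import pandas as pd
import pytest

from flimfret.celldeath import (
    classify_cells,
    death_by_expression_bins,
    default_venus_bins,
    object_filters,
    pearson_colocalization,
    train_linear_classifier,
    two_sd_flags,
)
from flimfret.exceptions import ParameterError, SchemaError
from flimfret.synthgen import CELL_FEATURES, gen_cell_features


def controls(separation, n=500, seed=0):
    df = gen_cell_features(n_per_class=n, class_separation=separation, n_cells=0, seed=seed)
    pos = df[df["control_label"] == "positive"]
    neg = df[df["control_label"] == "negative"]
    return pos, neg


class TestClassifier:
    def test_high_accuracy_on_separated_controls(self):
        pos, neg = controls(6.0)
        model = train_linear_classifier(pos, neg)
        assert model.training_summary["training_accuracy"] >= 0.99

    def test_chance_accuracy_on_identical_distributions(self):
        pos, neg = controls(0.0)
        model = train_linear_classifier(pos, neg)
        acc = model.training_summary["training_accuracy"]
        assert abs(acc - 0.5) < 0.08  # within binomial noise of chance

    def test_duplicated_feature_gives_same_predictions(self):
        pos, neg = controls(3.0)
        cells = gen_cell_features(n_per_class=10, class_separation=3.0, n_cells=300, seed=9)
        base = train_linear_classifier(pos, neg)
        dup_feat = CELL_FEATURES + ["tmre_copy"]
        pos2 = pos.assign(tmre_copy=pos["tmre_total"])
        neg2 = neg.assign(tmre_copy=neg["tmre_total"])
        cells2 = cells.assign(tmre_copy=cells["tmre_total"])
        dup = train_linear_classifier(pos2, neg2, features=dup_feat)
        pd.testing.assert_series_equal(classify_cells(base, cells), classify_cells(dup, cells2))

    def test_agrees_with_sklearn_lda(self):
        # independent reference implementation on a well-conditioned problem
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        pos, neg = controls(3.0, n=400, seed=3)
        cells = gen_cell_features(n_per_class=10, class_separation=3.0, n_cells=500, seed=11)
        model = train_linear_classifier(pos, neg)
        ours = classify_cells(model, cells) == "dead"

        X = pd.concat([pos, neg])[CELL_FEATURES].to_numpy()
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(cells[CELL_FEATURES].to_numpy())
        agreement = np.mean(ours.to_numpy() == (ref == 1))
        assert agreement > 0.97

    def test_insufficient_controls(self):
        pos, neg = controls(3.0, n=120)
        with pytest.raises(ParameterError):
            train_linear_classifier(pos.head(50), neg)

    def test_zero_variance_feature_dropped_with_warning(self):
        pos, neg = controls(3.0, n=150)
        pos2 = pos.assign(flat=1.0)
        neg2 = neg.assign(flat=1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            model = train_linear_classifier(pos2, neg2, features=CELL_FEATURES + ["flat"])
        assert "flat" not in model.feature_names

    def test_centroids_and_tie_rule(self):
        pos, neg = controls(6.0)
        model = train_linear_classifier(pos, neg)
        centroids = pd.DataFrame(
            {f: [pos[f].mean(), neg[f].mean()] for f in model.feature_names}
        )
        labels = classify_cells(model, centroids)
        assert list(labels) == ["dead", "alive"]
        # a cell scoring exactly at the threshold labels alive
        w, thr = model.weights, model.bias
        x_on_boundary = model.feature_means + model.feature_sds * (thr * w / (w @ w))
        boundary = pd.DataFrame([dict(zip(model.feature_names, x_on_boundary))])
        assert model.scores(boundary)[0] == pytest.approx(thr, abs=1e-9)
        assert classify_cells(model, boundary)[0] == "alive"

    def test_missing_feature_schema_error(self):
        pos, neg = controls(3.0, n=150)
        model = train_linear_classifier(pos, neg)
        with pytest.raises(SchemaError):
            classify_cells(model, pos.drop(columns=["tmre_total"]))


class TestTwoSdFlags:
    def test_strict_cutoff(self):
        ref = pd.DataFrame({"tmre_total": np.r_[np.full(20, 100.0), np.full(20, 120.0)],
                            "nuclear_area": np.full(40, 1000.0) + np.r_[np.full(20, -50.0), np.full(20, 50.0)]})
        mu, sd = ref["tmre_total"].mean(), ref["tmre_total"].std(ddof=1)
        cells = pd.DataFrame({
            "tmre_total": [mu - 2.0001 * sd, mu - 1.9 * sd],
            "nuclear_area": [1000.0, 1000.0],
        })
        flags = two_sd_flags(cells, ref)
        assert list(flags["tmre_negative"]) == [True, False]
        assert not flags["small_nucleus"].any()

    def test_constructed_counts(self):
        rng = np.random.default_rng(0)
        ref = pd.DataFrame({"tmre_total": rng.normal(1000, 100, 200),
                            "nuclear_area": rng.normal(1200, 150, 200)})
        cutoff = ref["tmre_total"].mean() - 2 * ref["tmre_total"].std(ddof=1)
        vals = np.linspace(cutoff - 50, cutoff + 50, 50)  # 7 values strictly below? count them
        n_below = int((vals < cutoff).sum())
        cells = pd.DataFrame({"tmre_total": vals, "nuclear_area": np.full(50, 1200.0)})
        assert int(two_sd_flags(cells, ref)["tmre_negative"].sum()) == n_below

    def test_small_reference_rejected(self):
        ref = pd.DataFrame({"tmre_total": [1.0] * 5, "nuclear_area": [1.0] * 5})
        with pytest.raises(ParameterError):
            two_sd_flags(ref, ref)


class TestDeathCurve:
    def test_all_dead_bin(self):
        cells = pd.DataFrame({
            "venus_mean": np.linspace(10, 90, 90),
            "replicate_id": ["rep1", "rep2", "rep3"] * 30,
        })
        labels = pd.Series(["dead"] * 90)
        pts = death_by_expression_bins(labels, cells, [0.0, 100.0], min_cells=30)
        assert len(pts) == 1
        assert pts[0].pct_dead_mean == pytest.approx(100.0)
        assert pts[0].pct_dead_sem == pytest.approx(0.0)

    def test_sem_across_replicates(self):
        # replicate %Dead of 40, 50, 60 -> mean 50, SEM 5.774
        rows = []
        for rep, pct in (("r1", 40), ("r2", 50), ("r3", 60)):
            for i in range(10):
                rows.append({"venus_mean": 50.0, "replicate_id": rep, "dead": i < pct // 10})
        cells = pd.DataFrame(rows)
        labels = pd.Series(np.where(cells["dead"], "dead", "alive"))
        pts = death_by_expression_bins(labels, cells, [0.0, 100.0], min_cells=30)
        assert pts[0].pct_dead_mean == pytest.approx(50.0)
        assert pts[0].pct_dead_sem == pytest.approx(np.std([40, 50, 60], ddof=1) / np.sqrt(3))

    def test_minimum_cell_rule_drops_bin(self):
        cells = pd.DataFrame({"venus_mean": [10.0] * 29, "replicate_id": ["r1"] * 29})
        pts = death_by_expression_bins(pd.Series(["dead"] * 29), cells, [0.0, 100.0], min_cells=30)
        assert pts == []

    def test_single_replicate_sem_unavailable(self):
        cells = pd.DataFrame({"venus_mean": [10.0] * 40, "replicate_id": ["r1"] * 40})
        pts = death_by_expression_bins(pd.Series(["dead"] * 40), cells, [0.0, 100.0])
        assert np.isnan(pts[0].pct_dead_sem)

    def test_logistic_midpoint_recovered(self):
        # empirical 50% crossing of the death curve lands near the true EC50
        ec50 = 1000.0
        df = gen_cell_features(n_per_class=200, class_separation=6.0,
                               venus_death_ec50=ec50, venus_death_slope=2.5,
                               n_cells=6000, seed=13)
        pos = df[df["control_label"] == "positive"]
        neg = df[df["control_label"] == "negative"]
        tx = df[df["control_label"] == "none"].reset_index(drop=True)
        model = train_linear_classifier(pos, neg)
        labels = classify_cells(model, tx)
        pts = death_by_expression_bins(labels, tx, default_venus_bins(tx, 12))
        mids = np.array([(p.venus_bin[0] * p.venus_bin[1]) ** 0.5 for p in pts])
        pct = np.array([p.pct_dead_mean for p in pts])
        crossing = float(np.interp(50.0, pct, mids))  # pct is increasing in venus
        assert abs(crossing - ec50) / ec50 < 0.15

    def test_pct_dead_bounds_invariant(self):
        df = gen_cell_features(n_per_class=150, n_cells=2000, seed=4)
        tx = df[df["control_label"] == "none"].reset_index(drop=True)
        labels = pd.Series(np.where(tx["true_dead"], "dead", "alive"))
        for p in death_by_expression_bins(labels, tx, default_venus_bins(tx)):
            assert 0.0 <= p.pct_dead_mean <= 100.0


class TestObjectFilters:
    @pytest.fixture
    def cells(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "venus_mean": rng.uniform(0, 200, 80),
            "venus_median": rng.uniform(0, 200, 80),
            "mito_mean": rng.uniform(0, 2000, 80),
            "cell_area": rng.uniform(100, 9000, 80),
        })

    def test_single_failure_reason(self, cells):
        one = cells.iloc[[0]].assign(venus_mean=100.0, venus_median=100.0,
                                     mito_mean=500.0, cell_area=50.0)
        kept, counts = object_filters(one, venus_mean_min=10, venus_median_min=10,
                                      mito_band=(100, 1000), size_band=(200, 8000))
        assert counts["size"] == 1 and counts["kept"] == 0
        assert counts["venus_mean"] == counts["mito"] == 0

    def test_disabled_thresholds_identity(self, cells):
        kept, counts = object_filters(cells)
        assert len(kept) == len(cells) and counts["kept"] == 80

    def test_known_pass_count(self, cells):
        kwargs = dict(venus_mean_min=50, venus_median_min=50,
                      mito_band=(500.0, 1500.0), size_band=(1000.0, 8000.0))
        expected = int((
            (cells["venus_mean"] >= 50) & (cells["venus_median"] >= 50)
            & cells["mito_mean"].between(500, 1500) & cells["cell_area"].between(1000, 8000)
        ).sum())
        kept, counts = object_filters(cells, **kwargs)
        assert len(kept) == expected == counts["kept"]


class TestColocalization:
    def pixel_table(self, a, b, obj="o1", rep="r1", bg=(0.0, 0.0)):
        return pd.DataFrame({"object_id": obj, "replicate_id": rep,
                             "channel_a": a, "channel_b": b, "bg_a": bg[0], "bg_b": bg[1]})

    def test_perfect_linear_correlation(self):
        a = np.linspace(10, 100, 50)
        per_obj, summary = pearson_colocalization(self.pixel_table(a, 2 * a + 3))
        assert per_obj["r"].iloc[0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.linspace(10, 100, 50)
        per_obj, _ = pearson_colocalization(self.pixel_table(a, 200.0 - a))
        assert per_obj["r"].iloc[0] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(3)
        tbl = self.pixel_table(rng.uniform(50, 150, 10**4), rng.uniform(50, 150, 10**4))
        per_obj, _ = pearson_colocalization(tbl)
        assert abs(per_obj["r"].iloc[0]) < 0.05

    def test_background_shift_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(50, 150, 500)
        b = 0.5 * a + rng.uniform(0, 20, 500)
        r0 = pearson_colocalization(self.pixel_table(a, b))[0]["r"].iloc[0]
        r1 = pearson_colocalization(self.pixel_table(a + 30.0, b, bg=(30.0, 0.0)))[0]["r"].iloc[0]
        assert r1 == pytest.approx(r0)

    def test_replicate_aggregation(self):
        rng = np.random.default_rng(5)
        frames = []
        for rep in ("r1", "r2", "r3"):
            for obj in ("a", "b"):
                x = rng.uniform(10, 100, 100)
                frames.append(self.pixel_table(x, x + rng.normal(0, 5, 100),
                                               obj=f"{rep}{obj}", rep=rep))
        _, summary = pearson_colocalization(pd.concat(frames, ignore_index=True))
        assert summary["n_replicates"] == 3 and summary["n_objects"] == 6
        means = list(summary["replicate_means"].values())
        assert summary["mean_r"] == pytest.approx(np.mean(means))
        assert summary["sem_r"] == pytest.approx(np.std(means, ddof=1) / np.sqrt(3))

    def test_small_or_degenerate_objects_skipped(self):
        good = self.pixel_table(np.linspace(1, 50, 50), np.linspace(1, 50, 50))
        tiny = self.pixel_table(np.arange(5.0), np.arange(5.0), obj="tiny")
        flat = self.pixel_table(np.full(50, 7.0), np.linspace(1, 50, 50), obj="flat")
        with pytest.warns(UserWarning):
            per_obj, _ = pearson_colocalization(pd.concat([good, tiny, flat], ignore_index=True))
        assert list(per_obj["object_id"]) == ["o1"]
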