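"""classify: matrix assembly, linear SVM, jack-knife, island ranking."""

import numpy as np
import pandas as pd
import pytest

from cleavescan import (
    NORMAL,
    TUMOR,
    InputError,
    IslandRateMatrix,
    LinearSvmModel,
    build_matrix,
    jackknife_evaluate,
    predict,
    rank_islands,
    train_classifier,
)


def separable_matrix(n_per_class=20, n_islands=10, shift_sd=5.0, seed=0):
    """Two Gaussian clusters separated by `shift_sd` pooled SDs per island."""
    rng = np.random.default_rng(seed)
    normal = rng.normal(1.0, 0.1, size=(n_per_class, n_islands))
    tumor = rng.normal(1.0 - shift_sd * 0.1, 0.1, size=(n_per_class, n_islands))
    ids = [f"n{i}" for i in range(n_per_class)] + [f"t{i}" for i in range(n_per_class)]
    values = pd.DataFrame(
        np.vstack([normal, tumor]).clip(min=0),
        index=ids,
        columns=[f"isl{j}" for j in range(n_islands)],
    )
    labels = pd.Series(
        [NORMAL] * n_per_class + [TUMOR] * n_per_class, index=ids
    )
    return IslandRateMatrix(values, labels)


class TestBuildMatrix:
    def test_complete_tables_drop_nothing(self):
        tables = {f"s{i}": {"a": 1.0, "b": 2.0, "c": 3.0} for i in range(4)}
        labels = {f"s{i}": TUMOR for i in range(4)}
        m = build_matrix(tables, labels)
        assert m.values.shape == (4, 3) and m.dropped_islands == []

    def test_island_missing_in_most_samples_is_dropped(self):
        tables = {
            "s0": {"a": 1.0, "b": 2.0},
            "s1": {"a": 1.0},
            "s2": {"a": 1.0},
            "s3": {"a": 1.0},
        }
        m = build_matrix(tables, {s: NORMAL for s in tables})
        assert m.dropped_islands == ["b"]
        assert list(m.values.columns) == ["a"]

    def test_surviving_missing_cells_take_column_median(self):
        tables = {
            "s0": {"a": 1.0},
            "s1": {"a": 3.0},
            "s2": {"a": 7.0},
            "s3": {"a": 100.0, "b": 5.0},
        }
        # island a missing nowhere; in a 4-sample setting one NaN (25%) in a
        # column exceeds the default 0.2 threshold, so use 0.25
        tables["s0"]["b"] = 1.0
        tables["s1"]["b"] = 9.0
        m = build_matrix(tables, {s: NORMAL for s in tables}, max_missing_frac=0.25)
        assert m.values.loc["s2", "b"] == pytest.approx(np.median([1.0, 9.0, 5.0]))

    def test_nan_rate_counts_as_missing(self):
        tables = {
            "s0": {"a": float("nan"), "b": 1.0},
            "s1": {"a": float("nan"), "b": 2.0},
            "s2": {"a": 1.0, "b": 3.0},
        }
        m = build_matrix(tables, {s: NORMAL for s in tables})
        assert m.dropped_islands == ["a"]

    def test_too_few_samples_or_islands(self):
        with pytest.raises(InputError, match=">= 2 samples"):
            build_matrix({"s0": {"a": 1.0}}, {"s0": NORMAL})
        tables = {"s0": {"a": float("nan")}, "s1": {"a": 1.0}, "s2": {"a": 1.0},
                  "s3": {"a": 1.0}, "s4": {"a": 1.0}, "s5": {"a": float("nan")}}
        with pytest.raises(InputError, match="no islands"):
            build_matrix(tables, {s: NORMAL for s in tables}, max_missing_frac=0.1)


class TestTrainPredict:
    def test_separable_clusters_train_to_perfection(self):
        m = separable_matrix()
        model = train_classifier(m, seed=1)
        pred = predict(model, m.values)
        assert (pred == m.labels).all()

    def test_single_class_input_rejected(self):
        m = separable_matrix()
        labels = pd.Series(TUMOR, index=m.values.index)
        with pytest.raises(InputError, match="both"):
            train_classifier(IslandRateMatrix(m.values, labels))

    def test_two_point_model_midpoint_is_a_tie_resolved_to_normal(self):
        values = pd.DataFrame(
            [[0.0, 0.0], [2.0, 4.0]], index=["n0", "t0"], columns=["a", "b"]
        )
        labels = pd.Series([NORMAL, TUMOR], index=["n0", "t0"])
        model = train_classifier(IslandRateMatrix(values, labels), seed=0)
        midpoint = pd.DataFrame([[1.0, 2.0]], index=["mid"], columns=["a", "b"])
        labels_out, decision = predict(model, midpoint, return_decision=True)
        assert abs(decision.iloc[0]) < 1e-9
        # the documented tie rule: decision <= 0 predicts NORMAL
        exact = LinearSvmModel(
            feature_names=["a"], mean=np.zeros(1), scale=np.ones(1),
            weights=np.ones(1), bias=0.0, medians=np.zeros(1),
        )
        tie = predict(exact, pd.DataFrame([[0.0]], columns=["a"]))
        assert tie.iloc[0] == NORMAL

    def test_two_point_decision_is_perpendicular_bisector(self):
        values = pd.DataFrame(
            [[0.0, 0.0], [2.0, 2.0]], index=["n0", "t0"], columns=["a", "b"]
        )
        labels = pd.Series([NORMAL, TUMOR], index=["n0", "t0"])
        model = train_classifier(IslandRateMatrix(values, labels), seed=0)
        probes = pd.DataFrame(
            [[0.4, 0.4], [1.6, 1.6], [0.0, 1.9], [1.9, 0.0]],
            columns=["a", "b"],
        )
        pred = predict(model, probes)
        assert list(pred) == [NORMAL, TUMOR, NORMAL, NORMAL]

    def test_missing_feature_imputed_by_training_median(self):
        m = separable_matrix()
        model = train_classifier(m, seed=1)
        row = m.values.iloc[[0]].copy()
        median = float(np.median(m.values["isl3"]))
        with_nan = row.copy()
        with_nan.loc[:, "isl3"] = np.nan
        with_median = row.copy()
        with_median.loc[:, "isl3"] = median
        assert predict(model, with_nan).iloc[0] == predict(model, with_median).iloc[0]
        _, d1 = predict(model, with_nan, return_decision=True)
        _, d2 = predict(model, with_median, return_decision=True)
        assert d1.iloc[0] == pytest.approx(d2.iloc[0])

    def test_no_feature_overlap_rejected(self):
        m = separable_matrix()
        model = train_classifier(m, seed=1)
        alien = pd.DataFrame([[1.0]], columns=["other"])
        with pytest.raises(InputError, match="no overlap"):
            predict(model, alien)

    def test_feature_scale_invariance_of_predictions(self):
        m = separable_matrix()
        scaled_values = m.values.copy()
        scaled_values["isl2"] *= 37.0
        model = train_classifier(m, seed=1)
        model_scaled = train_classifier(IslandRateMatrix(scaled_values, m.labels), seed=1)
        p1 = predict(model, m.values)
        p2 = predict(model_scaled, scaled_values)
        assert (p1 == p2).all()

    def test_model_json_round_trip(self, tmp_path):
        m = separable_matrix()
        model = train_classifier(m, seed=1)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = LinearSvmModel.from_json(path)
        _, d1 = predict(model, m.values, return_decision=True)
        _, d2 = predict(loaded, m.values, return_decision=True)
        assert np.allclose(d1, d2)


class TestJackknife:
    def test_separable_fixture_reaches_100_percent(self):
        m = separable_matrix()
        report = jackknife_evaluate(m, rounds=50, seed=3)
        assert report.tp_pct == 100.0 and report.tn_pct == 100.0
        assert report.fp_pct == 0.0 and report.fn_pct == 0.0

    def test_percentages_pair_to_100(self):
        m = separable_matrix(shift_sd=0.5)
        report = jackknife_evaluate(m, rounds=20, seed=3)
        assert report.tp_pct + report.fn_pct == pytest.approx(100.0)
        assert report.tn_pct + report.fp_pct == pytest.approx(100.0)

    def test_permuted_labels_hover_around_chance(self):
        # shift 0: features are pure noise, so labels (then additionally
        # permuted) carry no information about them by construction
        rng = np.random.default_rng(7)
        m = separable_matrix(shift_sd=0.0, seed=5)
        permuted = pd.Series(
            rng.permutation(m.labels.to_numpy()), index=m.labels.index
        )
        report = jackknife_evaluate(IslandRateMatrix(m.values, permuted),
                                    rounds=100, seed=3)
        # per-sample predictions are sticky across overlapping training
        # sets, so in the worst case TP% ~ Binomial(20, 1/2)/20; a unit
        # test needs a band that holds with overwhelming probability
        # under the null: the central 99.9% band, 20%..80%
        assert 20.0 <= report.tp_pct <= 80.0
        assert 20.0 <= report.tn_pct <= 80.0

    def test_single_round_single_holdout_bookkeeping(self):
        m = separable_matrix(n_per_class=5)
        report = jackknife_evaluate(m, rounds=1, holdout_per_class=1, seed=9)
        counts = report.rounds[["tp", "tn", "fp", "fn"]].iloc[0]
        assert counts.sum() == 2

    def test_determinism_bit_identical(self):
        m = separable_matrix(shift_sd=1.0)
        r1 = jackknife_evaluate(m, rounds=10, seed=21)
        r2 = jackknife_evaluate(m, rounds=10, seed=21)
        pd.testing.assert_frame_equal(r1.rounds, r2.rounds)
        assert r1.summary() == r2.summary()

    def test_impossible_holdout_rejected(self):
        m = separable_matrix(n_per_class=3)
        with pytest.raises(InputError, match="holdout"):
            jackknife_evaluate(m, rounds=2, holdout_per_class=3, seed=0)


class TestRankIslands:
    def hand_matrix(self):
        values = pd.DataFrame(
            {
                "A": [1.0, 1.0, 2.0, 2.0],
                "B": [1.0, 1.0, 3.0, 3.0],
                "C": [1.0, 1.0, 1.0, 1.0],
            },
            index=["n0", "n1", "t0", "t1"],
        )
        labels = pd.Series([NORMAL, NORMAL, TUMOR, TUMOR], index=values.index)
        return IslandRateMatrix(values, labels)

    def test_order_and_signed_differences(self):
        ranking = rank_islands(self.hand_matrix())
        assert list(ranking.index) == ["B", "A", "C"]
        assert ranking.loc["B", "difference"] == pytest.approx(2.0)
        assert ranking.loc["A", "difference"] == pytest.approx(1.0)
        assert ranking.loc["C", "difference"] == pytest.approx(0.0)

    def test_identical_means_tie_break_by_island_id(self):
        values = pd.DataFrame(
            np.ones((4, 3)), index=["n0", "n1", "t0", "t1"], columns=["z", "m", "a"]
        )
        labels = pd.Series([NORMAL, NORMAL, TUMOR, TUMOR], index=values.index)
        ranking = rank_islands(IslandRateMatrix(values, labels))
        assert list(ranking.index) == ["a", "m", "z"]
        assert (ranking["difference"] == 0).all()

    def test_row_permutation_invariance(self):
        m = self.hand_matrix()
        order = ["t1", "n0", "t0", "n1"]
        shuffled = IslandRateMatrix(m.values.loc[order], m.labels.loc[order])
        pd.testing.assert_frame_equal(rank_islands(m), rank_islands(shuffled))

    def test_k_truncates_and_overlarge_k_warns(self):
        m = self.hand_matrix()
        assert list(rank_islands(m, k=2).index) == ["B", "A"]
        with pytest.warns(UserWarning, match="exceeds"):
            full = rank_islands(m, k=10)
        assert len(full) == 3

    def test_label_swap_negates_every_difference(self):
        m = self.hand_matrix()
        swap = {NORMAL: TUMOR, TUMOR: NORMAL}
        swapped = IslandRateMatrix(m.values, m.labels.map(swap))
        r1 = rank_islands(m)
        r2 = rank_islands(swapped)
        assert np.allclose(r1["difference"], -r2["difference"].loc[r1.index])
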