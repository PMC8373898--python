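"""Boosted-logistic super learner, nested CV, voting and reporting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anxmvpa.region_superlearner import (
    CVResult,
    HyperGrid,
    accuracy_by_covariate,
    classification_metrics,
    fit_boosted_logistic,
    majority_vote,
    nested_region_search,
)
from anxmvpa.volume_io import TimePointDataset


class TestFitBoostedLogistic:
    def test_separable_clouds_reach_training_accuracy_one(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(6, 1, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        clf = fit_boosted_logistic(X, y, seed=0)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_null_features_give_chance_cv_accuracy(self, rng):
        from sklearn.model_selection import cross_val_score

        X = rng.standard_normal((500, 4))
        y = rng.integers(0, 2, 500)
        clf = fit_boosted_logistic(X, y, n_estimators=10, seed=0)
        acc = cross_val_score(clf, X, y, cv=5).mean()
        # 95% binomial band around 0.5 at n=500
        band = 1.96 * np.sqrt(0.25 / 500)
        assert abs(acc - 0.5) < band + 0.02

    def test_single_estimator_reduces_to_bare_logistic(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.standard_normal((80, 3))
        y = (X[:, 0] + 0.5 * rng.standard_normal(80) > 0).astype(int)
        boosted = fit_boosted_logistic(X, y, n_estimators=1, seed=0)
        # boosting starts from uniform weights 1/n; match them exactly
        bare = LogisticRegression(C=1.0, max_iter=100, solver="lbfgs").fit(
            X, y, sample_weight=np.full(len(y), 1 / len(y))
        )
        np.testing.assert_array_equal(boosted.predict(X), bare.predict(X))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_boosted_logistic(rng.standard_normal((10, 2)), np.zeros(10))

    def test_nonfinite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            fit_boosted_logistic(X, [0, 1, 0, 1])


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes, expected",
        [
            (["anxious"] * 20 + ["non_anxious"] * 15, "anxious"),
            (["anxious"] * 35, "anxious"),
            (["non_anxious"] * 18 + ["anxious"] * 17, "non_anxious"),
        ],
    )
    def test_most_frequent_label_wins(self, votes, expected):
        assert majority_vote(votes) == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=40))
    def test_result_is_always_a_modal_label(self, votes):
        win = majority_vote(votes)
        counts = {lab: votes.count(lab) for lab in set(votes)}
        assert counts[win] == max(counts.values())


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = ["anxious", "non_anxious"] * 10
        m = classification_metrics(y, y)
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_majority_class_baseline_is_23_of_45(self):
        y_true = ["non_anxious"] * 23 + ["anxious"] * 22
        y_pred = ["non_anxious"] * 45
        m = classification_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(23 / 45)
        assert round(100 * m["accuracy"], 1) == 51.1

    def test_hand_counted_confusion_table(self):
        # TP=3, FP=1, FN=2, TN=4 for the positive class
        y_true = ["pos"] * 3 + ["neg"] * 1 + ["pos"] * 2 + ["neg"] * 4
        y_pred = ["pos"] * 3 + ["pos"] * 1 + ["neg"] * 2 + ["neg"] * 4
        m = classification_metrics(y_true, y_pred)
        assert m["per_class"]["pos"]["precision"] == pytest.approx(0.75)
        assert m["per_class"]["pos"]["recall"] == pytest.approx(0.6)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            classification_metrics([1, 0], [1])
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestHyperGrid:
    def test_defaults_are_the_printed_grid(self):
        g = HyperGrid()
        assert g.n_estimators == (10, 50, 100, 150)
        assert g.learning_rate == (0.05, 1.0, 2.0)
        assert g.max_iterations == (100, 500, 1000)
        assert g.penalty == ("l1", "l2", "none")
        assert g.C == (0.5, 1.0, 2.0)
        assert len(g.points()) == 4 * 3 * 3 * 3 * 3

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid(n_estimators=())


@pytest.fixture(scope="module")
def tiny_search(tiny_ds):
    return nested_region_search(
        tiny_ds, HyperGrid.reduced(), outer_k=3, inner_k=3, seed=0
    )


class TestNestedRegionSearch:
    def test_planted_region_recovered(self, tiny_search, tiny_cohort):
        # 12-subject smoke cohort: the ranking must find the planted region and
        # beat the majority baseline; the quantitative accuracy bound is
        # checked at study scale in the acceptance tests
        result, ranking = tiny_search
        assert ranking.top(1)[0] == tiny_cohort.spec.signal_region_id
        assert result.metrics["accuracy"] > 0.5
        assert ranking.table["mean_acc"].iloc[0] >= 0.75

    def test_no_subject_straddles_folds(self, tiny_search):
        result, _ = tiny_search
        for sid, fold in result.fold_of.items():
            assert sid not in result.fold_train_subjects[fold]
        # each subject predicted in exactly one outer fold
        assert set(result.fold_of) == set(result.subject_ids)

    def test_majority_vote_beats_mean_timepoint_accuracy(self, tiny_search):
        result, _ = tiny_search
        tp_acc = np.mean(
            [result.subject_timepoint_accuracy(s) for s in result.subject_ids]
        )
        subj_acc = result.metrics["accuracy"]
        assert tp_acc > 0.5  # planted signal decodes above chance per time point
        assert subj_acc >= tp_acc - 1e-12

    def test_single_region_trivially_selected(self, tiny_ds):
        result, ranking = nested_region_search(
            tiny_ds, HyperGrid.reduced(), outer_k=3, inner_k=2, seed=0,
            region_ids=[1],
        )
        assert all(c["region_id"] == 1 for c in result.chosen.values())
        assert ranking.table["region_id"].tolist() == [1]

    def test_ranking_equivariant_to_region_relabeling(self, tiny_ds):
        _, ranking = nested_region_search(
            tiny_ds, HyperGrid.reduced(), outer_k=3, inner_k=3, seed=0
        )
        relabel = {1: 12, 2: 27, 3: 3, 4: 8}
        ds2 = TimePointDataset(
            features=tiny_ds.features,
            stimulus_labels=tiny_ds.stimulus_labels,
            group_labels=tiny_ds.group_labels,
            subject_ids=list(tiny_ds.subject_ids),
            region_index={relabel[r]: sl for r, sl in tiny_ds.region_index.items()},
        )
        _, ranking2 = nested_region_search(
            ds2, HyperGrid.reduced(), outer_k=3, inner_k=3, seed=0
        )
        mapped = ranking.table.assign(
            region_id=ranking.table["region_id"].map(relabel)
        )
        merged = mapped.merge(ranking2.table, on="region_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["mean_acc_a"], merged["mean_acc_b"])

    def test_whole_brain_scores_below_planted_region_when_diluted(self):
        """With many noise regions (4000 voxels vs ~1000 training rows) the
        whole-brain pseudo-region dilutes the planted signal and scores below
        the signal region itself."""
        from anxmvpa.synthetic_data import CohortSpec, generate_cohort

        for seed in (3, 4):
            cohort = generate_cohort(
                CohortSpec(seed=seed, group_effect=0.5, stim_effect=0.0,
                           n_regions=100, voxels_per_region=40,
                           atlas_shape=(16, 16, 16), signal_region_id=7)
            )
            ds = cohort.to_dataset()
            _, ranking = nested_region_search(
                ds, HyperGrid.reduced(), seed=seed, outer_k=3, inner_k=3,
                region_ids=[7], include_whole_brain=True,
            )
            table = ranking.table.set_index("region_id")
            from anxmvpa.volume_io import WHOLE_BRAIN

            assert table.loc[7, "mean_acc"] > table.loc[WHOLE_BRAIN, "mean_acc"]

    def test_too_few_subjects_rejected(self, tiny_ds):
        ds_small = TimePointDataset(
            features=tiny_ds.features[:3],
            stimulus_labels=tiny_ds.stimulus_labels,
            group_labels=tiny_ds.group_labels[:3],
            subject_ids=list(tiny_ds.subject_ids[:3]),
            region_index=tiny_ds.region_index,
        )
        with pytest.raises(ValueError, match="fewer subjects"):
            nested_region_search(ds_small, HyperGrid.reduced(), outer_k=5)


class TestAccuracyByCovariate:
    def _perfect_result(self, subjects, t=35):
        return CVResult(
            subject_ids=subjects,
            y_true=np.array(["anxious"] * len(subjects)),
            y_pred=np.array(["anxious"] * len(subjects)),
            timepoint_preds={s: np.array(["anxious"] * t) for s in subjects},
            fold_of={s: 0 for s in subjects},
            fold_train_subjects={0: []},
            chosen={},
            metrics={},
            fold_metrics=None,
        )

    def test_perfect_predictions_have_degenerate_ci(self):
        res = self._perfect_result(["s1", "s2", "s3", "s4"])
        out = accuracy_by_covariate(res, {s: "site0" for s in res.subject_ids})
        assert out["mean_accuracy"].iloc[0] == 1.0
        assert out["ci_low"].iloc[0] == out["ci_high"].iloc[0] == 1.0

    def test_single_subject_category_fraction(self):
        res = self._perfect_result(["s1", "s2"])
        res.timepoint_preds["s2"] = np.array(
            ["anxious"] * 21 + ["non_anxious"] * 14
        )
        out = accuracy_by_covariate(res, {"s1": "a", "s2": "b"}, n_boot=200)
        row = out[out.category == "b"].iloc[0]
        assert row["mean_accuracy"] == pytest.approx(21 / 35)

    def test_ci_contains_point_estimate(self, tiny_search):
        result, _ = tiny_search
        cov = {s: ("even" if i % 2 == 0 else "odd")
               for i, s in enumerate(result.subject_ids)}
        out = accuracy_by_covariate(result, cov, n_boot=500, seed=3)
        assert ((out.ci_low - 1e-12 <= out.mean_accuracy)
                & (out.mean_accuracy <= out.ci_high + 1e-12)).all()

    def test_unknown_subject_rejected(self, tiny_search):
        result, _ = tiny_search
        cov = {s: "x" for s in result.subject_ids}
        cov["sub-zz"] = "x"
        with pytest.raises(KeyError):
            accuracy_by_covariate(result, cov)
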