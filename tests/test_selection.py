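"""mRMR scores, greedy selection, stopping rule, and report round trips."""

import dataclasses

import numpy as np
import pytest

from mrmrkit.io import (
    read_feature_table,
    read_selection_report,
    write_feature_table,
    write_selection_report,
)
from mrmrkit.mi import build_cache, entropy
from mrmrkit.selection import (
    FeatureTable,
    MRMRSelector,
    SelectionConfig,
    incremental_score,
    redundancy_R,
    relevance_D,
    select_features,
)
from conftest import naive_mrmr_order, random_table


@pytest.fixture
def small_cache(rng):
    X = rng.standard_normal((80, 6))
    y = rng.integers(0, 2, size=80)
    return build_cache(X, y)


class TestScores:
    def test_singleton_relevance_and_redundancy(self, small_cache):
        assert relevance_D([3], small_cache) == small_cache.relevance[3]
        assert redundancy_R([3], small_cache) == pytest.approx(
            entropy(small_cache.codes[3]), abs=1e-12)

    def test_pair_relevance_is_mean(self, small_cache):
        a, b = small_cache.relevance[1], small_cache.relevance[4]
        assert relevance_D([1, 4], small_cache) == pytest.approx((a + b) / 2)

    def test_independent_unit_entropy_pair_redundancy(self):
        # two independent balanced binary features: diagonal 1+1, off-diag 0
        x0 = np.repeat([0.0, 1.0], 50)
        x1 = np.tile([0.0, 1.0], 50)
        cache = build_cache(np.column_stack([x0, x1]), (x0 + x1 >= 1).astype(int))
        assert redundancy_R([0, 1], cache) == pytest.approx(0.5, abs=1e-12)

    def test_scores_match_naive_loops(self, rng, small_cache):
        subset = [0, 2, 5]
        assert relevance_D(subset, small_cache) == pytest.approx(
            sum(small_cache.relevance[j] for j in subset) / 3, abs=1e-12)
        naive_R = sum(small_cache.pairwise(i, j) for i in subset for j in subset) / 9
        assert redundancy_R(subset, small_cache) == pytest.approx(naive_R, abs=1e-12)
        j = 4
        naive_J = small_cache.relevance[j] - np.mean(
            [small_cache.pairwise(i, j) for i in subset])
        assert incremental_score(j, subset, small_cache) == pytest.approx(naive_J, abs=1e-12)

    def test_empty_subset_and_reselection_rejected(self, small_cache):
        with pytest.raises(ValueError):
            relevance_D([], small_cache)
        with pytest.raises(ValueError):
            redundancy_R([], small_cache)
        with pytest.raises(ValueError):
            incremental_score(2, [2], small_cache)

    def test_incremental_score_reduces_to_relevance_when_nothing_selected(self, small_cache):
        assert incremental_score(2, [], small_cache) == small_cache.relevance[2]

    def test_duplicate_of_selected_perfect_predictor_scores_zero(self):
        y = np.tile([0, 1], 30)
        col = y.astype(float)
        cache = build_cache(np.column_stack([col, col]), y)
        assert incremental_score(1, [0], cache) == pytest.approx(0.0, abs=1e-12)


class TestSelector:
    def test_single_feature_table_exhausts(self, rng):
        X = rng.standard_normal((20, 1))
        y = rng.integers(0, 2, size=20)
        sel = MRMRSelector(cv_folds=5).fit(X, y)
        assert sel.selected_ == [0]
        assert sel.stopped_reason_ == "exhausted"

    def test_label_duplicate_feature_wins_first_pick(self, rng):
        y = rng.integers(0, 2, size=100)
        X = rng.standard_normal((100, 6))
        X[:, 3] = y
        sel = MRMRSelector(stop_on_accuracy_drop=False, max_features=3).fit(X, y)
        assert sel.steps_[0].chosen == 3
        assert sel.steps_[0].J_score == pytest.approx(sel.cache_.relevance[3])

    def test_first_pick_is_argmax_relevance(self, rng):
        for _ in range(10):
            X, y = random_table(rng)
            sel = MRMRSelector(stop_on_accuracy_drop=False, max_features=1).fit(X, y)
            assert sel.steps_[0].chosen == int(np.argmax(sel.cache_.relevance))

    def test_phi_identity_and_distinct_choices(self, rng):
        X, y = random_table(rng, n=60, m=10)
        sel = MRMRSelector(stop_on_accuracy_drop=False).fit(X, y)
        chosen = [s.chosen for s in sel.steps_]
        assert len(set(chosen)) == len(chosen) == 10
        for s in sel.steps_:
            assert s.Phi == pytest.approx(s.D - s.R, abs=1e-12)
        assert sel.stopped_reason_ == "exhausted"

    def test_matches_naive_reference_selector(self, rng):
        """Cached incremental selection order equals a from-scratch reference
        that recomputes every mutual information each step."""
        for _ in range(10):
            X, y = random_table(rng)
            sel = MRMRSelector(stop_on_accuracy_drop=False).fit(X, y)
            assert sel.selected_ == naive_mrmr_order(X, y, X.shape[1])

    def test_max_features_cap(self, rng):
        X, y = random_table(rng, n=50, m=12)
        sel = MRMRSelector(stop_on_accuracy_drop=False, max_features=4).fit(X, y)
        assert len(sel.selected_) == 4
        assert sel.stopped_reason_ == "max_features"

    def test_determinism_bit_identical(self, rng):
        X, y = random_table(rng, n=60, m=8)
        runs = [MRMRSelector(cv_folds=5, random_state=7).fit(X, y) for _ in range(2)]
        assert runs[0].selected_ == runs[1].selected_
        assert [dataclasses.asdict(s) for s in runs[0].steps_] == \
               [dataclasses.asdict(s) for s in runs[1].steps_]

    def test_accuracy_drop_discards_newest(self, rng):
        # one noisy-but-informative feature + pure noise: adding a noise
        # feature lowers the paired CV accuracy and terminates selection
        y = np.tile([0, 1], 60)
        X = np.column_stack([y + 0.8 * rng.standard_normal(120)] +
                            [rng.standard_normal(120) for _ in range(8)])
        sel = MRMRSelector(cv_folds=10, random_state=0).fit(X, y)
        assert sel.selected_[0] == 0
        assert sel.stopped_reason_ == "accuracy_drop"
        assert len(sel.selected_) == len(sel.steps_)  # discarded pick not recorded
        assert all(s.cv_accuracy is not None for s in sel.steps_)

    def test_validation_errors(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            MRMRSelector().fit(X, np.zeros(20))  # single class
        with pytest.raises(ValueError):
            MRMRSelector(cv_folds=30).fit(X, np.tile([0, 1], 10))  # folds > n
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            MRMRSelector().fit(X, np.tile([0, 1], 10))

    def test_sklearn_transform_contract(self, rng):
        X, y = random_table(rng, n=50, m=8)
        sel = MRMRSelector(stop_on_accuracy_drop=False, max_features=3)
        Xt = sel.fit(X, y).transform(X)
        assert Xt.shape == (50, 3)
        mask = sel.get_support()
        assert mask.sum() == 3
        assert np.array_equal(Xt, X[:, sorted(sel.selected_)])
        # get_params/set_params round trip (pipeline compatibility)
        params = sel.get_params()
        assert MRMRSelector(**params).get_params() == params


class TestTableIO:
    def test_round_trip(self, tmp_path, rng):
        table = FeatureTable(features=rng.standard_normal((5, 4)),
                             labels=np.array(["a", "b", "a", "b", "a"]))
        p = tmp_path / "t.csv"
        write_feature_table(table, p)
        back = read_feature_table(p)
        assert np.allclose(back.features, table.features)
        assert list(back.labels) == list(table.labels)
        assert back.feature_names == table.feature_names

    def test_missing_label_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="label column"):
            read_feature_table(p, "class")

    def test_non_numeric_cell_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b,class\n1,2,x\n3,oops,y\n")
        with pytest.raises(ValueError, match="column 'b', row 1"):
            read_feature_table(p)

    def test_report_round_trip(self, tmp_path, rng):
        X, y = random_table(rng, n=40, m=6)
        sel = MRMRSelector(stop_on_accuracy_drop=False, max_features=3).fit(X, y)
        p = tmp_path / "report.json"
        write_selection_report(sel.result_(), p, feature_names=[f"f{i}" for i in range(6)],
                               config={"bins": 10}, seed=0)
        back = read_selection_report(p)
        assert back.selected == sel.selected_
        assert back.stopped_reason == sel.stopped_reason_
        assert [s.chosen for s in back.steps] == [s.chosen for s in sel.steps_]


def test_select_features_wrapper_equals_estimator(rng):
    X, y = random_table(rng, n=50, m=7)
    table = FeatureTable(features=X, labels=y)
    res = select_features(table, SelectionConfig(stop_on_accuracy_drop=False))
    sel = MRMRSelector(stop_on_accuracy_drop=False).fit(X, y)
    assert res.selected == sel.selected_
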