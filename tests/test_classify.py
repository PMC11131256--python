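import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from skelquant.classify import (
    CLASSIFIERS,
    COMBINATIONS,
    STRATEGIES,
    ClassifierSpec,
    averaged_ranking,
    derive_seed,
    evaluate_combination,
    grid_cv_scores,
    make_splits,
    tune_and_fit,
)
from skelquant.classify import _build_forest, _build_xgboost
from skelquant.features import DESCRIPTORS, LABEL_COLUMN
from skelquant.skeleton import ADHD, NON_ADHD


def _toy_dataset(rng, n_per_group=20, shift=4.0):
    """A feature table where var_th_9_10 separates the groups."""
    data = {}
    for d in DESCRIPTORS:
        a = rng.normal(10, 2, n_per_group)
        b = rng.normal(10, 2, n_per_group)
        if d == "var_th_9_10":
            a = a + shift * 2
        data[d] = np.abs(np.concatenate([a, b]))
    df = pd.DataFrame(data, index=[f"s{i}" for i in range(2 * n_per_group)])
    df[LABEL_COLUMN] = [ADHD] * n_per_group + [NON_ADHD] * n_per_group
    return df


class TestCombinations:
    def test_seventeen_combinations_with_expected_membership(self):
        assert len(COMBINATIONS) == 17
        assert COMBINATIONS["thigh_related"] == ("var_l_9_10", "var_th_9_10")
        assert len(COMBINATIONS["shoulder_related"]) == 4
        assert len(COMBINATIONS["hip_related"]) == 4
        assert len(COMBINATIONS["length_related"]) == 5
        assert len(COMBINATIONS["angle_related"]) == 6
        assert COMBINATIONS["all"] == DESCRIPTORS
        singles = [k for k, v in COMBINATIONS.items() if len(v) == 1]
        assert len(singles) == 11


class TestGrids:
    def test_grid_sizes_match_documented_products(self):
        assert len(CLASSIFIERS["adaboost"].grid) == 6
        assert len(CLASSIFIERS["decision_tree"].grid) == 5
        assert len(CLASSIFIERS["knn"].grid) == 3
        assert len(CLASSIFIERS["random_forest"].grid) == 3 * 5 * 6
        assert len(CLASSIFIERS["svm"].grid) == 4 * 4
        assert len(CLASSIFIERS["xgboost"].grid) == 3 * 5 * 6

    def test_grid_order_last_parameter_fastest(self):
        grid = CLASSIFIERS["svm"].grid
        assert grid[0] == {"gamma": 50, "C": 0.001}
        assert grid[1] == {"gamma": 50, "C": 0.01}
        assert grid[4] == {"gamma": 100, "C": 0.001}


class TestMakeSplits:
    def test_each_strategy_yields_100_stratified_pairs(self):
        labels = np.array([ADHD] * 48 + [NON_ADHD] * 48)
        for name, strat in STRATEGIES.items():
            splits = make_splits(labels, strat, seed=3)
            assert len(splits) == 100
            y = labels == ADHD
            for tr, te in splits[:10]:
                assert set(tr) | set(te) <= set(range(96))
                assert len(set(tr) & set(te)) == 0
                n_pos = y[te].sum()
                n_neg = len(te) - n_pos
                if name == "cv10x10":
                    assert len(te) in (9, 10)
                    assert 4 <= n_pos <= 5 and 4 <= n_neg <= 5
                elif name == "holdout82":
                    assert len(te) in (19, 20)
                    assert 9 <= n_pos <= 11
                else:
                    assert 37 <= len(te) <= 39
                    assert 18 <= n_pos <= 20

    def test_kfold_covers_every_subject_once_per_repetition(self):
        labels = np.array([ADHD] * 48 + [NON_ADHD] * 48)
        splits = make_splits(labels, STRATEGIES["cv10x10"], seed=0)
        first_rep = np.concatenate([te for _, te in splits[:10]])
        assert sorted(first_rep) == list(range(96))

    def test_same_seed_identical_splits(self):
        labels = np.array([ADHD] * 12 + [NON_ADHD] * 12)
        a = make_splits(labels, STRATEGIES["holdout64"], seed=5)
        b = make_splits(labels, STRATEGIES["holdout64"], seed=5)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)


class TestTuning:
    def test_single_point_grid_is_chosen(self, rng):
        spec = ClassifierSpec(
            "knn", ("n_neighbors",), ((3,),), CLASSIFIERS["knn"].builder, seeded=False
        )
        X = rng.normal(size=(30, 2))
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        model = tune_and_fit(spec, X, y, seed=0)
        assert model.params == {"n_neighbors": 3}

    def test_separable_data_stump_fits_training_set_perfectly(self):
        X = np.r_[np.full((10, 1), 5.0), np.full((10, 1), -5.0)]
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        model = tune_and_fit(CLASSIFIERS["decision_tree"], X, y, seed=1)
        assert np.array_equal(model.predict(X), y)
        assert model.cv_accuracy == 1.0

    def test_degenerate_training_set_rejected(self):
        X = np.zeros((10, 1))
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError):
            tune_and_fit(CLASSIFIERS["decision_tree"], X, y, seed=0)

    @pytest.mark.parametrize(
        "name,builder,param_values",
        [
            ("adaboost", None, None),
            ("random_forest", _build_forest, ((2,), (3,), (1, 5, 10, 20, 30, 50))),
            ("xgboost", _build_xgboost, ((0.2,), (3,), (1, 5, 10, 20, 30, 50))),
        ],
    )
    def test_grid_scores_match_naive_replay(self, rng, name, builder, param_values):
        """Prefix evaluation of ensemble grids equals point-by-point refits."""
        base = CLASSIFIERS[name]
        spec = base if builder is None else ClassifierSpec(
            name, base.param_names, param_values, builder, ensemble_param="n_estimators"
        )
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + rng.normal(0, 1.5, 40) > 0).astype(int)
        seed = 42
        fast = grid_cv_scores(spec, X, y, seed)
        folds = list(StratifiedKFold(5, shuffle=True, random_state=seed).split(X, y))
        naive = []
        for gi, params in enumerate(spec.grid):
            accs = []
            for f, (tr, va) in enumerate(folds):
                est = spec.build(params, X.shape[1], derive_seed(seed, spec.group_index(gi), f))
                est.fit(X[tr], y[tr])
                accs.append(np.mean(est.predict(X[va]) == y[va]))
            naive.append(np.mean(accs))
        assert np.allclose(fast, naive)

    def test_max_features_clamped_for_narrow_subsets(self, rng):
        X = rng.normal(size=(30, 1))
        y = (X[:, 0] > 0).astype(int)
        model = tune_and_fit(CLASSIFIERS["random_forest"], X, y, seed=0)
        assert model.params["max_features"] == 1


class TestEvaluateCombination:
    def test_separated_data_scores_high_with_every_index(self, rng):
        ds = _toy_dataset(rng, shift=12.0)
        res = evaluate_combination(
            ds, "var_th_9_10", "decision_tree",
            STRATEGIES["holdout82"].with_pairs(10), seed=0,
        )
        for index in ("accuracy", "sensitivity", "specificity", "auc"):
            assert res[index] >= 0.95

    def test_label_permutation_scores_near_chance(self, rng):
        ds = _toy_dataset(rng, shift=6.0)
        ds[LABEL_COLUMN] = rng.permutation(ds[LABEL_COLUMN].to_numpy())
        res = evaluate_combination(
            ds, "var_th_9_10", "decision_tree",
            STRATEGIES["holdout64"].with_pairs(20), seed=0,
        )
        assert abs(res["accuracy"] - 0.5) < 0.2

    def test_same_master_seed_reproduces_cell(self, rng):
        ds = _toy_dataset(rng)
        kwargs = dict(
            combination="thigh_related", classifier="knn",
            strategy=STRATEGIES["holdout64"].with_pairs(5), seed=123,
        )
        assert evaluate_combination(ds, **kwargs) == evaluate_combination(ds, **kwargs)


def _fake_results(rng, strategy="cv10x10"):
    rows = []
    for combo in COMBINATIONS:
        for clf in CLASSIFIERS:
            rows.append(
                {
                    "combination": combo,
                    "classifier": clf,
                    "strategy": strategy,
                    "n_reps": 100,
                    **{
                        k: rng.uniform(0.4, 1.0)
                        for k in ("accuracy", "sensitivity", "specificity", "auc")
                    },
                }
            )
    return pd.DataFrame(rows)


class TestAveragedRanking:
    def test_dominating_combination_ranks_first_everywhere(self, rng):
        df = _fake_results(rng)
        for k in ("accuracy", "sensitivity", "specificity", "auc"):
            df[k] = df[k].where(df["combination"] != "thigh_related", 1.5)
        table = averaged_ranking(df)
        assert (table.loc["thigh_related"] == 1.0).all()

    def test_identical_combinations_share_average_rank(self, rng):
        df = _fake_results(rng)
        mask = df["combination"].isin(["var_l_1_2", "var_l_1_5"])
        for k in ("accuracy", "sensitivity", "specificity", "auc"):
            df.loc[mask, k] = 2.0  # best, tied
        table = averaged_ranking(df)
        assert (table.loc["var_l_1_2"] == 1.5).all()
        assert (table.loc["var_l_1_5"] == 1.5).all()

    def test_ranks_match_independent_sort_oracle(self, rng):
        df = _fake_results(rng)
        table = averaged_ranking(df)
        # oracle: descending rank with average ties = 1 + #greater + (#equal - 1)/2
        for combo in COMBINATIONS:
            per_clf = []
            for clf in CLASSIFIERS:
                col = df[df.classifier == clf].set_index("combination")["accuracy"]
                value = col[combo]
                per_clf.append(1 + (col > value).sum() + ((col == value).sum() - 1) / 2)
            assert table.loc[combo, "accuracy_avg_rank"] == pytest.approx(np.mean(per_clf))

    def test_rank_sum_is_conserved_per_index(self, rng):
        table = averaged_ranking(_fake_results(rng))
        for col in table.columns:
            assert table[col].sum() == pytest.approx(17 * 18 / 2)

    def test_mixed_strategies_require_selection(self, rng):
        df = pd.concat([_fake_results(rng), _fake_results(rng, "holdout82")])
        with pytest.raises(ValueError):
            averaged_ranking(df)
        table = averaged_ranking(df, strategy="holdout82")
        assert len(table) == 17
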