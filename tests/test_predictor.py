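import numpy as np
import pandas as pd
import pytest

from autogs.errors import (
    ConfigError,
    DegenerateInputError,
    SchemaMismatchError,
    UndefinedStatisticError,
)
from autogs.predictor import (
    FeatureSet,
    assemble_features,
    evaluate,
    make_cv_scheme,
    pcc,
    percent_change,
    permutation_importance,
    predict,
    train_stacked_ensemble,
)


class TestPCC:
    def test_identical_vectors(self):
        assert pcc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_negated_vector(self):
        assert pcc([1, 2, 3, 4], [-1, -2, -3, -4]) == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # frozen from the closed-form Pearson formula on this pair
        assert pcc([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8]) == pytest.approx(0.990847, abs=5e-6)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pcc([1, 2, 3], [5, 5, 5])

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert pcc(3 * a + 7, b) == pytest.approx(pcc(a, b))
        assert pcc(a, 0.1 * b - 2) == pytest.approx(pcc(a, b))


class TestPercentChange:
    @pytest.mark.parametrize(
        "base,improved,expected",
        [
            (0.736, 0.878, 19.29),
            (0.482, 0.619, 28.42),
            (0.5, 0.5, 0.0),
        ],
    )
    def test_examples(self, base, improved, expected):
        assert percent_change(base, improved) == pytest.approx(expected, abs=0.005)

    def test_zero_baseline(self):
        with pytest.raises(UndefinedStatisticError):
            percent_change(0.0, 0.5)


class TestAssembleFeatures:
    def test_rows_and_marker_only_columns(self, small_trial):
        tr = small_trial
        markers = tr.genotypes.marker_ids[:10]
        fs = assemble_features(tr.genotypes, markers, tr.rdeps, tr.trait_table, "none")
        assert len(fs.X) == tr.trait_table.values.size  # balanced table: G×E rows
        assert list(fs.X.columns) == markers
        assert (fs.provenance == "marker").all()

    def test_reduced_mode_appends_9xW_columns(self, small_trial):
        tr = small_trial
        fs = assemble_features(
            tr.genotypes, tr.genotypes.marker_ids[:5], tr.rdeps, tr.trait_table, "reduced"
        )
        n_ep_cols = (fs.provenance == "RD_EP").sum()
        assert n_ep_cols == 9 * 36
        assert fs.X.shape[1] == 5 + 324

    def test_rows_in_same_env_share_ep_subvector(self, small_trial):
        tr = small_trial
        fs = assemble_features(
            tr.genotypes, tr.genotypes.marker_ids[:5], tr.rdeps, tr.trait_table, "reduced"
        )
        ep_cols = fs.provenance[fs.provenance == "RD_EP"].index
        env = fs.environments[0]
        rows = fs.X[fs.environments == env]
        assert (rows[ep_cols].nunique() == 1).all()

    def test_raw_mode_truncates_to_common_season(self, small_trial):
        tr = small_trial
        fs = assemble_features(
            tr.genotypes, tr.genotypes.marker_ids[:2], None, tr.trait_table,
            "raw", raw_ep_tables=tr.ep_tables,
        )
        n_days = min(len(t.daily) for t in tr.ep_tables.values())
        assert (fs.provenance == "Raw_EP").sum() == 9 * n_days

    def test_missing_env_profile_rejected(self, small_trial):
        tr = small_trial
        partial = dict(list(tr.rdeps.items())[:-1])
        with pytest.raises(ConfigError):
            assemble_features(
                tr.genotypes, tr.genotypes.marker_ids[:2], partial, tr.trait_table, "reduced"
            )


class TestCVSchemes:
    def _rows(self, n_geno, n_env):
        return pd.MultiIndex.from_product(
            [[f"g{i}" for i in range(n_geno)], [f"e{j}" for j in range(n_env)]],
            names=["genotype_id", "env_id"],
        )

    def test_fivefold_partitions_rows(self):
        rows = self._rows(20, 5)
        cv = make_cv_scheme(rows, "fivefold", seed=0)
        assert len(cv.folds) == 5
        all_test = np.concatenate([te for _, te, _ in cv.folds])
        assert sorted(all_test) == list(range(len(rows)))
        assert {len(te) for _, te, _ in cv.folds} == {20}

    def test_scenario2_one_fold_per_environment(self):
        rows = self._rows(10, 7)
        cv = make_cv_scheme(rows, "scenario2", seed=0)
        assert len(cv.folds) == 7
        for tr, te, label in cv.folds:
            test_envs = set(rows[te].get_level_values(1))
            train_envs = set(rows[tr].get_level_values(1))
            assert test_envs == {label}
            assert label not in train_envs

    @pytest.mark.parametrize("scheme", ["scenario1", "scenario3"])
    def test_genotype_exclusion_contracts(self, scheme):
        rows = self._rows(30, 4)
        cv = make_cv_scheme(rows, scheme, seed=1, n_repeats=3)
        for tr, te, _ in cv.folds:
            assert len(np.intersect1d(tr, te)) == 0
            train_g = set(rows[tr].get_level_values(0))
            test_g = set(rows[te].get_level_values(0))
            assert not train_g & test_g or scheme == "scenario2"
            if scheme == "scenario3":
                assert not set(rows[tr].get_level_values(1)) & set(
                    rows[te].get_level_values(1)
                )

    def test_scenario2_single_environment_rejected(self):
        rows = self._rows(10, 1)
        with pytest.raises(ConfigError):
            make_cv_scheme(rows, "scenario2", seed=0)


def linear_feature_set(n=80, n_feat=3, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_feat)), columns=[f"f{i}" for i in range(n_feat)],
        index=pd.MultiIndex.from_arrays(
            [[f"g{i}" for i in range(n)], ["e1"] * n], names=["genotype_id", "env_id"]
        ),
    )
    y = X @ np.arange(1, n_feat + 1) + 0.5
    return FeatureSet(X=X, response=y.rename("y"), provenance=pd.Series("marker", index=X.columns))


class TestStackedEnsemble:
    def test_linear_target_fit_with_bayes_base(self):
        fs = linear_feature_set()
        model = train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=1, seed=0)
        assert pcc(fs.response, model.fitted_values) > 0.999

    def test_same_seed_identical_meta_weights(self):
        fs = linear_feature_set(seed=3)
        kw = dict(base_learners=("lgbm", "bayes"), tuning_budget=2, seed=5,
                  inner_k=3, tuning_cv=2, search_space="fast")
        m1 = train_stacked_ensemble(fs, **kw)
        m2 = train_stacked_ensemble(fs, **kw)
        assert np.array_equal(m1.meta.coef_, m2.meta.coef_)
        assert m1.meta.intercept_ == m2.meta.intercept_
        assert m1.base_params == m2.base_params

    def test_training_rows_repredicted_match_fitted(self):
        fs = linear_feature_set(seed=1)
        model = train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=1, seed=0)
        again = predict(model, fs.X)
        assert np.allclose(again, model.fitted_values)

    def test_single_row_and_permutation_equivariance(self):
        fs = linear_feature_set(seed=2)
        model = train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=1, seed=0)
        one = predict(model, fs.X.iloc[[5]])
        assert one.shape == (1,)
        perm = np.random.default_rng(0).permutation(len(fs.X))
        assert np.allclose(predict(model, fs.X.iloc[perm]), model.fitted_values[perm])

    def test_schema_mismatch_lists_columns(self):
        fs = linear_feature_set()
        model = train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=1, seed=0)
        bad = fs.X.rename(columns={"f0": "other"})
        with pytest.raises(SchemaMismatchError) as err:
            predict(model, bad)
        assert "f0" in err.value.missing and "other" in err.value.extra

    def test_too_few_rows_rejected(self):
        fs = linear_feature_set(n=80)
        small = FeatureSet(
            X=fs.X.iloc[:30], response=fs.response.iloc[:30], provenance=fs.provenance
        )
        with pytest.raises(DegenerateInputError):
            train_stacked_ensemble(small, base_learners=("bayes",), tuning_budget=1)

    def test_zero_budget_rejected(self):
        fs = linear_feature_set()
        with pytest.raises(ConfigError):
            train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=0)


class TestPermutationImportance:
    def test_planted_dominant_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 100
        X = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=list("abcd"),
            index=pd.MultiIndex.from_arrays(
                [[f"g{i}" for i in range(n)], ["e1"] * n]
            ),
        )
        y = (10 * X["a"] + 0.1 * X["b"] + rng.normal(0, 0.1, n)).rename("y")
        fs = FeatureSet(X=X, response=y, provenance=pd.Series("marker", index=X.columns))
        model = train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=1, seed=0)
        imp = permutation_importance(model, X, y, n_repeats=3, seed=1)
        assert imp.index[0] == "a"
        assert imp.loc["a", "rank"] == 1
        assert imp.loc["a", "effect_sign"] == 1.0
        # near-irrelevant features have near-zero importance
        assert abs(imp.loc["c", "importance"]) < 0.05
        assert abs(imp.loc["d", "importance"]) < 0.05

    def test_deterministic_under_seed(self):
        fs = linear_feature_set(seed=4)
        model = train_stacked_ensemble(fs, base_learners=("bayes",), tuning_budget=1, seed=0)
        i1 = permutation_importance(model, fs.X, fs.response, n_repeats=2, seed=9)
        i2 = permutation_importance(model, fs.X, fs.response, n_repeats=2, seed=9)
        pd.testing.assert_frame_equal(i1, i2)


class TestEvaluate:
    def test_fivefold_on_learnable_signal(self):
        fs = linear_feature_set(n=100, seed=6)
        cv = make_cv_scheme(fs.X.index, "fivefold", seed=0)
        res = evaluate(fs, cv, base_learners=("bayes",), tuning_budget=1, seed=0)
        assert len(res.fold_pcc) == 5
        assert res.mean_pcc > 0.99
        assert res.to_frame().shape == (5, 2)
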