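"""Elastic-net response model: feature assembly, normalization/imputation,
model selection, permutation inference and cross-arm application."""

import numpy as np
import pandas as pd
import pytest
from sklearn.impute import KNNImputer
from sklearn.model_selection import permutation_test_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from eegsef.containers import DEFAULT_BANDS, FRONTAL_CHANNELS
from eegsef.events import sef_columns
from eegsef.power import apf_columns
from eegsef.predict import (ElasticNetResponseModel, assemble_features,
                            cross_arm_apply, permutation_test, responder_flag)


def _toy_tables(n=36, seed=0, missing=False):
    rng = np.random.default_rng(seed)
    cols = sef_columns(FRONTAL_CHANNELS, DEFAULT_BANDS)
    ids = [f"S{i:03d}" for i in range(n)]
    sef = pd.DataFrame(rng.standard_normal((n, len(cols))), index=ids, columns=cols)
    if missing:
        sef.iloc[0, sef.columns.get_loc("F7_beta_duration")] = np.nan
    hamd_pre = rng.integers(18, 31, n)
    pct = rng.normal(-45, 18, n)
    hamd_post = np.clip(np.round(hamd_pre * (1 + pct / 100)), 0, 52)
    clinical = pd.DataFrame({"subject_id": ids, "arm": "sertraline",
                             "hamd_pre": hamd_pre, "hamd_post": hamd_post,
                             "age": 40.0, "sex": "F"})
    return sef, clinical


class TestAssemble:
    def test_sef_only_is_85_columns(self):
        sef, clinical = _toy_tables()
        X, y = assemble_features(sef, None, clinical, "sef")
        assert X.shape[1] == 85
        assert list(X.columns[:-1]) == list(sef.columns)
        assert X.columns[-1] == "hamd_pre"

    def test_percent_change_and_responder_rule(self):
        sef, clinical = _toy_tables(n=13)
        clinical.loc[0, ["hamd_pre", "hamd_post"]] = (20, 8)
        X, y = assemble_features(sef, None, clinical, "sef")
        assert y.iloc[0] == pytest.approx(-60.0)
        assert responder_flag([y.iloc[0]])[0]
        assert not responder_flag([-49.9])[0]

    def test_missing_cells_carried_to_model(self):
        sef, clinical = _toy_tables(missing=True)
        X, _ = assemble_features(sef, None, clinical, "sef")
        assert X["F7_beta_duration"].isna().sum() == 1

    def test_subject_without_outcome_dropped(self):
        sef, clinical = _toy_tables()
        clinical.loc[3, "hamd_post"] = np.nan
        X, y = assemble_features(sef, None, clinical, "sef")
        assert len(X) == len(sef) - 1 and "S003" not in X.index

    def test_both_adds_apf_width(self):
        sef, clinical = _toy_tables(n=16)
        rng = np.random.default_rng(1)
        apf = pd.DataFrame(rng.standard_normal((16, 133)), index=sef.index,
                           columns=apf_columns(FRONTAL_CHANNELS))
        X, _ = assemble_features(sef, apf, clinical, "both")
        assert X.shape[1] == 84 + 133 + 1


class TestImputation:
    def test_knn_imputer_mean_of_two_nearest(self):
        """Hand-computed 4-row example: the missing cell becomes the mean
        of the two nearest rows' values (in standardized space)."""
        X = pd.DataFrame({
            "a": [0.0, 0.1, -0.1, 10.0],
            "b": [np.nan, 2.0, 4.0, 40.0],
        })
        pipe = Pipeline([("scale", StandardScaler()), ("impute", KNNImputer(n_neighbors=2))])
        Xt = pipe.fit_transform(X)
        scaler = pipe.named_steps["scale"]
        # rows 1 and 2 are nearest to row 0 along the observed coordinate
        expected_std = (Xt[1, 1] + Xt[2, 1]) / 2.0
        assert Xt[0, 1] == pytest.approx(expected_std)
        back = Xt[0, 1] * scaler.scale_[1] + scaler.mean_[1]
        assert back == pytest.approx((2.0 + 4.0) / 2.0)

    def test_no_missing_identity(self, rng):
        X = rng.standard_normal((10, 4))
        pipe = Pipeline([("scale", StandardScaler()), ("impute", KNNImputer(n_neighbors=2))])
        Xt = pipe.fit_transform(X)
        np.testing.assert_allclose(Xt, StandardScaler().fit_transform(X))
        np.testing.assert_allclose(Xt.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xt.std(axis=0), 1.0, atol=1e-9)


class TestFit:
    def test_perfect_linear_signal_recovered(self):
        rng = np.random.default_rng(3)
        n = 36
        X = pd.DataFrame(rng.standard_normal((n, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = -50.0 + 12.0 * X["f2"].to_numpy()
        m = ElasticNetResponseModel(alphas=(1e-10,), l1_ratios=(0.5,),
                                    fit_intercept_options=(True,), tol=1e-12,
                                    random_state=0).fit(X, y)
        assert -m.test_score_ < 1e-6
        # coefficient is in the z-scored space of the training rows
        train_sd = X["f2"].iloc[m.train_index_].std(ddof=0)
        assert m.coef_[2] == pytest.approx(12.0 * train_sd, rel=1e-3)

    def test_grid_covers_reference_hyperparameters(self):
        m = ElasticNetResponseModel()
        assert 3.0 in m.alphas
        assert set(m.l1_ratios) >= {0.1, 0.5, 0.9}
        assert set(m.fit_intercept_options) == {True, False}

    def test_deterministic_given_seed(self):
        sef, clinical = _toy_tables(n=30, seed=5)
        X, y = assemble_features(sef, None, clinical, "sef")
        m1 = ElasticNetResponseModel(random_state=7).fit(X, y)
        m2 = ElasticNetResponseModel(random_state=7).fit(X, y)
        np.testing.assert_array_equal(m1.coef_, m2.coef_)
        assert m1.best_params_ == m2.best_params_
        assert m1.train_score_ == m2.train_score_
        assert m1.test_score_ == m2.test_score_
        np.testing.assert_array_equal(m1.train_index_, m2.train_index_)

    def test_zero_variance_feature_dropped_and_reported(self):
        sef, clinical = _toy_tables(n=24, seed=2)
        sef["Fz_alpha_span"] = 3.14
        X, y = assemble_features(sef, None, clinical, "sef")
        m = ElasticNetResponseModel(random_state=1).fit(X, y)
        assert "Fz_alpha_span" in m.dropped_features_
        assert "Fz_alpha_span" not in m.feature_names_
        assert m.report_.dropped_features == ["Fz_alpha_span"]

    def test_too_few_subjects_rejected(self):
        sef, clinical = _toy_tables(n=10)
        X, y = assemble_features(sef, None, clinical, "sef")
        with pytest.raises(ValueError):
            ElasticNetResponseModel().fit(X, y)


class TestPermutation:
    def test_train_phase_matches_sklearn_permutation_test_score(self):
        """Dual-route check: the fold-precomputed permutation loop
        reproduces sklearn's permutation_test_score exactly (same seed,
        same folds, same selected hyperparameters)."""
        sef, clinical = _toy_tables(n=27, seed=11)
        X, y = assemble_features(sef, None, clinical, "sef")
        m = ElasticNetResponseModel(random_state=3).fit(X, y)
        res = permutation_test(m, n_permutations=120, random_state=42)

        Xtr = X.iloc[m.train_index_][m.feature_names_]
        ytr = y.to_numpy()[m.train_index_]
        p = m.best_params_
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("impute", KNNImputer(n_neighbors=2)),
            ("en", __import__("sklearn.linear_model", fromlist=["ElasticNet"]).ElasticNet(
                alpha=p["alpha"], l1_ratio=p["l1_ratio"],
                fit_intercept=p["fit_intercept"], max_iter=50_000)),
        ])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score, perm_scores, p_skl = permutation_test_score(
                pipe, Xtr, ytr, cv=m.cv_folds_,
                scoring="neg_root_mean_squared_error",
                n_permutations=120, random_state=42,
            )
        assert res["observed_train"] == pytest.approx(score, abs=1e-10)
        np.testing.assert_allclose(res["null_train"], perm_scores, atol=1e-8)
        assert res["p_train"] == pytest.approx(p_skl, abs=1e-12)

    def test_p_lower_bound_when_observed_beats_all(self):
        rng = np.random.default_rng(8)
        n = 36
        X = pd.DataFrame(rng.standard_normal((n, 5)))
        y = -50.0 + 10.0 * X[1].to_numpy()
        m = ElasticNetResponseModel(alphas=(1e-8,), l1_ratios=(0.5,),
                                    fit_intercept_options=(True,),
                                    random_state=0).fit(X, y)
        res = permutation_test(m, n_permutations=150, random_state=1)
        assert res["p_test"] == pytest.approx(1.0 / 151.0)
        assert res["p_train"] == pytest.approx(1.0 / 151.0)

    def test_training_phase_blind_to_test_outcomes(self):
        """No leakage: altering held-out outcomes cannot change the
        training-phase observed score or null distribution."""
        sef, clinical = _toy_tables(n=27, seed=13)
        X, y = assemble_features(sef, None, clinical, "sef")
        m = ElasticNetResponseModel(random_state=5).fit(X, y)
        y2 = y.to_numpy().copy()
        rng = np.random.default_rng(0)
        y2[m.test_index_] = rng.permutation(y2[m.test_index_])
        r1 = permutation_test(m, X, y.to_numpy(), n_permutations=100, random_state=9)
        r2 = permutation_test(m, X, y2, n_permutations=100, random_state=9)
        assert r1["observed_train"] == r2["observed_train"]
        np.testing.assert_array_equal(r1["null_train"], r2["null_train"])

    def test_minimum_permutations_enforced(self):
        sef, clinical = _toy_tables(n=24)
        X, y = assemble_features(sef, None, clinical, "sef")
        m = ElasticNetResponseModel(random_state=1).fit(X, y)
        with pytest.raises(ValueError):
            permutation_test(m, n_permutations=50)


class TestCrossArm:
    def test_same_arm_gives_identical_predictions(self):
        sef, clinical = _toy_tables(n=24, seed=21)
        X, y = assemble_features(sef, None, clinical, "sef")
        m = ElasticNetResponseModel(random_state=2).fit(X, y)
        res = cross_arm_apply(m, X, y.to_numpy(), n_permutations=100, random_state=0)
        np.testing.assert_allclose(
            res["predictions"]["predicted"].to_numpy(), m.predict(X), atol=1e-12)

    def test_layout_mismatch_rejected(self):
        sef, clinical = _toy_tables(n=24, seed=22)
        X, y = assemble_features(sef, None, clinical, "sef")
        m = ElasticNetResponseModel(random_state=2).fit(X, y)
        with pytest.raises(ValueError, match="layout"):
            cross_arm_apply(m, X.iloc[:, :40], y.to_numpy())
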