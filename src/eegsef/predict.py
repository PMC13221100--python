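"""Elastic-net prediction of HAM-D percentage change with stratified
cross-validated hyperparameter search, held-out evaluation and
permutation significance testing.

The estimator follows the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
wraps a Pipeline of z-scoring (``StandardScaler``), K-nearest-neighbour
imputation in standardized space (``KNNImputer``, k=2) and
``ElasticNet``. Model selection is a grid search over regularization
strength, L1 ratio and intercept inclusion, scored by negative RMSE in
stratified 3-fold cross-validation on a stratified 2/3 training split;
stratification uses the binary responder flag (HAM-D decrease >= 50%).

Permutation tests shuffle the outcome and refit with the selected
hyperparameters: the training-phase p averages scores over the same
folds used for selection (the semantics of
``sklearn.model_selection.permutation_test_score``, exploiting that the
X-side preprocessing is outcome-independent and can be precomputed per
fold); the test-phase p shuffles held-out outcomes against the frozen
model's predictions. p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.impute import KNNImputer
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils import check_random_state

from .events import sef_columns
from .power import apf_columns

log = logging.getLogger(__name__)

#: HAM-D percentage change at or below which a subject is a responder
#: (a decrease of at least 50%).
RESPONDER_PCT = -50.0


def percent_change_outcome(clinical: pd.DataFrame) -> pd.Series:
    out = 100.0 * (clinical["hamd_post"] - clinical["hamd_pre"]) / clinical["hamd_pre"]
    out.index = clinical["subject_id"]
    out.name = "pct_change"
    return out


def responder_flag(y) -> np.ndarray:
    return np.asarray(y) <= RESPONDER_PCT


def remitter_flag(clinical: pd.DataFrame, threshold: int = 7) -> np.ndarray:
    """Remission: post-treatment HAM-D of ``threshold`` (7) or less."""
    return clinical["hamd_post"].to_numpy() <= threshold


def assemble_features(
    sef: pd.DataFrame = None,
    apf: pd.DataFrame = None,
    clinical: pd.DataFrame = None,
    feature_set: str = "sef",
):
    """Join per-subject feature tables with the clinical outcome.

    ``sef``/``apf`` are wide tables indexed by subject id; ``clinical``
    must carry subject_id, hamd_pre and hamd_post. Subjects lacking a
    clinical outcome are dropped with a log entry. The feature matrix is
    the selected feature block(s) plus the pre-treatment HAM-D score as
    the final column (85 columns for SEF only with 7 channels x 3 bands x
    4 features).

    Returns ``(X, y)``: DataFrame of features and Series of %change.
    """
    if feature_set not in ("sef", "apf", "both"):
        raise ValueError("feature_set must be 'sef', 'apf' or 'both'")
    blocks = []
    if feature_set in ("sef", "both"):
        if sef is None:
            raise ValueError("feature_set includes SEF but no SEF table given")
        blocks.append(sef)
    if feature_set in ("apf", "both"):
        if apf is None:
            raise ValueError("feature_set includes APF but no APF table given")
        blocks.append(apf)
    X = pd.concat(blocks, axis=1)

    clin = clinical.set_index("subject_id")
    ok = clin["hamd_post"].notna() & clin["hamd_pre"].notna() & (clin["hamd_pre"] > 0)
    dropped = clin.index[~ok]
    if len(dropped):
        log.info("dropping %d subjects without clinical outcome: %s",
                 len(dropped), list(dropped))
    clin = clin[ok]
    common = X.index.intersection(clin.index)
    X = X.loc[common].copy()
    clin = clin.loc[common]
    X["hamd_pre"] = clin["hamd_pre"].astype(float)
    y = 100.0 * (clin["hamd_post"] - clin["hamd_pre"]) / clin["hamd_pre"]
    y.name = "pct_change"
    return X, y


def _neg_rmse(y_true, y_pred) -> float:
    return -float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def _safe_pearson_r(a, b) -> float:
    """Pearson r, NaN for degenerate (constant) inputs — e.g. a maximally
    regularized model predicting a constant."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class ModelReport:
    """Serializable summary of a fitted response model."""

    hyperparameters: dict
    fold_scores: list
    train_score: float
    test_score: float
    train_r2: float
    train_pearson_r: float
    coefficients: dict
    intercept: float
    dropped_features: list
    predictions: pd.DataFrame
    permutation: dict = field(default_factory=dict)
    permutation_importance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "hyperparameters": self.hyperparameters,
            "fold_scores": list(map(float, self.fold_scores)),
            "train_score": self.train_score,
            "test_score": self.test_score,
            "train_r2": self.train_r2,
            "train_pearson_r": self.train_pearson_r,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "dropped_features": list(self.dropped_features),
            "permutation": self.permutation,
            "permutation_importance": self.permutation_importance,
        }
        return d


class ElasticNetResponseModel(BaseEstimator, RegressorMixin):
    """Elastic-net treatment-response model with internal model selection.

    Parameters
    ----------
    alphas, l1_ratios, fit_intercept_options : sequences
        Hyperparameter grid. The defaults bracket the regime where strong
        regularization with a mixed penalty is selected on this kind of
        wide, weak-signal feature matrix.
    n_splits : int
        Stratified CV folds for the grid search.
    test_size : float
        Held-out fraction of the outer stratified split.
    n_neighbors : int
        K for KNN imputation of missing feature cells (standardized space).
    random_state : int or None
        Seeds the outer split, fold shuffling and any downstream
        permutation draws; identical inputs and seed give identical fits.

    Attributes (after ``fit``)
    ----------
    best_params_ : dict of selected hyperparameters
    coef_, intercept_ : fitted elastic-net weights (kept-feature order)
    train_score_, test_score_ : negative RMSE (CV mean; held-out)
    train_r2_, train_pearson_r_ : in-sample predicted-vs-true agreement
    train_index_, test_index_ : row positions of the outer split
    report_ : :class:`ModelReport`
    """

    def __init__(
        self,
        alphas=(0.1, 0.3, 1.0, 3.0, 10.0),
        l1_ratios=(0.1, 0.5, 0.9),
        fit_intercept_options=(True, False),
        n_splits=3,
        test_size=1.0 / 3.0,
        n_neighbors=2,
        max_split_retries=20,
        tol=1e-4,
        random_state=None,
    ):
        self.alphas = alphas
        self.l1_ratios = l1_ratios
        self.fit_intercept_options = fit_intercept_options
        self.n_splits = n_splits
        self.test_size = test_size
        self.n_neighbors = n_neighbors
        self.max_split_retries = max_split_retries
        self.tol = tol
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, float))

    def _make_pipeline(self, alpha, l1_ratio, fit_intercept) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("impute", KNNImputer(n_neighbors=self.n_neighbors)),
            ("en", ElasticNet(alpha=alpha, l1_ratio=l1_ratio,
                              fit_intercept=fit_intercept, max_iter=50_000,
                              tol=self.tol)),
        ])

    def _stratified_folds(self, n_train, strat, seed):
        """Shuffled stratified folds whose validation parts see both
        outcome classes (when both exist); reshuffles on degenerate draws."""
        both = strat.sum() >= self.n_splits and (~strat).sum() >= self.n_splits
        for attempt in range(self.max_split_retries):
            skf = StratifiedKFold(self.n_splits, shuffle=True, random_state=seed + attempt)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                folds = list(skf.split(np.zeros(n_train), strat))
            if not both:
                if attempt == 0:
                    log.warning("too few responders/non-responders to stratify "
                                "%d folds; folds may be single-class", self.n_splits)
                return folds
            if all(len(np.unique(strat[val])) == 2 for _, val in folds):
                return folds
            log.info("stratified fold draw %d degenerate; reshuffling", attempt)
        return folds

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = self._as_frame(X)
        y = np.asarray(y, float)
        if len(X) < 4 * self.n_splits:
            raise ValueError(f"need at least {4 * self.n_splits} subjects")
        rng = check_random_state(self.random_state)
        split_seed, fold_seed = rng.randint(0, 2**31 - 1, size=2)

        strat = responder_flag(y)
        stratify = strat if (strat.sum() >= 2 and (~strat).sum() >= 2) else None
        if stratify is None:
            log.warning("outer split not stratified: a responder class has < 2 members")
        idx = np.arange(len(X))
        train_idx, test_idx = train_test_split(
            idx, test_size=self.test_size, stratify=stratify, random_state=split_seed
        )
        self.train_index_, self.test_index_ = np.sort(train_idx), np.sort(test_idx)

        Xtr = X.iloc[self.train_index_]
        ytr = y[self.train_index_]

        sd = Xtr.std(axis=0, ddof=0, skipna=True)
        n_obs = Xtr.notna().sum(axis=0)
        bad = Xtr.columns[(sd.fillna(0.0) == 0.0) | (n_obs == 0)]
        if len(bad):
            log.warning("dropping %d zero-variance features: %s", len(bad), list(bad))
        self.dropped_features_ = list(bad)
        self.feature_names_ = [c for c in X.columns if c not in set(bad)]
        Xtr = Xtr[self.feature_names_]

        folds = self._stratified_folds(len(Xtr), strat[self.train_index_], fold_seed)
        self.cv_folds_ = folds

        grid = {
            "en__alpha": list(self.alphas),
            "en__l1_ratio": list(self.l1_ratios),
            "en__fit_intercept": list(self.fit_intercept_options),
        }
        gs = GridSearchCV(
            self._make_pipeline(1.0, 0.5, True), grid,
            scoring="neg_root_mean_squared_error", cv=folds, refit=True,
            error_score="raise",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gs.fit(Xtr, ytr)

        self.best_params_ = {k.replace("en__", ""): v for k, v in gs.best_params_.items()}
        self.pipeline_ = gs.best_estimator_
        self.cv_results_ = gs.cv_results_
        i = gs.best_index_
        self.fold_scores_ = [gs.cv_results_[f"split{k}_test_score"][i]
                             for k in range(self.n_splits)]
        self.train_score_ = float(gs.best_score_)

        en = self.pipeline_.named_steps["en"]
        self.coef_ = en.coef_.copy()
        self.intercept_ = float(en.intercept_)

        Xte = X.iloc[self.test_index_][self.feature_names_]
        yte = y[self.test_index_]
        pred_te = self.pipeline_.predict(Xte)
        self.test_score_ = _neg_rmse(yte, pred_te)
        self.predictions_ = pd.DataFrame(
            {"true": yte, "predicted": pred_te}, index=Xte.index
        )

        pred_tr = self.pipeline_.predict(Xtr)
        ss_res = np.sum((ytr - pred_tr) ** 2)
        ss_tot = np.sum((ytr - ytr.mean()) ** 2)
        self.train_r2_ = float(1.0 - ss_res / ss_tot)
        self.train_pearson_r_ = _safe_pearson_r(ytr, pred_tr)
        self._X_fit, self._y_fit = X, y
        return self

    def predict(self, X):
        X = self._as_frame(X)[self.feature_names_]
        return self.pipeline_.predict(X)

    @property
    def report_(self) -> ModelReport:
        return ModelReport(
            hyperparameters=dict(self.best_params_),
            fold_scores=self.fold_scores_,
            train_score=self.train_score_,
            test_score=self.test_score_,
            train_r2=self.train_r2_,
            train_pearson_r=self.train_pearson_r_,
            coefficients=dict(zip(self.feature_names_, self.coef_)),
            intercept=self.intercept_,
            dropped_features=self.dropped_features_,
            predictions=self.predictions_,
        )


def _fold_transforms(model: ElasticNetResponseModel, Xtr: pd.DataFrame):
    """Per-fold (Xt_train, Xt_val) with the X-side preprocessing fitted on
    the fold's training part; identical under any permutation of y."""
    out = []
    for tr, val in model.cv_folds_:
        prep = Pipeline([
            ("scale", StandardScaler()),
            ("impute", KNNImputer(n_neighbors=model.n_neighbors)),
        ])
        Xt_tr = prep.fit_transform(Xtr.iloc[tr])
        Xt_val = prep.transform(Xtr.iloc[val])
        out.append((tr, val, Xt_tr, Xt_val))
    return out


def _en_like(model: ElasticNetResponseModel) -> ElasticNet:
    p = model.best_params_
    return ElasticNet(alpha=p["alpha"], l1_ratio=p["l1_ratio"],
                      fit_intercept=p["fit_intercept"], max_iter=50_000,
                      tol=model.tol)


def permutation_test(
    model: ElasticNetResponseModel,
    X=None,
    y=None,
    n_permutations: int = 5000,
    random_state=None,
) -> dict:
    """One-sided permutation significance of a fitted response model.

    Training phase: outcomes of the training split are shuffled, the
    elastic net (selected hyperparameters) is refit per CV fold and the
    mean fold score forms the null distribution for the observed mean CV
    score. Test phase: held-out outcomes are shuffled against the frozen
    model's predictions. Returns a dict with p values and null scores.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    X = model._X_fit if X is None else model._as_frame(X)
    y = model._y_fit if y is None else np.asarray(y, float)
    rng = check_random_state(random_state)

    Xtr = X.iloc[model.train_index_][model.feature_names_]
    ytr = y[model.train_index_]
    folds = _fold_transforms(model, Xtr)

    def cv_score(yy):
        scores = []
        for tr, val, Xt_tr, Xt_val in folds:
            en = _en_like(model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                en.fit(Xt_tr, yy[tr])
            scores.append(_neg_rmse(yy[val], en.predict(Xt_val)))
        return float(np.mean(scores))

    observed_train = cv_score(ytr)
    null_train = np.array([cv_score(rng.permutation(ytr)) for _ in range(n_permutations)])
    p_train = (1.0 + np.sum(null_train >= observed_train)) / (1.0 + n_permutations)

    yte = y[model.test_index_]
    pred = model.predictions_["predicted"].to_numpy()
    observed_test = _neg_rmse(yte, pred)
    null_test = np.array([
        _neg_rmse(rng.permutation(yte), pred) for _ in range(n_permutations)
    ])
    p_test = (1.0 + np.sum(null_test >= observed_test)) / (1.0 + n_permutations)

    return {
        "p_train": float(p_train),
        "p_test": float(p_test),
        "observed_train": observed_train,
        "observed_test": observed_test,
        "null_train": null_train,
        "null_test": null_test,
        "n_permutations": int(n_permutations),
    }


def cross_arm_apply(
    model: ElasticNetResponseModel,
    X_other,
    y_other,
    n_permutations: int = 5000,
    random_state=None,
) -> dict:
    """Apply a frozen fitted model (including its normalization and
    imputation) to another treatment arm and permutation-test the fit.

    The null shuffles the other arm's outcomes against the frozen
    predictions; nothing is refit.
    """
    X_other = model._as_frame(X_other)
    missing = [c for c in model.feature_names_ if c not in X_other.columns]
    if missing:
        raise ValueError(f"feature layout mismatch; missing columns: {missing[:5]} ...")
    y_other = np.asarray(y_other, float)
    rng = check_random_state(random_state)
    pred = model.predict(X_other)
    observed = _neg_rmse(y_other, pred)
    null = np.array([
        _neg_rmse(rng.permutation(y_other), pred) for _ in range(n_permutations)
    ])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    r = _safe_pearson_r(y_other, pred)
    return {
        "score": observed,
        "p": float(p),
        "pearson_r": r,
        "predictions": pd.DataFrame({"true": y_other, "predicted": pred},
                                    index=X_other.index),
        "n_permutations": int(n_permutations),
    }


def expected_feature_columns(channels, bands, feature_set="sef"):
    """Documented feature-matrix layout (excluding the hamd_pre column)."""
    if feature_set == "sef":
        return sef_columns(channels, bands)
    if feature_set == "apf":
        return apf_columns(channels, bands)
    return sef_columns(channels, bands) + apf_columns(channels, bands)
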