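"""Post-hoc biomarker analyses: permutation feature importance, corrected
channel-level correlations with the outcome, responder/remitter group
comparisons and age-matched control subsampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.utils import check_random_state


def permutation_importance(
    model,
    X,
    y,
    n_repeats: int = 10,
    importance_cutoff: float = 1.5,
    top_k: int = 5,
    random_state=None,
) -> pd.DataFrame:
    """Permutation importance of a fitted response model's features.

    Importance is the mean drop in negative-RMSE score over ``n_repeats``
    independent shuffles of each feature column. Features are ranked by
    absolute importance; the returned table flags the top-``top_k`` set
    and those whose |importance| exceeds ``importance_cutoff``.
    """
    X = model._as_frame(X)[model.feature_names_]
    y = np.asarray(y, float)
    res = _sk_permutation_importance(
        model.pipeline_, X, y,
        scoring="neg_root_mean_squared_error",
        n_repeats=n_repeats, random_state=random_state,
    )
    df = pd.DataFrame({
        "feature": model.feature_names_,
        "importance": res.importances_mean,
        "importance_sd": res.importances_std,
    })
    df["abs_importance"] = df["importance"].abs()
    df = df.sort_values("abs_importance", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    # zero-importance ties are not "most predictive" features
    df["top_k"] = (df["rank"] <= top_k) & (df["abs_importance"] > 0)
    df["above_cutoff"] = df["abs_importance"] > importance_cutoff
    return df


def channel_level_correlations(
    features,
    X: pd.DataFrame,
    y,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pearson correlation of selected feature columns with the outcome,
    corrected for multiple comparisons across exactly those features.

    A constant feature records NaN (undefined), not zero. ``correction``
    is ``'bonferroni'`` (default) or ``'holm'``; corrected p values are
    clipped at 1 and are never below the raw p.
    """
    y = np.asarray(y, float)
    if len(y) < 3:
        raise ValueError("need >= 3 subjects")
    features = list(features)
    if not features:
        return pd.DataFrame(columns=["feature", "r", "p_raw", "n", "p_corrected"])
    rows = []
    for f in features:
        v = X[f].to_numpy(float)
        ok = np.isfinite(v) & np.isfinite(y)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"feature": f, "r": np.nan, "p_raw": np.nan, "n": int(ok.sum())})
            continue
        r, p = stats.pearsonr(v[ok], y[ok])
        rows.append({"feature": f, "r": float(r), "p_raw": float(p), "n": int(ok.sum())})
    df = pd.DataFrame(rows)
    m = int(df["p_raw"].notna().sum())
    if correction == "bonferroni":
        df["p_corrected"] = np.minimum(1.0, df["p_raw"] * m)
    elif correction == "holm":
        p = df["p_raw"].to_numpy(float)
        order = np.argsort(np.where(np.isfinite(p), p, np.inf))
        adj = np.full_like(p, np.nan)
        running = 0.0
        rank = 0
        for i in order:
            if not np.isfinite(p[i]):
                continue
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
            rank += 1
        df["p_corrected"] = adj
    else:
        raise ValueError("correction must be 'bonferroni' or 'holm'")
    return df


def group_compare(
    values,
    groups,
    alternative: str = "less",
    equal_var: bool = True,
):
    """Two-sample t-test of a feature between two groups.

    ``groups`` is a boolean/binary array; group True (e.g. responders) is
    the first sample. One-sided by default (``alternative='less'``: first
    group smaller); Student pooled-variance by default, Welch via
    ``equal_var=False``. Returns ``(t, p)``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups).astype(bool)
    a, b = values[groups], values[~groups]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(t), float(p)


def age_matched_subsample(
    patients: pd.DataFrame,
    controls: pd.DataFrame,
    random_state=None,
):
    """Greedy nearest-age matching of one patient per control.

    Controls are visited in an order randomized by ``random_state``; each
    takes the still-unmatched patient with the smallest absolute age
    difference. Returns ``(matched_patient_ids, mean_abs_age_diff)``.
    """
    if len(patients) < len(controls):
        raise ValueError("need at least as many patients as controls")
    rng = check_random_state(random_state)
    order = rng.permutation(len(controls))
    pat_ids = patients["subject_id"].to_numpy()
    pat_age = patients["age"].to_numpy(float)
    available = np.ones(len(patients), bool)
    matched, diffs = [], []
    for ci in order:
        c_age = float(controls["age"].iloc[ci])
        cand = np.where(available)[0]
        best = cand[np.argmin(np.abs(pat_age[cand] - c_age))]
        available[best] = False
        matched.append(pat_ids[best])
        diffs.append(abs(pat_age[best] - c_age))
    return list(matched), float(np.mean(diffs))
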