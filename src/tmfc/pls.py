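"""Partial least squares association of dynamic features with outcomes.

One PLS1 regression per response variable (global cognition, memory, tau
and amyloid burden), fitted on log-transformed, z-scored predictors, with
the latent-variable count chosen by cross-validated MSE and predictor
significance judged by variable-importance-in-projection (VIP > 1).

For a fitted model with unit-norm weight vectors w_a, scores t_a and
response loadings q_a, the response variance captured by component a is
SS_a = q_a^2 * ||t_a||^2 and

    VIP_j = sqrt( p * sum_a SS_a * (w_ja / ||w_a||)^2 / sum_a SS_a ),

whose squares average to 1 over the p predictors, making 1 the natural
significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold


@dataclass
class PLSModel:
    weights: np.ndarray          # p x A, unit-norm columns
    x_loadings: np.ndarray       # p x A
    scores: np.ndarray           # n x A
    y_loadings: np.ndarray       # A
    explained_variance: np.ndarray  # per-LV fraction of response variance
    n_components: int
    predictor_names: list[str]
    estimator: PLSRegression


@dataclass
class VIPReport:
    vip: pd.Series
    significant: pd.Series
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vip": self.vip, "significant": self.significant,
             "r_squared": self.r_squared}
        )


def preprocess(X: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Log-transform skewed columns, then z-score every column.

    Continuous columns get ``log(x + eps)`` with ``eps`` half the smallest
    positive value of the column (guarding exact zeros); binary columns
    (two or fewer distinct values) are z-scored without the log.  Constant
    columns become all-zero with a warning.
    """
    out = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        binary = len(np.unique(v)) <= 2
        if log_transform and not binary:
            positive = v[v > 0]
            if positive.size == 0:
                warnings.warn(f"column {col!r} has no positive values; "
                              "log transform skipped", RuntimeWarning)
            else:
                eps = positive.min() / 2.0
                if np.any(v < 0):
                    warnings.warn(f"column {col!r} has negative values; "
                                  "log transform skipped", RuntimeWarning)
                else:
                    v = np.log(v + eps)
        sd = v.std()
        if sd == 0:
            warnings.warn(f"column {col!r} is constant; zeroed after centering",
                          RuntimeWarning)
            out[col] = np.zeros_like(v)
        else:
            out[col] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=X.index)


def fit_pls(X: np.ndarray | pd.DataFrame, y: np.ndarray, n_components: int) -> PLSModel:
    """NIPALS PLS1 fit with per-component deflation and orthogonal scores."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rank = np.linalg.matrix_rank(Xa - Xa.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds predictor rank {rank}")
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(Xa, y)
    W = est.x_weights_
    T = est.x_scores_
    q = est.y_loadings_.ravel()
    ss_y = ((y - y.mean()) ** 2).sum()
    ss_comp = (q**2) * (T**2).sum(axis=0)
    explained = ss_comp / ss_y if ss_y > 0 else np.zeros_like(ss_comp)
    return PLSModel(weights=W, x_loadings=est.x_loadings_, scores=T,
                    y_loadings=q, explained_variance=explained,
                    n_components=n_components, predictor_names=names,
                    estimator=est)


def select_components_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    max_components: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Latent-variable count minimizing K-fold cross-validated MSE.

    Deterministic given seed and fold count; ties break toward fewer
    components.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    folds = min(folds, n)
    max_components = int(min(max_components, Xa.shape[1], n - int(np.ceil(n / folds)) - 1))
    max_components = max(max_components, 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros(max_components)
    for train, test in kf.split(Xa):
        rank = np.linalg.matrix_rank(Xa[train] - Xa[train].mean(axis=0))
        for a in range(1, max_components + 1):
            k = min(a, max(rank, 1))
            est = PLSRegression(n_components=k, scale=False)
            est.fit(Xa[train], y[train])
            pred = est.predict(Xa[test]).ravel()
            mse[a - 1] += ((pred - y[test]) ** 2).sum()
    mse /= n
    return int(np.argmin(mse)) + 1


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPReport:
    """Per-predictor VIP scores and the VIP > 1 significance flags."""
    W = model.weights
    ss = model.explained_variance
    p = W.shape[0]
    total = ss.sum()
    if total <= 0:
        warnings.warn("model explains no response variance; VIP undefined",
                      RuntimeWarning)
        vip = pd.Series(np.nan, index=model.predictor_names)
        return VIPReport(vip=vip, significant=vip > threshold, r_squared=0.0)
    wnorm = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip_vals = np.sqrt(p * (wnorm**2 @ ss) / total)
    vip = pd.Series(vip_vals, index=model.predictor_names)
    return VIPReport(vip=vip, significant=vip > threshold,
                     r_squared=float(total))


DEFAULT_RESPONSES = ("MMSE", "ADAS_Q4", "tau_suvr", "amyloid_suvr")
PLS_COVARIATES = ("age", "sex", "education", "cognitive_status")


def run_pls_suite(
    cohort: pd.DataFrame,
    feature_cols: list[str],
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
    reference_group: str = "CN_Abneg",
    impaired_groups: tuple[str, ...] = ("MCI_Abpos", "AD_Abpos"),
    max_components: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, VIPReport]:
    """One PLS model per response over the amyloid-positive subjects.

    Predictors are the dynamic features plus age, sex, education, and a
    binary cognitive-status covariate (0 = cognitively normal, 1 = impaired).
    """
    sub = cohort[cohort["group"] != reference_group].reset_index(drop=True)
    sub = sub.assign(cognitive_status=sub["group"].isin(impaired_groups).astype(float))
    predictors = feature_cols + list(PLS_COVARIATES)
    X = preprocess(sub[predictors])
    reports: dict[str, VIPReport] = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(responses))
    for resp, s in zip(responses, seeds):
        if resp not in sub.columns:
            warnings.warn(f"response {resp!r} missing; skipped", RuntimeWarning)
            continue
        y = sub[resp].to_numpy(dtype=float)
        k = select_components_cv(X, y, max_components=max_components,
                                 folds=folds, seed=int(s) % (2**31))
        model = fit_pls(X, y, n_components=k)
        reports[resp] = vip_scores(model)
    return reports
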