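"""Group discrimination with stepwise-AIC logistic models and bootstrap ROC.

Three feature pools are compared for each patient group versus the
amyloid-negative controls: the dynamic functional measures (model F), the
risk factors age, sex and APOE e4 (model R), and their union (model F+R).
Variable selection is bidirectional stepwise search minimizing AIC; model
scores are evaluated with the rank-based (Mann–Whitney) AUC, a stratified
bootstrap of 1000 replicates, and the cutpoint maximizing
sensitivity + specificity (Youden's J).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class ModelSpec:
    pool: list[str]
    selected: list[str]
    coefficients: dict[str, float]
    aic: float
    aic_trace: list[float] = field(default_factory=list)
    separation_warning: bool = False
    model: object | None = None


@dataclass
class AUCResult:
    auc: float
    replicates: np.ndarray
    cutpoint: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int]
    n_redrawn: int = 0


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """GLM-Binomial fit with an iteration cap; returns (result, separation_flag)."""
    design = sm.add_constant(X, has_constant="add")
    sep = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            return None, True
    fitted = res.fittedvalues
    if np.any(fitted > 1 - 1e-10) or np.any(fitted < 1e-10):
        sep = True
    if not np.isfinite(res.aic):
        return None, True
    return res, sep


def stepwise_logistic(
    features: pd.DataFrame,
    labels: np.ndarray,
    direction: str = "both",
) -> ModelSpec:
    """Bidirectional stepwise logistic regression minimizing AIC.

    Starts from the intercept-only model; at each step every single-variable
    addition (and, for ``direction='both'``, removal) is scored by AIC and
    the best strictly-improving step is taken.  Ties break toward the
    smaller model, then lexicographically, so the search is deterministic.
    """
    labels = np.asarray(labels, dtype=float)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pool = list(features.columns)
    selected: list[str] = []
    res, sep_any = _fit_logit(features[selected], labels)
    current_aic = res.aic
    trace = [current_aic]
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, int, str, str]] = []
        if direction in ("both", "backward"):
            for name in selected:
                trial = [c for c in selected if c != name]
                r, sep = _fit_logit(features[trial], labels)
                if r is not None:
                    candidates.append((r.aic, 0, name, "drop"))
                    sep_any |= sep
        if direction in ("both", "forward"):
            for name in pool:
                if name in selected:
                    continue
                r, sep = _fit_logit(features[selected + [name]], labels)
                if r is not None:
                    candidates.append((r.aic, 1, name, "add"))
                    sep_any |= sep
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        best_aic, _, best_name, action = candidates[0]
        if best_aic < current_aic - 1e-9:
            if action == "add":
                selected.append(best_name)
            else:
                selected.remove(best_name)
            current_aic = best_aic
            trace.append(current_aic)
            improved = True
    selected = sorted(selected)  # canonical order, shared with predict_scores
    res, sep = _fit_logit(features[selected], labels)
    sep_any |= sep
    if sep_any:
        warnings.warn("possible separation in logistic fit; coefficients "
                      "capped at the iteration limit", RuntimeWarning, stacklevel=2)
    coefs = dict(zip(res.params.index, res.params.values))
    return ModelSpec(pool=pool, selected=selected, coefficients=coefs,
                     aic=float(res.aic), aic_trace=trace,
                     separation_warning=sep_any, model=res)


def predict_scores(spec: ModelSpec, features: pd.DataFrame) -> np.ndarray:
    design = sm.add_constant(features[spec.selected], has_constant="add")
    return np.asarray(spec.model.predict(design))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann–Whitney rank formulation with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_cutpoint(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Cutpoint maximizing sensitivity + specificity; returns (cut, sens, spec)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)
    best = (-np.inf, thresholds[0], 0.0, 0.0)
    n1 = labels.sum()
    n0 = len(labels) - n1
    for t in thresholds:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec
        if j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best[1], best[2], best[3]


def roc_curve_table(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr) over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores)
    tps = np.cumsum(labels[order])
    fps = np.cumsum(1 - labels[order])
    tpr = np.concatenate([[0.0], tps / max(labels.sum(), 1)])
    fpr = np.concatenate([[0.0], fps / max((1 - labels).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def roc_auc_bootstrap(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> AUCResult:
    """Point AUC plus a class-stratified bootstrap of AUC replicates.

    Resampling is stratified by class (each class resampled with replacement
    from its own members), so every replicate contains both classes; the
    per-replicate cutpoint maximizes sensitivity + specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    auc = rank_auc(scores, labels)
    reps = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        while len(np.unique(labels[idx])) < 2:  # unreachable under stratification
            idx = rng.choice(len(labels), len(labels))
            redrawn += 1
        reps[b] = rank_auc(scores[idx], labels[idx])
    cut, sens, spec = youden_cutpoint(scores, labels)
    pred = scores >= cut
    confusion = {
        "tp": int((pred & (labels == 1)).sum()),
        "fn": int((~pred & (labels == 1)).sum()),
        "fp": int((pred & (labels == 0)).sum()),
        "tn": int((~pred & (labels == 0)).sum()),
    }
    if redrawn:
        warnings.warn(f"{redrawn} bootstrap replicates redrawn", RuntimeWarning)
    return AUCResult(auc=auc, replicates=reps, cutpoint=float(cut),
                     sensitivity=float(sens), specificity=float(spec),
                     confusion=confusion, n_redrawn=redrawn)


def compare_auc_models(*replicate_sets: np.ndarray) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) across bootstrap AUC replicate sets."""
    if len(replicate_sets) < 2:
        raise ValueError("need at least 2 replicate sets")
    arrays = [np.asarray(r, dtype=float) for r in replicate_sets]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        return 0.0, 1.0  # scipy refuses fully identical samples
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def cross_validated_scores(
    spec: ModelSpec,
    features: pd.DataFrame,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predicted probabilities for the already-selected model.

    Refits the selected variable set on each training fold (the selection
    itself is not repeated, so some optimism remains); useful as a check on
    the in-sample ROC, which is the default and is optimistic by
    construction.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels, dtype=float)
    scores = np.full(len(labels), np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(features, labels):
        res, _ = _fit_logit(features.iloc[train][spec.selected], labels[train])
        design = sm.add_constant(features.iloc[test][spec.selected],
                                 has_constant="add")
        if res is None:
            scores[test] = labels[train].mean()
        else:
            scores[test] = np.asarray(res.predict(design))
    return scores


RISK_FACTORS = ["age", "sex", "apoe4"]


def run_classification_suite(
    cohort: pd.DataFrame,
    feature_cols: list[str],
    reference_group: str = "CN_Abneg",
    n_boot: int = 1000,
    seed: int = 0,
    cross_validate: bool = False,
) -> dict[str, dict]:
    """Fit models F, R and F+R for each patient group vs the reference.

    Returns, per comparison, the selected models, their AUC results, the
    Kruskal–Wallis comparison of the three bootstrap replicate sets, and the
    ROC tables.  With ``cross_validate`` the scores are out-of-fold
    predictions of the selected model instead of in-sample fits.
    """
    groups = [g for g in cohort["group"].unique() if g != reference_group]
    pools = {
        "F": feature_cols,
        "R": RISK_FACTORS,
        "F+R": feature_cols + RISK_FACTORS,
    }
    out: dict[str, dict] = {}
    rng = np.random.SeedSequence(seed)
    for g, child in zip(groups, rng.spawn(len(groups))):
        sub = cohort[cohort["group"].isin([g, reference_group])].reset_index(drop=True)
        y = (sub["group"] == g).to_numpy().astype(int)
        if y.sum() < 10 or (len(y) - y.sum()) < 10:
            warnings.warn(f"small class in {g} vs {reference_group}; "
                          "fit proceeds but may be unstable", RuntimeWarning)
        comp: dict[str, dict] = {}
        boot_seeds = child.generate_state(len(pools))
        for (name, pool), bs in zip(pools.items(), boot_seeds):
            spec = stepwise_logistic(sub[pool], y)
            if cross_validate:
                scores = cross_validated_scores(spec, sub[pool], y,
                                                seed=int(bs) % (2**31))
            else:
                scores = predict_scores(spec, sub[pool])
            auc_res = roc_auc_bootstrap(scores, y, n_boot=n_boot, seed=int(bs) % (2**31))
            comp[name] = {"model": spec, "auc": auc_res,
                          "roc": roc_curve_table(scores, y)}
        h, p = compare_auc_models(*[comp[m]["auc"].replicates for m in pools])
        comp["kruskal"] = {"H": h, "p": p}
        out[f"{g}_vs_{reference_group}"] = comp
    return out
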