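"""Group inference: robust outlier screening, covariate-adjusted permutation
tests between groups, and FDR control across the family of comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .measures import MEASURES

MAD_SCALE = 1.4826  # normal-consistency constant


def mad_outlier_mask(values: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Flag values more than ``threshold`` scaled-MADs from the median.

    The MAD is scaled by 1.4826 so the threshold is in normal-sd units.
    When the MAD is zero, any value that deviates from the median at all is
    infinitely many MADs away and is flagged (with a warning); if all values
    are equal nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for MAD screening")
    med = np.median(values)
    dev = np.abs(values - med)
    mad = np.median(dev)
    if mad == 0:
        mask = dev > 0
        if mask.any():
            warnings.warn(
                "MAD is zero; flagging every value that deviates from the median",
                RuntimeWarning,
                stacklevel=2,
            )
        return mask
    return dev / (MAD_SCALE * mad) > threshold


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of y on an intercept plus covariate columns."""
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    X = np.column_stack([np.ones(len(y)), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Two-sided permutation test of a mean difference.

    The statistic is ``mean(a) - mean(b)``; group labels are permuted
    jointly and the p-value uses the add-one correction
    ``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)``, which is valid for
    any number of permutations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    t_obs = a.mean() - b.mean()
    # vectorized label permutations: argsort of iid uniforms is a uniform
    # random permutation per row
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vals = pooled[order]
    t_perm = perm_vals[:, :na].mean(axis=1) - perm_vals[:, na:].mean(axis=1)
    p = (1.0 + np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-15)) / (1.0 + n_perm)
    return float(t_obs), float(p)


def freedman_lane_test(
    y: np.ndarray,
    group_a: np.ndarray,
    covariates: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Covariate-adjusted permutation test via the Freedman–Lane scheme.

    The reduced model (intercept + covariates) is fitted once; permuted
    residuals are re-projected onto the residual space of the covariates
    before the group mean difference is recomputed, which keeps the
    covariate adjustment inside the permutation distribution.
    ``group_a`` is a boolean mask of the first group.
    """
    y = np.asarray(y, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    if group_a.sum() < 2 or (~group_a).sum() < 2:
        raise ValueError("both groups need at least 2 observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    X = np.column_stack([np.ones(len(y)), cov])
    q, _ = np.linalg.qr(X)
    resid = y - q @ (q.T @ y)

    def stat(e):
        return e[group_a].mean() - e[~group_a].mean()

    t_obs = stat(resid)
    order = np.argsort(rng.random((n_perm, len(y))), axis=1)
    perm = resid[order]                            # n_perm x n
    perm = perm - (perm @ q) @ q.T                 # re-residualize each draw
    t_perm = (perm[:, group_a].mean(axis=1) - perm[:, ~group_a].mean(axis=1))
    p = (1.0 + np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-15)) / (1.0 + n_perm)
    return float(t_obs), float(p)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted q-values, rejection flags)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, reject


def screen_outliers(
    cohort: pd.DataFrame,
    feature_cols: list[str],
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Drop subjects whose average dynamic measures are MAD outliers.

    Each subject's three measures are averaged across systems; screening is
    pooled across the whole sample, and a subject flagged on any measure is
    removed.
    """
    keep = np.ones(len(cohort), dtype=bool)
    for measure in MEASURES:
        cols = [c for c in feature_cols if c.startswith(measure + "_")]
        if not cols:
            continue
        avg = cohort[cols].mean(axis=1).to_numpy()
        keep &= ~mad_outlier_mask(avg, threshold=threshold)
    return cohort.loc[keep].reset_index(drop=True)


def run_group_comparisons(
    cohort: pd.DataFrame,
    feature_cols: list[str],
    reference_group: str = "CN_Abneg",
    n_perm: int = 10_000,
    q: float = 0.05,
    mad_threshold: float = 3.0,
    adjust_for: tuple[str, ...] = ("age", "sex"),
    scheme: str = "residualize",
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation tests of every dynamic feature, each patient group vs reference.

    Subjects are first screened with the MAD rule, features are residualized
    on the adjustment covariates across the retained sample, each comparison
    uses a two-sided permutation test on the residuals, and BH-FDR is
    applied across the full family of measure x system x comparison tests.
    ``scheme='freedman_lane'`` instead keeps the covariate adjustment inside
    the permutation distribution (refitting on each comparison's subjects).
    """
    if scheme not in ("residualize", "freedman_lane"):
        raise ValueError(f"unknown scheme {scheme!r}")
    clean = screen_outliers(cohort, feature_cols, threshold=mad_threshold)
    groups = [g for g in clean["group"].unique() if g != reference_group]
    if reference_group not in set(clean["group"]):
        raise ValueError(f"reference group {reference_group!r} absent after screening")
    rng = np.random.default_rng(seed)
    cov = clean[list(adjust_for)].to_numpy(dtype=float)
    rows = []
    for col in feature_cols:
        resid = residualize(clean[col].to_numpy(dtype=float), cov)
        for g in groups:
            a = resid[(clean["group"] == g).to_numpy()]
            b = resid[(clean["group"] == reference_group).to_numpy()]
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"comparison {g} vs {reference_group} skipped "
                              f"for {col}: group too small", RuntimeWarning)
                continue
            if scheme == "freedman_lane":
                pair = clean["group"].isin([g, reference_group]).to_numpy()
                stat, p = freedman_lane_test(
                    clean.loc[pair, col].to_numpy(dtype=float),
                    (clean.loc[pair, "group"] == g).to_numpy(),
                    cov[pair], n_perm=n_perm, seed=rng,
                )
            else:
                stat, p = permutation_test(a, b, n_perm=n_perm, seed=rng)
            measure, system = col.split("_", 1)
            rows.append(
                {"measure": measure, "system": system,
                 "comparison": f"{g}_vs_{reference_group}",
                 "statistic": stat, "p": p}
            )
    results = pd.DataFrame(rows)
    if len(results):
        adjusted, reject = fdr_bh(results["p"].to_numpy(), q=q)
        results["q"] = adjusted
        results["rejected"] = reject
    return results
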