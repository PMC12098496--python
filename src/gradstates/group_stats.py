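"""Covariate-adjusted mass-univariate group statistics and clinical correlations.

Group comparisons fit, per feature, the linear model

    value ~ intercept + group + age + sex

and report the group coefficient's t statistic with n - p degrees of freedom
(p = number of model columns).  Without covariates this reduces exactly to the
classical pooled two-sample t test.  Multiple-comparison control is
Benjamini-Hochberg FDR for edge/metric families and a permutation-based
cluster-extent correction (max-cluster-size null over group-label
permutations) for voxel-level gradient maps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("gradstates.group_stats")


def _design(groups: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """[1, group(0/1), covariates...]; sex is coded 0/1, age left in years."""
    g = np.asarray(groups)
    if g.dtype.kind in "UO":
        levels = sorted(set(g.tolist()))
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 group levels, got {levels}")
        # 'patient' coded 1 against 'control' when present, else lexicographic
        one = "patient" if "patient" in levels else levels[1]
        g = (g == one).astype(float)
    else:
        g = g.astype(float)
    cols = [np.ones(len(g)), g]
    if covariates is not None:
        for name in covariates.columns:
            v = covariates[name]
            if v.dtype.kind in "UO":
                lv = sorted(set(v.tolist()))
                if len(lv) > 2:
                    raise ValueError(f"covariate {name!r} has >2 levels")
                v = (v == lv[-1]).astype(float)
            cols.append(np.asarray(v, float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates?)")
    return X


def _group_t(values: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised OLS t statistic of the group column for every feature."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough subjects for the model")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ values  # p x m
    resid = values - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
    t = beta[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(pvals, np.finfo(float).tiny, 1.0), df


def adjusted_group_test(values: np.ndarray, groups, covariates: pd.DataFrame | None = None,
                        feature_names=None) -> pd.DataFrame:
    """Per-feature covariate-adjusted two-sample comparison.

    ``values`` is subjects x features.  Returns a table with t, two-sided p,
    effect direction (+1 where the group coded 1 is higher), and df.  Features
    with missing values are tested on complete cases feature by feature.
    """
    values = np.atleast_2d(np.asarray(values, float))
    n, m = values.shape
    if n != len(np.asarray(groups)):
        raise ValueError("values rows must match the number of subjects")
    X = _design(np.asarray(groups), covariates)
    for lvl in (0.0, 1.0):
        if (X[:, 1] == lvl).sum() < 3:
            raise ValueError("need at least 3 subjects per group")
    complete = np.isfinite(values).all(axis=0)
    t = np.full(m, np.nan)
    p = np.full(m, np.nan)
    if complete.any():
        t_c, p_c, df = _group_t(values[:, complete], X)
        t[complete], p[complete] = t_c, p_c
    else:
        df = n - X.shape[1]
    for j in np.flatnonzero(~complete):
        mask = np.isfinite(values[:, j])
        if mask.sum() - X.shape[1] < 1 or len(set(X[mask, 1])) < 2:
            continue  # untestable feature stays NaN
        t[j], p[j], _ = (v[0] if np.ndim(v) else v for v in
                         _group_t(values[mask][:, [j]], X[mask]))
    names = (list(feature_names) if feature_names is not None
             else [f"f{j}" for j in range(m)])
    return pd.DataFrame({
        "feature": names, "t": t, "p": p,
        "direction": np.sign(t), "df": df,
    })


def welch_group_test(values: np.ndarray, groups, feature_names=None) -> pd.DataFrame:
    """Unequal-variance (Welch) two-sample alternative, no covariates."""
    values = np.atleast_2d(np.asarray(values, float))
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()))
    a, b = values[g == levels[0]], values[g == levels[1]]
    t, p = stats.ttest_ind(b, a, equal_var=False)
    names = (list(feature_names) if feature_names is not None
             else [f"f{j}" for j in range(values.shape[1])])
    return pd.DataFrame({"feature": names, "t": t, "p": p, "direction": np.sign(t)})


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    ok = np.isfinite(p)
    if not ((p[ok] > 0) & (p[ok] <= 1)).all():
        raise ValueError("p values must lie in (0, 1]")
    mask = np.zeros(p.shape, bool)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return mask


# ---------------------------------------------------------------------------
# Permutation cluster-extent correction
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    clusters: pd.DataFrame  # cluster_id, region, size, peak_t, voxel indices, p
    t_map: np.ndarray
    voxel_threshold: float
    null_max_sizes: np.ndarray


def _cluster_sizes(supra: np.ndarray, region_labels: np.ndarray) -> list[tuple[int, int]]:
    """Connected runs of supra-threshold voxels under chain adjacency within
    regions; returns (start_index, size) per cluster."""
    clusters = []
    i, n = 0, len(supra)
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1] and region_labels[j + 1] == region_labels[i]:
                j += 1
            clusters.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return clusters


def cluster_correct_permutation(values: np.ndarray, groups,
                                covariates: pd.DataFrame | None,
                                region_labels, voxel_p: float = 0.001,
                                cluster_p: float = 0.05, n_perm: int = 1000,
                                seed: int = 0) -> ClusterResult:
    """Cluster-extent correction by group-label permutation.

    Voxels are thresholded at the two-sided ``voxel_p`` on the adjusted t map;
    contiguous supra-threshold runs (chain adjacency within each region) form
    clusters; the null distribution of the maximal cluster size over
    ``n_perm`` permutations yields cluster p values as
    (1 + #{null >= size}) / (1 + n_perm).
    """
    if (n_perm + 1) * cluster_p < 1.0:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve cluster_p={cluster_p}; "
            f"need at least {int(np.ceil(1.0 / cluster_p)) - 1} permutations"
        )
    values = np.asarray(values, float)
    region_labels = np.asarray(region_labels)
    X = _design(np.asarray(groups), covariates)
    t_obs, _, df = _group_t(values, X)
    t_crit = stats.t.isf(voxel_p / 2.0, df)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    Xp = X.copy()
    for b in range(n_perm):
        Xp[:, 1] = rng.permutation(X[:, 1])
        if len(set(Xp[:, 1])) < 2:
            continue
        t_b, _, _ = _group_t(values, Xp)
        sizes = _cluster_sizes(np.abs(t_b) > t_crit, region_labels)
        null_max[b] = max((s for _, s in sizes), default=0)

    rows = []
    for cid, (start, size) in enumerate(_cluster_sizes(np.abs(t_obs) > t_crit,
                                                       region_labels)):
        idx = np.arange(start, start + size)
        p = (1.0 + (null_max >= size).sum()) / (1.0 + n_perm)
        rows.append({
            "cluster_id": cid, "region": region_labels[start], "size": int(size),
            "peak_t": float(t_obs[idx][np.argmax(np.abs(t_obs[idx]))]),
            "start": int(start),
            "cluster_p": float(p), "significant": bool(p < cluster_p),
        })
    cols = ["cluster_id", "region", "size", "peak_t", "start", "cluster_p",
            "significant"]
    return ClusterResult(pd.DataFrame(rows, columns=cols), t_obs,
                         float(t_crit), null_max)


# ---------------------------------------------------------------------------
# Clinical correlations
# ---------------------------------------------------------------------------

def clinical_correlations(features: pd.DataFrame, clinical: pd.DataFrame,
                          variables=None, group: str | None = "patient") -> pd.DataFrame:
    """Pearson r, R^2 = r^2 and two-sided p between each feature column and
    each clinical variable, patients-only by default.

    Pairs with < 4 complete observations or zero variance are flagged and
    excluded (r = NaN, excluded = True).
    """
    clin = clinical.set_index("subject_id") if "subject_id" in clinical.columns else clinical
    if group is not None and "group" in clin.columns:
        clin = clin[clin["group"] == group]
    common = [s for s in features.index if s in clin.index]
    if variables is None:
        variables = [c for c in clin.columns
                     if c not in ("group", "sex") and clin[c].dtype.kind in "fi"]
    rows = []
    for feat in features.columns:
        x_all = features.loc[common, feat].to_numpy(float)
        for var in variables:
            y_all = clin.loc[common, var].to_numpy(float)
            mask = np.isfinite(x_all) & np.isfinite(y_all)
            x, y = x_all[mask], y_all[mask]
            excluded, r, p = False, np.nan, np.nan
            if len(x) < 4 or np.std(x) == 0 or np.std(y) == 0:
                excluded = True
                logger.warning("pair (%s, %s) excluded (n=%d or zero variance)",
                               feat, var, len(x))
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"feature": feat, "variable": var, "r": r,
                         "R2": r**2 if np.isfinite(r) else np.nan,
                         "p": p, "n": int(mask.sum()), "excluded": excluded})
    return pd.DataFrame(rows)
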