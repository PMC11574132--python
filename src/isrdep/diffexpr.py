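"""Per-contrast differential statistics.

Three paths, matching the three data platforms:

- microarray: per-gene one-way ANOVA on a two-group contrast, BH-corrected
  across all genes in the table;
- RNA-seq: additive ANCOVA ``Expression ~ Group + Sex`` per gene (Type II
  F for the group factor), BH across genes, followed by all-pairwise Tukey
  post hoc contrasts on the sex-adjusted group means;
- feature tables (proteomics/metabolomics): two-sided t-tests (Student or
  Welch), BH across all features.

All fits are vectorized across genes; the ANCOVA uses one QR decomposition
per design matrix rather than a per-gene model object.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    GROUPS,
    AncovaResult,
    ContrastResult,
    DesignError,
    ExpressionMatrix,
    group_samples,
    validate_design,
)

logger = logging.getLogger(__name__)

#: all six pairwise group contrasts, named gB_vs_gA with B the later group
PAIRWISE_CONTRASTS = [
    f"g{j + 1}_vs_g{i + 1}" for i, j in itertools.combinations(range(4), 2)
]


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q(i) = min over j with p(j) >= p(i) of m * p(j) / rank(j), clipped at 1;
    tied p-values share one q.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def log2_fold_change(
    m: ExpressionMatrix, design: pd.DataFrame, contrast: tuple[str, str]
) -> pd.Series:
    """mean(B) - mean(A) per gene on log2 scale for contrast (A, B)."""
    if m.scale == "counts":
        raise ValueError("log2_fold_change requires log2-scale input")
    a, b = contrast
    cols_a = group_samples(design, a)
    cols_b = group_samples(design, b)
    if not cols_a or not cols_b:
        raise DesignError(f"contrast groups ({a}, {b}) not found in design")
    return m.values[cols_b].mean(axis=1) - m.values[cols_a].mean(axis=1)


def _two_group_f(va: np.ndarray, vb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA F and p across rows for two groups."""
    na, nb = va.shape[1], vb.shape[1]
    ma, mb = va.mean(axis=1), vb.mean(axis=1)
    grand = (na * ma + nb * mb) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((va - ma[:, None]) ** 2).sum(axis=1) + ((vb - mb[:, None]) ** 2).sum(axis=1)
    df2 = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / df2)
    p = stats.f.sf(f, 1, df2)
    zero_var = ssw <= 0
    if zero_var.any():
        logger.warning("%d genes with zero within-group variance", int(zero_var.sum()))
        same_mean = np.isclose(ma, mb)
        p = np.where(zero_var, np.where(same_mean, 1.0, 0.0), p)
        f = np.where(zero_var, np.where(same_mean, 0.0, np.inf), f)
    return f, p


def oneway_anova(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    name: str | None = None,
) -> ContrastResult:
    """Two-group one-way ANOVA per gene with BH across all genes."""
    a, b = contrast
    cols_a = group_samples(design, a)
    cols_b = group_samples(design, b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError("both contrast groups need >= 2 samples")
    va = m.values[cols_a].to_numpy(dtype=float)
    vb = m.values[cols_b].to_numpy(dtype=float)
    _, p = _two_group_f(va, vb)
    table = pd.DataFrame(
        {
            "log2fc": vb.mean(axis=1) - va.mean(axis=1),
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=m.values.index,
    )
    return ContrastResult(name=name or f"{b}_vs_{a}", table=table)


def _design_matrices(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full, sex-only and group-only treatment-coded design matrices."""
    group_d = np.stack(
        [(design["group"] == g).to_numpy(float) for g in GROUPS[1:]], axis=1
    )
    sex_d = (design["sex"] == "M").to_numpy(float)[:, None]
    ones = np.ones((len(design), 1))
    x_full = np.hstack([ones, group_d, sex_d])
    x_sex = np.hstack([ones, sex_d])
    x_group = np.hstack([ones, group_d])
    return x_full, x_sex, x_group


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of y for OLS on x (via QR)."""
    q, _ = np.linalg.qr(x)
    fitted_ss = (q.T @ y) ** 2
    return (y**2).sum(axis=0) - fitted_ss.sum(axis=0)


def ancova_fit(
    m: ExpressionMatrix, design: pd.DataFrame, include_sex: bool = True
) -> AncovaResult:
    """Additive per-gene ANCOVA Expression ~ Group + Sex.

    group_p is the Type II F-test for the 4-level group factor (model
    comparison against the sex-only reduced model — identical to Type II
    sums of squares in the no-interaction model); sex_p analogously.
    Sex-adjusted group means evaluate the fit at the observed male
    fraction.

    With ``include_sex=False`` the covariate is dropped and the model
    nests down to the 4-group one-way ANOVA (sex_p is NaN, adjusted means
    are plain group means).
    """
    validate_design(design)
    if include_sex and design["sex"].nunique() < 2:
        raise DesignError("both sexes must be represented")
    x_full, x_sex, x_group = _design_matrices(design)
    if not include_sex:
        x_full, x_sex = x_group, x_group[:, :1]
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise DesignError("rank-deficient design (group and sex confounded)")
    y = m.values[design["sample_id"]].to_numpy(dtype=float).T  # samples x genes
    n, p_full = x_full.shape
    df_resid = n - p_full
    if df_resid < 1:
        raise DesignError("no residual degrees of freedom")

    rss_full = _rss(x_full, y)
    rss_sex = _rss(x_sex, y)
    rss_group = _rss(x_group, y) if include_sex else rss_full

    def f_test(rss_reduced: np.ndarray, df_num: int) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_reduced - rss_full) / df_num) / (rss_full / df_resid)
        pv = stats.f.sf(f, df_num, df_resid)
        degenerate = rss_full <= 1e-12
        if degenerate.any():
            no_effect = (rss_reduced - rss_full) <= 1e-12
            pv = np.where(degenerate, np.where(no_effect, 1.0, 0.0), pv)
            f = np.where(degenerate, np.where(no_effect, 0.0, np.inf), f)
        return f, pv

    group_f, group_p = f_test(rss_sex, 3)
    if include_sex:
        _, sex_p = f_test(rss_group, 1)
    else:
        sex_p = np.full(y.shape[1], np.nan)

    beta, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    male_frac = float((design["sex"] == "M").mean())
    adj = {}
    for gi, g in enumerate(GROUPS):
        mu = beta[0] + (beta[-1] * male_frac if include_sex else 0.0)
        if gi > 0:
            mu = mu + beta[gi]
        adj[f"adj_mean_{g}"] = mu

    table = pd.DataFrame(
        {
            "group_f": group_f,
            "group_p": group_p,
            "sex_p": sex_p,
            "group_fdr": bh_adjust(group_p),
            **adj,
        },
        index=m.values.index,
    )
    mse = pd.Series(rss_full / df_resid, index=m.values.index, name="mse")
    group_n = {g: len(group_samples(design, g)) for g in GROUPS}
    return AncovaResult(table=table, df_resid=df_resid, mse=mse, group_n=group_n)


#: grid for interpolated studentized-range tail probabilities; scipy's
#: quadrature costs ~20 ms per point, prohibitive genome-wide
_Q_GRID = np.concatenate([[0.0], np.geomspace(1e-3, 100.0, 200)])


@lru_cache(maxsize=16)
def _studentized_range_logsf_grid(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    sf = stats.studentized_range.sf(_Q_GRID, k, df)
    return _Q_GRID, np.log(np.clip(sf, 1e-300, 1.0))


def _studentized_range_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Upper tail of the studentized range; exact for small batches,
    log-linear grid interpolation genome-wide."""
    q = np.asarray(q, dtype=float)
    if q.size <= 64:
        return stats.studentized_range.sf(q, k, df)
    grid, logsf = _studentized_range_logsf_grid(k, int(df))
    return np.exp(np.interp(q, grid, logsf))


def posthoc_pairwise(a: AncovaResult, method: str = "tukey") -> AncovaResult:
    """Tukey HSD over all six pairwise group contrasts on adjusted means.

    Uses the studentized-range distribution with the ANCOVA's pooled
    residual MSE and df (Tukey-Kramer SEs for unbalanced groups).
    """
    if method != "tukey":
        raise ValueError(f"unsupported post hoc method {method!r}")
    k = len(GROUPS)
    mse = a.mse.to_numpy()
    for name in PAIRWISE_CONTRASTS:
        gb, ga = name.split("_vs_")
        ia, ib = int(ga[1]) - 1, int(gb[1]) - 1
        mean_a = a.table[f"adj_mean_{GROUPS[ia]}"].to_numpy()
        mean_b = a.table[f"adj_mean_{GROUPS[ib]}"].to_numpy()
        na, nb = a.group_n[GROUPS[ia]], a.group_n[GROUPS[ib]]
        est = mean_b - mean_a
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(est) / (se / np.sqrt(2.0))
        adj_p = _studentized_range_sf(q, k, a.df_resid)
        zero = se <= 0
        if zero.any():
            adj_p = np.where(zero, np.where(np.isclose(est, 0.0), 1.0, 0.0), adj_p)
        adj_p = np.clip(np.nan_to_num(adj_p, nan=1.0), 0.0, 1.0)
        a.posthoc[name] = pd.DataFrame(
            {"estimate": est, "adjusted_p": adj_p}, index=a.table.index
        )
    return a


def posthoc_contrast_result(a: AncovaResult, name: str) -> ContrastResult:
    """Package one post hoc contrast as a ContrastResult.

    ``p`` carries the Tukey-adjusted post hoc p-value; ``fdr`` is a BH
    adjustment of those across genes (informational; the RNA-seq
    dependence rule gates on the ANCOVA group FDR and the post hoc p).
    """
    if name not in a.posthoc:
        raise KeyError(f"post hoc contrast {name!r} not computed")
    ph = a.posthoc[name]
    table = pd.DataFrame(
        {
            "log2fc": ph["estimate"],
            "p": ph["adjusted_p"],
            "fdr": bh_adjust(ph["adjusted_p"].to_numpy()),
        },
        index=ph.index,
    )
    return ContrastResult(name=name, table=table)


def feature_ttest(
    features: ExpressionMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    variant: str = "student",
    name: str | None = None,
) -> ContrastResult:
    """Two-sided t-test per feature (Student pooled or Welch), BH across features."""
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a, b = contrast
    cols_a = group_samples(design, a)
    cols_b = group_samples(design, b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError("both contrast groups need >= 2 samples")
    va = features.values[cols_a].to_numpy(dtype=float)
    vb = features.values[cols_b].to_numpy(dtype=float)
    res = stats.ttest_ind(vb, va, axis=1, equal_var=(variant == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    # constant features on both sides: equal means -> p 1, else p 0
    nan_mask = np.isnan(p)
    if nan_mask.any():
        same = np.isclose(vb.mean(axis=1), va.mean(axis=1))
        p = np.where(nan_mask, np.where(same, 1.0, 0.0), p)
    table = pd.DataFrame(
        {
            "log2fc": vb.mean(axis=1) - va.mean(axis=1),
            "t": np.nan_to_num(np.asarray(res.statistic, dtype=float), nan=0.0),
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=features.values.index,
    )
    return ContrastResult(name=name or f"{b}_vs_{a}", table=table)
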