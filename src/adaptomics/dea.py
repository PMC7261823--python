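"""Differential expression at protein and mRNA level.

Protein-level testing uses an empirical-Bayes moderated t statistic in
which the prior variance for each gene follows a smoothed trend of the
log residual variance against log2 of the gene's PSM count, so genes
quantified by many spectra borrow a tighter prior.  mRNA-level testing
is a deliberately simplified negative-binomial Wald test: size factors
by median-of-ratios, gene-wise method-of-moments dispersions shrunk
toward a parametric trend, and a delta-method Wald statistic on the
log2 fold change of normalised condition means.

Significance cutoffs follow the profiling conventions used throughout
the package: |log2FC| > 1 with adjusted p < 0.01 for mRNA and
|log2FC| > 0.5 with adjusted p < 0.01 for protein.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import linkage
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .quant import ProteinRatioMatrix

logger = logging.getLogger(__name__)

#: level-specific significance cutoffs: (|log2FC| threshold, adjusted-p threshold)
CUTOFFS = {"mrna": (1.0, 0.01), "protein": (0.5, 0.01)}

DEA_COLUMNS = ["gene", "log2fc", "p_raw", "p_adj", "significant", "evidence_n", "level", "contrast"]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the ranking and propagated as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] <= 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _estimate_prior(log_var: np.ndarray, log2_npsm: np.ndarray, df_resid: float,
                    max_prior_df: float = 100.0) -> tuple[np.ndarray, float]:
    """Prior variance trend and prior df for the moderated test.

    The trend of log residual variance over log2(PSM count) is fitted by
    lowess (global mean fallback below 50 genes); the prior degrees of
    freedom come from a method-of-moments fit on the trend residuals,
    using the fact that log(s^2/sigma^2) has variance
    trigamma(d/2) + trigamma(d0/2) under the scaled-F model.
    """
    n = log_var.size
    if n >= 50 and np.ptp(log2_npsm) > 0:
        order = np.argsort(log2_npsm, kind="stable")
        fitted = np.empty(n)
        smoothed = lowess(log_var[order], log2_npsm[order], frac=0.75, return_sorted=False)
        fitted[order] = smoothed
    else:
        fitted = np.full(n, log_var.mean())
    z = log_var - fitted
    bias = special.digamma(df_resid / 2.0) - np.log(df_resid / 2.0)
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 1e-10:
        prior_df = max_prior_df
    else:
        prior_df = min(2.0 * _trigamma_inverse(excess), max_prior_df)
    prior_bias = special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0)
    # E[log s^2] = log sigma^2 + bias(d) - bias(d0); undo both to centre the prior
    log_s0 = fitted - bias + prior_bias
    return np.exp(log_s0), prior_df


def moderated_protein_dea(
    matrix: ProteinRatioMatrix,
    groups: dict[str, str],
    contrast: tuple[str, str],
    level: str = "protein",
) -> pd.DataFrame:
    """PSM-count-aware moderated t-test between two conditions.

    ``contrast = (test, reference)``: log2fc is mean(test) - mean(reference).
    Residual variance is pooled over all conditions in ``groups`` with at
    least two replicates, moderated toward the PSM-count trend prior.
    """
    test_cond, ref_cond = contrast
    cols_by_cond: dict[str, list[str]] = {}
    for sample, cond in groups.items():
        if sample in matrix.samples:
            cols_by_cond.setdefault(cond, []).append(sample)
    for cond in contrast:
        if len(cols_by_cond.get(cond, [])) < 2:
            raise ValueError(f"condition {cond!r} needs >=2 replicates in the matrix")
    vals = matrix.values
    df_resid = sum(len(c) - 1 for c in cols_by_cond.values() if len(c) >= 2)
    # pooled within-condition residual variance
    ss = np.zeros(len(vals))
    for cols in cols_by_cond.values():
        if len(cols) >= 2:
            sub = vals[cols].to_numpy()
            ss += np.nansum((sub - np.nanmean(sub, axis=1, keepdims=True)) ** 2, axis=1)
    s2 = ss / df_resid
    mean_test = vals[cols_by_cond[test_cond]].mean(axis=1)
    mean_ref = vals[cols_by_cond[ref_cond]].mean(axis=1)
    lfc = (mean_test - mean_ref).to_numpy()

    usable = s2 > 0
    if not usable.any():
        raise ValueError("no gene has positive residual variance; cannot moderate")
    n_psm = matrix.n_psms.to_numpy(dtype=float)
    s0_sq = np.full(len(vals), np.nan)
    s0_sub, prior_df = _estimate_prior(np.log(s2[usable]), np.log2(n_psm[usable]), df_resid)
    s0_sq[usable] = s0_sub
    if (~usable).any():
        logger.warning("%d gene(s) with zero residual variance get the mean prior", int((~usable).sum()))
        s0_sq[~usable] = np.nanmean(s0_sub)
    s2_post = (prior_df * s0_sq + df_resid * s2) / (prior_df + df_resid)
    n1 = len(cols_by_cond[test_cond])
    n2 = len(cols_by_cond[ref_cond])
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_stat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p_raw = np.clip(2.0 * stats.t.sf(np.abs(t_stat), df_resid + prior_df), np.nextafter(0, 1), 1.0)
    res = pd.DataFrame({
        "gene": vals.index,
        "log2fc": lfc,
        "p_raw": p_raw,
        "evidence_n": n_psm.astype(int),
        "level": level,
        "contrast": f"{test_cond}:{ref_cond}",
    })
    res["p_adj"] = bh_adjust(res["p_raw"])
    res, _ = call_significant(res, level)
    return res[DEA_COLUMNS].reset_index(drop=True)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has all-positive counts; cannot compute size factors")
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def nb_count_dea(
    counts: pd.DataFrame,
    groups: dict[str, str],
    contrast: tuple[str, str],
    level: str = "mrna",
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """Simplified negative-binomial Wald test on a gene x sample count matrix.

    Counts are normalised by median-of-ratios size factors; per-gene
    dispersion is the method-of-moments estimate from within-condition
    variances, floored at ``min_dispersion`` and shrunk 50/50 toward the
    parametric trend alpha(mu) = a0 + a1/mu; the Wald statistic tests the
    log2 ratio of normalised condition means (delta method).  Genes with
    zero counts everywhere are excluded.
    """
    test_cond, ref_cond = contrast
    cols_by_cond: dict[str, list[str]] = {}
    for sample, cond in groups.items():
        if sample in counts.columns:
            cols_by_cond.setdefault(cond, []).append(sample)
    for cond in contrast:
        if len(cols_by_cond.get(cond, [])) < 2:
            raise ValueError(f"condition {cond!r} needs >=2 replicate columns")
    if not (counts.to_numpy() >= 0).all():
        raise ValueError("counts must be non-negative")
    keep = counts.sum(axis=1) > 0
    if (~keep).any():
        logger.info("excluding %d all-zero gene(s)", int((~keep).sum()))
    counts = counts.loc[keep]
    sf = size_factors(counts)
    norm = counts / sf

    # method-of-moments dispersion pooled over the two contrasted conditions
    mu_parts, var_parts, n_parts = [], [], []
    for cond in contrast:
        sub = norm[cols_by_cond[cond]].to_numpy()
        mu_parts.append(sub.mean(axis=1))
        var_parts.append(sub.var(axis=1, ddof=1))
        n_parts.append(sub.shape[1])
    mu_all = np.average(mu_parts, axis=0, weights=n_parts)
    var_within = np.average(var_parts, axis=0, weights=[n - 1 for n in n_parts])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = (var_within - mu_all) / mu_all**2
    alpha_gene = np.where(np.isfinite(alpha_gene), alpha_gene, min_dispersion)
    alpha_gene = np.maximum(alpha_gene, min_dispersion)
    # parametric trend alpha(mu) = a0 + a1/mu, coefficients kept non-negative
    ok = mu_all > 0
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mu_all[ok]])
    coef, *_ = np.linalg.lstsq(design, alpha_gene[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    alpha_trend = np.where(ok, a0 + a1 / np.maximum(mu_all, 1e-12), min_dispersion)
    alpha = np.maximum(0.5 * alpha_gene + 0.5 * alpha_trend, min_dispersion)

    mu_test = norm[cols_by_cond[test_cond]].mean(axis=1).to_numpy()
    mu_ref = norm[cols_by_cond[ref_cond]].mean(axis=1).to_numpy()
    n_test = len(cols_by_cond[test_cond])
    n_ref = len(cols_by_cond[ref_cond])
    pc = 0.5  # pseudo-count on the normalised scale guards zero means
    lfc = np.log2((mu_test + pc) / (mu_ref + pc))
    var_mean_test = (mu_test + alpha * mu_test**2) / n_test
    var_mean_ref = (mu_ref + alpha * mu_ref**2) / n_ref
    se = np.sqrt(var_mean_test / (mu_test + pc) ** 2 + var_mean_ref / (mu_ref + pc) ** 2) / np.log(2)
    se = np.maximum(se, 1e-12)
    z = lfc / se
    # t reference with Satterthwaite-style effective df: the plug-in
    # variance makes a plain normal reference anti-conservative at
    # triplicate n, while the residual df alone ignores the information
    # in the trend half of the shrunk dispersion.  With shrinkage weight
    # w = 0.5 on the (essentially infinite-df) trend, the variance of the
    # shrunk estimator is w^2 times the gene-wise one, giving
    # df_eff = df_resid / w^2 = 4 * df_resid.
    df_resid = (n_test - 1) + (n_ref - 1)
    df_eff = 4.0 * df_resid
    p_raw = np.clip(2.0 * stats.t.sf(np.abs(z), df_eff), np.nextafter(0, 1), 1.0)
    res = pd.DataFrame({
        "gene": counts.index,
        "log2fc": lfc,
        "p_raw": p_raw,
        "evidence_n": mu_all,
        "level": level,
        "contrast": f"{test_cond}:{ref_cond}",
    })
    res["p_adj"] = bh_adjust(res["p_raw"])
    res, _ = call_significant(res, level)
    return res[DEA_COLUMNS].reset_index(drop=True)


def call_significant(dea: pd.DataFrame, level: str) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply level-specific cutoffs; return flagged table and up/down counts."""
    if level not in CUTOFFS:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(CUTOFFS)}")
    lfc_cut, p_cut = CUTOFFS[level]
    dea = dea.copy()
    if dea.empty:
        dea["significant"] = pd.Series(dtype=bool)
        return dea, {"up": 0, "down": 0}
    dea["significant"] = (dea["log2fc"].abs() > lfc_cut) & (dea["p_adj"] < p_cut)
    up = int((dea["significant"] & (dea["log2fc"] > 0)).sum())
    down = int((dea["significant"] & (dea["log2fc"] < 0)).sum())
    return dea, {"up": up, "down": down}


def cluster_samples(matrix: pd.DataFrame | ProteinRatioMatrix, method: str = "average") -> np.ndarray:
    """Hierarchical clustering of sample columns on 1 - Pearson r distance."""
    vals = matrix.values if isinstance(matrix, ProteinRatioMatrix) else matrix
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 sample columns to cluster")
    sd = vals.std(axis=0, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance column(s): {flat}")
    corr = np.corrcoef(vals.to_numpy().T)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    return linkage(np.maximum(dist[iu], 0.0), method=method)
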