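"""Negative-binomial differential expression over count matrices.

This is a self-contained two-group (optionally paired) NB Wald test in the
spirit of the standard RNA-seq GLM pipeline: median-of-ratios size
factors, moment-based dispersion estimates shrunk toward a log-linear
mean-dispersion trend, and a Wald statistic on the group coefficient of a
log-link NB GLM.  It is deliberately simple — no outlier refitting, no
posterior fold-change shrinkage — because the downstream enrichment
benchmarks depend on the *ranking and selection* of genes, not on any one
DE tool's refinements.  The interface is tabular, so externally computed
DE results can be substituted via TSV.

Counts are genes x samples, nonnegative integers.  Fold changes use the
log2 convention throughout.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneList
from .ora import bh_adjust

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "base_mean", "log2_fold_change", "stat", "p_value", "fdr"]

_MIN_DISPERSION = 1e-8
_MAX_DISPERSION = 100.0
_ETA_BOUND = 30.0


def low_count_filter(counts: pd.DataFrame, min_mean: float = 10.0) -> pd.DataFrame:
    """Drop genes with fewer than ``min_mean`` reads per sample on average.

    The survivors define the background list for enrichment analysis.
    """
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers in count matrix")
    return counts.loc[counts.mean(axis=1) >= min_mean]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per gene, the reference is the geometric mean across samples over genes
    with all-positive counts; the factor for a sample is the median ratio
    to that reference.  If no gene is positive in every sample, falls back
    to total-count scaling (normalised to geometric mean 1) with a warning.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        logger.warning("no gene with positive counts in every sample; using total-count scaling")
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts; cannot normalise")
        sf = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(sf, index=counts.columns)
    la = np.log(arr[allpos])
    ref = la.mean(axis=1)
    sf = np.exp(np.median(la - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def _align_labels(labels, columns: pd.Index, what: str) -> np.ndarray:
    if isinstance(labels, (pd.Series, Mapping)):
        ser = pd.Series(labels)
        missing = [c for c in columns if c not in ser.index]
        if missing:
            raise ValueError(f"{what} labels missing for samples: {missing}")
        return ser.reindex(columns).to_numpy()
    out = np.asarray(list(labels), dtype=object)
    if out.shape[0] != len(columns):
        raise ValueError(f"{what} labels length {out.shape[0]} != number of samples {len(columns)}")
    return out


def _dispersion_trend(base_mean: np.ndarray, mom: np.ndarray) -> np.ndarray:
    """Log-linear mean-dispersion trend fitted to binned moment estimates.

    Moment estimates at small replicate numbers are extremely noisy and
    conditioning on positivity biases them upward, so the trend is fitted
    to per-bin *means* of the raw (possibly negative) moment estimates,
    floored before taking logs.  Returns the trend dispersion per gene.
    """
    ok = base_mean > 0
    lm = np.log(base_mean[ok])
    vals = mom[ok]
    n_bins = max(5, min(25, vals.size // 50))
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, lm, side="right") - 1, 0, n_bins - 1)
    bx, by = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < 3:
            continue
        bx.append(lm[sel].mean())
        by.append(np.log(max(vals[sel].mean(), _MIN_DISPERSION)))
    trend = np.full_like(base_mean, np.log(_MIN_DISPERSION), dtype=float)
    if len(bx) >= 2:
        slope, intercept = np.polyfit(bx, by, 1)
        trend[ok] = intercept + slope * lm
    elif len(bx) == 1:
        trend[ok] = by[0]
    return np.exp(np.clip(trend, np.log(_MIN_DISPERSION), np.log(_MAX_DISPERSION)))


def _estimate_dispersions(norm: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion: method of moments, 50/50 log-shrunk to the trend.

    The geometric (log-scale) average of per-gene and trend dispersions
    systematically underestimates the truth because E[log chi2_d/d] < 0;
    the per-gene term is therefore debiased by the chi-square log-bias for
    the residual degrees of freedom before averaging.
    """
    from scipy.special import digamma

    base_mean = norm.mean(axis=1)
    n_total = norm.shape[1]
    dof = max(n_total - len(group_masks), 1)
    ss = np.zeros(norm.shape[0])
    for mask in group_masks:
        sub = norm[:, mask]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (pooled_var - base_mean) / np.square(base_mean)
    mom = np.where(np.isfinite(mom), mom, 0.0)
    trend = _dispersion_trend(base_mean, mom)
    mom_f = np.clip(mom, _MIN_DISPERSION, _MAX_DISPERSION)
    log_bias = digamma(dof / 2.0) - np.log(dof / 2.0)
    alpha = np.exp(0.5 * (np.log(mom_f) - log_bias) + 0.5 * np.log(trend))
    return np.clip(alpha, _MIN_DISPERSION, _MAX_DISPERSION)


def _moderated_df(residual_dof: int) -> float:
    """Effective degrees of freedom of the shrunken variance estimate.

    The 50/50 log-scale shrinkage toward the trend quarters the variance of
    the log-dispersion estimate; the matching chi-square degrees of freedom
    solve trigamma(d/2) = trigamma(dof/2) / 4 (the moderated-t construction).
    The Wald statistic is referred to a t distribution with these df, which
    interpolates between the raw residual-df t and the normal reference.
    """
    from scipy.optimize import brentq
    from scipy.special import polygamma

    dof = max(residual_dof, 1)
    target = 0.25 * float(polygamma(1, dof / 2.0))
    return float(brentq(lambda d: float(polygamma(1, d / 2.0)) - target, dof, 1e6))


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
    pairing: Mapping[str, str] | pd.Series | Sequence[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test per gene; optional pairing indicators.

    ``groups`` assigns each sample one of exactly two labels.
    ``reference`` names the control group (positive log2 fold changes mean
    higher expression in the other group); if omitted, the
    lexicographically smaller label is the reference.  ``pairing`` adds
    subject indicator columns to the design for paired experiments.
    Returns a frame with columns ``gene_id, base_mean, log2_fold_change,
    stat, p_value, fdr`` in the input gene order, with BH correction over
    all tested genes.
    """
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers in count matrix")
    grp = _align_labels(groups, counts.columns, "group")
    levels = sorted(set(grp))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group labels, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} is not one of the group labels {levels}")
        levels = [reference] + [lv for lv in levels if lv != reference]
    for lv in levels:
        if (grp == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    pair = _align_labels(pairing, counts.columns, "pairing") if pairing is not None else None

    # Sort samples by name so results are invariant to input column order.
    order = np.argsort(counts.columns.to_numpy(dtype=object))
    counts = counts.iloc[:, order]
    grp = grp[order]
    if pair is not None:
        pair = pair[order]

    genes = counts.index.to_numpy(dtype=object)
    y = counts.to_numpy(dtype=float)
    n_genes, n_samples = y.shape

    sf = size_factors(counts).to_numpy()
    norm = y / sf
    base_mean = norm.mean(axis=1)

    case = grp == levels[1]
    masks = [~case, case]
    alpha = _estimate_dispersions(norm, masks)

    # design: intercept, case indicator, then subject indicators (drop first)
    cols = [np.ones(n_samples), case.astype(float)]
    if pair is not None:
        subjects = sorted(set(pair))
        for s in subjects[1:]:
            cols.append((pair == s).astype(float))
    X = np.column_stack(cols)
    p = X.shape[1]
    offset = np.log(sf)

    beta = np.zeros((n_genes, p))
    eps = 0.5
    mean_ctrl = norm[:, masks[0]].mean(axis=1)
    mean_case = norm[:, masks[1]].mean(axis=1)
    beta[:, 0] = np.log(mean_ctrl + eps)
    beta[:, 1] = np.log(mean_case + eps) - np.log(mean_ctrl + eps)

    ridge = 1e-6 * np.eye(p)
    a = alpha[:, None]
    XtWX = None
    for _ in range(60):
        eta = np.clip(beta @ X.T + offset, -_ETA_BOUND, _ETA_BOUND)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("sp,gs,sq->gpq", X, W, X, optimize=True)
        XtWz = np.einsum("sp,gs,gs->gp", X, W, z, optimize=True)
        new_beta = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < 1e-10:
            break

    cov = np.linalg.inv(XtWX + ridge)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    stat = beta[:, 1] / se
    log2fc = beta[:, 1] / np.log(2.0)
    # Reference distribution: moderated t when the (estimated) dispersion
    # dominates the variance, approaching normal in the Poisson-limited
    # regime where the dispersion contributes ~nothing to the SE.
    base_df = _moderated_df(n_samples - p)
    disp_weight = np.clip(alpha * base_mean / (1.0 + alpha * base_mean), 1e-4, 1.0)
    df = base_df / disp_weight
    pval = 2.0 * stats.t.sf(np.abs(stat), df)
    pval = np.clip(pval, 1e-300, 1.0)

    # degenerate genes: zero counts in every sample carry no information
    dead = y.sum(axis=1) == 0
    stat[dead] = 0.0
    log2fc[dead] = 0.0
    pval[dead] = 1.0

    return pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": base_mean,
            "log2_fold_change": log2fc,
            "stat": stat,
            "p_value": pval,
            "fdr": bh_adjust(pval),
        }
    )


def _direction_subset(de: pd.DataFrame, direction: str) -> pd.DataFrame:
    if direction == "up":
        return de[de["log2_fold_change"] > 0]
    if direction == "down":
        return de[de["log2_fold_change"] < 0]
    if direction == "both":
        return de
    raise ValueError(f"direction must be 'up', 'down' or 'both', got {direction!r}")


def select_foreground(
    de: pd.DataFrame,
    direction: str,
    alpha: float = 0.05,
    fallback_n: int = 200,
) -> GeneList:
    """Foreground selection rule: FDR < alpha, else the top genes by p-value.

    Genes of the matching sign with FDR below ``alpha`` are selected; if
    fewer than ``fallback_n`` qualify, the ``fallback_n`` smallest-p genes
    of matching sign are taken instead.  Ties broken by (p, gene_id).
    """
    sub = _direction_subset(de, direction).sort_values(
        ["p_value", "gene_id"], kind="mergesort"
    )
    sig = sub[sub["fdr"] < alpha]
    if len(sig) >= fallback_n:
        chosen = sig
    else:
        if len(sub) < fallback_n:
            logger.warning(
                "only %d genes available for direction %s (< fallback %d); returning all",
                len(sub), direction, fallback_n,
            )
        chosen = sub.head(fallback_n)
    return GeneList.from_ids("foreground", chosen["gene_id"].tolist())


def select_foreground_topk(de: pd.DataFrame, direction: str, k: int) -> GeneList:
    """The ``k`` smallest-p genes of the matching sign (fixed-size foreground)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = _direction_subset(de, direction).sort_values(
        ["p_value", "gene_id"], kind="mergesort"
    )
    if len(sub) < k:
        logger.warning(
            "requested top %d genes but only %d available for direction %s",
            k, len(sub), direction,
        )
    return GeneList.from_ids("foreground", sub.head(k)["gene_id"].tolist())


def write_de_results(de: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        de.to_csv(fh, sep="\t", index=False)


def read_de_results(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE results file {path} missing columns: {missing}")
    return de
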