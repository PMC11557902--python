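"""Preranked functional class scoring (simplified GSEA-style comparator).

All detected genes are ranked by a differential-expression statistic and
each gene set is scored by the classic running-sum enrichment statistic:
walking down the ranked list, hitting a set member advances the sum by
that gene's |score|^w (normalised by the total over hits) and missing
retreats by 1/(n_genes - n_hits).  The enrichment score (ES) is the signed
maximum deviation from zero; positive ES means the set piles up among
up-regulated genes.

Significance comes from a gene-sampling null: the ES is recomputed for
random same-size gene sets, and the p-value is the same-sign exceedance
fraction with the usual +1 correction.  Because the null depends only on
the ranking and the set size, the null distribution is shared between
sets of equal size.  BH correction always runs over *all* tested sets, so
this path is structurally immune to the FDR problem.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import GeneSetLibrary, filter_by_size, restrict_to_background
from .ora import bh_adjust

logger = logging.getLogger(__name__)

FCS_COLUMNS = ["set_id", "es", "p_value", "fdr", "direction"]


@dataclass(frozen=True)
class FCSRecord:
    set_id: str
    es: float
    p_value: float
    fdr: float
    direction: str  # "up" if ES > 0 else "down"


def rank_genes(de: pd.DataFrame) -> pd.Series:
    """Rank genes descending by test statistic; ties broken by gene id.

    Returns a Series mapping gene_id -> statistic in ranked order.
    """
    if de["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in DE results")
    ordered = de.sort_values(
        ["stat", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(
        ordered["stat"].to_numpy(dtype=float), index=ordered["gene_id"].to_numpy(dtype=object)
    )


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n_genes: int
) -> np.ndarray:
    """Vectorised running-sum extremum for rows of sorted hit positions.

    ``positions`` is (n_rows, m) with each row sorted ascending;
    ``weights`` is the matching |score|^w values.  The running sum only
    needs evaluation just before and just after each hit: between hits it
    decays linearly, so the extrema occur at hit boundaries.
    """
    n_rows, m = positions.shape
    if m == n_genes:
        return np.ones(n_rows)
    wsum = weights.sum(axis=1, keepdims=True)
    flat = wsum[:, 0] == 0
    if flat.any():
        # all-zero scores at the hit positions: fall back to equal weights
        weights = weights.copy()
        weights[flat] = 1.0
        wsum = weights.sum(axis=1, keepdims=True)
    cw = np.cumsum(weights, axis=1) / wsum
    step = 1.0 / (n_genes - m)
    miss = (positions - np.arange(m)) * step
    after = cw - miss          # running sum just after each hit
    before = after - weights / wsum  # just before each hit
    pos_max = after.max(axis=1)
    neg_min = before.min(axis=1)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def enrichment_score(
    ranked: pd.Series, set_members: Iterable[str], weight_exponent: int = 1
) -> float:
    """Classic running-sum ES for one set against a ranked list.

    ``weight_exponent`` 0 gives the unweighted Kolmogorov-Smirnov-like
    statistic (invariant under monotone re-scoring); 1 weights hits by
    |score| as in standard GSEA.
    """
    members = set(set_members)
    mask = np.fromiter((g in members for g in ranked.index), dtype=bool, count=len(ranked))
    positions = np.flatnonzero(mask)
    if positions.size == 0:
        raise ValueError("no set members present in the ranked list")
    scores = ranked.to_numpy(dtype=float)
    w = np.abs(scores[positions]) ** weight_exponent
    return float(_es_from_positions(w[None, :], positions[None, :], len(ranked))[0])


def _sample_positions(n: int, m: int, n_rows: int, rng: np.random.Generator) -> np.ndarray:
    """(n_rows, m) sorted positions sampled without replacement from range(n)."""
    pos = rng.integers(0, n, size=(n_rows, m))
    pos.sort(axis=1)
    for _ in range(1000):
        bad = (np.diff(pos, axis=1) == 0).any(axis=1)
        if not bad.any():
            return pos
        pos[bad] = rng.integers(0, n, size=(int(bad.sum()), m))
        pos.sort(axis=1)
    raise RuntimeError("failed to sample distinct positions")  # pragma: no cover


def null_enrichment_scores(
    ranked: pd.Series,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: int = 1,
) -> np.ndarray:
    """ES null distribution for random sets of ``set_size`` genes."""
    n = len(ranked)
    if not (0 < set_size <= n):
        raise ValueError("set_size must be in [1, n_genes]")
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    pos = _sample_positions(n, set_size, n_perm, rng)
    return _es_from_positions(abs_w[pos], pos, n)


def _same_sign_pvalue(es_obs: float, null: np.ndarray) -> float:
    if es_obs >= 0:
        same = null[null > 0]
        exceed = int((same >= es_obs).sum())
    else:
        same = null[null < 0]
        exceed = int((same <= es_obs).sum())
    return (1 + exceed) / (1 + same.size)


def permutation_pvalue(
    ranked: pd.Series,
    set_members: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: int = 1,
    null: np.ndarray | None = None,
) -> float:
    """Gene-sampling permutation p-value for one set.

    p = (1 + #{same-sign null ES at least as extreme}) / (1 + #{same-sign
    nulls}); deterministic given the seed.  A precomputed null (from
    :func:`null_enrichment_scores`) may be supplied to share work between
    same-size sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = [g for g in set_members if g in ranked.index]
    es = enrichment_score(ranked, members, weight_exponent)
    if null is None:
        rng = np.random.default_rng(seed)
        null = null_enrichment_scores(ranked, len(set(members)), n_perm, rng, weight_exponent)
    return _same_sign_pvalue(es, null)


def run_fcs(
    de: pd.DataFrame,
    lib: GeneSetLibrary,
    n_perm: int = 1000,
    seed: int | None = None,
    min_set_size: int = 5,
    max_set_size: int | None = None,
    weight_exponent: int = 1,
) -> list[FCSRecord]:
    """Score every library set against the full ranking.

    The library is restricted to the ranked universe and size-filtered as
    in ORA; sets with no member in the ranking are skipped with a warning
    (this happens inside the restriction step).  BH runs over all tested
    sets.  Records sorted by (p, set_id).
    """
    ranked = rank_genes(de)
    work = restrict_to_background(lib, list(ranked.index))
    work = filter_by_size(work, min_set_size, max_set_size)
    if len(work) == 0:
        logger.warning("no gene sets left after restriction/size filtering; empty FCS result")
        return []

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows: list[tuple[str, float, float]] = []
    for gs in work:
        es = enrichment_score(ranked, gs.members, weight_exponent)
        size = len(gs)
        if size not in null_cache:
            null_cache[size] = null_enrichment_scores(ranked, size, n_perm, rng, weight_exponent)
        rows.append((gs.set_id, es, _same_sign_pvalue(es, null_cache[size])))

    fdr = bh_adjust([p for _, _, p in rows])
    records = [
        FCSRecord(set_id=s, es=es, p_value=p, fdr=float(q),
                  direction="up" if es > 0 else "down")
        for (s, es, p), q in zip(rows, fdr)
    ]
    records.sort(key=lambda r: (r.p_value, r.set_id))
    return records


def fcs_to_frame(records: Iterable[FCSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.es, r.p_value, r.fdr, r.direction) for r in records],
        columns=FCS_COLUMNS,
    )


def significant_signed_sets(records: Iterable[FCSRecord], alpha: float) -> dict[str, set[str]]:
    """Significant set ids split by direction of the enrichment score."""
    out: dict[str, set[str]] = {"up": set(), "down": set()}
    for r in records:
        if r.fdr < alpha:
            out[r.direction].add(r.set_id)
    return out
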