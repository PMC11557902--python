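"""Scoring, run comparison, and benchmark orchestration.

Predictions are signed (set_id, direction) pairs; a truly up-regulated
set found only in the down list counts as both a false positive and a
false negative.  Precision, recall and F1 are computed over these pairs
against the simulated ground truth.  The Jaccard index between two
significant-set collections quantifies how much an analysis changes when
a failure mode is fixed.

The simulation study mirrors the benchmark design: per replicate a fresh
random library and truth are drawn, pseudosamples are generated, the DE
engine selects the foreground (FDR < 0.05, falling back to the 200
smallest-p genes per direction), and each enrichment method is scored
against the truth.  The six methods:

====================  =====================================================
ora_default           both failure modes active (shrunken universe, BH over
                      overlapping sets only) — the behaviour of popular
                      default pipelines
ora_bgfix             default plus the append-the-background workaround
ora_fdrfix            default plus the p = 1 padding workaround
ora_bothfix           both workarounds — provably identical to ora_correct
ora_correct           full background universe, BH over all detected sets
fcs                   preranked functional class scoring comparator
====================  =====================================================
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import fcs as fcs_mod
from .de import low_count_filter, nb_wald_test, select_foreground, select_foreground_topk
from .genesets import GeneList, GeneSetLibrary, append_universe_set
from .ora import (
    ORARecord,
    apply_fdr_workaround,
    config_for_mode,
    expected_test_count,
    run_ora,
    significant_sets,
)
from .simulate import SimConfig, SimTruth, make_pseudosamples, synthetic_baseline

logger = logging.getLogger(__name__)

METHODS = ("ora_default", "ora_bgfix", "ora_fdrfix", "ora_bothfix", "ora_correct", "fcs")

#: engine configuration behind each ORA benchmark method:
#: (bg workaround applied, fdr workaround applied, engine mode)
_ORA_METHODS = {
    "ora_default": (False, False, "bug-both"),
    "ora_bgfix": (True, False, "bug-both"),
    "ora_fdrfix": (False, True, "bug-both"),
    "ora_bothfix": (True, True, "bug-both"),
    "ora_correct": (False, False, "correct"),
}


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F1 over signed (set, direction) calls."""

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    precision_defined: bool = True


@dataclass(frozen=True)
class ComparisonSummary:
    """Differences between two ORA runs over comparable libraries."""

    jaccard: float
    n_sig_a: int
    n_sig_b: int
    gained: tuple[str, ...]  # significant in b but not a
    lost: tuple[str, ...]    # significant in a but not b
    deltas: pd.DataFrame     # per shared set: p/fdr for both runs and deltas (b - a)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b|; two empty collections compare as identical (1.0)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.info("jaccard of two empty sets reported as 1.0 (identical outcomes)")
        return 1.0
    return len(sa & sb) / len(union)


def score_against_truth(
    sig_up: Iterable[str], sig_down: Iterable[str], truth: SimTruth
) -> Metrics:
    """Precision/recall/F1 of signed predictions against the simulated truth."""
    pred = {(s, "up") for s in sig_up} | {(s, "down") for s in sig_down}
    true = set(truth.signed_pairs)
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    if tp + fp == 0:
        precision, precision_defined = 0.0, False
    else:
        precision, precision_defined = tp / (tp + fp), True
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return Metrics(precision, recall, f1, tp, fp, fn, precision_defined)


def compare_runs(
    records_a: Sequence[ORARecord], records_b: Sequence[ORARecord], alpha: float = 0.05
) -> ComparisonSummary:
    """Jaccard of significant sets, gained/lost lists, per-set p/FDR deltas."""
    sig_a = significant_sets(records_a, alpha)
    sig_b = significant_sets(records_b, alpha)
    by_a = {r.set_id: r for r in records_a}
    by_b = {r.set_id: r for r in records_b}
    shared = sorted(set(by_a) & set(by_b))
    deltas = pd.DataFrame(
        {
            "set_id": shared,
            "p_a": [by_a[s].p_value for s in shared],
            "p_b": [by_b[s].p_value for s in shared],
            "fdr_a": [by_a[s].fdr for s in shared],
            "fdr_b": [by_b[s].fdr for s in shared],
        }
    )
    deltas["p_delta"] = deltas["p_b"] - deltas["p_a"]
    deltas["fdr_delta"] = deltas["fdr_b"] - deltas["fdr_a"]
    return ComparisonSummary(
        jaccard=jaccard(sig_a, sig_b),
        n_sig_a=len(sig_a),
        n_sig_b=len(sig_b),
        gained=tuple(sorted(sig_b - sig_a)),
        lost=tuple(sorted(sig_a - sig_b)),
        deltas=deltas,
    )


def run_ora_method(
    method: str,
    fg: GeneList,
    bg: GeneList,
    lib: GeneSetLibrary,
    alpha: float = 0.05,
    min_set_size: int = 5,
    max_set_size: int | None = None,
    detection_min: int = 2,
) -> list[ORARecord]:
    """Run one benchmark ORA variant (see module docstring) for one foreground."""
    try:
        use_bg_fix, use_fdr_fix, mode = _ORA_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown ORA method {method!r}") from None
    cfg = config_for_mode(
        mode,
        min_set_size=min_set_size,
        max_set_size=max_set_size,
        detection_min=detection_min,
        alpha=alpha,
    )
    run_lib = append_universe_set(lib, bg) if use_bg_fix else lib
    records = run_ora(fg, bg, run_lib, cfg)
    if use_fdr_fix:
        expected = expected_test_count(run_lib, bg, cfg)
        records = apply_fdr_workaround(records, expected)
    return records


def _signed_ora_calls(
    method: str,
    fg_up: GeneList,
    fg_down: GeneList,
    bg: GeneList,
    lib: GeneSetLibrary,
    **kwargs,
) -> tuple[set[str], set[str]]:
    alpha = kwargs.get("alpha", 0.05)
    up = significant_sets(run_ora_method(method, fg_up, bg, lib, **kwargs), alpha)
    down = significant_sets(run_ora_method(method, fg_down, bg, lib, **kwargs), alpha)
    return up, down


def run_simulation_study(
    sim_config: SimConfig,
    methods: Sequence[str] = METHODS,
    n_reps: int = 100,
    noise_grid: Sequence[float] = (0.0, 0.2, 0.4, 0.6),
    seed: int | None = None,
    alpha: float = 0.05,
    fallback_n: int = 200,
    n_perm: int = 1000,
    min_set_size: int = 5,
    detection_min: int = 2,
    baseline: pd.Series | None = None,
) -> pd.DataFrame:
    """Benchmark enrichment methods on simulated data with known truth.

    Per noise level and replicate: simulate an experiment (fresh random
    library and truth), run the DE engine on the background genes, select
    the up/down foregrounds, run every method, and score the signed calls.
    Returns a long-format frame (method, noise_sd, rep, precision, recall,
    f1, tp, fp, fn).  Deterministic given the seed.
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {METHODS}")
    master = np.random.SeedSequence(seed)
    base_ss, reps_ss = master.spawn(2)
    if baseline is None:
        baseline = synthetic_baseline(
            sim_config.n_genes, seed=base_ss.generate_state(1)[0] % 2**31
        )
    rep_streams = reps_ss.spawn(len(noise_grid) * n_reps)

    rows = []
    groups = None
    for i_noise, noise in enumerate(noise_grid):
        for rep in range(n_reps):
            ss = rep_streams[i_noise * n_reps + rep]
            sim_seed, fcs_seed = (s.generate_state(1)[0] % 2**31 for s in ss.spawn(2))
            cfg = replace(sim_config, noise_sd=float(noise), seed=int(sim_seed))
            sim = make_pseudosamples(baseline, cfg)
            if groups is None or len(groups) != sim.counts.shape[1]:
                groups = pd.Series(
                    ["case" if c.startswith("case") else "ctrl" for c in sim.counts.columns],
                    index=sim.counts.columns,
                )
            counts_bg = sim.counts.loc[list(sim.background.ids)]
            de = nb_wald_test(counts_bg, groups, reference="ctrl")
            fg_up = select_foreground(de, "up", alpha=alpha, fallback_n=fallback_n)
            fg_down = select_foreground(de, "down", alpha=alpha, fallback_n=fallback_n)
            for method in methods:
                if method == "fcs":
                    recs = fcs_mod.run_fcs(
                        de, sim.library, n_perm=n_perm, seed=int(fcs_seed),
                        min_set_size=min_set_size,
                    )
                    signed = fcs_mod.significant_signed_sets(recs, alpha)
                    sig_up, sig_down = signed["up"], signed["down"]
                else:
                    sig_up, sig_down = _signed_ora_calls(
                        method, fg_up, fg_down, sim.background, sim.library,
                        alpha=alpha, min_set_size=min_set_size,
                        detection_min=detection_min,
                    )
                m = score_against_truth(sig_up, sig_down, sim.truth)
                rows.append(
                    (method, float(noise), rep, m.precision, m.recall, m.f1,
                     m.tp, m.fp, m.fn, m.precision_defined)
                )
    return pd.DataFrame(
        rows,
        columns=["method", "noise_sd", "rep", "precision", "recall", "f1",
                 "tp", "fp", "fn", "precision_defined"],
    )


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method, per-noise mean metrics with Monte-Carlo standard errors.

    Precision is averaged over the replicates where it is defined (at
    least one call made); replicates with zero calls are counted in
    ``n_no_calls`` rather than entering the precision mean as artificial
    zeros.  Recall and F1 average over all replicates.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        out: dict[str, float] = {"n_reps": n, "n_no_calls": int((~g["precision_defined"]).sum())}
        defined = g[g["precision_defined"]]
        nd = len(defined)
        out["precision_mean"] = defined["precision"].mean() if nd else np.nan
        out["precision_se"] = (
            defined["precision"].std(ddof=1) / np.sqrt(nd) if nd > 1 else np.nan
        )
        for col in ("recall", "f1"):
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_se"] = g[col].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series(out)

    return (
        results.groupby(["method", "noise_sd"])[
            ["precision", "recall", "f1", "precision_defined"]
        ]
        .apply(_agg)
        .reset_index()
    )


def run_foreground_sweep(
    de: pd.DataFrame,
    bg: GeneList,
    lib: GeneSetLibrary,
    sizes: Sequence[int] = (125, 250, 500, 1000, 2000),
    modes: tuple[str, str] = ("bug-fdr", "correct"),
    alpha: float = 0.05,
    min_set_size: int = 5,
    detection_min: int = 2,
) -> pd.DataFrame:
    """Jaccard between two engine modes as the foreground size varies.

    Per size and direction the top-k smallest-p genes are selected, both
    modes are run, and the Jaccard of the signed significant sets is
    recorded.  Sizes must be ascending.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    rows = []
    for size in sizes:
        signed: dict[str, set[tuple[str, str]]] = {m: set() for m in modes}
        n_sig = {m: 0 for m in modes}
        for direction in ("up", "down"):
            fg = select_foreground_topk(de, direction, size)
            for mode in set(modes):
                cfg = config_for_mode(
                    mode, min_set_size=min_set_size, detection_min=detection_min, alpha=alpha
                )
                sig = significant_sets(run_ora(fg, bg, lib, cfg), alpha)
                signed[mode] |= {(s, direction) for s in sig}
        a, b = modes
        rows.append(
            (size, jaccard({f"{s}:{d}" for s, d in signed[a]},
                           {f"{s}:{d}" for s, d in signed[b]}),
             len(signed[a]), len(signed[b]))
        )
    return pd.DataFrame(rows, columns=["foreground_size", "jaccard", "n_sig_a", "n_sig_b"])


def _signed_calls_for_dataset(
    counts: pd.DataFrame,
    groups: pd.Series,
    pairing: pd.Series | None,
    lib: GeneSetLibrary,
    method: str,
    alpha: float,
    min_mean: float,
    fallback_n: int,
    n_perm: int,
    fcs_seed: int | None,
    min_set_size: int,
    detection_min: int,
) -> set[tuple[str, str]]:
    filtered = low_count_filter(counts, min_mean)
    bg = GeneList.from_ids("background", filtered.index.tolist())
    de = nb_wald_test(filtered, groups, pairing)
    if method == "fcs":
        recs = fcs_mod.run_fcs(de, lib, n_perm=n_perm, seed=fcs_seed, min_set_size=min_set_size)
        signed = fcs_mod.significant_signed_sets(recs, alpha)
        return {(s, "up") for s in signed["up"]} | {(s, "down") for s in signed["down"]}
    fg_up = select_foreground(de, "up", alpha=alpha, fallback_n=fallback_n)
    fg_down = select_foreground(de, "down", alpha=alpha, fallback_n=fallback_n)
    up, down = _signed_ora_calls(
        "ora_correct" if method == "ora" else method, fg_up, fg_down, bg, lib,
        alpha=alpha, min_set_size=min_set_size, detection_min=detection_min,
    )
    return {(s, "up") for s in up} | {(s, "down") for s in down}


def downsample_consistency(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    pairing: Mapping[str, str] | pd.Series,
    lib: GeneSetLibrary,
    sizes: Sequence[int],
    n_reps: int = 50,
    methods: Sequence[str] = ("ora", "fcs"),
    alpha: float = 0.05,
    seed: int | None = None,
    min_mean: float = 10.0,
    fallback_n: int = 200,
    n_perm: int = 1000,
    min_set_size: int = 5,
    detection_min: int = 2,
) -> pd.DataFrame:
    """Subject-level down-sampling consistency of enrichment calls.

    The significant signed sets on the full paired dataset are computed
    once per method.  Then, per subsample size and replicate, that many
    subjects are drawn without replacement, the paired DE + enrichment
    pipeline is re-run, and calls are counted as *consistent* (present in
    the full-data result with the same direction) or *inconsistent*.  The
    inconsistent proportion estimates the realised false discovery rate.
    """
    groups = pd.Series(groups)
    pairing = pd.Series(pairing)
    subjects = sorted(pairing.unique())
    for size in sizes:
        if size > len(subjects):
            raise ValueError(f"subsample size {size} exceeds number of subjects {len(subjects)}")
        if size < 2:
            raise ValueError("subsample size must be >= 2")

    master = np.random.SeedSequence(seed)
    full_ss, reps_ss = master.spawn(2)
    full_calls = {}
    for method in methods:
        full_calls[method] = _signed_calls_for_dataset(
            counts, groups, pairing, lib, method, alpha, min_mean, fallback_n,
            n_perm, int(full_ss.generate_state(1)[0] % 2**31), min_set_size, detection_min,
        )

    rep_streams = reps_ss.spawn(len(sizes) * n_reps)
    rows = []
    for i_size, size in enumerate(sizes):
        for rep in range(n_reps):
            ss = rep_streams[i_size * n_reps + rep]
            pick_seed, fcs_seed = (s.generate_state(1)[0] % 2**31 for s in ss.spawn(2))
            rng = np.random.default_rng(int(pick_seed))
            chosen = set(rng.choice(np.asarray(subjects, dtype=object), size=size, replace=False))
            cols = [c for c in counts.columns if pairing[c] in chosen]
            sub_counts = counts[cols]
            sub_groups = groups[cols]
            sub_pairing = pairing[cols]
            for method in methods:
                calls = _signed_calls_for_dataset(
                    sub_counts, sub_groups, sub_pairing, lib, method, alpha,
                    min_mean, fallback_n, n_perm, int(fcs_seed), min_set_size,
                    detection_min,
                )
                consistent = len(calls & full_calls[method])
                inconsistent = len(calls - full_calls[method])
                total = consistent + inconsistent
                rows.append(
                    (method, size, rep, consistent, inconsistent,
                     inconsistent / total if total else 0.0, len(full_calls[method]))
                )
    return pd.DataFrame(
        rows,
        columns=["method", "size", "rep", "n_consistent", "n_inconsistent",
                 "prop_inconsistent", "n_full"],
    )
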