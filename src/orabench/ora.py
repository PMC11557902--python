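"""Overrepresentation analysis with switchable failure-mode emulation.

The correct test is the upper-tail hypergeometric: given a universe of N
detected genes of which K belong to a set, and a foreground of n genes of
which k belong to the set, the enrichment p-value is P(X >= k) for
X ~ Hypergeometric(N, K, n), identical to the one-sided ("greater")
Fisher exact test on the 2x2 table.  Fold enrichment is
(k/n) / (K/N), the observed over expected overlap.

Two documented failure modes of popular tools are reproduced on demand:

``background_handling="annotated_only"`` (the *background problem*)
    the universe is silently intersected with the genes annotated to at
    least one library set, shrinking N and deflating both fold enrichment
    and significance.

``fdr_scope="overlapping_only"`` (the *FDR problem*)
    sets with zero foreground overlap are dropped *before* the
    Benjamini-Hochberg correction, understating the number of tests m and
    deflating FDR values.

The correct mode is ``retain_all`` + ``all_detected``.  The published
workarounds — appending the whole background as a gene set
(:func:`orabench.genesets.append_universe_set`) and padding the p-value
vector with ones before re-running BH (:func:`apply_fdr_workaround`) —
recover the correct analysis exactly.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import (
    GeneList,
    GeneSetLibrary,
    UNIVERSE_SET_ID,
    annotated_genes,
    filter_by_size,
    restrict_to_background,
)

logger = logging.getLogger(__name__)

BACKGROUND_MODES = ("retain_all", "annotated_only")
FDR_SCOPES = ("all_detected", "overlapping_only")

#: CLI-facing mode names -> (background_handling, fdr_scope)
MODES = {
    "correct": ("retain_all", "all_detected"),
    "bug-bg": ("annotated_only", "all_detected"),
    "bug-fdr": ("retain_all", "overlapping_only"),
    "bug-both": ("annotated_only", "overlapping_only"),
}

# Smallest p-value we propagate; hypergeometric tails can underflow to 0.0
# but BH input must stay in (0, 1].
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class ContingencyTable:
    """The k/n/K/N quadruple behind one ORA test.

    k: foreground genes in the set (within the universe)
    n: effective foreground size
    K: set size within the universe
    N: universe size
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if min(self.k, self.n, self.K, self.N) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.k > min(self.n, self.K):
            raise ValueError(f"k={self.k} exceeds min(n={self.n}, K={self.K})")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"K={self.K} or n={self.n} exceeds N={self.N}")


@dataclass(frozen=True)
class ORAConfig:
    """Parameters of an ORA run, including which failure modes to emulate.

    detection_min is the number of background members a set needs before it
    counts as "detected" (and therefore as a test); the default of 2
    matches the published FDR workaround.  Size filtering is applied to
    background-restricted membership by default (``size_filter_on_restricted``),
    mirroring tools that filter on the genes actually detected in the
    dataset; set it to False to filter on raw library sizes instead.
    """

    background_handling: str = "retain_all"
    fdr_scope: str = "all_detected"
    min_set_size: int = 5
    max_set_size: int | None = None
    detection_min: int = 2
    alpha: float = 0.05
    size_filter_on_restricted: bool = True

    def __post_init__(self) -> None:
        if self.background_handling not in BACKGROUND_MODES:
            raise ValueError(f"unknown background_handling {self.background_handling!r}")
        if self.fdr_scope not in FDR_SCOPES:
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.detection_min < 1:
            raise ValueError("detection_min must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if self.max_set_size is not None and self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size exceeds max_set_size")


def config_for_mode(mode: str, **overrides) -> ORAConfig:
    """Build an :class:`ORAConfig` from a named mode (correct / bug-bg / bug-fdr / bug-both)."""
    try:
        background_handling, fdr_scope = MODES[mode]
    except KeyError:
        raise ValueError(f"unknown ORA mode {mode!r}; expected one of {sorted(MODES)}") from None
    return ORAConfig(
        background_handling=background_handling, fdr_scope=fdr_scope, **overrides
    )


@dataclass(frozen=True)
class ORARecord:
    """Per-set result of one ORA test under a stated mode."""

    set_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fold_enrichment: float  # NaN when undefined (n == 0 or K == 0)
    fdr: float
    overlap_members: tuple[str, ...]


def hypergeom_pvalue(t: ContingencyTable) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    Equals the one-sided ("greater") Fisher exact p on the 2x2 table.
    P(X >= 0) is exactly 1.
    """
    p = float(hypergeom.sf(t.k - 1, t.N, t.K, t.n))
    return min(max(p, _P_FLOOR), 1.0)


def fold_enrichment(t: ContingencyTable) -> float:
    """Observed/expected overlap ratio (k/n)/(K/N); NaN when n or K is zero."""
    if t.n == 0 or t.K == 0:
        return math.nan
    return (t.k / t.n) / (t.K / t.N)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sanitize_foreground(fg: GeneList | Iterable[str], bg_set: frozenset[str]) -> tuple[str, ...]:
    ids = tuple(fg.ids) if isinstance(fg, GeneList) else tuple(dict.fromkeys(fg))
    kept = tuple(g for g in ids if g in bg_set)
    n_dropped = len(ids) - len(kept)
    if n_dropped:
        logger.warning("dropped %d foreground genes absent from the background", n_dropped)
    return kept


def build_contingency(
    fg: GeneList | Iterable[str],
    bg: GeneList | Iterable[str],
    set_members: Iterable[str],
    mode: str = "retain_all",
    annotated: Iterable[str] | None = None,
) -> ContingencyTable:
    """Build the 2x2 table for one set under a background-handling mode.

    ``retain_all`` uses the full background as universe; ``annotated_only``
    intersects the universe (and the foreground) with the annotated genes,
    which must then be supplied.  Foreground genes outside the background
    are dropped with a logged count.
    """
    if mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown background handling mode {mode!r}")
    bg_ids = tuple(bg.ids) if isinstance(bg, GeneList) else tuple(dict.fromkeys(bg))
    if not bg_ids:
        raise ValueError("background is empty")
    bg_set = frozenset(bg_ids)
    fg_ids = _sanitize_foreground(fg, bg_set)
    members = frozenset(set_members)
    if mode == "annotated_only":
        if annotated is None:
            raise ValueError("annotated gene universe required for annotated_only mode")
        ann = frozenset(annotated)
        universe = frozenset(g for g in bg_set if g in ann)
    else:
        universe = bg_set
    if not universe:
        raise ValueError("universe is empty")
    fg_eff = tuple(g for g in fg_ids if g in universe)
    k = sum(1 for g in fg_eff if g in members)
    K = len(members & universe)
    return ContingencyTable(k=k, n=len(fg_eff), K=K, N=len(universe))


def run_ora(
    fg: GeneList | Iterable[str],
    bg: GeneList | Iterable[str],
    lib: GeneSetLibrary,
    config: ORAConfig = ORAConfig(),
) -> list[ORARecord]:
    """Test every detected set for overrepresentation of the foreground.

    The library is restricted to the background and size-filtered; a set is
    *detected* when at least ``config.detection_min`` of its members are in
    the background.  Under ``fdr_scope="all_detected"`` every detected set
    is reported (k = 0 yields p = 1 from the test itself) and BH runs over
    all of them; under ``"overlapping_only"`` sets with k = 0 are silently
    dropped *before* BH — the FDR problem.  The reserved universe set, if
    present, contributes to the annotated universe but is never tested or
    reported.  Records are sorted by (p, set_id).
    """
    bg_ids = tuple(bg.ids) if isinstance(bg, GeneList) else tuple(dict.fromkeys(bg))
    if not bg_ids:
        raise ValueError("background is empty")
    bg_set = frozenset(bg_ids)
    fg_ids = _sanitize_foreground(fg, bg_set)

    work, ann = _prepare_library(lib, bg_ids, config)

    if config.background_handling == "annotated_only":
        universe = frozenset(g for g in bg_set if g in ann)
    else:
        universe = bg_set
    if not universe:
        raise ValueError("universe is empty")
    fg_eff = frozenset(g for g in fg_ids if g in universe)
    n = len(fg_eff)
    N = len(universe)

    detected = [gs for gs in work if len(gs) >= config.detection_min]
    if not detected:
        logger.warning("no gene sets detected in the background; empty result")
        return []

    rows: list[ORARecord] = []
    for gs in detected:
        members = gs.member_set
        K = len(members & universe)
        overlap = tuple(sorted(fg_eff & members))
        k = len(overlap)
        t = ContingencyTable(k=k, n=n, K=K, N=N)
        rows.append(
            ORARecord(
                set_id=gs.set_id,
                k=k, n=n, K=K, N=N,
                p_value=hypergeom_pvalue(t),
                fold_enrichment=fold_enrichment(t),
                fdr=math.nan,
                overlap_members=overlap,
            )
        )

    if config.fdr_scope == "overlapping_only":
        rows = [r for r in rows if r.k > 0]
        if not rows:
            logger.warning("no sets overlap the foreground; empty result under overlapping_only")
            return []

    fdr = bh_adjust([r.p_value for r in rows])
    rows = [replace(r, fdr=float(q)) for r, q in zip(rows, fdr)]
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows


def _prepare_library(
    lib: GeneSetLibrary, bg_ids: tuple[str, ...], config: ORAConfig
) -> tuple[GeneSetLibrary, frozenset[str]]:
    """Background-restrict and size-filter the library.

    Returns the testable library (reserved universe set excluded) and the
    annotated-gene universe computed from the restricted but *unfiltered*
    library including the reserved set, matching tools that build their
    universe from the full annotation before any size filtering.
    """
    base = restrict_to_background(lib, bg_ids)
    ann = annotated_genes(base)
    testable = GeneSetLibrary(gs for gs in base if gs.set_id != UNIVERSE_SET_ID)
    if config.size_filter_on_restricted:
        work = filter_by_size(testable, config.min_set_size, config.max_set_size)
    else:
        raw = GeneSetLibrary(gs for gs in lib if gs.set_id != UNIVERSE_SET_ID)
        raw = filter_by_size(raw, config.min_set_size, config.max_set_size)
        work = restrict_to_background(raw, bg_ids)
    return work, ann


def expected_test_count(
    lib: GeneSetLibrary, bg: GeneList | Iterable[str], config: ORAConfig
) -> int:
    """Number of sets that *should* be counted as tests.

    These are the sets with at least ``config.detection_min`` members in the
    background (after size filtering), i.e. the number of records an
    ``all_detected`` run would report.  Used to size the p = 1 padding of
    the FDR workaround.
    """
    bg_ids = tuple(bg.ids) if isinstance(bg, GeneList) else tuple(dict.fromkeys(bg))
    work, _ = _prepare_library(lib, bg_ids, config)
    return sum(1 for gs in work if len(gs) >= config.detection_min)


def apply_fdr_workaround(records: list[ORARecord], expected_set_count: int) -> list[ORARecord]:
    """Re-correct FDR values after padding the p-value vector with ones.

    ``expected_set_count`` is the number of tests that should have been
    counted (sets with >= detection_min background members).  The missing
    ``expected - observed`` tests are represented by p = 1 entries, BH is
    re-run, and the corrected FDR values are written back.  The corrected
    values can only be larger than (or equal to) the originals.
    """
    if expected_set_count < len(records):
        raise ValueError(
            f"expected_set_count ({expected_set_count}) is smaller than the number of "
            f"observed records ({len(records)})"
        )
    if not records:
        return []
    padded = [r.p_value for r in records] + [1.0] * (expected_set_count - len(records))
    fdr = bh_adjust(padded)[: len(records)]
    return [replace(r, fdr=float(q)) for r, q in zip(records, fdr)]


def significant_sets(records: Iterable[ORARecord], alpha: float) -> set[str]:
    """Set ids with FDR strictly below alpha.

    Since FDR values are capped at 1, ``alpha >= 1`` selects every
    reported set.
    """
    if alpha >= 1.0:
        return {r.set_id for r in records}
    return {r.set_id for r in records if r.fdr < alpha}


# ---------------------------------------------------------------------------
# tabular round-trip

_COLUMNS = ["set_id", "k", "n", "K", "N", "p_value", "fold_enrichment", "fdr", "overlap"]


def records_to_frame(records: Iterable[ORARecord]) -> pd.DataFrame:
    rows = [
        (r.set_id, r.k, r.n, r.K, r.N, r.p_value, r.fold_enrichment, r.fdr,
         ",".join(r.overlap_members))
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ORARecord]:
    out = []
    for row in frame.itertuples(index=False):
        overlap = tuple(str(row.overlap).split(",")) if isinstance(row.overlap, str) and row.overlap else ()
        out.append(
            ORARecord(
                set_id=str(row.set_id), k=int(row.k), n=int(row.n), K=int(row.K),
                N=int(row.N), p_value=float(row.p_value),
                fold_enrichment=float(row.fold_enrichment), fdr=float(row.fdr),
                overlap_members=overlap,
            )
        )
    return out
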