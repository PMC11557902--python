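"""Simulated RNA-seq experiments with pathway-level ground truth.

The generator emulates the benchmark construction used to quantify the
two ORA failure modes: start from a deeply sequenced single-sample count
profile, down-sample it to a fixed read depth by a multinomial draw
("thinning") once per pseudosample, perturb every count by an independent
multiplicative Gaussian factor, and inject signed fold changes into the
member genes of randomly chosen gene sets in the case samples only.

Defaults follow the study conditions: a library of 200 random sets of 30
genes, 5% of sets differentially expressed with an equal up/down split, a
log2 fold-change magnitude of 0.5, thinning to 20 million reads, and
three pseudosamples per group.  "Multiplied by a log-fold change of 0.5"
is interpreted as multiplication by 2**(+/-0.5), consistent with the log2
convention of the DE engine.  Genes that land in both an up- and a
down-regulated set receive no injected signal.

Everything is deterministic given the seed; independent child streams are
derived with :class:`numpy.random.SeedSequence` so that adding samples or
noise never perturbs unrelated draws.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .de import low_count_filter
from .genesets import GeneList, GeneSet, GeneSetLibrary

logger = logging.getLogger(__name__)

NOISE_MODES = ("fixed", "per_gene")


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulated experiment.

    noise_sd is the standard deviation of the multiplicative Gaussian
    noise factor (mean 1); ``noise_mode="fixed"`` applies that SD to every
    gene x sample cell, while ``"per_gene"`` draws each gene's SD
    uniformly from [0, noise_sd] first (the alternative reading of the
    benchmark's noise description).
    """

    n_genes: int = 20000
    n_sets: int = 200
    set_size: int = 30
    frac_de: float = 0.05
    log2fc_magnitude: float = 0.5
    target_depth: int = 20_000_000
    noise_sd: float = 0.3
    noise_mode: str = "fixed"
    n_per_group: int = 3
    min_mean: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("frac_de must be in [0, 1]")
        n_de = self.frac_de * self.n_sets
        if abs(n_de - round(n_de)) > 1e-9 or (round(n_de) % 2 != 0) or (0 < round(n_de) < 2):
            raise ValueError(
                "frac_de * n_sets must be an even integer >= 2 (or zero) "
                f"for an equal up/down split; got {n_de}"
            )
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @property
    def n_de_sets(self) -> int:
        return int(round(self.frac_de * self.n_sets))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated experiment.

    ``up_genes``/``down_genes`` are the member unions of the chosen sets;
    ``conflicted_genes`` (members of both an up and a down set) receive no
    injected signal.
    """

    up_set_ids: tuple[str, ...]
    down_set_ids: tuple[str, ...]
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    conflicted_genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.up_set_ids) & set(self.down_set_ids):
            raise ValueError("a set cannot be both up- and down-regulated")
        object.__setattr__(self, "conflicted_genes", frozenset(self.up_genes & self.down_genes))

    @property
    def signed_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            [(s, "up") for s in self.up_set_ids] + [(s, "down") for s in self.down_set_ids]
        )


class SimResult(NamedTuple):
    counts: pd.DataFrame
    truth: SimTruth
    background: GeneList
    library: GeneSetLibrary


def _child_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    return list(np.random.SeedSequence(seed).spawn(n))


def synthetic_baseline(
    n_genes: int = 20000,
    seed: int | None = None,
    meanlog: float = 4.0,
    sdlog: float = 2.0,
    min_total: int = 50_000_000,
) -> pd.Series:
    """Synthetic deep-coverage single-sample count profile.

    A heavy-tailed log-normal expression model (meanlog 4, sdlog 2 on the
    natural-log scale, rounded to integers) spanning several orders of
    magnitude, rescaled so the library totals at least ``min_total`` reads
    — a stand-in for a deeply sequenced real profile used as the thinning
    source.  Deterministic given the seed.
    """
    if n_genes < 1000:
        raise ValueError("n_genes must be >= 1000 for a plausible expression profile")
    rng = np.random.default_rng(seed)
    counts = np.rint(rng.lognormal(mean=meanlog, sigma=sdlog, size=n_genes))
    total = counts.sum()
    if total < min_total:
        counts = np.rint(counts * (min_total / total * 1.01))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    return pd.Series(counts.astype(np.int64), index=genes, name="baseline")


def random_library(
    gene_ids: Sequence[str],
    n_sets: int = 200,
    set_size: int = 30,
    seed: int | None = None,
) -> GeneSetLibrary:
    """Library of random gene sets, each a uniform sample without replacement.

    Sets are drawn independently of one another, so overlap between sets
    is allowed (and expected).  Deterministic given the seed.
    """
    ids = np.asarray(list(gene_ids), dtype=object)
    if set_size > ids.size:
        raise ValueError(f"set_size {set_size} exceeds number of genes {ids.size}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_sets)))
    lib = GeneSetLibrary()
    for i in range(n_sets):
        members = rng.choice(ids, size=set_size, replace=False)
        lib.add(GeneSet(f"SET{i:0{width}d}", "random simulated gene set", tuple(members)))
    return lib


def select_de_sets(
    lib: GeneSetLibrary, frac_de: float = 0.05, seed: int | None = None
) -> SimTruth:
    """Choose the differentially expressed sets: half up, half down."""
    n_de = frac_de * len(lib)
    if abs(n_de - round(n_de)) > 1e-9 or (round(n_de) % 2 != 0) or (0 < round(n_de) < 2):
        raise ValueError("frac_de * n_sets must be an even integer >= 2 (or zero)")
    n_de = int(round(n_de))
    if n_de == 0:
        return SimTruth((), (), frozenset(), frozenset())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(lib.set_ids, dtype=object), size=n_de, replace=False)
    up, down = tuple(chosen[: n_de // 2]), tuple(chosen[n_de // 2 :])
    up_genes = frozenset(g for s in up for g in lib[s].members)
    down_genes = frozenset(g for s in down for g in lib[s].members)
    return SimTruth(up, down, up_genes, down_genes)


def thin_counts(
    counts: pd.Series, target_depth: int, seed: int | None = None
) -> pd.Series:
    """Multinomial down-sampling to an exact total read depth.

    One multinomial draw of ``target_depth`` reads with probabilities
    proportional to the input counts: the output total equals the target
    exactly and zero counts stay zero.
    """
    arr = counts.to_numpy(dtype=np.float64)
    total = arr.sum()
    if target_depth > total:
        raise ValueError(f"target_depth {target_depth} exceeds total counts {int(total)}")
    rng = np.random.default_rng(seed)
    thinned = rng.multinomial(int(target_depth), arr / total)
    return pd.Series(thinned.astype(np.int64), index=counts.index, name=counts.name)


def add_noise(
    counts: pd.Series | pd.DataFrame,
    noise_sd: float,
    seed: int | None = None,
    noise_mode: str = "fixed",
) -> pd.Series | pd.DataFrame:
    """Multiply each count by an independent Normal(1, sd) factor.

    Factors are truncated at zero (no negative counts) and the result is
    rounded to the nearest integer.  ``noise_mode="per_gene"`` first draws
    a per-gene SD uniformly from [0, noise_sd].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_mode not in NOISE_MODES:
        raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
    if noise_sd == 0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    arr = counts.to_numpy(dtype=np.float64)
    shape = arr.shape
    if noise_mode == "per_gene":
        sd = rng.uniform(0.0, noise_sd, size=shape[0])
        scale = np.broadcast_to(sd.reshape((-1,) + (1,) * (len(shape) - 1)), shape)
    else:
        scale = noise_sd
    factors = np.clip(rng.normal(loc=1.0, scale=scale, size=shape), 0.0, None)
    noised = np.rint(arr * factors).astype(np.int64)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(noised, index=counts.index, columns=counts.columns)
    return pd.Series(noised, index=counts.index, name=counts.name)


def inject_signal(
    counts: pd.Series | pd.DataFrame,
    truth: SimTruth,
    log2fc_magnitude: float,
) -> pd.Series | pd.DataFrame:
    """Apply the signed fold change to true genes (case samples only).

    Every column of ``counts`` is treated as a case sample: up genes are
    multiplied by 2**m, down genes by 2**-m, conflicted genes left
    unchanged, results rounded to integers.
    """
    m = float(log2fc_magnitude)
    out = counts.to_numpy(dtype=np.float64).copy()
    index = counts.index
    up = index.isin(truth.up_genes - truth.conflicted_genes)
    down = index.isin(truth.down_genes - truth.conflicted_genes)
    out[up] = out[up] * 2.0 ** m
    out[down] = out[down] * 2.0 ** (-m)
    out = np.rint(out).astype(np.int64)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=index, columns=counts.columns)
    return pd.Series(out, index=index, name=counts.name)


def make_pseudosamples(
    baseline: pd.Series,
    config: SimConfig,
    library: GeneSetLibrary | None = None,
    truth: SimTruth | None = None,
) -> SimResult:
    """Generate a full pseudosample experiment from a baseline profile.

    Control and case pseudosamples are produced by independently thinning
    the baseline to ``config.target_depth`` and adding multiplicative
    noise; the case samples then receive the injected signal.  The
    background list is defined by the low-count filter on the finished
    matrix.  If no library/truth is supplied, a random library over the
    baseline genes and a fresh truth are drawn from the same seed stream.
    """
    if baseline.sum() < config.target_depth:
        raise ValueError("baseline total is below the thinning target depth")
    ss = _child_seeds(config.seed, 2 + 2 * 2 * config.n_per_group)
    lib_seed, truth_seed = ss[0], ss[1]
    sample_seeds = ss[2:]

    if library is None:
        library = random_library(
            list(baseline.index), config.n_sets, config.set_size,
            seed=lib_seed.generate_state(1)[0] % 2**31,
        )
    if truth is None:
        truth = select_de_sets(
            library, config.frac_de, seed=truth_seed.generate_state(1)[0] % 2**31
        )

    columns = {}
    names = [f"ctrl_{i + 1}" for i in range(config.n_per_group)] + [
        f"case_{i + 1}" for i in range(config.n_per_group)
    ]
    for j, name in enumerate(names):
        thin_seed = sample_seeds[2 * j].generate_state(1)[0] % 2**31
        noise_seed = sample_seeds[2 * j + 1].generate_state(1)[0] % 2**31
        col = thin_counts(baseline, config.target_depth, seed=thin_seed)
        col = add_noise(col, config.noise_sd, seed=noise_seed, noise_mode=config.noise_mode)
        columns[name] = col
    counts = pd.DataFrame(columns)

    case_cols = [n for n in names if n.startswith("case_")]
    counts[case_cols] = inject_signal(counts[case_cols], truth, config.log2fc_magnitude)

    background = GeneList.from_ids(
        "background", low_count_filter(counts, config.min_mean).index.tolist()
    )
    return SimResult(counts=counts, truth=truth, background=background, library=library)
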