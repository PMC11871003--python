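"""Embedding evaluation by known-relationship seed pairs against a null.

A model is scored by the fraction of known-relationship symptom pairs whose
cosine similarity exceeds the 95th percentile of a null similarity
distribution. The null is built by drawing tokens of the daytime-impairment
semantic supertype from the model vocabulary and computing pairwise cosine
similarities; under random geometry a pair beats the 95th percentile with
probability 0.05, so 0.05 is the metric's chance floor. Scores are medians
across several re-draws of the null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_prep import SemanticLexicon
from .embedding_ensemble import EmbeddingModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedPair:
    term_a: str
    term_b: str

    def __post_init__(self):
        if self.term_a == self.term_b:
            raise ValueError(f"seed pair members must differ, got {self.term_a!r} twice")


def read_seed_pairs(path) -> List[SeedPair]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields")
            pairs.append(SeedPair(parts[0], parts[1]))
    return pairs


def write_seed_pairs(pairs: Sequence[SeedPair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.term_a}\t{p.term_b}\n")


def nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic.

    A tiny tolerance inside the ceiling keeps ranks stable when q*n is an
    integer up to float round-off (e.g. 0.037 * 1000).
    """
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(q * n - 1e-9))
    return float(sorted_values[k - 1])


def null_distribution(
    model: EmbeddingModel,
    lexicon: SemanticLexicon,
    n_tokens: int = 10_000,
    seed: int = 0,
    pair_budget: int = 1_000_000,
    percentile: float = 0.95,
) -> Tuple[np.ndarray, float]:
    """Similarity sample over random supertype-token pairs and its threshold.

    Draws ``min(n_tokens, available)`` daytime-impairment supertype tokens
    from the model vocabulary without replacement (if the pool is smaller
    than ``n_tokens`` the whole pool is used, logged). Similarities are
    computed over all unordered pairs when that count fits the pair budget,
    else over a uniform pair subsample. The threshold is the nearest-rank
    ``percentile`` of the similarity sample.
    """
    pool = [t for t in model.tokens if lexicon.is_supertype(t)]
    if len(pool) < 2:
        raise ValueError(
            f"need at least 2 supertype tokens in the vocabulary, found {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    if len(pool) > n_tokens:
        idx = rng.choice(len(pool), size=n_tokens, replace=False)
        drawn = [pool[i] for i in idx]
    else:
        drawn = pool
        if len(pool) < n_tokens:
            logger.info(
                "supertype pool (%d) smaller than requested %d tokens; using all",
                len(pool), n_tokens,
            )
    m = len(drawn)
    units = model.unit_vectors()
    rows = np.array([model.index[t] for t in drawn])
    U = units[rows]
    n_all_pairs = m * (m - 1) // 2
    if n_all_pairs <= pair_budget:
        sims = (U @ U.T)[np.triu_indices(m, k=1)]
    else:
        ii = rng.integers(0, m, size=pair_budget)
        jj = rng.integers(0, m - 1, size=pair_budget)
        jj = np.where(jj >= ii, jj + 1, jj)  # uniform j != i
        sims = np.einsum("bd,bd->b", U[ii], U[jj])
    sims = np.sort(sims)
    threshold = nearest_rank(sims, percentile)
    return sims, threshold


@dataclass
class MetricResult:
    per_run_fractions: List[float]
    median_fraction: float
    threshold_per_run: List[float]
    n_pairs_scored: int
    n_pairs_skipped_oov: int


def evaluate_model(
    model: EmbeddingModel,
    seed_pairs: Sequence[SeedPair],
    lexicon: SemanticLexicon,
    n_runs: int = 5,
    seeds: Optional[Sequence[int]] = None,
    n_tokens: int = 10_000,
    pair_budget: int = 1_000_000,
) -> MetricResult:
    """Fraction of seed pairs whose similarity beats the per-run null
    threshold, median across runs. OOV pairs are skipped and reported, not
    scored as failures.
    """
    if not seed_pairs:
        raise ValueError("seed pair list is empty")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    vocab = model.index
    scorable, skipped = [], 0
    for p in seed_pairs:
        if p.term_a in vocab and p.term_b in vocab:
            scorable.append(p)
        else:
            skipped += 1
    if not scorable:
        raise ValueError("no seed pair has both members in the vocabulary")
    sims = np.array([model.similarity(p.term_a, p.term_b) for p in scorable])
    fractions, thresholds = [], []
    for s in seeds:
        _, thr = null_distribution(
            model, lexicon, n_tokens=n_tokens, seed=s, pair_budget=pair_budget
        )
        thresholds.append(thr)
        fractions.append(float(np.mean(sims > thr)))
    return MetricResult(
        per_run_fractions=fractions,
        median_fraction=float(np.median(fractions)),
        threshold_per_run=thresholds,
        n_pairs_scored=len(scorable),
        n_pairs_skipped_oov=skipped,
    )
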