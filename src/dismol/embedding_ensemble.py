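"""Skip-gram embedding trainer, hyperparameter search and bootstrap ensemble.

The disease-specific language model is a distributional word embedding
trained on the tokenized note corpus. Training uses skip-gram with negative
sampling (SGNS), minibatched in numpy with a seeded generator so that a fixed
(corpus, config, seed) triple always yields the same vectors. The final model
is an ensemble of (by default) eight members trained on sentence-level
bootstrap resamples of the corpus; the distance between two tokens is the
mean cosine distance across members, which damps the neighbour instability of
any single stochastic training run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .corpus_prep import TokenizedCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """SGNS hyperparameters. Defaults are small-corpus friendly."""

    dim: int = 50
    window: int = 4
    min_count: int = 2
    negative: int = 5
    epochs: int = 5
    alpha: float = 0.025
    subsample: float = 0.0  # frequent-token subsampling threshold; 0 = off
    seed: int = 0

    def validate(self) -> None:
        if self.dim <= 0:
            raise ValueError(f"dim must be positive, got {self.dim}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")
        if self.negative < 1:
            raise ValueError(f"negative must be >= 1, got {self.negative}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


@dataclass
class EmbeddingModel:
    """A trained embedding: vocabulary, vectors and the config that made it."""

    tokens: List[str]
    vectors: np.ndarray  # (V, d)
    train_config: TrainConfig
    index: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.tokens)}
        if self.vectors.shape[0] != len(self.tokens):
            raise ValueError("vector count does not match vocabulary size")

    @property
    def vocabulary(self) -> set:
        return set(self.index)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.index[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def similarity(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        return float(
            va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        )

    def distance(self, a: str, b: str) -> float:
        return 1.0 - self.similarity(a, b)

    def unit_vectors(self) -> np.ndarray:
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        return self.vectors / np.maximum(norms, 1e-12)


def _build_vocab(sentences: Sequence[Sequence[str]], min_count: int):
    counts: Dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    # deterministic order: by descending count then token
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return kept, counts


def train_embedding(corpus: TokenizedCorpus, config: TrainConfig) -> EmbeddingModel:
    """Train SGNS vectors on ``corpus.sentences``.

    Deterministic under a fixed config seed (single worker, seeded numpy
    generator for init, window sizes, pair shuffling and negative draws).
    Tokens below ``min_count`` are excluded from the vocabulary.
    """
    config.validate()
    if not corpus.sentences:
        raise ValueError("cannot train on an empty corpus")
    tokens, counts = _build_vocab(corpus.sentences, config.min_count)
    if not tokens:
        raise ValueError("no token reaches min_count; vocabulary is empty")
    index = {t: i for i, t in enumerate(tokens)}
    rng = np.random.default_rng(config.seed)
    V, d = len(tokens), config.dim
    W = (rng.random((V, d), dtype=np.float64) - 0.5) / d
    C = np.zeros((V, d), dtype=np.float64)

    freq = np.array([counts[t] for t in tokens], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()
    total = freq.sum()
    keep_prob = np.ones(V)
    if config.subsample > 0:
        f = freq / total
        keep_prob = np.minimum(1.0, np.sqrt(config.subsample / f))

    sent_ids = [
        np.array([index[t] for t in sent if t in index], dtype=np.int64)
        for sent in corpus.sentences
    ]
    sent_ids = [s for s in sent_ids if len(s) >= 2]
    if not sent_ids:
        raise ValueError("no sentence has two in-vocabulary tokens")

    # rough pair count for the linear learning-rate schedule
    approx_pairs = sum(len(s) for s in sent_ids) * config.window * config.epochs
    seen = 0
    batch_size = 1024
    for _ in range(config.epochs):
        centers: List[int] = []
        contexts: List[int] = []
        for s in sent_ids:
            if config.subsample > 0:
                mask = rng.random(len(s)) < keep_prob[s]
                s = s[mask]
                if len(s) < 2:
                    continue
            b = rng.integers(1, config.window + 1, size=len(s))
            for i in range(len(s)):
                lo, hi = max(0, i - b[i]), min(len(s), i + b[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(s[i])
                        contexts.append(s[j])
        ci = np.asarray(centers, dtype=np.int64)
        oi = np.asarray(contexts, dtype=np.int64)
        perm = rng.permutation(len(ci))
        ci, oi = ci[perm], oi[perm]
        for start in range(0, len(ci), batch_size):
            c = ci[start : start + batch_size]
            o = oi[start : start + batch_size]
            B = len(c)
            lr = config.alpha * max(1e-4, 1.0 - seen / max(approx_pairs, 1))
            seen += B
            ni = rng.choice(V, size=(B, config.negative), p=noise)
            wc = W[c]  # (B, d)
            co = C[o]
            cn = C[ni]  # (B, k, d)
            s_pos = expit(np.einsum("bd,bd->b", wc, co))
            g_pos = (1.0 - s_pos) * lr  # (B,)
            s_neg = expit(np.einsum("bd,bkd->bk", wc, cn))
            g_neg = -s_neg * lr  # (B, k)
            grad_w = g_pos[:, None] * co + np.einsum("bk,bkd->bd", g_neg, cn)
            np.add.at(C, o, g_pos[:, None] * wc)
            np.add.at(
                C,
                ni.ravel(),
                (g_neg[:, :, None] * wc[:, None, :]).reshape(-1, W.shape[1]),
            )
            np.add.at(W, c, grad_w)
    return EmbeddingModel(tokens=tokens, vectors=W, train_config=config)


@dataclass
class HyperparameterSpace:
    """Per-hyperparameter choice lists plus a random-search budget."""

    choices: Mapping[str, Sequence]
    search_budget: int = 10
    search_seed: int = 0

    def __post_init__(self):
        if self.search_budget < 1:
            raise ValueError("search_budget must be >= 1")
        for k, v in self.choices.items():
            if len(v) == 0:
                raise ValueError(f"hyperparameter {k!r} has an empty range")

    def grid_size(self) -> int:
        n = 1
        for v in self.choices.values():
            n *= len(v)
        return n

    def sample(self) -> List[TrainConfig]:
        """Random sample of configs, without replacement, up to the budget."""
        keys = sorted(self.choices)
        rng = np.random.default_rng(self.search_seed)
        n_grid = self.grid_size()
        budget = min(self.search_budget, n_grid)
        picked: List[TrainConfig] = []
        seen = set()
        while len(picked) < budget:
            combo = tuple(
                self.choices[k][rng.integers(len(self.choices[k]))] for k in keys
            )
            if combo in seen:
                continue
            seen.add(combo)
            picked.append(replace(TrainConfig(), **dict(zip(keys, combo))))
        return picked


def hyperparameter_search(
    corpus: TokenizedCorpus,
    space: HyperparameterSpace,
    evaluator: Callable[[EmbeddingModel], float],
) -> Tuple[TrainConfig, List[Tuple[TrainConfig, float]]]:
    """Random search: train one model per sampled config, score with
    ``evaluator``, return the argmax config plus the full score log.
    Ties break toward the earliest-sampled configuration.
    """
    configs = space.sample()
    log: List[Tuple[TrainConfig, float]] = []
    best, best_score = None, -np.inf
    for cfg in configs:
        model = train_embedding(corpus, cfg)
        score = float(evaluator(model))
        log.append((cfg, score))
        if score > best_score:
            best, best_score = cfg, score
    return best, log


@dataclass
class EnsembleModel:
    """Bootstrap ensemble; queries are restricted to the shared vocabulary."""

    members: List[EmbeddingModel]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        shared = set(self.members[0].index)
        for m in self.members[1:]:
            shared &= set(m.index)
        self.shared_vocabulary = shared

    def _check(self, token: str) -> None:
        if token not in self.shared_vocabulary:
            raise KeyError(f"token {token!r} not in the ensemble's shared vocabulary")

    def distance(self, a: str, b: str) -> float:
        """Mean cosine distance across members; symmetric, in [0, 2]."""
        self._check(a)
        self._check(b)
        return float(np.mean([m.distance(a, b) for m in self.members]))

    def distances_to_all(self, query: str) -> Dict[str, float]:
        """Ensemble distance from ``query`` to every shared-vocabulary token."""
        self._check(query)
        acc: Dict[str, float] = {}
        shared = sorted(self.shared_vocabulary)
        total = np.zeros(len(shared))
        for m in self.members:
            units = m.unit_vectors()
            qv = units[m.index[query]]
            idx = np.array([m.index[t] for t in shared])
            total += 1.0 - units[idx] @ qv
        total /= len(self.members)
        return dict(zip(shared, total))

    def nearest_terms(
        self,
        query: str,
        k: Optional[int] = None,
        distance_threshold: Optional[float] = None,
    ) -> List[Tuple[str, float]]:
        """Tokens nearest to ``query`` by ensemble distance, ascending,
        ties broken lexicographically; the query itself is excluded."""
        dists = self.distances_to_all(query)
        dists.pop(query, None)
        ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
        if distance_threshold is not None:
            ranked = [kv for kv in ranked if kv[1] <= distance_threshold]
        if k is not None:
            ranked = ranked[:k]
        return ranked


def ensemble_distance(ensemble: EnsembleModel, a: str, b: str) -> float:
    return ensemble.distance(a, b)


def build_ensemble(
    corpus: TokenizedCorpus,
    best_config: TrainConfig,
    n_models: int = 8,
    base_seed: int = 0,
) -> EnsembleModel:
    """Train ``n_models`` members on sentence bootstrap resamples.

    Member ``i`` resamples the corpus sentences with replacement (resample
    size = corpus size) with seed ``base_seed + i`` and trains with that same
    seed, so weights are independently initialized per member.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not corpus.sentences:
        raise ValueError("cannot build an ensemble on an empty corpus")
    members = []
    n = len(corpus.sentences)
    for i in range(n_models):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        pick = rng.integers(0, n, size=n)
        boot = TokenizedCorpus(
            sentences=[corpus.sentences[j] for j in pick],
            token_stats=corpus.token_stats,
            n_patients_total=corpus.n_patients_total,
        )
        members.append(train_embedding(boot, replace(best_config, seed=seed)))
    return EnsembleModel(members=members)


def save_ensemble(ensemble: EnsembleModel, directory) -> None:
    """Persist members as text vector files plus a manifest."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    manifest = {"n_members": len(ensemble.members), "members": []}
    for i, m in enumerate(ensemble.members):
        fname = f"member_{i:02d}.vec"
        with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
            fh.write(f"{len(m.tokens)} {m.vectors.shape[1]}\n")
            for t, row in zip(m.tokens, m.vectors):
                fh.write(t + " " + " ".join(repr(float(x)) for x in row) + "\n")
        manifest["members"].append(
            {"file": fname, "config": m.train_config.__dict__}
        )
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_ensemble(directory) -> EnsembleModel:
    import json
    import os

    with open(os.path.join(directory, "manifest.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    members = []
    for entry in manifest["members"]:
        path = os.path.join(directory, entry["file"])
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            V, d = int(header[0]), int(header[1])
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vectors = np.array(rows, dtype=np.float64)
        if vectors.shape != (V, d):
            raise ValueError(f"{path}: vector block does not match header")
        members.append(
            EmbeddingModel(
                tokens=tokens,
                vectors=vectors,
                train_config=TrainConfig(**entry["config"]),
            )
        )
    return EnsembleModel(members=members)
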