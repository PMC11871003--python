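"""Ontology enrichment: candidate retrieval and the four admission filters.

Candidates are tokens the embedding ensemble places unusually close to a seed
term: a (seed, token) pair is retrieved when its ensemble cosine distance
falls in the closest 3.7% of a reference distance distribution over random
token pairs (the 0.963 percentile of similarity). Retrieved candidates then
pass, in order, a semantic-supertype filter, a patient-frequency filter
(present in at least 0.24% of patients, ceiling at the boundary), and a
directionality-clarity filter; survivors go to explicit expert review — the
pipeline never auto-accepts. Finally the enriched ontology is checked for
lexical consistency: inflections sharing a lemma must carry identical domain
sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .context_directionality import (
    IMPAIRMENT_WHEN_ASSERTED,
    Ontology,
    OntologyTerm,
    TriggerLexicon,
    has_clear_directionality,
)
from .corpus_prep import SemanticLexicon, TokenizedCorpus, lemma
from .embedding_ensemble import EnsembleModel
from .seedpair_metric import nearest_rank

logger = logging.getLogger(__name__)


@dataclass
class CandidateTerm:
    token: str
    source_seeds: List[str]
    ensemble_dist: float
    semantic_type: str = ""
    n_patients: int = 0
    directionality_clear: Optional[bool] = None
    directionality_counts: Dict[str, int] = field(default_factory=dict)
    review_status: str = "pending"  # pending | accepted | rejected

    def __post_init__(self):
        if self.ensemble_dist < 0:
            raise ValueError("ensemble_dist must be >= 0")


def pairwise_distance_threshold(
    ensemble: EnsembleModel,
    percentile: float = 0.963,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> float:
    """Distance cutoff: the (1-percentile) nearest-rank quantile of ensemble
    distances over random shared-vocabulary token pairs."""
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile {percentile} outside (0, 1)")
    vocab = sorted(ensemble.shared_vocabulary)
    if len(vocab) < 2:
        raise ValueError("shared vocabulary too small")
    rng = np.random.default_rng(seed)
    m = len(vocab)
    n_all = m * (m - 1) // 2
    if n_all <= n_pairs:
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
    else:
        ii = rng.integers(0, m, size=n_pairs)
        jj = rng.integers(0, m - 1, size=n_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)
    total = np.zeros(len(ii))
    for member in ensemble.members:
        units = member.unit_vectors()
        rows = np.array([member.index[t] for t in vocab])
        U = units[rows]
        total += 1.0 - np.einsum("bd,bd->b", U[ii], U[jj])
    dists = np.sort(total / len(ensemble.members))
    return nearest_rank(dists, 1.0 - percentile)


def retrieve_candidates(
    ensemble: EnsembleModel,
    simple_ontology: Ontology,
    percentile: float = 0.963,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> List[CandidateTerm]:
    """Retrieve near-seed tokens below the percentile distance threshold.

    Out-of-vocabulary seeds are logged and skipped. A token retrieved by
    several seeds is reported once, at its minimal distance, with every
    contributing seed recorded; seed terms are never their own candidates.
    """
    threshold = pairwise_distance_threshold(
        ensemble, percentile=percentile, n_pairs=n_pairs, seed=seed
    )
    seed_surfaces = set()
    for term in simple_ontology.terms:
        seed_surfaces.update(term.surface.split())
    found: Dict[str, CandidateTerm] = {}
    for term in simple_ontology.terms:
        s = term.surface
        if s not in ensemble.shared_vocabulary:
            logger.info("seed term %r not in shared vocabulary; skipped", s)
            continue
        for token, dist in ensemble.distances_to_all(s).items():
            if token in seed_surfaces or dist >= threshold:
                continue
            if token in found:
                cand = found[token]
                if s not in cand.source_seeds:
                    cand.source_seeds.append(s)
                if dist < cand.ensemble_dist:
                    cand.ensemble_dist = dist
            else:
                found[token] = CandidateTerm(
                    token=token, source_seeds=[s], ensemble_dist=dist
                )
    return sorted(found.values(), key=lambda c: (c.ensemble_dist, c.token))


def apply_supertype_filter(
    candidates: Iterable[CandidateTerm], lexicon: SemanticLexicon
) -> List[CandidateTerm]:
    """Keep candidates whose token carries the daytime-impairment supertype."""
    kept = []
    for c in candidates:
        c.semantic_type = lexicon.semantic_type(c.token)
        if lexicon.is_supertype(c.token):
            kept.append(c)
    return kept


def min_patient_count(n_patients_total: int, min_fraction: float = 0.0024) -> int:
    """Smallest patient count satisfying the at-least-``min_fraction`` rule."""
    if n_patients_total <= 0:
        raise ValueError("n_patients_total must be positive")
    return math.ceil(min_fraction * n_patients_total)


def apply_frequency_filter(
    candidates: Iterable[CandidateTerm],
    corpus: TokenizedCorpus,
    min_fraction: float = 0.0024,
) -> List[CandidateTerm]:
    """Keep candidates present in at least ``min_fraction`` of all patients."""
    cutoff = min_patient_count(corpus.n_patients_total, min_fraction)
    kept = []
    for c in candidates:
        c.n_patients = corpus.n_patients_with(c.token)
        if c.n_patients >= cutoff:
            kept.append(c)
    return kept


def apply_directionality_filter(
    candidates: Iterable[CandidateTerm],
    sample_sentences: Sequence[Sequence[str]],
    triggers: Optional[TriggerLexicon] = None,
    min_resolvable_share: float = 0.8,
) -> List[CandidateTerm]:
    """Keep candidates whose corpus uses resolve clearly to asserted/negated."""
    if triggers is None:
        triggers = TriggerLexicon.default()
    kept = []
    for c in candidates:
        clear, counts = has_clear_directionality(
            c.token, sample_sentences, triggers, min_resolvable_share
        )
        c.directionality_clear = clear
        c.directionality_counts = counts
        if clear:
            kept.append(c)
    return kept


def apply_expert_review(
    candidates: Sequence[CandidateTerm],
    decisions: Mapping[str, str],
    domain_assignments: Mapping[str, Iterable[str]],
    seed_ontology: Ontology,
) -> Ontology:
    """Fold expert accept/reject decisions into the enriched ontology.

    Every surviving candidate must carry a decision, and every accepted one
    a non-empty domain assignment — the framework aids experts, it does not
    replace them. The result is the seed ontology plus accepted terms
    (polarity defaults to impairment-when-asserted) with provenance traces.
    """
    missing = [c.token for c in candidates if c.token not in decisions]
    if missing:
        raise ValueError(f"missing expert decision for: {sorted(missing)}")
    bad = [
        c.token
        for c in candidates
        if decisions[c.token] == "accepted" and not set(domain_assignments.get(c.token, ()))
    ]
    if bad:
        raise ValueError(f"accepted tokens without domain assignment: {sorted(bad)}")
    terms = list(seed_ontology.terms)
    provenance = dict(seed_ontology.provenance)
    seen = {t.surface for t in terms}
    for c in candidates:
        c.review_status = decisions[c.token]
        if c.review_status != "accepted" or c.token in seen:
            continue
        terms.append(
            OntologyTerm(
                surface=c.token,
                domains=frozenset(domain_assignments[c.token]),
                polarity=IMPAIRMENT_WHEN_ASSERTED,
            )
        )
        provenance[c.token] = {
            "source_seeds": list(c.source_seeds),
            "ensemble_dist": c.ensemble_dist,
            "semantic_type": c.semantic_type,
            "n_patients": c.n_patients,
            "directionality_counts": dict(c.directionality_counts),
        }
        seen.add(c.token)
    return Ontology(terms=terms, provenance=provenance)


def check_lexical_consistency(
    ontology: Ontology,
) -> List[Tuple[Tuple[str, ...], Dict[str, FrozenSet[str]]]]:
    """List lemma classes whose member terms disagree on domain sets."""
    by_lemma: Dict[Tuple[str, ...], Dict[str, FrozenSet[str]]] = {}
    for t in ontology.terms:
        by_lemma.setdefault(t.lemma_key, {})[t.surface] = t.domains
    return [
        (key, members)
        for key, members in sorted(by_lemma.items())
        if len({d for d in members.values()}) > 1
    ]


def resolve_lexical_consistency(ontology: Ontology, mode: str = "union") -> Ontology:
    """Resolve inconsistent lemma classes; ``union`` assigns the class the
    union of member domains, ``report`` returns the ontology unchanged."""
    if mode == "report":
        return ontology
    if mode != "union":
        raise ValueError(f"unknown mode {mode!r}")
    violations = check_lexical_consistency(ontology)
    union_by_lemma = {
        key: frozenset().union(*members.values()) for key, members in violations
    }
    terms = [
        replace(t, domains=union_by_lemma[t.lemma_key])
        if t.lemma_key in union_by_lemma
        else t
        for t in ontology.terms
    ]
    return Ontology(terms=terms, provenance=dict(ontology.provenance))


def enrich(
    ensemble: EnsembleModel,
    simple_ontology: Ontology,
    lexicon: SemanticLexicon,
    corpus: TokenizedCorpus,
    decisions: Mapping[str, str],
    domain_assignments: Mapping[str, Iterable[str]],
    triggers: Optional[TriggerLexicon] = None,
    percentile: float = 0.963,
    min_fraction: float = 0.0024,
    min_resolvable_share: float = 0.8,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> Tuple[Ontology, List[CandidateTerm]]:
    """Run the full filter pipeline in order and return the validated
    ontology plus the retrieved-candidate log (with filter traces)."""
    retrieved = retrieve_candidates(
        ensemble, simple_ontology, percentile=percentile, n_pairs=n_pairs, seed=seed
    )
    stage = apply_supertype_filter(retrieved, lexicon)
    stage = apply_frequency_filter(stage, corpus, min_fraction)
    stage = apply_directionality_filter(
        stage, corpus.sentences, triggers, min_resolvable_share
    )
    enriched = apply_expert_review(stage, decisions, domain_assignments, simple_ontology)
    enriched = resolve_lexical_consistency(enriched, mode="union")
    return enriched, retrieved
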