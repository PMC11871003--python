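"""Enrichment filter pipeline against brute-force oracles."""

import numpy as np
import pytest

import dismol as dm
from dismol.context_directionality import (
    IMPAIRMENT_WHEN_ASSERTED,
    Ontology,
    OntologyTerm,
    TriggerLexicon,
)
from dismol.corpus_prep import SemanticLexicon, TokenizedCorpus
from dismol.ontology_enrichment import (
    CandidateTerm,
    apply_directionality_filter,
    apply_expert_review,
    apply_frequency_filter,
    apply_supertype_filter,
    check_lexical_consistency,
    min_patient_count,
    pairwise_distance_threshold,
    resolve_lexical_consistency,
    retrieve_candidates,
)
from dismol.seedpair_metric import nearest_rank


def _cand(token, dist=0.1, seeds=("fatigue",)):
    return CandidateTerm(token=token, source_seeds=list(seeds), ensemble_dist=dist)


class TestPercentileRetrieval:
    def test_quantile_threshold_on_synthetic_distribution(self):
        """Distance sample {0.01k : k=1..1000}: keeping the closest 3.7%
        puts the nearest-rank cutoff at 0.37."""
        dists = np.sort(np.arange(1, 1001) * 0.01)
        assert nearest_rank(dists, 1 - 0.963) == pytest.approx(0.37)

    def test_bad_percentile_rejected(self, small_ensemble):
        seeds = dm.default_seed_ontology()
        with pytest.raises(ValueError, match="percentile"):
            retrieve_candidates(small_ensemble, seeds, percentile=1.2)

    def test_candidates_match_brute_force_and_dedup(self, small_ensemble):
        """Retrieved set equals an independent recomputation: for every
        (seed, token) pair, keep tokens strictly below the pairwise
        threshold; duplicates keep the minimal distance and all seeds."""
        seeds = dm.default_seed_ontology()
        got = retrieve_candidates(small_ensemble, seeds, seed=0)
        thr = pairwise_distance_threshold(small_ensemble, seed=0)
        seed_surfaces = {t.surface for t in seeds.terms}
        expected = {}
        for term in seeds.terms:
            if term.surface not in small_ensemble.shared_vocabulary:
                continue
            for tok in small_ensemble.shared_vocabulary:
                if tok in seed_surfaces:
                    continue
                d = small_ensemble.distance(term.surface, tok)
                if d < thr:
                    prev = expected.get(tok)
                    if prev is None or d < prev[0]:
                        expected[tok] = (d, prev[1] | {term.surface} if prev else {term.surface})
                    else:
                        expected[tok] = (prev[0], prev[1] | {term.surface})
        assert {c.token for c in got} == set(expected)
        for c in got:
            assert c.ensemble_dist == pytest.approx(expected[c.token][0])
            assert set(c.source_seeds) == expected[c.token][1]

    def test_seed_never_its_own_candidate(self, small_ensemble):
        got = retrieve_candidates(small_ensemble, dm.default_seed_ontology(), seed=0)
        seeds = {t.surface for t in dm.default_seed_ontology().terms}
        assert not seeds & {c.token for c in got}


class TestSupertypeFilter:
    def test_matches_brute_force_lexicon_scan(self):
        lex = SemanticLexicon(
            {f"t{i}": ("s", i % 3 == 0) for i in range(100)}
        )
        cands = [_cand(f"t{i}") for i in range(100)] + [_cand("unlisted")]
        kept = apply_supertype_filter(cands, lex)
        assert {c.token for c in kept} == {f"t{i}" for i in range(0, 100, 3)}

    def test_unknown_token_dropped(self):
        kept = apply_supertype_filter([_cand("mystery")], SemanticLexicon({}))
        assert kept == []


class TestFrequencyFilter:
    def test_large_cohort_boundary(self):
        """At the 82,672-patient denominator the 0.24% rule needs
        ceil(198.41) = 199 patients."""
        assert min_patient_count(82_672, 0.0024) == 199

    def test_boundary_kept_and_below_dropped(self):
        corpus = TokenizedCorpus(
            sentences=[],
            token_stats={"at_cut": (500, 199), "below": (500, 198), "zero": (1, 0)},
            n_patients_total=82_672,
        )
        kept = apply_frequency_filter(
            [_cand("at_cut"), _cand("below"), _cand("zero")], corpus
        )
        assert [c.token for c in kept] == ["at_cut"]

    def test_zero_patient_denominator_rejected(self):
        corpus = TokenizedCorpus(sentences=[], token_stats={}, n_patients_total=0)
        with pytest.raises(ValueError):
            apply_frequency_filter([_cand("x")], corpus)


class TestDirectionalityFilter:
    def test_matches_per_candidate_oracle(self):
        """Retained set equals per-token clarity evaluation on a small
        hand-made note sample."""
        sents = (
            [["reports", "clearword"]] * 8
            + [["if", "vagueword"]] * 8 + [["vagueword", "seen"]] * 2
            + [["denies", "negword"]] * 5
        )
        cands = [_cand("clearword"), _cand("vagueword"), _cand("negword")]
        kept = apply_directionality_filter(cands, sents)
        expected = []
        for c in ("clearword", "vagueword", "negword"):
            clear, _ = dm.has_clear_directionality(
                c, sents, TriggerLexicon.default()
            )
            if clear:
                expected.append(c)
        assert [c.token for c in kept] == expected
        assert "vagueword" not in {c.token for c in kept}  # 0.2 resolvable

    def test_hypothetical_only_candidate_dropped(self):
        sents = [["if", "maybeword", "returns"]] * 5
        kept = apply_directionality_filter([_cand("maybeword")], sents)
        assert kept == []


class TestExpertReview:
    def test_accept_subset(self):
        seeds = dm.default_seed_ontology()
        cands = [_cand("weariness"), _cand("blurword")]
        decisions = {"weariness": "accepted", "blurword": "rejected"}
        domains = {"weariness": ("physical",)}
        ont = apply_expert_review(cands, decisions, domains, seeds)
        assert "weariness" in ont.surfaces() and "blurword" not in ont.surfaces()
        assert len(ont.terms) == len(seeds.terms) + 1
        assert ont.provenance["weariness"]["source_seeds"] == ["fatigue"]

    def test_all_rejected_leaves_seeds_only(self):
        seeds = dm.default_seed_ontology()
        ont = apply_expert_review(
            [_cand("x")], {"x": "rejected"}, {}, seeds
        )
        assert ont.surfaces() == seeds.surfaces()

    def test_missing_decision_is_error_listing_tokens(self):
        with pytest.raises(ValueError, match="orphan"):
            apply_expert_review([_cand("orphan")], {}, {}, dm.default_seed_ontology())

    def test_accepted_without_domains_is_error(self):
        with pytest.raises(ValueError, match="domain"):
            apply_expert_review(
                [_cand("x")], {"x": "accepted"}, {}, dm.default_seed_ontology()
            )

    def test_multi_domain_acceptance(self):
        ont = apply_expert_review(
            [_cand("bleary")],
            {"bleary": "accepted"},
            {"bleary": ("physical", "cognition")},
            dm.default_seed_ontology(),
        )
        term = next(t for t in ont.terms if t.surface == "bleary")
        assert term.domains == frozenset({"physical", "cognition"})


class TestLexicalConsistency:
    def _ont(self):
        A = IMPAIRMENT_WHEN_ASSERTED
        return Ontology(terms=[
            OntologyTerm("fatigue", frozenset({"physical"}), A),
            OntologyTerm(
                "fatigued", frozenset({"physical", "cognition", "emotional"}), A
            ),
            OntologyTerm("mood", frozenset({"emotional"}), A),
        ])

    def test_same_lemma_different_domains_is_violation(self):
        violations = check_lexical_consistency(self._ont())
        assert len(violations) == 1
        (_, members), = violations
        assert set(members) == {"fatigue", "fatigued"}

    def test_union_resolution_aligns_domains(self):
        fixed = resolve_lexical_consistency(self._ont(), mode="union")
        assert check_lexical_consistency(fixed) == []
        doms = {t.surface: t.domains for t in fixed.terms}
        assert doms["fatigue"] == doms["fatigued"] == frozenset(
            {"physical", "cognition", "emotional"}
        )

    def test_unique_lemmas_no_violation(self):
        assert check_lexical_consistency(dm.default_seed_ontology()) == []

    def test_matches_brute_force_grouping(self):
        """Violation list equals a direct group-by-lemma recomputation on a
        20-term ontology."""
        A = IMPAIRMENT_WHEN_ASSERTED
        rng = np.random.default_rng(3)
        bases = ["alpha", "beta", "gamma", "delta", "epsilon"]
        forms = []
        for b in bases:
            forms += [b, b + "s", b + "ed", b + "ing"]
        doms = [
            frozenset({["physical", "cognition", "emotional"][rng.integers(3)]})
            for _ in forms
        ]
        ont = Ontology(terms=[OntologyTerm(f, d, A) for f, d in zip(forms, doms)])
        got = {key for key, _ in check_lexical_consistency(ont)}
        groups = {}
        for t in ont.terms:
            groups.setdefault(t.lemma_key, set()).add(t.domains)
        expected = {k for k, v in groups.items() if len(v) > 1}
        assert got == expected


class TestFullPipelineOnPlantedBundle:
    def test_planted_synonyms_survive_to_review(
        self, small_ensemble, model_bundle, model_corpus, model_config
    ):
        """Every planted synonym reaches the expert-review stage; accepting
        exactly the planted set reproduces the planted ontology's surfaces."""
        planted = sorted(
            {s for syns in model_config.planted_synonym_map.values() for s in syns}
        )
        cands = retrieve_candidates(small_ensemble, model_bundle.seed_ontology, seed=0)
        stage = apply_supertype_filter(cands, model_bundle.semantic_lexicon)
        stage = apply_frequency_filter(stage, model_corpus)
        stage = apply_directionality_filter(stage, model_corpus.sentences)
        surviving = {c.token for c in stage}
        assert set(planted) <= surviving
        # each stage shrinks (or keeps) its input
        assert len(cands) >= len(surviving)
        decisions = {
            c.token: ("accepted" if c.token in planted else "rejected")
            for c in stage
        }
        domains = {
            syn: sorted(
                next(t for t in model_bundle.seed_ontology.terms if t.surface == seed).domains
            )
            for seed, syns in model_config.planted_synonym_map.items()
            for syn in syns
        }
        ont = apply_expert_review(stage, decisions, domains, model_bundle.seed_ontology)
        expected = set(dm.planted_ontology(model_config).surfaces())
        assert set(ont.surfaces()) == expected
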