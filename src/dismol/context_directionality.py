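"""Trigger/scope directionality for symptom mentions, ConText-style.

Clinical notes assert, deny, hypothesise and attribute symptoms; counting a
raw string match as a symptom occurrence badly over-counts. This module
implements a rule-based contextual-modifier algorithm in the ConText family:
trigger phrases (negation, pseudo-negation, hypothetical, historical, family,
termination) project a scope over neighbouring tokens within a sentence, and
a term mention inside a scope carries the trigger's category as a modifier.

It also owns the ontology data model (terms with surface form, lemma key,
domain memberships and polarity) and the polarity logic that decides when a
modified mention counts as a confirmed daytime-impairment event: most symptom
terms are an impairment when asserted ("reports fatigue"), but a positive
state term such as "happy" is an impairment precisely when negated ("not
being happy").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .corpus_prep import lemma, sentences

logger = logging.getLogger(__name__)

DOMAINS: Tuple[str, ...] = ("cognition", "emotional", "physical")

CATEGORIES = (
    "negation",
    "pseudo_negation",
    "hypothetical",
    "historical",
    "family",
    "termination",
)

#: Polarity values for ontology terms.
IMPAIRMENT_WHEN_ASSERTED = "impairment_when_asserted"
IMPAIRMENT_WHEN_NEGATED = "impairment_when_negated"


@dataclass(frozen=True)
class OntologyTerm:
    """A symptom term: surface form, lemma key, domains and polarity."""

    surface: str
    domains: FrozenSet[str]
    polarity: str = IMPAIRMENT_WHEN_ASSERTED
    lemma_key: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.domains:
            raise ValueError(f"term {self.surface!r}: domains must be non-empty")
        bad = set(self.domains) - set(DOMAINS)
        if bad:
            raise ValueError(f"term {self.surface!r}: unknown domains {sorted(bad)}")
        if self.polarity not in (IMPAIRMENT_WHEN_ASSERTED, IMPAIRMENT_WHEN_NEGATED):
            raise ValueError(f"term {self.surface!r}: bad polarity {self.polarity!r}")
        if not self.lemma_key:
            object.__setattr__(
                self, "lemma_key", tuple(lemma(t) for t in self.surface.split())
            )

    @property
    def tokens(self) -> Tuple[str, ...]:
        return tuple(self.surface.split())


@dataclass
class Ontology:
    """A collection of :class:`OntologyTerm` with optional provenance."""

    terms: List[OntologyTerm]
    provenance: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for t in self.terms:
            if t.surface in seen:
                raise ValueError(f"duplicate term surface {t.surface!r}")
            seen.add(t.surface)

    def surfaces(self) -> List[str]:
        return [t.surface for t in self.terms]

    def by_domain(self, domain: str) -> List[OntologyTerm]:
        return [t for t in self.terms if domain in t.domains]

    def to_json(self, path) -> None:
        payload = {
            "terms": [
                {
                    "surface": t.surface,
                    "lemma": list(t.lemma_key),
                    "domains": sorted(t.domains),
                    "polarity": t.polarity,
                    "provenance": self.provenance.get(t.surface, {}),
                }
                for t in self.terms
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Ontology":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        terms, prov = [], {}
        for row in payload["terms"]:
            terms.append(
                OntologyTerm(
                    surface=row["surface"],
                    domains=frozenset(row["domains"]),
                    polarity=row["polarity"],
                    lemma_key=tuple(row.get("lemma") or ()),
                )
            )
            if row.get("provenance"):
                prov[row["surface"]] = row["provenance"]
        return cls(terms=terms, provenance=prov)


@dataclass(frozen=True)
class Trigger:
    phrase: str
    category: str
    direction: str  # forward | backward | bidirectional
    max_scope: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"trigger {self.phrase!r}: bad category {self.category!r}")
        if self.direction not in ("forward", "backward", "bidirectional"):
            raise ValueError(f"trigger {self.phrase!r}: bad direction {self.direction!r}")

    @property
    def tokens(self) -> Tuple[str, ...]:
        return tuple(self.phrase.split())


# Compact default trigger set modelled on the published ConText categories.
# max_scope counts tokens beyond the trigger; 0 means "to sentence boundary".
_DEFAULT_TRIGGERS: List[Tuple[str, str, str, int]] = [
    # negation, forward
    ("no", "negation", "forward", 5),
    ("not", "negation", "forward", 5),
    ("denies", "negation", "forward", 6),
    ("denied", "negation", "forward", 6),
    ("denying", "negation", "forward", 6),
    ("without", "negation", "forward", 5),
    ("absence of", "negation", "forward", 5),
    ("negative for", "negation", "forward", 6),
    ("free of", "negation", "forward", 5),
    ("never developed", "negation", "forward", 5),
    ("no evidence of", "negation", "forward", 6),
    ("no sign of", "negation", "forward", 6),
    ("no complaints of", "negation", "forward", 6),
    ("rules out", "negation", "forward", 5),
    ("ruled out", "negation", "forward", 5),
    ("cannot", "negation", "forward", 5),
    ("resolved", "negation", "backward", 5),
    # negation, backward
    ("was ruled out", "negation", "backward", 5),
    ("is ruled out", "negation", "backward", 5),
    ("unlikely", "negation", "backward", 5),
    # pseudo-negation: looks like negation, is not
    ("no increase", "pseudo_negation", "forward", 0),
    ("no change", "pseudo_negation", "forward", 0),
    ("not only", "pseudo_negation", "forward", 0),
    ("not cause", "pseudo_negation", "forward", 0),
    ("not certain if", "pseudo_negation", "forward", 0),
    ("gram negative", "pseudo_negation", "forward", 0),
    # hypothetical
    ("if", "hypothetical", "forward", 8),
    ("return if", "hypothetical", "forward", 8),
    ("should", "hypothetical", "forward", 6),
    ("could", "hypothetical", "forward", 6),
    ("risk of", "hypothetical", "forward", 6),
    ("possible", "hypothetical", "forward", 5),
    ("possibly", "hypothetical", "forward", 5),
    ("in case", "hypothetical", "forward", 8),
    ("watch for", "hypothetical", "forward", 8),
    ("may develop", "hypothetical", "forward", 6),
    # historical
    ("history of", "historical", "forward", 6),
    ("previous", "historical", "forward", 5),
    ("previously", "historical", "forward", 5),
    ("in the past", "historical", "backward", 6),
    ("years ago", "historical", "backward", 6),
    # family
    ("family history of", "family", "forward", 6),
    ("mother", "family", "forward", 5),
    ("father", "family", "forward", 5),
    ("sister", "family", "forward", 5),
    ("brother", "family", "forward", 5),
    ("aunt", "family", "forward", 5),
    ("uncle", "family", "forward", 5),
    ("grandmother", "family", "forward", 5),
    ("grandfather", "family", "forward", 5),
    # termination: ends any open scope
    ("but", "termination", "bidirectional", 0),
    ("however", "termination", "bidirectional", 0),
    ("although", "termination", "bidirectional", 0),
    ("though", "termination", "bidirectional", 0),
    ("aside from", "termination", "bidirectional", 0),
    ("except", "termination", "bidirectional", 0),
    ("apart from", "termination", "bidirectional", 0),
    ("still", "termination", "bidirectional", 0),
    ("yet", "termination", "bidirectional", 0),
    ("which", "termination", "bidirectional", 0),
    ("who", "termination", "bidirectional", 0),
]


@dataclass
class TriggerLexicon:
    """Phrase -> (category, direction, max_scope) lookup, longest-match-first."""

    triggers: List[Trigger]

    @classmethod
    def default(cls) -> "TriggerLexicon":
        return cls([Trigger(*row) for row in _DEFAULT_TRIGGERS])

    @classmethod
    def from_tsv(cls, path) -> "TriggerLexicon":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                    )
                phrase, cat, direction, scope = parts
                rows.append(Trigger(phrase, cat, direction, int(scope)))
        return cls(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.triggers:
                fh.write(f"{t.phrase}\t{t.category}\t{t.direction}\t{t.max_scope}\n")


@dataclass
class TermMention:
    """A matched ontology term within one sentence of one section."""

    term: OntologyTerm
    token_span: Tuple[int, int]  # 0-based half-open within the sentence
    encounter_id: Optional[str] = None
    section_name: Optional[str] = None
    modifiers: Set[str] = field(default_factory=set)

    def __post_init__(self):
        start, end = self.token_span
        if not start < end:
            raise ValueError(f"empty span {self.token_span}")


def _ngram_index(ontology: Ontology):
    """(surface n-gram -> term, lemma n-gram -> term, max phrase length)."""
    by_surface: Dict[Tuple[str, ...], OntologyTerm] = {}
    by_lemma: Dict[Tuple[str, ...], OntologyTerm] = {}
    max_len = 1
    for term in ontology.terms:
        toks = term.tokens
        by_surface.setdefault(toks, term)
        by_lemma.setdefault(term.lemma_key, term)
        max_len = max(max_len, len(toks))
    return by_surface, by_lemma, max_len


def match_terms(tokens: Sequence[str], ontology: Ontology) -> List[TermMention]:
    """Longest-first, non-overlapping term matching on surface or lemma key."""
    by_surface, by_lemma, max_len = _ngram_index(ontology)
    lemmas = [lemma(t) for t in tokens]
    mentions: List[TermMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for width in range(min(max_len, n - i), 0, -1):
            gram = tuple(tokens[i : i + width])
            term = by_surface.get(gram)
            if term is None:
                term = by_lemma.get(tuple(lemmas[i : i + width]))
            if term is not None:
                hit = TermMention(term=term, token_span=(i, i + width))
                break
        if hit is not None:
            mentions.append(hit)
            i = hit.token_span[1]
        else:
            i += 1
    return mentions


def _find_triggers(tokens: Sequence[str], lexicon: TriggerLexicon):
    """Non-overlapping trigger matches, longest phrase first.

    A pseudo-negation match claims its tokens before any shorter negation
    trigger can, which is exactly the suppression rule: within a tie on
    length, pseudo-negation wins.
    """
    order = sorted(
        lexicon.triggers,
        key=lambda t: (-len(t.tokens), 0 if t.category == "pseudo_negation" else 1),
    )
    claimed = [False] * len(tokens)
    found = []  # (start, end, Trigger)
    for trig in order:
        w = len(trig.tokens)
        for i in range(0, len(tokens) - w + 1):
            if tuple(tokens[i : i + w]) == trig.tokens and not any(claimed[i : i + w]):
                for j in range(i, i + w):
                    claimed[j] = True
                found.append((i, i + w, trig))
    found.sort(key=lambda x: x[0])
    return found


def _scopes(tokens: Sequence[str], lexicon: TriggerLexicon):
    """Yield (category, scope_start, scope_end) half-open token ranges."""
    found = _find_triggers(tokens, lexicon)
    terminators = [(s, e) for s, e, t in found if t.category == "termination"]
    out = []
    n = len(tokens)
    for s, e, trig in found:
        if trig.category in ("termination", "pseudo_negation"):
            continue
        ranges = []
        if trig.direction in ("forward", "bidirectional"):
            end = n if trig.max_scope == 0 else min(n, e + trig.max_scope)
            for ts, _ in terminators:
                if e <= ts < end:
                    end = ts
                    break
            ranges.append((e, end))
        if trig.direction in ("backward", "bidirectional"):
            start = 0 if trig.max_scope == 0 else max(0, s - trig.max_scope)
            for _, te in reversed(terminators):
                if start < te <= s:
                    start = te
                    break
            ranges.append((start, s))
        for a, b in ranges:
            if a < b:
                out.append((trig.category, a, b))
    return out


def apply_modifiers(
    tokens: Sequence[str],
    mentions: Iterable[TermMention],
    lexicon: TriggerLexicon,
) -> List[TermMention]:
    """Fill each mention's ``modifiers`` from trigger scopes in its sentence.

    A mention is modified when its span overlaps a trigger's scope; scopes
    run up to ``max_scope`` tokens (0 = sentence boundary) and are cut short
    by the first termination trigger in their direction. Pure function of
    (tokens, lexicon); scopes never cross the sentence.
    """
    scope_list = _scopes(tokens, lexicon)
    out = []
    for m in mentions:
        ms, me = m.token_span
        mods = {
            cat for cat, a, b in scope_list if ms < b and a < me
        }
        m.modifiers = mods
        out.append(m)
    return out


def confirm_event(mention: TermMention, count_historical: bool = True) -> bool:
    """Decide whether a modifier-resolved mention is a confirmed impairment.

    Confirmed iff the term's polarity agrees with its negation status:
    an ``impairment_when_asserted`` term must not be negated, an
    ``impairment_when_negated`` term (the "happy" pattern) must be.
    Hypothetical and family-attributed mentions are never confirmed.
    Historical mentions count by default — history is handled upstream by
    dropping the past-medical-history section, not by the modifier.
    """
    mods = mention.modifiers
    if "hypothetical" in mods or "family" in mods:
        return False
    if not count_historical and "historical" in mods:
        return False
    negated = "negation" in mods
    if mention.term.polarity == IMPAIRMENT_WHEN_NEGATED:
        return negated
    return not negated


def has_clear_directionality(
    token: str,
    sample_sentences: Iterable[Sequence[str]],
    lexicon: TriggerLexicon,
    min_resolvable_share: float = 0.8,
) -> Tuple[bool, Dict[str, int]]:
    """Check whether a token's uses resolve to asserted/negated often enough.

    Each occurrence is classified: ambiguous if inside a hypothetical or
    family scope, negated if inside a negation scope, else asserted. The
    token has clear directionality when the resolvable (asserted + negated)
    share of its occurrences is at least ``min_resolvable_share``.
    """
    counts = {"asserted": 0, "negated": 0, "ambiguous": 0}
    for sent in sample_sentences:
        positions = [i for i, t in enumerate(sent) if t == token]
        if not positions:
            continue
        scope_list = _scopes(sent, lexicon)
        for i in positions:
            cats = {cat for cat, a, b in scope_list if a <= i < b}
            if "hypothetical" in cats or "family" in cats:
                counts["ambiguous"] += 1
            elif "negation" in cats:
                counts["negated"] += 1
            else:
                counts["asserted"] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"token {token!r} has zero occurrences in the sample")
    share = (counts["asserted"] + counts["negated"]) / total
    return share >= min_resolvable_share, counts
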