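"""Note-section filtering, tokenization, lemma keys and patient-frequency stats.

This module defines the corpus contract consumed by the embedding trainer and
by the patient-frequency enrichment filter: physician notes are reduced to the
five clinically current section types, split into lowercase word-token
sentences, and summarised into per-token counts with a distinct-patient
denominator.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

logger = logging.getLogger(__name__)

#: The section types retained for modelling, in canonical order. Past medical
#: history is deliberately absent: it records conditions that may predate and
#: be unrelated to the disorder under study.
RETAINED_SECTIONS: Tuple[str, ...] = (
    "chief_complaint",
    "review_of_systems",
    "physical_exam",
    "assessment",
    "history_of_present_illness",
)

#: All section names a well-formed encounter may carry.
KNOWN_SECTIONS: Tuple[str, ...] = RETAINED_SECTIONS + ("past_medical_history",)

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
_TOKEN = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def select_sections(encounter):
    """Return a copy of ``encounter`` keeping only the five retained sections.

    Section order is preserved; ``past_medical_history`` is dropped silently
    (it is a known section, excluded by design) and unknown section names are
    dropped with a warning. Idempotent.
    """
    kept = []
    for name, text in encounter.sections:
        if name in RETAINED_SECTIONS:
            kept.append((name, text))
        elif name not in KNOWN_SECTIONS:
            logger.warning(
                "encounter %s: dropping unknown section %r",
                encounter.encounter_id, name,
            )
    return replace(encounter, sections=tuple(kept))


def sentences(text: str) -> List[List[str]]:
    """Split ``text`` into sentences of lowercase word tokens.

    Sentences break on terminal punctuation (``.``, ``!``, ``?``); tokens are
    runs of lowercase letters/digits, with internal hyphens kept.
    """
    out = []
    for raw in _SENTENCE_SPLIT.split(text.lower()):
        toks = _TOKEN.findall(raw)
        if toks:
            out.append(toks)
    return out


def tokenize(text: str) -> List[str]:
    """Flat lowercase token sequence of ``text`` (sentence structure dropped)."""
    return [t for sent in sentences(text) for t in sent]


# Irregulars that the suffix rules would mishandle. The lemma is a grouping
# key, not a display form, so keys need not be dictionary words.
_LEMMA_EXCEPTIONS: Dict[str, str] = {
    "worse": "bad",
    "worst": "bad",
    "better": "good",
    "best": "good",
    "felt": "feel",
    "slept": "sleep",
    "woke": "wake",
    "was": "be",
    "were": "be",
    "is": "be",
    "are": "be",
    "been": "be",
}

_DOUBLED = re.compile(r"([b-df-hj-np-tv-z])\1$")


def _undouble(stem: str) -> str:
    return _DOUBLED.sub(r"\1", stem)


def _strip_once(t: str) -> str:
    if len(t) >= 5 and t.endswith("ies"):
        t = t[:-3] + "y"
    elif len(t) >= 5 and t.endswith("ing"):
        t = _undouble(t[:-3])
        if t.endswith("i"):
            t = t[:-1] + "y"  # "tidying" family joins the -ies/-ied key
    elif len(t) >= 5 and t.endswith("ed"):
        t = _undouble(t[:-2])
        if t.endswith("i"):
            t = t[:-1] + "y"  # "denied" -> "deny"
    elif len(t) >= 5 and t.endswith("es"):
        t = t[:-2]
    elif len(t) >= 4 and t.endswith("s") and not t.endswith("ss"):
        t = t[:-1]
    if len(t) >= 4 and t.endswith("e"):
        t = t[:-1]
    return t


def lemma(token: str) -> str:
    """Rule-based lemma key: suffix stripping over a small exception table.

    Deterministic and idempotent (the suffix rules are iterated to a
    fixpoint); same-lemma inflections ("fatigue", "fatigued", "fatigues")
    map to one key. The key is a grouping label, not a display form — a
    trailing silent ``e`` is stripped so ``-ed`` forms land on the same key
    as their base.
    """
    t = token.lower()
    if t in _LEMMA_EXCEPTIONS:
        t = _LEMMA_EXCEPTIONS[t]
    while True:
        nxt = _strip_once(t)
        if nxt == t:
            return t
        t = nxt


@dataclass
class TokenizedCorpus:
    """Sentence-level corpus plus per-token patient-frequency statistics.

    ``token_stats`` maps token -> (total occurrence count, number of distinct
    patients whose retained note sections contain the token at least once);
    ``n_patients_total`` is the denominator for patient-frequency filters.
    """

    sentences: List[List[str]]
    token_stats: Dict[str, Tuple[int, int]]
    n_patients_total: int

    def n_patients_with(self, token: str) -> int:
        return self.token_stats.get(token, (0, 0))[1]

    def total_count(self, token: str) -> int:
        return self.token_stats.get(token, (0, 0))[0]


def corpus_stats(encounters: Iterable) -> TokenizedCorpus:
    """Build a :class:`TokenizedCorpus` from section-filtered encounters.

    Every sentence of every retained section contributes to ``sentences``;
    the distinct-patient count for a token counts patients, not encounters.
    """
    all_sentences: List[List[str]] = []
    totals: Counter = Counter()
    patients_with: Dict[str, set] = {}
    patient_ids = set()
    for enc in encounters:
        patient_ids.add(enc.patient_id)
        for _, text in enc.sections:
            for sent in sentences(text):
                all_sentences.append(sent)
                for tok in sent:
                    totals[tok] += 1
                    patients_with.setdefault(tok, set()).add(enc.patient_id)
    stats = {
        tok: (totals[tok], len(patients_with[tok])) for tok in totals
    }
    return TokenizedCorpus(
        sentences=all_sentences,
        token_stats=stats,
        n_patients_total=len(patient_ids),
    )


UNKNOWN_SEMANTIC_TYPE = "unknown"


@dataclass
class SemanticLexicon:
    """Token -> (semantic type, daytime-impairment supertype flag) lookup.

    Unlisted tokens resolve to the designated ``unknown`` type with the
    supertype flag off, so lexicon coverage gaps fail closed.
    """

    entries: Dict[str, Tuple[str, bool]] = field(default_factory=dict)

    def semantic_type(self, token: str) -> str:
        return self.entries.get(token, (UNKNOWN_SEMANTIC_TYPE, False))[0]

    def is_supertype(self, token: str) -> bool:
        return self.entries.get(token, (UNKNOWN_SEMANTIC_TYPE, False))[1]

    def supertype_tokens(self) -> List[str]:
        return sorted(t for t, (_, flag) in self.entries.items() if flag)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok in sorted(self.entries):
                st, flag = self.entries[tok]
                fh.write(f"{tok}\t{st}\t{'1' if flag else '0'}\n")

    @classmethod
    def from_tsv(cls, path) -> "SemanticLexicon":
        entries: Dict[str, Tuple[str, bool]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 tab-separated "
                        f"fields, got {len(parts)}"
                    )
                tok, st, flag = parts
                entries[tok] = (st, flag == "1")
        return cls(entries=entries)
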