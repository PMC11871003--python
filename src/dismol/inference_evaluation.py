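"""Encounter-level impairment inference, ICD baselines and accuracy scoring.

The validated ontology is applied to each encounter's retained note sections;
a domain is flagged present when at least one directionality-confirmed term
mention occurs in it (the number of mentions does not change the flag, but
every confirmed event is kept for downstream rate counting). Two ICD-10
baselines flag an encounter from same-day claims through editable
domain->code maps. Predictions are scored against gold annotations with
sensitivity, precision and F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .context_directionality import (
    DOMAINS,
    Ontology,
    TriggerLexicon,
    apply_modifiers,
    confirm_event,
    match_terms,
)
from .corpus_prep import select_sections, sentences

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SymptomEvent:
    """One confirmed term hit at one encounter."""

    encounter_id: str
    patient_id: str
    date: object  # datetime.date
    term_surface: str
    domains: FrozenSet[str]
    section_name: str


@dataclass
class EncounterImpairment:
    encounter_id: str
    patient_id: str
    date: object
    per_domain: Dict[str, bool]
    confirmed_events: List[SymptomEvent] = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return any(self.per_domain.values())


def infer_encounters(
    encounters: Iterable,
    ontology: Ontology,
    triggers: Optional[TriggerLexicon] = None,
    count_historical: bool = True,
) -> List[EncounterImpairment]:
    """One :class:`EncounterImpairment` per encounter, from confirmed events."""
    if triggers is None:
        triggers = TriggerLexicon.default()
    out = []
    for enc in encounters:
        enc = select_sections(enc)
        events: List[SymptomEvent] = []
        for section_name, text in enc.sections:
            for sent in sentences(text):
                mentions = match_terms(sent, ontology)
                if not mentions:
                    continue
                for m in apply_modifiers(sent, mentions, triggers):
                    if confirm_event(m, count_historical=count_historical):
                        events.append(
                            SymptomEvent(
                                encounter_id=enc.encounter_id,
                                patient_id=enc.patient_id,
                                date=enc.date,
                                term_surface=m.term.surface,
                                domains=m.term.domains,
                                section_name=section_name,
                            )
                        )
        flags = {
            d: any(d in ev.domains for ev in events) for d in DOMAINS
        }
        out.append(
            EncounterImpairment(
                encounter_id=enc.encounter_id,
                patient_id=enc.patient_id,
                date=enc.date,
                per_domain=flags,
                confirmed_events=events,
            )
        )
    return out


@dataclass
class IcdRepresentation:
    """A named domain -> ICD-10 code-set map; codes match prefix-aware."""

    name: str
    code_map: Mapping[str, Sequence[str]]

    def __post_init__(self):
        for d, codes in self.code_map.items():
            if not codes:
                raise ValueError(f"{self.name}: empty code set for domain {d!r}")

    def matches(self, domain: str, claim_code: str) -> bool:
        if domain not in self.code_map:
            raise KeyError(f"{self.name}: domain {domain!r} not mapped")
        for code in self.code_map[domain]:
            if claim_code == code or claim_code.startswith(code):
                return True
        return False


# Default expert-style code sets for the synthetic study. ICD-clin is the
# narrow expert selection; ICD-clin-DiSMOL widens each domain with codes
# matched to ontology-derived symptoms, so it covers a superset.
ICD_CLIN = {
    "cognition": ("R41.3",),
    "emotional": ("F32.9",),
    "physical": ("R53.83",),
}
ICD_CLIN_DISMOL = {
    "cognition": ("R41.3", "R41.84", "R41.0"),
    "emotional": ("F32.9", "F41.9", "F43.2"),
    "physical": ("R53.83", "R53.1", "R53.0", "M62.81"),
}


def icd_clin() -> IcdRepresentation:
    return IcdRepresentation("ICD-clin", ICD_CLIN)


def icd_clin_dismol() -> IcdRepresentation:
    return IcdRepresentation("ICD-clin-DiSMOL", ICD_CLIN_DISMOL)


def icd_flags(
    claims: Iterable,
    representation: IcdRepresentation,
    encounters: Iterable,
) -> List[EncounterImpairment]:
    """Flag each encounter's domains from same-patient same-day claims.

    A domain is present iff the patient has a claim on the encounter date
    whose code prefix-matches the domain's code set; each matching claim is
    recorded as one event (so ICD representations can feed rate counting).
    """
    by_patient_date: Dict[Tuple[str, object], List[str]] = {}
    for c in claims:
        by_patient_date.setdefault((c.patient_id, c.date), []).append(c.code)
    out = []
    for enc in encounters:
        codes = by_patient_date.get((enc.patient_id, enc.date), [])
        events: List[SymptomEvent] = []
        flags = {}
        for d in representation.code_map:
            hit_codes = [c for c in codes if representation.matches(d, c)]
            flags[d] = bool(hit_codes)
            for code in hit_codes:
                events.append(
                    SymptomEvent(
                        encounter_id=enc.encounter_id,
                        patient_id=enc.patient_id,
                        date=enc.date,
                        term_surface=code,
                        domains=frozenset((d,)),
                        section_name="claims",
                    )
                )
        out.append(
            EncounterImpairment(
                encounter_id=enc.encounter_id,
                patient_id=enc.patient_id,
                date=enc.date,
                per_domain=flags,
                confirmed_events=events,
            )
        )
    return out


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ScoreResult:
    counts: ConfusionCounts
    sensitivity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def f1_score(precision: Optional[float], sensitivity: Optional[float]) -> Optional[float]:
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        return None
    return 2 * precision * sensitivity / (precision + sensitivity)


def score(
    predictions: Mapping[object, bool],
    gold: Mapping[object, bool],
) -> ScoreResult:
    """Confusion counts plus sensitivity/precision/F1 over matching units.

    ``predictions`` and ``gold`` map the same unit keys (encounter id, or
    (encounter id, domain) pairs) to booleans. Zero-denominator ratios are
    reported as ``None`` (undefined), never as 0.
    """
    if set(predictions) != set(gold):
        missing = set(gold) ^ set(predictions)
        raise ValueError(
            f"predictions and gold cover different units ({len(missing)} mismatched)"
        )
    c = ConfusionCounts()
    for unit, truth in gold.items():
        pred = predictions[unit]
        if pred and truth:
            c.tp += 1
        elif pred and not truth:
            c.fp += 1
        elif not pred and truth:
            c.fn += 1
        else:
            c.tn += 1
    sens = _safe_div(c.tp, c.tp + c.fn)
    prec = _safe_div(c.tp, c.tp + c.fp)
    return ScoreResult(counts=c, sensitivity=sens, precision=prec, f1=f1_score(prec, sens))


def impairments_to_units(
    impairments: Sequence[EncounterImpairment],
    level: str = "encounter_domain",
) -> Dict[object, bool]:
    """Flatten impairment records to a unit->flag map for :func:`score`."""
    if level == "encounter_overall":
        return {imp.encounter_id: imp.overall for imp in impairments}
    if level == "encounter_domain":
        return {
            (imp.encounter_id, d): flag
            for imp in impairments
            for d, flag in imp.per_domain.items()
        }
    raise ValueError(f"unknown level {level!r}")


def relative_improvement(metric_new: float, metric_old: float) -> float:
    """Percent change of a metric against a baseline: 100*(new-old)/old."""
    if metric_old == 0:
        raise ValueError("baseline metric is zero; relative improvement undefined")
    return 100.0 * (metric_new - metric_old) / metric_old
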