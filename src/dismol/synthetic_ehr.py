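"""Self-contained synthetic EHR bundle generator.

Every downstream stage of the framework (corpus prep, embedding training,
seed-pair evaluation, enrichment filters, directionality inference, ICD
baselines, treatment-effect estimation) is testable offline on bundles built
here. A bundle emulates the seven inputs of the real study feed: sectioned
physician notes, ICD-10 claims, drug dispensings, patient demographics, a
seed symptom ontology over three domains, a token semantic-type lexicon with
a daytime-impairment supertype flag, known-relationship seed pairs, and gold
per-note annotations.

Planted structure, all configurable:

* synonym tokens that co-occur in-sentence with their seed terms, so an
  embedding trained on the corpus places them near the seeds;
* negation / hypothetical trigger patterns at configurable rates;
* a past-medical-history section carrying distractor symptom mentions that
  must be excluded by the section filter;
* claims mixing insomnia diagnoses, domain symptom codes (emitted with a
  deliberately low sensitivity, emulating under-coding), comorbidities and
  exclusion codes;
* dispensings whose drug class multiplies the per-domain symptom emission
  rate after the first dispensing — the planted treatment effect that the
  effect estimator must recover.

Sentence text comes from a small template grammar, not a language model, so
generation is reproducible and fast; the language is schematic by design.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .context_directionality import (
    DOMAINS,
    IMPAIRMENT_WHEN_ASSERTED,
    IMPAIRMENT_WHEN_NEGATED,
    Ontology,
    OntologyTerm,
)
from .corpus_prep import RETAINED_SECTIONS, SemanticLexicon
from .inference_evaluation import ICD_CLIN_DISMOL
from .seedpair_metric import SeedPair, read_seed_pairs, write_seed_pairs

logger = logging.getLogger(__name__)

ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[A-Za-z0-9]{1,4})?$")

#: Fixed drug-name -> class table (closed sets; extensible via config).
DRUG_CLASS_TABLE: Dict[str, str] = {
    "estazolam": "benzodiazepine",
    "flurazepam": "benzodiazepine",
    "lorazepam": "benzodiazepine",
    "quazepam": "benzodiazepine",
    "temazepam": "benzodiazepine",
    "triazolam": "benzodiazepine",
    "eszopiclone": "non_bzra",
    "zaleplon": "non_bzra",
    "zolpidem": "non_bzra",
    "trazodone": "trazodone",
}
DRUG_CLASSES = ("trazodone", "benzodiazepine", "non_bzra")

INSOMNIA_CODES = ("G47.00", "F51.01")
EXCLUSION_CODES: Dict[str, Tuple[str, ...]] = {
    "palliative_care": ("Z51.5",),
    "active_malignancy": ("C34.1", "C50.9"),
    "pregnancy": ("Z33.1", "O09.90"),
}
COMORBIDITY_CODES = ("I10", "E11.9", "F41.1", "F32.1", "E66.9", "J44.9")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_year: int
    sex: str  # F | M


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    patient_id: str
    date: date
    sections: Tuple[Tuple[str, str], ...]  # (section_name, text), ordered


@dataclass(frozen=True)
class ClaimRecord:
    patient_id: str
    date: date
    code: str


@dataclass(frozen=True)
class DispensingRecord:
    patient_id: str
    date: date
    drug_name: str
    drug_class: str


@dataclass(frozen=True)
class GoldAnnotation:
    encounter_id: str
    domain: str
    present: bool


def default_seed_ontology() -> Ontology:
    """Seed ("simple") ontology: 14 item-stem terms over three domains plus
    expert-style synonyms. Item texts are paraphrased stand-ins, not the
    licensed questionnaire wording. ``happy`` and ``energy`` carry negated
    polarity: their absence, not presence, is the impairment.
    """
    A, N = IMPAIRMENT_WHEN_ASSERTED, IMPAIRMENT_WHEN_NEGATED
    items = [
        # 14 item stems
        ("concentration", ("cognition",), A),
        ("memory", ("cognition",), A),
        ("alertness", ("cognition",), A),
        ("attention", ("cognition",), A),
        ("irritability", ("emotional",), A),
        ("mood", ("emotional",), A),
        ("anxious", ("emotional",), A),
        ("tense", ("emotional",), A),
        ("happy", ("emotional",), N),
        ("fatigue", ("physical",), A),
        ("tired", ("physical",), A),
        ("sleepiness", ("physical", "cognition"), A),
        ("drowsy", ("physical",), A),
        ("energy", ("physical",), N),
        # expert synonyms
        ("foggy", ("cognition",), A),
        ("grumpy", ("emotional",), A),
        ("exhaustion", ("physical",), A),
        ("weakness", ("physical",), A),
        ("sluggish", ("physical",), A),
    ]
    return Ontology(
        terms=[
            OntologyTerm(surface=s, domains=frozenset(d), polarity=p)
            for s, d, p in items
        ]
    )


def default_synonym_map() -> Dict[str, Tuple[str, ...]]:
    """Planted synthetic synonyms per seed term (domains inherited)."""
    return {
        "fatigue": ("weariness",),
        "sleepiness": ("somnolence",),
        "drowsy": ("groggy",),
        "concentration": ("distractibility",),
        "irritability": ("crankiness",),
        "anxious": ("jittery",),
    }


def default_seed_pairs(
    ontology: Ontology, synonym_map: Mapping[str, Sequence[str]]
) -> List[SeedPair]:
    pairs = [SeedPair(seed, syn) for seed in sorted(synonym_map)
             for syn in synonym_map[seed]]
    related = [
        ("fatigue", "tired"),
        ("fatigue", "exhaustion"),
        ("sleepiness", "drowsy"),
        ("tired", "weakness"),
        ("concentration", "attention"),
        ("memory", "concentration"),
        ("irritability", "anxious"),
        ("mood", "irritability"),
    ]
    surfaces = set(ontology.surfaces())
    pairs.extend(SeedPair(a, b) for a, b in related if {a, b} <= surfaces)
    return pairs


@dataclass
class GenerationConfig:
    """Knobs of the synthetic study. Defaults define the study conditions."""

    n_patients: int = 500
    date_range: Tuple[date, date] = (date(2018, 1, 1), date(2019, 12, 31))
    planted_synonym_map: Dict[str, Tuple[str, ...]] = field(
        default_factory=default_synonym_map
    )
    negation_rate: float = 0.15
    #: probability that each section appears on a note (hpi always present so
    #: every note has a home for its symptom sentences)
    section_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "chief_complaint": 0.9,
            "review_of_systems": 0.6,
            "physical_exam": 0.5,
            "assessment": 0.7,
            "history_of_present_illness": 1.0,
            "past_medical_history": 0.3,
        }
    )
    #: per drug class, multiplicative change of the per-domain symptom
    #: emission rate after the first dispensing
    treatment_effect_spec: Dict[str, float] = field(
        default_factory=lambda: {
            "trazodone": 1.05,
            "benzodiazepine": 1.2,
            "non_bzra": 1.15,
        }
    )
    rng_seed: int = 0

    # emission / cohort structure
    baseline_symptom_rate: float = 0.4  # Poisson mean per domain per note
    treated_fraction: float = 0.6
    encounters_before_mean: float = 6.0
    encounters_during_mean: float = 3.0
    followup_days: int = 91
    t0_encounter_prob: float = 0.1  # visit on the treatment start day itself
    co_mention_rate: float = 0.6  # synonym sentence also names its seed term
    hypothetical_rate: float = 0.05  # filler-only hypothetical sentences
    pmh_symptom_rate: float = 0.5  # distractor mention in past medical history
    icd_sensitivity: float = 0.2  # claim emitted per gold-present domain
    icd_false_positive_rate: float = 0.02
    comorbidity_rate: float = 0.3
    violation_fraction: float = 0.05  # treated patients breaking a cohort rule
    n_filler_vocab: int = 120
    n_filler_supertype: int = 80
    drug_class_table: Dict[str, str] = field(
        default_factory=lambda: dict(DRUG_CLASS_TABLE)
    )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients: must be >= 0")
        start, end = self.date_range
        if start >= end:
            raise ValueError("date_range: start must precede end")
        for name in (
            "negation_rate", "treated_fraction", "co_mention_rate",
            "hypothetical_rate", "pmh_symptom_rate", "icd_sensitivity",
            "icd_false_positive_rate", "comorbidity_rate",
            "violation_fraction", "t0_encounter_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: probability {v} outside [0, 1]")
        for sec, p in self.section_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"section_mix[{sec!r}]: probability {p} outside [0, 1]")
        for cls, m in self.treatment_effect_spec.items():
            if m <= 0:
                raise ValueError(f"treatment_effect_spec[{cls!r}]: multiplier {m} must be > 0")
        if self.baseline_symptom_rate < 0:
            raise ValueError("baseline_symptom_rate: must be >= 0")
        if self.followup_days < 1:
            raise ValueError("followup_days: must be >= 1")


@dataclass
class Bundle:
    patients: List[Patient]
    encounters: List[Encounter]
    claims: List[ClaimRecord]
    dispensings: List[DispensingRecord]
    seed_ontology: Ontology
    semantic_lexicon: SemanticLexicon
    seed_pairs: List[SeedPair]
    gold_annotations: List[GoldAnnotation]


_ASSERT_TEMPLATES = (
    "patient reports {t} during the day",
    "complains of {t} at work",
    "notable {t} on interview",
    "{t} reported since last visit",
)
_ASSERT_CO_TEMPLATES = (
    "patient reports {seed} and {t} most days",
    "describes {seed} with marked {t}",
)
_NEGATED_TEMPLATES = (
    "denies {t} during the day",
    "no {t} reported",
    "negative for {t}",
)
# negated-polarity terms ("happy", "energy"): the impairment is the negation
_NEGPOL_IMPAIRED_TEMPLATES = (
    "patient is not {t} these days",
    "reports no {t} lately",
)
_NEGPOL_OK_TEMPLATES = (
    "patient is {t} overall",
    "reports {t} most days",
)
_PMH_TEMPLATES = (
    "history of {t} in the past",
    "{t} years ago",
)


class _Generator:
    def __init__(self, config: GenerationConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.rng_seed)
        self.ontology = default_seed_ontology()
        self._check_synonyms()
        self.terms_by_domain: Dict[str, List[OntologyTerm]] = {d: [] for d in DOMAINS}
        self.syn_to_seed: Dict[str, str] = {}
        all_terms: List[OntologyTerm] = list(self.ontology.terms)
        for seed_surface, syns in sorted(self.cfg.planted_synonym_map.items()):
            seed_term = next(
                t for t in self.ontology.terms if t.surface == seed_surface
            )
            for syn in syns:
                all_terms.append(
                    OntologyTerm(
                        surface=syn,
                        domains=seed_term.domains,
                        polarity=seed_term.polarity,
                    )
                )
                self.syn_to_seed[syn] = seed_surface
        self.emission_terms = all_terms
        for t in all_terms:
            for d in t.domains:
                self.terms_by_domain[d].append(t)
        self.filler = [f"filler{i:03d}" for i in range(self.cfg.n_filler_vocab)]
        self.dayimp_filler = [
            f"dayimp{i:03d}" for i in range(self.cfg.n_filler_supertype)
        ]
        # Filler tokens are grouped into disjoint "topics" and each filler
        # sentence draws from a single topic: without this, every background
        # token shares every context and the embedding geometry collapses
        # into one tight cluster, which would make null similarity
        # distributions degenerate.
        pool = self.filler + self.dayimp_filler
        order = self.rng.permutation(len(pool))
        shuffled = [pool[i] for i in order]
        size = 10
        self.topics = [
            shuffled[i : i + size] for i in range(0, len(shuffled), size)
        ]
        self._enc_counter = 0

    def _check_synonyms(self) -> None:
        surfaces = set(self.ontology.surfaces())
        for seed, syns in self.cfg.planted_synonym_map.items():
            if seed not in surfaces:
                raise ValueError(
                    f"planted_synonym_map: seed {seed!r} is not a seed-ontology term"
                )
            for syn in syns:
                if syn in surfaces:
                    raise ValueError(
                        f"planted_synonym_map: synonym {syn!r} collides with a seed term"
                    )

    # ---- vocabulary artefacts -------------------------------------------

    def lexicon(self) -> SemanticLexicon:
        entries: Dict[str, Tuple[str, bool]] = {}
        for t in self.emission_terms:
            for tok in t.surface.split():
                entries[tok] = ("sign_or_symptom", True)
        for tok in self.dayimp_filler:
            entries[tok] = ("finding", True)
        for tok in self.filler:
            entries[tok] = ("other", False)
        return SemanticLexicon(entries=entries)

    # ---- sentence grammar ------------------------------------------------

    def _pick(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def _filler_sentence(self) -> str:
        n = int(self.rng.integers(4, 9))
        topic = self._pick(self.topics)
        toks = [self._pick(topic) for _ in range(n)]
        if self.rng.random() < self.cfg.hypothetical_rate:
            toks = ["return", "if"] + toks
        return " ".join(toks)

    def _symptom_sentence(self, term: OntologyTerm, negated_surface: bool) -> str:
        """A sentence mentioning ``term``, negated or plainly asserted.

        Whether the mention is an impairment follows from the term's
        polarity: an asserted-polarity term is impairing when asserted, a
        negated-polarity term ("happy", "energy") when negated. With
        ``negation_rate`` = 0 no sentence carries a negation trigger.
        """
        t = term.surface
        if term.polarity == IMPAIRMENT_WHEN_NEGATED:
            tmpl = self._pick(
                _NEGPOL_IMPAIRED_TEMPLATES if negated_surface else _NEGPOL_OK_TEMPLATES
            )
            return tmpl.format(t=t)
        if negated_surface:
            return self._pick(_NEGATED_TEMPLATES).format(t=t)
        if t in self.syn_to_seed and self.rng.random() < self.cfg.co_mention_rate:
            return self._pick(_ASSERT_CO_TEMPLATES).format(
                seed=self.syn_to_seed[t], t=t
            )
        return self._pick(_ASSERT_TEMPLATES).format(t=t)

    # ---- notes -----------------------------------------------------------

    def _note(self, patient_id: str, when: date, rate_multiplier: float):
        """Build one encounter + its gold flags for each domain."""
        cfg = self.cfg
        present_sections = [
            s for s in RETAINED_SECTIONS if self.rng.random() < cfg.section_mix.get(s, 0)
        ]
        if "history_of_present_illness" not in present_sections:
            present_sections.append("history_of_present_illness")
        symptom_sentences: List[str] = []
        gold = {d: False for d in DOMAINS}
        for d in DOMAINS:
            lam = cfg.baseline_symptom_rate * rate_multiplier
            k = int(self.rng.poisson(lam))
            for _ in range(k):
                term = self._pick(self.terms_by_domain[d])
                negated_surface = self.rng.random() < cfg.negation_rate
                impaired = (
                    negated_surface
                    if term.polarity == IMPAIRMENT_WHEN_NEGATED
                    else not negated_surface
                )
                symptom_sentences.append(self._symptom_sentence(term, negated_surface))
                if impaired:
                    for dd in term.domains:
                        gold[dd] = True
                    # a co-mentioned seed term shares the synonym's domains,
                    # so the gold flags above already cover it
        sections = []
        for s in present_sections:
            sents = [self._filler_sentence() for _ in range(int(self.rng.integers(1, 4)))]
            if s == "history_of_present_illness":
                sents.extend(symptom_sentences)
            sections.append((s, ". ".join(sents) + "."))
        if self.rng.random() < cfg.section_mix.get("past_medical_history", 0):
            if self.rng.random() < cfg.pmh_symptom_rate:
                term = self._pick(self.emission_terms)
                txt = self._pick(_PMH_TEMPLATES).format(t=term.surface) + "."
            else:
                txt = self._filler_sentence() + "."
            sections.append(("past_medical_history", txt))
        self._enc_counter += 1
        enc = Encounter(
            encounter_id=f"E{self._enc_counter:07d}",
            patient_id=patient_id,
            date=when,
            sections=tuple(sections),
        )
        return enc, gold

    # ---- top-level generation -------------------------------------------

    def generate(self) -> Bundle:
        cfg = self.cfg
        start, end = cfg.date_range
        span = (end - start).days
        patients: List[Patient] = []
        encounters: List[Encounter] = []
        claims: List[ClaimRecord] = []
        dispensings: List[DispensingRecord] = []
        gold: List[GoldAnnotation] = []
        drug_names_by_class: Dict[str, List[str]] = {c: [] for c in DRUG_CLASSES}
        for name, cls in sorted(cfg.drug_class_table.items()):
            drug_names_by_class.setdefault(cls, []).append(name)

        for i in range(cfg.n_patients):
            pid = f"P{i:06d}"
            sex = "F" if self.rng.random() < 0.55 else "M"
            treated = self.rng.random() < cfg.treated_fraction
            violation = treated and self.rng.random() < cfg.violation_fraction
            vio_kind = (
                self._pick(("late_diagnosis", "underage", "exclusion_code"))
                if violation
                else None
            )

            if treated:
                lo = 182 + 30
                hi = max(lo + 1, span - cfg.followup_days - 14)
                t0 = start + timedelta(days=int(self.rng.integers(lo, hi)))
                drug_class = self._pick(DRUG_CLASSES)
                mult = cfg.treatment_effect_spec.get(drug_class, 1.0)
                birth_year = (
                    t0.year - 16
                    if vio_kind == "underage"
                    else t0.year - int(self.rng.integers(20, 80))
                )
            else:
                t0 = None
                drug_class = None
                mult = 1.0
                birth_year = start.year - int(self.rng.integers(20, 80))
            patients.append(Patient(patient_id=pid, birth_year=birth_year, sex=sex))

            # encounters
            def _emit(when: date, multiplier: float):
                enc, g = self._note(pid, when, multiplier)
                encounters.append(enc)
                for d in DOMAINS:
                    gold.append(GoldAnnotation(enc.encounter_id, d, g[d]))
                # claims coupled to gold flags (under-coded on purpose)
                for d in DOMAINS:
                    if g[d] and self.rng.random() < cfg.icd_sensitivity:
                        code = self._pick(ICD_CLIN_DISMOL[d])
                        claims.append(ClaimRecord(pid, when, code))
                if self.rng.random() < cfg.icd_false_positive_rate:
                    d = self._pick(DOMAINS)
                    claims.append(ClaimRecord(pid, when, self._pick(ICD_CLIN_DISMOL[d])))

            if treated:
                # visit counts are untruncated Poisson draws: a window with
                # zero visits is still 182 (or followup_days) observed days,
                # so expected visit density is identical pre/post and the
                # planted rate ratio is exactly the class multiplier
                n_b = int(self.rng.poisson(cfg.encounters_before_mean))
                for off in sorted(
                    int(x) for x in self.rng.integers(1, 183, size=n_b)
                ):
                    _emit(t0 - timedelta(days=off), 1.0)
                if self.rng.random() < cfg.t0_encounter_prob:
                    _emit(t0, mult)
                n_d = int(self.rng.poisson(cfg.encounters_during_mean))
                for off in sorted(
                    int(x) for x in self.rng.integers(1, cfg.followup_days + 1, size=n_d)
                ):
                    _emit(t0 + timedelta(days=off), mult)
            else:
                n_e = max(1, int(self.rng.poisson(cfg.encounters_before_mean)))
                for off in sorted(int(x) for x in self.rng.integers(0, span + 1, size=n_e)):
                    _emit(start + timedelta(days=off), 1.0)

            # insomnia diagnosis claim
            if treated:
                dx_off = (
                    int(self.rng.integers(200, 300))
                    if vio_kind == "late_diagnosis"
                    else int(self.rng.integers(1, 181))
                )
                claims.append(
                    ClaimRecord(pid, t0 - timedelta(days=dx_off), self._pick(INSOMNIA_CODES))
                )
            else:
                off = int(self.rng.integers(0, span + 1))
                claims.append(
                    ClaimRecord(pid, start + timedelta(days=off), self._pick(INSOMNIA_CODES))
                )

            if treated and vio_kind == "exclusion_code":
                kind = self._pick(sorted(EXCLUSION_CODES))
                code = self._pick(EXCLUSION_CODES[kind])
                claims.append(
                    ClaimRecord(pid, t0 - timedelta(days=int(self.rng.integers(0, 120))), code)
                )
            if self.rng.random() < cfg.comorbidity_rate:
                off = int(self.rng.integers(0, span + 1))
                claims.append(
                    ClaimRecord(pid, start + timedelta(days=off), self._pick(COMORBIDITY_CODES))
                )

            # dispensings: first fill at t0, refills every ~30 days
            if treated:
                drug = self._pick(drug_names_by_class[drug_class])
                day = t0
                while day <= t0 + timedelta(days=cfg.followup_days - 30):
                    dispensings.append(DispensingRecord(pid, day, drug, drug_class))
                    day = day + timedelta(days=int(self.rng.integers(27, 34)))

        ontology = self.ontology
        pairs = default_seed_pairs(ontology, cfg.planted_synonym_map)
        return Bundle(
            patients=patients,
            encounters=encounters,
            claims=claims,
            dispensings=dispensings,
            seed_ontology=ontology,
            semantic_lexicon=self.lexicon(),
            seed_pairs=pairs,
            gold_annotations=gold,
        )


def generate_bundle(config: Optional[GenerationConfig] = None) -> Bundle:
    """Generate a full synthetic bundle; deterministic under a fixed seed."""
    if config is None:
        config = GenerationConfig()
    return _Generator(config).generate()


def planted_ontology(config: Optional[GenerationConfig] = None) -> Ontology:
    """The full emission vocabulary: seed terms plus planted synonyms.

    This is the ground-truth analogue of a validated enriched ontology —
    what a perfect enrichment-plus-expert-review run over the synthetic
    corpus would produce.
    """
    if config is None:
        config = GenerationConfig()
    return Ontology(terms=list(_Generator(config).emission_terms))


def stratified_split(
    patients: Sequence[Patient],
    n_test: int,
    seed: int = 0,
    reference_year: int = 2018,
) -> Tuple[List[Patient], List[Patient]]:
    """Split patients into (train, test) stratified by sex and age decade.

    Test-set size is exactly ``n_test``; strata contribute proportionally
    (largest-remainder rounding), mirroring an age/sex-stratified hold-out.
    """
    if not 0 <= n_test <= len(patients):
        raise ValueError("n_test outside [0, n_patients]")
    rng = np.random.default_rng(seed)
    strata: Dict[Tuple[str, int], List[Patient]] = {}
    for p in patients:
        decade = (reference_year - p.birth_year) // 10
        strata.setdefault((p.sex, decade), []).append(p)
    keys = sorted(strata)
    total = len(patients)
    quotas = {k: n_test * len(strata[k]) / total for k in keys}
    counts = {k: int(quotas[k]) for k in keys}
    short = n_test - sum(counts.values())
    for k in sorted(keys, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    test_ids = set()
    for k in keys:
        pool = strata[k]
        take = min(counts[k], len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        test_ids.update(pool[i].patient_id for i in idx)
    # top up if some stratum was too small
    if len(test_ids) < n_test:
        rest = [p.patient_id for p in patients if p.patient_id not in test_ids]
        extra = rng.choice(len(rest), size=n_test - len(test_ids), replace=False)
        test_ids.update(rest[i] for i in extra)
    train = [p for p in patients if p.patient_id not in test_ids]
    test = [p for p in patients if p.patient_id in test_ids]
    return train, test


# ---- persistence ---------------------------------------------------------

BUNDLE_FILES = (
    "patients.csv",
    "encounters.jsonl",
    "claims.csv",
    "dispensings.csv",
    "seed_ontology.json",
    "semantic_lexicon.tsv",
    "seed_pairs.tsv",
    "gold_annotations.csv",
)


def write_bundle(bundle: Bundle, directory) -> Dict[str, int]:
    """Write a bundle as plain-text files; returns a manifest of row counts."""
    os.makedirs(directory, exist_ok=True)
    p = lambda name: os.path.join(directory, name)
    with open(p("patients.csv"), "w", encoding="utf-8") as fh:
        fh.write("patient_id,birth_year,sex\n")
        for pt in bundle.patients:
            fh.write(f"{pt.patient_id},{pt.birth_year},{pt.sex}\n")
    with open(p("encounters.jsonl"), "w", encoding="utf-8") as fh:
        for enc in bundle.encounters:
            fh.write(
                json.dumps(
                    {
                        "encounter_id": enc.encounter_id,
                        "patient_id": enc.patient_id,
                        "date": enc.date.isoformat(),
                        "sections": [
                            {"name": n, "text": t} for n, t in enc.sections
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    with open(p("claims.csv"), "w", encoding="utf-8") as fh:
        fh.write("patient_id,date,code\n")
        for c in bundle.claims:
            fh.write(f"{c.patient_id},{c.date.isoformat()},{c.code}\n")
    with open(p("dispensings.csv"), "w", encoding="utf-8") as fh:
        fh.write("patient_id,date,drug_name,drug_class\n")
        for d in bundle.dispensings:
            fh.write(
                f"{d.patient_id},{d.date.isoformat()},{d.drug_name},{d.drug_class}\n"
            )
    bundle.seed_ontology.to_json(p("seed_ontology.json"))
    bundle.semantic_lexicon.to_tsv(p("semantic_lexicon.tsv"))
    write_seed_pairs(bundle.seed_pairs, p("seed_pairs.tsv"))
    with open(p("gold_annotations.csv"), "w", encoding="utf-8") as fh:
        fh.write("encounter_id,domain,present\n")
        for g in bundle.gold_annotations:
            fh.write(f"{g.encounter_id},{g.domain},{int(g.present)}\n")
    manifest = {
        "patients": len(bundle.patients),
        "encounters": len(bundle.encounters),
        "claims": len(bundle.claims),
        "dispensings": len(bundle.dispensings),
        "seed_pairs": len(bundle.seed_pairs),
        "gold_annotations": len(bundle.gold_annotations),
    }
    with open(p("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _parse_date(s: str, file: str, recno: int) -> date:
    try:
        return date.fromisoformat(s)
    except ValueError:
        raise ValueError(f"{file}: record {recno}: bad date {s!r}") from None


def read_bundle(directory) -> Bundle:
    """Read a bundle back; malformed records raise naming file and record."""
    p = lambda name: os.path.join(directory, name)
    patients = []
    with open(p("patients.csv"), encoding="utf-8") as fh:
        next(fh)
        for recno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 3:
                raise ValueError(f"patients.csv: record {recno}: expected 3 fields")
            patients.append(Patient(parts[0], int(parts[1]), parts[2]))
    encounters = []
    with open(p("encounters.jsonl"), encoding="utf-8") as fh:
        for recno, line in enumerate(fh, start=1):
            try:
                row = json.loads(line)
            except json.JSONDecodeError:
                raise ValueError(f"encounters.jsonl: record {recno}: bad JSON") from None
            encounters.append(
                Encounter(
                    encounter_id=row["encounter_id"],
                    patient_id=row["patient_id"],
                    date=_parse_date(row["date"], "encounters.jsonl", recno),
                    sections=tuple((s["name"], s["text"]) for s in row["sections"]),
                )
            )
    claims = []
    with open(p("claims.csv"), encoding="utf-8") as fh:
        next(fh)
        for recno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 3:
                raise ValueError(f"claims.csv: record {recno}: expected 3 fields")
            pid, ds, code = parts
            if not ICD10_RE.match(code):
                raise ValueError(
                    f"claims.csv: record {recno}: code {code!r} is not valid ICD-10 syntax"
                )
            claims.append(ClaimRecord(pid, _parse_date(ds, "claims.csv", recno), code))
    dispensings = []
    with open(p("dispensings.csv"), encoding="utf-8") as fh:
        next(fh)
        for recno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 4:
                raise ValueError(f"dispensings.csv: record {recno}: expected 4 fields")
            pid, ds, name, cls = parts
            dispensings.append(
                DispensingRecord(pid, _parse_date(ds, "dispensings.csv", recno), name, cls)
            )
    gold = []
    with open(p("gold_annotations.csv"), encoding="utf-8") as fh:
        next(fh)
        for recno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 3:
                raise ValueError(
                    f"gold_annotations.csv: record {recno}: expected 3 fields"
                )
            gold.append(GoldAnnotation(parts[0], parts[1], parts[2] == "1"))
    return Bundle(
        patients=patients,
        encounters=encounters,
        claims=claims,
        dispensings=dispensings,
        seed_ontology=Ontology.from_json(p("seed_ontology.json")),
        semantic_lexicon=SemanticLexicon.from_tsv(p("semantic_lexicon.tsv")),
        seed_pairs=read_seed_pairs(p("seed_pairs.tsv")),
        gold_annotations=gold,
    )
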