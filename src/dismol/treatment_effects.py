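"""Within-subject pre/post treatment-effect estimation per 100 patient-years.

Cohorts are built per drug class from claims and dispensings: the index date
t0 is the first dispensing of the class; inclusion requires an insomnia
diagnosis within six months before t0 and age >= 18 at t0; palliative-care,
active-malignancy and pregnancy codes on or before t0 exclude. Confirmed
symptom events are counted in a 182-day baseline window [t0-182, t0) and an
on-treatment window (t0, t0+followup]; the index day itself is censored.

Rates are events per 100 patient-years (365.25-day years), pooled over the
cohort. The average treatment effect is the pooled rate difference
(during - before). Two percent-change quantities are reported: the aggregate
ratio ATE/rate_before, and the mean +- SD of per-patient relative changes in
annualized rates (patients with zero baseline events are excluded from the
latter, logged). Significance uses a two-sided paired t-test on per-patient
annualized-rate differences, with Benjamini-Hochberg FDR across the run's
hypothesis family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .context_directionality import DOMAINS
from .inference_evaluation import EncounterImpairment
from .synthetic_ehr import (
    EXCLUSION_CODES,
    INSOMNIA_CODES,
    ClaimRecord,
    DispensingRecord,
    Patient,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
ALL_DOMAINS = "all_domains"


@dataclass
class CohortSpec:
    drug_class: str
    insomnia_codes: Tuple[str, ...] = INSOMNIA_CODES
    max_days_dx_to_start: int = 183  # "within 6 months prior"
    min_age: int = 18
    exclusion_codes: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(EXCLUSION_CODES)
    )
    baseline_days: int = 182
    followup_grace_days: int = 30  # days-supply after the last dispensing

    def __post_init__(self):
        if self.baseline_days <= 0:
            raise ValueError("baseline_days must be positive")
        if not self.insomnia_codes:
            raise ValueError("insomnia code set must be non-empty")
        for kind, codes in self.exclusion_codes.items():
            if not codes:
                raise ValueError(f"exclusion code set {kind!r} must be non-empty")


@dataclass
class PatientEffectRecord:
    patient_id: str
    t0: date
    baseline_days_observed: int
    followup_days_observed: int
    events_before: Dict[str, int] = field(default_factory=dict)
    events_during: Dict[str, int] = field(default_factory=dict)


def _code_matches(claim_code: str, codes: Iterable[str]) -> bool:
    return any(claim_code == c or claim_code.startswith(c) for c in codes)


def build_cohort(
    claims: Sequence[ClaimRecord],
    dispensings: Sequence[DispensingRecord],
    patients: Sequence[Patient],
    spec: CohortSpec,
) -> Tuple[List[PatientEffectRecord], List[Tuple[str, str]]]:
    """Apply inclusion/exclusion rules; returns records and an exclusion log.

    Age at t0 is computed from birth year (calendar-year arithmetic; the
    real feed exposes no birth date). Every exclusion is logged as
    (patient_id, rule).
    """
    demo = {p.patient_id: p for p in patients}
    t0_by_patient: Dict[str, date] = {}
    last_disp: Dict[str, date] = {}
    for d in dispensings:
        if d.drug_class != spec.drug_class:
            continue
        if d.patient_id not in demo:
            raise ValueError(
                f"patient {d.patient_id!r} has dispensings but no demographics"
            )
        if d.patient_id not in t0_by_patient or d.date < t0_by_patient[d.patient_id]:
            t0_by_patient[d.patient_id] = d.date
        if d.patient_id not in last_disp or d.date > last_disp[d.patient_id]:
            last_disp[d.patient_id] = d.date
    claims_by_patient: Dict[str, List[ClaimRecord]] = {}
    for c in claims:
        claims_by_patient.setdefault(c.patient_id, []).append(c)

    records: List[PatientEffectRecord] = []
    excluded: List[Tuple[str, str]] = []
    for pid in sorted(t0_by_patient):
        t0 = t0_by_patient[pid]
        pclaims = claims_by_patient.get(pid, [])
        has_dx = any(
            _code_matches(c.code, spec.insomnia_codes)
            and t0 - timedelta(days=spec.max_days_dx_to_start) < c.date < t0
            for c in pclaims
        )
        if not has_dx:
            excluded.append((pid, "no_insomnia_dx_within_window"))
            continue
        age = t0.year - demo[pid].birth_year
        if age < spec.min_age:
            excluded.append((pid, "underage"))
            continue
        hit = None
        for kind, codes in sorted(spec.exclusion_codes.items()):
            if any(_code_matches(c.code, codes) and c.date <= t0 for c in pclaims):
                hit = kind
                break
        if hit:
            excluded.append((pid, hit))
            continue
        followup_end = last_disp[pid] + timedelta(days=spec.followup_grace_days)
        followup_days = (followup_end - t0).days
        if followup_days <= 0:
            excluded.append((pid, "no_followup_time"))
            continue
        records.append(
            PatientEffectRecord(
                patient_id=pid,
                t0=t0,
                baseline_days_observed=spec.baseline_days,
                followup_days_observed=followup_days,
            )
        )
    return records, excluded


def count_events(
    records: Sequence[PatientEffectRecord],
    impairments: Sequence[EncounterImpairment],
) -> List[PatientEffectRecord]:
    """Fill per-window event counts from confirmed events.

    An event spanning k domains adds 1 to each of those k domain counts but
    only 1 to the all-domains count (multi-domain terms are one occurrence).
    The index day t0 belongs to neither window.
    """
    by_patient: Dict[str, List] = {}
    for imp in impairments:
        for ev in imp.confirmed_events:
            by_patient.setdefault(ev.patient_id, []).append(ev)
    for rec in records:
        before = {d: 0 for d in DOMAINS}
        before[ALL_DOMAINS] = 0
        during = {d: 0 for d in DOMAINS}
        during[ALL_DOMAINS] = 0
        w_start = rec.t0 - timedelta(days=rec.baseline_days_observed)
        w_end = rec.t0 + timedelta(days=rec.followup_days_observed)
        for ev in by_patient.get(rec.patient_id, []):
            if w_start <= ev.date < rec.t0:
                target = before
            elif rec.t0 < ev.date <= w_end:
                target = during
            else:
                continue
            target[ALL_DOMAINS] += 1
            for d in ev.domains:
                target[d] += 1
        rec.events_before = before
        rec.events_during = during
    return list(records)


def rate_per_100py(total_events: float, total_days: float) -> float:
    """Events per 100 patient-years of observed time."""
    if total_days <= 0:
        raise ValueError("total_days must be positive")
    return total_events / (total_days / DAYS_PER_YEAR) * 100.0


@dataclass
class EffectResult:
    ontology_name: str
    domain: str
    n_patients: int
    rate_before: float
    rate_during: float
    ate: float
    ci95: Tuple[float, float]
    aggregate_pct: Optional[float]
    within_subject_pct: Optional[float]
    within_subject_sd: Optional[float]
    n_zero_baseline_excluded: int
    p_value: Optional[float]
    q_value: Optional[float] = None


def estimate_effect(
    records: Sequence[PatientEffectRecord],
    domain: str,
    ontology_name: str = "DiSMOL",
) -> EffectResult:
    """Effect estimate for one domain over a counted cohort."""
    if len(records) < 2:
        raise ValueError("need at least 2 records with observed windows")
    eb = np.array([r.events_before.get(domain, 0) for r in records], dtype=float)
    ed = np.array([r.events_during.get(domain, 0) for r in records], dtype=float)
    db = np.array([r.baseline_days_observed for r in records], dtype=float)
    dd = np.array([r.followup_days_observed for r in records], dtype=float)
    rate_before = rate_per_100py(eb.sum(), db.sum())
    rate_during = rate_per_100py(ed.sum(), dd.sum())
    ate = rate_during - rate_before
    rb = eb / db * DAYS_PER_YEAR * 100.0  # per-patient annualized rates
    rd = ed / dd * DAYS_PER_YEAR * 100.0
    diffs = rd - rb
    n = len(diffs)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if sd_diff > 0:
        tcrit = stats.t.ppf(0.975, n - 1)
        half = tcrit * sd_diff / math.sqrt(n)
        ci = (mean_diff - half, mean_diff + half)
        tstat = mean_diff / (sd_diff / math.sqrt(n))
        p = float(2 * stats.t.sf(abs(tstat), n - 1))
    else:
        ci = (mean_diff, mean_diff)
        p = None
        logger.warning(
            "%s/%s: zero variance of paired differences; p undefined",
            ontology_name, domain,
        )
    aggregate_pct = 100.0 * ate / rate_before if rate_before > 0 else None
    nz = rb > 0
    n_excluded = int((~nz).sum())
    if nz.any():
        rel = (rd[nz] - rb[nz]) / rb[nz] * 100.0
        ws_pct = float(rel.mean())
        ws_sd = float(rel.std(ddof=1)) if nz.sum() > 1 else None
    else:
        ws_pct = ws_sd = None
    return EffectResult(
        ontology_name=ontology_name,
        domain=domain,
        n_patients=n,
        rate_before=rate_before,
        rate_during=rate_during,
        ate=ate,
        ci95=ci,
        aggregate_pct=aggregate_pct,
        within_subject_pct=ws_pct,
        within_subject_sd=ws_sd,
        n_zero_baseline_excluded=n_excluded,
        p_value=p,
    )


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted q-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q.tolist()


def adjust_family(results: Sequence[EffectResult]) -> List[EffectResult]:
    """Attach BH q-values across one run's full hypothesis family."""
    testable = [r for r in results if r.p_value is not None]
    qs = bh_fdr([r.p_value for r in testable]) if testable else []
    for r, q in zip(testable, qs):
        r.q_value = q
    return list(results)


def estimate_all(
    records: Sequence[PatientEffectRecord],
    ontology_name: str = "DiSMOL",
    domains: Sequence[str] = (ALL_DOMAINS,) + DOMAINS,
) -> List[EffectResult]:
    return [estimate_effect(records, d, ontology_name) for d in domains]
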