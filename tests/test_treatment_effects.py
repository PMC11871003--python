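"""Cohort construction, windowed counting, rates, effects and BH-FDR."""

from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

import dismol as dm
from dismol.inference_evaluation import EncounterImpairment, SymptomEvent
from dismol.synthetic_ehr import ClaimRecord, DispensingRecord, Patient
from dismol.treatment_effects import (
    ALL_DOMAINS,
    CohortSpec,
    PatientEffectRecord,
    adjust_family,
    bh_fdr,
    build_cohort,
    count_events,
    estimate_effect,
    rate_per_100py,
)

T0 = date(2018, 9, 1)


def _patient(pid="p1", birth_year=1980):
    return Patient(patient_id=pid, birth_year=birth_year, sex="F")


def _disp(pid="p1", day=T0, cls="benzodiazepine"):
    return DispensingRecord(pid, day, "temazepam", cls)


def _dx(pid="p1", days_before=100):
    return ClaimRecord(pid, T0 - timedelta(days=days_before), "G47.00")


def _spec():
    return CohortSpec(drug_class="benzodiazepine")


class TestBuildCohort:
    def test_straightforward_inclusion(self):
        recs, excl = build_cohort(
            [_dx(days_before=100)], [_disp()], [_patient(birth_year=1998)], _spec()
        )
        assert len(recs) == 1 and excl == []
        assert recs[0].t0 == T0

    def test_diagnosis_older_than_six_months_excluded(self):
        recs, excl = build_cohort(
            [_dx(days_before=200)], [_disp()], [_patient()], _spec()
        )
        assert recs == [] and excl == [("p1", "no_insomnia_dx_within_window")]

    def test_diagnosis_at_exact_window_edge_excluded(self):
        # open interval: exactly 183 days before t0 is outside
        recs, excl = build_cohort(
            [_dx(days_before=183)], [_disp()], [_patient()], _spec()
        )
        assert recs == []

    def test_underage_excluded(self):
        recs, excl = build_cohort(
            [_dx()], [_disp()], [_patient(birth_year=T0.year - 17)], _spec()
        )
        assert excl == [("p1", "underage")]

    def test_pregnancy_code_before_t0_excluded(self):
        claims = [_dx(), ClaimRecord("p1", T0 - timedelta(days=10), "Z33.1")]
        recs, excl = build_cohort(claims, [_disp()], [_patient()], _spec())
        assert excl == [("p1", "pregnancy")]

    def test_exclusion_code_after_t0_does_not_exclude(self):
        claims = [_dx(), ClaimRecord("p1", T0 + timedelta(days=10), "Z33.1")]
        recs, excl = build_cohort(claims, [_disp()], [_patient()], _spec())
        assert len(recs) == 1

    def test_t0_is_first_dispensing_of_the_class(self):
        disps = [
            _disp(day=T0 + timedelta(days=40)),
            _disp(day=T0),
            DispensingRecord("p1", T0 - timedelta(days=300), "zolpidem", "non_bzra"),
        ]
        recs, _ = build_cohort([_dx()], disps, [_patient()], _spec())
        assert recs[0].t0 == T0

    def test_dispensing_without_demographics_is_error(self):
        with pytest.raises(ValueError, match="demographics"):
            build_cohort([_dx()], [_disp()], [], _spec())


class TestCountEvents:
    def _imp(self, events):
        return EncounterImpairment(
            encounter_id="e", patient_id="p1", date=T0,
            per_domain={}, confirmed_events=events,
        )

    def _event(self, day, domains=("physical",)):
        return SymptomEvent("e", "p1", day, "fatigue", frozenset(domains), "hpi")

    def test_t0_censored_from_both_windows(self):
        rec = PatientEffectRecord("p1", T0, 182, 91)
        imp = self._imp([self._event(T0)])
        count_events([rec], [imp])
        assert rec.events_before[ALL_DOMAINS] == 0
        assert rec.events_during[ALL_DOMAINS] == 0

    def test_boundary_days(self):
        rec = PatientEffectRecord("p1", T0, 182, 91)
        imp = self._imp([
            self._event(T0 - timedelta(days=1)),
            self._event(T0 + timedelta(days=1)),
            self._event(T0 - timedelta(days=182)),   # first day of baseline
            self._event(T0 - timedelta(days=183)),   # outside
            self._event(T0 + timedelta(days=91)),    # last day of follow-up
            self._event(T0 + timedelta(days=92)),    # outside
        ])
        count_events([rec], [imp])
        assert rec.events_before["physical"] == 2
        assert rec.events_during["physical"] == 2

    def test_multi_domain_event_counts_once_in_all_domains(self):
        rec = PatientEffectRecord("p1", T0, 182, 91)
        imp = self._imp([self._event(T0 - timedelta(days=5),
                                     domains=("physical", "cognition"))])
        count_events([rec], [imp])
        assert rec.events_before["physical"] == 1
        assert rec.events_before["cognition"] == 1
        assert rec.events_before[ALL_DOMAINS] == 1

    def test_matches_brute_force_date_filter_oracle(self):
        """Window totals equal a direct date-comparison recount on a
        10-patient random fixture."""
        rng = np.random.default_rng(6)
        recs, imps = [], []
        for i in range(10):
            pid = f"p{i}"
            recs.append(PatientEffectRecord(pid, T0, 182, 91))
            events = [
                SymptomEvent("e", pid, T0 + timedelta(days=int(o)), "fatigue",
                             frozenset({"physical"}), "hpi")
                for o in rng.integers(-250, 150, size=40)
            ]
            imps.append(EncounterImpairment("e", pid, T0, {}, events))
        count_events(recs, imps)
        for rec, imp in zip(recs, imps):
            before = sum(
                1 for ev in imp.confirmed_events
                if T0 - timedelta(days=182) <= ev.date < T0
            )
            during = sum(
                1 for ev in imp.confirmed_events
                if T0 < ev.date <= T0 + timedelta(days=91)
            )
            assert rec.events_before[ALL_DOMAINS] == before
            assert rec.events_during[ALL_DOMAINS] == during


class TestRates:
    def test_worked_example(self):
        """50 events over 100 patients x 182 days -> 100.34 per 100 PY."""
        assert rate_per_100py(50, 100 * 182) == pytest.approx(100.34, abs=0.005)

    def test_zero_events_zero_rate(self):
        assert rate_per_100py(0, 1000) == 0.0

    def test_scale_invariance(self):
        assert rate_per_100py(10, 500) == pytest.approx(rate_per_100py(20, 1000))

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            rate_per_100py(5, 0)


def _record_with_rates(pid, before, during, days=36525):
    """days = 36525 (100 years) makes count == rate per 100 patient-years."""
    return PatientEffectRecord(
        pid, T0, days, days,
        events_before={ALL_DOMAINS: before}, events_during={ALL_DOMAINS: during},
    )


class TestEstimateEffect:
    def test_closed_form_t_test_on_three_patients(self):
        """Per-patient annualized differences (1, 2, 3) -> t = 3.464,
        two-sided p ~ 0.0742 at 2 degrees of freedom."""
        recs = [
            _record_with_rates("a", 0, 1),
            _record_with_rates("b", 0, 2),
            _record_with_rates("c", 0, 3),
        ]
        r = estimate_effect(recs, ALL_DOMAINS)
        assert r.p_value == pytest.approx(0.0742, abs=2e-4)
        expected_p = float(stats.ttest_1samp([1.0, 2.0, 3.0], 0.0).pvalue)
        assert r.p_value == pytest.approx(expected_p)

    def test_ate_is_pooled_rate_difference(self):
        recs = [
            _record_with_rates("a", 10, 14),
            _record_with_rates("b", 6, 10),
        ]
        r = estimate_effect(recs, ALL_DOMAINS)
        assert r.rate_before == pytest.approx(8.0)
        assert r.rate_during == pytest.approx(12.0)
        assert r.ate == pytest.approx(4.0)
        assert np.sign(r.ate) == np.sign(r.rate_during - r.rate_before)
        assert r.aggregate_pct == pytest.approx(50.0)

    def test_zero_baseline_patients_excluded_from_within_subject(self):
        recs = [
            _record_with_rates("a", 0, 5),
            _record_with_rates("b", 10, 15),
            _record_with_rates("c", 10, 5),
        ]
        r = estimate_effect(recs, ALL_DOMAINS)
        assert r.n_zero_baseline_excluded == 1
        assert r.within_subject_pct == pytest.approx((50.0 - 50.0) / 2)

    def test_zero_variance_reports_undefined_p(self):
        recs = [_record_with_rates("a", 5, 8), _record_with_rates("b", 2, 5)]
        r = estimate_effect(recs, ALL_DOMAINS)  # both diffs = +3
        assert r.p_value is None

    def test_needs_two_records(self):
        with pytest.raises(ValueError, match="2 records"):
            estimate_effect([_record_with_rates("a", 1, 2)], ALL_DOMAINS)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == [0.03]

    def test_hand_oracle_equal_spacing(self):
        """p = (0.01, 0.02, 0.03, 0.04): every step-up minimum is 0.04."""
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_hand_oracle_mixed(self):
        # ranks: 0.005*4/1=0.02; 0.04*4/2=0.08; 0.04*4/3 -> min with later
        got = bh_fdr([0.04, 0.005, 0.9, 0.03])
        assert got == pytest.approx([0.0533333333, 0.02, 0.9, 0.0533333333])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(25)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_fdr(list(p)) == pytest.approx(list(q_ref))

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.random(15))
        q = np.array(bh_fdr(list(p)))
        assert np.all(np.diff(q) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_q_at_least_p_in_family(self):
        recs = [
            _record_with_rates("a", 3, 9),
            _record_with_rates("b", 4, 8),
            _record_with_rates("c", 5, 2),
        ]
        for rec in recs:
            for d in dm.DOMAINS:
                rec.events_before[d] = rec.events_before[ALL_DOMAINS]
                rec.events_during[d] = rec.events_during[ALL_DOMAINS] + 1
        results = adjust_family(dm.estimate_all(recs))
        for r in results:
            if r.p_value is not None:
                assert r.q_value >= r.p_value - 1e-12
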