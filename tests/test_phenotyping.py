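import datetime as dt

import pytest

from depehr.cohort import Note, PatientRecord, Visit
from depehr.phenotyping import (
    BASE_CHANNELS,
    ChannelClassification,
    EvidenceChannel,
    PhenotypingError,
    apply_selection_criteria,
    attribution_split,
    build_paired_table,
    classify_channel,
    classify_cohort,
    combine_channels,
)
from depehr.textmine import Mention

D0 = dt.date(2015, 6, 1)


def make_patient(
    pid="P1",
    stage="II",
    chemo=True,
    n_before=2,
    n_after=2,
    codes_by_visit=None,
    cancer_type="breast",
    diagnosis_date=D0,
):
    visits = []
    dates = [D0 - dt.timedelta(days=30 * (i + 1)) for i in range(n_before)] + [
        D0 + dt.timedelta(days=30 * i) for i in range(n_after)
    ]
    for i, date in enumerate(sorted(dates)):
        vid = f"{pid}V{i}"
        codes = (codes_by_visit or {}).get(i, [])
        visits.append(Visit(vid, date, codes, [Note("es", "control.")]))
    return PatientRecord(
        patient_id=pid,
        sex="F",
        age_at_diagnosis=60.0,
        cancer_type=cancer_type,
        stage=stage,
        chemotherapy=chemo,
        diagnosis_date=diagnosis_date,
        visits=visits,
    )


def make_mention(patient, visit_idx, category="drug_substance", negated=False):
    v = patient.visits[visit_idx]
    return Mention(
        patient_id=patient.patient_id,
        visit_id=v.visit_id,
        note_index=0,
        surface="citalopram",
        start=0,
        end=10,
        category=category,
        concept_id="N06AB04",
        canonical="citalopram",
        edit_distance=0,
        negated=negated,
    )


class TestSelectionCriteria:
    def test_too_few_visits_excluded(self):
        p = make_patient(n_before=1, n_after=2)
        included, reasons = apply_selection_criteria([p])
        assert included == []
        assert reasons["P1"] == "insufficient_visits"

    def test_three_visits_total_excluded(self):
        p = make_patient(n_before=2, n_after=1)
        _, reasons = apply_selection_criteria([p])
        assert reasons["P1"] == "insufficient_visits"

    def test_stage_iv_excluded(self):
        _, reasons = apply_selection_criteria([make_patient(stage="IV")])
        assert reasons["P1"] == "stage_iv"

    def test_missing_treatment_information_excluded(self):
        _, reasons = apply_selection_criteria([make_patient(chemo=None)])
        assert reasons["P1"] == "incomplete_treatment_information"

    def test_qualifying_patient_included(self):
        included, reasons = apply_selection_criteria([make_patient()])
        assert len(included) == 1 and reasons == {}

    def test_first_failing_rule_reported(self):
        p = make_patient(stage="IV", n_before=1)
        _, reasons = apply_selection_criteria([p])
        assert reasons["P1"] == "insufficient_visits"

    def test_missing_diagnosis_date_is_a_data_error(self):
        p = make_patient()
        p.diagnosis_date = None
        with pytest.raises(PhenotypingError, match="diagnosis date"):
            apply_selection_criteria([p])


class TestClassifyChannel:
    def test_icd_after_only(self):
        p = make_patient(codes_by_visit={3: ["311"]})
        c = classify_channel(p, EvidenceChannel.ICD)
        assert c.temporal_class == "after_only"

    def test_icd_code_prefix_counts(self):
        p = make_patient(codes_by_visit={0: ["296.20"]})
        assert classify_channel(p, EvidenceChannel.ICD).temporal_class == "before_only"

    def test_cancer_codes_are_not_depression_evidence(self):
        p = make_patient(codes_by_visit={0: ["174.9"], 3: ["153.4"]})
        assert classify_channel(p, EvidenceChannel.ICD).temporal_class == "none"

    def test_negated_mention_is_not_evidence(self):
        p = make_patient()
        m = make_mention(p, 0, negated=True)
        c = classify_channel(p, EvidenceChannel.DRUG, mentions=[m])
        assert c.temporal_class == "none"

    def test_channel_independence(self):
        p = make_patient()
        m = make_mention(p, 0, category="disorder_term")
        assert (
            classify_channel(p, EvidenceChannel.DISORDER_TERM, mentions=[m]).temporal_class
            == "before_only"
        )
        assert (
            classify_channel(p, EvidenceChannel.DRUG, mentions=[m]).temporal_class
            == "none"
        )

    def test_diagnosis_day_tie_rule(self):
        p = make_patient()
        m = make_mention(p, 2)  # visit dated exactly on the index date
        assert p.visits[2].date == D0
        after = classify_channel(p, EvidenceChannel.DRUG, mentions=[m])
        assert after.temporal_class == "after_only"
        before = classify_channel(
            p, EvidenceChannel.DRUG, mentions=[m], diagnosis_day_is_after=False
        )
        assert before.temporal_class == "before_only"

    def test_combined_channel_rejected_here(self):
        with pytest.raises(PhenotypingError):
            classify_channel(make_patient(), EvidenceChannel.COMBINED)


class TestCombineChannels:
    def _cls(self, pid, channel, tclass):
        return ChannelClassification(pid, channel, tclass)

    def test_union_semantics(self):
        per = [
            ChannelClassification("P1", EvidenceChannel.ICD, "after_only",
                                  events_after=["e"]),
            ChannelClassification("P1", EvidenceChannel.DRUG, "before_only",
                                  events_before=["e"]),
            ChannelClassification("P1", EvidenceChannel.DISORDER_TERM, "none"),
        ]
        assert combine_channels(per).temporal_class == "both"

    def test_all_none(self):
        per = [self._cls("P1", ch, "none") for ch in BASE_CHANNELS]
        assert combine_channels(per).temporal_class == "none"

    def test_single_after_only(self):
        per = [
            ChannelClassification("P1", EvidenceChannel.ICD, "none"),
            ChannelClassification("P1", EvidenceChannel.DRUG, "none"),
            ChannelClassification("P1", EvidenceChannel.DISORDER_TERM,
                                  "after_only", events_after=["e"]),
        ]
        assert combine_channels(per).temporal_class == "after_only"

    def test_missing_channel_rejected(self):
        per = [self._cls("P1", EvidenceChannel.ICD, "none")]
        with pytest.raises(PhenotypingError):
            combine_channels(per)


class TestPairedTable:
    def test_study_shaped_counts(self):
        cls = (
            [ChannelClassification(f"B{i}", EvidenceChannel.ICD, "both") for i in range(164)]
            + [ChannelClassification(f"P{i}", EvidenceChannel.ICD, "before_only") for i in range(89)]
            + [ChannelClassification(f"A{i}", EvidenceChannel.ICD, "after_only") for i in range(575)]
            + [ChannelClassification(f"N{i}", EvidenceChannel.ICD, "none") for i in range(3410)]
        )
        t = build_paired_table(cls)
        assert (t.n_total_considered, t.b, t.c, t.n_with) == (4074, 89, 575, 664)
        assert t.n_both_excluded == 164
        assert t.n_without == 3410

    def test_all_none(self):
        cls = [ChannelClassification(f"P{i}", EvidenceChannel.ICD, "none") for i in range(5)]
        t = build_paired_table(cls)
        assert (t.b, t.c, t.n_with) == (0, 0, 0)

    def test_degenerate_all_both(self):
        cls = [ChannelClassification(f"P{i}", EvidenceChannel.ICD, "both") for i in range(3)]
        assert build_paired_table(cls).n_total_considered == 0

    def test_duplicate_ids_rejected(self):
        cls = [
            ChannelClassification("P1", EvidenceChannel.ICD, "none"),
            ChannelClassification("P1", EvidenceChannel.ICD, "both"),
        ]
        with pytest.raises(PhenotypingError):
            build_paired_table(cls)

    def test_partition_invariant_on_synthetic_cohort(self, clean_cohort):
        from depehr.pipeline import run_study

        _, patients, _ = clean_cohort
        report, mentions = run_study(patients)
        n = report.n_selected
        for name, t in report.paired.items():
            assert t.n_total_considered + t.n_both_excluded == n


class TestAttribution:
    def _chan(self, pid, channel, tclass):
        return ChannelClassification(pid, channel, tclass)

    def test_ten_patient_hand_enumeration(self):
        """Hand-enumerated: patients 0-3 ICD-positive (2 of them also
        text-positive), 4-6 text-only, 7-9 negative -> split (4, 3)."""
        icd, drug, dis = [], [], []
        for i in range(10):
            pid = f"P{i}"
            icd.append(self._chan(pid, EvidenceChannel.ICD,
                                  "after_only" if i < 4 else "none"))
            drug.append(self._chan(pid, EvidenceChannel.DRUG,
                                   "before_only" if i in (0, 4, 5) else "none"))
            dis.append(self._chan(pid, EvidenceChannel.DISORDER_TERM,
                                  "both" if i in (1, 6) else "none"))
        assert attribution_split(icd, [drug, dis]) == (4, 3)

    def test_no_text_only_patients(self):
        icd = [self._chan("P1", EvidenceChannel.ICD, "after_only")]
        drug = [self._chan("P1", EvidenceChannel.DRUG, "none")]
        dis = [self._chan("P1", EvidenceChannel.DISORDER_TERM, "none")]
        assert attribution_split(icd, [drug, dis]) == (1, 0)

    def test_mismatched_patient_sets_rejected(self):
        icd = [self._chan("P1", EvidenceChannel.ICD, "none")]
        drug = [self._chan("P2", EvidenceChannel.DRUG, "none")]
        with pytest.raises(PhenotypingError):
            attribution_split(icd, [drug])

    def test_matches_set_arithmetic_on_synthetic_cohort(self, clean_cohort):
        _, patients, truth = clean_cohort
        from depehr.pipeline import run_study

        report, mentions = run_study(patients)
        included_ids = {
            p.patient_id for p in apply_selection_criteria(patients)[0]
        }
        icd_pos = {
            pid
            for pid in included_ids
            if truth.channel_classes[pid]["icd"] != "none"
        }
        text_pos = {
            pid
            for pid in included_ids
            if truth.channel_classes[pid]["drug"] != "none"
            or truth.channel_classes[pid]["disorder"] != "none"
        }
        expected = (len(icd_pos), len(text_pos - icd_pos))
        assert report.attribution == expected
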