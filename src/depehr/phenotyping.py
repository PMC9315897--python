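"""Patient selection, per-channel temporal classification, paired tables.

Each patient's depression evidence is classified per evidence channel
(ICD codes, antidepressant mentions, disorder-term mentions) relative to
the cancer-diagnosis index date into {none, before_only, after_only,
both}; a combined channel takes the union. Paired before/after tables
exclude the "both" patients and feed McNemar's test on the discordant
counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .cohort import PatientRecord, Visit
from .lexicons import CodeSet, code_matches, default_depression_codes
from .textmine import Mention


class PhenotypingError(ValueError):
    pass


class EvidenceChannel(str, Enum):
    ICD = "icd"
    DRUG = "drug"
    DISORDER_TERM = "disorder"
    COMBINED = "combined"


BASE_CHANNELS = (
    EvidenceChannel.ICD,
    EvidenceChannel.DRUG,
    EvidenceChannel.DISORDER_TERM,
)

_MENTION_CATEGORIES = {
    EvidenceChannel.DRUG: {"drug_substance", "drug_brand"},
    EvidenceChannel.DISORDER_TERM: {"disorder_term"},
}


@dataclass(frozen=True)
class EvidenceEvent:
    date: object  # datetime.date
    kind: str  # "icd" or "mention"
    detail: str


@dataclass
class ChannelClassification:
    patient_id: str
    channel: EvidenceChannel
    temporal_class: str  # none | before_only | after_only | both
    events_before: list[EvidenceEvent] = field(default_factory=list)
    events_after: list[EvidenceEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Selection criteria

_EXCLUSION_ORDER = (
    "multiple_or_unqualified_cancer",
    "insufficient_visits",
    "stage_iv",
    "incomplete_treatment_information",
)


def apply_selection_criteria(
    patients: list[PatientRecord],
) -> tuple[list[PatientRecord], dict[str, str]]:
    """Study inclusion filter.

    Included iff: exactly one qualifying cancer (breast or colorectal);
    >= 2 visits strictly before and >= 2 on-or-after the index date;
    stage in {in_situ, I, II, III}; treatment information present. Each
    excluded patient is tagged with its first failing rule, in that
    order.
    """
    included: list[PatientRecord] = []
    exclusions: dict[str, str] = {}
    for p in patients:
        if p.diagnosis_date is None:
            raise PhenotypingError(
                f"patient {p.patient_id} is missing a diagnosis date"
            )
        reason = None
        if p.cancer_type not in ("breast", "colorectal"):
            reason = "multiple_or_unqualified_cancer"
        elif len(p.visits_before()) < 2 or len(p.visits_on_or_after()) < 2:
            reason = "insufficient_visits"
        elif p.stage == "IV":
            reason = "stage_iv"
        elif p.chemotherapy is None:
            reason = "incomplete_treatment_information"
        if reason is None:
            included.append(p)
        else:
            exclusions[p.patient_id] = reason
    return included, exclusions


# ---------------------------------------------------------------------------
# Per-channel classification


def _visit_has_depression_code(visit: Visit, codes: CodeSet) -> bool:
    return any(code_matches(c, codes) for c in visit.icd_codes)


def classify_channel(
    patient: PatientRecord,
    channel: EvidenceChannel,
    mentions: list[Mention] | None = None,
    depression_codes: CodeSet | None = None,
    diagnosis_day_is_after: bool = True,
) -> ChannelClassification:
    """Classify one patient's evidence on one base channel.

    Evidence events are depression-coded visits (ICD channel) or
    non-negated mentions of the channel's categories; an event dated on
    the diagnosis day counts as "after" by default (configurable).
    """
    if channel not in BASE_CHANNELS:
        raise PhenotypingError(f"classify_channel cannot handle {channel}")
    if patient.diagnosis_date is None:
        raise PhenotypingError(
            f"patient {patient.patient_id} is missing a diagnosis date"
        )
    index_date = patient.diagnosis_date
    before: list[EvidenceEvent] = []
    after: list[EvidenceEvent] = []

    def bucket(date, event: EvidenceEvent) -> None:
        if date < index_date or (date == index_date and not diagnosis_day_is_after):
            before.append(event)
        else:
            after.append(event)

    if channel is EvidenceChannel.ICD:
        codes = depression_codes or default_depression_codes()
        for v in patient.visits:
            if _visit_has_depression_code(v, codes):
                bucket(v.date, EvidenceEvent(v.date, "icd", v.visit_id))
    else:
        cats = _MENTION_CATEGORIES[channel]
        visit_dates = {v.visit_id: v.date for v in patient.visits}
        for m in mentions or []:
            if m.patient_id != patient.patient_id:
                continue
            if m.negated or m.category not in cats:
                continue
            if m.visit_id not in visit_dates:
                raise PhenotypingError(
                    f"mention references unknown visit {m.visit_id}"
                )
            date = visit_dates[m.visit_id]
            bucket(date, EvidenceEvent(date, "mention", m.canonical))

    cls = _temporal(bool(before), bool(after))
    return ChannelClassification(
        patient_id=patient.patient_id,
        channel=channel,
        temporal_class=cls,
        events_before=before,
        events_after=after,
    )


def _temporal(before: bool, after: bool) -> str:
    if before and after:
        return "both"
    if before:
        return "before_only"
    if after:
        return "after_only"
    return "none"


def combine_channels(
    classifications: list[ChannelClassification],
) -> ChannelClassification:
    """Union of the three base channels for one patient."""
    have = {c.channel for c in classifications}
    if have != set(BASE_CHANNELS):
        raise PhenotypingError(
            f"combine_channels needs all of {[c.value for c in BASE_CHANNELS]}"
        )
    pids = {c.patient_id for c in classifications}
    if len(pids) != 1:
        raise PhenotypingError("classifications span multiple patients")
    before = [e for c in classifications for e in c.events_before]
    after = [e for c in classifications for e in c.events_after]
    return ChannelClassification(
        patient_id=pids.pop(),
        channel=EvidenceChannel.COMBINED,
        temporal_class=_temporal(bool(before), bool(after)),
        events_before=before,
        events_after=after,
    )


def classify_cohort(
    patients: list[PatientRecord],
    mentions: list[Mention],
    depression_codes: CodeSet | None = None,
    diagnosis_day_is_after: bool = True,
) -> dict[str, dict[EvidenceChannel, ChannelClassification]]:
    """Classify every patient on every channel (including COMBINED)."""
    by_patient: dict[str, list[Mention]] = {}
    for m in mentions:
        by_patient.setdefault(m.patient_id, []).append(m)
    out: dict[str, dict[EvidenceChannel, ChannelClassification]] = {}
    for p in patients:
        per = {
            ch: classify_channel(
                p,
                ch,
                mentions=by_patient.get(p.patient_id, []),
                depression_codes=depression_codes,
                diagnosis_day_is_after=diagnosis_day_is_after,
            )
            for ch in BASE_CHANNELS
        }
        per[EvidenceChannel.COMBINED] = combine_channels(list(per.values()))
        out[p.patient_id] = per
    return out


# ---------------------------------------------------------------------------
# Paired tables and attribution


@dataclass
class PairedTable:
    """Before/after paired layout for one channel.

    ``both`` patients are excluded; among the ``n_total_considered``
    remaining, ``b`` have evidence only before and ``c`` only after the
    index date (the McNemar discordant counts).
    """

    n_total_considered: int
    n_both_excluded: int
    b: int
    c: int

    @property
    def n_with(self) -> int:
        return self.b + self.c

    @property
    def n_without(self) -> int:
        return self.n_total_considered - self.n_with

    def __post_init__(self) -> None:
        if min(self.n_total_considered, self.n_both_excluded, self.b, self.c) < 0:
            raise PhenotypingError("paired-table counts must be non-negative")
        if self.n_with > self.n_total_considered:
            raise PhenotypingError("b + c exceeds the considered total")


def build_paired_table(
    classifications: list[ChannelClassification],
) -> PairedTable:
    ids = [c.patient_id for c in classifications]
    if len(ids) != len(set(ids)):
        raise PhenotypingError("duplicate patient ids in classifications")
    counts = {"none": 0, "before_only": 0, "after_only": 0, "both": 0}
    for c in classifications:
        counts[c.temporal_class] += 1
    return PairedTable(
        n_total_considered=len(classifications) - counts["both"],
        n_both_excluded=counts["both"],
        b=counts["before_only"],
        c=counts["after_only"],
    )


def attribution_split(
    icd: list[ChannelClassification],
    text_channels: list[list[ChannelClassification]],
) -> tuple[int, int]:
    """Partition evidence-positive patients into ICD-detected vs text-only.

    Among patients with any depression evidence on any channel in any
    period, ``text_only`` counts those with no ICD evidence at all;
    ``icd_detected`` is the rest.
    """
    icd_by_pid = {c.patient_id: c for c in icd}
    all_pids = set(icd_by_pid)
    for chan in text_channels:
        if {c.patient_id for c in chan} != all_pids:
            raise PhenotypingError("channel classifications cover different patients")
    positive: set[str] = {
        c.patient_id
        for chan in [icd, *text_channels]
        for c in chan
        if c.temporal_class != "none"
    }
    text_only = sum(
        1 for pid in positive if icd_by_pid[pid].temporal_class == "none"
    )
    return len(positive) - text_only, text_only


# ---------------------------------------------------------------------------
# IO


def write_classifications(
    classifications: dict[str, dict[EvidenceChannel, ChannelClassification]],
    path: str | Path,
) -> None:
    rows = [
        {
            "patient_id": pid,
            "channel": ch.value,
            "temporal_class": c.temporal_class,
            "n_events_before": len(c.events_before),
            "n_events_after": len(c.events_after),
        }
        for pid, per in classifications.items()
        for ch, c in per.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_paired_tables(
    tables: dict[str, PairedTable], path: str | Path
) -> None:
    payload = {
        name: {
            "n_total_considered": t.n_total_considered,
            "n_both_excluded": t.n_both_excluded,
            "b": t.b,
            "c": t.c,
            "n_with": t.n_with,
            "n_without": t.n_without,
        }
        for name, t in tables.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
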