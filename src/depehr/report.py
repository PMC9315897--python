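"""Study-shaped report tables and summary statistics.

Renders the analysis outputs in the standard results-table layout for
this design: T1 (cancer type x stage, with ICD-coded depression after the
index date), T2-T4 (per-channel paired before/after tables by cancer
type), T5 (the combined channel), and T6 (attribution of depression
detection to coded data vs text mining), plus the McNemar and chi-square
statistics computed from the same counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import PatientRecord, STAGES
from .phenotyping import (
    BASE_CHANNELS,
    ChannelClassification,
    EvidenceChannel,
    PairedTable,
    PhenotypingError,
    attribution_split,
    build_paired_table,
)
from .stats import McNemarResult, chisq_independence, mcnemar_cc, proportion_cell


@dataclass
class ReportTable:
    table_id: str
    title: str
    columns: list[str]
    rows: list[list[str]]  # first cell is the row label


@dataclass
class StudyReport:
    n_selected: int
    exclusion_counts: dict[str, int]
    paired: dict[str, PairedTable]
    mcnemar: dict[str, McNemarResult]
    attribution: tuple[int, int]  # (icd_detected, text_only)
    chemo_chi2: tuple[float, int, float] | None
    tables: list[ReportTable] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_selected": self.n_selected,
            "exclusion_counts": self.exclusion_counts,
            "paired": {
                name: {
                    "n_total_considered": t.n_total_considered,
                    "n_both_excluded": t.n_both_excluded,
                    "b": t.b,
                    "c": t.c,
                }
                for name, t in self.paired.items()
            },
            "mcnemar": {
                name: {"b": r.b, "c": r.c, "chi2": r.chi2, "df": r.df, "p": r.p}
                for name, r in self.mcnemar.items()
            },
            "attribution": {
                "icd_detected": self.attribution[0],
                "text_only": self.attribution[1],
            },
            "chemo_chi2": None
            if self.chemo_chi2 is None
            else {
                "chi2": self.chemo_chi2[0],
                "df": self.chemo_chi2[1],
                "p": self.chemo_chi2[2],
            },
            "tables": [
                {
                    "table_id": t.table_id,
                    "title": t.title,
                    "columns": t.columns,
                    "rows": t.rows,
                }
                for t in self.tables
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False))


_CHANNEL_TITLES = {
    EvidenceChannel.ICD: "ICD-9-CM depression diagnosis codes",
    EvidenceChannel.DRUG: "antidepressant drug mentions",
    EvidenceChannel.DISORDER_TERM: "depressive-disorder concept mentions",
    EvidenceChannel.COMBINED: "any evidence channel (combined)",
}


def _paired_rows(
    patients_by_id: dict[str, PatientRecord],
    classifications: list[ChannelClassification],
) -> list[list[str]]:
    rows = []
    groups = [
        ("Breast", lambda p: p.cancer_type == "breast"),
        ("Colorectal", lambda p: p.cancer_type == "colorectal"),
        ("Total", lambda p: True),
    ]
    for label, pred in groups:
        sub = [
            c for c in classifications if pred(patients_by_id[c.patient_id])
        ]
        t = build_paired_table(sub)
        if t.n_with == 0 or t.n_total_considered == 0:
            rows.append([label, "0/0", "0/0", "0/0", "0/0"])
            continue
        rows.append(
            [
                label,
                proportion_cell(t.b, t.n_with),
                proportion_cell(t.c, t.n_with),
                proportion_cell(t.n_with, t.n_total_considered),
                proportion_cell(t.n_without, t.n_total_considered),
            ]
        )
    return rows


def render_tables(
    patients: list[PatientRecord],
    classifications: dict[str, dict[EvidenceChannel, ChannelClassification]],
) -> list[ReportTable]:
    """Build T1-T6-shaped tables from selected patients and their
    per-channel classifications."""
    if not patients:
        return []
    pids = {p.patient_id for p in patients}
    if set(classifications) != pids:
        missing = pids.symmetric_difference(classifications)
        raise PhenotypingError(
            f"patients and classifications disagree on ids: {sorted(missing)[:5]}"
        )
    by_id = {p.patient_id: p for p in patients}
    tables = []

    # T1: type x stage, with ICD-coded depression after the index date
    rows = []
    for ctype, label in (("breast", "Breast"), ("colorectal", "Colorectal")):
        sub = [p for p in patients if p.cancer_type == ctype]
        n_type = len(sub)
        for stage in [s for s in STAGES if s != "IV"]:
            stage_p = [p for p in sub if p.stage == stage]
            dep_after = sum(
                1
                for p in stage_p
                if classifications[p.patient_id][EvidenceChannel.ICD].temporal_class
                in ("after_only", "both")
            )
            if n_type and stage_p:
                rows.append(
                    [
                        f"{label} {stage}",
                        proportion_cell(len(stage_p), n_type),
                        proportion_cell(dep_after, len(stage_p)),
                    ]
                )
        if n_type:
            dep_all = sum(
                1
                for p in sub
                if classifications[p.patient_id][EvidenceChannel.ICD].temporal_class
                in ("after_only", "both")
            )
            rows.append(
                [
                    f"{label} all stages",
                    proportion_cell(n_type, n_type),
                    proportion_cell(dep_all, n_type),
                ]
            )
    tables.append(
        ReportTable(
            "T1",
            "Patients by cancer type and stage, with ICD-coded depression "
            "after the cancer diagnosis",
            ["Group", "Patients, n/N (%)", "Depression (ICD) after, n/N (%)"],
            rows,
        )
    )

    paired_cols = [
        "Cancer type",
        "Before index date, n/N (%)",
        "After index date, n/N (%)",
        "With depression, n/N (%)",
        "Without depression, n/N (%)",
    ]
    for tid, channel in zip(
        ("T2", "T3", "T4", "T5"),
        (
            EvidenceChannel.ICD,
            EvidenceChannel.DRUG,
            EvidenceChannel.DISORDER_TERM,
            EvidenceChannel.COMBINED,
        ),
    ):
        chan_cls = [classifications[pid][channel] for pid in sorted(pids)]
        tables.append(
            ReportTable(
                tid,
                f"Patients with {_CHANNEL_TITLES[channel]} before and after "
                "the cancer diagnosis date",
                paired_cols,
                _paired_rows(by_id, chan_cls),
            )
        )

    # T6: attribution (ICD-detected vs text-mining-only), by cancer type
    rows = []
    for label, pred in (
        ("Breast", lambda p: p.cancer_type == "breast"),
        ("Colorectal", lambda p: p.cancer_type == "colorectal"),
        ("Total", lambda p: True),
    ):
        sub_ids = sorted(pid for pid in pids if pred(by_id[pid]))
        icd = [classifications[pid][EvidenceChannel.ICD] for pid in sub_ids]
        texts = [
            [classifications[pid][ch] for pid in sub_ids]
            for ch in (EvidenceChannel.DRUG, EvidenceChannel.DISORDER_TERM)
        ]
        icd_detected, text_only = attribution_split(icd, texts)
        n_pos = icd_detected + text_only
        if n_pos == 0:
            rows.append([label, "0/0", "0/0"])
            continue
        rows.append(
            [
                label,
                proportion_cell(icd_detected, n_pos),
                proportion_cell(text_only, n_pos),
            ]
        )
    tables.append(
        ReportTable(
            "T6",
            "Depression-positive patients detected by ICD codes vs "
            "exclusively by text mining",
            ["Cancer type", "ICD-detected, n/N (%)", "Text-mining only, n/N (%)"],
            rows,
        )
    )
    return tables


def build_report(
    patients: list[PatientRecord],
    classifications: dict[str, dict[EvidenceChannel, ChannelClassification]],
    exclusions: dict[str, str] | None = None,
) -> StudyReport:
    """Paired tables, McNemar tests, attribution and the chemotherapy
    association for a classified cohort."""
    paired: dict[str, PairedTable] = {}
    mcnemar: dict[str, McNemarResult] = {}
    pids = sorted(p.patient_id for p in patients)
    for channel in (*BASE_CHANNELS, EvidenceChannel.COMBINED):
        chan_cls = [classifications[pid][channel] for pid in pids]
        t = build_paired_table(chan_cls)
        paired[channel.value] = t
        if t.b + t.c > 0:
            mcnemar[channel.value] = mcnemar_cc(t.b, t.c)

    icd = [classifications[pid][EvidenceChannel.ICD] for pid in pids]
    texts = [
        [classifications[pid][ch] for pid in pids]
        for ch in (EvidenceChannel.DRUG, EvidenceChannel.DISORDER_TERM)
    ]
    attribution = attribution_split(icd, texts) if pids else (0, 0)

    chemo_chi2 = None
    by_id = {p.patient_id: p for p in patients}
    table = [[0, 0], [0, 0]]
    for pid in pids:
        p = by_id[pid]
        if p.chemotherapy is None:
            continue
        depressed = (
            classifications[pid][EvidenceChannel.COMBINED].temporal_class != "none"
        )
        table[int(bool(p.chemotherapy))][int(depressed)] += 1
    try:
        chemo_chi2 = chisq_independence(table)
    except Exception:
        chemo_chi2 = None

    exclusion_counts: dict[str, int] = {}
    for reason in (exclusions or {}).values():
        exclusion_counts[reason] = exclusion_counts.get(reason, 0) + 1

    return StudyReport(
        n_selected=len(patients),
        exclusion_counts=exclusion_counts,
        paired=paired,
        mcnemar=mcnemar,
        attribution=attribution,
        chemo_chi2=chemo_chi2,
        tables=render_tables(patients, classifications),
    )
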