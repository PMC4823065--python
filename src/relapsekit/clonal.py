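"""Blast-adjusted allele frequencies and clonal evolution patterns.

A raw variant allele frequency (VAF) in a marrow sample underestimates the
prevalence of a mutation among tumor cells when the sample also contains
non-leukemic cells. Dividing by the blast fraction gives the
"% variant in tumor":

    adjusted = 100 * [v / (v + w)] / (blast_pct / 100)

For a heterozygous diploid mutation this is half the percentage of tumor
cells carrying it, so ~50% means the mutation is present in virtually every
tumor cell. Complete-remission samples are left unadjusted (no blast
compartment to normalise by).

Patient-level patterns follow from mutation sharing between diagnosis and
relapse alone: a relapse carrying only mutations already seen at diagnosis
points to a surviving subclone; partial overlap with private mutations on
both sides points to a common progenitor; zero overlap marks the relapse as
a genetically distinct second malignancy.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .datamodel import ClonalPattern, MutationStatus, ReadCountRecord, Stage
from .util import round_half_up

logger = logging.getLogger(__name__)

#: Adjusted values above this are possible under sampling noise or blast
#: underestimates and are flagged rather than clipped.
SUPER_CLONAL_LIMIT = 100.0

#: A mutation counts as present at a stage when it has more variant reads
#: than this (the strict > rule of the upstream call-quality filter).
PRESENCE_MIN_VAR_READS = 3


def adjusted_vaf(var_reads: int, wt_reads: int, blast_pct: Optional[float] = None) -> float:
    """Blast-adjusted "% variant in tumor", rounded half-up to 1 decimal.

    With ``blast_pct`` absent (CR samples) the raw VAF percentage is
    returned. Values above 100 are returned as computed; use
    :func:`is_super_clonal` to flag them.
    """
    total = var_reads + wt_reads
    if total <= 0:
        raise ValueError("zero total reads: VAF undefined")
    raw = 100.0 * var_reads / total
    if blast_pct is None:
        return round_half_up(raw, 1)
    if blast_pct <= 0:
        raise ValueError("blast_pct must be positive")
    return round_half_up(raw / (blast_pct / 100.0), 1)


def is_super_clonal(adjusted: float) -> bool:
    """True when an adjusted value exceeds 100% of tumor cells."""
    return adjusted > SUPER_CLONAL_LIMIT


def mutation_status(present_at_diagnosis: bool, present_at_relapse: bool) -> MutationStatus:
    """Classify one mutation by its presence at diagnosis and relapse."""
    if not (present_at_diagnosis or present_at_relapse):
        raise ValueError("mutation absent at both stages is not a mutation of this patient")
    if present_at_diagnosis and present_at_relapse:
        return MutationStatus.shared
    if present_at_diagnosis:
        return MutationStatus.diagnosis_specific
    return MutationStatus.relapse_specific


def classify_pattern(statuses: Sequence[MutationStatus]) -> ClonalPattern:
    """Patient-level clonal evolution pattern from per-mutation statuses.

    With S shared, D diagnosis-specific and R relapse-specific mutations:
    S = 0 -> second malignancy; S > 0 with D = R = 0 -> subclone survival;
    S > 0 with private mutations on either side -> common progenitor.
    Order-invariant and total over every non-empty combination.
    """
    if not statuses:
        raise ValueError("need at least one mutation status")
    counts = Counter(MutationStatus(s) for s in statuses)
    shared = counts[MutationStatus.shared]
    diag = counts[MutationStatus.diagnosis_specific]
    rel = counts[MutationStatus.relapse_specific]
    if shared == 0:
        return ClonalPattern.second_malignancy
    if diag == 0 and rel == 0:
        return ClonalPattern.subclone_survival
    return ClonalPattern.common_progenitor


def vaf_shift(diag_adj: float, relapse_adj: float, min_shift: float = 5.0) -> str:
    """Direction of the adjusted-VAF change from diagnosis to relapse.

    Returns "rising" / "falling" when the move exceeds ``min_shift``
    percentage points, else "stable".
    """
    if diag_adj < 0 or relapse_adj < 0:
        raise ValueError("adjusted VAFs must be non-negative")
    delta = relapse_adj - diag_adj
    if delta > min_shift:
        return "rising"
    if delta < -min_shift:
        return "falling"
    return "stable"


# ---------------------------------------------------------------------------
# report over a read-count table

@dataclass(frozen=True)
class MutationReport:
    patient: str
    gene: str
    aa_change: str
    adjusted_diagnosis: Optional[float]
    adjusted_relapse: Optional[float]
    adjusted_cr: Optional[float]
    status: MutationStatus
    shift: Optional[str]
    super_clonal: bool


@dataclass(frozen=True)
class PatientReport:
    patient: str
    pattern: ClonalPattern
    mutations: tuple[MutationReport, ...]


def build_reports(
    records: Iterable[ReadCountRecord],
    min_shift: float = 5.0,
    presence_min_var_reads: int = PRESENCE_MIN_VAR_READS,
) -> list[PatientReport]:
    """Per-mutation adjusted VAFs, statuses, shifts and per-patient patterns.

    Records are grouped by (patient, gene, amino-acid change); a mutation is
    present at a stage when its variant reads exceed
    ``presence_min_var_reads`` there. Mutations detected at neither tumor
    stage are dropped with a warning (they contribute no status). Mutations
    lacking a stage record leave that stage's adjusted value as None; the
    shift needs both tumor stages.
    """
    grouped: dict[tuple[str, str, str], dict[Stage, ReadCountRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        key = (rec.patient, rec.gene, rec.aa_change)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        if rec.stage in grouped[key]:
            raise ValueError(f"duplicate stage {rec.stage.value} for {key}")
        grouped[key][rec.stage] = rec

    per_patient: dict[str, list[MutationReport]] = {}
    patient_order: list[str] = []
    for key in order:
        patient, gene, aa = key
        stages = grouped[key]
        adj = {}
        for stage in Stage:
            rec = stages.get(stage)
            adj[stage] = None if rec is None else adjusted_vaf(rec.var_reads, rec.wt_reads, rec.blast_pct)
        present = {
            stage: (stages[stage].var_reads > presence_min_var_reads if stage in stages else False)
            for stage in (Stage.diagnosis, Stage.relapse)
        }
        if not (present[Stage.diagnosis] or present[Stage.relapse]):
            logger.warning("%s %s %s: undetected at both tumor stages; dropped", patient, gene, aa)
            continue
        status = mutation_status(present[Stage.diagnosis], present[Stage.relapse])
        shift = None
        if adj[Stage.diagnosis] is not None and adj[Stage.relapse] is not None:
            shift = vaf_shift(adj[Stage.diagnosis], adj[Stage.relapse], min_shift)
        report = MutationReport(
            patient=patient, gene=gene, aa_change=aa,
            adjusted_diagnosis=adj[Stage.diagnosis],
            adjusted_relapse=adj[Stage.relapse],
            adjusted_cr=adj[Stage.CR],
            status=status, shift=shift,
            super_clonal=any(v is not None and is_super_clonal(v) for v in adj.values()),
        )
        if patient not in per_patient:
            per_patient[patient] = []
            patient_order.append(patient)
        per_patient[patient].append(report)

    return [
        PatientReport(
            patient=p,
            pattern=classify_pattern([m.status for m in per_patient[p]]),
            mutations=tuple(per_patient[p]),
        )
        for p in patient_order
    ]
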