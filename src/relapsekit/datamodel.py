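"""Domain types for matched diagnosis/remission/relapse/donor leukemia genomics.

The central objects are per-sample variant calls with read counts, matched
patient trios (diagnosis, complete remission, relapse) plus the transplant
donor, Sanger/exome read-count records carrying marrow blast percentages,
STR electropherogram profiles, and cohort-level mutation tables.

Coordinates are 1-based throughout (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Effect(str, Enum):
    """Predicted coding consequence of a variant."""

    nonsynonymous = "nonsynonymous"
    synonymous = "synonymous"
    frameshift = "frameshift"
    stopgain = "stopgain"
    inframe_indel = "inframe_indel"
    splice_site = "splice_site"
    other = "other"


class Stage(str, Enum):
    """Sampling time point relative to transplant."""

    diagnosis = "diagnosis"
    CR = "CR"
    relapse = "relapse"


class Group(str, Enum):
    relapsed = "relapsed"
    non_relapsed = "non_relapsed"


class MutationStatus(str, Enum):
    """Presence pattern of a mutation across diagnosis and relapse.

    ``diagnosis_only_nonrelapsed`` is reserved for patients who never
    relapsed (there is no relapse sample to compare against).
    """

    diagnosis_specific = "diagnosis_specific"
    shared = "shared"
    relapse_specific = "relapse_specific"
    diagnosis_only_nonrelapsed = "diagnosis_only_nonrelapsed"


class ClonalPattern(str, Enum):
    """Patient-level clonal evolution pattern from diagnosis to relapse.

    subclone_survival: the relapse clone pre-existed as a subclone of the
    diagnosed tumor (every relapse mutation was already present).
    common_progenitor: diagnosis and relapse clones share an ancestor but
    each acquired private mutations.
    second_malignancy: the relapse shares no mutation with the diagnosis
    tumor and behaves as a genetically distinct leukemia.
    """

    subclone_survival = "subclone_survival"
    common_progenitor = "common_progenitor"
    second_malignancy = "second_malignancy"


#: Effects treated as protein-altering for candidate selection.
PROTEIN_ALTERING = frozenset(
    {
        Effect.nonsynonymous,
        Effect.frameshift,
        Effect.stopgain,
        Effect.inframe_indel,
        Effect.splice_site,
    }
)


@dataclass(frozen=True)
class VariantCall:
    """One variant observation in one sample.

    ``pos`` is 1-based. ``var_reads``/``ref_reads`` are the allelic depths
    at the site in this sample.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect
    var_reads: int
    ref_reads: int
    mapping_quality: float = 60.0
    base_quality: float = 30.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.var_reads < 0 or self.ref_reads < 0:
            raise ValueError("read counts must be non-negative")
        if not isinstance(self.effect, Effect):
            object.__setattr__(self, "effect", Effect(self.effect))

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity used for matching across samples."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.var_reads + self.ref_reads

    @property
    def vaf(self) -> float:
        """Variant allele frequency; 0.0 at zero depth."""
        d = self.depth
        return self.var_reads / d if d else 0.0


@dataclass(frozen=True)
class ReadCountRecord:
    """Variant/wild-type read counts for one mutation at one stage.

    ``blast_pct`` is the marrow blast percentage of the sample, used to
    adjust the raw VAF to a per-tumor-cell prevalence. It is absent
    (``None``) exactly for complete-remission samples, which are not
    blast-adjusted.
    """

    patient: str
    gene: str
    aa_change: str
    stage: Stage
    var_reads: int
    wt_reads: int
    blast_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.stage, Stage):
            object.__setattr__(self, "stage", Stage(self.stage))
        if self.var_reads < 0 or self.wt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.stage is Stage.CR:
            if self.blast_pct is not None:
                raise ValueError("CR records carry no blast percentage")
        else:
            if self.blast_pct is None:
                raise ValueError(f"{self.stage.value} record requires blast_pct")
            if not (0 < self.blast_pct <= 100):
                raise ValueError("blast_pct must be in (0, 100]")


@dataclass
class PatientTrio:
    """Matched diagnosis / CR / relapse call sets plus the donor's calls.

    ``relapse_calls`` is None for non-relapsed patients, whose status is
    assessed from diagnosis and CR only.
    """

    patient: str
    diagnosis_calls: list[VariantCall]
    cr_calls: list[VariantCall]
    donor_calls: list[VariantCall]
    relapse_calls: Optional[list[VariantCall]] = None
    group: Group = Group.relapsed

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            self.group = Group(self.group)
        if (self.relapse_calls is not None) != (self.group is Group.relapsed):
            raise ValueError("relapse_calls present iff group is relapsed")


@dataclass
class STRProfile:
    """Per-locus electropherogram peak heights for one sample.

    ``loci`` maps locus name -> {allele repeat number -> peak height}.
    Heights are in relative fluorescence units (RFU) and must be positive;
    absent peaks are simply absent from the map.
    """

    sample_id: str
    loci: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for locus, peaks in self.loci.items():
            for rep, h in peaks.items():
                if rep <= 0 or int(rep) != rep:
                    raise ValueError(f"{locus}: repeat numbers must be positive integers")
                if h <= 0:
                    raise ValueError(f"{locus}: peak heights must be > 0 (allele {rep})")

    def alleles(self, locus: str) -> set[int]:
        return set(self.loci.get(locus, {}))


@dataclass(frozen=True)
class CohortRecord:
    """One mutation of one patient in the cohort table."""

    patient: str
    group: Group
    gene: str
    mutation_id: str
    status: MutationStatus
    cohort: str = "extension"  # "discovery" (exome trios) or "extension"

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))
        if not isinstance(self.status, MutationStatus):
            object.__setattr__(self, "status", MutationStatus(self.status))
        if self.group is Group.non_relapsed and self.status is not MutationStatus.diagnosis_only_nonrelapsed:
            raise ValueError("non-relapsed patients carry status diagnosis_only_nonrelapsed")


@dataclass
class CohortMutationTable:
    """Patient x gene x mutation records plus explicit group denominators.

    Group sizes are metadata, never inferred from the records: patients
    without any mutation have no record at all, so record counts cannot
    recover cohort denominators.
    """

    records: list[CohortRecord]
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for r in self.records:
            k = (r.patient, r.gene, r.mutation_id)
            if k in seen:
                raise ValueError(f"duplicate (patient, gene, mutation): {k}")
            seen.add(k)


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs for candidate somatic mutation selection.

    Defaults implement the selection rule: tumor VAF >= 15% with >= 20x
    depth in either tumor sample, remission VAF < 0.5%, and the upstream
    call-quality rule (mapping quality > 30, base quality > 15, variant
    reads > 3 — all strict).
    """

    min_tumor_vaf: float = 0.15
    min_tumor_depth: int = 20
    max_remission_vaf: float = 0.005
    min_mapping_quality: float = 30.0
    min_base_quality: float = 15.0
    min_var_reads: int = 3  # strict: var_reads > 3 survives
    require_both_tumors: bool = False  # "either" tumor sample by default

    def __post_init__(self) -> None:
        for name in ("min_tumor_vaf", "min_tumor_depth", "max_remission_vaf",
                     "min_mapping_quality", "min_base_quality", "min_var_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_tumor_vaf > 1 or self.max_remission_vaf > 1:
            raise ValueError("VAF thresholds are fractions in [0, 1]")


@dataclass(frozen=True)
class Clone:
    """A clone in a perfect-phylogeny clone tree.

    ``mutations`` is the clone's full genotype (its own plus all inherited
    mutations); ``fraction_at_*`` is the fraction of tumor cells whose exact
    genotype is this clone's, at that stage.
    """

    id: str
    mutations: frozenset[str]
    fraction_at_diagnosis: float
    fraction_at_relapse: float
    parent: Optional[str] = None


@dataclass
class CloneModel:
    """Ground-truth clonal architecture for a simulated patient."""

    clones: list[Clone]
    blast_pct_diagnosis: float
    blast_pct_relapse: float
    residual_cr_fraction: float = 0.0

    def __post_init__(self) -> None:
        by_id = {c.id: c for c in self.clones}
        for c in self.clones:
            if not (0 <= c.fraction_at_diagnosis <= 1 and 0 <= c.fraction_at_relapse <= 1):
                raise ValueError(f"clone {c.id}: fractions must lie in [0, 1]")
            if c.parent is not None:
                parent = by_id.get(c.parent)
                if parent is None:
                    raise ValueError(f"clone {c.id}: unknown parent {c.parent}")
                if not c.mutations >= parent.mutations:
                    raise ValueError(
                        f"clone {c.id} violates perfect phylogeny: "
                        "child mutation set must contain the parent's"
                    )
        for stage_attr in ("fraction_at_diagnosis", "fraction_at_relapse"):
            total = sum(getattr(c, stage_attr) for c in self.clones)
            if total > 1 + 1e-9:
                raise ValueError(f"{stage_attr} fractions sum to {total:.3f} > 1")
        for pct in (self.blast_pct_diagnosis, self.blast_pct_relapse):
            if not (0 < pct <= 100):
                raise ValueError("blast percentages must be in (0, 100]")
        if not (0 <= self.residual_cr_fraction <= 1):
            raise ValueError("residual_cr_fraction must be in [0, 1]")

    def mutation_cell_fraction(self, mutation: str, stage: Stage) -> float:
        """Fraction of tumor cells carrying ``mutation`` at ``stage``."""
        attr = "fraction_at_diagnosis" if stage is Stage.diagnosis else "fraction_at_relapse"
        return sum(getattr(c, attr) for c in self.clones if mutation in c.mutations)

    def mutations(self) -> set[str]:
        out: set[str] = set()
        for c in self.clones:
            out |= c.mutations
        return out


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic cohort generator.

    Depth is drawn per site as negative binomial with ``mean_depth`` and
    ``depth_dispersion`` (0 degenerates to a fixed depth), emulating the
    wide per-site spread of exome read counts (~15-170x around a ~100x
    mean). ``str_noise_cv`` is the coefficient of variation of the
    multiplicative lognormal peak-height noise; ``stutter_rate`` adds a
    minus-one-repeat stutter peak as that fraction of the parent peak.
    """

    mean_depth: float = 100.0
    depth_dispersion: float = 0.3
    n_known_snp_contaminants: int = 20
    n_donor_variants: int = 5
    str_noise_cv: float = 0.1
    stutter_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in ("depth_dispersion", "n_known_snp_contaminants",
                     "n_donor_variants", "str_noise_cv", "stutter_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class InformativeLocus:
    """An STR locus usable for chimerism quantification.

    Carries the CR(patient)-specific and donor-specific alleles detected in
    the relapse sample and the patient-cell ratio computed from their peak
    heights.
    """

    locus: str
    cr_specific_alleles: frozenset[int]
    donor_specific_alleles: frozenset[int]
    ratio: float

    def __post_init__(self) -> None:
        if not self.cr_specific_alleles or not self.donor_specific_alleles:
            raise ValueError("informative locus requires both specific-allele sets non-empty")
        if not (0 <= self.ratio <= 1):
            raise ValueError("ratio must lie in [0, 1]")
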