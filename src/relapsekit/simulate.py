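"""Synthetic diagnosis/CR/relapse/donor data with known ground truth.

The generator emulates the observable layer of a matched-trio relapse
study so every downstream stage runs offline:

* a perfect-phylogeny clone tree per patient, with per-clone cell
  fractions at diagnosis and relapse chosen to realise one of the three
  clonal evolution patterns (surviving subclone, common progenitor,
  second malignancy);
* per-site read counts: depth ~ negative binomial around ``mean_depth``
  (the exome trios averaged ~106x with per-site spread of roughly
  15-170 reads), variant reads ~ Binomial(depth, f/2 x blast fraction)
  for a heterozygous mutation carried by a cell fraction f;
* germline contaminants (known SNPs, present in every sample and listed
  in the generated blacklist) and donor-private variants that leak into
  the relapse sample through the non-blast donor compartment;
* STR electropherograms as peak heights proportional to cell fractions
  with multiplicative lognormal noise and optional minus-one-repeat
  stutter;
* cohort mutation tables with per-gene Bernoulli mutation rates per group.

All randomness flows from ``SimParams.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import (
    Clone,
    CloneModel,
    CohortMutationTable,
    CohortRecord,
    Effect,
    Group,
    MutationStatus,
    PatientTrio,
    ReadCountRecord,
    SimParams,
    Stage,
    STRProfile,
    VariantCall,
)
from .datamodel import ClonalPattern
from .chimerism import DEFAULT_LOCI
from .clonal import classify_pattern, mutation_status

Key = tuple[str, int, str, str]

_PROTEIN_ALTERING_CYCLE = (
    Effect.nonsynonymous, Effect.nonsynonymous, Effect.frameshift,
    Effect.nonsynonymous, Effect.stopgain, Effect.inframe_indel,
)

#: Default blast percentages for simulated tumor samples (study marrows
#: carried >30% blasts; the exome trios ranged 33-95%).
DEFAULT_BLAST_DIAGNOSIS = 90.0
DEFAULT_BLAST_RELAPSE = 90.0


def default_clone_model(pattern: ClonalPattern, residual_cr_fraction: float = 0.0) -> CloneModel:
    """Canonical clone tree realising a clonal evolution pattern.

    subclone_survival: founder (5 mutations, 70% of diagnosis cells as
    exact genotype) with a subclone (3 extra mutations, 30%) that takes
    over the relapse. common_progenitor: an ancestral genotype (2 shared
    mutations) whose two children — the diagnosis clone (5 private) and
    the relapse clone (2 private) — each fully occupy their stage.
    second_malignancy: two unrelated clones (4 mutations each), one per
    stage, sharing nothing.
    """
    pattern = ClonalPattern(pattern)
    m = [f"M{i:02d}" for i in range(12)]
    if pattern is ClonalPattern.subclone_survival:
        founder = frozenset(m[0:5])
        sub = founder | frozenset(m[5:8])
        clones = [
            Clone(id="founder", mutations=founder, fraction_at_diagnosis=0.7, fraction_at_relapse=0.0),
            Clone(id="subclone", mutations=sub, parent="founder",
                  fraction_at_diagnosis=0.3, fraction_at_relapse=1.0),
        ]
    elif pattern is ClonalPattern.common_progenitor:
        progenitor = frozenset(m[0:2])
        clones = [
            Clone(id="progenitor", mutations=progenitor, fraction_at_diagnosis=0.0, fraction_at_relapse=0.0),
            Clone(id="diagnosis_clone", mutations=progenitor | frozenset(m[2:7]),
                  parent="progenitor", fraction_at_diagnosis=1.0, fraction_at_relapse=0.0),
            Clone(id="relapse_clone", mutations=progenitor | frozenset(m[7:9]),
                  parent="progenitor", fraction_at_diagnosis=0.0, fraction_at_relapse=1.0),
        ]
    else:  # second malignancy: disjoint trees
        clones = [
            Clone(id="primary", mutations=frozenset(m[0:4]), fraction_at_diagnosis=1.0, fraction_at_relapse=0.0),
            Clone(id="secondary", mutations=frozenset(m[4:8]), fraction_at_diagnosis=0.0, fraction_at_relapse=1.0),
        ]
    return CloneModel(
        clones=clones,
        blast_pct_diagnosis=DEFAULT_BLAST_DIAGNOSIS,
        blast_pct_relapse=DEFAULT_BLAST_RELAPSE,
        residual_cr_fraction=residual_cr_fraction,
    )


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    pattern: ClonalPattern
    statuses: dict[str, MutationStatus]          # mutation id -> truth
    somatic_keys: dict[str, Key]                 # mutation id -> variant site
    blacklist: set[Key]                          # known-SNP contaminant sites
    donor_keys: set[Key]                         # donor-private variant sites


@dataclass
class SimulatedPatient:
    clone_model: CloneModel
    trio: PatientTrio
    readcounts: list[ReadCountRecord]
    truth: GroundTruth


def _sample_depth(rng: np.random.Generator, params: SimParams) -> int:
    if params.depth_dispersion == 0:
        return max(1, int(round(params.mean_depth)))
    # NB with variance m + dispersion * m^2
    size = 1.0 / params.depth_dispersion
    p = size / (size + params.mean_depth)
    return max(1, int(rng.negative_binomial(size, p)))


def _site_catalog(mutation_ids: list[str], start: int = 0) -> dict[str, tuple[Key, str, Effect]]:
    out = {}
    for i, mid in enumerate(mutation_ids, start=start):
        key = (f"chr{(i % 22) + 1}", 1_000_000 + 1_000 * i, "A", "G")
        out[mid] = (key, f"GENE{i:03d}", _PROTEIN_ALTERING_CYCLE[i % len(_PROTEIN_ALTERING_CYCLE)])
    return out


def simulate_patient(
    pattern: ClonalPattern,
    params: SimParams,
    model: Optional[CloneModel] = None,
    patient: str = "SIM001",
) -> SimulatedPatient:
    """Simulate one matched trio plus donor calls under a clonal pattern.

    Returns the clone model, the call-level trio (including germline
    known-SNP contaminants present everywhere and donor-private variants
    leaking into the relapse sample), a read-count table in the exome
    report layout, and the ground truth.
    """
    pattern = ClonalPattern(pattern)
    model = model if model is not None else default_clone_model(pattern)
    rng = np.random.default_rng(params.seed)

    muts = sorted(model.mutations())
    catalog = _site_catalog(muts)
    truth_statuses: dict[str, MutationStatus] = {}
    for mid in muts:
        cf_d = model.mutation_cell_fraction(mid, Stage.diagnosis)
        cf_r = model.mutation_cell_fraction(mid, Stage.relapse)
        truth_statuses[mid] = mutation_status(cf_d > 0, cf_r > 0)
    if classify_pattern(list(truth_statuses.values())) is not pattern:
        raise ValueError(f"clone model does not realise pattern {pattern.value}")

    blast_d = model.blast_pct_diagnosis / 100.0
    blast_r = model.blast_pct_relapse / 100.0

    def draw(p: float) -> tuple[int, int]:
        depth = _sample_depth(rng, params)
        var = int(rng.binomial(depth, min(1.0, p)))
        return var, depth - var

    calls: dict[Stage, list[VariantCall]] = {s: [] for s in Stage}
    donor_calls: list[VariantCall] = []
    readcounts: list[ReadCountRecord] = []

    def add_call(stage_list: list[VariantCall], sample: str, key: Key, gene: str,
                 effect: Effect, var: int, ref: int) -> None:
        stage_list.append(
            VariantCall(sample_id=sample, chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                        gene=gene, effect=effect, var_reads=var, ref_reads=ref)
        )

    for mid in muts:
        key, gene, effect = catalog[mid]
        cf_d = model.mutation_cell_fraction(mid, Stage.diagnosis)
        cf_r = model.mutation_cell_fraction(mid, Stage.relapse)
        vd, rd = draw(cf_d / 2.0 * blast_d)
        vr, rr = draw(cf_r / 2.0 * blast_r)
        vcr, rcr = draw(model.residual_cr_fraction * cf_d / 2.0)
        add_call(calls[Stage.diagnosis], f"{patient}-D", key, gene, effect, vd, rd)
        add_call(calls[Stage.relapse], f"{patient}-TR", key, gene, effect, vr, rr)
        add_call(calls[Stage.CR], f"{patient}-CR", key, gene, effect, vcr, rcr)
        readcounts.extend([
            ReadCountRecord(patient=patient, gene=gene, aa_change=mid, stage=Stage.diagnosis,
                            var_reads=vd, wt_reads=rd, blast_pct=model.blast_pct_diagnosis),
            ReadCountRecord(patient=patient, gene=gene, aa_change=mid, stage=Stage.relapse,
                            var_reads=vr, wt_reads=rr, blast_pct=model.blast_pct_relapse),
            ReadCountRecord(patient=patient, gene=gene, aa_change=mid, stage=Stage.CR,
                            var_reads=vcr, wt_reads=rcr),
        ])

    # germline known-SNP contaminants: heterozygous in patient and donor alike
    snp_ids = [f"SNP{i:03d}" for i in range(params.n_known_snp_contaminants)]
    snp_catalog = _site_catalog(snp_ids, start=100)
    blacklist: set[Key] = set()
    for i, sid in enumerate(snp_ids):
        key, gene, _ = snp_catalog[sid]
        effect = Effect.synonymous if i % 2 else Effect.nonsynonymous
        blacklist.add(key)
        for stage, sample in ((Stage.diagnosis, f"{patient}-D"), (Stage.CR, f"{patient}-CR"),
                              (Stage.relapse, f"{patient}-TR")):
            v, r = draw(0.5)
            add_call(calls[stage], sample, key, gene, effect, v, r)
        v, r = draw(0.5)
        add_call(donor_calls, f"{patient}-DONOR", key, gene, effect, v, r)

    # donor-private variants: heterozygous in the donor, visible in the
    # relapse sample through its non-blast (donor-hematopoiesis) fraction
    donor_ids = [f"DNR{i:03d}" for i in range(params.n_donor_variants)]
    donor_catalog = _site_catalog(donor_ids, start=200)
    donor_keys: set[Key] = set()
    for did in donor_ids:
        key, gene, effect = donor_catalog[did]
        donor_keys.add(key)
        v, r = draw(0.5)
        add_call(donor_calls, f"{patient}-DONOR", key, gene, effect, v, r)
        v, r = draw(0.5 * (1.0 - blast_r))
        add_call(calls[Stage.relapse], f"{patient}-TR", key, gene, effect, v, r)

    trio = PatientTrio(
        patient=patient,
        diagnosis_calls=calls[Stage.diagnosis],
        cr_calls=calls[Stage.CR],
        relapse_calls=calls[Stage.relapse],
        donor_calls=donor_calls,
        group=Group.relapsed,
    )
    truth = GroundTruth(pattern=pattern, statuses=truth_statuses,
                        somatic_keys={mid: catalog[mid][0] for mid in muts},
                        blacklist=blacklist, donor_keys=donor_keys)
    return SimulatedPatient(clone_model=model, trio=trio, readcounts=readcounts, truth=truth)


# ---------------------------------------------------------------------------
# STR mixtures

def default_str_templates(
    seed: int = 0,
    n_loci: int = 15,
    base_height: float = 1000.0,
) -> tuple[STRProfile, STRProfile]:
    """Patient (CR) and donor STR genotypes over the default 15-locus panel.

    Every locus is constructed informative: patient alleles {r, r+2} and
    donor alleles {r+1, r+3}, so each side has two private alleles and
    qualifying pairs one repeat unit apart exist. All base peaks share one
    height, making noise-free mixtures exactly recoverable.
    """
    rng = np.random.default_rng(seed)
    loci = list(DEFAULT_LOCI)[:n_loci] + [f"LOC{i}" for i in range(max(0, n_loci - len(DEFAULT_LOCI)))]
    patient_loci, donor_loci = {}, {}
    for locus in loci:
        r = int(rng.integers(8, 16))
        patient_loci[locus] = {r: base_height, r + 2: base_height}
        donor_loci[locus] = {r + 1: base_height, r + 3: base_height}
    return (STRProfile(sample_id="CR", loci=patient_loci),
            STRProfile(sample_id="DONOR", loci=donor_loci))


def simulate_str_mixture(
    patient_alleles: STRProfile,
    donor_alleles: STRProfile,
    patient_fraction: float,
    params: SimParams,
) -> tuple[STRProfile, STRProfile, STRProfile]:
    """Mix patient and donor STR profiles into a relapse electropherogram.

    Each relapse peak is the owner-weighted sum of the template heights,
    scaled by multiplicative lognormal noise of coefficient of variation
    ``str_noise_cv``; with ``stutter_rate`` > 0 a stutter peak of that
    relative height is added one repeat unit below each true peak.
    Returns (cr, donor, relapse) profiles.
    """
    if not (0.0 <= patient_fraction <= 1.0):
        raise ValueError("patient_fraction must lie in [0, 1]")
    rng = np.random.default_rng(params.seed)
    cv = params.str_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))

    relapse_loci: dict[str, dict[int, float]] = {}
    for locus in patient_alleles.loci:
        if locus not in donor_alleles.loci:
            continue
        pat = patient_alleles.loci[locus]
        don = donor_alleles.loci[locus]
        if not (set(pat) - set(don)) or not (set(don) - set(pat)):
            warnings.warn(f"locus {locus}: no private allele on one side; locus will be uninformative")
        peaks: dict[int, float] = {}
        for allele in set(pat) | set(don):
            h = patient_fraction * pat.get(allele, 0.0) + (1.0 - patient_fraction) * don.get(allele, 0.0)
            if h <= 0:
                continue
            if cv > 0:
                h *= float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
            peaks[allele] = h
        if params.stutter_rate > 0:
            for allele, h in list(peaks.items()):
                if allele - 1 >= 1:
                    peaks[allele - 1] = peaks.get(allele - 1, 0.0) + params.stutter_rate * h
        relapse_loci[locus] = peaks

    cr = STRProfile(sample_id=patient_alleles.sample_id, loci=patient_alleles.loci)
    donor = STRProfile(sample_id=donor_alleles.sample_id, loci=donor_alleles.loci)
    relapse = STRProfile(sample_id="RELAPSE", loci=relapse_loci)
    return cr, donor, relapse


# ---------------------------------------------------------------------------
# cohort tables

def simulate_cohort(
    n_relapsed: int,
    n_nonrelapsed: int,
    gene_effects: dict[str, dict[str, float]],
    params: SimParams,
    status_distribution: Optional[dict[MutationStatus, float]] = None,
) -> CohortMutationTable:
    """Bernoulli per-patient per-gene mutation indicators for two groups.

    ``gene_effects`` maps gene -> {"relapse_mut_prob": p1,
    "nonrelapse_mut_prob": p0}. Relapsed patients' mutations draw a status
    from ``status_distribution`` (uniform over diagnosis-specific / shared /
    relapse-specific when not given); non-relapsed mutations are
    diagnosis-only by construction.
    """
    rng = np.random.default_rng(params.seed)
    statuses = [MutationStatus.diagnosis_specific, MutationStatus.shared, MutationStatus.relapse_specific]
    if status_distribution is None:
        probs = [1 / 3] * 3
    else:
        probs = [status_distribution.get(s, 0.0) for s in statuses]
        total = sum(probs)
        if total <= 0:
            raise ValueError("status_distribution must have positive mass")
        probs = [p / total for p in probs]

    for gene, eff in gene_effects.items():
        for k in ("relapse_mut_prob", "nonrelapse_mut_prob"):
            if not (0.0 <= eff[k] <= 1.0):
                raise ValueError(f"{gene}: {k} must lie in [0, 1]")

    records: list[CohortRecord] = []
    counter = 0
    for group, n, prob_key in (
        (Group.relapsed, n_relapsed, "relapse_mut_prob"),
        (Group.non_relapsed, n_nonrelapsed, "nonrelapse_mut_prob"),
    ):
        prefix = "SIM" if group is Group.relapsed else "SIMN"
        for i in range(n):
            pid = f"{prefix}{i:03d}"
            for gene, eff in gene_effects.items():
                if rng.random() >= eff[prob_key]:
                    continue
                if group is Group.relapsed:
                    status = statuses[int(rng.choice(3, p=probs))]
                else:
                    status = MutationStatus.diagnosis_only_nonrelapsed
                counter += 1
                records.append(
                    CohortRecord(patient=pid, group=group, gene=gene,
                                 mutation_id=f"sim{counter:05d}", status=status,
                                 cohort="extension")
                )
    return CohortMutationTable(
        records=records,
        group_sizes={
            "relapsed": n_relapsed,
            "relapsed_extension": n_relapsed,
            "non_relapsed": n_nonrelapsed,
        },
    )
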