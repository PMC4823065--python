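"""Candidate somatic mutation selection from matched tumor/remission/donor calls.

The selection compares each tumor sample (diagnosis and, when available,
relapse) against the same patient's complete-remission sample, which serves
as the germline reference, and against the transplant donor's calls, which
rule out variants that entered the relapse sample with donor hematopoiesis.

A variant site survives when, after a per-call quality pre-filter and
removal of known germline SNPs from a user-supplied blacklist:

* VAF >= 15% with depth >= 20x in at least one tumor sample (both
  conditions in the same sample; a "both tumors" mode is configurable),
* remission VAF < 0.5% (no remission record counts as 0, with a warning),
* the predicted effect alters the protein, and
* the variant is absent from the donor (any donor variant reads exclude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .datamodel import (
    Effect,
    FilterThresholds,
    Group,
    PatientTrio,
    PROTEIN_ALTERING,
    Stage,
    VariantCall,
)

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]


def quality_prefilter(calls: Iterable[VariantCall], t: FilterThresholds) -> list[VariantCall]:
    """Keep calls passing the strict per-call quality rule.

    All three bounds are strict inequalities: mapping quality > 30, base
    quality > 15 and variant reads > 3 at the defaults.
    """
    return [
        c for c in calls
        if c.mapping_quality > t.min_mapping_quality
        and c.base_quality > t.min_base_quality
        and c.var_reads > t.min_var_reads
    ]


def remove_known_snps(calls: Iterable[VariantCall], blacklist: set[Key]) -> list[VariantCall]:
    """Drop calls whose (chrom, pos, ref, alt) is a known germline SNP."""
    return [c for c in calls if c.key not in blacklist]


def is_protein_altering(effect: Effect) -> bool:
    """True for effects expected to change the protein product."""
    if not isinstance(effect, Effect):
        effect = Effect(effect)  # raises ValueError for unknown labels
    return effect in PROTEIN_ALTERING


@dataclass(frozen=True)
class SomaticCandidate:
    """A selected candidate with the tumor stage(s) that support it."""

    call: VariantCall
    tumor_stages: tuple[Stage, ...]


def _remission_vaf(cr_by_key: dict[Key, VariantCall], key: Key) -> float:
    rec = cr_by_key.get(key)
    if rec is None:
        logger.warning("no remission coverage at %s:%d %s>%s; treating VAF as 0", *key)
        return 0.0
    if rec.depth == 0:
        logger.warning("zero remission depth at %s:%d %s>%s; treating VAF as 0", *key)
        return 0.0
    return rec.vaf


def call_somatic_candidates(
    trio: PatientTrio,
    t: Optional[FilterThresholds] = None,
    blacklist: Optional[set[Key]] = None,
) -> list[SomaticCandidate]:
    """Apply the full candidate-selection rule to a matched patient trio.

    Returns one candidate per variant site, keyed by (chrom, pos, ref, alt),
    carrying the representative tumor call and every tumor stage in which
    the VAF/depth condition held. Donor-origin variants are excluded and
    logged. The complete-remission call set is the mandatory germline
    reference: an empty one is an error rather than an all-pass.
    """
    t = t or FilterThresholds()
    blacklist = blacklist or set()
    if not trio.cr_calls:
        raise ValueError(f"patient {trio.patient}: remission (CR) call set is empty; cannot select somatic candidates")

    tumor_sets = [(Stage.diagnosis, trio.diagnosis_calls)]
    if trio.relapse_calls is not None:
        tumor_sets.append((Stage.relapse, trio.relapse_calls))

    cr_by_key = {c.key: c for c in trio.cr_calls}
    donor_present = {c.key for c in quality_prefilter(trio.donor_calls, t) if c.var_reads > 0}

    passing: dict[Key, tuple[VariantCall, list[Stage]]] = {}
    for stage, calls in tumor_sets:
        kept = remove_known_snps(quality_prefilter(calls, t), blacklist)
        for c in kept:
            if c.depth < t.min_tumor_depth or c.vaf < t.min_tumor_vaf:
                continue
            if c.key in passing:
                passing[c.key][1].append(stage)
            else:
                passing[c.key] = (c, [stage])

    out: list[SomaticCandidate] = []
    for key, (call, stages) in passing.items():
        if t.require_both_tumors and len(stages) < len(tumor_sets):
            continue
        if not is_protein_altering(call.effect):
            continue
        if _remission_vaf(cr_by_key, key) >= t.max_remission_vaf:
            continue
        if key in donor_present:
            logger.info("excluding donor-origin variant %s:%d %s>%s", *key)
            continue
        out.append(SomaticCandidate(call=call, tumor_stages=tuple(stages)))
    out.sort(key=lambda c: (c.call.chrom, c.call.pos, c.call.ref, c.call.alt))
    return out
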