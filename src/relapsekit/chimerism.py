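"""STR peak-height chimerism: percent patient cells in a post-HSCT sample.

After allogeneic transplant a relapse marrow sample is a mixture of patient
and donor hematopoiesis. Both genomes are genotyped at highly polymorphic
short tandem repeat (STR) loci; alleles private to the patient (seen in the
pre-transplant CR sample) or to the donor act as lineage markers. At each
"informative" locus — one where at least one patient-specific and one
donor-specific allele are both detected in the mixed sample, and some such
pair differs by at most one repeat unit (so amplification efficiency is
comparable) — the patient-cell ratio is

    ratio = sum(heights of patient-specific peaks)
          / [same + sum(heights of donor-specific peaks)]

and the overall patient-cell percentage is 100x the unweighted mean ratio
over informative loci.
"""

from __future__ import annotations

from typing import Iterable

from .datamodel import InformativeLocus, STRProfile

#: Minimum peak height (RFU) for an allele to count as detected.
DEFAULT_DETECTION_THRESHOLD = 50.0

#: Maximum repeat-unit difference between a patient- and donor-specific
#: allele pair for a locus to qualify ("less than two repeat units").
DEFAULT_MAX_REPEAT_DIFF = 1

#: Identifiler panel (the 15 autosomal loci, sex marker excluded).
DEFAULT_LOCI = (
    "D8S1179", "D21S11", "D7S820", "CSF1PO", "D3S1358", "TH01", "D13S317",
    "D16S539", "D2S1338", "D19S433", "vWA", "TPOX", "D18S51", "D5S818", "FGA",
)


def specific_alleles(cr: STRProfile, donor: STRProfile, locus: str) -> tuple[set[int], set[int]]:
    """Alleles private to the patient (CR) and to the donor at ``locus``."""
    if locus not in cr.loci:
        raise KeyError(f"locus {locus!r} missing from CR profile {cr.sample_id!r}")
    if locus not in donor.loci:
        raise KeyError(f"locus {locus!r} missing from donor profile {donor.sample_id!r}")
    cr_alleles = cr.alleles(locus)
    donor_alleles = donor.alleles(locus)
    return cr_alleles - donor_alleles, donor_alleles - cr_alleles


def _detected(relapse: STRProfile, locus: str, alleles: set[int], threshold: float) -> set[int]:
    peaks = relapse.loci.get(locus, {})
    return {a for a in alleles if peaks.get(a, 0.0) >= threshold}


def locus_ratio(
    relapse: STRProfile,
    locus: str,
    cr_specific: set[int],
    donor_specific: set[int],
) -> float:
    """Patient-cell ratio at one informative locus from relapse peak heights."""
    peaks = relapse.loci.get(locus, {})
    cr_sum = sum(peaks.get(a, 0.0) for a in cr_specific)
    donor_sum = sum(peaks.get(a, 0.0) for a in donor_specific)
    total = cr_sum + donor_sum
    if total <= 0:
        raise ValueError(f"locus {locus!r}: zero specific peak height contradicts informativeness")
    return cr_sum / total


def informative_loci(
    cr: STRProfile,
    donor: STRProfile,
    relapse: STRProfile,
    max_repeat_diff: int = DEFAULT_MAX_REPEAT_DIFF,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> list[InformativeLocus]:
    """Select usable loci and compute their patient-cell ratios.

    A locus qualifies when at least one CR-specific and one donor-specific
    allele are each detected (peak at or above ``detection_threshold``) in
    the relapse profile, and some detected (CR-specific, donor-specific)
    pair differs by at most ``max_repeat_diff`` repeat units. The ratio then
    sums over all detected specific alleles, not only the qualifying pair.
    """
    shared_loci = [l for l in cr.loci if l in donor.loci]
    out: list[InformativeLocus] = []
    for locus in shared_loci:
        cr_spec, donor_spec = specific_alleles(cr, donor, locus)
        cr_seen = _detected(relapse, locus, cr_spec, detection_threshold)
        donor_seen = _detected(relapse, locus, donor_spec, detection_threshold)
        if not cr_seen or not donor_seen:
            continue
        if not any(abs(a - b) <= max_repeat_diff for a in cr_seen for b in donor_seen):
            continue
        out.append(
            InformativeLocus(
                locus=locus,
                cr_specific_alleles=frozenset(cr_seen),
                donor_specific_alleles=frozenset(donor_seen),
                ratio=locus_ratio(relapse, locus, cr_seen, donor_seen),
            )
        )
    return out


def estimate_patient_fraction(loci: Iterable[InformativeLocus]) -> float:
    """Percent patient cells: 100x the unweighted mean per-locus ratio."""
    loci = list(loci)
    if not loci:
        raise ValueError("no informative loci: chimerism cannot be estimated")
    return 100.0 * sum(l.ratio for l in loci) / len(loci)


def estimate_chimerism(
    cr: STRProfile,
    donor: STRProfile,
    relapse: STRProfile,
    max_repeat_diff: int = DEFAULT_MAX_REPEAT_DIFF,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> tuple[float, list[InformativeLocus]]:
    """End-to-end estimate; returns (percent patient cells, loci used)."""
    loci = informative_loci(cr, donor, relapse, max_repeat_diff, detection_threshold)
    return estimate_patient_fraction(loci), loci
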