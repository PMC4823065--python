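"""Candidate somatic selection: unit rules, oracle equivalence, monotonicity."""

import dataclasses

import numpy as np
import pytest

from relapsekit.datamodel import Effect, FilterThresholds, Group, PatientTrio, VariantCall
from relapsekit.somatic import (
    call_somatic_candidates,
    is_protein_altering,
    quality_prefilter,
    remove_known_snps,
)
from conftest import make_call, make_trio


def test_quality_prefilter_strict_bounds(default_thresholds):
    at_bounds = make_call(var_reads=3, mapping_quality=30.0, base_quality=15.0)
    above = make_call(var_reads=4, mapping_quality=31.0, base_quality=16.0)
    assert quality_prefilter([at_bounds], default_thresholds) == []
    assert quality_prefilter([above], default_thresholds) == [above]
    assert quality_prefilter([], default_thresholds) == []


def test_blacklist_is_exact_tuple_match():
    call = make_call(chrom="chr1", pos=100, ref="A", alt="G")
    assert remove_known_snps([call], {("chr1", 100, "A", "G")}) == []
    assert remove_known_snps([call], {("chr1", 100, "A", "T")}) == [call]


def test_blacklist_set_difference_counts():
    calls = [make_call(pos=100 + i) for i in range(10)]
    blacklist = {("chr1", 100 + i, "A", "G") for i in range(4)}
    assert len(remove_known_snps(calls, blacklist)) == 6


@pytest.mark.parametrize(
    "effect, expected",
    [
        (Effect.nonsynonymous, True),
        (Effect.frameshift, True),
        (Effect.stopgain, True),
        (Effect.inframe_indel, True),
        (Effect.splice_site, True),
        (Effect.synonymous, False),
        (Effect.other, False),
    ],
)
def test_protein_altering_classification(effect, expected):
    assert is_protein_altering(effect) is expected


def test_protein_altering_rejects_unknown_label():
    with pytest.raises(ValueError):
        is_protein_altering("missense_variant")


def test_tumor_vaf_and_depth_rule():
    # VAF 56.1% at depth 41 with a clean remission: selected
    good = make_trio(
        diagnosis=[make_call(var_reads=23, ref_reads=18)],
        cr=[make_call(sample_id="CR", var_reads=0, ref_reads=83)],
        relapse=[make_call(var_reads=0, ref_reads=60)],
    )
    assert len(call_somatic_candidates(good)) == 1
    # VAF 14.9% even at depth 1000: below the >=15% bound
    low = make_trio(
        diagnosis=[make_call(var_reads=149, ref_reads=851)],
        cr=[make_call(sample_id="CR", var_reads=0, ref_reads=83)],
        relapse=[make_call(var_reads=0, ref_reads=60)],
    )
    assert call_somatic_candidates(low) == []


def test_remission_contamination_excludes():
    trio = make_trio(
        diagnosis=[make_call(var_reads=30, ref_reads=30)],
        cr=[make_call(sample_id="CR", var_reads=1, ref_reads=99)],  # 1% in CR
        relapse=[make_call(var_reads=0, ref_reads=60)],
    )
    assert call_somatic_candidates(trio) == []


def test_donor_origin_variant_excluded():
    site = dict(chrom="chr5", pos=777, ref="C", alt="T")
    trio = make_trio(
        diagnosis=[make_call(**site, var_reads=0, ref_reads=60)],
        relapse=[make_call(**site, var_reads=30, ref_reads=30)],
        donor=[make_call(**site, sample_id="DON", var_reads=25, ref_reads=25)],
    )
    assert call_somatic_candidates(trio) == []


def test_empty_remission_set_is_an_error():
    trio = PatientTrio(
        patient="P1", diagnosis_calls=[make_call()], cr_calls=[],
        relapse_calls=[], donor_calls=[], group=Group.relapsed,
    )
    with pytest.raises(ValueError, match="remission"):
        call_somatic_candidates(trio)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on randomized trios

def brute_force_keys(trio, t, blacklist):
    """Single-predicate reimplementation over the union of tumor sites."""
    def qual(c):
        return (c.mapping_quality > t.min_mapping_quality
                and c.base_quality > t.min_base_quality
                and c.var_reads > t.min_var_reads)

    tumor_calls = list(trio.diagnosis_calls) + list(trio.relapse_calls or [])
    cr = {c.key: c for c in trio.cr_calls}
    donor_present = {c.key for c in trio.donor_calls if qual(c) and c.var_reads > 0}
    out = set()
    for key in {c.key for c in tumor_calls}:
        passing = [
            c for c in tumor_calls
            if c.key == key and qual(c) and key not in blacklist
            and c.depth >= t.min_tumor_depth and c.vaf >= t.min_tumor_vaf
        ]
        if not passing:
            continue
        if not is_protein_altering(passing[0].effect):
            continue
        cr_call = cr.get(key)
        cr_vaf = cr_call.vaf if cr_call is not None and cr_call.depth > 0 else 0.0
        if cr_vaf >= t.max_remission_vaf:
            continue
        if key in donor_present:
            continue
        out.add(key)
    return out


def random_trio(rng, n_variants=50):
    effects = list(Effect)
    sites = []
    for i in range(n_variants):
        sites.append(dict(
            chrom=f"chr{rng.integers(1, 5)}", pos=int(1000 + i), ref="A", alt="G",
            gene=f"G{i}", effect=effects[rng.integers(0, len(effects))],
        ))

    def sample_calls(sample, p_zero):
        calls = []
        for s in sites:
            depth = int(rng.integers(5, 120))
            var = 0 if rng.random() < p_zero else int(rng.binomial(depth, rng.uniform(0.02, 0.6)))
            calls.append(VariantCall(
                sample_id=sample, var_reads=var, ref_reads=depth - var,
                mapping_quality=float(rng.uniform(20, 70)), base_quality=float(rng.uniform(10, 40)),
                **s,
            ))
        return calls

    trio = PatientTrio(
        patient="R", group=Group.relapsed,
        diagnosis_calls=sample_calls("D", 0.3),
        cr_calls=sample_calls("CR", 0.8),
        relapse_calls=sample_calls("TR", 0.3),
        donor_calls=sample_calls("DON", 0.7),
    )
    blacklist = {(s["chrom"], s["pos"], s["ref"], s["alt"])
                 for s in sites if rng.random() < 0.15}
    return trio, blacklist


@pytest.mark.parametrize("seed", range(20))
def test_filter_equals_brute_force_oracle_on_random_trios(seed, default_thresholds):
    rng = np.random.default_rng(seed)
    trio, blacklist = random_trio(rng)
    got = {c.call.key for c in call_somatic_candidates(trio, default_thresholds, blacklist)}
    assert got == brute_force_keys(trio, default_thresholds, blacklist)


def test_filter_is_idempotent(default_thresholds):
    rng = np.random.default_rng(7)
    trio, blacklist = random_trio(rng)
    first = call_somatic_candidates(trio, default_thresholds, blacklist)
    refiltered = PatientTrio(
        patient=trio.patient, group=trio.group,
        diagnosis_calls=[c.call for c in first],
        cr_calls=trio.cr_calls,
        relapse_calls=[c.call for c in first],
        donor_calls=trio.donor_calls,
    )
    second = call_somatic_candidates(refiltered, default_thresholds, blacklist)
    assert {c.call.key for c in second} == {c.call.key for c in first}


@pytest.mark.parametrize("field, tighter", [
    ("min_tumor_vaf", 0.30),
    ("min_tumor_depth", 40),
    ("max_remission_vaf", 0.001),
])
def test_tightening_thresholds_never_adds_candidates(field, tighter, default_thresholds):
    rng = np.random.default_rng(11)
    trio, blacklist = random_trio(rng)
    base = {c.call.key for c in call_somatic_candidates(trio, default_thresholds, blacklist)}
    strict = dataclasses.replace(default_thresholds, **{field: tighter})
    tightened = {c.call.key for c in call_somatic_candidates(trio, strict, blacklist)}
    assert tightened <= base
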