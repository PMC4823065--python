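"""Generator ground truth, determinism, and downstream recovery."""

import numpy as np
import pytest

from relapsekit.clonal import adjusted_vaf, build_reports
from relapsekit.datamodel import (
    ClonalPattern,
    Clone,
    CloneModel,
    Group,
    MutationStatus,
    SimParams,
    Stage,
)
from relapsekit.simulate import (
    default_clone_model,
    default_str_templates,
    simulate_cohort,
    simulate_patient,
    simulate_str_mixture,
)
from relapsekit.somatic import call_somatic_candidates


def test_clone_model_rejects_broken_phylogeny():
    with pytest.raises(ValueError, match="perfect phylogeny"):
        CloneModel(
            clones=[
                Clone(id="a", mutations=frozenset({"m1", "m2"}),
                      fraction_at_diagnosis=0.5, fraction_at_relapse=0.5),
                Clone(id="b", mutations=frozenset({"m3"}), parent="a",
                      fraction_at_diagnosis=0.2, fraction_at_relapse=0.2),
            ],
            blast_pct_diagnosis=90, blast_pct_relapse=90,
        )


def test_clone_fractions_must_not_exceed_unity():
    with pytest.raises(ValueError, match="sum"):
        CloneModel(
            clones=[
                Clone(id="a", mutations=frozenset({"m1"}),
                      fraction_at_diagnosis=0.7, fraction_at_relapse=0.0),
                Clone(id="b", mutations=frozenset({"m1", "m2"}), parent="a",
                      fraction_at_diagnosis=0.6, fraction_at_relapse=1.0),
            ],
            blast_pct_diagnosis=90, blast_pct_relapse=90,
        )


def test_second_malignancy_shares_no_mutation():
    sim = simulate_patient(ClonalPattern.second_malignancy, SimParams(seed=3))
    model = sim.clone_model
    diag = {m for m in model.mutations() if model.mutation_cell_fraction(m, Stage.diagnosis) > 0}
    rel = {m for m in model.mutations() if model.mutation_cell_fraction(m, Stage.relapse) > 0}
    assert diag and rel and not (diag & rel)
    assert all(s is not MutationStatus.shared for s in sim.truth.statuses.values())


def test_subclone_survival_has_no_relapse_novel_mutations():
    sim = simulate_patient(ClonalPattern.subclone_survival, SimParams(seed=4))
    model = sim.clone_model
    diag = {m for m in model.mutations() if model.mutation_cell_fraction(m, Stage.diagnosis) > 0}
    rel = {m for m in model.mutations() if model.mutation_cell_fraction(m, Stage.relapse) > 0}
    assert rel <= diag and diag & rel


def test_common_progenitor_has_all_three_status_classes():
    sim = simulate_patient(ClonalPattern.common_progenitor, SimParams(seed=5))
    statuses = set(sim.truth.statuses.values())
    assert statuses == {MutationStatus.shared, MutationStatus.diagnosis_specific,
                        MutationStatus.relapse_specific}


def test_deep_sequencing_limit_recovers_clone_fractions():
    """At depth 1e5 the blast-adjusted VAF of every mutation sits within one
    percentage point of 100 x cell_fraction / 2 (heterozygous expectation)."""
    params = SimParams(seed=11, mean_depth=1e5, depth_dispersion=0.0,
                       n_known_snp_contaminants=0, n_donor_variants=0)
    sim = simulate_patient(ClonalPattern.subclone_survival, params)
    model = sim.clone_model
    by_mut = {}
    for rec in sim.readcounts:
        if rec.stage is Stage.CR:
            continue
        adj = adjusted_vaf(rec.var_reads, rec.wt_reads, rec.blast_pct)
        truth = 100 * model.mutation_cell_fraction(rec.aa_change, rec.stage) / 2
        by_mut[(rec.aa_change, rec.stage)] = (adj, truth)
    for adj, truth in by_mut.values():
        assert adj == pytest.approx(truth, abs=1.0)


def test_zero_residual_disease_means_clean_cr_reads():
    sim = simulate_patient(ClonalPattern.common_progenitor, SimParams(seed=6))
    assert sim.clone_model.residual_cr_fraction == 0.0
    somatic_keys = set(sim.truth.somatic_keys.values())
    for call in sim.trio.cr_calls:
        if call.key in somatic_keys:
            assert call.var_reads == 0


def test_residual_disease_shows_up_in_cr():
    model = default_clone_model(ClonalPattern.subclone_survival, residual_cr_fraction=0.2)
    params = SimParams(seed=7, mean_depth=500, depth_dispersion=0.0)
    sim = simulate_patient(ClonalPattern.subclone_survival, params, model=model)
    cr_var = sum(r.var_reads for r in sim.readcounts if r.stage is Stage.CR)
    assert cr_var > 0


def test_identical_seed_identical_output():
    a = simulate_patient(ClonalPattern.common_progenitor, SimParams(seed=42))
    b = simulate_patient(ClonalPattern.common_progenitor, SimParams(seed=42))
    assert a.readcounts == b.readcounts
    assert a.trio.diagnosis_calls == b.trio.diagnosis_calls
    c = simulate_patient(ClonalPattern.common_progenitor, SimParams(seed=43))
    assert c.readcounts != a.readcounts


def test_simulated_trio_filter_recovers_true_somatic_sites():
    """With clone fractions >= 0.3 and ~100x depth the candidate filter
    recovers the true somatic sites and rejects SNP/donor contaminants."""
    for seed in range(5):
        sim = simulate_patient(ClonalPattern.subclone_survival,
                               SimParams(seed=seed, mean_depth=100, depth_dispersion=0.0))
        got = {c.call.key for c in call_somatic_candidates(sim.trio, blacklist=sim.truth.blacklist)}
        assert got == set(sim.truth.somatic_keys.values())
        assert not (got & sim.truth.blacklist)
        assert not (got & sim.truth.donor_keys)


@pytest.mark.parametrize("pattern", list(ClonalPattern))
def test_pattern_recovery_rate_at_depth_100(pattern):
    """The classifier recovers the generating pattern in >= 95% of 200
    seeded replicates at a fixed 100x depth with clone fractions >= 0.3."""
    hits = 0
    n = 200
    for seed in range(n):
        sim = simulate_patient(pattern, SimParams(
            seed=seed, mean_depth=100, depth_dispersion=0.0,
            n_known_snp_contaminants=0, n_donor_variants=0))
        reports = build_reports(sim.readcounts)
        hits += reports[0].pattern is pattern
    assert hits / n >= 0.95


def test_str_mixture_determinism_and_stutter():
    pat, don = default_str_templates(seed=1)
    p = SimParams(seed=2, str_noise_cv=0.1)
    r1 = simulate_str_mixture(pat, don, 0.4, p)[2]
    r2 = simulate_str_mixture(pat, don, 0.4, p)[2]
    assert r1.loci == r2.loci
    stuttered = simulate_str_mixture(pat, don, 0.4, SimParams(seed=2, stutter_rate=0.1))[2]
    assert any(len(peaks) > len(r1.loci[l]) for l, peaks in stuttered.loci.items())


def test_cohort_generator_empty_when_probabilities_zero():
    table = simulate_cohort(10, 10, {"G1": {"relapse_mut_prob": 0.0, "nonrelapse_mut_prob": 0.0}},
                            SimParams(seed=1))
    assert table.records == []
    assert table.group_sizes["relapsed"] == 10


def test_cohort_generator_determinism():
    eff = {"G1": {"relapse_mut_prob": 0.4, "nonrelapse_mut_prob": 0.1}}
    a = simulate_cohort(20, 20, eff, SimParams(seed=9))
    b = simulate_cohort(20, 20, eff, SimParams(seed=9))
    assert a.records == b.records


def test_cohort_generator_matches_specified_bernoulli_rates():
    """Across 2000 replicates of a 28 vs 30 cohort the mean mutated
    fractions sit within 2 points of the specified 46% and 17% rates."""
    eff = {"G1": {"relapse_mut_prob": 0.46, "nonrelapse_mut_prob": 0.17}}
    rel, non = [], []
    for seed in range(2000):
        t = simulate_cohort(28, 30, eff, SimParams(seed=seed))
        rel.append(len({r.patient for r in t.records if r.group is Group.relapsed}) / 28)
        non.append(len({r.patient for r in t.records if r.group is Group.non_relapsed}) / 30)
    assert np.mean(rel) * 100 == pytest.approx(46.0, abs=2.0)
    assert np.mean(non) * 100 == pytest.approx(17.0, abs=2.0)


def test_relapsed_statuses_follow_supplied_distribution():
    eff = {"G1": {"relapse_mut_prob": 1.0, "nonrelapse_mut_prob": 0.0}}
    table = simulate_cohort(50, 0, eff, SimParams(seed=3),
                            status_distribution={MutationStatus.shared: 1.0})
    assert all(r.status is MutationStatus.shared for r in table.records)
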