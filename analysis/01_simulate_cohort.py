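"""Generate the synthetic study: one matched trio per clonal evolution
pattern, STR mixtures at several chimerism levels, and a two-group cohort
mutation table. All downstream analysis steps run off these outputs plus
the packaged read-count and recurrence tables.

Writes results/simulated/<pattern>/ with the TSV schemas plus ground truth.
"""

import sys
from pathlib import Path

import yaml

from relapsekit import io
from relapsekit.datamodel import ClonalPattern, SimParams
from relapsekit.simulate import (
    default_str_templates,
    simulate_cohort,
    simulate_patient,
    simulate_str_mixture,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = SimParams(seed=SEED)

    for pattern in ClonalPattern:
        d = OUT / pattern.value
        d.mkdir(exist_ok=True)
        sim = simulate_patient(pattern, params)
        io.write_variant_table(sim.trio.diagnosis_calls, d / "diagnosis.tsv")
        io.write_variant_table(sim.trio.cr_calls, d / "cr.tsv")
        io.write_variant_table(sim.trio.relapse_calls, d / "relapse.tsv")
        io.write_variant_table(sim.trio.donor_calls, d / "donor.tsv")
        io.write_readcount_table(sim.readcounts, d / "readcounts.tsv")
        io.write_blacklist(sim.truth.blacklist, d / "blacklist.tsv")
        truth = {"pattern": pattern.value,
                 "statuses": {m: s.value for m, s in sim.truth.statuses.items()}}
        (d / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
        print(f"{pattern.value}: {len(sim.truth.statuses)} somatic mutations, "
              f"{len(sim.truth.blacklist)} SNP contaminants, {len(sim.truth.donor_keys)} donor variants")

    pat, don = default_str_templates(seed=SEED)
    for frac in (0.1, 0.3, 0.7):
        cr, donor, relapse = simulate_str_mixture(pat, don, frac, SimParams(seed=SEED, str_noise_cv=0.1))
        d = OUT / f"str_mix_{int(frac * 100)}"
        d.mkdir(exist_ok=True)
        io.write_str_profiles([cr], d / "str_cr.tsv")
        io.write_str_profiles([donor], d / "str_donor.tsv")
        io.write_str_profiles([relapse], d / "str_relapse.tsv")
    print("STR mixtures at 10/30/70% patient cells written")

    # a 28-vs-30 cohort with one strongly relapse-associated gene set
    effects = {f"GENE{i}": {"relapse_mut_prob": 0.12, "nonrelapse_mut_prob": 0.02} for i in range(7)}
    effects["NEUTRAL1"] = {"relapse_mut_prob": 0.05, "nonrelapse_mut_prob": 0.05}
    table = simulate_cohort(28, 30, effects, SimParams(seed=SEED))
    io.write_cohort_table(table, OUT / "cohort_table.tsv")
    (OUT / "cohort_meta.yaml").write_text(yaml.safe_dump({"group_sizes": table.group_sizes}))
    print(f"cohort table: {len(table.records)} mutation records")


if __name__ == "__main__":
    main()
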