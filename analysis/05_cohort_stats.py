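"""Cohort-level statistics from the packaged recurrence table.

Recomputes the headline numbers: mutated-patient fractions per group, the
two-sided Fisher exact test on mutated vs non-mutated patients across the
relapsed and non-relapsed groups, per-gene recurrence frequencies, the
epigenetic-regulator enrichment, and the relapse-association gene rule.

Note the table lists only four identifiable mutated non-relapsed patients,
so the table-derived 2x2 test differs from the one computed with the
published carrier counts (13/28 vs 5/30); both are reported.

Writes results/cohort_stats.json.
"""

import json
from pathlib import Path

from relapsekit.datamodel import Group
from relapsekit.fixtures import EPIGENETIC_REGULATORS, load_table2
from relapsekit.stats import (
    epigenetic_regulator_fraction,
    fisher_exact_two_sided,
    gene_frequency,
    mutated_patient_fraction,
    relapse_associated_genes,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = load_table2()
    n_rel = table.group_sizes["relapsed_extension"]
    n_non = table.group_sizes["non_relapsed"]
    rel_mut = len({r.patient for r in table.records
                   if r.group is Group.relapsed and r.cohort == "extension"})
    non_mut = len({r.patient for r in table.records if r.group is Group.non_relapsed})

    result = {
        "mutated_relapsed_pct": mutated_patient_fraction(table, Group.relapsed, cohort="extension"),
        "fisher_p_published_counts": round(fisher_exact_two_sided(13, 15, 5, 25), 6),
        "fisher_p_table_identifiable": round(
            fisher_exact_two_sided(rel_mut, n_rel - rel_mut, non_mut, n_non - non_mut), 6),
        "epigenetic_regulator_pct_of_28": epigenetic_regulator_fraction(
            table, EPIGENETIC_REGULATORS, group_size=n_rel),
        "epigenetic_regulator_pct_of_mutated": epigenetic_regulator_fraction(
            table, EPIGENETIC_REGULATORS, group_size=rel_mut),
        "gene_frequency_pct_of_31": {
            g: gene_frequency(table, g, denominator=table.group_sizes["relapsed"])
            for g in sorted({r.gene for r in table.records})
        },
        "relapse_associated_genes": sorted(relapse_associated_genes(table)),
    }
    out = ROOT / "results" / "cohort_stats.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(result, indent=2) + "\n")
    print(f"{result['mutated_relapsed_pct']}% of 28 relapsed patients mutated "
          f"(p = {result['fisher_p_published_counts']} with published carrier counts)")
    print(f"epigenetic regulators: {result['epigenetic_regulator_pct_of_28']}% of 28, "
          f"{result['epigenetic_regulator_pct_of_mutated']}% of mutated")
    print("relapse-associated genes:", ", ".join(result["relapse_associated_genes"]))
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
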