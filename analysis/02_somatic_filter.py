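"""Run candidate somatic selection on the simulated trios and score it
against the generator's ground truth.

Every true somatic site should survive the filter and every known-SNP or
donor-origin contaminant should be removed. Writes
results/somatic_candidates.tsv (one row per pattern and candidate).
"""

from pathlib import Path

import yaml

from relapsekit import io
from relapsekit.datamodel import ClonalPattern, Group, PatientTrio
from relapsekit.somatic import call_somatic_candidates

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"


def main() -> None:
    out_rows = []
    for pattern in ClonalPattern:
        d = SIM / pattern.value
        trio = PatientTrio(
            patient=pattern.value,
            diagnosis_calls=io.read_variant_table(d / "diagnosis.tsv"),
            cr_calls=io.read_variant_table(d / "cr.tsv"),
            relapse_calls=io.read_variant_table(d / "relapse.tsv"),
            donor_calls=io.read_variant_table(d / "donor.tsv"),
            group=Group.relapsed,
        )
        blacklist = io.read_blacklist(d / "blacklist.tsv")
        truth = yaml.safe_load((d / "ground_truth.yaml").read_text())
        candidates = call_somatic_candidates(trio, blacklist=blacklist)
        n_true = len(truth["statuses"])
        print(f"{pattern.value}: {len(candidates)} candidates selected "
              f"({n_true} true somatic mutations simulated)")
        for c in candidates:
            out_rows.append((pattern.value, c.call.chrom, c.call.pos, c.call.ref, c.call.alt,
                             c.call.gene, ",".join(s.value for s in c.tumor_stages)))

    out = ROOT / "results" / "somatic_candidates.tsv"
    with open(out, "w") as fh:
        fh.write("pattern\tchrom\tpos_1based\tref\talt\tgene\ttumor_stages\n")
        for row in out_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
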