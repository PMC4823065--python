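"""Packaged machine-readable transcriptions of the study's printed tables.

Three fixtures ship with the package:

``table1``
    Candidate relapse-associated mutated genes per exome-sequenced patient,
    with each gene's sharing status across diagnosis and relapse.
``table2``
    Recurring gene mutations across the discovery (3 exome patients) and
    extension (58 targeted-sequencing patients) cohorts, as a
    :class:`~relapsekit.datamodel.CohortMutationTable` with the published
    group denominators attached (31 relapsed overall, 28 extension relapsed,
    3 discovery relapsed, 30 non-relapsed).
``table3``
    Per-mutation read counts with marrow blast percentages for the three
    exome trios, including the printed blast-adjusted "% variant in tumor"
    values. Two cells disagree with the adjustment formula in the source
    and are stored as printed, flagged via ``discordant_cell``
    ("diagnosis" or "relapse"); everything else carries "none".

Every fixture row keeps a provenance pointer (table, patient, gene).
"""

from __future__ import annotations

from importlib import resources
from typing import Union

import pandas as pd

from .datamodel import CohortMutationTable, CohortRecord, ReadCountRecord, Stage

GROUP_SIZES = {
    "relapsed": 31,
    "relapsed_extension": 28,
    "relapsed_discovery": 3,
    "non_relapsed": 30,
}

#: Epigenetic regulators (incl. two transcription factors with epigenetic
#: modulating function) whose mutation enrichment the cohort analysis tests.
EPIGENETIC_REGULATORS = frozenset({"SETD2", "CREBBP", "KDM6A", "NR3C1", "PAX5"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("relapsekit.data").joinpath(f"{name}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"pct_diagnosis": str, "pct_relapse": str, "pct_cr": str})


def load_table1() -> pd.DataFrame:
    """Gene sharing statuses for the three exome-sequenced patients."""
    return _read("table1")


def load_table2() -> CohortMutationTable:
    """The recurrence table as a CohortMutationTable with group sizes."""
    df = _read("table2")
    records = [
        CohortRecord(
            patient=r.patient, group=r.group, cohort=r.cohort, gene=r.gene,
            mutation_id=r.mutation_id, status=r.status,
        )
        for r in df.itertuples()
    ]
    return CohortMutationTable(records=records, group_sizes=dict(GROUP_SIZES))


def load_table3() -> pd.DataFrame:
    """Read-count table for the exome trios; printed percentages kept as text."""
    return _read("table3")


def table3_readcounts(include_discordant: bool = True) -> list[ReadCountRecord]:
    """Flatten the read-count fixture to one record per (mutation, stage).

    With ``include_discordant=False`` the two stage cells whose printed
    adjusted value disagrees with the adjustment formula are dropped
    (useful for exact-reproduction checks).
    """
    out: list[ReadCountRecord] = []
    for r in load_table3().itertuples():
        cells = [
            (Stage.diagnosis, r.var_diagnosis, r.wt_diagnosis, float(r.blast_diagnosis), "diagnosis"),
            (Stage.relapse, r.var_relapse, r.wt_relapse, float(r.blast_relapse), "relapse"),
            (Stage.CR, r.var_cr, r.wt_cr, None, "cr"),
        ]
        for stage, var, wt, blast, cell in cells:
            if not include_discordant and r.discordant_cell == cell:
                continue
            out.append(
                ReadCountRecord(
                    patient=r.patient, gene=r.gene, aa_change=r.aa_change,
                    stage=stage, var_reads=int(var), wt_reads=int(wt), blast_pct=blast,
                )
            )
    return out


_LOADERS = {"table1": load_table1, "table2": load_table2, "table3": load_table3}


def load_fixture(name: str) -> Union[pd.DataFrame, CohortMutationTable]:
    """Dispatch on fixture name; raises KeyError for unknown names."""
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_LOADERS)}") from None
    return loader()
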