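"""Cohort-level mutation statistics.

Implements the two-sided Fisher exact test by minimum-likelihood summation
(the convention of mainstream statistics packages: the p-value sums the
hypergeometric probabilities of every table with the observed margins that
is no more probable than the observed one), plus the mutated-patient
fractions, per-gene recurrence frequencies and the relapse-association
gene rule used to call genes relapse-associated in a two-group cohort.

Patients are always counted uniquely: several mutations in one gene, or in
several genes, still count a patient once.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional

from .datamodel import CohortMutationTable, Group, MutationStatus
from .util import round_half_up

logger = logging.getLogger(__name__)

#: Relative tolerance when comparing table probabilities, guarding against
#: floating-point ties in the minimum-likelihood sum.
PROBABILITY_REL_TOL = 1e-7


def _log_hypergeom(a: int, r1: int, r2: int, c1: int, n: int) -> float:
    """log P(upper-left cell = a) for fixed margins r1, r2, c1."""
    return (
        math.lgamma(r1 + 1) - math.lgamma(a + 1) - math.lgamma(r1 - a + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - a + 1) - math.lgamma(r2 - (c1 - a) + 1)
        - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Exact log-factorial arithmetic; any zero margin returns p = 1.0 with a
    warning (no association is testable).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        logger.warning("degenerate 2x2 table (zero margin): p = 1.0")
        return 1.0
    log_obs = _log_hypergeom(a, r1, r2, c1, n)
    cutoff = log_obs + math.log1p(PROBABILITY_REL_TOL)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p = sum(
        math.exp(lp)
        for x in range(lo, hi + 1)
        if (lp := _log_hypergeom(x, r1, r2, c1, n)) <= cutoff
    )
    return min(p, 1.0)


def _unique_patients(
    table: CohortMutationTable,
    group: Group,
    genes: Optional[Iterable[str]] = None,
    cohort: Optional[str] = None,
    statuses: Optional[set[MutationStatus]] = None,
) -> set[str]:
    genes = None if genes is None else set(genes)
    return {
        r.patient
        for r in table.records
        if r.group is group
        and (genes is None or r.gene in genes)
        and (cohort is None or r.cohort == cohort)
        and (statuses is None or r.status in statuses)
    }


def mutated_patient_fraction(table: CohortMutationTable, group: Group, cohort: Optional[str] = None) -> float:
    """Percent of the group carrying at least one somatic mutation.

    The denominator comes from the table's ``group_sizes`` metadata, keyed
    by ``group`` or ``group_cohort`` — patients without mutations have no
    records, so sizes cannot be inferred.
    """
    group = Group(group)
    key = f"{group.value}_{cohort}" if cohort else group.value
    size = table.group_sizes.get(key)
    if size is None:
        raise KeyError(f"group size {key!r} missing from table metadata")
    carriers = _unique_patients(table, group, cohort=cohort)
    return round_half_up(100.0 * len(carriers) / size, 1)


def gene_frequency(table: CohortMutationTable, gene: str, denominator: int) -> float:
    """Percent of relapsed patients (all cohorts) mutated in ``gene``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    carriers = _unique_patients(table, Group.relapsed, genes=[gene])
    return round_half_up(100.0 * len(carriers) / denominator, 1)


def relapse_associated_genes(table: CohortMutationTable) -> set[str]:
    """Genes whose mutations track relapse.

    A gene qualifies when (i) at least two unique relapsed patients carry
    it, (ii) no non-relapsed patient does, and (iii) at least one relapsed
    patient's mutation in it is retained from diagnosis to relapse (shared)
    or newly acquired at relapse (relapse-specific).
    """
    genes = {r.gene for r in table.records}
    out = set()
    persistent = {MutationStatus.shared, MutationStatus.relapse_specific}
    for gene in genes:
        relapsed = _unique_patients(table, Group.relapsed, genes=[gene])
        nonrelapsed = _unique_patients(table, Group.non_relapsed, genes=[gene])
        retained = _unique_patients(table, Group.relapsed, genes=[gene], statuses=persistent)
        if len(relapsed) >= 2 and not nonrelapsed and retained:
            out.add(gene)
    return out


def epigenetic_regulator_fraction(
    table: CohortMutationTable,
    gene_set: Iterable[str],
    group_size: int,
    cohort: Optional[str] = "extension",
) -> float:
    """Percent of relapsed patients mutated in a gene set, over ``group_size``.

    The numerator counts unique relapsed carriers restricted to ``cohort``
    (default: the extension cohort, whose matched samples the enrichment
    analysis profiled); pass ``cohort=None`` to count across all cohorts.
    """
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    gene_set = set(gene_set)
    if not gene_set:
        return 0.0
    carriers = _unique_patients(table, Group.relapsed, genes=gene_set, cohort=cohort)
    return round_half_up(100.0 * len(carriers) / group_size, 1)
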