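import pytest

from relapsekit import fixtures
from relapsekit.datamodel import Effect, FilterThresholds, Group, PatientTrio, VariantCall


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_table1()


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_table2()


@pytest.fixture(scope="session")
def table3():
    return fixtures.load_table3()


@pytest.fixture
def default_thresholds():
    return FilterThresholds()


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    sample_id="S",
    gene="GENE1",
    effect=Effect.nonsynonymous,
    var_reads=30,
    ref_reads=30,
    mapping_quality=60.0,
    base_quality=30.0,
):
    return VariantCall(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        effect=effect, var_reads=var_reads, ref_reads=ref_reads,
        mapping_quality=mapping_quality, base_quality=base_quality,
    )


def make_trio(diagnosis=(), cr=(), relapse=(), donor=(), patient="P1"):
    """Trio helper; CR defaults to a harmless reference call so the
    mandatory-remission check passes."""
    cr = list(cr) or [make_call(sample_id="P1-CR", pos=999_999, var_reads=0, ref_reads=50)]
    return PatientTrio(
        patient=patient,
        diagnosis_calls=list(diagnosis),
        cr_calls=cr,
        relapse_calls=list(relapse),
        donor_calls=list(donor),
        group=Group.relapsed,
    )
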