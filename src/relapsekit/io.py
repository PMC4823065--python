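"""TSV schemas and minimal VCF import.

TSV is the canonical interchange format; all quantitative inputs this
package consumes exist as printed tables, so schemas are small, versioned
by their header line, and 1-based in coordinates (stated by the column name
``pos_1based``). The VCF reader is a convenience layer that maps the AD
(allelic depth) FORMAT field onto :class:`~relapsekit.datamodel.VariantCall`;
it is not a general VCF implementation.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Union

from .datamodel import (
    CohortMutationTable,
    CohortRecord,
    Effect,
    ReadCountRecord,
    Stage,
    STRProfile,
    VariantCall,
)

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos_1based", "ref", "alt", "gene", "effect",
    "var_reads", "ref_reads", "mapping_quality", "base_quality",
]
READCOUNT_COLUMNS = ["patient", "gene", "aa_change", "stage", "blast_pct", "var_reads", "wt_reads"]
STR_COLUMNS = ["sample_id", "locus", "allele_repeats", "height"]
COHORT_COLUMNS = ["patient", "group", "cohort", "gene", "mutation_id", "status"]

#: Marker for an absent value (CR blast percentage).
NA = "NA"


class SchemaError(ValueError):
    """Header does not match the documented schema."""


class ParseError(ValueError):
    """A data row could not be converted; message carries the line number."""


def _check_header(header: list[str], expected: list[str], path: PathLike) -> None:
    if header == expected:
        return
    missing = [c for c in expected if c not in header]
    extra = [c for c in header if c not in expected]
    parts = []
    if missing:
        parts.append(f"missing column(s) {missing}")
    if extra:
        parts.append(f"unexpected column(s) {extra}")
    if not parts:
        parts.append(f"column order must be {expected}")
    raise SchemaError(f"{path}: " + "; ".join(parts))


def _rows(path: PathLike, expected: list[str]) -> Iterable[tuple[int, dict[str, str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header {expected}")
        _check_header(header, expected, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected):
                raise ParseError(f"{path}:{lineno}: expected {len(expected)} fields, got {len(row)}")
            yield lineno, dict(zip(expected, row))


def _to_int(value: str, column: str, path: PathLike, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: column {column!r}: {value!r} is not an integer") from None


def _to_float(value: str, column: str, path: PathLike, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: column {column!r}: {value!r} is not a number") from None


# ---------------------------------------------------------------------------
# variant_calls.tsv

def read_variant_table(path: PathLike) -> list[VariantCall]:
    """Read a variant_calls.tsv into VariantCall records, order preserved."""
    calls = []
    for lineno, row in _rows(path, VARIANT_COLUMNS):
        try:
            effect = Effect(row["effect"])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unknown effect {row['effect']!r}") from None
        calls.append(
            VariantCall(
                sample_id=row["sample_id"],
                chrom=row["chrom"],
                pos=_to_int(row["pos_1based"], "pos_1based", path, lineno),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                effect=effect,
                var_reads=_to_int(row["var_reads"], "var_reads", path, lineno),
                ref_reads=_to_int(row["ref_reads"], "ref_reads", path, lineno),
                mapping_quality=_to_float(row["mapping_quality"], "mapping_quality", path, lineno),
                base_quality=_to_float(row["base_quality"], "base_quality", path, lineno),
            )
        )
    return calls


def _fmt(x: float) -> str:
    return f"{x:g}"


def write_variant_table(calls: Iterable[VariantCall], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for c in calls:
            w.writerow([c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.gene, c.effect.value,
                        c.var_reads, c.ref_reads, _fmt(c.mapping_quality), _fmt(c.base_quality)])


# ---------------------------------------------------------------------------
# readcounts.tsv

def read_readcount_table(path: PathLike) -> list[ReadCountRecord]:
    records = []
    for lineno, row in _rows(path, READCOUNT_COLUMNS):
        try:
            stage = Stage(row["stage"])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unknown stage {row['stage']!r}") from None
        blast = None if row["blast_pct"] == NA else _to_float(row["blast_pct"], "blast_pct", path, lineno)
        try:
            records.append(
                ReadCountRecord(
                    patient=row["patient"], gene=row["gene"], aa_change=row["aa_change"],
                    stage=stage,
                    var_reads=_to_int(row["var_reads"], "var_reads", path, lineno),
                    wt_reads=_to_int(row["wt_reads"], "wt_reads", path, lineno),
                    blast_pct=blast,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return records


def write_readcount_table(records: Iterable[ReadCountRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(READCOUNT_COLUMNS)
        for r in records:
            blast = NA if r.blast_pct is None else _fmt(r.blast_pct)
            w.writerow([r.patient, r.gene, r.aa_change, r.stage.value, blast, r.var_reads, r.wt_reads])


# ---------------------------------------------------------------------------
# str_profile.tsv — long format, one peak per row

def read_str_profiles(path: PathLike) -> dict[str, STRProfile]:
    """Read STR peaks; returns {sample_id: STRProfile}."""
    loci: dict[str, dict[str, dict[int, float]]] = {}
    for lineno, row in _rows(path, STR_COLUMNS):
        rep = _to_int(row["allele_repeats"], "allele_repeats", path, lineno)
        height = _to_float(row["height"], "height", path, lineno)
        loci.setdefault(row["sample_id"], {}).setdefault(row["locus"], {})[rep] = height
    return {sid: STRProfile(sample_id=sid, loci=l) for sid, l in loci.items()}


def write_str_profiles(profiles: Iterable[STRProfile], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(STR_COLUMNS)
        for p in profiles:
            for locus in sorted(p.loci):
                for rep in sorted(p.loci[locus]):
                    w.writerow([p.sample_id, locus, rep, _fmt(p.loci[locus][rep])])


# ---------------------------------------------------------------------------
# cohort_table.tsv

def read_cohort_table(path: PathLike, group_sizes: Optional[dict[str, int]] = None) -> CohortMutationTable:
    records = []
    for lineno, row in _rows(path, COHORT_COLUMNS):
        try:
            records.append(
                CohortRecord(
                    patient=row["patient"], group=row["group"], cohort=row["cohort"],
                    gene=row["gene"], mutation_id=row["mutation_id"], status=row["status"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return CohortMutationTable(records=records, group_sizes=dict(group_sizes or {}))


def write_cohort_table(table: CohortMutationTable, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COHORT_COLUMNS)
        for r in table.records:
            w.writerow([r.patient, r.group.value, r.cohort, r.gene, r.mutation_id, r.status.value])


# ---------------------------------------------------------------------------
# blacklist (known germline SNPs supplied by the user)

BLACKLIST_COLUMNS = ["chrom", "pos_1based", "ref", "alt"]


def read_blacklist(path: PathLike) -> set[tuple[str, int, str, str]]:
    """Read a user-supplied known-SNP blacklist keyed by (chrom, pos, ref, alt)."""
    out = set()
    for lineno, row in _rows(path, BLACKLIST_COLUMNS):
        out.add((row["chrom"], _to_int(row["pos_1based"], "pos_1based", path, lineno),
                 row["ref"], row["alt"]))
    return out


def write_blacklist(entries: Iterable[tuple[str, int, str, str]], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(BLACKLIST_COLUMNS)
        for chrom, pos, ref, alt in sorted(entries):
            w.writerow([chrom, pos, ref, alt])


# ---------------------------------------------------------------------------
# minimal VCF import

def import_vcf_minimal(path: PathLike, sample: str, effect_info_key: Optional[str] = None) -> list[VariantCall]:
    """Import VariantCalls from a VCF using the per-sample AD field.

    Multi-allelic records are expanded to one call per ALT allele with the
    matching slice of AD. The coding effect is taken from ``effect_info_key``
    in INFO when given and recognised, else ``other``. Positions stay
    1-based as in the VCF.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        if sample not in vcf.header.samples:
            raise KeyError(f"sample {sample!r} not in VCF header (has {list(vcf.header.samples)})")
        for rec in vcf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            if ad is None or all(v is None for v in ad):
                raise ValueError(f"record {rec.chrom}:{rec.pos} lacks AD for sample {sample!r}")
            effect = Effect.other
            if effect_info_key is not None:
                raw = rec.info.get(effect_info_key)
                if isinstance(raw, tuple):
                    raw = raw[0]
                try:
                    effect = Effect(str(raw))
                except ValueError:
                    effect = Effect.other
            def info_get(key, default):
                try:
                    value = rec.info.get(key, default)
                except (KeyError, ValueError):  # key absent from the header
                    return default
                return default if value is None else value

            mq = info_get("MQ", 60.0)
            for i, alt in enumerate(rec.alts or ()):
                calls.append(
                    VariantCall(
                        sample_id=sample, chrom=rec.chrom, pos=rec.pos,
                        ref=rec.ref, alt=alt, gene=str(info_get("GENE", "")),
                        effect=effect,
                        var_reads=int(ad[i + 1]), ref_reads=int(ad[0]),
                        mapping_quality=float(mq),
                        base_quality=30.0,
                    )
                )
    return calls
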