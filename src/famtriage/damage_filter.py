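"""The "potentially damaging" variant filter.

SNPs must clear all four thresholds — scaled CADD strictly greater than 20,
gnomAD MAF strictly less than 0.01, impact severity HIGH, and exonic
classification. Indels and SVs are exempt from the CADD and MAF thresholds
(such variants commonly lack both annotations, most likely owing to their
rarity in the general population) and need only HIGH impact and exonic
status. Compound-heterozygous pairs apply the CADD/impact/exonic tests to
each member but relax the frequency rule: only one member must be rare
(MAF < 0.01), allowing a rare allele paired with a relatively common one
whose combined population frequency is still low.

A SNP missing its CADD or MAF annotation fails the filter by default
(silent passage would inflate the candidate list); ``missing_maf_as_rare``
flips the frequency half of that rule for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .inheritance import InheritanceCall, InheritanceClass
from .variant_io import Category, FamilyTable, Impact, VariantRecord


@dataclass(frozen=True)
class DamageThresholds:
    """Thresholds defining "potentially damaging"; defaults are the study's.

    ``min_cadd`` is exclusive (a score of exactly 20 fails) and ``max_maf``
    is exclusive (a frequency of exactly 0.01 fails).
    """

    min_cadd: float = 20.0
    max_maf: float = 0.01
    required_impact: Impact = Impact.HIGH
    require_exonic: bool = True
    missing_maf_as_rare: bool = False

    def __post_init__(self) -> None:
        if self.min_cadd < 0:
            raise ValueError("min_cadd must be non-negative")
        if not (0 < self.max_maf <= 1):
            raise ValueError("max_maf must be in (0, 1]")


DEFAULT_THRESHOLDS = DamageThresholds()


def _impact_exonic_ok(record: VariantRecord, thresholds: DamageThresholds) -> bool:
    if record.impact is not thresholds.required_impact:
        return False
    if thresholds.require_exonic and record.exonic is not True:
        return False
    return True


def _maf_rare(record: VariantRecord, thresholds: DamageThresholds) -> bool:
    if record.gmaf is None:
        return thresholds.missing_maf_as_rare
    return record.gmaf < thresholds.max_maf


def snp_damaging(record: VariantRecord, thresholds: DamageThresholds = DEFAULT_THRESHOLDS) -> bool:
    """CADD > 20, MAF < 0.01, HIGH impact, exonic — all strict."""
    if record.category is not Category.SNP:
        raise ValueError(f"snp_damaging applied to {record.category.value} record")
    if not _impact_exonic_ok(record, thresholds):
        return False
    if record.cadd_scaled is None or record.cadd_scaled <= thresholds.min_cadd:
        return False
    return _maf_rare(record, thresholds)


def indel_sv_damaging(
    record: VariantRecord, thresholds: DamageThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """HIGH impact and exonic only; CADD and MAF are not required."""
    if record.category is Category.SNP:
        raise ValueError("indel_sv_damaging applied to SNP record")
    return _impact_exonic_ok(record, thresholds)


def record_damaging(
    record: VariantRecord, thresholds: DamageThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Category-dispatched single-record verdict."""
    if record.category is Category.SNP:
        return snp_damaging(record, thresholds)
    return indel_sv_damaging(record, thresholds)


def comp_het_damaging(
    pair: tuple[VariantRecord, VariantRecord],
    thresholds: DamageThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Pair verdict: both members pass their non-MAF tests; one member rare.

    Each member is judged by its own category rule (SNPs need CADD > 20,
    indels/SVs are exempt); the pair-level frequency rule requires
    min(MAF) < 0.01 across members with a known MAF. A pair in which no
    member has a known MAF passes the frequency rule only if it contains a
    non-SNP member (whose category rule never demanded a MAF) or
    ``missing_maf_as_rare`` is set.
    """
    rec_a, rec_b = pair

    def member_ok(rec: VariantRecord) -> bool:
        if not _impact_exonic_ok(rec, thresholds):
            return False
        if rec.category is Category.SNP:
            if rec.cadd_scaled is None or rec.cadd_scaled <= thresholds.min_cadd:
                return False
        return True

    if not (member_ok(rec_a) and member_ok(rec_b)):
        return False
    mafs = [r.gmaf for r in pair if r.gmaf is not None]
    if not mafs:
        if any(r.category is not Category.SNP for r in pair):
            return True
        return thresholds.missing_maf_as_rare
    return min(mafs) < thresholds.max_maf


def damaging_calls(
    calls: Iterable[InheritanceCall],
    records: FamilyTable | Mapping,
    thresholds: DamageThresholds = DEFAULT_THRESHOLDS,
) -> list[InheritanceCall]:
    """Filter inheritance calls down to the potentially damaging set.

    SIMPLE_HET and HOM_ALT calls keep their record's single-record verdict;
    COMP_HET calls use the pair rule. A pure predicate: output is a subset
    of input in input order, idempotent.

    Raises
    ------
    KeyError
        If a call references a variant key absent from *records*.
    """
    kept: list[InheritanceCall] = []
    for call in calls:
        try:
            recs = [records[k] for k in call.variants]
        except KeyError as exc:
            raise KeyError(f"call references unknown variant key: {exc}") from exc
        if call.klass is InheritanceClass.COMP_HET:
            ok = comp_het_damaging((recs[0], recs[1]), thresholds)
        else:
            ok = record_damaging(recs[0], thresholds)
        if ok:
            kept.append(call)
    return kept
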