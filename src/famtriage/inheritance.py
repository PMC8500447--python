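"""Classify child variants by inheritance pattern.

Four classes are recognized per child: simple heterozygous, homozygous
alternate, compound heterozygous, and — orthogonally — de novo (the child
carries an alternate allele undetected in either parent). Parental-exclusion
rules:

* homozygous-alternate calls are dropped when either parent is also
  homozygous alternate at the site (a variant shared with a healthy parent
  is unlikely to be disease causing);
* compound-heterozygous pairs require the two child heterozygotes to lie on
  opposite haplotypes (trans) within one phase set, are dropped if either
  parent carries the same trans pair, and are dropped if either member is
  homozygous alternate in a parent;
* simple heterozygotes have no parental exclusion.

Phase is taken at face value from the input (linked-read phasing upstream);
pairs that cannot be phase-resolved are excluded by default, with an
optional parent-transmission fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Optional

from .family_model import Pedigree
from .variant_io import FamilyTable, GenotypeCall, VariantKey, VariantRecord

log = logging.getLogger("famtriage")


class Zygosity(Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class InheritanceClass(str, Enum):
    SIMPLE_HET = "SIMPLE_HET"
    HOM_ALT = "HOM_ALT"
    COMP_HET = "COMP_HET"


@dataclass(frozen=True)
class InheritanceCall:
    """One classified (child, variant[-pair]) assignment.

    ``variants`` holds one key for SIMPLE_HET / HOM_ALT and an ordered pair
    of distinct same-gene keys for COMP_HET. For COMP_HET, ``de_novo`` is
    true if either member is de novo.
    """

    child_id: str
    variants: tuple[VariantKey, ...]
    klass: InheritanceClass
    de_novo: bool
    gene: Optional[str]

    def __post_init__(self) -> None:
        n = len(self.variants)
        if self.klass is InheritanceClass.COMP_HET:
            if n != 2 or self.variants[0] == self.variants[1]:
                raise ValueError("COMP_HET requires exactly two distinct variants")
        elif n != 1:
            raise ValueError(f"{self.klass.value} requires exactly one variant")


def zygosity(call: GenotypeCall) -> Zygosity:
    """Zygosity of a biallelic call; any missing allele gives MISSING."""
    if call.is_missing:
        return Zygosity.MISSING
    n_alt = call.alt_count
    if n_alt == 0:
        return Zygosity.HOM_REF
    if n_alt == 1:
        return Zygosity.HET
    return Zygosity.HOM_ALT


def is_de_novo(record: VariantRecord, child_id: str, pedigree: Pedigree) -> bool:
    """True iff the child carries the alternate and neither parent does.

    A missing parental genotype blocks de novo status (conservative: absence
    of evidence in a parent is not evidence of absence). A missing child
    genotype returns False with a log entry.
    """
    child = record.calls.get(child_id)
    if child is None or child.is_missing:
        log.info("de novo check: missing child call at %s for %s", record.key, child_id)
        return False
    if not child.has_alt:
        return False
    for parent_id in pedigree.parent_ids:
        parent = record.calls.get(parent_id)
        if parent is None or parent.is_missing or parent.has_alt:
            return False
    return True


def simple_het_calls(
    table: FamilyTable, child_id: str, pedigree: Pedigree
) -> list[InheritanceCall]:
    """One SIMPLE_HET call per record where the child is heterozygous.

    No parental exclusion applies; the de novo flag is attached per record.
    """
    calls = []
    for key, record in table.items():
        if zygosity(record.call(child_id)) is Zygosity.HET:
            calls.append(
                InheritanceCall(
                    child_id=child_id,
                    variants=(key,),
                    klass=InheritanceClass.SIMPLE_HET,
                    de_novo=is_de_novo(record, child_id, pedigree),
                    gene=record.gene,
                )
            )
    return calls


def hom_alt_calls(
    table: FamilyTable, child_id: str, pedigree: Pedigree
) -> list[InheritanceCall]:
    """HOM_ALT calls for the child, excluding sites hom-alt in a parent."""
    calls = []
    for key, record in table.items():
        if zygosity(record.call(child_id)) is not Zygosity.HOM_ALT:
            continue
        if any(
            zygosity(record.call(p)) is Zygosity.HOM_ALT for p in pedigree.parent_ids
        ):
            continue
        calls.append(
            InheritanceCall(
                child_id=child_id,
                variants=(key,),
                klass=InheritanceClass.HOM_ALT,
                de_novo=is_de_novo(record, child_id, pedigree),
                gene=record.gene,
            )
        )
    return calls


def _haplotype_of_alt(call: GenotypeCall) -> Optional[int]:
    """Haplotype index (0 or 1) carrying the alternate of a phased HET call."""
    if not call.phased or call.is_missing:
        return None
    a0, a1 = call.alleles
    if a0 >= 1 and a1 == 0:
        return 0
    if a1 >= 1 and a0 == 0:
        return 1
    return None


def _in_trans(call_a: GenotypeCall, call_b: GenotypeCall) -> Optional[bool]:
    """Whether two HET calls of one sample lie on opposite haplotypes.

    Returns None when phase cannot be resolved (either call unphased, or
    the calls belong to different phase sets).
    """
    hap_a, hap_b = _haplotype_of_alt(call_a), _haplotype_of_alt(call_b)
    if hap_a is None or hap_b is None:
        return None
    if call_a.phase_set != call_b.phase_set:
        return None
    return hap_a != hap_b


def compound_het_calls(
    table: FamilyTable,
    child_id: str,
    pedigree: Pedigree,
    infer_trans_from_parents: bool = False,
) -> list[InheritanceCall]:
    """Trans pairs of child heterozygotes within a gene, after exclusions.

    For each gene, every unordered pair of sites where the child is HET is a
    candidate. A pair is emitted iff:

    * the two alternates lie on opposite haplotypes, as judged by phased
      allele order within a shared phase set (with
      ``infer_trans_from_parents``, a pair unresolvable by phase is accepted
      when each variant can only have come from a different parent);
    * neither parent carries the same pair in trans (one member is ordinary
      transmission; the joint trans pair in a healthy parent disqualifies);
    * neither member is homozygous alternate in either parent.

    Pairs failing phase resolution are excluded with a log entry. Records
    without a gene symbol never form pairs.
    """
    by_gene: dict[str, list[tuple[VariantKey, VariantRecord]]] = {}
    for key, record in table.items():
        if record.gene is None:
            continue
        if zygosity(record.call(child_id)) is Zygosity.HET:
            by_gene.setdefault(record.gene, []).append((key, record))

    calls: list[InheritanceCall] = []
    for gene, sites in by_gene.items():
        sites = sorted(sites, key=lambda kv: (kv[0].chrom, kv[0].pos, kv[0].ref, kv[0].alt))
        for (key_a, rec_a), (key_b, rec_b) in combinations(sites, 2):
            child_a, child_b = rec_a.call(child_id), rec_b.call(child_id)
            trans = _in_trans(child_a, child_b)
            if trans is None and infer_trans_from_parents:
                trans = _trans_by_transmission(rec_a, rec_b, pedigree)
            if trans is None:
                log.info(
                    "comp het: phase unresolved for %s/%s in %s (child %s); pair excluded",
                    key_a, key_b, gene, child_id,
                )
                continue
            if not trans:
                continue
            if any(
                zygosity(rec.call(p)) is Zygosity.HOM_ALT
                for rec in (rec_a, rec_b)
                for p in pedigree.parent_ids
            ):
                continue
            if any(
                _in_trans(rec_a.call(p), rec_b.call(p)) is True
                for p in pedigree.parent_ids
            ):
                continue
            calls.append(
                InheritanceCall(
                    child_id=child_id,
                    variants=(key_a, key_b),
                    klass=InheritanceClass.COMP_HET,
                    de_novo=(
                        is_de_novo(rec_a, child_id, pedigree)
                        or is_de_novo(rec_b, child_id, pedigree)
                    ),
                    gene=gene,
                )
            )
    return calls


def _trans_by_transmission(
    rec_a: VariantRecord, rec_b: VariantRecord, pedigree: Pedigree
) -> Optional[bool]:
    """Fallback trans inference: each variant carried by a different parent.

    Only conclusive when exactly one parent carries each alternate and the
    two carriers differ; anything else stays unresolved.
    """
    father, mother = pedigree.parent_ids

    def carrier(rec: VariantRecord) -> Optional[str]:
        has_f = rec.call(father).has_alt
        has_m = rec.call(mother).has_alt
        if has_f and not has_m:
            return father
        if has_m and not has_f:
            return mother
        return None

    carrier_a, carrier_b = carrier(rec_a), carrier(rec_b)
    if carrier_a is None or carrier_b is None:
        return None
    return carrier_a != carrier_b


def classify_child(
    table: FamilyTable,
    child_id: str,
    pedigree: Pedigree,
    infer_trans_from_parents: bool = False,
) -> list[InheritanceCall]:
    """All inheritance calls for one child (simple het, hom alt, comp het)."""
    return (
        simple_het_calls(table, child_id, pedigree)
        + hom_alt_calls(table, child_id, pedigree)
        + compound_het_calls(table, child_id, pedigree, infer_trans_from_parents)
    )


def classify_family(
    table: FamilyTable,
    pedigree: Pedigree,
    infer_trans_from_parents: bool = False,
) -> list[InheritanceCall]:
    """Inheritance calls for every child, children classified independently."""
    calls: list[InheritanceCall] = []
    for child in pedigree.child_ids:
        calls.extend(classify_child(table, child, pedigree, infer_trans_from_parents))
    return calls
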