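"""Shared fixtures: a reference family and record factories."""

from __future__ import annotations

from typing import Optional

import pytest

from famtriage import (
    Category,
    GenotypeCall,
    Impact,
    Pedigree,
    VariantRecord,
)


@pytest.fixture
def quad_pedigree() -> Pedigree:
    """Two parents, four children (like the 4-child family in the study)."""
    return Pedigree("fam2", "30", "31", ("32", "33", "34", "35"))


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree("trio", "F", "M", ("C",))


def make_record(
    pedigree: Pedigree,
    genotypes: dict[str, tuple[Optional[int], Optional[int]]],
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "T",
    category: Category = Category.SNP,
    gene: Optional[str] = "GENE1",
    impact: Optional[Impact] = Impact.HIGH,
    exonic: Optional[bool] = True,
    cadd: Optional[float] = 25.0,
    gmaf: Optional[float] = 0.001,
    qual: float = 50.0,
    filter_status: str = "PASS",
    phased: bool = True,
    phase_set: Optional[int] = 1,
    end: Optional[int] = None,
) -> VariantRecord:
    """Build a family record; samples absent from *genotypes* are hom-ref."""
    calls = {}
    for sample in pedigree.sample_ids:
        alleles = genotypes.get(sample, (0, 0))
        missing = any(a is None for a in alleles)
        is_phased = phased and not missing
        calls[sample] = GenotypeCall(
            sample, alleles, phased=is_phased, phase_set=phase_set if is_phased else None
        )
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        end=end,
        category=category,
        qual=qual,
        filter_status=filter_status,
        gene=gene,
        impact=impact,
        exonic=exonic,
        cadd_scaled=cadd,
        gmaf=gmaf,
        calls=calls,
    )
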