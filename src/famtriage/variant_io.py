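"""Read, filter, normalize and merge family variant data.

Variants arrive as per-category VCFs (SNPs, mid-scale indels, large SVs are
called and phased separately and stay separate through the whole pipeline).
This module turns them into in-memory :class:`VariantRecord` tables keyed by
:class:`VariantKey`, applying the quality filter (QUAL >= 20 and FILTER ==
PASS), vt-style normalization of small variants (multi-allelic decomposition,
left alignment, parsimony trimming), and a bcftools-merge-style combination
of per-sample files into one family-wide table.

Functional annotations (gene symbol, impact severity, exonic status, scaled
CADD, gnomAD allele frequency) are consumed, never computed: they are read
from INFO fields (snpEff ANN entries or dedicated tags) or from a sidecar
TSV which, when present, overrides INFO values.

Coordinates are 1-based fully-closed VCF convention throughout.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from cyvcf2 import VCF

from .family_model import Pedigree

log = logging.getLogger("famtriage")

MIN_QUAL = 20.0  # inclusive, per the "quality score >= 20" rule
PASS_FILTER = "PASS"


class Category(str, Enum):
    """Variant category; the three files are processed separately."""

    SNP = "SNP"
    INDEL = "INDEL"
    SV = "SV"


class Impact(str, Enum):
    """snpEff-style impact severity classes."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call at one site.

    ``alleles`` are VCF allele indices (0 = reference, >= 1 = alternate,
    ``None`` = missing). When ``phased`` is true the pair is ordered
    (haplotype 0, haplotype 1) within ``phase_set``; unphased calls carry no
    haplotype meaning and no phase set.
    """

    sample_id: str
    alleles: tuple[Optional[int], Optional[int]]
    phased: bool = False
    phase_set: Optional[int] = None

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a is not None and a < 0:
                raise ValueError(f"negative allele index {a}")
        if self.phase_set is not None and not self.phased:
            raise ValueError("phase_set present on unphased call")

    @property
    def has_alt(self) -> bool:
        return any(a is not None and a >= 1 for a in self.alleles)

    @property
    def alt_count(self) -> int:
        return sum(1 for a in self.alleles if a is not None and a >= 1)

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)


@dataclass(frozen=True)
class VariantKey:
    """Identity of a variant for cross-sample merging.

    Small variants match on (chrom, pos, ref, alt); symbolic-ALT SVs also
    match on END, with zero positional tolerance.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    end: Optional[int] = None
    category: Category = Category.SNP

    def __str__(self) -> str:
        tail = f"-{self.end}" if self.end is not None else ""
        return f"{self.chrom}:{self.pos}{tail}:{self.ref}>{self.alt}"


@dataclass
class VariantRecord:
    """One normalized, biallelic variant with annotations and family calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    category: Category
    qual: Optional[float] = None
    filter_status: str = PASS_FILTER
    end: Optional[int] = None  # symbolic SVs only
    gene: Optional[str] = None
    impact: Optional[Impact] = None
    exonic: Optional[bool] = None
    cadd_scaled: Optional[float] = None
    gmaf: Optional[float] = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.gmaf is not None and not (0.0 <= self.gmaf <= 1.0):
            raise ValueError(f"gmaf out of [0,1]: {self.gmaf}")

    @property
    def key(self) -> VariantKey:
        end = self.end if self.alt.startswith("<") else None
        return VariantKey(self.chrom, self.pos, self.ref, self.alt, end, self.category)

    def call(self, sample_id: str) -> GenotypeCall:
        return self.calls[sample_id]


FamilyTable = dict[VariantKey, VariantRecord]

# snpEff consequence terms GEMINI treats as exonic
_EXONIC_TERMS = {
    "stop_gained", "stop_lost", "start_lost", "frameshift_variant",
    "missense_variant", "synonymous_variant", "inframe_insertion",
    "inframe_deletion", "exon_variant", "exon_loss_variant",
    "coding_sequence_variant", "transcript_ablation",
    "initiator_codon_variant", "stop_retained_variant",
    "protein_altering_variant",
}

_IMPACT_RANK = {Impact.HIGH: 0, Impact.MODERATE: 1, Impact.LOW: 2, Impact.MODIFIER: 3}


def _parse_ann(ann_value: str, alt: str) -> tuple[Optional[str], Optional[Impact], Optional[bool]]:
    """Extract (gene, impact, exonic) from a snpEff ANN INFO string.

    Takes the most severe entry matching *alt* (snpEff orders by severity,
    but we do not rely on that).
    """
    best: tuple[int, Optional[str], Optional[Impact], Optional[bool]] | None = None
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            continue
        allele, consequence, impact_s, gene = fields[0], fields[1], fields[2], fields[3]
        if allele and allele != alt:
            continue
        try:
            impact = Impact(impact_s)
        except ValueError:
            continue
        exonic = any(term in _EXONIC_TERMS for term in consequence.split("&"))
        rank = _IMPACT_RANK[impact]
        if best is None or rank < best[0]:
            best = (rank, gene or None, impact, exonic)
    if best is None:
        return None, None, None
    return best[1], best[2], best[3]


def _info_float(variant, *keys: str) -> Optional[float]:
    for key in keys:
        value = variant.INFO.get(key)
        if value is not None:
            try:
                return float(value)
            except (TypeError, ValueError):
                continue
    return None


def read_vcf(
    path: str | Path,
    pedigree: Pedigree,
    category: Category | str,
    sidecar: Optional[Mapping[tuple[str, int, str, str], dict]] = None,
) -> list[VariantRecord]:
    """Read a (possibly multi-sample) VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are split into biallelic records (allele indices for
    other alternates become missing). Annotations are taken from INFO —
    snpEff ``ANN`` entries plus ``CADD``/``GMAF``-style tags — and overridden
    by *sidecar* entries when provided (see
    :func:`load_annotation_sidecar`); absent values stay absent, never
    imputed. Malformed genotypes skip the record with a logged warning.

    Raises
    ------
    ValueError
        If no pedigree sample is present in the VCF header.
    """
    category = Category(category)
    vcf = VCF(str(path))
    samples = [s for s in vcf.samples if s in pedigree]
    if not samples:
        raise ValueError(
            f"{path}: no pedigree sample among VCF samples {list(vcf.samples)}"
        )
    sample_idx = [(s, vcf.samples.index(s)) for s in samples]

    records: list[VariantRecord] = []
    n_skipped = 0
    for variant in vcf:
        alts = list(variant.ALT)
        if not alts:
            continue
        try:
            genotypes = variant.genotypes  # [a0, a1, phased] per sample
        except Exception:  # malformed genotype field
            n_skipped += 1
            log.warning("skipping malformed genotype at %s:%s", variant.CHROM, variant.POS)
            continue
        try:
            phase_sets = variant.format("PS")
        except KeyError:  # PS absent from header: nothing is phase-set tagged
            phase_sets = None
        for alt_i, alt in enumerate(alts):
            alt_index = alt_i + 1
            calls: dict[str, GenotypeCall] = {}
            ok = True
            for sample, idx in sample_idx:
                gt = genotypes[idx]
                if len(gt) < 2:
                    ok = False
                    break
                raw = list(gt[:-1])
                phased = bool(gt[-1])
                if len(raw) == 1:  # haploid call; treat as homozygous
                    raw = [raw[0], raw[0]]
                alleles = tuple(
                    None if a < 0 else (1 if a == alt_index else (0 if a == 0 else None))
                    for a in raw[:2]
                )
                ps = None
                if phased and phase_sets is not None:
                    try:
                        ps_val = int(phase_sets[idx][0]) if phase_sets.ndim > 1 else int(phase_sets[idx])
                        ps = ps_val if ps_val > 0 else None
                    except (TypeError, ValueError, IndexError):
                        ps = None
                phased = phased and ps is not None
                calls[sample] = GenotypeCall(sample, alleles, phased, ps)
            if not ok:
                n_skipped += 1
                log.warning("skipping malformed genotype at %s:%s", variant.CHROM, variant.POS)
                continue

            gene, impact, exonic = None, None, None
            ann = variant.INFO.get("ANN")
            if ann:
                gene, impact, exonic = _parse_ann(str(ann), alt)
            gene_tag = variant.INFO.get("GENE") or variant.INFO.get("gene")
            if gene_tag:
                gene = str(gene_tag)
            impact_tag = variant.INFO.get("IMPACT") or variant.INFO.get("impact_severity")
            if impact_tag:
                try:
                    impact = Impact(str(impact_tag))
                except ValueError:
                    pass
            if variant.INFO.get("EXONIC") is not None:
                exonic = bool(variant.INFO.get("EXONIC"))

            end = None
            if alt.startswith("<"):
                info_end = variant.INFO.get("END")
                end = int(info_end) if info_end is not None else int(variant.end)

            record = VariantRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=alt,
                category=category,
                qual=float(variant.QUAL) if variant.QUAL is not None else None,
                filter_status=variant.FILTER or PASS_FILTER,
                end=end,
                gene=gene,
                impact=impact,
                exonic=exonic,
                cadd_scaled=_info_float(variant, "CADD", "CADD_SCALED", "cadd_scaled"),
                gmaf=_info_float(variant, "GMAF", "gnomAD_AF", "gmaf", "max_aaf_all"),
                calls=calls,
            )
            if sidecar is not None:
                record = _apply_sidecar(record, sidecar)
            records.append(record)
    if n_skipped:
        log.warning("%s: skipped %d record(s) with malformed genotypes", path, n_skipped)
    return records


def load_annotation_sidecar(path: str | Path) -> dict[tuple[str, int, str, str], dict]:
    """Load a sidecar annotation TSV keyed by (chrom, pos, ref, alt).

    Expected columns: chrom, pos, ref, alt, gene, impact, exonic,
    cadd_scaled, gmaf. Empty cells mean "absent".
    """
    table: dict[tuple[str, int, str, str], dict] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            entry: dict = {}
            if row.get("gene"):
                entry["gene"] = row["gene"]
            if row.get("impact"):
                entry["impact"] = Impact(row["impact"])
            if row.get("exonic"):
                entry["exonic"] = row["exonic"].strip().lower() in {"1", "true", "yes"}
            if row.get("cadd_scaled"):
                entry["cadd_scaled"] = float(row["cadd_scaled"])
            if row.get("gmaf"):
                entry["gmaf"] = float(row["gmaf"])
            table[key] = entry
    return table


def _apply_sidecar(
    record: VariantRecord, sidecar: Mapping[tuple[str, int, str, str], dict]
) -> VariantRecord:
    entry = sidecar.get((record.chrom, record.pos, record.ref, record.alt))
    if not entry:
        return record
    overridden = [
        f for f in entry if getattr(record, f) is not None and getattr(record, f) != entry[f]
    ]
    if overridden:
        log.info("sidecar overrides %s at %s", overridden, record.key)
    return replace(record, **entry)


def quality_filter(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep exactly the records with QUAL >= 20 and FILTER == PASS.

    A missing QUAL fails the filter (conservative). Order is preserved;
    the operation is idempotent.
    """
    return [
        r
        for r in records
        if r.qual is not None and r.qual >= MIN_QUAL and r.filter_status == PASS_FILTER
    ]


def _left_align_trim(
    chrom: str, pos: int, ref: str, alt: str, reference: Optional[Mapping[str, str]]
) -> tuple[int, str, str]:
    """vt-style normalization of one biallelic small variant.

    Repeatedly right-trims shared terminal bases (left-extending from the
    reference when an allele would become empty), then left-trims shared
    leading bases. *reference* maps contig name to its full sequence
    (0-based string); without it, only trimming that needs no context is
    applied.

    Raises
    ------
    ValueError
        If the reference sequence disagrees with the record's REF allele.
    """
    seq = reference.get(chrom) if reference is not None else None
    if seq is not None:
        if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: VCF REF {ref!r} vs "
                f"reference {seq[pos - 1 : pos - 1 + len(ref)]!r}"
            )
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif seq is not None and pos > 1:
            # one allele is about to empty: truncate and extend left instead
            base = seq[pos - 2]
            ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
        else:
            break  # no reference context (or at contig start): trim-only mode
    # left-trim shared leading bases, keeping at least one
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def normalize_small_variants(
    records: Iterable[VariantRecord],
    reference: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Left-align and parsimony-trim SNP/indel records; SVs pass untouched.

    Idempotent. Records are assumed already biallelic (decomposition happens
    at read time); *reference* maps contig to sequence for indel left
    alignment — without it, records must already be parsimony-trimmed.
    """
    out: list[VariantRecord] = []
    for record in records:
        if record.category is Category.SV or record.alt.startswith("<"):
            out.append(record)
            continue
        pos, ref, alt = _left_align_trim(
            record.chrom, record.pos, record.ref, record.alt, reference
        )
        if (pos, ref, alt) != (record.pos, record.ref, record.alt):
            record = replace(record, pos=pos, ref=ref, alt=alt)
        out.append(record)
    return out


def merge_family(
    sources: Sequence[Sequence[VariantRecord]],
    pedigree: Pedigree,
) -> FamilyTable:
    """Combine per-sample record sequences into one family-wide table.

    One row per :class:`VariantKey`. A pedigree sample with no call at a key
    — i.e. the site is absent from that sample's file — is assigned a
    homozygous-reference call, mirroring how a merged-then-queried workflow
    treats absent sites (a caveat: absence may also mean no coverage).

    Raises
    ------
    ValueError
        If two sources disagree on the REF allele at the same chrom/pos
        (a normalization bug upstream), if sources mix categories, or if a
        pedigree sample appears in no source.
    """
    seen_samples: set[str] = set()
    categories: set[Category] = set()
    table: FamilyTable = {}
    ref_at_pos: dict[tuple[str, int, Category], str] = {}
    for source in sources:
        for record in source:
            categories.add(record.category)
            if len(categories) > 1:
                raise ValueError(f"mixed categories in merge: {sorted(c.value for c in categories)}")
            if not record.alt.startswith("<"):
                pos_key = (record.chrom, record.pos, record.category)
                prior_ref = ref_at_pos.setdefault(pos_key, record.ref)
                if len(prior_ref) == len(record.ref) and prior_ref != record.ref:
                    raise ValueError(
                        f"conflicting REF alleles at {record.chrom}:{record.pos}: "
                        f"{prior_ref!r} vs {record.ref!r}"
                    )
            seen_samples.update(record.calls)
            key = record.key
            existing = table.get(key)
            if existing is None:
                table[key] = replace(record, calls=dict(record.calls))
            else:
                existing.calls.update(record.calls)
                # fill annotations the first source lacked
                for f in ("gene", "impact", "exonic", "cadd_scaled", "gmaf"):
                    if getattr(existing, f) is None and getattr(record, f) is not None:
                        setattr(existing, f, getattr(record, f))
    missing_samples = set(pedigree.sample_ids) - seen_samples
    if table and missing_samples:
        raise ValueError(
            f"pedigree sample(s) absent from all provided VCFs: {sorted(missing_samples)}"
        )
    n_filled = 0
    for record in table.values():
        for sample in pedigree.sample_ids:
            if sample not in record.calls:
                record.calls[sample] = GenotypeCall(sample, (0, 0))
                n_filled += 1
    if n_filled:
        log.info(
            "merge_family: filled %d absent site call(s) as homozygous reference "
            "(absence may also mean no coverage)",
            n_filled,
        )
    return table
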