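"""Simulate phased nuclear-family VCFs with planted inheritance classes.

Real WGS data for nuclear families cannot ship with the package, so this
module fabricates the study conditions: per-category VCF 4.2 files (SNPs,
indels, SVs) carrying phased genotypes, QUAL and FILTER fields, and the
annotation fields the triage pipeline consumes — together with a truth
manifest recording exactly what was planted, so every pipeline stage can be
checked against ground truth.

Background variants are Mendelian-consistent by construction (each child
allele is drawn uniformly from the transmitting parent's two alleles) and
annotated so they can never pass the damaging filter (MAF in [0.02, 0.5],
scaled CADD below 20, MODERATE/LOW impact); only planted variants drive
candidates, which makes truth-manifest assertions exact. QUAL values are
drawn so that a configurable fraction of background records falls below 20
and another fraction is non-PASS; the defaults leave ~72% of background
records passing the quality filter, in line with typical linked-read
callsets. All randomness flows from a single seed; output is deterministic.

Phasing convention: within each sample, haplotype 0 is paternal and
haplotype 1 is maternal for children; parents' own allele order is as drawn.
One phase set spans each chromosome (``fragmented_phase`` gives every site
its own phase set, exercising the unphased-pair exclusion path).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .family_model import Pedigree
from .inheritance import InheritanceClass
from .variant_io import Category, GenotypeCall, Impact, VariantKey, VariantRecord

_CONTIGS = [f"chr{i}" for i in range(1, 23)]
_NONPASS_FILTER = "10X_PHASING_INCONSISTENT"
_SV_LEN = 5000


class PlantClass(str, Enum):
    SIMPLE_HET = "SIMPLE_HET"
    HOM_ALT = "HOM_ALT"
    COMP_HET_TRANS = "COMP_HET_TRANS"
    COMP_HET_CIS_DECOY = "COMP_HET_CIS_DECOY"
    DE_NOVO = "DE_NOVO"


@dataclass(frozen=True)
class PlantSpec:
    """One planted signal: a variant (or comp-het pair) in chosen children.

    Annotation fields left ``None`` are filled from *intended_pass*: a
    passing SNP gets CADD 25 / MAF 0.001 / HIGH / exonic, a passing indel or
    SV gets HIGH / exonic with no CADD or MAF; a failing plant gets MODERATE
    impact (everything else favorable), so failure is attributable to one
    annotation.
    """

    gene: str
    child_targets: tuple[str, ...]
    klass: PlantClass
    category: Category = Category.SNP
    cadd_scaled: Optional[float] = None
    gmaf: Optional[float] = None
    impact: Optional[Impact] = None
    exonic: Optional[bool] = None
    intended_pass: bool = True

    def __post_init__(self) -> None:
        if not self.child_targets:
            raise ValueError("plant must target at least one child")


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one planted record (one VCF line)."""

    key: VariantKey
    gene: str
    plant_klass: PlantClass
    pair_index: int  # 0 for singletons; 0/1 for the two sites of a pair
    child_targets: tuple[str, ...]
    expected_class: InheritanceClass  # per targeted child
    expected_de_novo: bool
    intended_pass: bool
    expected_sharing: int
    genotypes: dict[str, tuple[int, int]] = field(hash=False, default_factory=dict)


@dataclass
class TruthManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def by_gene(self, gene: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.gene == gene]

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(
                [
                    "chrom", "pos", "ref", "alt", "end", "category", "gene",
                    "plant_klass", "pair_index", "child_targets",
                    "expected_class", "expected_de_novo", "intended_pass",
                    "expected_sharing",
                ]
            )
            for e in self.entries:
                writer.writerow(
                    [
                        e.key.chrom, e.key.pos, e.key.ref, e.key.alt,
                        e.key.end if e.key.end is not None else "",
                        e.key.category.value, e.gene, e.plant_klass.value,
                        e.pair_index, ",".join(e.child_targets),
                        e.expected_class.value, int(e.expected_de_novo),
                        int(e.intended_pass), e.expected_sharing,
                    ]
                )


@dataclass
class SimulationResult:
    pedigree: Pedigree
    records: dict[Category, list[VariantRecord]]
    manifest: TruthManifest
    vcf_paths: dict[Category, Path] = field(default_factory=dict)
    manifest_path: Optional[Path] = None


def _background_genotypes(
    pedigree: Pedigree, rng: np.random.Generator, alt_freq: float
) -> dict[str, tuple[int, int]]:
    """Mendelian-consistent phased genotypes: parents drawn from the allele
    frequency, each child allele drawn uniformly from the transmitting
    parent's pair (haplotype 0 paternal, 1 maternal)."""
    father = (int(rng.random() < alt_freq), int(rng.random() < alt_freq))
    mother = (int(rng.random() < alt_freq), int(rng.random() < alt_freq))
    genotypes = {pedigree.father_id: father, pedigree.mother_id: mother}
    for child in pedigree.child_ids:
        genotypes[child] = (father[rng.integers(0, 2)], mother[rng.integers(0, 2)])
    return genotypes


def _plant_genotypes(
    plant: PlantSpec, pair_index: int, pedigree: Pedigree
) -> dict[str, tuple[int, int]]:
    """Genotypes realizing a plant at one site; non-targets are hom-ref."""
    father, mother = pedigree.parent_ids
    genotypes: dict[str, tuple[int, int]] = {s: (0, 0) for s in pedigree.sample_ids}
    if plant.klass is PlantClass.SIMPLE_HET:
        genotypes[mother] = (0, 1)
        for child in plant.child_targets:
            genotypes[child] = (0, 1)  # maternal alt on haplotype 1
    elif plant.klass is PlantClass.HOM_ALT:
        genotypes[father] = (1, 0)
        genotypes[mother] = (0, 1)
        for child in plant.child_targets:
            genotypes[child] = (1, 1)
    elif plant.klass is PlantClass.DE_NOVO:
        for child in plant.child_targets:
            genotypes[child] = (0, 1)  # parents stay hom-ref
    elif plant.klass is PlantClass.COMP_HET_TRANS:
        if pair_index == 0:  # maternal member, child alt on haplotype 1
            genotypes[mother] = (0, 1)
            for child in plant.child_targets:
                genotypes[child] = (0, 1)
        else:  # paternal member, child alt on haplotype 0
            genotypes[father] = (0, 1)
            for child in plant.child_targets:
                genotypes[child] = (1, 0)
    elif plant.klass is PlantClass.COMP_HET_CIS_DECOY:
        # both members on the mother's haplotype 1; the child inherits both
        # on its maternal haplotype -> cis, never a compound het
        genotypes[mother] = (0, 1)
        for child in plant.child_targets:
            genotypes[child] = (0, 1)
    else:  # pragma: no cover
        raise ValueError(f"unknown plant class {plant.klass}")
    return genotypes


def _plant_annotations(plant: PlantSpec) -> dict:
    if plant.intended_pass:
        impact = plant.impact if plant.impact is not None else Impact.HIGH
        exonic = plant.exonic if plant.exonic is not None else True
        if plant.category is Category.SNP:
            cadd = plant.cadd_scaled if plant.cadd_scaled is not None else 25.0
            gmaf = plant.gmaf if plant.gmaf is not None else 0.001
        else:
            cadd, gmaf = plant.cadd_scaled, plant.gmaf
    else:
        impact = plant.impact if plant.impact is not None else Impact.MODERATE
        exonic = plant.exonic if plant.exonic is not None else True
        cadd = plant.cadd_scaled if plant.cadd_scaled is not None else (
            25.0 if plant.category is Category.SNP else None
        )
        gmaf = plant.gmaf if plant.gmaf is not None else (
            0.001 if plant.category is Category.SNP else None
        )
    return {"impact": impact, "exonic": exonic, "cadd_scaled": cadd, "gmaf": gmaf}


def _expected_class(plant: PlantSpec) -> tuple[InheritanceClass, bool]:
    if plant.klass is PlantClass.SIMPLE_HET:
        return InheritanceClass.SIMPLE_HET, False
    if plant.klass is PlantClass.DE_NOVO:
        return InheritanceClass.SIMPLE_HET, True
    if plant.klass is PlantClass.HOM_ALT:
        return InheritanceClass.HOM_ALT, False
    if plant.klass is PlantClass.COMP_HET_TRANS:
        return InheritanceClass.COMP_HET, False
    # cis decoy: each member is seen as an ordinary simple het
    return InheritanceClass.SIMPLE_HET, False


def simulate_family(
    pedigree: Pedigree,
    n_background: int,
    plants: Sequence[PlantSpec],
    seed: int,
    out_dir: Optional[str | Path] = None,
    frac_low_qual: float = 0.15,
    frac_non_pass: float = 0.15,
    background_alt_freq: float = 0.3,
    fragmented_phase: bool = False,
) -> SimulationResult:
    """Generate per-category family VCFs, a sidecar-free annotation set
    (annotations ride in INFO), and the truth manifest.

    Background SNPs go to the SNP file; planted records go to their
    category's file. With *out_dir* set, writes ``snps.vcf`` / ``indels.vcf``
    / ``svs.vcf`` (only categories with records) plus ``manifest.tsv``.
    Deterministic for a given *seed*.
    """
    for plant in plants:
        unknown = set(plant.child_targets) - set(pedigree.child_ids)
        if unknown:
            raise ValueError(f"plant targets unknown child(ren): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    records: dict[Category, list[VariantRecord]] = {c: [] for c in Category}
    manifest = TruthManifest()

    # lay out sites: background first, then plants, round-robin over contigs
    next_pos = {c: 10_000 for c in _CONTIGS}
    contig_cycle = 0
    phase_set_counter = [1]

    def take_site(contig_hint: Optional[str] = None) -> tuple[str, int]:
        nonlocal contig_cycle
        chrom = contig_hint or _CONTIGS[contig_cycle % len(_CONTIGS)]
        if contig_hint is None:
            contig_cycle += 1
        pos = next_pos[chrom]
        next_pos[chrom] = pos + int(rng.integers(500, 5_000))
        return chrom, pos

    def phase_set_for(chrom: str) -> int:
        if fragmented_phase:
            phase_set_counter[0] += 1
            return phase_set_counter[0]
        return _CONTIGS.index(chrom) + 1

    def make_calls(
        genotypes: dict[str, tuple[int, int]], chrom: str
    ) -> dict[str, GenotypeCall]:
        ps = phase_set_for(chrom)
        return {
            s: GenotypeCall(s, g, phased=True, phase_set=ps)
            for s, g in genotypes.items()
        }

    bases = "ACGT"
    for i in range(n_background):
        genotypes = _background_genotypes(pedigree, rng, background_alt_freq)
        while not any(sum(g) > 0 for g in genotypes.values()):
            genotypes = _background_genotypes(pedigree, rng, background_alt_freq)
        chrom, pos = take_site()
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        low_qual = rng.random() < frac_low_qual
        non_pass = rng.random() < frac_non_pass
        records[Category.SNP].append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                category=Category.SNP,
                qual=round(float(rng.uniform(5.0, 19.9) if low_qual else rng.uniform(20.0, 60.0)), 1),
                filter_status=_NONPASS_FILTER if non_pass else "PASS",
                gene=f"BG{i % max(1, n_background // 3):04d}",
                impact=Impact.MODERATE if rng.random() < 0.5 else Impact.LOW,
                exonic=bool(rng.random() < 0.5),
                cadd_scaled=round(float(rng.uniform(0.0, 19.0)), 2),
                gmaf=round(float(rng.uniform(0.02, 0.5)), 4),
                calls=make_calls(genotypes, chrom),
            )
        )

    for plant in plants:
        n_sites = 2 if plant.klass in (
            PlantClass.COMP_HET_TRANS, PlantClass.COMP_HET_CIS_DECOY
        ) else 1
        ann = _plant_annotations(plant)
        expected_class, expected_dn = _expected_class(plant)
        pair_chrom: Optional[str] = None
        for pair_index in range(n_sites):
            chrom, pos = take_site(contig_hint=pair_chrom)
            pair_chrom = chrom  # second member of a pair shares the contig
            genotypes = _plant_genotypes(plant, pair_index, pedigree)
            if plant.category is Category.SV:
                ref, alt, end = "N", "<DEL>", pos + _SV_LEN
            elif plant.category is Category.INDEL:
                ref = "C" + "AT" * int(rng.integers(2, 5))
                alt, end = "C", None
            else:
                ref = bases[int(rng.integers(0, 4))]
                alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                end = None
            # comp-het members: second member may have any MAF (rare+common)
            gmaf = ann["gmaf"]
            if (
                plant.klass is PlantClass.COMP_HET_TRANS
                and pair_index == 1
                and plant.category is Category.SNP
                and plant.gmaf is None
            ):
                gmaf = 0.30
            record = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                end=end,
                category=plant.category,
                qual=round(float(rng.uniform(30.0, 60.0)), 1),
                filter_status="PASS",
                gene=plant.gene,
                impact=ann["impact"],
                exonic=ann["exonic"],
                cadd_scaled=ann["cadd_scaled"],
                gmaf=gmaf,
                calls=make_calls(genotypes, chrom),
            )
            records[plant.category].append(record)
            manifest.entries.append(
                ManifestEntry(
                    key=record.key,
                    gene=plant.gene,
                    plant_klass=plant.klass,
                    pair_index=pair_index,
                    child_targets=plant.child_targets,
                    expected_class=expected_class,
                    expected_de_novo=expected_dn,
                    intended_pass=plant.intended_pass,
                    expected_sharing=len(plant.child_targets),
                    genotypes=genotypes,
                )
            )

    for cat in records:
        records[cat].sort(key=lambda r: (_CONTIGS.index(r.chrom), r.pos, r.alt))

    result = SimulationResult(pedigree=pedigree, records=records, manifest=manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = {Category.SNP: "snps.vcf", Category.INDEL: "indels.vcf", Category.SV: "svs.vcf"}
        for cat, recs in records.items():
            if recs:
                path = out_dir / names[cat]
                write_vcf(recs, pedigree, path)
                result.vcf_paths[cat] = path
        result.manifest_path = out_dir / "manifest.tsv"
        manifest.write(result.manifest_path)
    return result


def write_vcf(
    records: Sequence[VariantRecord], pedigree: Pedigree, path: str | Path
) -> None:
    """Emit records as a multi-sample VCF 4.2 text file.

    Annotations travel as INFO tags (GENE, IMPACT, EXONIC, CADD, GMAF, and
    END/SVTYPE for symbolic SVs); genotypes as GT with a PS phase-set tag.
    """
    samples = list(pedigree.sample_ids)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact severity">',
        '##INFO=<ID=EXONIC,Number=1,Type=Integer,Description="1 if exonic">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="Scaled CADD score">',
        '##INFO=<ID=GMAF,Number=1,Type=Float,Description="gnomAD global MAF">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of SV">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##FILTER=<ID=10X_PHASING_INCONSISTENT,Description="Phasing inconsistent">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
    ]
    for contig in _CONTIGS:
        lines.append(f"##contig=<ID={contig},length=250000000>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for r in records:
        info_parts = []
        if r.gene is not None:
            info_parts.append(f"GENE={r.gene}")
        if r.impact is not None:
            info_parts.append(f"IMPACT={r.impact.value}")
        if r.exonic is not None:
            info_parts.append(f"EXONIC={int(r.exonic)}")
        if r.cadd_scaled is not None:
            info_parts.append(f"CADD={r.cadd_scaled}")
        if r.gmaf is not None:
            info_parts.append(f"GMAF={r.gmaf}")
        if r.alt.startswith("<"):
            if r.end is not None:
                info_parts.append(f"END={r.end}")
            info_parts.append(f"SVTYPE={r.alt.strip('<>')}")
        info = ";".join(info_parts) if info_parts else "."
        cols = []
        for sample in samples:
            call = r.calls.get(sample)
            if call is None:
                cols.append("./.")
                continue
            sep = "|" if call.phased else "/"
            gt = sep.join("." if a is None else str(a) for a in call.alleles)
            if call.phased and call.phase_set is not None:
                cols.append(f"{gt}:{call.phase_set}")
            else:
                cols.append(f"{gt}:.")
        qual = "." if r.qual is None else f"{r.qual:g}"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t{r.filter_status}"
            f"\t{info}\tGT:PS\t" + "\t".join(cols)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def per_sample_exports(
    records: Sequence[VariantRecord], pedigree: Pedigree
) -> dict[str, list[VariantRecord]]:
    """Split a family table into single-sample callsets, as a per-sample
    caller would produce them: each sample's file holds only the sites where
    that sample carries an alternate allele, with only its own call."""
    from dataclasses import replace

    out: dict[str, list[VariantRecord]] = {s: [] for s in pedigree.sample_ids}
    for record in records:
        for sample in pedigree.sample_ids:
            call = record.calls.get(sample)
            if call is not None and call.has_alt:
                out[sample].append(replace(record, calls={sample: call}))
    return out


def mendelian_violation_scan(
    records: Sequence[VariantRecord], pedigree: Pedigree
) -> int:
    """Count (record, child) pairs whose genotype is impossible given the
    parents: no assignment of one paternal and one maternal allele can
    produce the child's unordered pair. Missing genotypes are skipped."""
    father, mother = pedigree.parent_ids
    violations = 0
    for record in records:
        f_call = record.calls.get(father)
        m_call = record.calls.get(mother)
        if f_call is None or m_call is None or f_call.is_missing or m_call.is_missing:
            continue
        for child in pedigree.child_ids:
            c_call = record.calls.get(child)
            if c_call is None or c_call.is_missing:
                continue
            possible = {
                frozenset_pair(fa, ma)
                for fa in f_call.alleles
                for ma in m_call.alleles
            }
            if frozenset_pair(*c_call.alleles) not in possible:
                violations += 1
    return violations


def frozenset_pair(a: int, b: int) -> tuple[int, int]:
    """Order-free representation of an unordered diploid genotype."""
    return (a, b) if a <= b else (b, a)
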