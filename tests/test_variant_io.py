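import random
import subprocess

import pytest

from famtriage import (
    Category,
    Impact,
    Pedigree,
    VariantKey,
    merge_family,
    normalize_small_variants,
    quality_filter,
    read_vcf,
    simulate_family,
)
from famtriage.variant_io import _left_align_trim, load_annotation_sidecar
from conftest import make_record

from dataclasses import replace


# ---------------------------------------------------------------- quality


def test_quality_filter_boundaries(trio_pedigree):
    ped = trio_pedigree
    records = [
        make_record(ped, {"C": (0, 1)}, pos=100, qual=19.9),
        make_record(ped, {"C": (0, 1)}, pos=200, qual=20.0),
        make_record(ped, {"C": (0, 1)}, pos=300, qual=45.0,
                    filter_status="10X_PHASING_INCONSISTENT"),
        replace(make_record(ped, {"C": (0, 1)}, pos=400), qual=None),
    ]
    kept = quality_filter(records)
    assert [r.pos for r in kept] == [200]


def test_quality_filter_matches_independent_scan_and_is_idempotent(trio_pedigree):
    rng = random.Random(20210)
    records = []
    for i in range(50):
        records.append(
            make_record(
                trio_pedigree,
                {"C": (0, 1)},
                pos=1000 + i,
                qual=round(rng.uniform(0, 40), 1),
                filter_status=rng.choice(["PASS", "PASS", "LOWCOV"]),
            )
        )
    kept = quality_filter(records)
    expected = [r for r in records if r.qual >= 20 and r.filter_status == "PASS"]
    assert kept == expected
    assert quality_filter(kept) == kept


# ------------------------------------------------------------- normalize


def _edited_sequence(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def _brute_force_normalize(seq: str, pos: int, ref: str, alt: str):
    """Leftmost-parsimonious representation by exhaustive enumeration of all
    equivalent (pos', ref', alt') triples over the contig."""
    target = _edited_sequence(seq, pos, ref, alt)
    best = None
    for p in range(1, len(seq) + 1):
        for ref_len in range(1, 10):
            if p - 1 + ref_len > len(seq):
                break
            cand_ref = seq[p - 1 : p - 1 + ref_len]
            alt_end = len(target) - (len(seq) - (p - 1 + ref_len))
            if alt_end < p:  # alt would be empty or negative
                continue
            cand_alt = target[p - 1 : alt_end]
            if _edited_sequence(seq, p, cand_ref, cand_alt) != target:
                continue
            score = (len(cand_ref) + len(cand_alt), p)
            if best is None or score < best[0]:
                best = (score, (p, cand_ref, cand_alt))
    return best[1]


def test_left_alignment_matches_brute_force_enumeration():
    # a deletion placed ambiguously inside a short tandem repeat
    seq = "TTTTCAACAACATTTT"
    pos, ref = 5, "CAACA"
    assert seq[pos - 1 : pos + 4] == ref
    alt = "CA"
    got = _left_align_trim("chr1", pos, ref, alt, {"chr1": seq})
    assert got == _brute_force_normalize(seq, pos, ref, alt)


@pytest.mark.parametrize("seed", range(5))
def test_left_alignment_matches_brute_force_on_random_indels(seed):
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(40))
    # repeat-rich middle to make left-shifts likely
    seq = seq[:15] + rng.choice(["ACACACAC", "AAAAAAA", "TAGTAGTAG"]) + seq[23:]
    pos = rng.randrange(10, 28)
    ref_len = rng.randrange(1, 5)
    ref = seq[pos - 1 : pos - 1 + ref_len]
    alt = ref + seq[pos - 1 + ref_len : pos - 1 + ref_len + rng.randrange(0, 3)] or "A"
    if alt == ref:
        alt = ref + "G"
    got = _left_align_trim("c", pos, ref, alt, {"c": seq})
    assert got == _brute_force_normalize(seq, pos, ref, alt)


def test_normalize_is_idempotent_and_leaves_svs_untouched(trio_pedigree):
    ped = trio_pedigree
    seq = "TTTTCAACAACATTTT"
    snp = make_record(ped, {"C": (0, 1)}, pos=3, ref="T", alt="G")
    indel = make_record(ped, {"C": (0, 1)}, pos=5, ref="CAACA", alt="CA",
                        category=Category.INDEL)
    sv = make_record(ped, {"C": (0, 1)}, pos=7, ref="N", alt="<DEL>",
                     category=Category.SV, end=5007)
    out = normalize_small_variants([snp, indel, sv], reference={"chr1": seq})
    assert out[0] == snp  # already normalized
    assert out[2] == sv  # SV passthrough
    again = normalize_small_variants(out, reference={"chr1": seq})
    assert again == out


def test_normalize_reference_mismatch_raises(trio_pedigree):
    rec = make_record(trio_pedigree, {"C": (0, 1)}, pos=2, ref="CC", alt="C",
                      category=Category.INDEL)
    with pytest.raises(ValueError, match="reference mismatch"):
        normalize_small_variants([rec], reference={"chr1": "AAAAAA"})


def test_normalization_agrees_with_bcftools(tmp_path, trio_pedigree):
    """bcftools norm is the independent oracle on a tiny fixture."""
    seq = "GGGTACACACACACGTTTAAAGCGCGCGTTACGTACGT"
    ref_fa = tmp_path / "ref.fa"
    ref_fa.write_text(">chr1\n" + seq + "\n")
    subprocess.run(["samtools", "faidx", str(ref_fa)], check=True)
    variants = [  # (pos, ref, alt) unnormalized
        (8, "CACAC", "CAC"),  # deletion inside AC repeat
        (20, "AA", "AAA"),  # insertion inside A run
        (29, "TTA", "TTT"),  # block substitution with shared prefix
    ]
    vcf = tmp_path / "in.vcf"
    lines = ["##fileformat=VCFv4.2", f"##contig=<ID=chr1,length={len(seq)}>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS"]
    for pos, ref, alt in variants:
        assert seq[pos - 1 : pos - 1 + len(ref)] == ref
        lines.append(f"chr1\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT\t0/1")
    vcf.write_text("\n".join(lines) + "\n")
    out = subprocess.run(
        ["bcftools", "norm", "-f", str(ref_fa), str(vcf)],
        capture_output=True, text=True, check=True,
    )
    expected = []
    for line in out.stdout.splitlines():
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        expected.append((int(fields[1]), fields[3], fields[4]))
    for (pos, ref, alt), exp in zip(variants, expected):
        got = _left_align_trim("chr1", pos, ref, alt, {"chr1": seq})
        assert got == exp


# ----------------------------------------------------------------- merge


def test_merge_two_samples_sharing_one_key(quad_pedigree):
    ped = quad_pedigree
    a = make_record(ped, {"32": (0, 1)})
    a = replace(a, calls={"32": a.calls["32"]})
    b = make_record(ped, {"33": (0, 1)})
    b = replace(b, calls={"33": b.calls["33"]})
    # remaining samples only appear via other records in their own files
    background = [
        replace(make_record(ped, {s: (0, 1)}, pos=50 + i, gene=None),
                calls={s: make_record(ped, {s: (0, 1)}, pos=50 + i).calls[s]})
        for i, s in enumerate(["30", "31", "34", "35"])
    ]
    table = merge_family([[a], [b], background], ped)
    key = a.key
    row = table[key]
    assert len(row.calls) == len(ped)
    assert row.calls["32"].has_alt and row.calls["33"].has_alt
    # samples whose files lack the site are called homozygous reference
    assert row.calls["34"].alleles == (0, 0)
    assert row.calls["30"].alleles == (0, 0)


def test_merge_conflicting_ref_raises(trio_pedigree):
    ped = trio_pedigree
    a = make_record(ped, {"C": (0, 1)}, ref="A", alt="T")
    b = make_record(ped, {"C": (0, 1)}, ref="G", alt="T")
    with pytest.raises(ValueError, match="conflicting REF"):
        merge_family([[a], [b]], ped)


def test_merge_missing_pedigree_sample_raises(trio_pedigree):
    ped = trio_pedigree
    a = make_record(ped, {"C": (0, 1)})
    a = replace(a, calls={"C": a.calls["C"]})
    with pytest.raises(ValueError, match="absent from all provided VCFs"):
        merge_family([[a]], ped)


def test_merge_no_duplicate_keys_and_full_calls(quad_pedigree):
    """Merging per-sample exports recovers one row per distinct planted key."""
    from famtriage import per_sample_exports

    ped = quad_pedigree
    sim = simulate_family(ped, 60, [], seed=11)
    records = sim.records[Category.SNP]
    exports = per_sample_exports(records, ped)
    table = merge_family(list(exports.values()), ped)
    expected_keys = {r.key for r in records
                     if any(c.has_alt for c in r.calls.values())}
    assert set(table) == expected_keys
    assert all(len(row.calls) == len(ped) for row in table.values())


# --------------------------------------------------------------- read_vcf


def test_read_vcf_sixteen_sample_family(tmp_path):
    """A 16-sample synthetic VCF reads back one record per planted site,
    each carrying a call for every family member."""
    ped = Pedigree("big", "P1", "P2", tuple(f"k{i}" for i in range(14)))
    sim = simulate_family(ped, 100, [], seed=5, out_dir=tmp_path)
    records = read_vcf(sim.vcf_paths[Category.SNP], ped, Category.SNP)
    assert len(records) == 100
    assert all(len(r.calls) == 16 for r in records)
    # genotypes round-trip exactly against the generator's in-memory records
    by_key = {r.key: r for r in sim.records[Category.SNP]}
    for rec in records:
        src = by_key[rec.key]
        for sample, call in rec.calls.items():
            assert call.alleles == src.calls[sample].alleles
            assert call.phased == src.calls[sample].phased


def test_read_vcf_parses_ann_and_cadd(tmp_path, trio_pedigree):
    vcf = tmp_path / "ann.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        '##INFO=<ID=ANN,Number=.,Type=String,Description="snpEff">\n'
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tC\n"
        "chr1\t500\t.\tG\tT\t60\tPASS\t"
        "ANN=T|stop_gained|HIGH|BRCA2|ENSG1|transcript|tx1|Coding|1/10|c.1A>T;CADD=25.1"
        "\tGT\t0/0\t0/1\t0/1\n"
    )
    (rec,) = read_vcf(vcf, trio_pedigree, Category.SNP)
    assert rec.impact is Impact.HIGH
    assert rec.cadd_scaled == pytest.approx(25.1)
    assert rec.gene == "BRCA2"
    assert rec.exonic is True  # stop_gained is an exonic consequence


def test_read_vcf_multiallelic_split(tmp_path, trio_pedigree):
    vcf = tmp_path / "multi.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tC\n"
        "chr1\t700\t.\tG\tA,T\t60\tPASS\t.\tGT\t0/1\t0/2\t1/2\n"
    )
    records = read_vcf(vcf, trio_pedigree, Category.SNP)
    assert len(records) == 2
    assert {r.alt for r in records} == {"A", "T"}
    assert all(r.pos == 700 and r.ref == "G" for r in records)
    rec_a = next(r for r in records if r.alt == "A")
    assert rec_a.calls["F"].alleles == (0, 1)
    assert rec_a.calls["M"].alleles == (0, None)  # the other alternate: masked


def test_sidecar_overrides_info(tmp_path, trio_pedigree):
    vcf = tmp_path / "s.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000000>\n"
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tC\n"
        "chr1\t500\t.\tG\tT\t60\tPASS\tCADD=10\tGT\t0/0\t0/1\t0/1\n"
    )
    sidecar_file = tmp_path / "ann.tsv"
    sidecar_file.write_text(
        "chrom\tpos\tref\talt\tgene\timpact\texonic\tcadd_scaled\tgmaf\n"
        "chr1\t500\tG\tT\tMYGENE\tHIGH\ttrue\t31.5\t0.004\n"
    )
    sidecar = load_annotation_sidecar(sidecar_file)
    (rec,) = read_vcf(vcf, trio_pedigree, Category.SNP, sidecar=sidecar)
    assert rec.cadd_scaled == pytest.approx(31.5)  # sidecar wins over INFO
    assert rec.gene == "MYGENE" and rec.impact is Impact.HIGH
    assert rec.gmaf == pytest.approx(0.004)


def test_read_vcf_without_pedigree_samples_raises(tmp_path, trio_pedigree):
    vcf = tmp_path / "x.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tOTHER\n"
        "chr1\t1\t.\tA\tT\t60\tPASS\t.\tGT\t0/1\n"
    )
    with pytest.raises(ValueError, match="no pedigree sample"):
        read_vcf(vcf, trio_pedigree, Category.SNP)


def test_variant_key_identity():
    k1 = VariantKey("chr1", 100, "A", "T")
    assert k1 == VariantKey("chr1", 100, "A", "T")
    assert k1 != VariantKey("chr1", 100, "A", "G")
    sv1 = VariantKey("chr1", 100, "N", "<DEL>", end=5100, category=Category.SV)
    sv2 = VariantKey("chr1", 100, "N", "<DEL>", end=5200, category=Category.SV)
    assert sv1 != sv2  # SVs match on END too, zero tolerance
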