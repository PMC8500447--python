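# Methods

## Model and assumptions

The pipeline treats a nuclear family — two unaffected parents and N
children, exactly one of whom is assumed affected — as a closed genetic
system. Three assumptions drive the filters:

1. **Parental exclusion.** A variant configuration observed in a healthy
   parent is unlikely to be disease causing in a child. Hence
   homozygous-alternate calls shared with a hom-alt parent are dropped, a
   compound-het pair jointly carried in trans by a parent is dropped, and
   a pair member that is hom-alt in a parent disqualifies the pair.
   Simple heterozygotes have no parental exclusion: a causal dominant
   allele with incomplete penetrance could legitimately sit in a parent,
   and dropping all parent-shared hets would erase nearly every inherited
   candidate.
2. **Sibling exclusion.** A gene damaged in 3+ of the children is unlikely
   to explain a disease present in one. Genes carried by exactly two
   children are retained deliberately: the second carrier may be a
   not-yet-affected sibling, or an epistatic partner variant may be
   missing.
3. **Annotation-defined damage.** "Potentially damaging" is a conjunction
   of consumed annotations — scaled CADD > 20 (strict), gnomAD MAF < 0.01
   (strict), impact HIGH, exonic — not a computed property. Indels and SVs
   are exempted from the CADD/MAF terms because those annotations are
   routinely absent for them; requiring them would silently delete the
   categories. For a compound-het pair only one member must be rare: a
   rare allele in trans with a common one still yields a rare diplotype.

Phase is taken at face value from the input (the intended upstream is
linked-read phasing). Two child heterozygotes are called trans only when
both are phased within the same phase set and their alternate alleles sit
on opposite haplotypes; unresolvable pairs are excluded and logged. An
optional fallback (`infer_trans_from_parents`) accepts a pair when each
member can only have come from a different parent; it is off by default
because it silently converts a phasing question into a transmission
assumption. The exclusion default undercalls compound hets on sparsely
phased data; that is the conservative direction.

A de novo flag requires the child to carry the alternate and **both**
parents to be confidently non-carriers; a missing parental genotype blocks
the flag rather than permitting it.

## Scoring

Each candidate gene arrives with two non-negative scores: a literature
gene–disease connection score and a disease-likelihood score (consumed
from a VarElect-style export; the package never computes them). Each
column is competition-ranked descending — ties share the minimal rank and
the next rank is skipped (1,2,3,3,5) — the two ranks are averaged, and
the averages are competition-ranked ascending to give the final rank.
Competition ranking is forced by the points formula: with points
`6 − final_rank` over the top five, a 3rd-place tie must yield points
(3,3) followed by a 5th-place gene worth 1; dense ranking could never
produce that pattern. Averaging two independent rank lists, rather than
either raw score, keeps one noisy evidence type from dominating.

Points are divided evenly among a gene's carrier children, de-prioritizing
shared variants without discarding them. Totals are summed per child; the
argmax child is the prediction. A tied maximum sets a tie flag and emits
no prediction — inventing a tie-break would fabricate methodology. If the
top-five cutoff itself is tied, all genes sharing the 5th rank are
included at their common point value (logged prominently; the original
protocol never hit this case).

Candidate genes absent from the score table cannot be ranked; they are
excluded from scoring and listed in the run report.

Two ancillaries: `chance_probability` computes the probability of
predicting every family correctly by chance, multiplying the per-family
values **after** rounding to 3 decimals (sizes 5, 4, 7 →
0.20 × 0.25 × 0.143 = 0.00715; an unrounded mode gives 1/140 ≈ 0.00714) —
the rounded product is the convention matched by the published arithmetic.
`count_uniformity_test` is a chi-squared goodness-of-fit of per-child
damaging-variant counts against uniformity (scipy `chisquare`, k−1 df).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_cadd` | 20 | scaled-CADD lower bound, exclusive; ~top 1% deleteriousness |
| `max_maf` | 0.01 | gnomAD global AF upper bound, exclusive |
| `required_impact` | HIGH | snpEff-style severity class required |
| `require_exonic` | true | exonic classification required |
| `missing_maf_as_rare` | false | treat absent MAF as rare (sensitivity analyses) |
| `max_shared_children` | 2 | sibling-sharing cutoff per gene |
| `top_n` | 5 | genes earning points (`top_n + 1 − rank`) |

The MAF field is consumed verbatim as the annotated gnomAD global allele
frequency; whether a folded minor-allele frequency is wanted for AF > 0.5
sites is left to the annotation source, and the ambiguity is noted here
rather than resolved silently.

## Numerical and representational choices

- Coordinates are 1-based, fully closed, VCF convention.
- QUAL ≥ 20 is inclusive; a missing QUAL fails the quality filter.
- Small-variant normalization is the standard left-align/parsimony-trim
  recursion (right-trim shared terminal bases, left-extending from the
  reference when an allele would empty; then left-trim shared leading
  bases). Without reference context only context-free trimming is applied.
  Multi-allelic decomposition maps a genotype's other-alternate indices to
  missing rather than reference (conservative).
- On merge, a sample whose file lacks a site becomes homozygous reference.
  This is required for de novo logic to work over per-sample callsets, but
  absence can also mean no coverage; the run log records how many calls
  were filled this way. Symbolic SVs match on (chrom, pos, SVTYPE, END)
  with zero positional tolerance — exactness is testable, and the
  synthetic generator emits exact coordinates.
- A sidecar annotation table overrides INFO-derived annotations; every
  override is logged. Records without a gene symbol are kept for variant
  counts but cannot enter gene-level stages.
- In per-sharing-level summaries, a compound-het pair counts as one
  variant (call-level counting), matching how published family tables
  count "variants"; the pair's two keys are still tracked individually.

## Synthetic families

`simulate_family` emulates the study's data shape: per-category phased
VCF 4.2 files with QUAL/FILTER fields, INFO annotations (gene, impact,
exonic, CADD, gnomAD MAF), per-chromosome phase sets, and a truth
manifest. Background sites are Mendelian-consistent by construction (each
child allele drawn uniformly from the transmitting parent's pair) and
annotated to be un-damaging with certainty (MAF ∈ [0.02, 0.5], CADD < 19,
MODERATE/LOW impact), so planted signals fully determine the candidate
set and manifest assertions are exact, not statistical. Default QUAL/PASS
fractions (15% low-QUAL, 15% non-PASS, independent) leave ≈ 72% of
background records passing the quality filter, comparable to real
linked-read callsets. Planted classes cover simple het, hom alt, de novo,
trans compound het (rare member paired with a MAF 0.30 common member),
and a cis decoy that must *not* be called compound het.

What the generator does **not** emulate: realistic allele-frequency
spectra, LD and recombination, sequencing error, genotyping dropout,
fragmentary phasing (beyond an all-or-nothing `fragmented_phase` switch),
and multi-gene overlap of variants. Passing tests therefore demonstrate
the correctness of the classification/filtering/scoring logic under clean
conditions, not robustness to real-data noise.

Problem sizes used in the test suite — tens to hundreds of background
sites, families of 1–14 children, 20 simulation seeds — were chosen as the
smallest sizes at which every code path (all inheritance classes, all
categories, sharing levels beyond the cutoff) is exercised with exact
expectations.

## Known limitations

- One published child ranking is not reproduced by table arithmetic: from
  the first family's top-five table the third-ranked child by points is
  the one reported as ranked fourth of five. The published per-child
  ordering beyond the top-five genes is unspecified; the package
  reproduces the table arithmetic (totals 3 vs 2.5 vs 0.5) and makes no
  guess at extra inputs.
- Autosomal logic only: no X-linked, mitochondrial, imprinting, or
  mosaicism handling.
- The pipeline consumes annotations; disagreements between annotation
  sources (beyond the sidecar-overrides-INFO rule) are out of scope.
- Exactly-one-affected-child is an assumption of the scoring stage, not a
  checked property.
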