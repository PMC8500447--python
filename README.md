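# famtriage

Pedigree-aware variant triage for nuclear families: given phased,
annotated whole-genome variant calls for two parents and N children —
only one of whom has been diagnosed with a disease, and without being told
which — rank the children by how likely each is to be the affected one.

The package targets the study design where population-scale association is
powerless (a single family, private and rare variants, small N) but the
unaffected siblings carry real information: a variant shared by many
healthy siblings is unlikely to explain a disease present in only one
child. It was built around pediatric-cancer case families, but nothing in
the machinery is cancer-specific.

## What it computes

Starting from per-category multi-sample VCFs (SNPs, mid-scale indels,
large structural variants, each phased; processed separately throughout):

1. **Quality filter** — keep records with QUAL ≥ 20 and `FILTER == PASS`.
2. **Normalization** — decompose multi-allelic sites, left-align and
   parsimony-trim small variants (SVs pass through).
3. **Family merge** — one row per variant key across all samples; a sample
   whose single-sample callset lacks a site is treated as homozygous
   reference.
4. **Inheritance classification**, per child:
   *simple heterozygous* (one alt allele); *homozygous alternate*
   (excluded if either parent is also hom-alt); *compound heterozygous*
   (two hets in one gene on opposite haplotypes within a phase set,
   excluded if a parent carries the same trans pair or is hom-alt for a
   member); and a *de novo* flag (neither parent carries the alt).
5. **Damaging filter** — SNPs need scaled CADD > 20, gnomAD MAF < 0.01,
   impact HIGH, exonic; indels/SVs need only HIGH + exonic; a
   compound-het pair needs only one rare member.
6. **Sibling-sharing filter** — keep genes with damaging calls in at most
   two children.
7. **Scoring** — competition-rank the surviving genes twice (gene–disease
   connection score, disease-likelihood score), average the two ranks,
   re-rank the averages; gene *g* with final rank *r* ≤ 5 is worth
   `6 − r` points, split evenly among its carrier children; the child with
   the highest point total is the predicted proband.

A synthetic-family generator (`famtriage.synthetic_family`) emits
Mendelian-consistent phased VCFs with planted inheritance classes and a
truth manifest, so the whole pipeline is testable end to end with no data
download.

## Worked example

Score a published-style candidate table directly (no VCFs needed). With
`scores.tsv`:

```text
gene	connection_score	likelihood_score
TNNT3	100	100
SIRPB1	90	90
TRMT1	80	80
ITGB4	70	70
DCHS1	60	60
```

and `carriers.tsv`:

```text
gene	child_id
TNNT3	43
SIRPB1	41
TRMT1	44
ITGB4	43
DCHS1	42
```

```bash
famtriage replay --scores scores.tsv --carriers carriers.tsv \
    --children 38,39,40,41,42,43,44
```

prints

```text
TNNT3	rank 1	points 5
SIRPB1	rank 2	points 4
TRMT1	rank 3	points 3
ITGB4	rank 4	points 2
DCHS1	rank 5	points 1
43	7
41	4
44	3
42	1
38	0
39	0
40	0
predicted child: 43
```

Child 43 carries sole variants in the rank-1 (5 points) and rank-4
(2 points) genes, totalling 7 — the highest aggregate, so 43 is predicted
to be the affected child; child 41 (4 points from the rank-2 gene) is
ranked second.

The full VCF path is driven by a YAML config:

```bash
famtriage simulate --seed 7 --children a,b,c,d --out-dir sim/
famtriage run --config run.yaml     # pedigree, vcfs, gene_scores, out_dir
```

`run` writes a sharing summary, the candidate set, ranked genes, and a
`prediction.json` with per-child totals and the predicted child.

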