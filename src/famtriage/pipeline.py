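"""End-to-end orchestration: VCFs in, prediction out.

Stages run in a fixed order — read, quality-filter, normalize (small
variants), merge per category, classify inheritance, apply the damaging
filter, apply the sibling-sharing gene filter, then rank/score/predict —
with per-stage record counts collected into a run log. The analysis path
contains no randomness; repeated runs on the same inputs are identical.

A "replay" entry point starts from a candidate-gene/carrier table plus the
gene score table, skipping all variant processing; printed result tables
from a study can thereby serve as fixtures without any sequence data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .cohort_filter import (
    CandidateSet,
    apply_sharing_filter,
    sharing_summary,
    sharing_table,
)
from .damage_filter import DamageThresholds, damaging_calls
from .family_model import Pedigree, load_pedigree
from .gene_scoring import (
    ChildScoreTable,
    GeneScoreRecord,
    load_gene_scores,
    score_candidates,
    unranked_genes,
)
from .inheritance import InheritanceCall, InheritanceClass, classify_family
from .variant_io import (
    Category,
    FamilyTable,
    VariantKey,
    load_annotation_sidecar,
    merge_family,
    normalize_small_variants,
    quality_filter,
    read_vcf,
)

log = logging.getLogger("famtriage")

STATUS_PREDICTED = "prediction made"
STATUS_TIE = "tie"
STATUS_NO_CANDIDATES = "no candidates"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    pedigree: Path
    vcfs: dict[Category, list[Path]] = field(default_factory=dict)
    annotations: Optional[Path] = None  # sidecar TSV, overrides INFO
    gene_scores: Optional[Path] = None
    thresholds: DamageThresholds = field(default_factory=DamageThresholds)
    max_shared_children: int = 2
    top_n: int = 5
    out_dir: Optional[Path] = None
    infer_trans_from_parents: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        vcfs = {
            Category(cat.upper()): [Path(p) for p in paths]
            for cat, paths in raw.get("vcfs", {}).items()
        }
        thr = raw.get("thresholds", {})
        return cls(
            pedigree=Path(raw["pedigree"]),
            vcfs=vcfs,
            annotations=Path(raw["annotations"]) if raw.get("annotations") else None,
            gene_scores=Path(raw["gene_scores"]) if raw.get("gene_scores") else None,
            thresholds=DamageThresholds(**thr) if thr else DamageThresholds(),
            max_shared_children=int(raw.get("max_shared_children", 2)),
            top_n=int(raw.get("top_n", 5)),
            out_dir=Path(raw["out_dir"]) if raw.get("out_dir") else None,
            infer_trans_from_parents=bool(raw.get("infer_trans_from_parents", False)),
        )

    def validate(self) -> None:
        paths = [self.pedigree, self.annotations, self.gene_scores]
        paths += [p for ps in self.vcfs.values() for p in ps]
        missing = [str(p) for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class RunResult:
    pedigree: Pedigree
    stage_counts: dict[str, int]
    sharing: pd.DataFrame
    candidates: CandidateSet
    ranked: list[GeneScoreRecord]
    scores: Optional[ChildScoreTable]
    unranked: list[str]
    status: str


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages; fail fast on missing inputs.

    Raises on configuration errors before any variant processing begins.
    """
    config.validate()
    pedigree = load_pedigree(config.pedigree)
    sidecar = (
        load_annotation_sidecar(config.annotations) if config.annotations else None
    )

    counts: dict[str, int] = {}
    merged: dict[Category, FamilyTable] = {}
    for category, paths in config.vcfs.items():
        sources = []
        n_read = n_pass = 0
        for path in paths:
            records = read_vcf(path, pedigree, category, sidecar=sidecar)
            n_read += len(records)
            passing = quality_filter(records)
            n_pass += len(passing)
            if category is not Category.SV:
                passing = normalize_small_variants(passing)
            sources.append(passing)
        merged[category] = merge_family(sources, pedigree)
        counts[f"{category.value}.read"] = n_read
        counts[f"{category.value}.pass_quality"] = n_pass
        counts[f"{category.value}.merged_sites"] = len(merged[category])

    all_records: dict[VariantKey, object] = {}
    calls: list[InheritanceCall] = []
    for category, table in merged.items():
        all_records.update(table)
        cat_calls = classify_family(
            table, pedigree, infer_trans_from_parents=config.infer_trans_from_parents
        )
        counts[f"{category.value}.inheritance_calls"] = len(cat_calls)
        calls.extend(cat_calls)
    counts["inheritance_calls"] = len(calls)

    damaging = damaging_calls(calls, all_records, config.thresholds)
    counts["damaging_calls"] = len(damaging)

    sharing = sharing_table(damaging, pedigree)
    candidates = apply_sharing_filter(
        sharing, damaging, family_id=pedigree.family_id,
        max_children=config.max_shared_children,
    )
    counts["candidate_calls"] = len(candidates.calls)
    counts["candidate_genes"] = len(candidates.genes)
    summary = sharing_summary(sharing, max_level=len(pedigree.child_ids))

    ranked: list[GeneScoreRecord] = []
    scores: Optional[ChildScoreTable] = None
    missing_rank: list[str] = []
    if not candidates.calls:
        status = STATUS_NO_CANDIDATES
    elif config.gene_scores is None:
        status = STATUS_NO_CANDIDATES if not candidates.calls else "candidates only"
    else:
        score_rows = load_gene_scores(config.gene_scores)
        ranked, scores = score_candidates(
            score_rows, candidates, pedigree, top_n=config.top_n
        )
        missing_rank = unranked_genes(candidates, ranked)
        if scores.tie_flag:
            status = STATUS_TIE
        elif scores.has_prediction:
            status = STATUS_PREDICTED
        else:
            status = STATUS_NO_CANDIDATES

    result = RunResult(
        pedigree=pedigree,
        stage_counts=counts,
        sharing=summary,
        candidates=candidates,
        ranked=ranked,
        scores=scores,
        unranked=missing_rank,
        status=status,
    )
    if config.out_dir is not None:
        _write_artifacts(result, Path(config.out_dir))
    return result


def replay_tables(
    gene_scores: Sequence[tuple[str, float, float]],
    carriers: Sequence[tuple[str, str]],
    pedigree: Pedigree,
    top_n: int = 5,
) -> tuple[list[GeneScoreRecord], ChildScoreTable]:
    """Score from a (gene, carrier-child) table directly — no variant data.

    Each carrier row becomes a placeholder simple-het call, so a published
    candidate/carrier table can be pushed through the exact ranking,
    even-split allocation, and aggregation arithmetic.
    """
    calls = []
    for i, (gene, child) in enumerate(carriers):
        key = VariantKey(chrom="replay", pos=i + 1, ref="N", alt="A")
        calls.append(
            InheritanceCall(
                child_id=child,
                variants=(key,),
                klass=InheritanceClass.SIMPLE_HET,
                de_novo=False,
                gene=gene,
            )
        )
    candidates = CandidateSet(family_id=pedigree.family_id, calls=calls)
    return score_candidates(gene_scores, candidates, pedigree, top_n=top_n)


def load_carrier_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a carriers TSV with columns gene, child_id (one row per carrier)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "child_id"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns gene, child_id")
    return [(str(r.gene), str(r.child_id)) for r in df.itertuples()]


def _write_artifacts(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.sharing.to_csv(out_dir / "sharing_summary.tsv", sep="\t", index=False)
    result.candidates.to_frame().to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    if result.ranked:
        pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "connection_rank": r.connection_rank,
                    "likelihood_rank": r.likelihood_rank,
                    "avg_rank": r.avg_rank,
                    "final_rank": r.final_rank,
                    "points": r.points,
                }
                for r in result.ranked
            ]
        ).to_csv(out_dir / "ranked_genes.tsv", sep="\t", index=False)
    payload = {
        "family_id": result.pedigree.family_id,
        "status": result.status,
        "stage_counts": result.stage_counts,
        "unranked_genes": result.unranked,
    }
    if result.scores is not None:
        payload.update(
            {
                "predicted_child": result.scores.predicted_child,
                "tie_flag": result.scores.tie_flag,
                "totals": result.scores.totals,
                "ordering": result.scores.ordering,
                "awarded": {
                    f"{child}:{gene}": pts
                    for (child, gene), pts in sorted(result.scores.awarded.items())
                },
            }
        )
    (out_dir / "prediction.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    log.info("wrote artifacts to %s", out_dir)
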