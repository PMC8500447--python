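"""Rank candidate genes and score children to predict the proband.

Gene-phenotype evidence arrives as a two-column score table per gene
(VarElect-export style): a gene-disease *connection* score and a *disease
likelihood* score. Each column is ranked independently, descending, with
competition ranking (ties share the minimal rank; the next rank is skipped,
e.g. 1,2,3,3,5). The two ranks are averaged per gene and the average is
itself competition-ranked ascending to give the final rank. Averaging the
two ranks balances the two complementary evidence types so neither
dominates.

Points follow 6 - final_rank over the top five genes (5,4,3,2,1; a rank-3
tie yields 3,3 then 1 for 5th). Each top gene's points are divided evenly
among the children carrying a qualifying variant in it — sharing among
siblings lowers priority — and per-child sums are aggregated. The child
with the highest aggregate is predicted to be the one diagnosed with a
pediatric tumor; a tied maximum yields no prediction (the protocol produced
a single child per family, and inventing a tie-break would fabricate
methodology).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .cohort_filter import CandidateSet
from .family_model import Pedigree


@dataclass(frozen=True)
class GeneScoreRecord:
    """One gene's scores, ranks, and allocated points."""

    gene: str
    connection_score: float
    likelihood_score: float
    connection_rank: int
    likelihood_rank: int
    avg_rank: float
    final_rank: int
    points: float

    def __post_init__(self) -> None:
        if self.connection_rank < 1 or self.likelihood_rank < 1 or self.final_rank < 1:
            raise ValueError("ranks must be >= 1")


@dataclass
class ChildScoreTable:
    """Per-child aggregate scores and the resulting prediction."""

    family_id: str
    totals: dict[str, float]
    awarded: dict[tuple[str, str], float]  # (child, gene) -> points
    predicted_child: Optional[str]
    tie_flag: bool
    ordering: list[str] = field(default_factory=list)  # children, descending score

    @property
    def has_prediction(self) -> bool:
        return self.predicted_child is not None


def _competition_rank(values: Sequence[float], descending: bool) -> list[int]:
    """Competition ("1,2,3,3,5") rank of each value."""
    ranks = []
    for v in values:
        if descending:
            better = sum(1 for other in values if other > v)
        else:
            better = sum(1 for other in values if other < v)
        ranks.append(1 + better)
    return ranks


def rank_genes(
    scores: Iterable[tuple[str, float, float]], top_n: int = 5
) -> list[GeneScoreRecord]:
    """Rank (gene, connection_score, likelihood_score) rows.

    Both score columns are competition-ranked descending (highest score =
    rank 1); the final rank is the competition rank of the ascending rank
    average. Points are ``top_n + 1 - final_rank``, floored at zero, so the
    default top five earn 5,4,3,2,1 before ties. Output is sorted by final
    rank (ties by gene symbol for stability).

    Raises
    ------
    ValueError
        On an empty table or a non-numeric score (naming the gene).
    """
    rows = list(scores)
    if not rows:
        raise ValueError("gene score table is empty")
    genes, conns, likes = [], [], []
    for gene, conn, like in rows:
        try:
            conns.append(float(conn))
            likes.append(float(like))
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric score for gene {gene!r}") from None
        genes.append(str(gene))
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene(s) in score table: {dupes}")
    conn_ranks = _competition_rank(conns, descending=True)
    like_ranks = _competition_rank(likes, descending=True)
    avg_ranks = [(c + l) / 2 for c, l in zip(conn_ranks, like_ranks)]
    final_ranks = _competition_rank(avg_ranks, descending=False)
    records = [
        GeneScoreRecord(
            gene=g,
            connection_score=c,
            likelihood_score=l,
            connection_rank=cr,
            likelihood_rank=lr,
            avg_rank=ar,
            final_rank=fr,
            points=float(max(0, top_n + 1 - fr)),
        )
        for g, c, l, cr, lr, ar, fr in zip(
            genes, conns, likes, conn_ranks, like_ranks, avg_ranks, final_ranks
        )
    ]
    records.sort(key=lambda r: (r.final_rank, r.gene))
    return records


def load_gene_scores(path: str | Path) -> list[tuple[str, float, float]]:
    """Read a gene score TSV with columns gene, connection_score, likelihood_score."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "connection_score", "likelihood_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        (str(r.gene), float(r.connection_score), float(r.likelihood_score))
        for r in df.itertuples()
    ]


def unranked_genes(candidates: CandidateSet, ranked: Iterable[GeneScoreRecord]) -> list[str]:
    """Candidate genes absent from the score table (cannot be ranked)."""
    scored = {r.gene for r in ranked}
    return sorted(candidates.genes - scored)


def allocate_points(
    ranked: Iterable[GeneScoreRecord],
    candidates: CandidateSet,
    top_n: int = 5,
) -> dict[tuple[str, str], float]:
    """Split each top-ranked gene's points evenly among its carrier children.

    Considers genes with ``final_rank <= top_n`` (competition ranking can
    admit more than *top_n* genes when the cutoff rank is tied; all tied
    genes are included with their shared points). Every such gene must have
    at least one carrier in the candidate set — candidate genes all do, by
    construction.
    """
    carrier_map = candidates.carrier_map()
    awarded: dict[tuple[str, str], float] = {}
    top = [r for r in ranked if r.final_rank <= top_n]
    if len(top) > top_n:
        import logging

        logging.getLogger("famtriage").warning(
            "top-%d cutoff tied: %d genes share the selection", top_n, len(top)
        )
    for record in top:
        carriers = carrier_map.get(record.gene, set())
        if not carriers:
            raise AssertionError(
                f"top-ranked gene {record.gene!r} has no carriers in the candidate set"
            )
        share = record.points / len(carriers)
        for child in sorted(carriers):
            awarded[(child, record.gene)] = share
    return awarded


def aggregate_and_predict(
    awarded: dict[tuple[str, str], float],
    pedigree: Pedigree,
    family_id: Optional[str] = None,
) -> ChildScoreTable:
    """Sum awarded points per child and predict the affected child.

    Every pedigree child appears in the totals (zero if unrewarded). The
    prediction is the argmax child; a shared maximum sets ``tie_flag`` and
    emits no prediction. ``ordering`` lists children by descending total
    (ties in pedigree order). An empty award set yields no prediction.
    """
    totals = {child: 0.0 for child in pedigree.child_ids}
    for (child, _gene), points in awarded.items():
        if child not in totals:
            raise ValueError(f"awarded child {child!r} not in pedigree")
        totals[child] += points
    ordering = sorted(pedigree.child_ids, key=lambda c: -totals[c])
    if not awarded:
        return ChildScoreTable(
            family_id=family_id or pedigree.family_id,
            totals=totals,
            awarded={},
            predicted_child=None,
            tie_flag=False,
            ordering=ordering,
        )
    best = max(totals.values())
    winners = [c for c in pedigree.child_ids if totals[c] == best]
    tie = len(winners) > 1
    return ChildScoreTable(
        family_id=family_id or pedigree.family_id,
        totals=totals,
        awarded=dict(awarded),
        predicted_child=None if tie else winners[0],
        tie_flag=tie,
        ordering=ordering,
    )


def score_candidates(
    scores: Iterable[tuple[str, float, float]],
    candidates: CandidateSet,
    pedigree: Pedigree,
    top_n: int = 5,
) -> tuple[list[GeneScoreRecord], ChildScoreTable]:
    """Convenience wrapper: rank, restrict to candidate genes, allocate, predict.

    Score-table genes outside the candidate set are ignored; candidate genes
    missing from the score table are excluded from ranking (reported via
    :func:`unranked_genes`).
    """
    candidate_genes = candidates.genes
    usable = [(g, c, l) for g, c, l in scores if g in candidate_genes]
    if not usable:
        return [], aggregate_and_predict({}, pedigree)
    ranked = rank_genes(usable, top_n=top_n)
    awarded = allocate_points(ranked, candidates, top_n=top_n)
    return ranked, aggregate_and_predict(awarded, pedigree)


def chance_probability(
    children_per_family: Sequence[int],
    rounding: int = 3,
    use_rounded: bool = True,
) -> tuple[list[float], float]:
    """Probability of guessing every family's affected child by chance.

    Per-family probability is 1/size rounded to *rounding* decimals; the
    joint probability is, by default, the product of the ROUNDED values
    (e.g. sizes 5, 4, 7 give 0.20 x 0.25 x 0.143 = 0.00715). With
    ``use_rounded=False`` the exact product of 1/size is returned instead.
    """
    if any(n < 1 for n in children_per_family):
        raise ValueError("family sizes must be >= 1")
    if not children_per_family:
        raise ValueError("at least one family required")
    per_family = [round(1.0 / n, rounding) for n in children_per_family]
    joint = 1.0
    if use_rounded:
        for p in per_family:
            joint *= p
    else:
        for n in children_per_family:
            joint *= 1.0 / n
    return per_family, joint


def count_uniformity_test(counts: Sequence[float]) -> tuple[float, float]:
    """Chi-squared goodness of fit of per-child damaging-variant counts
    against a uniform expectation (total/k per child), k-1 df.

    Raises
    ------
    ValueError
        With fewer than two children, or all-zero counts (the expectation
        is undefined).
    """
    if len(counts) < 2:
        raise ValueError("need counts for at least two children")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all counts are zero; uniformity test undefined")
    statistic, p_value = stats.chisquare(counts)
    return float(statistic), float(p_value)
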