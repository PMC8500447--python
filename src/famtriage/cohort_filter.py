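"""Sibling-sharing summary and the at-most-two-children gene filter.

If several children of one family carry a potentially damaging variant in
the same gene, that gene is unlikely to explain a disease present in only
one child; but a variant shared between the affected child and a single
unaffected sibling is tolerated (the sibling may simply not have developed
disease yet, or an epistatic partner may be missing). Hence genes are kept
when 1 or 2 children carry damaging calls in them and discarded at 3+.

Counting unit: a compound-heterozygous pair counts as ONE variant (and the
same variant key carried by two children counts once), matching how the
per-sharing-level summary tabulates "variants" and "genes".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .family_model import Pedigree
from .inheritance import InheritanceCall, InheritanceClass


def _variant_unit(call: InheritanceCall) -> frozenset:
    """Distinctness unit for counting: a key, or the pair for comp hets."""
    return frozenset(call.variants)


@dataclass(frozen=True)
class GeneSharing:
    """Per-gene carrier summary over one family's damaging calls."""

    gene: str
    carrier_children: frozenset[str]
    n_variants: int  # distinct variant units (comp-het pair = 1)

    def __post_init__(self) -> None:
        if not self.carrier_children:
            raise ValueError("carrier_children must be non-empty")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass
class CandidateSet:
    """Damaging calls surviving the sharing filter, grouped by gene."""

    family_id: str
    calls: list[InheritanceCall] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {c.gene for c in self.calls if c.gene is not None}

    def carriers(self, gene: str) -> set[str]:
        return {c.child_id for c in self.calls if c.gene == gene}

    def carrier_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for call in self.calls:
            if call.gene is not None:
                out.setdefault(call.gene, set()).add(call.child_id)
        return out

    @property
    def n_variants(self) -> int:
        """Distinct variant units across all retained calls."""
        return len({(_variant_unit(c)) for c in self.calls})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": c.gene,
                "child_id": c.child_id,
                "klass": c.klass.value,
                "de_novo": c.de_novo,
                "variants": ";".join(str(k) for k in c.variants),
            }
            for c in self.calls
        ]
        return pd.DataFrame(rows, columns=["gene", "child_id", "klass", "de_novo", "variants"])


def sharing_table(
    calls: Iterable[InheritanceCall], pedigree: Optional[Pedigree] = None
) -> list[GeneSharing]:
    """One row per gene with at least one damaging call in at least one child.

    Calls without a gene symbol are skipped (they cannot participate in
    gene-level stages). *pedigree* is accepted for interface symmetry and
    sanity-checks call children against it when given.
    """
    carriers: dict[str, set[str]] = {}
    units: dict[str, set[frozenset]] = {}
    for call in calls:
        if call.gene is None:
            continue
        if pedigree is not None and call.child_id not in pedigree.child_ids:
            raise ValueError(f"call child {call.child_id!r} not in pedigree")
        carriers.setdefault(call.gene, set()).add(call.child_id)
        units.setdefault(call.gene, set()).add(_variant_unit(call))
    return [
        GeneSharing(gene, frozenset(carriers[gene]), len(units[gene]))
        for gene in sorted(carriers)
    ]


def sharing_summary(
    sharing: Iterable[GeneSharing], max_level: Optional[int] = None
) -> pd.DataFrame:
    """Per-sharing-level summary: how many variants/genes are carried by
    exactly k children, for k = 1..max_level (default: max observed)."""
    sharing = list(sharing)
    levels = [len(s.carrier_children) for s in sharing]
    top = max_level or (max(levels) if levels else 0)
    rows = []
    for k in range(1, top + 1):
        at_level = [s for s in sharing if len(s.carrier_children) == k]
        rows.append(
            {
                "n_children": k,
                "n_variants": sum(s.n_variants for s in at_level),
                "n_genes": len(at_level),
            }
        )
    return pd.DataFrame(rows, columns=["n_children", "n_variants", "n_genes"])


def apply_sharing_filter(
    sharing: Iterable[GeneSharing],
    calls: Iterable[InheritanceCall],
    family_id: str = "",
    max_children: int = 2,
) -> CandidateSet:
    """Retain genes carried by at least one and at most *max_children* children.

    All damaging calls in retained genes pass through unchanged.
    """
    kept_genes = {
        s.gene for s in sharing if 1 <= len(s.carrier_children) <= max_children
    }
    kept = [c for c in calls if c.gene in kept_genes]
    return CandidateSet(family_id=family_id, calls=kept)
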