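"""Nuclear-family pedigree model.

A pedigree here is deliberately minimal: two parents and an ordered list of
children. Affected status is *not* part of the pedigree — the triage pipeline
is blind to phenotype, and truth labels belong only to evaluation inputs.

The on-disk format is a PED-like whitespace-delimited text file with one row
per sample::

    <family_id> <sample_id> <father_id|0> <mother_id|0> <role>

where ``role`` is one of ``father``, ``mother``, ``child``. Lines starting
with ``#`` are comments. Exactly one family per file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


@dataclass(frozen=True)
class Pedigree:
    """Two parents and an ordered, non-empty list of children.

    All sample identifiers must be distinct; parents are never listed among
    the children. Child order is preserved as given (it carries no meaning
    beyond stable reporting order).
    """

    family_id: str
    father_id: str
    mother_id: str
    child_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.child_ids:
            raise PedigreeError("pedigree must contain at least one child")
        members = [self.father_id, self.mother_id, *self.child_ids]
        if len(set(members)) != len(members):
            dupes = sorted({m for m in members if members.count(m) > 1})
            raise PedigreeError(f"duplicate sample identifier(s): {dupes}")

    @property
    def parent_ids(self) -> tuple[str, str]:
        return (self.father_id, self.mother_id)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        """All members: father, mother, then children in given order."""
        return (self.father_id, self.mother_id, *self.child_ids)

    def __len__(self) -> int:
        return 2 + len(self.child_ids)

    def __contains__(self, sample_id: object) -> bool:
        return sample_id in self.sample_ids


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-like file and return a validated :class:`Pedigree`.

    Raises
    ------
    PedigreeError
        On duplicate identifiers, zero children, a sample claiming more
        than one role, or anything other than exactly two parents.
    FileNotFoundError
        If *path* does not exist.
    """
    path = Path(path)
    family_ids: list[str] = []
    fathers: list[str] = []
    mothers: list[str] = []
    children: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise PedigreeError(
                f"{path}:{lineno}: expected 5 whitespace-delimited fields, got {len(parts)}"
            )
        fam, sample, _father, _mother, role = parts
        family_ids.append(fam)
        role = role.lower()
        if role == "father":
            fathers.append(sample)
        elif role == "mother":
            mothers.append(sample)
        elif role == "child":
            children.append(sample)
        else:
            raise PedigreeError(f"{path}:{lineno}: unknown role {role!r}")
    if not family_ids:
        raise PedigreeError(f"{path}: no samples found")
    if len(set(family_ids)) != 1:
        raise PedigreeError(f"{path}: more than one family in file: {sorted(set(family_ids))}")
    if len(fathers) != 1 or len(mothers) != 1:
        raise PedigreeError(
            f"{path}: exactly one father and one mother required "
            f"(got {len(fathers)} father(s), {len(mothers)} mother(s))"
        )
    return Pedigree(
        family_id=family_ids[0],
        father_id=fathers[0],
        mother_id=mothers[0],
        child_ids=tuple(children),
    )


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """Write *pedigree* in the PED-like format accepted by :func:`load_pedigree`."""
    path = Path(path)
    lines = [
        f"{pedigree.family_id}\t{pedigree.father_id}\t0\t0\tfather",
        f"{pedigree.family_id}\t{pedigree.mother_id}\t0\t0\tmother",
    ]
    for child in pedigree.child_ids:
        lines.append(
            f"{pedigree.family_id}\t{child}\t{pedigree.father_id}\t{pedigree.mother_id}\tchild"
        )
    path.write_text("\n".join(lines) + "\n")
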