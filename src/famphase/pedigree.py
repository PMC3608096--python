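"""Pedigree data model and PED-format input/output.

A pedigree is an ordered collection of individuals with parent links, sex,
affection status and a flag marking which members were sequenced.  The PED
dialect is the common 6-column whitespace-delimited one::

    family  id  father  mother  sex  phenotype

with ``0`` meaning missing parent/sex/phenotype, sex coded 1=male / 2=female,
and phenotype coded 1=unaffected / 2=affected / 0=unknown.  Extra columns are
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "write_pedigree",
]

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
AFF_CODES = {"1": "unaffected", "2": "affected", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFF_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (dangling parent, duplicate id, cycle)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Founders have both parent ids ``None``; non-founders must have both
    parents present in the same pedigree.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    sequenced: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r}")
        if self.affection not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"bad affection {self.affection!r}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"{self.id}: individuals must have either both or neither parent"
            )


@dataclass
class Pedigree:
    """Validated, ordered collection of :class:`Individual`.

    Validation enforces unique ids, resolvable parent links, consistent
    parent sexes and acyclic ancestry.
    """

    individuals: list[Individual]
    name: str = "FAM1"
    _index: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for ind in self.individuals:
            if ind.id in self._index:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._index[ind.id] = ind
        for ind in self.individuals:
            for which, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                parent = self._index.get(pid)
                if parent is None:
                    raise PedigreeError(f"{ind.id}: {which} {pid!r} not in pedigree")
                want = "male" if which == "father" else "female"
                if parent.sex not in (want, "unknown"):
                    raise PedigreeError(
                        f"{ind.id}: {which} {pid!r} has sex {parent.sex!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"cyclic ancestry involving {iid!r}")
            state[iid] = 0
            ind = self._index[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id, [])

    # -- lookups ---------------------------------------------------------
    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        return self._index[iid]

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [i for i in self.individuals if not i.is_founder]

    def members(self, *, affection: str | None = None, sequenced: bool | None = None) -> list[Individual]:
        out = self.individuals
        if affection is not None:
            out = [i for i in out if i.affection == affection]
        if sequenced is not None:
            out = [i for i in out if i.sequenced == sequenced]
        return list(out)

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self.individuals if iid in (i.father_id, i.mother_id)]

    def with_sequenced(self, ids: Iterable[str]) -> "Pedigree":
        """Return a copy with ``sequenced`` set exactly for ``ids``."""
        ids = set(ids)
        unknown = ids - set(self._index)
        if unknown:
            raise PedigreeError(f"sequenced ids not in pedigree: {sorted(unknown)}")
        return Pedigree(
            [replace(i, sequenced=i.id in ids) for i in self.individuals], name=self.name
        )

    def subset(self, ids: Iterable[str]) -> "Pedigree":
        """Restrict to ``ids``, cutting parent links that leave the subset.

        An individual with only one retained parent becomes a founder (both
        links cut), keeping the both-or-neither invariant.
        """
        keep = set(ids)
        out = []
        for ind in self.individuals:
            if ind.id not in keep:
                continue
            fa = ind.father_id if ind.father_id in keep else None
            mo = ind.mother_id if ind.mother_id in keep else None
            if fa is None or mo is None:
                fa = mo = None
            out.append(replace(ind, father_id=fa, mother_id=mo))
        return Pedigree(out, name=self.name)


def parse_pedigree(text: str, *, sequenced_ids: Iterable[str] | None = None) -> Pedigree:
    """Parse 6-column PED text into a validated :class:`Pedigree`.

    ``sequenced_ids`` optionally marks the sequenced subset (PED itself does
    not carry that information).
    """
    individuals = []
    name = "FAM1"
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"line {lineno}: expected ≥6 PED columns, got {len(fields)}")
        fam, iid, fa, mo, sex, pheno = fields[:6]
        name = fam
        individuals.append(
            Individual(
                id=iid,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=SEX_CODES.get(sex, "unknown"),
                affection=AFF_CODES.get(pheno, "unknown"),
            )
        )
    ped = Pedigree(individuals, name=name)
    if sequenced_ids is not None:
        ped = ped.with_sequenced(sequenced_ids)
    return ped


def write_pedigree(ped: Pedigree) -> str:
    """Serialize a pedigree back to 6-column PED text."""
    lines = []
    for ind in ped:
        lines.append(
            "\t".join(
                [
                    ped.name,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_OUT[ind.sex],
                    _AFF_OUT[ind.affection],
                ]
            )
        )
    return "\n".join(lines) + "\n"
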