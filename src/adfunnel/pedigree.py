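"""Pedigree model and 6-column PED parsing.

PED lines are whitespace-delimited: family, individual, father, mother,
sex (1=male, 2=female, 0=unknown) and phenotype (2=affected, 1=unaffected,
0=unknown). A "0" parent marks a founder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Union

__all__ = ["Individual", "Pedigree", "PedigreeError", "read_pedigree"]


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigrees."""


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affected: Optional[bool]  # None = unknown phenotype

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


_SEX = {"1": "male", "2": "female", "0": "unknown"}
_PHENO = {"2": True, "1": False, "0": None}


@dataclass
class Pedigree:
    """An ordered collection of individuals with resolved parentage."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        seen = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = self.by_id
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"individual {iid!r} is its own ancestor")
            state[iid] = 0
            ind = by_id[iid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id, [])

    @property
    def by_id(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.individuals}

    @property
    def sample_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def affected_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.affected is True]

    @property
    def unaffected_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.affected is False]

    @property
    def founder_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.is_founder]


def read_pedigree(source: Union[str, Path, IO[str], Iterable[str]]) -> Pedigree:
    """Parse a 6-column PED file into a :class:`Pedigree`.

    Accepts a path, an open text stream, or an iterable of lines. Blank
    lines and ``#`` comments are ignored. Errors name the offending line.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_pedigree(fh)
    individuals: list[Individual] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise PedigreeError(
                f"PED line {lineno}: expected 6 columns, got {len(fields)}"
            )
        _family, iid, father, mother, sex, pheno = fields
        if sex not in _SEX:
            raise PedigreeError(f"PED line {lineno}: bad sex code {sex!r}")
        if pheno not in _PHENO:
            raise PedigreeError(f"PED line {lineno}: bad phenotype code {pheno!r}")
        individuals.append(
            Individual(
                id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX[sex],
                affected=_PHENO[pheno],
            )
        )
    return Pedigree(individuals)
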