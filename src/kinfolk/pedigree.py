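"""Pedigree model and 6-column PED parsing.

Individuals carry sex, parent links, a sequenced/available flag and a
carrier-genotype label (biallelic / monoallelic / noncarrier / unknown) used
when grouping burden tests by carrier-parent status.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

SEXES = ("male", "female", "unknown")
CARRIER_STATUSES = ("biallelic", "monoallelic", "noncarrier", "unknown")


class PedigreeError(ValueError):
    pass


@dataclass
class Individual:
    id: str
    sex: str = "unknown"
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    sequenced: bool = True
    carrier_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"{self.id}: invalid sex {self.sex!r}")
        if self.carrier_status not in CARRIER_STATUSES:
            raise PedigreeError(
                f"{self.id}: invalid carrier status {self.carrier_status!r}")


class Pedigree:
    """A validated, acyclic pedigree graph."""

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"individual {ind.id!r} listed twice")
            self._members[ind.id] = ind
        for ind in self._members.values():
            for pid in (ind.mother_id, ind.father_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"{ind.id}: parent {pid!r} referenced but never defined")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    "cyclic parentage involving " + " -> ".join(stack + [iid]))
            state[iid] = 0
            ind = self._members[iid]
            for pid in (ind.mother_id, ind.father_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for iid in self._members:
            visit(iid, [])

    # -- access ------------------------------------------------------------
    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    def __iter__(self):
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def parents_of(self, iid: str) -> set[str]:
        ind = self._members[iid]
        return {p for p in (ind.mother_id, ind.father_id) if p is not None}

    def children_of(self, iid: str) -> set[str]:
        return {
            c.id for c in self._members.values()
            if iid in (c.mother_id, c.father_id)
        }

    def ancestors_of(self, iid: str) -> set[str]:
        out: set[str] = set()
        frontier = self.parents_of(iid)
        while frontier:
            out |= frontier
            frontier = set().union(*(self.parents_of(p) for p in frontier))
        return out

    def is_lineal(self, a: str, b: str) -> bool:
        """True when ``a`` and ``b`` lie on one ancestor-descendant line.

        Used by the variant-sharing filter: a variant seen in a parent and
        their own child is plausibly a transmitted de novo mutation, while
        sharing between, say, cousins indicates inheritance from an
        unsequenced founder.
        """
        return a == b or a in self.ancestors_of(b) or b in self.ancestors_of(a)

    def full_siblings_of(self, iid: str) -> set[str]:
        ind = self._members[iid]
        if ind.mother_id is None or ind.father_id is None:
            return set()
        return {
            o.id for o in self._members.values()
            if o.id != iid
            and o.mother_id == ind.mother_id
            and o.father_id == ind.father_id
        }

    def full_sibling_sets(self) -> list[set[str]]:
        groups: dict[tuple[str, str], set[str]] = {}
        for ind in self._members.values():
            if ind.mother_id is not None and ind.father_id is not None:
                groups.setdefault((ind.mother_id, ind.father_id), set()).add(ind.id)
        return [g for g in groups.values() if len(g) >= 2]


_PED_SEX = {"1": "male", "2": "female"}


def load_pedigree(source) -> Pedigree:
    """Parse a 6-column PED file (family, id, father, mother, sex, phenotype).

    A 7th optional column is read as the carrier-status label. The PED
    convention of "0" for a missing parent maps to an absent link.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            return load_pedigree(fh)
    if isinstance(source, str):
        source = io.StringIO(source)

    individuals = []
    seen: set[str] = set()
    for lineno, line in enumerate(source, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"PED line {lineno}: expected >= 6 columns")
        _fam, iid, father, mother, sex, _pheno = fields[:6]
        if iid in seen:
            raise PedigreeError(f"individual {iid!r} listed twice")
        seen.add(iid)
        carrier = fields[6] if len(fields) > 6 else "unknown"
        if carrier not in CARRIER_STATUSES:
            carrier = "unknown"
        individuals.append(Individual(
            id=iid,
            sex=_PED_SEX.get(sex, "unknown"),
            mother_id=None if mother == "0" else mother,
            father_id=None if father == "0" else father,
            carrier_status=carrier,
        ))
    return Pedigree(individuals)


def write_ped(pedigree: Pedigree, path: str, family_id: str = "FAM1") -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write("\t".join([
                family_id, ind.id,
                ind.father_id or "0", ind.mother_id or "0",
                sex_code[ind.sex], "-9", ind.carrier_status,
            ]) + "\n")
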