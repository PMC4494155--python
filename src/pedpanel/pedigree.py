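"""Pedigree representation, validation, nuclear-unit decomposition and kinship.

A pedigree is a directed acyclic graph: one node per individual, one edge
from each known parent to each of its children.  Founders are individuals
with no recorded parents.  The module provides

* a 6-column tab-delimited reader/writer (``id, father, mother, sex,
  birth_year, sequenced``; ``0`` or empty marks an unknown parent),
* decomposition of the pedigree into trio / duo / singleton units, the
  shape required by Mendelian-constrained genotype refinement — parents
  shared by several children are replicated into one unit per child,
* the recursive pedigree kinship coefficient phi, with phi(i,i) =
  (1 + F_i)/2 where F_i is the inbreeding coefficient.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "Individual",
    "Pedigree",
    "NuclearUnit",
    "PedigreeError",
    "load_pedigree",
    "write_pedigree",
]

SEXES = ("M", "F", "U")


class PedigreeError(ValueError):
    """Structural or validation problem in a pedigree."""


@dataclass
class Individual:
    iid: str
    sex: str = "U"  # 'M', 'F', 'U'
    birth_year: Optional[int] = None
    father: Optional[str] = None
    mother: Optional[str] = None
    sequenced: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"individual {self.iid}: invalid sex {self.sex!r}")


class Pedigree:
    """Directed acyclic multigenerational pedigree.

    Validation enforced at construction: referenced parents exist, no
    individual is its own ancestor, nobody is used both as a father and
    as a mother, and (when both years are known) children are born
    strictly after their parents.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.members[ind.iid] = ind
        self._validate_parents()
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.members)
        for ind in self.members.values():
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    self._graph.add_edge(parent, ind.iid)
        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise PedigreeError(
                f"pedigree contains a cycle through individual {cycle[0][0]!r}"
            )
        self._validate_years()
        self._topo = list(nx.topological_sort(self._graph))
        self._kin_cache: dict[tuple[str, str], float] = {}
        self._depth = {iid: 0 for iid in self._topo}
        for iid in self._topo:
            ind = self.members[iid]
            for p in (ind.father, ind.mother):
                if p is not None:
                    self._depth[iid] = max(self._depth[iid], self._depth[p] + 1)

    def _validate_parents(self) -> None:
        as_father: set[str] = set()
        as_mother: set[str] = set()
        for ind in self.members.values():
            for role, parent in (("father", ind.father), ("mother", ind.mother)):
                if parent is None:
                    continue
                if parent not in self.members:
                    raise PedigreeError(
                        f"individual {ind.iid}: unknown {role} id {parent!r}"
                    )
                (as_father if role == "father" else as_mother).add(parent)
        both = as_father & as_mother
        if both:
            raise PedigreeError(
                f"individual {sorted(both)[0]!r} used as both father and mother"
            )
        for iid in as_father:
            if self.members[iid].sex == "F":
                raise PedigreeError(f"female individual {iid!r} used as father")
            self.members[iid].sex = "M"
        for iid in as_mother:
            if self.members[iid].sex == "M":
                raise PedigreeError(f"male individual {iid!r} used as mother")
            self.members[iid].sex = "F"

    def _validate_years(self) -> None:
        for ind in self.members.values():
            if ind.birth_year is None:
                continue
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                py = self.members[parent].birth_year
                if py is not None and ind.birth_year <= py:
                    raise PedigreeError(
                        f"individual {ind.iid} born {ind.birth_year} not after "
                        f"parent {parent} born {py}"
                    )

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self.members[iid]
        except KeyError:
            raise KeyError(f"individual {iid!r} not in pedigree") from None

    @property
    def ids(self) -> list[str]:
        return list(self.members)

    @property
    def founders(self) -> list[str]:
        return [
            i.iid
            for i in self.members.values()
            if i.father is None and i.mother is None
        ]

    def sequenced_ids(self) -> list[str]:
        return [i.iid for i in self.members.values() if i.sequenced]

    def topological_order(self) -> list[str]:
        """Parents always precede children."""
        return list(self._topo)

    def direct_children(self, iid: str, restrict_to_sequenced: bool = False) -> set[str]:
        """Immediate (one-generation) children of *iid*."""
        if iid not in self.members:
            raise KeyError(f"individual {iid!r} not in pedigree")
        kids = set(self._graph.successors(iid))
        if restrict_to_sequenced:
            kids = {k for k in kids if self.members[k].sequenced}
        return kids

    # -- nuclear-unit decomposition ------------------------------------

    def decompose_units(self, sequenced_only: bool = True) -> list["NuclearUnit"]:
        """Break the pedigree into trio / duo / singleton units.

        Each (sequenced) individual appears exactly once as the child of
        one unit; a parent with several children or mates is replicated
        across units, with ``replicate_index`` counting its replications.
        A child whose parents are both unknown (or, with
        ``sequenced_only``, both unsequenced) becomes a singleton.
        """
        units: list[NuclearUnit] = []
        replication: dict[str, int] = {}

        def usable(pid: Optional[str]) -> Optional[str]:
            if pid is None:
                return None
            if sequenced_only and not self.members[pid].sequenced:
                return None
            return pid

        pool = self.sequenced_ids() if sequenced_only else self.ids
        for iid in sorted(pool):
            f = usable(self.members[iid].father)
            m = usable(self.members[iid].mother)
            if f is not None and m is not None:
                kind = "trio"
            elif f is not None or m is not None:
                kind = "duo"
            else:
                kind = "singleton"
            rep = 0
            for p in (f, m):
                if p is not None:
                    replication[p] = replication.get(p, 0) + 1
                    rep = max(rep, replication[p])
            units.append(NuclearUnit(kind=kind, father=f, mother=m, child=iid,
                                     replicate_index=rep))
        return units

    # -- kinship -------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Pedigree kinship coefficient phi(a, b).

        Recursive rule with founders unrelated: phi(i,i) = (1 +
        phi(father_i, mother_i)) / 2, and for i != j, recursing on the
        parents of whichever individual is deeper in the pedigree (and
        hence cannot be an ancestor of the other):
        phi(i,j) = (phi(father_i, j) + phi(mother_i, j)) / 2.
        """
        for iid in (a, b):
            if iid not in self.members:
                raise KeyError(f"individual {iid!r} not in pedigree")
        return self._phi(a, b)

    def _phi(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        ia, ib = self.members[a], self.members[b]
        if a == b:
            if ia.father is not None and ia.mother is not None:
                phi = 0.5 * (1.0 + self._phi(ia.father, ia.mother))
            else:
                phi = 0.5
        else:
            # recurse on the deeper individual: it cannot be an ancestor
            # of the shallower one
            if self._depth[a] < self._depth[b]:
                a, b, ia, ib = b, a, ib, ia
            if ia.father is None and ia.mother is None:
                phi = 0.0
            else:
                phi = 0.0
                for p in (ia.father, ia.mother):
                    phi += 0.5 * (self._phi(p, b) if p is not None else 0.0)
        self._kin_cache[key] = phi
        return phi

    def kinship_matrix(self, ids: Optional[list[str]] = None):
        import numpy as np

        ids = list(ids) if ids is not None else self.ids
        n = len(ids)
        K = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                K[i, j] = K[j, i] = self.kinship(ids[i], ids[j])
        return K


@dataclass(frozen=True)
class NuclearUnit:
    """A trio (both parents), duo (one parent) or singleton unit."""

    kind: str  # 'trio' | 'duo' | 'singleton'
    father: Optional[str]
    mother: Optional[str]
    child: str
    replicate_index: int = 0

    def __post_init__(self):
        if self.kind == "trio" and (self.father is None or self.mother is None):
            raise PedigreeError("trio unit requires both parents")
        if self.kind == "duo" and (self.father is None) == (self.mother is None):
            raise PedigreeError("duo unit requires exactly one parent")

    @property
    def parents(self) -> list[str]:
        return [p for p in (self.father, self.mother) if p is not None]

    @property
    def member_ids(self) -> list[str]:
        return self.parents + [self.child]


# -- file dialect ------------------------------------------------------

_COLUMNS = ["id", "father", "mother", "sex", "birth_year", "sequenced"]

_SEX_IN = {"m": "M", "male": "M", "1": "M", "f": "F", "female": "F", "2": "F",
           "u": "U", "unknown": "U", "0": "U", "": "U"}


def load_pedigree(path) -> Pedigree:
    """Read a 6-column tab-delimited pedigree file (with header).

    Columns: id, father, mother, sex, birth_year, sequenced.  ``0`` or
    an empty field denotes an unknown parent / unknown birth year; sex
    accepts M/F/U or PLINK-style 1/2/0.
    """
    individuals = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _COLUMNS[:4] if c not in (reader.fieldnames or [])]
        if missing:
            raise PedigreeError(f"pedigree file missing columns: {missing}")
        for row in reader:
            def _parent(v: Optional[str]) -> Optional[str]:
                v = (v or "").strip()
                return None if v in ("", "0", "NA") else v

            year = (row.get("birth_year") or "").strip()
            seq = (row.get("sequenced") or "1").strip().lower()
            individuals.append(
                Individual(
                    iid=row["id"].strip(),
                    sex=_SEX_IN.get(row["sex"].strip().lower(), row["sex"].strip()),
                    birth_year=int(year) if year not in ("", "0", "NA") else None,
                    father=_parent(row.get("father")),
                    mother=_parent(row.get("mother")),
                    sequenced=seq in ("1", "true", "yes"),
                )
            )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_COLUMNS)
        for ind in ped.members.values():
            w.writerow([
                ind.iid,
                ind.father or "0",
                ind.mother or "0",
                ind.sex,
                ind.birth_year if ind.birth_year is not None else "0",
                int(ind.sequenced),
            ])


def write_fam(ped: Pedigree, path, family_id: str = "FAM1") -> None:
    """Export as standard 6-column FAM (single constant family id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        sex_out = {"M": "1", "F": "2", "U": "0"}
        for ind in ped.members.values():
            w.writerow([family_id, ind.iid, ind.father or "0", ind.mother or "0",
                        sex_out[ind.sex], "-9"])
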