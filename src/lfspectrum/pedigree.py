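"""Family graphs and kinship-degree queries.

Degree follows the clinical-genetics convention (expected genome
sharing), not raw graph distance: full siblings are first degree even
though the path through a shared parent has length two; half-siblings,
grandparents and avuncular pairs are second degree. For consanguineous
loops the minimal degree over all common ancestors is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from lfspectrum.cohort_model import Cohort, Individual


class PedigreeError(KeyError):
    """Raised for lookups of ids not present in the pedigree."""


@dataclass
class Pedigree:
    family_id: str
    members: set[str] = field(default_factory=set)
    parents: dict[str, tuple[Optional[str], Optional[str]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for child, (father, mother) in self.parents.items():
            for endpoint in (child, father, mother):
                if endpoint is not None and endpoint not in self.members:
                    raise PedigreeError(
                        f"parent edge endpoint {endpoint!r} not a member"
                    )
        self._check_acyclic()

    @classmethod
    def from_individuals(
        cls, family_id: str, individuals: Iterable[Individual]
    ) -> "Pedigree":
        members = set()
        parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
        for ind in individuals:
            if ind.family_id != family_id:
                continue
            members.add(ind.individual_id)
            if ind.father_id or ind.mother_id:
                parents[ind.individual_id] = (ind.father_id, ind.mother_id)
        return cls(family_id=family_id, members=members, parents=parents)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> dict[str, "Pedigree"]:
        return {
            fid: cls.from_individuals(fid, cohort.family_members(fid))
            for fid in cohort.family_ids()
        }

    # -- internals -------------------------------------------------------

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str) -> None:
            if state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise PedigreeError(f"parent edges form a cycle at {node!r}")
            state[node] = 0
            for p in self.parents.get(node, (None, None)):
                if p is not None:
                    visit(p)
            state[node] = 1

        for m in self.members:
            visit(m)

    def _require(self, individual_id: str) -> None:
        if individual_id not in self.members:
            raise PedigreeError(
                f"{individual_id!r} not in family {self.family_id!r}"
            )

    def parent_ids(self, individual_id: str) -> tuple[str, ...]:
        return tuple(
            p for p in self.parents.get(individual_id, ()) if p is not None
        )

    def ancestor_depths(self, individual_id: str) -> dict[str, int]:
        """Map ancestor id -> minimal number of parent steps (self -> 0)."""
        self._require(individual_id)
        depths = {individual_id: 0}
        frontier = [individual_id]
        while frontier:
            nxt = []
            for node in frontier:
                for p in self.parent_ids(node):
                    d = depths[node] + 1
                    if p not in depths or d < depths[p]:
                        depths[p] = d
                        nxt.append(p)
            frontier = nxt
        return depths

    def _ancestor_items(self, individual_id: str) -> dict[tuple, int]:
        """Minimal depths of ancestor *items*: individuals and couples.

        A couple item ("c", father, mother) is reachable at depth d+1
        from a descendant at depth d whose both parents are known; it
        stands for joint descent from the pair and is what makes full
        siblings (and relationships routed through them) one degree
        closer than the raw path length.
        """
        depths = self.ancestor_depths(individual_id)
        items: dict[tuple, int] = {}
        for node, d in depths.items():
            items[("i", node)] = min(items.get(("i", node), d), d)
            f, m = self.parents.get(node, (None, None))
            if f is not None and m is not None:
                key = ("c", f, m)
                items[key] = min(items.get(key, d + 1), d + 1)
        return items

    # -- queries ---------------------------------------------------------

    def kinship_degree(self, a: str, b: str) -> Optional[int]:
        """Genealogical degree between two members, ``None`` if unrelated.

        Minimal over common-ancestor routes of (steps up + steps down),
        counting descent from a shared parental *couple* as one degree
        less: full siblings 1, half-siblings/grandparents/avuncular 2,
        first cousins 3. Consanguineous loops resolve to the minimum.
        """
        self._require(a)
        self._require(b)
        if a == b:
            raise ValueError("kinship_degree requires two distinct individuals")
        ia = self._ancestor_items(a)
        ib = self._ancestor_items(b)
        best: Optional[int] = None
        for key in set(ia) & set(ib):
            bonus = 1 if key[0] == "c" else 0
            deg = ia[key] + ib[key] - bonus
            if best is None or deg < best:
                best = deg
        return best

    def relatives_within_degree(self, a: str, max_degree: int) -> set[str]:
        """All members related to ``a`` at degree <= ``max_degree``."""
        self._require(a)
        out = set()
        for b in self.members:
            if b == a:
                continue
            deg = self.kinship_degree(a, b)
            if deg is not None and deg <= max_degree:
                out.add(b)
        return out
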