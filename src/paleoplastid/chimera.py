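"""Detection of chimeric proteins from homology-hit intervals.

A protein searched against a taxonomically classified reference library
yields *components*: the query intervals of its hits (e-value <= 1e-5,
boundary inclusive), each labelled with the subject's lineage.  Components
overlapping by more than 70% of *each* of their lengths belong to the same
component family (transitive closure); families are then merged when one
family's representative span is covered by more than 70% of its length by
another's, iterated to a fixed point.  A family's origin is the unanimous
lineage of its top three members by bitscore (unanimity over what exists
for smaller families).  A protein is chimeric when two assigned families of
different lineages occupy distinct regions of the protein (their spans fail
the mutual->70% overlap rule); the N-/C-terminal domain labels follow the
span midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core_io import HitRecord

EVALUE_MAX = 1e-5
OVERLAP_FRACTION = 0.70
TOP_N = 3


@dataclass(frozen=True)
class Component:
    subject_id: str
    query_interval: tuple[int, int]
    bitscore: float
    lineage: str

    @property
    def length(self) -> int:
        return self.query_interval[1] - self.query_interval[0]


@dataclass
class ComponentFamily:
    family_id: int
    members: list[Component]
    assigned_lineage: str = "unassigned"

    @property
    def span(self) -> tuple[int, int]:
        return (min(c.query_interval[0] for c in self.members),
                max(c.query_interval[1] for c in self.members))

    @property
    def midpoint(self) -> float:
        lo, hi = self.span
        return (lo + hi) / 2


@dataclass
class ChimeraCall:
    query_id: str
    chimeric: bool
    domains: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    @property
    def ntd_origin(self) -> str | None:
        return self.domains[0][0] if self.domains else None

    @property
    def ctd_origin(self) -> str | None:
        return self.domains[-1][0] if self.domains else None


def collect_components(hits: Sequence[HitRecord],
                       lineage_of_subject: Callable[[str], str],
                       evalue_max: float = EVALUE_MAX) -> list[Component]:
    """One component per hit with e-value <= the cutoff (inclusive)."""
    out = []
    for hit in hits:
        if hit.evalue <= evalue_max:
            out.append(Component(subject_id=hit.subject_id,
                                 query_interval=hit.query_interval,
                                 bitscore=hit.bitscore,
                                 lineage=lineage_of_subject(hit.subject_id)))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _mutual_overlap(a: tuple[int, int], b: tuple[int, int],
                    fraction: float = OVERLAP_FRACTION) -> bool:
    ov = _overlap(a, b)
    la, lb = a[1] - a[0], b[1] - b[0]
    return ov > fraction * la and ov > fraction * lb


def group_component_families(components: Sequence[Component],
                             fraction: float = OVERLAP_FRACTION,
                             ) -> list[ComponentFamily]:
    """Two-stage grouping: mutual->70% component overlap (transitive
    closure), then merging of families nested >70% inside another, iterated
    to a fixed point.  Output order follows ascending span midpoint and is
    invariant under permutation of the input."""
    comps = sorted(components,
                   key=lambda c: (c.query_interval, c.subject_id, -c.bitscore))
    n = len(comps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _mutual_overlap(comps[i].query_interval,
                               comps[j].query_interval, fraction):
                parent[find(i)] = find(j)
    groups: dict[int, list[Component]] = {}
    for i, c in enumerate(comps):
        groups.setdefault(find(i), []).append(c)
    families = [ComponentFamily(family_id=k, members=m)
                for k, m in enumerate(
                    sorted(groups.values(),
                           key=lambda m: (min(c.query_interval[0] for c in m),
                                          max(c.query_interval[1] for c in m))))]

    # family-level merge: X absorbed into Y when >70% of X's span is inside
    # Y; applied in canonical span order so the fixed point is deterministic
    changed = True
    while changed:
        changed = False
        families.sort(key=lambda f: (f.span, len(f.members)))
        for i in range(len(families)):
            for j in range(len(families)):
                if i == j:
                    continue
                x, y = families[i], families[j]
                lx = x.span[1] - x.span[0]
                if lx and _overlap(x.span, y.span) > fraction * lx:
                    y.members.extend(x.members)
                    del families[i]
                    changed = True
                    break
            if changed:
                break
    families.sort(key=lambda f: (f.midpoint, f.span))
    for k, fam in enumerate(families):
        fam.family_id = k
        fam.members.sort(key=lambda c: (-c.bitscore, c.subject_id))
    return families


def assign_family_origin(family: ComponentFamily,
                         top_n: int = TOP_N) -> str:
    """Unanimous lineage of the top-``top_n`` members by bitscore (ties by
    subject id); smaller families require unanimity over what exists."""
    if not family.members:
        raise ValueError("empty component family")
    top = sorted(family.members,
                 key=lambda c: (-c.bitscore, c.subject_id))[:top_n]
    lineages = {c.lineage for c in top}
    family.assigned_lineage = (next(iter(lineages)) if len(lineages) == 1
                               else "unassigned")
    return family.assigned_lineage


def detect_chimeras(query_id: str,
                    families: Sequence[ComponentFamily],
                    fraction: float = OVERLAP_FRACTION) -> ChimeraCall:
    """Chimeric when >=2 assigned families with different lineages occupy
    regions that fail the mutual overlap rule; domains ordered N to C by
    span midpoint."""
    assigned = [f for f in families if f.assigned_lineage != "unassigned"]
    assigned.sort(key=lambda f: (f.midpoint, f.span))
    call = ChimeraCall(query_id=query_id, chimeric=False,
                       domains=[(f.assigned_lineage, f.span) for f in assigned])
    for i in range(len(assigned)):
        for j in range(i + 1, len(assigned)):
            a, b = assigned[i], assigned[j]
            if a.assigned_lineage == b.assigned_lineage:
                continue
            if not _mutual_overlap(a.span, b.span, fraction):
                call.chimeric = True
    return call


def analyse_protein(query_id: str,
                    hits: Sequence[HitRecord],
                    lineage_of_subject: Callable[[str], str],
                    evalue_max: float = EVALUE_MAX,
                    fraction: float = OVERLAP_FRACTION,
                    top_n: int = TOP_N) -> ChimeraCall:
    """collect -> group -> assign -> detect for one protein."""
    components = collect_components(hits, lineage_of_subject, evalue_max)
    families = group_component_families(components, fraction)
    for fam in families:
        assign_family_origin(fam, top_n)
    return detect_chimeras(query_id, families, fraction)
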