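"""Homologous plastid-protein group (HPPG) assembly and curation.

A seed protein's hits against a designated outgroup library define a
*floating threshold*: the e-value (and, for zero/zero ties, the hit-list
rank) of its first outgroup hit.  Seeds that match one another more
strongly than either matches the outgroup are merged; the surviving seed
then recruits members from the full in-group library under the same cap.

An HPPG is called *conserved* when its taxonomic footprint passes at least
one conservation pattern over the three ochrophyte groups:

* P1: >=2/3 of chrysistan and >=3/5 of diatom sub-categories;
* P2: >=2/3 of chrysistan and >=2/3 of hypogyristean sub-categories;
* P3: >=1 chrysistan, >=2/3 hypogyristean and >=3/5 diatom sub-categories.

Curation then removes members that terminate inside the conserved domain or
start more than 50 consensus positions after it, trims gappy columns
(trimAl -gt 0.5 semantics), and finally checks that the gene tree contains
an ochrophyte clade that is monophyletic or paraphyletic to at most one of
five non-ochrophyte groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio.Align import substitution_matrices

from .core_io import (GAP, HitRecord, SequenceRecord, TaxonomyScheme, logger,
                      subcategory_of)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutgroupCap:
    """Floating threshold from the seed's best outgroup hit.

    ``open`` caps (no outgroup hit at all) admit everything and are flagged.
    """

    evalue: float = math.inf
    bitscore: float = 0.0
    rank: int = 0
    open_cap: bool = True

    def admits(self, hit: HitRecord) -> bool:
        """Strictly-stronger-than-outgroup rule; 0/0 ties fall back to rank."""
        if self.open_cap:
            return True
        if hit.evalue == 0.0 and self.evalue == 0.0:
            return hit.rank < self.rank
        return hit.evalue < self.evalue


@dataclass
class ConservationPattern:
    pattern_id: str
    min_fractions: dict[str, float]      # group -> minimum presence fraction

    def passes(self, presence: Mapping[str, int],
               taxonomy: TaxonomyScheme) -> bool:
        for group, minimum in self.min_fractions.items():
            subs = taxonomy.ochrophyte_groups[group]
            present = sum(1 for s in subs if presence.get(s, 0) >= 1)
            if present / len(subs) < minimum - 1e-12:
                return False
        return True


def default_patterns() -> list[ConservationPattern]:
    return [
        ConservationPattern("P1", {"chrysista": 2 / 3, "diatoms": 3 / 5}),
        ConservationPattern("P2", {"chrysista": 2 / 3, "hypogyristea": 2 / 3}),
        ConservationPattern("P3", {"chrysista": 1 / 3, "hypogyristea": 2 / 3,
                                   "diatoms": 3 / 5}),
    ]


@dataclass
class HPPG:
    """One homologous plastid-protein group."""

    hppg_id: str
    seed_id: str
    member_ids: list[str]
    presence: dict[str, int] = field(default_factory=dict)
    conservation_patterns_passed: set[str] = field(default_factory=set)
    status: str = "candidate"         # candidate -> conserved -> curated -> ancestral
    cap: OutgroupCap | None = None

    _STATUS_ORDER = ("candidate", "conserved", "curated", "ancestral")

    def advance_status(self, new: str) -> None:
        order = self._STATUS_ORDER
        if order.index(new) >= order.index(self.status):
            self.status = new

    def recount_presence(self, taxonomy: TaxonomyScheme) -> None:
        counts: dict[str, int] = {}
        for sid in self.member_ids:
            sub = subcategory_of(sid)
            if taxonomy.is_ochrophyte(sub):
                counts[sub] = counts.get(sub, 0) + 1
        self.presence = counts


# ---------------------------------------------------------------------------
# caps and clustering
# ---------------------------------------------------------------------------

def compute_outgroup_cap(seed_id: str,
                         outgroup_hits: Sequence[HitRecord]) -> OutgroupCap:
    """Cap = (evalue, bitscore, rank) of the rank-1 outgroup hit; an empty
    hit list yields an open cap (flagged)."""
    if not outgroup_hits:
        logger.info("%s: no outgroup hit; open cap", seed_id)
        return OutgroupCap()
    top = min(outgroup_hits, key=lambda h: h.rank)
    return OutgroupCap(evalue=top.evalue, bitscore=top.bitscore,
                       rank=top.rank, open_cap=False)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_seeds(seed_candidates: Sequence[str],
                all_vs_all_hits: Mapping[str, Sequence[HitRecord]],
                outgroup_caps: Mapping[str, OutgroupCap],
                organism_precedence: Sequence[str],
                ) -> tuple[list[str], dict[str, str]]:
    """Collapse redundant seed candidates by transitive closure.

    ``a`` and ``b`` merge when a's hit against b is admitted by a's cap (or
    vice versa).  One seed survives per cluster: first by the organism
    precedence list, then by the lowest e-value against its own outgroup
    top hit.  Returns (retained seeds, candidate -> retained map).
    """
    if len(set(organism_precedence)) != len(organism_precedence):
        raise ValueError("organism precedence list contains duplicates")
    prec = {org: i for i, org in enumerate(organism_precedence)}
    cand = set(seed_candidates)
    for c in cand:
        if c not in outgroup_caps:
            raise KeyError(f"candidate {c} has no outgroup cap")
    uf = _UnionFind(cand)
    for a in seed_candidates:
        cap = outgroup_caps[a]
        for hit in all_vs_all_hits.get(a, ()):
            if hit.subject_id in cand and cap.admits(hit):
                uf.union(a, hit.subject_id)
    clusters: dict[str, list[str]] = {}
    for c in seed_candidates:
        clusters.setdefault(uf.find(c), []).append(c)

    def seed_key(sid: str):
        species = sid.split("|")[1] if "|" in sid else sid
        cap = outgroup_caps[sid]
        return (prec.get(species, len(prec)), cap.evalue, sid)

    retained: list[str] = []
    merge_map: dict[str, str] = {}
    for members in clusters.values():
        keep = min(members, key=seed_key)
        retained.append(keep)
        for m in members:
            merge_map[m] = keep
    return sorted(retained), merge_map


def trim_to_first_met(residues: str) -> str | None:
    pos = residues.find("M")
    return residues[pos:] if pos >= 0 else None


def grow_hppg(seed: SequenceRecord,
              library_hits: Sequence[HitRecord],
              cap: OutgroupCap,
              taxonomy: TaxonomyScheme,
              sequences: Mapping[str, SequenceRecord] | None = None,
              ) -> tuple[HPPG, dict[str, str]]:
    """Recruit in-group members under the floating cap.

    Members are N-terminally trimmed to their first methionine before
    binning; a member with no methionine is excluded (logged).  Returns the
    HPPG and the trimmed member sequences.
    """
    members = [seed.seq_id]
    trimmed: dict[str, str] = {}
    seed_trim = trim_to_first_met(seed.residues)
    if seed_trim is not None:
        trimmed[seed.seq_id] = seed_trim
    for hit in sorted(library_hits, key=lambda h: h.rank):
        if hit.subject_id == seed.seq_id or hit.subject_id in members:
            continue
        if not cap.admits(hit):
            continue
        if sequences is not None:
            rec = sequences.get(hit.subject_id)
            if rec is None:
                continue
            t = trim_to_first_met(rec.residues)
            if t is None:
                logger.info("%s: no methionine, excluded from %s",
                            hit.subject_id, seed.seq_id)
                continue
            trimmed[hit.subject_id] = t
        members.append(hit.subject_id)
    hppg = HPPG(hppg_id=seed.seq_id, seed_id=seed.seq_id, member_ids=members,
                cap=cap)
    hppg.recount_presence(taxonomy)
    return hppg, trimmed


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def evaluate_conservation(hppg: HPPG,
                          taxonomy: TaxonomyScheme,
                          patterns: Sequence[ConservationPattern] | None = None,
                          ) -> set[str]:
    """Patterns passed by the group's taxonomic footprint; sets status to
    ``conserved`` when at least one passes."""
    patterns = patterns if patterns is not None else default_patterns()
    passed = {p.pattern_id for p in patterns
              if p.passes(hppg.presence, taxonomy)}
    hppg.conservation_patterns_passed = passed
    if passed:
        hppg.advance_status("conserved")
    return passed


def select_conservation_patterns(
        candidate_patterns: Sequence[ConservationPattern],
        positive_control_hppgs: Sequence[HPPG],
        negative_control_hppgs: Sequence[HPPG],
        taxonomy: TaxonomyScheme,
        ) -> list[tuple[ConservationPattern, float, float]]:
    """Rank candidate patterns by how well they separate positive from
    negative control HPPGs (2x2 chi-squared on pass/fail x control set).

    Returns (pattern, statistic, p) sorted by ascending p.
    """
    from scipy.stats import chi2_contingency

    if not positive_control_hppgs or not negative_control_hppgs:
        raise ValueError("both control sets must be non-empty")
    results = []
    for pattern in candidate_patterns:
        pos_pass = sum(1 for h in positive_control_hppgs
                       if pattern.passes(h.presence, taxonomy))
        neg_pass = sum(1 for h in negative_control_hppgs
                       if pattern.passes(h.presence, taxonomy))
        table = [[pos_pass, len(positive_control_hppgs) - pos_pass],
                 [neg_pass, len(negative_control_hppgs) - neg_pass]]
        if min(sum(row) for row in table) == 0 or \
                min(table[0][j] + table[1][j] for j in (0, 1)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = chi2_contingency(table, correction=False)
        results.append((pattern, float(stat), float(p)))
    if all(not pattern.passes(h.presence, taxonomy)
           for pattern in candidate_patterns for h in positive_control_hppgs):
        logger.warning("no candidate pattern passes any positive control")
    return sorted(results, key=lambda r: (r[2], r[0].pattern_id))


# ---------------------------------------------------------------------------
# alignment curation
# ---------------------------------------------------------------------------

def _column_conserved(column: str, fraction: float) -> bool:
    """>= ``fraction`` of all rows identical or BLOSUM62-positive to the
    modal residue (gaps count against)."""
    residues = [c for c in column if c != GAP]
    if not residues:
        return False
    modal = max(set(residues), key=lambda r: (residues.count(r), r))
    similar = 0
    for c in residues:
        try:
            if c == modal or _BLOSUM62[modal, c] > 0:
                similar += 1
        except IndexError:
            continue
    return similar / len(column) >= fraction - 1e-12


def conserved_domain_bounds(alignment: Mapping[str, str],
                            fraction: float = 0.7) -> tuple[int, int] | None:
    """First and last conserved column (inclusive), or None."""
    if not alignment:
        return None
    ncol = len(next(iter(alignment.values())))
    rows = list(alignment.values())
    conserved = [i for i in range(ncol)
                 if _column_conserved("".join(r[i] for r in rows), fraction)]
    if not conserved:
        return None
    return conserved[0], conserved[-1]


def _consensus_columns(alignment: Mapping[str, str],
                       keep_fraction: float = 0.5) -> list[int]:
    rows = list(alignment.values())
    ncol = len(rows[0]) if rows else 0
    out = []
    for i in range(ncol):
        nongap = sum(1 for r in rows if r[i] != GAP)
        if nongap / len(rows) >= keep_fraction - 1e-12:
            out.append(i)
    return out


def curate_alignment(hppg: HPPG,
                     alignment: Mapping[str, str],
                     taxonomy: TaxonomyScheme,
                     patterns: Sequence[ConservationPattern] | None = None,
                     n_truncation_max: int = 50,
                     domain_fraction: float = 0.7,
                     ) -> tuple[HPPG | None, dict[str, str]]:
    """Remove members that start >50 consensus positions after the conserved
    domain or end before it; re-evaluate conservation afterwards.

    The conserved domain is the first/last column where >=70% of members are
    identical or BLOSUM62-positive to the modal residue; truncation is
    measured in consensus positions (columns with >=50% occupancy).  Returns
    (curated HPPG or None if no pattern survives, curated alignment).
    """
    missing = [m for m in hppg.member_ids if m not in alignment]
    if missing:
        raise ValueError(f"alignment missing members: {missing}")
    sub_alignment = {m: alignment[m] for m in hppg.member_ids}
    bounds = conserved_domain_bounds(sub_alignment, domain_fraction)
    if bounds is None:
        logger.warning("%s: no conserved domain; curation skipped", hppg.hppg_id)
        kept = dict(sub_alignment)
        curated = replace_members(hppg, list(kept), taxonomy)
        evaluate_conservation(curated, taxonomy, patterns)
        return (curated if curated.conservation_patterns_passed else None, kept)
    start, end = bounds
    consensus = _consensus_columns(sub_alignment)
    consensus_rank = {col: i for i, col in enumerate(consensus)}

    def consensus_offset(col: int, anchor: int) -> int:
        """Consensus positions between anchor and col."""
        ra = consensus_rank.get(anchor)
        if ra is None:
            ra = sum(1 for c in consensus if c < anchor)
        rc = sum(1 for c in consensus if c <= col)
        return rc - ra

    kept: dict[str, str] = {}
    for member, row in sub_alignment.items():
        first = next((i for i, c in enumerate(row) if c != GAP), None)
        last = next((i for i in range(len(row) - 1, -1, -1)
                     if row[i] != GAP), None)
        if first is None:
            continue
        late = consensus_offset(first, start) if first > start else 0
        if late > n_truncation_max:
            logger.info("%s removed from %s: starts %d consensus positions "
                        "into the conserved domain", member, hppg.hppg_id, late)
            continue
        if last is not None and last < end:
            logger.info("%s removed from %s: terminates inside the conserved "
                        "domain", member, hppg.hppg_id)
            continue
        kept[member] = row
    curated = replace_members(hppg, list(kept), taxonomy)
    evaluate_conservation(curated, taxonomy, patterns)
    if not curated.conservation_patterns_passed:
        return None, kept
    curated.advance_status("curated")
    return curated, kept


def replace_members(hppg: HPPG, member_ids: list[str],
                    taxonomy: TaxonomyScheme) -> HPPG:
    new = HPPG(hppg_id=hppg.hppg_id, seed_id=hppg.seed_id,
               member_ids=list(member_ids), cap=hppg.cap)
    new.status = hppg.status
    new.recount_presence(taxonomy)
    return new


def trim_columns(alignment: Mapping[str, str],
                 keep_fraction: float = 0.5) -> dict[str, str]:
    """trimAl -gt style column filter: keep columns whose non-gap fraction
    is >= ``keep_fraction`` (boundary kept); row order preserved."""
    if not alignment:
        raise ValueError("empty alignment")
    rows = list(alignment.items())
    ncol = len(rows[0][1])
    nrow = len(rows)
    keep = [i for i in range(ncol)
            if sum(1 for _, r in rows if r[i] != GAP) / nrow
            >= keep_fraction - 1e-12]
    if not keep:
        raise ValueError("alignment vanished: every column below threshold")
    return {name: "".join(row[i] for i in keep) for name, row in rows}


# ---------------------------------------------------------------------------
# gene-tree clade check
# ---------------------------------------------------------------------------

_CLADE_GROUPS = ("prokaryotes", "red algae", "green algae",
                 "aplastidic stramenopiles", "other eukaryotes")


def _clade_check_group(lineage: str, taxonomy: TaxonomyScheme) -> str | None:
    """Collapse a lineage onto the five interrupting groups; CASH lineages,
    chlorarachniophytes (rhizaria) and euglenids are ignored entirely."""
    if lineage in taxonomy.cash_lineages:
        return None
    if lineage in ("viruses",):
        return "prokaryotes"
    if lineage == "glaucophytes":
        return "other eukaryotes"
    if lineage in _CLADE_GROUPS:
        return lineage
    return lineage if lineage != "ochrophytes" else "ochrophytes"


def _bipartitions(tree: dendropy.Tree):
    leaves = list(tree.leaf_node_iter())
    all_set = frozenset(id(l) for l in leaves)
    by_id = {id(l): l for l in leaves}
    seen = set()
    for node in tree.preorder_node_iter():
        below = frozenset(id(l) for l in node.leaf_iter())
        for side in (below, all_set - below):
            if side and side not in seen:
                seen.add(side)
                yield [by_id[i] for i in side]


def check_ochrophyte_clade(tree: dendropy.Tree,
                           taxonomy: TaxonomyScheme,
                           patterns: Sequence[ConservationPattern] | None = None,
                           ) -> tuple[bool, set[str]]:
    """Pass when some clade (either side of any edge) holds enough ochrophyte
    sub-categories to satisfy a conservation pattern while its non-ochrophyte
    leaves all belong to a single one of the five interrupting groups.

    Returns (pass, offending groups of the best candidate clade).
    """
    patterns = patterns if patterns is not None else default_patterns()
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 4:
        return False, {"uninformative"}
    best_offenders: set[str] = set()
    for side in _bipartitions(tree):
        presence: dict[str, int] = {}
        interrupting: set[str] = set()
        for leaf in side:
            lin = getattr(leaf, "lineage", None)
            sub = getattr(leaf, "sub_category", None)
            if lin == "ochrophytes":
                presence[sub] = presence.get(sub, 0) + 1
            else:
                group = _clade_check_group(lin, taxonomy)
                if group is not None:
                    interrupting.add(group)
        if not any(p.passes(presence, taxonomy) for p in patterns):
            continue
        if len(interrupting) <= 1:
            return True, set()
        if not best_offenders or len(interrupting) < len(best_offenders):
            best_offenders = interrupting
    return False, best_offenders or {"no qualifying clade"}
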