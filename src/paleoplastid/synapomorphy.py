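"""Uniquely shared residues between a focal clade and a putative donor.

The screen works on curated alignments reduced to one sequence per
sub-category.  A column is a candidate synapomorphy when

* some residue is held by at least 2/3 of the ungapped focal sequences,
* at least one donor sequence holds the same residue,
* no exclusion-set sequence holds it, and
* at least one exclusion-set sequence is ungapped at that column
  (so absence is informative, not missing data).

Each qualifying residue is then mapped onto a reference topology of the
donor sub-categories: the residue is assigned to the deepest node whose
clade has more matching than non-matching-or-gapped sub-categories
(*observed* mode), or, treating gaps as matches, the earliest possible
origin (*earliest* mode).  HPPGs enter the analysis only after passing a
strict vertical-inheritance screen of their gene trees, and individual
sequences are validated by ranked-hit consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
from scipy.stats import chi2_contingency

from .core_io import GAP, TaxonomyScheme, leaf_label, logger


# ---------------------------------------------------------------------------
# vertical-inheritance screening of gene trees
# ---------------------------------------------------------------------------

@dataclass
class LineageScreenRules:
    """Which lineages are watched for multiple clades, which lineages a
    watched lineage may absorb (allowed paraphyly), and which leaves are
    ignored outright."""

    watched: tuple[str, ...]
    allowances: Mapping[str, frozenset[str]] = field(default_factory=dict)
    ignored: frozenset[str] = frozenset()
    min_separators: int = 2


def green_screen_rules() -> LineageScreenRules:
    """Screen for the green-donor dataset: ochrophyte/cryptomonad/haptophyte/
    red/green clades watched; green algae may be paraphyletic to cryptomonads,
    haptophytes and ochrophytes; ochrophytes to cryptomonads and haptophytes."""
    return LineageScreenRules(
        watched=("ochrophytes", "cryptomonads", "haptophytes",
                 "red algae", "green algae"),
        allowances={
            "green algae": frozenset({"cryptomonads", "haptophytes",
                                      "ochrophytes"}),
            "ochrophytes": frozenset({"cryptomonads", "haptophytes"}),
        },
        ignored=frozenset({"chlorarachniophytes", "euglenids",
                           "other alveolates", "dinotoms"}))


def haptophyte_screen_rules() -> LineageScreenRules:
    """Screen for the haptophyte-transfer dataset: ochrophytes (and each
    ochrophyte group) may absorb haptophytes; hypogyristea may absorb
    diatoms."""
    return LineageScreenRules(
        watched=("ochrophytes", "haptophytes",
                 "group:diatoms", "group:hypogyristea", "group:chrysista"),
        allowances={
            "ochrophytes": frozenset({"haptophytes"}),
            "group:diatoms": frozenset({"haptophytes"}),
            "group:hypogyristea": frozenset({"haptophytes", "group:diatoms"}),
            "group:chrysista": frozenset({"haptophytes"}),
        },
        ignored=frozenset({"chlorarachniophytes", "euglenids",
                           "other alveolates", "dinotoms"}))


def _leaf_class(leaf, taxonomy: TaxonomyScheme, group_level: bool) -> str:
    lin = getattr(leaf, "lineage", "")
    if group_level and lin == "ochrophytes":
        group = taxonomy.group_of(getattr(leaf, "sub_category", ""))
        return f"group:{group}" if group else lin
    return lin


def _clades_of_class(tree: dendropy.Tree, cls: str,
                     taxonomy: TaxonomyScheme,
                     rules: LineageScreenRules) -> list[list]:
    """Maximal clades whose leaves are all of ``cls`` or absorbable under
    the allowances; ignored leaves are transparent."""
    group_level = cls.startswith("group:")
    absorb = set(rules.allowances.get(cls, frozenset())) | {cls}
    if cls == "ochrophytes":
        absorb |= {"group:diatoms", "group:hypogyristea", "group:chrysista"}

    def leaf_ok(leaf) -> bool:
        lin = getattr(leaf, "lineage", "")
        if lin in rules.ignored:
            return True
        c_group = _leaf_class(leaf, taxonomy, True)
        c_plain = _leaf_class(leaf, taxonomy, False)
        return bool({c_group, c_plain} & absorb)

    def has_member(node) -> bool:
        for leaf in node.leaf_iter():
            if getattr(leaf, "lineage", "") in rules.ignored:
                continue
            lc = _leaf_class(leaf, taxonomy, group_level)
            if lc == cls:
                return True
        return False

    out: list[list] = []

    def walk(node) -> bool:
        leaves = list(node.leaf_iter())
        if all(leaf_ok(l) for l in leaves):
            return True
        pure = []
        for child in node.child_nodes():
            if walk(child):
                pure.append(child)
        for child in pure:
            if has_member(child):
                out.append(list(child.leaf_iter()))
        return False

    root = tree.seed_node
    if walk(root):
        if has_member(root):
            out.append(list(root.leaf_iter()))
    return out


def screen_vertical_inheritance(tree: dendropy.Tree,
                                taxonomy: TaxonomyScheme,
                                rules: LineageScreenRules,
                                ) -> tuple[bool, set[str]]:
    """Exclude trees in which any watched lineage splits into two or more
    multi-sequence clades separated by at least two outside sequences.

    Returns (include, offending lineages).
    """
    offenders: set[str] = set()
    for cls in rules.watched:
        group_level = cls.startswith("group:")
        clades = _clades_of_class(tree, cls, taxonomy, rules)
        multi = []
        for leaves in clades:
            n = sum(1 for l in leaves
                    if _leaf_class(l, taxonomy, group_level) == cls)
            if n > 1:
                multi.append({leaf_label(l) for l in leaves})
        if len(multi) < 2:
            continue
        # separation: outside sequences not belonging to any of the clades
        inside = set().union(*multi)
        outside = [l for l in tree.leaf_node_iter()
                   if leaf_label(l) not in inside
                   and getattr(l, "lineage", "") not in rules.ignored]
        if len(outside) >= rules.min_separators:
            offenders.add(cls)
    return (not offenders), offenders


# ---------------------------------------------------------------------------
# per-sequence validation
# ---------------------------------------------------------------------------

@dataclass
class MemberValidation:
    seq_id: str
    keep: bool
    reason: str = ""


def validate_member_sequence(
        seq_id: str,
        query_class: str,
        global_hit_classes: Sequence[str],
        within_hits: Sequence[tuple[str, str]],   # (class, sub_category)
        query_sub_category: str,
        taxonomy: TaxonomyScheme,
        consecutive_min: int = 3,
        glaucophyte_ok: frozenset[str] = frozenset(
            {"cyanobacteria-class", "red algae", "green algae"}),
        within_allowances: Mapping[str, frozenset[str]] | None = None,
        require_better_than: Mapping[str, frozenset[str]] | None = None,
        evalue_by_class: Mapping[str, float] | None = None,
) -> MemberValidation:
    """Two-stage ranked-hit validation of one aligned sequence.

    Stage 1 (global): the first ``consecutive_min`` hits against the
    composite library must share the query's class (ochrophyte queries are
    tested at group level upstream by passing the group as ``query_class``).

    Stage 2 (within-alignment): the first non-self hit must come from a
    different sub-category of the same class, with the documented
    exceptions: glaucophyte queries may hit cyanobacteria/red/green
    (single-representative allowance); classes listed in
    ``within_allowances`` may hit those classes first provided (when
    ``require_better_than``/``evalue_by_class`` are given) their best
    same-class hit is stronger than the best hit of each competing class;
    and when no other sub-category of the class exists in the alignment, a
    same-sub-category hit suffices.
    """
    prefix = list(global_hit_classes[:consecutive_min])
    if len(prefix) < consecutive_min or any(c != query_class for c in prefix):
        if query_class != "glaucophytes":
            return MemberValidation(seq_id, False, "global lineage")
    if not within_hits:
        return MemberValidation(seq_id, False, "no within-alignment hits")
    first_class, first_sub = within_hits[0]
    if query_class == "glaucophytes":
        if first_class in glaucophyte_ok or first_class == "glaucophytes":
            return MemberValidation(seq_id, True)
        return MemberValidation(seq_id, False, "glaucophyte affinity")
    allowances = (within_allowances or {}).get(query_class, frozenset())
    if first_class == query_class and first_sub != query_sub_category:
        return MemberValidation(seq_id, True)
    if first_class in allowances:
        if require_better_than and evalue_by_class:
            own = evalue_by_class.get(query_class)
            competitors = require_better_than.get(query_class, frozenset())
            if own is None:
                return MemberValidation(seq_id, False,
                                        "no same-class hit to compare")
            for comp in competitors:
                e = evalue_by_class.get(comp)
                if e is not None and e <= own:
                    return MemberValidation(seq_id, False,
                                            f"weaker than {comp}")
        return MemberValidation(seq_id, True)
    if first_class == query_class and first_sub == query_sub_category:
        others = {sub for cls, sub in within_hits
                  if cls == query_class and sub != query_sub_category}
        if not others:
            return MemberValidation(seq_id, True)   # same-sub-category fallback
        return MemberValidation(seq_id, False, "same sub-category only")
    return MemberValidation(seq_id, False, "within-alignment lineage")


# ---------------------------------------------------------------------------
# shared-residue scan
# ---------------------------------------------------------------------------

@dataclass
class SharedResidueCall:
    column: int
    residue: str
    focal_share_fraction: float
    donor_sub_categories: frozenset[str]
    origin_node_observed: str = ""
    origin_node_earliest: str = ""


def find_unique_shared_residues(alignment: Mapping[str, str],
                                focal_set: Sequence[str],
                                donor_set: Sequence[str],
                                exclusion_sets: Sequence[Sequence[str]],
                                focal_fraction: float = 2 / 3,
                                ) -> list[SharedResidueCall]:
    """Columns uniquely shared between the focal set and the donor set."""
    exclusion = [sid for group in exclusion_sets for sid in group]
    ncol = len(next(iter(alignment.values())))
    calls: list[SharedResidueCall] = []
    for col in range(ncol):
        focal_res = [alignment[s][col] for s in focal_set]
        ungapped = [r for r in focal_res if r != GAP]
        if not ungapped:
            continue
        counts: dict[str, int] = {}
        for r in ungapped:
            counts[r] = counts.get(r, 0) + 1
        residue, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        share = n / len(ungapped)
        if share < focal_fraction - 1e-12:
            continue
        donors = frozenset(s.split("|", 1)[0] for s in donor_set
                           if alignment[s][col] == residue)
        if not donors:
            continue
        excl_res = [alignment[s][col] for s in exclusion]
        if residue in excl_res:
            continue
        if not any(r != GAP for r in excl_res):
            continue
        calls.append(SharedResidueCall(column=col, residue=residue,
                                       focal_share_fraction=share,
                                       donor_sub_categories=donors))
    return calls


# ---------------------------------------------------------------------------
# origin node on a reference topology
# ---------------------------------------------------------------------------

def _node_name(node) -> str:
    if node.is_leaf():
        return leaf_label(node)
    return node.label or "+".join(sorted(leaf_label(l)
                                         for l in node.leaf_iter()))


def infer_origin_node(tree: dendropy.Tree,
                      status_by_leaf: Mapping[str, str],
                      mode: str = "observed") -> str:
    """Deepest node of the reference topology whose clade has more matching
    than non-matching-or-gapped leaves.

    ``status_by_leaf`` maps each leaf (sub-category) to "match", "mismatch"
    or "gap"; missing leaves are treated as gaps.  In ``earliest`` mode gaps
    count as matches.  Candidates are restricted to ancestors of the
    matching leaves, so the earliest node is always an ancestor-or-equal of
    the observed one; with no qualifying internal node, the single matching
    leaf is returned.
    """
    if mode not in ("observed", "earliest"):
        raise ValueError(f"unknown mode {mode!r}")
    matches = [l for l in tree.leaf_node_iter()
               if status_by_leaf.get(leaf_label(l), "gap") == "match"]
    if not matches:
        raise ValueError("residue matches no leaf of the reference topology")
    # path from the LCA of the matches up to the root
    node = matches[0]
    if len(matches) > 1:
        labels = {leaf_label(l) for l in matches}
        while node is not None and not labels <= {
                leaf_label(l) for l in node.leaf_iter()}:
            node = node.parent_node
    best = None
    while node is not None:
        n_match = n_against = 0
        for leaf in node.leaf_iter():
            status = status_by_leaf.get(leaf_label(leaf), "gap")
            if status == "match" or (mode == "earliest" and status == "gap"):
                n_match += 1
            else:
                n_against += 1
        if n_match > n_against:
            best = node
        node = node.parent_node
    if best is None:
        best = matches[0]
    return _node_name(best)


def annotate_origin_nodes(calls: Sequence[SharedResidueCall],
                          tree: dendropy.Tree,
                          alignment: Mapping[str, str],
                          donor_set: Sequence[str]) -> None:
    """Fill in observed/earliest origin nodes for each shared-residue call.

    Reference-topology leaves are donor sub-categories; a donor sequence's
    status at the call's column is match / mismatch / gap.
    """
    sub_of = {s: s.split("|", 1)[0] for s in donor_set}
    for call in calls:
        status: dict[str, str] = {}
        for s in donor_set:
            ch = alignment[s][call.column]
            status[sub_of[s]] = ("match" if ch == call.residue
                                 else "gap" if ch == GAP else "mismatch")
        call.origin_node_observed = infer_origin_node(tree, status, "observed")
        call.origin_node_earliest = infer_origin_node(tree, status, "earliest")


# ---------------------------------------------------------------------------
# composition bias and concatenated-alignment tabulation
# ---------------------------------------------------------------------------

def composition_bias_filter(alignment: Mapping[str, str],
                            lineage_a: Sequence[str],
                            lineage_b: Sequence[str],
                            alpha: float = 0.05,
                            ) -> tuple[list[str], dict[str, str]]:
    """Flag amino acids whose frequencies differ between two lineages
    (per-residue 2x2 chi-squared, p <= alpha) and gap them out everywhere."""
    if not lineage_a or not lineage_b:
        raise ValueError("both lineages need at least one sequence")

    def counts(seq_ids: Sequence[str]) -> dict[str, int]:
        c: dict[str, int] = {}
        for sid in seq_ids:
            for ch in alignment[sid]:
                if ch != GAP:
                    c[ch] = c.get(ch, 0) + 1
        return c

    ca, cb = counts(lineage_a), counts(lineage_b)
    total_a, total_b = sum(ca.values()), sum(cb.values())
    flagged: list[str] = []
    for aa in sorted(set(ca) | set(cb)):
        na, nb = ca.get(aa, 0), cb.get(aa, 0)
        table = [[na, total_a - na], [nb, total_b - nb]]
        if min(na + nb, (total_a - na) + (total_b - nb)) == 0:
            logger.info("composition filter: %s degenerate, skipped", aa)
            continue
        stat, p, _, _ = chi2_contingency(table, correction=False)
        if p <= alpha:
            flagged.append(aa)
    flagged_set = set(flagged)
    filtered = {sid: "".join(GAP if ch in flagged_set else ch for ch in row)
                for sid, row in alignment.items()}
    return flagged, filtered


def count_shared_residues_concatenated(
        alignment: Mapping[str, str],
        focal_ids: Sequence[str],
        partner_lineages: Mapping[str, Sequence[str]],
        mode: str = "strict",
        majority_count: int | None = None) -> dict[str, int]:
    """Per-partner-lineage counts of columns uniquely shared with the focal
    set.

    ``strict``: the residue must appear in every focal sequence;
    ``majority``: in at least ``majority_count`` focal sequences (default
    half, rounded up).  The residue must occur in the partner lineage under
    consideration and in no other partner lineage.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown mode {mode!r}")
    if majority_count is None:
        majority_count = (len(focal_ids) + 1) // 2
    ncol = len(next(iter(alignment.values())))
    out = {lin: 0 for lin in partner_lineages}
    for col in range(ncol):
        focal_res = [alignment[s][col] for s in focal_ids]
        ungapped = [r for r in focal_res if r != GAP]
        if mode == "strict":
            if len(set(focal_res)) != 1 or focal_res[0] == GAP:
                continue
            residue = focal_res[0]
        else:
            counts: dict[str, int] = {}
            for r in ungapped:
                counts[r] = counts.get(r, 0) + 1
            if not counts:
                continue
            residue, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            if n < majority_count:
                continue
        holders = [lin for lin, ids in partner_lineages.items()
                   if any(alignment[s][col] == residue for s in ids)]
        if len(holders) == 1:
            out[holders[0]] += 1
    return out
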