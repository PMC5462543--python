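"""Evolutionary origin assignment for HPPGs.

Two independent lines of evidence are combined:

* the *consecutive top-hit* rule — the lineage of the first ranked hit,
  reported as determined only when the first three or more hits resolve in
  the same lineage;
* the *sister-group* rule — after rooting the gene tree on its most
  phylogenetically complex non-focal clade, the origin is the lineage of the
  focal clade's sister, accepted only when the focal lineage is monophyletic,
  exactly one sister exists, and the sister holds at least two sequences
  from at least two sub-categories of a single lineage.

Only agreement of the two yields a combined, high-confidence origin; on
disagreement the call is unresolved (low confidence) and the tree origin is
preferred for annotation when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy

from .core_io import TaxonomyScheme, leaf_label

AMBIGUOUS = "ambiguous"
UNDETERMINED = "undetermined"
UNRESOLVED = "unresolved"


@dataclass
class OriginCall:
    hppg_id: str
    blast_origin: str = AMBIGUOUS
    blast_consecutive: int = 0
    tree_origin: str = UNDETERMINED
    sister_sub_categories: frozenset[str] = frozenset()
    combined_origin: str = UNRESOLVED
    confidence: str = "low"
    annotation: str = ""          # best-effort label for unresolved calls


# ---------------------------------------------------------------------------
# ranked-hit rule
# ---------------------------------------------------------------------------

def blast_top_hit_origin(hit_lineages: Sequence[str],
                         consecutive_min: int = 3) -> tuple[str, int]:
    """Lineage of the rank-1 hit and the length of the maximal same-lineage
    prefix; the origin is ambiguous below ``consecutive_min``."""
    if not hit_lineages:
        return AMBIGUOUS, 0
    first = hit_lineages[0]
    consecutive = 0
    for lin in hit_lineages:
        if lin != first:
            break
        consecutive += 1
    if consecutive >= consecutive_min:
        return first, consecutive
    return AMBIGUOUS, consecutive


def reduced_library_top_hit(hit_lineages: Sequence[str],
                            excluded_lineage: str,
                            consecutive_min: int = 3) -> tuple[str, int]:
    """Top-hit rule after removing hits from the query's own lineage."""
    kept = [lin for lin in hit_lineages if lin != excluded_lineage]
    return blast_top_hit_origin(kept, consecutive_min)


def deeper_affinity_hits(hit_lineages: Sequence[str],
                         primary_origin: str,
                         consecutive_min: int = 3) -> tuple[str, int]:
    """Next-deepest origin from ranked hits: drop the primary-lineage prefix
    and apply the consecutive rule to the suffix."""
    i = 0
    while i < len(hit_lineages) and hit_lineages[i] == primary_origin:
        i += 1
    suffix = [lin for lin in hit_lineages[i:] if lin != primary_origin]
    return blast_top_hit_origin(suffix, consecutive_min)


# ---------------------------------------------------------------------------
# tree rooting and sister groups
# ---------------------------------------------------------------------------

def _leaf_lineage(leaf: dendropy.Node) -> str:
    return getattr(leaf, "lineage", "")


def prune_cash_lineages(tree: dendropy.Tree,
                        taxonomy: TaxonomyScheme) -> dendropy.Tree:
    """Copy of the tree without CASH / chlorarachniophyte / euglenid leaves.

    Origin assignment ignores lineages with histories of serial
    endosymbiosis; they are retained only for the CASH position analysis.
    """
    from .core_io import annotate_tree
    pruned = tree.clone(depth=1)
    drop = [leaf.taxon for leaf in pruned.leaf_node_iter()
            if leaf.taxon is not None
            and taxonomy.lineage_of(leaf_label(leaf).split("|", 1)[0])
            in taxonomy.cash_lineages]
    if drop:
        pruned.prune_taxa(drop)
    return annotate_tree(pruned, taxonomy)


def _leaf_subcat(leaf: dendropy.Node) -> str:
    return getattr(leaf, "sub_category", "")


def root_on_complex_clade(tree: dendropy.Tree,
                          focal_leaf_ids: set[str]) -> dendropy.Tree:
    """Root on the edge whose far side (no focal leaves) contains the most
    distinct lineages (ties: sub-categories, leaves, smallest label).

    The focal clade's own subtending edge is excluded, otherwise the
    complement of the focal clade would always win and the sister group
    would degenerate to the entire rest of the tree.
    """
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    n_focal = sum(1 for l in leaves if leaf_label(l) in focal_leaf_ids)
    candidates = []   # (n lineages, n subcats, n leaves, edge, smallest label)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        below = list(edge.head_node.leaf_iter())
        below_labels = {leaf_label(l) for l in below}
        focal_below = len(below_labels & focal_leaf_ids)
        if focal_below == 0:
            side = below                       # far side is the clade below
        elif focal_below == n_focal:
            if len(below) == focal_below:
                continue                       # the focal clade's own edge
            side = [l for l in leaves if leaf_label(l) not in below_labels]
        else:
            continue                           # focal leaves on both sides
        if not side:
            continue
        lineages = {_leaf_lineage(l) for l in side}
        subcats = {_leaf_subcat(l) for l in side}
        smallest = min(leaf_label(l) for l in side)
        candidates.append(((len(lineages), len(subcats), len(side)),
                           smallest, edge))
    best = None
    if candidates:
        top = max(c[0] for c in candidates)
        best = min((c for c in candidates if c[0] == top),
                   key=lambda c: c[1])[2]
    if best is None:
        raise ValueError("no candidate rooting edge")
    length = best.length or 1.0
    tree.reroot_at_edge(best, length1=length / 2, length2=length / 2,
                        update_bipartitions=True,
                        suppress_unifurcations=True)
    return tree


def _find_monophyletic(tree: dendropy.Tree,
                       leaf_ids: set[str]) -> dendropy.Node | None:
    """Node whose leaf set is exactly ``leaf_ids`` in the rooted tree."""
    for node in tree.preorder_node_iter():
        below = {leaf_label(l) for l in node.leaf_iter()}
        if below == leaf_ids:
            return node
    return None


def tree_sister_origin(tree: dendropy.Tree,
                       focal_leaf_ids: set[str],
                       lineage_of: Callable[[dendropy.Node], str] | None = None,
                       ) -> tuple[str, frozenset[str]]:
    """Origin of the focal clade from its sister group in the rooted tree.

    Returns (lineage or "undetermined", sister sub-categories).
    """
    lineage_of = lineage_of or _leaf_lineage
    present = {leaf_label(l) for l in tree.leaf_node_iter()} & focal_leaf_ids
    if not present:
        raise ValueError("focal clade absent from tree")
    rooted = root_on_complex_clade(tree, present)
    focal = _find_monophyletic(rooted, present)
    if focal is None:
        return UNDETERMINED, frozenset()
    parent = focal.parent_node
    if parent is None:
        return UNDETERMINED, frozenset()
    sisters = [c for c in parent.child_nodes() if c is not focal]
    if len(sisters) != 1:
        return UNDETERMINED, frozenset()
    sister_leaves = list(sisters[0].leaf_iter())
    lineages = {lineage_of(l) for l in sister_leaves}
    subcats = frozenset(_leaf_subcat(l) for l in sister_leaves)
    if len(lineages) != 1 or len(sister_leaves) < 2 or len(subcats) < 2:
        return UNDETERMINED, subcats
    return next(iter(lineages)), subcats


def deeper_affinity_tree(tree: dendropy.Tree,
                         focal_leaf_ids: set[str],
                         ) -> tuple[str, frozenset[str]]:
    """Sister of the (focal + primary sister) clade, under the same
    constraints as the primary sister-group rule."""
    present = {leaf_label(l) for l in tree.leaf_node_iter()} & focal_leaf_ids
    rooted = root_on_complex_clade(tree, present)
    focal = _find_monophyletic(rooted, present)
    if focal is None or focal.parent_node is None:
        return UNDETERMINED, frozenset()
    expanded = {leaf_label(l) for l in focal.parent_node.leaf_iter()}
    node = focal.parent_node
    grand = node.parent_node
    if grand is None:
        return UNDETERMINED, frozenset()
    sisters = [c for c in grand.child_nodes() if c is not node]
    if len(sisters) != 1:
        return UNDETERMINED, frozenset()
    leaves = list(sisters[0].leaf_iter())
    lineages = {_leaf_lineage(l) for l in leaves}
    subcats = frozenset(_leaf_subcat(l) for l in leaves)
    if len(lineages) != 1 or len(leaves) < 2 or len(subcats) < 2:
        return UNDETERMINED, subcats
    return next(iter(lineages)), subcats


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combine_origins(hppg_id: str,
                    blast_call: tuple[str, int],
                    tree_call: tuple[str, frozenset[str]]) -> OriginCall:
    """Union of the two analyses: agreement gives a combined high-confidence
    origin; otherwise unresolved/low, annotated by the tree sister where
    available, else by the top-hit identity."""
    blast_origin, consecutive = blast_call
    tree_origin, subcats = tree_call
    call = OriginCall(hppg_id=hppg_id, blast_origin=blast_origin,
                      blast_consecutive=consecutive, tree_origin=tree_origin,
                      sister_sub_categories=subcats)
    blast_ok = blast_origin != AMBIGUOUS
    tree_ok = tree_origin != UNDETERMINED
    if blast_ok and tree_ok and blast_origin == tree_origin:
        call.combined_origin = blast_origin
        call.confidence = "high"
        call.annotation = blast_origin
    else:
        call.combined_origin = UNRESOLVED
        call.confidence = "low"
        call.annotation = (tree_origin if tree_ok
                           else (blast_origin if blast_ok else ""))
    return call


# ---------------------------------------------------------------------------
# CASH lineage position on the gene tree
# ---------------------------------------------------------------------------

CASH_CATEGORIES = ("internal:diatoms", "internal:hypogyristea",
                   "internal:chrysista", "internal:ambiguous",
                   "external:immediate-sister", "external:within-red",
                   "external:within-green", "external:other")

#: lineages whose clade must span >=2 sub-categories to be recorded
_NEED_TWO_SUBCATS = {"other alveolates", "cryptomonads", "haptophytes"}
#: lineages that must include >=1 plastid-targeted sequence
_NEED_PLASTID = {"dinotoms", "cryptomonads", "haptophytes"}


def _maximal_pure_clades(tree: dendropy.Tree, lineage: str) -> list:
    """Maximal nodes whose leaves are all of ``lineage``."""
    out = []

    def walk(node) -> bool:
        leaves = list(node.leaf_iter())
        if all(_leaf_lineage(l) == lineage for l in leaves):
            return True
        pure_children = []
        for child in node.child_nodes():
            if walk(child):
                pure_children.append(child)
        out.extend(pure_children)
        return False

    root = tree.seed_node
    if walk(root):
        out.append(root)
    return out


def annotate_cash_position(tree: dendropy.Tree,
                           cash_lineage: str,
                           taxonomy: TaxonomyScheme,
                           plastid_targeted: set[str] | None = None,
                           ) -> tuple[str | None, str]:
    """Position of one CASH lineage relative to the ochrophyte clade.

    Returns (category or None, reason).  The position is recorded only when
    the lineage forms a single clade in the rooted tree, spans enough
    sub-categories, and (where required) contains a plastid-targeted
    sequence.
    """
    och_ids = {leaf_label(l) for l in tree.leaf_node_iter()
               if _leaf_lineage(l) == "ochrophytes"}
    if not och_ids:
        raise ValueError("no ochrophyte leaves in tree")
    cash_ids = {leaf_label(l) for l in tree.leaf_node_iter()
                if _leaf_lineage(l) == cash_lineage}
    if not cash_ids:
        return None, "lineage absent"
    rooted = root_on_complex_clade(tree, och_ids | cash_ids)
    clades = _maximal_pure_clades(rooted, cash_lineage)
    if len(clades) != 1:
        return None, f"{len(clades)} evolutionarily distinct groups"
    clade = clades[0]
    leaves = list(clade.leaf_iter())
    subcats = {_leaf_subcat(l) for l in leaves}
    if cash_lineage in _NEED_TWO_SUBCATS and len(subcats) < 2:
        return None, "only one sub-category"
    if cash_lineage in _NEED_PLASTID and plastid_targeted is not None:
        if not any(leaf_label(l) in plastid_targeted for l in leaves):
            return None, "no plastid-targeted sequence"

    # classify by the closest non-CASH context above the clade
    node = clade.parent_node
    while node is not None:
        context = [l for l in node.leaf_iter()
                   if _leaf_lineage(l) not in taxonomy.cash_lineages]
        if context:
            break
        node = node.parent_node
    if node is None:
        return None, "no non-CASH context"
    lineages = {_leaf_lineage(l) for l in context}
    if lineages == {"ochrophytes"}:
        if {leaf_label(l) for l in context} >= och_ids:
            # sister to the complete ochrophyte clade, not inside it
            return "external:immediate-sister", ""
        groups = {taxonomy.group_of(_leaf_subcat(l)) for l in context}
        groups.discard(None)
        if len(groups) == 1:
            return f"internal:{next(iter(groups))}", ""
        return "internal:ambiguous", ""
    if "ochrophytes" in lineages:
        # first context mixes ochrophytes and outgroups: the clade branches
        # between the ochrophytes and the first outgroup
        och_context = [l for l in context if _leaf_lineage(l) == "ochrophytes"]
        if {leaf_label(l) for l in och_context} >= och_ids:
            return "external:immediate-sister", ""
        return "internal:ambiguous", ""
    if lineages == {"red algae"}:
        return "external:within-red", ""
    if lineages == {"green algae"}:
        return "external:within-green", ""
    return "external:other", ""
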