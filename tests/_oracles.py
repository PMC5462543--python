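"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration, quadratic
graph closure, and a textbook Smith-Waterman, sharing no code with the
package internals they validate.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def smith_waterman_score(a: str, b: str, gap_open: float = 11.0,
                         gap_extend: float = 2.0) -> float:
    """Affine-gap local alignment score (Gotoh three-matrix recursion)."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)   # gap in a (vertical)
    F = np.full((n + 1, m + 1), neg)   # gap in b (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def transitive_closure_clusters(items: list[str],
                                related) -> list[frozenset]:
    """Connected components of the symmetric closure of ``related(a, b)``."""
    adj = {x: set() for x in items}
    for a, b in itertools.combinations(items, 2):
        if related(a, b) or related(b, a):
            adj[a].add(b)
            adj[b].add(a)
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen:
            continue
        stack, comp = [x], set()
        while stack:
            y = stack.pop()
            if y in comp:
                continue
            comp.add(y)
            stack.extend(adj[y] - comp)
        seen |= comp
        out.append(frozenset(comp))
    return out


def shared_residue_columns(alignment: dict[str, str], focal: list[str],
                           donors: list[str], exclusions: list[str],
                           focal_fraction: float = 2 / 3) -> list[int]:
    """Exhaustive per-column scan for uniquely shared residues."""
    ncol = len(next(iter(alignment.values())))
    hits = []
    for col in range(ncol):
        f = [alignment[s][col] for s in focal]
        ungapped = [r for r in f if r != "-"]
        if not ungapped:
            continue
        best = None
        for residue in sorted(set(ungapped)):
            share = ungapped.count(residue) / len(ungapped)
            if share >= focal_fraction - 1e-12:
                if best is None or ungapped.count(residue) > ungapped.count(best):
                    best = residue
        if best is None:
            continue
        if not any(alignment[s][col] == best for s in donors):
            continue
        excl = [alignment[s][col] for s in exclusions]
        if best in excl:
            continue
        if all(r == "-" for r in excl):
            continue
        hits.append(col)
    return hits


def chimera_families_bruteforce(intervals: list[tuple[int, int]],
                                fraction: float = 0.70) -> list[frozenset]:
    """Graph closure over the mutual->70% overlap rule, then iterated
    family-level span merging, returned as frozensets of member indices."""

    def overlap(x, y):
        return max(0, min(x[1], y[1]) - max(x[0], y[0]))

    def mutual(x, y):
        ov = overlap(x, y)
        return ov > fraction * (x[1] - x[0]) and ov > fraction * (y[1] - y[0])

    idx = list(range(len(intervals)))
    comps = transitive_closure_clusters(
        [str(i) for i in idx],
        lambda a, b: mutual(intervals[int(a)], intervals[int(b)]))
    fams = [set(int(i) for i in c) for c in comps]

    def span(members):
        return (min(intervals[i][0] for i in members),
                max(intervals[i][1] for i in members))

    changed = True
    while changed:
        changed = False
        fams.sort(key=lambda f: (span(f), len(f)))
        for i in range(len(fams)):
            for j in range(len(fams)):
                if i == j:
                    continue
                sx, sy = span(fams[i]), span(fams[j])
                lx = sx[1] - sx[0]
                if lx and overlap(sx, sy) > fraction * lx:
                    fams[j] |= fams[i]
                    del fams[i]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(f) for f in fams]
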