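"""Enrichment statistics: uniquely shared groups, targeting preferences,
functional categories, neighbour concordance and coexpression.

All observed-vs-expected comparisons use a two-cell goodness-of-fit
chi-squared on [in-category, remainder] against [expected, total-expected]
with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, f_oneway

from .core_io import logger


@dataclass
class EnrichmentResult:
    label: str
    observed: float
    expected: float
    statistic: float
    p: float
    significant: bool

    def __post_init__(self) -> None:
        assert 0 <= self.p <= 1


# ---------------------------------------------------------------------------
# uniquely shared groups between lineage pairs
# ---------------------------------------------------------------------------

def count_unique_shared(presence: Mapping[str, Mapping[str, set[str]]],
                        lineage_pair: tuple[str, str],
                        mode: str,
                        subcats_per_lineage: Mapping[str, int],
                        majority: float = 2 / 3) -> int:
    """Count HPPGs uniquely shared between an ordered (focal, partner) pair.

    ``presence`` maps hppg -> lineage -> sub-categories present; only HPPGs
    present in exactly two of the watched lineages qualify.  Modes:
    ``majority+any`` needs a >=2/3 sub-category majority of the focal
    lineage and >=1 partner sub-category; ``majority+majority`` needs the
    majority on both sides.
    """
    if mode not in ("majority+any", "majority+majority"):
        raise ValueError(f"unknown mode {mode!r}")
    focal, partner = lineage_pair
    count = 0
    for hppg, by_lineage in presence.items():
        involved = {lin for lin, subs in by_lineage.items() if subs}
        if involved != {focal, partner}:
            continue

        def has_majority(lin: str) -> bool:
            total = subcats_per_lineage[lin]
            return len(by_lineage[lin]) / total >= majority - 1e-12

        if not has_majority(focal):
            continue
        if mode == "majority+majority" and not has_majority(partner):
            continue
        count += 1
    return count


def expected_unique_shared(pair_counts: Mapping[tuple[str, str], int],
                           correction: str = "published",
                           ) -> dict[tuple[str, str], float]:
    """Expected uniquely-shared counts per pair under random assortment.

    Involvement proportions ``p_i`` are the fractions of uniquely shared
    groups involving lineage ``i``.  The raw expectation for an ordered
    (focal, partner) pair is ``p_focal * p_partner`` of the total.

    ``correction="published"`` reproduces the published worked example:
    the diagonal mass mistakenly allocated to "shared within the partner
    lineage only" (``p_partner**2``) is excluded and the remainder rescaled,
    i.e. ``E = total * p_f*p_p / (1 - p_p**2)`` — proportions (1/2, 1/2)
    give one third.  ``correction="normalized"`` instead rescales all
    cross-pair products so the expectations sum exactly to the observed
    cross-pair total.
    """
    lineages = sorted({lin for pair in pair_counts for lin in pair})
    if len(lineages) < 2:
        raise ValueError("no cross pairs: need at least two lineages")
    total = sum(pair_counts.values())
    if total == 0:
        return {pair: 0.0 for pair in pair_counts}
    involvement = {lin: 0 for lin in lineages}
    for (a, b), n in pair_counts.items():
        involvement[a] += n
        involvement[b] += n
    p = {lin: involvement[lin] / total for lin in lineages}

    if correction == "published":
        out = {}
        for (f, q) in pair_counts:
            denom = 1.0 - p[q] ** 2
            if denom <= 0:       # partner involved in every group
                out[(f, q)] = float(total * p[f])
            else:
                out[(f, q)] = total * p[f] * p[q] / denom
        return out
    if correction == "normalized":
        # p normalised over involvements (each group contributes two)
        q = {lin: involvement[lin] / (2 * total) for lin in lineages}
        weights = {pair: q[pair[0]] * q[pair[1]] for pair in pair_counts}
        wsum = sum(weights.values())
        if wsum == 0:
            raise ValueError("degenerate involvement proportions")
        return {pair: total * w / wsum for pair, w in weights.items()}
    raise ValueError(f"unknown correction {correction!r}")


def expected_pair_fraction(p_focal: float, p_partner: float) -> float:
    """Corrected expected fraction for one (focal, partner) pair under the
    published correction; (1/2, 1/2) -> 1/3."""
    return p_focal * p_partner / (1.0 - p_partner ** 2)


# ---------------------------------------------------------------------------
# the chi-squared workhorse
# ---------------------------------------------------------------------------

def chi_squared_obs_exp(observed: float, expected: float, total: float,
                        alpha: float = 0.05,
                        label: str = "") -> EnrichmentResult:
    """Two-cell goodness-of-fit: [observed, total-observed] against
    [expected, total-expected], df = 1."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    if total < observed:
        raise ValueError("total smaller than observed")
    if total <= expected:
        raise ValueError("total must exceed expected")
    diff = observed - expected
    stat = diff ** 2 / expected + diff ** 2 / (total - expected)
    p = float(chi2.sf(stat, df=1))
    return EnrichmentResult(label=label, observed=observed, expected=expected,
                            statistic=float(stat), p=p,
                            significant=p < alpha)


# ---------------------------------------------------------------------------
# targeting and category enrichment
# ---------------------------------------------------------------------------

def targeting_enrichment(families: pd.DataFrame,
                         alpha: float = 0.05,
                         origin_column: str = "origin",
                         call_column: str = "plastid",
                         ) -> dict[str, EnrichmentResult]:
    """Per-origin enrichment of plastid-targeting calls.

    Expected count for origin O = total plastid-targeted families x
    (families of origin O / all families); expectations therefore sum to
    the total plastid-targeted count.
    """
    total = len(families)
    plastid_total = int(families[call_column].sum())
    out: dict[str, EnrichmentResult] = {}
    for origin, sub in families.groupby(origin_column):
        n_o = len(sub)
        observed = int(sub[call_column].sum())
        expected = plastid_total * n_o / total
        if expected <= 0 or n_o <= expected:
            logger.info("targeting enrichment for %s skipped (degenerate)",
                        origin)
            continue
        out[origin] = chi_squared_obs_exp(observed, expected, n_o,
                                          alpha=alpha, label=str(origin))
    return out


def category_enrichment(subset_counts: Mapping[str, int],
                        background_counts: Mapping[str, int],
                        alpha: float = 0.05) -> dict[str, EnrichmentResult]:
    """Functional-category (KOG-class style) enrichment of a subset against
    the background distribution."""
    subset_total = sum(subset_counts.values())
    background_total = sum(background_counts.values())
    out: dict[str, EnrichmentResult] = {}
    for cat in sorted(subset_counts):
        if cat not in background_counts:
            logger.info("category %s absent from background, skipped", cat)
            continue
        expected = subset_total * background_counts[cat] / background_total
        if expected <= 0 or subset_total <= expected:
            continue
        out[cat] = chi_squared_obs_exp(subset_counts[cat], expected,
                                       subset_total, alpha=alpha, label=cat)
    return out


# ---------------------------------------------------------------------------
# neighbour-origin concordance
# ---------------------------------------------------------------------------

def neighbour_origin_concordance(pairs: Sequence[tuple[str, str]],
                                 origin_map: Mapping[str, str],
                                 alpha: float = 0.05) -> EnrichmentResult:
    """Do biochemical neighbours share evolutionary origins more often than
    chance?  Expected = n_pairs * sum_o q_o^2 with q the origin proportions
    among proteins appearing in (resolved) pairs."""
    resolved = [(a, b) for a, b in pairs
                if origin_map.get(a) not in (None, "unresolved")
                and origin_map.get(b) not in (None, "unresolved")]
    if len(resolved) < 2:
        raise ValueError("fewer than 2 resolved pairs")
    proteins = [p for pair in resolved for p in pair]
    counts: dict[str, int] = {}
    for p in proteins:
        o = origin_map[p]
        counts[o] = counts.get(o, 0) + 1
    q = {o: n / len(proteins) for o, n in counts.items()}
    expected = len(resolved) * sum(v ** 2 for v in q.values())
    observed = sum(1 for a, b in resolved if origin_map[a] == origin_map[b])
    if observed == expected:
        return EnrichmentResult(label="neighbour concordance",
                                observed=observed, expected=expected,
                                statistic=0.0, p=1.0, significant=False)
    return chi_squared_obs_exp(observed, expected, len(resolved), alpha=alpha,
                               label="neighbour concordance")


# ---------------------------------------------------------------------------
# coexpression by origin
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionSummary:
    class_means: dict[tuple[str, str], float]
    class_values: dict[tuple[str, str], np.ndarray]
    separation_p: dict[tuple[str, str], float]   # (origin, other) -> p
    flagged: list[str]


def coexpression_by_origin(expression: pd.DataFrame,
                           gene_to_origin: Mapping[str, str],
                           alpha: float = 0.05) -> CoexpressionSummary:
    """Pairwise Pearson correlations grouped into origin-pair classes.

    For each origin O a one-way comparison of within-O correlations against
    each O-other class is run; O is *flagged* (origin-specific coregulation)
    only when its within-class mean exceeds every cross-class mean with all
    comparisons significant at a Bonferroni-adjusted level (``alpha``
    divided by the number of separation comparisons in the whole table, so
    ``alpha`` is a family-wise error rate).  Constant expression vectors
    are excluded.
    """
    genes = [g for g in expression.index if g in gene_to_origin]
    data = expression.loc[genes].to_numpy(dtype=float)
    sd = data.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        logger.info("constant expression vectors excluded: %s", dropped)
    genes = [g for g, k in zip(genes, keep) if k]
    data = data[keep]
    if len(genes) < 3:
        raise ValueError("need at least 3 usable genes")
    corr = np.corrcoef(data)
    origins = [gene_to_origin[g] for g in genes]
    classes: dict[tuple[str, str], list[float]] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            key = tuple(sorted((origins[i], origins[j])))
            classes.setdefault(key, []).append(float(corr[i, j]))
    class_values = {k: np.asarray(v) for k, v in classes.items()}
    class_means = {k: float(v.mean()) for k, v in class_values.items()}
    separation_p: dict[tuple[str, str], float] = {}
    comparisons_by_origin: dict[str, list[tuple[str, float]]] = {}
    for origin in sorted(set(origins)):
        within_key = (origin, origin)
        if within_key not in class_values or len(class_values[within_key]) < 2:
            continue
        within = class_values[within_key]
        for other in sorted(set(origins)):
            if other == origin:
                continue
            key = tuple(sorted((origin, other)))
            if key not in class_values or len(class_values[key]) < 2:
                continue
            _stat, p = f_oneway(within, class_values[key])
            separation_p[(origin, other)] = float(p)
            comparisons_by_origin.setdefault(origin, []).append(
                (other, float(p)))
    n_tests = max(1, len(separation_p))
    level = alpha / n_tests
    flagged: list[str] = []
    for origin, comps in comparisons_by_origin.items():
        within = class_values[(origin, origin)]
        if comps and all(
                p < level
                and within.mean() > class_values[
                    tuple(sorted((origin, other)))].mean()
                for other, p in comps):
            flagged.append(origin)
    return CoexpressionSummary(class_means=class_means,
                               class_values=class_values,
                               separation_p=separation_p, flagged=flagged)
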