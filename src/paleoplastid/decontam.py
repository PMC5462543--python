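"""Cross-library contamination removal by identity-distribution thresholding.

Transcriptome libraries assembled side by side can carry each other's
contigs.  For every pair of libraries the distribution of best cross-library
percent identities has a peak at the typical between-species identity; in
the presence of cross-contamination there is a second peak at ~100%.  The
threshold is the minimum between the two peaks; contigs whose best
cross-library identity exceeds it are treated as potential contaminants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import HitRecord, SequenceRecord, logger

N_BINS = 100          # 1-point bins over [0, 100]; 100 falls in the [99,100] bin
HIGH_PEAK_BIN = 99
EVALUE_MAX = 1e-5     # hits weaker than this carry no homology evidence
IDENTITY_FLOOR = 97.0  # verbatim carryover is near-identical; below this a
                       # cross-library match is taken as genuine homology


@dataclass
class IdentityHistogram:
    """Best-cross-library identity histogram for an ordered library pair."""

    library_a: str
    library_b: str
    counts: np.ndarray                       # length 100
    best_identity: dict[str, float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return int(self.counts.sum()) == 0


def _bin_of(identity: float) -> int:
    return min(int(identity), N_BINS - 1)


def pairwise_identity_distribution(
        library_a: Sequence[SequenceRecord],
        library_b: Sequence[SequenceRecord],
        hits: Mapping[str, Sequence[HitRecord]],
        evalue_max: float = EVALUE_MAX) -> IdentityHistogram:
    """One histogram entry per contig of ``library_a`` with >=1 significant
    hit in ``library_b``: the percent identity of its best such hit."""
    if not library_a or not library_b:
        raise ValueError("both libraries must be non-empty")
    b_ids = {rec.seq_id for rec in library_b}
    counts = np.zeros(N_BINS, dtype=int)
    best: dict[str, float] = {}
    for rec in library_a:
        cross = [h for h in hits.get(rec.seq_id, ())
                 if h.subject_id in b_ids and h.evalue <= evalue_max]
        if not cross:
            continue
        top = min(cross, key=lambda h: h.rank)
        best[rec.seq_id] = top.percent_identity
        counts[_bin_of(top.percent_identity)] += 1
    hist = IdentityHistogram(
        library_a=library_a[0].library_id, library_b=library_b[0].library_id,
        counts=counts, best_identity=best)
    if hist.empty:
        logger.info("no cross-library evidence for %s vs %s",
                    hist.library_a, hist.library_b)
    return hist


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Moving average with edge replication, so mass in the terminal
    [99,100] bin is not diluted by the array boundary."""
    pad = window // 2
    padded = np.concatenate([np.repeat(counts[0], pad),
                             counts.astype(float),
                             np.repeat(counts[-1], pad)])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _local_maxima(smoothed: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus report their first bin."""
    maxima = []
    n = len(smoothed)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[j + 1] if j + 1 < n else -np.inf
        if smoothed[i] > 0 and smoothed[i] > left and smoothed[i] > right:
            maxima.append(i)
        i = j + 1
    return maxima


def find_contamination_threshold(hist: IdentityHistogram,
                                 smoothing_window: int = 3) -> int | None:
    """Minimum between the between-species peak and the ~100% peak.

    After moving-average smoothing the lower peak is the highest local
    maximum below the [99,100] region (ties toward the lowest identity) and
    the upper peak is the near-identity mass itself.  The threshold is the
    bin of the valley minimum strictly between them, ties broken toward the
    lowest identity; the valley must lie strictly below both peaks.
    Returns None for empty, unimodal, or no-near-identity histograms.
    """
    if hist.empty:
        return None
    if hist.counts[HIGH_PEAK_BIN] == 0:
        return None                               # no ~100% peak
    smoothed = _smooth(hist.counts, smoothing_window)
    maxima = [m for m in _local_maxima(smoothed) if m < HIGH_PEAK_BIN - 1]
    if not maxima:
        return None                               # unimodal at the top
    lower = max(maxima, key=lambda m: (smoothed[m], -m))
    upper_height = smoothed[HIGH_PEAK_BIN - 1:].max()
    valley = slice(lower + 1, HIGH_PEAK_BIN)
    if valley.start >= valley.stop:
        return None
    rel = int(np.argmin(smoothed[valley]))        # argmin takes the first tie
    threshold = valley.start + rel
    if smoothed[threshold] >= min(smoothed[lower], upper_height):
        return None                               # no genuine valley
    return threshold


@dataclass
class DecontamReport:
    removed: dict[str, list[str]]        # library -> removed seq ids
    totals: dict[str, int]               # library -> contigs before filtering

    def removed_fraction(self, library: str) -> float:
        total = self.totals.get(library, 0)
        return len(self.removed.get(library, [])) / total if total else 0.0

    @property
    def all_removed(self) -> set[str]:
        return {sid for ids in self.removed.values() for sid in ids}


def remove_cross_contaminants(
        libraries: Mapping[str, Sequence[SequenceRecord]],
        hits: Mapping[str, Sequence[HitRecord]],
        thresholds: Mapping[tuple[str, str], int | None],
        histograms: Mapping[tuple[str, str], IdentityHistogram] | None = None,
        coverage: Mapping[str, float] | None = None,
        coverage_ratio_max: float = 0.2,
) -> tuple[dict[str, list[SequenceRecord]], DecontamReport]:
    """Drop contigs whose best cross-library identity exceeds the pair's
    threshold; pairs without a threshold pass through unchanged.

    When per-contig ``coverage`` (RPKM-like abundance) is supplied, the
    higher-coverage copy of a cross-matching pair is retained: a genuine
    contig and its verbatim carryover copy are sequence-identical, so
    abundance is what distinguishes source from contaminant.
    """
    removed: dict[str, list[str]] = {lib: [] for lib in libraries}
    kept: dict[str, list[SequenceRecord]] = {}
    seq_library = {rec.seq_id: lib
                   for lib, recs in libraries.items() for rec in recs}

    def best_cross(rec: SequenceRecord, b: str) -> HitRecord | None:
        cross = [h for h in hits.get(rec.seq_id, ())
                 if seq_library.get(h.subject_id) == b
                 and h.evalue <= EVALUE_MAX]
        return min(cross, key=lambda h: h.rank) if cross else None

    for lib, recs in libraries.items():
        kept[lib] = []
        for rec in recs:
            contaminated = False
            for (a, b), thr in thresholds.items():
                if thr is None or a != lib:
                    continue
                top = best_cross(rec, b)
                if top is None or top.percent_identity <= thr:
                    continue
                if top.percent_identity < IDENTITY_FLOOR:
                    continue     # not near-identical, so not carryover
                if coverage is not None:
                    own = coverage.get(rec.seq_id)
                    partner = coverage.get(top.subject_id)
                    # carryover contamination is far below the genuine copy;
                    # near-equal abundance means two genuine contigs
                    if own is not None and partner is not None \
                            and own >= coverage_ratio_max * partner:
                        continue
                contaminated = True
                break
            if contaminated:
                removed[lib].append(rec.seq_id)
            else:
                kept[lib].append(rec)
    report = DecontamReport(
        removed=removed,
        totals={lib: len(recs) for lib, recs in libraries.items()})
    return kept, report


def decontaminate(libraries: Mapping[str, Sequence[SequenceRecord]],
                  hits: Mapping[str, Sequence[HitRecord]],
                  smoothing_window: int = 3,
                  coverage: Mapping[str, float] | None = None,
                  coverage_ratio_max: float = 0.2,
                  ) -> tuple[dict[str, list[SequenceRecord]], DecontamReport]:
    """Full procedure over every ordered library pair."""
    libs = sorted(libraries)
    histograms: dict[tuple[str, str], IdentityHistogram] = {}
    thresholds: dict[tuple[str, str], int | None] = {}
    for a in libs:
        for b in libs:
            if a == b or not libraries[a] or not libraries[b]:
                continue
            hist = pairwise_identity_distribution(libraries[a], libraries[b],
                                                  hits)
            histograms[(a, b)] = hist
            thresholds[(a, b)] = find_contamination_threshold(
                hist, smoothing_window)
    return remove_cross_contaminants(libraries, hits, thresholds, histograms,
                                     coverage, coverage_ratio_max)
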