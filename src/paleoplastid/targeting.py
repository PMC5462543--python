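"""Targeting prediction, the dual-targeting screen, and family consensus.

Real analyses use external plastid predictors (ASAFind/HECTAR-style) and a
mitochondrial presequence predictor (Mitofates-style).  Those tools stay
outside this package: their outputs are accepted as TSV adapters.  A
built-in rule-based predictor matching the synthetic presequence grammar
(hydrophobic signal region then an ASAFAP-like motif) is provided so the
pipeline runs end-to-end on generated data.

The dual-targeting screen scores both the full-length N-terminus and, when
a methionine exists at positions 2-31 of the precursor, the alternative
N-terminus starting at the first such methionine; a protein is called dual
when it is plastid-targeted and either score reaches the cutoff (0.35).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .core_io import SequenceRecord, logger
from .synthetic_data import rule_based_mito_score

_MOTIF = re.compile(r"ASAF[AG]P")
_HYDROPHOBIC = set("FLIVAMW")

MITO_SCORE_CUTOFF = 0.35
DOWNSTREAM_MET_WINDOW = 30     # residues after the initiator methionine
SEARCH_WINDOW = 60             # motif must occur within this N-terminal span


@dataclass
class TargetingPrediction:
    seq_id: str
    plastid_call: bool
    plastid_score: float = 0.0
    mito_score_full: float = 0.0
    mito_score_downstream: float | None = None
    dual_call: bool = False

    @property
    def best_mito_score(self) -> float:
        scores = [self.mito_score_full]
        if self.mito_score_downstream is not None:
            scores.append(self.mito_score_downstream)
        return max(scores)


def _has_signal_region(prefix: str) -> bool:
    """A run of >=6 hydrophobic residues starting within the first 15."""
    run = 0
    for i, ch in enumerate(prefix[:24]):
        if ch in _HYDROPHOBIC:
            run += 1
            if run >= 6 and i - run + 1 <= 15:
                return True
        else:
            run = 0
    return False


def predict_plastid(record: SequenceRecord) -> TargetingPrediction:
    """Built-in plastid-targeting call from the presequence grammar.

    True when an N-terminal hydrophobic signal region is followed by an
    ASAFAP-like motif within the first ~60 residues.
    """
    seq = record.residues
    m = _MOTIF.search(seq[:SEARCH_WINDOW + 6])
    call = bool(m) and m.start() >= 8 and _has_signal_region(seq[1:m.start()]
                                                             if m else "")
    score = 1.0 if call else 0.0
    return TargetingPrediction(seq_id=record.seq_id, plastid_call=call,
                               plastid_score=score)


def read_predictions_tsv(path: str | Path) -> dict[str, TargetingPrediction]:
    """Adapter for external predictor output: TSV of
    ``seq_id  tool_name  call  score`` (call in {0,1,true,false})."""
    out: dict[str, TargetingPrediction] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                logger.warning("targeting TSV row skipped (needs 4 columns): %r",
                               line)
                continue
            sid, _tool, call, score = parts[0], parts[1], parts[2], parts[3]
            out[sid] = TargetingPrediction(
                seq_id=sid,
                plastid_call=call.lower() in ("1", "true", "yes", "plastid"),
                plastid_score=float(score))
    return out


def downstream_met_start(seq: str,
                         window: int = DOWNSTREAM_MET_WINDOW) -> int | None:
    """0-based index of the first methionine at precursor positions 2..1+window
    (1-based 2..31 with the default window), or None."""
    segment = seq[1:1 + window]
    pos = segment.find("M")
    return 1 + pos if pos >= 0 else None


def screen_dual_targeting(record: SequenceRecord,
                          mito_scorer: Callable[[str], float]
                          = rule_based_mito_score,
                          plastid: TargetingPrediction | None = None,
                          cutoff: float = MITO_SCORE_CUTOFF,
                          window: int = DOWNSTREAM_MET_WINDOW
                          ) -> TargetingPrediction:
    """Score the full N-terminus and the next-downstream-methionine variant;
    apply the dual-targeting rule."""
    if plastid is None:
        plastid = predict_plastid(record)
    full = float(mito_scorer(record.residues))
    start = downstream_met_start(record.residues, window)
    downstream = (float(mito_scorer(record.residues[start:]))
                  if start is not None else None)
    pred = TargetingPrediction(
        seq_id=record.seq_id, plastid_call=plastid.plastid_call,
        plastid_score=plastid.plastid_score, mito_score_full=full,
        mito_score_downstream=downstream)
    pred.dual_call = pred.plastid_call and pred.best_mito_score >= cutoff
    return pred


def classify(pred: TargetingPrediction,
             cutoff: float = MITO_SCORE_CUTOFF) -> str:
    """Single localisation label for consensus building."""
    if pred.dual_call:
        return "dual"
    if pred.plastid_call:
        return "plastid"
    if pred.best_mito_score >= cutoff:
        return "mito"
    return "none"


def family_targeting_consensus(predictions: Sequence[TargetingPrediction],
                               family_size_class: str = "ochrophyte",
                               consensus_fraction: float = 2 / 3,
                               cutoff: float = MITO_SCORE_CUTOFF) -> str:
    """Consensus localisation of one gene family.

    Ochrophyte families: the call must be the plurality AND held by >=2/3 of
    members.  Small (three-member, haptophyte-style) families: the >=2/3
    rule alone.  Anything else is "unassigned".
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    labels = [classify(p, cutoff) for p in predictions]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    leaders = sorted(lab for lab, n in counts.items() if n == best)
    n = len(labels)
    if family_size_class == "haptophyte":
        for lab in leaders:
            if counts[lab] / n >= consensus_fraction:
                return lab
        return "unassigned"
    if len(leaders) != 1:            # tie: no plurality
        return "unassigned"
    lab = leaders[0]
    if counts[lab] / n >= consensus_fraction:
        return lab
    return "unassigned"


def predict_all(records: Iterable[SequenceRecord],
                external: Mapping[str, TargetingPrediction] | None = None,
                mito_scorer: Callable[[str], float] = rule_based_mito_score,
                cutoff: float = MITO_SCORE_CUTOFF,
                window: int = DOWNSTREAM_MET_WINDOW
                ) -> dict[str, TargetingPrediction]:
    """Plastid + dual predictions for a set of records; external predictor
    calls override the built-in plastid rule where present."""
    out: dict[str, TargetingPrediction] = {}
    for rec in records:
        base = None
        if external is not None:
            base = external.get(rec.seq_id)
            if base is None:
                logger.info("%s missing from external predictions; "
                            "treated as not predicted", rec.seq_id)
        if base is None:
            base = predict_plastid(rec)
        out[rec.seq_id] = screen_dual_targeting(
            rec, mito_scorer, plastid=base, cutoff=cutoff, window=window)
    return out
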