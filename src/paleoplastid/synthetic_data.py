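"""Synthetic multi-lineage protein datasets with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without any real sequence data:

* a reference taxonomy with eleven ochrophyte sub-categories in three groups
  plus CASH and outgroup lineages (one species/library per sub-category);
* protein families of designated donor origin (red algae, green algae,
  aplastidic stramenopiles, prokaryotes).  Each family evolves along a gene
  tree in which the ochrophyte clade nests *inside* the donor lineage's
  clade, so both the ranked-hit signal (consecutive same-lineage top hits)
  and the tree signal (donor sister-group) point at the planted origin;
* N-terminal presequences: a hydrophobic signal region followed by an
  "ASAFAP"-like motif for plastid-targeted members, an arginine/lysine-rich
  leader for mitochondrial ones, and an internal downstream methionine
  giving an R/K-rich alternative N-terminus for dually targeted members;
* verbatim cross-library contamination, fused chimeric proteins joining
  mature domains of two families with different origins, truncated members,
  and an expression matrix whose correlation blocks are independent of
  origin (a planted null for the coexpression analysis);
* a deterministic similarity scorer standing in for BLASTp: best local
  alignment under BLOSUM62 with affine gaps, Karlin-Altschul style bitscore
  ``(lambda*S - ln K)/ln 2`` and e-value ``m*n*2**(-bitscore)``.

The same seed always produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import (AMINO_ACIDS, GAP, HitRecord, SequenceRecord,
                      TaxonomyScheme, default_taxonomy, logger, rank_hits,
                      write_alignment, write_fasta, write_hit_table)

# species (= library) per sub-category
SPECIES: dict[str, str] = {
    "px": "Esil", "raphidophytes": "Haka", "pesc": "Ngad",
    "pelagophytes": "Aano", "dictyochophytes": "Dspe", "bolidophytes": "Bpra",
    "corethron": "Ccor", "radial_centrics": "Rset", "thalassiosirales": "Tpse",
    "odontellids": "Oaur", "pennates": "Ptri",
    "cryptomonads_a": "Gthe", "cryptomonads_b": "Rsal",
    "pavlovophytes": "Plut", "prymnesiales": "Ctob", "isochrysidales": "Ehux",
    "dinotoms": "Gfol", "dinoflagellates": "Smin",
    "euglenids": "Egra", "chlorarachniophytes": "Bnat",
    "cyanidiales": "Cmer", "florideophytes": "Chon",
    "porphyridiophytes": "Ppur", "rhodellophytes": "Rvio",
    "stylonematophytes": "Shin",
    "prasinodermophytes": "Pcol", "mamiellophytes": "Otau",
    "chlorophyceae": "Crei", "trebouxiophytes": "Cvar", "streptophytes": "Atha",
    "glaucophytes": "Cpar",
    "oomycetes": "Psoj", "labyrinthulomycetes": "Alim", "slopalinids": "Bhom",
    "amoebozoa": "Ddis", "opisthokonts": "Scer",
    "cyanobacteria": "Syne", "proteobacteria": "Ecol", "actinobacteria": "Mtub",
    "ncldv": "Mimi",
}

#: seed retention preference (genome species), most preferred first
ORGANISM_PRECEDENCE = ("Ptri", "Tpse", "Ccor", "Rset", "Oaur", "Aano",
                       "Esil", "Ngad", "Haka", "Dspe", "Bpra")

ORIGIN_CODES = {"red algae": "red", "green algae": "grn",
                "aplastidic stramenopiles": "host", "prokaryotes": "prok"}

# branch-length units: ochrophyte-internal edges are short relative to the
# stem and outgroup edges, so in-group hits always outrank the outgroup cap;
# deep rooting outgroups are pushed further out so donor-lineage hits always
# outrank them in turn
OCH_EDGE = 0.7
OUT_EDGE = 1.8
DEEP_EDGE = 5.0

#: libraries backed by complete genomes: seed sequences come from these;
#: contaminants and fused proteins are planted in transcriptome libraries
GENOME_SPECIES = ("Ptri", "Tpse", "Rset", "Aano", "Ngad", "Esil")

_HYDROPHOBIC = "FLIVAM"

# BLOSUM62 background amino-acid frequencies (order follows AMINO_ACIDS);
# under these the expected score of a random aligned pair is negative, so
# unrelated sequences do not accumulate positive local alignments
_BG = np.array([0.078, 0.024, 0.052, 0.059, 0.044, 0.083, 0.025, 0.062,
                0.056, 0.092, 0.024, 0.041, 0.043, 0.034, 0.051, 0.059,
                0.055, 0.072, 0.014, 0.034])
_BG = _BG / _BG.sum()


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.choice(20, n, p=_BG)])


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------

def _default_families() -> dict[str, int]:
    return {"red algae": 10, "green algae": 6,
            "aplastidic stramenopiles": 5, "prokaryotes": 5}


def _default_plastid_fractions() -> dict[str, float]:
    return {"red algae": 0.85, "green algae": 0.80,
            "aplastidic stramenopiles": 0.35, "prokaryotes": 0.35}


@dataclass
class SimulationParams:
    """Knobs of the generator; the defaults define the study conditions."""

    seed: int = 0
    families_per_origin: dict[str, int] = field(default_factory=_default_families)
    plastid_fraction_per_origin: dict[str, float] = field(
        default_factory=_default_plastid_fractions)
    substitution_rate_per_branch: float = 0.05   # per site per branch unit
    indel_rate: float = 0.004                    # events per site per branch unit
    contamination_rate: float = 0.02             # per ochrophyte contig
    fusion_count: int = 6
    presequence_length_range: tuple[int, int] = (30, 50)
    expression_block_correlation: float = 0.6
    mature_length: int = 240
    subcat_presence_prob: float = 0.9
    dual_fraction: float = 0.15                  # of plastid families
    mito_fraction: float = 0.10                  # of non-plastid families
    presequence_dropout: float = 0.05            # per member
    truncated_member_rate: float = 0.04
    cash_internal_fraction: float = 0.25         # haptophytes inside hypogyristea
    cash_external_fraction: float = 0.15         # haptophytes sister to ochrophytes
    n_conditions: int = 24
    n_expression_blocks: int = 5

    def validate(self) -> None:
        probs = [self.contamination_rate, self.subcat_presence_prob,
                 self.dual_fraction, self.mito_fraction,
                 self.presequence_dropout, self.truncated_member_rate,
                 self.cash_internal_fraction, self.cash_external_fraction,
                 *self.plastid_fraction_per_origin.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0,1]")
        if any(n < 0 for n in self.families_per_origin.values()):
            raise ValueError("family counts must be non-negative")
        if not -1 <= self.expression_block_correlation <= 1:
            raise ValueError("expression_block_correlation must be in [-1,1]")
        lo, hi = self.presequence_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad presequence_length_range")


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per emitted sequence, one per family."""

    sequences: pd.DataFrame   # index seq_id
    families: pd.DataFrame    # index family id

    def origin_of_family(self, family: str) -> str:
        return self.families.loc[family, "origin"]


@dataclass
class SyntheticDataset:
    params: SimulationParams
    taxonomy: TaxonomyScheme
    records: list[SequenceRecord]
    hits: dict[str, list[HitRecord]]
    alignments: dict[str, dict[str, str]]   # family -> seq_id -> aligned row
    trees: dict[str, str]                   # family -> newick
    expression: pd.DataFrame                # family x condition
    coverage: dict[str, float]              # per-contig RPKM-like abundance
    truth: SyntheticTruth

    def records_by_library(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.library_id, []).append(rec)
        return out

    def record(self, seq_id: str) -> SequenceRecord:
        if not hasattr(self, "_index"):
            self._index = {r.seq_id: r for r in self.records}
        return self._index[seq_id]

    def write(self, outdir: str | Path) -> list[Path]:
        """Write every artefact as plain text; deterministic file order."""
        outdir = Path(outdir)
        (outdir / "libraries").mkdir(parents=True, exist_ok=True)
        (outdir / "alignments").mkdir(exist_ok=True)
        (outdir / "trees").mkdir(exist_ok=True)
        written: list[Path] = []
        for lib, recs in sorted(self.records_by_library().items()):
            p = outdir / "libraries" / f"{lib}.fasta"
            write_fasta(recs, p)
            written.append(p)
        p = outdir / "hits.tsv"
        write_hit_table(self.hits, p)
        written.append(p)
        for fam in sorted(self.alignments):
            p = outdir / "alignments" / f"{fam}.afa"
            write_alignment(self.alignments[fam], p)
            written.append(p)
        for fam in sorted(self.trees):
            p = outdir / "trees" / f"{fam}.nwk"
            p.write_text(self.trees[fam] + "\n")
            written.append(p)
        p = outdir / "expression.tsv"
        self.expression.to_csv(p, sep="\t")
        written.append(p)
        p = outdir / "coverage.tsv"
        with open(p, "w") as fh:
            fh.write("seq_id\trpkm\n")
            for sid in sorted(self.coverage):
                fh.write(f"{sid}\t{self.coverage[sid]:.4f}\n")
        written.append(p)
        p = outdir / "truth_sequences.tsv"
        self.truth.sequences.to_csv(p, sep="\t")
        written.append(p)
        p = outdir / "truth_families.tsv"
        self.truth.families.to_csv(p, sep="\t")
        written.append(p)
        return written


# ---------------------------------------------------------------------------
# similarity scorer (BLASTp stand-in)
# ---------------------------------------------------------------------------

@dataclass
class ScoringParams:
    """Local-alignment scoring; Karlin-Altschul constants for gapped BLOSUM62."""

    gap_open: float = 11.0
    gap_extend: float = 2.0
    lambda_: float = 0.267
    k: float = 0.041
    max_evalue: float = 10.0
    word_size: int = 4
    min_shared_words: int = 3   # 0 disables the word prefilter (align all pairs)
    xdrop: float = 35.0


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _alignment_columns(aln, matrix, gap_open: float, gap_extend: float):
    """Flatten one local alignment into per-column records
    ``(score, qpos, spos, match)`` with affine gap costs."""
    qblocks, sblocks = aln.aligned
    qseq, sseq = str(aln.target), str(aln.query)
    cols = []
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_qe is not None:
            for k, qpos in enumerate(range(prev_qe, qs)):      # gap in subject
                cost = -(gap_open if k == 0 else gap_extend)
                cols.append((cost, qpos, None, False))
            for k, spos in enumerate(range(prev_se, ss)):      # gap in query
                cost = -(gap_open if k == 0 else gap_extend)
                cols.append((cost, None, spos, False))
        for qpos, spos in zip(range(qs, qe), range(ss, se)):
            a, b = qseq[qpos], sseq[spos]
            cols.append((float(matrix[a, b]), qpos, spos, a == b))
        prev_qe, prev_se = qe, se
    return cols


def _segment_alignment(cols, xdrop: float = 35.0, max_gap_run: int = 10,
                       window: int = 20, min_bad_run: int = 15):
    """Split an alignment path into maximal high-scoring segments.

    Three BLAST-like rules apply: (a) a long gap run (> ``max_gap_run``
    columns) ends a segment; (b) a sustained negative-similarity stretch —
    every ``window``-column sum negative across at least ``min_bad_run``
    consecutive offsets — ends a segment, since genuine HSPs score
    positively on average while random bridges between two homologous
    regions do not; (c) within a chunk, X-drop semantics close a segment
    once the running score falls ``xdrop`` below its maximum (or to zero).

    Yields (score, identities, columns, query_interval, subject_interval).
    """
    chunks: list[list] = [[]]
    gap_run = 0
    for c in cols:
        if c[1] is None or c[2] is None:
            gap_run += 1
            if gap_run > max_gap_run:
                if chunks[-1]:
                    chunks.append([])
                continue
        else:
            gap_run = 0
        chunks[-1].append(c)
    for chunk in chunks:
        for piece in _split_negative_stretches(chunk, window, min_bad_run):
            yield from _segment_chunk(piece, xdrop)


def _split_negative_stretches(cols, window: int, min_bad_run: int):
    n = len(cols)
    if n <= 2 * window:
        return [cols]
    scores = np.array([c[0] for c in cols], dtype=float)
    sums = np.convolve(scores, np.ones(window), mode="valid")
    bad = sums < 0
    pieces = []
    start = 0
    i = 0
    while i < len(bad):
        if bad[i]:
            j = i
            while j < len(bad) and bad[j]:
                j += 1
            if j - i >= min_bad_run:     # sustained negative stretch
                pieces.append(cols[start:i])
                start = j + window - 1
                i = j
                continue
            i = j
        else:
            i += 1
    pieces.append(cols[start:])
    return [p for p in pieces if p]


def _segment_chunk(cols, xdrop: float):
    i = 0
    n = len(cols)
    while i < n:
        cur = 0.0
        best = 0.0
        best_end = -1
        j = i
        while j < n:
            cur += cols[j][0]
            if cur > best:
                best, best_end = cur, j
            if cur <= 0 or best - cur > xdrop:
                break
            j += 1
        if best > 0 and best_end >= i:
            seg = cols[i:best_end + 1]
            qpos = [c[1] for c in seg if c[1] is not None]
            spos = [c[2] for c in seg if c[2] is not None]
            if qpos and spos:
                ident = sum(1 for c in seg if c[3])
                yield (best, ident, len(seg),
                       (min(qpos), max(qpos) + 1), (min(spos), max(spos) + 1))
            i = best_end + 1
        else:
            i = j + 1 if j >= i else i + 1
        # skip any non-positive run
        while i < n and cols[i][0] <= 0:
            i += 1


def _candidate_pairs(records: Sequence[SequenceRecord],
                     params: ScoringParams) -> Iterable[tuple[int, int]]:
    if params.min_shared_words <= 0:
        n = len(records)
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j
        return
    k = params.word_size
    index: dict[str, list[int]] = {}
    words: list[set[str]] = []
    for i, rec in enumerate(records):
        w = {rec.residues[p:p + k] for p in range(len(rec.residues) - k + 1)}
        words.append(w)
        for word in w:
            index.setdefault(word, []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for word, members in index.items():
        if len(members) < 2:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (members[a], members[b])
                shared[key] = shared.get(key, 0) + 1
    for (i, j), n in sorted(shared.items()):
        if n >= params.min_shared_words:
            yield i, j


def compute_similarity_scores(
        records: Sequence[SequenceRecord],
        params: ScoringParams | None = None) -> dict[str, list[HitRecord]]:
    """All-vs-all ranked hit table from exact local alignment.

    Self-hits are excluded, sequences shorter than 3 residues skipped with a
    warning, and pairs with no positive-scoring local alignment produce no
    hit.  Output lists satisfy the HitRecord ordering invariants.
    """
    if params is None:
        params = ScoringParams()
    usable = []
    for rec in records:
        if len(rec.residues) < 3:
            logger.warning("%s: shorter than 3 residues, skipped", rec.seq_id)
            continue
        usable.append(rec)
    if len(usable) < 2:
        raise ValueError("need at least 2 usable sequences")
    aligner = _make_aligner(params)
    matrix = aligner.substitution_matrix
    ln2 = np.log(2.0)
    raw: dict[str, list[HitRecord]] = {rec.seq_id: [] for rec in usable}
    for i, j in _candidate_pairs(usable, params):
        a, b = usable[i], usable[j]
        alns = aligner.align(a.residues, b.residues)
        if alns.score <= 0:
            continue
        cols = _alignment_columns(alns[0], matrix,
                                  params.gap_open, params.gap_extend)
        for score, ident, columns, q_int, s_int in _segment_alignment(
                cols, xdrop=params.xdrop):
            bitscore = (params.lambda_ * score - np.log(params.k)) / ln2
            evalue = float(len(a) * len(b) * 2.0 ** (-bitscore))
            if evalue > params.max_evalue:
                continue
            pident = 100.0 * ident / columns
            raw[a.seq_id].append(HitRecord(
                query_id=a.seq_id, subject_id=b.seq_id, rank=0,
                percent_identity=pident, query_interval=q_int,
                subject_interval=s_int, evalue=evalue, bitscore=float(bitscore)))
            raw[b.seq_id].append(HitRecord(
                query_id=b.seq_id, subject_id=a.seq_id, rank=0,
                percent_identity=pident, query_interval=s_int,
                subject_interval=q_int, evalue=evalue, bitscore=float(bitscore)))
    return {q: rank_hits(hits) for q, hits in raw.items() if hits}


# ---------------------------------------------------------------------------
# sequence evolution with alignment tracking
# ---------------------------------------------------------------------------

class _Evolver:
    """Evolves a root sequence along a nested-tuple tree, tracking homology.

    A sequence is a list of ``(column_id, residue)``; insertions mint new
    column ids spliced into a master column order so that the final leaf
    rows form a consistent multiple alignment.
    """

    def __init__(self, rng: np.random.Generator, sub_rate: float,
                 indel_rate: float):
        self.rng = rng
        self.sub_rate = sub_rate
        self.indel_rate = indel_rate
        self.order: list[int] = []
        self._next_col = 0

    def new_column(self, after_index: int | None) -> int:
        cid = self._next_col
        self._next_col += 1
        if after_index is None:
            self.order.append(cid)
        else:
            self.order.insert(after_index + 1, cid)
        return cid

    def root(self, residues: str) -> list[tuple[int, str]]:
        return [(self.new_column(None), r) for r in residues]

    def _mutate(self, seq: list[tuple[int, str]],
                length: float) -> list[tuple[int, str]]:
        rng = self.rng
        p_sub = min(0.9, self.sub_rate * length)
        out = []
        for cid, res in seq:
            if rng.random() < p_sub:
                res = AMINO_ACIDS[rng.choice(20, p=_BG)]
            out.append((cid, res))
        n_events = rng.poisson(self.indel_rate * length * max(1, len(out)))
        for _ in range(n_events):
            if not out:
                break
            k = int(rng.integers(1, 4))
            if rng.random() < 0.5:          # deletion
                pos = int(rng.integers(0, len(out)))
                del out[pos:pos + k]
            else:                           # insertion
                pos = int(rng.integers(0, len(out)))
                anchor = self.order.index(out[pos][0])
                for step in range(k):
                    cid = self.new_column(anchor + step)
                    out.insert(pos + 1 + step,
                               (cid, AMINO_ACIDS[rng.choice(20, p=_BG)]))
        return out

    def evolve(self, tree, seq: list[tuple[int, str]],
               out: dict[str, list[tuple[int, str]]]) -> None:
        """``tree`` is a leaf label or ``(length, children...)`` tuple."""
        if isinstance(tree, str):
            out[tree] = seq
            return
        length = tree[0]
        mutated = self._mutate(seq, length)
        for child in tree[1:]:
            self.evolve(child, list(mutated), out)

    def rows(self, leaves: Mapping[str, list[tuple[int, str]]]) -> dict[str, str]:
        pos = {cid: i for i, cid in enumerate(self.order)}
        used = sorted({cid for seq in leaves.values() for cid, _ in seq},
                      key=pos.__getitem__)
        col_index = {cid: i for i, cid in enumerate(used)}
        rows = {}
        for name, seq in leaves.items():
            row = [GAP] * len(used)
            for cid, res in seq:
                row[col_index[cid]] = res
            rows[name] = "".join(row)
        return rows


# ---------------------------------------------------------------------------
# gene-tree templates
# ---------------------------------------------------------------------------

def _och_template(present: set[str], hap_internal: bool):
    """Ochrophyte clade as nested (length, children...) tuples; haptophyte
    clade optionally nested sister to the pelagophyte+dictyochophyte pair."""
    e = OCH_EDGE

    def leaf(sub):
        return (e, sub) if sub in present else None

    def node(*children):
        kids = [c for c in children if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return (e, *kids)

    chrysista = node(leaf("px"), node(leaf("raphidophytes"), leaf("pesc")))
    pd_pair = node(leaf("pelagophytes"), leaf("dictyochophytes"))
    if hap_internal and pd_pair is not None:
        pd_pair = node(pd_pair, _hap_template())
    hypo = node(pd_pair, leaf("bolidophytes"))
    diatoms = node(leaf("corethron"),
                   node(leaf("radial_centrics"),
                        node(leaf("thalassiosirales"),
                             node(leaf("odontellids"), leaf("pennates")))))
    return node(chrysista, node(hypo, diatoms))


def _hap_template():
    e = OCH_EDGE
    return (e, (e, (e, "pavlovophytes"), (e, "prymnesiales")),
            (e, "isochrysidales"))


def _origin_template(origin: str, och, hap_external: bool):
    """Full gene tree: ochrophytes nested inside the donor lineage's clade,
    with deeper outgroup taxa for rooting."""
    e = OUT_EDGE
    d = DEEP_EDGE
    if hap_external:
        och = (e, och, _hap_template())
    if origin == "red algae":
        core = (e, (e, "cyanidiales"),
                (e, (e, "florideophytes"),
                 (e, (e, (e, "porphyridiophytes"), (e, "rhodellophytes")), och)))
        return (e, (d, "cyanobacteria"), (d, "proteobacteria"),
                (e, (d, "glaucophytes"), core))
    if origin == "green algae":
        reds = (d, (e, "glaucophytes"),
                (e, (e, "cyanidiales"), (e, "florideophytes"),
                 (e, "porphyridiophytes")))
        greens = (e, (e, "streptophytes"),
                  (e, (e, "prasinodermophytes"),
                   (e, (e, "mamiellophytes"),
                    (e, (e, (e, "chlorophyceae"), (e, "trebouxiophytes")), och))))
        return (e, (d, "cyanobacteria"), (d, "proteobacteria"), (e, reds, greens))
    if origin == "aplastidic stramenopiles":
        return (e, (d, "cyanobacteria"),
                (d, (e, "amoebozoa"), (e, "opisthokonts")),
                (e, (e, "slopalinids"),
                 (e, (e, (e, "oomycetes"), (e, "labyrinthulomycetes")), och)))
    if origin == "prokaryotes":
        return (e, (d, (e, "amoebozoa"), (e, "opisthokonts")),
                (e, (e, "proteobacteria"),
                 (e, (e, (e, "cyanobacteria"), (e, "actinobacteria")), och)))
    raise ValueError(f"no gene-tree template for origin {origin!r}")


def _template_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree[1:]:
        out.extend(_template_leaves(child))
    return out


def _template_newick(tree, labels: Mapping[str, str]) -> str:
    def walk(node) -> str:
        if isinstance(node, str):
            return labels[node]
        parts = ",".join(walk(c) for c in node[1:])
        return f"({parts})"

    return walk(tree) + ";"


# ---------------------------------------------------------------------------
# presequences and the built-in mitochondrial scorer
# ---------------------------------------------------------------------------

def make_plastid_presequence(rng: np.random.Generator, lo: int, hi: int,
                             dual: bool = False) -> str:
    """Signal region then an ASAFAP-like motif, total length in [lo, hi].

    Dual-targeted presequences carry an internal methionine followed by an
    R/K-rich stretch, so the downstream-methionine rescan finds a strong
    mitochondrial signal.
    """
    target = int(rng.integers(lo, hi + 1))
    signal = "".join(rng.choice(list(_HYDROPHOBIC), 9))
    core = "M" + signal
    if dual:
        core += "M" + "".join(rng.choice(list("RRKKLSA"), 12))
    motif = "ASAF" + ("A" if rng.random() < 0.5 else "G") + "P"
    filler_len = max(0, target - len(core) - len(motif))
    filler = "".join(rng.choice(list("STAGPQNH"), filler_len))
    return core + filler + motif


def make_mito_presequence(rng: np.random.Generator) -> str:
    return "M" + "".join(rng.choice(list("RKLSRKAT"), 24))


def rule_based_mito_score(n_terminus: str) -> float:
    """Composition score in [0,1] of an N-terminus: net positive charge of
    the first 20 residues, scaled.  Synthetic stand-in for a mitochondrial
    presequence predictor."""
    window = n_terminus[:20]
    pos = sum(window.count(c) for c in "RK")
    neg = sum(window.count(c) for c in "DE")
    return float(min(1.0, max(0.0, (pos - neg) / 6.0)))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _seq_id(sub: str, local: str) -> str:
    return f"{sub}|{SPECIES[sub]}|{local}"


def simulate_dataset(params: SimulationParams,
                     taxonomy: TaxonomyScheme | None = None,
                     scoring: ScoringParams | None = None) -> SyntheticDataset:
    """Generate sequences, hits, alignments, trees, expression and truth."""
    params.validate()
    if sum(params.families_per_origin.values()) == 0:
        raise ValueError("empty design: families_per_origin is all zero")
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.presequence_length_range

    records: list[SequenceRecord] = []
    alignments: dict[str, dict[str, str]] = {}
    trees: dict[str, str] = {}
    seq_rows: list[dict] = []
    fam_rows: list[dict] = []
    och_subs = taxonomy.ochrophyte_sub_categories
    fam_members: dict[str, list[str]] = {}       # family -> och member seq ids
    fam_mature: dict[str, dict[str, str]] = {}   # family -> seq_id -> mature seq

    for origin in params.families_per_origin:
        code = ORIGIN_CODES[origin]
        for fi in range(params.families_per_origin[origin]):
            fam = f"{code}{fi:03d}"
            plastid = rng.random() < params.plastid_fraction_per_origin[origin]
            dual = plastid and rng.random() < params.dual_fraction
            mito = (not plastid) and rng.random() < params.mito_fraction
            hap_roll = rng.random()
            if plastid and hap_roll < params.cash_internal_fraction:
                cash_position = "internal:hypogyristea"
            elif plastid and hap_roll < (params.cash_internal_fraction
                                         + params.cash_external_fraction):
                cash_position = "external:immediate-sister"
            else:
                cash_position = "none"

            present = {s for s in och_subs
                       if rng.random() < params.subcat_presence_prob}
            while len(present) < 4:     # keep the family analysable
                present.add(och_subs[int(rng.integers(0, len(och_subs)))])

            och = _och_template(present, cash_position == "internal:hypogyristea")
            template = _origin_template(
                origin, och, cash_position == "external:immediate-sister")

            evolver = _Evolver(rng, params.substitution_rate_per_branch,
                               params.indel_rate)
            root_seq = "M" + _random_residues(rng, params.mature_length - 1)
            leaves: dict[str, list[tuple[int, str]]] = {}
            evolver.evolve(template, evolver.root(root_seq), leaves)

            labels = {sub: _seq_id(sub, fam) for sub in leaves}
            trees[fam] = _template_newick(template, labels)
            rows = evolver.rows(leaves)

            # per-member processing: truncation, presequence, emission
            members: list[str] = []
            mature_of: dict[str, str] = {}
            preseqs: dict[str, str] = {}
            targeting: dict[str, str] = {}
            for sub in sorted(leaves):
                sid = labels[sub]
                mature = rows[sub].replace(GAP, "")
                is_och = taxonomy.is_ochrophyte(sub)
                is_hap = taxonomy.lineage_of(sub) == "haptophytes"
                label = "none"
                pre = ""
                truncated = False
                if is_och and rng.random() < params.truncated_member_rate:
                    truncated = True
                    t = int(rng.integers(55, 91))
                    mature = mature[t:]
                    # gap the removed prefix in the alignment row
                    row = rows[sub]
                    kept = 0
                    chars = list(row)
                    for idx, ch in enumerate(chars):
                        if ch != GAP:
                            kept += 1
                            if kept <= t:
                                chars[idx] = GAP
                    rows[sub] = "".join(chars)
                if (is_och or is_hap) and not truncated:
                    if plastid and rng.random() >= params.presequence_dropout:
                        pre = make_plastid_presequence(rng, lo, hi, dual=dual)
                        label = "dual" if dual else "plastid"
                    elif mito and is_och:
                        pre = make_mito_presequence(rng)
                        label = "mito"
                full = pre + mature
                rec = SequenceRecord(seq_id=sid, species_id=SPECIES[sub],
                                     sub_category=sub, library_id=SPECIES[sub],
                                     residues=full)
                records.append(rec)
                seq_rows.append(dict(
                    seq_id=sid, family=fam, library=SPECIES[sub],
                    sub_category=sub, origin=origin, targeting=label,
                    contaminant_source="", is_fusion=False,
                    fusion_breakpoint=-1, fusion_n_origin="", fusion_c_origin=""))
                mature_of[sid] = mature
                preseqs[sid] = pre
                if is_och:
                    members.append(sid)

            # alignment: right-justified presequence block + evolved columns
            width = max((len(preseqs[labels[s]]) for s in leaves), default=0)
            aln: dict[str, str] = {}
            for sub in sorted(leaves):
                sid = labels[sub]
                pre = preseqs[sid]
                aln[sid] = GAP * (width - len(pre)) + pre + rows[sub]
            alignments[fam] = aln
            fam_members[fam] = members
            fam_mature[fam] = mature_of
            fam_rows.append(dict(family=fam, origin=origin,
                                 plastid_targeted=plastid, dual=dual,
                                 mito=mito, cash_position=cash_position))

    truth_seq = {r["seq_id"]: r for r in seq_rows}
    # RPKM-like abundances: contaminant carryover is orders of magnitude
    # below the genuine copy, as in real cross-contaminated assemblies
    coverage = {r["seq_id"]: float(np.exp(rng.normal(np.log(50.0), 1.0)))
                for r in seq_rows}

    # ---- cross-library contamination (verbatim copies) -------------------
    och_records = [r for r in records if taxonomy.is_ochrophyte(r.sub_category)]
    och_libs = sorted({r.library_id for r in och_records})
    n_contam = 0
    for rec in list(och_records):
        if rng.random() >= params.contamination_rate:
            continue
        foreign = [l for l in och_libs
                   if l != rec.library_id and l not in GENOME_SPECIES]
        lib = foreign[int(rng.integers(0, len(foreign)))]
        sub = next(s for s, sp in SPECIES.items() if sp == lib)
        src_row = truth_seq[rec.seq_id]
        sid = _seq_id(sub, f"{src_row['family']}_c{n_contam}")
        n_contam += 1
        records.append(SequenceRecord(seq_id=sid, species_id=SPECIES[sub],
                                      sub_category=sub, library_id=lib,
                                      residues=rec.residues))
        row = dict(src_row)
        row.update(seq_id=sid, library=lib, sub_category=sub,
                   contaminant_source=rec.library_id)
        seq_rows.append(row)
        truth_seq[sid] = row
        coverage[sid] = coverage[rec.seq_id] * float(rng.uniform(0.005, 0.05))

    # ---- chimeric fusion proteins ---------------------------------------
    plastid_fams = [r["family"] for r in fam_rows if r["plastid_targeted"]]
    fam_origin = {r["family"]: r["origin"] for r in fam_rows}
    pairs: list[tuple[str, str]] = []
    attempt = 0
    while len(pairs) < params.fusion_count and attempt < 200:
        attempt += 1
        if len(plastid_fams) < 2:
            break
        a, b = rng.choice(plastid_fams, 2, replace=False)
        if fam_origin[a] != fam_origin[b] and (a, b) not in pairs:
            pairs.append((str(a), str(b)))
    if len(pairs) < params.fusion_count:
        logger.warning("planted only %d of %d requested fusions",
                       len(pairs), params.fusion_count)
    for fa, fb in pairs:
        donor_a = fam_members[fa][int(rng.integers(0, len(fam_members[fa])))]
        donor_b = fam_members[fb][int(rng.integers(0, len(fam_members[fb])))]
        mat_a = fam_mature[fa][donor_a]
        mat_b = fam_mature[fb][donor_b]
        ba = int(rng.integers(int(0.4 * len(mat_a)), int(0.6 * len(mat_a))))
        bb = int(rng.integers(int(0.4 * len(mat_b)), int(0.6 * len(mat_b))))
        transcriptome_subs = [s for s in och_subs
                              if SPECIES[s] not in GENOME_SPECIES]
        sub = transcriptome_subs[int(rng.integers(0, len(transcriptome_subs)))]
        pre = make_plastid_presequence(rng, lo, hi)
        # the fusion postdates the parent families: let it diverge so it is
        # not sequence-identical to either parent
        fused = list(mat_a[:ba] + mat_b[bb:])
        p_sub = min(0.9, 2.5 * params.substitution_rate_per_branch)
        for k in range(len(fused)):
            if rng.random() < p_sub:
                fused[k] = AMINO_ACIDS[rng.choice(20, p=_BG)]
        full = pre + "".join(fused)
        sid = _seq_id(sub, f"{fa}_x_{fb}")
        records.append(SequenceRecord(seq_id=sid, species_id=SPECIES[sub],
                                      sub_category=sub, library_id=SPECIES[sub],
                                      residues=full))
        seq_rows.append(dict(
            seq_id=sid, family=f"{fa}_x_{fb}", library=SPECIES[sub],
            sub_category=sub, origin=fam_origin[fa], targeting="plastid",
            contaminant_source="", is_fusion=True,
            fusion_breakpoint=len(pre) + ba,
            fusion_n_origin=fam_origin[fa], fusion_c_origin=fam_origin[fb]))
        coverage[sid] = float(np.exp(rng.normal(np.log(50.0), 1.0)))

    # ---- expression (block structure independent of origin) --------------
    families = [r["family"] for r in fam_rows]
    expression = simulate_expression(
        rng, families, params.expression_block_correlation,
        params.n_conditions, params.n_expression_blocks)

    truth = SyntheticTruth(
        sequences=pd.DataFrame(seq_rows).set_index("seq_id"),
        families=pd.DataFrame(fam_rows).set_index("family"))

    hits = compute_similarity_scores(records, scoring)
    return SyntheticDataset(params=params, taxonomy=taxonomy, records=records,
                            hits=hits, alignments=alignments, trees=trees,
                            expression=expression, coverage=coverage,
                            truth=truth)


def simulate_expression(rng: np.random.Generator, genes: Sequence[str],
                        block_correlation: float, n_conditions: int,
                        n_blocks: int = 5) -> pd.DataFrame:
    """Expression profiles with correlation blocks assigned independently of
    any gene metadata (a null for origin-structured coexpression)."""
    rho = abs(block_correlation)
    sign = 1.0 if block_correlation >= 0 else -1.0
    factors = rng.standard_normal((n_blocks, n_conditions))
    data = np.empty((len(genes), n_conditions))
    for i in range(len(genes)):
        b = int(rng.integers(0, n_blocks))
        noise = rng.standard_normal(n_conditions)
        data[i] = sign * np.sqrt(rho) * factors[b] + np.sqrt(1 - rho) * noise
    return pd.DataFrame(data, index=list(genes),
                        columns=[f"cond{c:02d}" for c in range(n_conditions)])


def simulate_family_labels(rng: np.random.Generator, n_families: int,
                           origin_probs: Mapping[str, float],
                           plastid_fraction_per_origin: Mapping[str, float]
                           ) -> pd.DataFrame:
    """Label-level families (origin + plastid call) for enrichment-scale
    analyses where sequences are not needed."""
    origins = list(origin_probs)
    p = np.array([origin_probs[o] for o in origins], dtype=float)
    p = p / p.sum()
    draws = rng.choice(len(origins), n_families, p=p)
    rows = []
    for i, oi in enumerate(draws):
        origin = origins[int(oi)]
        rows.append(dict(family=f"fam{i:05d}", origin=origin,
                         plastid=bool(rng.random()
                                      < plastid_fraction_per_origin[origin])))
    return pd.DataFrame(rows).set_index("family")
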