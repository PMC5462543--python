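"""Formats, taxonomy and configuration shared by every pipeline stage.

The pipeline touches a handful of plain-text formats:

* protein FASTA with a ``sub_category|species|seq_id`` header dialect
  (aligned FASTA uses ``-`` for gaps);
* ranked similarity hit tables as 12-column BLAST ``outfmt 6``-style TSV
  (1-based inclusive coordinates on disk, 0-based half-open in memory);
* Newick gene trees whose leaf labels carry the same header dialect, so every
  leaf resolves to a taxonomic sub-category and lineage;
* YAML key/value configuration.

The taxonomy scheme mirrors the study design for ochrophyte plastid
proteomes: eleven ochrophyte sub-categories in three groups (chrysista,
hypogyristea, diatoms), the CASH lineages with plastids of secondary red
origin (cryptomonads, haptophytes, dinotoms, other alveolates) plus the
green-plastid secondary lineages (euglenids, chlorarachniophytes), and the
outgroup lineages used for the floating similarity threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import yaml

logger = logging.getLogger("paleoplastid")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class ParseError(ValueError):
    """A file did not match the documented dialect."""


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

OCHROPHYTE_GROUPS: dict[str, tuple[str, ...]] = {
    "chrysista": ("px", "raphidophytes", "pesc"),
    "hypogyristea": ("pelagophytes", "dictyochophytes", "bolidophytes"),
    "diatoms": ("corethron", "radial_centrics", "thalassiosirales",
                "odontellids", "pennates"),
}

CASH_LINEAGES = ("cryptomonads", "haptophytes", "dinotoms",
                 "other alveolates", "euglenids", "chlorarachniophytes")

OUTGROUP_LINEAGES = ("red algae", "green algae", "aplastidic stramenopiles",
                     "other eukaryotes", "prokaryotes", "viruses")


@dataclass(frozen=True)
class TaxonomyScheme:
    """Mapping of sub-categories to lineages and ochrophyte groups.

    ``sub_categories`` maps every sub-category name to its lineage;
    ``ochrophyte_groups`` partitions the eleven ochrophyte sub-categories
    into the three groups (sizes 3/3/5).
    """

    lineages: tuple[str, ...]
    sub_categories: Mapping[str, str]
    ochrophyte_groups: Mapping[str, tuple[str, ...]]
    cash_lineages: tuple[str, ...] = CASH_LINEAGES
    outgroup_lineages: tuple[str, ...] = OUTGROUP_LINEAGES

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group, subs in self.ochrophyte_groups.items():
            if seen & set(subs):
                raise ValueError(f"ochrophyte groups overlap at {group}")
            seen |= set(subs)
        sizes = sorted(len(v) for v in self.ochrophyte_groups.values())
        if sizes != [3, 3, 5]:
            raise ValueError(f"ochrophyte group sizes must be 3/3/5, got {sizes}")
        if len(set(self.lineages)) != len(self.lineages):
            raise ValueError("duplicate lineage names")
        for sub, lin in self.sub_categories.items():
            if lin not in self.lineages:
                raise ValueError(f"sub-category {sub!r} maps to unknown lineage {lin!r}")

    # -- lookups ----------------------------------------------------------
    def lineage_of(self, sub_category: str) -> str:
        try:
            return self.sub_categories[sub_category]
        except KeyError:
            raise KeyError(f"unknown sub-category: {sub_category!r}") from None

    def group_of(self, sub_category: str) -> str | None:
        """Ochrophyte group of a sub-category, or None for non-ochrophytes."""
        for group, subs in self.ochrophyte_groups.items():
            if sub_category in subs:
                return group
        return None

    def is_ochrophyte(self, sub_category: str) -> bool:
        return self.group_of(sub_category) is not None

    def is_cash(self, lineage: str) -> bool:
        return lineage in self.cash_lineages

    def is_outgroup(self, lineage: str) -> bool:
        """True for lineages usable as floating-threshold outgroups."""
        return lineage != "ochrophytes" and lineage not in self.cash_lineages

    @property
    def ochrophyte_sub_categories(self) -> tuple[str, ...]:
        return tuple(s for subs in self.ochrophyte_groups.values() for s in subs)


def default_taxonomy() -> TaxonomyScheme:
    """The built-in taxonomy used by the synthetic datasets.

    One sub-category per taxon bin; the ochrophyte bins follow the
    3 chrysista / 3 hypogyristea / 5 diatom layout.
    """
    subs: dict[str, str] = {}
    for subs_in_group in OCHROPHYTE_GROUPS.values():
        for s in subs_in_group:
            subs[s] = "ochrophytes"
    cash = {
        "cryptomonads_a": "cryptomonads", "cryptomonads_b": "cryptomonads",
        "pavlovophytes": "haptophytes", "prymnesiales": "haptophytes",
        "isochrysidales": "haptophytes",
        "dinotoms": "dinotoms", "dinoflagellates": "other alveolates",
        "euglenids": "euglenids", "chlorarachniophytes": "chlorarachniophytes",
    }
    outgroup = {
        "cyanidiales": "red algae", "florideophytes": "red algae",
        "porphyridiophytes": "red algae", "rhodellophytes": "red algae",
        "stylonematophytes": "red algae",
        "prasinodermophytes": "green algae", "mamiellophytes": "green algae",
        "chlorophyceae": "green algae", "trebouxiophytes": "green algae",
        "streptophytes": "green algae",
        "glaucophytes": "glaucophytes",
        "oomycetes": "aplastidic stramenopiles",
        "labyrinthulomycetes": "aplastidic stramenopiles",
        "slopalinids": "aplastidic stramenopiles",
        "amoebozoa": "other eukaryotes", "opisthokonts": "other eukaryotes",
        "cyanobacteria": "prokaryotes", "proteobacteria": "prokaryotes",
        "actinobacteria": "prokaryotes",
        "ncldv": "viruses",
    }
    subs.update(cash)
    subs.update(outgroup)
    lineages = ("ochrophytes",) + CASH_LINEAGES + OUTGROUP_LINEAGES + ("glaucophytes",)
    return TaxonomyScheme(lineages=lineages, sub_categories=subs,
                          ochrophyte_groups=OCHROPHYTE_GROUPS)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its taxonomic provenance.

    ``seq_id`` is the full ``sub_category|species|local_id`` header and is
    globally unique; ``library_id`` defaults to the species (one sequence
    library per species).
    """

    seq_id: str
    species_id: str
    sub_category: str
    library_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class HitRecord:
    """A single ranked similarity hit (BLAST-like)."""

    query_id: str = field(compare=False)
    subject_id: str = field(compare=False)
    rank: int = field(compare=False)
    percent_identity: float = field(compare=False)
    query_interval: tuple[int, int] = field(compare=False)   # 0-based half-open
    subject_interval: tuple[int, int] = field(compare=False)
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError("evalue and bitscore must be non-negative")
        for lo, hi in (self.query_interval, self.subject_interval):
            if lo < 0 or hi <= lo:
                raise ValueError(f"bad interval [{lo},{hi})")


def subcategory_of(seq_id: str) -> str:
    """Sub-category token of a ``sub_category|species|id`` identifier."""
    return seq_id.split("|", 1)[0]


def species_of(seq_id: str) -> str:
    parts = seq_id.split("|")
    if len(parts) < 3:
        raise ParseError(f"not a sub_category|species|id identifier: {seq_id!r}")
    return parts[1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Named thresholds used across the pipeline.

    Values mirror the published rules: orthologue admission strictly below
    the first-outgroup-hit e-value; >=3 consecutive same-lineage top hits for
    an unambiguous similarity-based origin; conservation majorities of 2/3
    (groups of three) and 3/5 (diatoms); members truncated by >50 residues at
    the N-terminus removed at curation; trimAl-style -gt 0.5 column trimming;
    chimera component grouping at >70% mutual overlap with top-3 bitscore
    lineage unanimity; mitochondrial dual-targeting screen at a 0.35 score
    cutoff with a downstream-methionine rescan window of 30 residues.
    """

    outgroup_cap_strict: bool = True
    hit_evalue_max: float = 1e-5
    consecutive_hits_min: int = 3
    chrysista_majority: float = 2 / 3
    hypogyristea_majority: float = 2 / 3
    diatom_majority: float = 3 / 5
    haptophyte_majority: float = 2 / 3
    n_truncation_max: int = 50
    column_gap_keep_fraction: float = 0.5
    conserved_column_fraction: float = 0.7
    chimera_overlap_fraction: float = 0.70
    chimera_top_n: int = 3
    mito_score_cutoff: float = 0.35
    downstream_met_window: int = 30
    focal_residue_fraction: float = 2 / 3
    family_consensus_fraction: float = 2 / 3
    alpha: float = 0.05
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "chrysista_majority": self.chrysista_majority,
            "hypogyristea_majority": self.hypogyristea_majority,
            "diatom_majority": self.diatom_majority,
            "haptophyte_majority": self.haptophyte_majority,
            "column_gap_keep_fraction": self.column_gap_keep_fraction,
            "conserved_column_fraction": self.conserved_column_fraction,
            "chimera_overlap_fraction": self.chimera_overlap_fraction,
            "focal_residue_fraction": self.focal_residue_fraction,
            "family_consensus_fraction": self.family_consensus_fraction,
            "alpha": self.alpha,
        }
        for name, value in fractions.items():
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must be in (0,1], got {value}")
        for name in ("consecutive_hits_min", "n_truncation_max",
                     "downstream_met_window", "chimera_top_n", "smoothing_window"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0 <= self.mito_score_cutoff <= 1:
            raise ConfigError("mito_score_cutoff must be in [0,1]")
        if self.hit_evalue_max <= 0:
            raise ConfigError("hit_evalue_max must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML mapping; unknown keys are errors, not defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a key/value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _record_from_header(header: str, body: str, lineno: int,
                        taxonomy: TaxonomyScheme | None) -> SequenceRecord:
    parts = header.split("|")
    if len(parts) < 3 or any(not p for p in parts[:3]):
        raise ParseError(
            f"line {lineno}: header {header!r} does not follow "
            "'sub_category|species|seq_id'")
    sub, species = parts[0], parts[1]
    library = parts[3] if len(parts) > 3 else species
    if taxonomy is not None and sub not in taxonomy.sub_categories:
        raise ParseError(f"line {lineno}: unknown sub-category {sub!r}")
    return SequenceRecord(seq_id="|".join(parts[:3]), species_id=species,
                          sub_category=sub, library_id=library, residues=body)


def read_fasta(path: str | Path,
               taxonomy: TaxonomyScheme | None = None) -> list[SequenceRecord]:
    """Read protein FASTA in the ``sub_category|species|seq_id`` dialect.

    Residues are upper-cased and terminal ``*`` stop symbols stripped.
    Records with an empty body are rejected with a warning; a malformed
    header raises :class:`ParseError` naming the line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        body = "".join(chunks).upper().strip("*")
        if not body:
            logger.warning("%s: empty sequence for %r, record skipped", path, header)
            return
        records.append(_record_from_header(header, body, header_line, taxonomy))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, header_line, chunks = line[1:].strip(), lineno, []
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence data before first header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment(path: str | Path) -> dict[str, str]:
    """Aligned FASTA (gap '-') as an ordered ``seq_id -> row`` mapping."""
    rows: dict[str, str] = {}
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    rows[header] = "".join(chunks).upper()
                header, chunks = line[1:].strip(), []
            else:
                chunks.append(line)
    if header is not None:
        rows[header] = "".join(chunks).upper()
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        raise ParseError(f"{path}: ragged alignment rows (lengths {sorted(lengths)})")
    return rows


def write_alignment(rows: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in rows.items():
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ("qseqid sseqid pident length mismatch gapopen "
                "qstart qend sstart send evalue bitscore").split()


def _hit_sort_key(h: HitRecord):
    return (h.evalue, -h.bitscore, h.subject_id)


def rank_hits(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Sort one query's hits (evalue asc, bitscore desc, subject asc) and
    re-number ranks consecutively from 1."""
    ordered = sorted(hits, key=_hit_sort_key)
    return [dataclasses.replace(h, rank=i) for i, h in enumerate(ordered, 1)]


def read_hit_table(path: str | Path) -> dict[str, list[HitRecord]]:
    """Read a 12-column BLAST outfmt-6-like TSV into ranked per-query lists.

    On-disk coordinates are 1-based inclusive; in memory they become 0-based
    half-open. Duplicate (query, subject, interval) rows keep the
    best-bitscore copy.
    """
    best: dict[tuple, HitRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
            hit = HitRecord(query_id=parts[0], subject_id=parts[1], rank=0,
                            percent_identity=pident,
                            query_interval=(qstart - 1, qend),
                            subject_interval=(sstart - 1, send),
                            evalue=evalue, bitscore=bitscore)
            key = (hit.query_id, hit.subject_id, hit.query_interval,
                   hit.subject_interval)
            if key in best:
                logger.info("duplicate hit row at line %d, keeping best bitscore", lineno)
                if hit.bitscore <= best[key].bitscore:
                    continue
            best[key] = hit
    by_query: dict[str, list[HitRecord]] = {}
    for hit in best.values():
        by_query.setdefault(hit.query_id, []).append(hit)
    return {q: rank_hits(hits) for q, hits in sorted(by_query.items())}


def write_hit_table(hits_by_query: Mapping[str, Sequence[HitRecord]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for query in hits_by_query:
            for h in hits_by_query[query]:
                qs, qe = h.query_interval
                ss, se = h.subject_interval
                alen = max(qe - qs, se - ss)
                fh.write("\t".join([
                    h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                    str(alen), "0", "0", str(qs + 1), str(qe),
                    str(ss + 1), str(se), format_evalue(h.evalue),
                    f"{h.bitscore:.1f}"]) + "\n")


def format_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    return f"{e:.3e}"


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def annotate_tree(tree: dendropy.Tree, taxonomy: TaxonomyScheme) -> dendropy.Tree:
    """Attach ``sub_category``/``lineage`` annotations to every leaf.

    Leaf labels must follow the ``sub_category|species|seq_id`` dialect (or be
    bare sub-category names); unresolvable labels raise a ParseError listing
    the offenders.
    """
    bad: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else (leaf.label or "")
        sub = label.split("|", 1)[0]
        if sub in taxonomy.sub_categories:
            leaf.sub_category = sub
            leaf.lineage = taxonomy.lineage_of(sub)
        else:
            bad.append(label)
    if bad:
        raise ParseError(f"leaf labels with unknown sub-category: {bad}")
    return tree


def read_tree(path: str | Path, taxonomy: TaxonomyScheme) -> dendropy.Tree:
    """Read a Newick tree (support values allowed, rooting optional) and
    annotate every leaf with its sub-category and lineage."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return annotate_tree(tree, taxonomy)


def parse_tree(newick: str, taxonomy: TaxonomyScheme) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return annotate_tree(tree, taxonomy)


def leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else (node.label or "")
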