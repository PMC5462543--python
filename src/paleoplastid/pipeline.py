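"""End-to-end orchestration: simulate -> decontam -> targeting -> assemble
-> conserve -> curate -> origin -> synapomorphy -> chimera -> enrich.

Every stage writes a JSON manifest (inputs, parameters, in/out counts) and
plain-TSV outputs under the run directory; reruns with the same
configuration and seed reproduce byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import chimera as chimera_mod
from . import decontam as decontam_mod
from .core_io import (ConfigError, PipelineConfig, TaxonomyScheme,
                      default_taxonomy, logger, parse_tree, subcategory_of)
from .enrichment_stats import coexpression_by_origin, targeting_enrichment
from .hppg_assembly import (HPPG, check_ochrophyte_clade, compute_outgroup_cap,
                            curate_alignment, default_patterns,
                            evaluate_conservation, grow_hppg, merge_seeds,
                            trim_columns)
from .origin_assignment import (annotate_cash_position, blast_top_hit_origin,
                                combine_origins, prune_cash_lineages,
                                tree_sister_origin)
from .synapomorphy import (annotate_origin_nodes, find_unique_shared_residues,
                           green_screen_rules, screen_vertical_inheritance)
from .synthetic_data import (GENOME_SPECIES, ORGANISM_PRECEDENCE,
                             SimulationParams, SyntheticDataset,
                             simulate_dataset)
from .targeting import family_targeting_consensus, predict_all

STAGES = ("simulate", "decontam", "targeting", "assemble", "conserve",
          "curate", "origin", "synapomorphy", "chimera", "enrich")

GREEN_REFERENCE_NEWICK = ("(streptophytes,(prasinodermophytes,"
                          "(mamiellophytes,(chlorophyceae,trebouxiophytes))));")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    decontam_enabled: bool = True
    simulation: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, template in (("simulation", SimulationParams),
                                  ("thresholds", PipelineConfig)):
            sub = raw.get(section, {})
            fields = {f.name for f in dataclasses.fields(template)}
            bad = set(sub) - fields
            if bad:
                raise ConfigError(f"unknown {section} keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    dataset: SyntheticDataset
    removed_contaminants: set[str]
    predictions: dict
    hppgs: dict[str, HPPG]                  # ancestral (post clade check)
    assembled: dict[str, HPPG]              # post growth, pre conservation
    curated: dict[str, HPPG]
    curated_alignments: dict[str, dict[str, str]]
    origin_calls: dict[str, object]
    cash_positions: dict[str, tuple[str | None, str]]
    consensus_targeting: dict[str, str]
    chimera_calls: dict[str, object]
    shared_residues: dict[str, list]
    stage_counts: dict[str, dict[str, int]]

    def summary_sha256(self) -> str:
        path = self.outdir / "summary.tsv"
        return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: Mapping,
                    counts: Mapping[str, int]) -> None:
    manifest = {"stage": stage, "parameters": dict(params),
                "counts": dict(counts)}
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n")


def _lineage_of_subject(taxonomy: TaxonomyScheme):
    def f(seq_id: str) -> str:
        return taxonomy.lineage_of(subcategory_of(seq_id))
    return f


def run_pipeline(config: RunConfig | str | Path,
                 outdir: str | Path | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Execute the whole chain; see the module docstring for stage order."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = default_taxonomy()
    thresholds = PipelineConfig(**config.thresholds)
    patterns = default_patterns()
    lineage_of = _lineage_of_subject(taxonomy)
    counts: dict[str, dict[str, int]] = {}

    def stage_dir(i: int, name: str) -> Path:
        d = out / f"stage{i:02d}_{name}"
        d.mkdir(exist_ok=True)
        return d

    # ---- 1. simulate ----------------------------------------------------
    sim_params = SimulationParams(seed=config.seed, **config.simulation)
    dataset = simulate_dataset(sim_params, taxonomy)
    d = stage_dir(1, "simulate")
    dataset.write(d / "data")
    counts["simulate"] = {"sequences": len(dataset.records),
                          "families": len(dataset.truth.families)}
    _write_manifest(d, "simulate", dataclasses.asdict(sim_params),
                    counts["simulate"])

    records_by_id = {r.seq_id: r for r in dataset.records}
    och_libraries = {lib: recs
                     for lib, recs in dataset.records_by_library().items()
                     if taxonomy.is_ochrophyte(recs[0].sub_category)}

    # ---- 2. decontam -----------------------------------------------------
    d = stage_dir(2, "decontam")
    removed: set[str] = set()
    if config.decontam_enabled:
        kept_libs, report = decontam_mod.decontaminate(
            och_libraries, dataset.hits,
            smoothing_window=thresholds.smoothing_window,
            coverage=dataset.coverage)
        removed = report.all_removed
        rows = [{"library": lib, "removed": len(ids),
                 "total": report.totals[lib],
                 "fraction": round(report.removed_fraction(lib), 4)}
                for lib, ids in sorted(report.removed.items())]
        pd.DataFrame(rows).to_csv(d / "report.tsv", sep="\t", index=False)
        och_libraries = kept_libs
    counts["decontam"] = {"removed": len(removed),
                          "kept": sum(len(v) for v in och_libraries.values())}
    _write_manifest(d, "decontam",
                    {"enabled": config.decontam_enabled}, counts["decontam"])

    usable = [r for recs in och_libraries.values() for r in recs]
    cash_records = [r for r in dataset.records
                    if taxonomy.lineage_of(r.sub_category)
                    in ("haptophytes", "cryptomonads", "dinotoms")]

    # ---- 3. targeting ----------------------------------------------------
    d = stage_dir(3, "targeting")
    predictions = predict_all(usable + cash_records,
                              cutoff=thresholds.mito_score_cutoff,
                              window=thresholds.downstream_met_window)
    rows = [{"seq_id": sid, "plastid": int(p.plastid_call),
             "mito_full": round(p.mito_score_full, 4),
             "mito_downstream": (round(p.mito_score_downstream, 4)
                                 if p.mito_score_downstream is not None else ""),
             "dual": int(p.dual_call)}
            for sid, p in sorted(predictions.items())]
    pd.DataFrame(rows).to_csv(d / "predictions.tsv", sep="\t", index=False)
    plastid_ids = {sid for sid, p in predictions.items() if p.plastid_call}
    counts["targeting"] = {"predicted_plastid": len(plastid_ids),
                           "screened": len(predictions)}
    _write_manifest(d, "targeting",
                    {"cutoff": thresholds.mito_score_cutoff}, counts["targeting"])

    # ---- 4. assemble -----------------------------------------------------
    d = stage_dir(4, "assemble")
    candidates = sorted(
        sid for sid in plastid_ids
        if sid in records_by_id
        and taxonomy.is_ochrophyte(subcategory_of(sid))
        and records_by_id[sid].library_id in GENOME_SPECIES)
    caps = {}
    for sid in candidates:
        outgroup_hits = [h for h in dataset.hits.get(sid, ())
                         if taxonomy.is_outgroup(lineage_of(h.subject_id))]
        caps[sid] = compute_outgroup_cap(sid, outgroup_hits)
    retained, merge_map = merge_seeds(candidates, dataset.hits, caps,
                                      ORGANISM_PRECEDENCE)
    member_pool = {r.seq_id: r for r in usable if r.seq_id in plastid_ids}
    hppgs: dict[str, HPPG] = {}
    for sid in retained:
        library_hits = [h for h in dataset.hits.get(sid, ())
                        if h.subject_id in member_pool]
        hppg, _trimmed = grow_hppg(records_by_id[sid], library_hits,
                                   caps[sid], taxonomy, member_pool)
        hppgs[sid] = hppg
    pd.DataFrame([{"hppg": h.hppg_id, "members": len(h.member_ids)}
                  for h in hppgs.values()]).to_csv(
        d / "hppgs.tsv", sep="\t", index=False)
    counts["assemble"] = {"seed_candidates": len(candidates),
                          "hppgs": len(hppgs)}
    _write_manifest(d, "assemble", {"precedence": ORGANISM_PRECEDENCE},
                    counts["assemble"])

    # ---- 5. conserve -----------------------------------------------------
    d = stage_dir(5, "conserve")
    conserved: dict[str, HPPG] = {}
    for sid, hppg in hppgs.items():
        if evaluate_conservation(hppg, taxonomy, patterns):
            conserved[sid] = hppg
    pd.DataFrame([{"hppg": h.hppg_id,
                   "patterns": ",".join(sorted(h.conservation_patterns_passed))}
                  for h in conserved.values()]).to_csv(
        d / "conserved.tsv", sep="\t", index=False)
    counts["conserve"] = {"conserved": len(conserved)}
    _write_manifest(d, "conserve",
                    {"patterns": [p.pattern_id for p in patterns]},
                    counts["conserve"])

    # alignment lookup: the family alignment containing the seed
    seed_alignment: dict[str, tuple[str, dict[str, str]]] = {}
    for fam, aln in dataset.alignments.items():
        for sid in aln:
            seed_alignment[sid] = (fam, aln)

    # ---- 6. curate -------------------------------------------------------
    d = stage_dir(6, "curate")
    curated: dict[str, HPPG] = {}
    curated_alignments: dict[str, dict[str, str]] = {}
    hppg_family: dict[str, str] = {}
    for sid, hppg in conserved.items():
        if sid not in seed_alignment:
            logger.warning("%s: no alignment found, dropped at curation", sid)
            continue
        fam, aln = seed_alignment[sid]
        in_aln = [m for m in hppg.member_ids if m in aln]
        if len(in_aln) < len(hppg.member_ids):
            logger.info("%s: %d members outside the alignment dropped",
                        sid, len(hppg.member_ids) - len(in_aln))
        slim = HPPG(hppg_id=hppg.hppg_id, seed_id=hppg.seed_id,
                    member_ids=in_aln, cap=hppg.cap)
        slim.recount_presence(taxonomy)
        slim.status = hppg.status
        result, kept_aln = curate_alignment(
            slim, aln, taxonomy, patterns,
            n_truncation_max=thresholds.n_truncation_max,
            domain_fraction=thresholds.conserved_column_fraction)
        if result is None:
            continue
        # keep donor/outgroup rows alongside members for downstream scans
        full_rows = {m: aln[m] for m in aln
                     if m in kept_aln or m not in set(hppg.member_ids)}
        curated[sid] = result
        curated_alignments[sid] = trim_columns(
            full_rows, thresholds.column_gap_keep_fraction)
        hppg_family[sid] = fam
    pd.DataFrame([{"hppg": h.hppg_id, "members": len(h.member_ids)}
                  for h in curated.values()]).to_csv(
        d / "curated.tsv", sep="\t", index=False)
    counts["curate"] = {"curated": len(curated)}
    _write_manifest(d, "curate",
                    {"n_truncation_max": thresholds.n_truncation_max},
                    counts["curate"])

    # ---- 7. origin -------------------------------------------------------
    d = stage_dir(7, "origin")
    origin_calls: dict[str, object] = {}
    cash_positions: dict[str, tuple[str | None, str]] = {}
    ancestral: dict[str, HPPG] = {}
    trees = {}
    for sid, hppg in curated.items():
        fam = hppg_family[sid]
        tree = parse_tree(dataset.trees[fam], taxonomy)
        trees[sid] = tree
        ok, _offenders = check_ochrophyte_clade(tree, taxonomy, patterns)
        if not ok:
            continue
        hppg.advance_status("ancestral")
        ancestral[sid] = hppg
        hit_lineages = [lineage_of(h.subject_id)
                        for h in dataset.hits.get(sid, ())
                        if taxonomy.is_outgroup(lineage_of(h.subject_id))]
        blast_call = blast_top_hit_origin(hit_lineages,
                                          thresholds.consecutive_hits_min)
        origin_tree = prune_cash_lineages(tree, taxonomy)
        och_ids = {l.taxon.label for l in origin_tree.leaf_node_iter()
                   if getattr(l, "lineage", "") == "ochrophytes"}
        try:
            tree_call = tree_sister_origin(origin_tree, och_ids)
        except ValueError:
            tree_call = ("undetermined", frozenset())
        origin_calls[sid] = combine_origins(sid, blast_call, tree_call)
        hap_plastid = {r.seq_id for r in cash_records
                       if predictions[r.seq_id].plastid_call}
        try:
            cash_positions[sid] = annotate_cash_position(
                tree, "haptophytes", taxonomy, hap_plastid)
        except ValueError:
            cash_positions[sid] = (None, "no ochrophyte leaves")
    pd.DataFrame([{"hppg": sid, "blast": c.blast_origin,
                   "consecutive": c.blast_consecutive, "tree": c.tree_origin,
                   "combined": c.combined_origin, "confidence": c.confidence,
                   "cash": cash_positions[sid][0] or ""}
                  for sid, c in sorted(origin_calls.items())]).to_csv(
        d / "origins.tsv", sep="\t", index=False)
    counts["origin"] = {
        "ancestral": len(ancestral),
        "combined_determined": sum(1 for c in origin_calls.values()
                                   if c.confidence == "high")}
    _write_manifest(d, "origin",
                    {"consecutive_min": thresholds.consecutive_hits_min},
                    counts["origin"])

    # ---- 8. synapomorphy (green-origin HPPGs) ----------------------------
    d = stage_dir(8, "synapomorphy")
    green_tree = parse_tree(GREEN_REFERENCE_NEWICK, taxonomy)
    rules = green_screen_rules()
    shared: dict[str, list] = {}
    rng = np.random.default_rng(config.seed + 17)
    for sid, call in sorted(origin_calls.items()):
        if call.combined_origin != "green algae":
            continue
        include, _off = screen_vertical_inheritance(trees[sid], taxonomy, rules)
        if not include:
            continue
        aln = curated_alignments[sid]
        rows = _reduce_one_per_subcat(aln, rng)
        focal = [s for s in rows
                 if taxonomy.is_ochrophyte(subcategory_of(s))]
        donors = [s for s in rows
                  if taxonomy.lineage_of(subcategory_of(s)) == "green algae"]
        excl_red = [s for s in rows
                    if taxonomy.lineage_of(subcategory_of(s)) == "red algae"]
        excl_glauco = [s for s in rows
                       if taxonomy.lineage_of(subcategory_of(s))
                       == "glaucophytes"]
        if not (focal and donors and (excl_red or excl_glauco)):
            continue
        calls = find_unique_shared_residues(
            rows, focal, donors, [excl_red, excl_glauco],
            thresholds.focal_residue_fraction)
        annotate_origin_nodes(calls, green_tree, rows, donors)
        shared[sid] = calls
    pd.DataFrame([{"hppg": sid, "column": c.column, "residue": c.residue,
                   "observed_node": c.origin_node_observed,
                   "earliest_node": c.origin_node_earliest}
                  for sid, calls in sorted(shared.items())
                  for c in calls]).to_csv(
        d / "shared_residues.tsv", sep="\t", index=False)
    counts["synapomorphy"] = {
        "hppgs_screened": len(shared),
        "shared_residues": sum(len(v) for v in shared.values())}
    _write_manifest(d, "synapomorphy",
                    {"focal_fraction": thresholds.focal_residue_fraction},
                    counts["synapomorphy"])

    # ---- 9. chimera ------------------------------------------------------
    d = stage_dir(9, "chimera")
    chimera_calls: dict[str, object] = {}
    for rec in sorted(usable, key=lambda r: r.seq_id):
        if rec.seq_id not in plastid_ids:
            continue
        hits = [h for h in dataset.hits.get(rec.seq_id, ())
                if taxonomy.is_outgroup(lineage_of(h.subject_id))]
        if not hits:
            continue
        chimera_calls[rec.seq_id] = chimera_mod.analyse_protein(
            rec.seq_id, hits, lineage_of,
            evalue_max=thresholds.hit_evalue_max,
            fraction=thresholds.chimera_overlap_fraction,
            top_n=thresholds.chimera_top_n)
    chimeric = {sid: c for sid, c in chimera_calls.items() if c.chimeric}
    pd.DataFrame([{"query": sid, "ntd": c.ntd_origin, "ctd": c.ctd_origin,
                   "domains": len(c.domains)}
                  for sid, c in sorted(chimeric.items())]).to_csv(
        d / "chimeras.tsv", sep="\t", index=False)
    counts["chimera"] = {"screened": len(chimera_calls),
                         "chimeric": len(chimeric)}
    _write_manifest(d, "chimera",
                    {"evalue_max": thresholds.hit_evalue_max},
                    counts["chimera"])

    # ---- 10. enrich ------------------------------------------------------
    d = stage_dir(10, "enrich")
    consensus: dict[str, str] = {}
    for sid, hppg in ancestral.items():
        preds = [predictions[m] for m in hppg.member_ids if m in predictions]
        if preds:
            consensus[sid] = family_targeting_consensus(
                preds, consensus_fraction=thresholds.family_consensus_fraction,
                cutoff=thresholds.mito_score_cutoff)
    family_table = pd.DataFrame(
        [{"hppg": sid, "origin": origin_calls[sid].combined_origin,
          "plastid": consensus.get(sid, "unassigned") in ("plastid", "dual")}
         for sid in sorted(ancestral) if sid in origin_calls])
    enrich_rows = []
    if not family_table.empty:
        results = targeting_enrichment(family_table.set_index("hppg"),
                                       alpha=thresholds.alpha)
        for origin, res in sorted(results.items()):
            enrich_rows.append({"origin": origin, "observed": res.observed,
                                "expected": round(res.expected, 3),
                                "p": f"{res.p:.4g}",
                                "significant": int(res.significant)})
    pd.DataFrame(enrich_rows).to_csv(d / "targeting_enrichment.tsv",
                                     sep="\t", index=False)
    # coexpression over recovered families with a determined origin
    fam_origin = {hppg_family[sid]: origin_calls[sid].combined_origin
                  for sid in ancestral
                  if sid in origin_calls
                  and origin_calls[sid].confidence == "high"}
    coexpr_flagged: list[str] = []
    if len(fam_origin) >= 6:
        try:
            summary = coexpression_by_origin(dataset.expression, fam_origin,
                                             alpha=thresholds.alpha)
            coexpr_flagged = summary.flagged
        except ValueError:
            pass
    (d / "coexpression_flags.tsv").write_text(
        "flagged_origin\n" + "".join(o + "\n" for o in coexpr_flagged))
    counts["enrich"] = {"consensus_calls": len(consensus),
                        "coexpression_flags": len(coexpr_flagged)}
    _write_manifest(d, "enrich", {"alpha": thresholds.alpha}, counts["enrich"])

    # ---- summary ---------------------------------------------------------
    with open(out / "summary.tsv", "w") as fh:
        fh.write("stage\tkey\tvalue\n")
        for stage in STAGES:
            for key, value in sorted(counts.get(stage, {}).items()):
                fh.write(f"{stage}\t{key}\t{value}\n")

    return PipelineResult(
        outdir=out, dataset=dataset, removed_contaminants=removed,
        predictions=predictions, hppgs=ancestral, assembled=hppgs,
        curated=curated,
        curated_alignments=curated_alignments, origin_calls=origin_calls,
        cash_positions=cash_positions, consensus_targeting=consensus,
        chimera_calls=chimera_calls, shared_residues=shared,
        stage_counts=counts)


def _reduce_one_per_subcat(rows: Mapping[str, str],
                           rng: np.random.Generator) -> dict[str, str]:
    """One randomly selected row per sub-category, seeded globally; the
    selection is the lowest seq id under a seeded shuffle."""
    by_sub: dict[str, list[str]] = {}
    for sid in sorted(rows):
        by_sub.setdefault(subcategory_of(sid), []).append(sid)
    out = {}
    for sub in sorted(by_sub):
        ids = by_sub[sub]
        pick = ids[int(rng.integers(0, len(ids)))]
        out[pick] = rows[pick]
    return out
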