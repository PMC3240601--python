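"""Stage orchestration: simulate -> orthologs -> matrix -> search ->
support -> enrich -> report, over a single YAML run configuration.

Each stage reads only files, writes its outputs plus a JSON manifest
(version, seed, parameters, input checksums, wall time), and never mutates
its inputs.  All randomness derives from the master seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import AnnotationMap, enrich_nodes, results_frame, tier_report
from .matrix import CharacterMatrix, read_fasta_matrix, read_nexus, write_nexus
from .orthology import (FamilyAssignment, GeneFamily, assign_families,
                        build_guide_tree, extract_ortholog_sets,
                        insert_all_ests, order_ests, read_hit_table,
                        sample_co_orthologs, write_ortholog_sets)
from .parsimony import SearchConfig, fitch_length, search_mp
from .simulate import SimConfig, sim_est_sampling, simulate_dataset
from .supermatrix import (PartitionedSupermatrix, build_supermatrix,
                          filter_by_representation, filter_min_taxa)
from .support import (SupportTable, bootstrap_support, load_support_table,
                      pbs_table)
from .trees import PhyloTree, parse_newick

STAGES = ("simulate", "orthologs", "matrix", "search", "support", "enrich",
          "report")


class ConfigError(ValueError):
    """Invalid run configuration (unknown keys, bad values)."""


class PipelineError(RuntimeError):
    """A stage failed at run time (missing inputs, empty results...)."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) under {where!r}: {', '.join(unknown)}")
    return cls(**data)


@dataclass
class OrthologParams:
    cutoff: float = 1e-20


@dataclass
class MatrixParams:
    min_taxa: int = 4
    representation_threshold: float = 0.10
    genus_representation_threshold: float = 0.30


@dataclass
class SearchParams:
    n_replicates: int = 4
    move: str = "SPR"
    max_held: int = 100
    exhaustive_cap: int = 9
    ratchet_iterations: int = 0


@dataclass
class SupportParams:
    bootstrap_replicates: int = 0
    tie_strategy: str = "single"
    n_replicates: int = 2
    max_held: int = 20


@dataclass
class EnrichParams:
    correction: str = "benjamini-hochberg"
    tier_thresholds: tuple = (0.01, 0.05, 0.10)
    tier_on: str = "raw"


@dataclass
class RunConfig:
    workdir: str = "run"
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    orthologs: OrthologParams = field(default_factory=OrthologParams)
    matrix: MatrixParams = field(default_factory=MatrixParams)
    search: SearchParams = field(default_factory=SearchParams)
    support: SupportParams = field(default_factory=SupportParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        allowed = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - allowed)
        if unknown:
            raise ConfigError(f"unknown key(s): {', '.join(unknown)}")
        sub = {}
        for f in fields(cls):
            if f.name in ("workdir", "seed"):
                continue
            spec = raw.get(f.name, {}) or {}
            typ = {"simulate": SimConfig, "orthologs": OrthologParams,
                   "matrix": MatrixParams, "search": SearchParams,
                   "support": SupportParams, "enrich": EnrichParams}[f.name]
            sub[f.name] = _from_mapping(typ, dict(spec), f.name)
        cfg = cls(workdir=str(raw.get("workdir", "run")),
                  seed=int(raw.get("seed", 0)), **sub)
        # master seed flows into the simulator unless set explicitly
        if "seed" not in (raw.get("simulate") or {}):
            cfg.simulate.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(workdir: Path, stage: str, cfg: RunConfig,
                    inputs: list[Path], outputs: list[Path],
                    t0: float, extra: Optional[dict] = None) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": [str(p) for p in outputs],
        "wall_time_s": round(time.time() - t0, 3),
    }
    if extra:
        manifest.update(extra)
    out = workdir / f"manifest_{stage}.json"
    out.write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r}: required input {path} is missing "
            "(run the preceding stage first)")
    return path


def _stage_seed(master: int, tag: str) -> int:
    return (master * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    simdir = workdir / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    simulate_dataset(cfg.simulate, outdir=simdir)
    outs = [simdir / "hits.tsv", simdir / "annotations.tsv",
            simdir / "species_tree.nwk", simdir / "truth.json"]
    _write_manifest(workdir, "simulate", cfg, [], outs, t0)
    return simdir


def _load_families(simdir: Path, stage: str) -> list[GeneFamily]:
    famdir = _require(simdir / "families", stage)
    out = []
    for fasta in sorted(famdir.glob("*.fasta")):
        fid = fasta.stem
        aln = read_fasta_matrix(fasta)
        species_of = {g: g.rsplit("|", 1)[1] for g in aln.taxa}
        guide_path = simdir / "guide_trees" / f"{fid}.nwk"
        guide = None
        if guide_path.exists():
            guide = parse_newick(guide_path.read_text(), min_leaves=2)
        out.append(GeneFamily(fid, aln, species_of, guide))
    if not out:
        raise PipelineError(f"stage {stage!r}: no family FASTA files found")
    return out


def stage_orthologs(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    simdir = workdir / "sim"
    hits_path = _require(simdir / "hits.tsv", "orthologs")
    families = _load_families(simdir, "orthologs")
    hits = read_hit_table(hits_path)
    assignment = assign_families(hits, cfg.orthologs.cutoff)

    genetree_dir = workdir / "gene_trees"
    genetree_dir.mkdir(parents=True, exist_ok=True)
    all_sets = []
    log = {"unassigned": assignment.unassigned, "ties": assignment.ties,
           "skipped_families": []}
    for fam in families:
        members_in_aln = set(fam.alignment.taxa)
        guide_leaves = (set(fam.guide_tree.leaf_labels)
                        if fam.guide_tree is not None else set())
        ests = sorted(q for q, f in assignment.assigned.items()
                      if f == fam.family_id and q in members_in_aln
                      and q not in guide_leaves)
        if fam.guide_tree is not None and fam.guide_tree.n_leaves >= 2:
            ordered = order_ests(fam, hits, ests)
            gene_tree, _ = insert_all_ests(fam, ordered)
        else:
            usable = sorted(guide_leaves | set(ests))
            if len(usable) < 3:
                log["skipped_families"].append(fam.family_id)
                continue
            gene_tree = build_guide_tree(
                fam.alignment.subset_taxa(usable),
                SearchConfig(n_replicates=2, max_held=1,
                             seed=_stage_seed(cfg.seed, fam.family_id)))
        (genetree_dir / f"{fam.family_id}.nwk").write_text(
            gene_tree.newick() + "\n")
        osets = extract_ortholog_sets(gene_tree, fam.species_of,
                                      fam.family_id)
        for oset in osets:
            all_sets.append(sample_co_orthologs(
                oset, _stage_seed(cfg.seed, oset.set_id)))
    if not all_sets:
        raise PipelineError("stage 'orthologs': no ortholog sets extracted")
    out_path = workdir / "orthologs.tsv"
    write_ortholog_sets(all_sets, out_path)
    (workdir / "orthologs_log.json").write_text(json.dumps(log, indent=1))
    _write_manifest(workdir, "orthologs", cfg, [hits_path],
                    [out_path, genetree_dir], t0,
                    {"n_sets": len(all_sets)})
    return out_path


def _load_ortholog_sets(path: Path):
    from .orthology import OrthologSet
    df = pd.read_csv(path, sep="\t")
    sets = []
    for sid, grp in df.groupby("set_id", sort=True):
        species_of = dict(zip(grp["gene_id"], grp["species_id"]))
        sets.append(OrthologSet(str(sid), str(grp["family_id"].iloc[0]),
                                frozenset(grp["gene_id"]), species_of))
    return sets


def stage_matrix(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    simdir = workdir / "sim"
    osets_path = _require(workdir / "orthologs.tsv", "matrix")
    families = _load_families(simdir, "matrix")
    alignments = {f.family_id: f.alignment for f in families}
    osets = _load_ortholog_sets(osets_path)
    # EST missingness already acts at the family level (unsequenced genes
    # never enter the families), so assembly is followed only by the
    # published filters
    sm = build_supermatrix(osets, alignments, min_taxa=3)
    sm = filter_min_taxa(sm, cfg.matrix.min_taxa)
    sm = filter_by_representation(sm, cfg.matrix.representation_threshold)
    nex = workdir / "supermatrix.nex"
    prov = workdir / "provenance.tsv"
    datatype = "protein" if cfg.simulate.alphabet == "protein" else "dna"
    sm.write(nex, prov, datatype=datatype)
    _write_manifest(workdir, "matrix", cfg, [osets_path], [nex, prov], t0,
                    {"n_partitions": len(sm.partition_names),
                     "n_taxa": sm.matrix.n_taxa,
                     "n_characters": sm.matrix.n_columns})
    return nex


def _search_config(cfg: RunConfig, tag: str,
                   params=None) -> SearchConfig:
    p = params or cfg.search
    return SearchConfig(
        n_replicates=getattr(p, "n_replicates", cfg.search.n_replicates),
        move=cfg.search.move,
        max_held=getattr(p, "max_held", cfg.search.max_held),
        seed=_stage_seed(cfg.seed, tag),
        ratchet_iterations=cfg.search.ratchet_iterations,
        exhaustive_cap=cfg.search.exhaustive_cap)


def stage_search(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    nex = _require(workdir / "supermatrix.nex", "search")
    m = read_nexus(nex)
    res = search_mp(m, _search_config(cfg, "search"))
    trees_path = workdir / "mp_trees.nwk"
    trees_path.write_text(
        "".join(t.newick(lengths=False) + "\n" for t in res.trees))
    run_log = {"score": res.score, "n_trees": len(res.trees),
               "exact": res.exact, "seed": res.seed}
    (workdir / "search.json").write_text(json.dumps(run_log, indent=1))
    _write_manifest(workdir, "search", cfg, [nex],
                    [trees_path, workdir / "search.json"], t0, run_log)
    return trees_path


def stage_support(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    nex = _require(workdir / "supermatrix.nex", "support")
    trees_path = _require(workdir / "mp_trees.nwk", "support")
    m = read_nexus(nex)
    best = parse_newick(trees_path.read_text().splitlines()[0])
    boot = None
    if cfg.support.bootstrap_replicates > 0:
        boot = bootstrap_support(m, best, cfg.support.bootstrap_replicates,
                                 _stage_seed(cfg.seed, "bootstrap"),
                                 _search_config(cfg, "bootstrap",
                                                cfg.support))
    table = pbs_table(m, best, _search_config(cfg, "pbs", cfg.support),
                      tie_strategy=cfg.support.tie_strategy,
                      bootstrap_pct=boot)
    pbs_path = workdir / "pbs.tsv"
    nodes_path = workdir / "nodes.tsv"
    table.write_tsv(pbs_path, nodes_path)
    _write_manifest(workdir, "support", cfg, [nex, trees_path],
                    [pbs_path, nodes_path], t0,
                    {"best_score": table.best_score,
                     "n_nodes": len(table.node_ids)})
    return pbs_path


def stage_enrich(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    pbs_path = _require(workdir / "pbs.tsv", "enrich")
    nodes_path = _require(workdir / "nodes.tsv", "enrich")
    trees_path = _require(workdir / "mp_trees.nwk", "enrich")
    ann_path = _require(workdir / "sim" / "annotations.tsv", "enrich")
    best = parse_newick(trees_path.read_text().splitlines()[0])
    table = load_support_table(pbs_path, nodes_path, best)
    ann = AnnotationMap.read_tsv(ann_path)
    # annotations are keyed by family (reference gene); copy them onto the
    # partitions (ortholog sets) each family produced
    prov = pd.read_csv(_require(workdir / "provenance.tsv", "enrich"),
                       sep="\t")
    per_partition = {str(r["partition"]): ann.terms_of[str(r["family"])]
                     for _, r in prov.iterrows()
                     if str(r["family"]) in ann.terms_of}
    ann = AnnotationMap(per_partition, ann.labels, ann.parents)
    results = enrich_nodes(table, ann, cfg.enrich.correction)
    out = workdir / "enrichment.tsv"
    results_frame(results).to_csv(out, sep="\t", index=False)
    _write_manifest(workdir, "enrich", cfg, [pbs_path, nodes_path, ann_path],
                    [out], t0, {"n_tests": len(results)})
    return out


def stage_report(cfg: RunConfig) -> Path:
    t0 = time.time()
    workdir = Path(cfg.workdir)
    enr_path = _require(workdir / "enrichment.tsv", "report")
    df = pd.read_csv(enr_path, sep="\t")
    thresholds = list(cfg.enrich.tier_thresholds)
    col = "p" if cfg.enrich.tier_on == "raw" else "q"
    tiers = {str(t): int((df[col] < t).sum()) for t in thresholds}
    tiers_adj = {str(t): int((df["q"] < t).sum()) for t in thresholds}
    top = (df.sort_values(["q", "p"]).head(10)
           .to_dict(orient="records") if len(df) else [])
    report = {"tier_counts": tiers, "tier_counts_adjusted": tiers_adj,
              "tier_on": cfg.enrich.tier_on, "top_pairs": top}
    out = workdir / "report.json"
    out.write_text(json.dumps(report, indent=1))
    _write_manifest(workdir, "report", cfg, [enr_path], [out], t0)
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "orthologs": stage_orthologs,
    "matrix": stage_matrix,
    "search": stage_search,
    "support": stage_support,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_stage(stage: str, cfg: RunConfig) -> Path:
    if stage not in _STAGE_FUNCS:
        raise ConfigError(
            f"unknown stage {stage!r}; choose from {', '.join(STAGES)}")
    return _STAGE_FUNCS[stage](cfg)


def run_all(cfg: RunConfig) -> dict[str, Path]:
    return {stage: run_stage(stage, cfg) for stage in STAGES}
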