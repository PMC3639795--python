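"""End-to-end orchestration: extract -> cluster -> coding -> features ->
rank -> tree, as one reproducible, seeded run with persisted stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    cluster_features,
    coding_potential,
    genome_io,
    homology_clustering,
    iorf_extraction,
    ranking_stats,
    rna_structure,
)
from .homology_clustering import Cluster
from .iorf_extraction import LocatedIORF, PylisRegion

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    fasta: str
    gff: str | None = None
    positives: str | None = None  # file listing positive iORF or cluster ids
    hits: str | None = None  # optional precomputed blast outfmt-6 hits
    outdir: str = "pylseeker_run"
    seed: int = 17
    evalue: float = 1e-6
    min_downstream: int = 100
    alpha: float = 0.05
    coding_rule: str = "positive"  # see coding_potential.filter_clusters_by_coding
    strict_reciprocal: bool = False
    syn_codons_variant: str = "percent_identity"
    null_reps: int = ranking_stats.DEFAULT_REPS
    band: int = 15  # alignment band for 100-nt regions (see methods note)
    structure_max_pairs: int = 6  # strongest base pairs kept per position
    max_structure_members: int = 4  # per-cluster member cap for f_structure
    tree_leaves_per_cluster: int = 3
    run_tree: bool = True

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise FileNotFoundError(f"fasta not found: {self.fasta}")
        if self.gff is not None and not Path(self.gff).exists():
            raise FileNotFoundError(f"annotations not found: {self.gff}")
        if self.positives is not None and not Path(self.positives).exists():
            raise FileNotFoundError(f"positives file not found: {self.positives}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.min_downstream < 0:
            raise ValueError("min_downstream must be >= 0")


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and check a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


# ----------------------------------------------------------------- stage I/O


def write_iorfs_tsv(iorfs: list[LocatedIORF], path: str | Path) -> None:
    """Persist iORFs (1-based inclusive coordinates on output)."""
    rows = []
    for li in iorfs:
        o = li.orf
        rows.append(
            {
                "iorf_id": li.iorf_id,
                "genome_id": o.genome_id,
                "strand": o.strand,
                "start": o.start + 1,
                "uag_pos": o.uag_pos + 1,
                "stop_end": o.stop_end,
                "fwd_start": li.fwd_start + 1,
                "fwd_end": li.fwd_end,
                "nt_seq": o.nt_seq,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def extract_stage(genomes: list[genome_io.GenomeRecord], min_downstream: int):
    iorfs: list[LocatedIORF] = []
    for g in genomes:
        iorfs.extend(iorf_extraction.find_iorfs(g, min_downstream))
    pylis = {li.iorf_id: iorf_extraction.extract_pylis(li) for li in iorfs}
    return iorfs, pylis


def cluster_stage(
    cfg: RunConfig,
    genomes: list[genome_io.GenomeRecord],
    iorfs: list[LocatedIORF],
    pylis: dict[str, PylisRegion],
) -> list[Cluster]:
    if cfg.hits:
        matches = homology_clustering.read_blast_hits(cfg.hits, iorfs, cfg.evalue)
    else:
        total_nt = sum(len(g) for g in genomes)
        matches = homology_clustering.search_backend(
            list(pylis.values()), total_nt, cfg.evalue
        )
    clusters = homology_clustering.build_clusters(matches, iorfs, cfg.strict_reciprocal)
    annotations = {g.genome_id: g.features for g in genomes}
    return homology_clustering.prune_clusters(clusters, annotations)


def coding_stage(
    cfg: RunConfig,
    genomes: list[genome_io.GenomeRecord],
    clusters: list[Cluster],
):
    models = {}
    for g in genomes:
        cds = coding_potential.extract_training_cds(g)
        models[g.genome_id] = coding_potential.train_coding_model(cds, g.genome_id)
    member_scores: dict[str, float] = {}
    for cl in clusters:
        for m in cl.members:
            if m.iorf_id not in member_scores:
                member_scores[m.iorf_id] = coding_potential.score_iorf(
                    models[m.orf.genome_id], m
                ).log_odds
    f_cod = {cl.cluster_id: coding_potential.f_coding(cl, member_scores) for cl in clusters}
    surviving = coding_potential.filter_clusters_by_coding(clusters, f_cod, cfg.coding_rule)
    return models, member_scores, f_cod, surviving


def _structure_members(cluster: Cluster, cap: int) -> list[str]:
    ids = sorted(cluster.member_ids)
    if len(ids) <= cap:
        return ids
    idx = np.linspace(0, len(ids) - 1, cap).round().astype(int)
    return [ids[i] for i in idx]


def feature_stage(
    cfg: RunConfig,
    clusters: list[Cluster],
    pylis: dict[str, PylisRegion],
    f_cod: dict[str, float],
) -> list[cluster_features.FeatureVector]:
    bpp_cache: dict[str, rna_structure.BasePairMatrix] = {}

    def bpp(iid: str) -> rna_structure.BasePairMatrix:
        if iid not in bpp_cache:
            bpp_cache[iid] = rna_structure.basepair_probabilities(pylis[iid].nt)
        return bpp_cache[iid]

    vectors = []
    for cl in clusters:
        regions = [pylis[i] for i in cl.member_ids]
        f_size, f_org, f_up, f_down = cluster_features.simple_features(cl)
        ids = _structure_members(cl, cfg.max_structure_members)
        pair_scores = [
            rna_structure.pmcomp_score(
                bpp(a), bpp(b), band=cfg.band, max_pairs_per_pos=cfg.structure_max_pairs
            )
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        ]
        raw = {
            "f_size": f_size,
            "f_organisms": f_org,
            "f_upstream": f_up,
            "f_downstream": f_down,
            "f_diversity": cluster_features.f_diversity(regions),
            "f_syn_codons": cluster_features.f_syn_codons(regions, cfg.syn_codons_variant),
            "f_structure": rna_structure.f_structure(pair_scores),
            "f_coding": f_cod[cl.cluster_id],
        }
        vectors.append(cluster_features.FeatureVector(cl.cluster_id, raw))
    return cluster_features.normalize_features(vectors)


def load_positives(path: str | Path, clusters: list[Cluster]) -> list[str]:
    """Resolve a positives file (one iORF or cluster id per line) to
    cluster ids."""
    wanted = {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    pos: list[str] = []
    for cl in clusters:
        if cl.cluster_id in wanted or wanted & set(cl.member_ids):
            pos.append(cl.cluster_id)
    return sorted(set(pos))


def rank_stage(
    cfg: RunConfig,
    vectors: list[cluster_features.FeatureVector],
    positives: list[str],
):
    if not positives:
        raise ValueError(
            "no positive clusters resolved; the ranking stage requires at "
            "least one known positive example"
        )
    N = len(vectors)
    null = ranking_stats.sample_mean_rank_null(
        N, len(positives), cfg.null_reps, seed=cfg.seed
    )
    normalized = {v.cluster_id: v.normalized for v in vectors}
    pvalues: dict[str, float] = {}
    feature_ranks: dict[str, dict[str, int]] = {}
    for feat in cluster_features.ALL_FEATURES:
        ranks = ranking_stats.rank_clusters(
            {cid: normalized[cid][feat] for cid in normalized}, "high"
        )
        feature_ranks[feat] = ranks
        pvalues[feat] = ranking_stats.mean_rank_pvalue(
            [ranks[p] for p in positives], null
        )
    selected = ranking_stats.select_significant_features(pvalues, cfg.alpha)
    if not selected:
        raise ValueError("no feature is significant at alpha; cannot rank")
    model = ranking_stats.optimize_weights(normalized, selected, positives, seed=cfg.seed)
    table = ranking_stats.final_ranking(model, normalized)
    stats = {
        "N": N,
        "n_positives": len(positives),
        "reps": null.reps,
        "mu": null.mu,
        "sigma": null.sigma,
        "pvalues": pvalues,
        "selected": selected,
        "weights": model.weights,
        "objective": model.objective,
        "seed": cfg.seed,
        "positives": positives,
    }
    return model, table, stats


def tree_stage(
    cfg: RunConfig,
    clusters: list[Cluster],
    positives: list[str],
    pylis: dict[str, PylisRegion],
) -> rna_structure.PhyloTree | None:
    """NJ dendrogram of PYLIS regions from the positive clusters,
    distances 1/score from the structural alignment."""
    leaf_ids: list[str] = []
    for cl in clusters:
        if cl.cluster_id in positives:
            leaf_ids.extend(_structure_members(cl, cfg.tree_leaves_per_cluster))
    if len(leaf_ids) < 3:
        logger.warning("tree stage skipped: fewer than 3 leaves")
        return None
    mats = {i: rna_structure.basepair_probabilities(pylis[i].nt) for i in leaf_ids}
    n = len(leaf_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = rna_structure.pmcomp_score(
                mats[leaf_ids[i]], mats[leaf_ids[j]],
                band=cfg.band, max_pairs_per_pos=cfg.structure_max_pairs,
            )
            d[i, j] = d[j, i] = rna_structure.struct_distance(s)
    return rna_structure.neighbor_joining(d, leaf_ids)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages, persisting each stage's output in the run
    directory; returns the run directory path."""
    cfg.validate()
    if cfg.positives is None:
        raise ValueError("ranking requires a positives file in the config")
    if cfg.gff is None:
        raise ValueError("the coding stage requires annotations (gff) in the config")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name):
        t0 = time.time()
        logger.info("stage %s", name)
        return lambda **extra: log.append({"stage": name, "wall_s": round(time.time() - t0, 3), **extra})

    done = stage("load")
    genomes = genome_io.read_fasta(cfg.fasta)
    if cfg.gff:
        for g in genomes:
            g.features = genome_io.read_annotations(cfg.gff, genome=g)
    done(genomes=len(genomes))

    done = stage("extract")
    iorfs, pylis = extract_stage(genomes, cfg.min_downstream)
    write_iorfs_tsv(iorfs, outdir / "iorfs.tsv")
    done(iorfs=len(iorfs))

    done = stage("cluster")
    clusters = cluster_stage(cfg, genomes, iorfs, pylis)
    done(clusters=len(clusters))

    done = stage("coding")
    models, member_scores, f_cod, surviving = coding_stage(cfg, genomes, clusters)
    for gid, model in models.items():
        model.to_json(outdir / f"coding_model_{gid}.json")
    done(clusters_surviving=len(surviving))

    done = stage("features")
    vectors = feature_stage(cfg, surviving, pylis, f_cod)
    feat_rows = []
    for v in vectors:
        row = {"cluster_id": v.cluster_id}
        row.update(v.raw)
        row.update({f"norm_{k}": x for k, x in v.normalized.items()})
        feat_rows.append(row)
    pd.DataFrame(feat_rows).to_csv(outdir / "features.tsv", sep="\t", index=False)
    clusters_json = {
        cl.cluster_id: cl.member_ids for cl in surviving
    }
    (outdir / "clusters.json").write_text(json.dumps(clusters_json, indent=1))
    done(features=len(vectors))

    done = stage("rank")
    positives = load_positives(cfg.positives, surviving)
    model, table, stats = rank_stage(cfg, vectors, positives)
    table.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
    (outdir / "stats.json").write_text(json.dumps(stats, indent=1))
    done(selected=stats["selected"])

    if cfg.run_tree:
        done = stage("tree")
        tree = tree_stage(cfg, surviving, positives, pylis)
        if tree is not None:
            (outdir / "tree.nwk").write_text(tree.newick + "\n")
        done()

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return outdir


__all__ = [
    "RunConfig",
    "cluster_stage",
    "coding_stage",
    "extract_stage",
    "feature_stage",
    "load_positives",
    "rank_stage",
    "run_pipeline",
    "tree_stage",
    "validate_config",
    "write_iorfs_tsv",
]
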