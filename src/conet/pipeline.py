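"""End-to-end pipeline driver: counts to networks, reports, and curves.

Runs the full analysis per sample group (e.g. one network per season):
optional second-level clustering, abundance and prevalence filtering,
normalization, environmental co-rows, null-model thresholds, consensus
network, topology, keystone calls, and the extinction-scenario attack curve.
Every randomized stage draws its seed deterministically from the master seed
plus the stage name, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io
from ._util import derive_seed
from .clustering import aggregate_counts, build_nscs, filter_min_abundance
from .keystone import find_key_nodes
from .network import build_consensus, determine_thresholds
from .preprocessing import append_env, normalize, prevalence_filter
from .robustness import cascading_attack, summary_json
from .topology import compute_topology

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    counts_path: str
    out_dir: str
    env_path: str | None = None
    similarity_path: str | None = None
    groups_path: str | None = None
    seed: int = 0

    cluster_threshold: float = 97.0
    min_total_abundance: int = 3
    min_prevalence: float = 0.10
    normalization_variant: str = "log-ratio"
    pseudocount: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.01
    n_jitter: int = 1000
    persistence_cutoff: float = 0.5
    n_boot: int = 10_000
    ci: float = 0.95
    attack_removals: int | None = None
    loss_levels: tuple[float, ...] = (0.5, 0.95)
    stage_seeds: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "loss_levels" in payload:
            payload["loss_levels"] = tuple(payload["loss_levels"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loss_levels"] = list(self.loss_levels)
        return d

    def stage_seed(self, stage: str) -> int:
        if stage in self.stage_seeds:
            return self.stage_seeds[stage]
        return derive_seed(self.seed, stage)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the pipeline; returns the output directory.

    Writes, per sample group: the filtered count table, the normalized table,
    the threshold JSON, the consensus network (GraphML + edge-list TSV), the
    topology report (JSON + two-column TSV), the keystone table, and the
    attack curve (CSV + summary JSON); plus a run manifest recording the
    configuration, its hash, every stage seed, and the SHA-256 of every
    artifact.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    counts = io.read_counts(config.counts_path)
    if config.similarity_path:
        sim = io.read_similarity(config.similarity_path)
        assignment = build_nscs(sim, threshold=config.cluster_threshold)
        counts = aggregate_counts(counts, assignment)
        io.write_assignment(assignment, out_dir / "nsc_assignment.tsv")
    counts = filter_min_abundance(counts, config.min_total_abundance)

    env = io.read_table(config.env_path) if config.env_path else None

    if config.groups_path:
        groups = io.read_groups(config.groups_path)
        missing = sorted(set(counts.columns) - set(groups))
        if missing:
            raise ValueError(f"samples missing from group file: {missing}")
        unknown = sorted(set(groups) - set(counts.columns))
        if unknown:
            raise ValueError(f"group file lists unknown samples: {unknown}")
    else:
        groups = {s: "all" for s in counts.columns}
    group_names = sorted(set(groups.values()))

    artifacts: list[Path] = []
    stage_seeds_used: dict[str, int] = {}
    for group in group_names:
        samples = [s for s in counts.columns if groups[s] == group]
        gdir = out_dir / group
        gdir.mkdir(exist_ok=True)
        logger.info("group %s: %d samples", group, len(samples))

        sub = counts[samples]
        filtered = prevalence_filter(sub, config.min_prevalence)
        io.write_table(filtered, gdir / "filtered_counts.tsv")

        norm = normalize(
            filtered,
            variant=config.normalization_variant,
            pseudocount=config.pseudocount,
        )
        if env is not None:
            norm = append_env(norm, env)
        io.write_normalized(norm, gdir / "normalized.tsv")

        t_seed = config.stage_seed(f"thresholds:{group}")
        stage_seeds_used[f"thresholds:{group}"] = t_seed
        thresholds = determine_thresholds(
            norm,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=t_seed,
        )
        (gdir / "thresholds.json").write_text(thresholds.to_json() + "\n")

        c_seed = config.stage_seed(f"consensus:{group}")
        stage_seeds_used[f"consensus:{group}"] = c_seed
        abundances = filtered.sum(axis=1).astype(float).to_dict()
        net = build_consensus(
            norm,
            thresholds,
            n_jitter=config.n_jitter,
            persistence_cutoff=config.persistence_cutoff,
            seed=c_seed,
            abundances=abundances,
        )
        io.write_graphml(net, gdir / "network.graphml")
        io.write_edge_list(net, gdir / "edges.tsv")

        if net.number_of_nodes() > 0:
            m_seed = config.stage_seed(f"modularity:{group}")
            stage_seeds_used[f"modularity:{group}"] = m_seed
            report = compute_topology(net, modularity_seed=m_seed)
            (gdir / "topology.json").write_text(report.to_json() + "\n")
            (gdir / "topology_table.tsv").write_text(report.to_table())

        if net.number_of_nodes() >= 3:
            k_seed = config.stage_seed(f"keystones:{group}")
            stage_seeds_used[f"keystones:{group}"] = k_seed
            keys = find_key_nodes(net, n_boot=config.n_boot, ci=config.ci, seed=k_seed)
            keys.table.to_csv(gdir / "keystones.tsv", sep="\t")
            (gdir / "keystones.json").write_text(keys.summary_json() + "\n")

        if net.number_of_nodes() > 0 and net.number_of_edges() > 0:
            n_rem = config.attack_removals
            if n_rem is None or n_rem > net.number_of_nodes():
                n_rem = net.number_of_nodes()
            curve = cascading_attack(net, n_removals=n_rem)
            (gdir / "attack.csv").write_text(curve.to_csv())
            (gdir / "attack_summary.json").write_text(
                summary_json(curve, config.loss_levels) + "\n"
            )
        artifacts.extend(sorted(p for p in gdir.iterdir() if p.is_file()))

    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest = {
        "package": "conet",
        "master_seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stage_seeds": stage_seeds_used,
        "groups": group_names,
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p) for p in artifacts
        },
    }
    io.write_json(manifest, out_dir / "manifest.json")
    return out_dir
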