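"""End-to-end orchestration: filter -> extract -> tally -> per-library and
cross-library reports, with a machine-readable run manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from . import __version__
from .annotate import AnchorConfig, annotate_all
from .clustering import assign_clusters, nj_tree, pairwise_distances, write_distance_tsv
from .codon import cohort_rare_codon_stats, load_usage_table, write_codon_report_tsv
from .errors import PipelineStageError, UndefinedStatisticError, VnarpanError
from .repertoire import (
    length_stats,
    shared_abundance_correlation,
    top_n,
    trajectory,
    write_comparison_json,
    write_trajectories_tsv,
)
from .repertoire import tally as tally_records
from .seqio import filter_by_length, read_sequences, write_round_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full-pipeline configuration.

    inputs maps library name -> list of per-round read files (round 0 first,
    contiguous). organisms maps library name -> 'bacteria' or 'yeast'.
    """

    inputs: dict[str, list[str]]
    out_dir: str
    organisms: dict[str, str] = field(default_factory=dict)
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    min_len: int = 400
    strict_min_len: bool = True
    top_n_cluster: int = 100
    top_n_codon: int = 10
    cluster_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.inputs:
            raise ValueError("at least one library is required")
        for library, paths in self.inputs.items():
            if not paths:
                raise ValueError(f"library {library!r} has no round files")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = json.load(handle)
        anchors = AnchorConfig(**raw.get("anchors", {}))
        return cls(
            inputs=raw["inputs"],
            out_dir=raw["out_dir"],
            organisms=raw.get("organisms", {}),
            anchors=anchors,
            min_len=raw.get("min_len", 400),
            strict_min_len=raw.get("strict_min_len", True),
            top_n_cluster=raw.get("top_n_cluster", 100),
            top_n_codon=raw.get("top_n_codon", 10),
            cluster_threshold=raw.get("cluster_threshold", 0.5),
            seed=raw.get("seed", 0),
        )

    def to_jsonable(self) -> dict:
        return {
            "inputs": self.inputs,
            "out_dir": self.out_dir,
            "organisms": self.organisms,
            "anchors": {
                "five_prime_pattern": self.anchors.five_prime_pattern,
                "three_prime_pattern": self.anchors.three_prime_pattern,
                "min_cdr3_len": self.anchors.min_cdr3_len,
                "max_cdr3_len": self.anchors.max_cdr3_len,
            },
            "min_len": self.min_len,
            "strict_min_len": self.strict_min_len,
            "top_n_cluster": self.top_n_cluster,
            "top_n_codon": self.top_n_codon,
            "cluster_threshold": self.cluster_threshold,
            "seed": self.seed,
        }


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return (and write) the manifest.

    Any stage failure raises PipelineStageError; partial outputs stay on
    disk and the manifest records a FAILED marker for the stage.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_jsonable(),
        "config_hash": _config_hash(cfg),
        "libraries": {},
        "comparisons": {},
        "status": "RUNNING",
    }
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")

    def flush():
        with open(manifest_path, "w", encoding="utf-8") as out:
            json.dump(manifest, out, indent=1)

    def fail(stage: str, exc: Exception):
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        flush()
        raise PipelineStageError(stage, str(exc)) from exc

    tables_by_library: dict[str, list] = {}
    for library, paths in cfg.inputs.items():
        lib_entry: dict = {"rounds": []}
        manifest["libraries"][library] = lib_entry
        tables = []
        for round_idx, path in enumerate(paths):
            stage = f"{library}/R{round_idx}"
            if not os.path.exists(path):
                fail(stage, FileNotFoundError(f"missing round file {path!r}"))
            try:
                reads = list(read_sequences(path))
                kept, fstats = filter_by_length(reads, cfg.min_len, cfg.strict_min_len)
                records, rstats = annotate_all(kept, cfg.anchors)
                table = tally_records(records, label=f"{library}/R{round_idx}")
                table_path = os.path.join(cfg.out_dir, f"{library}_R{round_idx}_table.tsv")
                write_round_table(table, table_path)
                lstats = length_stats(table)
            except VnarpanError as exc:
                fail(stage, exc)
            tables.append(table)
            log.info(
                "%s: %d reads, %d after length filter, %d CDR3s (%d unique), %d rejected",
                stage, len(reads), fstats.kept, table.total, table.n_unique, rstats.total,
            )
            lib_entry["rounds"].append(
                {
                    "input": path,
                    "reads": len(reads),
                    "length_filter": {"kept": fstats.kept, "dropped": fstats.dropped},
                    "rejections": dict(rstats.by_reason),
                    "cdr3_reads": table.total,
                    "unique_cdr3": table.n_unique,
                    "length_median": lstats.median,
                    "length_max": lstats.max,
                    "table": table_path,
                }
            )
        tables_by_library[library] = tables

        # trajectories of the final round's top clonotypes
        try:
            final = tables[-1]
            tops = [c for c, _, _ in top_n(final, cfg.top_n_codon)]
            traj_path = os.path.join(cfg.out_dir, f"{library}_trajectories.tsv")
            write_trajectories_tsv(traj_path, [trajectory(tables, c) for c in tops])
            lib_entry["trajectories"] = traj_path

            # homology clustering of the final round's top clonotypes
            cluster_seqs = [c for c, _, _ in top_n(final, cfg.top_n_cluster)]
            if len(cluster_seqs) >= 2:
                dm = pairwise_distances(cluster_seqs)
                tree = nj_tree(dm)
                newick_path = os.path.join(cfg.out_dir, f"{library}_top{cfg.top_n_cluster}.nwk")
                with open(newick_path, "w", encoding="utf-8") as out:
                    out.write(tree.to_newick() + "\n")
                dist_path = os.path.join(cfg.out_dir, f"{library}_distances.tsv")
                write_distance_tsv(dist_path, dm)
                clusters = assign_clusters(dm, cfg.cluster_threshold)
                clusters_path = os.path.join(cfg.out_dir, f"{library}_clusters.tsv")
                with open(clusters_path, "w", encoding="utf-8") as out:
                    out.write("cdr3\tcluster\n")
                    for label in dm.labels:
                        out.write(f"{label}\t{clusters[label]}\n")
                lib_entry["tree"] = newick_path
                lib_entry["distances"] = dist_path
                lib_entry["clusters"] = clusters_path

            # codon report on the final round, per-library organism
            organism = cfg.organisms.get(library, "bacteria")
            usage = load_usage_table(organism)
            cstats = cohort_rare_codon_stats(final, usage, top=cfg.top_n_codon)
            codon_path = os.path.join(cfg.out_dir, f"{library}_codon_report.tsv")
            write_codon_report_tsv(codon_path, cstats)
            lib_entry["codon"] = {
                "organism": organism,
                "mean_rare_pct": cstats.mean,
                "sd_rare_pct": cstats.sd,
                "n": cstats.n,
                "report": codon_path,
            }
        except VnarpanError as exc:
            fail(f"{library}/reports", exc)

    # cross-library shared-abundance correlations (first and final round)
    libraries = list(cfg.inputs)
    for i in range(len(libraries)):
        for j in range(i + 1, len(libraries)):
            a_name, b_name = libraries[i], libraries[j]
            pair_key = f"{a_name}~{b_name}"
            entry: dict = {}
            for which, idx in (("round0", 0), ("final", -1)):
                ta = tables_by_library[a_name][idx]
                tb = tables_by_library[b_name][idx]
                try:
                    r, n_shared = shared_abundance_correlation(ta, tb)
                    cmp_path = os.path.join(
                        cfg.out_dir, f"{pair_key.replace('~', '_')}_{which}.json"
                    )
                    write_comparison_json(cmp_path, ta, tb, r, n_shared)
                    entry[which] = {"r": r, "n_shared": n_shared, "report": cmp_path}
                except UndefinedStatisticError as exc:
                    entry[which] = {"error": str(exc)}
            manifest["comparisons"][pair_key] = entry

    manifest["status"] = "OK"
    flush()
    return manifest
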