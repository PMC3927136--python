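"""End-to-end workflow: filter -> classify (NBC and/or search+LCA) -> novelty
-> per-sample comparison, with a machine-readable run log.

Identical configuration and seed give byte-identical artifacts.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

from . import __version__
from .compare import build_count_table, subsample
from .lca import LCAConfig, assign_lca, summarize_assignments, write_assignment_table
from .nbc import NBCConfig, classify_many, train, write_classification_table
from .novelty import NoveltyConfig, profile_leaf_groups, tier_reads
from .preprocess import FilterConfig, ReadRecord, quality_filter, remove_by_name
from .search import SearchConfig, search_nucleotide, write_hits_tabular
from .seqio import read_group_file, parse_fasta, write_fasta
from .taxonomy import ReferenceDB

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_reads"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    output_dir: str
    method: str = "both"  # "nbc", "lca", or "both"
    seed: int = 0
    removal_names: frozenset[str] = frozenset()
    subsample_depth: Optional[int] = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    nbc_cfg: NBCConfig = field(default_factory=NBCConfig)
    search_cfg: SearchConfig = field(default_factory=SearchConfig)
    lca_cfg: LCAConfig = field(default_factory=LCAConfig)
    novelty_cfg: NoveltyConfig = field(default_factory=NoveltyConfig)


def load_reads(fasta_path, group_path=None) -> list[ReadRecord]:
    groups = read_group_file(group_path) if group_path else {}
    return [
        ReadRecord(name.split()[0], seq, groups.get(name.split()[0], "all"))
        for name, seq in parse_fasta(fasta_path)
    ]


def run_pipeline(
    reads: list[ReadRecord], db: ReferenceDB, cfg: RunConfig
) -> dict[str, str]:
    """Run the full workflow; returns a mapping of artifact name -> path."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    log: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "method": cfg.method,
        "parameters": {
            "filter": asdict(cfg.filter_cfg),
            "nbc": asdict(cfg.nbc_cfg),
            "search": asdict(cfg.search_cfg),
            "lca": asdict(cfg.lca_cfg),
            "novelty": asdict(cfg.novelty_cfg),
        },
        "stages": {},
    }

    def path(name: str) -> str:
        p = os.path.join(cfg.output_dir, name)
        artifacts[name] = p
        return p

    # ---- filter -----------------------------------------------------------
    try:
        kept, rejected = quality_filter(reads, cfg.filter_cfg)
        kept, unmatched = remove_by_name(kept, set(cfg.removal_names))
        write_fasta(((r.read_id, r.sequence) for r in kept), path("filtered.fasta"))
        with open(path("rejected.tsv"), "w", encoding="utf-8") as fh:
            fh.write("read_id\treason\n")
            for read, reason in rejected:
                fh.write(f"{read.read_id}\t{reason}\n")
        log["stages"]["filter"] = {
            "in": len(reads),
            "kept": len(kept),
            "rejected": len(rejected),
            "removed_by_name": len(reads) - len(rejected) - len(kept),
            "unmatched_removal_names": unmatched,
        }
    except Exception as exc:  # noqa: BLE001 - stage accounting
        raise PipelineError("filter", exc) from exc

    nbc_results = None
    if cfg.method in ("nbc", "both"):
        try:
            model = train(db, cfg.nbc_cfg)
            nbc_results = classify_many(kept, model, cfg.nbc_cfg, cfg.seed)
            write_classification_table(nbc_results, path("nbc_classifications.tsv"))
            log["stages"]["nbc"] = {"classified": len(nbc_results)}
        except Exception as exc:
            raise PipelineError("nbc", exc) from exc

    assignments = None
    report = None
    if cfg.method in ("lca", "both"):
        try:
            hitsets = [search_nucleotide(r, db, cfg.search_cfg) for r in kept]
            write_hits_tabular(hitsets, path("hits.tsv"))
            log["stages"]["search"] = {
                "queries": len(hitsets),
                "with_hits": sum(1 for h in hitsets if h),
            }
        except Exception as exc:
            raise PipelineError("search", exc) from exc
        try:
            assignments = [assign_lca(h, db.tree, cfg.lca_cfg) for h in hitsets]
            write_assignment_table(assignments, path("assignments.tsv"))
            counts, unassigned = summarize_assignments(assignments, db.tree)
            with open(path("node_counts.tsv"), "w", encoding="utf-8") as fh:
                fh.write("node\treads\n")
                for name, count in counts.most_common():
                    fh.write(f"{name}\t{count}\n")
                fh.write(f"(unassigned)\t{unassigned}\n")
            log["stages"]["lca"] = {
                "assigned": len(assignments) - unassigned,
                "unassigned": unassigned,
            }
        except Exception as exc:
            raise PipelineError("lca", exc) from exc
        try:
            report = tier_reads(
                kept, hitsets, db, db.tree,
                cfg.novelty_cfg, cfg.lca_cfg, cfg.search_cfg,
            )
            profile_leaf_groups(report, kept, db, cfg.novelty_cfg, cfg.search_cfg)
            report.write_tier_table(path("tier_report.tsv"))
            with open(path("mismatch_profiles.tsv"), "w", encoding="utf-8") as fh:
                fh.write("taxon\treference\tconserved_mismatches\tpositions\n")
                for taxon, prof in sorted(report.group_profiles.items()):
                    fh.write(
                        f"{taxon}\t{prof.reference_accession}\t{prof.count}\t"
                        + ",".join(map(str, prof.positions))
                        + "\n"
                    )
            log["stages"]["novelty"] = dict(report.tier_counts())
        except Exception as exc:
            raise PipelineError("novelty", exc) from exc

        try:
            by_sample: dict[str, list] = {}
            for read, assignment in zip(kept, assignments):
                by_sample.setdefault(read.sample or "all", []).append(assignment)
            table = build_count_table(by_sample, db.tree)
            if cfg.subsample_depth is not None:
                table = subsample(table, cfg.subsample_depth, cfg.seed)
            table.to_tsv(path("count_table.tsv"))
            log["stages"]["compare"] = {
                "samples": len(table.samples),
                "nodes": len(table.nodes),
            }
        except Exception as exc:
            raise PipelineError("compare", exc) from exc

    if nbc_results is not None and assignments is not None:
        try:
            lines = ["read_id\tnbc_node\tlca_node\tagree"]
            agree = 0
            for res, assignment in zip(nbc_results, assignments):
                lca_name = assignment.node.name if assignment.node else "-"
                same = res.reported_taxon == lca_name
                agree += same
                lines.append(
                    f"{res.read_id}\t{res.reported_taxon}\t{lca_name}\t"
                    f"{int(same)}"
                )
            with open(path("nbc_vs_lca.tsv"), "w", encoding="utf-8") as fh:
                fh.write("\n".join(lines) + "\n")
            log["stages"]["agreement"] = {
                "reads": len(nbc_results),
                "agreeing": agree,
            }
        except Exception as exc:
            raise PipelineError("agreement", exc) from exc

    with open(path("run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return artifacts
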