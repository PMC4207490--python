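"""End-to-end orchestration: annotations + domain tables -> classified clusters.

Chains the pipeline stages in order: shell-gene identification, locus
construction, pfam filtering and profiling, satellite classification,
corpus statistics over the scoring corpus (complete, non-satellite loci),
all-pairs similarity, hierarchical Markov clustering, confirmed-category
assignment, and per-cluster summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io
from .classify import (
    LocusCategory,
    SATELLITE,
    assign_confirmed,
    classify_satellites,
    summarize_categories,
)
from .cluster import ClusterNode, build_network, cluster_tree
from .config import RunConfig
from .loci import build_loci, identify_shell_genes
from .model import DomainHit, Gene, LocusPfamProfile, ProspectiveLocus, Scaffold
from .profiles import filter_pfam_hits, profile_locus
from .scoring import CorpusPfamStats, ScoreBreakdown, score_all_pairs
from .summary import occurrence_all_levels, representatives_all_levels

logger = logging.getLogger("bmclocus")


@dataclass
class PipelineResult:
    scaffolds: list[Scaffold] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    loci: list[ProspectiveLocus] = field(default_factory=list)
    profiles: dict[str, LocusPfamProfile] = field(default_factory=dict)
    assignments: list = field(default_factory=list)
    categories: list[LocusCategory] = field(default_factory=list)
    stats: Optional[CorpusPfamStats] = None
    breakdowns: list[ScoreBreakdown] = field(default_factory=list)
    tree: Optional[ClusterNode] = None
    summary: Optional[pd.DataFrame] = None

    @property
    def genome_of(self) -> dict[str, str]:
        return {locus.locus_id: locus.genome_id for locus in self.loci}


def discover_annotations(input_dir: str | Path) -> list[Path]:
    """Annotation files under a directory (GenBank .gbk/.gb/.gbff or .gff3)."""
    input_dir = Path(input_dir)
    paths = []
    for pattern in ("*.gbk", "*.gb", "*.gbff", "*.gff3"):
        paths.extend(sorted(input_dir.glob(pattern)))
    return paths


def run_pipeline(
    annotation_paths: Sequence[str | Path],
    shell_domtbl: str | Path,
    pfam_domtbl: str | Path,
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """Run every stage and return all intermediate and final objects."""
    config = config or RunConfig()
    result = PipelineResult()

    for path in annotation_paths:
        path = Path(path)
        fmt = "gff3" if path.suffix == ".gff3" else "genbank"
        fasta = path.with_suffix(".faa") if fmt == "gff3" else None
        if fasta is not None and not fasta.exists():
            fasta = None
        scaffolds, genes, _ = io.read_annotation(path, format=fmt, fasta_path=fasta)
        result.scaffolds.extend(scaffolds)
        result.genes.extend(genes)

    shell_hits = io.read_domtbl(shell_domtbl)
    pfam_hits = io.read_domtbl(pfam_domtbl)

    shell_genes = identify_shell_genes(
        shell_hits, result.genes, threshold=config.shell_evalue
    )
    result.loci = build_loci(
        shell_genes, result.genes, result.scaffolds, window=config.window
    )
    logger.info(
        "built %d prospective loci (%d truncated)",
        len(result.loci), sum(l.truncated for l in result.loci),
    )

    filtered = filter_pfam_hits(pfam_hits, evalue_cut=config.pfam_evalue)
    for locus in result.loci:
        if locus.truncated:
            continue
        profile, assignments = profile_locus(locus, filtered)
        result.profiles[locus.locus_id] = profile
        result.assignments.extend(assignments)

    # satellite rules are genome-level
    by_genome: dict[str, list[ProspectiveLocus]] = {}
    for locus in result.loci:
        by_genome.setdefault(locus.genome_id, []).append(locus)
    for genome_id in sorted(by_genome):
        result.categories.extend(
            classify_satellites(
                by_genome[genome_id],
                result.assignments,
                bmc_associated_pfams=config.bmc_associated_pfams,
                nearby_radius=config.nearby_radius,
            )
        )

    satellite_ids = {
        c.locus_id for c in result.categories if c.category == SATELLITE
    }
    scoring_profiles = [
        p for locus_id, p in sorted(result.profiles.items())
        if locus_id not in satellite_ids
    ]
    if len(scoring_profiles) >= 2:
        result.stats = CorpusPfamStats.from_profiles(scoring_profiles)
        result.breakdowns = score_all_pairs(
            scoring_profiles, params=config.scoring, stats=result.stats
        )
        plan = dict(config.plan)
        plan["root"] = (config.inflation, config.score_cutoff)
        result.tree = cluster_tree(result.breakdowns, plan)
        if config.confirmed_anchors:
            result.categories = assign_confirmed(
                result.categories, result.tree, config.confirmed_anchors
            )
    result.summary = summarize_categories(
        result.categories, result.loci, result.genome_of
    )
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every tabular and network output of a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_locus_table(result.loci, outdir / "loci.tsv")
    io.write_profile_table(result.assignments, outdir / "profiles.tsv")
    io.write_category_table(result.categories, outdir / "categories.tsv")
    if result.summary is not None:
        result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    if result.breakdowns:
        io.write_score_table(result.breakdowns, outdir / "scores.tsv")
    if result.tree is not None:
        io.write_cluster_table(result.tree, outdir / "clusters.tsv")
        edges, singletons = build_network(result.breakdowns, score_cutoff=0.0)
        cluster_of = {}
        for top in result.tree.children:
            for leaf in top.leaves():
                for member in leaf.members:
                    cluster_of[member] = {"cluster": leaf.name}
        io.write_graphml(
            edges, outdir / "network.graphml",
            singletons=singletons, node_attributes=cluster_of,
        )
        profiles = result.profiles
        scored = {p.locus_id: p for p in profiles.values() if p.locus_id in cluster_of}
        io.write_occurrence_table(
            occurrence_all_levels(result.tree, scored), outdir / "occurrence.tsv"
        )
        io.write_representatives_table(
            representatives_all_levels(result.tree, scored),
            outdir / "representatives.tsv",
        )
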