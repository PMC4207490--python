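"""Per-cluster pfam occurrence and representative-locus selection.

For each cluster at every tree level, the proportion of member loci
containing each pfam is tabulated (heatmap-ready long format).  One
representative locus per cluster is chosen to best capture the cluster's
pfam diversity: its representative score adds the occurrence proportions of
every pfam it contains and subtracts those of every cluster pfam it lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .cluster import ClusterNode
from .model import LocusPfamProfile


@dataclass(frozen=True)
class PfamOccurrence:
    cluster_name: str
    pfam_acc: str
    proportion: float


@dataclass(frozen=True)
class RepresentativeChoice:
    cluster_name: str
    locus_id: str
    representative_score: float
    tie_break_applied: str  # none | characterized | reference | majority_pfam_override


def pfam_occurrence(
    cluster: ClusterNode, profiles: Mapping[str, LocusPfamProfile]
) -> list[PfamOccurrence]:
    """Proportion of cluster members containing each pfam (rows sorted by accession)."""
    members = sorted(cluster.members)
    if not members:
        raise ValueError(f"cluster {cluster.name} is empty")
    counts: dict[str, int] = {}
    for locus_id in members:
        for p in profiles[locus_id].pfam_set:
            counts[p] = counts.get(p, 0) + 1
    return [
        PfamOccurrence(cluster.name, p, counts[p] / len(members))
        for p in sorted(counts)
    ]


def occurrence_all_levels(
    root: ClusterNode, profiles: Mapping[str, LocusPfamProfile]
) -> list[PfamOccurrence]:
    """Occurrence rows for every cluster in the tree (excluding the root)."""
    rows: list[PfamOccurrence] = []

    def _walk(node: ClusterNode) -> None:
        rows.extend(pfam_occurrence(node, profiles))
        for child in node.children:
            _walk(child)

    for top in root.children:
        _walk(top)
    return rows


def representative_score(
    locus_id: str,
    proportions: Mapping[str, float],
    profiles: Mapping[str, LocusPfamProfile],
) -> float:
    """Sum of proportions of pfams the locus contains minus those it lacks."""
    pfams = profiles[locus_id].pfam_set
    return sum(
        prop if p in pfams else -prop for p, prop in sorted(proportions.items())
    )


def select_representative(
    cluster: ClusterNode,
    profiles: Mapping[str, LocusPfamProfile],
    characterized: Sequence[str] = (),
    reference: Sequence[str] = (),
) -> RepresentativeChoice:
    """Pick the cluster member that best captures its pfam diversity.

    The highest representative score wins; exact ties prefer a
    characterized locus, then one from a reference genome, then the
    lexicographically smallest locus_id.  If a pfam present in the majority
    of members is missing from the winner but present in the runner-up, the
    runner-up is selected instead (applied once, to the top two only).
    """
    members = sorted(cluster.members)
    if not members:
        raise ValueError(f"cluster {cluster.name} is empty")
    proportions = {
        o.pfam_acc: o.proportion for o in pfam_occurrence(cluster, profiles)
    }
    scores = {m: representative_score(m, proportions, profiles) for m in members}
    # scores are sums of rationals c/n; round so summation order cannot turn
    # a mathematical tie (granularity ~1/n^2) into a spurious strict order
    rounded = {m: round(s, 9) for m, s in scores.items()}
    characterized_set, reference_set = set(characterized), set(reference)

    def rank_key(locus_id: str) -> tuple:
        return (
            -rounded[locus_id],
            0 if locus_id in characterized_set else 1,
            0 if locus_id in reference_set else 1,
            locus_id,
        )

    ranked = sorted(members, key=rank_key)
    top = ranked[0]
    tie_break = "none"
    tied = [m for m in members if rounded[m] == rounded[top]]
    if len(tied) > 1:
        if top in characterized_set:
            tie_break = "characterized"
        elif top in reference_set:
            tie_break = "reference"
        else:
            tie_break = "none"  # resolved lexicographically
    if len(ranked) > 1:
        runner_up = ranked[1]
        majority = {p for p, prop in proportions.items() if prop > 0.5}
        missing = majority - profiles[top].pfam_set
        if missing & profiles[runner_up].pfam_set:
            return RepresentativeChoice(
                cluster.name, runner_up, scores[runner_up], "majority_pfam_override"
            )
    return RepresentativeChoice(cluster.name, top, scores[top], tie_break)


def representatives_all_levels(
    root: ClusterNode,
    profiles: Mapping[str, LocusPfamProfile],
    characterized: Sequence[str] = (),
    reference: Sequence[str] = (),
) -> list[RepresentativeChoice]:
    choices: list[RepresentativeChoice] = []

    def _walk(node: ClusterNode) -> None:
        choices.append(select_representative(node, profiles, characterized, reference))
        for child in node.children:
            _walk(child)

    for top in root.children:
        _walk(top)
    return choices
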