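"""Satellite identification and locus category assignment.

Satellite loci carry an insufficient shell-gene complement (only PF00936-
based BMC-H/T genes or only PF03319-based BMC-P genes, not both) and rely on
another BMC locus in the same genome for the missing components.  A locus is
a satellite when three conditions all hold: insufficient complement, all
shell genes contiguous, and at least one other non-satellite locus in the
genome — and no common BMC-associated pfam sits immediately next to the
shell genes.  Loci failing only the multi-locus condition, or carrying
nearby BMC-associated pfams, are satellite-like.  Satellites are excluded
from corpus statistics, scoring and clustering; satellite-like loci stay in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import BMC_P, PfamAssignment, ProspectiveLocus, SHELL_CLASSES

logger = logging.getLogger("bmclocus")

SATELLITE = "satellite"
SATELLITE_LIKE = "satellite-like"
CANDIDATE = "candidate"
CONFIRMED = "confirmed"
TRUNCATED = "truncated"

#: pfams extremely common among BMC loci, used for the "BMC-associated gene
#: immediately nearby" satellite veto: aldehyde dehydrogenase, iron-containing
#: alcohol dehydrogenase, PduL phosphotransacylase, PduV/EutP
DEFAULT_BMC_ASSOCIATED_PFAMS = frozenset(
    {"PF00171", "PF00465", "PF06130", "PF10662"}
)

#: "immediately nearby": within this many ORFs of a shell gene
DEFAULT_NEARBY_RADIUS = 2


@dataclass
class LocusCategory:
    locus_id: str
    category: str
    rationale: list[str] = field(default_factory=list)
    type_label: Optional[str] = None


def _insufficient_shell(locus: ProspectiveLocus) -> bool:
    """Only PF00936-based (H/T) or only PF03319-based (P) shell genes."""
    counts = locus.shell_class_counts()
    has_hex = counts["BMC-H"] + counts["BMC-T"] > 0
    has_pent = counts[BMC_P] > 0
    return has_hex != has_pent


def _shell_contiguous(locus: ProspectiveLocus) -> bool:
    """All shell genes at consecutive ordinals, no intervening gene."""
    ordinals = sorted(sg.gene.ordinal for sg in locus.shell_genes)
    return all(b - a == 1 for a, b in zip(ordinals, ordinals[1:]))


def _bmc_pfam_nearby(
    locus: ProspectiveLocus,
    assignments: Sequence[PfamAssignment],
    bmc_pfams: frozenset[str],
    radius: int,
) -> bool:
    """Any BMC-associated pfam within ``radius`` ORFs of a shell gene?"""
    shell_ordinals = [sg.gene.ordinal for sg in locus.shell_genes]
    gene_ordinals = {g.gene_id: g.ordinal for g in locus.genes}
    for a in assignments:
        if a.locus_id != locus.locus_id or a.pfam_acc not in bmc_pfams:
            continue
        ordinal = gene_ordinals.get(a.gene_id)
        if ordinal is None:
            continue
        if any(abs(ordinal - so) <= radius for so in shell_ordinals):
            return True
    return False


def classify_satellites(
    loci: Sequence[ProspectiveLocus],
    assignments: Sequence[PfamAssignment] = (),
    bmc_associated_pfams: frozenset[str] = DEFAULT_BMC_ASSOCIATED_PFAMS,
    nearby_radius: int = DEFAULT_NEARBY_RADIUS,
) -> list[LocusCategory]:
    """Classify all loci of one genome as satellite / satellite-like / candidate.

    Requires the genome's full locus list, since the third satellite
    condition (another non-satellite locus exists) is genome-level.
    Truncated loci are categorized ``truncated`` and take no part in the
    satellite logic.
    """
    complete = [l for l in loci if not l.truncated]
    insufficient = {l.locus_id: _insufficient_shell(l) for l in complete}
    contiguous = {l.locus_id: _shell_contiguous(l) for l in complete}
    # non-satellite anchors: loci with a sufficient (or non-contiguous) complement
    n_non_satellite = sum(
        1
        for l in complete
        if not (insufficient[l.locus_id] and contiguous[l.locus_id])
    )

    categories: list[LocusCategory] = []
    for locus in loci:
        if locus.truncated:
            categories.append(
                LocusCategory(locus.locus_id, TRUNCATED, ["truncated_by_scaffold_edge"])
            )
            continue
        rationale: list[str] = []
        if not insufficient[locus.locus_id]:
            categories.append(
                LocusCategory(locus.locus_id, CANDIDATE, ["sufficient_shell_complement"])
            )
            continue
        rationale.append("insufficient_shell_complement")
        if not contiguous[locus.locus_id]:
            rationale.append("shell_genes_not_contiguous")
            categories.append(LocusCategory(locus.locus_id, CANDIDATE, rationale))
            continue
        rationale.append("contiguous_shell_genes")
        nearby = _bmc_pfam_nearby(
            locus, assignments, bmc_associated_pfams, nearby_radius
        )
        other_locus = n_non_satellite >= 1
        if nearby:
            rationale.append("bmc_associated_pfam_nearby")
            categories.append(LocusCategory(locus.locus_id, SATELLITE_LIKE, rationale))
        elif not other_locus:
            rationale.append("no_other_non_satellite_locus")
            categories.append(LocusCategory(locus.locus_id, SATELLITE_LIKE, rationale))
        else:
            rationale.append("other_non_satellite_locus_present")
            rationale.append("no_bmc_associated_pfam_nearby")
            categories.append(LocusCategory(locus.locus_id, SATELLITE, rationale))
    return categories


def assign_confirmed(
    categories: Sequence[LocusCategory],
    cluster_root,
    anchors: Mapping[str, str],
) -> list[LocusCategory]:
    """Promote candidates sharing a locus-type cluster with an anchor.

    ``anchors`` maps a locus_id (or a dotted cluster name) to a type label
    for an experimentally characterized locus.  For a locus anchor, the
    deepest cluster containing it defines the locus type; all candidate
    members become ``confirmed`` with that label.
    """
    confirmed: dict[str, str] = {}
    for anchor, label in anchors.items():
        node = cluster_root.find(anchor)
        if node is None:
            # locus-id anchor: deepest leaf cluster containing it
            for leaf in cluster_root.leaves():
                if anchor in leaf.members:
                    node = leaf
                    break
        if node is None:
            logger.warning("anchor %s not found in corpus; label %s skipped", anchor, label)
            continue
        for locus_id in node.members:
            confirmed[locus_id] = label
    out: list[LocusCategory] = []
    for cat in categories:
        if cat.category == CANDIDATE and cat.locus_id in confirmed:
            out.append(
                LocusCategory(
                    cat.locus_id,
                    CONFIRMED,
                    cat.rationale + ["clustered_with_characterized_anchor"],
                    type_label=confirmed[cat.locus_id],
                )
            )
        else:
            out.append(cat)
    return out


def summarize_categories(
    categories: Iterable[LocusCategory],
    loci: Sequence[ProspectiveLocus] = (),
    genome_of: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Category counts plus mean shell-gene class complement per complete locus.

    Returns a long-format table: rows count each category (zero-filled),
    genomes per category when genome assignments are given, and the average
    BMC-H/T/P gene counts per non-truncated locus.
    """
    cats = list(categories)
    rows = []
    counts = {c: 0 for c in (SATELLITE, SATELLITE_LIKE, CANDIDATE, CONFIRMED, TRUNCATED)}
    for cat in cats:
        counts[cat.category] += 1
    for name, value in counts.items():
        rows.append({"metric": f"n_{name}", "value": float(value)})
    rows.append({"metric": "n_loci", "value": float(len(cats))})
    if genome_of:
        rows.append(
            {"metric": "n_genomes", "value": float(len(set(genome_of.values())))}
        )
        satellite_genomes = {
            genome_of[c.locus_id] for c in cats
            if c.category == SATELLITE and c.locus_id in genome_of
        }
        rows.append(
            {"metric": "n_satellite_genomes", "value": float(len(satellite_genomes))}
        )
    complete = [l for l in loci if not l.truncated]
    if complete:
        for shell_class in SHELL_CLASSES:
            mean = sum(
                l.shell_class_counts()[shell_class] for l in complete
            ) / len(complete)
            key = shell_class.replace("-", "_").lower()
            rows.append({"metric": f"mean_{key}_per_locus", "value": mean})
    return pd.DataFrame(rows, columns=["metric", "value"])
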