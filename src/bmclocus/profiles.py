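"""Pfam assignment to locus genes and ORF distance from the envelope.

Each locus is represented downstream by its pfam set (shell-protein genes
excluded).  Every pfam carries the minimum number of open reading frames
between the envelope and the gene encoding it: 0 for genes overlapping the
envelope, counted in intervening genes otherwise.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import DomainHit, Gene, LocusPfamProfile, PfamAssignment, ProspectiveLocus

#: loose per-domain e-value cutoff for pfam assignment
PFAM_EVALUE = 0.01

#: fraction of the shorter alignment that two same-protein alignments must
#: share before the higher-e-value one is discarded
OVERLAP_FRACTION = 0.5


def _overlap_violates(a: DomainHit, b: DomainHit, fraction: float) -> bool:
    overlap = min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1
    if overlap <= 0:
        return False
    return overlap > fraction * min(a.ali_length, b.ali_length)


def resolve_overlaps(
    hits: Sequence[DomainHit], fraction: float = OVERLAP_FRACTION
) -> list[DomainHit]:
    """Greedy-by-e-value elimination of overlapping same-protein alignments.

    Hits are considered best-first (e-value ascending; ties by smaller
    ali_start then lexicographic pfam accession, for determinism); a hit is
    kept only if it overlaps no already-kept hit by more than ``fraction``
    of the shorter alignment.  The survivors contain no violating pair.
    """
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.evalue, h.ali_start, h.pfam_acc)):
        if all(not _overlap_violates(hit, other, fraction) for other in kept):
            kept.append(hit)
    return kept


def filter_pfam_hits(
    hits: Iterable[DomainHit],
    evalue_cut: float = PFAM_EVALUE,
    overlap_fraction: float = OVERLAP_FRACTION,
) -> list[DomainHit]:
    """Apply the e-value cutoff, then resolve overlapping alignments per protein."""
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.evalue <= evalue_cut:
            by_protein.setdefault(hit.protein_id, []).append(hit)
    filtered: list[DomainHit] = []
    for protein_id in sorted(by_protein):
        filtered.extend(resolve_overlaps(by_protein[protein_id], overlap_fraction))
    return filtered


def orf_distance(gene: Gene, locus: ProspectiveLocus) -> int:
    """Minimal ORF distance between the envelope and ``gene``.

    A gene sharing any bp with the envelope is inside (distance 0).  An
    outside gene is d ORFs away when it is the d-th gene beyond the nearest
    envelope-bounding shell gene (ordinal difference): the gene immediately
    adjacent to the envelope edge is at d=1.
    """
    if gene.overlaps(locus.envelope_start, locus.envelope_end):
        return 0
    bounding = [
        min(locus.shell_genes, key=lambda sg: sg.gene.start).gene,
        max(locus.shell_genes, key=lambda sg: sg.gene.end).gene,
    ]
    return min(abs(gene.ordinal - b.ordinal) for b in bounding)


def profile_locus(
    locus: ProspectiveLocus, filtered_hits: Iterable[DomainHit]
) -> tuple[LocusPfamProfile, list[PfamAssignment]]:
    """Build a locus pfam profile from overlap-filtered hits.

    Shell-protein genes are excluded.  A pfam occurring on several genes is
    stored once with the minimal ORF distance (and the e-value of the hit at
    that distance).  Loci with no pfam-bearing non-shell gene yield an empty
    profile, which is valid.
    """
    if locus.truncated:
        raise ValueError(
            f"locus {locus.locus_id} is truncated; profiles are built only for "
            "complete loci"
        )
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for hit in filtered_hits:
        hits_by_protein.setdefault(hit.protein_id, []).append(hit)

    shell_ids = locus.shell_gene_ids
    assignments: list[PfamAssignment] = []
    for gene in locus.genes:
        if gene.gene_id in shell_ids or not gene.protein_id:
            continue
        gene_hits = hits_by_protein.get(gene.protein_id)
        if not gene_hits:
            continue
        d = orf_distance(gene, locus)
        for hit in gene_hits:
            assignments.append(
                PfamAssignment(
                    locus_id=locus.locus_id,
                    gene_id=gene.gene_id,
                    pfam_acc=hit.pfam_acc,
                    evalue=hit.evalue,
                    distance=d,
                )
            )

    distances: dict[str, int] = {}
    for a in assignments:
        if a.pfam_acc not in distances or a.distance < distances[a.pfam_acc]:
            distances[a.pfam_acc] = a.distance
    return LocusPfamProfile(locus_id=locus.locus_id, distances=distances), assignments
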