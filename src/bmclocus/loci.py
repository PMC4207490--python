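"""Shell-protein gene identification and prospective BMC locus construction.

A prospective BMC locus is the union of windows extending 10 kb upstream and
downstream of each shell-protein gene; overlapping windows on one scaffold
merge into a single locus.  The *envelope* is the largest region of the locus
flanked by shell-protein genes.  Loci clipped by a scaffold end are flagged
``truncated`` (potentially incomplete) and excluded from downstream scoring
by default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .model import BMC_H, BMC_P, BMC_T, DomainHit, Gene, ProspectiveLocus, Scaffold, ShellGene
from .profiles import resolve_overlaps

logger = logging.getLogger("bmclocus")

#: default e-value threshold for accepting a shell-protein homolog
SHELL_EVALUE = 1e-05

#: default half-window around a shell gene, in bp
WINDOW_BP = 10_000

#: accessions treated as the BMC-H/BMC-T shell domain. Includes plain
#: PF00936 and the common name given to expanded/custom builds of that HMM.
PF00936_LIKE = frozenset({"PF00936", "PF00936_expanded"})
PF03319_ACCS = frozenset({"PF03319"})


def identify_shell_genes(
    hits: Iterable[DomainHit],
    genes: Sequence[Gene],
    threshold: float = SHELL_EVALUE,
    pf00936_like: frozenset[str] = PF00936_LIKE,
    pf03319_accs: frozenset[str] = PF03319_ACCS,
) -> list[ShellGene]:
    """Accept genes with qualifying shell-domain hits as shell proteins.

    Hits with per-domain e-value <= ``threshold`` qualify.  Classification
    follows domain architecture: one PF00936-like domain -> BMC-H, two or
    more (the fused pseudohexamer) -> BMC-T, a PF03319 domain -> BMC-P.
    Domains counted toward the BMC-T call are de-duplicated with the same
    >50%-overlap resolution used for pfam filtering, so a re-reported
    alignment is not mistaken for a fusion.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.pfam_acc in pf00936_like or hit.pfam_acc in pf03319_accs:
            by_protein.setdefault(hit.protein_id, []).append(hit)

    gene_by_protein = {g.protein_id: g for g in genes if g.protein_id}
    shell_genes: list[ShellGene] = []
    for protein_id in sorted(by_protein):
        qualifying = [h for h in by_protein[protein_id] if h.evalue <= threshold]
        if not qualifying:
            continue
        gene = gene_by_protein.get(protein_id)
        if gene is None:
            logger.warning("shell hit on unknown protein %s; skipped", protein_id)
            continue
        hex_hits = resolve_overlaps(
            [h for h in qualifying if h.pfam_acc in pf00936_like]
        )
        pent_hits = [h for h in qualifying if h.pfam_acc in pf03319_accs]
        if hex_hits and pent_hits:
            logger.warning(
                "protein %s carries both PF00936-like and PF03319 domains; "
                "classifying by the lower e-value",
                protein_id,
            )
            if min(h.evalue for h in hex_hits) <= min(h.evalue for h in pent_hits):
                pent_hits = []
            else:
                hex_hits = []
        if hex_hits:
            shell_class = BMC_T if len(hex_hits) >= 2 else BMC_H
            best = min(h.evalue for h in hex_hits)
            count = len(hex_hits)
        else:
            shell_class = BMC_P
            best = min(h.evalue for h in pent_hits)
            count = len(pent_hits)
        shell_genes.append(
            ShellGene(gene=gene, shell_class=shell_class, best_evalue=best, domain_count=count)
        )
    return shell_genes


def _merge_windows(
    windows: list[tuple[int, int, bool, ShellGene]]
) -> list[tuple[int, int, bool, list[ShellGene]]]:
    """Union overlapping closed intervals; abutting-but-disjoint stay apart."""
    merged: list[tuple[int, int, bool, list[ShellGene]]] = []
    for start, end, clipped, shell in sorted(windows, key=lambda w: (w[0], w[1])):
        if merged and start <= merged[-1][1]:  # >=1 shared bp
            prev_start, prev_end, prev_clip, members = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end), prev_clip or clipped, members + [shell])
        else:
            merged.append((start, end, clipped, [shell]))
    return merged


def build_loci(
    shell_genes: Sequence[ShellGene],
    genes: Sequence[Gene],
    scaffolds: Sequence[Scaffold],
    window: int = WINDOW_BP,
    genome_id: Optional[str] = None,
) -> list[ProspectiveLocus]:
    """Merge per-shell-gene windows into prospective BMC loci.

    Per scaffold, the interval [start - window, end + window] around each
    shell gene is clipped to the scaffold, then overlapping intervals are
    unioned; each union is one locus.  Membership is every gene sharing at
    least one bp with the locus span; the envelope runs from the minimum
    shell-gene start to the maximum shell-gene end.  A locus is ``truncated``
    only if clipping actually occurred (a scaffold ending exactly at the
    window edge is not truncation).
    """
    scaffold_by_id = {s.scaffold_id: s for s in scaffolds}
    genes_by_scaffold: dict[str, list[Gene]] = {}
    for gene in genes:
        genes_by_scaffold.setdefault(gene.scaffold_id, []).append(gene)

    by_scaffold: dict[str, list[ShellGene]] = {}
    for sg in shell_genes:
        by_scaffold.setdefault(sg.gene.scaffold_id, []).append(sg)

    loci: list[ProspectiveLocus] = []
    for scaffold_id in sorted(by_scaffold):
        scaffold = scaffold_by_id[scaffold_id]
        windows = []
        for sg in by_scaffold[scaffold_id]:
            raw_start = sg.gene.start - window
            raw_end = sg.gene.end + window
            start = max(1, raw_start)
            end = min(scaffold.length, raw_end)
            clipped = raw_start < 1 or raw_end > scaffold.length
            windows.append((start, end, clipped, sg))
        for span_start, span_end, clipped, members in _merge_windows(windows):
            env_start = min(sg.gene.start for sg in members)
            env_end = max(sg.gene.end for sg in members)
            member_genes = sorted(
                (
                    g
                    for g in genes_by_scaffold.get(scaffold_id, [])
                    if g.overlaps(span_start, span_end)
                ),
                key=lambda g: g.ordinal,
            )
            gid = genome_id or scaffold.genome_id
            loci.append(
                ProspectiveLocus(
                    locus_id=f"{scaffold_id}:{span_start}-{span_end}",
                    genome_id=gid,
                    scaffold_id=scaffold_id,
                    span_start=span_start,
                    span_end=span_end,
                    envelope_start=env_start,
                    envelope_end=env_end,
                    genes=member_genes,
                    shell_genes=sorted(members, key=lambda sg: sg.gene.start),
                    truncated=clipped,
                )
            )
    return loci
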