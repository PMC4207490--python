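"""Core data model for BMC locus analysis.

Bacterial microcompartments (BMCs) are proteinaceous organelles whose shells
are built from hexameric (BMC-H, one PF00936 domain), pseudohexameric
(BMC-T, two fused PF00936 domains) and pentameric (BMC-P, one PF03319
domain) proteins.  The genes encoding a BMC and its encapsulated enzymes are
typically clustered on the chromosome; this package works with such gene
neighborhoods ("prospective BMC loci") as its unit of analysis.

All genomic coordinates are 1-based and inclusive on both ends (GenBank
convention); GFF3 input is already 1-based inclusive and is taken as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Shell protein classes by domain architecture.
BMC_H = "BMC-H"
BMC_T = "BMC-T"
BMC_P = "BMC-P"

SHELL_CLASSES = (BMC_H, BMC_T, BMC_P)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene (open reading frame) on a scaffold.

    ``ordinal`` is the 0-based rank of the gene along its scaffold ordered by
    start coordinate; it is the unit in which ORF distances are counted and
    is derived from coordinates, never from file order.
    """

    gene_id: str
    scaffold_id: str
    start: int  # 1-based, inclusive
    end: int  # inclusive, end >= start
    strand: str  # "+" or "-"
    protein_id: Optional[str]
    ordinal: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    def overlaps(self, start: int, end: int) -> bool:
        """True if this gene shares >= 1 bp with the closed interval [start, end]."""
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class Scaffold:
    """A replicon or contig carrying genes."""

    scaffold_id: str
    length: int
    genome_id: str


@dataclass(frozen=True)
class DomainHit:
    """One domain row from an hmmsearch per-domain table (domtblout).

    ``evalue`` is the independent (per-domain) e-value; ``ali_start`` /
    ``ali_end`` are 1-based inclusive residue coordinates of the alignment on
    the target protein.
    """

    protein_id: str
    pfam_acc: str
    evalue: float
    ali_start: int
    ali_end: int
    hmm_length: int = 0

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"hit {self.pfam_acc} on {self.protein_id}: ali_start > ali_end"
            )
        if self.evalue <= 0:
            raise ValueError(
                f"hit {self.pfam_acc} on {self.protein_id}: e-value must be positive"
            )

    @property
    def ali_length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class ShellGene:
    """A gene accepted as a BMC shell protein homolog.

    ``shell_class`` follows domain architecture: a single PF00936-like domain
    gives BMC-H, two or more give BMC-T (the fused pseudohexamer), and a
    PF03319 domain gives BMC-P.
    """

    gene: Gene
    shell_class: str
    best_evalue: float
    domain_count: int

    def __post_init__(self) -> None:
        if self.shell_class not in SHELL_CLASSES:
            raise ValueError(f"unknown shell class {self.shell_class!r}")


@dataclass
class ProspectiveLocus:
    """A merged genomic window around one or more shell-protein genes.

    The *span* is the union of the +/- window intervals (clipped to the
    scaffold); the *envelope* is the maximal sub-interval bounded by shell
    protein genes (min shell start to max shell end).  ``truncated`` is set
    when any contributing window was clipped by a scaffold end, which marks
    the locus as potentially incomplete.
    """

    locus_id: str
    genome_id: str
    scaffold_id: str
    span_start: int
    span_end: int
    envelope_start: int
    envelope_end: int
    genes: list[Gene] = field(default_factory=list)
    shell_genes: list[ShellGene] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.span_start <= self.envelope_start <= self.envelope_end <= self.span_end):
            raise ValueError(
                f"locus {self.locus_id}: envelope must lie within the span"
            )

    @property
    def shell_gene_ids(self) -> set[str]:
        return {sg.gene.gene_id for sg in self.shell_genes}

    def shell_class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in SHELL_CLASSES}
        for sg in self.shell_genes:
            counts[sg.shell_class] += 1
        return counts


@dataclass(frozen=True)
class PfamAssignment:
    """A filtered pfam hit attributed to a (non-shell) locus gene.

    ``distance`` is the minimum number of open reading frames between the
    envelope and the gene carrying the pfam; 0 means the gene overlaps the
    envelope.
    """

    locus_id: str
    gene_id: str
    pfam_acc: str
    evalue: float
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("ORF distance cannot be negative")


@dataclass
class LocusPfamProfile:
    """A locus represented by its pfam set with per-pfam minimal ORF distance."""

    locus_id: str
    distances: dict[str, int] = field(default_factory=dict)

    @property
    def pfam_set(self) -> frozenset[str]:
        return frozenset(self.distances)

    def distance(self, pfam_acc: str) -> int:
        return self.distances[pfam_acc]
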