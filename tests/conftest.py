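"""Shared fixtures: in-memory locus builders and a session synthetic corpus."""

from __future__ import annotations

import pytest

from bmclocus import (
    DomainHit,
    Gene,
    LocusPfamProfile,
    ProspectiveLocus,
    Scaffold,
    ShellGene,
    generate_corpus,
)


def make_genes(n: int, scaffold_id: str = "s1", pitch: int = 1000,
               length: int = 900, offset: int = 0) -> list[Gene]:
    """n genes at fixed pitch with ordinals 0..n-1."""
    genes = []
    for i in range(n):
        start = offset + i * pitch + 1
        genes.append(
            Gene(
                gene_id=f"{scaffold_id}_g{i}",
                scaffold_id=scaffold_id,
                start=start,
                end=start + length - 1,
                strand="+",
                protein_id=f"{scaffold_id}_p{i}",
                ordinal=i,
            )
        )
    return genes


def make_shell(gene: Gene, shell_class: str = "BMC-H",
               evalue: float = 1e-10) -> ShellGene:
    count = 2 if shell_class == "BMC-T" else 1
    return ShellGene(gene=gene, shell_class=shell_class,
                     best_evalue=evalue, domain_count=count)


def make_locus(genes, shell_indices, locus_id="L1", genome_id="G1",
               shell_classes=None, truncated=False) -> ProspectiveLocus:
    """Locus over all given genes with shell genes at the given ordinals."""
    shell_genes = []
    for rank, i in enumerate(shell_indices):
        cls = shell_classes[rank] if shell_classes else "BMC-H"
        shell_genes.append(make_shell(genes[i], cls))
    env_start = min(sg.gene.start for sg in shell_genes)
    env_end = max(sg.gene.end for sg in shell_genes)
    return ProspectiveLocus(
        locus_id=locus_id,
        genome_id=genome_id,
        scaffold_id=genes[0].scaffold_id,
        span_start=min(g.start for g in genes),
        span_end=max(g.end for g in genes),
        envelope_start=env_start,
        envelope_end=env_end,
        genes=list(genes),
        shell_genes=shell_genes,
        truncated=truncated,
    )


def make_profile(locus_id: str, pfams: dict[str, int]) -> LocusPfamProfile:
    return LocusPfamProfile(locus_id=locus_id, distances=dict(pfams))


def make_hit(protein_id="p1", pfam_acc="PF00001", evalue=1e-10,
             ali_start=1, ali_end=100, hmm_length=100) -> DomainHit:
    return DomainHit(protein_id=protein_id, pfam_acc=pfam_acc, evalue=evalue,
                     ali_start=ali_start, ali_end=ali_end, hmm_length=hmm_length)


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """Deterministic zero-noise synthetic corpus (3 types x 5 loci + plants)."""
    outdir = tmp_path_factory.mktemp("corpus")
    generate_corpus(outdir, seed=11)
    return outdir
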