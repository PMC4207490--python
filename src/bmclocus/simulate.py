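"""Deterministic synthetic genomes with planted BMC locus types.

Generates small multi-genome corpora in the same standard formats the
pipeline consumes (GenBank or GFF3 + protein FASTA annotations, HMMER3
per-domain tables) so every stage is testable without downloads.  Each
planted locus follows a :class:`LocusTemplate` describing its ordered gene
layout; the generator also plants a bare satellite locus, a locus truncated
at a scaffold edge, and a protein with two overlapping pfam alignments, to
exercise the satellite rules, the truncation flag and the overlap filter.

Layout geometry uses 900 bp genes at a 1000 bp pitch, so a 10 kb window
spans about ten ORFs and every distance-weight regime (d = 0 .. 4+) is
reachable.  Shell and pfam e-values are drawn log-uniformly inside their
accepting bands (1e-30 .. 1e-6); decoy hits are drawn above the thresholds
(shell: 1e-4 .. 1e-2; pfam: 0.02 .. 1) so both sides of each cutoff are
exercised.  All randomness flows from a single seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

GENE_LENGTH = 900
GENE_PITCH = 1000
MARGIN = 3000

#: decoy pfams never used by a template
DECOY_PFAMS = tuple(f"PF9{i:04d}" for i in range(1, 9))


@dataclass(frozen=True)
class GeneSpec:
    """One gene in a template layout: a shell class, pfams, or empty."""

    shell_class: Optional[str] = None  # BMC-H / BMC-T / BMC-P
    pfams: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.shell_class and self.pfams:
            raise ValueError("a gene spec is either shell or pfam-bearing, not both")


@dataclass
class LocusTemplate:
    """Ordered gene layout of one planted locus type.

    The envelope of a realized locus runs from the first to the last shell
    gene; pfam genes before/after the shell block land outside the envelope
    at known ORF distances.
    """

    type_name: str
    layout: list[GeneSpec]
    identifying_pfam: Optional[str] = None

    def __post_init__(self) -> None:
        if not any(spec.shell_class for spec in self.layout):
            raise ValueError(
                f"template {self.type_name!r} is infeasible: no shell gene in layout"
            )

    @property
    def pfams(self) -> set[str]:
        return {p for spec in self.layout for p in spec.pfams}


def default_templates() -> list[LocusTemplate]:
    """Three distinct planted locus types, loosely modeled on PDU-, EUT- and
    alpha-carboxysome-style gene neighborhoods."""
    s, p = (
        lambda cls: GeneSpec(shell_class=cls),
        lambda *accs: GeneSpec(pfams=tuple(accs)),
    )
    return [
        # propanediol-utilization-style metabolosome: dehydratase subunits,
        # full catalytic core, cobalamin reactivation, regulator, transporter
        LocusTemplate(
            "typeA",
            [
                p("PF01261"),  # d=2 beyond the left envelope edge
                GeneSpec(),
                s("BMC-H"), s("BMC-H"),
                p("PF02286"), p("PF02287"), p("PF02288"),
                p("PF00171"), p("PF00465"), p("PF06130"),
                p("PF10662"), p("PF02310"), p("PF01923"),
                p("PF00072"), p("PF02690"),
                s("BMC-T"), s("BMC-P"),
            ],
            identifying_pfam="PF02286",
        ),
        # ethanolamine-utilization-style metabolosome: ammonia lyase
        # subunits, catalytic core, eutJ/eutQ-like accessories, regulator
        LocusTemplate(
            "typeB",
            [
                s("BMC-H"),
                p("PF06751"), p("PF05985"),
                p("PF00171"), p("PF00465"), p("PF10662"),
                p("PF04816"), p("PF06249"), p("PF01512"),
                p("PF00571"), p("PF12640"),
                s("BMC-T"), s("BMC-P"),
                p("PF04061"),  # d=1 beyond the right envelope edge
            ],
            identifying_pfam="PF06751",
        ),
        # alpha-carboxysome-style locus: CsoS2/CsoSCA analogs, RuBisCO
        # subunits, carbon-uptake and regulatory neighbors
        LocusTemplate(
            "typeC",
            [
                s("BMC-H"), s("BMC-H"),
                p("PF12288"), p("PF08936"),
                p("PF00101"), p("PF00016"),
                p("PF02788"), p("PF10070"), p("PF00126"),
                s("BMC-P"),
                GeneSpec(), GeneSpec(), GeneSpec(),
                p("PF13360"),  # d=4 beyond the right envelope edge
            ],
            identifying_pfam="PF12288",
        ),
    ]


@dataclass
class _Row:
    """One per-domain table row prior to formatting."""

    protein_id: str
    pfam_acc: str
    evalue: float
    ali_start: int
    ali_end: int
    hmm_length: int
    protein_length: int


@dataclass
class _GenomeBuild:
    genome_id: str
    scaffolds: list[tuple[str, int, list[dict]]] = field(default_factory=list)


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(10 ** rng.uniform(np.log10(low), np.log10(high)))


def _build_scaffold(
    scaffold_id: str,
    specs: Sequence[GeneSpec],
    rng: np.random.Generator,
    shell_rows: list[_Row],
    pfam_rows: list[_Row],
    n_flank: int = 8,
    leading_flank: Optional[int] = None,
    dropout_rate: float = 0.0,
    extra_pfam_rate: float = 0.0,
    margin: int = MARGIN,
) -> tuple[str, int, list[dict]]:
    """Lay genes at fixed pitch and emit their domain-table rows."""
    lead = n_flank if leading_flank is None else leading_flank
    all_specs = (
        [GeneSpec()] * lead + list(specs) + [GeneSpec()] * n_flank
    )
    genes: list[dict] = []
    for idx, spec in enumerate(all_specs):
        start = margin + idx * GENE_PITCH + 1
        end = start + GENE_LENGTH - 1
        gene_id = f"{scaffold_id}_g{idx:03d}"
        protein_id = f"{scaffold_id}_p{idx:03d}"
        plen = GENE_LENGTH // 3
        genes.append(
            {
                "gene_id": gene_id,
                "protein_id": protein_id,
                "start": start,
                "end": end,
                "strand": "+" if idx % 2 == 0 else "-",
                "length": plen,
            }
        )
        if spec.shell_class:
            acc = "PF03319" if spec.shell_class == "BMC-P" else "PF00936"
            n_domains = 2 if spec.shell_class == "BMC-T" else 1
            for dom in range(n_domains):
                offset = dom * 110
                shell_rows.append(
                    _Row(
                        protein_id, acc,
                        _log_uniform(rng, 1e-30, 1e-6),
                        5 + offset, 95 + offset,
                        90 if acc == "PF00936" else 80, plen,
                    )
                )
        pfams = list(spec.pfams)
        if pfams and extra_pfam_rate > 0 and rng.random() < extra_pfam_rate:
            pfams.append(str(rng.choice(DECOY_PFAMS)))
        cursor = 1
        for acc in pfams:
            if dropout_rate > 0 and rng.random() < dropout_rate:
                continue
            span = min(100, plen - cursor)
            pfam_rows.append(
                _Row(
                    protein_id, acc,
                    _log_uniform(rng, 1e-30, 1e-6),
                    cursor, cursor + span - 1, span, plen,
                )
            )
            cursor += span + 10
    total_len = margin + len(all_specs) * GENE_PITCH + margin
    return scaffold_id, total_len, genes


_DOMTBL_HEADER = (
    "#{:<24} {:>10} {:>5} {:<20} {:>10} {:>5} {:>9} {:>6} {:>5} {:>3} {:>3} "
    "{:>9} {:>9} {:>6} {:>5} {:>5} {:>5} {:>5} {:>5} {:>5} {:>5} {:>4} {}"
).format(
    "target name", "accession", "tlen", "query name", "accession", "qlen",
    "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue", "score",
    "bias", "from", "to", "from", "to", "from", "to", "acc",
    "description of target",
)


def write_domtbl(rows: Sequence[_Row], path: Path) -> None:
    """Write rows in HMMER3 per-domain tabular format (domtblout)."""
    grouped: dict[tuple[str, str], list[_Row]] = {}
    for row in rows:
        grouped.setdefault((row.pfam_acc, row.protein_id), []).append(row)
    lines = [_DOMTBL_HEADER]
    for (pfam_acc, protein_id) in sorted(grouped):
        group = grouped[(pfam_acc, protein_id)]
        full_e = min(r.evalue for r in group)
        for num, row in enumerate(group, start=1):
            lines.append(
                f"{protein_id:<25} {'-':>10} {row.protein_length:>5} "
                f"{pfam_acc:<20} {pfam_acc + '.1':>10} {row.hmm_length:>5} "
                f"{full_e:>9.2g} {50.0:>6.1f} {0.1:>5.1f} {num:>3} {len(group):>3} "
                f"{row.evalue:>9.2g} {row.evalue:>9.2g} {45.0:>6.1f} {0.1:>5.1f} "
                f"{1:>5} {row.hmm_length:>5} {row.ali_start:>5} {row.ali_end:>5} "
                f"{max(1, row.ali_start - 2):>5} {row.ali_end + 2:>5} {0.95:>4.2f} "
                f"synthetic protein"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_genbank(build: _GenomeBuild, path: Path) -> None:
    records = []
    for scaffold_id, length, genes in build.scaffolds:
        record = SeqRecord(
            Seq("A" * length),
            id=scaffold_id,
            name=scaffold_id[:16],
            description="synthetic genome",
            annotations={
                "molecule_type": "DNA",
                "organism": build.genome_id,
                "date": "01-JAN-2000",
            },
        )
        for gene in genes:
            feature = SeqFeature(
                FeatureLocation(
                    gene["start"] - 1, gene["end"], strand=1 if gene["strand"] == "+" else -1
                ),
                type="CDS",
                qualifiers={
                    "locus_tag": [gene["gene_id"]],
                    "protein_id": [gene["protein_id"]],
                    "translation": ["M" + "A" * (gene["length"] - 1)],
                },
            )
            record.features.append(feature)
        records.append(record)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "genbank")


def _write_gff3(build: _GenomeBuild, gff_path: Path, faa_path: Path) -> None:
    lines = ["##gff-version 3"]
    fasta = []
    for scaffold_id, length, genes in build.scaffolds:
        lines.append(f"##sequence-region {scaffold_id} 1 {length}")
        for gene in genes:
            attrs = (
                f"ID={gene['gene_id']};protein_id={gene['protein_id']};"
                f"locus_tag={gene['gene_id']}"
            )
            lines.append(
                "\t".join(
                    [
                        scaffold_id, "bmclocus_sim", "CDS",
                        str(gene["start"]), str(gene["end"]), ".",
                        gene["strand"], "0", attrs,
                    ]
                )
            )
            fasta.append(f">{gene['protein_id']}\nM{'A' * (gene['length'] - 1)}")
    gff_path.write_text("\n".join(lines) + "\n")
    faa_path.write_text("\n".join(fasta) + "\n")


def generate_corpus(
    outdir: str | Path,
    templates: Optional[Sequence[LocusTemplate]] = None,
    n_per_type: int = 5,
    dropout_rate: float = 0.0,
    extra_pfam_rate: float = 0.0,
    seed: int = 0,
    fmt: str = "genbank",
    include_satellite: bool = True,
    include_truncated: bool = True,
    include_overlap_pair: bool = True,
) -> pd.DataFrame:
    """Write a synthetic corpus and return its ground-truth table.

    One genome per planted locus instance (scaffold id doubles as the truth
    key), plus optional extra genomes exercising the satellite rules, the
    truncation flag and the overlap filter.  Outputs: per-genome annotation
    files, ``shell.domtbl``, ``pfam.domtbl`` and ``truth.tsv`` under
    ``outdir``.
    """
    templates = list(templates) if templates is not None else default_templates()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    shell_rows: list[_Row] = []
    pfam_rows: list[_Row] = []
    builds: list[_GenomeBuild] = []
    truth_rows: list[dict] = []

    for template in templates:
        for i in range(n_per_type):
            genome_id = f"{template.type_name}_g{i}"
            scaffold_id = f"{template.type_name}_s{i}"
            build = _GenomeBuild(genome_id)
            build.scaffolds.append(
                _build_scaffold(
                    scaffold_id, template.layout, rng, shell_rows, pfam_rows,
                    dropout_rate=dropout_rate, extra_pfam_rate=extra_pfam_rate,
                )
            )
            builds.append(build)
            truth_rows.append(
                {
                    "genome_id": genome_id,
                    "scaffold_id": scaffold_id,
                    "type_name": template.type_name,
                    "category": "candidate",
                }
            )

    if include_satellite:
        # one genome with a full locus plus a bare two-gene BMC-H satellite
        genome_id = "satellite_g0"
        build = _GenomeBuild(genome_id)
        build.scaffolds.append(
            _build_scaffold(
                f"{genome_id}_main", templates[0].layout, rng, shell_rows, pfam_rows
            )
        )
        build.scaffolds.append(
            _build_scaffold(
                f"{genome_id}_sat",
                [GeneSpec(shell_class="BMC-H"), GeneSpec(shell_class="BMC-H")],
                rng, shell_rows, pfam_rows,
            )
        )
        builds.append(build)
        truth_rows.append(
            {
                "genome_id": genome_id, "scaffold_id": f"{genome_id}_main",
                "type_name": templates[0].type_name, "category": "candidate",
            }
        )
        truth_rows.append(
            {
                "genome_id": genome_id, "scaffold_id": f"{genome_id}_sat",
                "type_name": "satellite", "category": "satellite",
            }
        )

    if include_truncated:
        # a shell gene close to the scaffold start: the window clips -> truncated
        genome_id = "truncated_g0"
        build = _GenomeBuild(genome_id)
        build.scaffolds.append(
            _build_scaffold(
                f"{genome_id}_s0",
                [GeneSpec(shell_class="BMC-H"), GeneSpec(pfams=("PF00171",))],
                rng, shell_rows, pfam_rows,
                leading_flank=0, margin=500,
            )
        )
        builds.append(build)
        truth_rows.append(
            {
                "genome_id": genome_id, "scaffold_id": f"{genome_id}_s0",
                "type_name": "truncated", "category": "truncated",
            }
        )

    if include_overlap_pair:
        # two overlapping alignments on a flank protein of the first locus:
        # residues 1-100 vs 40-140 (61/100 overlap), the worse e-value must go
        target = f"{templates[0].type_name}_s0_p{8 + len(templates[0].layout):03d}"
        pfam_rows.append(_Row(target, "PF91001", 1e-10, 1, 100, 100, 300))
        pfam_rows.append(_Row(target, "PF91002", 1e-3, 40, 140, 101, 300))

    # decoy hits above each threshold
    decoy_protein = f"{templates[0].type_name}_s0_p000"
    shell_rows.append(
        _Row(decoy_protein, "PF00936", _log_uniform(rng, 1e-4, 1e-2), 5, 95, 90, 300)
    )
    pfam_rows.append(
        _Row(decoy_protein, str(rng.choice(DECOY_PFAMS)),
             _log_uniform(rng, 0.02, 1.0), 1, 80, 80, 300)
    )

    for build in builds:
        if fmt == "genbank":
            _write_genbank(build, outdir / f"{build.genome_id}.gbk")
        elif fmt in ("gff3", "gff3+fasta"):
            _write_gff3(
                build,
                outdir / f"{build.genome_id}.gff3",
                outdir / f"{build.genome_id}.faa",
            )
        else:
            raise ValueError(f"unknown output format {fmt!r}")
    write_domtbl(shell_rows, outdir / "shell.domtbl")
    write_domtbl(pfam_rows, outdir / "pfam.domtbl")
    truth = pd.DataFrame(
        truth_rows, columns=["genome_id", "scaffold_id", "type_name", "category"]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    _validate_truth(outdir, builds, truth, fmt)
    return truth


def _validate_truth(
    outdir: Path, builds: list[_GenomeBuild], truth: pd.DataFrame, fmt: str
) -> None:
    """Ground truth must be consistent with the emitted annotations."""
    written_scaffolds = {s[0] for b in builds for s in b.scaffolds}
    missing = set(truth["scaffold_id"]) - written_scaffolds
    if missing:
        raise RuntimeError(f"truth table references unwritten scaffolds: {missing}")
    suffix = ".gbk" if fmt == "genbank" else ".gff3"
    for build in builds:
        if not (outdir / f"{build.genome_id}{suffix}").exists():
            raise RuntimeError(f"annotation for {build.genome_id} was not written")
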