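"""Readers and writers: genome annotations, HMMER domain tables, TSV/network outputs.

GenBank parsing and the HMMER3 per-domain table (domtblout) go through
Biopython (``SeqIO``/``SearchIO``); GFF3 is read as a plain 9-column table.
Coordinates are normalized to 1-based inclusive internally (GenBank
convention; GFF3 is already 1-based inclusive).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import networkx as nx
from Bio import SearchIO, SeqIO

from .model import DomainHit, Gene, ProspectiveLocus, Scaffold

logger = logging.getLogger("bmclocus")

# minimum whitespace-separated fields in a HMMER3 per-domain table row
_DOMTBL_MIN_FIELDS = 23


class AnnotationParseError(ValueError):
    """Raised when a genome annotation or domain table cannot be parsed."""


def _assign_ordinals(
    raw: list[tuple[str, str, int, int, str, Optional[str]]]
) -> list[Gene]:
    """Build Gene records with per-scaffold ordinals derived from coordinates.

    Ordinals rank genes by start coordinate (ties by end then id), so the
    result is independent of the order features appear in the file.
    """
    genes: list[Gene] = []
    by_scaffold: dict[str, list[tuple]] = {}
    for rec in raw:
        by_scaffold.setdefault(rec[1], []).append(rec)
    for scaffold_id in sorted(by_scaffold):
        ranked = sorted(by_scaffold[scaffold_id], key=lambda r: (r[2], r[3], r[0]))
        for ordinal, (gene_id, scf, start, end, strand, protein_id) in enumerate(ranked):
            genes.append(
                Gene(
                    gene_id=gene_id,
                    scaffold_id=scf,
                    start=start,
                    end=end,
                    strand=strand,
                    protein_id=protein_id,
                    ordinal=ordinal,
                )
            )
    return genes


def _read_genbank(
    path: Path, genome_id: Optional[str]
) -> tuple[list[Scaffold], list[Gene], dict[str, str]]:
    scaffolds: list[Scaffold] = []
    raw: list[tuple] = []
    proteins: dict[str, str] = {}
    n_records = 0
    for record in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        gid = genome_id or record.annotations.get("organism") or record.id
        scaffolds.append(
            Scaffold(scaffold_id=record.id, length=len(record.seq), genome_id=gid)
        )
        cds_index = 0
        for feature in record.features:
            if feature.type != "CDS":
                continue
            cds_index += 1
            if feature.location is None:
                logger.warning(
                    "CDS %d on %s has no coordinates; skipped", cds_index, record.id
                )
                continue
            # compound (join) locations collapse to min start / max end
            start = int(feature.location.start) + 1
            end = int(feature.location.end)
            strand = "-" if feature.location.strand == -1 else "+"
            quals = feature.qualifiers
            protein_id = quals.get("protein_id", [None])[0]
            gene_id = quals.get("locus_tag", [None])[0] or protein_id or (
                f"{record.id}_cds{cds_index}"
            )
            if protein_id is None:
                logger.warning("CDS %s on %s lacks protein_id", gene_id, record.id)
            raw.append((gene_id, record.id, start, end, strand, protein_id))
            translation = quals.get("translation", [None])[0]
            if protein_id and translation:
                proteins[protein_id] = translation
    if n_records == 0:
        raise AnnotationParseError(f"{path}: no GenBank records found")
    return scaffolds, _assign_ordinals(raw), proteins


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def _read_gff3(
    path: Path, fasta_path: Optional[Path], genome_id: Optional[str]
) -> tuple[list[Scaffold], list[Gene], dict[str, str]]:
    gid = genome_id or Path(path).stem
    region_lengths: dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            if line.startswith("##sequence-region"):
                fields = line.split()
                if len(fields) >= 4:
                    region_lengths[fields[1]] = int(fields[3])
            if line.startswith("##FASTA"):
                break
    try:
        table = pd.read_csv(
            path, sep="\t", comment="#", names=_GFF_COLUMNS, dtype=str, header=None
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise AnnotationParseError(f"{path}: not parseable as GFF3 ({exc})") from exc
    if table.empty:
        raise AnnotationParseError(f"{path}: no GFF3 feature lines found")
    cds = table[table["type"] == "CDS"]
    grouped: dict[str, list] = {}
    for idx, row in cds.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise AnnotationParseError(
                f"{path}: bad coordinates in CDS record at data row {idx + 1}"
            ) from exc
        attrs = _gff_attributes(row["attributes"] or "")
        gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"cds{idx}"
        grouped.setdefault(gene_id, []).append(
            (row["seqid"], start, end, row["strand"], attrs)
        )
    raw: list[tuple] = []
    for gene_id, parts in grouped.items():
        scaffold_id = parts[0][0]
        start = min(p[1] for p in parts)
        end = max(p[2] for p in parts)
        strand = parts[0][3] if parts[0][3] in ("+", "-") else "+"
        attrs = parts[0][4]
        protein_id = attrs.get("protein_id") or attrs.get("Name")
        if protein_id is None:
            logger.warning("CDS %s in %s lacks a protein_id attribute", gene_id, path)
        raw.append((gene_id, scaffold_id, start, end, strand, protein_id))

    proteins: dict[str, str] = {}
    if fasta_path is not None:
        proteins = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    scaffold_ids = sorted({r[1] for r in raw} | set(region_lengths))
    scaffolds = []
    for scaffold_id in scaffold_ids:
        length = region_lengths.get(
            scaffold_id, max((r[3] for r in raw if r[1] == scaffold_id), default=1)
        )
        scaffolds.append(Scaffold(scaffold_id=scaffold_id, length=length, genome_id=gid))
    return scaffolds, _assign_ordinals(raw), proteins


def read_annotation(
    path: str | Path,
    format: str = "genbank",
    fasta_path: Optional[str | Path] = None,
    genome_id: Optional[str] = None,
) -> tuple[list[Scaffold], list[Gene], dict[str, str]]:
    """Parse a genome annotation into scaffolds, genes and protein sequences.

    Parameters
    ----------
    path
        GenBank flat file or GFF3 file.
    format
        ``"genbank"`` or ``"gff3"``; for GFF3 a companion protein FASTA may
        be given via ``fasta_path``.
    genome_id
        Override the genome identifier (default: organism annotation for
        GenBank, file stem for GFF3).

    Returns
    -------
    (scaffolds, genes, proteins)
        Genes carry per-scaffold ordinals; proteins are keyed by protein_id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _read_genbank(path, genome_id)
    if format in ("gff3", "gff3+fasta"):
        return _read_gff3(path, Path(fasta_path) if fasta_path else None, genome_id)
    raise ValueError(f"unknown annotation format {format!r}")


def read_domtbl(path: str | Path) -> list[DomainHit]:
    """Read a HMMER3 per-domain table (domtblout) into DomainHit records.

    One hit per domain row, using the independent (per-domain) e-value
    column.  Comment lines are ignored.
    """
    path = Path(path)
    with open(path) as handle:
        for row_number, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.split()) < _DOMTBL_MIN_FIELDS:
                raise AnnotationParseError(
                    f"{path}: row {row_number} has fewer than "
                    f"{_DOMTBL_MIN_FIELDS} columns; not a per-domain table"
                )
    hits: list[DomainHit] = []
    for query in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        accession = getattr(query, "accession", None)
        pfam_acc = accession.split(".")[0] if accession and accession != "-" else query.id
        for hit in query:
            for hsp in hit.hsps:
                hits.append(
                    DomainHit(
                        protein_id=hit.id,
                        pfam_acc=pfam_acc,
                        evalue=float(hsp.evalue),
                        ali_start=int(hsp.hit_start) + 1,
                        ali_end=int(hsp.hit_end),
                        hmm_length=int(query.seq_len or 0),
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# tabular / network output


def write_edge_list(edges: Iterable, path: str | Path) -> None:
    """Write similarity edges as TSV (locus_i, locus_j, score to 6 decimals)."""
    rows = []
    for edge in edges:
        i, j, score = edge.locus_i, edge.locus_j, edge.score
        if not pd.notna(score) or score in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite score on edge ({i}, {j})")
        rows.append((i, j, f"{score:.6f}"))
    frame = pd.DataFrame(rows, columns=["locus_i", "locus_j", "score"])
    frame.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    frame = pd.read_csv(path, sep="\t", dtype={"locus_i": str, "locus_j": str})
    return [
        (row.locus_i, row.locus_j, float(row.score)) for row in frame.itertuples()
    ]


def write_graphml(
    edges: Iterable,
    path: str | Path,
    singletons: Sequence[str] = (),
    node_attributes: Optional[dict[str, dict]] = None,
) -> None:
    """Write the similarity network as GraphML with optional node attributes."""
    graph = nx.Graph()
    for node in singletons:
        graph.add_node(node)
    for edge in edges:
        graph.add_edge(edge.locus_i, edge.locus_j, score=float(edge.score))
    if node_attributes:
        for node, attrs in node_attributes.items():
            if node in graph:
                graph.nodes[node].update(attrs)
    nx.write_graphml(graph, str(path))


def write_score_table(breakdowns: Iterable, path: str | Path) -> None:
    """Write full score breakdowns (positive/negative components) as TSV."""
    frame = pd.DataFrame(
        [
            {
                "locus_i": b.locus_i,
                "locus_j": b.locus_j,
                "positive": round(b.positive, 6),
                "negative": round(b.negative, 6),
                "score": round(b.score, 6),
            }
            for b in breakdowns
        ],
        columns=["locus_i", "locus_j", "positive", "negative", "score"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_locus_table(loci: Sequence[ProspectiveLocus], path: str | Path) -> None:
    rows = []
    for locus in loci:
        counts = locus.shell_class_counts()
        rows.append(
            {
                "locus_id": locus.locus_id,
                "genome_id": locus.genome_id,
                "scaffold_id": locus.scaffold_id,
                "span_start": locus.span_start,
                "span_end": locus.span_end,
                "envelope_start": locus.envelope_start,
                "envelope_end": locus.envelope_end,
                "n_genes": len(locus.genes),
                "n_bmc_h": counts["BMC-H"],
                "n_bmc_t": counts["BMC-T"],
                "n_bmc_p": counts["BMC-P"],
                "truncated": locus.truncated,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "locus_id", "genome_id", "scaffold_id", "span_start", "span_end",
            "envelope_start", "envelope_end", "n_genes", "n_bmc_h", "n_bmc_t",
            "n_bmc_p", "truncated",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_profile_table(assignments: Iterable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "locus_id": a.locus_id,
                "pfam_acc": a.pfam_acc,
                "gene_id": a.gene_id,
                "evalue": a.evalue,
                "distance": a.distance,
            }
            for a in assignments
        ],
        columns=["locus_id", "pfam_acc", "gene_id", "evalue", "distance"],
    ).to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"locus_id": str, "pfam_acc": str, "gene_id": str}
    )


def write_cluster_table(root, path: str | Path) -> None:
    """Write cluster membership: one row per locus per tree level."""
    rows = []

    def _walk(node):
        for locus_id in sorted(node.members):
            rows.append(
                {
                    "cluster": node.name,
                    "level": node.level,
                    "locus_id": locus_id,
                    "inflation": node.inflation,
                    "score_cutoff": node.score_cutoff,
                }
            )
        for child in node.children:
            _walk(child)

    for top in root.children:
        _walk(top)
    pd.DataFrame(
        rows, columns=["cluster", "level", "locus_id", "inflation", "score_cutoff"]
    ).to_csv(path, sep="\t", index=False)


def write_category_table(categories: Iterable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "category": c.category,
                "type_label": c.type_label or "",
                "rationale": ";".join(c.rationale),
            }
            for c in categories
        ],
        columns=["locus_id", "category", "type_label", "rationale"],
    ).to_csv(path, sep="\t", index=False)


def write_occurrence_table(occurrences: Iterable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cluster": o.cluster_name,
                "pfam_acc": o.pfam_acc,
                "proportion": round(o.proportion, 6),
            }
            for o in occurrences
        ],
        columns=["cluster", "pfam_acc", "proportion"],
    ).to_csv(path, sep="\t", index=False)


def write_representatives_table(choices: Iterable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cluster": c.cluster_name,
                "locus_id": c.locus_id,
                "representative_score": round(c.representative_score, 6),
                "tie_break": c.tie_break_applied,
            }
            for c in choices
        ],
        columns=["cluster", "locus_id", "representative_score", "tie_break"],
    ).to_csv(path, sep="\t", index=False)
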