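"""Readers and writers for the standard formats the pipeline touches.

FASTA is read with Biopython, GFF3 with gffutils; tabular files with
pandas or plain line parsing (alignment hits need per-line error
reporting).  All writers emit the same dialects the readers accept, so
record sets round-trip field-for-field.
"""
from __future__ import annotations

import logging
import math
import os
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    AlignmentHit,
    Environment,
    GeneAnnotation,
    GenomeRecord,
    ProvirusRecord,
    RANKS,
    SampleMetadata,
    TaxonomyLabel,
    TRNAAnnotation,
    ViralGene,
    check_no_overlap,
)

log = logging.getLogger("lysoscape")

_VALID_NT = set("ACGT")

METADATA_COLUMNS = [
    "genome_id", "sample_id", "environment", "depth_m", "latitude",
    "longitude", "completeness", "contamination", *RANKS, "mdt_hours",
]

PROVIRUS_COLUMNS = [
    "provirus_id", "host_genome_id", "contig_id", "start", "end",
    "category", "tvc_id", "tvg_id", "tvotu_id",
]

VIRAL_GENE_COLUMNS = [
    "provirus_id", "gene_id", "position_index", "start", "end", "strand",
    "flags", "metabolic_flag", "auxiliary_score", "category_label",
    "product_label",
]


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_NT:
        return seq
    return "".join(c if c in _VALID_NT else "N" for c in seq)


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() in {"", "NA", "na", "None"}:
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    return s or None


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def parse_metadata(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    if "genome_id" not in df.columns:
        raise ValueError(f"{path}: metadata table lacks a genome_id column")
    dupes = df["genome_id"][df["genome_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate genome_id {sorted(set(dupes))}")
    return df


def _metadata_row_to_fields(row: pd.Series):
    meta = SampleMetadata(
        sample_id=_opt_str(row.get("sample_id")) or "",
        environment=Environment(_opt_str(row.get("environment")) or "other"),
        depth_m=_opt_float(row.get("depth_m")),
        latitude=_opt_float(row.get("latitude")),
        longitude=_opt_float(row.get("longitude")),
        sample_type_source=_opt_str(row.get("sample_type_source")) or "",
    )
    taxonomy = TaxonomyLabel.from_values(
        **{r: _opt_str(row.get(r)) for r in RANKS}
    )
    return meta, taxonomy


# ---------------------------------------------------------------------------
# genomes (FASTA + GFF3 + metadata TSV)
# ---------------------------------------------------------------------------

def _translate(contig: str, ann: GeneAnnotation) -> Optional[str]:
    sub = contig[ann.start - 1 : ann.end]
    if ann.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    n_codons = len(sub) // 3
    if n_codons == 0:
        return None
    prot = str(Seq(sub[: n_codons * 3]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot or None


def _read_gff_features(gff_path: Union[str, Path]):
    """Yield gffutils features; tolerate an empty (header-only) file."""
    text = Path(gff_path).read_text()
    has_features = any(
        line.strip() and not line.startswith("#") for line in text.splitlines()
    )
    if not has_features:
        return []
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return list(db.all_features())


def parse_genomes(
    fasta_paths: Sequence[Union[str, Path]],
    gff_path: Union[str, Path],
    metadata_tsv: Union[str, Path],
) -> List[GenomeRecord]:
    """Load one GenomeRecord per FASTA file.

    The genome id is the FASTA file stem; GFF3 seqids must match contig
    ids; metadata rows are keyed by genome_id.  Unknown nucleotide
    characters are normalised to N; absent metadata values stay missing.
    """
    meta_df = parse_metadata(metadata_tsv).set_index("genome_id")

    contigs_by_genome: Dict[str, Dict[str, str]] = {}
    contig_to_genome: Dict[str, str] = {}
    for fp in fasta_paths:
        gid = Path(fp).stem
        if gid in contigs_by_genome:
            raise ValueError(f"duplicate genome_id {gid!r}")
        contigs: Dict[str, str] = {}
        for rec in SeqIO.parse(str(fp), "fasta"):
            contigs[rec.id] = normalize_sequence(str(rec.seq))
            contig_to_genome[rec.id] = gid
        if not contigs:
            raise ValueError(f"{fp}: no sequences")
        contigs_by_genome[gid] = contigs

    cds_by_genome: Dict[str, List[GeneAnnotation]] = {g: [] for g in contigs_by_genome}
    trna_by_genome: Dict[str, List[TRNAAnnotation]] = {g: [] for g in contigs_by_genome}

    for feat in _read_gff_features(gff_path):
        gid = contig_to_genome.get(feat.seqid)
        fid = feat.attributes.get("ID", [feat.id or "?"])[0]
        if gid is None:
            raise ValueError(
                f"GFF feature {fid} references absent contig {feat.seqid}"
            )
        if feat.featuretype == "CDS":
            ann = GeneAnnotation(
                gene_id=fid,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product_label=feat.attributes.get("product", [""])[0],
                kegg_like_category=(feat.attributes.get("kegg_category") or [None])[0],
            )
            contig = contigs_by_genome[gid].get(feat.seqid, "")
            if ann.end > len(contig):
                raise ValueError(
                    f"gene {fid}: end {ann.end} beyond contig "
                    f"{feat.seqid} length {len(contig)}"
                )
            ann.protein_seq = _translate(contig, ann)
            cds_by_genome[gid].append(ann)
        elif feat.featuretype == "tRNA":
            trna_by_genome[gid].append(
                TRNAAnnotation(
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    isotype=feat.attributes.get("isotype", ["Und"])[0],
                )
            )

    genomes: List[GenomeRecord] = []
    for gid, contigs in contigs_by_genome.items():
        if gid not in meta_df.index:
            raise ValueError(f"genome {gid}: no metadata row")
        row = meta_df.loc[gid]
        meta, taxonomy = _metadata_row_to_fields(row)
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                contigs=contigs,
                completeness=_opt_float(row.get("completeness")),
                contamination=_opt_float(row.get("contamination")),
                taxonomy=taxonomy,
                metadata=meta,
                cds=sorted(cds_by_genome[gid], key=lambda a: (a.contig_id, a.start)),
                trnas=sorted(trna_by_genome[gid], key=lambda a: (a.contig_id, a.start)),
                mdt_hours=_opt_float(row.get("mdt_hours")),
            )
        )
    return genomes


def write_genomes(
    genomes: Iterable[GenomeRecord],
    fasta_dir: Union[str, Path],
    gff_path: Union[str, Path],
    metadata_tsv: Union[str, Path],
) -> List[Path]:
    """Inverse of :func:`parse_genomes` (one FASTA per genome)."""
    fasta_dir = Path(fasta_dir)
    fasta_dir.mkdir(parents=True, exist_ok=True)
    fasta_paths = []
    gff_lines = ["##gff-version 3"]
    meta_rows = []
    for g in genomes:
        fp = fasta_dir / f"{g.genome_id}.fasta"
        SeqIO.write(
            [SeqRecord(Seq(s), id=cid, description="") for cid, s in g.contigs.items()],
            str(fp), "fasta",
        )
        fasta_paths.append(fp)
        for ann in g.cds:
            attrs = f"ID={ann.gene_id}"
            if ann.product_label:
                attrs += f";product={ann.product_label}"
            if ann.kegg_like_category:
                attrs += f";kegg_category={ann.kegg_like_category}"
            gff_lines.append(
                f"{ann.contig_id}\tlysoscape\tCDS\t{ann.start}\t{ann.end}"
                f"\t.\t{ann.strand}\t0\t{attrs}"
            )
        for i, t in enumerate(g.trnas):
            gff_lines.append(
                f"{t.contig_id}\tlysoscape\ttRNA\t{t.start}\t{t.end}"
                f"\t.\t{t.strand}\t.\tID={t.contig_id}_trna{i+1};isotype={t.isotype}"
            )
        m = g.metadata or SampleMetadata(sample_id="")
        row = {
            "genome_id": g.genome_id,
            "sample_id": m.sample_id,
            "environment": m.environment.value,
            "depth_m": m.depth_m,
            "latitude": m.latitude,
            "longitude": m.longitude,
            "completeness": g.completeness,
            "contamination": g.contamination,
            **{r: g.taxonomy.get(r) for r in RANKS},
            "mdt_hours": g.mdt_hours,
        }
        meta_rows.append(row)
    Path(gff_path).write_text("\n".join(gff_lines) + "\n")
    pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(
        metadata_tsv, sep="\t", index=False
    )
    return fasta_paths


# ---------------------------------------------------------------------------
# proviruses
# ---------------------------------------------------------------------------

def parse_proviruses(
    table_path: Union[str, Path],
    gene_flag_table: Optional[Union[str, Path]] = None,
) -> List[ProvirusRecord]:
    """Read the provirus coordinate table plus optional gene-flag table.

    Coordinates are 1-based inclusive.  Gene flags are semicolon
    separated tokens; a terL flag implies terminase.
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    genes_by_pv: Dict[str, List[ViralGene]] = {}
    if gene_flag_table is not None:
        gdf = pd.read_csv(gene_flag_table, sep="\t", dtype=str)
        for _, row in gdf.iterrows():
            flags = set(
                tok for tok in (_opt_str(row.get("flags")) or "").split(";") if tok
            )
            score = _opt_str(row.get("auxiliary_score"))
            start = _opt_str(row.get("start"))
            end = _opt_str(row.get("end"))
            gene = ViralGene(
                gene_id=row["gene_id"],
                position_index=int(row["position_index"]),
                flags=flags,
                metabolic_flag=_opt_str(row.get("metabolic_flag")),
                auxiliary_score=int(float(score)) if score is not None else None,
                category_label=_opt_str(row.get("category_label")) or "",
                product_label=_opt_str(row.get("product_label")) or "",
                start=int(float(start)) if start is not None else None,
                end=int(float(end)) if end is not None else None,
                strand=_opt_str(row.get("strand")) or "+",
            )
            genes_by_pv.setdefault(row["provirus_id"], []).append(gene)

    proviruses = []
    for _, row in df.iterrows():
        pid = row["provirus_id"]
        genes = sorted(
            genes_by_pv.get(pid, []), key=lambda g: g.position_index
        )
        proviruses.append(
            ProvirusRecord(
                provirus_id=pid,
                host_genome_id=row["host_genome_id"],
                contig_id=row["contig_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                genes=genes,
                category=_opt_str(row.get("category")) or "caudo_or_unclassified",
                tvc_id=_opt_str(row.get("tvc_id")),
                tvg_id=_opt_str(row.get("tvg_id")),
                tvotu_id=_opt_str(row.get("tvotu_id")),
            )
        )
    check_no_overlap(proviruses)
    return proviruses


def write_proviruses(
    proviruses: Iterable[ProvirusRecord],
    table_path: Union[str, Path],
    gene_flag_table: Optional[Union[str, Path]] = None,
) -> None:
    rows, gene_rows = [], []
    for pv in proviruses:
        rows.append({
            "provirus_id": pv.provirus_id,
            "host_genome_id": pv.host_genome_id,
            "contig_id": pv.contig_id,
            "start": pv.start,
            "end": pv.end,
            "category": pv.category.value,
            "tvc_id": pv.tvc_id,
            "tvg_id": pv.tvg_id,
            "tvotu_id": pv.tvotu_id,
        })
        for g in pv.genes:
            gene_rows.append({
                "provirus_id": pv.provirus_id,
                "gene_id": g.gene_id,
                "position_index": g.position_index,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "flags": ";".join(sorted(g.flags)),
                "metabolic_flag": g.metabolic_flag,
                "auxiliary_score": g.auxiliary_score,
                "category_label": g.category_label,
                "product_label": g.product_label,
            })
    pd.DataFrame(rows, columns=PROVIRUS_COLUMNS).to_csv(
        table_path, sep="\t", index=False
    )
    if gene_flag_table is not None:
        pd.DataFrame(gene_rows, columns=VIRAL_GENE_COLUMNS).to_csv(
            gene_flag_table, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# tabular alignment hits (outfmt-6 dialect)
# ---------------------------------------------------------------------------

def parse_hits(path: Union[str, Path]) -> List[AlignmentHit]:
    """Parse a 12-column tabular alignment file (optional 13th column =
    query coverage).  Malformed rows are rejected with line numbers."""
    hits: List[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_coverage=float(fields[12]) if len(fields) == 13 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})")
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_id, h.subject_id, f"{h.pct_identity:g}",
                str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                str(h.qstart), str(h.qend), str(h.sstart), str(h.send),
                f"{h.evalue:g}", f"{h.bitscore:g}",
            ]
            if h.query_coverage is not None:
                fields.append(f"{h.query_coverage:g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED conversion (0-based half-open, writers only)
# ---------------------------------------------------------------------------

def interval_to_bed(contig_id: str, start: int, end: int, name: str = ".") -> str:
    """1-based inclusive interval -> one BED line (0-based half-open)."""
    return f"{contig_id}\t{start - 1}\t{end}\t{name}"


def interval_from_bed(line: str) -> Tuple[str, int, int, str]:
    """Inverse of :func:`interval_to_bed`."""
    contig, s, e, *rest = line.rstrip("\n").split("\t")
    return contig, int(s) + 1, int(e), (rest[0] if rest else ".")
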