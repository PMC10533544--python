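"""Shared domain types for the lysoscape pipeline.

Coordinate convention: all intervals are 1-based and inclusive (GFF3
convention) everywhere inside the package.  Conversions to other
conventions (e.g. BED) happen only in writers.

Missing values are represented as ``None`` — never silently defaulted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Set


class Environment(str, Enum):
    SEAWATER = "seawater"
    SEDIMENT = "sediment"
    OTHER = "other"


class ProvirusCategory(str, Enum):
    CAUDO_OR_UNCLASSIFIED = "caudo_or_unclassified"
    INOVIRALES = "inovirales"
    OTHER = "other"


#: taxonomy ranks from most to least inclusive
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: viral gene flags recognised by the pipeline
VIRAL_GENE_FLAGS = {"terL", "zot", "terminase", "integrase", "structural"}


@dataclass
class SampleMetadata:
    """Provenance of the sample a genome was recovered from."""

    sample_id: str
    environment: Environment = Environment.OTHER
    depth_m: Optional[float] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    sample_type_source: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.environment, str):
            self.environment = Environment(self.environment)
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError(
                f"sample {self.sample_id}: negative depth {self.depth_m}"
            )


@dataclass
class TaxonomyLabel:
    """Ordered rank labels; a missing rank implies all lower ranks missing."""

    ranks: Dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranks = {r: self.ranks.get(r) for r in RANKS}
        seen_missing = False
        for r in RANKS:
            if self.ranks[r] is None:
                seen_missing = True
            elif seen_missing:
                raise ValueError(
                    f"rank '{r}' is labelled but a higher rank is missing"
                )

    def get(self, rank: str) -> Optional[str]:
        return self.ranks.get(rank)

    @classmethod
    def from_values(cls, **kwargs: Optional[str]) -> "TaxonomyLabel":
        return cls(ranks={r: kwargs.get(r) for r in RANKS})


@dataclass
class GeneAnnotation:
    """A protein-coding gene on a host contig."""

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    protein_seq: Optional[str] = None
    product_label: str = ""
    kegg_like_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.protein_seq is not None and len(self.protein_seq) < 1:
            raise ValueError(f"gene {self.gene_id}: empty protein")


@dataclass
class TRNAAnnotation:
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    isotype: str = "Und"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tRNA: start > end")


@dataclass
class GenomeRecord:
    """A host genome: contigs plus annotations, quality and provenance."""

    genome_id: str
    contigs: Dict[str, str]
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    taxonomy: TaxonomyLabel = field(default_factory=TaxonomyLabel)
    metadata: Optional[SampleMetadata] = None
    cds: List[GeneAnnotation] = field(default_factory=list)
    trnas: List[TRNAAnnotation] = field(default_factory=list)
    mdt_hours: Optional[float] = None

    def __post_init__(self) -> None:
        # an empty contig set is tolerated (a fully-proviral genome after
        # excision); parsers reject empty inputs before construction
        if self.contigs and self.size_bp <= 0:
            raise ValueError(f"genome {self.genome_id}: empty genome")
        if self.mdt_hours is not None and self.mdt_hours <= 0:
            raise ValueError(f"genome {self.genome_id}: non-positive MDT")
        for ann in list(self.cds) + list(self.trnas):
            contig = self.contigs.get(ann.contig_id)
            name = getattr(ann, "gene_id", "tRNA")
            if contig is None:
                raise ValueError(
                    f"genome {self.genome_id}: feature {name} references "
                    f"absent contig {ann.contig_id}"
                )
            if ann.end > len(contig) or ann.start < 1:
                raise ValueError(
                    f"genome {self.genome_id}: feature {name} interval "
                    f"[{ann.start},{ann.end}] outside contig "
                    f"{ann.contig_id} (length {len(contig)})"
                )

    @property
    def size_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class ViralGene:
    """A gene on a provirus, with functional flags used by the screens.

    ``start``/``end`` (optional) are 1-based positions relative to the
    provirus interval; they let the codon-usage stage read the gene
    sequence off the provirus.
    """

    gene_id: str
    position_index: int
    flags: Set[str] = field(default_factory=set)
    metabolic_flag: Optional[str] = None
    auxiliary_score: Optional[int] = None
    category_label: str = ""
    product_label: str = ""
    start: Optional[int] = None
    end: Optional[int] = None
    strand: str = "+"

    def __post_init__(self) -> None:
        self.flags = set(self.flags)
        unknown = self.flags - VIRAL_GENE_FLAGS
        if unknown:
            raise ValueError(f"gene {self.gene_id}: unknown flags {unknown}")
        if "terL" in self.flags:
            self.flags.add("terminase")  # TerL is a terminase subunit


@dataclass
class ProvirusRecord:
    """A provirus interval on a host contig."""

    provirus_id: str
    host_genome_id: str
    contig_id: str
    start: int
    end: int
    genes: List[ViralGene] = field(default_factory=list)
    category: ProvirusCategory = ProvirusCategory.CAUDO_OR_UNCLASSIFIED
    tvc_id: Optional[str] = None
    tvg_id: Optional[str] = None
    tvotu_id: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.category, str):
            self.category = ProvirusCategory(self.category)
        if self.length_bp < 1:
            raise ValueError(f"provirus {self.provirus_id}: empty interval")
        idx = [g.position_index for g in self.genes]
        if len(idx) != len(set(idx)):
            raise ValueError(
                f"provirus {self.provirus_id}: duplicate gene position_index"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class AlignmentHit:
    """One row of a 12/13-column tabular alignment (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    query_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("alignment length < 1")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass
class AttSite:
    """A detected attL/attR exact direct-repeat pair flanking a provirus."""

    provirus_id: str
    attL_interval: tuple  # (start, end) 1-based inclusive on the host contig
    attR_interval: tuple
    length_bp: int
    core_seq: str
    boundary_offset_sum: int

    def __post_init__(self) -> None:
        if self.length_bp != len(self.core_seq):
            raise ValueError("att core length mismatch")


@dataclass
class IntegrationLocus:
    """The reconstructed empty (pre-integration) host locus."""

    provirus_id: str
    reconstructed_seq: str
    locus_class: str  # tRNA | protein_coding | noncoding
    trna_isotype: Optional[str] = None
    gene_id: Optional[str] = None
    flank_genes: List[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.locus_class == "tRNA" and self.trna_isotype is None:
            raise ValueError("tRNA locus without isotype")


@dataclass
class InteractionEdge:
    """A weighted edge in the infection or coinfection network."""

    node_a: str
    node_b: str
    weight: int
    edge_type: str  # infection | coinfection

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("edge weight < 1")


def check_no_overlap(proviruses: List[ProvirusRecord]) -> None:
    """Raise if two proviruses of one host overlap on a contig."""
    by_contig: Dict[tuple, List[ProvirusRecord]] = {}
    for pv in proviruses:
        by_contig.setdefault((pv.host_genome_id, pv.contig_id), []).append(pv)
    for (_, contig_id), pvs in by_contig.items():
        pvs = sorted(pvs, key=lambda p: (p.start, p.end))
        for a, b in zip(pvs, pvs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping proviruses on contig {contig_id}: "
                    f"{a.provirus_id} [{a.start},{a.end}] and "
                    f"{b.provirus_id} [{b.start},{b.end}]"
                )
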