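"""Synthetic stratified marine community with ground truth.

The generator emulates the structure of a marine prokaryotic genome
collection: genomes stratified by environment x depth zone, each
stratum with its own lysogeny probability; lysogens receive proviruses
inserted by the duplication model of site-specific integration (a
single att core already present in the host becomes exact attL ...
provirus ... attR direct repeats); proviruses carry single-copy marker
genes (TerL, or Zot for Inovirales), integrases, structural genes,
candidate metabolic genes and occasional tRNAs.

Host sequences are i.i.d. nucleotides at a per-genus GC target with
protein-coding genes planted by codon sampling — there is no
phylogenetic structure or read-level noise.  Planted att repeats are
guaranteed unambiguous within their detection windows
(rejection-sampled), so recovery ground truth is exact.  A fixed seed
gives byte-identical output files.

``feature_effect`` couples the per-genus GC target to the lysogeny
probability (p = stratum p + effect * (GC - GC midpoint), clipped to
[0, 1]) so genus-level feature-LyR correlation recovery can be tested;
the default of 0 leaves every stratum exactly binomial.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .attsites import maximal_matches
from .datamodel import AlignmentHit
from . import io as lio

log = logging.getLogger("lysoscape")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}

_ISOTYPES = (
    "Leu", "Ser", "Arg", "Ala", "Gly", "Pro", "Thr", "Val", "Ile", "Lys",
    "Asn", "Asp", "Glu", "Gln", "His", "Met", "Phe", "Trp", "Tyr", "Cys",
    "Und",
)
# integration and viral-cargo hotspots lean toward Leu/Ser/Arg
_ISOTYPE_W = np.array([6, 5, 5] + [1] * 17 + [0.5], dtype=float)

_HOST_GENE_CATEGORIES = (
    "two-component system", "transporter", "transcription factor",
    "carbohydrate metabolism", "amino acid metabolism", "ribosomal protein",
    "", "", "",
)

_AMG_CATEGORIES = (
    "CAZy", "Transporter", "Photosynthesis", "MISC",
    "DNA methylase", "nucleotide metabolism",
)
_AMG_CATEGORY_W = np.array([4, 2, 1, 2, 1, 1], dtype=float)

DistSpec = Union[int, float, Tuple[float, float], Tuple[str, float]]


@dataclass
class Stratum:
    environment: str
    zone: str  # epipelagic | mesopelagic | deep_sea
    n_genomes: int
    lysogeny_prob: float

    def __post_init__(self) -> None:
        if not (0 <= self.lysogeny_prob <= 1):
            raise ValueError("lysogeny_prob outside [0,1]")


def default_strata() -> List[Stratum]:
    """A small marine panel: seawater dominated by the epipelagic,
    sediment by the deep sea; per-stratum lysogeny probabilities follow
    the reported pattern of lysogeny rising with depth in seawater and
    staying near-constant in sediment."""
    return [
        Stratum("seawater", "epipelagic", 18, 0.36),
        Stratum("seawater", "mesopelagic", 4, 0.45),
        Stratum("seawater", "deep_sea", 6, 0.53),
        Stratum("sediment", "epipelagic", 4, 0.46),
        Stratum("sediment", "mesopelagic", 6, 0.49),
        Stratum("sediment", "deep_sea", 12, 0.47),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    strata: List[Stratum] = field(default_factory=default_strata)
    genome_length_bp: Tuple[int, int] = (500_000, 2_000_000)
    gc_target: Union[float, Tuple[float, float]] = (0.35, 0.65)
    lysogeny_prob: Optional[float] = None  # overrides every stratum
    proviruses_per_lysogen: DistSpec = ("poisson_plus1", 1.65)
    provirus_length_bp: Tuple[int, int] = (10_000, 60_000)
    att_length_bp: Tuple[int, int] = (12, 30)
    scmp_prob: float = 0.8
    inovirales_prob: float = 0.05
    cds_density: float = 0.9  # genes per kb
    codon_profile: Optional[Dict[str, Sequence[float]]] = None  # per genus
    feature_effect: float = 0.0
    n_genera: int = 10
    genera_per_class: int = 3
    locus_class_probs: Dict[str, float] = field(
        default_factory=lambda: {"trna": 0.16, "cds": 0.40, "noncoding": 0.44}
    )
    viral_trna_prob: float = 0.25
    n_tvcs: int = 8
    tvc_missing_prob: float = 0.15
    n_tvgs: int = 6
    tvotus_per_tvg: int = 2
    window: int = 1000
    hit_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "recruit_pass": 40, "recruit_fail": 20,
            "crispr_pass": 30, "crispr_fail": 15,
            "homology_pass": 25, "homology_fail": 15,
        }
    )

    def __post_init__(self) -> None:
        for p in (self.scmp_prob, self.inovirales_prob, self.viral_trna_prob,
                  self.tvc_missing_prob):
            if not (0 <= p <= 1):
                raise ValueError("probability outside [0,1]")
        a_lo, a_hi = self.att_length_bp
        if not (2 <= a_lo <= a_hi <= 145):
            raise ValueError("att_length_bp must lie within [2,145]")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "strata" in raw:
            raw["strata"] = [Stratum(**s) for s in raw["strata"]]
        for key in ("genome_length_bp", "provirus_length_bp", "att_length_bp",
                    "gc_target", "proviruses_per_lysogen"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PlantedProvirus:
    provirus_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive, final coordinates
    end: int
    att_core: str
    attL_interval: Tuple[int, int]
    attR_interval: Tuple[int, int]
    locus_class: str
    trna_isotype: Optional[str]
    category: str
    has_terL: bool
    has_zot: bool
    tvc_id: Optional[str]
    tvg_id: str
    tvotu_id: str


@dataclass
class PlantedGenome:
    genome_id: str
    contig_id: str
    environment: str
    zone: str
    genus: str
    clazz: str
    gc_target: float
    lysogeny_prob: float
    is_lysogen: bool
    mdt_hours: Optional[float]


@dataclass
class GroundTruth:
    config: SimulationConfig
    genomes: List[PlantedGenome]
    proviruses: List[PlantedProvirus]
    final_contigs: Dict[str, str]
    pre_insertion_contigs: Dict[str, str]
    paths: Dict[str, object]

    def expected_reconstruction(self, provirus_id: str) -> str:
        """Final contig with this provirus replaced by its att core."""
        pv = next(p for p in self.proviruses if p.provirus_id == provirus_id)
        seq = self.final_contigs[pv.contig_id]
        return seq[: pv.start - 1] + pv.att_core + seq[pv.end :]


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    at = (1 - gc) / 2
    gcp = gc / 2
    codes = rng.choice(4, size=n, p=[at, gcp, gcp, at])
    return _BASES[codes].tobytes().decode("ascii")


def _codon_probs(gc: float) -> np.ndarray:
    """Independent-position codon probabilities at the GC target, stop
    codons removed and renormalised."""
    at = (1 - gc) / 2
    gcp = gc / 2
    base_p = {"A": at, "C": gcp, "G": gcp, "T": at}
    p = np.array(
        [0.0 if c in _STOPS else base_p[c[0]] * base_p[c[1]] * base_p[c[2]]
         for c in _CODONS]
    )
    return p / p.sum()


_CODON_BYTES = np.frombuffer("".join(_CODONS).encode(), dtype=np.uint8).reshape(64, 3)

_RC = bytes.maketrans(b"ACGT", b"TGCA")


def _sample_gene(rng: np.random.Generator, codon_p: np.ndarray,
                 n_codons: int) -> str:
    idx = rng.choice(64, size=n_codons, p=codon_p)
    body = _CODON_BYTES[idx].reshape(-1).tobytes()
    return ("ATG" + body.decode("ascii") + "TAA")


def _draw(rng: np.random.Generator, spec: DistSpec) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    if isinstance(spec, tuple) and isinstance(spec[0], str):
        kind, param = spec
        if kind == "poisson_plus1":
            return 1 + int(rng.poisson(param))
        raise ValueError(f"unknown distribution {kind!r}")
    lo, hi = spec
    return int(rng.integers(int(lo), int(hi) + 1))


# ---------------------------------------------------------------------------
# host and provirus construction
# ---------------------------------------------------------------------------

@dataclass
class _Element:
    kind: str  # cds | trna | gap
    start0: int  # 0-based, end-exclusive
    end0: int
    strand: str = "+"
    isotype: str = ""
    category: str = ""


def _build_host(
    rng: np.random.Generator, length: int, gc: float, codon_p: np.ndarray,
    cds_density: float,
) -> Tuple[str, List[_Element]]:
    parts: List[str] = []
    elements: List[_Element] = []
    pos = 0
    mean_gene = 606  # 200 codons + start/stop
    gap_mean = max(60, int(round(1000.0 / max(cds_density, 1e-6) - mean_gene)))
    while pos < length:
        gap_len = int(rng.integers(max(20, gap_mean // 5),
                                   max(21, int(gap_mean * 1.8))))
        parts.append(_random_seq(rng, gap_len, gc))
        elements.append(_Element("gap", pos, pos + gap_len))
        pos += gap_len
        if pos >= length:
            break
        if rng.random() < 0.08:
            iso = _ISOTYPES[rng.choice(len(_ISOTYPES),
                                       p=_ISOTYPE_W / _ISOTYPE_W.sum())]
            t_seq = _random_seq(rng, 75, gc)
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(t_seq)
            elements.append(_Element("trna", pos, pos + 75, strand, isotype=iso))
            pos += 75
        else:
            n_codons = int(rng.integers(100, 301))
            gene = _sample_gene(rng, codon_p, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                gene = gene.encode().translate(_RC)[::-1].decode()
            cat = _HOST_GENE_CATEGORIES[rng.integers(len(_HOST_GENE_CATEGORIES))]
            parts.append(gene)
            elements.append(
                _Element("cds", pos, pos + len(gene), strand, category=cat)
            )
            pos += len(gene)
    return "".join(parts), elements


@dataclass
class _ViralGeneSpec:
    gene_id: str
    position_index: int
    start0: int  # relative to interior V, 0-based end-exclusive
    end0: int
    strand: str
    flags: List[str]
    metabolic_flag: Optional[str]
    auxiliary_score: Optional[int]
    category_label: str
    product_label: str


def _build_provirus_interior(
    rng: np.random.Generator, target_len: int, gc: float,
    codon_p: np.ndarray, category: str, scmp_prob: float,
    viral_trna_prob: float, pv_id: str,
) -> Tuple[str, List[_ViralGeneSpec], List[Tuple[int, int, str]], bool, bool]:
    """Interior sequence (between the att copies), viral genes with
    interior-relative coordinates, and viral tRNA intervals."""
    parts: List[str] = []
    genes: List[_ViralGeneSpec] = []
    trnas: List[Tuple[int, int, str]] = []
    pos = 0
    idx = 0

    def add_gap(n: int) -> None:
        nonlocal pos
        parts.append(_random_seq(rng, n, gc))
        pos += n

    def add_gene(flags, metabolic, score, cat, prod) -> None:
        nonlocal pos, idx
        n_codons = int(rng.integers(80, 250))
        gene = _sample_gene(rng, codon_p, n_codons)
        strand = "+" if rng.random() < 0.7 else "-"
        if strand == "-":
            gene = gene.encode().translate(_RC)[::-1].decode()
        idx += 1
        genes.append(_ViralGeneSpec(
            gene_id=f"{pv_id}_g{idx:03d}", position_index=idx,
            start0=pos, end0=pos + len(gene), strand=strand,
            flags=list(flags), metabolic_flag=metabolic,
            auxiliary_score=score, category_label=cat, product_label=prod,
        ))
        parts.append(gene)
        pos += len(gene)

    add_gap(int(rng.integers(80, 160)))
    add_gene(["integrase"], None, None, "", "integrase")
    has_terL = has_zot = False
    if category == "inovirales":
        if rng.random() < scmp_prob:
            add_gap(int(rng.integers(40, 120)))
            add_gene(["zot"], None, None, "", "zonular occludens toxin")
            has_zot = True
    else:
        if rng.random() < scmp_prob:
            add_gap(int(rng.integers(40, 120)))
            add_gene(["terL"], None, None, "", "terminase large subunit")
            has_terL = True
    planted_trna = rng.random() < viral_trna_prob
    while pos < target_len - 800:
        add_gap(int(rng.integers(40, 160)))
        r = rng.random()
        if r < 0.35:
            add_gene(["structural"], None, None, "",
                     rng.choice(["major capsid protein", "tail fiber",
                                 "portal protein", "baseplate"]))
        elif r < 0.55:
            score = int(rng.integers(1, 6))
            cat = _AMG_CATEGORIES[rng.choice(len(_AMG_CATEGORIES),
                                             p=_AMG_CATEGORY_W / _AMG_CATEGORY_W.sum())]
            add_gene([], "M", score, cat, "putative metabolic protein")
        elif r < 0.62 and planted_trna:
            iso = _ISOTYPES[rng.choice(len(_ISOTYPES),
                                       p=_ISOTYPE_W / _ISOTYPE_W.sum())]
            trnas.append((pos, pos + 75, iso))
            parts.append(_random_seq(rng, 75, gc))
            pos += 75
            planted_trna = False
        else:
            add_gene([], None, None, "", "hypothetical protein")
    add_gap(max(10, target_len - pos))
    return "".join(parts), genes, trnas, has_terL, has_zot


def _att_unambiguous(pseudo: str, att_len: int, window: int,
                     max_len: int = 145) -> bool:
    """True iff the planted att pair is the only window-constrained
    maximal repeat of length >= att_len in the assembled provirus."""
    L = len(pseudo)
    w = min(window, L // 2)
    left_hi = min(w + max_len, L)
    right_lo = max(L - w - max_len, 0)
    left = pseudo[:left_hi]
    right = pseudo[right_lo:]
    for ia, ib, m in maximal_matches(left, right, min_len=att_len):
        a_start = ia
        b_start = right_lo + ib
        b_end = b_start + m
        if a_start >= w or (L - b_end) >= w:
            continue
        if b_start < a_start + m:
            continue
        if not (a_start == 0 and m == att_len and b_end == L):
            return False
    return True


# ---------------------------------------------------------------------------
# the community simulator
# ---------------------------------------------------------------------------

def _depth_for_zone(rng: np.random.Generator, zone: str) -> float:
    if zone == "epipelagic":
        return float(np.round(rng.uniform(2, 195), 1))
    if zone == "mesopelagic":
        return float(np.round(rng.uniform(205, 990), 1))
    d = rng.uniform(1010, 5800)
    if rng.random() < 0.1:
        d = rng.uniform(6000, 10900)
    return float(np.round(d, 1))


def simulate_community(
    config: SimulationConfig, outdir: Union[str, Path]
) -> GroundTruth:
    """Generate the community and write FASTA/GFF3/TSV files plus a
    ground_truth.json sidecar.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)

    gc_lo, gc_hi = (
        (config.gc_target, config.gc_target)
        if isinstance(config.gc_target, (int, float)) else config.gc_target
    )
    gc_mid = (gc_lo + gc_hi) / 2

    genera = [f"genus{g+1:03d}" for g in range(config.n_genera)]
    genus_gc = {g: float(rng.uniform(gc_lo, gc_hi)) for g in genera}
    genus_codon_p = {}
    for g in genera:
        if config.codon_profile and g in config.codon_profile:
            arr = np.asarray(config.codon_profile[g], dtype=float)
            genus_codon_p[g] = arr / arr.sum()
        else:
            genus_codon_p[g] = _codon_probs(genus_gc[g])

    tvg_pool = [f"tVG{i+1:03d}" for i in range(config.n_tvgs)]
    tvc_pool = [f"tVC{i+1:03d}" for i in range(config.n_tvcs)]
    tvc_w = np.array([4.0, 3.0] + [1.0] * (config.n_tvcs - 2))[: config.n_tvcs]
    tvc_w = tvc_w / tvc_w.sum()

    planted_genomes: List[PlantedGenome] = []
    planted_pvs: List[PlantedProvirus] = []
    final_contigs: Dict[str, str] = {}
    pre_insertion: Dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    meta_rows = []
    fasta_paths: List[Path] = []
    pv_rows = []
    pv_gene_rows = []

    genome_no = 0
    genus_cycle = 0
    for s_idx, stratum in enumerate(config.strata):
        base_p = (
            config.lysogeny_prob
            if config.lysogeny_prob is not None else stratum.lysogeny_prob
        )
        n_samples = max(1, stratum.n_genomes // 8)
        for _ in range(stratum.n_genomes):
            genome_no += 1
            gid = f"G{genome_no:05d}"
            cid = f"{gid}_c1"
            genus = genera[genus_cycle % len(genera)]
            genus_cycle += 1
            clazz = f"class{(genera.index(genus) // config.genera_per_class) + 1:02d}"
            gc = genus_gc[genus]
            codon_p = genus_codon_p[genus]

            length = _draw(rng, config.genome_length_bp)
            host_seq, elements = _build_host(
                rng, length, gc, codon_p, config.cds_density
            )
            p_lys = float(np.clip(
                base_p + config.feature_effect * (gc - gc_mid), 0.0, 1.0
            ))
            is_lysogen = bool(rng.random() < p_lys)

            n_pv = _draw(rng, config.proviruses_per_lysogen) if is_lysogen else 0
            insertions = _plan_insertions(
                rng, host_seq, elements, n_pv, config, gc, codon_p, gid
            )
            final_seq, pv_records, shifted_elements, viral_features = (
                _assemble_contig(host_seq, elements, insertions, cid, gid)
            )

            final_contigs[cid] = final_seq
            pre_insertion[cid] = host_seq
            planted_pvs.extend(pv_records)
            is_lysogen = bool(pv_records)  # no eligible site -> nonlysogen

            # --- viral memberships and gene tables
            for pv, ins in zip(pv_records, insertions):
                tvg = tvg_pool[int(rng.choice(len(tvg_pool)))]
                tvotu = f"{tvg}_otu{int(rng.integers(1, config.tvotus_per_tvg + 1))}"
                tvc = (
                    None if rng.random() < config.tvc_missing_prob
                    else tvc_pool[int(rng.choice(len(tvc_pool), p=tvc_w))]
                )
                pv.tvc_id, pv.tvg_id, pv.tvotu_id = tvc, tvg, tvotu
                pv_rows.append(dict(
                    provirus_id=pv.provirus_id, host_genome_id=gid,
                    contig_id=cid, start=pv.start, end=pv.end,
                    category=pv.category, tvc_id=tvc, tvg_id=tvg,
                    tvotu_id=tvotu,
                ))
                for gsp in ins.genes:
                    pv_gene_rows.append(dict(
                        provirus_id=pv.provirus_id, gene_id=gsp.gene_id,
                        position_index=gsp.position_index,
                        # provirus-relative 1-based (attL occupies 1..a)
                        start=ins.att_len + gsp.start0 + 1,
                        end=ins.att_len + gsp.end0,
                        strand=gsp.strand,
                        flags=";".join(gsp.flags),
                        metabolic_flag=gsp.metabolic_flag,
                        auxiliary_score=gsp.auxiliary_score,
                        category_label=gsp.category_label,
                        product_label=gsp.product_label,
                    ))

            # --- write FASTA + GFF features
            fp = outdir / "genomes" / f"{gid}.fasta"
            _write_fasta(fp, cid, final_seq)
            fasta_paths.append(fp)
            gene_no = 0
            trna_no = 0
            for el in shifted_elements:
                if el.kind == "cds":
                    gene_no += 1
                    attrs = f"ID={cid}_g{gene_no:04d};product=hypothetical protein"
                    if el.category:
                        attrs += f";kegg_category={el.category}"
                    gff_lines.append(
                        f"{cid}\tlysoscape-sim\tCDS\t{el.start0 + 1}\t{el.end0}"
                        f"\t.\t{el.strand}\t0\t{attrs}"
                    )
                elif el.kind == "trna":
                    trna_no += 1
                    gff_lines.append(
                        f"{cid}\tlysoscape-sim\ttRNA\t{el.start0 + 1}\t{el.end0}"
                        f"\t.\t{el.strand}\t.\tID={cid}_t{trna_no:03d};"
                        f"isotype={el.isotype}"
                    )
            for kind, s0, e0, strand, name, iso in viral_features:
                if kind == "cds":
                    gff_lines.append(
                        f"{cid}\tlysoscape-sim\tCDS\t{s0 + 1}\t{e0}\t.\t{strand}"
                        f"\t0\tID={name};product=viral protein"
                    )
                else:
                    gff_lines.append(
                        f"{cid}\tlysoscape-sim\ttRNA\t{s0 + 1}\t{e0}\t.\t+"
                        f"\t.\tID={name};isotype={iso}"
                    )

            depth = _depth_for_zone(rng, stratum.zone)
            mdt = None
            if rng.random() >= 0.05:
                centre = 4.2 if is_lysogen else 5.5
                mdt = float(np.round(rng.lognormal(np.log(centre), 0.5), 2))
            meta_rows.append(dict(
                genome_id=gid,
                sample_id=f"S{s_idx + 1}_{int(rng.integers(1, n_samples + 1)):02d}",
                environment=stratum.environment,
                depth_m=depth,
                latitude=float(np.round(rng.uniform(-60, 60), 3)),
                longitude=float(np.round(rng.uniform(-180, 180), 3)),
                completeness=float(np.round(rng.uniform(82, 99.9), 1)),
                contamination=float(np.round(rng.uniform(0, 4.5), 2)),
                domain="Bacteria" if genera.index(genus) < 0.8 * len(genera)
                       else "Archaea",
                phylum=f"phylum{(genera.index(genus) // (2 * config.genera_per_class)) + 1:02d}",
                **{"class": clazz},
                order=f"order_{clazz}",
                family=f"family_{genus}",
                genus=genus,
                species=None,
                mdt_hours=mdt,
            ))
            planted_genomes.append(PlantedGenome(
                genome_id=gid, contig_id=cid,
                environment=stratum.environment, zone=stratum.zone,
                genus=genus, clazz=clazz, gc_target=gc,
                lysogeny_prob=p_lys, is_lysogen=is_lysogen, mdt_hours=mdt,
            ))

    # --- write tables
    import pandas as pd

    gff_path = outdir / "annotations.gff3"
    gff_path.write_text("\n".join(gff_lines) + "\n")
    meta_path = outdir / "metadata.tsv"
    pd.DataFrame(meta_rows, columns=lio.METADATA_COLUMNS).to_csv(
        meta_path, sep="\t", index=False
    )
    pv_path = outdir / "proviruses.tsv"
    pd.DataFrame(pv_rows, columns=lio.PROVIRUS_COLUMNS).to_csv(
        pv_path, sep="\t", index=False
    )
    pv_genes_path = outdir / "viral_genes.tsv"
    pd.DataFrame(pv_gene_rows, columns=lio.VIRAL_GENE_COLUMNS).to_csv(
        pv_genes_path, sep="\t", index=False
    )

    host_sim_path = outdir / "host_similarity.tsv"
    pv_sim_path = outdir / "provirus_similarity.tsv"
    _write_similarities(rng, planted_genomes, planted_pvs,
                        host_sim_path, pv_sim_path)

    paths = {
        "fasta_dir": outdir / "genomes",
        "fasta_paths": fasta_paths,
        "gff": gff_path,
        "metadata": meta_path,
        "proviruses": pv_path,
        "viral_genes": pv_genes_path,
        "host_similarity": host_sim_path,
        "provirus_similarity": pv_sim_path,
        "ground_truth": outdir / "ground_truth.json",
    }
    truth = GroundTruth(
        config=config, genomes=planted_genomes, proviruses=planted_pvs,
        final_contigs=final_contigs, pre_insertion_contigs=pre_insertion,
        paths=paths,
    )
    _write_truth_json(truth, paths["ground_truth"])
    return truth


@dataclass
class _Insertion:
    p0: int  # 0-based insertion point in the host: att core = host[p0:p0+att_len]
    att_len: int
    interior: str
    genes: List[_ViralGeneSpec]
    trnas: List[Tuple[int, int, str]]
    locus_class: str
    trna_isotype: Optional[str]
    category: str
    has_terL: bool
    has_zot: bool


def _plan_insertions(
    rng, host_seq, elements, n_pv, config, gc, codon_p, gid
) -> List[_Insertion]:
    if n_pv == 0:
        return []
    cds_els = [e for e in elements if e.kind == "cds"]
    out: List[_Insertion] = []
    used: List[Tuple[int, int]] = []  # att intervals in host coords

    classes = list(config.locus_class_probs)
    class_p = np.array([config.locus_class_probs[c] for c in classes], float)
    class_p = class_p / class_p.sum()

    for j in range(n_pv):
        att_len = _draw(rng, config.att_length_bp)
        target_len = _draw(rng, config.provirus_length_bp)
        if target_len >= len(host_seq):
            raise ValueError(
                f"provirus length {target_len} exceeds host genome "
                f"{gid} ({len(host_seq)} bp)"
            )
        interior_len = max(2 * config.window, target_len - 2 * att_len)
        category = (
            "inovirales" if rng.random() < config.inovirales_prob
            else "caudo_or_unclassified"
        )
        pv_id = f"{gid}_pv{j + 1}"

        placed = False
        for attempt in range(40):
            mode = classes[int(rng.choice(len(classes), p=class_p))]
            anchor = _pick_anchor(rng, elements, cds_els, mode, att_len, used,
                                  len(host_seq))
            if anchor is None:
                continue
            p0, locus_class, isotype = anchor
            # viral composition is offset from the host's so virus-host
            # complementarity indices carry signal
            gc_v = float(np.clip(gc + rng.uniform(-0.1, 0.1), 0.25, 0.75))
            interior, genes, trnas, has_terL, has_zot = _build_provirus_interior(
                rng, interior_len, gc_v, _codon_probs(gc_v), category,
                config.scmp_prob, config.viral_trna_prob, pv_id,
            )
            att = host_seq[p0 : p0 + att_len]
            if "N" in att:
                continue
            pseudo = att + interior + att
            if _att_unambiguous(pseudo, att_len, config.window):
                used.append((p0, p0 + att_len))
                out.append(_Insertion(
                    p0=p0, att_len=att_len, interior=interior, genes=genes,
                    trnas=trnas, locus_class=locus_class,
                    trna_isotype=isotype, category=category,
                    has_terL=has_terL, has_zot=has_zot,
                ))
                placed = True
                break
        if not placed:
            log.warning("%s: no unambiguous att placement for provirus %d",
                        gid, j + 1)
    out.sort(key=lambda i: i.p0)
    return out


def _pick_anchor(rng, elements, cds_els, mode, att_len, used, host_len):
    """Choose the 0-based insertion point p0 so the att core
    host[p0:p0+att_len] sits at the tail of a tRNA/CDS or inside a gap,
    with >= 7 CDS on each side and clear of previously used sites."""

    def flank_ok(pos: int) -> bool:
        up = sum(1 for e in cds_els if e.end0 <= pos)
        down = sum(1 for e in cds_els if e.start0 >= pos + att_len)
        return up >= 7 and down >= 7

    def clear(p0: int) -> bool:
        return all(p0 + att_len + 10 < s or p0 > e + 10 for s, e in used)

    if mode == "trna":
        cands = [e for e in elements
                 if e.kind == "trna" and (e.end0 - e.start0) >= att_len]
    elif mode == "cds":
        cands = [e for e in cds_els if (e.end0 - e.start0) >= att_len + 6]
    else:
        cands = [e for e in elements
                 if e.kind == "gap" and (e.end0 - e.start0) >= att_len + 12]
    cands = [e for e in cands
             if flank_ok(e.end0 - att_len) and clear(e.end0 - att_len)]
    if not cands:
        return None
    el = cands[int(rng.integers(len(cands)))]
    if mode == "noncoding":
        p0 = el.start0 + 5
        if not (flank_ok(p0) and clear(p0)):
            return None
        return p0, "noncoding", None
    p0 = el.end0 - att_len
    if mode == "trna":
        return p0, "tRNA", el.isotype
    return p0, "protein_coding", None


def _assemble_contig(host_seq, elements, insertions, cid, gid):
    """Insert proviruses (duplicating each att core) and shift
    annotations into final coordinates."""
    pv_records: List[PlantedProvirus] = []
    viral_features = []  # (kind, start0, end0, strand, name, isotype)
    parts = []
    cursor = 0
    offset = 0
    boundaries = []  # (host boundary b0, inserted length)
    for j, ins in enumerate(insertions):
        a = ins.att_len
        b0 = ins.p0 + a  # host position after the att core
        parts.append(host_seq[cursor:b0])
        att = host_seq[ins.p0 : b0]
        ins_len = len(ins.interior) + a
        attL_start = ins.p0 + offset + 1  # 1-based final
        attL_end = attL_start + a - 1
        interior_start0 = b0 + offset  # 0-based final start of interior
        attR_start = interior_start0 + len(ins.interior) + 1
        attR_end = attR_start + a - 1
        parts.append(ins.interior)
        parts.append(att)
        for gsp in ins.genes:
            viral_features.append((
                "cds", interior_start0 + gsp.start0,
                interior_start0 + gsp.end0, gsp.strand, gsp.gene_id, "",
            ))
        for (s0, e0, iso) in ins.trnas:
            viral_features.append((
                "trna", interior_start0 + s0, interior_start0 + e0,
                "+", f"{cid}_pv{j+1}_trna{s0}", iso,
            ))
        pv_records.append(PlantedProvirus(
            provirus_id=f"{gid}_pv{j + 1}", genome_id=gid, contig_id=cid,
            start=attL_start, end=attR_end,
            att_core=att,
            attL_interval=(attL_start, attL_end),
            attR_interval=(attR_start, attR_end),
            locus_class=ins.locus_class, trna_isotype=ins.trna_isotype,
            category=ins.category, has_terL=ins.has_terL,
            has_zot=ins.has_zot, tvc_id=None, tvg_id="", tvotu_id="",
        ))
        boundaries.append((b0, ins_len))
        cursor = b0
        offset += ins_len
    parts.append(host_seq[cursor:])
    final_seq = "".join(parts)

    shifted = []
    for el in elements:
        if el.kind == "gap":
            continue
        shift = sum(ln for b0, ln in boundaries if b0 <= el.start0)
        shifted.append(dataclasses.replace(
            el, start0=el.start0 + shift, end0=el.end0 + shift
        ))
    return final_seq, pv_records, shifted, viral_features


def _write_fasta(path: Path, contig_id: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig_id}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")


def _write_similarities(rng, genomes, proviruses, host_path, pv_path) -> None:
    """Pairwise similarity tables consistent with the planted genus /
    tvOTU / tVG memberships."""
    lines = ["id_a\tid_b\tani_pct\tcoverage_pct"]
    by_genus: Dict[str, List[str]] = {}
    for g in genomes:
        by_genus.setdefault(g.genus, []).append(g.genome_id)
    for genus in sorted(by_genus):
        ids = by_genus[genus]
        for i in range(len(ids)):
            for k in range(i + 1, len(ids)):
                lines.append(
                    f"{ids[i]}\t{ids[k]}\t{rng.uniform(95.5, 99.5):.2f}"
                    f"\t{rng.uniform(62, 95):.2f}"
                )
    genera = sorted(by_genus)
    for i in range(len(genera) - 1):
        a = by_genus[genera[i]][0]
        b = by_genus[genera[i + 1]][0]
        lines.append(f"{a}\t{b}\t{rng.uniform(75, 90):.2f}"
                     f"\t{rng.uniform(20, 50):.2f}")
    Path(host_path).write_text("\n".join(lines) + "\n")

    lines = ["id_a\tid_b\tani_pct\tcoverage_pct"]
    by_tvotu: Dict[str, List[str]] = {}
    by_tvg: Dict[str, List[str]] = {}
    for pv in proviruses:
        by_tvotu.setdefault(pv.tvotu_id, []).append(pv.provirus_id)
        by_tvg.setdefault(pv.tvg_id, []).append(pv.provirus_id)
    for otu in sorted(by_tvotu):
        ids = by_tvotu[otu]
        for i in range(len(ids)):
            for k in range(i + 1, len(ids)):
                lines.append(
                    f"{ids[i]}\t{ids[k]}\t{rng.uniform(95.2, 99.5):.2f}"
                    f"\t{rng.uniform(86, 99):.2f}"
                )
    for tvg in sorted(by_tvg):
        otus = sorted({pv.tvotu_id for pv in proviruses if pv.tvg_id == tvg})
        for i in range(len(otus) - 1):
            a = by_tvotu[otus[i]][0]
            b = by_tvotu[otus[i + 1]][0]
            lines.append(f"{a}\t{b}\t{rng.uniform(72, 92):.2f}"
                         f"\t{rng.uniform(40, 85):.2f}")
    Path(pv_path).write_text("\n".join(lines) + "\n")


def _write_truth_json(truth: GroundTruth, path: Path) -> None:
    payload = {
        "seed": truth.config.seed,
        "strata": [dataclasses.asdict(s) for s in truth.config.strata],
        "feature_effect": truth.config.feature_effect,
        "genomes": [dataclasses.asdict(g) for g in truth.genomes],
        "proviruses": [
            {k: v for k, v in dataclasses.asdict(p).items()}
            for p in truth.proviruses
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# hit-table simulator
# ---------------------------------------------------------------------------

@dataclass
class HitTablesTruth:
    paths: Dict[str, Path]
    expected_pass: Dict[str, int]
    row_truth: Dict[str, Dict[str, bool]]  # table -> query_id -> passes
    spacer_lengths: Dict[str, int]
    array_sizes: Dict[str, int]
    virus_lengths_bp: Dict[str, int]
    metagenome_reads: Dict[str, int]


def simulate_hit_tables(
    config: SimulationConfig, outdir: Union[str, Path]
) -> HitTablesTruth:
    """Emit recruitment-, CRISPR- and homology-style alignment tables
    in which every row's pass/fail status against the downstream
    filters is known and recorded."""
    rng = np.random.default_rng(config.seed + 104729)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hc = config.hit_counts
    viruses = {f"MTV_{i+1:03d}": int(rng.integers(8000, 60000))
               for i in range(6)}
    virus_ids = sorted(viruses)
    metagenomes = {"POV_epi": 2_000_000_000, "POV_deep": 1_500_000_000}
    row_truth: Dict[str, Dict[str, bool]] = {
        "recruit": {}, "crispr": {}, "homology": {},
    }

    def hit(q, s, ident, length, mism, ev, bits):
        return AlignmentHit(
            query_id=q, subject_id=s, pct_identity=ident, aln_length=length,
            mismatches=mism, gap_opens=0, qstart=1, qend=length,
            sstart=1, send=length, evalue=ev, bitscore=bits,
        )

    # recruitment: e <= 1e-5, identity >= 95, length > 50
    recruit = []
    for i in range(hc.get("recruit_pass", 0)):
        q = f"read_p{i+1:04d}"
        recruit.append(hit(q, virus_ids[i % len(virus_ids)],
                           float(np.round(rng.uniform(95, 99.9), 1)),
                           int(rng.integers(60, 151)), 0, 1e-10,
                           float(np.round(rng.uniform(90, 250), 1))))
        row_truth["recruit"][q] = True
    fail_modes = ["identity", "length", "evalue"]
    for i in range(hc.get("recruit_fail", 0)):
        q = f"read_f{i+1:04d}"
        mode = fail_modes[i % 3]
        ident = 90.0 if mode == "identity" else 97.0
        length = 50 if mode == "length" else 100
        ev = 1e-4 if mode == "evalue" else 1e-10
        recruit.append(hit(q, virus_ids[i % len(virus_ids)], ident, length,
                           0, ev, 120.0))
        row_truth["recruit"][q] = False
    lio.write_hits(recruit, outdir / "recruit_hits.tsv")

    # CRISPR: array >= 3 spacers, full-length match, < 2 mismatches
    crispr = []
    spacer_lengths: Dict[str, int] = {}
    array_sizes: Dict[str, int] = {}
    for i in range(hc.get("crispr_pass", 0)):
        q = f"arr{i+1:03d}_sp1"
        sl = int(rng.integers(28, 41))
        spacer_lengths[q] = sl
        array_sizes[q] = int(rng.integers(3, 9))
        crispr.append(hit(q, virus_ids[i % len(virus_ids)],
                          100.0 if i % 2 == 0 else 97.0, sl,
                          i % 2, 1e-6, 60.0))
        row_truth["crispr"][q] = True
    for i in range(hc.get("crispr_fail", 0)):
        q = f"farr{i+1:03d}_sp1"
        sl = 32
        mode = ["mismatch", "coverage", "array"][i % 3]
        spacer_lengths[q] = sl
        array_sizes[q] = 2 if mode == "array" else 4
        crispr.append(hit(q, virus_ids[i % len(virus_ids)], 95.0,
                          sl - 1 if mode == "coverage" else sl,
                          2 if mode == "mismatch" else 0, 1e-6, 55.0))
        row_truth["crispr"][q] = False
    lio.write_hits(crispr, outdir / "crispr_hits.tsv")
    with open(outdir / "crispr_spacers.tsv", "w") as fh:
        fh.write("spacer_id\tspacer_length\tarray_size\n")
        for q in sorted(spacer_lengths):
            fh.write(f"{q}\t{spacer_lengths[q]}\t{array_sizes[q]}\n")

    # homology: bitscore > 50, e < 1e-3, identity > 70, length > 2500
    homology = []
    for i in range(hc.get("homology_pass", 0)):
        q = f"hvq_p{i+1:03d}"
        homology.append(hit(q, f"host{i % 7 + 1:02d}",
                            float(np.round(rng.uniform(70.5, 95), 1)),
                            int(rng.integers(2600, 6000)), 5, 1e-6,
                            float(np.round(rng.uniform(60, 300), 1))))
        row_truth["homology"][q] = True
    for i in range(hc.get("homology_fail", 0)):
        q = f"hvq_f{i+1:03d}"
        mode = ["bitscore", "evalue", "identity", "length"][i % 4]
        homology.append(hit(
            q, f"host{i % 7 + 1:02d}",
            70.0 if mode == "identity" else 85.0,
            2500 if mode == "length" else 3000,
            5,
            1e-3 if mode == "evalue" else 1e-6,
            50.0 if mode == "bitscore" else 120.0,
        ))
        row_truth["homology"][q] = False
    lio.write_hits(homology, outdir / "homology_hits.tsv")

    expected = {
        "recruit": sum(row_truth["recruit"].values()),
        "crispr": sum(row_truth["crispr"].values()),
        "homology": sum(row_truth["homology"].values()),
    }
    truth = HitTablesTruth(
        paths={
            "recruit": outdir / "recruit_hits.tsv",
            "crispr": outdir / "crispr_hits.tsv",
            "crispr_spacers": outdir / "crispr_spacers.tsv",
            "homology": outdir / "homology_hits.tsv",
            "truth": outdir / "hit_truth.json",
        },
        expected_pass=expected,
        row_truth=row_truth,
        spacer_lengths=spacer_lengths,
        array_sizes=array_sizes,
        virus_lengths_bp=viruses,
        metagenome_reads=metagenomes,
    )
    (outdir / "hit_truth.json").write_text(json.dumps(
        {"expected_pass": expected, "row_truth": row_truth,
         "virus_lengths_bp": viruses, "metagenome_reads": metagenomes},
        indent=1, sort_keys=True,
    ))
    return truth
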