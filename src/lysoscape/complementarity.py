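"""Alignment-free virus-host complementarity indices.

Two indices, both in [0, 1] with 0 = maximal compositional similarity:

* **d2\\*** — background-corrected oligonucleotide-frequency
  dissimilarity at word length k (default 6) with an order-m Markov
  background (default m = 2) estimated from each sequence itself.
  With word counts X_w over n_X windows and expected word probabilities
  p_w, the centred counts are X~_w = X_w - n_X p_w and

      D2* = sum_w  X~_w Y~_w / sqrt(n_X p^X_w  n_Y p^Y_w)
      d2* = (1 - D2* / (||X~|| ||Y~||)) / 2

  where ||X~|| = sqrt(sum_w X~_w^2 / (n_X p^X_w)).  Words whose
  expected probability is zero in either sequence are skipped in all
  three sums.

* **codon cosine distance** — 1 minus the cosine similarity of the two
  64-dimensional relative codon-frequency vectors.

The host background should be the provirus-excised genome so a virus
does not contribute to its own host signature.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _scipy_cosine

from .datamodel import GenomeRecord, ProvirusRecord
from .features import codon_counts, reverse_complement

log = logging.getLogger("lysoscape")

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ComplementarityParams:
    k: int = 6
    markov_order: int = 2
    strand_policy: str = "forward_only"  # or "with_reverse_complement"

    def __post_init__(self) -> None:
        if not (0 <= self.markov_order <= self.k - 2):
            raise ValueError("require 0 <= markov_order <= k - 2")
        if self.strand_policy not in {"forward_only", "with_reverse_complement"}:
            raise ValueError(f"unknown strand policy {self.strand_policy!r}")


@dataclass
class ComplementarityResult:
    virus_id: str
    host_id: str
    d2star: Optional[float]
    codon_distance: Optional[float]


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and everything else to -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for nt, code in _NT_CODE.items():
        out[arr == ord(nt)] = code
    return out


def _word_counts(codes: np.ndarray, k: int) -> Tuple[np.ndarray, int]:
    counts = np.zeros(4 ** k, dtype=np.int64)
    if codes.size < k:
        return counts, 0
    valid = codes >= 0
    if k == 1:
        words = codes[valid]
        np.add.at(counts, words, 1)
        return counts, int(words.size)
    # rolling base-4 codes over windows without N
    win_valid = np.ones(codes.size - k + 1, dtype=bool)
    words = np.zeros(codes.size - k + 1, dtype=np.int64)
    for i in range(k):
        seg = codes[i : codes.size - k + 1 + i]
        win_valid &= seg >= 0
        words = words * 4 + np.where(seg >= 0, seg, 0)
    words = words[win_valid]
    np.add.at(counts, words, 1)
    return counts, int(words.size)


def kmer_counts(seq: str, k: int) -> Tuple[np.ndarray, int]:
    """Sliding-window k-mer counts; windows containing N are skipped.

    Returns (counts over the 4^k words in lexicographic order, number of
    valid windows n).  Sequences shorter than k give an all-zero vector
    with n = 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return _word_counts(_encode(seq), k)


def kmer_counts_multi(seqs: Iterable[str], k: int) -> Tuple[np.ndarray, int]:
    """Sum of per-sequence k-mer counts (windows never cross sequences)."""
    total = np.zeros(4 ** k, dtype=np.int64)
    n = 0
    for s in seqs:
        c, m = kmer_counts(s, k)
        total += c
        n += m
    return total, n


def _word_probs_from_counts(
    counts_m: np.ndarray, counts_m1: np.ndarray, k: int, m: int
) -> np.ndarray:
    """Expected word probabilities for all 4^k words under an order-m
    Markov background whose parameters come from the m-mer and
    (m+1)-mer counts.  Unseen contexts give probability 0."""
    if m == 0:
        tot = counts_m1.sum()
        p1 = counts_m1 / tot if tot else np.zeros(4)
        probs = np.ones(4 ** k)
        for i in range(k):
            digit = (np.arange(4 ** k) >> (2 * (k - 1 - i))) & 3
            probs *= p1[digit]
        return probs

    # transition p(b | c): counts_m1 reshaped (4^m contexts, 4)
    trans_counts = counts_m1.reshape(4 ** m, 4).astype(float)
    row = trans_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(row > 0, trans_counts / row, 0.0)
    tot_m = counts_m.sum()
    p_prefix = counts_m / tot_m if tot_m else np.zeros(4 ** m)

    words = np.arange(4 ** k)
    digits = np.empty((4 ** k, k), dtype=np.int64)
    for i in range(k):
        digits[:, i] = (words >> (2 * (k - 1 - i))) & 3

    prefix_idx = np.zeros(4 ** k, dtype=np.int64)
    for i in range(m):
        prefix_idx = prefix_idx * 4 + digits[:, i]
    probs = p_prefix[prefix_idx]
    ctx = prefix_idx.copy()
    mask = 4 ** m
    for i in range(m, k):
        probs = probs * trans[ctx, digits[:, i]]
        ctx = (ctx * 4 + digits[:, i]) % mask
    return probs


def markov_word_prob(seq: str, k: int, m: int) -> np.ndarray:
    """Per-word expected probabilities (length-4^k vector) under the
    order-m Markov model estimated from ``seq`` itself."""
    if not (0 <= m <= k - 2):
        raise ValueError("require 0 <= m <= k - 2")
    counts_m1, _ = kmer_counts(seq, m + 1)
    counts_m, _ = (kmer_counts(seq, m) if m >= 1 else (np.array([1.0]), 1))
    return _word_probs_from_counts(counts_m, counts_m1, k, m)


@dataclass
class _SeqProfile:
    counts: np.ndarray
    n: int
    probs: np.ndarray


def _profile(seqs: Sequence[str], params: ComplementarityParams) -> _SeqProfile:
    if params.strand_policy == "with_reverse_complement":
        seqs = list(seqs) + [reverse_complement(s) for s in seqs]
    counts, n = kmer_counts_multi(seqs, params.k)
    m = params.markov_order
    counts_m1, _ = kmer_counts_multi(seqs, m + 1)
    counts_m = (
        kmer_counts_multi(seqs, m)[0] if m >= 1 else np.array([1.0])
    )
    probs = _word_probs_from_counts(counts_m, counts_m1, params.k, m)
    return _SeqProfile(counts=counts, n=n, probs=probs)


def d2star_from_profiles(x: _SeqProfile, y: _SeqProfile) -> Optional[float]:
    if x.n == 0 or y.n == 0:
        raise ValueError("d2* requires at least one valid window per sequence")
    keep = (x.probs > 0) & (y.probs > 0)
    if not keep.any():
        return None
    ex = x.n * x.probs[keep]
    ey = y.n * y.probs[keep]
    xt = x.counts[keep] - ex
    yt = y.counts[keep] - ey
    denom_w = np.sqrt(ex * ey)
    d2s = np.sum(xt * yt / denom_w)
    norm_x = np.sqrt(np.sum(xt * xt / ex))
    norm_y = np.sqrt(np.sum(yt * yt / ey))
    if norm_x == 0 or norm_y == 0:
        return None  # degenerate: counts match expectation exactly
    val = 0.5 * (1.0 - d2s / (norm_x * norm_y))
    # clip numerical noise at the boundaries
    return float(min(max(val, 0.0), 1.0))


def d2star(
    virus_seq: str | Sequence[str],
    host_seq: str | Sequence[str],
    params: Optional[ComplementarityParams] = None,
) -> Optional[float]:
    """d2* dissimilarity between two sequences (or sequence sets, e.g. a
    multi-contig genome).  Returns None for degenerate inputs."""
    params = params or ComplementarityParams()
    vs = [virus_seq] if isinstance(virus_seq, str) else list(virus_seq)
    hs = [host_seq] if isinstance(host_seq, str) else list(host_seq)
    return d2star_from_profiles(_profile(vs, params), _profile(hs, params))


def codon_cosine_distance(
    freq_v: np.ndarray, freq_h: np.ndarray
) -> Optional[float]:
    """1 - cosine similarity of two non-negative 64-vectors; None if a
    vector has zero norm."""
    v = np.asarray(freq_v, dtype=float)
    h = np.asarray(freq_h, dtype=float)
    if np.linalg.norm(v) == 0 or np.linalg.norm(h) == 0:
        return None
    d = float(_scipy_cosine(v, h))
    return min(max(d, 0.0), 1.0)


# ---------------------------------------------------------------------------
# pipeline table
# ---------------------------------------------------------------------------

def provirus_sequence(pv: ProvirusRecord, genome: GenomeRecord) -> str:
    return genome.contigs[pv.contig_id][pv.start - 1 : pv.end]


def provirus_codon_freq(pv: ProvirusRecord, seq: str) -> Optional[np.ndarray]:
    """Codon frequencies of a provirus from its gene coordinates
    (provirus-relative); falls back to frame-0 codons of the whole
    provirus when no gene coordinates are available."""
    gene_seqs: List[str] = []
    for g in pv.genes:
        if g.start is None or g.end is None:
            continue
        sub = seq[g.start - 1 : g.end]
        gene_seqs.append(reverse_complement(sub) if g.strand == "-" else sub)
    if not gene_seqs:
        gene_seqs = [seq]
    counts = codon_counts(gene_seqs)
    total = counts.sum()
    return counts / total if total else None


def complementarity_table(
    genomes: Sequence[GenomeRecord],
    proviruses: Sequence[ProvirusRecord],
    params: Optional[ComplementarityParams] = None,
    use_excised_host: bool = True,
) -> pd.DataFrame:
    """One row per virus-host pair: d2* and codon cosine distance.

    Host backgrounds default to the provirus-excised genome.  Pairs with
    a missing sequence yield rows with missing values.
    """
    from .features import compute_features, excise_proviruses

    params = params or ComplementarityParams()
    by_genome = {g.genome_id: g for g in genomes}
    rows = []
    host_profiles: Dict[str, Tuple[Optional[_SeqProfile], Optional[np.ndarray]]] = {}

    for gid, genome in by_genome.items():
        host = (
            excise_proviruses(genome, [p for p in proviruses
                                       if p.host_genome_id == gid])
            if use_excised_host else genome
        )
        seqs = list(host.contigs.values())
        try:
            prof = _profile(seqs, params) if seqs else None
        except ValueError:
            prof = None
        fv = compute_features(host) if host.contigs else None
        host_profiles[gid] = (prof, fv.codon_freq if fv is not None else None)

    for pv in proviruses:
        genome = by_genome.get(pv.host_genome_id)
        if genome is None or pv.contig_id not in genome.contigs:
            rows.append(dict(virus_id=pv.provirus_id, host_id=pv.host_genome_id,
                             d2star=None, codon_distance=None))
            continue
        seq = provirus_sequence(pv, genome)
        prof_h, codon_h = host_profiles[pv.host_genome_id]
        d2s = None
        if prof_h is not None and prof_h.n > 0:
            try:
                d2s = d2star_from_profiles(_profile([seq], params), prof_h)
            except ValueError:
                d2s = None
        codon_v = provirus_codon_freq(pv, seq)
        dc = (
            codon_cosine_distance(codon_v, codon_h)
            if codon_v is not None and codon_h is not None else None
        )
        rows.append(dict(virus_id=pv.provirus_id, host_id=pv.host_genome_id,
                         d2star=d2s, codon_distance=dc))
    return pd.DataFrame(rows, columns=["virus_id", "host_id", "d2star",
                                       "codon_distance"])


def genus_median_complementarity(
    pair_table: pd.DataFrame,
    genomes: Sequence[GenomeRecord],
    min_genomes: int = 5,
) -> pd.DataFrame:
    """Per-genus median d2* and codon distance, over genera with at
    least ``min_genomes`` genomes (smaller genera are excluded from the
    downstream LyR correlation)."""
    genus_of = {
        g.genome_id: g.taxonomy.get("genus") for g in genomes
    }
    genus_size: Dict[str, int] = {}
    for g in genomes:
        genus = g.taxonomy.get("genus")
        if genus is not None:
            genus_size[genus] = genus_size.get(genus, 0) + 1
    df = pair_table.assign(genus=pair_table["host_id"].map(genus_of))
    df = df[df["genus"].notna()]
    df = df[df["genus"].map(genus_size) >= min_genomes]
    med = (
        df.groupby("genus", sort=True)[["d2star", "codon_distance"]]
        .median()
        .reset_index()
    )
    med["n_genomes"] = med["genus"].map(genus_size)
    return med
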