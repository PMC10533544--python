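# Methods

This note documents the models and procedures implemented in
`lysoscape`, the defaults and why they were chosen, what the synthetic
community does and does not emulate, and the package's numerical
choices and known limitations.

## Data model and conventions

All genomic intervals are 1-based inclusive (the GFF3 convention)
throughout the package; only the BED writer converts to 0-based
half-open coordinates. Non-ACGT nucleotide characters are normalised
to N on input; how N is handled is then a per-operation decision (see
below). Missing metadata is an explicit missing state, never a
default: genomes with missing depth are excluded from depth-stratified
groups but retained everywhere else, and genomes with missing quality
values are excluded from the quality filter with a logged warning.

Quality filtering retains genomes with completeness > 80 % **and**
contamination < 5 %, both strict. Depth zones are half-open:
epipelagic [0, 200), mesopelagic [200, 1000), deep sea [1000, ∞) m;
aphotic means depth ≥ 1000 m and hadal ≥ 6000 m. Placing the 200 m
and 1000 m boundary samples in the deeper zone reconciles the two ways
the zone bounds are conventionally written ("200–1000 m" vs
"> 1000 m"); users binning near-boundary samples should be aware of
this choice.

## Lysogeny statistics

A genome is a lysogen iff it carries ≥ 1 provirus. LyR of a group is
`n_lysogens / n_genomes`. Reporting minima — genera need ≥ 5 and
classes ≥ 20 genomes — are applied by *flagging* undersized groups as
suppressed rather than dropping them, so summary tables remain
auditable. Polylysogeny (≥ 2 proviruses in one host) is counted only
over proviruses carrying their category's single-copy marker protein:
TerL for tailed/unclassified viruses, Zot for Inovirales. This guards
against a single viral genome split over several contigs being counted
as multiple proviruses. Fast growers are genomes with predicted
minimum doubling time < 5 h (strict); MDT values are inputs, not
estimated here.

Group comparisons use the two-sided Wilcoxon rank-sum test in its
large-sample normal approximation without continuity or tie
correction (`scipy.stats.ranksums` — deliberately, as that is the
routine this analysis tradition uses; midranks handle ties in the
statistic itself). Feature–LyR association is Pearson's r between
genus-level LyR and per-genus median features, with two-sided p from
the t distribution on n − 2 df; groups with fewer than 5 genera or
zero variance return a missing value with the reason recorded.
P-values are reported raw, mirroring field practice; a
Benjamini–Hochberg column is available behind a flag. Whether LyR
denominators should be the dereplicated or the full genome set is
exposed at the pipeline level: the `lyr` command dereplicates by
default (one representative per host-OTU × sample, chosen by
completeness, then genome size, then id) and accepts
`--no-dereplicate`.

## Host genomic features

Features of lysogens are computed on "pure" host genomes: provirus
intervals are excised, flanks concatenated, annotations overlapping a
removed interval by ≥ 1 bp dropped, and remaining coordinates
shifted. GC is (G+C)/(A+C+G+T) with N excluded from both numerator
and denominator (ambiguous bases carry no compositional signal).
Protein-coding density is the *count* of CDS per kb — the literal
proteins-per-kb definition, not a coding fraction. N-ARSC and C-ARSC
are the mean side-chain nitrogen and carbon atom counts per residue,
from the fixed atom table (R = 3 N; K, N, Q, W = 1 N; H = 2 N; C
counts 0–9 from Gly to Trp); residues outside the 20-letter alphabet
(stops, X) are skipped in numerator and denominator alike. Codon
frequencies are in-frame counts over all CDS nucleotide sequences,
normalised to sum to 1; codons containing N are skipped.

## Virus–host complementarity

d2\* is the background-corrected oligonucleotide dissimilarity: with
word counts X_w over n valid k-windows and expected word probabilities
p_w from an order-m Markov model estimated from the sequence itself,

    X̃_w  = X_w − n_X p_w^X
    D2*  = Σ_w X̃_w Ỹ_w / sqrt(n_X p_w^X n_Y p_w^Y)
    d2*  = ½ (1 − D2* / (sqrt(Σ_w X̃_w²/(n_X p_w^X)) · sqrt(Σ_w Ỹ_w²/(n_Y p_w^Y))))

Defaults are k = 6 with m = 2, the cited tool's standard setting; both
are configurable because the upstream description pins only "default
parameters". Windows containing N are skipped; words with zero
expected probability under either background contribute to none of
the three sums (this preserves symmetry and avoids division by zero);
m = 0 reduces the background to the product of mononucleotide
frequencies. Counting is forward-strand by default with a
reverse-complement augmentation flag, since strand handling is
unspecified upstream. The host background is the provirus-excised
genome by default — a virus must not contribute to its own host
signature — with a whole-genome flag. Codon distance is 1 − cosine
similarity of the 64-vectors; virus codon usage comes from the
provirus's annotated gene coordinates when available, else frame-0
codons of the whole provirus.

## Integration sites

Site-specific integration duplicates a host att core into exact attL
and attR direct repeats at the provirus boundaries. The scanner
enumerates *maximal* exact direct repeats (extension on either side
within the provirus breaks equality) with one copy starting in the
first 1000 bp of the provirus and the other ending in the last
1000 bp; windows truncate to non-overlap at the midpoint for short
proviruses. Candidates must have length in [min_len, 145]; runs that
extend past the scan region are recognised as longer than 145 bp and
rejected rather than silently truncated. Selection is: longest, then
smallest summed distance of attL start / attR end from the provirus
boundaries, then leftmost. The observed att length range in marine
proviruses reaches down to 2 bp, but a 2-bp exact repeat in two
1000-bp windows is a guaranteed chance match, so the default minimum
is 12 bp with a config override down to 2 — a deliberate
specificity-over-sensitivity default. Only direct repeats are scanned
(attL/attR are direct repeats by the recombination mechanism), and
one repeat copy per boundary window is required.

Only proviruses with ≥ 5 host ORFs on *each* flank are analysed. The
empty locus is host-upstream + one att core + host-downstream; it is
classified tRNA (precedence) / protein-coding / noncoding by overlap
of the att copies with host annotations, and locus context is
summarised over ≤ 5 flanking host genes per side.

## Clustering and networks

All threshold clustering is single-linkage (connected components over
pairs passing the thresholds): the grouping rule is not pinned
upstream, and single linkage is deterministic and input-order
independent. Host OTUs use ANI > 95 (strict) with coverage ≥ 60;
species-level viral OTUs use ANI ≥ 95 with coverage ≥ 85; viral genera
use identity ≥ 70 with coverage ignored. The strict/non-strict
asymmetry between the host and viral 95 % bounds preserves how the two
rules are stated; both are overridable. Coverage is taken as the
alignment-length fraction of the *shorter* sequence (the upstream
denominator is unstated; documented here). ANI tables are inputs —
their computation (MUMmer/VIRIDIC-style) is out of scope, as is
protein-profile clustering into tVCs (memberships are inputs).

Infection networks connect tVCs to host genera with edge weight = the
number of that tVC's proviruses in genomes of that genus; display/
enrichment minima are environment-specific (tVCs: ≥ 15 genomes in
seawater, ≥ 5 in sediment; genera: ≥ 20 / ≥ 5). A tVC present in all
six environment × zone groups is flagged cosmopolitan. Coinfection
edges count hosts in which two tVCs are both represented by
SCMP-bearing proviruses. Host range is the number of distinct host
taxa per cluster at genus/class/phylum with multi-taxon flags.

## Annotation screens

All inequality directions follow the source thresholds literally and
live in one table (`screens.THRESHOLDS`). AMGs: metabolic flag 'M',
auxiliary score 1–3 (any integer accepted on input; the retention rule
is 1–3), at least one structural/terminase/integrase gene strictly
before *and* after the candidate in gene order, and category not
matching the exclusion keywords {DNA methylase, nucleotide metabolism}
(configurable); the first failing rule is the recorded rejection
reason, so reasons partition rejected genes. Category abundance
deduplicates AMGs by gene id and divides by viral genomes per group.
CRISPR evidence: arrays ≥ 3 spacers, full spacer-length alignment,
< 2 mismatches. Homology evidence: bitscore > 50, e-value < 1e-3,
identity > 70, length > 2500 bp, all strict. Family assignment:
proteins with best-hit bitscore ≥ 50 vote; a family needs ≥ 50 % of
all the provirus's proteins. Recruitment: e ≤ 1e-5, identity ≥ 95,
length > 50 bp; each read counts once, assigned to its best-bitscore
virus (the multi-mapping rule is unspecified upstream; this is the
package's choice); abundance = reads / (kb × reads/10⁹).

## Synthetic community

The generator's defaults are the study conditions. Six environment ×
zone strata totalling 50 genomes, weighted toward epipelagic seawater
and deep-sea sediment; per-stratum lysogeny probabilities 0.36 / 0.45
/ 0.53 (seawater epi/meso/deep) and 0.46 / 0.49 / 0.47 (sediment) —
the reported pattern of lysogeny rising with depth in seawater and
staying flat in sediment. Genome lengths uniform 0.5–2 Mb; per-genus
GC uniform in (0.35, 0.65); proviruses per lysogen 1 + Poisson(1.65)
(mean 2.65, matching the reported mean); provirus lengths uniform
10–60 kb; att lengths uniform 12–30 bp (within the observed 2–145 bp
range and above the detector's specificity floor); TerL/Zot carriage
probability 0.8; CDS density 0.9 genes/kb; integration-target mix
0.16 tRNA / 0.40 protein-coding / 0.44 noncoding.

Host sequences are i.i.d. nucleotides at the GC target with genes
planted by codon sampling (stop-free interior, ATG/TAA bounds, random
strand) and 75-bp tRNA placeholders with hotspot-weighted isotypes
(Leu/Ser/Arg enriched). Insertion follows the duplication model: an
att core *already present in the host* (the tail of a tRNA or CDS, or
a gap segment) is duplicated around a generated viral interior, so
excision retaining one copy reproduces the pre-insertion sequence
exactly — the ground-truth invariant every reconstruction test uses.
Viral interiors carry an integrase, the category's single-copy marker
with probability 0.8, structural genes, candidate metabolic genes
with auxiliary scores 1–5, occasional tRNAs, and a GC offset of up to
±0.1 from the host so complementarity indices carry signal. Planted
att repeats are rejection-sampled until they are the *only*
window-constrained maximal repeat of their length or more, making
detection ground truth unambiguous. One global seeded random stream
makes outputs byte-identical per seed.

What the generator does **not** emulate: phylogenetic sequence
evolution (genera are labels over independent sequences), real codon
usage tables, read-level sequencing noise, assembly fragmentation
(one contig per genome), or provirus prediction errors (emitted
coordinates are true). Passing tests therefore demonstrate the
correctness of the *analytics* against a controlled generative model,
not robustness to upstream caller noise.

The hit-table generator emits recruitment-, CRISPR- and
homology-style alignment tables in which every row passes or fails a
known single rule, with the truth recorded alongside — the screens are
tested against exact expected counts.

## Problem sizes and numerics

The default test and acceptance scale is 50 genomes (0.5–2 Mb) for
the end-to-end run, 200 genomes per stratum for binomial LyR recovery,
120 planted proviruses for att recovery, 50 genera × 5 genomes for
correlation recovery, and 100 random pairs for d2\* oracle
equivalence (tolerance 1e-10; the optimised path agrees with explicit
enumeration to ~1e-16). d2\* is clipped to [0, 1] against
floating-point noise at the boundaries. GC recovery at 1 Mb is
accurate to |Δ| < 0.01; the residual bias (~0.004) comes from
stop-codon exclusion in coding regions and is documented rather than
corrected. Ties in att selection, family votes and dereplication all
break deterministically (documented in each docstring), so identical
inputs give identical outputs regardless of iteration order.

## Known limitations

* Provirus prediction, taxonomy assignment, MDT estimation, tVC
  computation and ANI calculation are inputs by design; garbage in,
  garbage out.
* The att scanner reports at most one repeat pair per provirus; tandem
  or nested integration systems are summarised by their single best
  repeat.
* The d2\* background is estimated per sequence; very short
  proviruses (< ~2 kb) give noisy backgrounds at m = 2, and unseen
  contexts yield zero-probability words that are skipped rather than
  smoothed.
* Coverage denominators for input similarity tables must match the
  shorter-sequence convention; tables computed with a different
  denominator shift cluster granularity.
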