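# Methods

This note documents the models, defaults and numerical choices behind
`gyrbench`, and what the synthetic benchmark does and does not demonstrate.

## The problem being modelled

*gyrB* amplicon sequencing targets a ~280 bp fragment of the DNA gyrase
subunit B gene with highly degenerate primers (F64
`MGNCCNGSNATGTAYATHGG` / R353 `CNCCRTGNARDCCDCCNGA`). Because *gyrB* is
single-copy and fast-evolving, clusters of amplicons separate strains
within a species. Two marker-specific effects shape the analysis:

1. **parE co-amplification.** Within *Firmicutes*, the paralog *parE*
   (topoisomerase IV subunit B) is similar enough to *gyrB* that the same
   primers amplify it; the *parE* share of a species' reads is roughly
   constant across samples but strongly species-dependent. Within
   *Proteobacteria* the paralog is too divergent to amplify. A
   paralog-aware reference database (both genes, gene-labelled) is
   therefore required for assignment.
2. **Absolute quantification.** Read fractions only become comparable
   across samples after anchoring to total bacterial load. Two qPCR
   calibrations convert threshold cycles to CFU·g⁻¹:
   Ct = 39.43 − 1.52·ln(CFU) for 16S-based probes and
   Ct = 40.98 − 1.44·ln(CFU) for housekeeping-gene probes. Absolute reads
   are n_a = n_r × Q / N_t with Q the all-bacteria qPCR load and N_t the
   per-sample read total after median-depth normalization.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies on,
not the sequences of real genomes.

**Compositions.** Presets MC1–MC4 encode the published mock designs
exactly: MC1/MC2/MC3 mix the same 15 species (8 *Firmicutes*, 7
*Proteobacteria*) at phylum splits 99/1, 50/50 and 1/99, with fixed
within-phylum percentages; MC4 mixes 14 strains of 5 species at 65/35.
The fifth mock of the original design (unknown, food-derived composition)
is deliberately not bundled.

**Reference amplicons.** Sequences are built top-down: a random root,
phylum ancestors (*Firmicutes* at 5% divergence from the root,
*Proteobacteria* at 30%), a *parE* ancestor branching off the *Firmicutes*
*gyrB* ancestor at 25%, and species backbones at 10% below their ancestor.
This geometry reproduces the observed paralog topology — *Firmicutes*
*parE* sequences are closer to *Firmicutes* *gyrB* than either is to
*Proteobacteria* *gyrB* — while keeping every pair well inside the K2P
model's saturation limit. Intra-species strain sequences realize a
*divergence plan* (pairwise edit distances) through substitutions at
disjoint positions; a plan is accepted when it admits an additive integer
star decomposition d(i,j) = x_i + x_j, which substitutions at disjoint
sites realize exactly. The default plan makes *L. sakei* 23K and DSM15831
nearly identical (2 edits) with DSM20017 distant (8 edits), *B.
thermosphacta* clonal (0 edits), and the two *L. gelidum* subspecies
clearly separated (12 edits). The generated set is verified: inter-species
pairs ≥ 7 edits (= 2d+1 at the clustering distance d = 3, so species never
chain together), *parE*–*gyrB* pairs ≥ 20% of the amplicon length.

**Reads.** Per sample, (strain, gene) class counts are multinomial with
probability proportional to strain fraction × parE split; each read copies
its reference with i.i.d. substitutions. Defaults: depth 5×10⁴ reads,
error rate 10⁻³ substitutions per base — the benchmark's stated study
condition; real runs have no published per-base error figure, so this is a
convention of the synthetic benchmark. The error model is
substitution-only by default so that amplicon lengths stay constant and the
clustering oracle stays simple; an indel mode (`indel_rate`) exists as a
flag. Chimeras (off by default, `chimera_rate`) join a prefix and suffix of
two distinct references at a uniform breakpoint and are emitted on top of
the true counts, so truth counts always sum to the nominal depth.

**parE fractions.** Defaults follow the reported per-taxon ranges:
*L. algidus* 0.80, *L. sakei* 0.30, *Brochothrix* 0.80, Leuconostocaceae
0.70–0.75, Carnobacteriaceae 0.80–0.85; *L. piscium*, for which no figure
is reported, is set once to 0.40 as a mid-range *Firmicutes* value; all
*Proteobacteria* are 0.

**qPCR.** Sample total loads are log-normal around 10⁸ CFU·g⁻¹ (SD 0.3
log₁₀, a typical spoilage load at the use-by date); species loads are the
total times the species' community fraction. Ct values follow the two
calibrations with Gaussian noise (default SD 0.15 cycles); at zero noise
the Ct↔CFU round trip is exact to 1e-9 relative.

**Quantification panel.** A 13-species panel (the quantified subset of the
mock species; the two dropped species were fixed once, arbitrarily) with 20
samples, species loads log-uniform over 10⁴–10⁹ CFU·g⁻¹, multinomial reads
weighted by load × 10^bias, per-observation lognormal read noise (0.3
log₁₀). Eleven species have near-zero bias (wobble SD 0.1 log₁₀); two carry
strong biases fixed by design — *L. algidus* +1.3 log₁₀ (over-amplified)
and *B. thermosphacta* −1.2 log₁₀ (under-amplified) — reproducing the
over/under-estimation structure of real food-sample quantification, where
11 of 13 species stayed within 1.0 log₁₀ median deviation.

What the generator does **not** emulate: real sequence content and codon
structure, quality-score profiles, PCR-cycle-dependent chimera kinetics,
length variation of real amplicons across taxa, primer-efficiency bias
(other than the parE split and the panel's species biases), or
contaminating taxa. Passing tests therefore demonstrate that the pipeline's
logic is correct under the stated statistical model, not that it is robust
to every artifact of real MiSeq data.

## Pipeline

**Clustering.** OTUs are the connected components of unique sequences
joined at Levenshtein distance ≤ d (default 3) — the single-linkage
reading of swarm's "d differences", chosen over Hamming distance so the
optional indel mode is covered. Small inputs (≤ 600 unique sequences) are
clustered by brute force over all pairs. Larger inputs use a pigeonhole
candidate filter: each sequence is cut into d+1 positional chunks; two
equal-length sequences within d substitutions must share at least one
chunk, so only chunk-sharing pairs are verified (banded edit distance,
early exit), with all-pairs verification across length buckets differing by
≤ d. Pairs already connected are skipped — this cannot change the final
components. The filter is exact for the default substitution-only error
model; an edit path between equal-length sequences that uses compensating
indels could in principle evade it, which is why the brute-force path
covers small inputs and the oracle tests. Representatives are the
highest-count member (lexicographic tie-break); ids are assigned in
decreasing total order (`Cluster_1` is the most abundant).

**Chimera removal** is an explicit simplification of de-novo detectors: an
OTU is flagged only when its representative decomposes exactly into a
prefix of one ≥2×-more-abundant OTU representative and a suffix of another,
and is not within d of any single parent. It can be switched off.

**Abundance filter.** "More than 10 reads in the whole dataset" is
implemented as total ≥ 11 over all samples (per-dataset, not per-sample);
the boundary is configurable.

**Assignment.** Global (end-to-end) unit-cost alignment replaces local
alignment — defensible because all amplicons span the same primer-bounded
region. Identity = matches / alignment columns × 100, computed from the
extended CIGAR. Ties on (edit distance, alignment length) are resolved by
lexicographic marker id, making results invariant to database order; tied
best hits with disagreeing taxonomies truncate to their lowest common rank,
and disagreeing gene labels yield `ambiguous`. Identity < 80% demotes the
assignment to phylum: intra-species marker identity runs around 94–95%, so
weaker hits carry no rank information.

**Quantification.** Species read counts (both gene labels pooled — *parE*
reads count toward their species) are median-depth normalized, converted to
n_a, and regressed in log₁₀ space against qPCR CFU per phylum stratum
(OLS; ≥ 3 detected points required; zeros excluded from log space and
reported as "not detected" — the handling of zeros is this package's
choice). Deviations are per-observation residuals; per species both the
signed median and the median absolute deviation are reported, since either
reading of "median deviation" is defensible; |median| < 0.1 log₁₀ is
called unbiased (an artifact convention).

**Rarefaction** uses the exact hypergeometric expectation
E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)] with log-gamma arithmetic rather
than repeated subsampling — deterministic and testable against Monte
Carlo. Curves are computed on the filtered table by default; the unfiltered
order is available by clustering with `min_total=0`.

**PCoA** is classical metric scaling (double-centering, `eigh`). Bray-Curtis
distances are non-Euclidean, so negative eigenvalues occur; they are
dropped from the variance denominator with a logged warning (no Cailliez
correction), and axis coordinates are eigenvectors scaled by √λ.

**Phylogenetics.** K2P distances use pairwise deletion of gapped/ambiguous
sites (the usual default when the deletion mode is unstated); unequal-length
pairs are end-to-end aligned first — a full MSA is out of scope because the
amplicons are coordinate-homologous by construction. Neighbor joining is the
standard Saitou–Nei agglomeration with the Q-criterion; ties are broken by
the lexicographically smallest pair of node keys (a node's key is its
smallest descendant label), so topologies are deterministic. Negative branch
lengths are clamped to zero with the deficit moved to the sibling edge. On
additive matrices the reconstruction is exact (tested to 1e-9).

## Problem sizes and determinism

The bundled benchmark runs each mock at 5×10⁴ reads — deep enough that the
rarest design fraction (0.05% of the community, 25 reads) clears the
≥ 11-read filter with margin, and that phylum fractions are measured to
±0.7% (3 binomial SDs) or better. The quantification panel uses 20 samples
× 13 species. Every random draw flows from one master seed through named
substreams per stage (reads, qPCR, panel, genome embedding), so a fixed
seed yields byte-identical FASTA and table output; the workflow manifest
records SHA-256 checksums of every file to make this checkable.

## Known limitations

* The chimera detector only finds exact two-parent crossovers; real
  chimeras with additional substitutions near the breakpoint escape it.
* The pigeonhole clustering filter's exactness argument covers
  substitution-only differences between equal-length sequences; the indel
  error mode falls back to coarser (length-bucket) candidate generation.
* Gene-level taxonomy is only as good as the reference set: a *parE* OTU of
  a species absent from the database will hit the nearest *parE* neighbor,
  exactly as with real reference gaps.
* The quantification model assumes the qPCR calibrations hold across the
  full load range; inhibitor effects and probe-specificity failures are not
  modelled.
* Real-data figures that depend on the original sequencing runs (food
  sample richness, ordination variance percentages, chimera rates) are out
  of scope for the synthetic benchmark.
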