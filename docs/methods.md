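# Methods

## Calling model

The unit of evidence is the per-site, strand-resolved count vector
(A, C, G, T on each strand) built from `samtools mpileup` text after a
Phred+33 base-quality floor (default 30). Mapping-quality filtering
(secondary/supplementary reads, NUMT-derived pairs) is assumed done
upstream by the aligner pipeline; the parser does not re-filter, and
overlapping mate pairs are counted however mpileup emitted them.

Substitutions and heteroplasmies are independent call types applied to
every site (a non-reference major allele with a significant minor
allele yields both). The criteria are deliberately simple and
threshold-based:

- strand concordance of the major (and, for heteroplasmy, minor)
  allele between forward and reverse strands — the main guard against
  strand-biased artifacts;
- strict per-strand support: each relevant allele needs more than
  `min_strand_reads` (default 3, i.e. ≥ 4) reads on *each* strand;
- a one-sided exact binomial test of the minor count against a fixed
  noise floor, H0: p = `noise_floor` (default 1%) vs H1: p > floor,
  at level `alpha` (default 0.05), computed as the upper tail
  P(X ≥ k) with n = total site depth;
- a positional mask of low-complexity/ambiguous regions (302–316,
  513–526, 566–573, 3106–3107, 16181–16194 in rCRS coordinates).

Choices the method leaves open, and the defaults taken here: the
significance level (0.05, one-sided, no multiple-testing correction),
the binomial trial count (total depth; major+minor available), the MAF
denominator (total depth; major+minor available), and tie-breaking for
equal allele counts (alphabetical, deterministic). Sites whose
reference base is `N` (rCRS 3107) are never called.

### Detection limits

These criteria impose a hard floor on sensitivity that depends on
depth. At ~600× (100,000 × 100 bp reads on 16,569 bp), a true 1.5%
heteroplasmy yields E[minor] ≈ 9 reads: the probability of ≥ 4 reads
on *both* strands is ≈ 0.5, and the exact binomial test of 1.5% vs the
1% floor at n ≈ 604 has power ≈ 0.34 at α = 0.05, so recall in this
cell is ≈ 0.3 — the package's simulation reports exactly this.
Recall rises steeply with MAF (≈ 0.86 at 2.5%, > 0.98 at 3.5%) and
with depth. Precision is ≈ 1.0 throughout: with a 3‰ per-base error
rate spread over three alternate bases, a spurious allele essentially
never reaches 4+ reads per strand *and* binomial significance.
Raising `alpha` can only add calls; raising `min_strand_reads` can
only remove them (both monotonicities are property-tested).

## Circular-genome handling

A pseudo-reference appends the first E bases (default 500, capped at
the genome length) to the linear sequence so reads spanning the origin
align contiguously; per-site counts at extension positions L+p are
folded back into p by element-wise summation, which conserves total
counts exactly. Folding assumes the upstream aligner reports one
alignment per read, so no read is double-counted across the junction.

## Simulator

The simulator is count-level by design: reads of length 100 are placed
uniformly on the circle, each read gets a strand with probability ½,
reads covering a planted site carry the alternate allele with
probability equal to the target MAF, and each emitted base is
independently miscalled to a uniformly chosen other base with
probability `error_rate` (default 3‰). These per-read Bernoulli draws
are aggregated exactly — coverage from the read-start layout, then
binomial (planted allele) and multinomial (error kernel) draws per
covered position — so no FASTQ or aligner is involved and the
evaluation isolates the calling criteria. What this does *not* emulate:
alignment artifacts, NUMT contamination, quality-score structure,
indels, chimeric reads, and within-read correlation of errors; results
on real data depend additionally on the upstream alignment pipeline.

Planted positions are drawn uniformly from unmasked, non-`N` sites
with alternate alleles uniform over the three non-reference bases.
Each replicate plants 50 heteroplasmies — sparse relative to 16,569
sites (no interference between sites) yet enough for stable
per-replicate precision/recall. A true positive must match position
and minor allele (position-only matching available). Undefined rates
(precision with zero calls; recall with empty truth) are reported as
absent, never as 0. The full grid (11 MAFs × 6 read counts × 100
replicates) runs in a few minutes on one CPU; the headline cell
(1.5%, 100k reads, 100 replicates) in ~20 s. All randomness flows
from one integer seed through a fixed per-(cell, replicate)
derivation, so a grid run and a single-cell run agree bit-for-bit.

## Copy number

`mtCN = (mt_depth / CDS_depth) · R_tumor`, with `R_tumor =
purity·ploidy + (1 − purity)·2` the convex mixture of tumor and
contaminating-normal ploidy. An alternate convention dividing
`R_tumor` by 2 (copy number per diploid-genome equivalent) is provided
behind a flag because both normalizations are in circulation; the
output records which was used. Purity and ploidy are taken as given.

## Distance matrices, dendrograms, wRFD

Coordinate distances are Euclidean in mm; heteroplasmy distances are
the Euclidean (or Manhattan) norm of the per-site MAF difference
vector with absent sites as MAF 0 — absence is informative, not
missing; scalar characteristics (mtCN) use absolute differences,
which makes the resulting dendrogram a caterpillar. Matrices are
min–max normalized over off-diagonal entries (constant matrices map
to zeros; divide-by-max offered), then trees are built —
normalization before tree building, neighbor joining by default
(negative branch lengths clamped to 0), UPGMA as an option. A
designated sample (e.g. the nontumor section) can root the tree as
outgroup; a sample without coordinates is simply absent from the
coordinate matrix.

The weighted Robinson–Foulds distance is the sum over the union of
nontrivial bipartitions of |w1 − w2|, where w is the inducing branch's
length and a split absent from a tree weighs 0; pendant (trivial)
splits are excluded, the two edges at a rooted-binary root are merged,
so the distance is a pseudometric on unrooted weighted topologies. The
implementation is cross-checked against a graph-cut brute-force
enumerator and scikit-bio's weighted RF (tips excluded).

Significance: the labels of one tree's leaves are permuted uniformly
(equivalent in distribution to permuting either tree's), the wRFD
recomputed, and `p = (1 + #{null ≤ observed}) / (1 + n)` with
n = 1000 permutations by default — the add-one convention never
reports 0. Under exchangeability the rejection rate at α = 0.05 is
exact, which the suite verifies over 200 spatially shuffled synthetic
tumors.

## Selection statistics

Classification: NC when no protein-coding gene covers the position;
otherwise the affected codon is translated with and without the
alternate allele under the vertebrate mitochondrial code (light-strand
genes via reverse complement); S only if silent in every covering gene
(overlapping genes, e.g. ATP8/ATP6, therefore resolve conservatively
to NS if either frame changes). Genes whose span is not a codon
multiple are padded with `A` to the next boundary, mirroring the
post-transcriptional polyadenylation that completes their stop codons.

Recurrent heteroplasmies are deduplicated by (position, ref, alt)
before counting — within one tumor they most plausibly descend from a
single mutation event — with carriers retained.

Ka/Ks uses Nei–Gojobori site counting over the concatenated coding
regions: each sense-codon position contributes its synonymous fraction
of the three possible changes (changes to stop codons count as
nonsynonymous; stop codons themselves are skipped), and
Ka = NS_obs/N_sites, Ks = S_obs/S_sites. This counting estimator was
chosen because the input is a sparse list of independent single-base
mutations, not an alignment of diverged sequences — maximum-likelihood
codon models add nothing at divergence ~10⁻³ and need an alignment.
Uniform draws from all possible coding changes give a ratio of 1 by
construction, which calibrates the estimator in the suite (within 0.1
at n = 2000). The 95% CI resamples the mutation list with replacement
(percentile bootstrap, 1000 draws by default); resamples with zero
synonymous draws are excluded and counted. Ks = 0 leaves the ratio
undefined and flagged, never infinite.

Group comparisons: two-sided Mann–Whitney U for MAF/frequency
contrasts (exact for small tie-free samples, tie-corrected normal
approximation otherwise); two-sided Fisher exact test for NS:S
proportion contrasts between gene sets.

## Synthetic tumor generator

Samples are placed uniformly in a 35 mm-diameter disc; heteroplasmic
sites belong either to tumor-wide shared events (present everywhere at
a common base MAF) or to one of 5 spatial subclones (3 private sites
each) whose expected MAF decays exponentially from the clone center
with a 10 mm correlation length. Observed MAFs add Gaussian noise
(σ = 0.005), clip to [0, 0.5], and fall to 0 (undetected) below a 1%
detection floor; per-sample mtCN is log-normal. Defaults (23 samples,
18 sites) mirror the scale of a microsectioned-tumor study. The
generator does not model nuclear SNV evolution, sequencing noise at
the read level, or clone competition; passing tree-comparison tests on
it demonstrates calibration and power of the statistics under a clean
spatial-clonal signal, not performance on any particular real tumor.
In shuffled mode the coordinates are permuted after MAF generation,
giving an exact null for type-I-error calibration; the clustered
defaults give the permutation test high power, which the suite checks.

## Problem sizes in the shipped checks

The test suite and acceptance script use: 100 replicates for the
headline simulation cell, 10 replicates for higher-MAF spot checks,
200 random tree pairs (≤ 6 leaves) for the wRFD oracle, 200 shuffled
tumors × 199 permutations for type-I calibration, and 2000 sampled
coding changes for the neutrality calibration. These sizes keep the
whole suite under a minute while leaving Monte-Carlo margins well
inside the asserted tolerances.

## Known limitations

- No indel calling, contamination modeling, or NUMT-aware
  realignment; the caller trusts its input counts.
- The binomial noise-floor test treats errors as independent across
  reads and strands; systematic context-specific errors would need an
  empirical error model.
- Copy-number estimates inherit any bias in the purity/ploidy inputs.
- The wRFD permutation test conditions on both topologies and branch
  lengths; it tests label assignment, not tree shape.
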