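# mitovar

Strand-aware detection of mitochondrial DNA heteroplasmies and
substitutions, with a built-in simulation study of the caller's
precision and recall, and the downstream analyses used to study
intratumor mtDNA heterogeneity: relative mtDNA copy number, distance
matrices and dendrograms over sample characteristics, weighted
Robinson–Foulds tree comparison with permutation significance, and
selection statistics (Ka/Ks, MAF comparisons).

## Who this is for

Groups working with deep short-read sequencing of human (or any
circular) mitochondrial genomes who need to call low-frequency
heteroplasmies — the coexistence of two mtDNA alleles within one
sample, quantified by the minor-allele fraction (MAF) — and to relate
per-sample heteroplasmy profiles to spatial sampling structure, copy
number and nuclear variation, e.g. across microsections of a single
tumor.

## The method

**Calling.** Input is a per-site, strand-resolved base-count table
(parsed from `samtools mpileup` text with a base-quality floor,
default Q30). At each site, with per-strand counts of the four bases:

- a **substitution** is called when the forward- and reverse-strand
  major alleles agree, differ from the reference allele, and each
  strand's major count is > 3 (configurable, strict);
- a **heteroplasmy** is called when the major *and* minor alleles agree
  between strands, each of the four (allele × strand) counts is > 3,
  the site is outside a low-complexity mask (rCRS 302–316, 513–526,
  566–573, 3106–3107, 16181–16194), and a one-sided exact binomial
  test rejects H0: minor fraction = 1% (the noise floor) at α = 0.05:

      p = P( X ≥ k_minor ),  X ~ Binomial(n = depth, p0 = 0.01)

  The reported MAF is k_minor / depth.

**Circular reference.** Reads spanning the circle's origin are handled
by aligning to a pseudo-reference with the first *E* bases (default
500) copied to the end (16,569 → 17,069 bp), then folding counts at
extension positions `L + p` back into `p` by element-wise summation.

**Evaluation.** A count-level simulator places uniform 100 bp reads on
the circle (strand ~ Bernoulli(½), per-base error 3‰, planted minor
alleles at fixed MAF) and scores calls as precision = TP/(TP+FP) and
recall = TP/(TP+FN) over a MAF × depth grid (MAF 1.5%–20.5%, 100k–1M
reads ≈ 500×–5000×, 100 replicates per cell).

**Downstream.** Relative copy number
`mtCN = (mt_depth / CDS_depth) · R_tumor` with
`R_tumor = purity·ploidy + (1 − purity)·2`; Euclidean/Manhattan
distance matrices over coordinates, MAF profiles and scalars, min–max
normalized; NJ or UPGMA dendrograms; weighted Robinson–Foulds distance
`wRFD(T1,T2) = Σ_s |w1(s) − w2(s)|` over nontrivial bipartitions, with
leaf-label permutation p-values; NC/S/NS classification under the
vertebrate mitochondrial code and Nei–Gojobori-style Ka/Ks with
bootstrap CIs.

## Worked example

Simulate one sample at ~500× with five planted 10% heteroplasmies,
call, and score:

```console
$ mitovar simulate --maf 0.1 --n-reads 100000 --n-heteroplasmies 5 \
    --seed 42 --out-prefix demo
100000 reads (~500x), 5 planted sites -> demo.counts.tsv / .truth.tsv

$ mitovar call --counts demo.counts.tsv --out-prefix demo_calls
0 substitutions, 5 heteroplasmies -> demo_calls.heteroplasmies.tsv

$ mitovar evaluate --calls demo_calls.heteroplasmies.tsv --truth demo.truth.tsv
TP=5 FP=0 FN=0 precision=1.0 recall=1.0

$ head -4 demo_calls.heteroplasmies.tsv
position  major  minor  maf     major_fwd  major_rev  minor_fwd  minor_rev  p_value
1511      C      A      0.0951  259        274        32         24         6.58e-36
7191      C      G      0.106   267        272        33         31         1.15e-43
7288      G      T      0.0961  261        275        26         31         8.94e-37
```

Each row is one called heteroplasmy: major/minor alleles, the MAF
(minor reads / total depth; e.g. 0.0951 means 9.5% of reads carry the
minor allele), per-strand support for both alleles, and the binomial
noise-floor p-value. All five planted sites were recovered with no
false positives — at 10% MAF and ~600× the caller is essentially
error-free; sensitivity drops near the 1%-floor detection limit (see
`docs/methods.md`).

Other entry points: `mitovar grid` (full precision/recall surface),
`mitovar mtcn`, `mitovar spatial` (dendrograms + wRFD + permutation
test from coordinate/MAF/mtCN/SNV tables), `mitovar selection`
(classification + Ka/Ks), `mitovar fixtures` (packaged and synthetic
data), `mitovar pseudo-ref`.

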