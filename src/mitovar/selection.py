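"""Selection analysis of mitochondrial mutations.

Mutations are classified as noncoding (NC) when no protein-coding gene
covers the position, otherwise as synonymous (S) or nonsynonymous (NS)
by translating the affected codon with and without the alternate allele
under the vertebrate mitochondrial code (NCBI table 2); light-strand
genes are read from the reverse complement.  A mutation covered by
overlapping genes is synonymous only if it leaves the amino acid
unchanged in *every* covering gene.

Ka/Ks follows the Nei-Gojobori (1986) counting approach: each codon
position contributes its fraction of synonymous single-base changes to
the synonymous site total (changes to stop codons count as
nonsynonymous), observed deduplicated mutations are tallied as S or NS,
and Ka = NS_obs / N_sites, Ks = S_obs / S_sites.  Confidence intervals
come from resampling the mutation list with replacement.

Genes whose annotated span is not a codon multiple (several mtDNA
genes end in an incomplete stop codon completed by polyadenylation)
are padded with ``A`` to the next codon boundary before translation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from scipy.stats import fisher_exact, mannwhitneyu

from .reference import MitoReference

__all__ = [
    "GeneAnnotation",
    "Mutation",
    "MutationAnnotation",
    "SelectionResult",
    "load_gene_annotations",
    "classify",
    "dedup",
    "ng86_site_counts",
    "ka_ks",
    "enumerate_coding_changes",
    "maf_compare",
    "geneset_compare",
]

_MITO_TABLE = unambiguous_dna_by_id[2]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene span, 1-based inclusive."""

    gene: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"invalid gene span {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class Mutation:
    """One observed mutation in one sample."""

    position: int
    ref: str
    alt: str
    sample: str = ""
    maf: Optional[float] = None


@dataclass(frozen=True)
class MutationAnnotation:
    position: int
    ref: str
    alt: str
    category: str  # "NC", "S", or "NS"
    genes: tuple[str, ...] = ()
    samples: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectionResult:
    ka: float
    ks: float
    ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_resamples: int
    ns_observed: int
    s_observed: int
    n_sites: float
    s_sites: float
    n_valid_resamples: int = 0


def load_gene_annotations(
    path: Optional[Union[str, Path]] = None
) -> list[GeneAnnotation]:
    """Load a gene table (default: the packaged 13 mtDNA coding genes)."""
    if path is None:
        path = Path(
            str(importlib.resources.files("mitovar") / "data" / "mt_coding_genes.tsv")
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneAnnotation(
            gene=str(r.gene), start=int(r.start), end=int(r.end), strand=str(r.strand)
        )
        for r in df.itertuples(index=False)
    ]


def _gene_cds(gene: GeneAnnotation, reference: MitoReference) -> str:
    raw = reference.sequence[gene.start - 1 : gene.end]
    if gene.strand == "-":
        raw = str(Seq(raw).reverse_complement())
    pad = (3 - len(raw) % 3) % 3
    return raw + "A" * pad


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def _codon_change(
    gene: GeneAnnotation, reference: MitoReference, position: int, alt: str
) -> tuple[str, str]:
    """Amino acids before/after the change, in ``gene``'s reading frame."""
    cds = _gene_cds(gene, reference)
    if gene.strand == "+":
        idx = position - gene.start
        alt_base = alt
    else:
        idx = gene.end - position
        alt_base = _COMPLEMENT[alt]
    codon_i, within = divmod(idx, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    return _translate_codon(codon), _translate_codon(mutated)


def classify(
    position: int,
    ref: str,
    alt: str,
    annotations: Sequence[GeneAnnotation],
    reference: MitoReference,
    samples: Sequence[str] = (),
) -> MutationAnnotation:
    """Assign NC / S / NS to a single-base change.

    Raises on a position outside the reference or a reference-allele
    mismatch.  A change is S only if every covering gene translates to
    the same amino acid with and without the alternate allele.
    """
    ref, alt = ref.upper(), alt.upper()
    if not 1 <= position <= len(reference):
        raise IndexError(f"position {position} outside reference")
    actual = reference.base(position)
    if actual != ref:
        raise ValueError(
            f"reference mismatch at {position}: expected {ref}, found {actual}"
        )
    if ref == alt:
        raise ValueError("ref and alt must differ")
    covering = [g for g in annotations if g.covers(position)]
    if not covering:
        return MutationAnnotation(position, ref, alt, "NC", (), tuple(samples))
    synonymous = all(
        before == after
        for before, after in (
            _codon_change(g, reference, position, alt) for g in covering
        )
    )
    return MutationAnnotation(
        position,
        ref,
        alt,
        "S" if synonymous else "NS",
        tuple(g.gene for g in covering),
        tuple(samples),
    )


def dedup(mutations: Iterable[Mutation]) -> list[Mutation]:
    """Collapse recurrent mutations to one record per (position, ref, alt).

    The same heteroplasmy seen in many samples of one tumor most likely
    descends from a single mutation event, so it counts once; the
    samples carrying it are retained in order of first appearance.
    """
    seen: dict[tuple[int, str, str], list[str]] = {}
    order: list[tuple[int, str, str]] = []
    for m in mutations:
        key = (m.position, m.ref.upper(), m.alt.upper())
        if key not in seen:
            seen[key] = []
            order.append(key)
        if m.sample:
            seen[key].append(m.sample)
    return [
        Mutation(position=k[0], ref=k[1], alt=k[2], sample=",".join(seen[k]))
        for k in order
    ]


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts of a CDS (NG86).

    Each position of each sense codon contributes the fraction of its 3
    possible single-base changes that are synonymous to the synonymous
    site total and the complement to the nonsynonymous total.  Stop
    codons are skipped; changes *to* a stop count as nonsynonymous.
    Returns ``(n_sites, s_sites)``.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be a codon multiple")
    n_sites = s_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon or codon in _MITO_TABLE.stop_codons:
            continue
        aa = _translate_codon(codon)
        for within in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[within]:
                    continue
                mut = codon[:within] + b + codon[within + 1 :]
                if _translate_codon(mut) == aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += 1.0 - syn / 3.0
    return n_sites, s_sites


def _total_site_counts(
    annotations: Sequence[GeneAnnotation], reference: MitoReference
) -> tuple[float, float]:
    n_sites = s_sites = 0.0
    for g in annotations:
        n, s = ng86_site_counts(_gene_cds(g, reference))
        n_sites += n
        s_sites += s
    return n_sites, s_sites


def ka_ks(
    mutations: Sequence[Mutation],
    annotations: Sequence[GeneAnnotation],
    reference: MitoReference,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Counting-method Ka/Ks over a deduplicated mutation list.

    Noncoding mutations are ignored.  The 95% CI is the 2.5/97.5
    percentile of the ratio over ``n_resamples`` with-replacement
    resamples of the mutation list; resamples with Ks = 0 are excluded
    from the percentiles (their number is reported via
    ``n_valid_resamples``).  Ks = 0 on the observed data leaves the
    ratio undefined (``None``).
    """
    n_sites, s_sites = _total_site_counts(annotations, reference)
    categories = [
        classify(m.position, m.ref, m.alt, annotations, reference).category
        for m in mutations
    ]
    coding = np.array([c for c in categories if c != "NC"])
    if coding.size == 0:
        return SelectionResult(
            ka=0.0, ks=0.0, ratio=None, ci_low=None, ci_high=None,
            n_resamples=n_resamples, ns_observed=0, s_observed=0,
            n_sites=n_sites, s_sites=s_sites,
        )
    ns_obs = int((coding == "NS").sum())
    s_obs = int((coding == "S").sum())
    ka = ns_obs / n_sites
    ks = s_obs / s_sites
    ratio = (ka / ks) if ks > 0 else None

    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_resamples):
        draw = rng.choice(coding, size=coding.size, replace=True)
        ns_b = (draw == "NS").sum() / n_sites
        s_b = (draw == "S").sum() / s_sites
        if s_b > 0:
            ratios.append(ns_b / s_b)
    if ratios:
        ci_low, ci_high = np.percentile(ratios, [2.5, 97.5])
    else:
        ci_low = ci_high = None
    return SelectionResult(
        ka=ka, ks=ks, ratio=ratio,
        ci_low=None if ci_low is None else float(ci_low),
        ci_high=None if ci_high is None else float(ci_high),
        n_resamples=n_resamples, ns_observed=ns_obs, s_observed=s_obs,
        n_sites=n_sites, s_sites=s_sites, n_valid_resamples=len(ratios),
    )


def enumerate_coding_changes(
    annotations: Sequence[GeneAnnotation], reference: MitoReference
) -> list[Mutation]:
    """Every possible single-base change at every coding position.

    Useful for neutrality calibration: mutations drawn uniformly from
    this list should give Ka/Ks near 1.
    """
    out = []
    covered: set[int] = set()
    for g in annotations:
        covered.update(range(g.start, g.end + 1))
    for pos in sorted(covered):
        ref = reference.base(pos)
        if ref == "N":
            continue
        for alt in "ACGT":
            if alt != ref:
                out.append(Mutation(position=pos, ref=ref, alt=alt))
    return out


def maf_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney U p-value between two MAF samples.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def geneset_compare(
    freq_a: Sequence[float],
    freq_b: Sequence[float],
    ns_s_a: tuple[int, int],
    ns_s_b: tuple[int, int],
) -> tuple[float, float]:
    """Compare a gene set against the background.

    Returns ``(frequency_p, proportion_p)``: a two-sided rank-sum test
    on the per-variant frequencies and a two-sided Fisher exact test on
    the 2x2 table of (NS, S) counts per group.
    """
    p_freq = maf_compare(freq_a, freq_b)
    table = np.array([list(ns_s_a), list(ns_s_b)], dtype=int)
    if (table < 0).any():
        raise ValueError("NS/S counts must be non-negative")
    _, p_prop = fisher_exact(table, alternative="two-sided")
    return p_freq, float(p_prop)
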