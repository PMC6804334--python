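"""Substitution and heteroplasmy calling from strand-resolved counts.

A *substitution* is called at a site when the forward- and reverse-strand
major alleles agree, differ from the reference allele, and each strand's
major count exceeds ``min_strand_reads``.

A *heteroplasmy* is called when

1. the major and minor alleles agree between strands,
2. each of the four (allele x strand) counts exceeds ``min_strand_reads``,
3. a one-sided exact binomial test rejects H0: minor fraction equals the
   noise floor (default 1%) in favour of a larger fraction at ``alpha``,
4. the position is outside the low-complexity mask.

The two call types are independent: a site whose non-reference major
allele also carries a significant minor allele yields both calls.  Ties
for major/minor are broken alphabetically (A < C < G < T).  Sites whose
reference allele is ``N`` are never called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binom

from .pileup import BASES, BASE_INDEX, CountTable, SiteCounts
from .reference import MitoReference, RegionMask

__all__ = [
    "CallerConfig",
    "SubstitutionCall",
    "HeteroplasmyCall",
    "call_site",
    "call_sample",
    "write_heteroplasmy_tsv",
    "write_vcf",
]


@dataclass(frozen=True)
class CallerConfig:
    """Tunable calling thresholds.

    ``min_strand_reads`` is a strict lower bound: an allele needs
    *more than* this many reads on each strand (default 3, i.e. >= 4).
    ``binomial_denominator`` selects the trial count of the noise-floor
    test: total site depth ("total", default) or major+minor only
    ("major_minor").  ``maf_denominator`` selects the minor-allele
    fraction denominator the same way.
    """

    min_strand_reads: int = 3
    noise_floor: float = 0.01
    alpha: float = 0.05
    mask: RegionMask = field(default_factory=RegionMask.default)
    maf_denominator: str = "total"
    binomial_denominator: str = "total"

    def __post_init__(self) -> None:
        if not 0 < self.noise_floor < 0.5:
            raise ValueError("noise_floor must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_strand_reads < 0:
            raise ValueError("min_strand_reads must be >= 0")
        for name in (self.maf_denominator, self.binomial_denominator):
            if name not in ("total", "major_minor"):
                raise ValueError(f"unknown denominator choice {name!r}")


@dataclass(frozen=True)
class SubstitutionCall:
    position: int
    ref_allele: str
    alt_allele: str
    fwd_support: int
    rev_support: int


@dataclass(frozen=True)
class HeteroplasmyCall:
    position: int
    major_allele: str
    minor_allele: str
    maf: float
    major_fwd: int
    major_rev: int
    minor_fwd: int
    minor_rev: int
    p_value: float

    @property
    def minor_total(self) -> int:
        return self.minor_fwd + self.minor_rev


def _major_minor(counts: np.ndarray) -> tuple[int, int]:
    """Indices of the top two alleles; ties broken alphabetically."""
    major = int(np.argmax(counts))
    rest = counts.copy()
    rest[major] = -1
    minor = int(np.argmax(rest))
    return major, minor


def call_site(
    site: SiteCounts,
    ref_allele: str,
    cfg: Optional[CallerConfig] = None,
) -> tuple[Optional[SubstitutionCall], Optional[HeteroplasmyCall]]:
    """Apply both call types to a single site.

    Returns ``(substitution_or_None, heteroplasmy_or_None)``.  An
    uncallable site (reference ``N``, empty counts, failed criteria)
    yields ``None`` in the corresponding slot; no exception is raised.
    """
    cfg = cfg or CallerConfig()
    ref_allele = ref_allele.upper()
    if ref_allele not in BASE_INDEX:
        return None, None
    fwd, rev = site.fwd, site.rev
    if fwd.sum() + rev.sum() == 0:
        return None, None
    t = cfg.min_strand_reads

    maj_f, min_f = _major_minor(fwd)
    maj_r, min_r = _major_minor(rev)

    sub: Optional[SubstitutionCall] = None
    if (
        maj_f == maj_r
        and BASES[maj_f] != ref_allele
        and fwd[maj_f] > t
        and rev[maj_r] > t
    ):
        sub = SubstitutionCall(
            position=site.position,
            ref_allele=ref_allele,
            alt_allele=BASES[maj_f],
            fwd_support=int(fwd[maj_f]),
            rev_support=int(rev[maj_r]),
        )

    het: Optional[HeteroplasmyCall] = None
    if (
        maj_f == maj_r
        and min_f == min_r
        and min_f != maj_f
        and fwd[maj_f] > t
        and rev[maj_f] > t
        and fwd[min_f] > t
        and rev[min_f] > t
        and site.position not in cfg.mask
    ):
        minor_count = int(fwd[min_f] + rev[min_f])
        major_count = int(fwd[maj_f] + rev[maj_f])
        total = int(fwd.sum() + rev.sum())
        n_trials = total if cfg.binomial_denominator == "total" else minor_count + major_count
        denom = total if cfg.maf_denominator == "total" else minor_count + major_count
        # one-sided exact binomial upper tail: P(X >= minor | n, noise floor)
        p_value = float(binom.sf(minor_count - 1, n_trials, cfg.noise_floor))
        if p_value < cfg.alpha:
            het = HeteroplasmyCall(
                position=site.position,
                major_allele=BASES[maj_f],
                minor_allele=BASES[min_f],
                maf=minor_count / denom,
                major_fwd=int(fwd[maj_f]),
                major_rev=int(rev[maj_f]),
                minor_fwd=int(fwd[min_f]),
                minor_rev=int(rev[min_f]),
                p_value=p_value,
            )
    return sub, het


def call_sample(
    sites: Union[CountTable, Sequence[SiteCounts]],
    ref: Optional[MitoReference] = None,
    cfg: Optional[CallerConfig] = None,
) -> tuple[list[SubstitutionCall], list[HeteroplasmyCall]]:
    """Sweep all sites of one sample, vectorized.

    The reference allele is taken from ``ref`` when given, otherwise from
    the count table's own ``ref`` column.  Calls are returned sorted by
    position.  Duplicate positions raise a ``ValueError``.
    """
    cfg = cfg or CallerConfig()
    table = CountTable.coerce(sites)  # validates duplicates / sorts
    n = len(table)
    if n == 0:
        return [], []
    if ref is not None:
        if table.positions.max() > len(ref):
            raise IndexError("site position exceeds reference length")
        seq = np.frombuffer(ref.sequence.encode(), dtype="S1").astype("U1")
        ref_alleles = seq[table.positions - 1]
    else:
        ref_alleles = table.ref

    fwd = table.counts[:, 0, :]
    rev = table.counts[:, 1, :]
    t = cfg.min_strand_reads

    maj_f = np.argmax(fwd, axis=1)
    maj_r = np.argmax(rev, axis=1)
    rest_f = fwd.copy()
    rest_f[np.arange(n), maj_f] = -1
    min_f = np.argmax(rest_f, axis=1)
    rest_r = rev.copy()
    rest_r[np.arange(n), maj_r] = -1
    min_r = np.argmax(rest_r, axis=1)

    ref_idx = np.array([BASE_INDEX.get(b, -1) for b in ref_alleles])
    callable_ = (ref_idx >= 0) & (table.depth() > 0)

    ar = np.arange(n)
    sub_ok = (
        callable_
        & (maj_f == maj_r)
        & (maj_f != ref_idx)
        & (fwd[ar, maj_f] > t)
        & (rev[ar, maj_r] > t)
    )

    masked = np.array([p in cfg.mask for p in table.positions])
    het_pre = (
        callable_
        & ~masked
        & (maj_f == maj_r)
        & (min_f == min_r)
        & (min_f != maj_f)
        & (fwd[ar, maj_f] > t)
        & (rev[ar, maj_f] > t)
        & (fwd[ar, min_f] > t)
        & (rev[ar, min_f] > t)
    )
    minor_count = fwd[ar, min_f] + rev[ar, min_f]
    major_count = fwd[ar, maj_f] + rev[ar, maj_f]
    total = table.depth()
    n_trials = total if cfg.binomial_denominator == "total" else minor_count + major_count
    denom = total if cfg.maf_denominator == "total" else minor_count + major_count
    p_values = np.ones(n)
    idx = np.flatnonzero(het_pre)
    if idx.size:
        p_values[idx] = binom.sf(
            minor_count[idx] - 1, n_trials[idx], cfg.noise_floor
        )
    het_ok = het_pre & (p_values < cfg.alpha)

    subs = [
        SubstitutionCall(
            position=int(table.positions[i]),
            ref_allele=str(ref_alleles[i]),
            alt_allele=BASES[maj_f[i]],
            fwd_support=int(fwd[i, maj_f[i]]),
            rev_support=int(rev[i, maj_r[i]]),
        )
        for i in np.flatnonzero(sub_ok)
    ]
    hets = [
        HeteroplasmyCall(
            position=int(table.positions[i]),
            major_allele=BASES[maj_f[i]],
            minor_allele=BASES[min_f[i]],
            maf=float(minor_count[i] / denom[i]),
            major_fwd=int(fwd[i, maj_f[i]]),
            major_rev=int(rev[i, maj_f[i]]),
            minor_fwd=int(fwd[i, min_f[i]]),
            minor_rev=int(rev[i, min_f[i]]),
            p_value=float(p_values[i]),
        )
        for i in np.flatnonzero(het_ok)
    ]
    return subs, hets


def write_heteroplasmy_tsv(
    calls: Sequence[HeteroplasmyCall], path: Union[str, Path]
) -> None:
    """Flat table mirroring the "major/minor: maf" reporting convention."""
    df = pd.DataFrame(
        {
            "position": [c.position for c in calls],
            "major": [c.major_allele for c in calls],
            "minor": [c.minor_allele for c in calls],
            "maf": [round(c.maf, 4) for c in calls],
            "major_fwd": [c.major_fwd for c in calls],
            "major_rev": [c.major_rev for c in calls],
            "minor_fwd": [c.minor_fwd for c in calls],
            "minor_rev": [c.minor_rev for c in calls],
            "p_value": [c.p_value for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_vcf(
    substitutions: Sequence[SubstitutionCall],
    heteroplasmies: Sequence[HeteroplasmyCall],
    ref: MitoReference,
    path: Union[str, Path],
) -> None:
    """Minimal VCF with AF and strand-support INFO fields."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.name},length={len(ref)}>",
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="SUB or HET">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele fraction">',
        '##INFO=<ID=SF,Number=2,Type=Integer,Description="Alt support fwd,rev">',
        '##INFO=<ID=PV,Number=1,Type=Float,Description="Noise-floor test p-value">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    rows = []
    for c in substitutions:
        rows.append(
            (
                c.position,
                f"{ref.name}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}"
                f"\t.\tPASS\tTYPE=SUB;SF={c.fwd_support},{c.rev_support}",
            )
        )
    for c in heteroplasmies:
        ref_allele = ref.base(c.position)
        alt = c.minor_allele if c.minor_allele != ref_allele else c.major_allele
        rows.append(
            (
                c.position,
                f"{ref.name}\t{c.position}\t.\t{ref_allele}\t{alt}\t.\tPASS\t"
                f"TYPE=HET;AF={c.maf:.6f};SF={c.minor_fwd},{c.minor_rev};"
                f"PV={c.p_value:.3e}",
            )
        )
    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\n".join(lines + [r[1] for r in rows]) + "\n")
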