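"""Simulation-based evaluation of the heteroplasmy caller.

Reads of fixed length are placed uniformly on the circular genome, each
read is assigned a strand with probability 1/2, every read covering a
planted heteroplasmic site carries the alternate allele with probability
equal to the site's target minor-allele fraction, and every emitted base
is independently miscalled to one of the three other bases with the
per-base error rate (default 3e-3, i.e. 3 per mille).

Because the caller consumes per-site counts only, the simulator
aggregates these per-read Bernoulli draws exactly into binomial and
multinomial draws per covered position and emits a
:class:`~mitovar.pileup.CountTable` directly — no FASTQ or alignment
step, so the evaluation isolates the calling criteria themselves.

The default grid mirrors the evaluation protocol: minor fractions
1.5% to 10.5% in 1% steps plus 20.5%, read counts 100k to 1M (about
500x to 5,000x on a 16,569 bp genome), 100 replicates per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .caller import CallerConfig, HeteroplasmyCall, call_sample
from .pileup import BASE_INDEX, BASES, CountTable
from .reference import MitoReference, RegionMask

__all__ = [
    "PAPER_MAF_GRID",
    "PAPER_READ_GRID",
    "SimConfig",
    "PlantedVariant",
    "SimTruth",
    "EvalResult",
    "make_truth",
    "simulate_counts",
    "evaluate_calls",
    "run_cell",
    "run_grid",
    "depth_label",
]

PAPER_MAF_GRID: tuple[float, ...] = (
    0.015, 0.025, 0.035, 0.045, 0.055, 0.065, 0.075, 0.085, 0.095, 0.105, 0.205,
)
PAPER_READ_GRID: tuple[int, ...] = (
    100_000, 200_000, 400_000, 600_000, 800_000, 1_000_000,
)


def depth_label(n_reads: int) -> str:
    """Nominal depth label for a read count (100k reads of 100 bp ~ '500x')."""
    return f"{n_reads // 200}x"


@dataclass(frozen=True)
class SimConfig:
    """Simulation study settings."""

    error_rate: float = 0.003
    read_length: int = 100
    n_heteroplasmies: int = 50
    replicates: int = 100
    maf_grid: tuple[float, ...] = PAPER_MAF_GRID
    n_reads_grid: tuple[int, ...] = PAPER_READ_GRID
    caller: CallerConfig = field(default_factory=CallerConfig)
    allele_aware: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if any(not 0 < m <= 0.5 for m in self.maf_grid):
            raise ValueError("maf values must be in (0, 0.5]")
        if self.read_length <= 0 or self.n_heteroplasmies < 0:
            raise ValueError("read_length must be > 0, n_heteroplasmies >= 0")


@dataclass(frozen=True)
class PlantedVariant:
    position: int
    ref: str
    alt: str
    target_maf: float


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of planted heteroplasmies for one replicate."""

    variants: tuple[PlantedVariant, ...]

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError("planted positions must be distinct")

    def __len__(self) -> int:
        return len(self.variants)

    def by_position(self) -> dict[int, PlantedVariant]:
        return {v.position: v for v in self.variants}


@dataclass(frozen=True)
class EvalResult:
    """Per-replicate confusion counts; undefined rates are None, never 0."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None


def make_truth(
    ref: MitoReference,
    n_heteroplasmies: int,
    maf: float,
    rng: np.random.Generator,
    mask: Optional[RegionMask] = None,
) -> SimTruth:
    """Plant variants uniformly on unmasked, non-N positions.

    Alternate alleles are drawn uniformly from the three non-reference
    bases; all planted sites share the target minor fraction ``maf``.
    """
    mask = mask if mask is not None else RegionMask.default()
    seq = np.frombuffer(ref.sequence.encode(), dtype="S1").astype("U1")
    eligible = np.array(
        [
            p
            for p in range(1, len(ref) + 1)
            if seq[p - 1] != "N" and p not in mask
        ]
    )
    if n_heteroplasmies > eligible.size:
        raise ValueError("more heteroplasmies requested than eligible positions")
    positions = np.sort(rng.choice(eligible, size=n_heteroplasmies, replace=False))
    variants = []
    for p in positions:
        r = seq[p - 1]
        alts = [b for b in BASES if b != r]
        a = alts[rng.integers(0, 3)]
        variants.append(PlantedVariant(int(p), str(r), a, maf))
    return SimTruth(tuple(variants))


def _error_kernel(base_idx: int, error_rate: float) -> np.ndarray:
    pv = np.full(4, error_rate / 3.0)
    pv[base_idx] = 1.0 - error_rate
    return pv


def simulate_counts(
    ref: MitoReference,
    truth: SimTruth,
    n_reads: int,
    cfg: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> CountTable:
    """Simulate one replicate's strand-resolved count table."""
    cfg = cfg or SimConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(ref)
    rl = cfg.read_length
    if rl > L:
        raise ValueError("read length exceeds genome length")
    for v in truth.variants:
        if not 1 <= v.position <= L:
            raise ValueError(f"planted position {v.position} outside 1..{L}")
        if ref.base(v.position) != v.ref:
            raise ValueError(f"truth ref mismatch at {v.position}")

    seq = np.frombuffer(ref.sequence.encode(), dtype="S1").astype("U1")
    ref_idx = np.array([BASE_INDEX.get(b, -1) for b in seq])

    # circular coverage per strand from uniform read starts (0-based)
    starts = rng.integers(0, L, size=n_reads)
    is_fwd = rng.random(n_reads) < 0.5
    cov = np.zeros((2, L), dtype=np.int64)
    for s_idx, sel in enumerate((is_fwd, ~is_fwd)):
        d = np.zeros(2 * L + 1, dtype=np.int64)
        np.add.at(d, starts[sel], 1)
        np.add.at(d, starts[sel] + rl, -1)
        lin = np.cumsum(d[:-1])
        cov[s_idx] = lin[:L] + lin[L:]

    counts = np.zeros((L, 2, 4), dtype=np.int64)
    e = cfg.error_rate
    planted = truth.by_position()
    planted_rows = np.array([p - 1 for p in planted], dtype=np.int64)

    for s in (0, 1):
        for b in range(4):
            rows = np.flatnonzero(ref_idx == b)
            if planted_rows.size:
                rows = rows[~np.isin(rows, planted_rows)]
            if rows.size == 0:
                continue
            counts[rows, s, :] = rng.multinomial(cov[s, rows], _error_kernel(b, e))
        for p, v in planted.items():
            row = p - 1
            n = int(cov[s, row])
            n_alt = int(rng.binomial(n, v.target_maf))
            obs = rng.multinomial(n - n_alt, _error_kernel(BASE_INDEX[v.ref], e))
            obs = obs + rng.multinomial(n_alt, _error_kernel(BASE_INDEX[v.alt], e))
            counts[row, s, :] = obs

    # reference-N positions are never called; leave their counts empty
    counts[ref_idx < 0] = 0
    return CountTable(np.arange(1, L + 1), seq, counts)


def evaluate_calls(
    calls: Sequence[HeteroplasmyCall],
    truth: SimTruth,
    allele_aware: bool = True,
) -> EvalResult:
    """Confusion counts of called heteroplasmies against planted truth.

    With ``allele_aware`` (default) a true positive must match both the
    position and the planted alternate allele as its minor allele;
    otherwise position alone suffices.
    """
    by_pos = truth.by_position()
    tp = fp = 0
    hit: set[int] = set()
    for c in calls:
        v = by_pos.get(c.position)
        if v is not None and (not allele_aware or c.minor_allele == v.alt):
            tp += 1
            hit.add(c.position)
        else:
            fp += 1
    fn = len(truth) - len(hit)
    return EvalResult(tp=tp, fp=fp, fn=fn)


def replicate_rng(seed: int, maf: float, n_reads: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator; grid and single runs agree."""
    return np.random.default_rng(
        [seed, n_reads, int(round(maf * 10_000)), replicate]
    )


def run_cell(
    ref: MitoReference,
    maf: float,
    n_reads: int,
    cfg: Optional[SimConfig] = None,
    seed: int = 0,
    replicates: Optional[int] = None,
) -> list[EvalResult]:
    """Simulate + call + evaluate one (maf, depth) grid cell."""
    cfg = cfg or SimConfig()
    reps = cfg.replicates if replicates is None else replicates
    results = []
    for rep in range(reps):
        rng = replicate_rng(seed, maf, n_reads, rep)
        truth = make_truth(ref, cfg.n_heteroplasmies, maf, rng, cfg.caller.mask)
        table = simulate_counts(ref, truth, n_reads, cfg, rng=rng)
        _, hets = call_sample(table, ref, cfg.caller)
        results.append(evaluate_calls(hets, truth, cfg.allele_aware))
    return results


def run_grid(
    ref: MitoReference,
    cfg: Optional[SimConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format precision/recall table over the full (maf, depth) grid."""
    cfg = cfg or SimConfig()
    rows = []
    for maf in cfg.maf_grid:
        for n_reads in cfg.n_reads_grid:
            for rep, res in enumerate(run_cell(ref, maf, n_reads, cfg, seed)):
                rows.append(
                    {
                        "maf": maf,
                        "n_reads": n_reads,
                        "depth_label": depth_label(n_reads),
                        "replicate": rep,
                        "tp": res.tp,
                        "fp": res.fp,
                        "fn": res.fn,
                        "precision": res.precision,
                        "recall": res.recall,
                    }
                )
    return pd.DataFrame(rows)
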