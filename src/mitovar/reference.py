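"""Circular mitochondrial reference handling.

The human mitochondrial genome is circular, so reads spanning the
origin (the D-loop region in rCRS coordinates) map poorly to a linear
reference.  The standard workaround is a *pseudo-reference*: the first
``E`` bases of the circle are appended to its end, reads are aligned to
this ``L + E`` bp linear sequence, and per-site counts are afterwards
folded back onto the canonical ``L`` coordinates by summing each
extension position ``L + p`` into position ``p``.

All public interfaces use 1-based inclusive coordinates, matching the
conventions of mtDNA variant nomenclature (e.g. "T16117C").
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pileup import CountTable, SiteCounts

__all__ = [
    "MitoReference",
    "PseudoReference",
    "RegionMask",
    "DEFAULT_MASK_INTERVALS",
    "DEFAULT_EXTENSION",
    "build_pseudo_reference",
    "fold_counts",
    "in_mask",
]

_ALPHABET = set("ACGTN")

#: Low-complexity / ambiguous rCRS regions excluded from heteroplasmy
#: calling (1-based inclusive).
DEFAULT_MASK_INTERVALS: tuple[tuple[int, int], ...] = (
    (302, 316),
    (513, 526),
    (566, 573),
    (3106, 3107),
    (16181, 16194),
)

#: Default number of bases copied from the head of the circle to its tail.
DEFAULT_EXTENSION = 500


@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial reference sequence.

    Parameters
    ----------
    sequence:
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    name:
        Sequence identifier (FASTA header).
    """

    sequence: str
    name: str = "chrM"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError("reference sequence must be non-empty")
        extra = set(seq) - _ALPHABET
        if extra:
            raise ValueError(f"invalid characters in reference: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.sequence[position - 1]

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "MitoReference":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single FASTA record, found {len(records)}")
        rec = records[0]
        return cls(sequence=str(rec.seq).upper(), name=rec.id)

    def to_fasta(self, path: Union[str, Path]) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([rec], str(path), "fasta")


@dataclass(frozen=True)
class PseudoReference:
    """A linearized circular reference with its head copied to its tail."""

    base: MitoReference
    extension_length: int
    pseudo_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        L = len(self.base)
        E = self.extension_length
        if not 0 <= E <= L:
            raise ValueError(
                f"extension_length must be in [0, {L}], got {E}"
            )
        seq = self.base.sequence + self.base.sequence[:E]
        object.__setattr__(self, "pseudo_sequence", seq)

    def __len__(self) -> int:
        return len(self.pseudo_sequence)

    def to_fasta(self, path: Union[str, Path]) -> None:
        name = f"{self.base.name}_pseudo{self.extension_length}"
        rec = SeqRecord(Seq(self.pseudo_sequence), id=name, description="")
        SeqIO.write([rec], str(path), "fasta")


def build_pseudo_reference(
    ref: MitoReference, extension_length: int = DEFAULT_EXTENSION
) -> PseudoReference:
    """Append the first ``extension_length`` bases of ``ref`` to its end."""
    return PseudoReference(base=ref, extension_length=extension_length)


@dataclass(frozen=True)
class RegionMask:
    """Sorted, non-overlapping set of 1-based inclusive intervals."""

    intervals: tuple[tuple[int, int], ...] = DEFAULT_MASK_INTERVALS

    def __post_init__(self) -> None:
        merged: list[tuple[int, int]] = []
        for start, end in sorted(self.intervals):
            if start > end or start < 1:
                raise ValueError(f"invalid interval ({start}, {end})")
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        object.__setattr__(self, "intervals", tuple(merged))

    def __contains__(self, position: int) -> bool:
        starts = [iv[0] for iv in self.intervals]
        idx = np.searchsorted(starts, position, side="right") - 1
        if idx < 0:
            return False
        start, end = self.intervals[idx]
        return start <= position <= end

    def positions(self) -> set[int]:
        """All masked positions (for small masks)."""
        out: set[int] = set()
        for start, end in self.intervals:
            out.update(range(start, end + 1))
        return out

    @classmethod
    def from_bed(cls, path: Union[str, Path]) -> "RegionMask":
        """Read a BED-like TSV (0-based half-open) into 1-based intervals."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed BED line: {line!r}")
                ivs.append((int(parts[1]) + 1, int(parts[2])))
        return cls(intervals=tuple(ivs))

    @classmethod
    def default(cls) -> "RegionMask":
        return cls(intervals=DEFAULT_MASK_INTERVALS)


def in_mask(position: int, mask: RegionMask) -> bool:
    """True iff ``position`` (1-based) falls inside any mask interval."""
    return position in mask


def default_mask_path() -> Path:
    """Path of the packaged default mask table (BED-like TSV)."""
    return Path(str(importlib.resources.files("mitovar") / "data" / "default_mask.tsv"))


def fold_counts(
    pseudo_counts: Union[CountTable, Sequence[SiteCounts]],
    L: int,
    E: int,
) -> CountTable:
    """Fold counts on pseudo coordinates ``1..L+E`` back to ``1..L``.

    Positions ``p <= E`` receive the element-wise sum of pseudo positions
    ``p`` and ``L + p``; positions ``E < p <= L`` pass through.  Total
    base counts are conserved exactly.
    """
    table = CountTable.coerce(pseudo_counts)
    if not 0 <= E <= L:
        raise ValueError(f"extension {E} must be in [0, {L}]")
    if table.positions.size and (
        table.positions.min() < 1 or table.positions.max() > L + E
    ):
        raise IndexError(
            f"pseudo positions outside 1..{L + E}: "
            f"range {table.positions.min()}..{table.positions.max()}"
        )
    counts = np.zeros((L, 2, 4), dtype=np.int64)
    ref = np.full(L, "N", dtype="U1")
    pos = table.positions
    folded = np.where(pos > L, pos - L, pos)
    np.add.at(counts, folded - 1, table.counts)
    # reference alleles: canonical coordinates win; extension rows only
    # fill positions not already described
    for p, r in zip(pos, table.ref):
        idx = (p - L if p > L else p) - 1
        if p <= L or ref[idx] == "N":
            ref[idx] = r
    keep = counts.sum(axis=(1, 2)) > 0
    keep |= np.isin(np.arange(1, L + 1), folded)
    positions = np.arange(1, L + 1)[keep]
    return CountTable(positions=positions, ref=ref[keep], counts=counts[keep])
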