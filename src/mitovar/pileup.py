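"""Strand-resolved per-site base counts and the samtools-mpileup parser.

The calling criteria operate on eight integers per site: counts of
A/C/G/T on the forward and reverse strands, after a base-quality floor.
``SiteCounts`` is the per-site record; ``CountTable`` is the vectorized
column store the caller and simulator use internally.  The two are
interconvertible and a TSV serialization round-trips bit-exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "BASE_INDEX",
    "SiteCounts",
    "CountTable",
    "PileupParseError",
    "parse_pileup",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TSV_COLUMNS = ["position", "ref", "A+", "C+", "G+", "T+", "A-", "C-", "G-", "T-"]


class PileupParseError(ValueError):
    """Raised on a malformed mpileup line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class SiteCounts:
    """Base counts at one reference position, split by strand.

    ``fwd`` and ``rev`` are length-4 integer arrays in A, C, G, T order.
    """

    position: int
    ref: str
    fwd: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    rev: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=np.int64)
        self.rev = np.asarray(self.rev, dtype=np.int64)
        if self.fwd.shape != (4,) or self.rev.shape != (4,):
            raise ValueError("fwd/rev must be length-4 count vectors")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("counts must be non-negative")
        self.ref = self.ref.upper()

    def depth(self) -> int:
        return int(self.fwd.sum() + self.rev.sum())

    def count(self, base: str, strand: str = "+") -> int:
        arr = self.fwd if strand == "+" else self.rev
        return int(arr[BASE_INDEX[base.upper()]])

    def __eq__(self, other: object) -> bool:  # array fields need explicit eq
        if not isinstance(other, SiteCounts):
            return NotImplemented
        return (
            self.position == other.position
            and self.ref == other.ref
            and bool((self.fwd == other.fwd).all())
            and bool((self.rev == other.rev).all())
        )


class CountTable:
    """Column-oriented collection of :class:`SiteCounts`.

    Attributes
    ----------
    positions : (N,) int array, 1-based, strictly increasing
    ref : (N,) unicode array of reference alleles
    counts : (N, 2, 4) int array; axis 1 is strand (0=forward, 1=reverse),
        axis 2 is base in A, C, G, T order
    """

    def __init__(self, positions: np.ndarray, ref: np.ndarray, counts: np.ndarray):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref = np.asarray(ref, dtype="U1")
        self.counts = np.asarray(counts, dtype=np.int64)
        n = self.positions.size
        if self.ref.shape != (n,) or self.counts.shape != (n, 2, 4):
            raise ValueError("inconsistent CountTable shapes")
        if n and (np.diff(self.positions) <= 0).any():
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.ref = self.ref[order]
            self.counts = self.counts[order]
            if (np.diff(self.positions) == 0).any():
                dup = self.positions[:-1][np.diff(self.positions) == 0]
                raise ValueError(f"duplicate positions: {dup[:5].tolist()}")

    def __len__(self) -> int:
        return self.positions.size

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def coerce(
        cls, sites: Union["CountTable", Sequence[SiteCounts]]
    ) -> "CountTable":
        if isinstance(sites, CountTable):
            return sites
        return cls.from_sites(sites)

    @classmethod
    def from_sites(cls, sites: Iterable[SiteCounts]) -> "CountTable":
        sites = list(sites)
        positions = np.array([s.position for s in sites], dtype=np.int64)
        ref = np.array([s.ref for s in sites], dtype="U1")
        counts = np.zeros((len(sites), 2, 4), dtype=np.int64)
        for i, s in enumerate(sites):
            counts[i, 0] = s.fwd
            counts[i, 1] = s.rev
        return cls(positions, ref, counts)

    def to_sites(self) -> list[SiteCounts]:
        return [
            SiteCounts(
                position=int(p), ref=str(r), fwd=c[0].copy(), rev=c[1].copy()
            )
            for p, r, c in zip(self.positions, self.ref, self.counts)
        ]

    def to_frame(self) -> pd.DataFrame:
        flat = self.counts.reshape(len(self), 8)
        df = pd.DataFrame(flat, columns=_TSV_COLUMNS[2:])
        df.insert(0, "ref", self.ref)
        df.insert(0, "position", self.positions)
        return df

    def write_tsv(self, path: Union[str, Path, io.TextIOBase]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: Union[str, Path, io.TextIOBase]) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"ref": str})
        missing = set(_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        counts = df[_TSV_COLUMNS[2:]].to_numpy(dtype=np.int64).reshape(-1, 2, 4)
        return cls(df["position"].to_numpy(), df["ref"].to_numpy(dtype="U1"), counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            (self.positions == other.positions).all()
            and (self.ref == other.ref).all()
            and (self.counts == other.counts).all()
        )


def _decode_base_column(
    bases: str, quals: str, ref: str, min_base_quality: int, line_number: int
) -> tuple[np.ndarray, np.ndarray]:
    """Decode one mpileup base string into forward/reverse A,C,G,T counts."""
    fwd = np.zeros(4, dtype=np.int64)
    rev = np.zeros(4, dtype=np.int64)
    ref = ref.upper()
    i = 0  # index into bases
    q = 0  # index into quals (advances once per read base)
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret + mapping-quality char; no read base consumed
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"indel marker without length at offset {i}", line_number
                )
            indel_len = int(bases[i + 1 : j])
            i = j + indel_len  # skip inserted/deleted sequence
            continue
        # a read base: consumes one quality character
        if q >= len(quals):
            raise PileupParseError(
                "more read bases than quality characters", line_number
            )
        qual = ord(quals[q]) - 33
        q += 1
        i += 1
        if qual < min_base_quality:
            continue
        if ch == ".":
            if ref in BASE_INDEX:
                fwd[BASE_INDEX[ref]] += 1
        elif ch == ",":
            if ref in BASE_INDEX:
                rev[BASE_INDEX[ref]] += 1
        elif ch in "ACGT":
            fwd[BASE_INDEX[ch]] += 1
        elif ch in "acgt":
            rev[BASE_INDEX[ch.upper()]] += 1
        # 'N', 'n', '*', '<', '>' are ignored: not one of the four bases
    if q != len(quals):
        raise PileupParseError(
            f"consumed {q} quality characters, expected {len(quals)}", line_number
        )
    return fwd, rev


def parse_pileup(
    stream: Union[str, io.TextIOBase, Iterable[str]],
    min_base_quality: int = 30,
) -> list[SiteCounts]:
    """Parse single-sample samtools-mpileup text into per-site counts.

    Uppercase bases and ``.`` count toward the forward strand, lowercase
    and ``,`` toward the reverse.  Indel blocks, read-start (``^`` plus
    mapping quality) and read-end (``$``) markers are skipped.  Bases
    whose Phred+33 quality is below ``min_base_quality`` are excluded.
    Deletions (``*``) and ``N`` never count toward the four base tallies.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[SiteCounts] = []
    for ln, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # tolerate space-separated toy input
            parts = line.split()
        if len(parts) < 6:
            if len(parts) >= 4 and parts[3] == "0":
                parts = parts[:4] + ["", ""]
            else:
                raise PileupParseError(
                    f"expected 6 columns, found {len(parts)}", ln
                )
        _chrom, pos_s, ref, _depth, bases, quals = parts[:6]
        try:
            pos = int(pos_s)
        except ValueError:
            raise PileupParseError(f"non-integer position {pos_s!r}", ln) from None
        fwd, rev = _decode_base_column(bases, quals, ref, min_base_quality, ln)
        out.append(SiteCounts(position=pos, ref=ref.upper(), fwd=fwd, rev=rev))
    return out
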