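"""Relative mtDNA copy number from depth ratios.

The relative mitochondrial copy number of a tumor sample is estimated
as ``mtCN = (mt_depth / CDS_depth) * R_tumor`` where ``R_tumor`` is the
effective nuclear ploidy of the sequenced cell mixture: a fraction
``purity`` of tumor cells at ``ploidy`` copies plus ``1 - purity``
normal cells at 2 copies, i.e. ``R_tumor = purity*ploidy +
(1-purity)*2``.  An alternate convention divides ``R_tumor`` by 2
(expressing copy number per *haploid-pair equivalent*); both are
supported and the chosen convention is recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import pandas as pd

__all__ = ["SamplePloidyRecord", "MtCNResult", "compute_mtcn", "compute_mtcn_table"]

CONVENTIONS = ("ploidy", "half")


@dataclass(frozen=True)
class SamplePloidyRecord:
    sample_id: str
    mt_depth: float
    cds_depth: float
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if self.mt_depth <= 0:
            raise ValueError("mt_depth must be > 0")
        if self.cds_depth == 0:
            raise ZeroDivisionError("cds_depth must be non-zero")
        if self.cds_depth < 0:
            raise ValueError("cds_depth must be > 0")
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must be in [0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be > 0")


@dataclass(frozen=True)
class MtCNResult:
    sample_id: str
    r_tumor: float
    mtcn: float
    convention: str


def compute_mtcn(
    rec: SamplePloidyRecord, convention: str = "ploidy"
) -> MtCNResult:
    """Purity/ploidy-corrected relative mtDNA copy number.

    ``convention="ploidy"`` (default): mtCN = depth ratio x R_tumor.
    ``convention="half"``: mtCN = depth ratio x R_tumor / 2.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    r_tumor = rec.purity * rec.ploidy + (1.0 - rec.purity) * 2.0
    ratio = rec.mt_depth / rec.cds_depth
    scale = r_tumor if convention == "ploidy" else r_tumor / 2.0
    return MtCNResult(
        sample_id=rec.sample_id,
        r_tumor=r_tumor,
        mtcn=ratio * scale,
        convention=convention,
    )


def compute_mtcn_table(
    df: pd.DataFrame, convention: str = "ploidy"
) -> pd.DataFrame:
    """Vectorized :func:`compute_mtcn` over a table with columns
    sample_id, mt_depth, cds_depth, purity, ploidy."""
    results = [
        compute_mtcn(
            SamplePloidyRecord(
                sample_id=str(row.sample_id),
                mt_depth=float(row.mt_depth),
                cds_depth=float(row.cds_depth),
                purity=float(row.purity),
                ploidy=float(row.ploidy),
            ),
            convention,
        )
        for row in df.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "r_tumor": [r.r_tumor for r in results],
            "mtcn": [r.mtcn for r in results],
            "convention": [r.convention for r in results],
        }
    )
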