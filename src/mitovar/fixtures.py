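"""Packaged data tables and synthetic input generators.

Two kinds of fixtures back the test surface:

* the published summary table of the three heteroplasmic sites shared
  across the 23 tumor microsections (positions 3424, 14804, 16117),
  transcribed verbatim to four decimal places; and
* seeded synthetic generators — a mitochondrial-genome-sized reference
  sequence and a spatial clonal tumor — providing inputs with the
  statistical structure the analysis assumes, without any download.

The synthetic tumor emulates microsections sampled from a ~35 mm
diameter tumor slice in which heteroplasmies arise in spatially
localized subclones: nearby samples share mutations with correlated
minor-allele fractions.  A "shuffled" mode permutes the sampling
coordinates after generating the MAF profiles, destroying the spatial
association while preserving both marginals — the null case for
calibrating the tree-comparison permutation test.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .reference import MitoReference

__all__ = [
    "load_table1",
    "table1_path",
    "synthetic_reference",
    "SyntheticTumorConfig",
    "SyntheticTumor",
    "generate_synthetic_tumor",
]

TABLE1_POSITIONS = (3424, 14804, 16117)


def table1_path() -> Path:
    return Path(
        str(
            importlib.resources.files("mitovar")
            / "data"
            / "table1_shared_heteroplasmies.tsv"
        )
    )


def load_table1() -> pd.DataFrame:
    """The shared-heteroplasmy summary of the 23 tumor microsections.

    Columns: sample, alleles_NNNN ("major/minor"), maf_NNNN for the
    three shared positions, and heteroplasmy_count (the sample's total
    number of heteroplasmies).  Samples lacking the 3424 heteroplasmy
    have missing values in the 3424 columns.
    """
    df = pd.read_csv(
        table1_path(),
        sep="\t",
        dtype={"sample": str},
    )
    return df


def synthetic_reference(
    length: int = 16_569,
    seed: int = 777,
    n_positions: tuple[int, ...] = (3107,),
    name: str = "chrM_synthetic",
) -> MitoReference:
    """A seeded random mitochondrial-genome-sized reference.

    Stands in for the 16,569 bp human reference where only length,
    circularity and the placeholder ``N`` (at rCRS position 3107 by
    default) matter; it is *not* the rCRS sequence.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    for p in n_positions:
        if 1 <= p <= length:
            seq[p - 1] = "N"
    return MitoReference(sequence="".join(seq), name=name)


@dataclass(frozen=True)
class SyntheticTumorConfig:
    """Spatial clonal model parameters.

    ``correlation_length_mm`` controls how fast a clone's MAF decays
    with distance from its center; 0 (or ``shuffled=True``) removes the
    spatial signal.  Defaults mirror the scale of the motivating study:
    23 microsections in a 35 mm disc carrying ~18 heteroplasmic sites,
    a few shared tumor-wide and the rest confined to local subclones.
    """

    n_samples: int = 23
    disc_diameter_mm: float = 35.0
    n_clones: int = 5
    sites_per_clone: int = 3
    n_shared_sites: int = 3
    clone_maf_range: tuple[float, float] = (0.05, 0.3)
    correlation_length_mm: float = 10.0
    maf_noise_sd: float = 0.005
    detection_floor: float = 0.01
    mtcn_log_sd: float = 0.4
    shuffled: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.disc_diameter_mm <= 0 or self.maf_noise_sd < 0:
            raise ValueError("invalid geometry/noise parameters")
        if self.correlation_length_mm <= 0:
            raise ValueError(
                "correlation_length_mm must be > 0; use shuffled=True for "
                "the spatially unstructured null"
            )
        lo, hi = self.clone_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("clone MAF range must lie in (0, 0.5]")


@dataclass(frozen=True)
class SyntheticTumor:
    coordinates: pd.DataFrame  # sample_id, x, y (mm)
    maf: pd.DataFrame  # samples x sites, MAF in [0, 0.5], 0 = absent
    mtcn: pd.Series  # per-sample relative copy number
    config: SyntheticTumorConfig = field(default_factory=SyntheticTumorConfig)


def _points_in_disc(
    n: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points in a disc centred at the origin."""
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_synthetic_tumor(
    config: Optional[SyntheticTumorConfig] = None,
    seed: int = 0,
) -> SyntheticTumor:
    """Generate coordinates, heteroplasmy MAF profiles and mtCN values.

    Each clone has a spatial center and private sites; a sample's
    expected MAF at a clone's sites decays exponentially with its
    distance to the clone center.  Shared sites are present in every
    sample.  Observed MAFs get Gaussian noise, are clipped to
    [0, 0.5], and values below the detection floor are zeroed
    (undetected).  Fully reproducible from ``seed``.
    """
    cfg = config or SyntheticTumorConfig()
    rng = np.random.default_rng(seed)
    radius = cfg.disc_diameter_mm / 2.0

    xy = _points_in_disc(cfg.n_samples, radius, rng)
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]

    centers = _points_in_disc(cfg.n_clones, radius, rng)
    lo, hi = cfg.clone_maf_range

    site_names: list[str] = []
    expected = []  # columns of samples x sites matrix

    for shared_i in range(cfg.n_shared_sites):
        base = rng.uniform(lo, hi)
        site_names.append(f"shared_{shared_i + 1}")
        expected.append(np.full(cfg.n_samples, base))

    for clone_i in range(cfg.n_clones):
        dist = np.linalg.norm(xy - centers[clone_i], axis=1)
        weight = np.exp(-dist / cfg.correlation_length_mm)
        for site_i in range(cfg.sites_per_clone):
            base = rng.uniform(lo, hi)
            site_names.append(f"clone{clone_i + 1}_{site_i + 1}")
            expected.append(base * weight)

    maf = np.column_stack(expected)
    maf = maf + rng.normal(0.0, cfg.maf_noise_sd, size=maf.shape)
    maf = np.clip(maf, 0.0, 0.5)
    maf[maf < cfg.detection_floor] = 0.0

    if cfg.shuffled:
        # break the spatial association, keep both marginals
        xy = xy[rng.permutation(cfg.n_samples)]

    coords = pd.DataFrame({"sample_id": sample_ids, "x": xy[:, 0], "y": xy[:, 1]})
    maf_df = pd.DataFrame(maf, index=sample_ids, columns=site_names)
    mtcn = pd.Series(
        np.exp(rng.normal(np.log(300.0), cfg.mtcn_log_sd, size=cfg.n_samples)),
        index=sample_ids,
        name="mtcn",
    )
    return SyntheticTumor(coordinates=coords, maf=maf_df, mtcn=mtcn, config=cfg)
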