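"""Recombination between block centers and Haldane map-distance conversion.

Crossovers in a meiosis occur only between blocks: each adjacent pair of
block centers carries a recombination fraction theta in [0, 0.5], with 0.5
forced at chromosome boundaries (independent assortment).  Map distances use
Haldane's mapping function, d_cM = -50 ln(1 - 2 theta), which assumes no
crossover interference; crossovers are sampled independently per interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecombinationMap",
    "fixed_map",
    "map_from_hotspots",
    "haldane_theta_to_cm",
    "haldane_cm_to_theta",
    "read_hotspot_table",
]


def haldane_theta_to_cm(theta: float) -> float:
    """Map distance in centimorgans for recombination fraction ``theta``.

    d = -50 ln(1 - 2 theta).  theta must lie in [0, 0.5); theta = 0.5
    corresponds to infinite distance and is rejected.
    """
    theta = float(theta)
    if theta < 0:
        raise ValueError(f"recombination fraction must be >= 0, got {theta}")
    if theta >= 0.5:
        raise ValueError(
            f"recombination fraction {theta} >= 0.5 has no finite map distance"
        )
    return -50.0 * np.log1p(-2.0 * theta)


def haldane_cm_to_theta(d_cm: float) -> float:
    """Recombination fraction for a map distance of ``d_cm`` centimorgans.

    theta = (1 - exp(-2 d / 100)) / 2; approaches 0.5 as d -> infinity.
    """
    d_cm = float(d_cm)
    if d_cm < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cm}")
    return -0.5 * np.expm1(-2.0 * d_cm / 100.0)


@dataclass
class RecombinationMap:
    """Per-interval recombination fractions between ordered block centers.

    ``interval_theta[i]`` applies between block centers i and i+1.
    ``chromosome_breaks`` lists interval indices forced to theta = 0.5
    because the flanking blocks lie on different chromosomes.
    """

    block_centers_bp: np.ndarray
    interval_theta: np.ndarray
    chromosome_breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.block_centers_bp = np.asarray(self.block_centers_bp, dtype=np.int64)
        self.interval_theta = np.asarray(self.interval_theta, dtype=float)
        if len(self.interval_theta) != max(len(self.block_centers_bp) - 1, 0):
            raise ValueError(
                "need exactly one recombination fraction per adjacent block pair"
            )
        if np.any(self.interval_theta < 0) or np.any(self.interval_theta > 0.5):
            bad = self.interval_theta[
                (self.interval_theta < 0) | (self.interval_theta > 0.5)
            ]
            raise ValueError(
                f"recombination fractions must lie in [0, 0.5], got {bad}; "
                "for unlinked blocks use 0.5"
            )
        for i in self.chromosome_breaks:
            if self.interval_theta[i] != 0.5:
                raise ValueError(f"chromosome break at interval {i} requires theta=0.5")

    @property
    def n_blocks(self) -> int:
        return len(self.block_centers_bp)

    def chromosome_index_of_block(self) -> np.ndarray:
        """0-based chromosome index per block, incremented at each break."""
        idx = np.zeros(self.n_blocks, dtype=np.int64)
        for i in sorted(self.chromosome_breaks):
            idx[i + 1:] += 1
        return idx

    def interval_cm(self) -> np.ndarray:
        """Haldane cM per interval; NaN at chromosome breaks (theta = 0.5)."""
        out = np.empty(len(self.interval_theta))
        breaks = set(self.chromosome_breaks)
        for i, th in enumerate(self.interval_theta):
            out[i] = np.nan if i in breaks or th >= 0.5 else haldane_theta_to_cm(th)
        return out


def fixed_map(
    theta: float, n_blocks: int, block_centers_bp=None
) -> RecombinationMap:
    """A map with the same recombination fraction between every adjacent pair
    of block centers (single chromosome)."""
    if not 0 <= theta <= 0.5:
        raise ValueError(
            f"recombination fraction must lie in [0, 0.5], got {theta}; "
            "for unlinked blocks use 0.5"
        )
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if block_centers_bp is None:
        span = 10_000
        block_centers_bp = span // 2 + span * np.arange(n_blocks)
    block_centers_bp = np.asarray(block_centers_bp, dtype=np.int64)
    if len(block_centers_bp) != n_blocks:
        raise ValueError("block_centers_bp length must equal n_blocks")
    return RecombinationMap(block_centers_bp, np.full(n_blocks - 1, float(theta)))


def read_hotspot_table(path) -> pd.DataFrame:
    """Read a hotspot TSV with header ``chrom start end rate_cM_Mb``
    (1-based inclusive coordinates, rate in cM/Mb)."""
    tab = pd.read_csv(path, sep=r"\s+")
    required = {"chrom", "start", "end", "rate_cM_Mb"}
    if not required.issubset(tab.columns):
        raise ValueError(f"hotspot table must have columns {sorted(required)}")
    return tab


def map_from_hotspots(
    hotspots: pd.DataFrame,
    block_centers_bp,
    block_chromosomes,
) -> RecombinationMap:
    """Build a recombination map from a hotspot table.

    Each hotspot contributes its own rate times its own width:
    d_cM = rate_cM_Mb * (end - start) / 1e6, which conserves the total map
    length of the table.  A hotspot is assigned to the interval between the
    two block centers that bracket its midpoint; hotspots not between any two
    centers (or spanning a chromosome boundary) are ignored.  Intervals whose
    flanking blocks sit on different chromosomes get theta = 0.5.
    """
    centers = np.asarray(block_centers_bp, dtype=np.int64)
    chroms = [str(c) for c in block_chromosomes]
    if len(chroms) != len(centers):
        raise ValueError("need one chromosome label per block center")
    for c in set(chroms):
        pos = centers[[i for i, x in enumerate(chroms) if x == c]]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"block centers not sorted within chromosome {c}")
    if (hotspots["rate_cM_Mb"] < 0).any():
        raise ValueError("hotspot rates must be >= 0")

    n = len(centers)
    theta = np.zeros(n - 1)
    breaks: list[int] = []
    for i in range(n - 1):
        if chroms[i] != chroms[i + 1]:
            theta[i] = 0.5
            breaks.append(i)
            continue
        lo, hi = centers[i], centers[i + 1]
        sub = hotspots[hotspots["chrom"].astype(str) == chroms[i]]
        mid = (sub["start"] + sub["end"]) / 2.0
        inside = sub[(mid > lo) & (mid <= hi)]
        d_cm = float(
            (inside["rate_cM_Mb"] * (inside["end"] - inside["start"]) / 1e6).sum()
        )
        theta[i] = haldane_cm_to_theta(d_cm)
    return RecombinationMap(centers, theta, breaks)
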