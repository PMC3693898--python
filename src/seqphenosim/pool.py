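"""Haplotype pools: the finite population of phased sequences from which all
founders and unrelated individuals are drawn under random mating.

A pool is a binary matrix (haplotypes x sites, 0 = ancestral, 1 = derived)
whose sites are grouped into recombination-free blocks.  Pools are either
generated internally -- each block carries an independent neutral coalescent
genealogy with infinite-sites mutations, so the site-frequency spectrum is
strongly enriched for rare variants -- or ingested from a plain 0/1 matrix
file, a phased VCF, or the text output of an external coalescent simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "VariantSite",
    "HaplotypePool",
    "generate_block_pool",
    "read_pool",
    "write_pool",
    "allele_frequency",
    "select_causal_sites",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSite:
    """Metadata for one polymorphic site in the pool."""

    site_index: int
    chromosome: str
    position_bp: int
    block_id: int
    derived_allele_freq: float


class PoolFormatError(ValueError):
    """Raised when an input haplotype file violates its declared format."""


@dataclass
class HaplotypePool:
    """A population of binary haplotypes over block-structured sites.

    Attributes
    ----------
    matrix
        uint8 array of shape (n_haplotypes, n_sites); 0 ancestral, 1 derived.
    chromosomes
        per-site chromosome label.
    positions_bp
        per-site 1-based physical position, strictly increasing within a
        chromosome.
    block_ids
        per-site block index, non-decreasing with position.
    """

    matrix: np.ndarray
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    block_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.block_ids = np.asarray(self.block_ids, dtype=np.int64)
        n_sites = self.matrix.shape[1]
        for name, arr in (
            ("chromosomes", self.chromosomes),
            ("positions_bp", self.positions_bp),
            ("block_ids", self.block_ids),
        ):
            if arr.shape != (n_sites,):
                raise ValueError(f"{name} must have one entry per site")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("pool matrix entries must be 0/1")
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions_bp[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {chrom}"
                )
        if np.any(np.diff(self.block_ids) < 0):
            raise ValueError("block ids must be non-decreasing along the genome")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_blocks(self) -> int:
        return len(np.unique(self.block_ids))

    def frequencies(self) -> np.ndarray:
        """Derived-allele frequency of every site (column means)."""
        return self.matrix.mean(axis=0)

    def minor_allele_frequencies(self) -> np.ndarray:
        f = self.frequencies()
        return np.minimum(f, 1.0 - f)

    @property
    def sites(self) -> list[VariantSite]:
        freqs = self.frequencies()
        return [
            VariantSite(i, str(self.chromosomes[i]), int(self.positions_bp[i]),
                        int(self.block_ids[i]), float(freqs[i]))
            for i in range(self.n_sites)
        ]

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "pos": self.positions_bp,
                "block": self.block_ids,
                "derived_freq": self.frequencies(),
            }
        )

    def block_centers_bp(self) -> np.ndarray:
        """Midpoint (bp) of each block's site span, in block order."""
        centers = []
        for b in np.unique(self.block_ids):
            pos = self.positions_bp[self.block_ids == b]
            centers.append((pos.min() + pos.max()) // 2)
        return np.asarray(centers, dtype=np.int64)

    def block_chromosomes(self) -> list[str]:
        """Chromosome label of each block, in block order."""
        out = []
        for b in np.unique(self.block_ids):
            labs = pd.unique(self.chromosomes[self.block_ids == b])
            if len(labs) != 1:
                raise ValueError(f"block {b} spans multiple chromosomes")
            out.append(str(labs[0]))
        return out

    def sites_in_block(self, block_id: int) -> np.ndarray:
        return np.flatnonzero(self.block_ids == block_id)

    def subset_sites(self, site_indices) -> "HaplotypePool":
        idx = np.asarray(site_indices, dtype=np.int64)
        return HaplotypePool(
            self.matrix[:, idx],
            self.chromosomes[idx],
            self.positions_bp[idx],
            self.block_ids[idx],
        )


# ---------------------------------------------------------------------------
# Built-in per-block coalescent generator
# ---------------------------------------------------------------------------

def _coalescent_block(n_hap: int, theta: float, rng: np.random.Generator):
    """One neutral constant-size coalescent genealogy with infinite-sites
    mutations (Hudson's algorithm).

    Time is measured in units of 2N generations, so the waiting time while k
    lineages remain is Exp(k(k-1)/2) and the mutation count is
    Poisson(theta * L / 2) for total branch length L, giving Watterson's
    E[S] = theta * sum_{i=1}^{n-1} 1/i.

    Returns a list of derived-carrier index arrays, one per segregating site.
    """
    n_nodes = 2 * n_hap - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n_hap))
    t = 0.0
    nxt = n_hap
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        # remove the two children, append the parent
        for x in sorted((i, j), reverse=True):
            active.pop(x)
        active.append(nxt)
        nxt += 1

    branch_len = np.zeros(n_nodes)
    has_parent = parent >= 0
    branch_len[has_parent] = time[parent[has_parent]] - time[has_parent]
    total = branch_len.sum()
    n_mut = rng.poisson(theta * total / 2.0)
    if n_mut == 0:
        return []

    # leaves under each node, built bottom-up in time order
    order = np.argsort(time, kind="stable")
    leaves: list = [None] * n_nodes
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for v in range(n_nodes):
        if parent[v] >= 0:
            children[parent[v]].append(v)
    for v in order:
        if v < n_hap:
            leaves[v] = np.array([v], dtype=np.int64)
        else:
            leaves[v] = np.concatenate([leaves[c] for c in children[v]])

    probs = branch_len / total
    mut_nodes = rng.choice(n_nodes, size=n_mut, p=probs)
    return [leaves[v] for v in mut_nodes]


def generate_block_pool(
    n_haplotypes: int,
    n_blocks: int,
    theta_per_block: float,
    block_span_bp: int = 10_000,
    chromosome: str = "1",
    seed: int = 0,
) -> HaplotypePool:
    """Generate a pool of ``n_haplotypes`` sequences over ``n_blocks``
    mutually independent recombination-free blocks.

    Each block carries an independent constant-population-size neutral
    coalescent genealogy with scaled mutation rate ``theta_per_block``
    (theta = 4 * N * mu per block).  Sites receive distinct uniform-random bp
    positions within the block's span; blocks are laid end to end.
    Monomorphic columns never arise (every mutation segregates).
    """
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if theta_per_block <= 0:
        raise ValueError("theta_per_block must be > 0")
    if block_span_bp < 1:
        raise ValueError("block_span_bp must be >= 1")

    cols, positions, blocks = [], [], []
    for b in range(n_blocks):
        rng = substream(seed, "pool-block", b)
        carriers = _coalescent_block(n_haplotypes, theta_per_block, rng)
        s = len(carriers)
        if s == 0:
            continue
        if s > block_span_bp:
            raise ValueError(
                f"block {b}: {s} sites exceed block span {block_span_bp} bp; "
                "increase block_span_bp"
            )
        pos = rng.choice(block_span_bp, size=s, replace=False)
        pos = np.sort(pos) + b * block_span_bp + 1
        order = np.arange(s)
        for k in order:
            col = np.zeros(n_haplotypes, dtype=np.uint8)
            col[carriers[k]] = 1
            cols.append(col)
        positions.extend(pos.tolist())
        blocks.extend([b] * s)

    if not cols:
        matrix = np.zeros((n_haplotypes, 0), dtype=np.uint8)
    else:
        matrix = np.column_stack(cols)
    return HaplotypePool(
        matrix,
        np.array([chromosome] * matrix.shape[1], dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(blocks, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def _drop_monomorphic(matrix: np.ndarray, chroms, pos, blocks):
    freq = matrix.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d monomorphic column(s)", dropped)
    return matrix[:, keep], chroms[keep], pos[keep], blocks[keep], dropped


def _read_matrix01_lines(lines, path, keep_pred=None):
    rows = []
    width = None
    for lineno, raw in lines:
        s = "".join(raw.split())
        if not s:
            continue
        if keep_pred is not None and not keep_pred(s):
            continue
        if set(s) - {"0", "1"}:
            raise PoolFormatError(
                f"{path}:{lineno}: non-binary character in haplotype line"
            )
        if width is None:
            width = len(s)
        elif len(s) != width:
            raise PoolFormatError(
                f"{path}:{lineno}: ragged haplotype line "
                f"(length {len(s)}, expected {width})"
            )
        rows.append(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise PoolFormatError(f"{path}: no haplotype lines found")
    return np.vstack(rows)


def _read_sites_tsv(path, n_sites):
    tab = pd.read_csv(path, sep=r"\s+")
    required = {"chrom", "pos", "block"}
    if not required.issubset(tab.columns):
        raise PoolFormatError(
            f"{path}: sites file must have columns {sorted(required)}"
        )
    if len(tab) != n_sites:
        raise PoolFormatError(
            f"{path}: {len(tab)} site rows but haplotypes have {n_sites} columns"
        )
    return (
        tab["chrom"].astype(str).to_numpy(dtype=object),
        tab["pos"].to_numpy(dtype=np.int64),
        tab["block"].to_numpy(dtype=np.int64),
    )


def _default_sites(n_sites):
    return (
        np.array(["1"] * n_sites, dtype=object),
        np.arange(1, n_sites + 1, dtype=np.int64),
        np.zeros(n_sites, dtype=np.int64),
    )


def _read_vcf_phased(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols, chroms, pos = [], [], []
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise PoolFormatError(f"{path}: VCF has no samples")
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise PoolFormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} is not biallelic"
            )
        col = np.empty(2 * n_samples, dtype=np.uint8)
        for i, g in enumerate(rec.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if not phased or a < 0 or b < 0:
                raise PoolFormatError(
                    f"{path}: unphased or missing genotype at "
                    f"{rec.CHROM}:{rec.POS} sample {vcf.samples[i]}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        cols.append(col)
        chroms.append(str(rec.CHROM))
        pos.append(int(rec.POS))
    if not cols:
        raise PoolFormatError(f"{path}: VCF has no variant records")
    matrix = np.column_stack(cols)
    chroms = np.array(chroms, dtype=object)
    pos = np.array(pos, dtype=np.int64)
    # one block per chromosome: the VCF carries no block structure
    _, blocks = np.unique(chroms, return_inverse=True)
    return matrix, chroms, pos, blocks.astype(np.int64)


def read_pool(
    haplotype_path,
    sites_path=None,
    format: str = "matrix01",
) -> HaplotypePool:
    """Read a haplotype pool from disk.

    ``matrix01``: one haplotype per line, characters 0/1, equal lengths, with
    an optional sites sidecar TSV (``chrom pos block``).  ``vcf_phased``: a
    fully phased VCF; haplotypes are the 2N sample haplotypes, one block per
    chromosome.  ``genome_out``: free text from an external coalescent
    simulator; any line whose non-whitespace characters are all 0/1 is taken
    as a haplotype and everything else (population headers etc.) is skipped.

    Monomorphic columns are dropped with a logged count.
    """
    haplotype_path = Path(haplotype_path)
    if format == "matrix01":
        with open(haplotype_path) as fh:
            matrix = _read_matrix01_lines(enumerate(fh, 1), haplotype_path)
        if sites_path is not None:
            chroms, pos, blocks = _read_sites_tsv(sites_path, matrix.shape[1])
        else:
            chroms, pos, blocks = _default_sites(matrix.shape[1])
    elif format == "genome_out":
        with open(haplotype_path) as fh:
            lines = [
                (i, line) for i, line in enumerate(fh, 1)
                if line.strip() and not (set("".join(line.split())) - {"0", "1"})
            ]
        matrix = _read_matrix01_lines(lines, haplotype_path)
        if sites_path is not None:
            chroms, pos, blocks = _read_sites_tsv(sites_path, matrix.shape[1])
        else:
            chroms, pos, blocks = _default_sites(matrix.shape[1])
    elif format == "vcf_phased":
        matrix, chroms, pos, blocks = _read_vcf_phased(haplotype_path)
    else:
        raise ValueError(f"unknown pool format: {format!r}")

    matrix, chroms, pos, blocks, _ = _drop_monomorphic(matrix, chroms, pos, blocks)
    return HaplotypePool(matrix, chroms, pos, blocks)


def write_pool(pool: HaplotypePool, stem) -> tuple[Path, Path]:
    """Write ``<stem>.hap`` (0/1 lines) and ``<stem>.sites`` (chrom pos block)."""
    stem = Path(stem)
    hap_path = stem.parent / (stem.name + ".hap")
    sites_path = stem.parent / (stem.name + ".sites")
    digits = pool.matrix + ord("0")
    with open(hap_path, "w") as fh:
        for row in digits:
            fh.write(row.tobytes().decode("ascii"))
            fh.write("\n")
    pd.DataFrame(
        {"chrom": pool.chromosomes, "pos": pool.positions_bp, "block": pool.block_ids}
    ).to_csv(sites_path, sep="\t", index=False)
    return hap_path, sites_path


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def allele_frequency(pool: HaplotypePool, site_index: int) -> float:
    """Derived-allele frequency (column mean) at one site."""
    if not 0 <= site_index < pool.n_sites:
        raise IndexError(f"site index {site_index} out of range [0, {pool.n_sites})")
    return float(pool.matrix[:, site_index].mean())


def select_causal_sites(
    pool: HaplotypePool,
    n: int,
    maf_range: tuple[float, float] = (0.0, 0.01),
    restrict_blocks=None,
    seed: int = 0,
) -> list[int]:
    """Draw ``n`` distinct causal site indices uniformly without replacement
    from sites whose minor-allele frequency lies in ``maf_range`` (inclusive),
    optionally restricted to a set of blocks.  Deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    low, high = maf_range
    maf = pool.minor_allele_frequencies()
    ok = (maf >= low) & (maf <= high)
    if restrict_blocks is not None:
        ok &= np.isin(pool.block_ids, np.asarray(list(restrict_blocks)))
    candidates = np.flatnonzero(ok)
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} sites with MAF in [{low}, {high}]"
            + ("" if restrict_blocks is None else f" in blocks {restrict_blocks}")
            + f"; {n} requested"
        )
    if n == 0:
        return []
    rng = substream(seed, "causal-sites")
    chosen = rng.choice(candidates, size=n, replace=False)
    return sorted(int(i) for i in chosen)
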