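"""PLINK text output (original ped/map format) plus a sidecar quantitative
phenotype file.

Alleles are coded 1 = ancestral, 2 = derived; the phenotype column uses
1 = unaffected, 2 = affected, 0 = unknown, or the raw trait value when only a
quantitative trait was simulated.  Genetic positions are cumulative Haldane
centimorgans from the chromosome's first site: zero within a block and a
block-to-block increment of -50 ln(1 - 2 theta_i).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cohort import Cohort, Individual, UNKNOWN
from .genmap import RecombinationMap, haldane_theta_to_cm
from .pool import HaplotypePool

__all__ = [
    "write_ped", "write_map", "write_pheno", "write_plink",
    "read_ped", "read_map",
]


def _individuals(cohort: Cohort | list[Individual]) -> list[Individual]:
    return cohort.individuals if isinstance(cohort, Cohort) else list(cohort)


def _pheno_field(ind: Individual, quantitative: bool) -> str:
    if quantitative:
        return "0" if ind.trait is None else repr(float(ind.trait))
    return str(ind.affected)


def write_ped(
    cohort: Cohort | list[Individual],
    pool: HaplotypePool,
    path,
    quantitative_pheno: bool | None = None,
) -> Path:
    """Write a PLINK ped file: FID IID PAT MAT SEX PHENO + 2 alleles/site.

    The trait value is placed in the PHENO column when no disease status was
    simulated (``quantitative_pheno=None`` auto-detects this); otherwise the
    affection status goes there and traits belong in the sidecar phenotype
    file.
    """
    inds = _individuals(cohort)
    if not inds:
        raise ValueError("cohort is empty")
    if quantitative_pheno is None:
        quantitative_pheno = all(i.affected == UNKNOWN for i in inds) and any(
            i.trait is not None for i in inds
        )
    if not quantitative_pheno and all(i.affected == UNKNOWN for i in inds):
        raise ValueError("cohort has neither affection status nor trait values")
    path = Path(path)
    sites = np.arange(pool.n_sites)
    blk = pool.block_ids[sites]
    with open(path, "w") as fh:
        for ind in inds:
            a = pool.matrix[np.asarray(ind.hap[0])[blk], sites] + 1
            b = pool.matrix[np.asarray(ind.hap[1])[blk], sites] + 1
            geno = np.empty(2 * pool.n_sites, dtype=np.uint8)
            geno[0::2] = a
            geno[1::2] = b
            lead = (f"{ind.family_id} {ind.individual_id} {ind.father_id} "
                    f"{ind.mother_id} {ind.sex} {_pheno_field(ind, quantitative_pheno)}")
            fh.write(lead + " " + " ".join(map(str, geno)) + "\n")
    return path


def map_positions_cm(pool: HaplotypePool, rmap: RecombinationMap) -> np.ndarray:
    """Cumulative genetic position (cM) per site, restarting at 0 on each
    chromosome; within-block distances are zero."""
    if rmap.n_blocks != pool.n_blocks:
        raise ValueError("recombination map does not cover the pool's blocks")
    block_list = np.unique(pool.block_ids)
    chrom_of_block = rmap.chromosome_index_of_block()
    cm_of_block = np.zeros(len(block_list))
    for i, theta in enumerate(rmap.interval_theta):
        if chrom_of_block[i + 1] != chrom_of_block[i]:
            cm_of_block[i + 1] = 0.0
        else:
            cm_of_block[i + 1] = cm_of_block[i] + haldane_theta_to_cm(theta)
    block_index = np.searchsorted(block_list, pool.block_ids)
    return cm_of_block[block_index]


def write_map(pool: HaplotypePool, rmap: RecombinationMap, path) -> Path:
    """Write a 4-column PLINK map file: chrom, snp id, cM, bp.

    Chromosome numbers come from the map's chromosome breaks; SNP ids are
    ``chr<k>_b<block>_<bp>``.
    """
    path = Path(path)
    cm = map_positions_cm(pool, rmap)
    block_list = np.unique(pool.block_ids)
    chrom_of_block = rmap.chromosome_index_of_block() + 1
    block_index = np.searchsorted(block_list, pool.block_ids)
    with open(path, "w") as fh:
        for s in range(pool.n_sites):
            c = chrom_of_block[block_index[s]]
            bp = pool.positions_bp[s]
            fh.write(f"{c} chr{c}_b{pool.block_ids[s]}_{bp} {cm[s]:.6f} {bp}\n")
    return path


def write_pheno(cohort: Cohort | list[Individual], path) -> Path:
    """Write the quantitative phenotype file: FID IID value (no header)."""
    inds = _individuals(cohort)
    path = Path(path)
    with open(path, "w") as fh:
        for ind in inds:
            val = "NA" if ind.trait is None else repr(float(ind.trait))
            fh.write(f"{ind.family_id} {ind.individual_id} {val}\n")
    return path


def write_plink(
    cohort: Cohort | list[Individual],
    pool: HaplotypePool,
    rmap: RecombinationMap,
    prefix,
    pheno_file: bool | None = None,
) -> list[Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (plus ``<prefix>.pheno``
    when traits were simulated alongside disease status)."""
    prefix = Path(prefix)
    inds = _individuals(cohort)

    def named(ext):
        return prefix.parent / (prefix.name + ext)

    out = [
        write_ped(cohort, pool, named(".ped")),
        write_map(pool, rmap, named(".map")),
    ]
    has_trait = any(i.trait is not None for i in inds)
    has_status = any(i.affected != UNKNOWN for i in inds)
    if pheno_file or (pheno_file is None and has_trait and has_status):
        out.append(write_pheno(cohort, named(".pheno")))
    return out


def read_ped(path):
    """Parse a text ped file back into (meta rows, allele matrix).

    Returns a list of 6-tuples (FID, IID, PAT, MAT, SEX, PHENO string) and an
    int array of shape (n_individuals, 2 * n_sites) with alleles as written.
    """
    meta, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2:
                raise ValueError(f"{path}:{lineno}: malformed ped row")
            meta.append(tuple(parts[:6]))
            rows.append(np.array(parts[6:], dtype=np.int64))
    if not rows:
        raise ValueError(f"{path}: empty ped file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged ped rows")
    return meta, np.vstack(rows)


def read_map(path):
    """Parse a 4-column map file into arrays (chrom, snp_id, cM, bp)."""
    chroms, ids, cms, bps = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: map rows need 4 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            cms.append(float(parts[2]))
            bps.append(int(parts[3]))
    return (np.array(chroms), np.array(ids), np.array(cms),
            np.array(bps, dtype=np.int64))
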