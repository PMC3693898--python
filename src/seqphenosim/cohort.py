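"""Cohort simulation: three-generation pedigrees by gene dropping with
affected-sib ascertainment, and unrelated case-control samples including a
fast conditional-genotype case sampler whose run time is independent of the
disease prevalence.

Because blocks recombine only at their boundaries, every haplotype carried by
a simulated individual is, within each block, an intact pool haplotype.  A
haplotype is therefore represented as an integer vector of length n_blocks of
pool row indices; a founder's haplotype repeats one row across all blocks and
a gamete mixes the two parental rows block by block.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .disease import DiseaseModel
from .genmap import RecombinationMap
from .pool import HaplotypePool
from .qtl import TraitModel, sample_trait

__all__ = [
    "Individual",
    "Pedigree",
    "Cohort",
    "draw_founder",
    "meiosis",
    "simulate_family",
    "ascertain",
    "simulate_families",
    "simulate_case_rejection",
    "simulate_control",
    "simulate_case_control",
    "case_control_mosaics",
    "fit_case_conditional",
    "ConditionalGenotypeDistribution",
    "CaseFastSampler",
    "genotype_matrix",
    "haplotype_alleles",
]

UNKNOWN, UNAFFECTED, AFFECTED = 0, 1, 2  # PLINK phenotype coding

DEFAULT_N_SIBS = 6  # 4 grandparents + 2 parents + 6 sibs = 12 members


@dataclass
class Individual:
    """One simulated person.

    ``hap`` has shape (2, n_blocks): pool row index per block for each of the
    two haplotypes.  ``affected`` uses PLINK coding (0 unknown, 1 unaffected,
    2 affected).  ``father_id``/``mother_id`` are 0 for founders.
    """

    family_id: str
    individual_id: int
    father_id: int
    mother_id: int
    sex: int
    hap: np.ndarray
    affected: int = UNKNOWN
    trait: float | None = None


@dataclass
class Pedigree:
    """A three-generation family: two grandparental couples, their two
    children who marry, and a sibship in the third generation."""

    family_id: str
    members: list[Individual]
    n_sibs: int

    def __post_init__(self) -> None:
        if len(self.members) != 6 + self.n_sibs:
            raise ValueError("pedigree must have 4 + 2 + n_sibs members")

    @property
    def founders(self) -> list[Individual]:
        return self.members[:4]

    @property
    def parents(self) -> list[Individual]:
        return self.members[4:6]

    @property
    def sibs(self) -> list[Individual]:
        return self.members[6:]

    def set_family_id(self, fid: str) -> None:
        self.family_id = fid
        for m in self.members:
            m.family_id = fid


@dataclass
class Cohort:
    """A simulated sample: pedigrees and/or unrelated individuals."""

    design: str  # "family" | "cc"
    pedigrees: list[Pedigree] = field(default_factory=list)
    unrelated: list[Individual] = field(default_factory=list)

    @property
    def individuals(self) -> list[Individual]:
        out = [m for ped in self.pedigrees for m in ped.members]
        out.extend(self.unrelated)
        return out


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def draw_founder(pool: HaplotypePool, rng: np.random.Generator) -> np.ndarray:
    """Two haplotypes drawn uniformly with replacement from the pool, as a
    (2, n_blocks) array of pool row indices."""
    if pool.n_haplotypes < 1:
        raise ValueError("pool is empty")
    rows = rng.integers(0, pool.n_haplotypes, size=2)
    return np.repeat(rows[:, None], pool.n_blocks, axis=1).astype(np.int32)


def meiosis(
    parent_hap: np.ndarray, rmap: RecombinationMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete: start from a fair-coin choice of parental haplotype for
    the first block, then switch haplotypes between blocks i and i+1 with
    probability theta_i, independently per interval (no interference)."""
    parent_hap = np.asarray(parent_hap)
    n_blocks = parent_hap.shape[1]
    if rmap.n_blocks != n_blocks:
        raise ValueError(
            f"recombination map covers {rmap.n_blocks} blocks but haplotypes "
            f"have {n_blocks}"
        )
    switches = rng.random(n_blocks) < np.concatenate(([0.5], rmap.interval_theta))
    strand = np.cumsum(switches) % 2
    return parent_hap[strand, np.arange(n_blocks)]


def haplotype_alleles(
    pool: HaplotypePool, hap_row: np.ndarray, sites: np.ndarray
) -> np.ndarray:
    """Alleles carried by one block-mosaic haplotype at the given sites."""
    sites = np.asarray(sites, dtype=np.int64)
    return pool.matrix[np.asarray(hap_row)[pool.block_ids[sites]], sites]


def _derived_counts(pool, individuals, sites) -> np.ndarray:
    sites = np.asarray(sites, dtype=np.int64)
    blk = pool.block_ids[sites]
    haps = np.stack([ind.hap for ind in individuals])  # (n, 2, B)
    rows0 = haps[:, 0, :][:, blk]
    rows1 = haps[:, 1, :][:, blk]
    return (pool.matrix[rows0, sites].astype(np.int8)
            + pool.matrix[rows1, sites].astype(np.int8))


def genotype_matrix(individuals, pool: HaplotypePool, sites=None) -> np.ndarray:
    """Derived-allele count matrix (individuals x sites)."""
    if sites is None:
        sites = np.arange(pool.n_sites)
    return _derived_counts(pool, list(individuals), sites)


def _assign_phenotypes(members, pool, disease, trait, rng) -> None:
    if disease is not None:
        counts = _derived_counts(pool, members, disease.causal_sites)
        pen = disease.penetrance(counts)
        u = rng.random(len(members))
        for ind, p, ui in zip(members, pen, u):
            ind.affected = AFFECTED if ui < p else UNAFFECTED
    if trait is not None:
        counts = _derived_counts(pool, members, trait.qtl_sites)
        y = sample_trait(counts, trait, rng=rng)
        for ind, yi in zip(members, y):
            ind.trait = float(yi)


def simulate_family(
    pool: HaplotypePool,
    rmap: RecombinationMap,
    disease: DiseaseModel | None = None,
    trait: TraitModel | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_sibs: int = DEFAULT_N_SIBS,
    family_id: str = "fam1",
) -> Pedigree:
    """Gene-drop one three-generation family.

    Four founders (two grandparental couples) are drawn from the pool; the
    father is a child of couple A, the mother of couple B (both produced by
    meiosis); the third generation holds ``n_sibs`` full siblings of that
    couple.  Affection status is drawn by comparing each member's penetrance
    to a uniform variate; traits are sampled if a trait model is supplied.
    """
    if disease is None and trait is None:
        raise ValueError("supply at least one of a disease or trait model")
    if rng is None:
        rng = substream(0 if seed is None else seed, "family")
    gp = [draw_founder(pool, rng) for _ in range(4)]
    father = np.stack([meiosis(gp[0], rmap, rng), meiosis(gp[1], rmap, rng)])
    mother = np.stack([meiosis(gp[2], rmap, rng), meiosis(gp[3], rmap, rng)])
    sibs = [
        np.stack([meiosis(father, rmap, rng), meiosis(mother, rmap, rng)])
        for _ in range(n_sibs)
    ]

    members = [
        Individual(family_id, 1, 0, 0, 1, gp[0]),
        Individual(family_id, 2, 0, 0, 2, gp[1]),
        Individual(family_id, 3, 0, 0, 1, gp[2]),
        Individual(family_id, 4, 0, 0, 2, gp[3]),
        Individual(family_id, 5, 1, 2, 1, father),
        Individual(family_id, 6, 3, 4, 2, mother),
    ]
    for k, hap in enumerate(sibs):
        members.append(Individual(family_id, 7 + k, 5, 6, 1 + k % 2, hap))
    _assign_phenotypes(members, pool, disease, trait, rng)
    return Pedigree(family_id, members, n_sibs)


def ascertain(ped: Pedigree, required_affected_sibs: int) -> bool:
    """True iff at least ``required_affected_sibs`` third-generation siblings
    are affected."""
    n_aff = sum(1 for s in ped.sibs if s.affected == AFFECTED)
    return n_aff >= required_affected_sibs


def simulate_families(
    pool: HaplotypePool,
    rmap: RecombinationMap,
    disease: DiseaseModel | None = None,
    trait: TraitModel | None = None,
    n_families: int = 100,
    required_affected_sibs: int = 1,
    n_sibs: int = DEFAULT_N_SIBS,
    seed: int = 0,
    n_workers: int = 1,
    ascertain_random: bool = False,
    return_stats: bool = False,
):
    """Rejection-sample families until ``n_families`` pass ascertainment.

    Every candidate family is generated from a substream keyed by its global
    attempt index, and the accepted families are the first ``n_families`` in
    attempt order -- so the output is byte-identical for any ``n_workers``
    with the same master seed.  With ``ascertain_random`` (quantitative-trait
    designs sampled from the population) no family is rejected.

    Aborts with the empirical acceptance rate after 1000 * n_families
    consecutive rejections.
    """
    no_ascertainment = ascertain_random or disease is None

    def make(i: int) -> Pedigree:
        rng = substream(seed, "family-attempt", i)
        return simulate_family(pool, rmap, disease, trait, rng=rng,
                               n_sibs=n_sibs, family_id=f"fam{i}")

    accepted: list[Pedigree] = []
    attempt = 0
    n_tried = 0
    consecutive_rejects = 0
    limit = 1000 * max(n_families, 1)
    batch = max(16, 8 * n_workers)
    pool_exec = ThreadPoolExecutor(n_workers) if n_workers > 1 else None
    try:
        while len(accepted) < n_families:
            idxs = range(attempt, attempt + batch)
            if pool_exec is not None:
                peds = list(pool_exec.map(make, idxs))
            else:
                peds = [make(i) for i in idxs]
            for ped in peds:
                if len(accepted) >= n_families:
                    break
                n_tried += 1
                if no_ascertainment or ascertain(ped, required_affected_sibs):
                    ped.set_family_id(f"fam{len(accepted) + 1}")
                    accepted.append(ped)
                    consecutive_rejects = 0
                else:
                    consecutive_rejects += 1
                    if consecutive_rejects > limit:
                        total = attempt + batch
                        raise RuntimeError(
                            f"ascertainment rate too low: {len(accepted)} "
                            f"families accepted in {total} attempts "
                            f"(~{len(accepted) / total:.2e})"
                        )
            attempt += batch
    finally:
        if pool_exec is not None:
            pool_exec.shutdown()
    if return_stats:
        return accepted, {"n_attempts": n_tried,
                          "acceptance_rate": n_families / n_tried}
    return accepted


# ---------------------------------------------------------------------------
# Unrelated case-control sampling
# ---------------------------------------------------------------------------

def _vector_meiosis(rows_a, rows_b, theta_full, rng):
    """Vectorized meiosis over (n, B) arrays of pool row indices.

    ``theta_full`` has length B with a leading 0.5 (fair coin for the first
    block) followed by the per-interval recombination fractions."""
    switches = rng.random(rows_a.shape) < theta_full
    strand = switches.cumsum(axis=1) % 2
    return np.where(strand == 0, rows_a, rows_b)


def _thirdgen_gametes(pool, rmap, n, rng):
    """(n, B) gametes with the block-mosaic distribution of one parental
    gamete of a third-generation member of a random-mating family: two
    founders, two meioses to make the parent, one meiosis to make the
    gamete."""
    B = pool.n_blocks
    f = rng.integers(0, pool.n_haplotypes, size=(n, 4))
    if B == 1:
        # a mosaic over one block is a uniform pool row
        return f[:, :1].copy()
    theta_full = np.concatenate(([0.5], rmap.interval_theta))

    def tiled(col):
        return np.repeat(f[:, col:col + 1], B, axis=1)

    parent_pat = _vector_meiosis(tiled(0), tiled(1), theta_full, rng)
    parent_mat = _vector_meiosis(tiled(2), tiled(3), theta_full, rng)
    return _vector_meiosis(parent_pat, parent_mat, theta_full, rng)


def _thirdgen_pairs(pool, rmap, n, rng):
    """(n, 2, B) haplotype mosaics of unrelated third-generation members of
    distinct random-mating families."""
    pat = _thirdgen_gametes(pool, rmap, n, rng)
    mat = _thirdgen_gametes(pool, rmap, n, rng)
    return np.stack([pat, mat], axis=1)


def _counts_from_mosaics(pool, mosaics, sites):
    sites = np.asarray(sites, dtype=np.int64)
    blk = pool.block_ids[sites]
    rows0 = mosaics[:, 0, :][:, blk]
    rows1 = mosaics[:, 1, :][:, blk]
    return (pool.matrix[rows0, sites].astype(np.int8)
            + pool.matrix[rows1, sites].astype(np.int8))


def _require_rmap(pool, rmap):
    if rmap is None:
        if pool.n_blocks > 1:
            raise ValueError(
                "a recombination map is required for a multi-block pool"
            )
        from .genmap import fixed_map
        rmap = fixed_map(0.0, 1, pool.block_centers_bp())
    return rmap


def _unrelated_with_status(
    pool: HaplotypePool,
    rmap: RecombinationMap,
    disease: DiseaseModel,
    n: int,
    want_affected: bool,
    rng: np.random.Generator,
    max_attempts: int = 2_000_000,
) -> np.ndarray:
    """Rejection-sample ``n`` unrelated individuals -- third-generation
    block mosaics, shape (n, 2, B) -- whose penetrance draw gives the
    requested affection status.  Vectorized in chunks."""
    out = np.empty((n, 2, pool.n_blocks), dtype=np.int64)
    got = 0
    attempts = 0
    chunk = max(256, min(4 * n, 100_000))
    while got < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"{'case' if want_affected else 'control'} sampling: "
                f"{got}/{n} accepted after {attempts} attempts; "
                "penetrance may be degenerate"
            )
        mosaics = _thirdgen_pairs(pool, rmap, chunk, rng)
        counts = _counts_from_mosaics(pool, mosaics, disease.causal_sites)
        pen = disease.penetrance(counts)
        hit = rng.random(chunk) < pen
        if not want_affected:
            hit = ~hit
        rows = mosaics[hit]
        take = min(len(rows), n - got)
        out[got:got + take] = rows[:take]
        got += take
        attempts += chunk
    return out


def _mosaic_to_individual(pool, mosaic, fid, iid, sex, affected) -> Individual:
    hap = np.asarray(mosaic, dtype=np.int32)
    if hap.ndim == 1:  # one row per haplotype: tile over blocks
        hap = np.repeat(hap[:, None], pool.n_blocks, axis=1)
    return Individual(fid, iid, 0, 0, sex, hap, affected=affected)


def simulate_case_rejection(
    pool: HaplotypePool,
    disease: DiseaseModel,
    rng: np.random.Generator,
    rmap: RecombinationMap | None = None,
) -> Individual:
    """One unrelated affected individual by rejection sampling."""
    rmap = _require_rmap(pool, rmap)
    mosaic = _unrelated_with_status(pool, rmap, disease, 1, True, rng)[0]
    return _mosaic_to_individual(pool, mosaic, "case", 1, 1, AFFECTED)


def simulate_control(
    pool: HaplotypePool,
    disease: DiseaseModel,
    rng: np.random.Generator,
    rmap: RecombinationMap | None = None,
) -> Individual:
    """One unrelated unaffected individual by rejection sampling."""
    rmap = _require_rmap(pool, rmap)
    mosaic = _unrelated_with_status(pool, rmap, disease, 1, False, rng)[0]
    return _mosaic_to_individual(pool, mosaic, "ctrl", 1, 1, UNAFFECTED)


@dataclass
class ConditionalGenotypeDistribution:
    """Empirical distribution of multilocus causal genotype vectors X among
    cases: P(X | affected) estimated from a pilot sample."""

    genotypes: np.ndarray  # (n_distinct, n_loci) derived-allele counts
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genotypes) == 0:
            raise ValueError("conditional distribution is empty")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("conditional probabilities must sum to 1")


def fit_case_conditional(
    pilot_counts: np.ndarray, n_loci: int | None = None
) -> ConditionalGenotypeDistribution:
    """Tabulate the empirical distribution of causal-site genotype vectors in
    a pilot set of cases (rows of derived-allele counts)."""
    pilot_counts = np.atleast_2d(np.asarray(pilot_counts))
    if pilot_counts.shape[0] < 1:
        raise ValueError("need at least one pilot case")
    uniq, counts = np.unique(pilot_counts, axis=0, return_counts=True)
    return ConditionalGenotypeDistribution(uniq, counts / counts.sum())


class CaseFastSampler:
    """Draw cases from P(X | affected) without further penetrance draws.

    A multilocus genotype X at the causal sites is drawn from the pilot
    conditional distribution; a phase assignment splits X uniformly into two
    per-haplotype allele vectors; each vector is matched to a uniformly
    chosen pool haplotype carrying those alleles at the causal sites.  If a
    phase has no matching haplotype the phase is redrawn (bounded), then X is
    redrawn.  The sampled individual is labeled affected outright, so the
    cost per case does not depend on the disease prevalence.

    When a recombination map is supplied, the matched rows fill only the
    blocks containing causal sites; all other blocks come from an
    unconditional third-generation mosaic, so regions unlinked to the causal
    loci keep their population distribution in cases.
    """

    def __init__(
        self,
        pool: HaplotypePool,
        causal_sites,
        cond: ConditionalGenotypeDistribution,
        rmap: RecombinationMap | None = None,
    ) -> None:
        self.pool = pool
        self.causal_sites = np.asarray(causal_sites, dtype=np.int64)
        self.cond = cond
        self.rmap = rmap
        self.causal_blocks = np.unique(pool.block_ids[self.causal_sites])
        sub = pool.matrix[:, self.causal_sites]
        self._lookup: dict[bytes, np.ndarray] = {}
        grouped: dict[bytes, list[int]] = {}
        for row, key in enumerate(map(np.ndarray.tobytes, sub)):
            grouped.setdefault(key, []).append(row)
        for key, rows in grouped.items():
            self._lookup[key] = np.asarray(rows, dtype=np.int64)

    def sample_pairs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` case haplotype mosaics, shape (n, 2, n_blocks)."""
        probs = self.cond.probabilities
        xs = rng.choice(len(probs), size=n, p=probs)
        matched = np.empty((n, 2), dtype=np.int64)
        for i, xi in enumerate(xs):
            matched[i] = self._one_pair(self.cond.genotypes[xi], xi, rng)
        if self.rmap is None or self.pool.n_blocks == 1:
            return np.repeat(matched[:, :, None], self.pool.n_blocks, axis=2)
        mosaics = _thirdgen_pairs(self.pool, self.rmap, n, rng)
        mosaics[:, :, self.causal_blocks] = matched[:, :, None]
        return mosaics

    def _one_pair(self, x, x_index, rng, max_x_redraws: int = 1000) -> tuple:
        for _ in range(max_x_redraws):
            pair = self._try_phase(x, rng)
            if pair is not None:
                return pair
            # no consistent haplotype pair for this X: redraw X
            x_index = rng.choice(len(self.cond.probabilities),
                                 p=self.cond.probabilities)
            x = self.cond.genotypes[x_index]
        raise RuntimeError(
            "no pool haplotype pair is consistent with the pilot case "
            "genotypes: pool and disease spec disagree"
        )

    def _try_phase(self, x, rng, max_phase_redraws: int = 64):
        het = np.flatnonzero(x == 1)
        base = (x == 2).astype(np.uint8)
        for _ in range(max_phase_redraws):
            vec_a = base.copy()
            vec_b = base.copy()
            if len(het):
                bits = rng.integers(0, 2, size=len(het)).astype(np.uint8)
                vec_a[het] = bits
                vec_b[het] = 1 - bits
            cand_a = self._lookup.get(vec_a.tobytes())
            cand_b = self._lookup.get(vec_b.tobytes())
            if cand_a is not None and cand_b is not None:
                return (cand_a[rng.integers(len(cand_a))],
                        cand_b[rng.integers(len(cand_b))])
            if not len(het):
                return None  # no phase freedom: this X is unmatchable
        return None

    def sample(self, rng: np.random.Generator) -> Individual:
        mosaic = self.sample_pairs(1, rng)[0]
        return _mosaic_to_individual(self.pool, mosaic, "case", 1, 1, AFFECTED)


def case_control_mosaics(
    pool: HaplotypePool,
    disease: DiseaseModel,
    n_cases: int,
    n_controls: int,
    rmap: RecombinationMap | None = None,
    fast_mode: bool = False,
    pilot_cases: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level case-control sampler: haplotype mosaics (n, 2, B) and a 0/1
    phenotype vector (cases first)."""
    rmap = _require_rmap(pool, rmap)
    rng_cases = substream(seed, "cc-cases")
    rng_controls = substream(seed, "cc-controls")
    if fast_mode:
        if pilot_cases < 1:
            raise ValueError("fast mode requires at least one pilot case")
        rng_pilot = substream(seed, "cc-pilot")
        pilot = _unrelated_with_status(pool, rmap, disease, pilot_cases, True,
                                       rng_pilot)
        pilot_counts = _counts_from_mosaics(pool, pilot, disease.causal_sites)
        sampler = CaseFastSampler(pool, disease.causal_sites,
                                  fit_case_conditional(pilot_counts), rmap)
        cases = sampler.sample_pairs(n_cases, rng_cases)
    else:
        cases = _unrelated_with_status(pool, rmap, disease, n_cases, True,
                                       rng_cases)
    controls = _unrelated_with_status(pool, rmap, disease, n_controls, False,
                                      rng_controls)
    mosaics = np.concatenate([cases, controls], axis=0)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return mosaics, y


def simulate_case_control(
    pool: HaplotypePool,
    disease: DiseaseModel,
    n_cases: int,
    n_controls: int,
    rmap: RecombinationMap | None = None,
    trait: TraitModel | None = None,
    fast_mode: bool = False,
    pilot_cases: int = 100,
    seed: int = 0,
) -> Cohort:
    """Simulate unrelated cases and controls.

    Cases come from rejection sampling, or (``fast_mode``) from the
    conditional-genotype sampler fitted to a ``pilot_cases``-sized pilot of
    rejection-sampled cases.  Controls always use rejection sampling (cheap
    unless the disease is very common).  Each individual is emitted as its
    own single-member family.  When a trait model is supplied, traits are
    sampled alongside the affection status.
    """
    mosaics, y = case_control_mosaics(
        pool, disease, n_cases, n_controls, rmap, fast_mode, pilot_cases, seed
    )
    unrelated = []
    for i in range(n_cases):
        unrelated.append(_mosaic_to_individual(
            pool, mosaics[i], f"case{i + 1}", 1, 1 + i % 2, AFFECTED))
    for i in range(n_controls):
        unrelated.append(_mosaic_to_individual(
            pool, mosaics[n_cases + i], f"ctrl{i + 1}", 1, 1 + i % 2, UNAFFECTED))
    if trait is not None and unrelated:
        counts = _counts_from_mosaics(pool, mosaics, trait.qtl_sites)
        traits = sample_trait(counts, trait, rng=substream(seed, "cc-traits"))
        for ind, t in zip(unrelated, traits):
            ind.trait = float(t)
    return Cohort(design="cc", unrelated=unrelated)
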