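"""Rare-variant variance-component score test and replicate harness.

The test is the weighted linear-kernel score statistic of the sequence
kernel association test family:

    Q = (y - ybar)' G W G' (y - ybar),   W = diag(w_j^2),

with the published default weights w_j = Beta(1, 25) density evaluated at
the sample minor-allele frequency of site j, which up-weights rare variants.
Under the null, Q is distributed as a mixture sum_j lambda_j chi^2_1 with
lambda_j the eigenvalues of sigma^2 W^(1/2) Gc' Gc W^(1/2) (Gc the centered
genotype matrix, sigma^2 = ybar (1 - ybar) for a binary trait); the p-value
comes from a moment-matched (mean/variance/kurtosis) scaled noncentral
chi-square approximation to that mixture, or from phenotype permutations.

The replicate harness repeatedly simulates a case-control dataset, runs the
test on a region, and reports the rejection rate at a nominal level -- power
when the region contains the causal loci, the type-I error rate when it is
unlinked to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ncx2

from ._rng import spawn_seed, substream
from .cohort import _counts_from_mosaics, case_control_mosaics
from .disease import DiseaseModel
from .genmap import RecombinationMap
from .pool import HaplotypePool

__all__ = [
    "TestRegion",
    "PowerResult",
    "CaseControlScenario",
    "beta_maf_weights",
    "vc_score_test",
    "estimate_rate",
]


@dataclass(frozen=True)
class TestRegion:
    """A contiguous-or-not set of pool site indices to test jointly."""

    site_indices: tuple
    label: str = "region"

    def __post_init__(self) -> None:
        if len(self.site_indices) == 0:
            raise ValueError("test region is empty")


@dataclass
class PowerResult:
    """Rejection rate of a test over simulation replicates."""

    label: str
    n_replicates: int
    alpha_level: float
    rejection_count: int

    @property
    def proportion(self) -> float:
        return self.rejection_count / self.n_replicates

    @property
    def se(self) -> float:
        p = self.proportion
        return float(np.sqrt(p * (1 - p) / self.n_replicates))


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density at the minor-allele frequencies (SKAT default
    a=1, b=25): w = maf^(a-1) (1-maf)^(b-1) / B(a, b)."""
    from scipy.stats import beta as beta_dist

    return beta_dist.pdf(np.asarray(maf, dtype=float), a, b)


def _liu_sf(q: float, lam: np.ndarray) -> float:
    """Survival function of sum lambda_j chi^2_1 at q, by the modified
    moment-matching of Liu, Tang & Zhang (matches mean, variance and
    kurtosis; skewness where attainable) to a scaled noncentral chi-square."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2 * delta))
    t = (q - c1) / np.sqrt(2.0 * c2)
    return float(ncx2.sf(t * sigma_x + mu_x, df, delta))


def vc_score_test(
    genotype_matrix: np.ndarray,
    phenotype: np.ndarray,
    weights: np.ndarray | None = None,
    p_method: str = "moment",
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """P-value of the weighted variance-component score test on a region.

    ``genotype_matrix`` holds derived-allele counts (individuals x sites);
    ``phenotype`` is a binary 0/1 (or 1/2) vector.  ``weights`` are per-site
    w_j, defaulting to the Beta(1, 25) density at the sample MAF.  p_method
    'moment' uses the chi-square-mixture approximation; 'permutation' uses
    ``n_permutations`` phenotype permutations (p in (0, 1]).
    """
    G = np.asarray(genotype_matrix, dtype=np.float64)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with at least one site")
    y = np.asarray(phenotype, dtype=np.float64)
    if y.shape != (G.shape[0],):
        raise ValueError("phenotype length must match the number of individuals")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("phenotype is constant")
    if len(classes) == 2:
        y = (y == classes.max()).astype(float)  # accepts 0/1 or 1/2 coding

    if weights is None:
        f = G.mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
        weights = beta_maf_weights(maf)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (G.shape[1],):
            raise ValueError("need one weight per site")
        if np.any(weights < 0):
            raise ValueError("weights must be >= 0")

    r = y - y.mean()
    Gw = G * weights
    score = Gw.T @ r
    q = float(score @ score)

    if p_method == "permutation":
        rng = substream(seed, "vc-permutation")
        perms = np.empty((len(y), n_permutations))
        for k in range(n_permutations):
            perms[:, k] = rng.permutation(r)
        qs = ((Gw.T @ perms) ** 2).sum(axis=0)
        return float((1 + np.sum(qs >= q)) / (1 + n_permutations))
    if p_method != "moment":
        raise ValueError("p_method must be 'moment' or 'permutation'")

    sigma2 = float(y.mean() * (1 - y.mean()))
    Gc = Gw - Gw.mean(axis=0)
    lam = np.linalg.eigvalsh(sigma2 * (Gc.T @ Gc))
    lam = lam[lam > 1e-10 * max(lam.max(), 1e-300)]
    if q <= 0 or len(lam) == 0:
        return 1.0
    return min(_liu_sf(q, lam), 1.0)


@dataclass
class CaseControlScenario:
    """A full simulation configuration for one replicate: draw ``n_cases``
    affected and ``n_controls`` unaffected unrelated individuals from the
    pool under the disease model (cases via the fast conditional-genotype
    sampler when ``fast_mode``)."""

    pool: HaplotypePool
    disease: DiseaseModel
    n_cases: int = 1000
    n_controls: int = 1000
    rmap: RecombinationMap | None = None
    fast_mode: bool = True
    pilot_cases: int = 100

    def replicate(self, seed: int) -> tuple[np.ndarray, np.ndarray]:
        """One dataset: haplotype mosaics (n, 2, B) and 0/1 phenotypes."""
        return case_control_mosaics(
            self.pool, self.disease, self.n_cases, self.n_controls,
            rmap=self.rmap, fast_mode=self.fast_mode,
            pilot_cases=self.pilot_cases, seed=seed,
        )


def estimate_rate(
    scenario: CaseControlScenario,
    region: TestRegion,
    n_replicates: int = 1000,
    alpha_level: float = 0.05,
    seed: int = 0,
    p_method: str = "moment",
) -> PowerResult:
    """Empirical rejection rate of the score test on ``region`` over
    ``n_replicates`` independently simulated datasets."""
    sites = np.asarray(region.site_indices, dtype=np.int64)
    hits = 0
    for rep in range(n_replicates):
        rep_seed = spawn_seed(seed, "replicate", rep)
        mosaics, y = scenario.replicate(rep_seed)
        G = _counts_from_mosaics(scenario.pool, mosaics, sites)
        p = vc_score_test(G, y, p_method=p_method, seed=rep_seed)
        if p < alpha_level:
            hits += 1
    return PowerResult(region.label, n_replicates, alpha_level, hits)
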