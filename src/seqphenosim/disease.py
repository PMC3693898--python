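"""Dichotomous disease models.

Two penetrance functions determine affection status from the genotypes at a
set of causal sites:

* Model 1 ("logistic"): P(affected | X) = expit(alpha + B.X), where X is the
  coded genotype vector, B the per-locus log odds ratios, and alpha either
  supplied directly (alpha = logit(f0), the baseline log odds with no mutant
  alleles) or solved by bisection so the population prevalence matches a
  user-specified K.

* Model 2 ("par"): P(affected | X) = f0 * prod_i GRR_i^k_i
  / (1 - f0 + f0 * prod_i GRR_i^k_i), with per-locus genotypic relative
  risks backed out of population attributable risks:
  GRR_i = PAR_i / ((1 - PAR_i) * R_i) + 1, R_i the risk-allele frequency.
  With all loci contributing equally to the total PAR, rarer variants get
  larger GRRs.  A protective locus uses 1/GRR_i.

Genotype coding k is shared by both models: the mutant-allele count (0,1,2)
under an additive model, presence/absence of a mutant allele (2/0) under a
dominant model, and presence/absence of a homozygous mutant genotype (2/0)
under a recessive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from ._rng import substream
from .pool import HaplotypePool

__all__ = [
    "DiseaseSpec",
    "DiseaseModel",
    "genotype_code",
    "code_genotypes",
    "penetrance_logistic",
    "penetrance_par",
    "par_to_grr",
    "split_par",
    "assign_risk_flags",
    "solve_alpha",
    "prevalence_at_alpha",
    "build_disease_model",
    "population_prevalence",
    "random_mating_counts",
]

MODES = ("additive", "dominant", "recessive")

ALPHA_LO, ALPHA_HI = -20.0, 20.0


def genotype_code(derived_allele_count: int, mode: str,
                  dominant_het_single: bool = False) -> int:
    """Code one genotype for the penetrance models (see module docstring).

    ``dominant_het_single`` is a compatibility switch that codes the dominant
    heterozygote as 1 instead of 2.
    """
    c = int(derived_allele_count)
    if c not in (0, 1, 2):
        raise ValueError(f"allele count must be 0, 1 or 2, got {c}")
    if mode == "additive":
        return c
    if mode == "dominant":
        if c == 0:
            return 0
        return 1 if (c == 1 and dominant_het_single) else 2
    if mode == "recessive":
        return 2 if c == 2 else 0
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def code_genotypes(counts, mode: str, dominant_het_single: bool = False) -> np.ndarray:
    """Vectorized :func:`genotype_code` over an array of allele counts."""
    counts = np.asarray(counts)
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValueError("allele counts must be 0, 1 or 2")
    if mode == "additive":
        return counts.astype(np.int8)
    if mode == "dominant":
        out = np.where(counts >= 1, 2, 0).astype(np.int8)
        if dominant_het_single:
            out[counts == 1] = 1
        return out
    if mode == "recessive":
        return np.where(counts == 2, 2, 0).astype(np.int8)
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def penetrance_logistic(X, alpha: float, beta) -> np.ndarray | float:
    """P(affected | X) = expit(alpha + B.X) for coded genotype vector(s) X.

    X may be one vector or a matrix of row vectors.
    """
    X = np.asarray(X, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X.shape[-1] != len(beta) and not (X.size == 0 and len(beta) == 0):
        raise ValueError(
            f"genotype vector length {X.shape[-1]} != beta length {len(beta)}"
        )
    p = expit(alpha + X @ beta)
    return float(p) if p.ndim == 0 else p


def penetrance_par(k, f0: float, grr) -> np.ndarray | float:
    """P(affected | k) = f0 * prod GRR_i^k_i / (1 - f0 + f0 * prod GRR_i^k_i).

    With every k_i = 0 this is exactly f0.  Computed on the log-odds scale:
    the model is the logistic model with alpha = logit(f0), beta = ln GRR.
    """
    if not 0 < f0 < 1:
        raise ValueError(f"baseline penetrance f0 must lie in (0,1), got {f0}")
    grr = np.atleast_1d(np.asarray(grr, dtype=float))
    if np.any(grr <= 0):
        raise ValueError("all genotypic relative risks must be > 0")
    k = np.asarray(k, dtype=float)
    if k.shape[-1] != len(grr) and not (k.size == 0 and len(grr) == 0):
        raise ValueError(f"coded vector length {k.shape[-1]} != GRR length {len(grr)}")
    p = expit(logit(f0) + k @ np.log(grr))
    return float(p) if p.ndim == 0 else p


def par_to_grr(par_i: float, risk_allele_freq: float) -> float:
    """GRR_i = PAR_i / ((1 - PAR_i) * R_i) + 1."""
    if not 0 <= par_i < 1:
        raise ValueError(f"per-locus PAR must lie in [0,1), got {par_i}")
    if not 0 < risk_allele_freq < 1:
        raise ValueError(
            f"risk allele frequency must lie in (0,1), got {risk_allele_freq}"
        )
    return par_i / ((1.0 - par_i) * risk_allele_freq) + 1.0


def split_par(par_total: float, n: int, scheme: str = "equal",
              seed: int = 0) -> np.ndarray:
    """Split a total population attributable risk over ``n`` loci.

    ``equal`` gives par_total / n everywhere; ``random`` draws a uniform
    point on the simplex (symmetric Dirichlet with concentration 1) scaled
    to the total, so the per-locus PARs are random but sum to par_total.
    """
    if not 0 <= par_total < 1:
        raise ValueError(f"total PAR must lie in [0,1), got {par_total}")
    if n < 1:
        raise ValueError("need at least one locus")
    if scheme == "equal":
        return np.full(n, par_total / n)
    if scheme == "random":
        if par_total == 0:
            return np.zeros(n)
        rng = substream(seed, "par-split")
        w = rng.dirichlet(np.ones(n))
        return w * par_total
    raise ValueError(f"scheme must be 'equal' or 'random', got {scheme!r}")


def assign_risk_flags(n: int, proportion_risk: float, seed: int = 0) -> np.ndarray:
    """Flag round(proportion_risk * n) loci, chosen uniformly, as risk
    (True); the rest are protective (False).  Deterministic given seed."""
    if not 0 <= proportion_risk <= 1:
        raise ValueError("proportion_risk must lie in [0, 1]")
    n_risk = int(np.floor(proportion_risk * n + 0.5))
    flags = np.zeros(n, dtype=bool)
    if n_risk:
        rng = substream(seed, "risk-flags")
        flags[rng.choice(n, size=n_risk, replace=False)] = True
    return flags


# ---------------------------------------------------------------------------
# Specs and resolved models
# ---------------------------------------------------------------------------

@dataclass
class DiseaseSpec:
    """User-facing disease model parameters (unresolved).

    For the logistic model exactly one of ``prevalence_K`` (alpha solved by
    bisection) or ``alpha`` must be given.  For the PAR model exactly one of
    ``par_total`` (split over loci), ``par_per_locus`` or ``fixed_grr``
    drives the relative risks.
    """

    causal_sites: list[int]
    mode: str = "additive"
    model: str = "logistic"
    # logistic
    beta: float | list[float] | None = None
    prevalence_K: float | None = None
    alpha: float | None = None
    epsilon: float = 0.001
    # PAR
    f0: float | None = None
    par_total: float | None = None
    par_scheme: str = "equal"
    par_per_locus: list[float] | None = None
    fixed_grr: float | None = None
    proportion_risk: float = 1.0
    risk_flags: list[bool] | None = None
    # conventions
    risk_allele: str = "derived"  # or "minor"
    dominant_het_single: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.model not in ("logistic", "par"):
            raise ValueError("model must be 'logistic' or 'par'")
        if self.risk_allele not in ("derived", "minor"):
            raise ValueError("risk_allele must be 'derived' or 'minor'")
        n = len(self.causal_sites)
        if self.model == "logistic":
            if self.beta is None and n > 0:
                raise ValueError("logistic model requires beta")
            if (self.prevalence_K is None) == (self.alpha is None):
                raise ValueError(
                    "logistic model needs exactly one of prevalence_K or alpha"
                )
            if self.prevalence_K is not None and not 0 < self.prevalence_K < 1:
                raise ValueError("prevalence_K must lie in (0,1)")
        else:
            if self.f0 is None or not 0 < self.f0 < 1:
                raise ValueError("PAR model requires baseline penetrance f0 in (0,1)")
            drivers = [self.par_total is not None, self.par_per_locus is not None,
                       self.fixed_grr is not None]
            if sum(drivers) != 1:
                raise ValueError(
                    "PAR model needs exactly one of par_total, par_per_locus "
                    "or fixed_grr"
                )
            if self.par_per_locus is not None and len(self.par_per_locus) != n:
                raise ValueError("par_per_locus must match the number of causal sites")
        if self.risk_flags is not None and len(self.risk_flags) != n:
            raise ValueError("risk_flags must match the number of causal sites")

    def beta_vector(self) -> np.ndarray:
        n = len(self.causal_sites)
        if self.beta is None:
            return np.zeros(n)
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if len(b) == 1 and n != 1:
            b = np.full(n, b[0])
        if len(b) != n:
            raise ValueError("beta must be scalar or one value per causal site")
        return b


@dataclass
class DiseaseModel:
    """A fully resolved penetrance model, ready to score genotypes.

    ``penetrance`` maps derived-allele counts at the causal sites (one row
    per individual) to affection probabilities.  ``risk_is_derived`` records,
    per locus, whether the risk allele is the derived allele; where it is
    not, counts are reflected (2 - c) before coding.
    """

    causal_sites: np.ndarray
    mode: str
    kind: str  # "logistic" | "par"
    alpha: float
    beta: np.ndarray  # log odds ratios; ln(GRR_eff) for the PAR model
    risk_is_derived: np.ndarray
    f0: float | None = None
    grr: np.ndarray | None = None  # effective GRRs (protective loci inverted)
    par_per_locus: np.ndarray | None = None
    risk_flags: np.ndarray | None = None
    dominant_het_single: bool = False
    n_penetrance_calls: int = field(default=0, compare=False)

    @property
    def n_loci(self) -> int:
        return len(self.causal_sites)

    def risk_counts(self, derived_counts) -> np.ndarray:
        c = np.asarray(derived_counts)
        if c.shape[-1] != self.n_loci:
            raise ValueError("count matrix width must equal the number of causal sites")
        return np.where(self.risk_is_derived, c, 2 - c)

    def coded(self, derived_counts) -> np.ndarray:
        return code_genotypes(self.risk_counts(derived_counts), self.mode,
                              self.dominant_het_single)

    def penetrance(self, derived_counts) -> np.ndarray:
        """Affection probability for derived-allele count vector(s)."""
        k = self.coded(derived_counts)
        self.n_penetrance_calls += 1
        return expit(self.alpha + k @ self.beta)


def random_mating_counts(
    pool: HaplotypePool, sites, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Derived-allele counts at ``sites`` for ``n`` random-mating individuals
    (two pool haplotypes drawn uniformly with replacement)."""
    sites = np.asarray(sites, dtype=np.int64)
    sub = pool.matrix[:, sites]
    h = rng.integers(0, pool.n_haplotypes, size=(n, 2))
    return sub[h[:, 0]].astype(np.int8) + sub[h[:, 1]].astype(np.int8)


def solve_alpha(
    pool: HaplotypePool,
    spec: DiseaseSpec,
    K: float,
    epsilon: float = 0.001,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Bisection search for the logistic intercept alpha in [-20, 20] such
    that the estimated prevalence satisfies |K_hat(alpha) - K| < epsilon.

    K_hat(alpha) is the mean penetrance over one fixed Monte-Carlo sample of
    ``n_mc`` random-mating genotype draws; reusing the same sample at every
    alpha makes K_hat a deterministic, monotone non-decreasing function, so
    bisection converges and the stopping rule is exact.
    """
    if not 0 < K < 1:
        raise ValueError("target prevalence K must lie in (0,1)")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    beta = spec.beta_vector()
    if len(spec.causal_sites) == 0:
        return float(logit(K))
    rng = substream(seed, "alpha-search")
    counts = random_mating_counts(pool, spec.causal_sites, n_mc, rng)
    risk_is_derived = _risk_is_derived(pool, spec)
    k = code_genotypes(np.where(risk_is_derived, counts, 2 - counts), spec.mode,
                       spec.dominant_het_single)
    s = k @ beta

    def k_hat(a: float) -> float:
        return float(expit(a + s).mean())

    lo, hi = ALPHA_LO, ALPHA_HI
    k_lo, k_hi = k_hat(lo), k_hat(hi)
    if not k_lo <= K <= k_hi:
        raise ValueError(
            f"target prevalence {K} unreachable for alpha in [{lo}, {hi}]: "
            f"K_hat({lo}) = {k_lo:.3g}, K_hat({hi}) = {k_hi:.3g}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        k_mid = k_hat(mid)
        if abs(k_mid - K) < epsilon:
            return mid
        if k_mid < K:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("alpha bisection failed to converge")


def prevalence_at_alpha(
    pool: HaplotypePool,
    spec: DiseaseSpec,
    alpha: float,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Prevalence estimate at a given intercept on the same fixed genotype
    sample used by :func:`solve_alpha` with the same seed -- for checking
    the bisection's stopping criterion after the fact."""
    if len(spec.causal_sites) == 0:
        return float(expit(alpha))
    rng = substream(seed, "alpha-search")
    counts = random_mating_counts(pool, spec.causal_sites, n_mc, rng)
    risk_is_derived = _risk_is_derived(pool, spec)
    k = code_genotypes(np.where(risk_is_derived, counts, 2 - counts), spec.mode,
                       spec.dominant_het_single)
    return float(expit(alpha + k @ spec.beta_vector()).mean())


def _risk_is_derived(pool: HaplotypePool, spec: DiseaseSpec) -> np.ndarray:
    sites = np.asarray(spec.causal_sites, dtype=np.int64)
    if spec.risk_allele == "derived":
        return np.ones(len(sites), dtype=bool)
    freqs = pool.frequencies()[sites]
    # minor allele is the risk allele; ties broken toward the derived allele
    return freqs <= 0.5


def build_disease_model(
    pool: HaplotypePool, spec: DiseaseSpec, seed: int = 0
) -> DiseaseModel:
    """Resolve a :class:`DiseaseSpec` against a pool into a scoring model.

    For the logistic model this solves alpha when a target prevalence was
    given.  For the PAR model it splits the total PAR, assigns risk/
    protective flags, converts PARs to genotypic relative risks from the
    risk-allele frequencies, and inverts the GRR at protective loci.
    """
    sites = np.asarray(spec.causal_sites, dtype=np.int64)
    n = len(sites)
    risk_is_derived = _risk_is_derived(pool, spec)
    if spec.model == "logistic":
        alpha = spec.alpha
        if alpha is None:
            alpha = solve_alpha(pool, spec, spec.prevalence_K, spec.epsilon,
                                seed=seed)
        return DiseaseModel(
            causal_sites=sites, mode=spec.mode, kind="logistic",
            alpha=float(alpha), beta=spec.beta_vector(),
            risk_is_derived=risk_is_derived,
            dominant_het_single=spec.dominant_het_single,
        )

    # PAR model
    freqs = pool.frequencies()[sites]
    risk_freq = np.where(risk_is_derived, freqs, 1.0 - freqs)
    if spec.risk_flags is not None:
        flags = np.asarray(spec.risk_flags, dtype=bool)
    else:
        flags = assign_risk_flags(n, spec.proportion_risk, seed)
    if spec.fixed_grr is not None:
        if spec.fixed_grr < 1:
            raise ValueError("fixed_grr must be >= 1 (protective loci are flagged)")
        grr = np.full(n, float(spec.fixed_grr))
        par = None
    else:
        if spec.par_per_locus is not None:
            par = np.asarray(spec.par_per_locus, dtype=float)
        else:
            par = split_par(spec.par_total, n, spec.par_scheme, seed)
        grr = np.array([par_to_grr(p, r) for p, r in zip(par, risk_freq)])
    grr_eff = np.where(flags, grr, 1.0 / grr)
    return DiseaseModel(
        causal_sites=sites, mode=spec.mode, kind="par",
        alpha=float(logit(spec.f0)), beta=np.log(grr_eff),
        risk_is_derived=risk_is_derived, f0=spec.f0, grr=grr_eff,
        par_per_locus=par, risk_flags=flags,
        dominant_het_single=spec.dominant_het_single,
    )


def population_prevalence(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_draws: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate (and standard error) of the population prevalence
    implied by a disease model: the mean penetrance over ``n_draws``
    random-mating individuals drawn from the pool."""
    rng = substream(seed, "prevalence")
    counts = random_mating_counts(pool, model.causal_sites, n_draws, rng)
    pen = model.penetrance(counts)
    k_hat = float(pen.mean())
    # SE of the mean affection indicator, not just of the mean penetrance
    se = float(np.sqrt(max(k_hat * (1 - k_hat), 0.0) / n_draws))
    return k_hat, se
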