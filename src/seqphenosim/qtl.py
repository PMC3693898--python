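"""Quantitative trait model.

A trait is Y = mu + sum_j G_j + P + E over M quantitative trait loci, where
G_j is the genotypic value at QTL j, P ~ Normal(0, V_poly) is a polygenic
component and E ~ Normal(0, V_E) is environmental noise with
V_E = V_P - sum_j V_Pj - V_poly.  Each QTL j explains a user-chosen fraction
f_j of the total phenotypic variance V_P (V_Pj = V_P * f_j); its genotypic
value a_j is backed out of V_Pj and the allele frequencies so that the
variance of the genotypic means over Hardy-Weinberg genotype frequencies is
exactly V_Pj:

    additive:  a_j = sqrt(V_Pj / (2 p q))
    dominant:  a_j = sqrt(V_Pj / (8 p q^3 + 4 p^2 q^2))
    recessive: a_j = sqrt(V_Pj / (8 p^3 q + 4 p^2 q^2))

with p the frequency of the minor allele A1 (the allele carrying the larger
trait value) and q = 1 - p.  The genotypic means for (A1A1, A1A2, A2A2) are
(a, 0, -a) additive, (a, a, -a) dominant and (a, -a, -a) recessive.

G_j is taken as the deterministic genotypic mean; the per-locus variance
V_Pj is the population variance induced by genotype frequencies rather than
individual-level noise, which would double-count variance (see the methods
note).  A ``literal_gj_noise`` switch adds Normal(0, V_Pj) noise per locus
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .pool import HaplotypePool

__all__ = [
    "QTLSpec",
    "TraitModel",
    "genotypic_value",
    "locus_mean",
    "build_trait_model",
    "sample_trait",
]

MODES = ("additive", "dominant", "recessive")


def genotypic_value(V_P: float, f_j: float, p_j: float, q_j: float,
                    mode: str) -> float:
    """Genotypic value a_j for a QTL explaining variance V_Pj = V_P * f_j at
    minor-allele frequency p_j (q_j = 1 - p_j)."""
    if V_P <= 0:
        raise ValueError("total phenotypic variance must be > 0")
    if f_j < 0:
        raise ValueError("variance fraction must be >= 0")
    if not (0 < p_j < 1) or abs(p_j + q_j - 1.0) > 1e-9:
        raise ValueError("allele frequencies must satisfy 0 < p < 1, p + q = 1")
    v = V_P * f_j
    if mode == "additive":
        denom = 2 * p_j * q_j
    elif mode == "dominant":
        denom = 8 * p_j * q_j**3 + 4 * p_j**2 * q_j**2
    elif mode == "recessive":
        denom = 8 * p_j**3 * q_j + 4 * p_j**2 * q_j**2
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return float(np.sqrt(v / denom))


def locus_mean(minor_allele_count: int, a_j: float, mode: str) -> float:
    """Genotypic mean mu_j for a genotype with the given count of the minor
    allele A1 (2 = A1A1, 1 = A1A2, 0 = A2A2)."""
    c = int(minor_allele_count)
    if c not in (0, 1, 2):
        raise ValueError(f"allele count must be 0, 1 or 2, got {c}")
    if mode == "additive":
        return float(a_j * (c - 1))
    if mode == "dominant":
        return float(a_j if c >= 1 else -a_j)
    if mode == "recessive":
        return float(a_j if c == 2 else -a_j)
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _locus_means(minor_counts: np.ndarray, a: np.ndarray, mode: str) -> np.ndarray:
    """Vectorized mu_j over an (n x M) matrix of minor-allele counts."""
    c = np.asarray(minor_counts)
    if mode == "additive":
        return a * (c - 1.0)
    if mode == "dominant":
        return np.where(c >= 1, a, -a)
    if mode == "recessive":
        return np.where(c == 2, a, -a)
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass
class QTLSpec:
    """User-facing quantitative trait parameters.

    ``f`` lists the fraction of V_P explained by each QTL.  The residual
    environmental variance V_P - sum(V_P * f) - V_poly must be non-negative;
    a violating spec is rejected at construction.
    """

    qtl_sites: list[int]
    mode: str = "additive"
    V_P: float = 1.0
    f: list[float] | None = None
    V_poly: float = 0.0
    mu: float = 0.0
    ascertain: str = "random"  # or "affected" (requires a disease spec)
    literal_gj_noise: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.V_P <= 0:
            raise ValueError("V_P must be > 0")
        if self.V_poly < 0:
            raise ValueError("V_poly must be >= 0")
        if self.f is None:
            self.f = [0.0] * len(self.qtl_sites)
        if len(self.f) != len(self.qtl_sites):
            raise ValueError("need one variance fraction per QTL site")
        if any(fj < 0 or fj >= 1 for fj in self.f):
            raise ValueError("variance fractions must lie in [0, 1)")
        if self.ascertain not in ("random", "affected"):
            raise ValueError("ascertain must be 'random' or 'affected'")
        if self.environmental_variance() < -1e-12:
            raise ValueError(
                "V_P - sum(V_Pj) - V_poly is negative: QTL variance fractions "
                "and polygenic variance exceed the total phenotypic variance"
            )

    def environmental_variance(self) -> float:
        return self.V_P - self.V_P * float(np.sum(self.f)) - self.V_poly


@dataclass
class TraitModel:
    """Resolved trait model: genotypic values plus variance components.

    ``minor_is_derived`` records, per QTL, whether the minor allele A1 is the
    pool's derived allele (ties at frequency 0.5 break toward derived);
    derived-allele counts are reflected where it is not.
    """

    qtl_sites: np.ndarray
    mode: str
    a: np.ndarray
    minor_is_derived: np.ndarray
    V_P: float
    V_Pj: np.ndarray
    V_poly: float
    V_E: float
    mu: float
    literal_gj_noise: bool = False

    def minor_counts(self, derived_counts) -> np.ndarray:
        c = np.asarray(derived_counts)
        if c.shape[-1] != len(self.qtl_sites):
            raise ValueError("count matrix width must equal the number of QTL")
        return np.where(self.minor_is_derived, c, 2 - c)

    def genetic_values(self, derived_counts) -> np.ndarray:
        """sum_j mu_j for each individual (rows of derived-allele counts)."""
        mus = _locus_means(self.minor_counts(derived_counts), self.a, self.mode)
        return mus.sum(axis=-1)


def build_trait_model(pool: HaplotypePool, spec: QTLSpec) -> TraitModel:
    """Resolve a :class:`QTLSpec` against a pool: determine each QTL's minor
    allele and genotypic value from its pool frequency."""
    sites = np.asarray(spec.qtl_sites, dtype=np.int64)
    freqs = pool.frequencies()[sites]
    minor_is_derived = freqs <= 0.5
    p = np.where(minor_is_derived, freqs, 1.0 - freqs)  # minor-allele freq
    a = np.array([
        genotypic_value(spec.V_P, fj, pj, 1.0 - pj, spec.mode)
        for fj, pj in zip(spec.f, p)
    ])
    v_pj = spec.V_P * np.asarray(spec.f, dtype=float)
    return TraitModel(
        qtl_sites=sites, mode=spec.mode, a=a, minor_is_derived=minor_is_derived,
        V_P=spec.V_P, V_Pj=v_pj, V_poly=spec.V_poly,
        V_E=max(spec.environmental_variance(), 0.0), mu=spec.mu,
        literal_gj_noise=spec.literal_gj_noise,
    )


def sample_trait(
    derived_counts,
    model: TraitModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Sample trait values Y = mu + sum_j G_j + P + E for individuals given
    their derived-allele counts at the QTL (one row per individual)."""
    if rng is None:
        rng = substream(0 if seed is None else seed, "trait")
    counts = np.atleast_2d(np.asarray(derived_counts))
    n = counts.shape[0]
    y = model.mu + model.genetic_values(counts)
    if model.literal_gj_noise:
        for v in model.V_Pj:
            if v > 0:
                y = y + rng.normal(0.0, np.sqrt(v), size=n)
    y = y + rng.normal(0.0, np.sqrt(model.V_poly), size=n) if model.V_poly > 0 else y
    y = y + rng.normal(0.0, np.sqrt(model.V_E), size=n) if model.V_E > 0 else y
    return np.asarray(y, dtype=float)
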