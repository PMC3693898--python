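"""Reference validation studies.

These bundle the simulator's components into the three end-to-end checks a
user of a phenotype simulator cares about: (1) the population prevalence
implied by the PAR disease model, (2) the accuracy of the logistic-model
intercept search, and (3) power and type-I error of the rare-variant score
test on simulated case-control data.  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import spawn_seed, substream
from .association import CaseControlScenario, PowerResult, TestRegion, estimate_rate
from .disease import (DiseaseSpec, build_disease_model, population_prevalence,
                      prevalence_at_alpha, solve_alpha)
from .genmap import fixed_map
from .pool import HaplotypePool, generate_block_pool, select_causal_sites

__all__ = [
    "implied_prevalence_study",
    "PowerStudy",
    "build_power_study",
    "alpha_search_study",
]


def implied_prevalence_study(
    f0: float,
    seed: int,
    par_total: float = 0.1,
    n_causal: int = 30,
    n_haplotypes: int = 2000,
    theta: float = 45.0,
    n_draws: int = 200_000,
) -> tuple[float, float]:
    """Population prevalence implied by the equal-split PAR model.

    A single-block coalescent pool of ``n_haplotypes`` sequences is
    generated, ``n_causal`` loci with MAF < 0.01 become risk variants under
    an additive PAR model with baseline penetrance ``f0`` and total PAR
    ``par_total`` split equally, and the prevalence is the mean penetrance
    over ``n_draws`` random-mating individuals.  Returns (estimate, SE).
    """
    pool = generate_block_pool(n_haplotypes, 1, theta,
                               seed=spawn_seed(seed, "prevalence-pool"))
    causal = select_causal_sites(pool, n_causal, (0.0, 0.01),
                                 seed=spawn_seed(seed, "prevalence-causal"))
    spec = DiseaseSpec(causal_sites=causal, mode="additive", model="par",
                       f0=f0, par_total=par_total)
    model = build_disease_model(pool, spec,
                                seed=spawn_seed(seed, "prevalence-model"))
    return population_prevalence(pool, model, n_draws,
                                 seed=spawn_seed(seed, "prevalence-mc"))


@dataclass
class PowerStudy:
    """A two-region case-control power study: one region holding the causal
    loci, one unlinked null region."""

    pool: HaplotypePool
    scenario: CaseControlScenario
    causal_region: TestRegion
    null_region: TestRegion

    def run(self, n_replicates: int, seed: int,
            alpha_level: float = 0.05) -> tuple[PowerResult, PowerResult]:
        power = estimate_rate(self.scenario, self.causal_region,
                              n_replicates, alpha_level,
                              seed=spawn_seed(seed, "power-reps"))
        type1 = estimate_rate(self.scenario, self.null_region,
                              n_replicates, alpha_level,
                              seed=spawn_seed(seed, "type1-reps"))
        return power, type1


def build_power_study(
    seed: int,
    n_haplotypes: int = 10_000,
    theta: float = 55.0,
    causal_region_size: int = 329,
    null_region_size: int = 355,
    n_causal: int = 30,
    f0: float = 0.1,
    par_total: float = 0.1,
    n_cases: int = 1000,
    n_controls: int = 1000,
    fast_mode: bool = True,
    pilot_cases: int = 100,
) -> PowerStudy:
    """Set up the two-region study: a coalescent pool over two unlinked
    blocks, the causal region trimmed to ``causal_region_size`` polymorphic
    sites (containing ``n_causal`` loci with MAF < 0.01 under an additive
    equal-split PAR model), the null region trimmed to
    ``null_region_size`` sites."""
    pool = generate_block_pool(n_haplotypes, 2, theta,
                               seed=spawn_seed(seed, "power-pool"))
    b0 = pool.sites_in_block(0)
    b1 = pool.sites_in_block(1)
    causal_region = tuple(int(i) for i in b0[:causal_region_size])
    null_region = tuple(int(i) for i in b1[:null_region_size])
    maf = pool.minor_allele_frequencies()
    rare_in_region = [i for i in causal_region if maf[i] < 0.01]
    rng = substream(seed, "power-causal")
    causal = sorted(int(i) for i in
                    rng.choice(rare_in_region, size=n_causal, replace=False))
    spec = DiseaseSpec(causal_sites=causal, mode="additive", model="par",
                       f0=f0, par_total=par_total)
    model = build_disease_model(pool, spec,
                                seed=spawn_seed(seed, "power-model"))
    rmap = fixed_map(0.5, 2, pool.block_centers_bp())
    scenario = CaseControlScenario(pool, model, n_cases, n_controls,
                                   rmap=rmap, fast_mode=fast_mode,
                                   pilot_cases=pilot_cases)
    return PowerStudy(pool, scenario,
                      TestRegion(causal_region, "causal"),
                      TestRegion(null_region, "null"))


def alpha_search_study(
    seed: int,
    n_configs: int = 20,
    targets: tuple[float, ...] = (0.05, 0.1, 0.2),
    epsilon: float = 0.001,
    n_mc: int = 200_000,
    n_haplotypes: int = 2000,
    theta: float = 45.0,
) -> float:
    """Maximum |K_hat(alpha) - K| over random logistic configurations.

    Each configuration draws 1-5 causal loci with MAF > 0.01 and per-locus
    log odds ratios uniform in [ln 1.2, ln 2]; alpha is solved by bisection
    on a fixed ``n_mc``-draw genotype sample and the prevalence re-evaluated
    at the returned alpha on the same sample.
    """
    pool = generate_block_pool(n_haplotypes, 1, theta,
                               seed=spawn_seed(seed, "alpha-pool"))
    maf = pool.minor_allele_frequencies()
    common = np.flatnonzero(maf > 0.01)
    rng = substream(seed, "alpha-configs")
    worst = 0.0
    for i in range(n_configs):
        K = targets[i % len(targets)]
        n_loci = int(rng.integers(1, 6))
        loci = sorted(int(s) for s in
                      rng.choice(common, size=n_loci, replace=False))
        beta = rng.uniform(np.log(1.2), np.log(2.0), size=n_loci).tolist()
        spec = DiseaseSpec(causal_sites=loci, model="logistic", beta=beta,
                           prevalence_K=K, epsilon=epsilon)
        cfg_seed = spawn_seed(seed, "alpha-config", i)
        alpha = solve_alpha(pool, spec, K, epsilon, n_mc, seed=cfg_seed)
        k_hat = prevalence_at_alpha(pool, spec, alpha, n_mc, seed=cfg_seed)
        worst = max(worst, abs(k_hat - K))
    return worst
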