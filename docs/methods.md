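# Methods

This note documents the models implemented in `seqphenosim`, the numerical
choices behind them, what the built-in data generator does and does not
emulate, and the design decisions taken where more than one reading was
defensible.

## Haplotype pool

The built-in generator produces, per block, one neutral coalescent genealogy
for a constant-size population (Hudson's algorithm: with `k` lineages the
waiting time to the next coalescence is exponential with rate `k(k−1)/2` in
units of 2N generations) and drops `Poisson(θ·L/2)` infinite-sites mutations
on the tree, `L` being the total branch length. This yields Watterson's
expectation `E[S] = θ Σ_{i=1}^{n−1} 1/i` segregating sites and the neutral
site-frequency spectrum, `P(derived count = i) ∝ 1/i`, which is what makes
the pool rich in rare variants: for 2000 haplotypes roughly 45% of sites
have MAF < 0.01. Mutations never produce monomorphic columns; ingested
pools have monomorphic columns dropped with a logged count. Sites get
distinct uniform-random bp positions inside a configurable per-block span
(default 10 kb), blocks laid end to end.

Blocks are **mutually independent genealogies**. Real adjacent blocks share
ancestry and are correlated at the population level; here linkage between
blocks enters only through the meioses simulated within the study (the
recombination map). This is a deliberate simplification: tests that rely on
between-block linkage disequilibrium existing *in the pool itself* are
outside what the generator emulates. Within a block, coalescent LD is fully
realistic (rare variants sit on few haplotype backgrounds).

Allele 1 is always the derived (mutant) allele and is the default risk /
trait-increasing candidate. A switch (`risk_allele="minor"`) instead treats
the minor allele as the risk allele, with counts reflected (`2 − c`) at
sites where the derived allele is the major one.

Seed policy: one master seed; every stochastic operation draws from an
independently keyed `numpy` `SeedSequence` substream (`_rng.substream`), so
results do not depend on execution order or worker count.

## Recombination map

Crossovers occur only between block centers: a gamete picks a starting
parental haplotype by fair coin and switches with probability `θᵢ` at each
interval, independently (no interference). Map distances use Haldane's
function `d_cM = −50 ln(1 − 2θ)` and its inverse; the round trip is exact to
1e−12 over `θ ∈ [0, 0.49]`.

Hotspot tables (`chrom start end rate_cM_Mb`) convert to per-interval `θ` by
summing `rate × width` over hotspots whose midpoint falls between two block
centers; the hotspot's own `end − start` width is used, which conserves the
table's total map length (the width convention is not otherwise pinned
down). Intervals spanning a chromosome boundary are forced to `θ = 0.5`.
Configured fractions above 0.5 are rejected with a message suggesting 0.5
(independent assortment) rather than silently clamped: a "recombination
fraction of 1" between two regions can only mean "unlinked".

## Disease models

Both penetrance models are computed on the log-odds scale; the PAR model is
the logistic model with `α = logit(f₀)` and `βᵢ = ln GRRᵢ`, which is exact
and numerically stable for large products of relative risks.

Genotype coding (shared by both models): additive → mutant-allele count
(0/1/2); dominant → 2 if any mutant allele else 0; recessive → 2 if
homozygous mutant else 0. Two consequences worth flagging:

- The dominant *heterozygote* therefore receives `GRR²` in the PAR model.
  An off-by-default switch (`dominant_het_single`) codes it as 1 instead,
  for users who want `GRR` per dominant genotype rather than per coded unit.
- The logistic model reuses the same coding, so a dominant `β` is the log
  odds ratio per coded unit (half the genotype effect), keeping `β`'s
  interpretation uniform across modes.

**Intercept search.** `K̂(α)` is estimated as the mean penetrance over one
fixed sample of 200,000 random-mating genotype draws (two pool haplotypes
with replacement). Using common random numbers across all `α` makes `K̂` a
deterministic, smooth, monotone non-decreasing function of `α`, so bisection
over `[−20, 20]` terminates with `|K̂(α) − K| < ε` exactly; unreachable
targets are reported with `K̂` at both endpoints. The default 200,000 draws
keep the Monte-Carlo standard error of `K̂` near 0.0007 for `K ≈ 0.1`, below
the default `ε = 0.001`.

**PAR model.** Per-locus PARs come from an equal split, a random split
(uniform on the simplex: symmetric Dirichlet with concentration 1, scaled to
the total), an explicit list, or a fixed GRR shared by all loci. Risk-allele
frequencies are taken from the pool, so `GRRᵢ = PARᵢ/((1−PARᵢ)Rᵢ) + 1`
assigns larger effects to rarer variants when PARs are equal. A configurable
fraction of loci is flagged protective (uniformly chosen,
`round(proportion·n)` of them) and uses `1/GRRᵢ`.

The population prevalence implied by the PAR model is not a user input; it
is estimated by Monte Carlo (mean penetrance over random-mating draws, with
a binomial standard error). For 30 equal-PAR rare loci with total PAR 0.1,
`f₀ = 0.1` implies a prevalence near 0.11 and `f₀ = 0.01` near 0.012 — the
product of per-locus expected odds factors is ≈ 1.2 in this regime.

## Quantitative traits

`Y = μ + Σⱼ Gⱼ + P + E`. The genotypic value formulas
(`aⱼ = √(V_Pj/2pq)` additive, `√(V_Pj/(8pq³+4p²q²))` dominant,
`√(V_Pj/(8p³q+4p²q²))` recessive, with `p` the minor-allele frequency) are
defined by the identity that the variance of the three genotypic means
`(aⱼ, 0, −aⱼ)` / `(aⱼ, aⱼ, −aⱼ)` / `(aⱼ, −aⱼ, −aⱼ)` over Hardy-Weinberg
genotype frequencies equals `V_Pj` exactly; the test suite asserts this to
1e−10 for all modes and random `p`.

`Gⱼ` is taken as the **deterministic** genotypic mean of the individual's
genotype. A literal reading in which `Gⱼ` is itself normal with variance
`V_Pj` *per individual* would add that variance on top of the
genotype-induced variance and push `Var(Y)` above `V_P`; the "variance
`V_Pj`" is the population variance induced by genotype frequencies, which
the `aⱼ` formulas already guarantee. The literal behavior is available
behind `literal_gj_noise` for comparison.

The genotypic contribution is not centered: the population mean of the
locus means is `a(p−q) ≠ 0` for an additive QTL, so `μ` is the general mean
*before* genotypic displacement. `V_E = V_P − Σ V_Pj − V_poly` must be
non-negative; a violating spec is rejected at construction, not at sampling.
Ties in minor-allele determination (frequency exactly 0.5) break toward the
derived allele. Note that the `Var(Y) = V_P` decomposition assumes QTL in
linkage equilibrium; QTL inside one block are correlated through coalescent
LD and the realized variance reflects those covariances.

## Cohorts

**Pedigree shape.** Twelve members in three generations: two grandparental
couples (4 founders), the father (child of couple A) and mother (child of
couple B), and six full siblings. No married-in spouses. Sibship size is
configurable; with `n_sibs ≠ 6` the family is no longer 12 members and the
member count is logged. Affection is assigned to every member by comparing
penetrance to a uniform draw, but only third-generation siblings count for
ascertainment (`≥ s` affected sibs, `s ∈ {1,2,3}` typically). Rejection
sampling aborts with the empirical acceptance rate after `1000 ×
n_families` consecutive rejections.

Because blocks recombine only at boundaries, every haplotype is represented
as a vector of pool-row indices, one per block; a Mendelian audit can verify
every non-founder haplotype decomposes into parental segments exactly.

**Unrelated individuals** are not drawn directly as founder haplotype
pairs. Cases and controls are defined as affected/unaffected
third-generation members of otherwise unascertained families, and the
package samples them as such, with a vectorized three-meiosis block mosaic.
The distinction matters: marginally, per block, a third-generation haplotype
is a uniform pool draw, but *jointly across unlinked blocks* it is a fresh
combination of independent pool rows, whereas a founder pair would carry one
pool row across all blocks. Conditioning cases on causal-block genotypes
would then drag each carrier row's entire genome along, duplicating
null-region haplotypes among cases and inflating the type-I error of
region tests on unlinked regions (observed: ~0.10 at nominal 0.05 with a
2000-row pool). The mosaic sampler restores the correct null behavior.

**Fast case sampler.** A pilot of `m` rejection-sampled cases (default 100)
gives the empirical conditional distribution of multilocus causal genotypes
`P(X | affected)`. Each fast case draws `X` from it, splits heterozygous
sites into two haplotype allele vectors by fair coins, and picks uniformly
among pool haplotypes matching each vector at the causal sites (phase
redrawn up to 64 times if unmatched, then `X` redrawn up to 1000 times, then
an error: pool and spec are inconsistent). Blocks without causal sites are
filled from an unconditional third-generation mosaic, for the same reason as
above. Fast cases are labeled affected without penetrance draws, so the cost
per case is independent of prevalence; the pilot's sampling error (at most
`m` distinct genotype patterns) is the price, and it slightly smooths the
case genotype distribution relative to exact rejection sampling.

**Thread invariance.** Candidate families are generated from substreams
keyed by a global attempt index and accepted in attempt order, so output is
byte-identical for any worker count under the same master seed.

## Score test

For genotype matrix `G` (derived-allele counts), binary phenotype `y`,
weights `wⱼ = Beta(1,25)` density at the sample MAF (the published default
for rare-variant variance-component tests):
`Q = (y − ȳ)ᵀ G W Gᵀ (y − ȳ)`, `W = diag(wⱼ²)`. The null distribution is
the mixture `Σ λⱼ χ²₁` with `λⱼ` the eigenvalues of
`σ² W^{1/2} Gcᵀ Gc W^{1/2}` (`Gc` column-centered, `σ² = ȳ(1−ȳ)`);
eigenvalues below 1e−10 of the maximum are discarded. The p-value uses the
moment-matching of Liu, Tang & Zhang (mean/variance matched exactly,
skewness when attainable, kurtosis otherwise) to a scaled noncentral
chi-square; a permutation mode (default 1000 phenotype permutations,
`p = (1 + #{Q* ≥ Q})/(1 + B)` so `p ∈ (0,1]`) is the assumption-free
fallback and agrees with the moment p-value to ~0.01 on null data. `Q = 0`
(e.g. an all-zero region) returns `p = 1`. Covariates are not supported.

## Validation studies and problem sizes

`seqphenosim.studies` fixes three end-to-end study configurations:

- *Implied prevalence*: 2000-haplotype single-block pool (θ = 45), 30
  causal sites with MAF < 0.01, additive equal-split PAR 0.1; prevalence
  from 200,000 random-mating draws.
- *Power / type-I error*: 10,000-haplotype two-block pool (θ = 55 per
  block, unlinked), causal region trimmed to its first 329 polymorphic
  sites (30 causal, MAF < 0.01, `f₀ = PAR = 0.1`, additive), null region
  trimmed to 355 sites; 1000 cases and 1000 controls per replicate, cases
  via the fast sampler with a 100-case pilot. The pool size is chosen so
  the MAF < 0.01 class spans ~100 distinct allele counts — small pools make
  case sampling reuse the few carrier haplotypes so heavily that region
  statistics saturate. The acceptance script runs 1000 replicates; the test
  suite runs 500.
- *Intercept search*: 20 random logistic configurations (1–5 loci with
  MAF > 0.01, per-locus β uniform in `[ln 1.2, ln 2]`, targets cycling
  through {0.05, 0.1, 0.2}), each solved with `ε = 0.001` on a fixed
  200,000-draw sample and re-evaluated on that sample.

## Known limitations

- No demographic history (growth, bottlenecks, migration), selection, or
  gene conversion in the built-in pool generator; use an external simulator
  and `read_pool` for those.
- Between-block LD exists only through within-study meioses (see above).
- One inheritance mode applies to all causal loci / QTL of a model.
- The PAR model's implied prevalence for very small `f₀` (≤ 0.001) is
  sensitive to the pool's frequency spectrum; only the `f₀ ∈ {0.1, 0.01}`
  regime is validated.
- No twins, half-sibs, arbitrary pedigrees, missing genotypes, or
  genotyping error; PLINK text output only (no binary bed/bim/fam).
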