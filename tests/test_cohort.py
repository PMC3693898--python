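"""Gene dropping, ascertainment and case-control samplers."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import seqphenosim as sps
from seqphenosim._rng import substream
from seqphenosim.cohort import (CaseFastSampler, _counts_from_mosaics,
                                ascertain, case_control_mosaics, draw_founder,
                                fit_case_conditional, genotype_matrix, meiosis,
                                simulate_families, simulate_family)
from seqphenosim.disease import build_disease_model


def mendelian_ok(ped, n_blocks):
    """Every non-founder haplotype decomposes into parental pool-row
    segments at block boundaries."""
    by_id = {m.individual_id: m for m in ped.members}
    for m in ped.members:
        if m.father_id == 0:
            continue
        pat, mat = by_id[m.father_id], by_id[m.mother_id]
        for b in range(n_blocks):
            if m.hap[0][b] not in (pat.hap[0][b], pat.hap[1][b]):
                return False
            if m.hap[1][b] not in (mat.hap[0][b], mat.hap[1][b]):
                return False
    return True


class TestMeiosis:
    def test_full_linkage_transmits_intact_haplotype(self, small_pool):
        rmap = sps.fixed_map(0.0, 3, small_pool.block_centers_bp())
        rng = substream(1, "m0")
        parent = draw_founder(small_pool, rng)
        for _ in range(20):
            g = meiosis(parent, rmap, rng)
            assert np.array_equal(g, parent[0]) or np.array_equal(g, parent[1])

    def test_recombinant_fraction_matches_theta(self, small_pool):
        """Adjacent-block switch frequency over many meioses equals theta
        within 3 binomial SE."""
        rmap = sps.fixed_map(0.2, 3, small_pool.block_centers_bp())
        rng = substream(2, "m2")
        parent = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int32)
        n = 10_000
        switches = np.empty((n, 2))
        for i in range(n):
            g = meiosis(parent, rmap, rng)
            switches[i] = np.abs(np.diff(g))
        se = np.sqrt(0.2 * 0.8 / n)
        assert np.all(np.abs(switches.mean(0) - 0.2) < 3 * se)

    def test_independent_assortment_at_half(self, small_pool):
        rmap = sps.fixed_map(0.5, 3, small_pool.block_centers_bp())
        rng = substream(3, "m5")
        parent = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int32)
        picks = np.array([meiosis(parent, rmap, rng) for _ in range(4000)])
        se = np.sqrt(0.25 / 4000)
        assert np.all(np.abs(picks.mean(0) - 0.5) < 4 * se)

    def test_block_mismatch_rejected(self, small_pool):
        rmap = sps.fixed_map(0.1, 2)
        parent = draw_founder(small_pool, substream(4, "m"))
        with pytest.raises(ValueError, match="blocks"):
            meiosis(parent, rmap, substream(4, "m"))


def test_founder_allele_frequencies_match_pool(small_pool):
    rng = substream(5, "founders")
    rows = rng.integers(0, small_pool.n_haplotypes, size=200_000)
    freqs = small_pool.matrix[rows].mean(0)
    pool_freqs = small_pool.frequencies()
    se = np.sqrt(pool_freqs * (1 - pool_freqs) / 200_000)
    assert np.all(np.abs(freqs - pool_freqs) < 4 * se)


class TestSimulateFamily:
    def _model(self, pool, alpha):
        spec = sps.DiseaseSpec(causal_sites=[0], model="logistic",
                               beta=[0.0], alpha=alpha)
        return build_disease_model(pool, spec)

    def test_forced_penetrance_affects_everyone(self, small_pool, small_rmap):
        model = self._model(small_pool, alpha=30.0)  # penetrance ~ 1
        ped = simulate_family(small_pool, small_rmap, model, seed=1)
        assert all(m.affected == 2 for m in ped.members)

    def test_structure_and_mendelian_audit(self, small_pool, small_rmap):
        model = self._model(small_pool, alpha=0.0)
        for seed in range(50):
            ped = simulate_family(small_pool, small_rmap, model, seed=seed)
            assert len(ped.members) == 12
            assert [m.individual_id for m in ped.founders] == [1, 2, 3, 4]
            assert mendelian_ok(ped, small_pool.n_blocks)

    def test_trait_only_family(self, small_pool, small_rmap):
        qtl = sps.select_causal_sites(small_pool, 2, (0.1, 0.5), seed=1)
        spec = sps.QTLSpec(qtl_sites=qtl, f=[0.05, 0.05], V_P=1.0)
        trait = sps.build_trait_model(small_pool, spec)
        ped = simulate_family(small_pool, small_rmap, trait=trait, seed=2)
        assert all(m.affected == 0 for m in ped.members)
        assert all(isinstance(m.trait, float) for m in ped.members)

    def test_requires_some_model(self, small_pool, small_rmap):
        with pytest.raises(ValueError):
            simulate_family(small_pool, small_rmap, seed=1)


class TestAscertain:
    def _ped_with_affected_sibs(self, small_pool, small_rmap, k):
        spec = sps.DiseaseSpec(causal_sites=[0], model="logistic",
                               beta=[0.0], alpha=-30.0)
        model = build_disease_model(small_pool, spec)
        ped = simulate_family(small_pool, small_rmap, model, seed=3)
        for s in ped.sibs[:k]:
            s.affected = 2
        return ped

    def test_boundaries(self, small_pool, small_rmap):
        ped = self._ped_with_affected_sibs(small_pool, small_rmap, 2)
        assert not ascertain(self._ped_with_affected_sibs(
            small_pool, small_rmap, 0), 1)
        assert ascertain(ped, 2)
        assert not ascertain(ped, 3)


class TestSimulateFamilies:
    def _model(self, pool, K=0.25):
        spec = sps.DiseaseSpec(causal_sites=[0], model="logistic",
                               beta=[0.3], prevalence_K=K)
        return build_disease_model(pool, spec, seed=6)

    def test_all_returned_families_pass_ascertainment(self, small_pool,
                                                      small_rmap):
        model = self._model(small_pool)
        peds = simulate_families(small_pool, small_rmap, model, n_families=30,
                                 required_affected_sibs=2, seed=7)
        assert len(peds) == 30
        assert all(ascertain(p, 2) for p in peds)

    def test_worker_count_does_not_change_output(self, small_pool, small_rmap):
        model = self._model(small_pool)
        runs = [
            simulate_families(small_pool, small_rmap, model, n_families=12,
                              required_affected_sibs=1, seed=8, n_workers=w)
            for w in (1, 2, 8)
        ]
        for other in runs[1:]:
            for a, b in zip(runs[0], other):
                assert a.family_id == b.family_id
                for ma, mb in zip(a.members, b.members):
                    assert np.array_equal(ma.hap, mb.hap)
                    assert ma.affected == mb.affected

    def test_random_ascertainment_accepts_everything(self, small_pool,
                                                     small_rmap):
        qtl = sps.select_causal_sites(small_pool, 1, (0.1, 0.5), seed=2)
        trait = sps.build_trait_model(
            small_pool, sps.QTLSpec(qtl_sites=qtl, f=[0.1], V_P=1.0))
        peds, stats = simulate_families(
            small_pool, small_rmap, trait=trait, n_families=10, seed=9,
            ascertain_random=True, return_stats=True)
        assert len(peds) == 10
        assert stats["n_attempts"] == 10

    def test_acceptance_rate_matches_brute_force(self, small_pool, small_rmap):
        """The rejection sampler's acceptance rate equals the brute-force
        fraction of unascertained families with >= 1 affected sib."""
        model = self._model(small_pool, K=0.15)
        raw, _ = simulate_families(small_pool, small_rmap, model,
                                   n_families=600, seed=10,
                                   ascertain_random=True, return_stats=True)
        brute = np.mean([ascertain(p, 1) for p in raw])
        _, stats = simulate_families(small_pool, small_rmap, model,
                                     n_families=200, required_affected_sibs=1,
                                     seed=11, return_stats=True)
        rate = stats["acceptance_rate"]
        se = np.sqrt(brute * (1 - brute) * (1 / 600 + 1 / stats["n_attempts"]))
        assert abs(rate - brute) < 3 * se

    def test_hopeless_ascertainment_aborts(self, small_pool, small_rmap):
        spec = sps.DiseaseSpec(causal_sites=[0], model="logistic",
                               beta=[0.0], alpha=-30.0)  # penetrance ~ 0
        model = build_disease_model(small_pool, spec)
        with pytest.raises(RuntimeError, match="ascertainment"):
            simulate_families(small_pool, small_rmap, model, n_families=2,
                              required_affected_sibs=1, seed=12)


@pytest.fixture(scope="module")
def single_locus_model(rare_pool):
    maf = rare_pool.minor_allele_frequencies()
    site = int(np.flatnonzero((maf > 0.25) & (maf < 0.35))[0])
    spec = sps.DiseaseSpec(causal_sites=[site], model="logistic",
                           beta=[np.log(2)], alpha=float(np.log(1 / 9)))
    return build_disease_model(rare_pool, spec), site


class TestCaseControlSampling:

    def _bayes_expected(self, pool, model, site, affected):
        p = pool.frequencies()[site]
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        pen = model.penetrance(np.arange(3).reshape(-1, 1))
        weight = pen if affected else 1 - pen
        probs = hwe * weight
        return probs / probs.sum()

    @pytest.mark.parametrize("affected", [True, False])
    def test_genotype_frequencies_match_bayes_rule(self, rare_pool,
                                                   single_locus_model,
                                                   affected):
        """Sampled case (control) genotype frequencies at the causal locus
        match P(g) P(D|g) / K (and its complement) from direct enumeration
        over the three genotypes."""
        model, site = single_locus_model
        n = 10_000
        mosaics, _ = case_control_mosaics(
            rare_pool, model, n if affected else 0, 0 if affected else n,
            seed=13)
        counts = _counts_from_mosaics(rare_pool, mosaics, [site])[:, 0]
        obs = np.bincount(counts, minlength=3) / n
        exp = self._bayes_expected(rare_pool, model, site, affected)
        se = np.sqrt(exp * (1 - exp) / n)
        assert np.all(np.abs(obs - exp) < 3 * se + 1e-9)

    def test_degenerate_penetrance_case_is_immediate(self, rare_pool):
        spec = sps.DiseaseSpec(causal_sites=[0], model="logistic",
                               beta=[0.0], alpha=30.0)
        model = build_disease_model(rare_pool, spec)
        ind = sps.simulate_case_rejection(rare_pool, model, substream(1, "c"))
        assert ind.affected == 2

    def test_impossible_case_aborts(self, rare_pool):
        spec = sps.DiseaseSpec(causal_sites=[0], model="logistic",
                               beta=[0.0], alpha=-37.0)  # penetrance ~ 1e-16
        model = build_disease_model(rare_pool, spec)
        with pytest.raises(RuntimeError, match="attempts"):
            case_control_mosaics(rare_pool, model, 10, 0, seed=1)


class TestFastCaseSampler:
    def test_conditional_distribution_normalizes(self):
        pilot = np.array([[0, 1], [0, 1], [2, 0]])
        cond = fit_case_conditional(pilot)
        assert cond.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(cond.genotypes) == 2

    def test_point_mass_pilot(self):
        cond = fit_case_conditional(np.tile([1, 0, 2], (5, 1)))
        assert len(cond.genotypes) == 1
        assert cond.probabilities[0] == 1.0

    def test_sampled_haplotypes_consistent_with_genotype(self, rare_pool,
                                                         par_model):
        """Homozygous-derived causal genotypes force both sampled haplotypes
        to carry the derived allele at that site."""
        site = int(par_model.causal_sites[0])
        cond = fit_case_conditional(np.array([[2] + [0] * 29]))
        sampler = CaseFastSampler(rare_pool, par_model.causal_sites, cond)
        pairs = sampler.sample_pairs(20, substream(2, "fc"))
        col = rare_pool.matrix[:, site]
        assert np.all(col[pairs[:, 0, 0]] == 1)
        assert np.all(col[pairs[:, 1, 0]] == 1)

    def test_fast_cases_reproduce_pilot_conditional(self, rare_pool, par_model):
        """The causal-genotype distribution of fast-sampled cases matches the
        pilot conditional distribution (chi-square)."""
        pilot_mosaics, _ = case_control_mosaics(rare_pool, par_model, 400, 0,
                                                seed=14)
        pilot = _counts_from_mosaics(rare_pool, pilot_mosaics,
                                     par_model.causal_sites)
        cond = fit_case_conditional(pilot)
        sampler = CaseFastSampler(rare_pool, par_model.causal_sites, cond)
        pairs = sampler.sample_pairs(8000, substream(4, "fc2"))
        sub = rare_pool.matrix[:, par_model.causal_sites]
        drawn = sub[pairs[:, 0, 0]] + sub[pairs[:, 1, 0]]
        # compare causal-burden (sum of causal alleles) distributions
        top = max(drawn.sum(1).max(), pilot.sum(1).max()) + 1
        tab = np.vstack([np.bincount(drawn.sum(1), minlength=top),
                         np.bincount(pilot.sum(1), minlength=top)])
        tab = tab[:, tab.sum(0) >= 10]
        chi2, p, *_ = chi2_contingency(tab)
        assert p > 0.01

    def test_fast_and_rejection_cases_agree(self, rare_pool, par_model):
        """With a large pilot, fast-mode and rejection-mode cases have the
        same causal-burden distribution (chi-square, alpha = 0.01)."""
        fast, _ = case_control_mosaics(rare_pool, par_model, 6000, 0,
                                       fast_mode=True, pilot_cases=10_000,
                                       seed=15)
        rej, _ = case_control_mosaics(rare_pool, par_model, 6000, 0,
                                      fast_mode=False, seed=16)
        b_fast = _counts_from_mosaics(rare_pool, fast,
                                      par_model.causal_sites).sum(1)
        b_rej = _counts_from_mosaics(rare_pool, rej,
                                     par_model.causal_sites).sum(1)
        top = max(b_fast.max(), b_rej.max()) + 1
        tab = np.vstack([np.bincount(b_fast, minlength=top),
                         np.bincount(b_rej, minlength=top)])
        tab = tab[:, tab.sum(0) >= 10]
        chi2, p, *_ = chi2_contingency(tab)
        assert p > 0.01

    def test_no_penetrance_draws_after_pilot(self, rare_pool, par_model):
        """Fast-mode cost is prevalence-independent: zero penetrance
        evaluations once the pilot conditional is fitted."""
        pilot_mosaics, _ = case_control_mosaics(rare_pool, par_model, 100, 0,
                                                seed=17)
        pilot = _counts_from_mosaics(rare_pool, pilot_mosaics,
                                     par_model.causal_sites)
        sampler = CaseFastSampler(rare_pool, par_model.causal_sites,
                                  fit_case_conditional(pilot))
        before = par_model.n_penetrance_calls
        sampler.sample_pairs(500, substream(5, "fc3"))
        assert par_model.n_penetrance_calls == before


def test_genotype_matrix_roundtrip(small_pool, small_rmap):
    spec = sps.DiseaseSpec(causal_sites=[0], model="logistic", beta=[0.0],
                           alpha=0.0)
    model = build_disease_model(small_pool, spec)
    ped = simulate_family(small_pool, small_rmap, model, seed=20)
    G = genotype_matrix(ped.members, small_pool)
    assert G.shape == (12, small_pool.n_sites)
    # founders carry their pool rows verbatim
    f = ped.members[0]
    expected = (small_pool.matrix[f.hap[0][0]].astype(int)
                + small_pool.matrix[f.hap[1][0]].astype(int))
    blocks_equal = small_pool.block_ids == 0
    assert np.array_equal(G[0][blocks_equal], expected[blocks_equal])
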