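"""Trait-level GRS methods: clumping, SBLUP, SBayesR, and cohort scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metagrs import (ArchitectureConfig, LDBlockMatrix, OverlapError,
                     SBayesRConfig, SumStatsTable, ValidationError,
                     WeightVector, clump, sblup, sbayesr, score_cohort,
                     simulate_effect_matrix, simulate_genotypes,
                     simulate_phenotypes, run_gwas)
from metagrs.grs import ld_block_matrix
from metagrs.simulate import GenotypeMatrix
from metagrs.sumstats import Variant


def _table_from(variants, beta, se=0.05, p=None, n=1000, eaf=0.3):
    m = len(variants)
    beta = np.asarray(beta, float)
    se = np.broadcast_to(np.asarray(se, float), (m,))
    if p is None:
        p = 2 * stats.norm.sf(np.abs(beta / se))
    return SumStatsTable(pd.DataFrame({
        "variant_id": [v.id for v in variants],
        "chromosome": [v.chrom for v in variants],
        "base_pair_location": [v.pos for v in variants],
        "effect_allele": [v.effect_allele for v in variants],
        "other_allele": [v.other_allele for v in variants],
        "beta": beta, "standard_error": se,
        "p_value": np.clip(p, 1e-300, 1.0), "n": n,
        "effect_allele_frequency": np.broadcast_to(eaf, (m,)),
    }), trait="toy")


def _variants(m):
    return [Variant(f"rs{j + 1}", "1", 100 * (j + 1), "A", "G")
            for j in range(m)]


def _one_block_ld(m, R):
    return LDBlockMatrix(_variants(m), [(np.arange(m), np.asarray(R))], 1000)


class TestClump:
    def test_no_ld_keeps_all_below_p_threshold(self):
        v = _variants(5)
        t = _table_from(v, [0.3, 0.2, 0.1, 0.05, 0.01],
                        p=[1e-8, 1e-6, 1e-4, 0.04, 0.5])
        ld = _one_block_ld(5, np.eye(5))
        wv = clump(t, ld, r2_threshold=0.1, p_threshold=0.05)
        assert list(wv.df["variant_id"]) == ["rs1", "rs2", "rs3", "rs4"]
        assert np.allclose(wv.df["weight"], [0.3, 0.2, 0.1, 0.05])

    def test_correlated_pair_keeps_smaller_p(self):
        v = _variants(2)
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        t = _table_from(v, [0.2, 0.1], p=[1e-8, 1e-4])
        wv = clump(t, _one_block_ld(2, R), r2_threshold=0.1)
        assert list(wv.df["variant_id"]) == ["rs1"]

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            m = 8
            A = rng.standard_normal((m + 4, m))
            R = np.corrcoef(A, rowvar=False)
            p = rng.random(m)
            v = _variants(m)
            t = _table_from(v, rng.standard_normal(m), p=p)
            ld = _one_block_ld(m, R)
            thr = 0.3
            wv = clump(t, ld, r2_threshold=thr)
            # oracle: literal greedy over p-sorted variants
            order = sorted(range(m), key=lambda j: (p[j], v[j].id))
            alive = [True] * m
            expect = []
            for j in order:
                if not alive[j]:
                    continue
                expect.append(v[j].id)
                alive[j] = False
                for k in range(m):
                    if alive[k] and R[j, k] ** 2 >= thr:
                        alive[k] = False
            assert sorted(wv.df["variant_id"]) == sorted(expect)

    def test_no_retained_pair_exceeds_r2_threshold(self, small_cohort):
        t, ld = small_cohort["sumstats"], small_cohort["ld"]
        for thr in (0.05, 0.2, 0.5):
            wv = clump(t, ld, r2_threshold=thr)
            kept = set(wv.df["variant_id"])
            for ix, R in ld.blocks:
                ids = [ld.variants[j].id for j in ix]
                for a in range(len(ix)):
                    for b in range(a + 1, len(ix)):
                        if ids[a] in kept and ids[b] in kept:
                            assert R[a, b] ** 2 < thr

    def test_invalid_threshold_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            clump(small_cohort["sumstats"], small_cohort["ld"], 0.0)


class TestSblup:
    def test_identity_ld_closed_form(self):
        v = _variants(3)
        t = _table_from(v, [0.2, -0.1, 0.05], n=1000, eaf=0.5)
        wv = sblup(t, _one_block_ld(3, np.eye(3)), h2=0.5, m_total=3)
        lam = 3 * (1 / 0.5 - 1)
        sd = np.sqrt(2 * 0.5 * 0.5)
        expect = np.array([0.2, -0.1, 0.05]) * sd * 1000 / (1000 + lam) / sd
        assert np.allclose(wv.df["weight"], expect, atol=1e-12)

    def test_h2_to_one_limit_returns_marginals(self):
        v = _variants(3)
        t = _table_from(v, [0.2, -0.1, 0.05], eaf=0.5)
        wv = sblup(t, _one_block_ld(3, np.eye(3)), h2=1 - 1e-12)
        assert np.allclose(wv.df["weight"], [0.2, -0.1, 0.05], atol=1e-6)

    def test_two_variant_block_matches_direct_solve(self):
        v = _variants(2)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        t = _table_from(v, [0.2, 0.1], n=1000, eaf=0.5)
        # pick h2 so that lambda = 500 with m_total = 2
        h2 = 2 / (2 + 500)
        wv = sblup(t, _one_block_ld(2, R), h2=h2, m_total=2)
        sd = np.sqrt(2 * 0.5 * 0.5)
        beta_std = np.array([0.2, 0.1]) * sd
        b = np.linalg.solve(1000 * R + 500 * np.eye(2), 1000 * beta_std)
        assert np.allclose(wv.df["weight"], b / sd, atol=1e-12)

    def test_invalid_h2_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            sblup(small_cohort["sumstats"], small_cohort["ld"], h2=1.5)


class TestSBayesR:
    def test_null_mixture_gives_zero_weights(self):
        v = _variants(5)
        t = _table_from(v, [0.1, 0.2, -0.1, 0.05, 0.0], eaf=0.5)
        cfg = SBayesRConfig(pi=(1.0, 0.0, 0.0, 0.0), iterations=50,
                            burn_in=10, update_pi=False,
                            update_sigma_beta=False, seed=0)
        wv = sbayesr(t, _one_block_ld(5, np.eye(5)), cfg)
        assert np.allclose(wv.df["weight"], 0.0)

    def test_single_variant_posterior_matches_mixture_closed_form(self):
        # fixed pi and sigma_beta2: the exact posterior is a discrete mixture
        # of normals; its mean is available in closed form
        beta_hat_std, n, sigma_b2 = 0.08, 5000.0, 0.01
        pi = np.array([0.5, 0.2, 0.2, 0.1])
        gamma = np.array([0.0, 0.01, 0.1, 1.0])
        psi = gamma[1:] * sigma_b2
        vtil = 1.0 / (n + 1.0 / psi)
        mu = vtil * n * beta_hat_std
        logw = np.log(pi[1:]) + 0.5 * np.log(vtil / psi) + mu**2 / (2 * vtil)
        logw = np.concatenate([[np.log(pi[0])], logw])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        exact_mean = float((w[1:] * mu).sum())

        v = _variants(1)
        t = _table_from(v, [beta_hat_std * np.sqrt(2)], n=int(n), eaf=0.5)
        # eaf 0.5 -> sd = sqrt(0.5): dosage beta = std beta / sd
        t.df["beta"] = beta_hat_std / np.sqrt(0.5)
        cfg = SBayesRConfig(pi=tuple(pi), sigma_beta2=sigma_b2,
                            iterations=4000, burn_in=500, update_pi=False,
                            update_sigma_beta=False, seed=3)
        wv = sbayesr(t, _one_block_ld(1, np.eye(1)), cfg)
        got_std = wv.df["weight"].iloc[0] * np.sqrt(0.5)
        # Monte-Carlo error of the posterior mean over ~3500 draws
        mc_se = np.sqrt(vtil.max() + mu.max() ** 2) / np.sqrt(3500 / 10)
        assert abs(got_std - exact_mean) < 3 * mc_se

    def test_null_statistics_are_shrunk(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = 50
            v = _variants(m)
            se = 0.05
            beta = rng.normal(0, se, m)
            t = _table_from(v, beta, se=se, n=400, eaf=0.5)
            cfg = SBayesRConfig(iterations=100, burn_in=20, seed=seed)
            wv = sbayesr(t, _one_block_ld(m, np.eye(m)), cfg)
            assert np.mean(np.abs(wv.df["weight"])) < np.mean(np.abs(beta))

    def test_seeded_determinism(self, small_cohort):
        cfg = SBayesRConfig(iterations=30, burn_in=5, seed=9)
        w1 = sbayesr(small_cohort["sumstats"], small_cohort["ld"], cfg)
        w2 = sbayesr(small_cohort["sumstats"], small_cohort["ld"], cfg)
        assert np.array_equal(w1.df["weight"], w2.df["weight"])

    def test_non_ascending_gamma_rejected(self):
        with pytest.raises(ValidationError):
            SBayesRConfig(gamma=(0.0, 0.1, 0.05, 1.0))


class TestPredictionOrdering:
    def test_sbayesr_ge_sblup_ge_clump(self):
        # polygenic architecture: joint-effect methods should not lose to
        # marginal clumping (small tolerance for Monte-Carlo noise)
        cors = {"clump": [], "sblup": [], "sbayesr": []}
        for seed in range(3):
            cfg = ArchitectureConfig(n_traits=1, h2=np.array([0.4]),
                                     rg=np.eye(1), causal_fraction=0.3,
                                     seed=seed)
            g = simulate_genotypes(4000, 600, 60, (0.1, 0.5),
                                   within_block_r=0.5, seed=seed)
            eff = simulate_effect_matrix(g.variants, cfg)
            ph = simulate_phenotypes(g, eff, cfg, seed=seed)
            ss = run_gwas(g, ph.traits[:, 0])
            ld = ld_block_matrix(g)
            gv = simulate_genotypes(3000, 600, 60, seed=seed + 500,
                                    population=g.population)
            phv = simulate_phenotypes(gv, eff, cfg, seed=seed + 500)
            truth = phv.genetic_values[:, 0]
            best_clump = max(
                np.corrcoef(score_cohort(gv, clump(ss, ld, r2)), truth)[0, 1]
                for r2 in (0.01, 0.1, 0.4))
            cors["clump"].append(best_clump)
            cors["sblup"].append(np.corrcoef(
                score_cohort(gv, sblup(ss, ld, 0.4)), truth)[0, 1])
            cors["sbayesr"].append(np.corrcoef(score_cohort(
                gv, sbayesr(ss, ld, SBayesRConfig(iterations=200, burn_in=50,
                                                  seed=seed))), truth)[0, 1])
        sb, bl, cl = (np.mean(cors[k]) for k in ("sbayesr", "sblup", "clump"))
        assert sb >= bl - 0.02
        assert bl >= cl - 0.02


class TestScoreCohort:
    def _geno(self, dosages, variants=None):
        dosages = np.asarray(dosages, float)
        m = dosages.shape[1]
        v = variants or _variants(m)
        return GenotypeMatrix([f"S{i}" for i in range(len(dosages))], v,
                              dosages, np.zeros(m, int))

    def _wv(self, variants, weights):
        return WeightVector(pd.DataFrame({
            "variant_id": [v.id for v in variants],
            "chromosome": [v.chrom for v in variants],
            "base_pair_location": [v.pos for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
            "weight": weights}))

    def test_zero_dosages_zero_scores(self):
        g = self._geno(np.zeros((3, 2)))
        wv = self._wv(g.variants, [0.5, -0.2])
        assert np.allclose(score_cohort(g, wv), 0.0)

    def test_single_variant_hand_value(self):
        g = self._geno([[2.0]])
        wv = self._wv(g.variants, [0.5])
        assert score_cohort(g, wv)[0] == pytest.approx(1.0)

    def test_mean_impute_uses_two_eaf(self):
        # empirical EAF 0.25 from observed dosages; missing -> 2*0.25 = 0.5
        g = self._geno([[np.nan], [1.0], [0.0], [1.0], [0.0]])
        wv = self._wv(g.variants, [0.8])
        s = score_cohort(g, wv, missing_policy="mean_impute")
        assert s[0] == pytest.approx(0.5 * 0.8)

    def test_skip_renormalize_rescales_by_count(self):
        g = self._geno([[1.0, np.nan], [1.0, 1.0]])
        wv = self._wv(g.variants, [0.5, 0.5])
        s = score_cohort(g, wv, missing_policy="skip_renormalize")
        assert s[0] == pytest.approx(0.5 * 2 / 1)
        assert s[1] == pytest.approx(1.0)

    def test_allele_flip_invariance_on_standardized_scores(self):
        g = simulate_genotypes(300, 20, 4, seed=8)
        rng = np.random.default_rng(8)
        w = rng.standard_normal(20)
        wv = self._wv(g.variants, w)
        s1 = score_cohort(g, wv)
        flipped = wv.df.copy()
        flip = rng.random(20) < 0.5
        ea = flipped["effect_allele"].to_numpy().copy()
        flipped.loc[flip, "effect_allele"] = flipped.loc[flip, "other_allele"]
        flipped.loc[flip, "other_allele"] = ea[flip]
        flipped.loc[flip, "weight"] *= -1
        s2 = score_cohort(g, WeightVector(flipped))
        z = lambda x: (x - x.mean()) / x.std()
        assert np.allclose(z(s1), z(s2), atol=1e-10)

    def test_no_overlap_raises_with_report(self):
        g = self._geno([[1.0]])
        other = [Variant("rsX", "2", 5, "A", "G")]
        wv = self._wv(other, [1.0])
        with pytest.raises(OverlapError, match="overlap"):
            score_cohort(g, wv)
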