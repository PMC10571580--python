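"""BayesB mixture prior, Bayes factors and window-variance inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import matqg as m
from matqg.geno_qc import Window
from matqg.mgwa import BayesBResult, MGWAError


class TestPi:
    def test_study_scale_value(self):
        assert m.compute_pi(349, 88_512) == 0.9987

    def test_formula_arithmetic(self):
        assert m.compute_pi(300, 3000) == 0.9667

    def test_too_few_snps_rejected(self):
        with pytest.raises(MGWAError, match="outside"):
            m.compute_pi(3, 1)


class TestEffectVariance:
    def test_uniform_frequency_arithmetic(self):
        p = np.full(88_512, 0.25)
        v = m.derive_effect_variance(1.0, 0.9987, p)
        assert v == pytest.approx(1.0 / (0.0013 * 33_192.0), rel=1e-6)

    def test_zero_genetic_variance(self):
        assert m.derive_effect_variance(0.0, 0.99, np.array([0.3])) == 0.0

    def test_linearity(self):
        p = np.random.default_rng(0).uniform(0.05, 0.5, 100)
        v1 = m.derive_effect_variance(1.0, 0.99, p)
        v2 = m.derive_effect_variance(2.0, 0.99, p)
        assert v2 == pytest.approx(2 * v1)

    def test_fixed_alleles_rejected(self):
        with pytest.raises(MGWAError, match="fixed"):
            m.derive_effect_variance(1.0, 0.99, np.array([0.0, 1.0]))


class TestBayesFactor:
    def test_posterior_equal_prior_gives_unity(self):
        pi = 0.9987
        assert m.compute_bayes_factor(1 - pi, pi) == pytest.approx(1.0)

    def test_threshold_solves_to_known_p_hat(self):
        pi = 0.9987
        assert m.compute_bayes_factor(0.0129, pi) > 10
        assert m.compute_bayes_factor(0.0128, pi) < 10

    def test_zero_and_one_limits(self):
        assert m.compute_bayes_factor(0.0, 0.99) == 0.0
        assert np.isinf(m.compute_bayes_factor(1.0, 0.99))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.01, 0.98), st.floats(0.011, 0.99))
    def test_monotone_in_inclusion_probability(self, p1, dp):
        p2 = min(p1 + dp * (1 - p1), 0.999999)
        pi = 0.97
        assert m.compute_bayes_factor(p2, pi) > m.compute_bayes_factor(p1, pi)


def micro_dataset(seed=0, k=20, qtl_col=3, alpha=1.0):
    rng = np.random.default_rng(seed)
    n_dams, per = 50, 4
    n = n_dams * per
    codes = rng.binomial(2, 0.4, size=(n_dams, k)).astype(np.int8)
    gm = m.GenotypeMatrix(codes, [f"D{i}" for i in range(n_dams)],
                          [f"s{j}" for j in range(k)])
    dam = np.repeat(np.arange(n_dams), per)
    y = alpha * codes[dam, qtl_col] + rng.normal(0, 1, n)
    df = pd.DataFrame({
        "animal": [f"O{i}" for i in range(n)],
        "dam": [f"D{d}" for d in dam],
        "litter": "x",
        "sex": rng.integers(2, size=n),
        "y": y,
    })
    return m.PhenotypeTable(df, ["y"], ["sex"]), gm


class TestRunBayesB:
    def test_planted_qtl_attains_maximum_inclusion(self):
        table, gm = micro_dataset()
        data = m.assign_dam_genotypes(table, gm, "y", fixed=("sex",))
        cfg = m.MGWAConfig(iterations=4000, burn_in=1000, thin=5, seed=2,
                           genetic_variance=0.5, pi=0.9)
        res = m.run_bayesb(data, gm, cfg)
        assert int(np.argmax(res.inclusion_prob)) == 3
        assert res.inclusion_prob[3] > 0.9
        assert res.effect_mean[3] == pytest.approx(1.0, abs=0.35)

    def test_constant_genotypes_return_prior_inclusion(self):
        table, gm = micro_dataset()
        gm = m.GenotypeMatrix(np.ones_like(gm.codes), gm.individuals, gm.markers)
        data = m.assign_dam_genotypes(table, gm, "y", fixed=("sex",))
        cfg = m.MGWAConfig(iterations=4000, burn_in=1000, thin=2, seed=3,
                           sigma2_alpha=0.1, pi=0.9)
        with pytest.warns(UserWarning, match="constant"):
            res = m.run_bayesb(data, gm, cfg)
        assert np.all(res.skipped)
        assert res.inclusion_prob.mean() == pytest.approx(0.1, abs=0.02)

    def test_missing_genotypes_rejected(self):
        table, gm = micro_dataset()
        gm.codes[0, 0] = m.MISSING
        data = m.assign_dam_genotypes(table, gm, "y", fixed=("sex",))
        with pytest.raises(MGWAError, match="missing"):
            m.run_bayesb(data, gm, m.MGWAConfig(iterations=100, burn_in=10,
                                                sigma2_alpha=0.1, pi=0.9))

    def test_default_chain_bookkeeping(self):
        cfg = m.MGWAConfig()
        assert m.n_retained(cfg.iterations, cfg.burn_in, cfg.thin) == 40_000

    def test_ungenotyped_dam_rejected(self):
        table, gm = micro_dataset()
        table.data.loc[0, "dam"] = "ghost"
        with pytest.raises(MGWAError, match="not genotyped"):
            m.assign_dam_genotypes(table, gm, "y", fixed=("sex",))


def fake_result(alpha_samples, Z, weights, markers, pi=0.9):
    n_ret = alpha_samples.shape[0]
    return BayesBResult(
        inclusion_prob=(np.abs(alpha_samples) > 0).mean(axis=0),
        effect_mean=alpha_samples.mean(axis=0),
        alpha_samples=alpha_samples.astype(np.float32),
        sigma2_e=np.ones(n_ret),
        mu=np.zeros(n_ret),
        pi=pi,
        sigma2_alpha=0.1,
        markers=markers,
        skipped=np.zeros(len(markers), dtype=bool),
        settings={},
        Z_dam=Z,
        dam_weights=weights,
    )


class TestWindowVariance:
    def test_single_window_explains_everything(self):
        rng = np.random.default_rng(1)
        k, n_dams = 5, 30
        Z = rng.normal(size=(k, n_dams))
        samples = rng.normal(size=(100, k))
        res = fake_result(samples, Z, np.ones(n_dams), [f"s{j}" for j in range(k)])
        win = [Window("1", 0, [f"s{j}" for j in range(k)])]
        out = m.window_variance(res, win)
        assert out["pct_var"].iloc[0] == pytest.approx(100.0)

    def test_null_chain_gives_zero_shares(self):
        k, n_dams = 4, 10
        Z = np.random.default_rng(2).normal(size=(k, n_dams))
        res = fake_result(np.zeros((50, k)), Z, np.ones(n_dams),
                          [f"s{j}" for j in range(k)])
        wins = [Window("1", 0, ["s0", "s1"]), Window("1", 1, ["s2", "s3"])]
        out = m.window_variance(res, wins)
        assert np.allclose(out["pct_var"], 0.0)

    def test_expected_share_is_uniform(self):
        assert m.expected_window_share_pct(1973) == pytest.approx(0.050684, abs=1e-5)

    def test_shares_sum_to_one_in_linkage_equilibrium(self):
        rng = np.random.default_rng(3)
        k, n_dams = 60, 40
        Z = rng.binomial(2, 0.4, size=(k, n_dams)).astype(float)
        Z -= Z.mean(axis=1, keepdims=True)
        samples = rng.normal(0, 0.2, size=(200, k)) * (rng.random((200, k)) < 0.2)
        res = fake_result(samples, Z, np.ones(n_dams), [f"s{j}" for j in range(k)])
        wins = [Window("1", i, [f"s{j}" for j in range(10 * i, 10 * i + 10)])
                for i in range(6)]
        total = m.window_variance(res, wins)["pct_var"].sum()
        assert total == pytest.approx(100.0, rel=0.05)


class TestCallAssociated:
    def make_inputs(self, pct, bf):
        wins = [Window("1", i, [f"s{i}"]) for i in range(len(pct))]
        wdf = pd.DataFrame({
            "chrom": ["1"] * len(pct), "mb_index": range(len(pct)),
            "start_bp": [w.start_bp for w in wins],
            "end_bp": [w.end_bp for w in wins],
            "n_snps": 1, "pct_var": pct,
        })
        sdf = pd.DataFrame({"marker": [f"s{i}" for i in range(len(pct))], "bf": bf})
        return wdf, sdf, wins

    def test_two_tier_rule(self):
        wdf, sdf, wins = self.make_inputs([1.2, 2.0, 0.7, 0.3],
                                          [12.0, 9.0, 11.0, 50.0])
        out = m.call_associated_windows(wdf, sdf, wins)
        assert list(out["tier"]) == ["primary", "", "secondary", ""]
        assert out["associated"].tolist() == [True, False, True, False]

    def test_strict_and_nonstrict_snp_counts(self):
        wdf, sdf, wins = self.make_inputs([1.5], [10.0])
        out = m.call_associated_windows(wdf, sdf, wins)
        assert out["n_snps_bf_gt"].iloc[0] == 0  # strict: BF must exceed 10
        assert out["n_snps_bf_ge"].iloc[0] == 1
        assert not out["associated"].iloc[0]
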