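"""Sampler correctness: design building, conjugate limits, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import matqg as m
from matqg.animal_models import (
    ModelError,
    VarianceComponents,
    build_design,
    sample_invwishart,
)


def one_litter_table(n=6, trait="y"):
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n):
        rows.append(
            {"animal": f"o{i}", "dam": "d", "litter": "L1",
             "sex": i % 2, trait: float(rng.normal())}
        )
    return m.PhenotypeTable(pd.DataFrame(rows), [trait], ["sex"])


@pytest.fixture
def litter_pedigree():
    return m.sort_and_validate(
        [("s", "0", "0"), ("d", "0", "0")] + [(f"o{i}", "s", "d") for i in range(6)]
    )


class TestModelSpec:
    @pytest.mark.parametrize(
        "mid,terms",
        [
            (1, ("direct",)),
            (2, ("direct", "maternal")),
            (3, ("direct", "litter")),
            (4, ("direct", "maternal", "litter")),
            (5, ("direct", "maternal", "maternal_env")),
        ],
    )
    def test_random_terms(self, mid, terms):
        assert m.ModelSpec(mid).random_terms == terms

    def test_retained_sample_arithmetic(self):
        assert m.n_retained(300_000, 20_000, 200) == 1400
        assert m.n_retained(500_000, 100_000, 10) == 40_000
        with pytest.raises(ModelError):
            m.n_retained(1000, 1000, 10)


class TestBuildDesign:
    def test_shared_litter_single_column(self, litter_pedigree):
        d = build_design(one_litter_table(), litter_pedigree, m.ModelSpec(3))
        Wc = d.Wc
        assert Wc.shape == (6, 1)
        assert Wc.toarray().sum() == 6

    def test_model1_has_no_maternal_or_litter_terms(self, litter_pedigree):
        d = build_design(one_litter_table(), litter_pedigree, m.ModelSpec(1))
        assert d.Zm is None and d.Wc is None and d.Wme is None
        assert d.Zd.shape == (6, litter_pedigree.n)

    def test_indicator_row_sums_are_one_per_factor(self, litter_pedigree):
        d = build_design(one_litter_table(), litter_pedigree, m.ModelSpec(4))
        X = d.X.toarray()
        # intercept + sex blocks, each contributing exactly one 1 per row
        assert np.all(X.sum(axis=1) == len(d.factor_names))

    def test_missing_dam_is_an_error(self, litter_pedigree):
        table = one_litter_table()
        table.data.loc[0, "dam"] = "nosuchdam"
        with pytest.raises(ModelError, match="absent from pedigree"):
            build_design(table, litter_pedigree, m.ModelSpec(2))


class TestInverseWishart:
    def test_moments_match_scipy(self):
        rng = np.random.default_rng(1)
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        draws = np.array([sample_invwishart(rng, 20, S) for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), S / (20 - 3), atol=0.01)
        sp = stats.invwishart(df=20, scale=S).rvs(2000, random_state=rng)
        assert np.allclose(draws.mean(axis=0), sp.mean(axis=0), atol=0.02)

    def test_univariate_reduces_to_scaled_inv_chi2(self):
        rng = np.random.default_rng(2)
        d = np.array([sample_invwishart(rng, 10, np.array([[4.0]]))[0, 0]
                      for _ in range(4000)])
        assert d.mean() == pytest.approx(4 / 8, rel=0.05)


class TestConjugateLimit:
    def test_residual_only_model_matches_closed_form_posterior(self):
        """Gibbs marginal of sigma2_e for the intercept-plus-noise model vs
        the analytic scaled-inverse-chi-square posterior (flat priors):
        sigma2 | y ~ S / chi2_{n-3} with S the centered sum of squares."""
        rng = np.random.default_rng(3)
        n = 40
        y = rng.normal(2.0, 1.3, n)
        ped = m.sort_and_validate([(f"a{i}", "0", "0") for i in range(n)])
        table = m.PhenotypeTable(
            pd.DataFrame({"animal": [f"a{i}" for i in range(n)],
                          "dam": "0", "litter": "x", "y": y}),
            ["y"], [],
        )
        res = m.run_gibbs(table, ped, m.ModelSpec(0), iterations=11_000,
                          burn_in=1_000, thin=1, seed=4)
        draws = res.samples["sigma2_e.y"].to_numpy()
        S = np.sum((y - y.mean()) ** 2)
        ks = stats.kstest(draws, lambda x: stats.invgamma((n - 3) / 2,
                                                          scale=S / 2).cdf(x))
        assert ks.pvalue > 0.01

    def test_constant_data_drives_residual_scale_to_zero(self):
        n = 30
        ped = m.sort_and_validate([(f"a{i}", "0", "0") for i in range(n)])
        table = m.PhenotypeTable(
            pd.DataFrame({"animal": [f"a{i}" for i in range(n)],
                          "dam": "0", "litter": "x", "y": 5.0}),
            ["y"], [],
        )
        res = m.run_gibbs(table, ped, m.ModelSpec(0), iterations=600,
                          burn_in=100, thin=1, seed=5)
        assert res.samples["sigma2_e.y"].mean() < 1e-6


class TestDeriveParameters:
    def test_model4_ratios(self):
        vc = VarianceComponents(
            G0=np.array([[0.45, 0.0], [0.0, 0.09]]),
            Cc=np.array([[0.14]]), Cme=None, R0=np.array([[0.32]]),
            traits=["IMF"], has_maternal=True,
        )
        gp = m.derive_parameters(vc)
        assert gp.h2d[0] == pytest.approx(0.45)
        assert gp.h2m[0] == pytest.approx(0.09)
        assert gp.c2[0] == pytest.approx(0.14)

    def test_perfect_direct_maternal_correlation(self):
        sd, sm = 0.4, 0.1
        cov = np.sqrt(sd * sm)
        vc = VarianceComponents(
            G0=np.array([[sd, cov], [cov, sm]]), Cc=None, Cme=None,
            R0=np.array([[0.5]]), traits=["y"], has_maternal=True,
        )
        assert m.derive_parameters(vc).rho_dm[0] == pytest.approx(1.0)

    def test_zero_variance_correlation_is_nan(self):
        vc = VarianceComponents(
            G0=np.array([[0.4, 0.0], [0.0, 0.0]]), Cc=None, Cme=None,
            R0=np.array([[0.6]]), traits=["y"], has_maternal=True,
        )
        assert np.isnan(m.derive_parameters(vc).rho_dm[0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_ratios_sum_to_one_with_residual_share(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(2, 2))
        G0 = L @ L.T + np.eye(2) * 0.01
        s2c, s2e = rng.uniform(0.01, 1, 2)
        vc = VarianceComponents(
            G0=G0, Cc=np.array([[s2c]]), Cme=None, R0=np.array([[s2e]]),
            traits=["y"], has_maternal=True,
        )
        gp = m.derive_parameters(vc)
        sigP = G0[0, 0] + G0[1, 1] + G0[0, 1] + s2c + s2e
        total = gp.h2d[0] + gp.h2m[0] + gp.c2[0] + G0[0, 1] / sigP + s2e / sigP
        assert total == pytest.approx(1.0)


class TestSummaries:
    def test_mean_median_of_uniform_grid(self):
        s = m.summarize(np.arange(1, 101, dtype=float))
        assert s.mean == pytest.approx(50.5)
        assert s.median == pytest.approx(50.5)

    def test_constant_chain_degenerates(self):
        s = m.summarize(np.full(50, 3.3))
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.hpd95 == (3.3, 3.3)
        assert s.mode == pytest.approx(3.3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ModelError, match="30"):
            m.summarize(np.arange(10.0))

    def brute_hpd(self, x, prob=0.95):
        x = np.sort(x)
        n = len(x)
        mlen = int(np.ceil(prob * n))
        best = None
        for i in range(n - mlen + 1):
            w = x[i + mlen - 1] - x[i]
            if best is None or w < best[0]:
                best = (w, (x[i], x[i + mlen - 1]))
        return best[1]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 9999), n=st.integers(30, 200))
    def test_hpd_matches_exhaustive_search(self, seed, n):
        x = np.random.default_rng(seed).exponential(2.0, n)
        assert m.hpd_interval(x) == self.brute_hpd(x)


class TestRunGibbs:
    def test_same_seed_identical_chains(self, litter_pedigree):
        table = one_litter_table()
        kw = dict(iterations=400, burn_in=100, thin=5, seed=9)
        a = m.run_gibbs(table, litter_pedigree, m.ModelSpec(4), **kw)
        b = m.run_gibbs(table, litter_pedigree, m.ModelSpec(4), **kw)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert len(a.samples) == m.n_retained(400, 100, 5)

    def test_bivariate_battery_row_per_trait(self):
        cfg = m.SimulationConfig(
            n_generations=1, base_sires=6, base_dams=30, n_lines=1,
            sires_per_gen=6, dams_per_gen=30, dams_per_sire=5, n_parities=2,
            litter_size=m.LitterSizeSpec(4, 2),
            traits=("IMF", "FA"), trait_means=[1.0, 20.0],
            G0_true=np.diag([0.4, 0.1, 0.4, 0.1]),
            c2=[0.1, 0.1], me2=0.0, R0_true=np.diag([0.4, 0.4]),
            fixed_effects=[m.FixedEffectSpec("sex", 2, np.array([0.0, 0.1]))],
            seed=12,
        )
        ds = m.simulate_dataset(cfg)
        out = m.fit_bivariate_battery(
            ds.phenotypes, ds.pedigree, ["IMF", "FA"],
            iterations=800, burn_in=200, thin=10, seed=1,
        )
        assert len(out) == 1
        assert {"h2d_mean", "h2m_mean", "rho_d_mean"} <= set(out.columns)
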