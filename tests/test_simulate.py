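"""Generator checks: design counts, truth bookkeeping, Monte-Carlo moments."""

import numpy as np
import pandas as pd
import pytest

import matqg as m
from matqg.simulate import ConfigError


def small_config(**kw):
    base = dict(
        n_generations=1,
        base_sires=2,
        base_dams=4,
        n_lines=1,
        sires_per_gen=2,
        dams_per_gen=4,
        dams_per_sire=2,
        n_parities=1,
        litter_size=m.LitterSizeSpec(2, 2, fixed=True),
        seed=0,
    )
    base.update(kw)
    return m.SimulationConfig(**base)


class TestPedigreeDesign:
    def test_counting_one_generation(self):
        ped = m.simulate_pedigree(small_config())
        # 6 founders + 4 litters of 2
        assert ped.n == 6 + 8
        assert ped.is_founder.sum() == 6

    def test_seeded_determinism(self):
        a = m.simulate_dataset(small_config(seed=5))
        b = m.simulate_dataset(small_config(seed=5))
        pd.testing.assert_frame_equal(a.pedigree.frame, b.pedigree.frame)
        pd.testing.assert_frame_equal(a.phenotypes.data, b.phenotypes.data)

    def test_infeasible_mating_design_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            small_config(dams_per_gen=5)

    def test_divergent_selection_keeps_extreme_dams(self):
        cfg = m.SimulationConfig(
            n_generations=2, base_sires=8, base_dams=40, n_lines=2,
            sires_per_gen=4, dams_per_gen=20, dams_per_sire=5, n_parities=2,
            litter_size=m.LitterSizeSpec(8, 4), seed=3,
            selection="divergent_on_trait1_top20pct",
        )
        ds = m.simulate_dataset(cfg)
        scores = ds.truth.dam_scores
        assert scores is not None and scores["selected"].any()
        for (line, gen), grp in scores.groupby(["line", "generation"]):
            sel = grp.loc[grp["selected"], "score"]
            if line == "H":
                assert sel.min() >= grp["score"].quantile(0.79)
            else:
                assert sel.max() <= grp["score"].quantile(0.21)


class TestBreedingValues:
    def test_zero_G0_gives_zero_breeding_values(self, fullsib_pedigree):
        bv = m.simulate_breeding_values(fullsib_pedigree, np.zeros((2, 2)), seed=1)
        assert np.all(bv == 0)

    def test_founder_covariance_matches_G0(self):
        ped = m.sort_and_validate([(f"f{i}", "0", "0") for i in range(100_000)])
        G0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        bv = m.simulate_breeding_values(ped, G0, seed=2)
        emp = np.cov(bv.T)
        se = 3.0 / np.sqrt(len(bv))  # ~3 MC standard errors on unit scale
        assert np.abs(emp - G0).max() < se

    def test_fullsib_direct_covariance_is_half_sigma2d(self):
        rows = []
        for f in range(4000):
            rows += [
                (f"s{f}", "0", "0"),
                (f"d{f}", "0", "0"),
                (f"a{f}", f"s{f}", f"d{f}"),
                (f"b{f}", f"s{f}", f"d{f}"),
            ]
        ped = m.sort_and_validate(rows)
        G0 = np.diag([0.8, 1e-12])
        bv = m.simulate_breeding_values(ped, G0, seed=3)
        idx = {a: i for i, a in enumerate(ped.ids)}
        a = np.array([bv[idx[f"a{f}"], 0] for f in range(4000)])
        b = np.array([bv[idx[f"b{f}"], 0] for f in range(4000)])
        cov = np.cov(a, b)[0, 1]
        assert cov == pytest.approx(0.5 * 0.8, abs=0.05)

    def test_non_psd_G0_rejected(self, trio_pedigree):
        with pytest.raises(ConfigError, match="positive semi-definite"):
            m.simulate_breeding_values(trio_pedigree, np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPhenotypes:
    def test_all_variances_zero_gives_exact_fixed_sums(self):
        cfg = small_config(
            G0_true=np.zeros((2, 2)), c2=0.0, me2=0.0, R0_true=0.0,
            trait_means=[1.0],
            fixed_effects=[m.FixedEffectSpec("sex", 2, np.array([0.0, 0.25]))],
        )
        ds = m.simulate_dataset(cfg)
        df = ds.phenotypes.data
        expected = 1.0 + 0.25 * (df["sex"] == 1)
        assert np.allclose(df["IMF"], expected)

    def test_litter_only_variance_makes_littermates_identical(self):
        cfg = small_config(
            G0_true=np.zeros((2, 2)), c2=0.5, me2=0.0, R0_true=0.0,
            fixed_effects=[],
        )
        df = m.simulate_dataset(cfg).phenotypes.data
        assert (df.groupby("litter")["IMF"].nunique() == 1).all()
        assert df["IMF"].nunique() > 1

    def test_variance_decomposition_recovered_at_scale(self):
        cfg = m.SimulationConfig(
            n_generations=1, base_sires=125, base_dams=625, n_lines=1,
            sires_per_gen=125, dams_per_gen=625, dams_per_sire=5, n_parities=2,
            litter_size=m.LitterSizeSpec(8, 1),
            G0_true=[[0.45, 0.0], [0.0, 0.09]], c2=0.14, me2=0.0, R0_true=0.32,
            fixed_effects=[], trait_means=[0.0], seed=9,
        )
        ds = m.simulate_dataset(cfg)
        total = ds.phenotypes.data["IMF"].var()
        assert total == pytest.approx(1.0, rel=0.05)

    def test_standalone_phenotypes_require_dam(self):
        ped = m.sort_and_validate([("s", "0", "0"), ("o", "s", "0")])
        bv = m.simulate_breeding_values(ped, np.eye(2), seed=0)
        with pytest.raises(ConfigError, match="no dam"):
            m.simulate_phenotypes(ped, bv, small_config())


class TestGenotypes:
    def test_empty_marker_set(self, trio_pedigree):
        gm, mm = m.simulate_genotypes(trio_pedigree, 0, 3, seed=1)
        assert gm.n_markers == 0 and mm.n_markers == 0

    def test_founder_allele_frequency_matches_generator(self):
        ped = m.sort_and_validate([(f"f{i}", "0", "0") for i in range(4000)])
        gm, _ = m.simulate_genotypes(ped, 20, 2, maf_range=(0.5, 0.5), seed=4)
        p = gm.allele_freq()
        assert np.abs(p - 0.5).max() < 4 * np.sqrt(0.25 / (2 * 4000))

    def test_offspring_codes_are_mendelian(self):
        cfg = small_config(seed=2)
        ds = m.simulate_dataset(cfg)
        gm, _ = m.simulate_genotypes(ds.pedigree, 50, 2, seed=5)
        idx = {a: i for i, a in enumerate(gm.individuals)}
        ped = ds.pedigree
        lo = {0: 0, 1: 0, 2: 1}
        hi = {0: 0, 1: 1, 2: 1}
        for i in range(ped.n):
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            if s < 0 or d < 0:
                continue
            cs, cd, co = gm.codes[s], gm.codes[d], gm.codes[i]
            lo_b = np.array([lo[c] for c in cs]) + np.array([lo[c] for c in cd])
            hi_b = np.array([hi[c] for c in cs]) + np.array([hi[c] for c in cd])
            assert np.all(co >= lo_b) and np.all(co <= hi_b)

    def test_bad_maf_range_rejected(self, trio_pedigree):
        with pytest.raises(ConfigError, match="maf_range"):
            m.simulate_genotypes(trio_pedigree, 5, 1, maf_range=(0.0, 0.6))


class TestDamQTL:
    @pytest.fixture
    def geno_dataset(self):
        cfg = small_config(seed=6, n_generations=1, base_dams=4)
        ds = m.simulate_dataset(cfg)
        gm, mm = m.simulate_genotypes(ds.pedigree, 40, 2, seed=7,
                                      chrom_length_bp=3_000_000)
        ds.genotypes, ds.marker_map = gm, mm
        return ds

    def test_zero_effect_leaves_phenotypes_unchanged(self, geno_dataset):
        win = m.build_windows(geno_dataset.marker_map)[0]
        out = m.inject_dam_qtl(geno_dataset, (win.chrom, win.mb_index), 0.0, 1)
        assert np.allclose(out.phenotypes.data["IMF"],
                           geno_dataset.phenotypes.data["IMF"])

    def test_heterozygous_dams_shift_constant(self, geno_dataset):
        win = m.build_windows(geno_dataset.marker_map)[0]
        probe = m.inject_dam_qtl(geno_dataset, (win.chrom, win.mb_index), 1.0, 1)
        col = geno_dataset.genotypes.markers.index(probe.truth.qtl["marker"].iloc[0])
        geno_dataset.genotypes.codes[:, col] = 1  # all dams heterozygous
        out = m.inject_dam_qtl(geno_dataset, (win.chrom, win.mb_index), 0.7, 1)
        shift = out.phenotypes.data["IMF"] - geno_dataset.phenotypes.data["IMF"]
        assert np.allclose(shift, 0.7)

    def test_regression_on_dam_genotype_recovers_effect(self):
        cfg = m.SimulationConfig(
            n_generations=1, base_sires=30, base_dams=150, n_lines=1,
            sires_per_gen=30, dams_per_gen=150, dams_per_sire=5, n_parities=1,
            litter_size=m.LitterSizeSpec(6, 6, fixed=True),
            G0_true=np.zeros((2, 2)), c2=0.0, me2=0.0, R0_true=0.2,
            fixed_effects=[], trait_means=[0.0], seed=8,
        )
        ds = m.simulate_dataset(cfg)
        gm, mm = m.simulate_genotypes(ds.pedigree, 30, 1, maf_range=(0.3, 0.5),
                                      seed=9, chrom_length_bp=5_000_000)
        ds.genotypes, ds.marker_map = gm, mm
        win = m.build_windows(mm)[0]
        out = m.inject_dam_qtl(ds, (win.chrom, win.mb_index), 0.6, 1)
        col = gm.markers.index(out.truth.qtl["marker"].iloc[0])
        rows = {a: i for i, a in enumerate(gm.individuals)}
        z = np.array([gm.codes[rows[d], col] for d in out.phenotypes.data["dam"]],
                     dtype=float)
        y = out.phenotypes.data["IMF"].to_numpy()
        slope = np.polyfit(z, y, 1)[0]  # least-squares oracle
        assert slope == pytest.approx(0.6, abs=0.05)

    def test_empty_window_rejected(self, geno_dataset):
        with pytest.raises(ConfigError, match="holds"):
            m.inject_dam_qtl(geno_dataset, ("1", 999), 1.0, 1)


class TestCompositeTraits:
    def test_sfa_sum_example(self):
        df = pd.DataFrame(
            {"C14:0": [1.0], "C15:0": [0.1], "C16:0": [26.0], "C17:0": [0.2],
             "C18:0": [9.0], "C16:1n7": [1.0], "C18:1n9": [20.0],
             "C18:2n6": [27.0]}
        )
        with pytest.warns(UserWarning, match="missing components"):
            out = m.derive_composite_traits(df)
        assert out["SFA"].iloc[0] == pytest.approx(36.3)
        assert out["MUFA"].iloc[0] == pytest.approx(21.0)

    def test_all_pufa_zero(self):
        df = pd.DataFrame({c: [1.0] for c in m.simulate.SFA_COMPONENTS})
        with pytest.warns(UserWarning):
            out = m.derive_composite_traits(df)
        assert out["PUFA"].iloc[0] == 0.0
        assert out["PUFA/SFA"].iloc[0] == 0.0

    def test_random_table_matches_naive_summation(self):
        rng = np.random.default_rng(11)
        cols = (m.simulate.SFA_COMPONENTS + m.simulate.MUFA_COMPONENTS
                + m.simulate.PUFA_COMPONENTS)
        df = pd.DataFrame(rng.uniform(0.1, 10, size=(50, len(cols))), columns=cols)
        out = m.derive_composite_traits(df)
        sfa = sum(df[c] for c in m.simulate.SFA_COMPONENTS)
        pufa = sum(df[c] for c in m.simulate.PUFA_COMPONENTS)
        assert np.allclose(out["SFA"], sfa)
        assert np.allclose(out["PUFA/SFA"], pufa / sfa)

    def test_zero_sfa_ratio_errors(self):
        df = pd.DataFrame({c: [0.0] for c in m.simulate.SFA_COMPONENTS})
        with pytest.warns(UserWarning):
            with pytest.raises(ZeroDivisionError):
                m.derive_composite_traits(df)
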