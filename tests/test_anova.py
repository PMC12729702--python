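import math

import numpy as np
import pandas as pd
import pytest

from phenodiv import (MeansMatrix, PhenotypeTable, anova_crd,
                      genetic_parameters, genetic_parameters_from_ms,
                      genotype_means, pearson_matrix)


class TestAnovaCrd:
    def test_hand_computed_two_genotypes(self, tiny_table):
        av = anova_crd(tiny_table, "x")
        assert av.ss_genotype == pytest.approx(16.0)
        assert av.ss_residual == pytest.approx(4.0)
        assert av.qm_g == pytest.approx(16.0)
        assert av.qm_r == pytest.approx(2.0)
        assert av.f_value == pytest.approx(8.0)
        assert av.df_genotype == 1 and av.df_residual == 2

    def test_sum_of_squares_additivity(self, random_table):
        for trait in random_table.traits:
            av = anova_crd(random_table, trait)
            assert av.ss_genotype + av.ss_residual == pytest.approx(
                av.ss_total, rel=1e-10)

    def test_matches_brute_force_double_loop(self, random_table):
        av = anova_crd(random_table, "t1")
        y = random_table.data["t1"].to_numpy()
        groups = random_table.data["genotype"].to_numpy()
        grand = y.mean()
        ss_g = ss_e = 0.0
        for geno in np.unique(groups):
            vals = y[groups == geno]
            ss_g += len(vals) * (vals.mean() - grand) ** 2
            for v in vals:
                ss_e += (v - vals.mean()) ** 2
        assert av.ss_genotype == pytest.approx(ss_g, rel=1e-10)
        assert av.ss_residual == pytest.approx(ss_e, rel=1e-10)

    def test_all_equal_degenerate(self):
        df = pd.DataFrame({"genotype": list("AABB"), "replicate": [1, 2] * 2,
                           "x": [5.0] * 4})
        with pytest.warns(UserWarning, match="degenerate"):
            av = anova_crd(PhenotypeTable(data=df, traits=("x",)), "x")
        assert av.ss_genotype == 0 and av.ss_residual == 0
        assert av.degenerate

    def test_zero_residual_infinite_f(self):
        df = pd.DataFrame({"genotype": list("AABB"), "replicate": [1, 2] * 2,
                           "x": [1.0, 1.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            av = anova_crd(PhenotypeTable(data=df, traits=("x",)), "x")
        assert math.isinf(av.f_value) and av.p_value == 0.0


class TestGeneticParameters:
    @pytest.mark.parametrize(
        "qm_g, qm_r, h2, ratio",
        [
            (1061.12, 99.40, 90.63, 1.55),   # seedling emergence
            (720.45, 265.81, 63.10, 0.65),   # mean emergence time
        ],
    )
    def test_reported_trial_cells(self, qm_g, qm_r, h2, ratio):
        gp = genetic_parameters_from_ms(qm_g, qm_r, k=4)
        assert gp.h2_percent == pytest.approx(h2, abs=0.01)
        assert gp.cvg_over_cve == pytest.approx(ratio, abs=0.01)

    def test_component_identities(self):
        gp = genetic_parameters_from_ms(12.0, 3.0, k=4, m=10.0)
        assert gp.sigma2_f == pytest.approx(gp.sigma2_g + gp.sigma2_e)
        assert gp.sigma2_f == pytest.approx(3.0)
        assert gp.sigma2_g == pytest.approx(2.25)
        assert gp.cvg_over_cve == pytest.approx(gp.cvg_percent / gp.cve_percent)
        assert gp.cv_percent == pytest.approx(gp.cve_percent)

    def test_no_genetic_variance(self):
        gp = genetic_parameters_from_ms(5.0, 5.0, k=4)
        assert gp.sigma2_g == 0 and gp.h2_percent == 0
        assert gp.cvg_over_cve == 0

    def test_negative_variance_flagged_not_hidden(self):
        gp = genetic_parameters_from_ms(2.0, 4.0, k=4)
        assert gp.negative_variance_flag
        assert gp.sigma2_g == pytest.approx(-0.5)
        assert gp.h2_percent == 0.0

    def test_scale_invariance_of_h2_ratio_f(self, random_table):
        av = anova_crd(random_table, "t1")
        gp = genetic_parameters(av)
        scaled = random_table.data.copy()
        scaled["t1"] = scaled["t1"] * 37.5
        av2 = anova_crd(PhenotypeTable(data=scaled, traits=random_table.traits),
                        "t1")
        gp2 = genetic_parameters(av2)
        assert av2.f_value == pytest.approx(av.f_value, rel=1e-10)
        assert gp2.h2_percent == pytest.approx(gp.h2_percent, rel=1e-10)
        assert gp2.cvg_over_cve == pytest.approx(gp.cvg_over_cve, rel=1e-10)
        # CVs are location-sensitive: shifting the trait changes them
        shifted = random_table.data.copy()
        shifted["t1"] = shifted["t1"] + 100.0
        gp3 = genetic_parameters(anova_crd(
            PhenotypeTable(data=shifted, traits=random_table.traits), "t1"))
        assert gp3.cvg_percent != pytest.approx(gp.cvg_percent, rel=1e-3)

    def test_expected_mean_squares_recovered(self, single_trait_config):
        # E[QMg] = k*sigma_g^2 + sigma_e^2, E[QMr] = sigma_e^2
        from phenodiv import simulate_phenotypes, sigma_g_for_h2

        h2, s2e, k = 0.9, 1.0, 4
        s2g = sigma_g_for_h2(h2, s2e, k)
        qmg, qmr = [], []
        for seed in range(500):
            av = anova_crd(
                simulate_phenotypes(single_trait_config(seed, h2, s2e)), "x")
            qmg.append(av.qm_g)
            qmr.append(av.qm_r)
        assert np.mean(qmg) == pytest.approx(k * s2g + s2e, rel=0.02)
        assert np.mean(qmr) == pytest.approx(s2e, rel=0.02)


class TestPearsonMatrix:
    def _means(self, data):
        return MeansMatrix(means=pd.DataFrame(data), k=4)

    def test_perfect_linearity(self):
        m = self._means({"x": [1.0, 2.0, 3.0], "y": [3.0, 5.0, 7.0]})
        corr = pearson_matrix(m)
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.p.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        m = self._means({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 4.0]})
        corr = pearson_matrix(m)
        assert corr.r.loc["x", "y"] == pytest.approx(0.9819805, abs=1e-6)

    def test_constant_trait_flagged(self):
        m = self._means({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 4.0]})
        corr = pearson_matrix(m)
        assert corr.undefined_traits == ("x",)
        assert np.isnan(corr.r.loc["x", "y"])
        assert corr.codes.loc["x", "y"] == ""

    def test_symmetric_psd(self, study_table):
        corr = pearson_matrix(genotype_means(study_table))
        r = corr.r.to_numpy()
        np.testing.assert_allclose(r, r.T)
        assert np.linalg.eigvalsh(r).min() >= -1e-8
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_p_values_match_scipy(self, study_table):
        from scipy import stats

        means = genotype_means(study_table)
        corr = pearson_matrix(means)
        r_ref, p_ref = stats.pearsonr(means.means["FL"], means.means["MET"])
        assert corr.r.loc["FL", "MET"] == pytest.approx(r_ref, rel=1e-10)
        assert corr.p.loc["FL", "MET"] == pytest.approx(p_ref, rel=1e-8)
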