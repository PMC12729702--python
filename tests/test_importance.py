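import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from phenodiv import (CanonicalVariateAnalysis, MeansMatrix, PhenotypeTable,
                      canonical_variates, genotype_means, mahalanobis_matrix,
                      pooled_residual_covariance, singh_contributions)
from phenodiv.divergence import PooledCovariance


def identity_cov(traits):
    p = len(traits)
    return PooledCovariance(
        S=pd.DataFrame(np.eye(p), index=traits, columns=traits),
        df=10, condition=1.0)


class TestSingh:
    def test_two_genotype_identity_cov(self):
        m = MeansMatrix(means=pd.DataFrame(
            {"a": [0.0, 3.0], "b": [0.0, 4.0]}, index=["A", "B"]), k=4)
        res = singh_contributions(m, identity_cov(["a", "b"]))
        assert res.percent["a"] == pytest.approx(36.0)
        assert res.percent["b"] == pytest.approx(64.0)
        assert res.total_d2 == pytest.approx(25.0)

    def test_sum_identity_with_total_d2(self, study_table):
        means = genotype_means(study_table)
        pooled = pooled_residual_covariance(study_table)
        res = singh_contributions(means, pooled)
        d2 = mahalanobis_matrix(means, pooled)
        total = d2.to_long()["distance"].sum()
        assert res.total_d2 == pytest.approx(total, rel=1e-6)
        assert res.s_j.sum() == pytest.approx(total, rel=1e-6)
        assert res.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_diagonal_cov_closed_form(self):
        x = pd.DataFrame({"a": [0.0, 1.0, 3.0], "b": [0.0, 2.0, 5.0]},
                         index=list("ABC"))
        s_diag = np.array([2.0, 5.0])
        pooled = PooledCovariance(
            S=pd.DataFrame(np.diag(s_diag), index=["a", "b"],
                           columns=["a", "b"]), df=6, condition=2.5)
        res = singh_contributions(MeansMatrix(means=x, k=4), pooled)
        xa = x.to_numpy()
        expected = np.zeros(2)
        for i in range(3):
            for j in range(i + 1, 3):
                expected += (xa[i] - xa[j]) ** 2 / s_diag
        np.testing.assert_allclose(res.s_j.to_numpy(), expected, rtol=1e-12)

    def test_per_pair_sum_identity_with_correlated_traits(self):
        # signed contributions may be negative yet must sum to the pair D2
        rng = np.random.default_rng(9)
        x = rng.normal(size=(2, 3))
        a = rng.normal(size=(3, 3))
        s = a @ a.T + 0.5 * np.eye(3)
        traits = ["a", "b", "c"]
        pooled = PooledCovariance(
            S=pd.DataFrame(s, index=traits, columns=traits),
            df=9, condition=float(np.linalg.cond(s)))
        m = MeansMatrix(means=pd.DataFrame(x, index=["A", "B"],
                                           columns=traits), k=3)
        res = singh_contributions(m, pooled)
        delta = x[0] - x[1]
        d2 = float(delta @ np.linalg.solve(s, delta))
        assert res.s_j.sum() == pytest.approx(d2, rel=1e-10)

    def test_scale_invariance_of_percents(self, study_table):
        means = genotype_means(study_table)
        pooled = pooled_residual_covariance(study_table)
        base = singh_contributions(means, pooled).percent
        scale = 100.0
        scaled_data = study_table.data.copy()
        scaled_data["FL"] = scaled_data["FL"] * scale
        scaled_table = PhenotypeTable(data=scaled_data,
                                      traits=study_table.traits)
        res2 = singh_contributions(
            genotype_means(scaled_table),
            pooled_residual_covariance(scaled_table)).percent
        np.testing.assert_allclose(res2.to_numpy(), base.to_numpy(),
                                   rtol=1e-7)


class TestCanonicalVariates:
    def test_single_trait_full_proportion(self, tiny_table):
        res = canonical_variates(tiny_table)
        assert res.eigenvalues.size == 1
        assert res.proportion[0] == pytest.approx(1.0)

    def test_well_separated_clouds(self):
        rng = np.random.default_rng(2)
        rows = []
        for i, center in enumerate([(0, 0), (50, 50)]):
            for j in range(10):
                rows.append({"genotype": f"G{i}", "replicate": j + 1,
                             "a": center[0] + rng.normal(),
                             "b": center[1] + rng.normal()})
        table = PhenotypeTable(data=pd.DataFrame(rows), traits=("a", "b"))
        res = canonical_variates(table)
        assert res.proportion[0] > 0.99

    def test_eigenvalues_match_generalized_eig_oracle(self, study_table):
        x = study_table.trait_matrix().to_numpy()
        y = study_table.data["genotype"].to_numpy()
        cva = CanonicalVariateAnalysis().fit(x, y)
        # brute-force W^-1 B spectrum
        classes = np.unique(y)
        p = x.shape[1]
        grand = x.mean(axis=0)
        b = np.zeros((p, p))
        w = np.zeros((p, p))
        for c in classes:
            xi = x[y == c]
            dev = xi.mean(axis=0) - grand
            b += xi.shape[0] * np.outer(dev, dev)
            resid = xi - xi.mean(axis=0)
            w += resid.T @ resid
        ref = np.sort(np.real(linalg.eigvals(np.linalg.solve(w, b))))[::-1]
        n_keep = cva.eigenvalues_.size
        np.testing.assert_allclose(cva.eigenvalues_, ref[:n_keep],
                                   rtol=1e-8, atol=1e-8)
        assert cva.proportion_.sum() == pytest.approx(1.0)
        assert (np.diff(cva.eigenvalues_) <= 1e-9).all()

    def test_rank_bounded_by_g_minus_1(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(3):  # 3 genotypes, 4 traits -> at most 2 variates
            for j in range(5):
                rows.append({"genotype": f"G{i}", "replicate": j + 1,
                             **{f"t{t}": rng.normal() for t in range(4)}})
        table = PhenotypeTable(data=pd.DataFrame(rows),
                               traits=tuple(f"t{t}" for t in range(4)))
        res = canonical_variates(table)
        assert res.eigenvalues.size == 2

    def test_proportions_invariant_under_linear_transform(self, study_table):
        rng = np.random.default_rng(6)
        res = canonical_variates(study_table)
        p = len(study_table.traits)
        a = rng.normal(size=(p, p)) + 2 * np.eye(p)
        transformed = study_table.trait_matrix().to_numpy() @ a.T
        df = study_table.data.copy()
        for ti, t in enumerate(study_table.traits):
            df[t] = transformed[:, ti]
        res2 = canonical_variates(
            PhenotypeTable(data=df, traits=study_table.traits))
        np.testing.assert_allclose(res2.proportion, res.proportion,
                                   rtol=1e-7, atol=1e-9)
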