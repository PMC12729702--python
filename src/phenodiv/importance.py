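"""Trait-importance decomposition and canonical variate analysis.

Singh's criterion decomposes the total pairwise Mahalanobis divergence into
additive per-trait shares.  Writing W = S^-1 for the inverted pooled
residual covariance and delta the mean-difference vector of a genotype
pair, the contribution of trait j to that pair's D2 is

    c_j = delta_j * (W delta)_j,

so that sum_j c_j = delta' W delta = D2 exactly.  Summing c_j over all
unordered pairs gives the trait totals S_j, whose percentages of
sum_j S_j rank the traits.  Contributions are kept signed: with strongly
correlated traits an individual c_j can be negative, but the identity with
the total divergence is preserved.

Canonical variate analysis (CVA) solves the generalized eigenproblem
``B v = lambda W v`` with B the between-genotype and W the pooled
within-genotype sums-of-products matrices on replicate-level data.  The
eigenvalues' proportions order the canonical axes by discriminative power;
genotype means projected on the eigenvectors give the canonical scores.
The solve whitens W through its Cholesky factor and uses a symmetric
eigensolver for numerical stability.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .divergence import PooledCovariance, SingularCovarianceError
from .io import MeansMatrix, PhenotypeTable, genotype_means

__all__ = [
    "SinghContribution",
    "CanonicalVariatesResult",
    "CanonicalVariateAnalysis",
    "singh_contributions",
    "canonical_variates",
]


@dataclasses.dataclass(frozen=True)
class SinghContribution:
    s_j: pd.Series          # per-trait summed contribution (D2 units)
    percent: pd.Series      # 100 * s_j / total
    total_d2: float         # sum over unordered pairs of D2

    def ranking(self) -> list[str]:
        return list(self.percent.sort_values(ascending=False).index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"contribution": self.s_j, "percent": self.percent})
        out["rank"] = out["percent"].rank(ascending=False).astype(int)
        return out.sort_values("rank")


def singh_contributions(means: MeansMatrix,
                        pooled: PooledCovariance) -> SinghContribution:
    """Per-trait share of total pairwise Mahalanobis D2 (Singh's method)."""
    w = pooled.inverse()
    x = means.values()
    g, p = x.shape
    s_j = np.zeros(p)
    for i in range(g):
        for j in range(i + 1, g):
            delta = x[i] - x[j]
            s_j += delta * (w @ delta)
    total = float(s_j.sum())
    if total == 0:
        raise ValueError("total divergence is zero; all genotype means equal")
    traits = list(means.traits)
    return SinghContribution(
        s_j=pd.Series(s_j, index=traits),
        percent=pd.Series(100.0 * s_j / total, index=traits),
        total_d2=total,
    )


@dataclasses.dataclass(frozen=True)
class CanonicalVariatesResult:
    eigenvalues: np.ndarray          # non-increasing, length min(p, g-1) kept
    proportion: np.ndarray
    cumulative: np.ndarray
    coefficients: pd.DataFrame       # trait x variate weighting coefficients
    scores: pd.DataFrame             # genotype x variate canonical scores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variate": [f"CV{i + 1}" for i in range(self.eigenvalues.size)],
            "eigenvalue": self.eigenvalues,
            "proportion": self.proportion,
            "cumulative": self.cumulative,
        })


class CanonicalVariateAnalysis(TransformerMixin, BaseEstimator):
    """Canonical variate analysis as a supervised sklearn transformer.

    ``fit(X, y)`` takes the replicate-level trait matrix X and genotype
    labels y.  ``transform`` projects rows onto the canonical axes.

    Attributes
    ----------
    eigenvalues_ : ndarray
        Non-negative eigenvalues of W^-1 B, non-increasing.
    proportion_, cumulative_ : ndarray
        Shares of the total discriminative variation.
    coef_ : ndarray (p x n_variates)
        Raw canonical weighting coefficients.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if x.ndim != 2:
            raise ValueError("X must be 2-d (observations x traits)")
        classes, idx = np.unique(y, return_inverse=True)
        g, p = classes.size, x.shape[1]
        if g < 2:
            raise ValueError("need at least 2 genotypes")
        grand = x.mean(axis=0)
        b = np.zeros((p, p))
        w = np.zeros((p, p))
        means = np.empty((g, p))
        for gi in range(g):
            xi = x[idx == gi]
            mi = xi.mean(axis=0)
            means[gi] = mi
            dev = mi - grand
            b += xi.shape[0] * np.outer(dev, dev)
            resid = xi - mi
            w += resid.T @ resid
        try:
            chol = linalg.cholesky(w, lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "within-genotype matrix is singular; remove collinear traits"
            ) from exc
        # whiten: W^-1 B has the eigenvalues of L^-1 B L^-T (symmetric)
        li_b = linalg.solve_triangular(chol, b, lower=True)
        m = linalg.solve_triangular(chol, li_b.T, lower=True)
        m = (m + m.T) / 2.0
        evals, evecs = linalg.eigh(m)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        # back-transform: v = L^-T u solves B v = lambda W v
        vecs = linalg.solve_triangular(chol.T, evecs[:, order], lower=False)
        n_keep = min(p, g - 1)
        self.classes_ = classes
        self.eigenvalues_ = evals[:n_keep]
        total = evals.sum()
        self.proportion_ = (self.eigenvalues_ / total if total > 0
                            else np.zeros(n_keep))
        self.cumulative_ = np.cumsum(self.proportion_)
        self.coef_ = vecs[:, :n_keep]
        self.means_ = means
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


def canonical_variates(table: PhenotypeTable) -> CanonicalVariatesResult:
    """CVA on a phenotype table; scores are projected genotype means."""
    cva = CanonicalVariateAnalysis().fit(
        table.trait_matrix().to_numpy(), table.data["genotype"].to_numpy()
    )
    means = genotype_means(table)
    variates = [f"CV{i + 1}" for i in range(cva.eigenvalues_.size)]
    return CanonicalVariatesResult(
        eigenvalues=cva.eigenvalues_,
        proportion=cva.proportion_,
        cumulative=cva.cumulative_,
        coefficients=pd.DataFrame(cva.coef_, index=list(table.traits),
                                  columns=variates),
        scores=pd.DataFrame(means.values() @ cva.coef_,
                            index=means.genotypes, columns=variates),
    )
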