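"""Genotype dissimilarity matrices for divergence analysis.

Two metrics are provided:

* the generalized Mahalanobis distance
  ``D2(i, i') = (xbar_i - xbar_i')' S^-1 (xbar_i - xbar_i')`` on genotype
  mean vectors, with S the pooled residual (within-genotype) covariance
  matrix estimated from the replicate-level data, and
* the standardized mean Euclidean distance, where each trait is centered
  and scaled to unit standard deviation across genotype means and
  ``d(i, i') = sqrt(mean_j (z_ij - z_i'j)^2)`` (the squared sum is divided
  by the number of traits).

D2 weights trait differences by the inverse residual covariance, removing
both scale and within-genotype correlation; the standardized Euclidean
variant removes scale only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg

from .io import MeansMatrix, PhenotypeTable

__all__ = [
    "PooledCovariance",
    "DistanceMatrix",
    "SingularCovarianceError",
    "pooled_residual_covariance",
    "mahalanobis_matrix",
    "standardized_euclidean_matrix",
]

_CONDITION_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular or numerically near-singular."""


@dataclasses.dataclass(frozen=True)
class PooledCovariance:
    """Pooled within-genotype (residual) covariance S with its df."""

    S: pd.DataFrame
    df: int
    condition: float

    @property
    def singular(self) -> bool:
        return not np.isfinite(self.condition) or self.condition > _CONDITION_LIMIT

    def inverse(self, ridge: float = 0.0) -> np.ndarray:
        """S^-1 by a stable symmetric solve; refuses near-singular S unless
        a positive ridge is supplied."""
        s = self.S.to_numpy(dtype=float)
        if ridge > 0:
            s = s + ridge * np.eye(s.shape[0])
        elif self.singular:
            raise SingularCovarianceError(
                f"pooled covariance condition {self.condition:.3g} exceeds "
                f"{_CONDITION_LIMIT:.0e}; remove collinear traits or pass a "
                "ridge"
            )
        ident = np.eye(s.shape[0])
        try:
            cho = linalg.cho_factor(s)
            return linalg.cho_solve(cho, ident)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise SingularCovarianceError(str(exc)) from exc


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric genotype-pair dissimilarities with a metric tag."""

    values: pd.DataFrame
    metric: str  # "mahalanobis_d2" or "euclidean_standardized"

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index.astype(str))

    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        """Unordered pair list (i < j in index order)."""
        labels = self.genotypes
        d = self.array()
        rows = [
            (labels[i], labels[j], d[i, j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return pd.DataFrame(rows, columns=["genotype_1", "genotype_2", "distance"])


def _as_distance(d: np.ndarray, labels: list[str], metric: str) -> DistanceMatrix:
    d = np.asarray(d, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # clip tiny negative rounding artifacts
    return DistanceMatrix(
        values=pd.DataFrame(d, index=labels, columns=labels), metric=metric
    )


def pooled_residual_covariance(table: PhenotypeTable) -> PooledCovariance:
    """Pooled residual covariance S = E/df from replicate-level data.

    E is the within-genotype sums-of-products matrix; df = g(k-1).
    """
    x = table.trait_matrix().to_numpy()
    groups = table.data["genotype"].to_numpy()
    centered = np.empty_like(x)
    for gname in np.unique(groups):
        mask = groups == gname
        centered[mask] = x[mask] - x[mask].mean(axis=0)
    df = table.g * (table.k - 1)
    e = centered.T @ centered
    s = e / df
    cond = float(np.linalg.cond(s)) if np.any(s) else float("inf")
    return PooledCovariance(
        S=pd.DataFrame(s, index=list(table.traits), columns=list(table.traits)),
        df=df,
        condition=cond,
    )


def mahalanobis_matrix(means: MeansMatrix, pooled: PooledCovariance,
                       ridge: float = 0.0) -> DistanceMatrix:
    """Pairwise generalized Mahalanobis D2 between genotype mean vectors."""
    w = pooled.inverse(ridge=ridge)
    x = means.values()
    # D2(i,j) = (xi-xj)' W (xi-xj); expand via the Gram matrix of W
    xw = x @ w
    q = np.einsum("ij,ij->i", xw, x)
    d2 = q[:, None] + q[None, :] - 2.0 * xw @ x.T
    return _as_distance(d2, means.genotypes, "mahalanobis_d2")


def standardized_euclidean_matrix(means: MeansMatrix) -> DistanceMatrix:
    """Standardized mean Euclidean distance between genotypes.

    Traits are z-scored across genotype means (sample sd, ddof=1); the
    squared coordinate differences are averaged over traits before the
    square root, making the metric invariant to per-trait affine rescaling.
    """
    x = means.values()
    sd = x.std(axis=0, ddof=1)
    zero = [t for t, s in zip(means.traits, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance trait(s) across genotypes: {zero}")
    z = (x - x.mean(axis=0)) / sd
    p = z.shape[1]
    q = np.einsum("ij,ij->i", z, z)
    d2 = (q[:, None] + q[None, :] - 2.0 * z @ z.T) / p
    d2[d2 < 0] = 0.0
    return _as_distance(np.sqrt(d2), means.genotypes, "euclidean_standardized")
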