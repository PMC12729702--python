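"""Scott-Knott clustering of treatment means.

The Scott-Knott procedure partitions g ordered treatment means into
non-overlapping homogeneous groups.  At each node the means are sorted and
the contiguous split maximizing the between-group sum of squares B0 is
found; the likelihood-ratio statistic

    lambda = pi / (2*(pi - 2)) * B0 / sigma0_hat^2

with

    sigma0_hat^2 = (sum_i (ybar_i - ybar)^2 + nu * s2_ybar) / (g + nu),
    s2_ybar = QMr / k,   nu = residual degrees of freedom,

is compared with the chi-square quantile at g/(pi-2) (fractional) degrees of
freedom.  If lambda exceeds the critical value the split is accepted and the
procedure recurses on both halves; nu and s2_ybar stay global while g is the
size of the node being tested.  Groups are labeled 'a', 'b', ... from the
highest-mean group downward, so means sharing a letter were never separated
by an accepted split.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["SplitRecord", "ScottKnottResult", "ScottKnott",
           "max_between_ss", "scott_knott"]

_PI = math.pi
_LAMBDA_FACTOR = _PI / (2.0 * (_PI - 2.0))


def max_between_ss(sorted_means: Sequence[float]) -> tuple[int, float]:
    """Maximal between-group sum of squares over contiguous splits.

    Returns ``(j, B0)`` where the first group is ``sorted_means[:j]``.
    B0(j) = T1^2/j + T2^2/(g-j) - (T1+T2)^2/g with T1, T2 the partial sums.
    Ties in the argmax resolve to the smallest j.
    """
    y = np.asarray(sorted_means, dtype=float)
    g = y.size
    if g < 2:
        raise ValueError("need at least 2 means to split")
    csum = np.cumsum(y)
    total = csum[-1]
    j = np.arange(1, g)
    b0 = csum[:-1] ** 2 / j + (total - csum[:-1]) ** 2 / (g - j) - total ** 2 / g
    best = int(np.argmax(b0))  # argmax returns the first maximum: smallest j
    return best + 1, float(b0[best])


@dataclasses.dataclass(frozen=True)
class SplitRecord:
    """One tested node of the recursion."""

    members: tuple[str, ...]
    split_index: int
    b0: float
    lambda_stat: float
    chi2_critical: float
    accepted: bool


@dataclasses.dataclass(frozen=True)
class ScottKnottResult:
    trait: str
    genotypes: tuple[str, ...]       # sorted by descending mean
    means: tuple[float, ...]         # matching order
    letters: dict[str, str]          # genotype -> group letter
    splits: tuple[SplitRecord, ...]
    n_groups: int


def _letter(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


class ScottKnott(BaseEstimator):
    """Scott-Knott means-grouping estimator.

    Parameters
    ----------
    qm_r : float
        Residual mean square from the per-trait ANOVA.
    k : int
        Replicates per treatment (so the variance of a mean is ``qm_r/k``).
    df_residual : int
        Residual degrees of freedom of the ANOVA.
    alpha : float, default 0.05
        Test size for each split decision.

    Attributes
    ----------
    labels_ : ndarray of str
        Group letter per input mean (input order).
    groups_ : list of list of int
        Indices (input order) per group, highest-mean group first.
    splits_ : tuple of SplitRecord
        Every tested node with its B0, lambda and critical value.
    """

    def __init__(self, qm_r: float = 1.0, k: int = 2,
                 df_residual: int = 1, alpha: float = 0.05):
        self.qm_r = qm_r
        self.k = k
        self.df_residual = df_residual
        self.alpha = alpha

    def fit(self, X, y=None):
        means = np.asarray(X, dtype=float).ravel()
        if means.size < 1:
            raise ValueError("no means supplied")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.qm_r < 0 or self.k < 1:
            raise ValueError("qm_r must be >= 0 and k >= 1")
        order = np.argsort(-means, kind="stable")  # descending
        labels_sorted = [f"g{i}" for i in range(means.size)]
        splits: list[SplitRecord] = []
        s2_ybar = self.qm_r / self.k
        nu = self.df_residual

        groups_sorted: list[list[int]] = []

        def recurse(idx: np.ndarray) -> None:
            if idx.size == 1:
                groups_sorted.append(list(idx))
                return
            # node means ascending for the split search
            node = means[idx][::-1]
            j_asc, b0 = max_between_ss(node)
            gsize = idx.size
            dev2 = float(((node - node.mean()) ** 2).sum())
            sigma0 = (dev2 + nu * s2_ybar) / (gsize + nu)
            lam = 0.0 if sigma0 == 0 else _LAMBDA_FACTOR * b0 / sigma0
            if sigma0 == 0 and b0 > 0:
                lam = math.inf
            dof = gsize / (_PI - 2.0)
            crit = float(stats.chi2.ppf(1.0 - self.alpha, dof))
            accept = bool(lam > crit)
            splits.append(SplitRecord(
                members=tuple(labels_sorted[i] for i in idx),
                split_index=j_asc, b0=b0, lambda_stat=lam,
                chi2_critical=crit, accepted=accept,
            ))
            if accept:
                # idx is descending; ascending split at j_asc means the
                # lower j_asc means — i.e. the last j_asc of idx.
                recurse(idx[: gsize - j_asc])
                recurse(idx[gsize - j_asc:])
            else:
                groups_sorted.append(list(idx))

        recurse(order)
        letters = np.empty(means.size, dtype=object)
        for gi, members in enumerate(groups_sorted):
            for i in members:
                letters[i] = _letter(gi)
        self.labels_ = letters
        self.groups_ = groups_sorted
        self.splits_ = tuple(splits)
        self.n_groups_ = len(groups_sorted)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def scott_knott(
    means: Sequence[float],
    qm_r: float,
    k: int,
    df_residual: int,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    trait: str = "",
) -> ScottKnottResult:
    """Functional wrapper around :class:`ScottKnott`."""
    values = np.asarray(means, dtype=float).ravel()
    if labels is None:
        labels = [str(i + 1) for i in range(values.size)]
    est = ScottKnott(qm_r=qm_r, k=k, df_residual=df_residual, alpha=alpha).fit(values)
    order = np.argsort(-values, kind="stable")
    return ScottKnottResult(
        trait=trait,
        genotypes=tuple(str(labels[i]) for i in order),
        means=tuple(float(values[i]) for i in order),
        letters={str(labels[i]): est.labels_[i] for i in range(values.size)},
        splits=est.splits_,
        n_groups=est.n_groups_,
    )
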