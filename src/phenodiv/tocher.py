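"""Tocher (Rao) optimization clustering on a distance matrix.

The classical Tocher procedure partitions genotypes using an inclusion
threshold theta = max over genotypes of their nearest-neighbor distance,
computed once from the full matrix.  Clusters form greedily: seed with the
globally closest unassigned pair, then repeatedly admit the unassigned
genotype whose mean distance to the current cluster is smallest, provided
that mean distance does not exceed theta; when no candidate qualifies the
cluster closes and a new one starts from the closest remaining pair.  A
single leftover genotype forms a singleton.  Clusters are labeled with
Roman numerals in formation order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .divergence import DistanceMatrix

__all__ = ["TocherResult", "TocherClustering", "tocher_threshold", "tocher_cluster"]


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for v, sym in vals:
        while n >= v:
            out += sym
            n -= v
    return out


@dataclasses.dataclass(frozen=True)
class TocherResult:
    clusters: dict[str, tuple[str, ...]]  # Roman numeral -> genotype labels
    theta: float
    mean_intra_distance: dict[str, float]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        return {g: c for c, members in self.clusters.items() for g in members}


def _coerce(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DistanceMatrix):
        return D.array(), D.genotypes
    d = np.asarray(D, dtype=float)
    return d, [str(i) for i in range(d.shape[0])]


def tocher_threshold(D) -> float:
    """theta = max_i min_{j != i} D(i, j)."""
    d, _ = _coerce(D)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genotypes")
    off = d + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    return float(off.min(axis=1).max())


class TocherClustering(ClusterMixin, BaseEstimator):
    """Tocher optimization clustering estimator (precomputed distances).

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per genotype (0 = first-formed cluster).
    clusters_ : list of list of int
        Member indices per cluster, in formation order.
    theta_ : float
        Inclusion threshold.
    """

    def fit(self, X, y=None):
        d, _ = _coerce(X)
        n = d.shape[0]
        if n < 2:
            raise ValueError("need at least 2 genotypes")
        theta = tocher_threshold(d)
        unassigned = list(range(n))
        clusters: list[list[int]] = []
        while unassigned:
            if len(unassigned) == 1:
                clusters.append([unassigned.pop()])
                break
            # seed: globally closest unassigned pair (ties: label order)
            best = None
            for a_pos, a in enumerate(unassigned):
                for b in unassigned[a_pos + 1:]:
                    key = (d[a, b], a, b)
                    if best is None or key < best:
                        best = key
            _, a, b = best
            current = [a, b]
            unassigned.remove(a)
            unassigned.remove(b)
            while unassigned:
                # candidate with the smallest mean distance to the cluster
                cand, cand_mean = None, None
                for c in unassigned:
                    mean_d = float(np.mean([d[c, m] for m in current]))
                    if cand is None or (mean_d, c) < (cand_mean, cand):
                        cand, cand_mean = c, mean_d
                if cand_mean <= theta:
                    current.append(cand)
                    unassigned.remove(cand)
                else:
                    break
            clusters.append(sorted(current))
        labels = np.empty(n, dtype=int)
        for ci, members in enumerate(clusters):
            labels[members] = ci
        self.labels_ = labels
        self.clusters_ = clusters
        self.theta_ = theta
        return self


def tocher_cluster(D) -> TocherResult:
    """Functional wrapper returning Roman-numeral labeled clusters."""
    d, names = _coerce(D)
    est = TocherClustering().fit(d)
    clusters: dict[str, tuple[str, ...]] = {}
    intra: dict[str, float] = {}
    for ci, members in enumerate(est.clusters_):
        label = _roman(ci + 1)
        clusters[label] = tuple(names[i] for i in members)
        if len(members) > 1:
            pair_d = [d[i, j] for ii, i in enumerate(members)
                      for j in members[ii + 1:]]
            intra[label] = float(np.mean(pair_d))
        else:
            intra[label] = 0.0
    return TocherResult(clusters=clusters, theta=est.theta_,
                        mean_intra_distance=intra)
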