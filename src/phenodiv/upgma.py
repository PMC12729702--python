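"""UPGMA hierarchical clustering with Mojena cutoff and Newick export.

UPGMA (unweighted pair-group method with arithmetic mean) merges at each
step the two clusters with the smallest average cross-pair distance; the
fusion height recorded for a merge is that average distance itself (the
hclust convention), which is also the scale on which Mojena's stopping rule
operates:

    h* = mean(fusion heights) + c * sd(fusion heights)

with sample standard deviation over the g-1 heights and a constant c
(1.25 by default, the value commonly recommended for this rule).  Cutting
every merge above h* yields the reported groups.  In the Newick export the
ultrametric convention is used instead: each leaf sits at depth
(root height)/2, so branch lengths are halved merge heights.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .divergence import DistanceMatrix

__all__ = ["Dendrogram", "MojenaCut", "UPGMAClustering",
           "upgma_tree", "cophenetic_matrix", "mojena_cut", "to_newick"]


@dataclasses.dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree in scipy linkage form.

    ``linkage`` is the (g-1) x 4 scipy matrix: each row merges two node ids
    (leaves are 0..g-1, internal nodes g, g+1, ...) at a fusion height, with
    the new cluster's leaf count in the last column.
    """

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def g(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()


@dataclasses.dataclass(frozen=True)
class MojenaCut:
    cutoff: float
    c: float
    mean_height: float
    sd_height: float
    n_groups: int
    membership: dict[str, int]
    degenerate: bool = False  # g == 2: sd undefined, single group returned


def _coerce(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DistanceMatrix):
        return D.array(), D.genotypes
    d = np.asarray(D, dtype=float)
    return d, [str(i) for i in range(d.shape[0])]


def upgma_tree(D) -> Dendrogram:
    """Average-linkage (true UPGMA) merge tree from a distance matrix."""
    d, labels = _coerce(D)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, labels=tuple(labels))


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Cophenetic distances: height of the first merge uniting each pair."""
    import pandas as pd

    coph = squareform(hierarchy.cophenet(tree.linkage))
    return DistanceMatrix(
        values=pd.DataFrame(coph, index=list(tree.labels),
                            columns=list(tree.labels)),
        metric="cophenetic",
    )


def mojena_cut(tree: Dendrogram, c: float = 1.25) -> MojenaCut:
    """Cut the dendrogram at mean(heights) + c * sd(heights).

    With only one merge (g = 2) the sd is undefined; a single group is
    returned with ``degenerate=True``.
    """
    if c <= 0:
        raise ValueError("Mojena constant c must be positive")
    h = tree.heights
    if h.size < 2:
        return MojenaCut(
            cutoff=float(h[0]), c=c, mean_height=float(h[0]),
            sd_height=float("nan"), n_groups=1,
            membership={lab: 1 for lab in tree.labels}, degenerate=True,
        )
    mean, sd = float(h.mean()), float(h.std(ddof=1))
    cutoff = mean + c * sd
    flat = hierarchy.fcluster(tree.linkage, t=cutoff, criterion="distance")
    return MojenaCut(
        cutoff=cutoff, c=c, mean_height=mean, sd_height=sd,
        n_groups=int(flat.max()),
        membership={lab: int(grp) for lab, grp in zip(tree.labels, flat)},
    )


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (heights halved)."""
    root = hierarchy.to_tree(tree.linkage)

    def render(node, parent_height: float) -> str:
        height = node.dist / 2.0
        branch = parent_height - height
        if node.is_leaf():
            return f"{_newick_label(tree.labels[node.id])}:{branch:.10g}"
        left = render(node.left, height)
        right = render(node.right, height)
        return f"({left},{right}):{branch:.10g}"

    height = root.dist / 2.0
    left = render(root.left, height)
    right = render(root.right, height)
    return f"({left},{right});"


class UPGMAClustering(ClusterMixin, BaseEstimator):
    """UPGMA + Mojena cut as a clustering estimator on precomputed distances.

    Parameters
    ----------
    mojena_c : float, default 1.25
        Constant of Mojena's stopping rule.

    Attributes
    ----------
    labels_ : ndarray of int
        Group id per genotype at the Mojena cutoff.
    tree_ : Dendrogram
    cut_ : MojenaCut
    """

    def __init__(self, mojena_c: float = 1.25):
        self.mojena_c = mojena_c

    def fit(self, X, y=None):
        tree = upgma_tree(X)
        cut = mojena_cut(tree, c=self.mojena_c)
        self.tree_ = tree
        self.cut_ = cut
        self.labels_ = np.asarray([cut.membership[lab] for lab in tree.labels])
        return self
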