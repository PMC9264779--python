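"""Community-structure clustering: similarity matrices, dendrograms, cuts.

Sites are compared by a presence/absence similarity (Jaccard, Sorensen, or
Bray-Curtis, which on binary data equals Sorensen similarity), clustered
agglomeratively on dissimilarity = 1 - similarity with group-average (UPGMA)
or complete (furthest-neighbour) linkage, and the dendrogram can be cut at a
similarity threshold to assign sites to groups or exported to Newick.

Sites are sorted lexicographically before linkage so the tree (and the group
labels, which follow first appearance in that order) never depend on the
input column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .checklist import OccurrenceMatrix
from .errors import ValidationError

METRICS = ("jaccard", "sorensen", "bray-curtis")
LINKAGES = ("average", "complete")


def similarity_matrix(matrix: OccurrenceMatrix, metric: str = "jaccard",
                      transform: str = "none") -> pd.DataFrame:
    """Site x site similarity (unit diagonal, symmetric).

    ``transform='log1p'`` applies log(1+x) to the incidence values before a
    Bray-Curtis comparison; on 0/1 data it rescales presences by a constant
    and is therefore a no-op for every supported metric.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if transform not in ("none", "log1p"):
        raise ValidationError(f"unknown transform {transform!r}")
    x = matrix.values_sites_by_species().astype(float)
    if transform == "log1p":
        x = np.log1p(x)
    pres = x > 0
    a = (pres.astype(float) @ pres.astype(float).T)
    s = pres.sum(axis=1).astype(float)
    b = s[:, None] - a
    c = b.T
    if metric == "jaccard":
        sim = a / (a + b + c)
    elif metric == "sorensen":
        sim = 2 * a / (2 * a + b + c)
    else:  # bray-curtis on the (possibly transformed) quantitative values
        num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
        sim = 1.0 - num / den
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.sites, columns=matrix.sites)


@dataclass
class Dendrogram:
    """A binary merge tree over sites, heights on the dissimilarity scale."""

    linkage_matrix: np.ndarray   # scipy linkage format
    labels: list[str]            # leaf order used for linkage (sorted)
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)


def cluster(similarity: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on dissimilarity = 1 - similarity."""
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")
    sim = similarity.to_numpy()
    if not np.allclose(sim, sim.T):
        raise ValidationError("similarity matrix is not symmetric")
    labels = sorted(similarity.index.tolist())
    sim = similarity.loc[labels, labels].to_numpy()
    dis = 1.0 - sim
    np.fill_diagonal(dis, 0.0)
    z = _scipy_linkage(squareform(dis, checks=False), method=linkage)
    return Dendrogram(linkage_matrix=z, labels=labels, method=linkage)


def cut_at(dendrogram: Dendrogram, similarity_threshold: float) -> pd.Series:
    """Group assignment: components joined at dissimilarity <= 1 - threshold.

    Group numbers start at 1 and follow the first member site in the
    dendrogram's (lexicographic) label order.
    """
    if not 0.0 <= similarity_threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    t = 1.0 - similarity_threshold
    raw = fcluster(dendrogram.linkage_matrix, t=t, criterion="distance")
    remap: dict[int, int] = {}
    groups = []
    for g in raw:
        if g not in remap:
            remap[g] = len(remap) + 1
        groups.append(remap[g])
    return pd.Series(groups, index=dendrogram.labels, name="group")


def to_newick(dendrogram: Dendrogram, fmt: str = "%.10g") -> str:
    """Newick export with ultrametric branch lengths.

    A merge at height h places both children at depth h/2 below the node, so
    the tree distance between two leaves equals their cophenetic
    dissimilarity.
    """
    z = dendrogram.linkage_matrix
    labels = dendrogram.labels
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    for k, (li, ri, h, _) in enumerate(z):
        height[n + k] = float(h)

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        li, ri = int(z[node - n, 0]), int(z[node - n, 1])
        parts = []
        for child in (li, ri):
            bl = (height[node] - height[child]) / 2.0
            parts.append(f"{render(child)}:{fmt % bl}")
        return "(" + ",".join(parts) + ")"

    root = n + len(z) - 1
    return render(root) + ";"
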