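"""Population-structure views of the PAV matrix.

Binary occupancy profiles are compared with simple-matching (default) or
Jaccard distance; the resulting matrix feeds a neighbor-joining tree
(Saitou–Nei, exact on additive distances) and Ward agglomerative clustering
cut into K groups labelled A, B, C, ... in order of decreasing size.

The Ward variant is "ward.D": the Lance–Williams update with coefficients
alpha_i = (n_i + n_k) / (n_i + n_j + n_k), beta = -n_k / (n_i + n_j + n_k),
gamma = 0 applied directly to squared-Euclidean dissimilarities (for binary
rows the squared Euclidean distance is the Hamming count).  It is computed
via the standard ward linkage on the raw rows — whose recurrence operates
on exactly those squared distances — with merge heights squared afterwards
to put them back on the squared-distance scale.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io_formats import TreeNode
from .pav_build import PAVMatrix

logger = logging.getLogger("panpav")

__all__ = [
    "DistanceMatrix",
    "pav_distance",
    "nj_tree",
    "ward_cluster",
    "WardResult",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")


def pav_distance(pav: PAVMatrix | pd.DataFrame,
                 metric: str = "simple-matching") -> DistanceMatrix:
    """Pairwise distances between accession PAV profiles.

    simple-matching: fraction of clusters whose presence differs.
    jaccard: 1 - |intersection| / |union| of presences; a pair with empty
    union gets distance 0 with a warning.
    """
    mat = pav.matrix if isinstance(pav, PAVMatrix) else pav
    ids = list(mat.columns)
    if len(ids) < 2:
        raise ValueError("need >= 2 accessions")
    x = mat.to_numpy().T.astype(bool)
    if metric == "simple-matching":
        d = squareform(pdist(x, metric="hamming"))
    elif metric == "jaccard":
        union = (x[:, None, :] | x[None, :, :]).sum(axis=2)
        if np.any((union == 0) & ~np.eye(len(ids), dtype=bool)):
            logger.warning("pav_distance: pair with empty union; distance set to 0")
        d = squareform(pdist(x, metric="jaccard"))
        d[union == 0] = 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids, d)


def nj_tree(dist: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Neighbor-joining tree (Saitou–Nei) from a distance matrix.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current agglomeration order.  Branch lengths come from the standard
    two-point formulas and are reported as computed; ``clamp_negative``
    clips them at zero.  The returned tree is unrooted, represented with a
    trifurcating top node.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dist.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dist.ids]
    active = list(range(n))

    def branch(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        vals = q[iu]
        # row-major upper triangle: the first minimum is the smallest (i, j)
        k = int(np.flatnonzero(vals == vals.min())[0])
        ii, jj = int(iu[0][k]), int(iu[1][k])
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = dij / 2 + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = branch(li)
        nodes[j].length = branch(lj)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for kk in active:
            new_row[kk] = (D[i, kk] + D[j, kk] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = branch((dab + dac - dbc) / 2)
    nodes[b].length = branch((dab + dbc - dac) / 2)
    nodes[c].length = branch((dac + dbc - dab) / 2)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


_ALPHA = string.ascii_uppercase


def _letter_label(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = _ALPHA[rem] + out
    return out


@dataclass
class WardResult:
    """Ward clustering output: labels plus the merge history."""

    labels: pd.Series            # row id -> letter label
    merge_history: np.ndarray    # scipy linkage matrix; heights on the
                                 # squared-Euclidean (ward.D) scale
    k: int


def ward_cluster(data: pd.DataFrame | np.ndarray, k: int = 8,
                 axis: str = "rows") -> WardResult:
    """Ward.D agglomerative clustering cut into exactly k clusters.

    ``axis="rows"`` clusters the matrix rows (pan-genes of a PAV table);
    ``axis="columns"`` clusters accessions.  Labels A, B, ... are assigned
    in order of decreasing cluster size, ties broken by first-row index.
    """
    if isinstance(data, PAVMatrix):
        data = data.matrix
    df = pd.DataFrame(data)
    if axis == "columns":
        df = df.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds {n} rows")
    link = hierarchy.linkage(x, method="ward")
    link = link.copy()
    link[:, 2] = link[:, 2] ** 2     # back to ward.D (squared-Euclidean) heights
    assign = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # relabel by decreasing size, ties by first occurrence
    first = {}
    size = {}
    for idx, c in enumerate(assign):
        size[c] = size.get(c, 0) + 1
        first.setdefault(c, idx)
    ordered = sorted(size, key=lambda c: (-size[c], first[c]))
    remap = {c: _letter_label(i) for i, c in enumerate(ordered)}
    labels = pd.Series([remap[c] for c in assign], index=df.index, name="cluster")
    return WardResult(labels, link, k)
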