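"""Per-group Pearson correlation of the marker panel and Ward clustering.

Correlation structure is examined separately in each participant group; the
marker-by-marker correlation matrix (with a p < 0.05 significance mask) is
then clustered with Ward's minimum-variance method on 1 - r dissimilarities,
giving a dendrogram and a leaf ordering for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CohortTable

ALPHA = 0.05


@dataclass
class CorrelationResult:
    group: str
    marker_names: tuple[str, ...]
    r: np.ndarray  # p x p, symmetric, unit diagonal
    p: np.ndarray  # p x p, symmetric, diagonal 1 by convention
    sig_mask: np.ndarray  # boolean, off-diagonal p < 0.05
    n: int


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` lists (cluster_a, cluster_b, height) for the n-1 merges;
    leaves are 0..n-1 and merge k creates cluster n+k (as in scipy linkage).
    Heights are the Ward criterion value of each merge (for Euclidean input
    this is twice the within-cluster variance increase).
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def leaf_order(self) -> list[int]:
        """Left-to-right dendrogram leaf ordering."""
        members = {}

        def leaves(c: int) -> list[int]:
            if c < self.n_leaves:
                return [c]
            return members[c]

        for k, (a, b, _) in enumerate(self.merges):
            members[self.n_leaves + k] = leaves(a) + leaves(b)
        if not self.merges:
            return list(range(self.n_leaves))
        return members[self.n_leaves + len(self.merges) - 1]

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0..k-1) from stopping before the last k-1 merges."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        members = {i: [i] for i in range(self.n_leaves)}
        active = set(range(self.n_leaves))
        for j, (a, b, _) in enumerate(self.merges[: self.n_leaves - k]):
            cid = self.n_leaves + j
            members[cid] = members.pop(a) + members.pop(b)
            active.discard(a)
            active.discard(b)
            active.add(cid)
        labels = np.empty(self.n_leaves, dtype=int)
        for lab, cid in enumerate(sorted(active)):
            labels[members[cid]] = lab
        return labels

    def to_newick(self, names: list[str] | None = None) -> str:
        """Newick text; branch lengths are merge-height increments."""
        names = names if names is not None else [str(i) for i in range(self.n_leaves)]
        height_of = {i: 0.0 for i in range(self.n_leaves)}

        def node(c: int) -> str:
            if c < self.n_leaves:
                return names[c]
            a, b, h = self.merges[c - self.n_leaves]
            return (
                f"({node(a)}:{h - height_of[a]:.6g},{node(b)}:{h - height_of[b]:.6g})"
            )

        for k, (_, _, h) in enumerate(self.merges):
            height_of[self.n_leaves + k] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return node(root) + ";"


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    return float(stats.pearsonr(x, y).statistic)


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via t = r sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| > 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def correlation_matrix(table: CohortTable, group: str) -> CorrelationResult:
    """All pairwise marker correlations within one participant group."""
    X = table.group_markers(group)
    n, p = X.shape
    if n < 4:
        raise ValueError(f"group {group} has n={n} < 4")
    r = np.eye(p)
    pv = np.ones((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rij = pearson_r(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rij
            pv[i, j] = pv[j, i] = pearson_p(rij, n)
    mask = (pv < ALPHA) & ~np.eye(p, dtype=bool)
    return CorrelationResult(
        group=group, marker_names=table.marker_names, r=r, p=pv, sig_mask=mask, n=n
    )


def ward_cluster(dissimilarity: np.ndarray) -> Dendrogram:
    """Ward's minimum-variance agglomeration of a dissimilarity matrix.

    Works on squared input dissimilarities with the Lance–Williams update
        d2(ij,k) = [(ni+nk) d2(i,k) + (nj+nk) d2(j,k) - nk d2(i,j)] / (ni+nj+nk);
    each merge joins the pair with the smallest current criterion value
    (ties broken toward the lowest cluster-id pair), and that value is the
    recorded height. Heights are non-decreasing.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity must be non-negative with zero diagonal")

    d2 = {}  # (cid_a, cid_b) with a < b -> squared dissimilarity
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = D[i, j] ** 2
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        new = n + step
        merges.append((a, b, float(h)))
        na, nb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            nc = size[c]
            dac = d2[(min(a, c), max(a, c))]
            dbc = d2[(min(b, c), max(b, c))]
            d2[(c, new)] = ((na + nc) * dac + (nb + nc) * dbc - nc * h) / (na + nb + nc)
        active = [c for c in active if c not in (a, b)] + [new]
        size[new] = na + nb
        d2 = {k: v for k, v in d2.items() if a not in k and b not in k}

    return Dendrogram(merges=merges, n_leaves=n)


def cluster_markers(corr: CorrelationResult, k: int = 2):
    """Cluster markers on 1 - r; returns the dendrogram, leaf order, the
    correlation matrix reordered by leaves, and the k-cluster memberships."""
    diss = 1.0 - corr.r
    np.fill_diagonal(diss, 0.0)
    diss = np.clip(diss, 0.0, None)
    dend = ward_cluster(diss)
    order = dend.leaf_order()
    reordered = corr.r[np.ix_(order, order)]
    labels = dend.cut(k)
    return dend, order, reordered, labels
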