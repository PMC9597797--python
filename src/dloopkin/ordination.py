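"""Ordination and clustering of dissimilarity matrices.

Non-metric multidimensional scaling (NMDS) embeds a dissimilarity matrix in
the plane by minimizing Kruskal stress-1,

    stress1 = sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 ),

where d are the embedded distances and dhat the disparities obtained by
monotone (isotonic, pool-adjacent-violators) regression of d on the observed
dissimilarities.  The optimisation is non-convex, so the embedding is run
from several random starts plus a classical-scaling start and the best
configuration is kept; the seed is recorded.

UPGMA (average-linkage agglomeration) clusters the same matrices into an
ultrametric dendrogram with merge heights equal to half the merge distance,
exported as Newick so standard tree viewers apply.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from dloopkin.tree_model import write_newick


def _as_square(dissimilarity) -> tuple[np.ndarray, list[str]]:
    if isinstance(dissimilarity, pd.DataFrame):
        labels = [str(x) for x in dissimilarity.index]
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        labels = [f"I{i + 1}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be square and symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity diagonal must be zero")
    return d, labels


def kruskal_stress1(diss: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration against observed dissimilarities."""
    iu = np.triu_indices(diss.shape[0], k=1)
    obs = diss[iu]
    emb = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
    denom = (emb**2).sum()
    if denom == 0:
        return 0.0
    order = np.argsort(obs, kind="stable")
    dhat = np.empty_like(emb)
    dhat[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), emb[order]
    )
    return float(np.sqrt(((dhat - emb) ** 2).sum() / denom))


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))


@dataclass
class OrdinationResult:
    """NMDS embedding: centered item coordinates, stress-1, provenance."""

    coordinates: pd.DataFrame  # items x dims
    stress: float
    n_restarts_used: int
    seed: int

    def to_tsv(self, path) -> None:
        self.coordinates.to_csv(path, sep="\t", lineterminator="\n")


def nmds(
    dissimilarity,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> OrdinationResult:
    """Best-of-restarts non-metric MDS minimizing Kruskal stress-1.

    One start is the classical-scaling configuration; the rest are random,
    derived deterministically from ``seed``.  An all-zero matrix is
    degenerate: coincident points and zero stress, with a warning.
    """
    d, labels = _as_square(dissimilarity)
    n = d.shape[0]
    if n < dims + 2:
        raise ValueError(f"need at least {dims + 2} items for a {dims}-D fit")
    if np.all(d == 0):
        warnings.warn("all-zero dissimilarity: degenerate embedding")
        coords = pd.DataFrame(
            np.zeros((n, dims)),
            index=labels,
            columns=[f"dim{k + 1}" for k in range(dims)],
        )
        return OrdinationResult(coords, 0.0, 0, seed)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray | None] = [_classical_scaling(d, dims)]
    starts += [None] * max(n_restarts - 1, 0)
    best_coords, best_stress = None, np.inf
    for start in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _ = smacof(
                d,
                metric=False,
                n_components=dims,
                init=start,
                n_init=1,
                max_iter=max_iter,
                eps=1e-12,
                random_state=int(rng.integers(2**31 - 1)),
                normalized_stress=True,
            )
        s = kruskal_stress1(d, coords)
        if s < best_stress:
            best_stress, best_coords = s, coords
    best_coords = best_coords - best_coords.mean(axis=0)
    frame = pd.DataFrame(
        best_coords, index=labels, columns=[f"dim{k + 1}" for k in range(dims)]
    )
    return OrdinationResult(frame, best_stress, len(starts), seed)


@dataclass
class Dendrogram:
    """UPGMA result: ultrametric tree plus the cophenetic structure."""

    tree: dendropy.Tree
    merge_heights: list[float]
    labels: list[str]

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 x the MRCA merge height)."""
        n = len(self.labels)
        tips = {
            leaf.taxon.label: leaf for leaf in self.tree.leaf_node_iter()
        }
        # depth of each node below the root
        depth: dict = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            depth[node] = (depth[parent] if parent else 0.0) + (
                node.edge.length or 0.0
            )
        root_h = max(depth[tips[l]] for l in self.labels)
        out = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = tips[self.labels[i]], tips[self.labels[j]]
            anc_a = set()
            cur = a
            while cur is not None:
                anc_a.add(cur)
                cur = cur.parent_node
            cur = b
            while cur not in anc_a:
                cur = cur.parent_node
            h = root_h - depth[cur]  # height of the MRCA above the tips
            out[i, j] = out[j, i] = 2.0 * h
        return pd.DataFrame(out, index=self.labels, columns=self.labels)

    def to_newick(self, path=None) -> str:
        return write_newick(self.tree, path)


def upgma(dissimilarity) -> Dendrogram:
    """Average-linkage agglomeration with smallest-index-pair tie-breaking.

    Merge heights are half the merge distances, so tip-to-tip cophenetic
    distances reproduce ultrametric inputs exactly.
    """
    d, labels = _as_square(dissimilarity)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")

    nodes: list[dendropy.Node] = []
    taxon_ns = dendropy.TaxonNamespace()
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_ns.require_taxon(label=lab)
        nodes.append(node)
    heights = [0.0] * n  # height of each active cluster's root
    sizes = [1] * n
    order = list(range(n))  # creation index, for tie-breaking
    active = list(range(n))
    d = d.astype(float).copy()
    merge_heights: list[float] = []

    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(range(len(active)), 2):
            i, j = active[a], active[b]
            key = (d[i, j], order[i], order[j])
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = d[i, j] / 2.0
        merge_heights.append(h)
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
        nodes[i].edge.length = h - heights[i]
        nodes[j].edge.length = h - heights[j]
        # average-linkage update, weighted by cluster sizes
        new = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new[c] = (sizes[i] * d[i, c] + sizes[j] * d[j, c]) / (
                sizes[i] + sizes[j]
            )
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new[:-1]
        d[:-1, -1] = new[:-1]
        nodes.append(parent)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        order.append(min(order[i], order[j]))
        active = [c for c in active if c not in (i, j)] + [d.shape[0] - 1]

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return Dendrogram(tree=tree, merge_heights=merge_heights, labels=labels)
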