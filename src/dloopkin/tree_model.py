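"""Tree model: Newick I/O, K2P distances, neighbour joining, outgroup
rooting, and haplogroup assignment by clade placement.

Trees are :class:`dendropy.Tree` objects throughout (rooted interpretation;
tips carry sequence ids as taxon labels).  The external maximum-likelihood
tree of a real analysis is simply parsed from Newick; the internal
neighbour-joining builder is a desk-scale surrogate used for synthetic data
and testing.

Haplogroup assignment places each query tip in the smallest ancestral clade
that contains at least one labelled reference; if all references in that
clade agree the query inherits their haplogroup, otherwise the nearest
reference by patristic distance decides (flagged as a fallback).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_RESOLVED = frozenset("ACGT")


class NewickParseError(ValueError):
    """Malformed Newick input."""


class SaturationError(ValueError):
    """K2P log argument non-positive: distance undefined (saturation)."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted :class:`dendropy.Tree`.

    Tip names and branch lengths are preserved; polytomies are kept as-is.
    Duplicate tip names or syntax errors raise :class:`NewickParseError`.
    """
    if ";" not in text:
        raise NewickParseError("Newick string lacks terminating semicolon")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"Newick parse failed: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise NewickParseError(f"duplicate tip name(s): {sorted(dup)}")
    tree.is_rooted = True
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize to Newick (quoted labels where needed); optionally write."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text + "\n")
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# distances


def k2p_distance(seq1: str, seq2: str, min_shared: int = 1) -> float:
    """Kimura two-parameter distance (substitutions/site).

    ``d = 1/2 ln(1/(1-2P-Q)) + 1/4 ln(1/(1-2Q))`` with P and Q the transition
    and transversion proportions over shared resolved (A/C/G/T) positions
    (pairwise deletion).  Raises :class:`SaturationError` when a log argument
    is non-positive and :class:`ValueError` when fewer than ``min_shared``
    sites are comparable.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _RESOLVED or b not in _RESOLVED:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if n < min_shared:
        raise ValueError(
            f"only {n} shared resolved sites (< {min_shared}); distance rejected"
        )
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined at P={P:.4f}, Q={Q:.4f}")
    return 0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)


def k2p_distance_matrix(
    records: Sequence, min_shared: int = 50
) -> pd.DataFrame:
    """Symmetric K2P distance matrix over records (pairwise deletion).

    Pairs sharing fewer than ``min_shared`` resolved sites are rejected with
    an error: partial D-loop fragments of near-disjoint coverage give
    meaningless distances.
    """
    ids = [r.id for r in records]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = k2p_distance(
            records[i].sequence, records[j].sequence, min_shared=min_shared
        )
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(dist: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Saitou–Nei neighbour joining, rooted at the final amalgamation.

    Ties in the Q criterion are broken by the smallest taxon-index pair (in
    input order), making the topology reproducible.  Requires a symmetric
    zero-diagonal matrix with at least 3 taxa.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"T{i + 1}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = d.copy()

    taxon_ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_ns.require_taxon(label=lab)
        nodes.append(node)
    order = list(range(n))  # creation index per active row, for tie-breaking
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a, b in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[a, b] - r[a] - r[b]
            key = (q, order[active[a]], order[active[b]])
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = length
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (d[i, c] + d[j, c] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        order.append(min(order[i], order[j]))
        active = [c for c in active if c not in (i, j)] + [d.shape[0] - 1]

    i, j = active
    dij = d[i, j]
    root = dendropy.Node()
    for child, length in ((nodes[i], dij / 2.0), (nodes[j], dij / 2.0)):
        root.add_child(child)
        child.edge.length = length
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# rooting


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_ids: Sequence[str]
) -> dendropy.Tree:
    """Root on the edge separating the outgroup tips from everything else.

    The branch is split evenly.  Raises if the outgroup is not a connectable
    group in the unrooted sense (i.e. no edge induces exactly that tip
    bipartition), listing the offending tips.
    """
    out = set(outgroup_ids)
    if not out:
        raise ValueError("outgroup_ids must be non-empty")
    work = tree.clone(depth=1)
    all_tips = set(tip_labels(work))
    missing = out - all_tips
    if missing:
        raise KeyError(f"outgroup tip(s) absent from tree: {sorted(missing)}")
    if out == all_tips:
        raise ValueError("outgroup cannot be the whole tree")

    # leaf set under each node
    leafset: dict[dendropy.Node, frozenset[str]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = frozenset([node.taxon.label])
        else:
            leafset[node] = frozenset().union(*(leafset[c] for c in node.child_nodes()))

    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        if leafset[node] == out or leafset[node] == frozenset(all_tips - out):
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup is not monophyletic in the unrooted sense: {sorted(out)}"
        )

    # already rooted correctly: root child subtends exactly the outgroup
    root_children = work.seed_node.child_nodes()
    if len(root_children) == 2 and any(leafset[c] == out for c in root_children):
        return work

    edge = target.edge
    length = edge.length if edge.length is not None else None
    if length is not None:
        work.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    else:
        work.reroot_at_edge(edge)
    work.is_rooted = True
    return work


# ---------------------------------------------------------------------------
# haplogroup assignment

HAPLOGROUPS = ("A", "B", "C", "D", "E")


@dataclass
class HaplogroupAssignment:
    """Haplogroup per tip id plus a support note per assignment.

    ``support[id]`` is ``"clade"`` when the smallest reference-containing
    ancestral clade was unanimous, ``"nearest"`` when the patristic-distance
    fallback decided, or ``"reference"`` for the reference tips themselves.
    """

    haplogroup: dict[str, str] = field(default_factory=dict)
    support: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {h: 0 for h in HAPLOGROUPS}
        for h in self.haplogroup.values():
            out[h] = out.get(h, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.haplogroup),
                "haplogroup": [self.haplogroup[i] for i in self.haplogroup],
                "support": [self.support[i] for i in self.haplogroup],
            }
        )


def _patristic_to_references(
    tree: dendropy.Tree, query: dendropy.Node, ref_nodes: Mapping[str, dendropy.Node]
) -> dict[str, float]:
    """Patristic distance from one query tip to each reference tip.

    Missing branch lengths count as 0; errors if the tree carries no branch
    lengths at all (topology-only trees cannot feed the distance fallback).
    """
    any_length = any(
        e.length not in (None, 0) for e in tree.preorder_edge_iter()
    )
    if not any_length:
        raise ValueError(
            "patristic fallback needs branch lengths; tree is topology-only"
        )

    def depth_chain(node):
        chain = {}
        depth = 0.0
        cur = node
        while cur is not None:
            chain[cur] = depth
            depth += cur.edge.length or 0.0
            cur = cur.parent_node
        return chain

    qchain = depth_chain(query)
    out = {}
    for rid, rnode in ref_nodes.items():
        depth = 0.0
        cur = rnode
        while cur not in qchain:
            depth += cur.edge.length or 0.0
            cur = cur.parent_node
        out[rid] = depth + qchain[cur]
    return out


def assign_haplogroups(
    tree: dendropy.Tree, reference_labels: Mapping[str, str]
) -> HaplogroupAssignment:
    """Assign every tip a haplogroup from labelled reference tips.

    Each query inherits the haplogroup of the smallest ancestral clade
    containing at least one reference, provided all references inside that
    clade agree; mosaic clades fall back to the nearest reference by
    patristic distance (flagged ``"nearest"``).  Requires at least one
    reference per haplogroup present among ``reference_labels``.
    """
    groups = set(reference_labels.values())
    if not groups:
        raise ValueError("no reference labels supplied")
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [rid for rid in reference_labels if rid not in tips]
    if missing:
        raise KeyError(f"reference tip(s) absent from tree: {missing}")

    # reference haplogroup multiset under each node
    refs_below: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            refs_below[node] = (
                {reference_labels[lab]} if lab in reference_labels else set()
            )
        else:
            refs_below[node] = set().union(
                *(refs_below[c] for c in node.child_nodes())
            )

    ref_nodes = {rid: tips[rid] for rid in reference_labels}
    result = HaplogroupAssignment()
    for lab, leaf in tips.items():
        if lab in reference_labels:
            result.haplogroup[lab] = reference_labels[lab]
            result.support[lab] = "reference"
            continue
        node = leaf.parent_node
        while node is not None and not refs_below[node]:
            node = node.parent_node
        if node is None:
            raise ValueError("tree contains no reference tips")
        found = refs_below[node]
        if len(found) == 1:
            result.haplogroup[lab] = next(iter(found))
            result.support[lab] = "clade"
        else:
            dists = _patristic_to_references(tree, leaf, ref_nodes)
            nearest = min(dists, key=lambda r: (dists[r], r))
            result.haplogroup[lab] = reference_labels[nearest]
            result.support[lab] = "nearest"
    return result


def read_reference_labels(path) -> dict[str, str]:
    """Read an ``id<TAB>haplogroup`` reference table."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("reference table needs two columns: id, haplogroup")
    first = df.iloc[0]
    if {str(first[0]).lower(), str(first[1]).lower()} == {"id", "haplogroup"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
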