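"""Type-1 and type-2 phylogenetic connection counting between breeds.

The central statistic of the pipeline.  Reading the rooted tree exactly as
exported:

* a **type-1 connection** links the breeds of two tips that are strictly
  sister (a *cherry*: an internal node whose children are exactly two tips);
* a **type-2 connection** links the breed of a tip whose sister clade is a
  cherry to the breed of each cherry tip (two links per configuration; the
  cherry-internal pair itself is counted only by type 1, never re-counted
  here).

Counts accumulate into a symmetric breed x breed integer matrix with
within-breed links on the diagonal.  Profiles express one focal breed's
partner counts as percentages, optionally merging partner breeds into
regional groups and truncating at a retention fraction — the form in which
breed affinity repertoires are compared.

Polytomies are handled by a logged generalization: a polytomy with m >= 2
tip children emits all C(m,2) tip pairs as type-1; maximum-likelihood trees
are binary so this never fires on real exports.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def find_type1_pairs(tree: dendropy.Tree) -> list[tuple[str, str]]:
    """Tip-id pairs of strictly sister sequences (cherries).

    For a binary internal node whose two children are both tips, emits that
    pair.  For a polytomy with m >= 2 tip children, emits all C(m,2) pairs
    (generalization, logged).  The root's own children are eligible.
    """
    pairs: list[tuple[str, str]] = []
    for node in tree.preorder_internal_node_iter():
        tip_children = [c.taxon.label for c in node.child_nodes() if c.is_leaf()]
        if len(node.child_nodes()) == 2 and len(tip_children) == 2:
            pairs.append((tip_children[0], tip_children[1]))
        elif len(node.child_nodes()) > 2 and len(tip_children) >= 2:
            logger.info(
                "polytomy with %d tip children: emitting all pairs",
                len(tip_children),
            )
            pairs.extend(itertools.combinations(tip_children, 2))
    return pairs


def find_type2_triples(tree: dendropy.Tree) -> list[tuple[str, str, str]]:
    """(tip, cherry-tip, cherry-tip) triples: a tip sister to a cherry.

    For every internal node with exactly two children, one a tip ``t`` and
    the other a cherry ``{x, y}``, emits ``(t, x, y)``.  Each triple stands
    for the two connections t–x and t–y; the x–y link is type 1 and is not
    re-counted.
    """
    triples: list[tuple[str, str, str]] = []
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2:
            continue
        for tip, other in ((children[0], children[1]), (children[1], children[0])):
            if not tip.is_leaf() or other.is_leaf():
                continue
            grand = other.child_nodes()
            if len(grand) == 2 and all(g.is_leaf() for g in grand):
                triples.append(
                    (tip.taxon.label, grand[0].taxon.label, grand[1].taxon.label)
                )
    return triples


@dataclass
class ConnectionMatrix:
    """Symmetric breed x breed matrix of connection counts.

    ``counts`` is a pandas DataFrame indexed by breed in both dimensions;
    the diagonal holds within-breed links.  ``kinship_type`` is 1 or 2.
    """

    counts: pd.DataFrame
    kinship_type: int

    @property
    def breeds(self) -> list[str]:
        return list(self.counts.index)

    def total(self) -> int:
        """Sum of the upper triangle plus the diagonal (each link once)."""
        arr = self.counts.to_numpy()
        return int(np.triu(arr).sum())

    def row_total(self, breed: str, include_self: bool = False) -> int:
        """Focal breed's links over all partners; diagonal excluded unless
        ``include_self``."""
        row = self.counts.loc[breed]
        total = int(row.sum())
        if not include_self:
            total -= int(self.counts.at[breed, breed])
        return total

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, kinship_type: int) -> "ConnectionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, kinship_type=kinship_type)


def connection_matrix(
    tree: dendropy.Tree,
    breed_of: Mapping[str, str],
    kinship_type: int,
    breeds: Sequence[str] | None = None,
) -> ConnectionMatrix:
    """Accumulate type-1 pairs or type-2 triples into breed counts.

    ``breed_of`` maps every tip id to a breed code; unresolvable tips raise.
    ``breeds`` fixes the matrix ordering (default: sorted codes present).
    """
    if kinship_type not in (1, 2):
        raise ValueError("kinship_type must be 1 or 2")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unresolved = [t for t in labels if t not in breed_of]
    if unresolved:
        raise KeyError(f"tip(s) with no breed: {unresolved}")

    if breeds is None:
        breeds = sorted({breed_of[t] for t in labels})
    idx = {b: k for k, b in enumerate(breeds)}
    counts = np.zeros((len(breeds), len(breeds)), dtype=int)

    if kinship_type == 1:
        links = find_type1_pairs(tree)
    else:
        links = [
            pair
            for (t, x, y) in find_type2_triples(tree)
            for pair in ((t, x), (t, y))
        ]
    for a, b in links:
        i, j = idx[breed_of[a]], idx[breed_of[b]]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    df = pd.DataFrame(counts, index=list(breeds), columns=list(breeds))
    return ConnectionMatrix(counts=df, kinship_type=kinship_type)


@dataclass
class BreedProfile:
    """One focal breed's partner repertoire as counts and percentages.

    ``partners`` maps partner (breed or merged group) to ``(count, percent)``
    where percents are over ALL partners; ``retained`` is the ordered list of
    partners kept after greedy truncation at the retention fraction, and
    ``retained_fraction`` the share of links they actually cover.
    """

    focal: str
    partners: dict[str, tuple[int, float]]
    retained: list[str]
    retained_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "partner": p,
                "count": self.partners[p][0],
                "percent": self.partners[p][1],
                "retained": p in self.retained,
            }
            for p in sorted(
                self.partners, key=lambda q: (-self.partners[q][0], q)
            )
        ]
        return pd.DataFrame(rows)


def breed_profile(
    matrix: ConnectionMatrix,
    focal: str,
    grouping: Mapping[str, str] | None = None,
    retention_fraction: float = 1.0,
    include_self: bool = False,
) -> BreedProfile:
    """Partner counts of a focal breed, merged by group and truncated.

    Percentages are computed over all partners (diagonal excluded unless
    ``include_self``); partners are then ranked by count (ties by name) and
    retained greedily until the cumulative percent reaches
    ``100 * retention_fraction``.
    """
    if focal not in matrix.breeds:
        raise KeyError(f"focal breed {focal!r} not in matrix")
    if not 0 < retention_fraction <= 1:
        raise ValueError("retention_fraction must be in (0, 1]")
    grouping = dict(grouping or {})
    merged: dict[str, int] = {}
    for partner in matrix.breeds:
        if partner == focal and not include_self:
            continue
        c = int(matrix.counts.at[focal, partner])
        if c == 0:
            continue
        group = grouping.get(partner, partner)
        merged[group] = merged.get(group, 0) + c
    total = sum(merged.values())
    partners = {
        g: (c, 100.0 * c / total if total else 0.0) for g, c in merged.items()
    }
    ranked = sorted(partners, key=lambda g: (-partners[g][0], g))
    retained: list[str] = []
    cum = 0.0
    for g in ranked:
        if cum >= 100.0 * retention_fraction:
            break
        retained.append(g)
        cum += partners[g][1]
    return BreedProfile(
        focal=focal,
        partners=partners,
        retained=retained,
        retained_fraction=cum / 100.0,
    )


def profile_distance_matrix(
    matrix: ConnectionMatrix, metric: str = "correlation"
) -> pd.DataFrame:
    """Breed x breed dissimilarity from connection profiles.

    ``metric="correlation"``: d(i,j) = 1 - Pearson r between the two breeds'
    partner rows, excluding both self-cells pairwise (a constant row gives an
    undefined correlation, reported as d = 1 with a warning).
    ``metric="similarity"``: d(i,j) = 1 - counts(i,j)/max(counts), the
    user-similarity transform.
    """
    breeds = matrix.breeds
    if len(breeds) < 3:
        raise ValueError("need at least 3 breeds")
    arr = matrix.counts.to_numpy(dtype=float)
    n = len(breeds)
    d = np.zeros((n, n))
    if metric == "similarity":
        mx = arr.max()
        if mx == 0:
            raise ValueError("all-zero connection matrix")
        d = 1.0 - arr / mx
        np.fill_diagonal(d, 0.0)
    elif metric == "correlation":
        undefined: list[tuple[str, str]] = []
        for i, j in itertools.combinations(range(n), 2):
            keep = [k for k in range(n) if k not in (i, j)]
            xi, xj = arr[i, keep], arr[j, keep]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                undefined.append((breeds[i], breeds[j]))
                d[i, j] = d[j, i] = 1.0
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            d[i, j] = d[j, i] = 1.0 - r
        if undefined:
            warnings.warn(
                f"constant profile row(s): correlation undefined for "
                f"{len(undefined)} pair(s) (e.g. {undefined[0]}); using d=1"
            )
    else:
        raise ValueError("metric must be 'correlation' or 'similarity'")
    return pd.DataFrame(d, index=breeds, columns=breeds)
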