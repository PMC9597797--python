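"""Pairwise PhiST between populations via distance-based AMOVA.

PhiST is the fixation index obtained from an analysis of molecular variance
on pairwise sequence differences (the default treatment of DNA haplotype
data in Arlequin).  With d(i,j) the number of differing resolved positions
between haplotypes i and j (pairwise deletion of missing data):

    SSD_total  = sum over all ordered pairs of d^2 / (2N)
    SSD_within = sum over populations of within-pop ordered d^2 / (2 n_p)
    SSD_among  = SSD_total - SSD_within
    sigma2_w   = SSD_within / (N - P)
    sigma2_a   = (SSD_among / (P - 1) - sigma2_w) / n_bar,
                 n_bar = (N - sum n_p^2 / N) / (P - 1)
    PhiST      = sigma2_a / (sigma2_a + sigma2_w)

Small negative values arise from sampling noise and are preserved (they
matter for faithful NMDS input); ``clamp_negative=True`` truncates at 0.

Population filters mirror the pre-analysis rules: populations below a
minimum size are dropped, then loci with more than 5% missing data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dloopkin.alignment_qc import MsAlignment, drop_high_missing_loci

logger = logging.getLogger(__name__)

_RESOLVED = frozenset("ACGT")


def pairwise_difference(seq1: str, seq2: str) -> int:
    """Count of differing positions where both sequences are resolved."""
    return sum(
        1
        for a, b in zip(seq1, seq2)
        if a != b and a in _RESOLVED and b in _RESOLVED
    )


def _difference_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_difference(seqs[i], seqs[j])
    return d


def _phi_st_from_distances(d: np.ndarray, sizes: list[int]) -> float:
    """AMOVA PhiST from a pooled distance matrix and population sizes."""
    N = d.shape[0]
    P = len(sizes)
    d2 = d**2
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = 0.0
    start = 0
    for n_p in sizes:
        block = d2[start : start + n_p, start : start + n_p]
        ssd_within += block.sum() / (2.0 * n_p)
        start += n_p
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - P)
    n_bar = (N - sum(n * n for n in sizes) / N) / (P - 1)
    sigma_a = (ssd_among / (P - 1) - sigma_w) / n_bar
    denom = sigma_a + sigma_w
    if denom == 0:
        warnings.warn("zero total variance; PhiST defined as 0")
        return 0.0
    return sigma_a / denom


def pairwise_phi_st(
    pop1_seqs: list[str],
    pop2_seqs: list[str],
    clamp_negative: bool = False,
) -> float:
    """PhiST between two populations of equal-length aligned sequences.

    Requires at least 2 sequences per population.  Identical monomorphic
    populations give 0 (with a zero-variance warning); a fixed monomorphic
    difference gives 1.  Negative estimates are preserved unless
    ``clamp_negative``.
    """
    if len(pop1_seqs) < 2 or len(pop2_seqs) < 2:
        raise ValueError("need at least 2 sequences per population")
    lengths = {len(s) for s in pop1_seqs + pop2_seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    d = _difference_matrix(list(pop1_seqs) + list(pop2_seqs))
    phi = _phi_st_from_distances(d, [len(pop1_seqs), len(pop2_seqs)])
    if clamp_negative:
        phi = max(phi, 0.0)
    return phi


def permutation_p(
    pop1_seqs: list[str],
    pop2_seqs: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for PhiST: individuals shuffled between the two
    populations, p = (b + 1)/(n_perm + 1) with b the number of permuted
    PhiST values >= the observed one."""
    seqs = list(pop1_seqs) + list(pop2_seqs)
    n1 = len(pop1_seqs)
    d = _difference_matrix(seqs)
    sizes = [n1, len(pop2_seqs)]
    observed = _phi_st_from_distances(d, sizes)
    rng = np.random.default_rng(seed)
    b = 0
    n = len(seqs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if _phi_st_from_distances(dp, sizes) >= observed:
                b += 1
    return (b + 1) / (n_perm + 1)


@dataclass
class FstMatrix:
    """Symmetric population x population PhiST matrix with sample sizes."""

    values: pd.DataFrame
    n_per_pop: dict[str, int]

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", lineterminator="\n")


def apply_population_filters(
    aln: MsAlignment,
    breed_table: pd.DataFrame,
    min_individuals: int = 3,
    max_missing_frac: float = 0.05,
) -> tuple[MsAlignment, pd.DataFrame]:
    """Drop populations below ``min_individuals``, then high-missing loci.

    Returns the filtered alignment and the filtered breed table.  Population
    identity is the breed code.
    """
    meta = breed_table.set_index("id")
    ids = aln.ids()
    missing = [i for i in ids if i not in meta.index]
    if missing:
        raise KeyError(f"alignment ids absent from breed table: {missing}")
    sizes = meta.loc[ids, "breed"].value_counts()
    keep_breeds = set(sizes[sizes >= min_individuals].index)
    dropped = sorted(set(sizes.index) - keep_breeds)
    if dropped:
        logger.info(
            "dropping %d population(s) with < %d individuals: %s",
            len(dropped),
            min_individuals,
            dropped,
        )
    keep_records = [
        r for r in aln.records if meta.at[r.id, "breed"] in keep_breeds
    ]
    filtered = MsAlignment(records=keep_records)
    filtered = drop_high_missing_loci(filtered, max_missing_frac)
    table = breed_table[breed_table["id"].isin({r.id for r in filtered.records})]
    return filtered, table.reset_index(drop=True)


def phi_st_matrix(
    aln: MsAlignment,
    breed_table: pd.DataFrame,
    clamp_negative: bool = False,
) -> FstMatrix:
    """All pairwise PhiST values between the populations in the alignment."""
    meta = breed_table.set_index("id")
    by_pop: dict[str, list[str]] = {}
    for r in aln.records:
        by_pop.setdefault(meta.at[r.id, "breed"], []).append(r.sequence)
    pops = sorted(by_pop)
    n = len(pops)
    vals = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, j in itertools.combinations(range(n), 2):
            vals[i, j] = vals[j, i] = pairwise_phi_st(
                by_pop[pops[i]], by_pop[pops[j]], clamp_negative=clamp_negative
            )
    return FstMatrix(
        values=pd.DataFrame(vals, index=pops, columns=pops),
        n_per_pop={p: len(by_pop[p]) for p in pops},
    )
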