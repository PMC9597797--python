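"""Column-level cleaning of the multiple alignment.

Three operations, all of which only ever *delete columns* (retained columns
keep their original order):

* :func:`trim_protruding_ends` — crop the alignment to the span covered by a
  set of reference sequences (the longest focal-breed sequences), removing
  the parts protruding on both sides;
* :func:`conserved_block_mask` — a Gblocks-style conserved-block selector
  (faithful in spirit, not byte-compatible with Gblocks);
* :func:`drop_high_missing_loci` — remove columns whose missing-data fraction
  exceeds a threshold (the pre-PhiST locus filter).

Column coordinates are 0-based half-open internally; reports use 1-based
inclusive coordinates, the convention of alignment viewers.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np

from dloopkin.io_formats import SequenceRecord

logger = logging.getLogger(__name__)

MISSING = frozenset("N-?")
GAP = "-"


@dataclass
class MsAlignment:
    """An aligned set of records (equal lengths) with an optional column mask."""

    records: list[SequenceRecord]
    column_mask: np.ndarray | None = None  # bool, True = retained

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.column_mask is not None:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if self.column_mask.shape != (self.length,):
                raise ValueError("column_mask length must equal alignment length")

    @property
    def length(self) -> int:
        return len(self.records[0]) if self.records else 0

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_matrix(self) -> np.ndarray:
        """Character matrix (n_sequences x length) of single-byte strings."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")

    def take_columns(self, keep: np.ndarray) -> "MsAlignment":
        """New alignment restricted to columns where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.length,):
            raise ValueError("keep mask length mismatch")
        idx = np.flatnonzero(keep)
        new_records = [
            _dc_replace(r, sequence="".join(r.sequence[i] for i in idx))
            for r in self.records
        ]
        return MsAlignment(records=new_records)


def trim_protruding_ends(
    aln: MsAlignment, reference_ids: Sequence[str]
) -> MsAlignment:
    """Crop to the span jointly covered (non-gap) by every reference sequence.

    Columns before the first and after the last position covered by *all*
    references are removed.  Raises if a reference is absent or if the joint
    coverage span is empty.
    """
    if not reference_ids:
        raise ValueError("reference_ids must be non-empty")
    by_id = {r.id: r for r in aln.records}
    missing = [rid for rid in reference_ids if rid not in by_id]
    if missing:
        raise KeyError(f"reference id(s) absent from alignment: {missing}")
    start, end = 0, aln.length  # half-open intersection of coverage spans
    for rid in reference_ids:
        seq = by_id[rid].sequence
        covered = [i for i, c in enumerate(seq) if c != GAP]
        if not covered:
            raise ValueError(f"reference {rid!r} is all-gap")
        start = max(start, covered[0])
        end = min(end, covered[-1] + 1)
    if start >= end:
        raise ValueError("reference coverage spans are disjoint (empty overlap)")
    keep = np.zeros(aln.length, dtype=bool)
    keep[start:end] = True
    logger.info(
        "trim_protruding_ends: retained columns %d..%d (1-based) of %d",
        start + 1,
        end,
        aln.length,
    )
    return aln.take_columns(keep)


def _column_status(
    col: Sequence[str], min_conserved: int, min_flank: int, allow_gaps: bool
) -> str:
    """Classify one column: 'bad' (gap / below threshold), 'cons' or 'flank'."""
    if not allow_gaps and GAP in col:
        return "bad"
    residues = [c for c in col if c not in MISSING]
    if not residues:
        return "bad"
    top = Counter(residues).most_common(1)[0][1]
    if top >= min_flank:
        return "flank"
    if top >= min_conserved:
        return "cons"
    return "bad"


def conserved_block_mask(
    aln: MsAlignment,
    min_conserved: int | None = None,
    min_flank: int | None = None,
    max_nonconserved_run: int = 8,
    min_block_len: int = 10,
    allow_gaps: bool = False,
) -> np.ndarray:
    """Gblocks-style conserved-block column mask.

    A column is *conserved* when its majority-residue count reaches
    ``min_conserved`` (default ``floor(n/2)+1``) and, with
    ``allow_gaps=False``, contains no gap; *flank-level* conserved when the
    count reaches ``min_flank`` (default ``ceil(0.85*n)``).  Retained columns
    form blocks of length >= ``min_block_len`` whose termini are flank-level
    conserved and which contain no run of more than ``max_nonconserved_run``
    non-conserved columns.  Returns a boolean mask over columns.

    The selector follows the published Gblocks defaults in spirit; it is not
    byte-compatible with the Gblocks program.
    """
    n = aln.n_sequences
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if min_conserved is None:
        min_conserved = n // 2 + 1
    if min_flank is None:
        min_flank = math.ceil(0.85 * n)
    min_flank = max(min_flank, min_conserved)

    mat = aln.to_matrix()
    status = [
        _column_status(mat[:, j], min_conserved, min_flank, allow_gaps)
        for j in range(aln.length)
    ]

    # Split into candidate blocks at runs of >max_nonconserved_run bad
    # columns; the breaking run itself is never retained.
    mask = np.zeros(aln.length, dtype=bool)
    blocks: list[tuple[int, int]] = []  # half-open candidate spans
    j = 0
    block_start = 0
    while j <= aln.length:
        if j == aln.length:
            if j > block_start:
                blocks.append((block_start, j))
            break
        if status[j] == "bad":
            run_start = j
            while j < aln.length and status[j] == "bad":
                j += 1
            if j - run_start > max_nonconserved_run:
                if run_start > block_start:
                    blocks.append((block_start, run_start))
                block_start = j
        else:
            j += 1

    for lo, hi in blocks:
        # trim each end to a flank-level conserved terminus
        while lo < hi and status[lo] != "flank":
            lo += 1
        while hi > lo and status[hi - 1] != "flank":
            hi -= 1
        # bad columns are never retained even inside a block
        span = [j for j in range(lo, hi) if status[j] != "bad"]
        if hi - lo >= min_block_len and span:
            for j in span:
                mask[j] = True
    logger.info(
        "conserved_block_mask: retained %d of %d columns", int(mask.sum()), aln.length
    )
    return mask


def drop_high_missing_loci(
    aln: MsAlignment, max_missing_frac: float = 0.05
) -> MsAlignment:
    """Remove columns whose fraction of missing symbols ({N, -, ?}) exceeds
    ``max_missing_frac``."""
    mat = aln.to_matrix()
    miss = np.isin(mat, list(MISSING)).mean(axis=0)
    keep = miss <= max_missing_frac
    return aln.take_columns(keep)
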