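"""Sequence and table I/O plus the database-assembly rules.

The analysis starts from a FASTA of D-loop haplotypes and a tab-separated
breed table mapping each sequence id to its breed (4-letter code), geographic
region and tail phenotype.  Two assembly rules operate on the sequences:

* within each breed, byte-identical sequences are collapsed to a single
  representative, to discard possibly related animals;
* a candidate pool is filtered by near-identity to a seed sequence (at most
  ``max_mismatch`` mismatches over shared resolved sites) and breeds are
  retained only when at least ``min_breed_occurrence`` of their candidates
  pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: Alphabet accepted in stored sequences.  '?' is tolerated on input and
#: treated as missing downstream (same as 'N').
VALID_CHARS = frozenset("ACGTN-?")

#: Geographic regions used in the breed table.
REGIONS = (
    "Egypt",
    "East Tropical Africa",
    "Europe",
    "Western Asia",
    "Central Asia",
    "Eastern Asia",
    "wild",
)

#: Closed set of tail phenotypes.
TAIL_PHENOTYPES = ("thin", "fat", "fat_rumped", "fat_base")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (bad header, illegal character...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One breed-labelled haplotype sequence.

    Parameters
    ----------
    id : str
        Unique identifier (e.g. a GenBank accession).
    sequence : str
        Upper-case sequence over ``{A,C,G,T,N,-,?}``.
    breed : str, optional
        4-letter breed code; required for every domestic record.
    region : str, optional
        One of :data:`REGIONS`.
    """

    id: str
    sequence: str
    breed: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Ids are the first whitespace-delimited token of each header; sequences are
    upper-cased.  Duplicate ids or illegal characters raise
    :class:`FastaFormatError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaFormatError(f"{path}: FASTA entry with empty header")
        if entry.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (UTF-8, LF line endings, 70-column wrap)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_breed_table(path: str | Path) -> pd.DataFrame:
    """Read the ``id<TAB>breed<TAB>region<TAB>tail`` metadata table.

    Unknown breed codes pass through with a logged warning; tail phenotypes
    must come from the closed set :data:`TAIL_PHENOTYPES` (empty allowed for
    wild accessions).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "breed", "region", "tail"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"breed table missing column(s): {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"breed table has duplicate id(s): {dups}")
    df["breed"] = df["breed"].str.upper()
    odd = df.loc[(df["breed"].str.len() != 4) & (df["region"] != "wild"), "breed"]
    for code in sorted(set(odd)):
        logger.warning("breed code %r is not a 4-letter code; passing through", code)
    bad_tail = set(df["tail"]) - set(TAIL_PHENOTYPES) - {""}
    if bad_tail:
        raise ValueError(f"unknown tail phenotype(s): {sorted(bad_tail)}")
    return df


def write_breed_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def attach_metadata(
    records: Sequence[SequenceRecord], breed_table: pd.DataFrame
) -> list[SequenceRecord]:
    """Return records with breed/region filled in from the table.

    Every record id must be resolvable in the table.
    """
    meta = breed_table.set_index("id")
    missing = [r.id for r in records if r.id not in meta.index]
    if missing:
        raise KeyError(f"ids absent from breed table: {missing}")
    return [
        replace(r, breed=meta.at[r.id, "breed"], region=meta.at[r.id, "region"])
        for r in records
    ]


@dataclass
class DedupReport:
    """Which ids were removed and which representative absorbed each."""

    removed: dict[str, str] = field(default_factory=dict)  # removed id -> kept id

    def __len__(self) -> int:
        return len(self.removed)


def dedup_identical_within_breed(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], DedupReport]:
    """Collapse byte-identical sequences within each breed.

    The representative of each identical group is the lexicographically
    smallest id (deterministic).  Identical sequences in *different* breeds
    are all kept: the rule's scope is within-breed only.  Input order of the
    kept records is preserved.
    """
    report = DedupReport()
    best: dict[tuple[str | None, str], str] = {}
    for rec in sorted(records, key=lambda r: r.id):
        key = (rec.breed, rec.sequence)
        best.setdefault(key, rec.id)
    kept: list[SequenceRecord] = []
    for rec in records:
        rep = best[(rec.breed, rec.sequence)]
        if rec.id == rep:
            kept.append(rec)
        else:
            report.removed[rec.id] = rep
    return kept, report


def count_mismatches(seq1: str, seq2: str) -> int:
    """Mismatches over positions where both sequences are resolved.

    Positions where either sequence carries ``-``, ``N`` or ``?`` are skipped
    (pairwise deletion): partial D-loop records have unequal coverage.
    """
    if len(seq1) != len(seq2):
        raise ValueError(
            f"sequences not aligned: lengths {len(seq1)} vs {len(seq2)}"
        )
    skip = set("N-?")
    return sum(
        1
        for a, b in zip(seq1, seq2)
        if a != b and a not in skip and b not in skip
    )


def filter_candidate_pool(
    seed: SequenceRecord,
    candidates: Sequence[SequenceRecord],
    max_mismatch: int = 2,
    min_breed_occurrence: int = 2,
) -> list[str]:
    """Breeds with enough near-identical candidates to a seed sequence.

    A candidate passes when it differs from ``seed`` by at most
    ``max_mismatch`` substitutions over shared resolved positions; a breed is
    retained when at least ``min_breed_occurrence`` of its candidates pass.
    Returns the sorted list of retained breed codes.
    """
    hits: dict[str, int] = {}
    for cand in candidates:
        if cand.breed is None:
            continue
        if count_mismatches(seed.sequence, cand.sequence) <= max_mismatch:
            hits[cand.breed] = hits.get(cand.breed, 0) + 1
    return sorted(b for b, n in hits.items() if n >= min_breed_occurrence)
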