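"""Removal of rRNA/tRNA/snRNA/snoRNA-derived reads by exact matching.

Library reads deriving from abundant structural RNAs would otherwise
masquerade as precursor candidates; they are removed by exact (sense or
antisense) matching against user-supplied reference FASTA.  Exact matching
mirrors the zero-mismatch mapping used for the short reads and keeps the
step a fully auditable filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import CollapsedRead, read_fasta, revcomp

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "other")


class EmptyDatabaseError(ValueError):
    """Screening against an empty reference set is refused (it would be a
    silent no-op)."""


@dataclass
class ContaminantDB:
    """Named contaminant reference sequences of one class.

    Sequences are normalized to uppercase DNA (U -> T).
    """

    records: list[tuple[str, str]]
    klass: str = "other"

    def __post_init__(self) -> None:
        if self.klass not in CONTAMINANT_CLASSES:
            raise ValueError(f"unknown contaminant class {self.klass!r}")
        norm = []
        names = set()
        for name, seq in self.records:
            if name in names:
                raise ValueError(f"duplicate contaminant name {name!r}")
            names.add(name)
            norm.append((name, seq.upper().replace("U", "T")))
        self.records = norm

    @classmethod
    def from_fasta(cls, path: str | Path, klass: str = "other") -> "ContaminantDB":
        return cls([(r.id, r.seq) for r in read_fasta(path)], klass)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ContaminantHit:
    read: CollapsedRead
    hit_name: str
    hit_class: str


def screen(
    reads: Sequence[CollapsedRead],
    dbs: ContaminantDB | Sequence[ContaminantDB],
    mode: str = "substring",
) -> tuple[list[CollapsedRead], list[ContaminantHit]]:
    """Partition reads into (clean, removed-with-annotation).

    A read is removed iff it occurs exactly — sense or antisense — as a
    substring of any reference record (``mode='substring'``), or matches a
    record end-to-end (``mode='full'``).  The partition is exact: every
    input read appears in exactly one of the outputs and counts are
    conserved.
    """
    if mode not in ("substring", "full"):
        raise ValueError(f"unknown screening mode {mode!r}")
    if isinstance(dbs, ContaminantDB):
        dbs = [dbs]
    if not dbs or all(len(db) == 0 for db in dbs):
        raise EmptyDatabaseError("contaminant database is empty")

    clean: list[CollapsedRead] = []
    removed: list[ContaminantHit] = []
    for read in reads:
        fwd, rc = read.seq, revcomp(read.seq)
        hit = None
        for db in dbs:
            for name, ref in db.records:
                if mode == "substring":
                    matched = fwd in ref or rc in ref
                else:
                    matched = fwd == ref or rc == ref
                if matched:
                    hit = ContaminantHit(read, name, db.klass)
                    break
            if hit:
                break
        if hit:
            removed.append(hit)
        else:
            clean.append(read)
    return clean, removed


def write_removal_report(hits: Iterable[ContaminantHit], path: str | Path) -> None:
    """TSV report: read sequence, count, hit name, contaminant class."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read_seq", "count", "hit_name", "hit_class"])
        for h in hits:
            w.writerow([h.read.seq, h.read.count, h.hit_name, h.hit_class])
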