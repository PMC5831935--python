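"""Read-level I/O and preprocessing for precursor-library sequencing.

FASTQ (phred+33) and FASTA handling, paired-end overlap merging, adapter
trimming, quality/length filtering and collapsing to unique sequences with
abundance counts.  Coordinates are 0-based half-open throughout the package;
length windows are closed intervals.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the {A,C,G,T,N} alphabet."""


@dataclass
class SeqRead:
    """One sequencing read: identifier, bases and per-base phred scores.

    ``qual`` is None for FASTA-derived reads.  An empty-marked read
    (``seq == ""``) signals a fully trimmed read to be dropped downstream.
    """

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def validate_alphabet(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise InvalidSequenceError(
                f"read {self.id!r} contains invalid characters {sorted(bad)!r}"
            )

    @property
    def mean_quality(self) -> float:
        if not self.qual:
            return 0.0
        return sum(self.qual) / len(self.qual)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique sequence with its abundance across the input library."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("collapsed read count must be positive")


class MergeFailure:
    """Marker returned when no acceptable paired-end overlap exists."""

    __slots__ = ("reason",)

    def __init__(self, reason: str = "no acceptable overlap"):
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MergeFailure({self.reason!r})"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SeqRead]:
    """Iterate phred+33 FASTQ records (gzip-transparent)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield SeqRead(
                rec.id, str(rec.seq).upper(),
                list(rec.letter_annotations["phred_quality"]),
            )


def read_fasta(path: str | Path) -> Iterator[SeqRead]:
    """Iterate FASTA records as quality-less reads (gzip-transparent).

    ``U`` is normalized to ``T`` so RNA-formatted references are accepted.
    """
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SeqRead(rec.id, str(rec.seq).upper().replace("U", "T"))


def write_fastq(reads: Iterable[SeqRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            if r.qual is None:
                raise ValueError(f"read {r.id!r} has no qualities")
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qual)
            SeqIO.write(rec, handle, "fastq")


def write_fasta(reads: Iterable[SeqRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            SeqIO.write(SeqRecord(Seq(r.seq), id=r.id, description=""), handle, "fasta")


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``>seq<i>_<count>`` headers.

    The ``id_count`` header convention keeps the abundance attached to the
    unique sequence, as mapping-pattern tools expect.
    """
    with _open_text(path, "wt") as handle:
        for i, c in enumerate(collapsed, start=1):
            handle.write(f">seq{i}_{c.count}\n{c.seq}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read collapsed FASTA written by :func:`write_collapsed_fasta`."""
    out = []
    for r in read_fasta(path):
        count = int(r.id.rsplit("_", 1)[1])
        out.append(CollapsedRead(r.seq, count))
    return out


def merge_pair(
    fwd: SeqRead,
    rev: SeqRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> SeqRead | MergeFailure:
    """Merge a read pair by its best 3'-overlap into a consensus read.

    ``rev`` is given in sequencing orientation and is reverse-complemented
    here.  The best overlap is the longest suffix(fwd)/prefix(revcomp(rev))
    alignment whose mismatch fraction is <= ``max_mismatch_frac``; at each
    overlap mismatch the base with the higher phred score wins and keeps its
    quality (ties go to the forward read).  Returns :class:`MergeFailure`
    when no overlap of at least ``min_overlap`` qualifies.
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    fwd.validate_alphabet()
    rev.validate_alphabet()
    rseq = revcomp(rev.seq)
    rqual = list(reversed(rev.qual)) if rev.qual is not None else None

    best = None  # (overlap_len)
    max_o = min(len(fwd.seq), len(rseq))
    for o in range(max_o, min_overlap - 1, -1):
        fs = fwd.seq[len(fwd.seq) - o:]
        rs = rseq[:o]
        mism = sum(1 for a, b in zip(fs, rs) if a != b)
        if mism / o <= max_mismatch_frac:
            best = o
            break
    if best is None:
        return MergeFailure()

    o = best
    off = len(fwd.seq) - o
    seq = list(fwd.seq[:off])
    qual = list(fwd.qual[:off]) if fwd.qual is not None else None
    for k in range(o):
        fa, ra = fwd.seq[off + k], rseq[k]
        fq = fwd.qual[off + k] if fwd.qual is not None else 0
        rq = rqual[k] if rqual is not None else 0
        if fa == ra or fq >= rq:
            seq.append(fa)
            if qual is not None:
                qual.append(max(fq, rq) if fa == ra else fq)
        else:
            seq.append(ra)
            if qual is not None:
                qual.append(rq)
    seq.extend(rseq[o:])
    if qual is not None:
        qual.extend(rqual[o:] if rqual is not None else [0] * (len(rseq) - o))
    return SeqRead(fwd.id, "".join(seq), qual)


def _find_adapter3(seq: str, adapter: str, min_partial: int) -> int:
    """Leftmost start of a full or 3'-terminal partial (>=min_partial prefix)
    occurrence of the 3' adapter; -1 if absent."""
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    # partial adapter running off the 3' end of the read
    max_p = min(len(adapter) - 1, len(seq))
    for plen in range(max_p, min_partial - 1, -1):
        if seq.endswith(adapter[:plen]):
            return len(seq) - plen
    return -1


def _find_adapter5(seq: str, adapter: str, min_partial: int) -> int:
    """End (exclusive) of a full or 5'-terminal partial (>=min_partial suffix)
    occurrence of the 5' adapter; -1 if absent."""
    pos = seq.find(adapter)
    if pos != -1:
        return pos + len(adapter)
    max_p = min(len(adapter) - 1, len(seq))
    for plen in range(max_p, min_partial - 1, -1):
        if seq.startswith(adapter[-plen:]):
            return plen
    return -1


def trim_adapters(
    read: SeqRead,
    adapter3: str,
    adapter5: str,
    min_partial: int = 8,
) -> SeqRead:
    """Trim 5' and 3' adapters (full or terminal partial matches >= ``min_partial`` nt).

    The 3' adapter and everything after it are removed; the 5' adapter and
    everything before it are removed.  Reads with adapters on one, both or
    neither end are all handled; qualities are trimmed in register.  A read
    trimmed to nothing is returned empty-marked.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    seq, qual = read.seq, read.qual
    end5 = _find_adapter5(seq, adapter5, min_partial)
    start = end5 if end5 != -1 else 0
    pos3 = _find_adapter3(seq[start:], adapter3, min_partial)
    end = start + pos3 if pos3 != -1 else len(seq)
    return SeqRead(read.id, seq[start:end], qual[start:end] if qual is not None else None)


def quality_filter(
    reads: Iterable[SeqRead],
    min_mean_phred: float = 30.0,
    max_n_frac: float = 0.10,
) -> list[SeqRead]:
    """Keep reads whose mean phred >= threshold and N fraction <= ``max_n_frac``."""
    kept = []
    for r in reads:
        if not r.seq or r.qual is None:
            continue
        if r.mean_quality < min_mean_phred:
            continue
        if r.seq.count("N") / len(r.seq) > max_n_frac:
            continue
        kept.append(r)
    return kept


def length_select(reads: Iterable[SeqRead], lo: int, hi: int) -> list[SeqRead]:
    """Keep reads with lo <= length <= hi (closed interval)."""
    if lo > hi:
        raise ValueError(f"invalid length window [{lo}, {hi}]")
    return [r for r in reads if lo <= len(r.seq) <= hi]


def collapse(reads: Iterable[SeqRead | str]) -> list[CollapsedRead]:
    """Collapse reads to unique sequences with counts (count-conserving).

    Output is sorted by descending count, then sequence, for determinism.
    """
    counts: dict[str, int] = {}
    for r in reads:
        s = r if isinstance(r, str) else r.seq
        if not s:
            continue
        counts[s] = counts.get(s, 0) + 1
    return [
        CollapsedRead(s, c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
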