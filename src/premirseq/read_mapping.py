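"""Zero-mismatch mapping of small-RNA reads onto long reads.

Small RNAs (18-34 nt) are placed on candidate precursor long reads by exact
sense-strand substring matching; placements are grouped into 5'-start
clusters.  A cluster window of a few nt accommodates the 1-nt "sliding
ladder" that Dicer-processed reads show around the true cleavage site while
keeping the mature- and star-arm clusters separate.  Profiles render to a
human-readable stacked-alignment text that round-trips through a parser.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import CollapsedRead

SHORT_LEN_MIN = 18
SHORT_LEN_MAX = 34


@dataclass(frozen=True)
class Placement:
    """One exact sense occurrence of a short read on a long read."""

    short_seq: str
    count: int
    long_id: str
    start: int  # 0-based
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.short_seq):
            raise ValueError("placement interval does not match sequence length")


@dataclass(frozen=True)
class Cluster:
    """Maximal group of placements whose 5' starts fall in a short window."""

    start_window: int
    end_window: int  # inclusive window of 5' starts
    dominant: Placement
    total_count: int
    placements: tuple[Placement, ...] = ()


@dataclass
class MappingProfile:
    """A long read with all of its short-read placements and clusters."""

    long_id: str
    long_seq: str
    placements: list[Placement]
    clusters: list[Cluster] = field(default_factory=list)


def map_short_to_long(
    shorts: Sequence[CollapsedRead],
    longs: Sequence[tuple[str, str]] | Sequence[CollapsedRead],
) -> list[Placement]:
    """All exact sense occurrences of each short read in each long read.

    ``longs`` is either (id, seq) pairs or collapsed reads (which get
    positional ids).  Shorts outside 18-34 nt are skipped with a warning.
    Multiple occurrences within one long read are all reported.
    """
    long_pairs: list[tuple[str, str]] = []
    for i, item in enumerate(longs):
        if isinstance(item, CollapsedRead):
            long_pairs.append((f"long{i + 1}", item.seq))
        else:
            long_pairs.append(item)

    by_seq: dict[str, int] = {}
    lengths: set[int] = set()
    for s in shorts:
        if not (SHORT_LEN_MIN <= len(s.seq) <= SHORT_LEN_MAX):
            warnings.warn(
                f"short read of length {len(s.seq)} outside "
                f"[{SHORT_LEN_MIN},{SHORT_LEN_MAX}] skipped"
            )
            continue
        by_seq[s.seq] = by_seq.get(s.seq, 0) + s.count
        lengths.add(len(s.seq))

    placements: list[Placement] = []
    for long_id, long_seq in long_pairs:
        n = len(long_seq)
        for ell in sorted(lengths):
            for start in range(0, n - ell + 1):
                window = long_seq[start:start + ell]
                count = by_seq.get(window)
                if count is not None:
                    placements.append(
                        Placement(window, count, long_id, start, start + ell)
                    )
    placements.sort(key=lambda p: (p.long_id, p.start, p.end))
    return placements


def build_profile(
    long_id: str,
    long_seq: str,
    placements: Sequence[Placement],
    cluster_window: int = 3,
) -> MappingProfile:
    """Group placements into 5'-start clusters of width ``cluster_window``.

    Clusters are maximal runs of placements whose consecutive 5' starts are
    within the window; the dominant placement is the highest-count one
    (ties broken by smallest start, then shortest read).
    """
    for p in placements:
        if p.long_id != long_id or p.end > len(long_seq):
            raise ValueError(f"placement {p} is not on long read {long_id!r}")
    ordered = sorted(placements, key=lambda p: (p.start, p.end))
    clusters: list[Cluster] = []
    group: list[Placement] = []

    def _flush() -> None:
        if not group:
            return
        dom = min(group, key=lambda p: (-p.count, p.start, p.end))
        clusters.append(
            Cluster(
                start_window=group[0].start,
                end_window=group[-1].start,
                dominant=dom,
                total_count=sum(p.count for p in group),
                placements=tuple(group),
            )
        )

    for p in ordered:
        if group and p.start - group[-1].start > cluster_window:
            _flush()
            group = []
        group.append(p)
    _flush()
    return MappingProfile(long_id, long_seq, ordered, clusters)


def render_profile_text(profile: MappingProfile) -> str:
    """Stacked-alignment text: long read on top, each placement at its
    offset with an ``xCOUNT`` suffix."""
    lines = [f">{profile.long_id}", profile.long_seq]
    for p in profile.placements:
        lines.append(" " * p.start + p.short_seq + f" x{p.count}")
    return "\n".join(lines) + "\n"


def parse_profile_text(text: str, cluster_window: int = 3) -> MappingProfile:
    """Inverse of :func:`render_profile_text` (clusters are rebuilt)."""
    lines = text.rstrip("\n").split("\n")
    if not lines or not lines[0].startswith(">"):
        raise ValueError("profile text must start with a '>' header line")
    long_id = lines[0][1:]
    long_seq = lines[1] if len(lines) > 1 else ""
    placements = []
    for line in lines[2:]:
        start = len(line) - len(line.lstrip(" "))
        body, xcount = line.strip().rsplit(" x", 1)
        placements.append(
            Placement(body, int(xcount), long_id, start, start + len(body))
        )
    return build_profile(long_id, long_seq, placements, cluster_window)


def write_placements_tsv(placements: Iterable[Placement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["short_seq", "count", "long_id", "start", "end"])
        for p in placements:
            w.writerow([p.short_seq, p.count, p.long_id, p.start, p.end])
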