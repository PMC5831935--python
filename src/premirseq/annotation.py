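"""Known/novel labeling by cross-mapping against reference miRNA sets.

Two retrieval strategies mirror how a genome-poor analysis leans on
conservation: (I) sample short reads that map exactly into any reference
precursor seed the retrieval of sample long reads (conserved duplexes align
into reference hairpins); (II) long reads containing a predicted novel
mature exactly are retrieved directly.  Retrieved long reads are then
re-profiled with the full short-read set so clusters are complete.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .read_mapping import MappingProfile, build_profile, map_short_to_long
from .sequence_io import CollapsedRead, read_fasta

_FAMILY_RE = re.compile(r"(miR|mir)[-_]?(\d+)", re.IGNORECASE)


def parse_family(name: str) -> str:
    """Family from a reference name: ``miR156a-ref`` -> ``miR156``.

    Names not following the miR<number><letter> convention are kept whole.
    """
    m = _FAMILY_RE.search(name)
    return f"miR{m.group(2)}" if m else name


@dataclass
class ReferenceSet:
    """Reference mature and precursor sequences (e.g., a plant miRNA
    database export)."""

    matures: list[tuple[str, str]]  # (name, seq), DNA-normalized
    precursors: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for attr in ("matures", "precursors"):
            recs = getattr(self, attr)
            names = [n for n, _ in recs]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate names in reference {attr}")
            setattr(
                self, attr,
                [(n, s.upper().replace("U", "T")) for n, s in recs],
            )

    @classmethod
    def from_fasta(cls, mature_path: str | Path, precursor_path: str | Path) -> "ReferenceSet":
        return cls(
            [(r.id, r.seq) for r in read_fasta(mature_path)],
            [(r.id, r.seq) for r in read_fasta(precursor_path)],
        )


@dataclass
class RetrievedLong:
    """A sample long read retrieved by a strategy, with its seeds and a
    full-profile rebuild."""

    long_id: str
    long_seq: str
    families: tuple[str, ...]
    seed_names: tuple[str, ...]
    profile: MappingProfile


def _profile_longs(
    hit_longs: Sequence[tuple[str, str]],
    shorts: Sequence[CollapsedRead],
    cluster_window: int = 3,
) -> dict[str, MappingProfile]:
    placements = map_short_to_long(shorts, hit_longs)
    by_long: dict[str, list] = {lid: [] for lid, _ in hit_longs}
    for p in placements:
        by_long[p.long_id].append(p)
    return {
        lid: build_profile(lid, seq, by_long[lid], cluster_window)
        for lid, seq in hit_longs
    }


def strategy_known(
    shorts: Sequence[CollapsedRead],
    longs: Sequence[tuple[str, str]],
    ref: ReferenceSet,
    cluster_window: int = 3,
) -> list[RetrievedLong]:
    """Conserved-precursor retrieval.

    Step 1: extract sample short reads mapping exactly into any reference
    precursor.  Step 2: map those shorts onto the sample long reads.
    Step 3: retrieve hit long reads and remap ALL shorts onto them for
    complete cluster formation.  Each retrieved long read carries the
    families of the reference precursors that seeded it.
    """
    if not ref.precursors:
        raise ValueError("reference precursor set is empty")
    seed_shorts: dict[str, set[str]] = {}
    for s in shorts:
        for name, pseq in ref.precursors:
            if s.seq in pseq:
                seed_shorts.setdefault(s.seq, set()).add(name)
    seeding = [s for s in shorts if s.seq in seed_shorts]
    if not seeding:
        return []
    hits = map_short_to_long(seeding, longs)
    hit_ids = {p.long_id for p in hits}
    hit_longs = [(lid, seq) for lid, seq in longs if lid in hit_ids]
    profiles = _profile_longs(hit_longs, shorts, cluster_window)

    seeds_by_long: dict[str, set[str]] = {lid: set() for lid in hit_ids}
    for p in hits:
        seeds_by_long[p.long_id].update(seed_shorts[p.short_seq])
    out = []
    for lid, seq in hit_longs:
        names = sorted(seeds_by_long[lid])
        fams = sorted({parse_family(n) for n in names})
        out.append(RetrievedLong(lid, seq, tuple(fams), tuple(names), profiles[lid]))
    return out


def strategy_novel(
    shorts: Sequence[CollapsedRead],
    longs: Sequence[tuple[str, str]],
    novel_matures: Sequence[str],
    cluster_window: int = 3,
) -> list[RetrievedLong]:
    """Novel-candidate retrieval: long reads containing a predicted novel
    mature sequence exactly, re-profiled with all shorts."""
    if not novel_matures:
        return []
    norm = [m.upper().replace("U", "T") for m in novel_matures]
    hit_longs = []
    seeds: dict[str, tuple[str, ...]] = {}
    for lid, seq in longs:
        found = tuple(m for m in norm if m in seq)
        if found:
            hit_longs.append((lid, seq))
            seeds[lid] = found
    profiles = _profile_longs(hit_longs, shorts, cluster_window)
    return [
        RetrievedLong(lid, seq, (), seeds[lid], profiles[lid])
        for lid, seq in hit_longs
    ]


def assign_family(
    candidate_seq: str,
    ref: ReferenceSet,
    stem_intervals: Sequence[tuple[int, int]] | None = None,
) -> tuple[str, ...]:
    """Families whose reference mature occurs exactly in the candidate
    (multi-label; empty tuple means novel).

    When ``stem_intervals`` is given, only matures lying fully inside one of
    the intervals (the stem arms) count.
    """
    seq = candidate_seq.upper().replace("U", "T")
    fams = set()
    for name, mat in ref.matures:
        pos = seq.find(mat)
        while pos != -1:
            if stem_intervals is None or any(
                lo <= pos and pos + len(mat) <= hi for lo, hi in stem_intervals
            ):
                fams.add(parse_family(name))
                break
            pos = seq.find(mat, pos + 1)
    return tuple(sorted(fams))


def write_annotation_tsv(retrieved: Iterable[RetrievedLong], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["long_id", "families", "seed_names"])
        for r in retrieved:
            w.writerow([r.long_id, ";".join(r.families) or "-", ";".join(r.seed_names)])
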