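"""Duplex geometry and the stem-loop acceptance criteria.

A candidate precursor must fold into a single stem-loop holding the mature
miRNA in its stem; the miRNA:miRNA* duplex read off the pairing table must
show at most four mismatches in total, no asymmetric bulge of four or more
bases, and read clusters consistent with staggered Dicer cleavage (mature
and star 5' ends at the duplex boundaries, 2-nt 3' overhangs).  Novel
candidates are additionally required to reach MFEI <= -0.70, which
separates genuine precursors from tRNA/rRNA/mRNA fragments; known-family
candidates report their MFEI but are not filtered on it.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .hairpin_folding import HairpinStructure
from .read_mapping import Cluster, MappingProfile

DICER_OVERHANG = 2  # nt, 3' overhang left by staggered Dicer-like cleavage


class LoopRegionError(ValueError):
    """The mature interval overlaps the terminal loop; such precursors are
    discarded, not processed."""


@dataclass(frozen=True)
class DuplexGeometry:
    """Geometry of the miRNA:miRNA* duplex on a folded precursor.

    The star interval is the mature's pairing range shifted ``DICER_OVERHANG``
    nt toward the star strand's 3' end, so that both strands carry the 2-nt
    3' overhang of a Dicer duplex.  Mismatches are unpaired duplex positions
    faced by an equal-length unpaired run; bulges are unpaired runs with no
    opposite-side counterpart (asymmetric loops contribute their matched part
    to mismatches and their excess to bulges).
    """

    mature_interval: tuple[int, int]
    star_interval: tuple[int, int]
    arm: str  # {'5p', '3p'}
    n_mismatches: int
    bulges: tuple[tuple[str, int], ...]  # (side in {'mature','star'}, length)
    max_internal_loop: int  # largest one-side unpaired run inside the duplex
    overhang3_mature: int
    overhang3_star: int

    @property
    def total_mismatch_load(self) -> int:
        """Mismatches plus bulged bases: the duplex imperfection budget."""
        return self.n_mismatches + sum(b for _, b in self.bulges)


@dataclass
class ValidationConfig:
    """Thresholds of the precursor acceptance criteria (serialized into
    every report)."""

    max_duplex_mismatches: int = 4
    max_bulge_len: int = 3
    mfei_max: float = -0.70  # applied to novel candidates only
    min_len: int = 40
    max_len: int = 241
    require_single_loop: bool = True
    overhang_target: int = 2
    overhang_tol: int = 1
    min_mature_count: int = 5
    cluster_start_tol: int = 1

    def __post_init__(self) -> None:
        for name in ("max_duplex_mismatches", "max_bulge_len", "min_len",
                     "max_len", "overhang_target", "overhang_tol",
                     "min_mature_count", "cluster_start_tol"):
            v = getattr(self, name)
            if not isinstance(v, (int, bool)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")
        if not (self.mfei_max == self.mfei_max and abs(self.mfei_max) < 1e6):
            raise ValueError("mfei_max must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PrecursorCandidate:
    """A long read with structure, duplex, mapping evidence and verdict."""

    long_id: str
    seq: str
    structure: HairpinStructure
    profile: MappingProfile
    duplex: DuplexGeometry | None = None
    criteria_flags: dict[str, bool] = field(default_factory=dict)
    confidence: str | None = None  # {'duplex-supported', 'expression-supported'}
    label: str = "novel"  # 'known:<families>' or 'novel'
    families: tuple[str, ...] = ()
    accepted: bool = False
    variants: list[str] = field(default_factory=list)
    p_value: float | None = None

    @property
    def is_known(self) -> bool:
        return self.label.startswith("known")

    def failed_criteria(self) -> list[str]:
        return sorted(k for k, v in self.criteria_flags.items() if not v)


def _nearest_paired(partner: dict[int, int], lo: int, hi: int, anchor: int) -> int | None:
    """Paired position within [lo, hi) closest to ``anchor``."""
    cands = [i for i in range(lo, hi) if i in partner]
    if not cands:
        return None
    return min(cands, key=lambda i: (abs(i - anchor), i))


def locate_duplex(
    structure: HairpinStructure,
    mature_interval: tuple[int, int],
    overhang: int = DICER_OVERHANG,
) -> DuplexGeometry:
    """Derive the miRNA* interval and duplex imperfections from the pairing
    table.

    Raises :class:`LoopRegionError` when the mature interval overlaps a
    terminal loop (the discard rule for loop-resident matures).
    """
    ms, me = mature_interval
    n = len(structure.seq)
    if not (0 <= ms < me <= n):
        raise ValueError(f"mature interval {mature_interval} outside sequence")
    partner = structure.partner

    for lo, hi in structure.terminal_loops():
        if ms < hi and me > lo:
            raise LoopRegionError(
                f"mature interval {mature_interval} overlaps terminal loop ({lo},{hi})"
            )

    paired = [i for i in range(ms, me) if i in partner]
    if not paired:
        raise LoopRegionError(
            f"mature interval {mature_interval} is entirely unpaired"
        )

    # anchor at the mature 5' end -> star 3' end (plus overhang); anchor at
    # (mature 3' end - overhang) -> star 5' end.  Unpaired anchors are
    # extrapolated from the nearest paired mature position.
    a5 = _nearest_paired(partner, ms, me, ms)
    a3 = _nearest_paired(partner, ms, me, me - 1 - overhang)
    star3 = partner[a5] + (a5 - ms) + overhang + 1
    star5 = partner[a3] - ((me - 1 - overhang) - a3)
    star5 = max(0, star5)
    star3 = min(n, star3)
    if star5 >= star3:
        raise LoopRegionError("degenerate star interval; mature abuts the loop")
    star_interval = (star5, star3)

    arm = "5p" if ms < partner[a5] else "3p"

    # walk the duplex region of the mature arm and classify unpaired runs
    mism = 0
    bulges: list[tuple[str, int]] = []
    max_loop = 0
    p_lo, p_hi = paired[0], paired[-1]
    # runs of unpaired mature positions between paired neighbors
    i = p_lo
    while i < p_hi:
        if i in partner:
            i += 1
            continue
        run_start = i
        while i < p_hi and i not in partner:
            i += 1
        run_len = i - run_start
        q_left, q_right = partner[run_start - 1], partner[i]
        gap = abs(q_left - q_right) - 1  # unpaired bases opposite the run
        max_loop = max(max_loop, run_len, gap)
        matched = min(run_len, gap)
        mism += matched
        if run_len > gap:
            bulges.append(("mature", run_len - gap))
        elif gap > run_len:
            bulges.append(("star", gap - run_len))
    # star-side-only gaps between consecutive paired mature positions
    for i, j in zip(paired, paired[1:]):
        if j - i == 1:
            gap = abs(partner[i] - partner[j]) - 1
            if gap > 0:
                bulges.append(("star", gap))
                max_loop = max(max_loop, gap)

    # leading/trailing unpaired mature bases beyond the overhang allowance
    # count toward the mismatch load (they face the stem without pairing)
    lead = p_lo - ms
    trail = (me - 1) - p_hi
    mism += lead + max(0, trail - overhang)

    ov_m = [i for i in paired if star_interval[0] <= partner[i] < star_interval[1]]
    if ov_m:
        if arm == "5p":
            overhang3_mature = me - (max(ov_m) + 1)
            overhang3_star = star_interval[1] - (partner[min(ov_m)] + 1)
        else:
            overhang3_mature = me - (max(ov_m) + 1)
            overhang3_star = star_interval[1] - (partner[min(ov_m)] + 1)
    else:
        overhang3_mature = overhang3_star = -1

    return DuplexGeometry(
        mature_interval=(ms, me),
        star_interval=star_interval,
        arm=arm,
        n_mismatches=mism,
        bulges=tuple(bulges),
        max_internal_loop=max_loop,
        overhang3_mature=overhang3_mature,
        overhang3_star=overhang3_star,
    )


def check_dicer_pattern(
    profile: MappingProfile,
    duplex: DuplexGeometry,
    config: ValidationConfig,
) -> str:
    """Classify the read signature as duplex-supported, expression-supported
    or fail.

    duplex-supported: one cluster's dominant 5' start within
    ``cluster_start_tol`` of the mature 5' end AND another cluster's within
    tolerance of the star 5' end AND both implied 3' overhangs within
    ``overhang_target +/- overhang_tol``.  expression-supported: only the
    mature cluster exists, with total count >= ``min_mature_count``.
    """
    tol = config.cluster_start_tol
    ms = duplex.mature_interval[0]
    ss = duplex.star_interval[0]

    def near(cluster: Cluster, pos: int) -> bool:
        return abs(cluster.dominant.start - pos) <= tol

    mature_clusters = [c for c in profile.clusters if near(c, ms)]
    star_clusters = [c for c in profile.clusters if near(c, ss)]

    if mature_clusters and star_clusters:
        ok_overhangs = all(
            abs(o - config.overhang_target) <= config.overhang_tol
            for o in (duplex.overhang3_mature, duplex.overhang3_star)
        )
        if ok_overhangs:
            return "duplex-supported"
    # expression support applies only when the mature cluster is the sole
    # read signal on the precursor (no star, no loop/degradation clusters)
    if mature_clusters and all(c in mature_clusters for c in profile.clusters):
        if sum(c.total_count for c in mature_clusters) >= config.min_mature_count:
            return "expression-supported"
    return "fail"


def validate(
    candidate: PrecursorCandidate,
    config: ValidationConfig | None = None,
) -> PrecursorCandidate:
    """Apply the stem-loop acceptance criteria and set per-criterion flags.

    Flags: length window, single terminal loop, mature within the stem,
    duplex mismatches, bulge sizes, total duplex imperfection budget,
    oversized internal loops, MFEI (novel candidates only), Dicer read
    pattern.  A candidate is accepted iff every applicable flag is true;
    every rejection names at least one failed criterion.
    """
    config = config or ValidationConfig()
    c = candidate
    flags: dict[str, bool] = {}
    flags["length"] = config.min_len <= len(c.seq) <= config.max_len
    flags["single_loop"] = (
        c.structure.n_loops == 1 if config.require_single_loop else True
    )

    if c.duplex is None:
        flags["mature_in_stem"] = False
        flags["dicer_pattern"] = False
    else:
        d = c.duplex
        flags["mature_in_stem"] = True
        flags["duplex_mismatches"] = d.n_mismatches <= config.max_duplex_mismatches
        flags["bulge_size"] = all(b <= config.max_bulge_len for _, b in d.bulges)
        flags["total_mismatch_load"] = (
            d.total_mismatch_load <= config.max_duplex_mismatches
        )
        flags["internal_loop"] = d.max_internal_loop <= config.max_bulge_len
        c.confidence = check_dicer_pattern(c.profile, d, config)
        flags["dicer_pattern"] = c.confidence != "fail"

    if not c.is_known:
        m = c.structure.mfei
        flags["mfei"] = m is not None and m <= config.mfei_max

    c.criteria_flags = flags
    c.accepted = all(flags.values())
    if c.confidence == "fail":
        c.confidence = None
    return c


def dedupe_variants(accepted: Sequence[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Collapse 3'-truncation/extension variants sharing a 5' end.

    Candidates whose shorter sequence matches the 5' prefix of the longer
    one over >= 90% of its length and that share the same mature interval
    collapse to the single longest representative; collapsed members are
    recorded on the representative's ``variants`` list.
    """
    remaining = sorted(accepted, key=lambda c: (-len(c.seq), c.long_id))
    out: list[PrecursorCandidate] = []
    for cand in remaining:
        rep = None
        for r in out:
            if cand.duplex and r.duplex and cand.duplex.mature_interval != r.duplex.mature_interval:
                continue
            if cand.duplex is None or r.duplex is None:
                if (cand.duplex is None) != (r.duplex is None):
                    continue
            short, long_ = (cand.seq, r.seq) if len(cand.seq) <= len(r.seq) else (r.seq, cand.seq)
            k = max(1, int(0.9 * len(short) + 0.9999))  # ceil(0.9 * len)
            if long_[:k] == short[:k]:
                rep = r
                break
        if rep is None:
            out.append(cand)
        else:
            rep.variants.append(cand.long_id)
    return out


def write_table(candidates: Iterable[PrecursorCandidate], path: str | Path) -> None:
    """Summary TSV: mature seq (RNA), precursor seq (RNA), MFEI, p-value,
    arm, confidence, label, flags."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([
            "long_id", "mature_seq", "precursor_seq", "length", "mfe", "mfei",
            "p_value", "arm", "confidence", "label", "accepted",
            "failed_criteria", "variants",
        ])
        for c in candidates:
            mi = c.duplex.mature_interval if c.duplex else None
            mature = c.seq[mi[0]:mi[1]].replace("T", "U") if mi else ""
            w.writerow([
                c.long_id, mature, c.seq.replace("T", "U"), len(c.seq),
                f"{c.structure.mfe:.2f}",
                f"{c.structure.mfei:.3f}" if c.structure.mfei is not None else "NA",
                f"{c.p_value:.3f}" if c.p_value is not None else "NA",
                c.duplex.arm if c.duplex else "NA",
                c.confidence or "NA", c.label, c.accepted,
                ";".join(c.failed_criteria()) or "-",
                ";".join(c.variants) or "-",
            ])
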