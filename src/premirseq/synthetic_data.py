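"""Ground-truthed synthetic sequencing data for the precursor pipeline.

The generator emulates the statistical structure of a precursor-library
experiment in a genome-poor plant: hairpin precursors (40-241 nt) carrying a
miRNA:miRNA* duplex in the stem, Dicer-processed small-RNA reads with a 1-nt
5' sliding ladder, star reads with 2-nt 3' overhang geometry, degradation
fragments, structural-RNA contaminant fragments, and adapter-flanked
paired-end long-library reads with phred strings.  Every emitted read and
precursor carries its origin in a :class:`TruthManifest`, so expected
pipeline output is fully determined and recoverable.

Design notes: terminal loops and paired-end tails are drawn from an {A,C}
alphabet at the target GC so they cannot base-pair internally (A-C is not a
pair), which keeps the *designed* stem the unambiguous minimum-free-energy
structure without conditioning the generator on any folding backend.
Read depths are negative-binomial (sRNA counts are overdispersed); the
mature 5' base is U-biased (prob 0.7) as real plant miRNA sets are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .contaminant_screen import ContaminantDB
from .sequence_io import SeqRead, revcomp

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
PAIRABLE = {"A": {"T"}, "T": {"A", "G"}, "G": {"C", "T"}, "C": {"G"}}

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def _rng(rng: np.random.Generator | int) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _weighted_base(rng: np.random.Generator, gc: float) -> str:
    return rng.choice(["G", "C", "A", "T"], p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])


def _stem_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(_weighted_base(rng, gc) for _ in range(n))


def _loop_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    # {A, C} alphabet: GC on target, no internal pairing possible
    return "".join(rng.choice(["C", "A"], p=[gc, 1 - gc]) for _ in range(n))


def _non_pairing_base(rng: np.random.Generator, opposite: str) -> str:
    choices = [b for b in "ACGT" if opposite not in PAIRABLE[b]]
    return str(rng.choice(choices))


@dataclass
class PrecursorTruth:
    """Ground truth for one planted precursor (or decoy)."""

    precursor_id: str
    seq: str
    mature_interval: tuple[int, int]
    star_interval: tuple[int, int]
    arm: str
    n_mismatches: int
    bulges: tuple[tuple[str, int], ...]
    family: str | None  # known family name, or None for novel
    kind: str  # good | mature_in_loop | excess_mismatch | oversized_bulge | contaminant
    expected_accept: bool
    expected_fail_criteria: tuple[str, ...] = ()
    has_star_reads: bool = True

    @property
    def mature_seq(self) -> str:
        s, e = self.mature_interval
        return self.seq[s:e]

    @property
    def star_seq(self) -> str:
        s, e = self.star_interval
        return self.seq[s:e]


@dataclass
class TruthManifest:
    """Everything the pipeline is expected to recover, serialized with the
    generated FASTQ."""

    precursors: list[PrecursorTruth]
    read_origins: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def by_id(self, pid: str) -> PrecursorTruth:
        return next(p for p in self.precursors if p.precursor_id == pid)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "precursors": [asdict(p) for p in self.precursors],
            "read_origins": self.read_origins,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        precs = []
        for p in raw["precursors"]:
            p["mature_interval"] = tuple(p["mature_interval"])
            p["star_interval"] = tuple(p["star_interval"])
            p["bulges"] = tuple(tuple(b) for b in p["bulges"])
            p["expected_fail_criteria"] = tuple(p["expected_fail_criteria"])
            precs.append(PrecursorTruth(**p))
        return cls(precs, raw["read_origins"], raw["params"])


def make_precursor(
    rng: np.random.Generator | int,
    mature_len: int = 21,
    ext_len: int = 6,
    loop_len: int = 12,
    arm: str = "5p",
    n_mismatches: int = 0,
    bulge_spec: Sequence[tuple[str, int]] = (),
    gc_target: float = 0.5,
    u_start_prob: float = 0.7,
    precursor_id: str = "P1",
    family: str | None = None,
) -> PrecursorTruth:
    """Build one hairpin precursor with planted duplex defects.

    The stem is ``mature + ext`` paired against its complement-walk across a
    ``loop_len`` terminal loop, with the 2-nt 3' overhang geometry of a Dicer
    duplex built in.  ``n_mismatches`` non-pairing substitutions and
    ``bulge_spec`` unpaired runs (side in {'mature','star'}) are planted in
    the duplex interior.  Mature length 18-24, total length must land in
    40-241.
    """
    rng = _rng(rng)
    if not (18 <= mature_len <= 24):
        raise ValueError("mature_len must be in 18-24")
    if not (4 <= loop_len <= 20):
        raise ValueError("loop_len must be in 4-20")
    if ext_len < 2:
        raise ValueError("ext_len must be >= 2")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    m = mature_len
    budget = n_mismatches + sum(b for _, b in bulge_spec)
    if budget > m - 8:
        raise ValueError("planted defects exceed the duplex interior")

    # defect placement within the duplex interior, clear of the anchors;
    # mature-side bulges run toward the 5' anchor, so their slots need
    # clearance of the bulge length.  Defects are spaced apart where the
    # interior allows, so separate planted imperfections stay separate
    # internal loops in the folded optimum (decoys with many defects fall
    # back to dense placement, which only makes them worse).
    maxb = max((b for _, b in bulge_spec), default=0)
    interior = list(range(3 + maxb, m - 5))
    n_slots = n_mismatches + len(bulge_spec)
    if n_slots > len(interior):
        raise ValueError("planted defects exceed the duplex interior")
    slots: list[int] = []
    if n_slots:
        shuffled = list(rng.permutation(interior))
        for spacing in (4 + maxb, 2, 1):
            slots = []
            for s in shuffled:
                if all(abs(s - t) >= spacing for t in slots):
                    slots.append(int(s))
                if len(slots) == n_slots:
                    break
            if len(slots) == n_slots:
                break
        if len(slots) < n_slots:
            raise ValueError("planted defects exceed the duplex interior")
        slots.sort()
    mism_at = set(slots[:n_mismatches])
    bulge_at = dict(zip(slots[n_mismatches:], bulge_spec))

    mature = list(_stem_seq(rng, m, gc_target))
    if rng.random() < u_start_prob:
        mature[0] = "T"

    # strong (G/C) closing pairs flanking each planted defect keep the
    # defect a local imperfection in the thermodynamic optimum instead of
    # widening into a larger internal loop
    def _strengthen(j: int) -> None:
        if 0 < j < m and mature[j] in "AT":
            mature[j] = str(rng.choice(["G", "C"]))

    for s in mism_at:
        _strengthen(s - 1)
        _strengthen(s + 1)
    for s, (side, blen) in bulge_at.items():
        if side == "star":
            _strengthen(s)
            _strengthen(s + 1)
        else:
            _strengthen(s + 1)
            _strengthen(s - blen)
    mature = "".join(mature)
    ext = _stem_seq(rng, ext_len, gc_target)

    if arm == "5p":
        arm5 = mature + ext  # 5' stem half, mature at the precursor 5' end
    else:
        arm3 = ext + mature  # 3' stem half, mature at the precursor 3' end

    # complement-walk of the mature-distal stem half, planting defects
    # opposite mature positions; record partner positions as emitted.
    def walk(source: str, mature_offset: int, skip_tail: int) -> tuple[list[str], dict[int, int], set[int]]:
        """Walk ``source`` 3'->5' emitting complements.

        mature positions are source indices [mature_offset, mature_offset+m);
        ``skip_tail`` source positions at the 3' end are left unpaired.
        Returns (emitted bases, source_idx -> emission order idx, skipped mature idx).
        """
        emitted: list[str] = []
        pos_of: dict[int, int] = {}
        skipped: set[int] = set()
        for i in range(len(source) - 1 - skip_tail, -1, -1):
            local = i - mature_offset  # mature-local index, may be negative
            if 0 <= local < m and local in bulge_at:
                side, blen = bulge_at[local]
                if side == "star":
                    for _ in range(blen):
                        emitted.append(_loop_seq(rng, 1, gc_target))
                elif side == "mature":
                    # leave blen mature positions unpaired
                    for k in range(blen):
                        if 0 <= local - k < m:
                            skipped.add(i - k)
                    # emit nothing for them
            if i in skipped:
                continue
            if 0 <= local < m and local in mism_at:
                emitted.append(_non_pairing_base(rng, source[i]))
            else:
                emitted.append(COMP[source[i]])
            pos_of[i] = len(emitted) - 1
        return emitted, pos_of, skipped

    loop = _loop_seq(rng, loop_len, gc_target)
    tail = _loop_seq(rng, 2, gc_target)

    if arm == "5p":
        emitted, pos_of, _ = walk(arm5, mature_offset=0, skip_tail=0)
        stem3 = "".join(emitted)
        seq = arm5 + loop + stem3 + tail
        off = len(arm5) + len(loop)
        gpos = {i: off + p for i, p in pos_of.items()}
        mature_interval = (0, m)
        star5 = gpos[m - 3]
        star3 = gpos[0] + 2 + 1
    else:
        emitted, pos_of, _ = walk(arm3, mature_offset=ext_len, skip_tail=2)
        stem5 = "".join(emitted)
        seq = stem5 + loop + arm3
        off = len(stem5) + len(loop)
        gpos = {i: p for i, p in pos_of.items()}  # stem5 starts at 0
        mature_interval = (off + ext_len, off + ext_len + m)
        star5 = gpos[ext_len + m - 3]
        star3 = gpos[ext_len] + 2 + 1
    star_interval = (star5, star3)

    if not (40 <= len(seq) <= 241):
        raise ValueError(f"precursor length {len(seq)} outside 40-241")

    load = n_mismatches + sum(b for _, b in bulge_spec)
    fails: list[str] = []
    if n_mismatches > 4:
        fails.append("duplex_mismatches")
    if any(b > 3 for _, b in bulge_spec):
        fails += ["bulge_size", "internal_loop"]
    if load > 4:
        fails.append("total_mismatch_load")
    kind = "good"
    if n_mismatches > 4:
        kind = "excess_mismatch"
    elif any(b > 3 for _, b in bulge_spec):
        kind = "oversized_bulge"

    return PrecursorTruth(
        precursor_id=precursor_id,
        seq=seq,
        mature_interval=mature_interval,
        star_interval=star_interval,
        arm=arm,
        n_mismatches=n_mismatches,
        bulges=tuple(bulge_spec),
        family=family,
        kind=kind,
        expected_accept=not fails,
        expected_fail_criteria=tuple(sorted(set(fails))),
    )


def make_loop_decoy(
    rng: np.random.Generator | int,
    precursor_id: str = "D1",
    gc_target: float = 0.5,
) -> PrecursorTruth:
    """A well-folding hairpin whose 'mature' reads straddle the terminal
    loop — the classic discard case."""
    rng = _rng(rng)
    # big loop so a 20-nt 'mature' window fits across the arm/loop boundary
    stem = _stem_seq(rng, 22, gc_target)
    loop = _loop_seq(rng, 18, gc_target)
    seq = stem + loop + revcomp(stem) + _loop_seq(rng, 2, gc_target)
    mstart = len(stem) - 6  # 6 nt in the stem, 14 in the loop
    mature_interval = (mstart, mstart + 20)
    return PrecursorTruth(
        precursor_id=precursor_id,
        seq=seq,
        mature_interval=mature_interval,
        star_interval=(0, 0),
        arm="5p",
        n_mismatches=0,
        bulges=(),
        family=None,
        kind="mature_in_loop",
        expected_accept=False,
        expected_fail_criteria=("mature_in_stem",),
        has_star_reads=False,
    )


def make_contaminant_db(
    rng: np.random.Generator | int,
    n_per_class: int = 3,
    length_range: tuple[int, int] = (90, 300),
) -> list[ContaminantDB]:
    """Synthetic structural-RNA reference sequences for the screen."""
    rng = _rng(rng)
    dbs = []
    for klass in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        recs = []
        for k in range(n_per_class):
            n = int(rng.integers(length_range[0], length_range[1] + 1))
            recs.append((f"{klass}_{k + 1}", _stem_seq(rng, n, 0.5)))
        dbs.append(ContaminantDB(recs, klass))
    return dbs


def make_contaminant_decoy(
    rng: np.random.Generator | int,
    dbs: Sequence[ContaminantDB],
    precursor_id: str = "C1",
) -> PrecursorTruth:
    """A long read that is an exact fragment of a contaminant reference."""
    rng = _rng(rng)
    db = dbs[int(rng.integers(len(dbs)))]
    name, ref = db.records[int(rng.integers(len(db.records)))]
    flen = int(rng.integers(60, min(120, len(ref)) + 1))
    start = int(rng.integers(0, len(ref) - flen + 1))
    frag = ref[start:start + flen]
    mstart = int(rng.integers(0, flen - 21 + 1))
    return PrecursorTruth(
        precursor_id=precursor_id,
        seq=frag,
        mature_interval=(mstart, mstart + 21),
        star_interval=(0, 0),
        arm="5p",
        n_mismatches=0,
        bulges=(),
        family=None,
        kind="contaminant",
        expected_accept=False,
        expected_fail_criteria=("contaminant_screen",),
        has_star_reads=False,
    )


@dataclass
class SyntheticReads:
    """Generated libraries plus their truth manifest."""

    long_fwd: list[SeqRead]
    long_rev: list[SeqRead]
    srna: list[SeqRead]
    manifest: TruthManifest


def make_reads(
    rng: np.random.Generator | int,
    truths: Sequence[PrecursorTruth],
    depth_mean: float = 30.0,
    depth_dispersion: float = 0.5,
    long_depth_mean: float = 6.0,
    jitter_prob: float = 0.15,
    star_fraction: float = 0.4,
    frag_rate: float = 0.0,
    low_quality_fraction: float = 0.0,
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    overlap_target: int = 30,
) -> SyntheticReads:
    """Emit the paired-end long library and the sRNA library for ``truths``.

    sRNA reads are drawn per precursor with negative-binomial depth
    (``depth_mean``, ``depth_dispersion``); a ``jitter_prob`` fraction slide
    1 nt at the 5' end (the sliding-ladder artifact); star reads are emitted
    at ``star_fraction`` of the mature depth for precursors with
    ``has_star_reads``.  Long-library inserts are the full precursor
    sequences (plus degradation fragments at ``frag_rate``), adapter-flanked
    and cut into overlapping read pairs with guaranteed overlap
    >= ``overlap_target``.  Fully seed-deterministic.
    """
    rng = _rng(rng)
    if not truths:
        raise ValueError("no precursor truths supplied")

    def nb(mean: float) -> int:
        # NB with mean and dispersion r: p = r/(r+mean)
        r = depth_dispersion * 10  # shape; dispersion 0.5 -> r=5
        p = r / (r + mean)
        return int(rng.negative_binomial(r, p))

    srna: list[SeqRead] = []
    origins: dict[str, dict] = {}

    def hi_qual(n: int) -> list[int]:
        return [int(q) for q in rng.integers(36, 41, size=n)]

    for t in truths:
        ms, me = t.mature_interval
        n_mat = max(1, nb(depth_mean)) if t.kind != "contaminant" else nb(depth_mean / 3)
        for k in range(n_mat):
            s = ms
            if rng.random() < jitter_prob:
                s = ms + int(rng.choice([-1, 1]))
            s = min(max(0, s), len(t.seq) - (me - ms))
            sub = t.seq[s:s + (me - ms)]
            rid = f"s_{t.precursor_id}_m{k}"
            srna.append(SeqRead(rid, sub, hi_qual(len(sub))))
            origins[rid] = {"origin": "mature", "source": t.precursor_id, "start": s}
        if t.has_star_reads and t.kind == "good":
            ss, se = t.star_interval
            n_star = max(1, int(round(star_fraction * n_mat)))
            for k in range(n_star):
                sub = t.seq[ss:se]
                rid = f"s_{t.precursor_id}_x{k}"
                srna.append(SeqRead(rid, sub, hi_qual(len(sub))))
                origins[rid] = {"origin": "star", "source": t.precursor_id, "start": ss}

    long_fwd: list[SeqRead] = []
    long_rev: list[SeqRead] = []

    def emit_pair(insert: str, rid: str, origin: dict, low_quality: bool) -> None:
        template = adapter5 + insert + adapter3
        n = len(template)
        rlen = min(n, (n + overlap_target + 1) // 2)
        fwd = template[:rlen]
        rev = revcomp(template[n - rlen:])
        q = [20] * rlen if low_quality else hi_qual(rlen)
        q2 = [20] * rlen if low_quality else hi_qual(rlen)
        long_fwd.append(SeqRead(rid + "/1", fwd, q))
        long_rev.append(SeqRead(rid + "/2", rev, q2))
        origins[rid] = origin

    for t in truths:
        n_copies = max(1, nb(long_depth_mean))
        for k in range(n_copies):
            low = rng.random() < low_quality_fraction
            rid = f"L_{t.precursor_id}_{k}"
            emit_pair(t.seq, rid, {"origin": t.kind, "source": t.precursor_id}, low)
        if frag_rate > 0:
            n_frag = int(rng.poisson(frag_rate * n_copies))
            for k in range(n_frag):
                flen = int(rng.integers(40, max(41, len(t.seq))))
                start = int(rng.integers(0, len(t.seq) - flen + 1))
                frag = t.seq[start:start + flen]
                rid = f"F_{t.precursor_id}_{k}"
                emit_pair(
                    frag, rid,
                    {"origin": "degradation", "source": t.precursor_id, "start": start},
                    False,
                )

    manifest = TruthManifest(
        precursors=list(truths),
        read_origins=origins,
        params={
            "depth_mean": depth_mean,
            "depth_dispersion": depth_dispersion,
            "long_depth_mean": long_depth_mean,
            "jitter_prob": jitter_prob,
            "star_fraction": star_fraction,
            "frag_rate": frag_rate,
            "low_quality_fraction": low_quality_fraction,
            "adapter3": adapter3,
            "adapter5": adapter5,
            "overlap_target": overlap_target,
        },
    )
    return SyntheticReads(long_fwd, long_rev, srna, manifest)


def make_reference_set(
    rng: np.random.Generator | int,
    truths: Sequence[PrecursorTruth],
    flank: tuple[int, int] = (15, 25),
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Reference (matures, precursors) emulating a plant miRNA database.

    For every known-family truth the reference precursor is an independent
    hairpin-unrelated sequence embedding the same mature (conservation of
    the mature, not of the precursor).
    """
    rng = _rng(rng)
    matures, precursors = [], []
    for t in truths:
        if t.family is None:
            continue
        left = _stem_seq(rng, int(rng.integers(*flank)), 0.5)
        right = _stem_seq(rng, int(rng.integers(*flank)), 0.5)
        matures.append((t.family, t.mature_seq))
        precursors.append((f"{t.family}-ref", left + t.mature_seq + right))
    return matures, precursors


def write_dataset(
    seed: int,
    outdir: str | Path,
    config_overrides: dict | None = None,
    **dataset_kwargs,
):
    """Write a full synthetic dataset plus a ready pipeline config.

    Emits paired long-library FASTQ, sRNA FASTQ, contaminant FASTA per
    class, reference mature/precursor FASTA, a novel-mature FASTA (every
    non-contaminant novel mature, so defective precursors are retrieved and
    must be rejected on criteria), the truth manifest and a ``config.yaml``.
    Returns (config, manifest).
    """
    from . import sequence_io as sio
    from .pipeline import PipelineConfig

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reads, dbs = standard_dataset(seed, **dataset_kwargs)
    sio.write_fastq(reads.long_fwd, out / "long_R1.fastq")
    sio.write_fastq(reads.long_rev, out / "long_R2.fastq")
    sio.write_fastq(reads.srna, out / "srna.fastq")
    reads.manifest.to_json(out / "manifest.json")
    contam_paths = {}
    for db in dbs:
        p = out / f"contaminant_{db.klass}.fasta"
        sio.write_fasta([sio.SeqRead(n, s) for n, s in db.records], p)
        contam_paths[db.klass] = str(p)
    matures, precs = make_reference_set(
        np.random.default_rng(seed + 1), reads.manifest.precursors
    )
    sio.write_fasta([sio.SeqRead(n, s) for n, s in matures], out / "ref_matures.fasta")
    sio.write_fasta([sio.SeqRead(n, s) for n, s in precs], out / "ref_precursors.fasta")
    novel = [
        sio.SeqRead(t.precursor_id + "_mature", t.mature_seq)
        for t in reads.manifest.precursors
        if t.family is None and t.kind != "contaminant"
    ]
    sio.write_fasta(novel, out / "novel_matures.fasta")
    cfg = PipelineConfig(
        long_fwd_fastq=str(out / "long_R1.fastq"),
        long_rev_fastq=str(out / "long_R2.fastq"),
        srna_fastq=str(out / "srna.fastq"),
        contaminant_fastas=contam_paths,
        ref_mature_fasta=str(out / "ref_matures.fasta"),
        ref_precursor_fasta=str(out / "ref_precursors.fasta"),
        novel_mature_fasta=str(out / "novel_matures.fasta"),
        adapter3=DEFAULT_ADAPTER3,
        adapter5=DEFAULT_ADAPTER5,
        outdir=str(out / "run"),
        seed=seed,
    )
    for k, v in (config_overrides or {}).items():
        setattr(cfg, k, v)
    cfg.to_yaml(out / "config.yaml")
    return cfg, reads.manifest


def standard_dataset(
    seed: int,
    n_good: int = 20,
    n_loop_decoys: int = 4,
    n_mismatch_decoys: int = 4,
    n_bulge_decoys: int = 4,
    n_contaminant_decoys: int = 4,
    known_fraction: float = 0.5,
    frag_rate: float = 0.0,
    low_quality_fraction: float = 0.05,
    star_dropout: float = 0.25,
) -> tuple[SyntheticReads, list[ContaminantDB]]:
    """The study-condition dataset: well-formed precursors plus every decoy
    class, with contaminant references and reads."""
    rng = np.random.default_rng(seed)
    truths: list[PrecursorTruth] = []
    for i in range(n_good):
        fam = f"miR{100 + i}" if rng.random() < known_fraction else None
        n_mm = int(rng.integers(0, 3))
        bulges = []
        if rng.random() < 0.3 and n_mm <= 1:
            bulges = [(str(rng.choice(["mature", "star"])), int(rng.integers(1, 3)))]
        t = make_precursor(
            rng,
            mature_len=int(rng.integers(20, 23)),
            ext_len=int(rng.integers(4, 9)),
            loop_len=int(rng.integers(8, 16)),
            arm="5p" if rng.random() < 0.67 else "3p",
            n_mismatches=n_mm,
            bulge_spec=bulges,
            precursor_id=f"P{i + 1:03d}",
            family=fam,
        )
        if rng.random() < star_dropout:
            t.has_star_reads = False
        truths.append(t)
    for i in range(n_loop_decoys):
        truths.append(make_loop_decoy(rng, precursor_id=f"DLOOP{i + 1}"))
    def _verified_defective(pid: str, **kwargs) -> PrecursorTruth:
        # a planted defect can occasionally be absorbed by the thermodynamic
        # optimum (the stem re-registers around it); the generator guarantees
        # its truth labels, so defect decoys are folded at construction and
        # resampled until the defect survives in the MFE structure
        from .hairpin_folding import fold
        from .precursor_validation import LoopRegionError, locate_duplex

        for _ in range(50):
            t = make_precursor(rng, precursor_id=pid, **kwargs)
            try:
                d = locate_duplex(fold(t.seq), t.mature_interval)
            except LoopRegionError:
                return t
            if (
                d.total_mismatch_load > 4
                or any(b > 3 for _, b in d.bulges)
                or d.max_internal_loop > 3
            ):
                return t
        raise RuntimeError(f"could not construct a defective decoy {pid}")

    for i in range(n_mismatch_decoys):
        truths.append(
            _verified_defective(
                f"DMM{i + 1}", n_mismatches=int(rng.integers(5, 7)),
                mature_len=22, ext_len=6,
                loop_len=int(rng.integers(8, 16)),
            )
        )
    for i in range(n_bulge_decoys):
        truths.append(
            _verified_defective(
                f"DBU{i + 1}",
                bulge_spec=[("star" if rng.random() < 0.5 else "mature",
                             int(rng.integers(4, 6)))],
                mature_len=22, ext_len=6,
                loop_len=int(rng.integers(8, 16)),
            )
        )
    dbs = make_contaminant_db(rng)
    for i in range(n_contaminant_decoys):
        truths.append(make_contaminant_decoy(rng, dbs, precursor_id=f"DCON{i + 1}"))
    reads = make_reads(
        rng, truths, frag_rate=frag_rate,
        low_quality_fraction=low_quality_fraction,
    )
    return reads, dbs
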