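"""End-to-end orchestration: reads in, validated precursors and metrics out.

Stage order: merge -> trim -> quality/length filter -> collapse ->
contaminant screen -> short-read mapping (known + novel retrieval
strategies) -> fold -> duplex/criteria validation -> variant dedupe ->
annotate -> report.  Every stage logs input/output counts to a ledger that
is monotone non-increasing through the filtering stages; a rerun with the
same config and seed is bit-identical apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import annotation as ann
from . import contaminant_screen as cs
from . import hairpin_folding as hf
from . import precursor_validation as pv
from . import read_mapping as rm
from . import reporting as rep
from . import sequence_io as sio

log = logging.getLogger("premirseq")


@dataclass
class PipelineConfig:
    """Flat-key config carrying every threshold of the pipeline.

    Defaults follow the analysis conditions: phred cutoff 30, assembled
    window 40-290, candidate window 40-241, sRNA window 18-34, zero-mismatch
    mapping, MFEI threshold -0.70 for novel candidates.
    """

    # inputs
    long_fwd_fastq: str = ""
    long_rev_fastq: str = ""
    srna_fastq: str = ""
    srna_collapsed_fasta: str = ""
    contaminant_fastas: dict[str, str] = field(default_factory=dict)  # class -> path
    ref_mature_fasta: str = ""
    ref_precursor_fasta: str = ""
    novel_mature_fasta: str = ""
    outdir: str = "premirseq_run"
    # merge/trim/filter
    adapter3: str = ""
    adapter5: str = ""
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    min_mean_phred: float = 30.0
    assembled_len: tuple[int, int] = (40, 290)
    candidate_len: tuple[int, int] = (40, 241)
    srna_len: tuple[int, int] = (18, 34)
    # mapping / folding / validation
    cluster_window: int = 3
    fold_backend: str = "vienna"
    n_shuffles: int = 99  # randomization test on accepted candidates; 0 skips
    seed: int = 1
    validation: pv.ValidationConfig = field(default_factory=pv.ValidationConfig)

    def validate_config(self) -> None:
        for name in ("assembled_len", "candidate_len", "srna_len"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: window ({lo},{hi}) has min > max")
        if self.min_overlap < 5:
            raise ValueError("min_overlap must be >= 5")
        if self.fold_backend not in ("vienna", "builtin"):
            raise ValueError(f"unknown fold_backend {self.fold_backend!r}")
        # re-run the validation-threshold checks
        pv.ValidationConfig(**dataclasses.asdict(self.validation))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        vc = d.pop("validation", {})
        cfg = cls(**{k: tuple(v) if k.endswith("_len") else v for k, v in d.items()})
        cfg.validation = pv.ValidationConfig(**vc)
        return cfg


@dataclass
class PipelineResult:
    candidates: list[pv.PrecursorCandidate]
    accepted: list[pv.PrecursorCandidate]
    ledger: dict[str, int]
    metrics: dict
    outdir: Path


def _ledger_entry(ledger: dict[str, int], stage: str, n: int) -> None:
    ledger[stage] = n
    log.info("%-28s %d", stage, n)


def preprocess_long_reads(
    fwd: Sequence[sio.SeqRead],
    rev: Sequence[sio.SeqRead],
    config: PipelineConfig,
    ledger: dict[str, int],
) -> list[sio.CollapsedRead]:
    """merge -> assembled-length window -> trim -> quality -> candidate
    window -> collapse."""
    _ledger_entry(ledger, "long_read_pairs", len(fwd))
    merged = []
    for f, r in zip(fwd, rev):
        m = sio.merge_pair(f, r, config.min_overlap, config.max_mismatch_frac)
        if not isinstance(m, sio.MergeFailure):
            merged.append(m)
    _ledger_entry(ledger, "merged", len(merged))
    merged = sio.length_select(merged, *config.assembled_len)
    _ledger_entry(ledger, "assembled_window", len(merged))
    if config.adapter3 and config.adapter5:
        merged = [
            sio.trim_adapters(m, config.adapter3, config.adapter5) for m in merged
        ]
        merged = [m for m in merged if m.seq]
    _ledger_entry(ledger, "adapter_trimmed", len(merged))
    merged = sio.quality_filter(merged, config.min_mean_phred)
    _ledger_entry(ledger, "quality_filtered", len(merged))
    merged = sio.length_select(merged, *config.candidate_len)
    _ledger_entry(ledger, "candidate_window", len(merged))
    collapsed = sio.collapse(merged)
    _ledger_entry(ledger, "unique_long_reads", len(collapsed))
    return collapsed


def load_srna(config: PipelineConfig, ledger: dict[str, int]) -> list[sio.CollapsedRead]:
    if config.srna_collapsed_fasta:
        shorts = sio.read_collapsed_fasta(config.srna_collapsed_fasta)
    elif config.srna_fastq:
        reads = list(sio.read_fastq(config.srna_fastq))
        _ledger_entry(ledger, "srna_raw", len(reads))
        shorts = sio.collapse(reads)
    else:
        raise ValueError("no sRNA input configured")
    lo, hi = config.srna_len
    shorts = [s for s in shorts if lo <= len(s.seq) <= hi]
    _ledger_entry(ledger, "srna_unique_in_window", len(shorts))
    return shorts


def _dominant_mature(profile: rm.MappingProfile) -> tuple[int, int] | None:
    """Mature interval = dominant placement of the highest-count cluster
    (one mature position per precursor; the higher-count arm wins)."""
    if not profile.clusters:
        return None
    best = max(profile.clusters, key=lambda c: (c.total_count, -c.start_window))
    return best.dominant.start, best.dominant.end


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate_config()
    for name in ("long_fwd_fastq", "long_rev_fastq", "srna_fastq",
                 "srna_collapsed_fasta", "ref_mature_fasta",
                 "ref_precursor_fasta", "novel_mature_fasta"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p}")
    for klass, p in config.contaminant_fastas.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"contaminant_fastas[{klass}]: {p}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger: dict[str, int] = {}

    fwd = list(sio.read_fastq(config.long_fwd_fastq))
    rev = list(sio.read_fastq(config.long_rev_fastq))
    longs = preprocess_long_reads(fwd, rev, config, ledger)

    # contaminant screen
    if config.contaminant_fastas:
        dbs = [
            cs.ContaminantDB.from_fasta(path, klass)
            for klass, path in sorted(config.contaminant_fastas.items())
        ]
        longs, removed = cs.screen(longs, dbs)
        cs.write_removal_report(removed, outdir / "contaminant_report.tsv")
        _ledger_entry(ledger, "contaminant_removed", len(removed))
    _ledger_entry(ledger, "clean_long_reads", len(longs))
    sio.write_collapsed_fasta(longs, outdir / "clean_longs.fasta")

    shorts = load_srna(config, ledger)
    long_pairs = [(f"long{i + 1}", c.seq) for i, c in enumerate(longs)]

    # retrieval strategies
    retrieved: dict[str, ann.RetrievedLong] = {}
    ref = None
    if config.ref_mature_fasta and config.ref_precursor_fasta:
        ref = ann.ReferenceSet.from_fasta(
            config.ref_mature_fasta, config.ref_precursor_fasta
        )
        for r in ann.strategy_known(shorts, long_pairs, ref, config.cluster_window):
            retrieved[r.long_id] = r
    if config.novel_mature_fasta:
        novel = [r.seq for r in sio.read_fasta(config.novel_mature_fasta)]
        for r in ann.strategy_novel(shorts, long_pairs, novel, config.cluster_window):
            retrieved.setdefault(r.long_id, r)
    if not ref and not config.novel_mature_fasta:
        # no references: profile every clean long read
        placements = rm.map_short_to_long(shorts, long_pairs)
        by_long: dict[str, list] = {}
        for p in placements:
            by_long.setdefault(p.long_id, []).append(p)
        for lid, seq in long_pairs:
            if lid in by_long:
                prof = rm.build_profile(lid, seq, by_long[lid], config.cluster_window)
                retrieved[lid] = ann.RetrievedLong(lid, seq, (), (), prof)
    _ledger_entry(ledger, "retrieved_long_reads", len(retrieved))

    # fold + validate
    candidates: list[pv.PrecursorCandidate] = []
    for lid in sorted(retrieved, key=lambda x: int(x.removeprefix("long") or 0) if x.startswith("long") else 0):
        r = retrieved[lid]
        structure = hf.fold(r.long_seq, backend=config.fold_backend)
        mature = _dominant_mature(r.profile)
        duplex = None
        if mature is not None:
            try:
                duplex = pv.locate_duplex(structure, mature)
            except pv.LoopRegionError:
                duplex = None
        cand = pv.PrecursorCandidate(
            long_id=lid, seq=r.long_seq, structure=structure,
            profile=r.profile, duplex=duplex,
        )
        if ref is not None:
            fams = ann.assign_family(r.long_seq, ref)
            if fams:
                cand.families = fams
                cand.label = "known:" + ",".join(fams)
        candidates.append(pv.validate(cand, config.validation))
    _ledger_entry(ledger, "candidates", len(candidates))

    accepted = [c for c in candidates if c.accepted]
    _ledger_entry(ledger, "accepted", len(accepted))
    accepted = pv.dedupe_variants(accepted)
    _ledger_entry(ledger, "accepted_deduped", len(accepted))

    if config.n_shuffles > 0:
        for c in accepted:
            c.p_value = hf.randomization_p(
                c.seq, config.n_shuffles, rng_seed=config.seed,
                backend=config.fold_backend,
            ).p_value

    # outputs
    pv.write_table(candidates, outdir / "candidates.tsv")
    sio.write_fasta(
        [sio.SeqRead(c.long_id, c.seq) for c in accepted],
        outdir / "accepted.fasta",
    )
    with open(outdir / "accepted.dbn", "w") as fh:
        for c in accepted:
            fh.write(f">{c.long_id}\n{c.structure.to_vienna()}")
    metrics = rep.summarize(candidates)
    metrics["ledger"] = ledger
    metrics["config"] = {
        "validation": config.validation.to_dict(),
        "fold_backend": config.fold_backend,
        "seed": config.seed,
        "n_shuffles": config.n_shuffles,
    }
    rep.write_metrics_json(metrics, outdir / "metrics.json")
    with open(outdir / "ledger.txt", "w") as fh:
        for k, v in ledger.items():
            fh.write(f"{k}\t{v}\n")
    return PipelineResult(candidates, accepted, ledger, metrics, outdir)


def score_against_manifest(result: PipelineResult, manifest) -> dict:
    """Recall/precision of accepted precursors against a synthetic truth
    manifest (sequences are the join key: long reads are full precursors)."""
    truth_by_seq = {t.seq: t for t in manifest.precursors}
    accepted_seqs = {c.seq for c in result.accepted}
    planted_good = [t for t in manifest.precursors if t.expected_accept]
    decoys = [t for t in manifest.precursors if not t.expected_accept]
    tp = sum(1 for t in planted_good if t.seq in accepted_seqs)
    decoys_accepted = sum(1 for t in decoys if t.seq in accepted_seqs)
    false_novel = sum(1 for s in accepted_seqs if s not in truth_by_seq)
    return {
        "n_planted_good": len(planted_good),
        "n_decoys": len(decoys),
        "recall": tp / len(planted_good) if planted_good else float("nan"),
        "decoys_accepted": decoys_accepted,
        "decoy_acceptance_rate": decoys_accepted / len(decoys) if decoys else 0.0,
        "accepted_not_planted": false_novel,
    }
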