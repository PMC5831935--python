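"""Summary statistics over accepted precursor candidates.

Length histograms for matures and precursors, 5'-terminal nucleotide
prevalence (plant miRNAs and their precursors are U-biased at the 5' end)
and the 5p/3p arm-of-origin tally.  Emitted as TSV plus a single JSON
metrics file for machine comparison.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .precursor_validation import PrecursorCandidate


def length_distribution(seqs: Sequence[str], kind: str = "precursor") -> dict:
    """Counts per integer length with min/max/mode."""
    if not seqs:
        raise ValueError(f"no {kind} sequences to summarize")
    lengths = [len(s) for s in seqs]
    hist = Counter(lengths)
    mode = min(sorted(hist, key=lambda k: (-hist[k], k))[:1])
    return {
        "kind": kind,
        "histogram": dict(sorted(hist.items())),
        "min": min(lengths),
        "max": max(lengths),
        "mode": mode,
        "n": len(lengths),
    }


def terminal_nt_summary(seqs: Sequence[str]) -> dict:
    """5'-terminal base counts and fractions (RNA alphabet, T reported as U)."""
    counts = {b: 0 for b in "ACGU"}
    for s in seqs:
        if s:
            b = s[0].upper().replace("T", "U")
            counts[b] = counts.get(b, 0) + 1
    n = sum(counts.values())
    fracs = {b: (c / n if n else 0.0) for b, c in counts.items()}
    return {"counts": counts, "fractions": fracs, "n": n}


def arm_summary(candidates: Sequence[PrecursorCandidate]) -> dict:
    """5p/3p counts over accepted candidates; enforces the one-arm rule."""
    counts = {"5p": 0, "3p": 0}
    for c in candidates:
        if c.duplex is None:
            continue
        counts[c.duplex.arm] += 1
    return {"counts": counts, "n": counts["5p"] + counts["3p"]}


def summarize(candidates: Sequence[PrecursorCandidate]) -> dict:
    """The full metrics bundle over accepted candidates."""
    accepted = [c for c in candidates if c.accepted]
    out: dict = {
        "n_candidates": len(candidates),
        "n_accepted": len(accepted),
        "n_known": sum(1 for c in accepted if c.is_known),
        "n_novel": sum(1 for c in accepted if not c.is_known),
    }
    if accepted:
        matures = [
            c.seq[c.duplex.mature_interval[0]:c.duplex.mature_interval[1]]
            for c in accepted if c.duplex
        ]
        precs = [c.seq for c in accepted]
        out["precursor_lengths"] = length_distribution(precs, "precursor")
        if matures:
            out["mature_lengths"] = length_distribution(matures, "mature")
            out["mature_5p_nt"] = terminal_nt_summary(matures)
        out["precursor_5p_nt"] = terminal_nt_summary(precs)
        out["arms"] = arm_summary(accepted)
        mfeis = [c.structure.mfei for c in accepted if c.structure.mfei is not None]
        if mfeis:
            out["mfei"] = {
                "min": min(mfeis), "max": max(mfeis),
                "mean": sum(mfeis) / len(mfeis),
            }
        pvals = [c.p_value for c in accepted if c.p_value is not None]
        if pvals:
            out["p_value"] = {
                "min": min(pvals), "max": max(pvals),
                "mean": sum(pvals) / len(pvals),
            }
    return out


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=1, sort_keys=True))


def write_summary_tsv(candidates: Sequence[PrecursorCandidate], path: str | Path) -> None:
    rows = []
    for c in candidates:
        rows.append({
            "long_id": c.long_id,
            "length": len(c.seq),
            "mfei": c.structure.mfei,
            "arm": c.duplex.arm if c.duplex else "NA",
            "label": c.label,
            "confidence": c.confidence or "NA",
            "accepted": c.accepted,
            "failed": ";".join(c.failed_criteria()) or "-",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
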