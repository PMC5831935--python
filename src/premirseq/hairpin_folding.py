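"""RNA secondary-structure prediction, MFEI and the shuffle-randomization test.

Two folding backends sit behind one contract:

* ``vienna`` — minimum free energy under the Turner nearest-neighbor model via
  the ViennaRNA bindings; this is the backend used to score real candidates.
* ``builtin`` — a dependency-light dynamic program over all pseudoknot-free
  structures under a simple pair + helix-stacking energy model.  Its energy
  terms are deliberately coarse, but the optimization is exact: on short
  sequences it provably returns the minimum of :func:`score_structure` over
  every nested structure, which makes it useful as a self-contained test
  backend.

The minimal folding free energy index,

    MFEI = 100 * MFE / length / GC%,

normalizes folding energy by length and GC content (GC on the 0-100 scale);
true pre-miRNAs fold markedly lower than tRNA/rRNA/mRNA at the same length
and composition, which makes MFEI the workhorse filter for novel candidates.

The randomization test compares the MFE of a candidate against folds of
dinucleotide-preserving shuffles (Altschul-Erickson Eulerian construction):
p = (1 + #{shuffles with MFE <= original}) / (1 + n_shuffles).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_FOLD_BASES = frozenset("ACGTU")

# simple energy model of the builtin backend (kcal/mol-like, arbitrary units)
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}
STACK_BONUS = -1.0  # applied to a pair whose immediate inner neighbor pairs
MIN_HAIRPIN_LOOP = 3


class FoldError(ValueError):
    pass


class UndefinedMFEIError(ZeroDivisionError):
    """MFEI is undefined at GC% == 0."""


def _norm_dna(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - frozenset("ACGT")
    if bad:
        raise FoldError(f"sequence contains non-ACGTU characters {sorted(bad)!r}")
    return s


def gc_percent(seq: str) -> float:
    """GC content on the 0-100 scale."""
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def mfei(mfe: float, length: int, gc: float) -> float:
    """MFEI = 100 * MFE / length / GC% (GC on the 0-100 scale)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if gc == 0:
        raise UndefinedMFEIError("MFEI undefined for GC% == 0")
    return 100.0 * mfe / length / gc


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    return sorted(pairs)


def dotbracket_from_pairs(pairs: Iterable[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def count_terminal_loops(pairs: Sequence[tuple[int, int]]) -> int:
    """Number of terminal (hairpin) loops: pairs enclosing no other pair."""
    paired = sorted(p for ij in pairs for p in ij)
    n_loops = 0
    for i, j in pairs:
        if not any(i < p < j for p in paired):
            n_loops += 1
    return n_loops


@dataclass
class HairpinStructure:
    """Predicted minimum-free-energy structure of one candidate sequence."""

    seq: str  # DNA alphabet, as analysed
    dotbracket: str
    pairs: list[tuple[int, int]]
    mfe: float  # kcal/mol
    gc_percent: float  # 0-100
    mfei: float | None
    n_loops: int
    backend: str

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def terminal_loops(self) -> list[tuple[int, int]]:
        """Half-open intervals of the terminal loops (innermost-pair interiors)."""
        paired = sorted(p for ij in self.pairs for p in ij)
        loops = []
        for i, j in self.pairs:
            if not any(i < p < j for p in paired):
                loops.append((i + 1, j))
        return sorted(loops)

    def to_vienna(self) -> str:
        return f"{self.seq.replace('T', 'U')}\n{self.dotbracket} ({self.mfe:.2f})\n"


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_ENERGY


def score_structure(seq: str, pairs: Iterable[tuple[int, int]]) -> float:
    """Energy of a nested structure under the builtin model.

    Sum of pair energies plus a stacking bonus for every pair whose
    immediate inner neighbor is also a pair.  This is the objective the
    builtin DP minimizes exactly.
    """
    s = _norm_dna(seq)
    pset = set(map(tuple, pairs))
    e = 0.0
    for i, j in pset:
        if not _can_pair(s[i], s[j]):
            raise ValueError(f"positions {i},{j} ({s[i]},{s[j]}) cannot pair")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError(f"pair ({i},{j}) closes a loop shorter than {MIN_HAIRPIN_LOOP}")
        e += PAIR_ENERGY[(s[i], s[j])]
        if (i + 1, j - 1) in pset:
            e += STACK_BONUS
    return e


def _fold_builtin(seq: str) -> tuple[str, float, list[tuple[int, int]]]:
    s = seq
    n = len(s)

    V: dict[tuple[int, int], float] = {}
    W: dict[tuple[int, int], float] = {}

    def v(i: int, j: int) -> float:
        """Best energy on [i, j] given that (i, j) pair."""
        if (i, j) in V:
            return V[(i, j)]
        e = PAIR_ENERGY[(s[i], s[j])]
        best = e + w(i + 1, j - 1)
        if (
            j - 1 - (i + 1) - 1 >= MIN_HAIRPIN_LOOP
            and _can_pair(s[i + 1], s[j - 1])
        ):
            best = min(best, e + STACK_BONUS + v(i + 1, j - 1))
        V[(i, j)] = best
        return best

    def w(i: int, j: int) -> float:
        """Best energy of any nested structure on [i, j]."""
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return 0.0
        if (i, j) in W:
            return W[(i, j)]
        best = w(i + 1, j)
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if _can_pair(s[i], s[k]):
                best = min(best, v(i, k) + w(k + 1, j))
        W[(i, j)] = best
        return best

    pairs: list[tuple[int, int]] = []

    def trace_w(i: int, j: int) -> None:
        while j - i >= MIN_HAIRPIN_LOOP + 1:
            val = w(i, j)
            if val == w(i + 1, j):
                i += 1
                continue
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if _can_pair(s[i], s[k]) and val == v(i, k) + w(k + 1, j):
                    trace_v(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("builtin fold traceback failed")

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        e = PAIR_ENERGY[(s[i], s[j])]
        if (
            j - 1 - (i + 1) - 1 >= MIN_HAIRPIN_LOOP
            and _can_pair(s[i + 1], s[j - 1])
            and v(i, j) == e + STACK_BONUS + v(i + 1, j - 1)
        ):
            trace_v(i + 1, j - 1)
        else:
            trace_w(i + 1, j - 1)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        mfe = w(0, n - 1) if n >= MIN_HAIRPIN_LOOP + 2 else 0.0
        if n >= MIN_HAIRPIN_LOOP + 2:
            trace_w(0, n - 1)
    finally:
        sys.setrecursionlimit(old)
    pairs.sort()
    return dotbracket_from_pairs(pairs, n), mfe, pairs


def _fold_vienna(seq: str) -> tuple[str, float, list[tuple[int, int]]]:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise FoldError(
            "ViennaRNA python bindings not available; use backend='builtin'"
        ) from exc
    db, mfe = RNA.fold(seq.replace("T", "U"))
    return db, float(mfe), pairs_from_dotbracket(db)


def fold(seq: str, backend: str = "vienna") -> HairpinStructure:
    """Minimum-free-energy pseudoknot-free structure of ``seq``.

    ``backend='vienna'`` uses the Turner nearest-neighbor model (ViennaRNA);
    ``backend='builtin'`` uses the package's exact simple-model DP.
    """
    s = _norm_dna(seq)
    if backend == "vienna":
        db, mfe, pairs = _fold_vienna(s)
    elif backend == "builtin":
        db, mfe, pairs = _fold_builtin(s)
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    gc = gc_percent(s)
    return HairpinStructure(
        seq=s,
        dotbracket=db,
        pairs=pairs,
        mfe=mfe,
        gc_percent=gc,
        mfei=mfei(mfe, len(s), gc) if gc > 0 else None,
        n_loops=count_terminal_loops(pairs),
        backend=backend,
    )


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def dinucleotide_shuffle(seq: str, rng: random.Random | int) -> str:
    """Random sequence with identical mono- and dinucleotide counts.

    Altschul-Erickson construction: the sequence is an Eulerian walk on the
    dinucleotide transition multigraph; a random last-exit edge set forming
    an arborescence into the final vertex guarantees the shuffled walk is
    again Eulerian.  First and last characters are preserved.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    if len(seq) < 3:
        return seq
    s = seq
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    # choose a random last-exit edge per non-terminal vertex until the
    # last-exit graph connects every used vertex to the terminal vertex
    non_terminal = [v for v in vertices if v != last and edges[v]]
    while True:
        last_exit = {v: rng.choice(edges[v]) for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        shuffled[v] = pool

    out = [s[0]]
    cur = s[0]
    idx = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass(frozen=True)
class RandomizationResult:
    """Dinucleotide-shuffle randomization test of folding energy."""

    p_value: float
    n_shuffles: int
    seed: int
    mfe: float  # of the original sequence


def randomization_p(
    seq: str,
    n_shuffles: int = 999,
    rng_seed: int = 0,
    backend: str = "vienna",
) -> RandomizationResult:
    """Add-one randomization p-value of the MFE against the dinucleotide-
    preserving null: p = (1 + #{MFE_shuffle <= MFE_orig}) / (1 + n)."""
    if len(seq) < 3:
        raise ValueError("sequence too short for a dinucleotide shuffle test")
    s = _norm_dna(seq)
    orig = fold(s, backend=backend).mfe
    rng = random.Random(rng_seed)
    hits = 0
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(s, rng)
        if fold(shuf, backend=backend).mfe <= orig:
            hits += 1
    return RandomizationResult(
        p_value=(1 + hits) / (1 + n_shuffles),
        n_shuffles=n_shuffles,
        seed=rng_seed,
        mfe=orig,
    )
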