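# Methods

## Problem setting and model

A plant pre-miRNA is a single-stranded RNA that folds back on itself into a
stem-loop. Dicer-like enzymes cut the stem in staggered fashion, releasing
a miRNA:miRNA\* duplex whose strands each carry a 2-nt 3′ overhang. This
geometry leaves two testable signatures in sequencing data: structurally, a
single-hairpin fold holding the mature sequence in the stem with a nearly
complementary star region; and in read space, small-RNA clusters whose 5′
ends pile up at the duplex boundaries. `premirseq` accepts a candidate
precursor only when both signatures are present (or, for mature-only
expression evidence, when the structural signature is present and the
mature cluster is deep enough).

Coordinates are 0-based half-open everywhere; length windows are closed
intervals. U is normalized to T internally; reports print RNA (U), FASTA
prints DNA (T).

## Pipeline stages and defaults

1. **Paired-end merging** — deterministic best-overlap merger: the longest
   suffix/prefix overlap (≥ `min_overlap`, default 10 nt) with mismatch
   fraction ≤ 0.1 is taken; at each overlap mismatch the higher-phred base
   wins and keeps its quality. This is a plumbing stand-in for statistical
   mergers such as PEAR; overlap merging is not where the scientific risk
   lives, and a deterministic rule is exactly testable.
2. **Adapter trimming** — leftmost full or ≥ 8-nt terminal-partial adapter
   occurrence; the 3′ adapter and everything after it, and the 5′ adapter
   and everything before it, are removed. The 8-nt partial floor avoids
   chance trimming of short motifs (expected < 10⁻⁴ per read end).
3. **Quality filter** — mean phred ≥ 30 per read. Reads with > 10% N are
   dropped here; N never counts as a match anywhere.
4. **Length windows** — 40–290 nt after merging, 40–241 nt after trimming
   (the candidate window; the lower bound excludes sRNA carry-over, the
   upper bound excludes mRNA degradation products).
5. **Collapsing** — unique sequences with counts; counts are conserved
   exactly (an invariant the tests assert).
6. **Contaminant screen** — a read is removed iff it occurs exactly, sense
   or antisense, as a substring of a user-supplied rRNA/tRNA/sn/snoRNA
   reference. Exactness (rather than mismatch-tolerant alignment) matches
   the zero-mismatch mapping used elsewhere and keeps the step auditable;
   an empty reference set is an error, not a no-op.
7. **Short-read mapping** — every exact sense occurrence of every 18–34 nt
   unique small-RNA read on every long read. Sense-only: both libraries
   are stranded and matures lie sense in their precursor. Multi-mapping
   reads are reported at every location, unweighted.
8. **Clustering** — placements whose 5′ starts fall within a 3-nt window
   form one cluster; the dominant placement is the highest-count one. The
   3-nt window absorbs the 1-nt 5′ "sliding ladder" jitter of Dicer
   products while keeping mature and star clusters (≥ ~15 nt apart)
   separate.
9. **Folding** — ViennaRNA MFE structure by default. MFEI =
   100·MFE/length/GC% with GC on the 0–100 scale (this scale reproduces
   the magnitudes of published precursor MFEIs, ≈ −0.3 … −0.95).
10. **Validation** — see below.
11. **Variant dedupe** — candidates sharing a 5′ prefix over ≥ 90% of the
    shorter sequence and the same mature interval collapse to the longest
    representative (3′-truncation/extension variants).

## Duplex geometry

The star interval is derived from the pairing table: the range paired with
the mature, shifted 2 nt toward the star's 3′ end, which is the standard
Dicer-duplex convention (both strands end with 2-nt 3′ overhangs). Unpaired
anchors are extrapolated from the nearest paired mature position, so
terminal fraying or a mismatch at an anchor shifts nothing by more than the
1-nt tolerance used in the cluster checks.

Unpaired runs inside the duplex are classified from the pairing table:
equal-length opposite runs are mismatches (one per position); one-sided
runs are bulges; unequal runs contribute their matched part to mismatches
and their excess to a bulge. The total imperfection budget
(mismatches + bulged bases) must be ≤ 4; any single one-sided run > 3
(an oversized bulge or internal loop) rejects independently.

Acceptance flags: length window, single terminal loop, mature in stem,
duplex mismatches ≤ 4, every bulge ≤ 3, total budget ≤ 4, internal loops
≤ 3, Dicer read pattern, and — for novel candidates only — MFEI ≤ −0.70.
The MFEI threshold is not applied to known-family candidates: several
published known precursors (e.g. miR167 at −0.339) sit well above it, and
conservation evidence substitutes. Every rejection names its failed
criteria; tightening any threshold provably never enlarges the accepted set
(property-tested).

The expression-supported call (mature-only cluster, ≥ 5 reads by default)
requires that no other read cluster exists on the precursor; if star or
loop clusters are present the candidate must pass the full duplex check.

## Randomization test

The null preserves mono- and dinucleotide composition: Altschul–Erickson
Eulerian-walk shuffling with first and last base fixed, uniform over
arrangements via a random last-exit arborescence. p = (1 + #{shuffles with
MFE ≤ observed}) / (1 + n); the add-one estimator avoids p = 0. Default
n = 999 standalone; the pipeline default is 99 (the p-value is reported,
not filtered on, so a coarser estimate on accepted candidates suffices).
p-values are bit-reproducible under a fixed seed.

## Folding backends

* `vienna` — ViennaRNA's Turner nearest-neighbor MFE fold; used for all
  real scoring. Published MFEI values reproduce within ±0.02 (energy
  parameter versions differ in the last decimal of MFE).
* `builtin` — an exact dynamic program over all pseudoknot-free structures
  under a deliberately simple energy model (pair energies GC −3, AU −2,
  GU −1; −1 per stacked pair; hairpin loops ≥ 3). Its optimization is
  provably exact: tests check it against exhaustive enumeration of every
  nested structure on sequences up to 18 nt. It exists to make the folding
  contract testable without thermodynamic tables, not to mimic Turner
  energies; every output records which backend produced it.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* hairpins 40–241 nt: mature (18–24 nt, 5′-U with probability 0.7, GC
  target 0.5) + stem extension + terminal loop (4–20 nt) + complement arm
  with planted mismatches/bulges + 2-nt overhang tail, on either arm;
* small-RNA reads at the mature/star 5′ ends with a 1-nt sliding-ladder
  jitter (probability 0.15), negative-binomial depth (mean 30, shape 5 —
  sRNA counts are overdispersed), star reads at 0.4× mature depth with a
  dropout class that exercises the expression-supported path;
* long-library paired-end reads: adapter-flanked templates cut with
  guaranteed ≥ 30 nt overlap, phred 36–40 with a configurable low-quality
  fraction; optional degradation fragments and exact contaminant
  fragments;
* decoy classes: mature-in-loop, > 4 mismatches, oversized bulges,
  contaminant-derived.

Two deliberate artificialities keep truth labels exact. Terminal loops and
tails are drawn from an {A,C} alphabet (at the target GC), which cannot
base-pair internally, so the designed stem is the unambiguous optimum
without conditioning the generator on a folding backend. And because a
planted defect can occasionally be absorbed by the thermodynamic optimum
(the stem re-registers around it), defect decoys are folded once at
construction and resampled until the defect survives — the generator
guarantees its labels rather than hoping for them. Planted defects in
well-formed precursors are spaced ≥ 4 nt apart and flanked by strong G/C
closing pairs for the same reason.

What passing tests on this generator do **not** show: robustness to
sequencing error (only uniform quality classes are modeled, no substitution
errors), to platform-specific artifacts, to heterogeneous loop composition,
or to the far larger multiplicity and fragment load of a real library.
They do show that every filter removes exactly what it claims to remove
and that the acceptance criteria recover planted Dicer-consistent hairpins
(≥ 95% at the 50+50 scale; the residual loss is precursors whose few
long-library copies all draw the low-quality class) while rejecting every
decoy class completely.

## Numerical and design choices

* All energies compared exactly: builtin-model energies are sums of
  half-integer constants, so DP tracebacks can test float equality safely.
* Cluster tie-breaks: highest count, then smallest start, then shortest
  read. Mature-arm choice when both arms carry clusters: higher total
  count (one mature position per precursor).
* Problem sizes in the tests (50 planted + 50 decoys; 10⁴-nt mapping
  oracle instances; 18-nt enumeration bound; 8-mer exhaustive shuffle
  check) are chosen so each oracle is airtight at a scale where brute
  force is still exact.
* `min_mature_count = 5` for expression-supported calls is a conservative
  invention (no published value exists); it is serialized into every
  report so downstream users can see and change it.

## Known limitations

* No mismatch-tolerant contaminant screen; divergent contaminant copies
  pass the screen and must be caught by the MFEI filter (which was its
  original purpose).
* The mapping-pattern text format is a functional, round-trippable
  rendering, not byte-compatible with any external tool.
* Known-candidate retrieval requires the mature to be conserved exactly;
  single-nucleotide family variants are retrieved only via their own
  reference entries.
* Partition-function/ensemble folding and suboptimal structures are out of
  scope; all structure statements refer to the single MFE structure.
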