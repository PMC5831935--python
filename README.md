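# premirseq

Discovery and validation of miRNA hairpin precursors (pre-miRNAs) directly
from sequencing data, for plants with little or no genome information.

Mature miRNA profiling by small-RNA sequencing is routine, but the hairpin
precursors they are excised from are rarely observed directly: pre-miRNAs
are low-abundance processing intermediates, and without a reference genome
the usual trick — fold the genomic flanks of a mapped mature read — is
unavailable. `premirseq` implements the alternative: sequence a
size-selected precursor library, merge/trim/filter the paired-end reads,
and treat every surviving 40–241 nt "long read" as a candidate hairpin to
be confirmed or rejected on structural and read-mapping evidence from a
matched small-RNA library.

## The criteria at the core

A candidate long read is accepted as a pre-miRNA when all of the following
hold:

* it folds (Turner nearest-neighbor model, via ViennaRNA) into a single
  stem-loop — an unambiguous hairpin with one terminal loop;
* the mature miRNA sits in the stem, never in the terminal loop;
* the miRNA:miRNA\* duplex read off the pairing table has ≤ 4 mismatches in
  total, and no asymmetric bulge or one-sided internal loop of ≥ 4 bases;
* small-RNA read clusters match Dicer processing: cluster 5′ ends at the
  mature and star duplex boundaries with 2-nt 3′ overhangs
  (*duplex-supported*), or a sufficiently deep mature-only cluster
  (*expression-supported*);
* for **novel** candidates, the minimal folding free energy index

  ```
  MFEI = (100 × MFE) / length / GC%
  ```

  must be ≤ −0.70, the empirical band separating true pre-miRNAs from
  tRNA/rRNA/mRNA fragments (≈ −0.59 … −0.65). Known-family candidates report
  their MFEI but are not filtered on it.

Candidates are additionally scored with a dinucleotide-preserving shuffle
randomization test (Altschul–Erickson): p = (1 + #{shuffles with MFE ≤
observed}) / (1 + n).

Known/novel labeling follows two cross-mapping strategies: sample short
reads that map exactly into a reference precursor set (e.g. a PMRD export)
seed retrieval of conserved candidates; long reads containing a predicted
novel mature retrieve novel candidates. Zero-mismatch exact matching is
used throughout.

Because real precursor libraries are large and not redistributable, the
package ships a first-class synthetic data generator
(`premirseq.synthetic_data`) that emits ground-truthed hairpins, Dicer-like
read ladders, degradation fragments, contaminant fragments and
adapter-flanked paired-end FASTQ, with a truth manifest that fully
determines the expected pipeline output.

## Worked example

Fold two known okra precursors from the bundled reference table:

```
$ premirseq fold two.fasta
>miR159 mfe=-20.00 mfei=-0.769 loops=1
UUUGGAUUGAAGGGAGCUCUAUUCUGUGAUGAAGCAAUUUUAUUGUGGACUAGAGUUUCUGAUCUGG
...(((((...((((((((((.(((((((((((.....))))))))))).)))))))))))))))..
>miR530 mfe=-21.10 mfei=-0.879 loops=1
UGCAUUUGCACCUGCACCUUCUCAUUACGAUAGGUGUCAAGUGGAAGUGCA
(((((((.(((.(((((((..((.....)).))))).)).))).)))))))
```

Both fold into single hairpins (`loops=1`) with MFEI below −0.70: miR159 at
−0.769 and miR530 at −0.879, i.e. far more stable per unit length and GC
than typical non-precursor RNA. `premirseq validate` adds the randomization
test (here p = 0.010 and 0.015 at 199 shuffles — fewer than 1.5% of
dinucleotide-preserving shuffles fold as stably).

An end-to-end run on synthetic data:

```
$ premirseq simulate --seed 1 --outdir ds --n-good 10 --n-decoys 2
$ premirseq run ds/config.yaml --manifest ds/manifest.json
{
 "long_read_pairs": 105,
 "merged": 105,
 ...
 "unique_long_reads": 18,
 "contaminant_removed": 2,
 "clean_long_reads": 16,
 "retrieved_long_reads": 16,
 "candidates": 16,
 "accepted": 9,
 "accepted_deduped": 9
}
accepted 9 precursors -> ds/run
```

The ledger counts every filtering stage; `ds/run/` holds the candidate
table (per-criterion flags for every rejection), accepted FASTA,
dot-bracket structures and a metrics JSON including recall/decoy scores
against the truth manifest.

## Layout

| module | role |
| --- | --- |
| `sequence_io` | FASTQ/FASTA I/O, paired-end merging, adapter trimming, quality/length filters, read collapsing |
| `contaminant_screen` | exact-match removal of rRNA/tRNA/sn/snoRNA fragments |
| `read_mapping` | zero-mismatch short-to-long mapping, cluster formation, mapping-pattern text |
| `hairpin_folding` | folding backends, MFEI, dinucleotide shuffle, randomization p |
| `precursor_validation` | duplex geometry, Dicer-pattern check, acceptance criteria, variant dedupe |
| `annotation` | known/novel retrieval strategies, family assignment |
| `reporting` | length/terminal-nt/arm summaries, metrics JSON |
| `synthetic_data` | ground-truthed generator for every stage |
| `pipeline`, `cli` | orchestration and the `premirseq` command |

See `docs/methods.md` for the model, parameter defaults and limitations.
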