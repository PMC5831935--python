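"""Bundled reference data.

A small curated set of known okra (*Abelmoschus esculentus*) miRNAs with
their published hairpin precursors and reported MFEI values, usable as a
known-reference set for the annotation strategies and as a realistic
fixture for folding and reporting.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .annotation import ReferenceSet


def okra_known_mirnas() -> pd.DataFrame:
    """Known okra miRNA/precursor table (columns: mirna_id, mature_seq,
    precursor_seq, reported_mfei)."""
    path = files("premirseq.data") / "okra_known_mirnas.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def okra_reference_set() -> ReferenceSet:
    """The bundled table as a :class:`ReferenceSet` for annotation."""
    df = okra_known_mirnas()
    return ReferenceSet(
        matures=list(zip(df.mirna_id, df.mature_seq)),
        precursors=[(f"{i}-pre", s) for i, s in zip(df.mirna_id, df.precursor_seq)],
    )
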