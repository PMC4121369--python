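"""Published single-subject differential-expression tables and bookkeeping.

The package ships plain-text transcriptions of the reported 47,XXY brain
differentially-expressed transcript tables (prefrontal cortex and
cerebellum; Illumina HT-12 nuIDs, hg19 probe positions, log2-scale fold
changes and Bonferroni-significant p-values per comparison family). They
serve as reference inputs for bookkeeping checks — e.g. counting up- vs
downregulated transcripts per family — and as a worked-example dataset.

P-values reported as "< 2e-16" are stored as 2e-16 (an upper bound).
Multi-segment probe positions are transcribed as their first segment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .util import XXYomicsError

_FILES = {
    "PFC": "de_genes_prefrontal_cortex.tsv",
    "CER": "de_genes_cerebellum.tsv",
}

FAMILY_COLUMNS = {"all": "fc_all", "males": "fc_males", "females": "fc_females"}


def load_de_table(tissue: str) -> pd.DataFrame:
    """Load the shipped DE-transcript table for ``tissue`` ("PFC" or "CER")."""
    if tissue not in _FILES:
        raise XXYomicsError(f"unknown tissue {tissue!r}; expected one of {sorted(_FILES)}")
    ref = resources.files("xxyomics.data") / _FILES[tissue]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in ("fc_all", "p_all", "fc_males", "p_males", "fc_females", "p_females"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def count_regulation(table: pd.DataFrame, family: str = "all") -> dict:
    """Count up- and downregulated transcripts in one comparison family.

    Only rows with a reported fold change in that family (i.e. significant
    in the source table) are counted.
    """
    if family not in FAMILY_COLUMNS:
        raise XXYomicsError(f"unknown family {family!r}")
    fc = table[FAMILY_COLUMNS[family]].dropna()
    return {
        "up": int((fc > 0).sum()),
        "down": int((fc < 0).sum()),
        "total": int(fc.size),
    }
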