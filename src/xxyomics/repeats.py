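"""Repeat-element (LINE-1 / Alu) global-methylation summaries.

Bisulfite-pyrosequencing assays interrogate three CpG sites per repeat
family; a sample's global-methylation estimate is the arithmetic mean of
the three. The index sample is then assessed as a cohort outlier per
tissue x assay with the same singleton z statistic used elsewhere:
hypomethylated when z <= -threshold, hypermethylated when z >= +threshold.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .singleton import phenotype_outlier_from_summary
from .util import XXYomicsError

CPG_COLUMNS = ["cpg1", "cpg2", "cpg3"]


def summarize_assay(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean of the three interrogated CpGs per sample x assay record.

    Records with a missing CpG are dropped with a warning. Fully methylated
    / unmethylated control records (``control`` column) are validated to
    exceed 90% / fall below 10% respectively.
    """
    missing_cols = [c for c in CPG_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise XXYomicsError(f"repeat-assay table lacks column(s) {missing_cols}")
    records = raw.copy()
    incomplete = records[CPG_COLUMNS].isna().any(axis=1)
    if incomplete.any():
        dropped = records.loc[incomplete, "sample_id"].tolist()
        warnings.warn(f"dropping {incomplete.sum()} record(s) with missing CpGs: {dropped}")
        records = records[~incomplete].copy()
    for col in CPG_COLUMNS:
        bad = (records[col] < 0) | (records[col] > 100)
        if bad.any():
            raise XXYomicsError(
                f"CpG percentage outside [0, 100] for sample {records.loc[bad, 'sample_id'].iloc[0]}"
            )
    records["mean_methylation"] = records[CPG_COLUMNS].mean(axis=1)
    control = records.get("control", pd.Series("", index=records.index)).fillna("")
    records["control_pass"] = pd.NA
    is_meth = control == "methylated"
    is_unmeth = control == "unmethylated"
    records.loc[is_meth, "control_pass"] = records.loc[is_meth, "mean_methylation"] > 90.0
    records.loc[is_unmeth, "control_pass"] = records.loc[is_unmeth, "mean_methylation"] < 10.0
    return records


def classify_direction(z: float, z_threshold: float = 2.0) -> str:
    if z <= -z_threshold:
        return "hypo"
    if z >= z_threshold:
        return "hyper"
    return "none"


def global_outlier_assessment(
    records: pd.DataFrame,
    index_sample: str,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Assess the index sample per tissue x assay.

    ``records`` is a summarized table (see :func:`summarize_assay`);
    control records are excluded, the reference excludes the index sample,
    and each tissue x assay cell needs >= 3 reference records to be
    testable.
    """
    control = records.get("control", pd.Series("", index=records.index)).fillna("")
    data = records[control == ""]
    rows = []
    for (tissue, assay), group in data.groupby(["tissue", "assay"], sort=True):
        is_index = group["sample_id"] == index_sample
        if not is_index.any():
            continue
        index_value = float(group.loc[is_index, "mean_methylation"].iloc[0])
        ref = group.loc[~is_index, "mean_methylation"]
        if len(ref) < 3:
            rows.append(
                {
                    "tissue": tissue,
                    "assay": assay,
                    "index_value": index_value,
                    "n_ref": len(ref),
                    "ref_mean": float("nan"),
                    "ref_sd": float("nan"),
                    "z": float("nan"),
                    "direction": "untestable",
                }
            )
            continue
        res = phenotype_outlier_from_summary(
            index_value, float(ref.mean()), float(ref.std(ddof=1)), n_ref=len(ref), z_threshold=z_threshold
        )
        rows.append(
            {
                "tissue": tissue,
                "assay": assay,
                "index_value": index_value,
                "n_ref": len(ref),
                "ref_mean": res["mean_ref"],
                "ref_sd": res["sd_ref"],
                "z": res["z"],
                "direction": classify_direction(res["z"], z_threshold),
            }
        )
    return pd.DataFrame(rows)
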