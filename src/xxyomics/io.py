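"""Readers and writers for the interchange formats.

All tabular interchange is plain TSV; genomic intervals are BED on disk.
Internal coordinates are 1-based inclusive (the array-manifest convention);
BED's 0-based half-open intervals are converted at this boundary.
Chromosome labels are normalized to unprefixed {1..22, X, Y} on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .util import FormatError, normalize_chromosome

PROBE_MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "strand",
    "context",
    "nearest_snp_distance",
    "nearest_snp_maf",
    "cross_reactive",
]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix (first column = feature id).

    Raises FormatError naming the offending row and column when a cell is
    not numeric.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[coerced.isna()][0]
            raise FormatError(
                f"{path}: non-numeric value at row '{row}', column '{col}'"
            )
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    # %.17g guarantees exact float64 round-trips through text
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_probe_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    _require_columns(df, ["probe_id", "chromosome", "position"], path)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    if (df["position"] <= 0).any():
        bad = df.loc[df["position"] <= 0, "probe_id"].iloc[0]
        raise FormatError(f"{path}: non-positive position for probe '{bad}'")
    if "cross_reactive" in df.columns:
        df["cross_reactive"] = df["cross_reactive"].astype(bool)
    return df


def write_probe_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_bed(path, extra_columns=()) -> pd.DataFrame:
    """Read a BED file into a 1-based inclusive interval table.

    A BED record ``chr1 99 300`` becomes the internal interval 100-300.
    ``extra_columns`` names columns 4, 5, ... in order.
    """
    names = ["chromosome", "start", "end", *extra_columns]
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            row = [normalize_chromosome(fields[0]), start + 1, end]
            row.extend(fields[3 : len(names)])
            row.extend([None] * (len(names) - len(row)))
            rows.append(row)
    df = pd.DataFrame(rows, columns=names)
    for col in extra_columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def write_bed(intervals: pd.DataFrame, path, extra_columns=()) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as handle:
        for _, row in intervals.iterrows():
            fields = [str(row["chromosome"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            fields.extend(str(row[c]) for c in extra_columns)
            handle.write("\t".join(fields) + "\n")


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, required, path)
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    return read_table(path, required=["sample_id", "individual_id", "reported_sex", "tissue"])


def read_snp_table(path) -> pd.DataFrame:
    df = read_table(path, required=["snp_id", "chromosome", "position", "region", "individual_id", "genotype", "baf"])
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    return df


def read_repeat_table(path) -> pd.DataFrame:
    df = read_table(path, required=["sample_id", "tissue", "assay", "cpg1", "cpg2", "cpg3"])
    if "control" in df.columns:
        df["control"] = df["control"].fillna("").astype(str)
    return df


def read_xci_peaks(path) -> pd.DataFrame:
    return read_table(
        path,
        required=["sample_id", "tissue", "replicate", "h1u", "h2u", "h1d", "h2d", "h1m", "h2m"],
    )


def read_blacklist(path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def write_blacklist(probe_ids, path) -> None:
    with open(path, "w") as handle:
        for pid in sorted(probe_ids):
            handle.write(f"{pid}\n")


def load_yaml_config(path, known_keys=None) -> dict:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    if known_keys is not None:
        unknown = sorted(set(data) - set(known_keys))
        if unknown:
            raise FormatError(f"{path}: unknown configuration key(s) {unknown}")
    return data


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=_default)
        handle.write("\n")


def read_json(path):
    with open(path) as handle:
        return json.load(handle)
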