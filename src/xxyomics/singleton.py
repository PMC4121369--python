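"""Singleton (N-of-1) outlier statistics.

The core statistic compares one index sample against a reference group per
feature: z = (x_index - mean_ref) / sd_ref, with a two-sided p-value from
the standard normal distribution and Bonferroni correction within each
comparison family. The normal reference (rather than a t distribution) is
the convention of the 450K singleton-outlier workflow; with moderate
reference sizes (~20-45) it is markedly anti-conservative in the extreme
tails that survive Bonferroni correction. A calibrated alternative — the
Crawford-Howell singleton t-test, t = z / sqrt(1 + 1/n_ref) with
df = n_ref - 1, which controls the family-wise error exactly — is
available via ``use_t=True``.

Comparison families are chromosome-aware: autosomal features may be
compared against the whole cohort, males only and females only; X-linked
features are compared with females only and Y-linked features with males
only, since only those references share the sex-chromosome dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .util import XXYomicsError

FAMILIES = ("all", "males", "females")


@dataclass(frozen=True)
class ComparisonPolicy:
    """Chromosome -> allowed comparison families."""

    x_families: tuple = ("females",)
    y_families: tuple = ("males",)
    autosome_families: tuple = FAMILIES

    def allowed(self, chromosome: str) -> tuple:
        if chromosome == "X":
            return self.x_families
        if chromosome == "Y":
            return self.y_families
        return self.autosome_families


DEFAULT_POLICY = ComparisonPolicy()


def reference_statistics(matrix: pd.DataFrame, group) -> pd.DataFrame:
    """Per-feature mean and sample SD (n-1 denominator) over ``group``."""
    group = list(group)
    if len(group) < 3:
        raise XXYomicsError("reference group must contain at least 3 samples")
    missing = [s for s in group if s not in matrix.columns]
    if missing:
        raise XXYomicsError(f"unknown reference sample(s) {missing}")
    sub = matrix[group].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "n_ref": len(group),
            "mean_ref": sub.mean(axis=1),
            "sd_ref": sub.std(axis=1, ddof=1),
        },
        index=matrix.index,
    )


def singleton_z_test(index_value: float, mean_ref: float, sd_ref: float, use_t: bool = False, n_ref: int | None = None):
    """z, two-sided p and effect for one index value vs reference mean/SD.

    Returns ``(z, p, effect)``. ``sd_ref`` must be positive; a zero-variance
    feature is untestable and should be excluded from the multiplicity count.
    """
    if sd_ref <= 0:
        raise XXYomicsError("sd_ref must be > 0; zero-variance features are untestable")
    z = (index_value - mean_ref) / sd_ref
    if use_t:
        if not n_ref or n_ref < 2:
            raise XXYomicsError("t-based mode needs n_ref >= 2")
        # Crawford-Howell singleton t: account for the reference-mean noise
        t_stat = z / np.sqrt(1.0 + 1.0 / n_ref)
        p = 2.0 * stats.t.sf(abs(t_stat), df=n_ref - 1)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(max(p, np.nextafter(0, 1))), float(index_value - mean_ref)


def run_singleton_screen(
    matrix: pd.DataFrame,
    index_sample: str,
    metadata: pd.DataFrame,
    manifest: pd.DataFrame,
    policy: ComparisonPolicy = DEFAULT_POLICY,
    alpha: float = 0.05,
    use_t: bool = False,
) -> pd.DataFrame:
    """Screen every feature of ``matrix`` for the index being an outlier.

    ``metadata`` must assign a reported sex ("M"/"F") to every reference
    column; ``manifest`` maps features to chromosomes (columns ``probe_id``,
    ``chromosome`` and optionally ``position``/``gene``). For each feature
    the test runs in every family its chromosome's policy allows, and
    Bonferroni correction uses the number of *testable* (positive reference
    SD) features within each family separately.

    Returns a long-format table: one row per feature x allowed family.
    """
    if index_sample not in matrix.columns:
        raise XXYomicsError(f"index sample {index_sample!r} not in matrix")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    ref_samples = [c for c in matrix.columns if c != index_sample]
    unknown = [s for s in ref_samples if s not in meta.index]
    if unknown:
        raise XXYomicsError(f"reference sample(s) without metadata: {unknown[:5]}")
    sexes = meta.loc[ref_samples, "reported_sex"]
    groups = {
        "all": ref_samples,
        "males": [s for s in ref_samples if sexes[s] == "M"],
        "females": [s for s in ref_samples if sexes[s] == "F"],
    }

    man = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    chroms = man.reindex(matrix.index)["chromosome"].astype(str)
    positions = (
        man.reindex(matrix.index)["position"] if "position" in man.columns else pd.Series(np.nan, index=matrix.index)
    )
    genes = man.reindex(matrix.index)["gene"] if "gene" in man.columns else None

    index_values = matrix[index_sample].to_numpy(dtype=float)
    frames = []
    for family in FAMILIES:
        group = groups[family]
        if len(group) < 3:
            continue
        allowed = np.array([family in policy.allowed(c) for c in chroms])
        if not allowed.any():
            continue
        ref = matrix[group].to_numpy(dtype=float)
        mean = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=1)
        testable = allowed & (sd > 0)
        m = int(testable.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (index_values - mean) / sd
        if use_t:
            t_stat = z / np.sqrt(1.0 + 1.0 / len(group))
            p = 2.0 * stats.t.sf(np.abs(t_stat), df=len(group) - 1)
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.maximum(p, np.nextafter(0, 1))
        p_adj = np.minimum(1.0, p * m)
        frame = pd.DataFrame(
            {
                "feature_id": matrix.index,
                "chromosome": chroms.to_numpy(),
                "position": positions.to_numpy(),
                "comparison": family,
                "n_ref": len(group),
                "index_value": index_values,
                "effect": index_values - mean,
                "z": z,
                "p": p,
                "p_adj": p_adj,
                "testable": testable,
                "m_tests": m,
            }
        )
        if genes is not None:
            frame.insert(1, "gene", genes.to_numpy())
        frame = frame[allowed].copy()
        frame.loc[~frame["testable"], ["z", "p", "p_adj"]] = np.nan
        frame["significant"] = frame["testable"] & (frame["p_adj"] < alpha)
        frames.append(frame)
    if not frames:
        raise XXYomicsError("no comparison family had >= 3 reference samples")
    out = pd.concat(frames, ignore_index=True)
    return out


def phenotype_outlier(value: float, ref_values, z_threshold: float = 2.0) -> dict:
    """Assess a scalar phenotype of the index against the cohort.

    Returns ``{"z", "outlier", "mean_ref", "sd_ref", "n_ref"}``; the verdict
    is outlier iff |z| >= ``z_threshold`` (the two-standard-deviation rule).
    """
    ref = np.asarray(ref_values, dtype=float)
    if ref.size < 3:
        raise XXYomicsError("need at least 3 reference values")
    mean, sd = float(ref.mean()), float(ref.std(ddof=1))
    return phenotype_outlier_from_summary(value, mean, sd, n_ref=ref.size, z_threshold=z_threshold)


def phenotype_outlier_from_summary(
    value: float, mean_ref: float, sd_ref: float, n_ref: int | None = None, z_threshold: float = 2.0
) -> dict:
    if sd_ref <= 0:
        raise XXYomicsError("zero reference SD: phenotype untestable")
    z = (value - mean_ref) / sd_ref
    return {
        "value": float(value),
        "z": float(z),
        "outlier": bool(abs(z) >= z_threshold),
        "mean_ref": float(mean_ref),
        "sd_ref": float(sd_ref),
        "n_ref": n_ref,
    }


def significant_sign_counts(results: pd.DataFrame) -> dict:
    """Up/down/zero bookkeeping of significant features per family."""
    out = {}
    for family, group in results.groupby("comparison"):
        sig = group[group["significant"].fillna(False)]
        up = int((sig["effect"] > 0).sum())
        down = int((sig["effect"] < 0).sum())
        zero = int((sig["effect"] == 0).sum())
        out[family] = {"up": up, "down": down, "zero": zero, "total": len(sig)}
    return out


def gene_set_outlier_report(
    results: pd.DataFrame,
    gene_sets: dict,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Outlier direction per gene x tissue x comparison for named gene sets.

    ``results`` is a concatenated screen table carrying ``gene`` and
    ``tissue`` columns. Direction is "up"/"down" when |z| >= ``z_threshold``
    (sign of the effect), "none" when tested below threshold and "missing"
    when the gene was absent or untestable in that cell. A per-gene
    ``consistent`` flag marks genes whose non-missing directions agree and
    include no "none". No aggregate statistic is claimed.
    """
    if not gene_sets or any(len(genes) == 0 for genes in gene_sets.values()):
        raise XXYomicsError("gene sets must be non-empty")
    if "gene" not in results.columns:
        raise XXYomicsError("results table lacks a 'gene' column")
    tissues = sorted(results["tissue"].unique()) if "tissue" in results.columns else [""]
    rows = []
    for set_name, genes in gene_sets.items():
        for gene in genes:
            hits = results[results["gene"] == gene]
            directions = []
            for tissue in tissues:
                sub = hits[hits["tissue"] == tissue] if "tissue" in hits.columns else hits
                for comparison in sorted(sub["comparison"].unique()) if len(sub) else []:
                    cell = sub[sub["comparison"] == comparison]
                    row = cell.iloc[0]
                    if not bool(row["testable"]) or pd.isna(row["z"]):
                        direction = "missing"
                    elif abs(row["z"]) >= z_threshold:
                        direction = "up" if row["effect"] > 0 else "down"
                    else:
                        direction = "none"
                    directions.append(direction)
                    rows.append(
                        {
                            "gene_set": set_name,
                            "gene": gene,
                            "tissue": tissue,
                            "comparison": comparison,
                            "direction": direction,
                            "z": float(row["z"]) if pd.notna(row["z"]) else np.nan,
                        }
                    )
                if len(sub) == 0:
                    directions.append("missing")
                    rows.append(
                        {
                            "gene_set": set_name,
                            "gene": gene,
                            "tissue": tissue,
                            "comparison": "",
                            "direction": "missing",
                            "z": np.nan,
                        }
                    )
            non_missing = [d for d in directions if d != "missing"]
            consistent = bool(non_missing) and len(set(non_missing)) == 1 and non_missing[0] != "none"
            for row in rows:
                if row["gene_set"] == set_name and row["gene"] == gene and "consistent" not in row:
                    row["consistent"] = consistent
    return pd.DataFrame(rows)
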