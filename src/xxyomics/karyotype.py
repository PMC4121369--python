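"""Sex-chromosome karyotype inference from integrated array evidence.

Each evidence channel is a deliberately simple, testable statistic:

* X methylation: exact 1-D 2-means on the per-sample mean beta over
  sex-dimorphic X probes (a scalar stand-in for the usual MDS sex check);
  the cluster with the higher mean beta is female-like, reflecting the
  intermediate methylation contributed by an inactive X.
* XIST expression: 2-means split into high/low.
* Y signal: fraction of Y methylation probes detected plus mean Y
  expression relative to the male (upper) expression cluster.
* Genotypes: X-SNP heterozygosity rate and B-allele-frequency band count.
  Two total sex-chromosome copies give heterozygote BAF bands at 1/2
  (3 bands with the homozygote bands at 0 and 1); three copies, as in the
  X-transposed region of a 47,XXY genome, give bands at 1/3 and 2/3
  (4 bands).

``call_karyotype`` integrates the channels by a fixed decision table with
genotype evidence taking precedence, and flags discordance with the
reported sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import XXYomicsError, two_means_1d

INDETERMINATE = "indeterminate"


@dataclass
class KaryotypeEvidence:
    """Per-sample evidence record; genotype channels may be missing (None)."""

    x_meth_cluster: str  # "female-like" | "male-like" | indeterminate
    x_meth_score: float
    xist_class: str  # "high" | "low" | indeterminate
    y_present: bool | None
    y_frac_detected: float | None = None
    y_mean_expression: float | None = None
    x_het_rate: float | None = None
    baf_band_count: int | None = None


@dataclass
class KaryotypeCall:
    sample_id: str
    call: str  # "46,XX" | "46,XY" | "47,XXY" | indeterminate
    evidence: KaryotypeEvidence
    reported_sex: str | None
    discordant_with_reported_sex: bool


def cluster_x_methylation(betas: pd.DataFrame) -> pd.DataFrame:
    """2-means cluster samples by mean beta over sex-dimorphic X probes.

    ``betas`` is probes x samples, restricted to the dimorphic X probes.
    Returns a frame indexed by sample with ``score`` (mean beta) and
    ``label`` ("female-like" for the higher-methylation cluster).
    """
    if betas.shape[0] < 5:
        raise XXYomicsError("need at least 5 X probes")
    if betas.shape[1] < 4:
        raise XXYomicsError("need at least 4 samples")
    scores = betas.mean(axis=0)
    fit = two_means_1d(scores.to_numpy())
    if fit is None:
        labels = [INDETERMINATE] * len(scores)
    else:
        cluster, _ = fit
        labels = np.where(cluster == 1, "female-like", "male-like")
    return pd.DataFrame({"score": scores, "label": labels})


def classify_xist(expression: pd.Series) -> pd.Series:
    """Split per-sample XIST log2 intensity into high/low by 2-means."""
    if len(expression) < 4:
        raise XXYomicsError("need at least 4 samples")
    fit = two_means_1d(np.asarray(expression, dtype=float))
    if fit is None:
        return pd.Series(INDETERMINATE, index=expression.index)
    cluster, _ = fit
    return pd.Series(np.where(cluster == 1, "high", "low"), index=expression.index)


def assess_y_signal(
    y_probe_detection: pd.DataFrame,
    y_expression: pd.DataFrame,
    detection_p_threshold: float = 0.05,
    min_frac_detected: float = 0.5,
) -> pd.DataFrame:
    """Flag per-sample Y-chromosome presence.

    A sample is Y-positive iff at least ``min_frac_detected`` of its Y
    methylation probes are detected (boundary inclusive) AND its mean Y
    expression lies within 2 SD of the male (upper 2-means) expression
    cluster. When the expression values do not split into two clusters the
    detection criterion alone decides.
    """
    if y_probe_detection.shape[0] < 3:
        raise XXYomicsError("need at least 3 Y probes")
    frac = (y_probe_detection <= detection_p_threshold).mean(axis=0)
    mean_expr = y_expression.mean(axis=0)
    fit = two_means_1d(mean_expr.to_numpy())
    if fit is None:
        expr_ok = pd.Series(True, index=mean_expr.index)
    else:
        cluster, _ = fit
        male_vals = mean_expr.to_numpy()[cluster == 1]
        mu, sd = float(male_vals.mean()), float(male_vals.std(ddof=0))
        sd = max(sd, 1e-8)
        expr_ok = (mean_expr - mu).abs() <= 2.0 * sd
    out = pd.DataFrame(
        {
            "frac_detected": frac,
            "mean_y_expression": mean_expr,
            "expression_male_like": expr_ok,
        }
    )
    out["y_present"] = (out["frac_detected"] >= min_frac_detected) & out["expression_male_like"]
    return out


def x_heterozygosity(genotypes: pd.DataFrame, min_snps: int = 20) -> pd.Series:
    """Heterozygosity rate of X-SNP genotype calls per individual.

    ``genotypes`` is long-format with columns ``individual_id`` and
    ``genotype`` (AA/AB/BB, missing as "NC" or NaN). Rate = het calls /
    non-missing calls.
    """
    required = {"individual_id", "genotype"}
    if not required.issubset(genotypes.columns):
        raise XXYomicsError(f"genotype table needs columns {sorted(required)}")
    rates = {}
    for ind, group in genotypes.groupby("individual_id", sort=True):
        calls = group["genotype"].astype(str)
        non_missing = calls.isin(["AA", "AB", "BB"])
        if len(group) < min_snps:
            raise XXYomicsError(f"individual {ind}: fewer than {min_snps} X SNPs")
        n_valid = int(non_missing.sum())
        if n_valid == 0:
            raise XXYomicsError(f"individual {ind}: all genotype calls missing")
        rates[ind] = float((calls == "AB").sum() / n_valid)
    return pd.Series(rates, name="x_het_rate")


def count_baf_bands(baf, bins: int = 50, min_mass_frac: float = 0.05):
    """Count B-allele-frequency bands by histogram peak detection.

    A band is a histogram bin holding more than ``min_mass_frac`` of the
    total mass and strictly exceeding both neighbors (one neighbor at the
    histogram edges). Returns ``(count, centers)``.
    """
    baf = np.asarray(baf, dtype=float)
    if baf.size < 200:
        raise XXYomicsError("need at least 200 BAF values for stable band counting")
    hist, edges = np.histogram(baf, bins=bins, range=(0.0, 1.0))
    total = hist.sum()
    centers = []
    i = 0
    while i < bins:
        j = i
        while j + 1 < bins and hist[j + 1] == hist[i]:
            j += 1
        # plateau of equal-height bins i..j counts as one candidate peak
        left_ok = i == 0 or hist[i - 1] < hist[i]
        right_ok = j == bins - 1 or hist[j + 1] < hist[i]
        if hist[i] > min_mass_frac * total and left_ok and right_ok:
            centers.append(float((edges[i] + edges[j + 1]) / 2))
        i = j + 1
    return len(centers), centers


def call_karyotype(
    evidence: KaryotypeEvidence,
    reported_sex: str | None = None,
    sample_id: str = "",
    het_rate_threshold: float = 0.02,
) -> KaryotypeCall:
    """Integrate evidence into a karyotype call (pure function of evidence).

    Decision table: female-like X without Y -> 46,XX; male-like X with Y ->
    46,XY; female-like X with Y -> 47,XXY, provided the genotype channel
    (when present) supports two X copies via het rate > ``het_rate_threshold``
    or a 4-band BAF structure; anything else is indeterminate.
    """
    x = evidence.x_meth_cluster
    y = evidence.y_present

    call = INDETERMINATE
    if x == "female-like" and y is False:
        call = "46,XX"
    elif x == "male-like" and y is True:
        call = "46,XY"
    elif x == "female-like" and y is True:
        genotyped = evidence.x_het_rate is not None or evidence.baf_band_count is not None
        if not genotyped:
            call = "47,XXY"
        else:
            het_support = (
                evidence.x_het_rate is not None and evidence.x_het_rate > het_rate_threshold
            )
            band_support = evidence.baf_band_count == 4
            call = "47,XXY" if (het_support or band_support) else INDETERMINATE

    sex_equivalent = {"46,XX": "F", "46,XY": "M", "47,XXY": "M"}.get(call)
    discordant = (
        reported_sex is not None
        and sex_equivalent is not None
        and sex_equivalent != reported_sex
    )
    return KaryotypeCall(
        sample_id=sample_id,
        call=call,
        evidence=evidence,
        reported_sex=reported_sex,
        discordant_with_reported_sex=bool(discordant),
    )
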