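"""Probe- and sample-level quality control.

Filter rules are applied in a declared order with first-rule-wins
attribution, so per-rule removal counts always sum to the total removed.
Filters only change membership: retained values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import XXYomicsError


class IndexMismatchError(XXYomicsError):
    pass


@dataclass
class FilterReport:
    """Per-rule removal counts plus the surviving probe ids."""

    n_input: int
    removed_per_rule: dict = field(default_factory=dict)
    surviving: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.removed_per_rule.values())

    @property
    def n_surviving(self) -> int:
        return len(self.surviving)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_per_rule": dict(self.removed_per_rule),
            "n_removed": self.n_removed,
            "n_surviving": self.n_surviving,
        }


def _check_axis(name: str, expected: pd.Index, got: pd.Index, axis: str) -> None:
    if len(expected) != len(got) or not expected.equals(got):
        raise IndexMismatchError(f"{name}: {axis} axis does not match the beta matrix")


def filter_methylation_probes(
    manifest: pd.DataFrame,
    betas: pd.DataFrame,
    beadcounts: pd.DataFrame | None = None,
    detection_p: pd.DataFrame | None = None,
    blacklist: set | None = None,
    snp_maf_threshold: float = 0.05,
    snp_distance_threshold: int = 10,
    beadcount_min: int = 3,
    beadcount_sample_frac: float = 0.05,
    detection_p_threshold: float = 0.05,
    detection_sample_frac: float = 0.01,
):
    """Apply the methylation probe filters in order.

    1. probes with a nearby common SNP (MAF > ``snp_maf_threshold`` within
       ``snp_distance_threshold`` bp of the CG target);
    2. non-CG-context probes;
    3. blacklisted (e.g. sex-chromosome cross-reactive) probes;
    4. beadcount/detection filter: beadcount < ``beadcount_min`` in more than
       ``beadcount_sample_frac`` of samples, or detection p >
       ``detection_p_threshold`` in more than ``detection_sample_frac`` of
       samples (the pfilter defaults of the standard 450K workflow).

    Returns ``(report, filtered_betas)``.
    """
    manifest = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    _check_axis("manifest", betas.index, pd.Index(manifest.index), "probe")
    if beadcounts is not None:
        _check_axis("beadcounts", betas.index, beadcounts.index, "probe")
        _check_axis("beadcounts", betas.columns, beadcounts.columns, "sample")
    if detection_p is not None:
        _check_axis("detection_p", betas.index, detection_p.index, "probe")
        _check_axis("detection_p", betas.columns, detection_p.columns, "sample")
    blacklist = set(blacklist or ())

    n_samples = betas.shape[1]
    removed = pd.Series("", index=betas.index, dtype=object)

    rule1 = (manifest["nearest_snp_maf"] > snp_maf_threshold) & (
        manifest["nearest_snp_distance"] <= snp_distance_threshold
    )
    rule2 = manifest["context"] != "CG"
    rule3 = betas.index.isin(blacklist)

    if beadcounts is not None:
        low_beads = (beadcounts < beadcount_min).sum(axis=1) / n_samples > beadcount_sample_frac
    else:
        low_beads = pd.Series(False, index=betas.index)
    if detection_p is not None:
        bad_detp = (detection_p > detection_p_threshold).sum(axis=1) / n_samples > detection_sample_frac
    else:
        bad_detp = pd.Series(False, index=betas.index)
    rule4 = low_beads | bad_detp

    rules = [
        ("snp_proximity", rule1.to_numpy()),
        ("non_cg_context", rule2.to_numpy()),
        ("blacklist", np.asarray(rule3)),
        ("pfilter", rule4.to_numpy()),
    ]
    report = FilterReport(n_input=len(betas))
    for name, mask in rules:
        hit = mask & (removed == "").to_numpy()
        removed.iloc[np.where(hit)[0]] = name
        report.removed_per_rule[name] = int(hit.sum())

    keep = removed == ""
    report.surviving = list(betas.index[keep])
    return report, betas.loc[keep]


def filter_expression_probes(intensities: pd.DataFrame, detection_p: pd.DataFrame):
    """Drop transcripts undetected (detection p > 0.01) in *every* sample."""
    _check_axis("detection_p", intensities.index, detection_p.index, "probe")
    _check_axis("detection_p", intensities.columns, detection_p.columns, "sample")
    undetected_everywhere = (detection_p > 0.01).all(axis=1)
    report = FilterReport(n_input=len(intensities))
    report.removed_per_rule["undetected_all_samples"] = int(undetected_everywhere.sum())
    keep = ~undetected_everywhere
    report.surviving = list(intensities.index[keep])
    return report, intensities.loc[keep]


def sample_identity_check(
    snp_probe_betas: pd.DataFrame,
    pairs,
    r_threshold: float = 0.9,
) -> pd.DataFrame:
    """Cross-tissue identity check from genotyping ("rs") probe betas.

    Pearson-correlates the trimodal rs-probe beta profiles of each sample
    pair; a pair is called "same individual" iff r >= ``r_threshold``.
    """
    if len(snp_probe_betas) < 10:
        raise XXYomicsError("need at least 10 SNP-type probes for identity checking")
    rows = []
    for a, b in pairs:
        for sid in (a, b):
            if sid not in snp_probe_betas.columns:
                raise XXYomicsError(f"unknown sample id {sid!r}")
        r = float(np.corrcoef(snp_probe_betas[a], snp_probe_betas[b])[0, 1])
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "r": r,
                "same_individual": bool(r >= r_threshold),
            }
        )
    return pd.DataFrame(rows)
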