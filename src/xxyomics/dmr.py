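"""Differentially methylated region (DMR) calling and CNV overlap screening.

A DMR is a run of >= ``min_probes`` *adjacent* significant probes: adjacency
is defined on the tested-probe grid (an intervening tested-but-nonsignificant
probe breaks a run) with the inter-probe gap capped at ``max_gap`` bp and the
total span capped at ``window`` bp. Runs longer than the window are split
greedily left-to-right into maximal chunks that fit. Member z-scores are
combined by Stouffer's method with equal weights: Z = sum(z_i)/sqrt(k) and
combined_p = Phi_bar(|Z|), the one-sided tail in the direction of the
combined signal (so two probes at z = 3 give 1 - Phi(6/sqrt(2))). No probe
autocorrelation correction is applied; this is a documented simplification
of the region-combination tool's Stouffer-Liptak-Kechris procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .util import XXYomicsError, normalize_chromosome


def _stouffer(z_values) -> tuple[float, float]:
    z = np.asarray(z_values, dtype=float)
    z_comb = z.sum() / np.sqrt(z.size)
    p = float(stats.norm.sf(abs(z_comb)))
    return float(z_comb), max(p, float(np.nextafter(0, 1)))


def call_dmrs(
    results: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    window: int = 500,
    min_probes: int = 2,
    max_gap: int | None = None,
) -> pd.DataFrame:
    """Aggregate adjacent significant probes into DMRs.

    ``results`` is a singleton-screen table (one row per tested probe and
    comparison family) carrying ``feature_id``, ``comparison``, ``z``,
    ``effect`` and ``significant``; genomic ``chromosome``/``position`` are
    taken from the table or merged in from ``manifest``. ``max_gap``
    defaults to ``window``.

    Returns one row per emitted region with member probes, mean effect,
    Stouffer-combined p and a sign-consistency flag.
    """
    if max_gap is None:
        max_gap = window
    results = results.copy()
    if "chromosome" not in results.columns or "position" not in results.columns:
        if manifest is None:
            raise XXYomicsError("results lack positions and no manifest was given")
        man = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
        results["chromosome"] = man.reindex(results["feature_id"])["chromosome"].to_numpy()
        results["position"] = man.reindex(results["feature_id"])["position"].to_numpy()
    if results["position"].isna().any():
        bad = results.loc[results["position"].isna(), "feature_id"].iloc[0]
        raise XXYomicsError(f"probe {bad!r} has no genomic position")

    tested = results[results["testable"]] if "testable" in results.columns else results
    regions = []
    for (comparison, chrom), group in tested.groupby(["comparison", "chromosome"], sort=True):
        group = group.sort_values("position", kind="stable")
        pos = group["position"].to_numpy(dtype=int)
        if np.unique(pos).size != pos.size:
            raise XXYomicsError(
                f"duplicated probe positions on chromosome {chrom} ({comparison})"
            )
        sig = group["significant"].fillna(False).to_numpy(dtype=bool)
        z = group["z"].to_numpy(dtype=float)
        effect = group["effect"].to_numpy(dtype=float)
        ids = group["feature_id"].to_numpy()

        # maximal runs of consecutive significant probes on the tested grid
        runs = []
        current = []
        for i in range(len(group)):
            if not sig[i]:
                if current:
                    runs.append(current)
                current = []
                continue
            if current and pos[i] - pos[current[-1]] > max_gap:
                runs.append(current)
                current = []
            current.append(i)
        if current:
            runs.append(current)

        for run in runs:
            # greedy left-to-right split into chunks with span <= window
            start_idx = 0
            while start_idx < len(run):
                end_idx = start_idx
                while (
                    end_idx + 1 < len(run)
                    and pos[run[end_idx + 1]] - pos[run[start_idx]] <= window
                ):
                    end_idx += 1
                chunk = run[start_idx : end_idx + 1]
                if len(chunk) >= min_probes:
                    z_comb, p_comb = _stouffer(z[chunk])
                    eff = effect[chunk]
                    regions.append(
                        {
                            "chromosome": chrom,
                            "start": int(pos[chunk[0]]),
                            "end": int(pos[chunk[-1]]),
                            "comparison": comparison,
                            "n_probes": len(chunk),
                            "probe_ids": ";".join(str(ids[i]) for i in chunk),
                            "mean_effect": float(eff.mean()),
                            "z_combined": z_comb,
                            "combined_p": p_comb,
                            "sign_consistent": bool((eff > 0).all() or (eff < 0).all()),
                        }
                    )
                start_idx = end_idx + 1
    columns = [
        "chromosome",
        "start",
        "end",
        "comparison",
        "n_probes",
        "probe_ids",
        "mean_effect",
        "z_combined",
        "combined_p",
        "sign_consistent",
    ]
    out = pd.DataFrame(regions, columns=columns)
    return out.sort_values(["comparison", "chromosome", "start"], kind="stable").reset_index(drop=True)


def overlap_cnv(dmrs: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Annotate each DMR with copy numbers of overlapping CNV segments.

    Intervals are 1-based inclusive on both sides; a single shared base pair
    counts as an overlap. Chromosome labels are normalized (chr1 == 1).
    Regions without any overlapping segment get an empty annotation.
    """
    dmrs = dmrs.copy()
    seg = segments.copy()
    if len(seg):
        seg["chromosome"] = seg["chromosome"].map(normalize_chromosome)
        if (seg["start"] > seg["end"]).any():
            raise XXYomicsError("CNV segment with start > end")
    annotations = []
    for _, region in dmrs.iterrows():
        chrom = normalize_chromosome(region["chromosome"])
        if len(seg):
            hits = seg[
                (seg["chromosome"] == chrom)
                & (seg["start"] <= region["end"])
                & (seg["end"] >= region["start"])
            ]
            annotations.append([int(c) for c in hits["copy_number"]])
        else:
            annotations.append([])
    dmrs["cnv_copy_numbers"] = [";".join(str(c) for c in a) for a in annotations]
    dmrs["cnv_overlap"] = [len(a) > 0 for a in annotations]
    return dmrs


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED-ready view: score = -log10(combined p)."""
    out = dmrs[["chromosome", "start", "end"]].copy()
    out["name"] = [
        f"{row.comparison}_{row.chromosome}:{row.start}-{row.end}" for row in dmrs.itertuples()
    ]
    out["score"] = (-np.log10(dmrs["combined_p"])).round(3)
    return out
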