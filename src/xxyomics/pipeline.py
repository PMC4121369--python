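"""End-to-end pipeline: QC -> karyotype -> singleton screens -> DMRs + CNV
overlap -> global methylation -> XCI -> report.

Operates on a cohort directory (as written by ``write_cohort``) or an
in-memory :class:`~xxyomics.synthetic.SyntheticCohort`. The index case is
discovered from the karyotype calls (the individual called 47,XXY) unless
the configuration names one explicitly; without an index the singleton
stages are skipped and the report says so. The report deliberately carries
no timestamp so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as xio
from .dmr import call_dmrs, dmrs_to_bed, overlap_cnv
from .karyotype import (
    KaryotypeEvidence,
    assess_y_signal,
    call_karyotype,
    classify_xist,
    cluster_x_methylation,
    count_baf_bands,
    x_heterozygosity,
)
from .qc import filter_expression_probes, filter_methylation_probes, sample_identity_check
from .repeats import global_outlier_assessment, summarize_assay
from .singleton import run_singleton_screen, significant_sign_counts
from .synthetic import SyntheticCohort, read_cohort
from .util import XXYomicsError
from .xci import average_replicates, xci_ratio

logger = logging.getLogger("xxyomics")


def _tool_version() -> str:
    from . import __version__

    return __version__

PIPELINE_CONFIG_KEYS = (
    "cohort_dir",
    "out_dir",
    "alpha",
    "dmr_window",
    "dmr_min_probes",
    "dmr_max_gap",
    "identity_r_threshold",
    "outlier_z_threshold",
    "het_rate_threshold",
    "index_individual",
    "seed",
)


@dataclass
class PipelineConfig:
    cohort_dir: str | None = None
    out_dir: str = "results"
    alpha: float = 0.05
    dmr_window: int = 500
    dmr_min_probes: int = 2
    dmr_max_gap: int | None = None
    identity_r_threshold: float = 0.9
    outlier_z_threshold: float = 2.0
    het_rate_threshold: float = 0.02
    index_individual: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise XXYomicsError("alpha must be in (0, 1)")
        for name in ("dmr_window", "dmr_min_probes", "identity_r_threshold", "outlier_z_threshold"):
            if getattr(self, name) <= 0:
                raise XXYomicsError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = xio.load_yaml_config(path, known_keys=PIPELINE_CONFIG_KEYS)
        return cls(**data)


class StageError(XXYomicsError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except XXYomicsError as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Run every stage; writes tables under ``config.out_dir`` and returns
    the run report (also written as ``report.json``)."""
    config.validate()
    if cohort is None:
        if config.cohort_dir is None:
            raise XXYomicsError("no cohort: set cohort_dir or pass a cohort object")
        cohort = read_cohort(config.cohort_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "tool_version": _tool_version(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    meta = cohort.metadata
    tissues = list(cohort.config.tissues)
    manifest = cohort.probes_meth

    # ---- stage: QC ----------------------------------------------------
    @_stage("qc")
    def stage_qc():
        blacklist = set(manifest.loc[manifest["cross_reactive"], "probe_id"])
        filtered_betas = {}
        filtered_expr = {}
        qc_report = {}
        for tissue in tissues:
            betas = cohort.betas[tissue]
            rs_mask = betas.index.str.startswith("rs")
            rep, kept = filter_methylation_probes(
                manifest[~manifest["probe_id"].str.startswith("rs")],
                betas[~rs_mask],
                beadcounts=cohort.beadcounts[tissue][~rs_mask],
                detection_p=cohort.detection_meth[tissue][~rs_mask],
                blacklist=blacklist,
            )
            logger.info("meth QC %s: %s", tissue, rep.to_dict())
            filtered_betas[tissue] = kept
            erep, ekept = filter_expression_probes(
                cohort.expression[tissue], cohort.detection_expr[tissue]
            )
            filtered_expr[tissue] = ekept
            qc_report[tissue] = {
                "methylation": rep.to_dict(),
                "expression": erep.to_dict(),
            }
        # cross-tissue identity from rs probes
        identity = None
        if len(tissues) >= 2:
            rs_all = {
                t: cohort.betas[t][cohort.betas[t].index.str.startswith("rs")] for t in tissues
            }
            t0, t1 = tissues[0], tissues[1]
            shared_inds = sorted(set(meta["individual_id"]))
            combined = pd.concat([rs_all[t0], rs_all[t1]], axis=1)
            pairs = [
                (f"{ind}_{t0}", f"{ind}_{t1}")
                for ind in shared_inds
                if f"{ind}_{t0}" in combined.columns and f"{ind}_{t1}" in combined.columns
            ]
            identity = sample_identity_check(combined, pairs, r_threshold=config.identity_r_threshold)
            qc_report["identity"] = {
                "n_pairs": len(identity),
                "n_matching": int(identity["same_individual"].sum()),
            }
        return filtered_betas, filtered_expr, qc_report, identity

    filtered_betas, filtered_expr, qc_report, identity = stage_qc()
    report["stages"]["qc"] = qc_report

    # ---- stage: karyotype --------------------------------------------
    @_stage("karyotype")
    def stage_karyotype():
        tissue = tissues[0]
        betas = cohort.betas[tissue]
        man = manifest.set_index("probe_id")
        x_dimorphic = man.index[(man["chromosome"] == "X") & (~man["cross_reactive"])]
        x_betas = betas.loc[betas.index.intersection(x_dimorphic)]
        x_clusters = cluster_x_methylation(x_betas)

        expr = cohort.expression[tissue]
        xist = classify_xist(expr.loc["txXIST"]) if "txXIST" in expr.index else None

        y_probes = man.index[man["chromosome"] == "Y"]
        y_det = cohort.detection_meth[tissue].loc[
            cohort.detection_meth[tissue].index.intersection(y_probes)
        ]
        eman = cohort.probes_expr.set_index("probe_id")
        y_expr_ids = eman.index[eman["chromosome"] == "Y"]
        y_expr = expr.loc[expr.index.intersection(y_expr_ids)]
        y_signal = assess_y_signal(y_det, y_expr)

        snps_x = cohort.snps[cohort.snps["region"] == "X"]
        het = x_heterozygosity(snps_x)
        xtr = cohort.snps[cohort.snps["region"] == "XTR"]
        bands = {}
        for ind, group in xtr.groupby("individual_id"):
            bands[ind], _ = count_baf_bands(group["baf"])

        calls = []
        sample_meta = meta[meta["tissue"] == tissue].set_index("sample_id")
        for sample_id in betas.columns:
            ind = sample_meta.loc[sample_id, "individual_id"]
            evidence = KaryotypeEvidence(
                x_meth_cluster=x_clusters.loc[sample_id, "label"],
                x_meth_score=float(x_clusters.loc[sample_id, "score"]),
                xist_class=str(xist[sample_id]) if xist is not None else "indeterminate",
                y_present=bool(y_signal.loc[sample_id, "y_present"]),
                y_frac_detected=float(y_signal.loc[sample_id, "frac_detected"]),
                y_mean_expression=float(y_signal.loc[sample_id, "mean_y_expression"]),
                x_het_rate=float(het[ind]) if ind in het.index else None,
                baf_band_count=bands.get(ind),
            )
            calls.append(
                call_karyotype(
                    evidence,
                    reported_sex=sample_meta.loc[sample_id, "reported_sex"],
                    sample_id=sample_id,
                    het_rate_threshold=config.het_rate_threshold,
                )
            )
        call_table = pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in calls],
                "individual_id": [sample_meta.loc[c.sample_id, "individual_id"] for c in calls],
                "call": [c.call for c in calls],
                "reported_sex": [c.reported_sex for c in calls],
                "discordant": [c.discordant_with_reported_sex for c in calls],
                "x_meth_score": [c.evidence.x_meth_score for c in calls],
                "xist_class": [c.evidence.xist_class for c in calls],
                "y_present": [c.evidence.y_present for c in calls],
                "x_het_rate": [c.evidence.x_het_rate for c in calls],
                "baf_band_count": [c.evidence.baf_band_count for c in calls],
            }
        )
        return call_table

    karyotype_calls = stage_karyotype()
    xio.write_table(karyotype_calls, out_dir / "karyotype_calls.tsv")
    report["stages"]["karyotype"] = {
        "calls": dict(zip(karyotype_calls["individual_id"], karyotype_calls["call"])),
        "n_discordant": int(karyotype_calls["discordant"].sum()),
    }

    # ---- locate the index case ---------------------------------------
    index_individual = config.index_individual
    if index_individual is None:
        hits = karyotype_calls.loc[karyotype_calls["call"] == "47,XXY", "individual_id"]
        index_individual = hits.iloc[0] if len(hits) == 1 else None
    report["index_individual"] = index_individual

    if index_individual is None:
        report["stages"]["singleton_screen"] = {"skipped": "no index case identified"}
        report["stages"]["dmr"] = {"skipped": "no index case identified"}
    else:
        screens = {}
        dmr_frames = []

        @_stage("singleton_screen")
        def stage_screen():
            for tissue in tissues:
                index_sample = f"{index_individual}_{tissue}"
                meth = run_singleton_screen(
                    filtered_betas[tissue], index_sample, meta, manifest, alpha=config.alpha
                )
                expr = run_singleton_screen(
                    filtered_expr[tissue], index_sample, meta, cohort.probes_expr, alpha=config.alpha
                )
                meth["tissue"] = tissue
                expr["tissue"] = tissue
                screens[(tissue, "methylation")] = meth
                screens[(tissue, "expression")] = expr
                xio.write_table(
                    meth[meth["significant"].fillna(False)], out_dir / f"meth_screen_{tissue}.tsv"
                )
                xio.write_table(
                    expr[expr["significant"].fillna(False)], out_dir / f"expr_screen_{tissue}.tsv"
                )
            return {
                f"{tissue}/{omic}": significant_sign_counts(frame)
                for (tissue, omic), frame in screens.items()
            }

        report["stages"]["singleton_screen"] = stage_screen()

        @_stage("dmr")
        def stage_dmr():
            summary = {}
            for tissue in tissues:
                dmrs = call_dmrs(
                    screens[(tissue, "methylation")],
                    manifest,
                    window=config.dmr_window,
                    min_probes=config.dmr_min_probes,
                    max_gap=config.dmr_max_gap,
                )
                dmrs = overlap_cnv(dmrs, cohort.cnv_segments)
                dmrs["tissue"] = tissue
                dmr_frames.append(dmrs)
                xio.write_table(dmrs, out_dir / f"dmrs_{tissue}.tsv")
                if len(dmrs):
                    xio.write_bed(
                        dmrs_to_bed(dmrs), out_dir / f"dmrs_{tissue}.bed", extra_columns=["name", "score"]
                    )
                summary[tissue] = {
                    "n_dmrs": int(len(dmrs)),
                    "n_cnv_overlap": int(dmrs["cnv_overlap"].sum()) if len(dmrs) else 0,
                }
            return summary

        report["stages"]["dmr"] = stage_dmr()

    # ---- stage: global methylation ------------------------------------
    @_stage("global_methylation")
    def stage_global():
        records = summarize_assay(cohort.repeats)
        results = {}
        if index_individual is not None:
            for tissue in tissues:
                index_sample = f"{index_individual}_{tissue}"
                assessment = global_outlier_assessment(
                    records, index_sample, z_threshold=config.outlier_z_threshold
                )
                for row in assessment.itertuples():
                    results[f"{row.tissue}/{row.assay}"] = {
                        "z": None if pd.isna(row.z) else round(float(row.z), 3),
                        "direction": row.direction,
                    }
        xio.write_table(records, out_dir / "repeat_methylation.tsv")
        return results or {"skipped": "no index case identified"}

    report["stages"]["global_methylation"] = stage_global()

    # ---- stage: phenotype outlier -------------------------------------
    @_stage("phenotype")
    def stage_phenotype():
        from .singleton import phenotype_outlier

        if index_individual is None:
            return {"skipped": "no index case identified"}
        per_ind = meta.drop_duplicates("individual_id").set_index("individual_id")
        out = {}
        for column in ("total_brain_mass", "cerebellum_mass"):
            if column not in per_ind.columns:
                continue
            value = float(per_ind.loc[index_individual, column])
            ref = per_ind.drop(index=index_individual)[column]
            res = phenotype_outlier(value, ref, z_threshold=config.outlier_z_threshold)
            out[column] = {"value": value, "z": round(res["z"], 3), "outlier": res["outlier"]}
        return out

    report["stages"]["phenotype"] = stage_phenotype()

    # ---- stage: XCI ---------------------------------------------------
    @_stage("xci")
    def stage_xci():
        if len(cohort.xci_peaks) == 0:
            return {"skipped": "no XCI peak data"}
        results = {}
        for peaks in average_replicates(cohort.xci_peaks):
            res = xci_ratio(peaks)
            results[f"{peaks.sample_id}/{peaks.tissue}"] = {
                "ratio": round(res.ratio, 4),
                "skewing_percent": round(res.skewing, 2),
                "mspi_control_pass": res.mspi_control_pass,
            }
        return results

    report["stages"]["xci"] = stage_xci()

    xio.write_json(report, out_dir / "report.json")
    return report
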