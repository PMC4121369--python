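"""Synthetic multi-omic cohort generator.

Emulates the statistical structure a single-subject sex-chromosome-aneuploidy
analysis relies on, for two brain tissues across a reference cohort plus one
optional index case:

* sex-dimorphic X-chromosome methylation (intermediate betas in samples with
  an inactive X, low island betas with a single active X);
* bimodal XIST expression (high whenever an inactive X is present);
* Y-chromosome probe signal only when a Y is present;
* X-SNP heterozygosity near zero for 46,XY, high for 46,XX / 47,XXY;
* B-allele-frequency band structure in the X-transposed region (XTR), where
  probes cross-hybridize to the summed X+Y copies: three bands for two total
  copies (46,XX / 46,XY) and four bands — heterozygote modes at 1/3 and
  2/3 — for the three copies of 47,XXY;
* spiked singleton DMRs / differentially expressed transcripts in the index;
* tissue-specific repeat-element (LINE-1 / Alu) global-methylation shifts;
* an AR-locus XCI peak-height assay and brain-mass phenotypes.

Methylation noise is Beta-distributed around a target mean with a precision
parameter, which respects the [0,1] support and the heteroscedasticity of
array beta values. All randomness flows from a single integer seed; a fixed
seed and config reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as xio
from .util import AUTOSOMES, ConfigError, normalize_chromosome

#: X-linked genes commonly escaping X inactivation (generator vocabulary).
ESCAPE_XCI_GENES = ("EIF1AX", "KDM6A", "PUDP", "ZFX")
#: Pseudoautosomal region gene sets (three copies in 47,XXY).
PAR1_GENES = ("SLC25A6", "GTPBP6", "DHRSX", "CSF2RA")
PAR2_GENES = ("SPRY3", "VAMP7")

_KARYOTYPES = ("46,XX", "46,XY", "47,XXY")

#: Printed reference mean, reference SD and index offset per tissue x assay
#: for the repeat-element pyrosequencing assays (percent methylation).
DEFAULT_REPEAT_PARAMS = {
    ("PFC", "LINE1"): (73.0, 2.3, -5.3),
    ("PFC", "Alu"): (28.1, 2.6, -2.6),
    ("CER", "LINE1"): (71.9, 2.1, 6.5),
    ("CER", "Alu"): (24.8, 0.8, -0.1),
}

#: XCI skewing percent of the index per tissue (subtle cortical imbalance,
#: none in cerebellum).
DEFAULT_XCI_SKEW = {"PFC": 7.5, "CER": 0.4}

#: Sex-stratified brain-mass distributions (grams): (total mean, total sd,
#: cerebellum mean, cerebellum sd).
BRAIN_MASS_PARAMS = {"M": (1454.0, 201.0, 175.0, 27.0), "F": (1325.0, 92.0, 160.0, 15.0)}


@dataclass(frozen=True)
class Spike:
    """A configured index-specific effect.

    ``comparison`` names the family in which the spike should reach
    significance: ``all`` shifts the index away from every reference sample;
    ``males`` / ``females`` make the locus sex-dimorphic with the index
    resembling the *other* sex, so only the named family sees the effect.
    ``effect`` is a beta difference for methylation and a log2 difference
    for expression.
    """

    chromosome: str
    start: int
    end: int
    effect: float
    tissue: str
    comparison: str = "all"
    kind: str = "methylation"
    n_probes: int = 3
    name: str = ""


DEFAULT_SPIKES = (
    Spike("8", 101224915, 101225361, 0.13, "PFC", "all", "methylation", 5, "SPAG1-like"),
    Spike("8", 101224915, 101225361, 0.13, "CER", "all", "methylation", 5, "SPAG1-like"),
    Spike("5", 784832, 784915, 0.50, "PFC", "all", "methylation", 3, "chr5-hyper"),
    Spike("17", 77680078, 77680232, -0.19, "CER", "all", "methylation", 2, "cnv-overlap"),
    Spike("3", 48266905, 48266954, 0.20, "PFC", "all", "expression", 1, "CAMP-like"),
    Spike("3", 48266905, 48266954, 0.20, "CER", "all", "expression", 1, "CAMP-like"),
    Spike("22", 38013841, 38013890, -0.83, "PFC", "males", "expression", 1, "GGA1-like"),
    Spike("2", 47606943, 47606992, 0.69, "PFC", "females", "expression", 1, "EPCAM-like"),
)

#: Escape-XCI / PAR expression behavior of the index: (gene, tissue or None
#: for both, log2 shift vs the reference baseline). Mirrors the observed
#: heterogeneity: some loci up in both tissues, some down, some one tissue.
DEFAULT_ESCAPE_PAR_EFFECTS = (
    ("EIF1AX", None, 0.6),
    ("GTPBP6", None, -0.4),
    ("SLC25A6", "CER", 0.5),
    ("DHRSX", None, 0.4),
)


@dataclass
class SimulationConfig:
    """Stated world of the synthetic cohort.

    ``n_individuals`` reference individuals (balanced sexes) are simulated in
    every tissue, plus one index case of ``index_karyotype`` when set.
    """

    n_individuals: int = 49
    n_probes_autosomal: int = 400
    n_probes_x: int = 100
    n_probes_y: int = 30
    n_probes_rs: int = 60
    n_expression_probes: int = 300
    n_snps_x: int = 500
    n_snps_xtr: int = 300
    tissues: tuple[str, ...] = ("PFC", "CER")
    index_karyotype: str | None = "47,XXY"
    spikes: tuple[Spike, ...] = DEFAULT_SPIKES
    escape_par_effects: tuple = DEFAULT_ESCAPE_PAR_EFFECTS
    repeat_params: dict = field(default_factory=lambda: dict(DEFAULT_REPEAT_PARAMS))
    xci_skew: dict = field(default_factory=lambda: dict(DEFAULT_XCI_SKEW))
    meth_precision: float = 400.0
    expr_sd: float = 0.05
    baf_sd: float = 0.02
    genotype_error: float = 0.005
    detection_fail_frac: float = 1e-4
    beadcount_mean: float = 14.0
    index_total_brain_mass: float = 1417.0
    index_cerebellum_mass: float = 111.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_probes_autosomal": self.n_probes_autosomal,
            "n_probes_x": self.n_probes_x,
            "n_probes_y": self.n_probes_y,
            "n_expression_probes": self.n_expression_probes,
            "n_snps_x": self.n_snps_x,
            "n_snps_xtr": self.n_snps_xtr,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0 (got {value})")
        if not self.tissues:
            raise ConfigError("tissue list must not be empty")
        if self.index_karyotype is not None and self.index_karyotype not in _KARYOTYPES:
            raise ConfigError(f"unknown index karyotype {self.index_karyotype!r}")
        index_has_y = self.index_karyotype in ("46,XY", "47,XXY")
        for spike in self.spikes:
            if self.index_karyotype is None:
                raise ConfigError("spikes configured but no index case requested")
            if spike.kind == "methylation" and not -1.0 <= spike.effect <= 1.0:
                raise ConfigError(
                    f"beta-scale spike effect {spike.effect} outside [-1, 1] ({spike.name or spike.chromosome})"
                )
            chrom = normalize_chromosome(spike.chromosome)
            if chrom == "Y" and not index_has_y:
                raise ConfigError(
                    f"spike on chromosome Y contradicts index karyotype {self.index_karyotype}"
                )
            if spike.tissue not in self.tissues:
                raise ConfigError(f"spike tissue {spike.tissue!r} not in configured tissues")
            if spike.comparison not in ("all", "males", "females"):
                raise ConfigError(f"unknown spike comparison {spike.comparison!r}")


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: all matrices plus ground truth."""

    config: SimulationConfig
    probes_meth: pd.DataFrame
    probes_expr: pd.DataFrame
    betas: dict
    beadcounts: dict
    detection_meth: dict
    expression: dict
    detection_expr: dict
    snps: pd.DataFrame
    cnv_segments: pd.DataFrame
    repeats: pd.DataFrame
    xci_peaks: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict

    @property
    def index_individual(self) -> str | None:
        return self.truth.get("index_individual")

    def sample_id(self, individual: str, tissue: str) -> str:
        return f"{individual}_{tissue}"


def _individual_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_individuals):
        sex = "F" if i % 2 == 0 else "M"
        rows.append(
            {
                "individual_id": f"REF{i + 1:03d}",
                "reported_sex": sex,
                "karyotype": "46,XX" if sex == "F" else "46,XY",
                "is_index": False,
            }
        )
    if config.index_karyotype is not None:
        rows.append(
            {
                "individual_id": "CASE001",
                # the index is recorded as male unless simulated as 46,XX
                "reported_sex": "F" if config.index_karyotype == "46,XX" else "M",
                "karyotype": config.index_karyotype,
                "is_index": True,
            }
        )
    return pd.DataFrame(rows)


def _x_count(karyotype: str) -> int:
    return {"46,XX": 2, "46,XY": 1, "47,XXY": 2}[karyotype]


def _has_y(karyotype: str) -> bool:
    return karyotype in ("46,XY", "47,XXY")


def _positions(rng: np.random.Generator, n: int, start: float = 1e6) -> np.ndarray:
    gaps = rng.integers(200, 2000, size=n)
    return (start + np.cumsum(gaps)).astype(int)


def _beta_noise(rng: np.random.Generator, mean, precision: float) -> np.ndarray:
    mu = np.clip(np.asarray(mean, dtype=float), 0.02, 0.98)
    return rng.beta(mu * precision, (1.0 - mu) * precision)


def _build_meth_manifest(config: SimulationConfig, rng: np.random.Generator):
    """Probe manifest: autosomal + X (island/escape strata) + Y + rs probes,
    QC-bait probes for every filter rule, and dedicated spike probes."""
    records = []

    def add(pid, chrom, pos, context="CG", snp_dist=1000, snp_maf=0.0, cross=False, stratum="autosomal"):
        records.append(
            {
                "probe_id": pid,
                "chromosome": chrom,
                "position": int(pos),
                "strand": "+",
                "context": context,
                "nearest_snp_distance": int(snp_dist),
                "nearest_snp_maf": float(snp_maf),
                "cross_reactive": bool(cross),
                "stratum": stratum,
            }
        )

    n_auto = config.n_probes_autosomal
    chroms = rng.choice(AUTOSOMES, size=n_auto)
    per_chrom_pos: dict[str, int] = {}
    for i in range(n_auto):
        chrom = str(chroms[i])
        # cumulative gaps keep positions strictly increasing per chromosome
        per_chrom_pos[chrom] = per_chrom_pos.get(chrom, 1_000_000) + int(rng.integers(2_000, 50_000))
        add(f"cg{i + 1:07d}", chrom, per_chrom_pos[chrom], stratum="autosomal")

    # QC bait probes exercising each removal rule deterministically
    for j in range(5):
        add(f"cgSNP{j:03d}", "7", 90_000_000 + j * 5_000, snp_dist=int(rng.integers(0, 11)), snp_maf=0.10, stratum="bait_snp")
    for j in range(3):
        add(f"ch{j + 1:07d}", "12", 60_000_000 + j * 5_000, context="CH", stratum="bait_ch")
    for j in range(4):
        add(f"cgXR{j:03d}", "X", 140_000_000 + j * 5_000, cross=True, stratum="bait_crossreactive")
    for j in range(3):
        add(f"cgLOWB{j:03d}", "4", 30_000_000 + j * 5_000, stratum="bait_beadcount")
    for j in range(3):
        add(f"cgHIDP{j:03d}", "4", 31_000_000 + j * 5_000, stratum="bait_detection")

    x_pos = _positions(rng, config.n_probes_x, start=3e6)
    for i in range(config.n_probes_x):
        stratum = "x_island" if i % 2 == 0 else "x_escape"
        add(f"cgX{i + 1:05d}", "X", x_pos[i], stratum=stratum)

    y_pos = _positions(rng, config.n_probes_y, start=2.7e6)
    for i in range(config.n_probes_y):
        add(f"cgY{i + 1:05d}", "Y", y_pos[i], stratum="y")

    rs_chroms = rng.choice(AUTOSOMES, size=config.n_probes_rs)
    for i in range(config.n_probes_rs):
        add(f"rs{i + 1:06d}", str(rs_chroms[i]), 5_000_000 + i * 10_000, stratum="rs")

    # dedicated spike probes (unique per region so both tissues share them)
    seen_regions = {}
    for spike in config.spikes:
        if spike.kind != "methylation":
            continue
        key = (normalize_chromosome(spike.chromosome), spike.start, spike.end, spike.n_probes)
        if key in seen_regions:
            continue
        chrom, start, end, n_probes = key
        positions = np.linspace(start, end, n_probes).astype(int)
        positions = np.unique(positions)
        ids = [f"cgSPK{len(seen_regions):02d}{k:02d}" for k in range(len(positions))]
        for pid, pos in zip(ids, positions):
            add(pid, chrom, pos, stratum="spike")
        seen_regions[key] = ids
    manifest = pd.DataFrame.from_records(records)
    return manifest, seen_regions


def _build_expr_manifest(config: SimulationConfig, rng: np.random.Generator):
    records = []

    def add(pid, gene, chrom, pos, stratum):
        records.append(
            {
                "probe_id": pid,
                "gene": gene,
                "chromosome": chrom,
                "position": int(pos),
                "strand": "+",
                "stratum": stratum,
            }
        )

    chroms = rng.choice(AUTOSOMES, size=config.n_expression_probes)
    for i in range(config.n_expression_probes):
        add(f"tx{i + 1:06d}", f"GENE{i + 1:04d}", str(chroms[i]), 10_000_000 + i * 12_345, "autosomal")
    add("txXIST", "XIST", "X", 73_040_000, "xist")
    for j, gene in enumerate(("RPS4Y1", "NLGN4Y", "TTTY14")):
        add(f"txY{j:02d}", gene, "Y", 2_712_151 + j * 7_000_000, "y")
    for j, gene in enumerate(ESCAPE_XCI_GENES):
        add(f"txESC{j:02d}", gene, "X", 20_000_000 + j * 5_000_000, "escape")
    for j, gene in enumerate(PAR1_GENES):
        add(f"txPAR1{j:02d}", gene, "X", 1_300_000 + j * 100_000, "par1")
    for j, gene in enumerate(PAR2_GENES):
        add(f"txPAR2{j:02d}", gene, "X", 154_900_000 + j * 100_000, "par2")
    spike_ids = {}
    for spike in config.spikes:
        if spike.kind != "expression":
            continue
        key = (normalize_chromosome(spike.chromosome), spike.start, spike.end)
        if key in spike_ids:
            continue
        pid = f"txSPK{len(spike_ids):02d}"
        add(pid, spike.name or pid, key[0], key[1], "spike")
        spike_ids[key] = pid
    return pd.DataFrame.from_records(records), spike_ids


def _spike_offsets(spike: Spike, sexes: np.ndarray, is_index: np.ndarray) -> np.ndarray:
    """Per-sample mean offsets realizing a spike's target comparison."""
    offsets = np.zeros(sexes.size)
    if spike.comparison == "all":
        offsets[is_index] = spike.effect
    elif spike.comparison == "females":
        # index looks male-like: males co-shifted, females at baseline
        offsets[(sexes == "M") & ~is_index] = spike.effect
        offsets[is_index] = spike.effect
    else:  # males
        offsets[(sexes == "F") & ~is_index] = spike.effect
        offsets[is_index] = spike.effect
    return offsets


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort from ``config``.

    Deterministic: the same config (including seed) reproduces the cohort
    exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    individuals = _individual_table(config)
    n_ind = len(individuals)
    karyotypes = individuals["karyotype"].to_numpy()
    sexes = individuals["reported_sex"].to_numpy()
    is_index = individuals["is_index"].to_numpy()
    ind_ids = individuals["individual_id"].to_numpy()

    manifest, spike_regions = _build_meth_manifest(config, rng)
    expr_manifest, expr_spike_ids = _build_expr_manifest(config, rng)

    # ---- per-probe baseline means ------------------------------------
    n_probes = len(manifest)
    strata = manifest["stratum"].to_numpy()
    base = np.empty(n_probes)
    kind_draw = rng.random(n_probes)
    base[kind_draw < 0.4] = rng.uniform(0.03, 0.15, size=(kind_draw < 0.4).sum())
    mid = (kind_draw >= 0.4) & (kind_draw < 0.6)
    base[mid] = rng.uniform(0.30, 0.70, size=mid.sum())
    base[kind_draw >= 0.6] = rng.uniform(0.75, 0.95, size=(kind_draw >= 0.6).sum())
    base[np.isin(strata, ["x_island", "x_escape", "y"])] = 0.10
    base[strata == "spike"] = 0.40

    # rs (genotyping) probes: trimodal per individual, tissue-invariant
    rs_mask = strata == "rs"
    rs_maf = rng.uniform(0.1, 0.5, size=rs_mask.sum())
    rs_geno = rng.binomial(2, rs_maf[:, None], size=(rs_mask.sum(), n_ind))
    rs_levels = np.array([0.06, 0.50, 0.94])

    x_island = strata == "x_island"
    has_inactive_x = np.array([_x_count(k) == 2 for k in karyotypes])
    has_y = np.array([_has_y(k) for k in karyotypes])

    spike_probe_ids = {pid for ids in spike_regions.values() for pid in ids}
    probe_index = pd.Index(manifest["probe_id"])

    betas = {}
    beadcounts = {}
    detection_meth = {}
    expression = {}
    detection_expr = {}
    truth_spikes = []

    n_expr = len(expr_manifest)
    expr_strata = expr_manifest["stratum"].to_numpy()
    expr_base = rng.normal(8.0, 1.5, size=n_expr)
    expr_base[expr_strata == "xist"] = 6.0
    expr_base[expr_strata == "y"] = 8.0
    expr_gene = expr_manifest["gene"].to_numpy()

    for tissue in config.tissues:
        sample_ids = [f"{ind}_{tissue}" for ind in ind_ids]

        # methylation target means: probes x individuals
        mean = np.tile(base[:, None], (1, n_ind))
        mean[np.ix_(x_island, has_inactive_x)] = 0.45
        # Y probes carry no real signal without a Y; junk intermediate betas
        mean[np.ix_(strata == "y", ~has_y)] = 0.50
        if rs_mask.any():
            mean[rs_mask] = rs_levels[rs_geno]
        for spike in config.spikes:
            if spike.kind != "methylation" or spike.tissue != tissue:
                continue
            key = (normalize_chromosome(spike.chromosome), spike.start, spike.end, spike.n_probes)
            ids = spike_regions[key]
            rows = probe_index.get_indexer(ids)
            offsets = _spike_offsets(spike, sexes, is_index)
            mean[rows, :] = np.clip(mean[rows, :] + offsets[None, :], 0.02, 0.98)
            for pid in ids:
                truth_spikes.append(
                    {
                        "feature_id": pid,
                        "kind": "methylation",
                        "tissue": tissue,
                        "comparison": spike.comparison,
                        "effect": spike.effect,
                        "name": spike.name,
                    }
                )
        beta = _beta_noise(rng, mean, config.meth_precision)
        betas[tissue] = pd.DataFrame(beta, index=probe_index.copy(), columns=sample_ids)

        # beadcounts: Poisson with a floor of 1 bead, plus low-bead bait
        beads = rng.poisson(config.beadcount_mean, size=(n_probes, n_ind)) + 1
        low_bait = strata == "bait_beadcount"
        n_low = max(1, int(np.ceil(0.08 * n_ind)))
        for row in np.where(low_bait)[0]:
            cols = rng.choice(n_ind, size=n_low, replace=False)
            beads[row, cols] = rng.integers(0, 3, size=n_low)
        beadcounts[tissue] = pd.DataFrame(beads, index=probe_index.copy(), columns=sample_ids)

        # detection p: good probes detect everywhere, rare random failures,
        # Y probes fail without a Y, bait probes fail in >1% of samples
        detp = rng.uniform(0.0, 0.01, size=(n_probes, n_ind))
        fails = rng.random((n_probes, n_ind)) < config.detection_fail_frac
        detp[fails] = rng.uniform(0.06, 1.0, size=fails.sum())
        y_rows = np.where(strata == "y")[0]
        detp[np.ix_(y_rows, ~has_y)] = rng.uniform(0.1, 1.0, size=(y_rows.size, (~has_y).sum()))
        hi_bait = np.where(strata == "bait_detection")[0]
        n_fail = max(1, int(np.ceil(0.02 * n_ind)))
        for row in hi_bait:
            cols = rng.choice(n_ind, size=n_fail, replace=False)
            detp[row, cols] = rng.uniform(0.06, 1.0, size=n_fail)
        detection_meth[tissue] = pd.DataFrame(detp, index=probe_index.copy(), columns=sample_ids)

        # ---- expression -------------------------------------------------
        emean = np.tile(expr_base[:, None], (1, n_ind))
        xist_rows = np.where(expr_strata == "xist")[0]
        emean[np.ix_(xist_rows, has_inactive_x)] += 4.0
        yexpr_rows = np.where(expr_strata == "y")[0]
        emean[np.ix_(yexpr_rows, ~has_y)] -= 4.0
        for gene, eff_tissue, shift in config.escape_par_effects:
            if eff_tissue is not None and eff_tissue != tissue:
                continue
            rows = np.where(expr_gene == gene)[0]
            emean[np.ix_(rows, np.where(is_index)[0])] += shift
        for spike in config.spikes:
            if spike.kind != "expression" or spike.tissue != tissue:
                continue
            key = (normalize_chromosome(spike.chromosome), spike.start, spike.end)
            pid = expr_spike_ids[key]
            row = expr_manifest.index[expr_manifest["probe_id"] == pid][0]
            offsets = _spike_offsets(spike, sexes, is_index)
            emean[row, :] += offsets
            truth_spikes.append(
                {
                    "feature_id": pid,
                    "kind": "expression",
                    "tissue": tissue,
                    "comparison": spike.comparison,
                    "effect": spike.effect,
                    "name": spike.name,
                }
            )
        evals = rng.normal(emean, config.expr_sd)
        expression[tissue] = pd.DataFrame(
            evals, index=pd.Index(expr_manifest["probe_id"]), columns=sample_ids
        )
        edetp = rng.uniform(0.0, 0.005, size=(n_expr, n_ind))
        edetp[np.ix_(yexpr_rows, ~has_y)] = rng.uniform(0.2, 1.0, size=(yexpr_rows.size, (~has_y).sum()))
        detection_expr[tissue] = pd.DataFrame(
            edetp, index=pd.Index(expr_manifest["probe_id"]), columns=sample_ids
        )

    # ---- SNP genotypes / BAF -----------------------------------------
    snp_rows = []
    x_counts = np.array([_x_count(k) for k in karyotypes])
    xtr_copies = x_counts + has_y.astype(int)  # probes see X + Y copies
    for region, n_snps, copies_vec, chrom, start in (
        ("X", config.n_snps_x, x_counts, "X", 10_000_000),
        ("XTR", config.n_snps_xtr, xtr_copies, "X", 88_400_000),
    ):
        freqs = rng.uniform(0.05, 0.95, size=n_snps)
        positions = start + np.arange(n_snps) * 4_000
        for s in range(n_snps):
            k_alleles = rng.binomial(copies_vec, freqs[s])
            baf = np.clip(k_alleles / copies_vec + rng.normal(0.0, config.baf_sd, size=n_ind), 0.0, 1.0)
            geno = np.where(k_alleles == 0, "AA", np.where(k_alleles == copies_vec, "BB", "AB"))
            # rare genotyping error: flip a call to AB
            err = rng.random(n_ind) < config.genotype_error
            geno = np.where(err, "AB", geno)
            for i in range(n_ind):
                snp_rows.append(
                    (f"snp{region}{s + 1:05d}", chrom, int(positions[s]), region, ind_ids[i], geno[i], float(baf[i]))
                )
    snps = pd.DataFrame(
        snp_rows,
        columns=["snp_id", "chromosome", "position", "region", "individual_id", "genotype", "baf"],
    )

    # ---- CNV segments of the index -----------------------------------
    cnv_rows = []
    if config.index_karyotype is not None:
        cnv_rows.append({"chromosome": "6", "start": 124_125_001, "end": 124_750_000, "copy_number": 4})
        for spike in config.spikes:
            if spike.name == "cnv-overlap":
                cnv_rows.append(
                    {
                        "chromosome": normalize_chromosome(spike.chromosome),
                        "start": spike.start - 1_000,
                        "end": spike.end + 1_000,
                        "copy_number": 3,
                    }
                )
    cnv_segments = pd.DataFrame(cnv_rows, columns=["chromosome", "start", "end", "copy_number"])

    # ---- repeat-element assays ---------------------------------------
    repeat_rows = []
    for tissue in config.tissues:
        for assay in ("LINE1", "Alu"):
            ref_mean, ref_sd, index_shift = config.repeat_params.get(
                (tissue, assay), (70.0, 2.0, 0.0)
            )
            sample_means = rng.normal(ref_mean, ref_sd, size=n_ind)
            sample_means[is_index] = ref_mean + index_shift
            cpgs = rng.normal(sample_means[:, None], 0.6, size=(n_ind, 3))
            cpgs = np.clip(cpgs, 0.0, 100.0)
            for i in range(n_ind):
                repeat_rows.append(
                    {
                        "sample_id": f"{ind_ids[i]}_{tissue}",
                        "tissue": tissue,
                        "assay": assay,
                        "cpg1": round(float(cpgs[i, 0]), 2),
                        "cpg2": round(float(cpgs[i, 1]), 2),
                        "cpg3": round(float(cpgs[i, 2]), 2),
                        "control": "",
                    }
                )
            for label, level in (("methylated", 97.5), ("unmethylated", 2.0)):
                vals = np.clip(rng.normal(level, 0.8, size=3), 0.0, 100.0)
                repeat_rows.append(
                    {
                        "sample_id": f"CTRL_{label.upper()}_{tissue}_{assay}",
                        "tissue": tissue,
                        "assay": assay,
                        "cpg1": round(float(vals[0]), 2),
                        "cpg2": round(float(vals[1]), 2),
                        "cpg3": round(float(vals[2]), 2),
                        "control": label,
                    }
                )
    repeats = pd.DataFrame(repeat_rows)

    # ---- XCI AR-assay peak heights (index only, informative het) ------
    xci_rows = []
    if config.index_karyotype == "47,XXY" or config.index_karyotype == "46,XX":
        for tissue in config.tissues:
            skew = config.xci_skew.get(tissue, 0.0)
            ratio = 0.5 + skew / 100.0
            for rep in range(1, 4):
                h1u = float(rng.normal(2000.0, 40.0))
                h2u = float(rng.normal(2000.0, 40.0))
                noise = rng.normal(0.0, 0.004)
                h1d = max(0.0, h1u * (ratio + noise) * 0.9)
                h2d = max(0.0, h2u * (1.0 - ratio - noise) * 0.9)
                xci_rows.append(
                    {
                        "sample_id": "CASE001",
                        "tissue": tissue,
                        "replicate": rep,
                        "allele1_size": 20,
                        "allele2_size": 26,
                        "h1u": round(h1u, 1),
                        "h2u": round(h2u, 1),
                        "h1d": round(h1d, 1),
                        "h2d": round(h2d, 1),
                        "h1m": round(float(rng.uniform(0.0, 30.0)), 1),
                        "h2m": round(float(rng.uniform(0.0, 30.0)), 1),
                    }
                )
    xci_peaks = pd.DataFrame(
        xci_rows,
        columns=[
            "sample_id",
            "tissue",
            "replicate",
            "allele1_size",
            "allele2_size",
            "h1u",
            "h2u",
            "h1d",
            "h2d",
            "h1m",
            "h2m",
        ],
    )

    # ---- metadata -----------------------------------------------------
    total_mass = np.empty(n_ind)
    cer_mass = np.empty(n_ind)
    for i in range(n_ind):
        tm, tsd, cm, csd = BRAIN_MASS_PARAMS[sexes[i]]
        total_mass[i] = rng.normal(tm, tsd)
        cer_mass[i] = rng.normal(cm, csd)
    total_mass[is_index] = config.index_total_brain_mass
    cer_mass[is_index] = config.index_cerebellum_mass

    meta_rows = []
    for tissue in config.tissues:
        for i in range(n_ind):
            meta_rows.append(
                {
                    "sample_id": f"{ind_ids[i]}_{tissue}",
                    "individual_id": ind_ids[i],
                    "reported_sex": sexes[i],
                    "tissue": tissue,
                    "total_brain_mass": round(float(total_mass[i]), 1),
                    "cerebellum_mass": round(float(cer_mass[i]), 1),
                }
            )
    metadata = pd.DataFrame(meta_rows)

    truth = {
        "karyotypes": dict(zip(ind_ids, karyotypes)),
        "index_individual": "CASE001" if config.index_karyotype is not None else None,
        "spiked_features": truth_spikes,
        "spike_probe_ids": sorted(spike_probe_ids),
    }

    manifest_out = manifest.copy()
    expr_manifest_out = expr_manifest.copy()
    return SyntheticCohort(
        config=config,
        probes_meth=manifest_out,
        probes_expr=expr_manifest_out,
        betas=betas,
        beadcounts=beadcounts,
        detection_meth=detection_meth,
        expression=expression,
        detection_expr=detection_expr,
        snps=snps,
        cnv_segments=cnv_segments,
        repeats=repeats,
        xci_peaks=xci_peaks,
        metadata=metadata,
        truth=truth,
    )


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["spikes"] = [dataclasses.asdict(s) for s in config.spikes]
    d["repeat_params"] = {f"{t}|{a}": list(v) for (t, a), v in config.repeat_params.items()}
    d["escape_par_effects"] = [list(e) for e in config.escape_par_effects]
    d["tissues"] = list(config.tissues)
    return d


def _config_from_jsonable(d: dict) -> SimulationConfig:
    d = dict(d)
    d["spikes"] = tuple(Spike(**s) for s in d.get("spikes", ()))
    d["repeat_params"] = {
        tuple(k.split("|")): tuple(v) for k, v in d.get("repeat_params", {}).items()
    }
    d["escape_par_effects"] = tuple(tuple(e) for e in d.get("escape_par_effects", ()))
    d["tissues"] = tuple(d.get("tissues", ("PFC", "CER")))
    return SimulationConfig(**d)


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write all cohort files under ``directory``; returns the JSON manifest.

    Matrices are TSV, CNV segments are BED (0-based half-open on disk) and a
    ``manifest.json`` records every file plus the generating configuration.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    def record(name, path):
        files[name] = path.name

    path = directory / "probes_methylation.tsv"
    xio.write_probe_manifest(cohort.probes_meth, path)
    record("probes_methylation", path)
    path = directory / "probes_expression.tsv"
    xio.write_probe_manifest(cohort.probes_expr, path)
    record("probes_expression", path)

    for tissue in cohort.config.tissues:
        for label, store in (
            ("betas", cohort.betas),
            ("beadcounts", cohort.beadcounts),
            ("detection_meth", cohort.detection_meth),
            ("expression", cohort.expression),
            ("detection_expr", cohort.detection_expr),
        ):
            path = directory / f"{label}_{tissue}.tsv"
            xio.write_matrix(store[tissue], path)
            record(f"{label}_{tissue}", path)

    path = directory / "snps.tsv"
    xio.write_table(cohort.snps, path)
    record("snps", path)

    path = directory / "cnv_index.bed"
    xio.write_bed(cohort.cnv_segments, path, extra_columns=["copy_number"])
    record("cnv_index", path)

    path = directory / "repeats.tsv"
    xio.write_table(cohort.repeats, path)
    record("repeats", path)

    path = directory / "xci_peaks.tsv"
    xio.write_table(cohort.xci_peaks, path)
    record("xci_peaks", path)

    path = directory / "metadata.tsv"
    xio.write_table(cohort.metadata, path)
    record("metadata", path)

    path = directory / "truth.json"
    xio.write_json(cohort.truth, path)
    record("truth", path)

    manifest = {
        "format_version": 1,
        "files": files,
        "config": _config_to_jsonable(cohort.config),
    }
    with open(directory / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as handle:
        manifest = json.load(handle)
    config = _config_from_jsonable(manifest["config"])
    files = manifest["files"]

    def mat(label):
        return xio.read_matrix(directory / files[label])

    betas, beads, detm, expr, dete = {}, {}, {}, {}, {}
    for tissue in config.tissues:
        betas[tissue] = mat(f"betas_{tissue}")
        beads[tissue] = mat(f"beadcounts_{tissue}")
        detm[tissue] = mat(f"detection_meth_{tissue}")
        expr[tissue] = mat(f"expression_{tissue}")
        dete[tissue] = mat(f"detection_expr_{tissue}")

    return SyntheticCohort(
        config=config,
        probes_meth=xio.read_probe_manifest(directory / files["probes_methylation"]),
        probes_expr=xio.read_probe_manifest(directory / files["probes_expression"]),
        betas=betas,
        beadcounts=beads,
        detection_meth=detm,
        expression=expr,
        detection_expr=dete,
        snps=xio.read_snp_table(directory / files["snps"]),
        cnv_segments=xio.read_bed(directory / files["cnv_index"], extra_columns=["copy_number"]),
        repeats=xio.read_repeat_table(directory / files["repeats"]),
        xci_peaks=xio.read_xci_peaks(directory / files["xci_peaks"]),
        metadata=xio.read_metadata(directory / files["metadata"]),
        truth=xio.read_json(directory / files["truth"]),
    )
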