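"""Singleton z statistics, comparison policy, phenotype and gene-set checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from xxyomics import (
    phenotype_outlier,
    phenotype_outlier_from_summary,
    reference_statistics,
    run_singleton_screen,
    singleton_z_test,
    gene_set_outlier_report,
)
from xxyomics.singleton import significant_sign_counts
from xxyomics.util import XXYomicsError


class TestReferenceStatistics:
    def test_closed_forms(self):
        m = pd.DataFrame({"a": [1.0, 5.0], "b": [2.0, 5.0], "c": [3.0, 5.0]}, index=["f1", "f2"])
        stats = reference_statistics(m, ["a", "b", "c"])
        assert stats.loc["f1", "mean_ref"] == pytest.approx(2.0)
        assert stats.loc["f1", "sd_ref"] == pytest.approx(1.0)
        assert stats.loc["f2", "sd_ref"] == 0.0  # constant feature

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 8)), columns=[f"s{i}" for i in range(8)])
        group = [f"s{i}" for i in range(5)]
        stats = reference_statistics(m, group)
        for feat in m.index:
            vals = [m.loc[feat, s] for s in group]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            assert stats.loc[feat, "mean_ref"] == pytest.approx(mean)
            assert stats.loc[feat, "sd_ref"] == pytest.approx(var**0.5)

    def test_too_small_group(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(XXYomicsError, match="at least 3"):
            reference_statistics(m, ["a", "b"])


class TestSingletonZ:
    def test_index_at_mean(self):
        z, p, effect = singleton_z_test(5.0, 5.0, 1.0)
        assert z == 0.0 and p == pytest.approx(1.0) and effect == 0.0

    def test_cerebellum_mass_arithmetic(self):
        z, p, effect = singleton_z_test(111.0, 170.0, 24.0)
        assert z == pytest.approx(-2.458, abs=0.001)
        assert effect == pytest.approx(-59.0)

    def test_normal_quantile_identity(self):
        _, p, _ = singleton_z_test(1.96, 0.0, 1.0)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_zero_sd_untestable(self):
        with pytest.raises(XXYomicsError, match="untestable"):
            singleton_z_test(1.0, 1.0, 0.0)

    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_equivariance(self, shift, scale):
        """Adding a constant leaves z unchanged; scaling scales the effect
        but not z."""
        z0, _, e0 = singleton_z_test(3.0, 1.0, 0.5)
        z1, _, e1 = singleton_z_test(3.0 + shift, 1.0 + shift, 0.5)
        z2, _, e2 = singleton_z_test(3.0 * scale, 1.0 * scale, 0.5 * scale)
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)
        assert z2 == pytest.approx(z0, rel=1e-9, abs=1e-9)
        assert e2 == pytest.approx(e0 * scale, rel=1e-9, abs=1e-9)


def _screen_fixture(effects, sd=0.03, n_per_sex=15, seed=0, chromosomes=None):
    """Gaussian matrix with an index column shifted by `effects` per feature."""
    rng = np.random.default_rng(seed)
    n_features = len(effects)
    males = [f"M{i}" for i in range(n_per_sex)]
    females = [f"F{i}" for i in range(n_per_sex)]
    samples = males + females + ["IDX"]
    base = rng.normal(0.5, 0.001, size=n_features)
    values = rng.normal(base[:, None], sd, size=(n_features, len(samples)))
    values[:, -1] = base + np.asarray(effects) + rng.normal(0, sd, n_features)
    matrix = pd.DataFrame(values, index=[f"f{i}" for i in range(n_features)], columns=samples)
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "reported_sex": ["M"] * n_per_sex + ["F"] * n_per_sex + ["M"],
        }
    )
    chroms = chromosomes or ["1"] * n_features
    manifest = pd.DataFrame(
        {
            "probe_id": matrix.index,
            "chromosome": chroms,
            "position": np.arange(n_features) * 1000 + 1,
        }
    )
    return matrix, metadata, manifest


class TestScreen:
    def test_policy_restricts_families(self):
        matrix, metadata, manifest = _screen_fixture([0.0, 0.0, 0.0], chromosomes=["1", "X", "Y"])
        out = run_singleton_screen(matrix, "IDX", metadata, manifest)
        by_feature = out.groupby("feature_id")["comparison"].apply(set)
        assert by_feature["f0"] == {"all", "males", "females"}
        assert by_feature["f1"] == {"females"}
        assert by_feature["f2"] == {"males"}

    def test_spiked_feature_significant_in_all_families(self):
        """Effect 0.5 at reference SD 0.03 is significant everywhere."""
        effects = [0.5] + [0.0] * 99
        matrix, metadata, manifest = _screen_fixture(effects)
        out = run_singleton_screen(matrix, "IDX", metadata, manifest)
        hit = out[(out["feature_id"] == "f0")]
        assert set(hit["comparison"]) == {"all", "males", "females"}
        assert hit["significant"].all()

    def test_bonferroni_is_per_family(self):
        matrix, metadata, manifest = _screen_fixture([0.0] * 10, chromosomes=["1"] * 5 + ["X"] * 5)
        out = run_singleton_screen(matrix, "IDX", metadata, manifest)
        females = out[out["comparison"] == "females"]
        assert (females["m_tests"] == 10).all()  # 5 autosomal + 5 X
        males = out[out["comparison"] == "males"]
        assert (males["m_tests"] == 5).all()

    def test_constant_feature_untestable_excluded_from_m(self):
        matrix, metadata, manifest = _screen_fixture([0.0] * 5)
        matrix.iloc[0] = 0.5  # exactly constant -> sd 0
        out = run_singleton_screen(matrix, "IDX", metadata, manifest)
        f0 = out[(out["feature_id"] == "f0") & (out["comparison"] == "all")].iloc[0]
        assert not f0["testable"] and np.isnan(f0["z"])
        assert (out.loc[out["comparison"] == "all", "m_tests"] == 4).all()

    def test_missing_index_errors(self):
        matrix, metadata, manifest = _screen_fixture([0.0])
        with pytest.raises(XXYomicsError, match="index sample"):
            run_singleton_screen(matrix, "NOPE", metadata, manifest)

    def test_sign_bookkeeping(self):
        effects = [0.5, -0.5, 0.4] + [0.0] * 50
        matrix, metadata, manifest = _screen_fixture(effects)
        out = run_singleton_screen(matrix, "IDX", metadata, manifest)
        counts = significant_sign_counts(out)
        for family, c in counts.items():
            assert c["up"] + c["down"] + c["zero"] == c["total"]
        assert counts["all"]["up"] >= 2 and counts["all"]["down"] >= 1

    def test_generator_spikes_recovered(self, default_cohort, pipeline_report):
        report, out_dir = pipeline_report
        sig = pd.read_csv(out_dir / "meth_screen_PFC.tsv", sep="\t")
        spiked = {
            s["feature_id"]
            for s in default_cohort.truth["spiked_features"]
            if s["tissue"] == "PFC" and s["kind"] == "methylation"
        }
        assert spiked <= set(sig["feature_id"])


class TestPhenotype:
    def test_printed_cerebellum_outlier(self):
        res = phenotype_outlier_from_summary(111.0, 170.0, 24.0)
        assert res["outlier"] and res["z"] < -2

    def test_printed_total_brain_mass_not_outlier(self):
        res = phenotype_outlier_from_summary(1417.0, 1410.0, 182.0)
        assert not res["outlier"]

    def test_value_at_mean(self):
        res = phenotype_outlier(5.0, [4.0, 5.0, 6.0, 5.0])
        assert res["z"] == pytest.approx(0.0)
        assert not res["outlier"]

    def test_zero_sd_untestable(self):
        with pytest.raises(XXYomicsError, match="untestable"):
            phenotype_outlier(1.0, [2.0, 2.0, 2.0])


class TestGeneSetReport:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=["feature_id", "gene", "tissue", "comparison", "z", "effect", "testable", "significant"],
        )

    def test_consistent_upregulation(self):
        rows = [
            (f"t{i}", "EIF1AX", tissue, comp, 4.0, 0.6, True, True)
            for i, (tissue, comp) in enumerate(
                [("PFC", "females"), ("CER", "females")]
            )
        ]
        out = gene_set_outlier_report(self._results(rows), {"escape": ["EIF1AX"]})
        assert (out["direction"] == "up").all()
        assert out["consistent"].all()

    def test_untestable_marked_missing_not_none(self):
        rows = [
            ("t1", "G1", "PFC", "all", 4.0, 0.5, True, True),
            ("t2", "G1", "CER", "all", np.nan, np.nan, False, False),
        ]
        out = gene_set_outlier_report(self._results(rows), {"s": ["G1"]})
        directions = dict(zip(out["tissue"], out["direction"]))
        assert directions["CER"] == "missing"
        assert directions["PFC"] == "up"

    def test_tissue_specific_par_gene(self):
        rows = [
            ("t1", "SLC25A6", "PFC", "females", 0.5, 0.01, True, False),
            ("t2", "SLC25A6", "CER", "females", 5.0, 0.5, True, True),
        ]
        out = gene_set_outlier_report(self._results(rows), {"par1": ["SLC25A6"]})
        directions = dict(zip(out["tissue"], out["direction"]))
        assert directions == {"PFC": "none", "CER": "up"}
        assert not out["consistent"].any()

    def test_empty_set_rejected(self):
        with pytest.raises(XXYomicsError, match="non-empty"):
            gene_set_outlier_report(self._results([]), {"s": []})
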