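"""Karyotype evidence channels and the integrated decision table."""

import numpy as np
import pandas as pd
import pytest

from xxyomics import (
    KaryotypeEvidence,
    assess_y_signal,
    call_karyotype,
    classify_xist,
    cluster_x_methylation,
    count_baf_bands,
    x_heterozygosity,
)
from xxyomics.util import XXYomicsError


def _karyotype_of(cohort, sample_id):
    meta = cohort.metadata.set_index("sample_id")
    return cohort.truth["karyotypes"][meta.loc[sample_id, "individual_id"]]


class TestXMethylationClustering:
    def test_generator_cohort_fully_separated(self, default_cohort):
        man = default_cohort.probes_meth.set_index("probe_id")
        x_ids = man.index[man["chromosome"] == "X"]
        betas = default_cohort.betas["PFC"]
        clusters = cluster_x_methylation(betas.loc[betas.index.intersection(x_ids)])
        for sample, row in clusters.iterrows():
            karyotype = _karyotype_of(default_cohort, sample)
            expected = "male-like" if karyotype == "46,XY" else "female-like"
            assert row["label"] == expected

    def test_xxy_index_clusters_with_females(self, default_cohort):
        man = default_cohort.probes_meth.set_index("probe_id")
        x_ids = man.index[man["chromosome"] == "X"]
        betas = default_cohort.betas["PFC"]
        clusters = cluster_x_methylation(betas.loc[betas.index.intersection(x_ids)])
        assert clusters.loc[f"{default_cohort.index_individual}_PFC", "label"] == "female-like"

    def test_identical_betas_indeterminate(self):
        betas = pd.DataFrame(0.5, index=[f"p{i}" for i in range(6)], columns=list("abcd"))
        clusters = cluster_x_methylation(betas)
        assert (clusters["label"] == "indeterminate").all()

    def test_preconditions(self):
        small = pd.DataFrame(0.5, index=["p1", "p2"], columns=list("abcd"))
        with pytest.raises(XXYomicsError, match="5 X probes"):
            cluster_x_methylation(small)


class TestXist:
    def test_bimodal_split(self, default_cohort):
        expr = default_cohort.expression["PFC"].loc["txXIST"]
        classes = classify_xist(expr)
        for sample, label in classes.items():
            karyotype = _karyotype_of(default_cohort, sample)
            assert label == ("low" if karyotype == "46,XY" else "high")

    def test_xxy_index_high(self, default_cohort):
        classes = classify_xist(default_cohort.expression["PFC"].loc["txXIST"])
        assert classes[f"{default_cohort.index_individual}_PFC"] == "high"

    def test_constant_indeterminate(self):
        classes = classify_xist(pd.Series(7.0, index=list("abcd")))
        assert (classes == "indeterminate").all()


class TestYSignal:
    def test_generator_cohort(self, default_cohort):
        man = default_cohort.probes_meth.set_index("probe_id")
        y_ids = man.index[man["chromosome"] == "Y"]
        det = default_cohort.detection_meth["PFC"]
        eman = default_cohort.probes_expr.set_index("probe_id")
        y_expr_ids = eman.index[eman["chromosome"] == "Y"]
        expr = default_cohort.expression["PFC"]
        out = assess_y_signal(det.loc[det.index.intersection(y_ids)], expr.loc[expr.index.intersection(y_expr_ids)])
        idx_sample = f"{default_cohort.index_individual}_PFC"
        assert bool(out.loc[idx_sample, "y_present"])
        for sample in out.index:
            karyotype = _karyotype_of(default_cohort, sample)
            if karyotype == "46,XX":
                assert not bool(out.loc[sample, "y_present"])

    def test_half_detected_boundary_inclusive(self):
        samples = ["m1", "m2", "s", "f1"]
        det = pd.DataFrame(0.9, index=[f"y{i}" for i in range(4)], columns=samples)
        det[["m1", "m2"]] = 0.001
        det.loc[["y0", "y1"], "s"] = 0.001  # exactly half of the Y probes
        expr = pd.DataFrame(
            {"m1": [8.0, 8.1], "m2": [8.1, 8.0], "s": [8.05, 8.05], "f1": [4.0, 4.1]},
            index=["e1", "e2"],
        )
        out = assess_y_signal(det, expr)
        assert bool(out.loc["s", "y_present"])
        assert not bool(out.loc["f1", "y_present"])

    def test_requires_y_probes(self):
        empty = pd.DataFrame(index=[], columns=["a", "b"], dtype=float)
        with pytest.raises(XXYomicsError, match="Y probes"):
            assess_y_signal(empty, empty)


class TestHeterozygosity:
    def test_counting(self):
        calls = ["AB"] * 30 + ["AA"] * 50 + ["BB"] * 20
        df = pd.DataFrame({"individual_id": "I1", "genotype": calls})
        assert x_heterozygosity(df)["I1"] == pytest.approx(0.30)

    def test_all_homozygous_zero(self):
        df = pd.DataFrame({"individual_id": "I1", "genotype": ["AA"] * 25})
        assert x_heterozygosity(df)["I1"] == 0.0

    def test_generator_rates_by_karyotype(self, default_cohort):
        het = x_heterozygosity(default_cohort.snps[default_cohort.snps["region"] == "X"])
        for ind, karyotype in default_cohort.truth["karyotypes"].items():
            if karyotype == "46,XY":
                assert het[ind] < 0.02
            else:
                assert het[ind] > 0.1

    def test_all_missing_errors(self):
        df = pd.DataFrame({"individual_id": "I1", "genotype": ["NC"] * 25})
        with pytest.raises(XXYomicsError, match="missing"):
            x_heterozygosity(df)


class TestBafBands:
    def test_diploid_three_bands(self):
        rng = np.random.default_rng(0)
        baf = np.concatenate(
            [np.zeros(100), np.full(100, 0.5), np.ones(100)]
        ) + rng.normal(0, 0.01, 300)
        count, centers = count_baf_bands(np.clip(baf, 0, 1))
        assert count == 3

    def test_trisomic_four_bands(self):
        rng = np.random.default_rng(1)
        baf = np.concatenate(
            [np.zeros(100), np.full(100, 1 / 3), np.full(100, 2 / 3), np.ones(100)]
        ) + rng.normal(0, 0.01, 400)
        count, centers = count_baf_bands(np.clip(baf, 0, 1))
        assert count == 4
        assert any(abs(c - 1 / 3) < 0.05 for c in centers)
        assert any(abs(c - 2 / 3) < 0.05 for c in centers)

    def test_all_zero_single_band(self):
        count, centers = count_baf_bands(np.zeros(300))
        assert count == 1

    def test_too_few_values(self):
        with pytest.raises(XXYomicsError, match="200"):
            count_baf_bands(np.zeros(100))

    def test_generator_band_counts(self, default_cohort):
        xtr = default_cohort.snps[default_cohort.snps["region"] == "XTR"]
        for ind, group in xtr.groupby("individual_id"):
            count, _ = count_baf_bands(group["baf"])
            karyotype = default_cohort.truth["karyotypes"][ind]
            assert count == (4 if karyotype == "47,XXY" else 3), ind


def _evidence(x="female-like", y=True, het=None, bands=None, xist="high"):
    return KaryotypeEvidence(
        x_meth_cluster=x, x_meth_score=0.3, xist_class=xist, y_present=y,
        x_het_rate=het, baf_band_count=bands,
    )


class TestCallKaryotype:
    @pytest.mark.parametrize(
        "evidence, reported, expected_call, expected_discordant",
        [
            (_evidence("female-like", True, het=0.25), "M", "47,XXY", False),
            (_evidence("female-like", True, het=None, bands=4), "M", "47,XXY", False),
            (_evidence("female-like", True, het=None, bands=None), "M", "47,XXY", False),
            (_evidence("female-like", True, het=0.005, bands=3), "M", "indeterminate", False),
            (_evidence("male-like", True), "M", "46,XY", False),
            (_evidence("female-like", False), "M", "46,XX", True),
            (_evidence("female-like", False), "F", "46,XX", False),
            (_evidence("male-like", False), "M", "indeterminate", False),
            (_evidence("indeterminate", True), "M", "indeterminate", False),
        ],
    )
    def test_decision_table(self, evidence, reported, expected_call, expected_discordant):
        call = call_karyotype(evidence, reported_sex=reported)
        assert call.call == expected_call
        assert call.discordant_with_reported_sex == expected_discordant

    def test_pure_function_of_evidence(self):
        ev = _evidence(het=0.3)
        a = call_karyotype(ev, reported_sex="M")
        b = call_karyotype(ev, reported_sex="M")
        assert a.call == b.call == "47,XXY"
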