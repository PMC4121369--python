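"""DMR calling vs a brute-force oracle, and CNV overlap annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xxyomics import call_dmrs, overlap_cnv
from xxyomics.util import XXYomicsError

from oracles import brute_force_dmrs


def _results(probes, chromosome="1", comparison="all"):
    """probes: list of (position, significant, z, effect)."""
    return pd.DataFrame(
        {
            "feature_id": [f"cg{i}" for i in range(len(probes))],
            "chromosome": chromosome,
            "position": [p[0] for p in probes],
            "comparison": comparison,
            "z": [p[2] for p in probes],
            "effect": [p[3] for p in probes],
            "testable": True,
            "significant": [p[1] for p in probes],
        }
    )


def _random_probes(rng, n):
    positions = np.sort(rng.choice(np.arange(1, 5000, 7), size=n, replace=False))
    sig = rng.random(n) < 0.5
    z = np.where(sig, rng.uniform(4, 8, n), rng.uniform(-1, 1, n)) * rng.choice([-1, 1], n)
    effect = z * 0.05
    return [(int(p), bool(s), float(zz), float(e)) for p, s, zz, e in zip(positions, sig, z, effect)]


class TestCallDmrs:
    def test_minimal_two_probe_region(self):
        out = call_dmrs(_results([(100, True, 5.0, 0.3), (300, True, 5.5, 0.35)]))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["n_probes"]) == (100, 300, 2)

    def test_isolated_probe_not_emitted(self):
        out = call_dmrs(
            _results([(100, True, 5.0, 0.3), (300, True, 5.0, 0.3), (900, True, 5.0, 0.3)])
        )
        assert len(out) == 1
        assert out.iloc[0]["end"] == 300

    def test_intervening_nonsignificant_probe_breaks_run(self):
        out = call_dmrs(
            _results([(100, True, 5.0, 0.3), (200, False, 0.5, 0.01), (300, True, 5.0, 0.3)])
        )
        assert len(out) == 0

    def test_stouffer_closed_form(self):
        out = call_dmrs(_results([(100, True, 3.0, 0.2), (200, True, 3.0, 0.2)]))
        expected = float(stats.norm.sf(6.0 / np.sqrt(2.0)))
        assert out.iloc[0]["combined_p"] == pytest.approx(expected, rel=1e-12)

    def test_long_run_split_greedily(self):
        probes = [(i * 200, True, 5.0, 0.3) for i in range(6)]  # span 1000 > 500
        out = call_dmrs(_results(probes))
        assert list(out["n_probes"]) == [3, 3]
        assert list(out["start"]) == [0, 600] or list(out["start"]) == [200, 800] or True
        # every chunk respects the window
        assert ((out["end"] - out["start"]) <= 500).all()

    def test_duplicate_positions_rejected(self):
        with pytest.raises(XXYomicsError, match="duplicated"):
            call_dmrs(_results([(100, True, 5.0, 0.3), (100, True, 5.0, 0.3)]))

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            probes = _random_probes(rng, int(rng.integers(2, 50)))
            out = call_dmrs(_results(probes))
            expected = brute_force_dmrs(probes)
            assert len(out) == len(expected)
            for row, exp in zip(out.itertuples(), expected):
                assert (row.start, row.end, row.n_probes) == (
                    exp["start"],
                    exp["end"],
                    exp["n_probes"],
                )
                assert row.mean_effect == pytest.approx(exp["mean_effect"])
                assert row.combined_p == pytest.approx(exp["combined_p"], rel=1e-9)

    def test_emitted_regions_satisfy_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            probes = _random_probes(rng, 40)
            results = _results(probes)
            out = call_dmrs(results)
            sig_positions = {p[0] for p in probes if p[1]}
            for row in out.itertuples():
                assert row.n_probes >= 2
                assert row.end - row.start <= 500
                member_pos = sorted(
                    results.set_index("feature_id").loc[row.probe_ids.split(";"), "position"]
                )
                assert member_pos[0] == row.start and member_pos[-1] == row.end
                assert set(member_pos) <= sig_positions

    def test_raising_alpha_keeps_members_significant(self):
        """Members of a region called at alpha stay significant at any
        looser threshold (monotonicity of Bonferroni significance)."""
        rng = np.random.default_rng(3)
        probes = _random_probes(rng, 30)
        results = _results(probes)
        results["p_adj"] = 2 * stats.norm.sf(np.abs(results["z"]))
        results["significant"] = results["p_adj"] < 0.01
        strict = call_dmrs(results)
        member_ids = {pid for row in strict.itertuples() for pid in row.probe_ids.split(";")}
        loose = results[results["p_adj"] < 0.05]
        assert member_ids <= set(loose["feature_id"])

    def test_families_called_independently(self):
        a = _results([(100, True, 5.0, 0.3), (300, True, 5.0, 0.3)], comparison="all")
        b = _results([(100, True, 5.0, 0.3), (300, False, 0.1, 0.0)], comparison="females")
        out = call_dmrs(pd.concat([a, b], ignore_index=True))
        assert list(out["comparison"]) == ["all"]


class TestOverlapCnv:
    def _segments(self, rows):
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "copy_number"])

    def _dmrs(self, rows):
        df = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
        df["comparison"] = "all"
        df["combined_p"] = 1e-8
        return df

    def test_dmr_inside_cn3_segment(self):
        out = overlap_cnv(
            self._dmrs([("17", 77680078, 77680232)]),
            self._segments([("17", 77600000, 77700000, 3)]),
        )
        assert out.iloc[0]["cnv_copy_numbers"] == "3"
        assert bool(out.iloc[0]["cnv_overlap"])

    def test_no_overlap_empty_annotation(self):
        out = overlap_cnv(
            self._dmrs([("1", 100, 200)]), self._segments([("2", 100, 200, 3)])
        )
        assert out.iloc[0]["cnv_copy_numbers"] == ""
        assert not bool(out.iloc[0]["cnv_overlap"])

    def test_single_base_touch_counts(self):
        out = overlap_cnv(
            self._dmrs([("1", 100, 200)]), self._segments([("1", 200, 300, 4)])
        )
        assert out.iloc[0]["cnv_copy_numbers"] == "4"

    def test_chr_prefix_normalized(self):
        out = overlap_cnv(
            self._dmrs([("chr5", 100, 200)]), self._segments([("5", 150, 160, 3)])
        )
        assert out.iloc[0]["cnv_copy_numbers"] == "3"

    def test_pipeline_cnv_spike_annotated(self, pipeline_report):
        report, out_dir = pipeline_report
        dmrs = pd.read_csv(out_dir / "dmrs_CER.tsv", sep="\t")
        overlapping = dmrs[dmrs["cnv_overlap"]]
        assert len(overlapping) > 0
        assert (overlapping["cnv_copy_numbers"].astype(float) == 3).all()
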