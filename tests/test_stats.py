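"""ROH summaries, burden regression, pedigree F, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rohmap.io import Pedigree, PhenotypeRecord
from rohmap.roh import ROHParams, ROHSegment, ROHSet, detect_roh
from rohmap.stats import (
    chromosome_homozygosity,
    compare_groups,
    pedigree_inbreeding,
    regress_phenotype_on_roh,
    summarize_roh,
)

from .conftest import DESK_ROH_PARAMS
from .oracles import naive_summaries


def _roh_set(segment_specs, sample_ids, marker_map):
    """segment_specs: (sample, chrom, first, last, start_bp, end_bp)."""
    segs = [
        ROHSegment(s, c, f, l, a, b, l - f + 1, 0, 0)
        for (s, c, f, l, a, b) in segment_specs
    ]
    return ROHSet(segs, ROHParams(min_snp=1, min_kb=0.001), list(sample_ids), marker_map)


@pytest.fixture
def simple_map():
    from rohmap.io import MarkerMap

    m = 200
    return MarkerMap(
        np.repeat([1, 2], m // 2),
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.concatenate([np.arange(1, m // 2 + 1), np.arange(1, m // 2 + 1)]) * 10_000,
    )


class TestSummaries:
    def test_two_segment_sample(self, simple_map):
        rs = _roh_set(
            [("a", 1, 0, 9, 10_000, 1_009_999), ("a", 2, 100, 119, 10_000, 3_009_999)],
            ["a", "b"],
            simple_map,
        )
        df = summarize_roh(rs).set_index("sample_id")
        assert df.loc["a", "n_segments"] == 2
        assert df.loc["a", "sum_kb"] == pytest.approx(4000.0)
        assert df.loc["a", "mean_kb"] == pytest.approx(2000.0)
        assert df.loc["a", "max_kb"] == pytest.approx(3000.0)

    def test_zero_segment_sample_present(self, simple_map):
        rs = _roh_set([], ["a", "b"], simple_map)
        df = summarize_roh(rs).set_index("sample_id")
        assert (df.loc["b"] == 0).all()

    def test_matches_naive_aggregation(self, tiny_sim):
        rs = detect_roh(tiny_sim["dataset"], DESK_ROH_PARAMS)
        df = summarize_roh(rs).set_index("sample_id")
        expected = naive_summaries(rs)
        for sample, (n, s, mean, mx, ssnp, msnp) in expected.items():
            row = df.loc[sample]
            assert row["n_segments"] == n
            assert row["sum_kb"] == pytest.approx(s)
            assert row["mean_kb"] == pytest.approx(mean)
            assert row["max_kb"] == pytest.approx(mx)
            assert row["sum_snp"] == ssnp and row["max_snp"] == msnp


class TestChromosomeHomozygosity:
    def test_quarter_coverage(self, simple_map):
        rs = _roh_set([("a", 1, 0, 9, 1, 25_000_000)], ["a"], simple_map)
        per_sample, mean, genome = chromosome_homozygosity(rs, {1: 100e6, 2: 100e6})
        assert per_sample.loc["a", 1] == pytest.approx(25.0)
        assert per_sample.loc["a", 2] == 0.0
        assert genome == pytest.approx(12.5)

    def test_matches_direct_summation(self, tiny_sim):
        rs = detect_roh(tiny_sim["dataset"], DESK_ROH_PARAMS)
        per_sample, _, _ = chromosome_homozygosity(rs)
        mm = rs.marker_map
        sample = rs.sample_ids[0]
        for chrom in (1, 2):
            sl = mm.chrom_slice(chrom)
            span = mm.position_bp[sl][-1] - mm.position_bp[sl][0] + 1
            direct = sum(
                s.length_bp
                for s in rs.segments
                if s.sample_id == sample and s.chromosome == chrom
            )
            assert per_sample.loc[sample, chrom] == pytest.approx(100 * direct / span)


class TestRegression:
    def test_noiseless_line_recovers_slope(self, simple_map):
        sums_kb = np.linspace(1000, 10_000, 10)
        summaries = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "n_segments": 1,
                "sum_kb": sums_kb,
                "mean_kb": sums_kb,
                "max_kb": sums_kb,
                "sum_snp": 10,
                "max_snp": 10,
            }
        )
        phen = [
            PhenotypeRecord(f"s{i}", 5.0 - 0.002 * (sums_kb[i] / 1000.0), 100)
            for i in range(10)
        ]
        r = regress_phenotype_on_roh(summaries, phen, "sum")
        assert r.beta == pytest.approx(-0.002)
        assert r.pearson_r == pytest.approx(-1.0)
        assert r.n == 10

    def test_constant_response_gives_zero_slope(self, simple_map):
        summaries = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "sum_kb": [1.0, 2.0, 3.0, 4.0],
                "mean_kb": 0.0,
                "max_kb": 0.0,
            }
        )
        phen = [PhenotypeRecord(s, 1.5, 10) for s in "abcd"]
        r = regress_phenotype_on_roh(summaries, phen, "sum")
        assert r.beta == pytest.approx(0.0) and r.pearson_r == 0.0

    def test_constant_metric_is_an_error(self):
        summaries = pd.DataFrame({"sample_id": list("abc"), "sum_kb": [5.0, 5.0, 5.0]})
        phen = [PhenotypeRecord(s, float(i), 10) for i, s in enumerate("abc")]
        with pytest.raises(ValueError, match="zero variance"):
            regress_phenotype_on_roh(summaries, phen, "sum")

    def test_kb_vs_mb_unit_consistency(self, rng):
        n = 60
        sums_kb = rng.uniform(1e3, 3e5, n)
        summaries = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "sum_kb": sums_kb})
        scr = -0.002 * sums_kb / 1000 + rng.normal(0, 2, n)
        phen = [PhenotypeRecord(f"s{i}", float(scr[i]), 10) for i in range(n)]
        r_mb = regress_phenotype_on_roh(summaries, phen, "sum")
        kb_version = summaries.assign(sum_kb=sums_kb * 1000)  # metric now in... x1000
        r_scaled = regress_phenotype_on_roh(kb_version, phen, "sum")
        assert r_scaled.beta * 1000 == pytest.approx(r_mb.beta)
        assert r_scaled.pearson_r == pytest.approx(r_mb.pearson_r)


class TestPedigreeF:
    def test_founder_is_zero(self):
        ped = Pedigree.from_records([("x", None, None)])
        assert pedigree_inbreeding(ped)["x"] == 0.0

    def test_full_sib_offspring(self):
        ped = Pedigree.from_records(
            [
                ("s", None, None),
                ("d", None, None),
                ("a", "s", "d"),
                ("b", "s", "d"),
                ("k", "a", "b"),
            ]
        )
        assert pedigree_inbreeding(ped)["k"] == pytest.approx(0.25)

    def test_half_sib_offspring(self):
        ped = Pedigree.from_records(
            [
                ("s", None, None),
                ("d1", None, None),
                ("d2", None, None),
                ("a", "s", "d1"),
                ("b", "s", "d2"),
                ("k", "a", "b"),
            ]
        )
        assert pedigree_inbreeding(ped)["k"] == pytest.approx(0.125)

    def test_cycle_detected(self):
        ped = Pedigree.from_records([("a", "b", None), ("b", "a", None)])
        with pytest.raises(ValueError, match="cycle"):
            pedigree_inbreeding(ped)

    def test_burden_correlates_with_pedigree_f(self, tiny_sim):
        """Genomic HBD burden tracks pedigree inbreeding in the simulator."""
        F = pedigree_inbreeding(tiny_sim["pedigree"])
        burden = tiny_sim["truth"].burden_mb
        common = burden.index
        f_vals = F.loc[common]
        if f_vals.std() > 0:
            r = np.corrcoef(f_vals, burden.loc[common])[0, 1]
            assert r > 0


class TestGroupComparison:
    def _summaries(self, values):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))], "mean_kb": values}
        )

    def test_identical_groups_null(self):
        s = self._summaries([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        c = compare_groups(s, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_matches_closed_form_welch(self, rng):
        hi = rng.normal(10, 1, 12)
        lo = rng.normal(20, 3, 9)
        s = self._summaries(np.concatenate([hi, lo]))
        c = compare_groups(s, [f"s{i}" for i in range(12)], [f"s{i}" for i in range(12, 21)])
        # closed-form Welch statistic
        se = np.sqrt(hi.var(ddof=1) / 12 + lo.var(ddof=1) / 9)
        t = (hi.mean() - lo.mean()) / se
        df = se**4 / (
            (hi.var(ddof=1) / 12) ** 2 / 11 + (lo.var(ddof=1) / 9) ** 2 / 8
        )
        assert c.statistic == pytest.approx(t)
        assert c.p_value == pytest.approx(2 * sps.t.sf(abs(t), df))
        assert c.mean_high == pytest.approx(hi.mean())
        assert c.mean_low == pytest.approx(lo.mean())

    def test_overlapping_groups_rejected(self):
        s = self._summaries([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(s, ["s0", "s1"], ["s1", "s2"])
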