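"""Extreme groups, consensus regions, and Fisher enrichment."""

import numpy as np
import pytest

from rohmap.enrichment import (
    build_consensus_regions,
    enrichment_scan,
    fisher_enrichment,
    min_attainable_p,
    select_extreme_groups,
)
from rohmap.io import MarkerMap, PhenotypeRecord
from rohmap.roh import ROHParams, ROHSegment, ROHSet, detect_roh

from .conftest import DESK_ROH_PARAMS
from .oracles import fisher_one_sided_exact, naive_marker_carriers


def _map(m=100, chrom=1):
    return MarkerMap(
        np.full(m, chrom, dtype=np.int64),
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.arange(1, m + 1, dtype=np.int64) * 1000,
    )


def _roh_set(spans, sample_ids, mm):
    """spans: (sample, first, last) on the single-chromosome map ``mm``."""
    segs = [
        ROHSegment(
            s, int(mm.chromosome[f]), f, l,
            int(mm.position_bp[f]), int(mm.position_bp[l]), l - f + 1, 0, 0,
        )
        for s, f, l in spans
    ]
    return ROHSet(segs, ROHParams(min_snp=1, min_kb=0.001), list(sample_ids), mm)


class TestExtremeGroups:
    def _records(self, scrs, breedings=None):
        breedings = breedings or [100] * len(scrs)
        return [
            PhenotypeRecord(f"s{i}", float(v), int(b))
            for i, (v, b) in enumerate(zip(scrs, breedings))
        ]

    def test_top_and_bottom(self):
        high, low = select_extreme_groups(self._records(range(1, 11)), 3)
        assert set(high) == {"s9", "s8", "s7"}
        assert set(low) == {"s0", "s1", "s2"}

    def test_tie_at_cutoff_prefers_more_breedings(self):
        recs = self._records([5, 4, 3, 3, 1, 0], breedings=[10, 10, 100, 900, 10, 10])
        high, _ = select_extreme_groups(recs, 3)
        assert "s3" in high and "s2" not in high

    def test_exact_partition(self):
        recs = self._records(range(6))
        high, low = select_extreme_groups(recs, 3)
        assert sorted(high + low) == [f"s{i}" for i in range(6)]

    def test_insufficient_samples(self):
        with pytest.raises(ValueError):
            select_extreme_groups(self._records(range(5)), 3)


class TestConsensus:
    def test_identical_roh_one_region(self):
        mm = _map()
        rs = _roh_set([("a", 0, 9), ("b", 0, 9)], ["a", "b"], mm)
        (region,) = build_consensus_regions(rs, min_snp=5, min_carriers=2)
        assert (region.first, region.last) == (0, 9)
        assert region.carrier_ids == frozenset({"a", "b"})

    def test_staggered_overlap(self):
        """A on markers 0-9, B on 5-14 -> shared region is markers 5-9."""
        mm = _map()
        rs = _roh_set([("a", 0, 9), ("b", 5, 14)], ["a", "b"], mm)
        (region,) = build_consensus_regions(rs, min_snp=5, min_carriers=2)
        assert (region.first, region.last) == (5, 9)
        assert region.n_snp == 5

    def test_disjoint_roh_no_shared_region(self):
        mm = _map()
        rs = _roh_set([("a", 0, 9), ("b", 20, 29)], ["a", "b"], mm)
        assert build_consensus_regions(rs, min_snp=1, min_carriers=2) == []

    def test_carrier_sets_match_per_marker_enumeration(self, tiny_sim):
        rs = detect_roh(tiny_sim["dataset"], DESK_ROH_PARAMS)
        regions = build_consensus_regions(rs, min_snp=1, min_carriers=1)
        mm = tiny_sim["dataset"].markers
        rng = np.random.default_rng(5)
        probe = rng.integers(0, mm.n_markers, 300)
        for marker in probe:
            containing = [r for r in regions if r.first <= marker <= r.last]
            truth = naive_marker_carriers(rs, int(marker))
            if containing:
                assert len(containing) == 1
                assert containing[0].carrier_ids == truth
            else:
                # with min_snp=1 and min_carriers=1, only carrier-free
                # markers fall outside every region
                assert truth == frozenset()

    def test_regions_disjoint_and_sorted(self, tiny_sim):
        rs = detect_roh(tiny_sim["dataset"], DESK_ROH_PARAMS)
        regions = build_consensus_regions(rs)
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for regs in by_chrom.values():
            for r1, r2 in zip(regs, regs[1:]):
                assert r1.end_bp < r2.start_bp


class TestFisher:
    def _region(self, carriers):
        mm = _map(10)
        from rohmap.enrichment import ConsensusRegion

        return ConsensusRegion(1, 1000, 5000, 0, 4, 5, frozenset(carriers))

    def test_small_table_exact(self):
        """a=3,b=0,c=0,d=3: p = C(3,3)C(3,0)/C(6,3) = 1/20."""
        region = self._region({"l1", "l2", "l3"})
        res = fisher_enrichment(region, ["l1", "l2", "l3"], ["h1", "h2", "h3"])
        assert res.p_value == pytest.approx(0.05, abs=1e-12)
        assert (res.a, res.b, res.c, res.d) == (3, 0, 0, 3)

    def test_no_carriers_p_one(self):
        region = self._region(set())
        res = fisher_enrichment(region, [f"l{i}" for i in range(5)], [f"h{i}" for i in range(5)])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_on_large_margins(self):
        region = self._region(
            {f"l{i}" for i in range(150)} | {f"h{i}" for i in range(80)}
        )
        low = [f"l{i}" for i in range(300)]
        high = [f"h{i}" for i in range(300)]
        res = fisher_enrichment(region, low, high)
        assert (res.a, res.b, res.c, res.d) == (150, 150, 80, 220)
        assert res.p_value == pytest.approx(fisher_one_sided_exact(150, 150, 80, 220), abs=1e-12)

    def test_monotone_in_low_carriers(self):
        """Moving a low-group sample from non-carrier to carrier never
        increases the enrichment p."""
        low = [f"l{i}" for i in range(20)]
        high = [f"h{i}" for i in range(20)]
        last = 1.1
        for a in range(0, 21):
            region = self._region(set(low[:a]) | set(high[:5]))
            p = fisher_enrichment(region, low, high).p_value
            assert p <= last + 1e-12
            last = p

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(self._region(set()), [], ["h1"])

    def test_odds_ratio_continuity_only_when_zero_cell(self):
        region = self._region({"l1", "l2", "h1"})
        res = fisher_enrichment(region, ["l1", "l2", "l3"], ["h1", "h2", "h3"])
        assert res.odds_ratio == pytest.approx((2 * 2) / (1 * 1))
        region0 = self._region({"l1", "l2", "l3"})
        res0 = fisher_enrichment(region0, ["l1", "l2", "l3"], ["h1", "h2", "h3"])
        assert res0.odds_ratio == pytest.approx((3.5 * 3.5) / (0.5 * 0.5))


class TestScan:
    def test_bonferroni_adjustment(self):
        mm = _map(1000)
        low = [f"l{i}" for i in range(10)]
        high = [f"h{i}" for i in range(10)]
        spans = []
        for k in range(60):
            first = k * 16
            for s in low[:3] + high[:3]:
                spans.append((s, first, first + 9))
        rs = _roh_set(spans, low + high, mm)
        results = enrichment_scan(
            build_consensus_regions(rs, min_snp=5, min_carriers=2), low, high
        )
        assert len(results) == 60
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 60 * r.p_value))
            assert r.significant == (r.p_adjusted <= 0.05)

    def test_smallest_attainable_p_bound(self):
        low = [f"l{i}" for i in range(12)]
        high = [f"h{i}" for i in range(10)]
        bound = min_attainable_p(12, 10)
        region = self._strong_region(low)
        p = fisher_enrichment(region, low, high).p_value
        assert p >= bound - 1e-15
        assert bound == pytest.approx(1 / 646646)

    def _strong_region(self, carriers):
        from rohmap.enrichment import ConsensusRegion

        return ConsensusRegion(1, 1000, 9000, 0, 8, 9, frozenset(carriers))

    def test_label_permutation_fpr_controlled(self, rng):
        """Random relabeling of the groups keeps the Bonferroni-significant
        fraction at or below alpha (within binomial error)."""
        mm = _map(2000)
        samples = [f"s{i}" for i in range(40)]
        spans = []
        for k in range(40):
            first = k * 45
            carriers = rng.choice(40, size=rng.integers(4, 20), replace=False)
            for ci in carriers:
                spans.append((samples[ci], first, first + 9))
        rs = _roh_set(spans, samples, mm)
        regions = build_consensus_regions(rs, min_snp=5, min_carriers=2)
        n_sig = 0
        n_tot = 0
        for _ in range(30):
            perm = rng.permutation(samples)
            low, high = list(perm[:20]), list(perm[20:])
            for res in enrichment_scan(regions, low, high, alpha=0.05):
                n_tot += 1
                n_sig += res.significant
        assert n_tot > 0
        # binomial slack at alpha=0.05
        assert n_sig / n_tot <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tot)
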