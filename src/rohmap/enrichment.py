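"""Consensus-ROH construction and enrichment testing in low-fertility bulls.

A consensus region is a maximal marker interval over which the set of animals
whose ROH covers every marker (the *carriers*) is constant.  Each region is
tested with a one-sided Fisher's exact test for an excess of carriers in the
low-fertility group, Bonferroni-corrected over the number of regions tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MarkerMap, PhenotypeRecord
from .roh import ROHSet


@dataclass(frozen=True)
class ConsensusRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    first: int  # global marker index
    last: int
    n_snp: int
    carrier_ids: frozenset

    def __post_init__(self) -> None:
        if self.n_snp != self.last - self.first + 1 or self.n_snp < 1:
            raise ValueError("region marker span inconsistent")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass(frozen=True)
class EnrichmentResult:
    region: ConsensusRegion
    a: int  # low-fertility carriers
    b: int  # low-fertility non-carriers
    c: int  # high-fertility carriers
    d: int  # high-fertility non-carriers
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None
    significant: bool | None = None


def select_extreme_groups(
    phenotypes: Iterable[PhenotypeRecord], n_per_group: int = 300
) -> tuple[list, list]:
    """Top and bottom ``n_per_group`` bulls of the SCR distribution.

    Ties at a cutoff admit the record with more breedings, then the smaller
    sample id.  Groups are disjoint by construction; a population smaller than
    ``2 * n_per_group`` is an error.
    """
    records = list(phenotypes)
    if len(records) < 2 * n_per_group:
        raise ValueError(
            f"need at least {2 * n_per_group} phenotyped samples, have {len(records)}"
        )
    high = sorted(records, key=lambda r: (-r.scr, -r.n_breedings, r.sample_id))
    high_ids = [r.sample_id for r in high[:n_per_group]]
    # the low group draws from the remainder so a tied band spanning both
    # cutoffs can never put one bull in both groups
    rest = high[n_per_group:]
    low = sorted(rest, key=lambda r: (r.scr, -r.n_breedings, r.sample_id))
    low_ids = [r.sample_id for r in low[:n_per_group]]
    return high_ids, low_ids


def build_consensus_regions(
    roh_set: ROHSet,
    marker_map: MarkerMap | None = None,
    min_snp: int = 5,
    min_carriers: int = 2,
) -> list:
    """Partition each chromosome at ROH boundaries into constant-carrier
    regions, merge adjacent intervals with identical carrier sets, and keep
    regions with at least ``min_carriers`` carriers and ``min_snp`` markers."""
    mm = marker_map if marker_map is not None else roh_set.marker_map
    regions: list = []
    by_chrom: dict = {}
    for seg in roh_set.segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom in sorted(by_chrom):
        sl = mm.chrom_slice(chrom)
        pos = mm.position_bp[sl]
        # carrier-set change points in local marker coordinates
        add: dict = {}
        remove: dict = {}
        cuts = set()
        for seg in by_chrom[chrom]:
            lo, hi = seg.first - sl.start, seg.last - sl.start
            add.setdefault(lo, []).append(seg.sample_id)
            remove.setdefault(hi + 1, []).append(seg.sample_id)
            cuts.add(lo)
            cuts.add(hi + 1)
        bounds = sorted(cuts)
        active: set = set()
        atoms: list = []  # (lo, hi_inclusive, frozenset carriers)
        for k, lo in enumerate(bounds[:-1]):
            # remove before add: back-to-back segments of one sample stay active
            active.difference_update(remove.get(lo, ()))
            active.update(add.get(lo, ()))
            hi = bounds[k + 1] - 1
            if active:
                atoms.append((lo, hi, frozenset(active)))
        # merge adjacent atoms with identical carrier sets
        merged: list = []
        for atom in atoms:
            if merged and merged[-1][2] == atom[2] and merged[-1][1] + 1 == atom[0]:
                merged[-1] = (merged[-1][0], atom[1], atom[2])
            else:
                merged.append(atom)
        for lo, hi, carriers in merged:
            n_snp = hi - lo + 1
            if len(carriers) >= min_carriers and n_snp >= min_snp:
                regions.append(
                    ConsensusRegion(
                        chromosome=int(chrom),
                        start_bp=int(pos[lo]),
                        end_bp=int(pos[hi]),
                        first=sl.start + lo,
                        last=sl.start + hi,
                        n_snp=n_snp,
                        carrier_ids=carriers,
                    )
                )
    regions.sort(key=lambda r: (r.chromosome, r.start_bp))
    return regions


def fisher_one_sided_p(a, b, c, d):
    """Upper-tail Fisher p for carrier excess in the low group.

    ``a``/``b``/``c``/``d`` are the 2x2 cells (low-carrier, low-noncarrier,
    high-carrier, high-noncarrier); numpy broadcasting is supported, so whole
    grids of tables can be evaluated in one call.
    """
    a = np.asarray(a)
    N = a + b + c + d
    K = a + c
    n1 = a + b
    p = np.minimum(sps.hypergeom.sf(a - 1, N, K, n1), 1.0)
    return float(p) if p.ndim == 0 else p


def fisher_enrichment(
    region: ConsensusRegion, low_ids: Sequence[str], high_ids: Sequence[str]
) -> EnrichmentResult:
    """One-sided Fisher's exact test for carrier excess in the low group.

    The p-value is the upper hypergeometric tail P(X >= a) with margins fixed
    at the group sizes and total carrier count.  The odds ratio (a*d)/(b*c)
    gets a 0.5 continuity addition to every cell only when some cell is zero;
    the correction never enters the p-value.
    """
    low, high = set(low_ids), set(high_ids)
    if not low or not high:
        raise ValueError("both fertility groups must be non-empty")
    if low & high:
        raise ValueError("fertility groups overlap")
    a = len(region.carrier_ids & low)
    c = len(region.carrier_ids & high)
    b = len(low) - a
    d = len(high) - c
    p = fisher_one_sided_p(a, b, c, d)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(region=region, a=a, b=b, c=c, d=d, odds_ratio=float(odds), p_value=p)


def min_attainable_p(n_low: int, n_high: int) -> float:
    """Lower bound on any one-sided Fisher p at the given group sizes:
    1 / C(n_low + n_high, n_low)."""
    return 1.0 / math.comb(n_low + n_high, n_low)


def enrichment_scan(
    regions: Sequence[ConsensusRegion],
    low_ids: Sequence[str],
    high_ids: Sequence[str],
    alpha: float = 0.05,
    min_snp_after: int | None = None,
) -> list:
    """Fisher-test every region and Bonferroni-adjust over the m regions
    tested; a region is significant when ``min(1, m*p) <= alpha``.

    By default the marker-count filter is applied when regions are built
    (before testing).  ``min_snp_after`` supports the alternative ordering
    in which all regions enter the Bonferroni family and short ones are
    dropped from the returned list only after testing.
    """
    m = len(regions)
    results = []
    for region in sorted(regions, key=lambda r: (r.chromosome, r.start_bp)):
        res = fisher_enrichment(region, low_ids, high_ids)
        p_adj = min(1.0, m * res.p_value)
        results.append(replace(res, p_adjusted=p_adj, significant=p_adj <= alpha))
    if min_snp_after is not None:
        results = [r for r in results if r.region.n_snp >= min_snp_after]
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Manhattan-style table: one row per region with -log10 p at its midpoint."""
    rows = []
    for r in results:
        reg = r.region
        rows.append(
            (
                reg.chromosome,
                reg.start_bp,
                reg.end_bp,
                reg.midpoint_bp,
                reg.n_snp,
                len(reg.carrier_ids),
                r.a,
                r.b,
                r.c,
                r.d,
                r.odds_ratio,
                r.p_value,
                -math.log10(r.p_value) if r.p_value > 0 else np.inf,
                r.p_adjusted,
                r.significant,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "midpoint_bp",
            "n_snp",
            "n_carriers",
            "low_carrier",
            "low_noncarrier",
            "high_carrier",
            "high_noncarrier",
            "odds_ratio",
            "p_value",
            "neg_log10_p",
            "p_adjusted",
            "significant",
        ],
    )
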