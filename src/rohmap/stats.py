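"""Per-animal ROH summaries, their association with fertility, pedigree
inbreeding, and extreme-group comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import Pedigree, PhenotypeRecord
from .roh import ROHSet

SUMMARY_COLUMNS = [
    "sample_id",
    "n_segments",
    "sum_kb",
    "mean_kb",
    "max_kb",
    "sum_snp",
    "max_snp",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS of SCR on an ROH burden metric (slope in SCR % per Mb)."""

    beta: float
    intercept: float
    se_beta: float
    t_value: float
    p_value: float
    pearson_r: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_high: float
    mean_low: float
    statistic: float
    p_value: float
    test: str = "welch"


def summarize_roh(roh_set: ROHSet) -> pd.DataFrame:
    """One row per sample in the universe (zero-segment samples included)."""
    rows = []
    for sample_id, segs in roh_set.by_sample().items():
        if segs:
            kb = np.array([s.length_kb for s in segs])
            snp = np.array([s.n_snp for s in segs])
            rows.append(
                (
                    sample_id,
                    len(segs),
                    kb.sum(),
                    kb.mean(),
                    kb.max(),
                    int(snp.sum()),
                    int(snp.max()),
                )
            )
        else:
            rows.append((sample_id, 0, 0.0, 0.0, 0.0, 0, 0))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def chromosome_homozygosity(
    roh_set: ROHSet, chrom_lengths: Mapping[int, float] | None = None
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Percent of each chromosome covered by ROH, per sample.

    Returns ``(per_sample, population_mean, genome_wide_mean)``.  Chromosome
    lengths default to the bp span of mapped markers; zero-length chromosomes
    are excluded with a warning.  The genome-wide value is the population mean
    of 100 * total ROH bp / total autosome bp.
    """
    mm = roh_set.marker_map
    chroms = [int(c) for c in mm.chromosomes()]
    if chrom_lengths is None:
        chrom_lengths = {}
        for c in chroms:
            sl = mm.chrom_slice(c)
            pos = mm.position_bp[sl]
            chrom_lengths[c] = float(pos[-1] - pos[0] + 1) if len(pos) else 0.0
    usable = []
    for c in chroms:
        if chrom_lengths.get(c, 0.0) <= 0:
            warnings.warn(f"chromosome {c} has zero length; excluded")
        else:
            usable.append(c)
    cover = pd.DataFrame(0.0, index=roh_set.sample_ids, columns=usable)
    for seg in roh_set.segments:
        if seg.chromosome in cover.columns:
            cover.loc[seg.sample_id, seg.chromosome] += seg.length_bp
    total_bp = sum(chrom_lengths[c] for c in usable)
    genome_pct = float((100.0 * cover.sum(axis=1) / total_bp).mean()) if total_bp else 0.0
    for c in usable:
        cover[c] = 100.0 * cover[c] / chrom_lengths[c]
    return cover, cover.mean(axis=0), genome_pct


def _metric_series(summaries: pd.DataFrame, metric: str) -> pd.Series:
    col = {"sum": "sum_kb", "mean": "mean_kb", "max": "max_kb"}.get(metric, metric)
    if col not in summaries.columns:
        raise KeyError(f"unknown ROH metric {metric!r}")
    return summaries.set_index("sample_id")[col]


def regress_phenotype_on_roh(
    summaries: pd.DataFrame,
    phenotypes: Iterable[PhenotypeRecord] | pd.DataFrame,
    metric: str = "sum",
) -> RegressionResult:
    """OLS of SCR on an ROH length metric, slope reported per Mb of ROH."""
    if not isinstance(phenotypes, pd.DataFrame):
        phenotypes = pd.DataFrame(
            [(r.sample_id, r.scr) for r in phenotypes], columns=["sample_id", "scr"]
        )
    scr = phenotypes.set_index("sample_id")["scr"]
    x_kb = _metric_series(summaries, metric)
    common = scr.index.intersection(x_kb.index)
    if len(common) < 3:
        raise ValueError("need at least 3 samples with both phenotype and summary")
    y = scr.loc[common].to_numpy(dtype=float)
    x_mb = x_kb.loc[common].to_numpy(dtype=float) / 1000.0
    if np.ptp(x_mb) == 0:
        raise ValueError(f"ROH metric {metric!r} has zero variance; slope undefined")
    fit = sm.OLS(y, sm.add_constant(x_mb)).fit()
    r = float(np.corrcoef(y, x_mb)[0, 1]) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        beta=float(fit.params[1]),
        intercept=float(fit.params[0]),
        se_beta=float(fit.bse[1]),
        t_value=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        pearson_r=r,
        n=len(common),
    )


def pedigree_inbreeding(pedigree: Pedigree) -> pd.Series:
    """Per-animal inbreeding coefficient F by the tabular (additive
    relationship) method: F(x) = kinship of x's parents; any animal with an
    unknown parent gets F = 0."""
    order = _topological_order(pedigree)
    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    F = np.zeros(n)
    for i, animal in enumerate(order):
        s, d = pedigree.parents(animal)
        si = index.get(s) if s is not None else None
        di = index.get(d) if d is not None else None
        if si is not None and di is not None:
            F[i] = 0.5 * A[si, di]
        A[i, i] = 1.0 + F[i]
        for j in range(i):
            a_js = A[j, si] if si is not None else 0.0
            a_jd = A[j, di] if di is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
    return pd.Series(F, index=list(order), name="F")


def _topological_order(pedigree: Pedigree) -> list:
    """Parents before offspring; raises on a pedigree cycle."""
    known = set(pedigree.ids)
    state: dict = {}
    order: list = []

    def visit(animal):
        if animal is None or animal not in known:
            return
        mark = state.get(animal)
        if mark == "done":
            return
        if mark == "active":
            raise ValueError(f"pedigree cycle involving {animal!r}")
        state[animal] = "active"
        s, d = pedigree.parents(animal)
        visit(s)
        visit(d)
        state[animal] = "done"
        order.append(animal)

    import sys

    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 10 * len(pedigree.ids) + 100))
    try:
        for a in pedigree.ids:
            visit(a)
    finally:
        sys.setrecursionlimit(limit)
    return order


def compare_groups(
    summaries: pd.DataFrame,
    high_ids: Sequence[str],
    low_ids: Sequence[str],
    metric: str = "mean",
    test: str = "welch",
) -> GroupComparison:
    """Compare an ROH metric between fertility groups (Welch t by default,
    Wilcoxon rank-sum with ``test='ranksum'``)."""
    high_ids, low_ids = list(high_ids), list(low_ids)
    if set(high_ids) & set(low_ids):
        raise ValueError("fertility groups overlap")
    if min(len(high_ids), len(low_ids)) < 2:
        raise ValueError("each group needs at least 2 samples")
    values = _metric_series(summaries, metric)
    hi = values.loc[high_ids].to_numpy(dtype=float)
    lo = values.loc[low_ids].to_numpy(dtype=float)
    if test == "welch":
        stat, p = sps.ttest_ind(hi, lo, equal_var=False)
        if np.isnan(stat):  # both groups constant
            stat, p = 0.0, 1.0
    elif test == "ranksum":
        stat, p = sps.mannwhitneyu(hi, lo, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        mean_high=float(hi.mean()),
        mean_low=float(lo.mean()),
        statistic=float(stat),
        p_value=float(p),
        test=test,
    )
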