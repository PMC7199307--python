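"""Sliding-window detection of runs of homozygosity (ROH).

The scanner mirrors the PLINK ``--homozyg`` procedure: slide a fixed-size
window of consecutive markers along each chromosome, call a window homozygous
when it holds at most ``window_max_het`` heterozygous and ``window_max_miss``
missing calls, and give every marker a hit fraction — the share of windows
containing it that are homozygous.  A marker enters a run when its hit
fraction reaches ``hit_threshold`` *and* its own call is homozygous and
non-missing.  Maximal runs of such markers are split at large inter-marker
gaps and filtered on marker count, physical length and SNP density.

Window sizes around 100 SNP are chosen so that a called run reflects
autozygosity (identity by descent) rather than chance identity by state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .io import MISSING, GenotypeDataset, MarkerMap

# guard against last-ulp effects when comparing hit counts to the threshold
_EPS = 1e-9


@dataclass(frozen=True)
class ROHParams:
    """Scanning parameters (PLINK 1.9 ``--homozyg`` defaults, 100-SNP window)."""

    window_snp: int = 100
    window_max_het: int = 1
    window_max_miss: int = 1
    hit_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snp <= 0 or self.min_snp <= 0:
            raise ValueError("window_snp and min_snp must be positive")
        if not (0.0 < self.hit_threshold <= 1.0):
            raise ValueError("hit_threshold must lie in (0, 1]")
        if self.window_max_het < 0 or self.window_max_miss < 0:
            raise ValueError("window allowances must be non-negative")
        if self.window_max_het + self.window_max_miss >= self.window_snp:
            raise ValueError("window allowances must total less than the window size")
        if min(self.min_kb, self.max_gap_kb, self.max_kb_per_snp) <= 0:
            raise ValueError("length thresholds must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: marker span (global indices) and 1-based bp span."""

    sample_id: str
    chromosome: int
    first: int
    last: int
    start_bp: int
    end_bp: int
    n_snp: int
    n_het: int
    n_miss: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp > end_bp")
        if self.n_snp != self.last - self.first + 1:
            raise ValueError("n_snp inconsistent with marker span")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class ROHSet:
    """All detected segments plus the parameters and sample universe used."""

    segments: list
    params: ROHParams
    sample_ids: list
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        universe = set(self.sample_ids)
        for seg in self.segments:
            if seg.sample_id not in universe:
                raise ValueError(f"segment sample {seg.sample_id!r} outside universe")

    def __len__(self) -> int:
        return len(self.segments)

    def by_sample(self) -> dict:
        out: dict = {s: [] for s in self.sample_ids}
        for seg in self.segments:
            out[seg.sample_id].append(seg)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (
                    s.sample_id,
                    s.chromosome,
                    s.first,
                    s.last,
                    s.start_bp,
                    s.end_bp,
                    s.length_kb,
                    s.n_snp,
                    s.n_het,
                    s.n_miss,
                )
                for s in self.segments
            ],
            columns=[
                "sample_id",
                "chromosome",
                "first",
                "last",
                "start_bp",
                "end_bp",
                "length_kb",
                "n_snp",
                "n_het",
                "n_miss",
            ],
        )


def window_is_homozygous(genotype_slice: Sequence[int], params: ROHParams) -> bool:
    """Window test: at most ``window_max_het`` hets and ``window_max_miss`` missing."""
    g = np.asarray(genotype_slice)
    if g.shape[-1] != params.window_snp:
        raise ValueError(
            f"window slice has {g.shape[-1]} markers, expected {params.window_snp}"
        )
    n_het = int((g == 1).sum())
    n_miss = int((g == MISSING).sum())
    return n_het <= params.window_max_het and n_miss <= params.window_max_miss


def _window_counts(calls: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window het and missing counts for every window of width ``w``.

    ``calls`` has shape (n_samples, m); returns two (n_samples, m - w + 1) arrays.
    """
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    chet = np.cumsum(het, axis=1)
    cmis = np.cumsum(mis, axis=1)
    zeros = np.zeros((calls.shape[0], 1), dtype=np.int32)
    chet = np.hstack([zeros, chet])
    cmis = np.hstack([zeros, cmis])
    return chet[:, w:] - chet[:, :-w], cmis[:, w:] - cmis[:, :-w]


def _hit_stats(calls: np.ndarray, params: ROHParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (homozygous-window hits, windows covering) on one chromosome.

    ``calls`` has shape (n_samples, m).  Windows are the ``m - w + 1``
    contiguous spans of ``w`` markers fully inside the chromosome; with fewer
    than ``w`` markers there are no windows and both outputs are zero.
    """
    n, m = calls.shape
    w = params.window_snp
    if m < w:
        return np.zeros((n, m), dtype=np.int64), np.zeros(m, dtype=np.int64)
    het_ct, mis_ct = _window_counts(calls, w)
    hom_win = (het_ct <= params.window_max_het) & (mis_ct <= params.window_max_miss)
    # windows containing marker i start in [max(0, i-w+1), min(i, m-w)]
    chw = np.cumsum(hom_win.astype(np.int64), axis=1)
    chw = np.hstack([np.zeros((n, 1), dtype=np.int64), chw])
    i = np.arange(m)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, m - w)
    hits = chw[:, hi + 1] - chw[:, lo]
    denom = hi - lo + 1
    return hits, denom


def snp_hit_fraction(sample_calls_on_chrom: Sequence[int], params: ROHParams) -> np.ndarray:
    """Fraction of homozygous windows overlapping each marker, one sample."""
    calls = np.asarray(sample_calls_on_chrom, dtype=np.int8).reshape(1, -1)
    if calls.shape[1] == 0:
        raise ValueError("chromosome has no markers")
    hits, denom = _hit_stats(calls, params)
    frac = np.zeros(calls.shape[1], dtype=float)
    nz = denom > 0
    frac[nz] = hits[0, nz] / denom[nz]
    return frac


def _runs_of_true(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (start, stop_exclusive) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def detect_roh(dataset: GenotypeDataset, params: ROHParams = ROHParams()) -> ROHSet:
    """Scan every sample and chromosome for runs of homozygosity."""
    segments: list = []
    markers = dataset.markers
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(int(chrom))
        calls = dataset.calls[:, sl]
        pos = markers.position_bp[sl]
        hits, denom = _hit_stats(calls, params)
        # marked: hit fraction >= threshold (integer-safe) and own call homozygous
        covered = denom > 0
        frac_ok = hits >= params.hit_threshold * denom - _EPS
        frac_ok &= covered[None, :]
        own_hom = (calls == 0) | (calls == 2)
        marked = frac_ok & own_hom
        gap_kb = np.diff(pos) / 1000.0
        big_gap = gap_kb > params.max_gap_kb
        for si, sample_id in enumerate(dataset.sample_ids):
            row = marked[si]
            for start, stop in _runs_of_true(row):
                # split the run at inter-marker gaps above max_gap_kb
                cut_points = [start]
                if stop - start > 1:
                    cuts = np.flatnonzero(big_gap[start : stop - 1]) + start + 1
                    cut_points.extend(int(c) for c in cuts)
                cut_points.append(stop)
                for a, b in itertools.pairwise(cut_points):
                    seg = _make_segment(
                        sample_id, int(chrom), sl.start, a, b, pos, calls[si], params
                    )
                    if seg is not None:
                        segments.append(seg)
    segments.sort(key=lambda s: (s.sample_id, s.chromosome, s.start_bp))
    return ROHSet(
        segments=segments,
        params=params,
        sample_ids=list(dataset.sample_ids),
        marker_map=markers,
    )


def _make_segment(
    sample_id: str,
    chrom: int,
    offset: int,
    a: int,
    b: int,
    pos: np.ndarray,
    sample_calls: np.ndarray,
    params: ROHParams,
):
    """Apply the length/density filters to the candidate run [a, b)."""
    n_snp = b - a
    if n_snp < params.min_snp:
        return None
    start_bp, end_bp = int(pos[a]), int(pos[b - 1])
    length_kb = (end_bp - start_bp + 1) / 1000.0
    if length_kb < params.min_kb:
        return None
    if length_kb / n_snp > params.max_kb_per_snp:
        return None
    span = sample_calls[a:b]
    return ROHSegment(
        sample_id=sample_id,
        chromosome=chrom,
        first=offset + a,
        last=offset + b - 1,
        start_bp=start_bp,
        end_bp=end_bp,
        n_snp=n_snp,
        n_het=int((span == 1).sum()),
        n_miss=int((span == MISSING).sum()),
    )
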