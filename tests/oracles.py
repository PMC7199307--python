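"""Independent brute-force oracles used by the tests.

Everything here enumerates directly from definitions — every window, every
marker, every 2x2 table — with no incremental tricks, so the production code
can be checked segment-for-segment against it.
"""

from __future__ import annotations

import math

from rohmap.io import MISSING


def naive_window_is_hom(window, params) -> bool:
    n_het = sum(1 for g in window if g == 1)
    n_mis = sum(1 for g in window if g == MISSING)
    return n_het <= params.window_max_het and n_mis <= params.window_max_miss


def _enumerate_windows(calls, params):
    """Homozygosity verdict for every window, each summed independently
    (direct enumeration; no running sums carried between windows)."""
    import numpy as np
    from numpy.lib.stride_tricks import sliding_window_view

    w = params.window_snp
    views = sliding_window_view(np.asarray(calls, dtype=np.int8), w)
    n_het = (views == 1).sum(axis=1)
    n_mis = (views == MISSING).sum(axis=1)
    return (n_het <= params.window_max_het) & (n_mis <= params.window_max_miss)


def naive_hit_fractions(calls, params):
    """Per-marker homozygous-window fraction for one sample's chromosome,
    by slicing out the covering windows of each marker."""
    m = len(calls)
    w = params.window_snp
    if m < w:
        return [0.0] * m
    windows = _enumerate_windows(calls, params)
    fracs = []
    for i in range(m):
        lo, hi = max(0, i - w + 1), min(i, m - w)  # windows containing marker i
        covering = windows[lo : hi + 1]
        fracs.append(float(covering.sum()) / len(covering))
    return fracs


def naive_detect_roh(dataset, params):
    """Enumerate-everything ROH detection.

    Returns a set of tuples (sample_id, chromosome, first, last, n_snp,
    start_bp, end_bp, n_het, n_miss) with global marker indices.
    """
    mm = dataset.markers
    out = set()
    chroms = sorted(set(int(c) for c in mm.chromosome))
    for si, sample in enumerate(dataset.sample_ids):
        for chrom in chroms:
            idx = [j for j in range(mm.n_markers) if mm.chromosome[j] == chrom]
            calls = [int(dataset.calls[si, j]) for j in idx]
            pos = [int(mm.position_bp[j]) for j in idx]
            m = len(calls)
            w = params.window_snp
            windows = _enumerate_windows(calls, params) if m >= w else []
            marked = []
            for i in range(m):
                if m >= w:
                    lo, hi = max(0, i - w + 1), min(i, m - w)
                    covering = windows[lo : hi + 1]
                    frac_ok = (
                        covering.sum() >= params.hit_threshold * len(covering) - 1e-9
                    )
                else:
                    frac_ok = False
                marked.append(bool(frac_ok) and calls[i] in (0, 2))
            # maximal runs of marked markers, split at big gaps
            runs = []
            start = None
            for i in range(m + 1):
                if i < m and marked[i]:
                    if start is None:
                        start = i
                    elif pos[i] - pos[i - 1] > params.max_gap_kb * 1000.0:
                        runs.append((start, i - 1))
                        start = i
                elif start is not None:
                    runs.append((start, i - 1))
                    start = None
            for a, b in runs:
                n_snp = b - a + 1
                length_kb = (pos[b] - pos[a] + 1) / 1000.0
                if n_snp < params.min_snp:
                    continue
                if length_kb < params.min_kb:
                    continue
                if length_kb / n_snp > params.max_kb_per_snp:
                    continue
                span = calls[a : b + 1]
                out.add(
                    (
                        sample,
                        chrom,
                        idx[a],
                        idx[b],
                        n_snp,
                        pos[a],
                        pos[b],
                        sum(1 for g in span if g == 1),
                        sum(1 for g in span if g == MISSING),
                    )
                )
    return out


def roh_set_as_tuples(roh_set):
    return {
        (
            s.sample_id,
            s.chromosome,
            s.first,
            s.last,
            s.n_snp,
            s.start_bp,
            s.end_bp,
            s.n_het,
            s.n_miss,
        )
        for s in roh_set.segments
    }


def naive_marker_carriers(roh_set, marker_index: int) -> frozenset:
    """Samples whose ROH covers the given global marker index."""
    return frozenset(
        s.sample_id for s in roh_set.segments if s.first <= marker_index <= s.last
    )


def fisher_one_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by full enumeration over tables with the same margins,
    using exact integer binomials."""
    N = a + b + c + d
    K = a + c
    n1 = a + b
    denom = math.comb(N, n1)
    num = sum(
        math.comb(K, j) * math.comb(N - K, n1 - j)
        for j in range(a, min(K, n1) + 1)
        if n1 - j >= 0
    )
    return num / denom


def gls_closed_form(y, X, V):
    """(X' V^-1 X)^-1 X' V^-1 y and its standard errors, straight from the
    definition."""
    import numpy as np

    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    b = C @ X.T @ Vi @ y
    return b, np.sqrt(np.diag(C))


def naive_summaries(roh_set):
    """Per-sample aggregation by plain iteration."""
    out = {}
    for sample in roh_set.sample_ids:
        segs = [s for s in roh_set.segments if s.sample_id == sample]
        if segs:
            kb = [s.length_kb for s in segs]
            snp = [s.n_snp for s in segs]
            out[sample] = (
                len(segs),
                sum(kb),
                sum(kb) / len(kb),
                max(kb),
                sum(snp),
                max(snp),
            )
        else:
            out[sample] = (0, 0.0, 0.0, 0.0, 0, 0)
    return out


def random_roh_dataset(rng, max_samples=30, max_markers=3000, n_chrom=None):
    """A random genotype dataset with implanted homozygous stretches so that
    detection actually fires."""
    import numpy as np

    from rohmap.io import GenotypeDataset, MarkerMap

    n = int(rng.integers(2, max_samples + 1))
    m = int(rng.integers(200, max_markers + 1))
    n_chrom = n_chrom or int(rng.integers(1, 4))
    chrom_of = np.sort(rng.integers(1, n_chrom + 1, m))
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        sel = chrom_of == c
        gaps = rng.integers(1000, 30000, sel.sum())
        pos[sel] = np.cumsum(gaps)
    ids = np.array([f"m{j}" for j in range(m)], dtype=object)
    markers = MarkerMap(chrom_of, ids, pos)
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8), size=(n, m), p=[0.42, 0.12, 0.42, 0.04]
    )
    # implant homozygous stretches
    for si in range(n):
        for _ in range(int(rng.integers(0, 4))):
            L = min(int(rng.integers(30, 400)), m)
            a = int(rng.integers(0, m - L + 1))
            block = rng.choice(np.array([0, 2], dtype=np.int8), size=L)
            noise = rng.random(L)
            block[noise < 0.01] = 1
            block[(noise >= 0.01) & (noise < 0.02)] = MISSING
            calls[si, a : a + L] = block
    return GenotypeDataset([f"s{i}" for i in range(n)], markers, calls)


def random_roh_params(rng):
    from rohmap.roh import ROHParams

    window = int(rng.integers(5, 26))
    max_het = int(rng.integers(0, 3))
    max_miss = int(rng.integers(0, 3))
    return ROHParams(
        window_snp=window,
        window_max_het=min(max_het, window - 2),
        window_max_miss=min(max_miss, window - 2 - min(max_het, window - 2)),
        hit_threshold=float(rng.uniform(0.02, 0.3)),
        min_snp=int(rng.integers(10, 61)),
        min_kb=float(rng.uniform(50, 400)),
        max_gap_kb=float(rng.uniform(100, 2000)),
        max_kb_per_snp=float(rng.uniform(20, 80)),
    )
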