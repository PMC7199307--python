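"""Gene-dropping simulator with exact identity-by-descent truth.

Founder haplotypes are drawn marker-by-marker from per-marker allele
frequencies and carry unique labels.  Offspring gametes are formed by
recombining parental haplotypes (crossover count Poisson in the chromosome's
map length, positions uniform), with both alleles *and* labels inherited
through the same crossovers — so homozygosity by descent (HBD) is read off
exactly as the marker spans where an individual's two labels agree.

Mating loops (a sire chosen among the dam's half/full sibs) generate long
autozygous tracts like those arising from recent common ancestors in real
cattle pedigrees; background relatedness comes from the small founder pool.

An SCR-like phenotype is layered on top:

    scr_i = mu + beta_sum * HBD_Mb_i + sum_r delta_r * carrier_r(i) + g_i + e_i

with g ~ N(0, G sigma_g2) using the realized genomic relationship matrix and
e ~ N(0, sigma_e2).  Defaults emulate the study conditions at desk scale:
29 chromosomes at real array density (~10 kb/SNP), an SCR sd near 2%, low
heritability as expected of a male-fertility trait, and a burden slope of
-0.002 SCR % per Mb.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gblup import compute_grm
from .io import (
    MISSING,
    GenotypeDataset,
    MarkerMap,
    Pedigree,
    PhenotypeRecord,
    write_genotypes,
    write_pedigree,
    write_phenotypes,
)


@dataclass(frozen=True)
class PlantedRegion:
    """A recessive-effect region: carriers are made homozygous by descent
    across the marker span and their SCR shifts by ``effect``."""

    chromosome: int
    start_marker: int  # local index within the chromosome
    end_marker: int  # inclusive
    effect: float  # SCR %
    carrier_fraction: float = 0.15


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 29
    markers_per_chromosome: int = 1000
    marker_spacing_kb: float = 10.0  # mean of exponential inter-marker gaps
    founder_freq_range: tuple = (0.05, 0.5)
    n_samples: int = 600  # final-generation (genotyped) animals
    n_founders: int = 40
    n_generations: int = 5
    loop_rate: float = 0.2  # fraction of matings between sibs/half-sibs
    map_length_morgans: float = 1.0
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    mu: float = 0.0
    beta_sum: float = -0.002  # SCR % per Mb of HBD burden
    planted_regions: tuple = ()
    sigma_g2: float = 0.4
    sigma_e2: float = 3.6
    grm_marker_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.loop_rate, self.genotyping_error_rate, self.missing_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder_freq_range must satisfy 0 < lo <= hi < 1")
        for r in self.planted_regions:
            if not (1 <= r.chromosome <= self.n_chromosomes):
                raise ValueError("planted region chromosome outside the map")
            if not (0 <= r.start_marker <= r.end_marker < self.markers_per_chromosome):
                raise ValueError("planted region markers outside the chromosome map")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["planted_regions"] = [asdict(r) for r in self.planted_regions]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    tracts: pd.DataFrame  # sample_id, chromosome, first, last, start_bp, end_bp, n_markers
    burden_mb: pd.Series  # per-sample HBD burden, Mb
    planted_carriers: dict  # region index -> list of carrier ids
    seed: int
    realized_effects: pd.DataFrame | None = None  # filled by simulate_phenotypes


# ---------------------------------------------------------------------------


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> MarkerMap:
    chroms, ids, pos = [], [], []
    for c in range(1, cfg.n_chromosomes + 1):
        gaps = rng.exponential(cfg.marker_spacing_kb * 1000.0, cfg.markers_per_chromosome)
        p = np.cumsum(np.maximum(1, gaps.round().astype(np.int64)))
        chroms.extend([c] * cfg.markers_per_chromosome)
        pos.extend(p.tolist())
        ids.extend(f"snp{c}_{j}" for j in range(cfg.markers_per_chromosome))
    return MarkerMap(
        np.asarray(chroms, dtype=np.int64),
        np.asarray(ids, dtype=object),
        np.asarray(pos, dtype=np.int64),
    )


def _gamete_sources(
    n: int, marker_morgans: list, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Which parental haplotype (0/1) each of ``n`` gametes copies at every
    marker.  Crossover counts are Poisson in the chromosome map length with
    uniform positions; the starting haplotype is fair."""
    total = sum(len(cm) for cm in marker_morgans)
    src = np.empty((n, total), dtype=np.int8)
    L = cfg.map_length_morgans
    start = 0
    for cm in marker_morgans:
        m = len(cm)
        k = rng.poisson(L, n)
        kmax = max(int(k.max()) if n else 0, 1)
        xo = rng.uniform(0.0, L, (n, kmax))
        xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
        crosses = (xo[:, :, None] <= cm[None, None, :]).sum(axis=1)
        first = rng.integers(0, 2, n)
        src[:, start : start + m] = (first[:, None] + crosses) % 2
        start += m
    return src


def _choose_parents(
    prev_ids: list,
    prev_sex: np.ndarray,
    pedigree: Pedigree,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Indices (sire, dam) into the previous generation; with probability
    ``loop_rate`` the sire shares a parent with the dam."""
    males = np.flatnonzero(prev_sex == 0)
    females = np.flatnonzero(prev_sex == 1)
    dam_i = int(rng.choice(females))
    sire_i = None
    if rng.random() < cfg.loop_rate:
        dam_parents = {p for p in pedigree.parents(prev_ids[dam_i]) if p is not None}
        if dam_parents:
            related = [
                i
                for i in males
                if dam_parents
                & {p for p in pedigree.parents(prev_ids[i]) if p is not None}
            ]
            if related:
                sire_i = int(rng.choice(np.asarray(related)))
    if sire_i is None:
        sire_i = int(rng.choice(males))
    return sire_i, dam_i


def simulate_genotypes(
    config: SimConfig,
) -> tuple[GenotypeDataset, Pedigree, SimTruth]:
    """Drop founder haplotypes through a looped pedigree and emit genotypes,
    the pedigree, and exact HBD truth for the final generation."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    total = markers.n_markers

    # per-chromosome marker positions on the genetic map (uniform cM/bp)
    marker_morgans = []
    for c in range(1, cfg.n_chromosomes + 1):
        sl = markers.chrom_slice(c)
        pos = markers.position_bp[sl].astype(float)
        span = pos[-1] - pos[0] + 1.0
        marker_morgans.append((pos - pos[0]) / span * cfg.map_length_morgans)

    freqs = rng.uniform(*cfg.founder_freq_range, total)

    # founders
    n_f = cfg.n_founders
    alleles = (rng.random((n_f, 2, total)) < freqs).astype(np.uint8)
    labels = np.arange(2 * n_f, dtype=np.int16).reshape(n_f, 2)[:, :, None] * np.ones(
        (1, 1, total), dtype=np.int16
    )
    ids = [f"G0_{i}" for i in range(n_f)]
    sex = rng.integers(0, 2, n_f)
    sex[: max(1, n_f // 2)] = 0  # guarantee both sexes
    sex[max(1, n_f // 2) :] = 1
    ped_rows = [(i, None, None) for i in ids]
    pedigree = Pedigree.from_records(ped_rows)

    for gen in range(1, cfg.n_generations + 1):
        n_next = cfg.n_samples
        next_ids = [f"G{gen}_{i}" for i in range(n_next)]
        next_sex = rng.integers(0, 2, n_next)
        next_sex[0], next_sex[1] = 0, 1  # both sexes always present
        sire_idx = np.empty(n_next, dtype=int)
        dam_idx = np.empty(n_next, dtype=int)
        for i in range(n_next):
            sire_idx[i], dam_idx[i] = _choose_parents(ids, sex, pedigree, cfg, rng)
            pedigree.ids.append(next_ids[i])
            pedigree.sire[next_ids[i]] = ids[sire_idx[i]]
            pedigree.dam[next_ids[i]] = ids[dam_idx[i]]
        next_alleles = np.empty((n_next, 2, total), dtype=np.uint8)
        next_labels = np.empty((n_next, 2, total), dtype=np.int16)
        for slot, par_idx in ((0, sire_idx), (1, dam_idx)):
            src = _gamete_sources(n_next, marker_morgans, cfg, rng)
            pa = alleles[par_idx]  # (n, 2, total)
            pl = labels[par_idx]
            next_alleles[:, slot, :] = np.where(src == 0, pa[:, 0, :], pa[:, 1, :])
            next_labels[:, slot, :] = np.where(src == 0, pl[:, 0, :], pl[:, 1, :])
        alleles, labels, ids, sex = next_alleles, next_labels, next_ids, next_sex

    # planted recessive regions: copy haplotype 0 over haplotype 1
    planted_carriers: dict = {}
    for ri, region in enumerate(cfg.planted_regions):
        sl = markers.chrom_slice(region.chromosome)
        lo = sl.start + region.start_marker
        hi = sl.start + region.end_marker + 1
        n_carriers = int(round(region.carrier_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_carriers, replace=False)
        for i in chosen:
            alleles[i, 1, lo:hi] = alleles[i, 0, lo:hi]
            labels[i, 1, lo:hi] = labels[i, 0, lo:hi]
        planted_carriers[ri] = sorted(ids[i] for i in chosen)

    # HBD truth from label identity
    tract_rows = []
    burden_bp = np.zeros(len(ids))
    for c in range(1, cfg.n_chromosomes + 1):
        sl = markers.chrom_slice(c)
        pos = markers.position_bp[sl]
        eq = labels[:, 0, sl] == labels[:, 1, sl]
        for i, sample in enumerate(ids):
            idx = np.flatnonzero(eq[i])
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[idx[0]], idx[breaks + 1]])
            stops = np.concatenate([idx[breaks], [idx[-1]]])
            for a, b in zip(starts, stops):
                tract_rows.append(
                    (
                        sample,
                        c,
                        sl.start + int(a),
                        sl.start + int(b),
                        int(pos[a]),
                        int(pos[b]),
                        int(b - a + 1),
                    )
                )
                burden_bp[i] += pos[b] - pos[a] + 1
    tracts = pd.DataFrame(
        tract_rows,
        columns=["sample_id", "chromosome", "first", "last", "start_bp", "end_bp", "n_markers"],
    )

    calls = (alleles[:, 0, :] + alleles[:, 1, :]).astype(np.int8)

    # genotyping error: replace with one of the other two codes
    if cfg.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING

    dataset = GenotypeDataset(ids, markers, calls)
    truth = SimTruth(
        tracts=tracts,
        burden_mb=pd.Series(burden_bp / 1e6, index=ids, name="burden_mb"),
        planted_carriers=planted_carriers,
        seed=cfg.seed,
    )
    return dataset, pedigree, truth


def simulate_phenotypes(
    dataset: GenotypeDataset, truth: SimTruth, config: SimConfig
) -> tuple[list, SimTruth]:
    """Draw SCR records for the genotyped animals (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    ids = dataset.sample_ids
    n = len(ids)
    burden = truth.burden_mb.loc[ids].to_numpy()
    scr = cfg.mu + cfg.beta_sum * burden
    carrier_effect = np.zeros(n)
    for ri, region in enumerate(cfg.planted_regions):
        carriers = set(truth.planted_carriers.get(ri, ()))
        ind = np.array([s in carriers for s in ids], dtype=float)
        carrier_effect += region.effect * ind
    scr = scr + carrier_effect
    g = np.zeros(n)
    if cfg.sigma_g2 > 0:
        grm = compute_grm(dataset, marker_step=cfg.grm_marker_step)
        G = grm.matrix + 1e-6 * np.eye(n)
        L = np.linalg.cholesky(G)
        g = np.sqrt(cfg.sigma_g2) * (L @ rng.standard_normal(n))
    e = np.sqrt(cfg.sigma_e2) * rng.standard_normal(n) if cfg.sigma_e2 > 0 else np.zeros(n)
    scr = scr + g + e
    # breedings span the range observed in real SCR releases
    n_breedings = np.exp(rng.uniform(np.log(300), np.log(136001), n)).astype(int)
    records = [
        PhenotypeRecord(s, float(v), int(nb)) for s, v, nb in zip(ids, scr, n_breedings)
    ]
    truth.realized_effects = pd.DataFrame(
        {
            "sample_id": ids,
            "burden_term": cfg.beta_sum * burden,
            "region_term": carrier_effect,
            "polygenic": g,
            "residual": e,
            "scr": scr,
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# fixture profiles
# ---------------------------------------------------------------------------

PROFILES: dict = {
    "tiny": SimConfig(
        n_chromosomes=5,
        markers_per_chromosome=400,
        n_samples=50,
        n_founders=12,
        n_generations=3,
        loop_rate=0.3,
        planted_regions=(PlantedRegion(1, 100, 249, effect=-3.0, carrier_fraction=0.2),),
    ),
    "desk": SimConfig(
        planted_regions=(PlantedRegion(1, 400, 699, effect=-3.0, carrier_fraction=0.15),),
    ),
}


def make_fixture(profile_name: str, out_dir, seed: int | None = None) -> dict:
    """Write a named simulation profile to disk (PED/MAP, BED set, phenotype,
    pedigree and truth TSVs, plus a manifest with the seed and config hash)."""
    if profile_name not in PROFILES:
        raise ValueError(f"unknown profile {profile_name!r}; have {sorted(PROFILES)}")
    cfg = PROFILES[profile_name]
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, pedigree, truth = simulate_genotypes(cfg)
    records, truth = simulate_phenotypes(dataset, truth, cfg)
    write_genotypes(dataset, out / "genotypes", format="ped")
    write_genotypes(dataset, out / "genotypes", format="bed")
    write_phenotypes(records, out / "phenotypes.tsv")
    write_pedigree(pedigree, out / "pedigree.tsv")
    truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
    truth.burden_mb.rename_axis("sample_id").reset_index().to_csv(
        out / "truth_burden.tsv", sep="\t", index=False, float_format="%.6g"
    )
    manifest = {
        "profile": profile_name,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_samples": cfg.n_samples,
        "n_markers": dataset.n_markers,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
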