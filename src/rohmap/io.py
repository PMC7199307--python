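"""Readers and writers for the file formats the pipeline touches.

Genotypes travel as PLINK text (PED/MAP) or binary (BED/BIM/FAM, SNP-major
v1.00).  Calls are stored as an ``int8`` matrix counting copies of a per-marker
reference allele: 0, 1, 2 or :data:`MISSING`.  The reference allele is the
first allele encountered in a PED file, or BIM A1 — run-of-homozygosity logic
only distinguishes hom / het / missing, so the orientation is arbitrary and
must not matter downstream.

Coordinates are 1-based inclusive base pairs internally (the PLINK ``.hom``
convention); BED3 export converts to 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class FileFormatError(ValueError):
    """A malformed input file (names the file, and the line when known)."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Sorted marker map: chromosome, marker id and 1-based bp position.

    Markers are sorted by (chromosome, position) with strictly increasing
    positions within a chromosome, and ids are unique.
    """

    chromosome: np.ndarray  # int
    marker_id: np.ndarray  # str (object dtype)
    position_bp: np.ndarray  # int64

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        ids = np.asarray(self.marker_id, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "marker_id", ids)
        object.__setattr__(self, "position_bp", pos)
        if not (len(chrom) == len(ids) == len(pos)):
            raise ValueError("marker map arrays have unequal lengths")
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids are not unique")
        key = np.lexsort((pos, chrom))
        if not np.array_equal(key, np.arange(len(pos))):
            raise ValueError("markers are not sorted by (chromosome, position)")
        same = chrom[1:] == chrom[:-1]
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise ValueError("positions not strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.position_bp)

    @property
    def n_markers(self) -> int:
        return len(self)

    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome labels, in map order."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(idx)]

    def chrom_slice(self, chrom: int) -> slice:
        """Contiguous index slice of one chromosome's markers."""
        lo = int(np.searchsorted(self.chromosome, chrom, side="left"))
        hi = int(np.searchsorted(self.chromosome, chrom, side="right"))
        return slice(lo, hi)

    def index_of(self, marker_id: str) -> int:
        hits = np.nonzero(self.marker_id == marker_id)[0]
        if len(hits) == 0:
            raise KeyError(marker_id)
        return int(hits[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "marker_id": self.marker_id,
                "position_bp": self.position_bp,
            }
        )


@dataclass(frozen=True)
class GenotypeDataset:
    """Samples x markers diploid call matrix plus its marker map."""

    sample_ids: list
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "sample_ids", list(self.sample_ids))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        if calls.shape != (len(self.sample_ids), self.markers.n_markers):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.sample_ids)}, {self.markers.n_markers})"
            )
        ok = (calls == MISSING) | ((calls >= 0) & (calls <= 2))
        if not ok.all():
            raise ValueError("genotype codes outside {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One sire-conception-rate record: SCR in percent, number of breedings."""

    sample_id: str
    scr: float
    n_breedings: int

    def __post_init__(self) -> None:
        if self.n_breedings < 1:
            raise ValueError(f"n_breedings must be >= 1, got {self.n_breedings}")


@dataclass
class Pedigree:
    """Three-column pedigree; unknown parents are None."""

    ids: list
    sire: dict = field(default_factory=dict)  # id -> sire id or None
    dam: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, rows: Iterable[tuple]) -> "Pedigree":
        ids, sire, dam = [], {}, {}
        for animal, s, d in rows:
            ids.append(animal)
            sire[animal] = s
            dam[animal] = d
        return cls(ids, sire, dam)

    def parents(self, animal: str) -> tuple:
        return self.sire.get(animal), self.dam.get(animal)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------


def _read_map(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chroms, ids, pos = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FileFormatError(f"{path}: line {lineno}: expected 4 MAP columns")
            try:
                chroms.append(int(parts[0]))
                pos.append(int(parts[3]))
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {lineno}: {exc}") from None
            ids.append(parts[1])
    return (
        np.asarray(chroms, dtype=np.int64),
        np.asarray(ids, dtype=object),
        np.asarray(pos, dtype=np.int64),
    )


def _sorted_dataset(
    sample_ids: Sequence[str],
    chroms: np.ndarray,
    ids: np.ndarray,
    pos: np.ndarray,
    calls: np.ndarray,
) -> GenotypeDataset:
    order = np.lexsort((pos, chroms))
    markers = MarkerMap(chroms[order], ids[order], pos[order])
    return GenotypeDataset(list(sample_ids), markers, calls[:, order])


def _read_ped_map(ped_path: Path, map_path: Path) -> GenotypeDataset:
    chroms, ids, pos = _read_map(map_path)
    n_markers = len(ids)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    ref_allele: list = [None] * n_markers
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise FileFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} "
                    f"fields for {n_markers} markers, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            row = np.empty(n_markers, dtype=np.int8)
            alleles = parts[6:]
            for j in range(n_markers):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":  # any half-missing call is missing
                    row[j] = MISSING
                    continue
                if ref_allele[j] is None:
                    ref_allele[j] = a
                row[j] = (a == ref_allele[j]) + (b == ref_allele[j])
                if row[j] == 0 and a != b:
                    row[j] = 1  # het written with neither allele == ref yet seen
            rows.append(row)
    calls = (
        np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8)
    )
    return _sorted_dataset(sample_ids, chroms, ids, pos, calls)


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP with alleles A (reference) and B."""
    m = dataset.markers
    with open(map_path, "w") as fh:
        for c, i, p in zip(m.chromosome, m.marker_id, m.position_bp):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    code_to_field = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for s, row in zip(dataset.sample_ids, dataset.calls):
            fields = [s, s, "0", "0", "0", "-9"]
            fields.extend(code_to_field[int(g)] for g in row)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM (SNP-major v1.00)
# ---------------------------------------------------------------------------

# 2-bit codes in .bed: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Our call counts A1 copies, so: 0b00 -> 2, 0b10 -> 1, 0b11 -> 0, 0b01 -> MISSING.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _read_bed_bim_fam(bed_path: Path, bim_path: Path, fam_path: Path) -> GenotypeDataset:
    with open(fam_path) as fh:
        sample_ids = [line.split()[1] for line in fh if line.strip()]
    chroms, ids, pos = [], [], []
    with open(bim_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise FileFormatError(f"{bim_path}: line {lineno}: expected 6 BIM columns")
            chroms.append(int(parts[0]))
            ids.append(parts[1])
            pos.append(int(parts[3]))
    n, m = len(sample_ids), len(ids)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FileFormatError(f"{bed_path}: invalid BED magic bytes (expected SNP-major v1.00)")
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != m * bytes_per_marker:
        raise FileFormatError(
            f"{bed_path}: body has {len(body)} bytes, expected {m * bytes_per_marker} "
            f"for {n} samples x {m} markers"
        )
    body = body.reshape(m, bytes_per_marker)
    # unpack the four 2-bit fields of every byte, little-end first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    calls = _BED_DECODE[codes].T.astype(np.int8)  # (n, m)
    return _sorted_dataset(
        sample_ids,
        np.asarray(chroms, dtype=np.int64),
        np.asarray(ids, dtype=object),
        np.asarray(pos, dtype=np.int64),
        calls,
    )


def write_bed_bim_fam(dataset: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    with open(fam_path, "w") as fh:
        for s in dataset.sample_ids:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    m = dataset.markers
    with open(bim_path, "w") as fh:
        for c, i, p in zip(m.chromosome, m.marker_id, m.position_bp):
            fh.write(f"{c}\t{i}\t0\t{p}\tA\tB\n")
    n = dataset.n_samples
    bytes_per_marker = (n + 3) // 4
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(dataset.n_markers):
            col = dataset.calls[:, j]
            codes = np.empty(n, dtype=np.uint8)
            codes[col == 2] = 0b00
            codes[col == MISSING] = 0b01
            codes[col == 1] = 0b10
            codes[col == 0] = 0b11
            padded = np.zeros(bytes_per_marker * 4, dtype=np.uint8)
            padded[:n] = codes
            packed = (
                padded[0::4]
                | (padded[1::4] << 2)
                | (padded[2::4] << 4)
                | (padded[3::4] << 6)
            )
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# public genotype entry points
# ---------------------------------------------------------------------------


def read_genotypes(prefix_or_paths, format: str = "auto") -> GenotypeDataset:
    """Read a genotype dataset from PLINK files.

    Parameters
    ----------
    prefix_or_paths
        Either a path prefix (``data`` for ``data.ped``/``data.map`` or
        ``data.bed``/``.bim``/``.fam``) or an explicit tuple of paths.
    format
        ``"ped"``, ``"bed"`` or ``"auto"`` (detect by which files exist).
    """
    if isinstance(prefix_or_paths, (tuple, list)):
        paths = [Path(p) for p in prefix_or_paths]
        if len(paths) == 2:
            return _read_ped_map(*paths)
        if len(paths) == 3:
            return _read_bed_bim_fam(*paths)
        raise ValueError("expected (ped, map) or (bed, bim, fam) paths")
    prefix = Path(prefix_or_paths)
    if format == "auto":
        format = "bed" if prefix.with_suffix(".bed").exists() else "ped"
    if format == "ped":
        return _read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    if format == "bed":
        return _read_bed_bim_fam(
            prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
        )
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(dataset: GenotypeDataset, prefix, format: str = "ped") -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "ped":
        write_ped_map(dataset, prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    elif format == "bed":
        write_bed_bim_fam(
            dataset, prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
        )
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotypes & pedigree
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> list:
    """Read a header-named TSV of SCR records (sample_id, scr, n_breedings).

    No de-duplication happens here; repeated bulls come back as repeated
    records (see :func:`rohmap.qc.dedupe_phenotypes`).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "scr", "n_breedings"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), 2):  # header is line 1
        try:
            scr = float(row.scr)
            nb = int(row.n_breedings)
            records.append(PhenotypeRecord(str(row.sample_id), scr, nb))
        except (TypeError, ValueError) as exc:
            raise FileFormatError(f"{path}: line {i}: {exc}") from None
    return records


def write_phenotypes(records: Iterable[PhenotypeRecord], path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.scr, r.n_breedings) for r in records],
        columns=["sample_id", "scr", "n_breedings"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pedigree(path) -> Pedigree:
    """Read a TSV pedigree with columns id, sire_id, dam_id ('0' = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "sire_id", "dam_id"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column {col!r}")
    rows = []
    for row in df.itertuples(index=False):
        s = None if row.sire_id in ("0", "NA", None) or pd.isna(row.sire_id) else row.sire_id
        d = None if row.dam_id in ("0", "NA", None) or pd.isna(row.dam_id) else row.dam_id
        rows.append((row.id, s, d))
    return Pedigree.from_records(rows)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire_id\tdam_id\n")
        for animal in ped.ids:
            s, d = ped.parents(animal)
            fh.write(f"{animal}\t{s or 0}\t{d or 0}\n")


# ---------------------------------------------------------------------------
# ROH tables and BED3 regions
# ---------------------------------------------------------------------------

_HOM_COLUMNS = [
    "sample_id",
    "chromosome",
    "snp1",
    "snp2",
    "pos1_bp",
    "pos2_bp",
    "length_kb",
    "n_snp",
    "n_het",
    "n_miss",
]


def write_roh_table(roh_set, path) -> None:
    """Write a PLINK ``.hom``-style TSV (1-based inclusive bp, kb lengths)."""
    from .roh import ROHSet  # local import to avoid a cycle

    assert isinstance(roh_set, ROHSet)
    rows = []
    ids = roh_set.marker_map.marker_id
    for seg in roh_set.segments:
        rows.append(
            (
                seg.sample_id,
                seg.chromosome,
                ids[seg.first],
                ids[seg.last],
                seg.start_bp,
                seg.end_bp,
                f"{seg.length_kb:.3f}",
                seg.n_snp,
                seg.n_het,
                seg.n_miss,
            )
        )
    pd.DataFrame(rows, columns=_HOM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_roh_table(path, marker_map: MarkerMap, params=None, sample_ids=None):
    """Read a ``.hom``-style table back into an :class:`~rohmap.roh.ROHSet`."""
    from .roh import ROHParams, ROHSegment, ROHSet

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    id_to_idx = {mid: i for i, mid in enumerate(marker_map.marker_id)}
    segments = []
    for row in df.itertuples(index=False):
        try:
            first, last = id_to_idx[row.snp1], id_to_idx[row.snp2]
        except KeyError as exc:
            raise FileFormatError(f"{path}: unknown marker id {exc}") from None
        segments.append(
            ROHSegment(
                sample_id=str(row.sample_id),
                chromosome=int(row.chromosome),
                first=first,
                last=last,
                start_bp=int(row.pos1_bp),
                end_bp=int(row.pos2_bp),
                n_snp=int(row.n_snp),
                n_het=int(row.n_het),
                n_miss=int(row.n_miss),
            )
        )
    if sample_ids is None:
        sample_ids = sorted({s.sample_id for s in segments})
    return ROHSet(
        segments=segments,
        params=params if params is not None else ROHParams(),
        sample_ids=list(sample_ids),
        marker_map=marker_map,
    )


def write_regions_bed(regions, path) -> None:
    """Write consensus regions as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\n")
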