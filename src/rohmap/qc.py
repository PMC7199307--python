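"""Marker-level quality control and phenotype de-duplication.

Markers are removed when they map off the 29 bovine autosomes, have a call
rate <= 0.95, or a minor allele frequency <= 0.05 — removal at equality is
deliberate.  A bull with several fertility evaluations keeps the record with
the most breedings (the most reliable one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import MISSING, GenotypeDataset, MarkerMap, PhenotypeRecord

DEFAULT_AUTOSOMES = tuple(range(1, 30))


@dataclass(frozen=True)
class QCReport:
    n_markers_in: int
    n_removed_nonautosomal: int
    n_removed_callrate: int
    n_removed_maf: int
    n_markers_out: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_nonautosomal + self.n_removed_callrate + self.n_removed_maf
        )
        if self.n_markers_out != self.n_markers_in - removed:
            raise ValueError("QC report counts do not balance")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def marker_frequencies(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (reference allele frequency, call rate) from non-missing calls.

    Markers with no non-missing calls get frequency NaN and call rate 0.
    """
    calls = dataset.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    dosage_sum = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, dosage_sum / (2.0 * np.maximum(n_obs, 1)), np.nan)
    call_rate = n_obs / max(dataset.n_samples, 1)
    return freq, call_rate


def apply_marker_qc(
    dataset: GenotypeDataset,
    maf_max_removed: float = 0.05,
    callrate_max_removed: float = 0.95,
    autosomes: Sequence[int] = DEFAULT_AUTOSOMES,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove markers failing the autosome / call-rate / MAF predicates.

    A retained marker satisfies ``chromosome in autosomes`` and
    ``call_rate > callrate_max_removed`` and ``maf > maf_max_removed``.
    For the report each removed marker is counted once, with precedence
    non-autosomal > call rate > MAF.  A marker with zero non-missing calls
    falls under the call-rate rule.
    """
    calls = dataset.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    dosage = np.where(obs, calls, 0).sum(axis=0)
    minor_count = np.minimum(dosage, 2 * n_obs - dosage)
    autosomal = np.isin(dataset.markers.chromosome, np.asarray(list(autosomes)))
    # boundary cases (MAF or call rate exactly at the threshold) must be
    # removed; compare in integer count space to dodge rounding
    callrate_ok = n_obs > callrate_max_removed * dataset.n_samples + 1e-9
    maf_ok = minor_count > maf_max_removed * 2 * n_obs + 1e-9

    keep = autosomal & callrate_ok & maf_ok
    n_nonauto = int((~autosomal).sum())
    n_callrate = int((autosomal & ~callrate_ok).sum())
    n_maf = int((autosomal & callrate_ok & ~maf_ok).sum())

    markers = dataset.markers
    kept_map = MarkerMap(
        markers.chromosome[keep], markers.marker_id[keep], markers.position_bp[keep]
    )
    out = GenotypeDataset(dataset.sample_ids, kept_map, dataset.calls[:, keep])
    report = QCReport(
        n_markers_in=dataset.n_markers,
        n_removed_nonautosomal=n_nonauto,
        n_removed_callrate=n_callrate,
        n_removed_maf=n_maf,
        n_markers_out=int(keep.sum()),
    )
    return out, report


def dedupe_phenotypes(records: Iterable[PhenotypeRecord]) -> list:
    """Keep one record per bull: most breedings, ties by larger \\|SCR\\|,
    remaining ties by input order."""
    best: dict = {}
    for pos, rec in enumerate(records):
        key = (-rec.n_breedings, -abs(rec.scr), pos)
        if rec.sample_id not in best or key < best[rec.sample_id][0]:
            best[rec.sample_id] = (key, rec)
    return [kr[1] for kr in best.values()]
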