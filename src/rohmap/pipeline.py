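"""End-to-end orchestration: QC -> ROH detection -> summaries -> extreme
groups -> consensus regions -> enrichment scan -> mixed-model validation.

All result tables are written as TSV with floats rounded at write time, so a
rerun with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import gblup, io, qc, roh, stats

logger = logging.getLogger("rohmap")

FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genotypes: str = ""
    genotype_format: str = "auto"
    phenotypes: str = ""
    pedigree: str | None = None
    out_dir: str = "rohmap_out"
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    maf_max_removed: float = 0.05
    callrate_max_removed: float = 0.95
    autosomes: tuple = tuple(range(1, 30))
    n_per_group: int = 300
    consensus_min_snp: int = 5
    consensus_min_carriers: int = 2
    alpha: float = 0.05
    t_threshold: float = 2.0
    grm_marker_step: int = 1
    variance_mode: str = "reml"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        roh_raw = raw.pop("roh_params", {})
        cfg = cls(**raw)
        cfg.roh_params = roh.ROHParams(**roh_raw)
        return cfg

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["autosomes"] = list(self.autosomes)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all result tables under ``config.out_dir``.

    Returns a bundle dict with the in-memory objects and output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": out}
    log_lines = [f"config: {dataclasses.asdict(config)}"]

    def stage(name: str, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    dataset = stage(
        "read_genotypes",
        lambda: io.read_genotypes(config.genotypes, format=config.genotype_format),
    )
    records = stage("read_phenotypes", lambda: io.read_phenotypes(config.phenotypes))

    def _qc():
        ds, report = qc.apply_marker_qc(
            dataset,
            maf_max_removed=config.maf_max_removed,
            callrate_max_removed=config.callrate_max_removed,
            autosomes=config.autosomes,
        )
        report.to_tsv(out / "qc_report.tsv")
        return ds, report

    dataset_qc, qc_report = stage("qc", _qc)
    records = stage("dedupe_phenotypes", lambda: qc.dedupe_phenotypes(records))

    roh_set = stage("detect_roh", lambda: roh.detect_roh(dataset_qc, config.roh_params))
    stage("write_roh", lambda: io.write_roh_table(roh_set, out / "roh.hom.tsv"))

    summaries = stage("summarize", lambda: stats.summarize_roh(roh_set))
    _write(summaries, out / "roh_summary.tsv")
    per_sample, per_chrom, genome_pct = stage(
        "chromosome_homozygosity", lambda: stats.chromosome_homozygosity(roh_set)
    )
    per_chrom.rename_axis("chromosome").rename("homozygosity_pct").reset_index().to_csv(
        out / "chromosome_homozygosity.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    def _regress():
        rows = []
        for metric in ("sum", "mean", "max"):
            try:
                r = stats.regress_phenotype_on_roh(summaries, records, metric)
            except ValueError as exc:
                logger.warning("regression on %s skipped: %s", metric, exc)
                continue
            rows.append((metric, r.beta, r.intercept, r.se_beta, r.t_value, r.p_value, r.pearson_r, r.n))
        return pd.DataFrame(
            rows,
            columns=["metric", "beta_per_mb", "intercept", "se", "t_value", "p_value", "pearson_r", "n"],
        )

    regression = stage("regression", _regress)
    _write(regression, out / "regression.tsv")

    high_ids, low_ids = stage(
        "select_groups", lambda: enr.select_extreme_groups(records, config.n_per_group)
    )
    pd.DataFrame(
        [("high", s) for s in high_ids] + [("low", s) for s in low_ids],
        columns=["group", "sample_id"],
    ).to_csv(out / "groups.tsv", sep="\t", index=False)

    def _compare():
        rows = []
        for metric in ("mean", "sum"):
            c = stats.compare_groups(summaries, high_ids, low_ids, metric)
            rows.append((metric, c.mean_high, c.mean_low, c.statistic, c.p_value))
        return pd.DataFrame(
            rows, columns=["metric", "mean_high", "mean_low", "t_statistic", "p_value"]
        )

    _write(stage("compare_groups", _compare), out / "group_comparison.tsv")

    regions = stage(
        "consensus",
        lambda: enr.build_consensus_regions(
            roh_set,
            min_snp=config.consensus_min_snp,
            min_carriers=config.consensus_min_carriers,
        ),
    )
    io.write_regions_bed(regions, out / "consensus_regions.bed")

    results = stage(
        "enrichment", lambda: enr.enrichment_scan(regions, low_ids, high_ids, config.alpha)
    )
    enrich_df = enr.enrichment_table(results)
    _write(enrich_df, out / "enrichment.tsv")

    significant = [r.region for r in results if r.significant]
    grm = stage(
        "grm", lambda: gblup.compute_grm(dataset_qc, marker_step=config.grm_marker_step)
    )
    pheno_df = pd.DataFrame(
        [(r.sample_id, r.scr) for r in records], columns=["sample_id", "scr"]
    )
    variance_mode = config.variance_mode
    validation = stage(
        "validate",
        lambda: gblup.validate_regions(
            significant,
            roh_set,
            pheno_df,
            grm,
            t_threshold=config.t_threshold,
            variance_mode=variance_mode,
        ),
    )
    _write(validation, out / "validation.tsv")

    log_lines.append(f"markers after qc: {qc_report.n_markers_out}")
    log_lines.append(f"roh segments: {len(roh_set)}")
    log_lines.append(f"consensus regions: {len(regions)}")
    log_lines.append(f"significant regions: {len(significant)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    config.to_yaml(out / "config_used.yaml")

    bundle.update(
        dataset=dataset_qc,
        qc_report=qc_report,
        roh_set=roh_set,
        summaries=summaries,
        chromosome_homozygosity=per_chrom,
        genome_homozygosity_pct=genome_pct,
        regression=regression,
        groups=(high_ids, low_ids),
        regions=regions,
        enrichment=enrich_df,
        validation=validation,
        grm=grm,
    )
    return bundle
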