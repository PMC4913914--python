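"""End-to-end pipeline: QC -> filter -> adjust -> DE -> consensus -> classify -> enrich.

A :class:`PipelineConfig` (loadable from YAML) names the inputs and
thresholds; :func:`run_pipeline` executes the stages in order, writes
every intermediate to the run directory, and stamps each output with the
config hash and seed so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import diffexpr, enrich, io, preprocess

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and resampling sizes for a pipeline run."""

    matrix: str = ""
    sheet: str = ""
    gmt: str = ""                 # optional; enrichment runs only if set
    out_dir: str = "progmark_run"
    min_rin: float = 6.0
    drop_fraction: float = 0.15
    remove_outliers: bool = True
    batch_key: str = "batch"
    covariates: tuple[str, ...] = ("age", "gender")
    p_anova: float = 0.05
    p_boot: float = 0.005
    p_perm: float = 0.05
    B_boot: int = 1000
    B_perm: int = 10000
    kappa_threshold: float = 0.4
    k_clusters: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the analysis, not where it lands
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage order: RIN filter -> PCA outlier removal -> variance pre-filter
    -> empirical-Bayes batch/covariate adjustment -> three-test DE ->
    consensus -> signature clustering classification -> (optional)
    over-representation against a GMT collection.  A stage failure raises
    with the stage name; all randomness flows from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed}
    (out / "run_info.json").write_text(
        json.dumps({**stamp, "config": asdict(config)}, indent=2, default=str)
    )
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    # no timestamps: rerunning an identical config must be bit-identical
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("progmark")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, out, stamp)
    finally:
        root.removeHandler(handler)
        handler.close()


class _StageError(RuntimeError):
    pass


class _stage:
    """Context manager that logs the running stage and names it on failure."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, _StageError):
            logger.error("stage %s: FAILED (%s)", self.name, exc)
            raise _StageError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def _run_stages(config: PipelineConfig, out: Path, stamp: dict) -> Path:
    with _stage("load"):
        matrix = io.read_matrix(config.matrix)
        sheet = io.read_sample_sheet(config.sheet)

    with _stage("qc"):
        sheet_qc, removed_rin = preprocess.filter_by_rin(sheet, config.min_rin)
        matrix = matrix[list(sheet_qc["sample_id"])]
        logger.info("RIN filter: removed %d samples %s",
                    len(removed_rin), removed_rin)
        outliers: list[str] = []
        if config.remove_outliers and matrix.shape[1] >= 4:
            outliers = preprocess.pca_outliers(matrix)
            keep = [s for s in matrix.columns if s not in outliers]
            matrix = matrix[keep]
            sheet_qc = sheet_qc[sheet_qc["sample_id"].isin(keep)].reset_index(
                drop=True)
            logger.info("PCA outliers removed: %s", outliers)

    with _stage("gene_filter"):
        matrix, n_dropped = preprocess.variance_prefilter(
            matrix, config.drop_fraction)
        logger.info("variance pre-filter: dropped %d genes, %d retained",
                    n_dropped, matrix.shape[0])

    with _stage("eb_adjust"):
        if (config.batch_key in sheet_qc.columns
                and sheet_qc[config.batch_key].nunique() > 1):
            matrix = preprocess.eb_adjust(
                matrix, sheet_qc, batch_key=config.batch_key,
                covariates=list(config.covariates),
            )
        io.write_matrix(matrix, out / "adjusted_matrix.tsv")

    groups = sheet_qc.set_index("sample_id")["group"]
    thresholds = diffexpr.Thresholds(
        anova=config.p_anova, boot=config.p_boot, perm=config.p_perm
    )
    with _stage("diffexpr"):
        table = diffexpr.de_table(
            matrix, groups, B_boot=config.B_boot, B_perm=config.B_perm,
            seed=config.seed, thresholds=thresholds,
        )
        table.assign(**stamp).to_csv(out / "de_results.tsv", sep="\t")

    with _stage("consensus"):
        calls = diffexpr.consensus(table, thresholds)
        io.write_gene_list(calls.intersection, out / "consensus_genes.txt")
        logger.info("DE: anova=%d boot=%d perm=%d consensus=%d",
                    len(calls.anova), len(calls.boot), len(calls.perm),
                    len(calls.intersection))

    with _stage("classify"):
        # cluster on the bootstrap-test signature, as the source analysis did
        signature = calls.boot if calls.boot else list(matrix.index[:50])
        tree = _classify.hclust_samples(matrix, signature)
        pd.DataFrame(
            tree.merges, columns=["node_a", "node_b", "height", "size"]
        ).to_csv(out / "linkage.tsv", sep="\t", index=False)
        report = _classify.classify_by_cut(tree, groups, k=config.k_clusters)
        report_rows = [
            {"group": g, "correct": report.correct[g], "total": report.totals[g]}
            for g in sorted(report.totals)
        ]
        pd.DataFrame(report_rows).assign(**stamp).to_csv(
            out / "classification.tsv", sep="\t", index=False
        )
        logger.info("classification: %s accuracy=%.3f",
                    report.correct, report.accuracy)

    if config.gmt:
        with _stage("enrich"):
            sets, descriptions = io.read_gmt(config.gmt)
            background = set(matrix.index)
            result = enrich.enrich_table(
                set(calls.intersection) or set(calls.boot), sets, background,
                descriptions,
            )
            result.assign(**stamp).to_csv(out / "enrichment.tsv", sep="\t")
            if len(result):
                groups_of_terms = enrich.group_terms(
                    {t: sets[t] & background for t in result.index}, background,
                    p_ease=result["p_ease"],
                    kappa_threshold=config.kappa_threshold,
                )
                (out / "term_groups.txt").write_text(
                    "".join("\t".join(g) + "\n" for g in groups_of_terms)
                )
    return out
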