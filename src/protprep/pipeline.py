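"""End-to-end pre-processing pipeline with an auditable record.

Stages run in the fixed workflow order — import, background
correction, CV filtering, replicate averaging, (optional) tag
subtraction, normalization, (optional) batch correction — with every
intermediate matrix persisted, per-stage record counts and warnings
captured, and the full configuration serialized into a JSON audit
record so a run can be reproduced exactly.  Tag subtraction and batch
correction are optional stages; the rest always run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from protprep._version import __version__ as _pkg_version
from protprep.background import correct_background
from protprep.batch import combat_adjust
from protprep.io import (
    Dialect,
    ExperimentLayout,
    SpotTable,
    assemble_experiment,
    read_layout,
    read_quantification_file,
    write_feature_matrix,
)
from protprep.mvd import mvd_report
from protprep.normalize import (
    normalize_cyclic_loess,
    normalize_log2,
    normalize_rlm,
    normalize_vsn,
)
from protprep.replicates import (
    CVPolicy,
    average_replicates,
    cv_summary_by_sample,
    filter_replicates,
    subtract_tag,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("protprep.pipeline")

STAGE_ORDER = (
    "import",
    "background",
    "cv_filter",
    "average",
    "tag_subtract",
    "normalize",
    "batch_correct",
)


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run.

    ``tag_subtract`` and ``batch_correct`` may be switched off; stage
    order itself is fixed.  Every parameter here has a CLI twin; the
    whole config is embedded in the audit record.
    """

    quantification_files: list[str] = field(default_factory=list)
    features_file: str = ""
    blocks_file: str = ""
    out_dir: str = "protprep_out"
    seed: int = 1

    header_dialect: str = "atf"
    skip_lines: int = 0

    background_method: str = "local"
    background_scope: str = "block"

    cv_cutoff_percent: float = 20.0
    low_intensity_threshold: float = 100.0
    min_replicates_kept: int = 2

    tag_subtract: bool = True
    tag_floor: float = 0.0

    normalization: str = "vsn"  # log2 | cyclic_loess | rlm | vsn
    log2_alpha_hat: float = 0.0
    loess_span: float = 0.7
    loess_cycles: int = 3
    vsn_trim_fraction: float = 0.1
    control_class: str = "control"

    batch_correct: bool = False
    batch_mode: str = "parametric"
    batch_mean_only: bool = False

    overwrite: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Outputs of a pipeline run: final matrix, per-stage artefacts, audit."""

    final_matrix: pd.DataFrame
    stage_matrices: dict
    cv_report: pd.DataFrame
    audit: dict
    out_dir: str


def _positive_policy(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Half-minimum-positive replacement for non-positive matrix cells.

    Log-scale normalizations need positive input; non-positive cells
    (possible after local/global correction or tag subtraction) are
    replaced, per sample, by half the smallest positive value in that
    sample.  Returns the matrix and the number of cells replaced.
    """
    out = matrix.copy()
    n_replaced = 0
    for col in out.columns:
        vals = out[col]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            pos = vals[vals > 0]
            if pos.empty:
                raise ValueError(f"sample {col!r}: no positive values; cannot apply half-minimum replacement")
            out.loc[bad, col] = pos.min() / 2.0
            n_replaced += int(bad.sum())
    return out, n_replaced


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the workflow described by ``config``.

    Every stage writes its matrix (TSV) into ``out_dir``; a stage
    failure marks the partial outputs with a ``.partial`` file naming
    the failed stage and re-raises.  The audit record (JSON) contains
    the package version, the full configuration, per-stage record
    counts and warnings.  Identical config + seed reproduces identical
    outputs bit for bit.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s %(message)s",
    )
    np.random.seed(config.seed % (2**31))
    os.makedirs(config.out_dir, exist_ok=True)
    audit: dict = {
        "package_version": _pkg_version,
        "config": asdict(config),
        "stages": [],
        "warnings": [],
    }
    stage_matrices: dict = {}
    current_stage = "import"
    try:
        dialect = Dialect(header=config.header_dialect, skip_lines=config.skip_lines)
        fragments = [read_quantification_file(p, dialect=dialect) for p in config.quantification_files]
        layout = read_layout(config.features_file, config.blocks_file)
        table = assemble_experiment(fragments, layout)
        audit["stages"].append({"stage": "import", "n_records": len(table), "n_files": len(fragments)})
        logger.info("import: %d spots from %d files", len(table), len(fragments))

        current_stage = "background"
        kwargs = {"scope": config.background_scope} if config.background_method == "half_moving_min" else {}
        table = correct_background(table, method=config.background_method, **kwargs)
        n_neg = int(table.data.get("negative_flag", pd.Series(False)).sum())
        audit["stages"].append(
            {"stage": "background", "method": config.background_method, "n_records": len(table), "n_negative": n_neg}
        )
        if n_neg:
            audit["warnings"].append(f"background: {n_neg} negative corrected values flagged")

        current_stage = "cv_filter"
        policy = CVPolicy(
            cutoff_percent=config.cv_cutoff_percent,
            low_intensity_threshold=config.low_intensity_threshold,
            min_replicates_kept=config.min_replicates_kept,
        )
        table, cv_report = filter_replicates(table, policy)
        n_fail = int((cv_report["status"] == "fail").sum())
        audit["stages"].append(
            {
                "stage": "cv_filter",
                "n_sets": len(cv_report),
                "n_fail": n_fail,
                "status_counts": cv_report["status"].value_counts().to_dict(),
            }
        )
        if n_fail:
            audit["warnings"].append(f"cv_filter: {n_fail} replicate sets failed the CV policy")
        cv_report.to_csv(os.path.join(config.out_dir, "cv_report.tsv"), sep="\t", index=False)
        cv_summary_by_sample(cv_report, config.cv_cutoff_percent).to_csv(
            os.path.join(config.out_dir, "cv_summary.tsv"), sep="\t", index=False
        )

        current_stage = "average"
        matrix = average_replicates(table, cv_report)
        stage_matrices["averaged"] = matrix
        audit["stages"].append({"stage": "average", "shape": list(matrix.shape)})

        if config.tag_subtract and layout.tag_of:
            current_stage = "tag_subtract"
            matrix = subtract_tag(matrix, layout, floor=config.tag_floor)
            stage_matrices["tag_subtracted"] = matrix
            audit["stages"].append({"stage": "tag_subtract", "n_tagged": len(layout.tag_of)})

        # analytes only from here on
        antigens = layout.features.loc[layout.features["feature_class"] == "antigen", "feature"]
        controls = list(layout.features.loc[layout.features["feature_class"] == "control", "feature"])
        analyte_matrix = matrix.loc[matrix.index.intersection(antigens)]

        current_stage = "normalize"
        fit_info: dict = {}
        if config.normalization == "log2":
            work, n_replaced = _positive_policy(analyte_matrix)
            normalized, n_dropped = normalize_log2(work, config.log2_alpha_hat)
            fit_info = {"alpha_hat": config.log2_alpha_hat, "n_nonpositive_replaced": n_replaced, "n_dropped": n_dropped}
        elif config.normalization == "cyclic_loess":
            work, n_replaced = _positive_policy(analyte_matrix)
            normalized = normalize_cyclic_loess(
                work, span=config.loess_span, n_cycles=config.loess_cycles, log_input=False
            )
            normalized, _ = normalize_log2(normalized, 0.0)
            fit_info = {"span": config.loess_span, "cycles": config.loess_cycles, "n_nonpositive_replaced": n_replaced}
        elif config.normalization == "rlm":
            full = matrix.loc[matrix.index.intersection(list(antigens) + controls)]
            work, n_replaced = _positive_policy(full)
            logged, _ = normalize_log2(work, 0.0)
            blocks = layout.blocks
            slide_of = dict(zip(blocks["sample"], blocks["slide"]))
            block_of = dict(zip(blocks["sample"], blocks["block"]))
            fit, adjusted = normalize_rlm(logged, controls, slide_of, block_of)
            normalized = adjusted.loc[adjusted.index.intersection(antigens)]
            fit_info = {
                "alpha": fit.alpha.to_dict(),
                "beta": {str(k): v for k, v in fit.beta.items()},
                "scale": fit.scale,
                "converged": fit.converged,
                "n_nonpositive_replaced": n_replaced,
            }
        elif config.normalization == "vsn":
            fit, normalized = normalize_vsn(
                analyte_matrix, background_corrected=True, trim_fraction=config.vsn_trim_fraction
            )
            fit_info = {"b": fit.b.to_dict(), "eta_sd": fit.eta_sd, "eps_sd": fit.eps_sd, "n_trimmed": fit.n_trimmed}
        else:
            raise ValueError(f"unknown normalization {config.normalization!r}")
        stage_matrices["normalized"] = normalized
        audit["stages"].append({"stage": "normalize", "method": config.normalization, "fit": fit_info})

        report = mvd_report(normalized)
        audit["mvd"] = report.to_dict()

        final = normalized
        if config.batch_correct:
            current_stage = "batch_correct"
            batches = pd.Series(layout.batch_of).reindex(final.columns)
            model, final = combat_adjust(
                final, batches, mode=config.batch_mode, mean_only=config.batch_mean_only
            )
            stage_matrices["batch_corrected"] = final
            audit["stages"].append(
                {
                    "stage": "batch_correct",
                    "mode": config.batch_mode,
                    "batches": {str(k): int(v) for k, v in batches.value_counts().items()},
                    "n_dropped_features": len(model.dropped_features),
                }
            )

        for name, m in stage_matrices.items():
            write_feature_matrix(
                m, os.path.join(config.out_dir, f"matrix_{name}.tsv"), overwrite=config.overwrite
            )
        audit_path = os.path.join(config.out_dir, "audit.json")
        with open(audit_path, "w") as fh:
            json.dump(audit, fh, indent=2, default=str, sort_keys=True)
        write_feature_matrix(
            final,
            os.path.join(config.out_dir, "matrix_final.tsv"),
            audit=audit["stages"],
            overwrite=config.overwrite,
        )
        logger.info("pipeline complete: final matrix %s", final.shape)
        return PipelineResult(
            final_matrix=final,
            stage_matrices=stage_matrices,
            cv_report=cv_report,
            audit=audit,
            out_dir=config.out_dir,
        )
    except Exception as exc:
        marker = os.path.join(config.out_dir, "RUN.partial")
        with open(marker, "w") as fh:
            fh.write(f"failed at stage {current_stage}: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", current_stage, exc)
        raise
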