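"""End-to-end orchestration: subject-level FD extraction and cohort statistics.

``run_subject`` takes one white-matter probability volume through
resampling, thresholding, thinning, hemisphere splitting and box counting
to a row of nine FD values with QC fields. ``run_cohort`` maps a manifest
of volumes onto a clinical table and produces the full report bundle:
per-outcome mixed-model fits with Tukey tables (primary and ALSFRS-R
sensitivity variants), Spearman correlation tables with FDR flags,
Kruskal-Wallis by El Escorial stratum, and a machine-readable JSON
summary. Failures are per-subject: one bad volume yields one failure row,
never a dead run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .fractal import FractalError, feature_fd
from .morphology import make_feature_set
from .volume_io import (
    FD_COLUMNS,
    ProbabilityVolume,
    VolumeError,
    read_volume,
    resample_isotropic,
    write_fd_report,
)

logger = logging.getLogger(__name__)

_FEATURES = ("skeleton", "surface", "general")
_HEMI_CODE = {"left": "lh", "right": "rh", "whole": "wb"}


@dataclasses.dataclass
class PipelineConfig:
    """Every knob of the pipeline, with reproducible defaults."""

    threshold: float = 0.5
    target_mm: float = 1.0
    resample: bool = True
    scales: Sequence[int] | None = None  # None = auto ladder per grid
    n_offsets: int = 1
    surface_connectivity: int = 6
    hemisphere_mode: int | str = "auto"
    covariates: tuple[str, ...] = ("age",)
    fdr_alpha: float = 0.05
    min_points: int = 4
    r2_floor: float = 0.98
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales) if self.scales is not None else "auto"
        d["covariates"] = list(self.covariates)
        return d


def run_subject(
    volume: str | Path | ProbabilityVolume,
    config: PipelineConfig | None = None,
    subject_id: str = "",
) -> dict:
    """Extract the nine FD values (and QC fields) from one volume.

    Returns a flat dict: ``fd_<feature>_<hemi>`` values plus per-measure
    voxel counts, fitted scale ranges and R². On failure the dict carries
    ``status="failed"``, the failing stage name and the error message.
    """
    config = config or PipelineConfig()
    row: dict = {"subject_id": subject_id, "status": "ok", "stage": "", "error": ""}
    stage = "read"
    try:
        if isinstance(volume, (str, Path)):
            prob = read_volume(volume)
        else:
            prob = volume
        if config.resample:
            stage = "resample"
            prob = resample_isotropic(prob, target_mm=config.target_mm)
        stage = "binarize"
        feature_sets = make_feature_set(
            prob,
            threshold=config.threshold,
            surface_connectivity=config.surface_connectivity,
            midline_index=config.hemisphere_mode,
        )
        stage = "box_count"
        for hemi_label, fs in feature_sets.items():
            code = _HEMI_CODE[hemi_label]
            estimates = feature_fd(
                fs,
                scales=config.scales,
                n_offsets=config.n_offsets,
                min_points=config.min_points,
                r2_floor=config.r2_floor,
            )
            for feat in _FEATURES:
                est = estimates[feat]
                row[f"fd_{feat}_{code}"] = est.fd
                row[f"qc_nvox_{feat}_{code}"] = getattr(fs, feat).count()
                row[f"qc_rmin_{feat}_{code}"] = est.scale_range[0]
                row[f"qc_rmax_{feat}_{code}"] = est.scale_range[1]
                row[f"qc_r2_{feat}_{code}"] = est.r_squared
    except (VolumeError, FractalError, FileNotFoundError) as exc:
        logger.error("subject %s failed at stage %s: %s", subject_id, stage, exc)
        row.update(status="failed", stage=stage, error=str(exc))
        for feat in _FEATURES:
            for code in _HEMI_CODE.values():
                row.setdefault(f"fd_{feat}_{code}", np.nan)
    return row


def _df_from_comparisons(comps) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "estimate": c.estimate,
                "p_adjusted": c.p_adjusted,
                "significant": c.significant,
            }
            for c in comps
        ]
    )


def _model_df(fit: cs.GroupModelFit) -> pd.DataFrame:
    rows = [
        {"term": name, "estimate": val} for name, val in fit.fixed_effects.items()
    ]
    rows += [
        {"term": f"adjusted_mean[{g}]", "estimate": m}
        for g, m in fit.adjusted_group_means.items()
    ]
    rows += [
        {"term": "random_effect_variance", "estimate": fit.random_effect_variance},
        {"term": "residual_variance", "estimate": fit.residual_variance},
        {"term": "p_age", "estimate": fit.p_age},
        {"term": "p_group", "estimate": fit.p_group},
        {"term": "n_obs", "estimate": fit.n_obs},
        {"term": "converged", "estimate": float(fit.converged)},
    ]
    return pd.DataFrame(rows)


def run_cohort(
    manifest: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    fd_table: pd.DataFrame | None = None,
) -> dict:
    """Cohort analysis: subject FD extraction followed by group statistics.

    ``manifest`` maps ``subject_id`` to ``volume_path``; ``clinical``
    carries demographics and clinical measures per subject. Passing a
    precomputed ``fd_table`` (e.g. from a synthetic cohort) skips the
    imaging stage. When ``outdir`` is given, the report bundle (TSVs +
    summary.json + effective_config.json) is written there.

    Returns the machine-readable summary dict.
    """
    config = config or PipelineConfig()
    summary: dict = {"config": config.to_dict(), "warnings": []}

    if fd_table is None:
        known = set(clinical["subject_id"])
        unknown = [s for s in manifest["subject_id"] if s not in known]
        if unknown:
            raise cs.CohortError(
                f"manifest subject id(s) missing from the clinical table: "
                f"{', '.join(map(str, unknown))}"
            )
        rows = [
            run_subject(p, config, subject_id=s)
            for s, p in zip(manifest["subject_id"], manifest["volume_path"])
        ]
        fd_rows = pd.DataFrame(rows)
        table = clinical.merge(fd_rows, on="subject_id", how="inner")
        summary["n_failed_subjects"] = int((fd_rows["status"] == "failed").sum())
    else:
        table = fd_table.copy()
        summary["n_failed_subjects"] = 0

    table = cs.log_transform_clinical(table)
    summary["n_subjects"] = int(len(table))

    # Outlier screen on the whole-brain skeleton, remove-and-refit once.
    try:
        flagged = cs.detect_outliers(table, "fd_skeleton_wb")
    except cs.CohortError:
        flagged = []
    if flagged:
        logger.warning("removing flagged outlier subject(s): %s", flagged)
        summary["outliers_removed"] = flagged
        table = table[~table["subject_id"].isin(flagged)]
    else:
        summary["outliers_removed"] = []

    models: dict[str, pd.DataFrame] = {}
    tukeys: dict[str, pd.DataFrame] = {}
    summary["models"] = {}
    for outcome in FD_COLUMNS:
        try:
            fit = cs.fit_group_model(table, outcome, covariates=config.covariates)
        except cs.CohortError as exc:
            summary["warnings"].append(f"{outcome}: {exc}")
            continue
        comps = cs.tukey_pairwise(fit)
        models[outcome] = _model_df(fit)
        tukeys[outcome] = _df_from_comparisons(comps)
        summary["models"][outcome] = {
            "p_group": fit.p_group,
            "p_age": fit.p_age,
            "adjusted_group_means": fit.adjusted_group_means,
            "significant_pairs": [
                [c.group_a, c.group_b] for c in comps if c.significant
            ],
        }

    # Sensitivity: ALSFRS-R as an extra fixed covariate, patients only.
    patients = table[table["alsfrs_r"].notna()]
    summary["sensitivity"] = {}
    if len(patients) >= 10 and patients["group"].nunique() >= 2:
        for outcome in FD_COLUMNS:
            try:
                fit = cs.fit_group_model(
                    patients, outcome, covariates=(*config.covariates, "alsfrs_r")
                )
            except cs.CohortError as exc:
                summary["warnings"].append(f"sensitivity {outcome}: {exc}")
                continue
            comps = cs.tukey_pairwise(fit)
            tukeys[f"{outcome}_sensitivity"] = _df_from_comparisons(comps)
            summary["sensitivity"][outcome] = {
                "p_group": fit.p_group,
                "significant_pairs": [
                    [c.group_a, c.group_b] for c in comps if c.significant
                ],
            }
    else:
        msg = "sensitivity analysis skipped: no usable ALSFRS-R scores"
        logger.warning(msg)
        summary["warnings"].append(msg)

    correlations: dict[str, pd.DataFrame] = {}
    summary["correlations"] = {}
    for measure in ("alsfrs_r", "ln_duration", "ln_progression_rate"):
        if measure not in table.columns or table[measure].notna().sum() < 10:
            summary["warnings"].append(f"correlations vs {measure} skipped")
            continue
        res = cs.spearman_fd_clinical(table, measure, fdr_alpha=config.fdr_alpha)
        correlations[measure] = pd.DataFrame(
            [
                {
                    "outcome": r.outcome_name,
                    "rho": r.rho,
                    "p_value": r.p_value,
                    "passes_fdr": r.passes_fdr,
                }
                for r in res
            ]
        )
        summary["correlations"][measure] = {
            r.outcome_name: {"rho": r.rho, "p": r.p_value, "fdr": r.passes_fdr}
            for r in res
        }

    summary["kruskal_ees"] = {}
    if "ees" in table.columns and table["ees"].notna().sum() >= 6:
        for outcome in FD_COLUMNS:
            try:
                kw = cs.kruskal_by_ees(table, outcome)
            except cs.CohortError as exc:
                summary["warnings"].append(f"kruskal {outcome}: {exc}")
                continue
            summary["kruskal_ees"][outcome] = {
                "H": kw["statistic"],
                "p": kw["p_value"],
            }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if all(c in table.columns for c in FD_COLUMNS):
            try:
                write_fd_report(table, outdir / "fd_table.tsv")
            except VolumeError:
                table.to_csv(outdir / "fd_table.tsv", sep="\t", index=False)
        for outcome, df in models.items():
            df.to_csv(outdir / f"model_{outcome}.tsv", sep="\t", index=False)
        for name, df in tukeys.items():
            df.to_csv(outdir / f"tukey_{name}.tsv", sep="\t", index=False)
        for measure, df in correlations.items():
            df.to_csv(outdir / f"correlations_{measure}.tsv", sep="\t", index=False)
        with open(outdir / "effective_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
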