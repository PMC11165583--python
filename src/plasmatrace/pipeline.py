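"""End-to-end orchestration: simulate -> calibrate -> cluster -> classify -> SEC.

A :class:`RunConfig` fixes the preset (or input files), seed and thresholds;
:func:`run_pipeline` executes every stage, persists each intermediate as a
plain-text artifact (TSV / Newick / JSON) and returns a report bundle whose
JSON summary is byte-identical for identical config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    app_classifier,
    calibration,
    longitudinal,
    quant_io,
    sec_complexome,
    synthetic_data,
)

logger = logging.getLogger("plasmatrace")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run."""

    preset: str = "p2_apr"
    seed: int = 0
    noise_cv: float = 0.1
    app_threshold: float = 0.25
    cluster_cut: float = 0.3
    coelution_threshold: float = 0.9
    peak_fold_threshold: float = 5.0
    out_dir: str = "plasmatrace_out"
    reference_table: str | None = None  # path; None -> bundled panel
    report_path: str | None = None  # run from files instead of simulating
    metadata_path: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "app_threshold",
            "cluster_cut",
            "coelution_threshold",
            "peak_fold_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ReportBundle:
    """Artifacts of one pipeline run."""

    config: RunConfig
    concentrations: calibration.ConcentrationMatrix
    model: calibration.CalibrationModel
    protein_tree: longitudinal.Dendrogram
    sample_tree: longitudinal.Dendrogram
    app_table: pd.DataFrame
    apr_calls: dict[str, app_classifier.APRCall]
    sec_groups: list[sec_complexome.CoelutionGroup] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _round(x: float, ndigits: int = 8) -> float:
    return float(round(float(x), ndigits))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "effective_config.yaml")

    # --- stage: input (simulate or load) ---------------------------------
    try:
        if config.report_path is not None:
            if config.metadata_path is None:
                raise ValueError("metadata_path required with report_path")
            table = quant_io.read_quant_table(
                config.report_path, config.metadata_path
            )
            design = None
        else:
            design = synthetic_data.preset(config.preset)
            table, truth = synthetic_data.generate_quant_table(
                design, noise_cv=config.noise_cv, seed=config.seed
            )
            table.write(out / "quant_report.tsv")
            quant_io.write_metadata(table.metadata, out / "metadata.tsv")
            truth.to_json(out / "truth.json")
        table = quant_io.filter_contaminant_classes(table)
    except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineStageError("simulate", e) from e

    # --- stage: calibrate -------------------------------------------------
    try:
        refs = quant_io.load_reference_table(config.reference_table)
        model = calibration.fit_concentration_model(table, refs)
        matrix = calibration.lfq_to_concentration(model, table)
        model.to_json(out / "calibration.json")
        matrix.write(out / "concentration_matrix.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("calibrate", e) from e

    # --- stage: cluster ---------------------------------------------------
    try:
        protein_tree = longitudinal.protein_dendrogram(matrix)
        sample_tree = longitudinal.sample_dendrogram(matrix)
        (out / "protein_dendrogram.nwk").write_text(protein_tree.to_newick() + "\n")
        (out / "sample_dendrogram.nwk").write_text(sample_tree.to_newick() + "\n")
        partition = longitudinal.cut_clusters(protein_tree, config.cluster_cut)
        pd.DataFrame(
            [
                {"cluster_index": i, "protein_id": p}
                for i, grp in enumerate(partition)
                for p in sorted(grp)
            ]
        ).to_csv(out / "protein_clusters.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("cluster", e) from e

    # --- stage: classify-app ---------------------------------------------
    try:
        apr_calls = app_classifier.detect_apr_peaks(
            matrix, fold_threshold=config.peak_fold_threshold
        )
        app_frames = []
        for donor, call in sorted(apr_calls.items()):
            if not call.peak_timepoints:
                continue
            frame = app_classifier.classify_all(
                matrix, call, threshold=config.app_threshold
            )
            frame.insert(0, "donor_id", donor)
            app_frames.append(frame)
        app_table = (
            pd.concat(app_frames, ignore_index=True)
            if app_frames
            else pd.DataFrame(
                columns=[
                    "donor_id",
                    "protein_id",
                    "app_class",
                    "fold_change_at_peak",
                    "hallmark_correlation",
                ]
            )
        )
        app_table.to_csv(out / "app_table.tsv", sep="\t", index=False,
                         float_format="%.8g")
        ratio = app_classifier.apoa_saa_ratio(matrix)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("classify-app", e) from e

    # --- stage: sec-analyze (simulated designs only) ----------------------
    sec_groups: list[sec_complexome.CoelutionGroup] = []
    sec_summary: dict = {}
    if design is not None:
        try:
            donor = design.donors[0]
            for d in design.donors:
                if d.peak_timepoints:
                    donor = d
                    break
            timepoint = min(donor.peak_timepoints) if donor.peak_timepoints else 1
            sec_table, sec_truth = synthetic_data.generate_sec_run(
                design,
                timepoint=timepoint,
                donor_id=donor.donor_id,
                noise_cv=0.0,
                seed=config.seed + 1,
            )
            mw_cal = sec_complexome.fit_mw_calibration(sec_table.calibrants)
            profiles = sec_complexome.build_elution_profiles(
                sec_table, mw_cal, monomer_mws=sec_truth.monomer_mw
            )
            sec_groups = sec_complexome.detect_coelution_groups(
                profiles, score_threshold=config.coelution_threshold
            )
            sec_table.write(out / "sec_fractions.tsv")
            mw_cal.to_json(out / "sec_mw_calibration.json")
            sec_complexome.groups_to_frame(sec_groups).to_csv(
                out / "sec_groups.tsv", sep="\t", index=False, float_format="%.8g"
            )
            sec_summary = {
                "donor": donor.donor_id,
                "timepoint": timepoint,
                "n_groups": len(sec_groups),
                "groups": [
                    {
                        "members": list(g.members),
                        "group_mw_kda": _round(g.group_mw, 4),
                    }
                    for g in sec_groups
                    if len(g.members) > 1
                ],
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("sec-analyze", e) from e

    # --- report -----------------------------------------------------------
    class_counts = (
        app_table["app_class"].value_counts().to_dict() if len(app_table) else {}
    )
    summary = {
        "seed": config.seed,
        "preset": None if design is None else design.name,
        "thresholds": {
            "app": config.app_threshold,
            "cluster_cut": config.cluster_cut,
            "coelution": config.coelution_threshold,
            "peak_fold": config.peak_fold_threshold,
        },
        "calibration": {
            "slope": _round(model.slope),
            "intercept": _round(model.intercept),
            "r_squared": _round(model.r_squared),
            "n_anchors": model.n_anchors,
        },
        "apr_peaks": {
            donor: sorted(call.peak_timepoints)
            for donor, call in sorted(apr_calls.items())
        },
        "n_apr_episodes": int(
            sum(len(c.peak_timepoints) for c in apr_calls.values())
        ),
        "app_counts": {
            k: int(v) for k, v in sorted(class_counts.items())
        },
        "apoa_saa_ratio": {
            s: (None if not np.isfinite(v) else _round(v, 6))
            for s, v in ratio.items()
        },
        "sec": sec_summary,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    logger.info("pipeline run complete: %s", out)
    return ReportBundle(
        config=config,
        concentrations=matrix,
        model=model,
        protein_tree=protein_tree,
        sample_tree=sample_tree,
        app_table=app_table,
        apr_calls=apr_calls,
        sec_groups=sec_groups,
        summary=summary,
    )
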