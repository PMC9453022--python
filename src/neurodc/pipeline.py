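"""End-to-end orchestration: simulate -> DC -> features -> select -> classify -> stats.

``run_pipeline`` executes the stages in order on synthetic data (or on
user-provided preprocessed NIfTI data dropped into the same layout),
writes every intermediate artifact under the output directory, and
finishes with a provenance record.  All randomness flows from the one
master seed in the config, so a rerun of the same config regenerates
byte-identical TSV/JSON artifacts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np


from . import io
from .classify import run_all_models, roc_coordinates
from .config import RunConfig
from .dc import dc_pipeline
from .features import build_feature_table
from .grids import generate_toy_atlas, generate_toy_geometry
from .select import correlation_prune, lasso_select, select_features
from .simulate import CohortSpec, simulate_cohort
from .stats import demographics_table, demographics_markdown

logger = logging.getLogger("neurodc")

__all__ = ["run_pipeline"]


def _stage(name: str):
    logger.info("stage=%s", name)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; returns paths and in-memory results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    _stage("geometry")
    geometry = generate_toy_geometry(
        shape=config.geometry.shape,
        voxel_size_mm=config.geometry.voxel_size_mm,
        mask_rule=config.geometry.mask_rule,
        radius=config.geometry.radius,
    )
    mask_path = out / "mask.nii.gz"
    io.save_mask(geometry, mask_path)

    _stage("atlas")
    atlas = generate_toy_atlas(
        geometry, config.atlas.n_regions, seed=config.seed + config.atlas.seed_offset
    )
    atlas_path = out / "atlas.nii.gz"
    io.save_atlas(atlas, atlas_path)

    _stage("cohort")
    spec = CohortSpec(
        n_group1=config.cohort.n_group1,
        n_group2=config.cohort.n_group2,
        n_timepoints=config.cohort.n_timepoints,
        effect_regions=tuple(config.cohort.effect_regions),
        effect_size=config.cohort.effect_size,
        base_coupling=config.cohort.base_coupling,
        noise_sd=config.cohort.noise_sd,
        signal_band_hz=config.cohort.signal_band_hz,
        sampling_interval_s=config.cohort.sampling_interval_s,
        seed=config.seed,
    )
    recordings, participants = simulate_cohort(geometry, atlas, spec, out_dir=out)
    artifacts.append(out / "participants.tsv")
    if config.save_bold:
        bold_dir = out / "bold"
        bold_dir.mkdir(exist_ok=True)
        for rec in recordings:
            io.save_bold(rec.bold, bold_dir / f"{rec.subject_id}_bold.nii.gz")

    _stage("dc_mapping")
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    zdc_maps = {}
    for rec in recordings:
        zdc = dc_pipeline(
            rec.bold,
            r0=config.dc.r0,
            variant=config.dc.variant,
            z_method=config.dc.z_method,
            fwhm_mm=config.dc.fwhm_mm,
            chunk_size=config.dc.chunk_size,
        )
        zdc_maps[rec.subject_id] = zdc
        io.save_map(zdc, maps_dir / f"{rec.subject_id}_zdc.nii.gz", sidecar=False)

    _stage("region_features")
    table = build_feature_table(zdc_maps, atlas, participants)
    features_path = out / "features.tsv"
    table.write_tsv(features_path)
    artifacts += [features_path, features_path.with_suffix(".columns.json")]

    _stage("feature_selection")
    selection = select_features(
        table,
        threshold=config.selection.prune_threshold,
        n_folds=config.selection.n_folds,
        seed=config.seed,
        alpha_grid=config.selection.alpha_grid(),
        mode=config.selection.mode,
    )
    selection_path = out / "selection.json"
    selection.write_json(selection_path)
    artifacts.append(selection_path)

    selected_names = list(selection.nonzero_features) or selection.kept_after_prune
    selected = table.select_columns(selected_names)

    _stage("classification")
    nested_selection = None
    if config.classify.nested_permutations:
        prune_threshold = config.selection.prune_threshold

        def nested_selection(matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
            names = [str(k) for k in range(matrix.shape[1])]
            kept = correlation_prune(matrix, names, threshold=prune_threshold)
            idx = np.array([int(k) for k in kept], dtype=int)
            res = lasso_select(
                matrix[:, idx],
                y,
                kept,
                alpha_grid=config.selection.alpha_grid(),
                n_folds=min(config.selection.n_folds, int(np.bincount(y).min())),
                seed=config.seed,
                mode=config.selection.mode,
            )
            return idx[[kept.index(n) for n in res.nonzero_features]]

    reports, comparison, held_out = run_all_models(
        selected.matrix,
        selected.y,
        selected.region_names,
        seed=config.seed,
        n_permutations=config.classify.n_permutations,
        grids=config.classify.grids,
        statistic=config.classify.permutation_statistic,
        selection=nested_selection,
        return_scores=True,
    )
    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    for name, report in reports.items():
        report.write_json(reports_dir / f"{name}_report.json")
        artifacts.append(reports_dir / f"{name}_report.json")
        roc = roc_coordinates(selected.y, held_out[name])
        roc_path = reports_dir / f"{name}_roc.tsv"
        roc.to_csv(roc_path, sep="\t", index=False, float_format="%.10g")
        artifacts.append(roc_path)
    comparison_path = out / "comparison.tsv"
    comparison.to_csv(comparison_path, sep="\t", float_format="%.10g")
    artifacts.append(comparison_path)

    _stage("cohort_stats")
    demo = demographics_table(participants, ["moca"], group_col="group")
    demo_path = out / "demographics.tsv"
    demo.to_csv(demo_path, sep="\t", index=False, float_format="%.10g")
    (out / "demographics.md").write_text(demographics_markdown(demo))
    artifacts += [demo_path, out / "demographics.md"]

    _stage("provenance")
    io.write_provenance(
        out,
        config.model_dump(mode="json"),
        artifacts,
        record_timestamps=config.record_timestamps,
    )

    return {
        "out_dir": out,
        "geometry": geometry,
        "atlas": atlas,
        "participants": participants,
        "feature_table": table,
        "selection": selection,
        "reports": reports,
        "comparison": comparison,
        "demographics": demo,
    }
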