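"""End-to-end orchestration: simulate -> preprocess -> fit -> infer ->
cross-validate -> downstream -> sensitivity, with a checksum manifest.

Each stage draws from its own named substream of the run seed, so re-running
any stage (or the whole pipeline) with the same config reproduces its output
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig, config_hash, save_config
from .crossval import run_cv
from .downstream import (
    cognition_regressions,
    compare_models,
    composite_scores,
    total_gmv,
)
from .inference import bootstrap_weights, cluster_z_map, permutation_test
from .io import load_cohort_inputs, save_blocks, write_cohort, write_manifest
from .plsc import fit_plsc
from .preprocess import prepare_blocks, transform_predictors
from .synth import (
    CohortSpec,
    PlantedComponent,
    default_u_true,
    generate_cognitive_scores,
    generate_cohort,
)

log = logging.getLogger("plscvbm")

__all__ = ["run_pipeline", "simulate_stage"]


def simulate_stage(cfg: RunConfig, out: Path) -> Path:
    spec = CohortSpec(
        n_subjects=cfg.n_subjects,
        grid_shape=tuple(cfg.grid_shape),
        voxel_size_mm=cfg.voxel_size_mm,
        smoothness_fwhm_mm=cfg.smoothness_fwhm_mm,
        planted_components=(
            PlantedComponent(default_u_true(), rho=cfg.planted_rho),
        ),
        seed=cfg.seed,
    )
    cohort = generate_cohort(spec)
    cohort.table = generate_cognitive_scores(
        cohort, {"executive": 0.2, "memory": 0.15, "processing_speed": 0.1}
    )
    write_cohort(cohort, out / "cohort")
    log.info("simulated cohort: N=%d, grid=%s", cohort.n_subjects, spec.grid_shape)
    return out / "cohort"


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and return the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    stages: list[str] = []

    if cfg.participants_csv is None:
        cohort_dir = simulate_stage(cfg, out)
        stages.append("simulate")
        participants = cohort_dir / "participants.csv"
        image_dir = cohort_dir / "gmv"
        mask_path = cohort_dir / "gm_probability.nii.gz"
    else:
        participants = Path(cfg.participants_csv)
        image_dir = Path(cfg.image_dir)
        mask_path = Path(cfg.mask_path)

    table, images, prob, affine = load_cohort_inputs(
        participants, image_dir, mask_path
    )
    log.info("loaded %d subjects", len(table))

    xblock, yblock, report, raw_y = prepare_blocks(
        table, images, prob, affine, threshold=cfg.mask_threshold
    )
    log.info(
        "preprocessing: %d -> %d subjects after exclusions; %d voxels in mask",
        report.n_input, xblock.n, yblock.v,
    )
    save_blocks(xblock, yblock, raw_y, out)
    report.to_frame().to_csv(out / "exclusions.tsv", sep="\t", index=False)
    stages.append("preprocess")

    model = fit_plsc(
        xblock.X, yblock.Y, R=cfg.n_components, column_names=xblock.column_names
    )
    np.savez_compressed(
        out / "model.npz", U=model.U, V=model.V, delta=model.delta,
        Lx=model.Lx, Ly=model.Ly,
    )
    summary = {
        "delta": model.delta.tolist(),
        "explained_covariance": model.explained_covariance.tolist(),
        "lv_correlations": model.lv_correlations.tolist(),
        "column_names": list(model.column_names),
        "sign_anchor": model.sign_anchor,
    }
    (out / "model.json").write_text(json.dumps(summary, indent=2))
    stages.append("fit")

    perm = permutation_test(
        xblock.X, yblock.Y, R=model.R,
        n_permutations=cfg.n_permutations, seed=cfg.seed,
    )
    perm.summary().to_csv(out / "permutation.tsv", sep="\t", index=False)
    stages.append("permute")

    boot = bootstrap_weights(
        xblock.X, yblock.Y, n_bootstraps=cfg.n_bootstraps,
        seed=cfg.seed, z_threshold=cfg.z_threshold, model=model,
    )
    np.savez_compressed(
        out / "bootstrap.npz", z_u=boot.z_u, z_v=boot.z_v,
        se_u=boot.se_u, se_v=boot.se_v,
    )
    stages.append("bootstrap")

    clusters = cluster_z_map(
        boot.z_v[:, 0], yblock, threshold=cfg.cluster_threshold,
        connectivity=cfg.connectivity, weights=model.V[:, 0],
    )
    clusters.to_frame().to_csv(out / "clusters_lv1.tsv", sep="\t", index=False)
    stages.append("cluster")

    # cross-validation works from the transformed (pre-residualization) data
    # of the same surviving sample used in the main fit
    transformed = transform_predictors(table)
    surv = transformed["subject_id"].isin(report.surviving_ids).to_numpy()
    sub = transformed.loc[surv].reset_index(drop=True)
    x_raw = sub[list(xblock.column_names)].to_numpy(float)
    y_raw = raw_y
    cv = run_cv(
        x_raw, y_raw,
        confounds_x=sub[["age", "sex"]].to_numpy(float),
        confounds_y=sub[["age", "sex", "tiv"]].to_numpy(float),
        R=min(cfg.cv_components, model.R),
        n_splits=cfg.cv_splits,
        test_fraction=cfg.cv_test_fraction,
        n_inner_permutations=cfg.cv_inner_permutations,
        seed=cfg.seed,
    )
    cv.to_frame().to_csv(out / "crossval.tsv", sep="\t", index=False)
    stages.append("crossval")

    # downstream: total GMV model comparison + cognition
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    totals = total_gmv(raw_y, voxel_volume, tiv=sub["tiv"].to_numpy(float))
    comparison = compare_models(
        totals["total_ml_adj"],
        sub["age"].to_numpy(float),
        sub["sex"].to_numpy(float),
        sub["bmi"].to_numpy(float),
        model.Lx[:, 0],
    )
    downstream_out = {
        "nested_F": comparison.f_statistic,
        "nested_p": comparison.p_value,
        "adj_r2_model1": comparison.adj_r2_model1,
        "adj_r2_model2": comparison.adj_r2_model2,
        "model2": comparison.model2.to_dict(orient="records"),
    }
    if "tmt_a" in sub.columns:
        comps = composite_scores(sub)
        reg = cognition_regressions(comps, model.Lx[:, 0], model.Ly[:, 0])
        downstream_out["cognition"] = reg.to_dict(orient="records")
    (out / "downstream.json").write_text(json.dumps(downstream_out, indent=2))
    stages.append("downstream")

    if cfg.variants:
        from .sensitivity import run_all_variants

        rep = run_all_variants(
            table, images, prob, affine, variants=tuple(cfg.variants),
            seed=cfg.seed, n_permutations=cfg.n_permutations,
            n_bootstraps=cfg.n_bootstraps,
        )
        rep.to_frame().to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        stages.append("sensitivity")

    write_manifest(out, cfg.to_dict() | {"config_hash": config_hash(cfg)}, cfg.seed, stages)
    return out
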