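"""Sensitivity re-analyses: configured re-runs of the main pipeline.

Five variants probe the robustness of the main decomposition:

* ``il6_detection`` — drop subjects whose IL6 sits at the assay detection
  limit (the clamp marker left by left-censoring);
* ``crp_outlier`` — drop subjects with CRP > 10 mg/l (possible acute
  inflammation);
* ``adiponectin_outlier`` — drop low outliers, value < mean - 5 SD on the
  log scale;
* ``medication_adjusted`` — residualize HbA1c on antidiabetic treatment and
  total cholesterol/HDL on lipid-lowering treatment before the analysis;
* ``add_sbp`` — add systolic blood pressure as a tenth predictor.

Each variant re-derives its exclusions from the raw table, reuses the same
seeds as the main analysis (so differences reflect data changes, not
resampling noise), and is compared to the main run by the correlation of
the shared predictor weights and the spatial correlation of the voxel
bootstrap-ratio maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import BootstrapResult, PermutationResult, bootstrap_weights, permutation_test
from .plsc import PlscModel, fit_plsc
from .preprocess import (
    ExclusionRule,
    adjust_for_medication,
    default_exclusion_rules,
    prepare_blocks,
)
from .synth import PREDICTORS

__all__ = ["VARIANTS", "VariantResult", "SensitivityReport", "run_variant", "run_all_variants", "run_main_analysis"]

VARIANTS = (
    "il6_detection",
    "crp_outlier",
    "adiponectin_outlier",
    "medication_adjusted",
    "add_sbp",
)

IL6_DETECTION_LIMIT = 1.5
CRP_OUTLIER_LIMIT = 10.0
ADIPONECTIN_OUTLIER_SD = 5.0


@dataclass
class VariantResult:
    variant: str
    n_subjects: int
    exclusion_counts: dict[str, int]
    predictors: tuple[str, ...]
    model: PlscModel
    permutation: PermutationResult | None
    bootstrap: BootstrapResult | None
    weight_correlation_with_main: float | None = None
    zmap_correlation_with_main: float | None = None


@dataclass
class SensitivityReport:
    main: VariantResult
    variants: dict[str, VariantResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in [self.main, *self.variants.values()]:
            rows.append(
                {
                    "variant": res.variant,
                    "n_subjects": res.n_subjects,
                    "n_excluded": sum(res.exclusion_counts.values()),
                    "n_predictors": len(res.predictors),
                    "delta1": res.model.delta[0],
                    "lv1_r": res.model.lv_correlations[0],
                    "lv1_p": (
                        res.permutation.p_values[0] if res.permutation else np.nan
                    ),
                    "weight_r_vs_main": res.weight_correlation_with_main,
                    "zmap_r_vs_main": res.zmap_correlation_with_main,
                }
            )
        return pd.DataFrame(rows)


def _variant_rules(variant: str | None) -> list[ExclusionRule]:
    rules = default_exclusion_rules()
    if variant == "il6_detection":
        rules.append(
            ExclusionRule("il6_censored", "il6", "censored", IL6_DETECTION_LIMIT)
        )
    elif variant == "crp_outlier":
        rules.append(ExclusionRule("crp>10", "crp", "max", CRP_OUTLIER_LIMIT))
    elif variant == "adiponectin_outlier":
        rules.append(
            ExclusionRule(
                "adiponectin<mean-5sd",
                "adiponectin",
                "low_outlier",
                ADIPONECTIN_OUTLIER_SD,
            )
        )
    return rules


def _analyse(
    table: pd.DataFrame,
    images: np.ndarray,
    probability_image: np.ndarray,
    affine: np.ndarray,
    variant: str | None,
    seed: int,
    n_permutations: int,
    n_bootstraps: int,
    mask_threshold: float = 0.3,
) -> VariantResult:
    if variant is not None and variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; options: {VARIANTS}")
    predictors = PREDICTORS + (("sbp",) if variant == "add_sbp" else ())
    work = table.copy()
    if variant == "medication_adjusted":
        work = adjust_for_medication(work)
    rules = _variant_rules(variant)

    from .preprocess import apply_exclusions

    kept, _precheck = apply_exclusions(work, rules)
    if len(kept) < 0.1 * len(table):
        raise RuntimeError(
            f"variant {variant!r} removed more than 90% of subjects "
            f"({len(kept)} of {len(table)} remain)"
        )

    xblock, yblock, report, _ = prepare_blocks(
        work,
        images,
        probability_image,
        affine,
        predictors=predictors,
        exclusion_rules=rules,
        threshold=mask_threshold,
    )
    if xblock.n < 0.1 * len(table):
        raise RuntimeError(
            f"variant {variant!r} removed more than 90% of subjects "
            f"({xblock.n} of {len(table)} remain)"
        )
    r_full = min(len(predictors), yblock.v, xblock.n - 1)
    model = fit_plsc(
        xblock.X, yblock.Y, R=r_full, column_names=xblock.column_names
    )
    perm = (
        permutation_test(
            xblock.X, yblock.Y, R=r_full, n_permutations=n_permutations, seed=seed
        )
        if n_permutations
        else None
    )
    boot = (
        bootstrap_weights(
            xblock.X, yblock.Y, n_bootstraps=n_bootstraps, seed=seed, model=model
        )
        if n_bootstraps
        else None
    )
    return VariantResult(
        variant=variant or "main",
        n_subjects=xblock.n,
        exclusion_counts=dict(report.counts),
        predictors=predictors,
        model=model,
        permutation=perm,
        bootstrap=boot,
    )


def run_main_analysis(
    table, images, probability_image, affine, seed=0,
    n_permutations=2000, n_bootstraps=2000,
) -> VariantResult:
    """The un-modified analysis all variants are compared against."""
    return _analyse(
        table, images, probability_image, affine, None, seed,
        n_permutations, n_bootstraps,
    )


def _compare_to_main(res: VariantResult, main: VariantResult) -> VariantResult:
    shared = [p for p in res.predictors if p in main.predictors]
    iu = [res.predictors.index(p) for p in shared]
    im = [main.predictors.index(p) for p in shared]
    wv, wm = res.model.U[iu, 0], main.model.U[im, 0]
    res.weight_correlation_with_main = float(np.corrcoef(wv, wm)[0, 1])
    if res.bootstrap is not None and main.bootstrap is not None:
        zv, zm = res.bootstrap.z_v[:, 0], main.bootstrap.z_v[:, 0]
        if zv.shape == zm.shape:
            res.zmap_correlation_with_main = float(np.corrcoef(zv, zm)[0, 1])
    return res


def run_variant(
    table,
    images,
    probability_image,
    affine,
    variant: str,
    main: VariantResult | None = None,
    seed: int = 0,
    n_permutations: int = 2000,
    n_bootstraps: int = 2000,
) -> VariantResult:
    """Run one sensitivity variant; seeds are shared with the main run."""
    res = _analyse(
        table, images, probability_image, affine, variant, seed,
        n_permutations, n_bootstraps,
    )
    if main is not None:
        res = _compare_to_main(res, main)
    return res


def run_all_variants(
    table,
    images,
    probability_image,
    affine,
    variants: tuple[str, ...] = VARIANTS,
    seed: int = 0,
    n_permutations: int = 2000,
    n_bootstraps: int = 2000,
) -> SensitivityReport:
    main = run_main_analysis(
        table, images, probability_image, affine, seed,
        n_permutations, n_bootstraps,
    )
    report = SensitivityReport(main=main)
    for variant in variants:
        report.variants[variant] = run_variant(
            table, images, probability_image, affine, variant, main,
            seed, n_permutations, n_bootstraps,
        )
    return report
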