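"""From raw participant tables and GMV images to analysis-ready matrices.

The pipeline order is fixed: exclusion filters, log transform of the
right-skewed assays, confound residualization (age/sex for the metabolic
panel; age/sex/TIV per voxel for GMV), then column standardization. Each
block records what was done to it, so every downstream result can be traced
back to a concrete sequence of transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import LOG_PREDICTORS, PREDICTORS

__all__ = [
    "ExclusionRule",
    "ExclusionReport",
    "MetabolicBlock",
    "VoxelBlock",
    "apply_exclusions",
    "transform_predictors",
    "residualize",
    "build_voxel_block",
    "standardize_columns",
    "adjust_for_medication",
    "build_metabolic_block",
    "default_exclusion_rules",
    "prepare_blocks",
]

GM_PROBABILITY_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# exclusion filters


@dataclass(frozen=True)
class ExclusionRule:
    """One subject-level filter.

    kind:
      * ``"min"``  — exclude subjects with column value < threshold
      * ``"max"``  — exclude subjects with column value > threshold
      * ``"censored"`` — exclude subjects whose value equals the detection
        limit (the marker left by clamp-style censoring)
      * ``"low_outlier"`` — exclude value < mean - k*SD, computed on the log
        scale when the column is one of the log-transformed assays
      * ``"missing"`` — exclude subjects with a missing value in the column
    """

    name: str
    column: str
    kind: str
    threshold: float | None = None

    def mask_excluded(self, table: pd.DataFrame) -> pd.Series:
        if self.column not in table.columns:
            raise KeyError(
                f"exclusion rule {self.name!r} references missing column "
                f"{self.column!r}"
            )
        col = table[self.column]
        if self.kind == "min":
            return col < self.threshold
        if self.kind == "max":
            return col > self.threshold
        if self.kind == "censored":
            return col <= self.threshold
        if self.kind == "low_outlier":
            vals = col.astype(float)
            if self.column in LOG_PREDICTORS and (vals > 0).all():
                vals = np.log(vals)
            k = 5.0 if self.threshold is None else self.threshold
            return vals < vals.mean() - k * vals.std(ddof=1)
        if self.kind == "missing":
            return col.isna()
        raise ValueError(f"unknown exclusion-rule kind {self.kind!r}")


@dataclass
class ExclusionReport:
    """Auditable record of how many subjects each rule removed, in order."""

    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    surviving_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "n_excluded": v} for k, v in self.counts.items()]
        rows.append({"rule": "_surviving", "n_excluded": self.n_surviving})
        return pd.DataFrame(rows)


def default_exclusion_rules(mmse_cutoff: int = 27) -> list[ExclusionRule]:
    """The screening filter applied in the main analysis: keep cognitively
    healthy subjects (MMSE >= cutoff)."""
    return [ExclusionRule("mmse<27", "mmse", "min", float(mmse_cutoff))]


def apply_exclusions(
    table: pd.DataFrame, rules: list[ExclusionRule]
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply filters sequentially; each rule counts only subjects still in
    the running sample, so counts sum consistently."""
    report = ExclusionReport(n_input=len(table))
    current = table
    for rule in rules:
        excl = rule.mask_excluded(current)
        report.counts[rule.name] = int(excl.sum())
        current = current.loc[~excl]
    report.surviving_ids = list(current["subject_id"])
    return current.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# column transforms


def transform_predictors(
    table: pd.DataFrame, log_columns: tuple[str, ...] = LOG_PREDICTORS
) -> pd.DataFrame:
    """Natural-log transform of the right-skewed assay columns.

    The remaining predictors are left untouched; scale is irrelevant after
    standardization, so the base of the logarithm is immaterial.
    """
    out = table.copy()
    for col in log_columns:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        bad = ~(vals > 0)
        if bad.any():
            sid = out.loc[bad, "subject_id"].iloc[0] if "subject_id" in out else "?"
            raise ValueError(
                f"non-positive value in log column {col!r} (subject {sid})"
            )
        out[col] = np.log(vals)
        out.attrs.setdefault("log_transformed", []).append(col)
    return out


def residualize(columns: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Per-column OLS residuals against the confounds (intercept included).

    Residuals are orthogonal to the confounds and the constant; applying the
    operation twice is a no-op.
    """
    x = np.atleast_2d(np.asarray(columns, dtype=float))
    if x.shape[0] == 1 and np.asarray(columns).ndim == 1:
        x = x.T
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    n = x.shape[0]
    if c.shape[0] != n:
        raise ValueError("columns and confounds have different N")
    design = np.column_stack([np.ones(n), c])
    if n <= design.shape[1]:
        raise ValueError("need N > number of confounds + 1")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "confound matrix is rank deficient after adding an intercept"
        )
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def standardize_columns(matrix: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center each column to mean 0 and scale to SD 1 (sample SD, N-1)."""
    x = np.asarray(matrix, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    zero = sd <= 0
    if zero.any():
        raise ValueError(
            f"zero-variance column(s) at index {np.flatnonzero(zero).tolist()}; "
            "drop constant columns upstream"
        )
    return (x - mean) / sd


def adjust_for_medication(table: pd.DataFrame) -> pd.DataFrame:
    """Medication-adjusted biomarker values.

    HbA1c is residualized on the antidiabetic-treatment flag; total
    cholesterol and HDL on the antihyperlipidemic flag (intercepts
    included — with a binary flag this is two-group mean subtraction).
    """
    for flag in ("antidiabetic_flag", "antihyperlipidemic_flag"):
        if flag not in table.columns:
            raise KeyError(f"medication adjustment requires column {flag!r}")
    out = table.copy()
    diab = out["antidiabetic_flag"].to_numpy(dtype=float)
    lip = out["antihyperlipidemic_flag"].to_numpy(dtype=float)

    def _adjust(vals: np.ndarray, flag: np.ndarray) -> np.ndarray:
        if flag.std() == 0:  # constant flag: the model reduces to the intercept
            return vals - vals.mean()
        return residualize(vals, flag)[:, 0]

    out["hba1c"] = _adjust(out["hba1c"].to_numpy(dtype=float), diab)
    for col in ("total_chol", "hdl"):
        out[col] = _adjust(out[col].to_numpy(dtype=float), lip)
    return out


# ---------------------------------------------------------------------------
# analysis-ready blocks


@dataclass
class MetabolicBlock:
    """N x p matrix of transformed, residualized, standardized predictors."""

    X: np.ndarray
    column_names: tuple[str, ...]
    transform_log: dict[str, list[str]] = field(default_factory=dict)
    confounders: tuple[str, ...] = ()

    def __post_init__(self):
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match matrix")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class VoxelBlock:
    """N x v matrix of masked, residualized, standardized GMV values.

    Columns follow raster order of the in-mask voxels (first grid axis
    fastest-varying in C order, i.e. ``np.flatnonzero(mask)`` order), so
    cluster coordinates are reproducible across runs.
    """

    Y: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    voxel_indices: np.ndarray  # v x 3 integer grid indices

    def __post_init__(self):
        if self.Y.shape[1] != int(self.mask.sum()):
            raise ValueError("column count does not equal mask size")
        if self.voxel_indices.shape != (self.Y.shape[1], 3):
            raise ValueError("voxel_indices must be v x 3")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def v(self) -> int:
        return self.Y.shape[1]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3D grid volume."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol

    def peak_mm(self, index3: np.ndarray) -> np.ndarray:
        """Map a voxel grid index to mm coordinates via the affine."""
        hom = np.append(np.asarray(index3, dtype=float), 1.0)
        return (self.affine @ hom)[:3]


def build_voxel_block(
    images: np.ndarray,
    probability_image: np.ndarray,
    affine: np.ndarray,
    threshold: float = GM_PROBABILITY_THRESHOLD,
) -> tuple[np.ndarray, VoxelBlock]:
    """Mask per-subject volumes into an N x v matrix.

    Returns the *unstandardized* masked matrix alongside the block skeleton;
    residualization/standardization are applied by the caller so that e.g.
    total-GMV computations can reuse the raw values.
    """
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim != 4:
        raise ValueError("images must be a 4D (N, i, j, k) array")
    if imgs.shape[1:] != probability_image.shape:
        raise ValueError(
            f"image grid {imgs.shape[1:]} does not match probability grid "
            f"{probability_image.shape}"
        )
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = probability_image >= threshold
    if not mask.any():
        raise ValueError("empty mask: no voxel reaches the probability threshold")
    raw = imgs[:, mask]
    voxel_indices = np.argwhere(mask)
    block = VoxelBlock(
        Y=raw.copy(), mask=mask, affine=np.asarray(affine), voxel_indices=voxel_indices
    )
    return raw, block


def build_metabolic_block(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTORS,
    confounders: tuple[str, ...] = ("age", "sex"),
    log_columns: tuple[str, ...] = LOG_PREDICTORS,
) -> MetabolicBlock:
    """transform -> residualize -> standardize for the predictor panel."""
    transformed = transform_predictors(table, log_columns=log_columns)
    x = transformed[list(predictors)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite predictor values after transform")
    conf = transformed[list(confounders)].to_numpy(dtype=float)
    resid = residualize(x, conf)
    std = standardize_columns(resid)
    return MetabolicBlock(
        X=std,
        column_names=tuple(predictors),
        transform_log={
            "log": [c for c in log_columns if c in table.columns],
            "residualized_on": list(confounders),
            "standardized": list(predictors),
        },
        confounders=tuple(confounders),
    )


def prepare_blocks(
    table: pd.DataFrame,
    images: np.ndarray,
    probability_image: np.ndarray,
    affine: np.ndarray,
    predictors: tuple[str, ...] = PREDICTORS,
    x_confounders: tuple[str, ...] = ("age", "sex"),
    y_confounders: tuple[str, ...] = ("age", "sex", "tiv"),
    threshold: float = GM_PROBABILITY_THRESHOLD,
    exclusion_rules: list[ExclusionRule] | None = None,
) -> tuple[MetabolicBlock, VoxelBlock, ExclusionReport, np.ndarray]:
    """Full preprocessing path producing both analysis-ready blocks.

    Returns (metabolic block, voxel block with standardized Y, exclusion
    report, unstandardized masked GMV matrix for the surviving subjects).
    """
    rules = (
        default_exclusion_rules() if exclusion_rules is None else exclusion_rules
    )
    kept, report = apply_exclusions(table, rules)
    keep_pos = np.flatnonzero(
        table["subject_id"].isin(kept["subject_id"]).to_numpy()
    )
    imgs = np.asarray(images)[keep_pos]

    xblock = build_metabolic_block(
        kept, predictors=predictors, confounders=x_confounders
    )
    raw_y, yblock = build_voxel_block(imgs, probability_image, affine, threshold)
    conf = kept[list(y_confounders)].to_numpy(dtype=float)
    resid = residualize(raw_y, conf)
    sd = resid.std(axis=0, ddof=1)
    keep_vox = sd > 0
    if not keep_vox.all():
        # constant voxels carry no information; drop them with a trace
        resid = resid[:, keep_vox]
        yblock = VoxelBlock(
            Y=resid,
            mask=yblock.to_volume(keep_vox.astype(float)).astype(bool),
            affine=yblock.affine,
            voxel_indices=yblock.voxel_indices[keep_vox],
        )
        raw_y = raw_y[:, keep_vox]
        yblock.Y = standardize_columns(resid)
    else:
        yblock.Y = standardize_columns(resid)
    return xblock, yblock, report, raw_y
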