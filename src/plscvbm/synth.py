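"""Synthetic cohort generator with planted cross-block latent structure.

Emulates the statistical shape of a population-based aging cohort in which a
nine-variable anthropometric/metabolic panel (BMI, WHR, HbA1c, total
cholesterol, HDL, CRP, IL6, adiponectin, leptin) covaries with voxelwise gray
matter volume (GMV):

* marginals follow published cohort summaries — normal for anthropometry and
  the clinical-chemistry panel, log-normal for the inflammation markers and
  adipokines (IL6, CRP, leptin, adiponectin), with IL6 left-censored at its
  assay detection limit of 1.5 pg/ml (values clamped, not missing);
* age, sex and total intracranial volume (TIV) confound both blocks, so
  confound residualization is genuinely required before the cross-block
  association can be recovered;
* one or more planted rank-one components tie the two blocks together: a
  shared standard-normal latent score enters the predictor block through a
  unit weight vector ``u_true`` and the voxel block through a smooth-blob
  unit pattern ``v_true``, calibrated so that the correlation between the
  two true latent scores equals the requested ``rho``;
* voxel noise is spatially smoothed to a configurable FWHM, mimicking the
  smoothness of modulated, kernel-smoothed VBM output.

Every cohort is bit-reproducible from its spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .seeding import stage_rng

__all__ = [
    "PREDICTORS",
    "LOG_PREDICTORS",
    "MarginalSpec",
    "PlantedComponent",
    "ConfoundSpec",
    "CohortSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_cognitive_scores",
    "default_u_true",
]

#: canonical predictor order used throughout the package
PREDICTORS = (
    "bmi",
    "whr",
    "hba1c",
    "total_chol",
    "hdl",
    "crp",
    "il6",
    "adiponectin",
    "leptin",
)

#: right-skewed assays modelled (and later analysed) on the log scale
LOG_PREDICTORS = ("crp", "il6", "adiponectin", "leptin")


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal for one raw predictor column."""

    family: str  # "normal" | "lognormal"
    mean: float
    sd: float

    def __post_init__(self):
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.sd > 0:
            raise ValueError(f"marginal SD must be > 0, got {self.sd}")

    def log_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln(value) matching the raw-scale mean/SD."""
        s2 = np.log1p((self.sd / self.mean) ** 2)
        return float(np.log(self.mean) - s2 / 2.0), float(np.sqrt(s2))


#: cohort-summary marginals for the default nine-variable panel
DEFAULT_MARGINALS: dict[str, MarginalSpec] = {
    "bmi": MarginalSpec("normal", 27.7, 4.1),
    "whr": MarginalSpec("normal", 0.96, 0.08),
    "hba1c": MarginalSpec("normal", 5.53, 0.59),
    "total_chol": MarginalSpec("normal", 5.86, 1.08),
    "hdl": MarginalSpec("normal", 5.85, 1.10),
    "crp": MarginalSpec("lognormal", 2.95, 7.40),
    "il6": MarginalSpec("lognormal", 3.76, 3.88),
    "adiponectin": MarginalSpec("lognormal", 7710.4, 4662.6),
    "leptin": MarginalSpec("lognormal", 12.187, 12.135),
}

#: assay lower detection limits (raw scale); values are clamped, not dropped
DEFAULT_CENSOR_LIMITS: dict[str, float] = {"il6": 1.5}


def default_u_true(p: int = 9) -> np.ndarray:
    """Unit predictor weight vector qualitatively matching an adiposity
    profile: strong positive BMI/leptin/CRP, negative adiponectin."""
    if p == 9:
        w = np.array([0.50, 0.30, 0.25, 0.10, 0.05, 0.33, 0.15, -0.35, 0.39])
    else:
        w = np.zeros(p)
        w[: min(3, p)] = [0.6, 0.5, 0.4][: min(3, p)]
    return w / np.linalg.norm(w)


@dataclass(frozen=True)
class PlantedComponent:
    """One rank-one cross-block association with known ground truth.

    Parameters
    ----------
    u_true:
        Unit weight vector over the predictors.
    rho:
        Target correlation of the two true latent scores, in [0, 1].
    blob_centers_vox:
        Voxel-grid centres of the Gaussian blobs forming the voxel pattern.
        ``None`` picks default interior locations.
    blob_sigma_mm:
        Spatial SD of each blob in mm.
    blob_signs:
        Sign of each blob (defaults to all -1: the "risk profile lowers
        GMV" orientation).
    """

    u_true: np.ndarray
    rho: float = 0.5
    blob_centers_vox: tuple[tuple[float, float, float], ...] | None = None
    blob_sigma_mm: float = 6.0
    blob_signs: tuple[int, ...] | None = None

    def __post_init__(self):
        u = np.asarray(self.u_true, dtype=float)
        if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-8):
            raise ValueError("u_true must have unit norm")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        object.__setattr__(self, "u_true", u)


@dataclass(frozen=True)
class ConfoundSpec:
    """Effect sizes (in SD units of each outcome column) and distributions
    of the confounders age, sex and TIV."""

    age_range: tuple[float, float] = (60.0, 79.0)
    sex_ratio: float = 0.556  # fraction male (sex = 1)
    tiv_mean_ml: float = 1400.0
    tiv_sd_ml: float = 120.0
    tiv_sex_shift_ml: float = 130.0  # added for males
    age_on_x: float = 0.20
    sex_on_x: float = 0.25
    age_on_y: float = -0.40
    sex_on_y: float = 0.30
    tiv_on_y: float = 0.40

    def __post_init__(self):
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age bounds must be ordered")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_subjects: int = 500
    grid_shape: tuple[int, int, int] = (22, 22, 11)
    voxel_size_mm: float = 2.0
    smoothness_fwhm_mm: float = 8.0
    n_predictors: int = 9
    planted_components: tuple[PlantedComponent, ...] = field(
        default_factory=lambda: (PlantedComponent(default_u_true()),)
    )
    confounds: ConfoundSpec = field(default_factory=ConfoundSpec)
    marginals: dict[str, MarginalSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    censor_limits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_LIMITS)
    )
    x_noise_sd: float = 1.0
    y_noise_sd: float = 1.0
    mmse_low_fraction: float = 0.02  # fraction scoring below 27
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid must have >= 2 voxels per axis")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("FWHM must be >= 0")
        if self.x_noise_sd < 0 or self.y_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        names = self.predictor_names
        for comp in self.planted_components:
            if comp.u_true.shape != (self.n_predictors,):
                raise ValueError(
                    f"u_true has length {comp.u_true.shape[0]}, "
                    f"expected n_predictors={self.n_predictors}"
                )
        for name in self.censor_limits:
            if name not in names:
                raise ValueError(f"censor limit for unknown column {name!r}")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        if self.n_predictors == 9:
            return PREDICTORS
        return tuple(f"x{i + 1}" for i in range(self.n_predictors))

    def marginal_for(self, name: str) -> MarginalSpec:
        return self.marginals.get(name, MarginalSpec("normal", 0.0, 1.0))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.grid_shape) * self.voxel_size_mm / 2.0
        return aff


@dataclass
class SyntheticTruth:
    """Ground truth planted in a cohort; the recovery target for tests."""

    u_true: np.ndarray  # p x C
    v_true: np.ndarray  # v_mask x C (unit columns over in-mask voxels)
    v_true_vol: np.ndarray  # C x grid volumes (zero outside mask)
    rho: np.ndarray  # C
    latent_scores: np.ndarray  # N x C shared latent t
    confound_spec: ConfoundSpec
    mask: np.ndarray  # boolean grid, probability >= 0.3


@dataclass
class SyntheticCohort:
    """A generated cohort: participant table, GMV images, mask, truth."""

    spec: CohortSpec
    table: pd.DataFrame
    gmv: np.ndarray  # N x grid, float64
    mask_probability: np.ndarray  # grid, in [0, 1]
    affine: np.ndarray
    truth: SyntheticTruth

    @property
    def n_subjects(self) -> int:
        return len(self.table)


def _mask_probability_image(shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth ellipsoidal gray-matter probability image in [0, 1].

    Roughly half of the grid exceeds the conventional 0.3 threshold, so
    masking is a real operation rather than a no-op.
    """
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    d2 = gx**2 + gy**2 + gz**2
    return np.exp(-d2 / (2 * 0.62**2))


def _smooth_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def _unit_variance_filter_norm(sigma_vox: float, shape) -> float:
    """L2 norm of the smoothing kernel: dividing a filtered white-noise
    field by this restores (approximately) unit pointwise variance."""
    if sigma_vox == 0:
        return 1.0
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma_vox, mode="constant")
    return float(np.sqrt((kernel**2).sum()))


def _build_v_true(
    spec: CohortSpec, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Blob patterns for each planted component, unit-norm over the mask.

    Returns (v_mask: v x C, v_vol: C x grid). Components are orthogonalized
    within the voxel block (Gram-Schmidt) so planted structure is identified.
    """
    shape = spec.grid_shape
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    cols = []
    vols = []
    default_centers = [
        (0.35, 0.5, 0.5),
        (0.65, 0.4, 0.45),
        (0.5, 0.65, 0.55),
    ]
    for ci, comp in enumerate(spec.planted_components):
        if comp.blob_centers_vox is not None:
            centers = [np.asarray(c, dtype=float) for c in comp.blob_centers_vox]
        else:
            # stagger default blob placement between components
            frac = default_centers[(ci) % len(default_centers)]
            centers = [
                np.array([f * (s - 1) for f, s in zip(frac, shape)]),
                np.array(
                    [(1 - f * 0.8) * (s - 1) * 0.7 for f, s in zip(frac, shape)]
                ),
            ]
        signs = comp.blob_signs or tuple(-1 for _ in centers)
        sigma_vox = comp.blob_sigma_mm / spec.voxel_size_mm
        vol = np.zeros(shape)
        for center, sign in zip(centers, signs):
            d2 = sum((g - c) ** 2 for g, c in zip(coords, center))
            vol += sign * np.exp(-d2 / (2 * sigma_vox**2))
        vec = vol[mask]
        # orthogonalize against previously planted voxel patterns
        for prev in cols:
            vec = vec - prev * (prev @ vec)
        nrm = np.linalg.norm(vec)
        if nrm < 1e-12:
            raise ValueError("degenerate (empty or collinear) blob pattern")
        vec = vec / nrm
        full = np.zeros(shape)
        full[mask] = vec
        cols.append(vec)
        vols.append(full)
    return np.column_stack(cols), np.stack(vols)


def _orthogonalize_u(components: tuple[PlantedComponent, ...]) -> np.ndarray:
    """Stacked u_true vectors, Gram-Schmidt orthonormalized in order."""
    us = []
    for comp in components:
        u = comp.u_true.copy()
        for prev in us:
            u = u - prev * (prev @ u)
        nrm = np.linalg.norm(u)
        if nrm < 1e-10:
            raise ValueError("planted u_true vectors are collinear")
        us.append(u / nrm)
    return np.column_stack(us)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort according to ``spec``; deterministic given its seed.

    Construction order (each step motivated by what the analysis must undo):

    1. shared standard-normal latent scores ``t_c``, one per component;
    2. predictor block: ``gamma_c * u_c t_c`` + white noise, with
       ``gamma_c = sqrt(rho_c / (1 - rho_c))`` so the true latent
       correlation equals ``rho_c`` at unit noise;
    3. voxel block: blob pattern times ``gamma_c * sqrt(v^T K v)`` (K the
       smoothed-noise covariance, so smoothing does not dilute rho) plus
       spatially smoothed unit-variance noise;
    4. confound effects of age/sex/TIV added to both blocks in SD units;
    5. columns rescaled to the target marginals (log-normal columns built by
       exponentiating a matched normal on the log scale);
    6. left-censoring applied last by clamping to the detection limit.
    """
    rng = stage_rng(spec.seed, "simulate")
    n = spec.n_subjects
    p = spec.n_predictors
    names = spec.predictor_names
    ncomp = len(spec.planted_components)
    conf = spec.confounds

    # --- confounders -----------------------------------------------------
    age = rng.uniform(*conf.age_range, size=n)
    sex = (rng.random(n) < conf.sex_ratio).astype(float)
    tiv = (
        conf.tiv_mean_ml
        + conf.tiv_sex_shift_ml * (sex - conf.sex_ratio)
        + rng.normal(0.0, conf.tiv_sd_ml, size=n)
    )
    age_z = (age - age.mean()) / age.std(ddof=1)
    sex_c = (sex - sex.mean()) / max(sex.std(ddof=1), 1e-12)
    tiv_z = (tiv - tiv.mean()) / tiv.std(ddof=1)

    # --- latent structure ------------------------------------------------
    t = rng.standard_normal((n, ncomp)) if ncomp else np.zeros((n, 0))
    rhos = np.array([c.rho for c in spec.planted_components])
    gammas = np.where(rhos < 1.0, np.sqrt(rhos / np.maximum(1.0 - rhos, 1e-12)), 1.0)
    u_mat = (
        _orthogonalize_u(spec.planted_components) if ncomp else np.zeros((p, 0))
    )

    x_latent = t * gammas @ u_mat.T if ncomp else np.zeros((n, p))
    x_noise = rng.standard_normal((n, p)) * spec.x_noise_sd
    x_std = x_latent + x_noise
    x_var = (u_mat**2 @ gammas**2 if ncomp else np.zeros(p)) + spec.x_noise_sd**2

    # confound effects on predictors (uniform effect sizes across columns)
    x_std = x_std + np.outer(age_z, np.full(p, conf.age_on_x)) + np.outer(
        sex_c, np.full(p, conf.sex_on_x)
    )
    x_var = x_var + conf.age_on_x**2 + conf.sex_on_x**2
    x_std = x_std / np.sqrt(x_var)

    # --- raw-scale marginals + censoring ---------------------------------
    table = pd.DataFrame({"subject_id": [f"sub-{i:05d}" for i in range(n)]})
    for j, name in enumerate(names):
        marg = spec.marginal_for(name)
        col = x_std[:, j]
        if marg.family == "lognormal":
            mu, sigma = marg.log_params()
            raw = np.exp(mu + sigma * col)
        else:
            raw = marg.mean + marg.sd * col
        limit = spec.censor_limits.get(name)
        if limit is not None:
            raw = np.maximum(raw, limit)
        table[name] = raw

    table["age"] = age
    table["sex"] = sex.astype(int)
    table["tiv"] = tiv

    # systolic blood pressure: age-linked, no planted cross-block loading
    table["sbp"] = (
        134.44
        + 16.24 * (0.25 * age_z + np.sqrt(1 - 0.25**2) * rng.standard_normal(n))
    )

    # MMSE: mostly 27-30, a small tail below the screening cut-off
    mmse = 30 - rng.binomial(3, 0.25, size=n)
    low = rng.random(n) < spec.mmse_low_fraction
    mmse[low] = rng.integers(20, 27, size=int(low.sum()))
    table["mmse"] = mmse

    # medication/diagnosis flags tied to the relevant biomarker
    hba1c_z = (table["hba1c"] - table["hba1c"].mean()) / table["hba1c"].std()
    chol_z = (table["total_chol"] - table["total_chol"].mean()) / table[
        "total_chol"
    ].std()
    p_diab = 1.0 / (1.0 + np.exp(-(1.5 * hba1c_z - 2.0)))
    p_lip = 1.0 / (1.0 + np.exp(-(1.0 * chol_z - 1.2)))
    table["antidiabetic_flag"] = (rng.random(n) < p_diab).astype(int)
    table["antihyperlipidemic_flag"] = (rng.random(n) < p_lip).astype(int)

    # --- voxel block ------------------------------------------------------
    prob = _mask_probability_image(spec.grid_shape)
    mask = prob >= 0.3
    v_mask, v_vol = (
        _build_v_true(spec, mask) if ncomp else (np.zeros((int(mask.sum()), 0)),
                                                 np.zeros((0, *spec.grid_shape)))
    )
    nvox = int(mask.sum())

    sigma_vox = _smooth_sigma_vox(spec.smoothness_fwhm_mm, spec.voxel_size_mm)
    knorm = _unit_variance_filter_norm(sigma_vox, spec.grid_shape)

    # scale the planted pattern so corr(X u_true, Y v_true) = rho despite
    # smoothed noise being correlated along the blob direction:
    # c = v^T K v with K = G G^T / ||g||^2 and G the (symmetric) filter.
    gamma_y = np.empty(ncomp)
    for c in range(ncomp):
        if sigma_vox > 0:
            gv = gaussian_filter(v_vol[c], sigma_vox, mode="constant")
            proj_var = float((gv[mask] ** 2).sum()) / knorm**2
        else:
            proj_var = 1.0
        gamma_y[c] = gammas[c] * np.sqrt(proj_var) * spec.y_noise_sd
        if spec.y_noise_sd == 0:
            gamma_y[c] = gammas[c]

    y = np.zeros((n, nvox))
    if ncomp:
        y += t * gamma_y @ v_mask.T
    if spec.y_noise_sd > 0:
        noise = np.empty((n, nvox))
        for i in range(n):
            field3 = rng.standard_normal(spec.grid_shape)
            if sigma_vox > 0:
                field3 = gaussian_filter(field3, sigma_vox, mode="constant") / knorm
            noise[i] = field3[mask]
        y += spec.y_noise_sd * noise

    y = (
        y
        + conf.age_on_y * age_z[:, None]
        + conf.sex_on_y * sex_c[:, None]
        + conf.tiv_on_y * tiv_z[:, None]
    )

    # map to GMV-like image units (positive, bounded-ish density values)
    y_sd = np.sqrt(
        (v_mask**2 @ gamma_y**2 if ncomp else 0.0)
        + spec.y_noise_sd**2
        + conf.age_on_y**2
        + conf.sex_on_y**2
        + conf.tiv_on_y**2
    )
    y_sd = np.maximum(y_sd, 1e-12)
    gmv_mask = 0.55 + 0.08 * (y / y_sd)

    gmv = np.zeros((n, *spec.grid_shape))
    gmv[:, mask] = gmv_mask

    truth = SyntheticTruth(
        u_true=u_mat,
        v_true=v_mask,
        v_true_vol=v_vol,
        rho=rhos,
        latent_scores=t,
        confound_spec=conf,
        mask=mask,
    )
    return SyntheticCohort(
        spec=spec,
        table=table,
        gmv=gmv,
        mask_probability=prob,
        affine=spec.affine,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cognitive scores

#: raw-score scales: (mean, sd) on the natural scale of each test
_COG_SCALES = {
    "animal_fluency": (23.0, 6.0),
    "s_words": (14.0, 5.0),
    "word_list_learned": (20.0, 4.0),
    "word_list_recalled": (7.0, 2.0),
    "word_list_recognized": (19.0, 1.2),
}


def generate_cognitive_scores(
    cohort: SyntheticCohort,
    loadings: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    component: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Append raw cognitive test scores with a known dependence on the true
    latent score.

    ``loadings`` maps domain -> target standardized slope of the domain
    composite regressed on the true latent score (default all 0). Each raw
    component receives a per-component coefficient solved so the composite
    attains the requested loading; counts are rounded and floored at zero,
    and TMT part B is built as part A times a positive ratio, so B >= A by
    construction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    loadings = dict(loadings or {})
    unknown = set(loadings) - {"executive", "memory", "processing_speed"}
    if unknown:
        raise ValueError(f"unknown cognitive domains: {sorted(unknown)}")
    for dom, val in loadings.items():
        if not -1.0 < val < 1.0:
            raise ValueError(f"loading for {dom} must lie in (-1, 1)")

    rng = stage_rng(
        cohort.spec.seed if seed is None else seed, "cognitive-scores"
    )
    t = cohort.truth.latent_scores[:, component]
    n = len(t)
    table = cohort.table.copy()

    def _latent_mix(a: float) -> np.ndarray:
        eps = rng.standard_normal(n) * noise_sd
        denom = np.sqrt(a**2 + noise_sd**2) if (a or noise_sd) else 1.0
        return (a * t + eps) / max(denom, 1e-12)

    def _comp_coeff(target: float, k: int) -> float:
        # composite = mean of k unit-variance pieces each correlated a/sqrt(a^2+s^2)
        # with t; solve corr(composite, t) = target for the per-piece a.
        if target == 0.0:
            return 0.0
        r2 = target**2
        a2 = r2 / max(k - (k - 1) * r2, 1e-12)  # per-piece squared correlation
        a = np.sqrt(a2 / max(1.0 - a2, 1e-12)) * max(noise_sd, 1e-12)
        return float(np.sign(target) * a)

    a_exec = _comp_coeff(loadings.get("executive", 0.0), 3)
    a_mem = _comp_coeff(loadings.get("memory", 0.0), 3)
    a_proc = _comp_coeff(loadings.get("processing_speed", 0.0), 1)

    def _count(name: str, z: np.ndarray) -> np.ndarray:
        mean, sd = _COG_SCALES[name]
        raw = np.rint(mean + sd * z)
        return np.maximum(raw, 0.0)

    table["animal_fluency"] = _count("animal_fluency", _latent_mix(a_exec))
    table["s_words"] = _count("s_words", _latent_mix(a_exec))

    # TMT: part A loads (negatively) on processing speed; the B/A ratio
    # loads negatively on the executive latent (slower switching = worse).
    tmt_a = 40.0 * np.exp(0.30 * _latent_mix(-a_proc))
    ratio = 1.35 * np.exp(0.25 * _latent_mix(-a_exec))
    table["tmt_a"] = tmt_a
    table["tmt_b"] = tmt_a * (1.0 + ratio)

    table["word_list_learned"] = _count("word_list_learned", _latent_mix(a_mem))
    table["word_list_recalled"] = _count("word_list_recalled", _latent_mix(a_mem))
    table["word_list_recognized"] = _count(
        "word_list_recognized", _latent_mix(a_mem)
    )
    return table


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different seed (convenience for seed sweeps)."""
    return replace(spec, seed=seed)
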