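"""Run configuration: YAML-backed schema, validation, seed plumbing.

A :class:`RunConfig` captures every tunable of the pipeline with the study
defaults (9 latent-variable pairs, 2000 permutations, 2000 bootstraps,
bootstrap-ratio stability threshold 2.3, cluster-forming |Z| > 5, gray-matter
probability mask at 0.3, twenty 80/20 cross-validation splits with 1000
inner permutations). Configs round-trip through YAML, and validation errors
name the offending field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    # paths (optional: the simulate stage can create the inputs)
    participants_csv: str | None = None
    image_dir: str | None = None
    mask_path: str | None = None
    out_dir: str = "plscvbm_run"

    # simulation
    n_subjects: int = 500
    grid_shape: tuple[int, int, int] = (22, 22, 11)
    voxel_size_mm: float = 2.0
    smoothness_fwhm_mm: float = 8.0
    planted_rho: float = 0.5

    # preprocessing
    mask_threshold: float = 0.3
    log_columns: tuple[str, ...] = ("crp", "il6", "adiponectin", "leptin")
    x_confounders: tuple[str, ...] = ("age", "sex")
    y_confounders: tuple[str, ...] = ("age", "sex", "tiv")
    mmse_cutoff: int = 27

    # inference
    n_components: int | str = "full"
    n_permutations: int = 2000
    n_bootstraps: int = 2000
    z_threshold: float = 2.3
    cluster_threshold: float = 5.0
    connectivity: int = 26

    # cross-validation
    cv_splits: int = 20
    cv_test_fraction: float = 0.2
    cv_inner_permutations: int = 1000
    cv_components: int = 2

    # variants
    variants: tuple[str, ...] = ()

    seed: int = 0

    def validate(self) -> None:
        def bad(field_name: str, msg: str):
            raise ValueError(f"config error at {field_name!r}: {msg}")

        positive = {
            "n_subjects": self.n_subjects,
            "n_permutations": self.n_permutations,
            "n_bootstraps": self.n_bootstraps,
            "cv_splits": self.cv_splits,
            "cv_inner_permutations": self.cv_inner_permutations,
            "cv_components": self.cv_components,
            "z_threshold": self.z_threshold,
            "cluster_threshold": self.cluster_threshold,
            "voxel_size_mm": self.voxel_size_mm,
        }
        for name, val in positive.items():
            if not val > 0:
                bad(name, f"must be positive, got {val}")
        if not 0 < self.mask_threshold < 1:
            bad("mask_threshold", f"must lie in (0, 1), got {self.mask_threshold}")
        if not 0 < self.cv_test_fraction < 1:
            bad("cv_test_fraction", "must lie in (0, 1)")
        if self.connectivity not in (6, 26):
            bad("connectivity", f"must be 6 or 26, got {self.connectivity}")
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            bad("grid_shape", "needs three axes with >= 2 voxels each")
        if not 0 <= self.planted_rho <= 1:
            bad("planted_rho", "must lie in [0, 1]")
        if self.smoothness_fwhm_mm < 0:
            bad("smoothness_fwhm_mm", "must be >= 0")
        if self.n_components != "full" and not (
            isinstance(self.n_components, int) and self.n_components > 0
        ):
            bad("n_components", "must be a positive integer or 'full'")
        from .sensitivity import VARIANTS

        for v in self.variants:
            if v not in VARIANTS:
                bad("variants", f"unknown variant {v!r}; options {VARIANTS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_shape", "log_columns", "x_confounders", "y_confounders", "variants"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config error: unknown field(s) {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("grid_shape", "log_columns", "x_confounders", "y_confounders", "variants"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
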