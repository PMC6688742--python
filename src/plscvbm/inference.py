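"""Resampling inference for PLSC: permutation p-values, bootstrap stability,
and cluster summaries of the voxelwise bootstrap-ratio map.

Permutation: rows of X are shuffled while Y stays fixed, breaking the
cross-block link but preserving each block's internal covariance. The null
distribution of each singular value is compared rank-by-rank to the observed
one, p_r = #(permuted delta_r > observed delta_r) / n_permutations. A p of 0
therefore means "below the resolution 1/n_permutations".

Bootstrap: subjects are resampled with replacement jointly in X and Y, the
decomposition recomputed, and each replicate aligned (component order and
sign) to the original weights before accumulating standard errors. The
bootstrap ratio Z = weight / SE flags a weight as stable when |Z| exceeds a
threshold (2.3 by convention here).

Clusters: connected components of suprathreshold |Z| voxels (26-neighbor
connectivity by default, as in FSL's cluster tool), reported with size, peak
|Z|, peak weight and peak mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .plsc import PlscModel, cross_product_svd, fit_plsc
from .preprocess import VoxelBlock, standardize_columns
from .seeding import stage_rng

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "Cluster",
    "ClusterSet",
    "permutation_test",
    "bootstrap_weights",
    "cluster_z_map",
]

Z_STABILITY_THRESHOLD = 2.3
CLUSTER_FORMING_Z = 5.0
Z_CAP = 50.0


@dataclass
class PermutationResult:
    n_permutations: int
    null_delta: np.ndarray  # n_permutations x R
    observed_delta: np.ndarray
    p_values: np.ndarray
    seed: int
    alpha: float = 0.05

    @property
    def resolution(self) -> float:
        """Smallest nonzero p the scheme can resolve."""
        return 1.0 / self.n_permutations

    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.p_values) + 1),
                "delta": self.observed_delta,
                "p": self.p_values,
                "p_display": [
                    f"<{self.resolution:g}" if p == 0 else f"{p:g}"
                    for p in self.p_values
                ],
                "significant": self.significant(),
            }
        )


@dataclass
class BootstrapResult:
    n_bootstraps: int
    se_u: np.ndarray  # p x R
    se_v: np.ndarray  # v x R
    z_u: np.ndarray
    z_v: np.ndarray
    z_threshold: float
    seed: int
    n_redrawn: int = 0
    degenerate_u: np.ndarray | None = None
    degenerate_v: np.ndarray | None = None
    mean_u: np.ndarray | None = None  # mean aligned bootstrap weights
    mean_v: np.ndarray | None = None

    @property
    def stable_mask_u(self) -> np.ndarray:
        return np.abs(self.z_u) > self.z_threshold

    @property
    def stable_mask_v(self) -> np.ndarray:
        return np.abs(self.z_v) > self.z_threshold


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    R: int | str = "full",
    n_permutations: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Permutation null for the singular values.

    Only X rows are permuted; permuting both blocks by the same permutation
    is a row relabeling and leaves the singular values unchanged.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    rmax = min(X.shape[1], Y.shape[1], n - 1)
    r = rmax if R == "full" else int(R)
    if not 1 <= r <= rmax:
        raise ValueError(f"R must lie in [1, {rmax}]")

    _, observed, _ = cross_product_svd(X, Y)
    observed = observed[:r]
    rng = stage_rng(seed, "permutation")
    null = np.empty((n_permutations, r))
    for b in range(n_permutations):
        perm = rng.permutation(n)
        _, s, _ = cross_product_svd(X[perm], Y)
        null[b] = s[:r]
    p_values = (null > observed).mean(axis=0)
    return PermutationResult(
        n_permutations=n_permutations,
        null_delta=null,
        observed_delta=observed,
        p_values=p_values,
        seed=seed,
        alpha=alpha,
    )


def _align_to_reference(
    u_ref: np.ndarray, u_boot: np.ndarray, v_boot: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reorder and sign-flip bootstrap components to match the reference.

    Greedy matching on |u_ref' u_boot| (the small p-dimensional side):
    repeatedly pick the largest remaining absolute inner product, assign
    that bootstrap axis to that reference slot, and orient the sign.
    """
    r = u_ref.shape[1]
    m = u_ref.T @ u_boot  # r x r
    order = np.full(r, -1)
    used = np.zeros(r, dtype=bool)
    absm = np.abs(m).copy()
    for _ in range(r):
        i, j = np.unravel_index(np.argmax(absm), absm.shape)
        order[i] = j
        used[j] = True
        absm[i, :] = -1.0
        absm[:, j] = -1.0
    signs = np.sign(m[np.arange(r), order])
    signs[signs == 0] = 1.0
    return u_boot[:, order] * signs, v_boot[:, order] * signs


def _procrustes_align(
    u_ref: np.ndarray, u_boot: np.ndarray, v_boot: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Full orthogonal Procrustes rotation of the bootstrap axes onto the
    reference subspace (rotation applied to both blocks)."""
    a, _, bt = np.linalg.svd(u_boot.T @ u_ref)
    q = a @ bt
    return u_boot @ q, v_boot @ q


def bootstrap_weights(
    X: np.ndarray,
    Y: np.ndarray,
    R: int | str = "full",
    n_bootstraps: int = 2000,
    seed: int = 0,
    z_threshold: float = Z_STABILITY_THRESHOLD,
    restandardize: bool = True,
    procrustes: bool = False,
    model: PlscModel | None = None,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Bootstrap standard errors and Z-like stability ratios of the weights.

    Subjects are resampled with replacement jointly in both blocks; each
    replicate's weights are aligned to the original decomposition before the
    per-weight SE is taken over replicates. Resamples that produce a
    constant predictor column are rejected and redrawn (logged).
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("bootstrap needs N >= 10")
    if model is None:
        model = fit_plsc(X, Y, R=R)
    r = model.R
    rng = stage_rng(seed, "bootstrap")

    boots_u = np.empty((n_bootstraps, model.U.shape[0], r))
    boots_v = np.empty((n_bootstraps, model.V.shape[0], r))
    n_redrawn = 0
    for b in range(n_bootstraps):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            xb = X[idx]
            if xb.std(axis=0).min() > 0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        yb = Y[idx]
        if restandardize:
            xb = standardize_columns(xb)
            sd = yb.std(axis=0, ddof=1)
            yb = (yb - yb.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        ub, _, vb = cross_product_svd(xb, yb)
        ub, vb = ub[:, :r], vb[:, :r]
        if procrustes:
            ub, vb = _procrustes_align(model.U, ub, vb)
        else:
            ub, vb = _align_to_reference(model.U, ub, vb)
        boots_u[b] = ub
        boots_v[b] = vb

    se_u = boots_u.std(axis=0, ddof=1)
    se_v = boots_v.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_u = np.where(se_u > 0, model.U / np.where(se_u > 0, se_u, 1.0), np.inf * np.sign(model.U))
        z_v = np.where(se_v > 0, model.V / np.where(se_v > 0, se_v, 1.0), np.inf * np.sign(model.V))
    degenerate_u = ~np.isfinite(z_u) | (np.abs(z_u) > Z_CAP)
    degenerate_v = ~np.isfinite(z_v) | (np.abs(z_v) > Z_CAP)
    z_u = np.clip(np.nan_to_num(z_u, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)
    z_v = np.clip(np.nan_to_num(z_v, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)
    return BootstrapResult(
        n_bootstraps=n_bootstraps,
        se_u=se_u,
        se_v=se_v,
        z_u=z_u,
        z_v=z_v,
        z_threshold=z_threshold,
        seed=seed,
        n_redrawn=n_redrawn,
        degenerate_u=degenerate_u,
        degenerate_v=degenerate_v,
        mean_u=boots_u.mean(axis=0),
        mean_v=boots_v.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# clusters


@dataclass
class Cluster:
    size: int
    peak_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_abs_z: float
    peak_z: float
    peak_weight: float | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    forming_threshold: float
    connectivity: int
    label_volume: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def total_voxels(self) -> int:
        return sum(c.size for c in self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "n_voxels": c.size,
                    "peak_i": c.peak_index[0],
                    "peak_j": c.peak_index[1],
                    "peak_k": c.peak_index[2],
                    "peak_x_mm": c.peak_mm[0],
                    "peak_y_mm": c.peak_mm[1],
                    "peak_z_mm": c.peak_mm[2],
                    "peak_abs_z": c.peak_abs_z,
                    "peak_z": c.peak_z,
                    "peak_weight": c.peak_weight,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "n_voxels", "peak_i", "peak_j", "peak_k",
                "peak_x_mm", "peak_y_mm", "peak_z_mm",
                "peak_abs_z", "peak_z", "peak_weight",
            ],
        )


def cluster_z_map(
    z_values: np.ndarray,
    block: VoxelBlock,
    threshold: float = CLUSTER_FORMING_Z,
    connectivity: int = 26,
    weights: np.ndarray | None = None,
) -> ClusterSet:
    """Connected suprathreshold clusters of the |Z| map.

    ``z_values`` (and optional ``weights``) are per-voxel vectors in the
    block's column order. Clusters are sorted by size descending.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if not block.mask.any():
        raise ValueError("empty mask")
    zvol = block.to_volume(np.asarray(z_values, dtype=float))
    wvol = block.to_volume(np.asarray(weights, dtype=float)) if weights is not None else None
    supra = (np.abs(zvol) > threshold) & block.mask
    structure = (
        np.ones((3, 3, 3), dtype=bool)
        if connectivity == 26
        else ndimage.generate_binary_structure(3, 1)
    )
    labels, n_labels = ndimage.label(supra, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n_labels + 1):
        members = np.argwhere(labels == lab)
        zs = zvol[tuple(members.T)]
        peak_pos = int(np.argmax(np.abs(zs)))
        peak_index = tuple(int(i) for i in members[peak_pos])
        peak_mm = tuple(float(x) for x in block.peak_mm(members[peak_pos]))
        clusters.append(
            Cluster(
                size=len(members),
                peak_index=peak_index,
                peak_mm=peak_mm,
                peak_abs_z=float(np.abs(zs[peak_pos])),
                peak_z=float(zs[peak_pos]),
                peak_weight=(
                    float(wvol[peak_index]) if wvol is not None else None
                ),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.peak_index))
    return ClusterSet(
        clusters=clusters,
        forming_threshold=threshold,
        connectivity=connectivity,
        label_volume=labels,
    )
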