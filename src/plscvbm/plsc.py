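"""Two-block partial least squares correlation (PLSC) via SVD.

Given column-standardized blocks X (N x p, metabolic panel) and Y (N x v,
voxelwise GMV), PLSC finds paired unit weight vectors (u_r, v_r) maximizing
the cross-block covariance cov(Xu, Yv). All pairs come at once from the
singular value decomposition of the p x v cross-product matrix

    X'Y = U diag(delta) V'

The latent scores are Lx = XU and Ly = YV; a component's share of the total
cross-block covariance is its singular value divided by the sum of all
singular values. The decomposition is computed economy-size on the p x v
cross-product (p is small), so memory scales with p*v, never v^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["PlscModel", "fit_plsc", "explained_covariance", "project", "cross_product_svd"]


@dataclass
class PlscModel:
    """Fitted PLSC decomposition.

    U (p x R) and V (v x R) hold the paired weight vectors ("saliences"),
    delta the singular values in descending order, Lx/Ly the latent scores,
    and lv_correlations the per-pair Pearson correlation corr(Lx_r, Ly_r).
    """

    U: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    full_delta: np.ndarray
    Lx: np.ndarray
    Ly: np.ndarray
    explained_covariance: np.ndarray
    lv_correlations: np.ndarray
    column_names: tuple[str, ...] = ()
    sign_anchor: str | None = None
    tied_singular_values: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def R(self) -> int:
        return self.delta.shape[0]


def cross_product_svd(X: np.ndarray, Y: np.ndarray):
    """Economy SVD of X'Y without ever forming a v x v object."""
    cross = X.T @ Y  # p x v
    u, s, vt = scipy.linalg.svd(cross, full_matrices=False)
    return u, s, vt.T


def explained_covariance(delta: np.ndarray, full_delta: np.ndarray) -> np.ndarray:
    """Fraction of total cross-block covariance per component:
    delta_r / sum(all singular values)."""
    delta = np.asarray(delta, dtype=float)
    full = np.asarray(full_delta, dtype=float)
    if full.size == 0:
        raise ValueError("full singular-value set is empty")
    if (delta < 0).any() or (full < 0).any():
        raise ValueError("singular values must be non-negative")
    total = full.sum()
    if total <= 0:
        raise ValueError("sum of singular values is zero; fractions undefined")
    return delta / total


def fit_plsc(
    X: np.ndarray,
    Y: np.ndarray,
    R: int | str = "full",
    column_names: tuple[str, ...] = (),
    sign_anchor: str | int | None = "bmi",
    flip: bool = False,
) -> PlscModel:
    """Fit the PLSC decomposition of two standardized blocks.

    Parameters
    ----------
    R:
        Number of component pairs to keep, or ``"full"`` for all
        min(p, v, N-1).
    sign_anchor:
        Column (name or index) used to orient each component: the sign is
        chosen so the metabolic latent score correlates positively with that
        raw column (BMI by default, the conventional "higher adiposity"
        orientation). SVD signs are otherwise arbitrary. ``None`` anchors on
        the largest-|weight| predictor instead.
    flip:
        Return the reflected (all signs negated) orientation, which is an
        equally valid solution of the same maximization.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"N mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite entries in input blocks")
    n, p = X.shape
    v = Y.shape[1]
    rmax = min(p, v, n - 1)
    if R == "full":
        r = rmax
    else:
        r = int(R)
        if not 1 <= r <= rmax:
            raise ValueError(f"R must lie in [1, {rmax}], got {r}")

    u_all, s_all, v_all = cross_product_svd(X, Y)
    u_all, s_all, v_all = u_all[:, :rmax], s_all[:rmax], v_all[:, :rmax]
    tied = bool(np.any(np.isclose(np.diff(s_all), 0.0, atol=1e-10 * max(s_all[0], 1.0))))

    # orient each component
    anchor_idx = None
    if sign_anchor is not None:
        if isinstance(sign_anchor, str):
            if column_names and sign_anchor in column_names:
                anchor_idx = column_names.index(sign_anchor)
        else:
            anchor_idx = int(sign_anchor)
    for comp in range(rmax):
        if anchor_idx is not None:
            ref = X[:, anchor_idx]
            score = X @ u_all[:, comp]
            sgn = np.sign(ref @ score) or 1.0
        else:
            j = int(np.argmax(np.abs(u_all[:, comp])))
            sgn = np.sign(u_all[j, comp]) or 1.0
        if flip:
            sgn = -sgn
        u_all[:, comp] *= sgn
        v_all[:, comp] *= sgn

    U, delta, V = u_all[:, :r], s_all[:r], v_all[:, :r]
    Lx = X @ U
    Ly = Y @ V
    with np.errstate(invalid="ignore"):
        denom = Lx.std(axis=0) * Ly.std(axis=0) * n
        lv_corr = np.where(
            denom > 0,
            ((Lx - Lx.mean(0)) * (Ly - Ly.mean(0))).sum(0) / np.where(denom > 0, denom, 1.0),
            np.nan,
        )
    return PlscModel(
        U=U,
        V=V,
        delta=delta,
        full_delta=s_all,
        Lx=Lx,
        Ly=Ly,
        explained_covariance=(
            explained_covariance(delta, s_all)
            if s_all.sum() > 0
            else np.full(r, np.nan)
        ),
        lv_correlations=lv_corr,
        column_names=tuple(column_names),
        sign_anchor=(
            column_names[anchor_idx]
            if anchor_idx is not None and column_names
            else (str(anchor_idx) if anchor_idx is not None else None)
        ),
        tied_singular_values=tied,
    )


def project(model: PlscModel, X_new: np.ndarray, Y_new: np.ndarray):
    """Latent scores for new data using the fitted weights (no refitting)."""
    X_new = np.asarray(X_new, dtype=float)
    Y_new = np.asarray(Y_new, dtype=float)
    if X_new.shape[1] != model.U.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.U.shape[0]}"
        )
    if Y_new.shape[1] != model.V.shape[0]:
        raise ValueError(
            f"Y_new has {Y_new.shape[1]} columns, model expects {model.V.shape[0]}"
        )
    return X_new @ model.U, Y_new @ model.V
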