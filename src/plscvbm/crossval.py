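"""Train/test reprojection scheme: repeated 80/20 splits with within-test
permutation nulls.

Each repeat draws a random 80% training set, estimates all preprocessing
parameters (confound regression coefficients, column means/SDs) and the PLSC
weights on the training set only, applies them to the held-out 20%, and
correlates the projected metabolic and brain scores in the test set. A null
distribution is built by permuting the rows of the test-set metabolic matrix
and reprojecting, so the p-value reflects how often a broken pairing yields
as strong a test correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsc import fit_plsc, project
from .preprocess import residualize
from .seeding import stage_rng

__all__ = ["CvSplitResult", "CvSummary", "run_cv"]


@dataclass
class CvSplitResult:
    split_id: int
    n_train: int
    n_test: int
    test_correlation: np.ndarray  # per component
    p_values: np.ndarray
    null_mean_correlation: np.ndarray
    seed: int
    flagged_degenerate: bool = False
    train_indices: np.ndarray | None = None
    U_train: np.ndarray | None = None  # training weights (leakage checks)


@dataclass
class CvSummary:
    splits: list[CvSplitResult]
    n_components: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    @property
    def test_correlations(self) -> np.ndarray:
        return np.array([s.test_correlation for s in self.splits])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([s.p_values for s in self.splits])

    @property
    def mean_correlation(self) -> np.ndarray:
        return self.test_correlations.mean(axis=0)

    @property
    def sd_correlation(self) -> np.ndarray:
        return self.test_correlations.std(axis=0, ddof=1)

    @property
    def mean_null_correlation(self) -> np.ndarray:
        return np.array([s.null_mean_correlation for s in self.splits]).mean(axis=0)

    def n_significant(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_values < alpha).sum(axis=0)

    def n_nonsignificant(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_values >= alpha).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "mean_test_r": self.mean_correlation,
                "sd_test_r": self.sd_correlation,
                "mean_null_r": self.mean_null_correlation,
                "n_significant": self.n_significant(),
                "n_splits": self.n_splits,
            }
        )


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two equally shaped score matrices."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    out = np.full(a.shape[1], np.nan)
    ok = denom > 0
    out[ok] = (ac * bc).sum(axis=0)[ok] / denom[ok]
    return out


def run_cv(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    confounds_x: np.ndarray,
    confounds_y: np.ndarray,
    R: int = 2,
    n_splits: int = 20,
    test_fraction: float = 0.2,
    n_inner_permutations: int = 1000,
    seed: int = 0,
    apply_train_params: bool = True,
    two_sided: bool = False,
) -> CvSummary:
    """Repeated 80/20 split-and-reproject validation.

    Parameters
    ----------
    X_raw, Y_raw:
        Transformed but not yet residualized/standardized matrices (log
        transforms applied; confound regression happens per split).
    confounds_x, confounds_y:
        Confound matrices for the metabolic and voxel blocks.
    apply_train_params:
        If True (default, the no-leakage convention), confound coefficients
        and column means/SDs estimated on the training set are applied to
        the test set. If False, training weights are projected onto the
        literal raw test matrices.
    two_sided:
        Compare |null correlation| >= |observed| instead of the one-sided
        signed comparison.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    n = X_raw.shape[0]
    p = X_raw.shape[1]
    n_test = int(round(n * test_fraction))
    n_train = n - n_test
    if n_test < max(3, 1):
        raise ValueError("test set smaller than 3 subjects")
    if n_test < p + 2:
        raise ValueError("test set must contain at least p + 2 subjects")
    rmax = min(p, Y_raw.shape[1], n_train - 1)
    if not 1 <= R <= rmax:
        raise ValueError(f"R must lie in [1, {rmax}]")

    rng = stage_rng(seed, "cross-validation")
    splits: list[CvSplitResult] = []
    for split_id in range(n_splits):
        for _attempt in range(100):
            order = rng.permutation(n)
            test_idx, train_idx = order[:n_test], order[n_test:]
            if X_raw[train_idx].std(axis=0).min() > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate split")

        def _fit_params(raw, conf_tr):
            design = np.column_stack([np.ones(len(conf_tr)), conf_tr])
            beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
            resid = raw - design @ beta
            mean = resid.mean(axis=0)
            sd = resid.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            return beta, mean, sd, (resid - mean) / sd

        bx, mx, sx, x_train = _fit_params(X_raw[train_idx], confounds_x[train_idx])
        by, my, sy, y_train = _fit_params(Y_raw[train_idx], confounds_y[train_idx])

        model = fit_plsc(x_train, y_train, R=R, sign_anchor=None)

        if apply_train_params:
            dx = np.column_stack([np.ones(n_test), confounds_x[test_idx]])
            dy = np.column_stack([np.ones(n_test), confounds_y[test_idx]])
            x_test = ((X_raw[test_idx] - dx @ bx) - mx) / sx
            y_test = ((Y_raw[test_idx] - dy @ by) - my) / sy
        else:
            x_test = X_raw[test_idx]
            y_test = Y_raw[test_idx]

        lx_test, ly_test = project(model, x_test, y_test)
        observed = _corr_columns(lx_test, ly_test)

        null = np.empty((n_inner_permutations, R))
        flagged = False
        for b in range(n_inner_permutations):
            for _attempt in range(100):
                perm = rng.permutation(n_test)
                xp = x_test[perm]
                if xp.std(axis=0).min() > 0:
                    break
                flagged = True
            null[b] = _corr_columns(xp @ model.U, ly_test)
        if two_sided:
            p_values = (np.abs(null) >= np.abs(observed)).mean(axis=0)
        else:
            p_values = (null >= observed).mean(axis=0)

        splits.append(
            CvSplitResult(
                split_id=split_id,
                n_train=n_train,
                n_test=n_test,
                test_correlation=observed,
                p_values=p_values,
                null_mean_correlation=null.mean(axis=0),
                seed=seed,
                flagged_degenerate=flagged,
                train_indices=train_idx.copy(),
                U_train=model.U.copy(),
            )
        )
    return CvSummary(splits=splits, n_components=R)
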