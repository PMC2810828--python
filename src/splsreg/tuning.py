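"""Tuning of the SPLS sparsity level and number of components.

Two schemes are provided:

* **Soft thresholding + cross-validation** -- a grid over the threshold
  fraction eta and the number of components K, scored by k-fold CV mean
  squared prediction error on the raw response scale.  Besides the plain
  minimum rule, the parsimony rule accepts any pair whose CV score is
  within 1.1x the minimum and picks the smallest K, then the largest
  eta, among those -- appropriate when the CV surface is flat.

* **Hard thresholding by FDR control** (univariate response only) --
  at each step the variables whose (partial-)correlation p-values
  survive the Benjamini-Hochberg procedure at level alpha are selected;
  the dense direction vector is hard-thresholded to exactly those
  components.  p-values come from the Fisher z-transform of the sample
  (partial) correlation, null law N(0, 1/(n - g - 3)) with g the number
  of conditioned-on latent scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import CenteredData
from .model import SPLSFit, _coef_predict, fit_spls

__all__ = [
    "CVResult",
    "FDRSelection",
    "partial_correlation_pvalues",
    "bh_select",
    "fit_spls_fdr",
    "kfold_cv_spls",
    "kfold_cv_spls_fdr",
]


@dataclass
class CVResult:
    """CV grid (eta, K, cv_error) and the chosen pair under the rule."""

    grid: pd.DataFrame
    chosen_eta: float
    chosen_K: int
    folds: int
    rule: str

    def to_csv(self, path) -> None:
        self.grid.to_csv(path, index=False)


@dataclass
class FDRSelection:
    """Per-variable correlations, z statistics, p-values and BH outcome."""

    r: np.ndarray
    z: np.ndarray
    pvals: np.ndarray
    alpha: float
    m_hat: int
    selected: np.ndarray


def partial_correlation_pvalues(
    X: np.ndarray, y: np.ndarray, T_prev: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-z p-values for the (partial) correlation of each X column with y.

    With conditioning scores T_prev (n x g, possibly empty), r_i is the
    plain correlation of the residuals of X_i and y after least-squares
    removal of T_prev; z_i = atanh(r_i) has null standard deviation
    1/sqrt(n - g - 3), giving two-sided normal p-values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    g = 0 if T_prev is None or T_prev.size == 0 else T_prev.shape[1]
    if n <= g + 3:
        raise ValueError(f"need n > g + 3 (n={n}, g={g})")
    Xr = X - X.mean(axis=0)
    yr = y - y.mean()
    if g:
        Tc = T_prev - T_prev.mean(axis=0)
        coef_x, *_ = np.linalg.lstsq(Tc, Xr, rcond=None)
        coef_y, *_ = np.linalg.lstsq(Tc, yr, rcond=None)
        Xr = Xr - Tc @ coef_x
        yr = yr - Tc @ coef_y
    sx = np.sqrt(np.sum(Xr**2, axis=0))
    sy = np.sqrt(np.sum(yr**2))
    denom = sx * sy
    denom[denom == 0] = np.inf  # zero-variance residual -> r = 0
    r = (Xr.T @ yr) / denom
    r = np.clip(r, -1.0, 1.0)
    exact = np.abs(r) == 1.0
    if np.any(exact):
        warnings.warn(
            "correlation of +/-1 encountered; its p-value is reported as 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    pvals = np.where(
        exact, 0.0, 2 * norm.sf(np.abs(z) * np.sqrt(n - g - 3))
    )
    return r, z, pvals


def bh_select(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection.

    With ordered p-values p_(1) <= ... <= p_(p), find
    m_hat = max{i : p_(i) <= i * alpha / p} (0 if none) and return the
    indices of the m_hat smallest p-values.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    p = pvals.size
    order = np.argsort(pvals, kind="stable")
    passed = np.flatnonzero(pvals[order] <= (np.arange(1, p + 1) * alpha / p))
    if passed.size == 0:
        return np.zeros(0, dtype=int)
    m_hat = int(passed[-1]) + 1
    return np.sort(order[:m_hat])


def fdr_screen(
    X: np.ndarray, y: np.ndarray, T_prev: np.ndarray | None, alpha: float
) -> FDRSelection:
    """One FDR-controlled hard-thresholding screen."""
    r, z, pvals = partial_correlation_pvalues(X, y, T_prev)
    selected = bh_select(pvals, alpha)
    return FDRSelection(
        r=r, z=z, pvals=pvals, alpha=alpha, m_hat=selected.size, selected=selected
    )


def fit_spls_fdr(
    data: CenteredData,
    K: int,
    alpha: float,
    variant: str = "nipals",
) -> SPLSFit:
    """SPLS with per-step hard thresholding by FDR control (univariate Y).

    At step k the screen conditions on the k-1 latent scores already in
    the model; the active set grows by the BH-selected variables and the
    usual refit/deflate loop proceeds.  Multivariate responses are
    rejected: the iterative multivariate solution has soft-threshold
    form, for which correlation-based FDR control is not applicable.
    """
    if data.q != 1:
        raise ValueError(
            "FDR-based hard thresholding applies to a univariate response only"
        )

    def selector(k, X1, Y1, inner):
        T_prev = None if inner is None else inner.T
        sel = fdr_screen(data.X, data.Y[:, 0], T_prev, alpha)
        if k == 1 and sel.selected.size == 0:
            raise ValueError(
                "FDR screen selected no variable at step 1; use a larger alpha"
            )
        return sel.selected

    return fit_spls(data, K=K, eta=0.0, variant=variant, selector=selector)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def _cv_grid(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    fit_for_fold,
    cells: list[tuple[float, int]],
    K_max: int,
    folds: int,
    seed: int,
    scale_x: bool,
    scale_y: bool | None,
) -> pd.DataFrame:
    """Shared CV loop: one K_max fit per (fold, eta) with per-step
    coefficient snapshots supplies every K in the grid."""
    from .data import center_scale

    n = X_raw.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    fold_idx = _fold_indices(n, folds, rng)
    etas = sorted({e for e, _ in cells})
    err = {cell: [] for cell in cells}
    for test_idx in fold_idx:
        if n - test_idx.size < K_max + 1:
            raise ValueError("a CV fold has fewer training rows than K+1")
        train = np.setdiff1d(np.arange(n), test_idx)
        dtr = center_scale(
            X_raw[train], Y_raw[train], scale_x=scale_x, scale_y=scale_y
        )
        for eta in etas:
            fit = fit_for_fold(dtr, eta, K_max)
            for k in range(1, K_max + 1):
                if (eta, k) not in err:
                    continue
                coef = fit.coef_history[min(k, len(fit.coef_history)) - 1]
                pred = _coef_predict(coef, X_raw[test_idx], dtr)
                err[(eta, k)].append(
                    float(np.mean((Y_raw[test_idx] - pred) ** 2))
                )
    rows = [
        {"eta": eta, "K": k, "cv_error": float(np.mean(err[(eta, k)]))}
        for (eta, k) in cells
    ]
    return pd.DataFrame(rows)


def _choose(grid: pd.DataFrame, rule: str) -> tuple[float, int]:
    best = grid["cv_error"].min()
    if rule == "min":
        row = grid.loc[grid["cv_error"].idxmin()]
        return float(row["eta"]), int(row["K"])
    if rule == "parsimony_1.1":
        # among near-flat cells prefer the sparsest direction (largest
        # eta), then the fewest components; eta-first keeps spurious
        # variables out when a dense low-K cell happens to score well
        ok = grid[grid["cv_error"] <= 1.1 * best]
        ok = ok.sort_values(["eta", "K"], ascending=[False, True])
        row = ok.iloc[0]
        return float(row["eta"]), int(row["K"])
    raise ValueError(f"unknown rule {rule!r}")


def kfold_cv_spls(
    X_raw,
    Y_raw,
    eta_grid=None,
    K_grid=None,
    folds: int = 10,
    rule: str = "parsimony_1.1",
    seed: int = 0,
    kappa: float = 0.4,
    variant: str = "nipals",
    scale_x: bool = True,
    scale_y: bool | None = None,
) -> CVResult:
    """Select (eta, K) for soft-thresholded SPLS by k-fold CV.

    Fold assignment is a seeded random permutation dealt round-robin;
    the CV error for a cell is the per-fold mean squared prediction
    error on the raw Y scale averaged over folds (not pooled).
    """
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    if Y_raw.ndim == 1:
        Y_raw = Y_raw[:, None]
    if eta_grid is None:
        eta_grid = np.round(np.arange(0.1, 1.0, 0.1), 1)
    if K_grid is None:
        K_grid = range(1, min(10, X_raw.shape[0] - 1) + 1)
    cells = [(float(e), int(k)) for e in eta_grid for k in K_grid]
    if not cells:
        raise ValueError("empty tuning grid")
    K_max = max(k for _, k in cells)

    def fit_for_fold(dtr, eta, K_max):
        return fit_spls(dtr, K=K_max, eta=eta, kappa=kappa, variant=variant)

    grid = _cv_grid(
        X_raw, Y_raw, fit_for_fold, cells, K_max, folds, seed, scale_x, scale_y
    )
    eta, K = _choose(grid, rule)
    return CVResult(grid=grid, chosen_eta=eta, chosen_K=K, folds=folds, rule=rule)


def kfold_cv_spls_fdr(
    X_raw,
    y_raw,
    alpha: float,
    K_grid=None,
    folds: int = 10,
    rule: str = "parsimony_1.1",
    seed: int = 0,
    variant: str = "nipals",
    scale_x: bool = True,
) -> CVResult:
    """Select K for FDR-thresholded SPLS (univariate Y) by k-fold CV.

    The grid is one-dimensional (alpha is prespecified); the returned
    ``chosen_eta`` field carries alpha for interface symmetry.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    if y_raw.ndim == 1:
        y_raw = y_raw[:, None]
    if K_grid is None:
        K_grid = range(1, min(10, X_raw.shape[0] - 1) + 1)
    cells = [(float(alpha), int(k)) for k in K_grid]
    if not cells:
        raise ValueError("empty tuning grid")
    K_max = max(k for _, k in cells)

    def fit_for_fold(dtr, _eta, K_max):
        return fit_spls_fdr(dtr, K=K_max, alpha=alpha, variant=variant)

    grid = _cv_grid(
        X_raw, y_raw, fit_for_fold, cells, K_max, folds, seed, scale_x, False
    )
    grid = grid.rename(columns={"eta": "alpha"})
    tmp = grid.rename(columns={"alpha": "eta"})
    _, K = _choose(tmp, rule)
    return CVResult(
        grid=grid, chosen_eta=float(alpha), chosen_K=K, folds=folds, rule=rule
    )
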