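"""The SPLS fitting algorithm: active-variable search with PLS refits.

At each step k = 1..K a sparse direction vector is computed on the
current cross-covariance (the NIPALS variant deflates the response, the
SIMPLS variant deflates the predictors), its support is merged into the
active set A, and a *dense* PLS fit with k components is refit on the
active submatrix.  The refit keeps the Krylov-subsequence structure of
the direction vectors inside the restricted predictor space, which a
naive per-step thresholding of PLS directions would destroy.  Final
coefficients are embedded into a full-length p x q matrix that is
exactly zero off the active set.

Because the number of latent components is bounded by the sample size
but the active set is not, the number of selected variables can exceed
n -- the behaviour that distinguishes this algorithm from forward
selection methods such as LARS in small-n, large-p problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import scipy.stats

from .data import CenteredData
from .direction import CrossCovariance, SparsityParams, sparse_direction
from .pls import PLSFit, fit_pls

__all__ = ["ActiveSet", "SPLSFit", "fit_spls", "deflate", "predict_spls"]


@dataclass
class ActiveSet:
    """Ordered active-variable indices plus the per-step support history."""

    indices: np.ndarray
    history: list[np.ndarray] = field(default_factory=list)


@dataclass
class SPLSFit:
    active: ActiveSet
    inner_fit: PLSFit
    coef_full: np.ndarray
    eta: float
    kappa: float
    K: int
    variant: str
    #: coefficient matrix after each step k = 1..K (full length, zero off
    #: the step's active set); coef_history[-1] is coef_full
    coef_history: list[np.ndarray] = field(default_factory=list)


def deflate(
    variant: str,
    data: CenteredData,
    X1: np.ndarray,
    Y1: np.ndarray,
    inner: PLSFit,
    active: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One deflation pass using the refit PLS estimates on the active set.

    NIPALS: Y1 <- residual of the *original* Y after least-squares
    projection onto the current latent scores (X is untouched).
    SIMPLS: X1 <- original X with each row projected onto the
    orthocomplement of the current projection-basis span (embedded in
    the full predictor space), so the deflated X1 satisfies X1 R = 0.
    Both maps are projections, hence idempotent.
    """
    T = inner.T
    G = T.T @ T
    if np.linalg.cond(G) > 1e12:
        raise ValueError("rank-deficient scores during deflation; reduce K")
    if variant == "nipals":
        Y1 = data.Y - T @ np.linalg.solve(G, T.T @ data.Y)
        return X1, Y1
    if variant == "simpls":
        R = np.zeros((data.p, inner.K))
        R[active, :] = inner.W
        # orthonormalize the projection basis, then project off its span
        Qb, _ = np.linalg.qr(R)
        X1 = data.X - (data.X @ Qb) @ Qb.T
        return X1, Y1
    raise ValueError(f"unknown SPLS variant {variant!r}")


def _noise_floor_passed(
    X_cur: np.ndarray, Y_cur: np.ndarray, g: int, alpha: float
) -> bool:
    """Is the strongest X-column/target correlation distinguishable from
    noise?  Fisher-z null with g conditioned dimensions, Bonferroni over
    the p*q correlations."""
    n, p = X_cur.shape
    q = Y_cur.shape[1]
    if n - g - 3 <= 0:
        return True
    sx = np.linalg.norm(X_cur, axis=0)
    sy = np.linalg.norm(Y_cur, axis=0)
    denom = np.outer(sx, sy)
    denom[denom == 0] = np.inf
    r_max = np.abs(X_cur.T @ Y_cur / denom).max()
    z = np.arctanh(min(r_max, 1 - 1e-12))
    p_min = 2 * scipy.stats.norm.sf(z * np.sqrt(n - g - 3)) * (p * q)
    return p_min <= alpha


def fit_spls(
    data: CenteredData,
    K: int,
    eta: float,
    kappa: float = 0.4,
    variant: str = "nipals",
    tol: float = 1e-6,
    maxit: int = 100,
    selector=None,
    guard_alpha: float | None = 0.05,
) -> SPLSFit:
    """Fit sparse PLS with K components at soft-threshold fraction eta.

    ``selector`` optionally overrides the per-step variable screen: it is
    called as ``selector(step_k, X1, Y1, inner_fit_or_None)`` and must
    return an index array of variables to add (used by the FDR-based
    hard-thresholding scheme).  By default the support of the sparse
    direction vector on the current cross-covariance is used.

    ``guard_alpha``: at steps k >= 2 the soft-threshold screen always has
    a maximal entry, even when the deflated cross-covariance is pure
    noise; the active set therefore only grows at such a step if the
    largest (conditional) correlation with the deflated target clears a
    Bonferroni-adjusted Fisher-z test at this level.  ``None`` disables
    the guard.  Step 1 and the refit loop are unaffected, so K is always
    honoured.
    """
    if not 1 <= K <= data.n - 1:
        raise ValueError(f"K={K} outside 1..n-1 = {data.n - 1}")
    if not 0 <= eta < 1:
        raise ValueError("eta must be in [0, 1)")
    params = SparsityParams(eta=eta, kappa=kappa, tol=tol, maxit=maxit)

    X1 = data.X
    Y1 = data.Y
    active = np.zeros(0, dtype=int)
    history: list[np.ndarray] = []
    coef_history: list[np.ndarray] = []
    inner = None
    for k in range(1, K + 1):
        if selector is None:
            Xc, Yc = (data.X, Y1) if variant == "nipals" else (X1, data.Y)
            Z = X1.T @ Y1 if variant == "nipals" else X1.T @ data.Y
            zmax = np.abs(Z).max()
            if zmax <= 1e-12 * max(1.0, np.abs(data.X).max() * data.n):
                raise ValueError(
                    f"degenerate deflated cross-covariance at step {k}"
                )
            if (
                k > 1
                and guard_alpha is not None
                and not _noise_floor_passed(Xc, Yc, k - 1, guard_alpha)
            ):
                new = np.zeros(0, dtype=int)
            else:
                new = sparse_direction(CrossCovariance(Z), params).support
        else:
            new = np.asarray(selector(k, X1, Y1, inner), dtype=int)
            if k == 1 and new.size == 0:
                raise ValueError(
                    "no variable passed the step-1 screen; relax the threshold"
                )
        active = np.union1d(active, new).astype(int)
        if active.size == 0:
            raise ValueError(
                f"empty support at step {k}; use a smaller eta"
            )
        history.append(active.copy())
        sub = CenteredData(
            X=data.X[:, active],
            Y=data.Y,
            x_center=data.x_center[active],
            x_scale=data.x_scale[active],
            y_center=data.y_center,
            y_scale=data.y_scale,
        )
        k_fit = min(k, active.size, np.linalg.matrix_rank(sub.X))
        inner = fit_pls(sub, k_fit, variant=variant)
        coef_full = np.zeros((data.p, data.q))
        coef_full[active, :] = inner.coef
        coef_history.append(coef_full)
        if k < K:
            X1, Y1 = deflate(variant, data, X1, Y1, inner, active)
    return SPLSFit(
        active=ActiveSet(indices=active, history=history),
        inner_fit=inner,
        coef_full=coef_history[-1],
        eta=eta,
        kappa=kappa,
        K=K,
        variant=variant,
        coef_history=coef_history,
    )


def predict_spls(fit: SPLSFit, X_new, data: CenteredData) -> np.ndarray:
    """Predict raw-scale responses; inactive variables have exactly zero weight."""
    Xc = data.transform_x(X_new)
    return data.inverse_transform_y(Xc @ fit.coef_full)


def _coef_predict(coef_full: np.ndarray, X_new, data: CenteredData) -> np.ndarray:
    Xc = data.transform_x(X_new)
    return data.inverse_transform_y(Xc @ coef_full)
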