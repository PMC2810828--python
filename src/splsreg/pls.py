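"""Classic partial least squares regression (NIPALS and SIMPLS).

Both algorithms extract K direction vectors w_k defining latent scores
T = XW; responses are regressed on the scores to obtain loadings Q and
regression coefficients ``coef = W (T'T)^{-1} T'Y`` on the centered
scale.  NIPALS extracts each direction with respect to successively
deflated matrices and maps the result back to the original X basis;
SIMPLS works directly in the original basis under the conjugacy
constraint that the scores are mutually orthogonal.

For a univariate response both algorithms yield the same directions
(up to sign) and hence the same coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import CenteredData

__all__ = [
    "PLSFit",
    "fit_pls_nipals",
    "fit_pls_simpls",
    "fit_pls",
    "pls_loadings_coefficients",
    "cg_solve",
    "predict",
]


@dataclass
class PLSFit:
    """Directions W (p x K), scores T = XW (n x K), loadings Q (q x K),
    coefficients (p x q) on the centered scale."""

    W: np.ndarray
    T: np.ndarray
    Q: np.ndarray
    coef: np.ndarray
    K: int
    variant: str


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Flip a direction vector so its largest-magnitude entry is positive.

    The PLS objective is sign-invariant; fixing the sign makes output
    reproducible across BLAS/LAPACK builds.
    """
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w


def _leading_left_sv(Z: np.ndarray) -> np.ndarray:
    """Leading left singular vector of Z (p x q), deterministic sign."""
    if Z.shape[1] == 1:
        v = Z[:, 0]
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("degenerate cross-covariance")
        return _fix_sign(v / nrm)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate cross-covariance")
    return _fix_sign(U[:, 0])


def cg_solve(
    A, b: np.ndarray, tol: float = 1e-10, maxit: int | None = None
) -> np.ndarray:
    """Solve Ax = b for symmetric positive-definite A by conjugate gradients.

    ``A`` may be a dense matrix or a callable implementing the
    matrix-vector product.  Returns x with relative residual
    ``||Ax - b|| / ||b|| <= tol``; raises ``RuntimeError`` (carrying the
    achieved residual) if that is not reached within ``min(m, maxit)``
    iterations plus a small slack for rounding.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = np.asarray(b, dtype=float)
    m = b.shape[0]
    matvec = A if callable(A) else (lambda v: np.asarray(A) @ v)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros(m)
    if maxit is None:
        maxit = m
    # CG terminates in at most m steps in exact arithmetic; allow a few
    # extra iterations for floating-point drift.
    limit = min(m, maxit) + 5
    x = np.zeros(m)
    r = b.copy()
    d = r.copy()
    rs = r @ r
    for _ in range(limit):
        if np.sqrt(rs) / bnorm <= tol:
            return x
        Ad = matvec(d)
        alpha = rs / (d @ Ad)
        x = x + alpha * d
        r = r - alpha * Ad
        rs_new = r @ r
        d = r + (rs_new / rs) * d
        rs = rs_new
    if np.sqrt(rs) / bnorm <= tol:
        return x
    raise RuntimeError(
        f"conjugate gradient did not converge: relative residual "
        f"{np.sqrt(rs) / bnorm:.3e} > tol {tol:.3e}"
    )


def _solve_gram(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve the (SPD) score Gram system G X = B column by column.

    Dimensions <= 5 use a direct factorization (CG overhead is not
    worthwhile there); larger systems use conjugate gradients.
    """
    B = np.atleast_2d(B.T).T
    if G.shape[0] <= 5:
        try:
            return scipy.linalg.solve(G, B, assume_a="pos")
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise ValueError(
                "rank-deficient scores; try a smaller number of components K"
            ) from e
    return np.column_stack([cg_solve(G, B[:, j]) for j in range(B.shape[1])])


def pls_loadings_coefficients(
    W: np.ndarray, data: CenteredData
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares loadings Q and coefficients for given directions W.

    Q minimizes ||Y - T Q'|| with T = XW, so the residual is orthogonal
    to every score column; coef = W (T'T)^{-1} T'Y is p x q.
    """
    T = data.X @ W
    G = T.T @ T
    # full column rank check via conditioning of the Gram matrix
    if np.linalg.cond(G) > 1e12:
        raise ValueError(
            "scores are rank deficient; try a smaller number of components K"
        )
    C = _solve_gram(G, T.T @ data.Y)  # (T'T)^{-1} T'Y, K x q
    Q = C.T  # q x K
    coef = W @ C
    return Q, coef


def fit_pls_nipals(data: CenteredData, K: int) -> PLSFit:
    """PLS via NIPALS: directions computed on successively deflated matrices.

    At step k the direction d_k is the leading left singular vector of
    X1'Y1 for the current deflated X1 (and Y1); both matrices are then
    deflated by the new score.  The direction matrix is mapped back to
    the original basis through W = D (P'D)^{-1} where P holds the X
    loadings, and the final columns are re-normalized to unit length.
    """
    _check_K(data, K)
    X1 = data.X.copy()
    Y1 = data.Y.copy()
    D = np.zeros((data.p, K))
    P = np.zeros((data.p, K))
    for k in range(K):
        Z = X1.T @ Y1
        if np.linalg.norm(Z) < 1e-12 * max(1.0, np.linalg.norm(data.X)):
            raise ValueError("degenerate cross-covariance")
        d = _leading_left_sv(Z)
        t = X1 @ d
        tt = t @ t
        p_load = X1.T @ t / tt
        q_load = Y1.T @ t / tt
        X1 -= np.outer(t, p_load)
        Y1 -= np.outer(t, q_load)
        D[:, k] = d
        P[:, k] = p_load
    # back-transform to the original X basis: T = X D (P'D)^{-1}
    W = D @ np.linalg.inv(P.T @ D)
    W = W / np.linalg.norm(W, axis=0)
    W = np.column_stack([_fix_sign(W[:, k]) for k in range(K)])
    Q, coef = pls_loadings_coefficients(W, data)
    return PLSFit(W=W, T=data.X @ W, Q=Q, coef=coef, K=K, variant="nipals")


def fit_pls_simpls(data: CenteredData, K: int) -> PLSFit:
    """PLS via SIMPLS: directions in the original basis, conjugate scores.

    The k-th direction maximizes the cross-covariance criterion subject
    to w' X'X w_j = 0 for earlier directions, achieved by projecting the
    cross-product matrix off the span of earlier X loadings before each
    singular-vector extraction (de Jong's algorithm).  Scores T = XW are
    mutually orthogonal.
    """
    _check_K(data, K)
    S = data.X.T @ data.Y
    if np.linalg.norm(S) < 1e-12 * max(1.0, np.linalg.norm(data.X)):
        raise ValueError("degenerate cross-covariance")
    W = np.zeros((data.p, K))
    V = np.zeros((data.p, K))  # orthonormal basis of the loading span
    for k in range(K):
        w = _leading_left_sv(S)
        t = data.X @ w
        p_load = data.X.T @ t / (t @ t)
        # orthonormalize the loading against previous basis vectors
        v = p_load - V[:, :k] @ (V[:, :k].T @ p_load)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(
                "degenerate deflated cross-covariance; reduce K"
            )
        v /= nv
        V[:, k] = v
        S = S - np.outer(v, v @ S)
        W[:, k] = w
    Q, coef = pls_loadings_coefficients(W, data)
    return PLSFit(W=W, T=data.X @ W, Q=Q, coef=coef, K=K, variant="simpls")


def fit_pls(data: CenteredData, K: int, variant: str = "nipals") -> PLSFit:
    if variant == "nipals":
        return fit_pls_nipals(data, K)
    if variant == "simpls":
        return fit_pls_simpls(data, K)
    raise ValueError(f"unknown PLS variant {variant!r}")


def _check_K(data: CenteredData, K: int) -> None:
    rank = np.linalg.matrix_rank(data.X)
    cap = min(data.n - 1, data.p, rank)
    if not 1 <= K <= cap:
        raise ValueError(
            f"K={K} outside the valid range 1..{cap} "
            f"(min of n-1={data.n - 1}, p={data.p}, rank={rank})"
        )


def predict(fit: PLSFit, X_new, data: CenteredData) -> np.ndarray:
    """Predict responses for raw (unscaled) predictors ``X_new``.

    Applies the stored training transform, multiplies by the centered
    coefficients and back-transforms to the raw Y scale.
    """
    Xc = data.transform_x(X_new)
    return data.inverse_transform_y(Xc @ fit.coef)
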