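"""Sparse PLS direction vectors.

The sparse direction problem couples the PLS eigen-problem for the
direction w with an L1-penalized surrogate c that is kept close to w:

    min_{w,c}  -kappa * w'Mc ... + (1-kappa) (c-w)'M(c-w)
               + lambda1 |c|_1 + lambda2 |c|^2,   subject to w'w = 1,

where M = Z Z' and Z = X'Y is the cross-covariance.  With lambda2 set
to infinity the c-update reduces to componentwise soft thresholding of
M w at a fraction ``eta`` of its largest absolute entry, so sparsity is
parameterized by the scale-free fraction eta in [0, 1) rather than by
an absolute penalty level.

For a univariate response the solution has a closed form: the soft
threshold of Z itself, independent of kappa.  For a multivariate
response the solver alternates a w-step (Lagrange-multiplier solution
of the quadratic subproblem) and a c-step (soft thresholding) until the
surrogate stabilizes.  The weight kappa < 1/2 down-weights the concave
part of the objective; kappa = 1/2 recovers the plain rank-one
singular-vector update, which is more prone to local solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .data import CenteredData

__all__ = [
    "SparsityParams",
    "DirectionVector",
    "CrossCovariance",
    "cross_covariance",
    "soft_threshold",
    "w_step",
    "c_step",
    "sparse_direction",
]


@dataclass
class SparsityParams:
    """Tuning knobs for the sparse direction solver.

    eta : soft-threshold fraction in [0, 1); larger is sparser.
    kappa : objective weight in (0, 0.5]; values < 0.5 temper the
        concave term and empirically avoid local solutions.
    tol : convergence tolerance on the max-abs change of the surrogate.
    maxit : iteration cap for the alternating solver.
    """

    eta: float = 0.5
    kappa: float = 0.4
    lambda2_infinite: bool = True
    tol: float = 1e-6
    maxit: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.eta < 1:
            raise ValueError("eta must be in [0, 1)")
        if not 0 < self.kappa <= 0.5:
            raise ValueError("kappa must be in (0, 0.5]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not self.lambda2_infinite:
            raise ValueError("only the lambda2 = infinity convention is supported")


@dataclass
class DirectionVector:
    """A unit-norm (or all-zero) p-vector with its nonzero support.

    ``raw`` carries the alternating solver's final surrogate on its own
    scale (the iteration is scale-sensitive through the w-step
    multiplier); it is ``None`` for closed-form directions.
    """

    values: np.ndarray
    raw: np.ndarray | None = None
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.flatnonzero(self.values)


class CrossCovariance:
    """Cross-covariance Z = X'Y and the implicit operator M = Z Z'.

    M is never materialized when p is large: products Mv are computed as
    Z (Z'v) at cost O(pq).  For the symmetric-matrix use case (e.g.
    running the solver on M = X'X) pass Z = X' so that ZZ' = X'X.
    """

    def __init__(self, Z: np.ndarray):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if not np.any(Z):
            raise ValueError("degenerate cross-covariance: X'Y is zero")
        self.Z = Z
        self.p, self.q = Z.shape
        self._svd: tuple[np.ndarray, np.ndarray] | None = None

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """M v = Z (Z' v)."""
        return self.Z @ (self.Z.T @ v)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Nonzero eigenpairs of M from the thin SVD of Z.

        Returns (U, mu) with M = U diag(mu) U' on its column space;
        cost O(p q^2), independent of p^2.
        """
        if self._svd is None:
            U, s, _ = np.linalg.svd(self.Z, full_matrices=False)
            self._svd = (U, s**2)
        return self._svd


def cross_covariance(data: CenteredData) -> CrossCovariance:
    """Z = X'Y for centered data; errors if the product is identically zero."""
    Z = data.X.T @ data.Y
    scale = max(1.0, float(np.abs(data.X).max() * np.abs(data.Y).max() * data.n))
    if np.abs(Z).max() <= 1e-12 * scale:
        raise ValueError("degenerate cross-covariance: X'Y is zero")
    return CrossCovariance(Z)


def soft_threshold(v: np.ndarray, eta: float) -> DirectionVector:
    """Soft threshold at a fraction eta of the maximal absolute entry.

    Each component becomes sign(v_i) (|v_i| - eta max_j |v_j|)_+ and the
    result is rescaled to unit norm.  The maximal entry always survives
    (ties at the maximum all survive), so the result is never zero.
    """
    v = np.asarray(v, dtype=float).ravel()
    if not 0 <= eta < 1:
        raise ValueError("eta must be in [0, 1)")
    amax = np.abs(v).max()
    if amax == 0:
        raise ValueError("cannot threshold a zero vector")
    shrunk = np.sign(v) * np.maximum(np.abs(v) - eta * amax, 0.0)
    return DirectionVector(shrunk / np.linalg.norm(shrunk))


def w_step(M: CrossCovariance, c: np.ndarray, kappa: float) -> np.ndarray:
    """Solve the w-subproblem for fixed surrogate c.

    kappa = 0.5: the subproblem is the rank-one singular-value problem
    with solution w = Mc / ||Mc||.  kappa < 0.5: the Lagrange-multiplier
    solution w = kappa' (M + lambda* I)^{-1} M c with kappa' =
    (1-kappa)/(1-2 kappa) and lambda* >= 0 chosen so that
    c'M (M + lambda I)^{-2} M c = kappa'^2.  The constraint function is
    strictly decreasing in lambda, so the root (when one exists) is
    unique; if even lambda = 0 cannot reach the required norm the
    unpenalized solution is returned.  Computed in the rank-q eigenbasis
    of M, so the cost is O(p q^2) and no p x p matrix is formed.
    """
    c = np.asarray(c, dtype=float).ravel()
    Mc = M.matvec(c)
    nrm = np.linalg.norm(Mc)
    if nrm == 0:
        raise ValueError("Mc = 0: surrogate is orthogonal to the operator range")
    if kappa == 0.5:
        return Mc / nrm
    kp = (1 - kappa) / (1 - 2 * kappa)
    U, mu = M.eig()
    a = U.T @ c  # coordinates of c in the eigenbasis; Mc = U (mu * a)
    b = mu * a

    def norm2(lam: float) -> float:
        return float(np.sum((b / (mu + lam)) ** 2))

    # ||(M + lam I)^{-1} M c||^2 falls monotonically from its lam=0 value
    if norm2(0.0) <= kp**2:
        lam_star = 0.0
    else:
        hi = max(mu.max(), 1.0)
        while norm2(hi) > kp**2:
            hi *= 2.0
            if hi > 1e300:  # pragma: no cover
                raise RuntimeError(
                    "lambda bracket overflow in the w-step root search"
                )
        lam_star = scipy.optimize.brentq(
            lambda lam: norm2(lam) - kp**2, 0.0, hi, xtol=1e-8, rtol=1e-12
        )
    w = kp * (U @ (b / (mu + lam_star)))
    return w


def c_step(M: CrossCovariance, w: np.ndarray, eta: float) -> np.ndarray:
    """Solve the c-subproblem for fixed w under the lambda2 = infinity rule.

    The penalized regression of Z'w on Z collapses to componentwise soft
    thresholding of M w = Z Z' w at fraction eta of its maximal entry.
    Returns the (unit-norm) thresholded vector scaled back to the
    magnitude of M w, so the surrogate keeps the natural scale of the
    operator between iterations.
    """
    Mw = M.matvec(np.asarray(w, dtype=float).ravel())
    nrm = np.linalg.norm(Mw)
    if nrm == 0:
        raise ValueError("M w = 0: direction is orthogonal to the operator range")
    return soft_threshold(Mw, eta).values * nrm


def sparse_direction(
    M: CrossCovariance | np.ndarray, params: SparsityParams
) -> DirectionVector:
    """Sparse direction vector for the cross-covariance Z (or operator M).

    Univariate response (q = 1): closed form -- the soft threshold of Z
    itself, independent of kappa, with no iteration.

    Multivariate response: alternate w-step and c-step, warm-started at
    the thresholded leading eigenvector of M (the dense PLS direction) so
    runs are deterministic; stop when the max-abs change of the
    normalized surrogate drops below tol or its support is unchanged on
    two consecutive iterations.  Returns the normalized surrogate.
    """
    if not isinstance(M, CrossCovariance):
        M = CrossCovariance(np.asarray(M))
    if M.q == 1:
        return soft_threshold(M.Z[:, 0], params.eta)

    # normalize the operator's scale so the iteration (whose multiplier
    # depends on the surrogate's magnitude) is invariant to rescaling Y
    scale = np.median(np.abs(M.Z[M.Z != 0]))
    M = CrossCovariance(M.Z / scale)
    U, mu = M.eig()
    v1 = U[:, int(np.argmax(mu))]
    # warm start at the thresholded dense direction; the sqrt(mu) scale
    # keeps the w-step's multiplier bracket in the operator's range
    c = soft_threshold(v1, params.eta).values * np.sqrt(mu.max())
    prev_unit = None
    prev_support = None
    stable = 0
    for _ in range(params.maxit):
        w = w_step(M, c, params.kappa)
        c = c_step(M, w, params.eta)
        unit = c / np.linalg.norm(c)
        support = np.flatnonzero(unit)
        if prev_unit is not None:
            if np.max(np.abs(unit - prev_unit)) < params.tol:
                return DirectionVector(unit, raw=c)
            if prev_support is not None and np.array_equal(support, prev_support):
                stable += 1
                if stable >= 5:
                    return DirectionVector(unit, raw=c)
            else:
                stable = 0
        prev_unit, prev_support = unit, support
    raise RuntimeError(
        f"sparse direction solver did not converge in {params.maxit} iterations "
        f"(last max-abs change {np.max(np.abs(unit - prev_unit)):.3e})"
    )
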