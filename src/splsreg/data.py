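"""Centering and scaling of predictor/response matrices.

All model fitting in this package operates on column-centered (and
optionally unit-scaled) matrices.  :class:`CenteredData` records the
transform so that fitted coefficients and predictions can be mapped back
to the raw scale of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CenteredData", "center_scale"]


@dataclass
class CenteredData:
    """Column-centered (optionally unit-scaled) X and Y with their transform.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Centered/scaled predictors.
    Y : ndarray of shape (n, q)
        Centered/scaled responses.
    x_center, x_scale : ndarray of shape (p,)
    y_center, y_scale : ndarray of shape (q,)
        The affine transform applied column-wise: ``X = (X_raw - center) / scale``.
        Scales are 1 when scaling was not requested.
    """

    X: np.ndarray
    Y: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    n: int = field(init=False)
    p: int = field(init=False)
    q: int = field(init=False)

    def __post_init__(self) -> None:
        self.n, self.p = self.X.shape
        self.q = self.Y.shape[1]
        if np.any(self.x_scale <= 0) or np.any(self.y_scale <= 0):
            raise ValueError("all scale entries must be strictly positive")

    def transform_x(self, X_raw: np.ndarray) -> np.ndarray:
        """Apply the stored training transform to new raw predictors."""
        X_raw = np.asarray(X_raw, dtype=float)
        if X_raw.ndim == 1:
            X_raw = X_raw[None, :]
        if X_raw.shape[1] != self.p:
            raise ValueError(
                f"expected {self.p} predictor columns, got {X_raw.shape[1]}"
            )
        return (X_raw - self.x_center) / self.x_scale

    def inverse_transform_y(self, Y_centered: np.ndarray) -> np.ndarray:
        """Map centered-scale responses back to the raw Y scale."""
        return Y_centered * self.y_scale + self.y_center


def _as_matrix(A, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2:
        raise ValueError(f"{name} must be a 2-d matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return A


def center_scale(
    X_raw,
    Y_raw,
    scale_x: bool = True,
    scale_y: bool | None = None,
) -> CenteredData:
    """Center (and optionally unit-scale) predictor and response columns.

    Parameters
    ----------
    X_raw : array-like of shape (n, p)
    Y_raw : array-like of shape (n, q) or (n,)
    scale_x : bool
        Divide each X column by its sample standard deviation (ddof=1).
    scale_y : bool or None
        As for X.  The default (``None``) scales Y only when it is
        multivariate: for a single response the scale of Y is immaterial
        to the fit, whereas for multiple responses unit-scaling guards
        against one response dominating the cross-covariance simply by
        having larger error variance.

    Raises
    ------
    ValueError
        On mismatched row counts, missing values, n < 3, or a
        zero-variance column when its scaling was requested.
    """
    X_raw = _as_matrix(X_raw, "X")
    Y_raw = _as_matrix(Y_raw, "Y")
    if X_raw.shape[0] != Y_raw.shape[0]:
        raise ValueError(
            f"X has {X_raw.shape[0]} rows but Y has {Y_raw.shape[0]}"
        )
    n, p = X_raw.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if scale_y is None:
        scale_y = Y_raw.shape[1] > 1

    x_center = X_raw.mean(axis=0)
    y_center = Y_raw.mean(axis=0)
    x_scale = np.ones(p)
    y_scale = np.ones(Y_raw.shape[1])
    if scale_x:
        sd = X_raw.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"cannot unit-scale constant X column(s) {bad.tolist()}"
            )
        x_scale = sd
    if scale_y:
        sd = Y_raw.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"cannot unit-scale constant Y column(s) {bad.tolist()}"
            )
        y_scale = sd

    return CenteredData(
        X=(X_raw - x_center) / x_scale,
        Y=(Y_raw - y_center) / y_scale,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
    )
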