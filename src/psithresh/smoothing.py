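"""Penalized cubic regression spline with GCV-chosen smoothness.

This is the smoothing engine behind the conductance-response fits: a
B-spline basis (statsmodels' ``BSplines``, second-derivative penalty) fitted
by penalized least squares, with the penalty weight chosen by generalized
cross-validation. The Demmler-Reinsch reparameterization makes the GCV
search a cheap eigenvalue sweep, so the smoother stays fast inside
replicate ensembles where thousands of fits are needed. statsmodels'
``GLMGam`` fits the identical model; tests cross-check against it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from statsmodels.gam.smooth_basis import BSplines

__all__ = ["PenalizedSpline"]


@dataclass
class PenalizedSpline:
    """Univariate penalized regression spline, y = f(x) + noise.

    Parameters
    ----------
    df : int
        Number of B-spline basis functions (knots are placed at quantiles
        by statsmodels). More basis functions sharpen the resolvable scale;
        the penalty controls effective degrees of freedom.
    degree : int
        Spline degree (3 = cubic).
    alpha : float or None
        Penalty weight on the integrated squared second derivative. None
        (default) selects it by GCV over a log-spaced grid with a golden
        refinement.
    """

    df: int = 25
    degree: int = 3
    alpha: float | None = None

    # populated by fit()
    alpha_: float = field(default=np.nan, init=False)
    edf_: float = field(default=np.nan, init=False)
    sigma2_: float = field(default=np.nan, init=False)
    coef_: np.ndarray | None = field(default=None, init=False)
    _basis: BSplines | None = field(default=None, init=False)
    _cov: np.ndarray | None = field(default=None, init=False)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PenalizedSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        n = x.size
        df = min(self.df, max(4, n - 1))
        self._basis = BSplines(
            x, df=[df], degree=[self.degree], include_intercept=True
        )
        X = self._basis.basis
        S = self._basis.penalty_matrices[0]

        XtX = X.T @ X
        Xty = X.T @ y
        # tiny ridge keeps the Cholesky valid when interior basis columns are
        # empty (sparse designs)
        eps = 1e-10 * np.trace(XtX) / XtX.shape[0]
        R = linalg.cholesky(XtX + eps * np.eye(XtX.shape[0]), lower=False)
        Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]), lower=False)
        A = Rinv.T @ S @ Rinv
        s, U = linalg.eigh(A)
        s = np.clip(s, 0.0, None)
        # rotated responses: fitted = X beta with beta = Rinv U diag(w) U' Rinv' Xty
        z = U.T @ (Rinv.T @ Xty)
        yty = float(y @ y)

        def rss_edf(alpha: float) -> tuple[float, float]:
            w = 1.0 / (1.0 + alpha * s)
            edf = float(np.sum(w))
            # RSS = y'y - 2 b'Xty + b'XtX b ; in rotated coords:
            # b'Xty = sum w z^2, b'XtX b = sum w^2 z^2
            rss = yty - 2.0 * float(np.sum(w * z**2)) + float(np.sum(w**2 * z**2))
            return max(rss, 0.0), edf

        def gcv(alpha: float) -> float:
            rss, edf = rss_edf(alpha)
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2

        if self.alpha is None:
            grid = np.logspace(-8, 6, 57)
            scores = [gcv(a) for a in grid]
            i = int(np.argmin(scores))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            # golden-section refinement in log space
            import math

            gr = (math.sqrt(5) - 1) / 2
            a_log, b_log = math.log(lo), math.log(hi)
            for _ in range(25):
                c = b_log - gr * (b_log - a_log)
                d = a_log + gr * (b_log - a_log)
                if gcv(math.exp(c)) < gcv(math.exp(d)):
                    b_log = d
                else:
                    a_log = c
            alpha = math.exp((a_log + b_log) / 2)
        else:
            alpha = float(self.alpha)

        w = 1.0 / (1.0 + alpha * s)
        beta = Rinv @ (U @ (w * z))
        rss, edf = rss_edf(alpha)
        self.alpha_ = alpha
        self.edf_ = edf
        self.coef_ = beta
        self.sigma2_ = rss / max(n - edf, 1e-8)
        # cov(beta) = sigma2 * Ainv XtX Ainv with Ainv = (XtX + alpha S)^-1
        M = Rinv @ (U * w) @ U.T @ Rinv.T  # = (XtX + alpha S)^-1 (up to eps ridge)
        self._cov = self.sigma2_ * (M @ XtX @ M)
        return self

    def _design(self, x_new: np.ndarray) -> np.ndarray:
        assert self._basis is not None, "call fit() first"
        x_new = np.asarray(x_new, dtype=float)
        return self._basis.transform(x_new[:, None])

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return self._design(x_new) @ self.coef_

    def predict_band(
        self, x_new: np.ndarray, level: float = 0.95
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Mean and pointwise confidence band on new points."""
        from scipy import stats

        B = self._design(x_new)
        mean = B @ self.coef_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self._cov, B), 0.0))
        zcrit = stats.norm.ppf(0.5 + level / 2)
        return mean, mean - zcrit * se, mean + zcrit * se
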