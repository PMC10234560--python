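"""Random-intercept linear mixed model, fit by maximum likelihood.

The sliding-window analyses refit one small mixed model (random intercept
per subject, two fixed slopes) at hundreds of time windows and, inside the
cluster permutation, a thousand more times per window.  This module
implements the exact profiled ML solution for that model family so the whole
grid is fit with vectorized linear algebra.

Model:  y = X beta + Z b + e,  b_j ~ N(0, s2_b),  e ~ N(0, s2).
With V0(th) = I + th Z Z' and th = s2_b / s2, the GLS estimate, the profiled
s2 and the profile log-likelihood are closed form given th:

    X' V0^-1 X = X'X - sum_j c_j (S_j X)'(S_j X),   c_j = th / (1 + th n_j),

where S_j sums the rows of group j; the analogous identities hold for
X' V0^-1 y and y' V0^-1 y, so every quantity factors through per-group sums
and many response columns (windows) share one set of sufficient statistics.
th is maximized per column by a coarse log-grid plus golden-section
refinement.  Fits agree with statsmodels MixedLM (ML); that cross-check
lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LmeFitResult", "RandomInterceptDesign", "fit_random_intercept", "fit_windows"]

_GRID = np.concatenate([[0.0], np.geomspace(1e-5, 1e3, 17)])
_GOLDEN_ITER = 12
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _inv_batched(A: np.ndarray) -> np.ndarray:
    """Invert a stack of small symmetric matrices; closed-form adjugate for
    p <= 3 (the hot path), LAPACK otherwise."""
    p = A.shape[-1]
    if p == 1:
        return 1.0 / A
    if p == 2:
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        out = np.empty_like(A)
        out[:, 0, 0] = A[:, 1, 1]
        out[:, 1, 1] = A[:, 0, 0]
        out[:, 0, 1] = -A[:, 0, 1]
        out[:, 1, 0] = -A[:, 1, 0]
        return out / det[:, None, None]
    if p == 3:
        a, b, c = A[:, 0, 0], A[:, 0, 1], A[:, 0, 2]
        d, e, f = A[:, 1, 0], A[:, 1, 1], A[:, 1, 2]
        g, h, i = A[:, 2, 0], A[:, 2, 1], A[:, 2, 2]
        c00 = e * i - f * h
        c01 = c * h - b * i
        c02 = b * f - c * e
        c10 = f * g - d * i
        c11 = a * i - c * g
        c12 = c * d - a * f
        c20 = d * h - e * g
        c21 = b * g - a * h
        c22 = a * e - b * d
        det = a * c00 + b * c10 + c * c20
        out = np.stack(
            [np.stack([c00, c01, c02], -1),
             np.stack([c10, c11, c12], -1),
             np.stack([c20, c21, c22], -1)],
            axis=1,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            return out / det[:, None, None]
    return np.linalg.inv(A)


@dataclass
class LmeFitResult:
    """Fixed effects of one random-intercept ML fit."""

    params: np.ndarray  # fixed-effect estimates, (p,)
    bse: np.ndarray  # standard errors, (p,)
    tvalues: np.ndarray  # params / bse
    loglik: float
    sigma2: float  # residual variance
    theta: float  # variance ratio s2_b / s2
    nobs: int
    random_intercepts: np.ndarray  # intercept BLUPs per group, (J,)


class RandomInterceptDesign:
    """Fixed design (X, groups) reused across many response columns.

    Permutations that reorder responses within groups leave the per-group
    response sums unchanged, so only X'Y has to be recomputed per shuffle;
    see :meth:`fit_sums`.
    """

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (observations x fixed effects)")
        groups = np.asarray(groups)
        self.n, self.p = X.shape
        self.labels, self.g = np.unique(groups, return_inverse=True)
        self.J = self.labels.size
        self.nj = np.bincount(self.g, minlength=self.J).astype(float)
        self.X = X
        self.XtX = X.T @ X
        GX = np.zeros((self.J, self.p))
        np.add.at(GX, self.g, X)
        self.GX = GX
        # per-group outer products, flattened: A(th) is one GEMM away
        self._M = (GX[:, :, None] * GX[:, None, :]).reshape(self.J, self.p**2)

    def group_sums(self, Y: np.ndarray) -> np.ndarray:
        GY = np.zeros((self.J, Y.shape[1]))
        np.add.at(GY, self.g, Y)
        return GY

    # -- profiled ML ---------------------------------------------------

    def _profile(self, XtY, GY, yty, theta):
        """Evaluate the profile at per-column theta.

        Returns (loglik (W,), beta (p, W), sigma2 (W,), Ainv (W, p, p))."""
        c = theta[None, :] / (1.0 + theta[None, :] * self.nj[:, None])  # (J, W)
        A = (self.XtX.reshape(-1)[None, :] - c.T @ self._M).reshape(
            -1, self.p, self.p
        )
        Ainv = _inv_batched(A)
        B = XtY - self.GX.T @ (c * GY)  # (p, W)
        beta = np.einsum("wpq,qw->pw", Ainv, B)
        q = yty - (c * GY**2).sum(axis=0)
        sigma2 = np.maximum((q - (beta * B).sum(axis=0)) / self.n, 1e-300)
        logdet = np.log1p(theta[None, :] * self.nj[:, None]).sum(axis=0)
        ll = -0.5 * self.n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet
        return ll, beta, sigma2, Ainv

    def _optimize_theta(self, XtY, GY, yty):
        W = XtY.shape[1]
        ll_grid = np.empty((_GRID.size, W))
        for i, th in enumerate(_GRID):
            ll_grid[i] = self._profile(XtY, GY, yty, np.full(W, th))[0]
        best = np.argmax(ll_grid, axis=0)
        a = _GRID[np.maximum(best - 1, 0)]
        b = _GRID[np.minimum(best + 1, _GRID.size - 1)]
        for _ in range(_GOLDEN_ITER):
            x1 = b - _INVPHI * (b - a)
            x2 = a + _INVPHI * (b - a)
            f1 = self._profile(XtY, GY, yty, x1)[0]
            f2 = self._profile(XtY, GY, yty, x2)[0]
            shrink_left = f1 >= f2  # maximum in [a, x2]
            b = np.where(shrink_left, x2, b)
            a = np.where(shrink_left, a, x1)
        theta = 0.5 * (a + b)
        ll_ref = self._profile(XtY, GY, yty, theta)[0]
        return np.where(ll_grid[0] >= ll_ref, 0.0, theta)

    def fit_sums(self, XtY, GY, yty):
        """Fit from sufficient statistics; returns
        (t, beta, loglik, sigma2, theta, Ainv)."""
        theta = self._optimize_theta(XtY, GY, yty)
        ll, beta, sigma2, Ainv = self._profile(XtY, GY, yty, theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = sigma2[:, None] * np.einsum("wpp->wp", Ainv)
            bse = np.sqrt(np.maximum(var, 0.0)).T
            t = beta / bse
        return t, beta, ll, sigma2, theta, Ainv

    def fit(self, Y: np.ndarray):
        """Fit every response column; returns (t (p,W), beta, loglik, singular)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        singular = ~np.isfinite(Y).all(axis=0) | (np.nanstd(Y, axis=0) <= 0)
        XtY = self.X.T @ Y
        GY = self.group_sums(Y)
        yty = (Y**2).sum(axis=0)
        t, beta, ll, *_ = self.fit_sums(XtY, GY, yty)
        singular = singular | ~np.isfinite(t).all(axis=0)
        t = t.copy()
        t[:, singular] = np.nan
        return t, beta, ll, singular


def fit_windows(X: np.ndarray, Y: np.ndarray, groups: np.ndarray):
    """Fit the random-intercept model for every response column of Y.

    Returns (tvalues (p, W), params (p, W), loglik (W,), singular (W,));
    singular columns (zero variance, non-finite data) carry NaN statistics.
    """
    return RandomInterceptDesign(X, groups).fit(Y)


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> LmeFitResult:
    """Single-response fit, including intercept BLUPs per group."""
    design = RandomInterceptDesign(X, groups)
    y = np.asarray(y, dtype=float).ravel()
    XtY = design.X.T @ y[:, None]
    GY = design.group_sums(y[:, None])
    yty = np.array([(y**2).sum()])
    t, beta, ll, sigma2, theta, Ainv = design.fit_sums(XtY, GY, yty)
    bse = np.sqrt(sigma2[0] * np.diag(Ainv[0]))
    th = float(theta[0])
    resid_sums = GY[:, 0] - design.GX @ beta[:, 0]
    blup = th / (1.0 + th * design.nj) * resid_sums
    return LmeFitResult(
        params=beta[:, 0],
        bse=bse,
        tvalues=beta[:, 0] / bse,
        loglik=float(ll[0]),
        sigma2=float(sigma2[0]),
        theta=th,
        nobs=design.n,
        random_intercepts=blup,
    )
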