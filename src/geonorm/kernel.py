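"""Nadaraya-Watson kernel regression from latent space back to volume space.

Given training pairs (x_i, y_i) — latent coordinates of the K neighbors and
their normalized volume vectors — the digital twin of a query point x is the
kernel-weighted local average

    Yhat(x) = sum_i K_h(x - x_i) y_i / sum_j K_h(x - x_j)

with an (unnormalized) Gaussian kernel K_h(u) = exp(-||u||^2 / (2 h^2)); the
normalization constant cancels in the ratio.  The bandwidth h is selected on
a grid by minimizing the mean squared leave-one-out residual over the
training pairs, ties going to the smallest h.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NadarayaWatsonRegressor",
    "BandwidthError",
    "default_bandwidth_grid",
    "UnderflowWarning",
]

#: grid multipliers applied to the median pairwise latent distance
DEFAULT_GRID_MULTIPLIERS = np.round(np.arange(0.1, 2.01, 0.1), 10)


class BandwidthError(RuntimeError):
    """No candidate bandwidth yields a defined leave-one-out prediction."""


class UnderflowWarning(UserWarning):
    """All kernel weights underflowed; nearest-neighbor fallback used."""


def default_bandwidth_grid(latent_points: np.ndarray) -> np.ndarray:
    """Candidate bandwidths: {0.1, ..., 2.0} x median pairwise distance."""
    x = np.asarray(latent_points, dtype=float)
    d2 = _sq_dists(x, x)
    iu = np.triu_indices(len(x), k=1)
    med = float(np.sqrt(np.median(d2[iu]))) if iu[0].size else 1.0
    if med <= 0:
        med = 1.0  # degenerate cloud: any h gives uniform weights
    return DEFAULT_GRID_MULTIPLIERS * med


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


class NadarayaWatsonRegressor(BaseEstimator, RegressorMixin):
    """Gaussian-kernel local-average regressor with LOO bandwidth selection.

    Parameters
    ----------
    bandwidth_grid : sequence of float > 0, or None
        Candidate bandwidths, in latent-space units.  ``None`` builds the
        default data-driven grid at fit time.

    Attributes
    ----------
    bandwidth_ : selected h.
    loo_mse_ : mean squared LOO residual at the selected h.
    X_, y_ : stored training pairs.
    """

    def __init__(self, bandwidth_grid=None):
        self.bandwidth_grid = bandwidth_grid

    def fit(self, X, y) -> "NadarayaWatsonRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise ValueError("X and y must have the same number of rows")
        if self.bandwidth_grid is None:
            grid = default_bandwidth_grid(X)
        else:
            grid = np.asarray(list(self.bandwidth_grid), dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("bandwidth grid must be non-empty with all h > 0")
        self.X_, self.y_ = X, y
        k = len(X)
        if k == 1:
            # sole training point: prediction is constant, h irrelevant
            self.bandwidth_ = float(np.min(grid))
            self.loo_mse_ = np.nan
            return self
        d2 = _sq_dists(X, X)
        best_h, best_mse = None, np.inf
        for h in np.sort(grid):
            w = np.exp(-d2 / (2.0 * h * h))
            np.fill_diagonal(w, 0.0)  # leave-one-out
            denom = w.sum(axis=1)
            if np.any(denom <= 0):
                continue  # undefined LOO prediction at this h
            pred = (w @ y) / denom[:, None]
            mse = float(np.mean((pred - y) ** 2))
            if mse < best_mse - 1e-15:  # ties -> smallest h (grid sorted)
                best_h, best_mse = float(h), mse
        if best_h is None:
            raise BandwidthError(
                "every candidate bandwidth left some training point with "
                "numerically zero kernel weights; supply larger h values"
            )
        self.bandwidth_ = best_h
        self.loo_mse_ = best_mse
        return self

    def predict(self, X) -> np.ndarray:
        """Digital-twin prediction Yhat at query latent points.

        Weights sum to one, so predictions are convex combinations of the
        training y_i.  If every weight underflows to zero for a query, the
        nearest training point's y is returned with a warning.
        """
        check_is_fitted(self, "bandwidth_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(self.X_) == 1:  # constant regressor, independent of h
            return np.tile(self.y_[0], (len(X), 1))
        w = self.weights(X)
        bad = ~np.isfinite(w).all(axis=1)
        out = np.empty((len(X), self.y_.shape[1]))
        ok = ~bad
        out[ok] = w[ok] @ self.y_
        if np.any(bad):
            warnings.warn(
                "kernel weights underflowed for some query points; falling "
                "back to the nearest training point",
                UnderflowWarning,
                stacklevel=2,
            )
            d2 = _sq_dists(X[bad], self.X_)
            out[bad] = self.y_[np.argmin(d2, axis=1)]
        return out

    def weights(self, X) -> np.ndarray:
        """Normalized kernel weights w_i(x); rows sum to 1 (NaN on underflow)."""
        check_is_fitted(self, "bandwidth_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = self.bandwidth_
        raw = np.exp(-_sq_dists(X, self.X_) / (2.0 * h * h))
        denom = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, raw / denom, np.nan)
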