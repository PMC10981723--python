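"""Low-dimensional manifold embedding of a neighbor set.

The personalized model represents the K nearest healthy controls of a test
subject in a latent space of small dimension d (default 2), then regresses
volumes on latent coordinates.  Two reducers are available:

* ``"umap"`` — uniform manifold approximation and projection, the
  nonlinear default; all randomness flows from the ``seed`` parameter so
  repeated fits are identical.
* ``"pca"`` — a deterministic linear alternative whose exact geometry
  (isometry on planar data, analytic out-of-sample projection) makes it
  the reducer of choice for large simulation studies and exact oracles.

Both expose the same fit/transform contract, so they are interchangeable
inside :class:`~geonorm.assessor.GeoNormAssessor`.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["ManifoldReducer", "DegenerateNeighborsWarning"]


class DegenerateNeighborsWarning(UserWarning):
    """The neighbor set has (numerically) no variance."""


class ManifoldReducer(BaseEstimator, TransformerMixin):
    """Seeded dimensionality reduction with out-of-sample projection.

    Parameters
    ----------
    latent_dim : int, default 2
        Dimension d of the latent space.
    reducer : {"umap", "pca"}, default "umap"
    seed : int, default 0
        Seeds all stochastic steps; same seed + same input gives identical
        latent coordinates.

    Attributes
    ----------
    embedding_ : (K, latent_dim) latent coordinates of the training rows.
    n_features_in_ : number of structure columns seen at fit.
    """

    def __init__(self, latent_dim: int = 2, reducer: str = "umap", seed: int = 0):
        self.latent_dim = latent_dim
        self.reducer = reducer
        self.seed = seed

    def fit(self, X, y=None) -> "ManifoldReducer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (neighbors x structures)")
        k, s = X.shape
        if k < self.latent_dim + 1:
            raise ValueError(
                f"need at least latent_dim+1={self.latent_dim + 1} rows, got {k}"
            )
        self.n_features_in_ = s
        self._degenerate_ = bool(np.ptp(X, axis=0).max() < 1e-12)
        if self._degenerate_:
            warnings.warn(
                "all neighbor rows are identical; latent space collapses to "
                "the origin",
                DegenerateNeighborsWarning,
                stacklevel=2,
            )
            self._mean_ = X.mean(axis=0)
            self.embedding_ = np.zeros((k, self.latent_dim))
            self._model_ = None
            return self
        if self.reducer == "pca":
            self._model_ = PCA(
                n_components=min(self.latent_dim, k - 1, s),
                svd_solver="full",
                random_state=self.seed,
            ).fit(X)
            emb = self._model_.transform(X)
        elif self.reducer == "umap":
            import umap  # deferred: heavy numba compilation on first use

            n_neighbors = min(15, k - 1)
            self._model_ = umap.UMAP(
                n_components=self.latent_dim,
                n_neighbors=n_neighbors,
                random_state=self.seed,
                transform_seed=self.seed,
            ).fit(X)
            emb = np.asarray(self._model_.embedding_, dtype=float)
        else:
            raise ValueError(f"unknown reducer {self.reducer!r}")
        # pad with zero columns if the data rank undercut latent_dim
        if emb.shape[1] < self.latent_dim:
            emb = np.hstack(
                [emb, np.zeros((k, self.latent_dim - emb.shape[1]))]
            )
        self.embedding_ = emb
        if not np.all(np.isfinite(self.embedding_)):
            raise RuntimeError("reducer produced non-finite latent coordinates")
        return self

    def transform(self, X) -> np.ndarray:
        """Project new subjects into the fitted latent space."""
        check_is_fitted(self, "embedding_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} structure columns, got {X.shape[1]}"
            )
        if self._degenerate_:
            return np.zeros((X.shape[0], self.latent_dim))
        out = np.asarray(self._model_.transform(X), dtype=float)
        if out.shape[1] < self.latent_dim:
            out = np.hstack(
                [out, np.zeros((X.shape[0], self.latent_dim - out.shape[1]))]
            )
        return out

    def inverse_transform(self, Z) -> np.ndarray:
        """Map latent points back to structure space (PCA reducer only)."""
        check_is_fitted(self, "embedding_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self._degenerate_:
            return np.tile(self._mean_, (Z.shape[0], 1))
        if self.reducer != "pca":
            raise NotImplementedError("inverse_transform requires the pca reducer")
        return self._model_.inverse_transform(Z[:, : self._model_.n_components_])
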