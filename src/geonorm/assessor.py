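"""Personalized normative assessment via digital twins.

For a test subject with S normalized structure volumes, the pipeline is:

1. select the K healthy controls closest to the subject in percent space;
2. embed those K controls into a low-dimensional manifold;
3. regress volumes on latent coordinates with a Nadaraya-Watson kernel and
   synthesize the subject's digital twin Yhat at its projected coordinates;
4. calibrate the null residual distribution by leave-one-out over the K
   neighbors (each neighbor held out, reconstructed by a model fit on the
   remaining K-1);
5. per structure: residual eps = Y - Yhat, z-score against the LOO residual
   mean/std, a personalized range [Yhat + q_alpha, Yhat + q_{1-alpha}] from
   the empirical LOO residual quantiles, a three-way label, and a
   permutation-style p from the rank of |z| among the held-out controls' |z|.

The subject itself is never part of the learned manifold, so its residual is
compared against genuinely out-of-sample model variability.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .kernel import NadarayaWatsonRegressor
from .lifespan import classify
from .manifold import ManifoldReducer

__all__ = [
    "NeighborSet",
    "ResidualCalibration",
    "DigitalTwinAssessment",
    "GeoNormAssessor",
    "select_nearest_controls",
    "calibrate_residuals_loo",
    "assess_subject",
]


@dataclasses.dataclass(frozen=True)
class NeighborSet:
    """The K controls nearest to a subject, sorted by distance."""

    control_ids: tuple[str, ...]
    indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be sorted non-decreasing")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def k(self) -> int:
        return len(self.control_ids)


@dataclasses.dataclass(frozen=True)
class ResidualCalibration:
    """Null residual distribution from leave-one-out over the neighbors.

    ``residuals`` holds one row per held-out neighbor (K x S); ``mean`` and
    ``std`` are the per-structure moments.  Structures with zero LOO spread
    cannot be z-scored and are listed in ``degenerate``.
    """

    residuals: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    degenerate: np.ndarray  # boolean mask, True where std == 0

    @property
    def k(self) -> int:
        return self.residuals.shape[0]


def select_nearest_controls(
    subject: np.ndarray,
    controls: pd.DataFrame,
    k: int = 30,
    metric: str = "euclidean",
) -> NeighborSet:
    """Pick the K controls with the smallest volume-difference distance.

    Distance is computed over all normalized structure volumes at once
    (Euclidean by default, ``"manhattan"`` optional); ties are broken by
    control row order.
    """
    values = np.asarray(controls, dtype=float)
    subject = np.asarray(subject, dtype=float).ravel()
    if subject.shape[0] != values.shape[1]:
        raise ValueError(
            f"subject has {subject.shape[0]} structures, controls have "
            f"{values.shape[1]}"
        )
    if not 1 <= k <= len(values):
        raise ValueError(f"k={k} must be in 1..{len(values)} (cohort size)")
    diff = values - subject
    if metric == "euclidean":
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    elif metric == "manhattan":
        dist = np.abs(diff).sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.argsort(dist, kind="stable")[:k]
    ids = (
        tuple(str(i) for i in controls.index[order])
        if isinstance(controls, pd.DataFrame)
        else tuple(str(i) for i in order)
    )
    return NeighborSet(control_ids=ids, indices=order, distances=dist[order])


def _fit_twin_model(
    neighbors: np.ndarray,
    latent_dim: int,
    reducer: str,
    seed: int,
    bandwidth_grid,
) -> tuple[ManifoldReducer, NadarayaWatsonRegressor]:
    manifold = ManifoldReducer(latent_dim=latent_dim, reducer=reducer, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-neighbor warnings handled upstream
        manifold.fit(neighbors)
        reg = NadarayaWatsonRegressor(bandwidth_grid=bandwidth_grid).fit(
            manifold.embedding_, neighbors
        )
    return manifold, reg


def calibrate_residuals_loo(
    neighbors: np.ndarray,
    latent_dim: int = 2,
    reducer: str = "pca",
    seed: int = 0,
    bandwidth_grid=None,
) -> ResidualCalibration:
    """Leave-one-out null residuals over a K x S neighbor matrix.

    Each neighbor in turn is held out; the manifold and kernel regressor are
    refit on the remaining K-1 (bandwidth re-selected within the fold), the
    held-out subject is embedded, and its residual eps = Y - Yhat recorded.
    """
    neighbors = np.asarray(neighbors, dtype=float)
    k = len(neighbors)
    if k < 3:
        raise ValueError(f"need at least 3 neighbors for LOO calibration, got {k}")
    residuals = np.empty_like(neighbors)
    for i in range(k):
        rest = np.delete(neighbors, i, axis=0)
        try:
            manifold, reg = _fit_twin_model(
                rest, latent_dim, reducer, seed, bandwidth_grid
            )
            x_held = manifold.transform(neighbors[i])
            residuals[i] = neighbors[i] - reg.predict(x_held)[0]
        except Exception as exc:  # surface which fold failed
            raise RuntimeError(f"LOO calibration failed at fold {i}") from exc
    std = residuals.std(axis=0, ddof=1)
    return ResidualCalibration(
        residuals=residuals,
        mean=residuals.mean(axis=0),
        std=std,
        degenerate=std <= 0,
    )


@dataclasses.dataclass(frozen=True)
class DigitalTwinAssessment:
    """Per-structure personalized assessment of one subject."""

    structure_names: tuple[str, ...]
    observed: np.ndarray  # Y, percent
    twin: np.ndarray  # Yhat, percent
    residual: np.ndarray  # eps = Y - Yhat
    z: np.ndarray  # (eps - loo_mean) / loo_std, NaN where uncalibrated
    perm_p: np.ndarray  # rank of |z| among held-out control |z|
    lower: np.ndarray
    upper: np.ndarray
    label: np.ndarray  # decreased/normal/increased; "uncalibrated" if std==0
    alpha: float
    neighbors: NeighborSet
    calibration: ResidualCalibration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": list(self.structure_names),
                "observed_pct": self.observed,
                "twin_pct": self.twin,
                "residual": self.residual,
                "z": self.z,
                "perm_p": self.perm_p,
                "lower": self.lower,
                "upper": self.upper,
                "label": self.label,
            }
        )


class GeoNormAssessor(BaseEstimator):
    """Digital-twin personalized normative model.

    Parameters
    ----------
    n_neighbors : int, default 30
        K, the number of nearest controls forming the reference set.
    latent_dim : int, default 2
        Manifold dimension.
    reducer : {"umap", "pca"}, default "umap"
    seed : int, default 0
        Seeds the manifold reducer (the only stochastic component).
    bandwidth_grid : sequence of float or None
        Candidate kernel bandwidths; None uses the data-driven default
        ({0.1..2.0} x median pairwise latent distance).
    alpha : float, default 0.05
        Tail probability per side for the personalized range.
    metric : {"euclidean", "manhattan"}, default "euclidean"
        Neighbor-selection distance.

    Attributes
    ----------
    controls_ : DataFrame of normalized control volumes (percent of ICV).
    structure_names_ : column labels of the control matrix.
    """

    def __init__(
        self,
        n_neighbors: int = 30,
        latent_dim: int = 2,
        reducer: str = "umap",
        seed: int = 0,
        bandwidth_grid=None,
        alpha: float = 0.05,
        metric: str = "euclidean",
    ):
        self.n_neighbors = n_neighbors
        self.latent_dim = latent_dim
        self.reducer = reducer
        self.seed = seed
        self.bandwidth_grid = bandwidth_grid
        self.alpha = alpha
        self.metric = metric

    def fit(self, X: pd.DataFrame, y=None) -> "GeoNormAssessor":
        """Store the normalized healthy-control matrix (percent of ICV)."""
        X = pd.DataFrame(X)
        if len(X) < self.n_neighbors:
            raise ValueError(
                f"need at least n_neighbors={self.n_neighbors} controls, "
                f"got {len(X)}"
            )
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        self.controls_ = X.astype(float)
        self.structure_names_ = list(X.columns)
        return self

    def assess(self, subject) -> DigitalTwinAssessment:
        """Full personalized assessment of one subject vector (percent)."""
        check_is_fitted(self, "controls_")
        subject = np.asarray(subject, dtype=float).ravel()
        controls = self.controls_
        # the subject must not double as its own reference
        dup = np.flatnonzero(
            np.all(np.isclose(controls.to_numpy(), subject, atol=1e-12), axis=1)
        )
        if dup.size:
            warnings.warn(
                f"subject coincides with control row(s) {dup.tolist()}; "
                "excluding them from the reference cohort",
                UserWarning,
                stacklevel=2,
            )
            controls = controls.drop(index=controls.index[dup])
            if len(controls) < self.n_neighbors:
                raise ValueError("too few controls left after excluding subject")
        neighbors = select_nearest_controls(
            subject, controls, k=self.n_neighbors, metric=self.metric
        )
        nb_values = controls.to_numpy(dtype=float)[neighbors.indices]
        manifold, reg = _fit_twin_model(
            nb_values, self.latent_dim, self.reducer, self.seed, self.bandwidth_grid
        )
        twin = reg.predict(manifold.transform(subject))[0]
        calib = calibrate_residuals_loo(
            nb_values,
            latent_dim=self.latent_dim,
            reducer=self.reducer,
            seed=self.seed,
            bandwidth_grid=self.bandwidth_grid,
        )
        residual = subject - twin
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(
                calib.degenerate, np.nan, (residual - calib.mean) / calib.std
            )
            z_loo = np.where(
                calib.degenerate[None, :],
                np.nan,
                (calib.residuals - calib.mean) / calib.std,
            )
        k = calib.k
        perm_p = (1.0 + np.sum(np.abs(z_loo) >= np.abs(z), axis=0)) / (k + 1.0)
        perm_p = np.where(calib.degenerate, np.nan, perm_p)
        q_lo = np.quantile(calib.residuals, self.alpha, axis=0)
        q_hi = np.quantile(calib.residuals, 1.0 - self.alpha, axis=0)
        lower, upper = twin + q_lo, twin + q_hi
        label = classify(subject, lower, upper)
        label = np.asarray(label, dtype=object)
        label[calib.degenerate] = "uncalibrated"
        return DigitalTwinAssessment(
            structure_names=tuple(self.structure_names_),
            observed=subject,
            twin=twin,
            residual=residual,
            z=z,
            perm_p=perm_p,
            lower=lower,
            upper=upper,
            label=label,
            alpha=self.alpha,
            neighbors=neighbors,
            calibration=calib,
        )

    def predict_labels(self, X: pd.DataFrame) -> pd.DataFrame:
        """Assess each row of X; returns a subjects x structures label frame."""
        check_is_fitted(self, "controls_")
        X = pd.DataFrame(X)
        rows = [self.assess(X.iloc[i].to_numpy()).label for i in range(len(X))]
        return pd.DataFrame(rows, index=X.index, columns=self.structure_names_)


def assess_subject(
    subject,
    controls: pd.DataFrame,
    n_neighbors: int = 30,
    latent_dim: int = 2,
    reducer: str = "umap",
    seed: int = 0,
    bandwidth_grid=None,
    alpha: float = 0.05,
    metric: str = "euclidean",
) -> DigitalTwinAssessment:
    """Functional wrapper over :class:`GeoNormAssessor`."""
    assessor = GeoNormAssessor(
        n_neighbors=n_neighbors,
        latent_dim=latent_dim,
        reducer=reducer,
        seed=seed,
        bandwidth_grid=bandwidth_grid,
        alpha=alpha,
        metric=metric,
    ).fit(controls)
    return assessor.assess(subject)
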