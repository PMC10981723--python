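"""Age-based lifespan normative model ("average normative values").

The traditional baseline: for each brain structure independently, the
normalized volume (percent of ICV) is regressed on age with a low-order
polynomial over a healthy control cohort, and a normative range is formed
by adding the empirical 5th and 95th percentiles of the fit residuals to
the fitted curve.  A subject's structure is labeled ``decreased`` /
``normal`` / ``increased`` by comparing its observed value to that range.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LifespanNormativeModel",
    "classify",
    "fit_lifespan",
    "ExtrapolationWarning",
]

LABELS = ("decreased", "normal", "increased")


class ExtrapolationWarning(UserWarning):
    """Normative range requested outside the ages seen during fitting."""


def classify(value, lower, upper):
    """Three-way label of observed values against a normative range.

    Values strictly below ``lower`` are ``"decreased"``, strictly above
    ``upper`` are ``"increased"``; boundaries inclusive map to ``"normal"``
    (printed ranges are rounded — the decision uses unrounded values).
    Broadcasts over array inputs.
    """
    value, lower, upper = np.broadcast_arrays(
        np.asarray(value, float), np.asarray(lower, float), np.asarray(upper, float)
    )
    out = np.full(value.shape, "normal", dtype=object)
    out[value < lower] = "decreased"
    out[value > upper] = "increased"
    if out.ndim == 0:
        return out.item()
    return out


class LifespanNormativeModel(BaseEstimator):
    """Per-structure polynomial age trajectory with residual-quantile bounds.

    Parameters
    ----------
    degree : int or "auto", default 2
        Polynomial order of the age trajectory.  ``"auto"`` selects the
        degree per structure from 1..max_degree by BIC.
    max_degree : int, default 3
        Largest degree considered ("low order" regime).
    lower_q, upper_q : float
        Residual quantile levels for the lower/upper normative bounds
        (defaults 0.05 / 0.95).

    Attributes
    ----------
    structure_names_ : list of fitted structure labels.
    coef_ : dict structure -> ascending polynomial coefficients
        (percent per year^k).
    degree_ : dict structure -> selected degree.
    residual_q05_, residual_q95_ : dict structure -> residual quantiles
        (percent).
    n_fit_ : number of controls used.
    age_range_ : (min, max) ages seen during fit.
    """

    def __init__(self, degree=2, max_degree=3, lower_q=0.05, upper_q=0.95):
        self.degree = degree
        self.max_degree = max_degree
        self.lower_q = lower_q
        self.upper_q = upper_q

    def fit(self, X: pd.DataFrame, ages) -> "LifespanNormativeModel":
        """Fit one polynomial + residual quantiles per structure column."""
        X = pd.DataFrame(X)
        ages = np.asarray(ages, dtype=float)
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages must be finite")
        if len(ages) != len(X):
            raise ValueError("ages length must match number of rows in X")
        if self.degree == "auto":
            candidates = list(range(1, self.max_degree + 1))
        else:
            if self.degree < 1 or self.degree > self.max_degree:
                raise ValueError(
                    f"degree must be in 1..{self.max_degree} or 'auto'"
                )
            candidates = [int(self.degree)]
        n = len(ages)
        if n < max(candidates) + 2:
            raise ValueError(
                f"need at least degree+2={max(candidates) + 2} controls, got {n}"
            )
        self.structure_names_ = list(X.columns)
        self.coef_: dict[str, np.ndarray] = {}
        self.degree_: dict[str, int] = {}
        self.residual_q05_: dict[str, float] = {}
        self.residual_q95_: dict[str, float] = {}
        for name in self.structure_names_:
            y = X[name].to_numpy(dtype=float)
            best = None
            for d in candidates:
                coef = np.polynomial.polynomial.polyfit(ages, y, d)
                resid = y - np.polynomial.polynomial.polyval(ages, coef)
                rss = float(resid @ resid)
                # BIC with Gaussian errors; k = d+1 coefficients
                bic = n * np.log(max(rss, 1e-300) / n) + (d + 1) * np.log(n)
                if best is None or bic < best[0] - 1e-12:
                    best = (bic, d, coef, resid)
            _, d, coef, resid = best
            self.coef_[name] = coef
            self.degree_[name] = d
            self.residual_q05_[name] = float(np.quantile(resid, self.lower_q))
            self.residual_q95_[name] = float(np.quantile(resid, self.upper_q))
        self.n_fit_ = n
        self.age_range_ = (float(ages.min()), float(ages.max()))
        return self

    def _check_structure(self, structure: str) -> None:
        if structure not in self.coef_:
            raise KeyError(f"unknown structure {structure!r}")

    def trajectory(self, structure: str, age) -> np.ndarray:
        """Fitted mean normalized volume at the given age(s)."""
        check_is_fitted(self, "coef_")
        self._check_structure(structure)
        return np.polynomial.polynomial.polyval(
            np.asarray(age, float), self.coef_[structure]
        )

    def normative_range(self, structure: str, age):
        """(lower, upper) normative bounds in percent at the given age.

        Ages outside the training span still return a range but raise an
        :class:`ExtrapolationWarning`.
        """
        check_is_fitted(self, "coef_")
        self._check_structure(structure)
        age_arr = np.asarray(age, float)
        lo_age, hi_age = self.age_range_
        if np.any(age_arr < lo_age) or np.any(age_arr > hi_age):
            warnings.warn(
                f"age outside training span [{lo_age:g}, {hi_age:g}]; "
                "normative range is an extrapolation",
                ExtrapolationWarning,
                stacklevel=2,
            )
        fitted = self.trajectory(structure, age_arr)
        return fitted + self.residual_q05_[structure], fitted + self.residual_q95_[structure]

    def predict_labels(self, X: pd.DataFrame, ages) -> pd.DataFrame:
        """Label every (subject, structure) against its age-specific range."""
        check_is_fitted(self, "coef_")
        X = pd.DataFrame(X)
        ages = np.asarray(ages, dtype=float)
        out = {}
        for name in self.structure_names_:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                lower, upper = self.normative_range(name, ages)
            out[name] = classify(X[name].to_numpy(dtype=float), lower, upper)
        return pd.DataFrame(out, index=X.index)

    def to_dict(self) -> dict:
        """JSON-serializable model (coefficients and quantiles per structure)."""
        check_is_fitted(self, "coef_")
        return {
            "n_fit": self.n_fit_,
            "age_range": list(self.age_range_),
            "lower_q": self.lower_q,
            "upper_q": self.upper_q,
            "structures": {
                name: {
                    "coefficients": self.coef_[name].tolist(),
                    "degree": self.degree_[name],
                    "residual_q05": self.residual_q05_[name],
                    "residual_q95": self.residual_q95_[name],
                }
                for name in self.structure_names_
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LifespanNormativeModel":
        model = cls(lower_q=payload["lower_q"], upper_q=payload["upper_q"])
        model.structure_names_ = list(payload["structures"])
        model.coef_ = {
            k: np.asarray(v["coefficients"], float)
            for k, v in payload["structures"].items()
        }
        model.degree_ = {k: v["degree"] for k, v in payload["structures"].items()}
        model.residual_q05_ = {
            k: v["residual_q05"] for k, v in payload["structures"].items()
        }
        model.residual_q95_ = {
            k: v["residual_q95"] for k, v in payload["structures"].items()
        }
        model.n_fit_ = payload["n_fit"]
        model.age_range_ = tuple(payload["age_range"])
        return model


def fit_lifespan(controls: pd.DataFrame, ages, degree=2) -> LifespanNormativeModel:
    """Functional wrapper over :class:`LifespanNormativeModel`."""
    return LifespanNormativeModel(degree=degree).fit(controls, ages)
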