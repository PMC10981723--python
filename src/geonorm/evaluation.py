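"""Diagnostic-performance statistics for paired normative models.

Compares the age-based average normative model with the personalized
digital-twin model on the same subjects: detection counts and sensitivities
against a surgical gold standard, an exact McNemar test on discordant
pairs, an exact-with-ties Wilcoxon signed-rank test for abnormal-region
counts, and region-count summaries of assessments.

The packaged epilepsy outcome fixture (28 surgery-confirmed focal cortical
dysplasia patients with per-patient outcomes of both models and the
radiological read) ships as a CSV resource and drives the worked examples.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assessor import DigitalTwinAssessment

__all__ = [
    "load_table1",
    "PairedOutcomeCounts",
    "detection_count",
    "sensitivity",
    "relative_detection_gain",
    "paired_counts",
    "mcnemar_exact",
    "wilcoxon_signed_rank",
    "abnormal_region_counts",
]

N_PATIENTS = 28


def load_table1() -> pd.DataFrame:
    """The packaged 28-patient epilepsy outcome fixture.

    Columns: patient, sex, age_years, age_at_onset_years, surgery_location,
    radiological_report, average_outcome, personalized_outcome.  "NA" means
    no abnormality reported and is kept as a literal string.
    """
    ref = resources.files("geonorm.data") / "table1_epilepsy.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False)
    if len(df) != N_PATIENTS:
        raise RuntimeError("corrupted fixture: expected 28 patients")
    return df


_METHOD_COL = {"average": "average_outcome", "personalized": "personalized_outcome"}


def detection_count(
    fixture: pd.DataFrame,
    method: str,
    subset: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> int:
    """Number of patients (optionally within a subset) labeled Increased."""
    col = _METHOD_COL[method]
    mask = fixture[col] == "Increased"
    if subset is not None:
        mask &= subset(fixture).astype(bool)
    return int(mask.sum())


def sensitivity(fixture: pd.DataFrame, method: str) -> float:
    """Detection count over all patients (every patient is surgery-confirmed
    positive), rounded half-up to 2 decimals."""
    frac = detection_count(fixture, method) / len(fixture)
    # round-half-up to match printed style (Python's round is half-even)
    return float(np.floor(frac * 100 + 0.5) / 100)


def relative_detection_gain(fixture: pd.DataFrame) -> int:
    """Percent increase in detections of the personalized over the average
    model, rounded to the nearest integer."""
    avg = detection_count(fixture, "average")
    per = detection_count(fixture, "personalized")
    if avg == 0:
        raise ZeroDivisionError("average model detected no patients")
    return int(np.floor(100.0 * (per - avg) / avg + 0.5))


@dataclasses.dataclass(frozen=True)
class PairedOutcomeCounts:
    """2x2 cross-tabulation of two paired binary outcomes.

    a: both positive; b: personalized-only; c: average-only; d: both negative.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def paired_counts(fixture: pd.DataFrame) -> PairedOutcomeCounts:
    avg = fixture["average_outcome"] == "Increased"
    per = fixture["personalized_outcome"] == "Increased"
    return PairedOutcomeCounts(
        a=int((avg & per).sum()),
        b=int((~avg & per).sum()),
        c=int((avg & ~per).sum()),
        d=int((~avg & ~per).sum()),
    )


def mcnemar_exact(counts: PairedOutcomeCounts) -> float:
    """Exact McNemar p-value on the discordant pairs.

    Under no disagreement the b discordant-one-way pairs among b+c follow
    Binomial(b+c, 1/2); the two-sided p is 2*P(X <= min(b, c)), clamped to
    1 (and 1 exactly when b+c == 0).  The exact form is required here: the
    chi-square approximation is invalid at the handful of discordant pairs
    typical of small paired cohorts.
    """
    m = counts.b + counts.c
    if m == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(counts.b, counts.c), m, 0.5)
    return float(min(p, 1.0))


def _exact_signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of W+ over all 2^n sign assignments.

    Conditional on the observed (mid-)ranks, the generating function of W+
    is prod_i (1 + t^{r_i}) / 2^n.  Mid-ranks live on a half-integer grid,
    so doubling makes every exponent integral and the product reduces to a
    sequence of sparse convolutions — exact even with ties, at any n that
    fits the grid.
    """
    scaled = np.rint(2 * ranks).astype(int)
    pmf = np.zeros(scaled.sum() + 1)
    pmf[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: len(pmf) - r]
        pmf = 0.5 * (pmf + shifted)
    support = np.arange(len(pmf)) / 2.0
    return support, pmf


def wilcoxon_signed_rank(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    statistic: str = "min",
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired count vectors.

    Zero differences are dropped, ties mid-ranked.  For n <= exact_max_n
    the p-value is exact (full enumeration of sign assignments via the
    generating function, valid with ties); larger n uses the normal
    approximation with tie correction.

    statistic : "min" returns min(W+, W-) (the conventional reported
        statistic); "positive" returns W+.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    w_minus = total - w_plus
    stat = min(w_plus, w_minus) if statistic == "min" else w_plus
    if statistic not in ("min", "positive"):
        raise ValueError(f"unknown statistic convention {statistic!r}")
    if n <= exact_max_n:
        support, pmf = _exact_signed_rank_distribution(ranks)
        p_le = pmf[support <= w_plus + 1e-9].sum()
        p_ge = pmf[support >= w_plus - 1e-9].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return float(stat), float(p)


def abnormal_region_counts(
    assessment: DigitalTwinAssessment | pd.DataFrame,
    exclude: set[str] | Sequence[str] = (),
) -> dict[str, int]:
    """Counts of abnormal structures in an assessment, minus an exclusion set
    (typically the operated/lesioned region)."""
    if isinstance(assessment, DigitalTwinAssessment):
        frame = assessment.to_frame()
    else:
        frame = assessment
    keep = ~frame["structure"].isin(set(exclude))
    labels = frame.loc[keep, "label"]
    inc = int((labels == "increased").sum())
    dec = int((labels == "decreased").sum())
    return {"increased": inc, "decreased_plus_increased": inc + dec}
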