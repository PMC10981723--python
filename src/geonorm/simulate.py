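"""Synthetic lifespan cohorts with manifold structure and focal lesions.

Emulates the tabular output of whole-brain segmentation on a healthy
lifespan cohort so the entire pipeline is testable without MRI data:

* ages uniform over the lifespan (default 9 months to 94 years);
* each structure follows a smooth low-order polynomial age trajectory of
  its normalized volume (percent of ICV);
* subject-level latent factors add correlated scaling across structures —
  the first factor is a global "brain size / brain age" scaling affecting
  all structures proportionally — creating the low-dimensional manifold
  structure the personalized model exploits;
* independent Gaussian measurement noise per structure;
* percent values are converted back to raw mm^3 through a simulated
  log-normal intracranial cavity volume.

Focal lesions (hypertrophy or atrophy) are injected multiplicatively into
single structures with ground-truth labels, emulating the apparent cortical
thickening of focal cortical dysplasia.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import StructureVolumeTable

__all__ = [
    "CohortSpec",
    "LesionSpec",
    "generate_controls",
    "inject_lesion",
]


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic healthy cohort.

    Relative scales are fractions of each structure's mean normalized
    volume: ``global_scale_sd`` is the between-subject sd of the shared
    proportional scaling factor, ``factor_sd`` that of the extra latent
    factors, ``noise_sd`` the per-structure measurement noise.
    """

    n_subjects: int
    n_structures: int = 132
    age_range: tuple[float, float] = (0.75, 94.0)
    n_factors: int = 3
    global_scale_sd: float = 0.10
    factor_sd: float = 0.03
    noise_sd: float = 0.015
    icv_mean: float = 1.45e6  # mm^3
    icv_log_sd: float = 0.09
    female_fraction: float = 0.47
    seed: int = 0
    atlas_seed: int | None = None  # fixes structure-level params across draws

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_structures < 1:
            raise ValueError("cohort must have >= 1 subject and structure")
        if self.noise_sd < 0 or self.factor_sd < 0 or self.global_scale_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if not 0 < self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing and positive")


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    """A focal lesion: one structure scaled by a multiplicative factor."""

    structure: str
    factor: float  # e.g. 1.3 hypertrophy, 0.7 atrophy

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("lesion factor must be > 0")

    @property
    def truth_label(self) -> str:
        if self.factor > 1:
            return "increased"
        if self.factor < 1:
            return "decreased"
        return "normal"


def _structure_params(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-structure trajectory and loading parameters, derived from the
    atlas seed so a given spec always describes the same virtual atlas.

    ``atlas_seed`` defaults to ``seed``; fixing it while varying ``seed``
    draws independent cohorts from the same virtual population.
    """
    atlas = spec.seed if spec.atlas_seed is None else spec.atlas_seed
    rng = np.random.default_rng(np.random.SeedSequence([atlas, 2201]))
    s = spec.n_structures
    # mean normalized volumes: log-uniform 0.05..2.5 percent of ICV, so 132
    # structures total roughly 80% of the cavity as in real segmentations
    mean_pct = np.exp(rng.uniform(np.log(0.05), np.log(2.5), size=s))
    # mild mostly-declining quadratic age trajectories
    b1 = rng.uniform(-0.15, 0.02, size=s)
    b2 = rng.uniform(-0.10, 0.02, size=s)
    loadings = rng.normal(0.0, spec.factor_sd, size=(s, spec.n_factors))
    loadings[:, 0] = spec.global_scale_sd  # shared proportional scaling
    return {"mean_pct": mean_pct, "b1": b1, "b2": b2, "loadings": loadings}


def trajectory_pct(spec: CohortSpec, ages: np.ndarray) -> np.ndarray:
    """Noise-free mean percent volumes at the given ages (n_ages x S)."""
    p = _structure_params(spec)
    lo, hi = spec.age_range
    u = (np.asarray(ages, float)[:, None] - 40.0) / 54.0
    return p["mean_pct"] * (1.0 + p["b1"] * u + p["b2"] * u**2)


def generate_controls(spec: CohortSpec) -> StructureVolumeTable:
    """Draw a healthy cohort; deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    n, s = spec.n_subjects, spec.n_structures
    p = _structure_params(spec)
    ages = rng.uniform(*spec.age_range, size=n)
    scores = rng.normal(size=(n, spec.n_factors))
    rel_noise = rng.normal(0.0, spec.noise_sd, size=(n, s))
    base = trajectory_pct(spec, ages)
    pct = base * (1.0 + scores @ p["loadings"].T + rel_noise)
    if np.any(pct <= 0):
        raise ValueError(
            "spec parameters produced non-positive normalized volumes; "
            "reduce factor/noise scales"
        )
    icv = spec.icv_mean * np.exp(
        rng.normal(0.0, spec.icv_log_sd, size=n) - spec.icv_log_sd**2 / 2
    )
    volumes = pct / 100.0 * icv[:, None]
    sex = np.where(rng.uniform(size=n) < spec.female_fraction, "F", "M")
    width = len(str(n))
    return StructureVolumeTable(
        subject_id=np.array([f"S{i:0{width}d}" for i in range(n)]),
        age=ages,
        sex=sex,
        icv=icv,
        volumes=volumes,
        structure_names=tuple(f"structure_{j:03d}" for j in range(s)),
    )


def inject_lesion(
    table: StructureVolumeTable, subject_id: str, lesion: LesionSpec
) -> tuple[StructureVolumeTable, dict]:
    """Multiply one subject's target structure volume by the lesion factor.

    Everything else (other structures, ICV, metadata) is unchanged; returns
    the modified table and a ground-truth record.
    """
    if lesion.structure not in table.structure_names:
        raise KeyError(f"unknown structure {lesion.structure!r}")
    rows = np.flatnonzero(table.subject_id == subject_id)
    if rows.size != 1:
        raise KeyError(f"unknown subject {subject_id!r}")
    i = int(rows[0])
    j = table.structure_names.index(lesion.structure)
    volumes = table.volumes.copy()
    volumes[i, j] *= lesion.factor
    lesioned = dataclasses.replace(table, volumes=volumes)
    truth = {
        "subject_id": subject_id,
        "structure": lesion.structure,
        "factor": lesion.factor,
        "label": lesion.truth_label,
    }
    return lesioned, truth
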