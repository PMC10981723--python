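"""Reading, validating and normalizing morphometry cohort tables.

A cohort table is a per-subject CSV of quantitative brain morphometry as
produced by whole-brain segmentation pipelines (e.g. AssemblyNet): one row
per subject with an identifier, age in years, sex, intracranial cavity
volume (ICV, mm^3), and one column of raw volume (mm^3) per labeled brain
structure.  All modeling downstream happens on volumes normalized to
percent of ICV, which removes head-size differences between subjects.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureVolumeTable",
    "SchemaError",
    "CohortValidationError",
    "DEFAULT_SCHEMA",
    "load_cohort",
    "write_cohort",
    "normalize_by_icv",
]

#: default CSV column names for the non-structure metadata columns
DEFAULT_SCHEMA: Mapping[str, str] = {
    "subject_id": "subject_id",
    "age": "age",
    "sex": "sex",
    "icv": "icv_mm3",
}

_VALID_SEX = frozenset({"F", "M", "unknown"})


class SchemaError(ValueError):
    """A required column cannot be resolved in the input file."""


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class StructureVolumeTable:
    """Validated per-subject morphometry cohort.

    Attributes
    ----------
    subject_id : array of str, unique within the table.
    age : array of float, years, non-negative.
    sex : array of str in {"F", "M", "unknown"}; metadata only, never used
        by the personalized model.
    icv : array of float, mm^3, strictly positive.
    volumes : (n_subjects, n_structures) float array of raw volumes, mm^3.
    structure_names : ordered structure labels shared by all rows.
    """

    subject_id: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    icv: np.ndarray
    volumes: np.ndarray
    structure_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.subject_id)
        if len(set(self.subject_id)) != n:
            raise CohortValidationError("subject_id values must be unique")
        if self.volumes.shape != (n, len(self.structure_names)):
            raise CohortValidationError(
                f"volumes shape {self.volumes.shape} does not match "
                f"{n} subjects x {len(self.structure_names)} structures"
            )
        if not np.all(np.isfinite(self.age)) or np.any(self.age < 0):
            raise CohortValidationError("ages must be finite and >= 0")
        bad_icv = ~np.isfinite(self.icv) | (self.icv <= 0)
        if np.any(bad_icv):
            idx = int(np.flatnonzero(bad_icv)[0])
            raise CohortValidationError(
                f"icv must be finite and > 0 (row {idx}, "
                f"subject {self.subject_id[idx]!r})"
            )
        bad_vol = ~np.isfinite(self.volumes) | (self.volumes < 0)
        if np.any(bad_vol):
            i, j = map(int, np.argwhere(bad_vol)[0])
            raise CohortValidationError(
                f"volumes must be finite and >= 0 (row {i}, subject "
                f"{self.subject_id[i]!r}, column {self.structure_names[j]!r})"
            )
        unknown_sex = set(self.sex) - _VALID_SEX
        if unknown_sex:
            raise CohortValidationError(f"invalid sex values: {sorted(unknown_sex)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def n_structures(self) -> int:
        return len(self.structure_names)

    def to_frame(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Round-trippable DataFrame with metadata then structure columns."""
        schema = dict(DEFAULT_SCHEMA if schema is None else schema)
        df = pd.DataFrame(
            {
                schema["subject_id"]: self.subject_id,
                schema["age"]: self.age,
                schema["sex"]: self.sex,
                schema["icv"]: self.icv,
            }
        )
        vol = pd.DataFrame(self.volumes, columns=list(self.structure_names))
        return pd.concat([df, vol], axis=1)


def _table_from_frame(df: pd.DataFrame, schema: Mapping[str, str]) -> StructureVolumeTable:
    schema = {**DEFAULT_SCHEMA, **dict(schema)}
    for key in ("subject_id", "age", "sex", "icv"):
        if schema[key] not in df.columns:
            raise SchemaError(
                f"required column {schema[key]!r} (role {key!r}) not found; "
                f"available columns: {list(df.columns)}"
            )
    meta_cols = {schema[k] for k in ("subject_id", "age", "sex", "icv")}
    structure_names = tuple(c for c in df.columns if c not in meta_cols)
    volumes = np.empty((len(df), len(structure_names)), dtype=float)
    for j, name in enumerate(structure_names):
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise CohortValidationError(
                f"non-numeric volume in column {name!r}, row {int(bad[0])}"
            )
        volumes[:, j] = col
    sex = df[schema["sex"]].astype(str).str.strip().to_numpy()
    sex = np.where(np.isin(sex, list(_VALID_SEX)), sex, "unknown")
    return StructureVolumeTable(
        subject_id=df[schema["subject_id"]].astype(str).to_numpy(),
        age=pd.to_numeric(df[schema["age"]]).to_numpy(dtype=float),
        sex=sex,
        icv=pd.to_numeric(df[schema["icv"]], errors="coerce").to_numpy(dtype=float),
        volumes=volumes,
        structure_names=structure_names,
    )


def load_cohort(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> StructureVolumeTable:
    """Read a cohort CSV into a validated :class:`StructureVolumeTable`.

    Every column not mapped to subject_id/age/sex/icv by ``schema`` is
    treated as a structure volume column, in file order.
    """
    df = pd.read_csv(path, dtype={0: str}, keep_default_na=False, na_values=[""])
    return _table_from_frame(df, schema or DEFAULT_SCHEMA)


def write_cohort(
    table: StructureVolumeTable,
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> None:
    """Write a cohort table back to CSV (inverse of :func:`load_cohort`)."""
    table.to_frame(schema).to_csv(path, index=False)


def normalize_by_icv(
    table: StructureVolumeTable, denominator: str = "icv"
) -> pd.DataFrame:
    """Express structure volumes as percent of head size.

    Parameters
    ----------
    table : validated cohort.
    denominator : ``"icv"`` divides by the intracranial cavity volume
        (the default reference normalization); ``"sum_of_structures"``
        divides by the per-subject total of all segmented structures.

    Returns
    -------
    DataFrame of percent values in [0, 100], indexed by subject_id, one
    column per structure.
    """
    if denominator == "icv":
        denom = table.icv
    elif denominator == "sum_of_structures":
        denom = table.volumes.sum(axis=1)
        if np.any(denom <= 0):
            raise CohortValidationError("sum of structure volumes must be > 0")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    values = 100.0 * table.volumes / denom[:, None]
    if np.any(values > 100.0 + 1e-9):
        raise CohortValidationError("normalized values exceed 100% of denominator")
    return pd.DataFrame(
        values,
        index=pd.Index(table.subject_id, name="subject_id"),
        columns=list(table.structure_names),
    )
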