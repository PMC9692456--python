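"""Cohort table container, validation, and CSV round-tripping.

The analysis operates on a two-group cohort of older adults: a physically
frail & sarcopenic group (``PFS``) and a control group (``CONTROL``), each
subject carrying demographic/functional covariates and a panel of 10 serum
marker concentrations (inflammatory, matrix-remodeling, mitochondrial and
senescence-related mediators).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical marker panel, in assay-panel order.
MARKER_NAMES = (
    "IL1β",
    "IL6",
    "TNFα",
    "ActivinA",
    "SerpinE1",
    "ICAM1",
    "TIMP1",
    "GDF15",
    "FGF21",
    "GFAP",
)

#: ASCII and common-variant aliases accepted on input, mapped to canonical names.
MARKER_ALIASES = {
    "IL1b": "IL1β",
    "IL1B": "IL1β",
    "IL-1b": "IL1β",
    "IL1beta": "IL1β",
    "IL-6": "IL6",
    "TNFa": "TNFα",
    "TNF-a": "TNFα",
    "TNFalpha": "TNFα",
    "Activin A": "ActivinA",
    "Serpin E1": "SerpinE1",
    "ICAM-1": "ICAM1",
    "TIMP-1": "TIMP1",
}

GROUP_LEVELS = ("PFS", "CONTROL")
SEX_LEVELS = ("F", "M")

COVARIATE_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "bmi",
    "sppb",
    "alm",
    "alm_bmi",
    "n_diseases",
    "n_medications",
)

_FLOAT_COVARIATES = ("age", "bmi", "alm", "alm_bmi")
_INT_COVARIATES = ("sppb", "n_diseases", "n_medications")


def canonical_marker_name(name: str) -> str:
    """Map a marker column header to its canonical panel name."""
    name = name.strip()
    return MARKER_ALIASES.get(name, name)


@dataclass
class ValidationReport:
    """Record of what ``read_cohort`` kept, dropped, and warned about."""

    n_rows_read: int = 0
    n_rows_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class CohortTable:
    """Complete-case cohort: per-subject covariates plus a marker matrix.

    ``markers`` is an ``(n_subjects, n_markers)`` float array aligned with
    ``marker_names``; concentrations are strictly positive in whatever unit
    each assay reports (units are opaque metadata here).
    """

    subject_id: np.ndarray  # str array
    group: np.ndarray  # str array, levels in GROUP_LEVELS
    age: np.ndarray
    sex: np.ndarray  # str array, levels in SEX_LEVELS
    bmi: np.ndarray
    sppb: np.ndarray  # int, 0..12
    alm: np.ndarray
    alm_bmi: np.ndarray
    n_diseases: np.ndarray
    n_medications: np.ndarray
    markers: np.ndarray
    marker_names: tuple[str, ...] = MARKER_NAMES

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUP_LEVELS:
            raise ValueError(f"unknown group label {group!r}; expected one of {GROUP_LEVELS}")
        return self.group == group

    def group_markers(self, group: str) -> np.ndarray:
        """Marker matrix restricted to one group's subjects."""
        return self.markers[self.group_mask(group)]

    def class_sizes(self) -> dict[str, int]:
        return {g: int(np.sum(self.group == g)) for g in GROUP_LEVELS}

    def marker_index(self, name: str) -> int:
        name = canonical_marker_name(name)
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def validate(self) -> None:
        """Raise ``ValueError`` on any structural invariant violation."""
        n = self.n_subjects
        if len(set(self.subject_id.tolist())) != n:
            raise ValueError("subject_id values must be unique")
        bad_groups = set(self.group.tolist()) - set(GROUP_LEVELS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}")
        bad_sex = set(self.sex.tolist()) - set(SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"unknown sex levels {sorted(bad_sex)}")
        if self.markers.shape != (n, len(self.marker_names)):
            raise ValueError(
                f"marker matrix shape {self.markers.shape} does not match "
                f"{n} subjects x {len(self.marker_names)} markers"
            )
        if len(self.marker_names) == 0:
            raise ValueError("marker panel is empty")
        if not np.all(np.isfinite(self.markers)):
            raise ValueError("marker matrix contains non-finite values")
        if np.any(self.markers <= 0):
            raise ValueError("marker concentrations must be strictly positive")
        if np.any((self.sppb < 0) | (self.sppb > 12)):
            raise ValueError("sppb outside 0..12")
        for col in ("age", "bmi", "alm"):
            if np.any(getattr(self, col) <= 0):
                raise ValueError(f"{col} must be > 0")
        if np.any(self.n_diseases < 0) or np.any(self.n_medications < 0):
            raise ValueError("counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "age": self.age,
                "sex": self.sex,
                "bmi": self.bmi,
                "sppb": self.sppb,
                "alm": self.alm,
                "alm_bmi": self.alm_bmi,
                "n_diseases": self.n_diseases,
                "n_medications": self.n_medications,
            }
        )
        for j, name in enumerate(self.marker_names):
            df[name] = self.markers[:, j]
        return df

    def subset_markers(self, names: list[str] | list[int]) -> "CohortTable":
        """New table restricted to the given marker columns (names or indices)."""
        idx = [n if isinstance(n, (int, np.integer)) else self.marker_index(n) for n in names]
        return CohortTable(
            subject_id=self.subject_id,
            group=self.group,
            age=self.age,
            sex=self.sex,
            bmi=self.bmi,
            sppb=self.sppb,
            alm=self.alm,
            alm_bmi=self.alm_bmi,
            n_diseases=self.n_diseases,
            n_medications=self.n_medications,
            markers=self.markers[:, idx],
            marker_names=tuple(self.marker_names[i] for i in idx),
        )

    def equals(self, other: "CohortTable", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if self.marker_names != other.marker_names or self.n_subjects != other.n_subjects:
            return False
        str_ok = all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in ("subject_id", "group", "sex")
        )
        num_ok = all(
            np.allclose(getattr(self, c), getattr(other, c), rtol=rtol, atol=atol)
            for c in ("age", "bmi", "alm", "alm_bmi")
        ) and all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in ("sppb", "n_diseases", "n_medications")
        )
        return str_ok and num_ok and np.allclose(self.markers, other.markers, rtol=rtol, atol=atol)


def _parse_row(row: pd.Series, marker_cols: list[str]) -> str | None:
    """Return a drop reason for an invalid/incomplete row, or None if clean."""
    for col in COVARIATE_COLUMNS + tuple(marker_cols):
        v = row[col]
        if v is None or (isinstance(v, float) and np.isnan(v)) or (isinstance(v, str) and v.strip() == ""):
            return f"missing {col}"
    for col in _FLOAT_COVARIATES + tuple(marker_cols):
        try:
            float(row[col])
        except (TypeError, ValueError):
            return f"non-numeric {col}"
    for col in _INT_COVARIATES:
        try:
            int(float(row[col]))
        except (TypeError, ValueError):
            return f"non-numeric {col}"
    if str(row["group"]) not in GROUP_LEVELS:
        return f"invalid group {row['group']!r}"
    if str(row["sex"]) not in SEX_LEVELS:
        return f"invalid sex {row['sex']!r}"
    sppb = int(float(row["sppb"]))
    if not 0 <= sppb <= 12:
        return f"sppb out of range ({sppb})"
    for col in ("age", "bmi", "alm"):
        if float(row[col]) <= 0:
            return f"non-positive {col}"
    for col in marker_cols:
        if float(row[col]) <= 0:
            return f"non-positive {col}"
    for col in ("n_diseases", "n_medications"):
        if int(float(row[col])) < 0:
            return f"negative {col}"
    return None


def read_cohort(
    path, marker_names: tuple[str, ...] = MARKER_NAMES
) -> tuple[CohortTable, ValidationReport]:
    """Read a cohort CSV, dropping (and logging) incomplete or invalid rows.

    The file must be comma-separated UTF-8 with a header row containing every
    covariate column and one column per marker (ASCII aliases accepted).
    A missing *column* is a hard error; a missing *value* drops that row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"empty cohort file: {path}")
    df = df.rename(columns={c: canonical_marker_name(c) for c in df.columns})
    marker_names = tuple(canonical_marker_name(m) for m in marker_names)
    required = list(COVARIATE_COLUMNS) + list(marker_names)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    report = ValidationReport(n_rows_read=len(df))
    keep_rows = []
    for _, row in df.iterrows():
        reason = _parse_row(row, list(marker_names))
        if reason is None:
            keep_rows.append(row)
        else:
            report.dropped.append((str(row.get("subject_id", "?")), reason))
    report.n_rows_kept = len(keep_rows)
    if not keep_rows:
        raise ValueError("no valid rows after validation")
    kept = pd.DataFrame(keep_rows)

    table = CohortTable(
        subject_id=kept["subject_id"].to_numpy(dtype=str),
        group=kept["group"].to_numpy(dtype=str),
        age=kept["age"].to_numpy(dtype=float),
        sex=kept["sex"].to_numpy(dtype=str),
        bmi=kept["bmi"].to_numpy(dtype=float),
        sppb=kept["sppb"].to_numpy(dtype=float).astype(int),
        alm=kept["alm"].to_numpy(dtype=float),
        alm_bmi=kept["alm_bmi"].to_numpy(dtype=float),
        n_diseases=kept["n_diseases"].to_numpy(dtype=float).astype(int),
        n_medications=kept["n_medications"].to_numpy(dtype=float).astype(int),
        markers=kept[list(marker_names)].to_numpy(dtype=float),
        marker_names=marker_names,
    )
    table.validate()
    return table, report


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table as CSV; floats use repr precision so the file
    round-trips bit-for-bit through :func:`read_cohort`."""
    table.validate()
    df = table.to_dataframe()
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False, float_format="%.17g")
    elif isinstance(path, io.TextIOBase):
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise TypeError(f"unsupported path type {type(path)!r}")
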