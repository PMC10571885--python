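"""Cohort data model, delimited-text I/O, derived biomarkers, sequences.

The central container is :class:`SurvivalDataset`: a subjects-by-features
covariate matrix ``X`` (NaN marks missing), a follow-up time vector ``T``
in integer years, and a per-task event indicator matrix ``E`` (one column
per cancer site or other event of interest). Recurrent models consume a
:class:`SequenceBatch`, the dataset unrolled into fixed-length per-subject
sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

MISSING_TOKENS = ["", "NA", "NaN", "nan"]


class SchemaError(ValueError):
    """A mandatory column is absent or the schema is malformed."""


class ParseError(ValueError):
    """A cell could not be parsed for its declared role."""


class LeftCensoredError(ValueError):
    """Terminal year precedes enrolment year."""


class MissingDataError(ValueError):
    """Operation requires complete data but missing values are present."""


@dataclass
class SurvivalDataset:
    """Right-censored cohort: covariates, follow-up times, event indicators.

    Attributes
    ----------
    subject_ids : ndarray of object
        Opaque per-subject identifiers.
    X : ndarray, shape (n, d)
        Covariates; ``NaN`` encodes a missing cell.
    feature_names : list of str
        Unique, ordered labels for the columns of ``X``.
    T : ndarray, shape (n,)
        Non-negative follow-up / event time in years.
    E : ndarray, shape (n, K)
        0/1 event indicator, one column per task.
    task_names : list of str
        Ordered event labels, one per column of ``E``.
    """

    subject_ids: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    T: np.ndarray
    E: np.ndarray
    task_names: list[str]

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.T = np.asarray(self.T, dtype=np.float64)
        self.E = np.atleast_2d(np.asarray(self.E))
        if self.E.shape[0] == 1 and self.X.shape[0] > 1:
            self.E = self.E.T
        self.feature_names = list(self.feature_names)
        self.task_names = list(self.task_names)
        n = self.X.shape[0]
        if not (len(self.subject_ids) == len(self.T) == self.E.shape[0] == n):
            raise ValueError("subject_ids, X, T, E must share the same number of rows")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal the number of columns of X")
        if len(self.task_names) != self.E.shape[1]:
            raise ValueError("task_names length must equal the number of columns of E")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        vals = np.unique(self.E[~np.isnan(self.E.astype(float))])
        if not np.all(np.isin(vals, [0, 1])):
            raise ParseError(f"event indicators must be 0/1, found {vals}")
        self.E = self.E.astype(np.int8)

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return self.E.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.X).any())

    def task_index(self, task: str) -> int:
        try:
            return self.task_names.index(task)
        except ValueError:
            raise KeyError(f"unknown task {task!r}; known: {self.task_names}") from None

    def events_for(self, task: str) -> np.ndarray:
        return self.E[:, self.task_index(task)]

    def subset(self, rows) -> "SurvivalDataset":
        rows = np.asarray(rows)
        return replace(self, subject_ids=self.subject_ids[rows], X=self.X[rows],
                       T=self.T[rows], E=self.E[rows])

    def select_features(self, names: list[str]) -> "SurvivalDataset":
        idx = [self.feature_names.index(f) for f in names]
        return replace(self, X=self.X[:, idx], feature_names=list(names))

    def copy(self) -> "SurvivalDataset":
        return replace(self, subject_ids=self.subject_ids.copy(), X=self.X.copy(),
                       T=self.T.copy(), E=self.E.copy())

    def to_frame(self, id_col: str = "id", time_col: str = "time") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, id_col, self.subject_ids)
        df[time_col] = self.T
        for k, t in enumerate(self.task_names):
            df[f"event_{t}"] = self.E[:, k]
        return df


@dataclass
class SequenceBatch:
    """A dataset unrolled to (n subjects, n_steps, d features) sequences."""

    data: np.ndarray
    n_steps: int
    mask: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("sequence data must be 3-dimensional (n, n_steps, d)")
        if self.n_steps < 1 or self.data.shape[1] != self.n_steps:
            raise ValueError("n_steps must be >= 1 and match the second axis")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def d(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# Schema-driven delimited-text I/O
# ---------------------------------------------------------------------------

def _load_schema(schema) -> dict:
    if isinstance(schema, (str,)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError("schema must be a mapping or a path to a YAML mapping")
    for key in ("covariates", "events", "time"):
        if key not in schema:
            raise SchemaError(f"schema is missing mandatory key {key!r}")
    return schema


def load_cohort(path, schema) -> SurvivalDataset:
    """Read a delimited cohort table into a :class:`SurvivalDataset`.

    ``schema`` maps column names to roles::

        {"id": "pid", "time": "time", "covariates": ["AGE", "SBP", ...],
         "events": {"thyroid": "event_thyroid", ...}}

    ``events`` may also be a plain list of column names, in which case the
    task names equal the column names. Unmapped columns are ignored with a
    logged warning; empty cells and ``NA`` become missing values.
    """
    schema = _load_schema(schema)
    df = pd.read_csv(path, na_values=MISSING_TOKENS, keep_default_na=False)

    events = schema["events"]
    if isinstance(events, list):
        events = {c: c for c in events}
    covariates = list(schema["covariates"])
    time_col = schema["time"]
    id_col = schema.get("id")

    mandatory = covariates + list(events.values()) + [time_col]
    absent = [c for c in mandatory if c not in df.columns]
    if absent:
        raise SchemaError(f"mandatory columns missing from {path}: {absent}")

    mapped = set(mandatory) | ({id_col} if id_col else set())
    unmapped = [c for c in df.columns if c not in mapped]
    if unmapped:
        log.warning("ignoring unmapped columns: %s", unmapped)

    X = np.empty((len(df), len(covariates)))
    for j, col in enumerate(covariates):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric covariate value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}")
        X[:, j] = parsed.to_numpy(dtype=np.float64)

    T = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=np.float64)
    if np.isnan(T).any() or (T < 0).any():
        raise ParseError(f"time column {time_col!r} must be non-negative and complete")

    E = np.empty((len(df), len(events)))
    for k, (task, col) in enumerate(events.items()):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        if np.isnan(vals).any() or not np.all(np.isin(vals, [0.0, 1.0])):
            offending = df[col][~pd.Series(vals).isin([0.0, 1.0])].iloc[0]
            raise ParseError(
                f"event column {col!r} must contain only 0/1, found {offending!r}")
        E[:, k] = vals

    ids = (df[id_col].to_numpy() if id_col
           else np.arange(len(df)).astype(str))
    return SurvivalDataset(ids, X, covariates, T, E, list(events.keys()))


def write_cohort(ds: SurvivalDataset, path, id_col: str = "id",
                 time_col: str = "time") -> None:
    """Write a dataset as CSV, round-trippable by :func:`load_cohort`."""
    ds.to_frame(id_col=id_col, time_col=time_col).to_csv(path, index=False, na_rep="")


def default_schema(ds: SurvivalDataset, id_col: str = "id",
                   time_col: str = "time") -> dict:
    """Schema under which :func:`write_cohort` output reloads identically."""
    return {"id": id_col, "time": time_col, "covariates": list(ds.feature_names),
            "events": {t: f"event_{t}" for t in ds.task_names}}


# ---------------------------------------------------------------------------
# Derived biomarkers
# ---------------------------------------------------------------------------

#: Derived feature -> required source columns.
DERIVED_SOURCES = {
    "BMI": ("WT", "HT"),
    "PP": ("SBP", "DBP"),
    "AGR": ("ALB", "GLOBULIN"),
    "CCR": ("AGE", "WT", "CREAT", "SEX"),
}


def derive_features(ds: SurvivalDataset, which=("BMI", "PP", "AGR", "CCR"),
                    report: dict | None = None) -> SurvivalDataset:
    """Append standard clinical derived biomarkers.

    BMI = WT / (HT/100)^2 with height in cm; PP = SBP - DBP;
    AGR = ALB / GLOBULIN; CCR (Cockcroft-Gault creatinine clearance)
    = (140 - AGE) * WT / (CREAT * 72), times 0.85 for women (SEX coded
    1 = male, 2 = female). Derived features whose sources are absent are
    skipped with a warning; rows with non-positive denominators get a
    missing derived value, counted in ``report``.
    """
    if report is None:
        report = {}
    cols = {f: ds.X[:, i] for i, f in enumerate(ds.feature_names)}
    new_cols, new_names = [], []

    for name in which:
        if name in ds.feature_names:
            continue
        sources = DERIVED_SOURCES[name]
        if any(s not in cols for s in sources):
            warnings.warn(f"cannot derive {name}: missing source columns "
                          f"{[s for s in sources if s not in cols]}")
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            if name == "BMI":
                denom_ok = cols["HT"] > 0
                vals = np.where(denom_ok, cols["WT"] / (cols["HT"] / 100.0) ** 2, np.nan)
            elif name == "PP":
                denom_ok = np.ones(ds.n, dtype=bool)
                vals = cols["SBP"] - cols["DBP"]
            elif name == "AGR":
                denom_ok = cols["GLOBULIN"] > 0
                vals = np.where(denom_ok, cols["ALB"] / cols["GLOBULIN"], np.nan)
            elif name == "CCR":
                denom_ok = cols["CREAT"] > 0
                vals = np.where(
                    denom_ok,
                    (140.0 - cols["AGE"]) * cols["WT"] / (cols["CREAT"] * 72.0), np.nan)
                vals = np.where(cols["SEX"] == 2, vals * 0.85, vals)
        report[name] = int(np.sum(~denom_ok))
        new_cols.append(vals)
        new_names.append(name)

    if not new_cols:
        return ds.copy()
    X = np.column_stack([ds.X] + new_cols)
    return replace(ds, X=X, feature_names=ds.feature_names + new_names)


def make_time_variable(enrol_year: int, terminal_year: int) -> int:
    """Follow-up time in whole years: terminal (diagnosis or exit) minus enrolment.

    Raises :class:`LeftCensoredError` when the terminal year precedes
    enrolment; such rows are exclusion candidates.
    """
    if terminal_year < enrol_year:
        raise LeftCensoredError(
            f"terminal year {terminal_year} precedes enrolment year {enrol_year}")
    return int(terminal_year) - int(enrol_year)


def to_sequences(ds: SurvivalDataset, n_steps: int) -> SequenceBatch:
    """Unroll the single-visit covariate vector into an n-step sequence.

    With one examination visit per subject, the visit vector is replicated
    across all steps (one visit = one subsequence of the full sequence);
    the mask marks every step valid. Requires complete data — impute first.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if ds.has_missing():
        raise MissingDataError("dataset contains missing values; impute before "
                               "building sequences")
    data = np.repeat(ds.X[:, None, :], n_steps, axis=1)
    return SequenceBatch(data, n_steps, feature_names=list(ds.feature_names))
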