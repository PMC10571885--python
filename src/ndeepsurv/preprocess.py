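"""Cohort filtering and imputation with an auditable exclusion report.

Pipeline order is fixed: drop left-censored rows, remove 6-SD outlier
rows, drop high-missingness features, impute the rest. The SD filter is
applied once (not iteratively) on the full input to this stage, matching
a filter-before-split pipeline; imputation statistics, by contrast, are
fit on training rows only to keep the evaluation leakage-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset

log = logging.getLogger(__name__)


@dataclass
class ExclusionReport:
    """Audit trail for one filtering step: who was removed and why."""

    step: str
    n_in: int
    n_out: int
    removed_ids: list = field(default_factory=list)
    reasons: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_in if self.n_in else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.removed_ids,
                             "reason": [self.reasons.get(i, self.step)
                                        for i in self.removed_ids]})


def drop_left_censored(ds: SurvivalDataset):
    """Remove rows whose event predates enrolment (negative follow-up time)."""
    keep = ds.T >= 0
    report = ExclusionReport("left_censored", ds.n, int(keep.sum()),
                             removed_ids=list(ds.subject_ids[~keep]))
    if report.n_out == 0:
        warnings.warn("all rows removed as left-censored")
    return ds.subset(keep), report


def filter_outliers(ds: SurvivalDataset, k: float = 6.0):
    """Remove rows with any feature more than ``k`` SDs from its mean.

    Means and SDs are computed per feature over non-missing values of the
    data given to this step. Constant features (zero SD) are skipped.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mean = np.nanmean(ds.X, axis=0)
    sd = np.nanstd(ds.X, axis=0, ddof=0)
    usable = sd > 0
    if not usable.all():
        log.info("zero-SD features skipped by outlier filter: %s",
                 [f for f, u in zip(ds.feature_names, usable) if not u])
    with np.errstate(invalid="ignore"):
        viol = np.abs(ds.X - mean) > k * sd
    viol &= usable  # broadcast over rows
    viol &= ~np.isnan(ds.X)
    keep = ~viol.any(axis=1)
    per_feature = {f: int(c) for f, c in zip(ds.feature_names, viol.sum(axis=0)) if c}
    report = ExclusionReport("outlier_6sd", ds.n, int(keep.sum()),
                             removed_ids=list(ds.subject_ids[~keep]),
                             reasons={i: "outlier" for i in ds.subject_ids[~keep]})
    report.reasons["per_feature"] = per_feature
    return ds.subset(keep), report


def filter_features_by_missingness(ds: SurvivalDataset, max_missing: float = 0.25):
    """Keep features with missing fraction strictly below ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    rates = np.isnan(ds.X).mean(axis=0)
    keep = rates < max_missing
    dropped = {f: float(r) for f, r, k in zip(ds.feature_names, rates, keep) if not k}
    if not keep.any():
        raise ValueError("every feature exceeds the missingness threshold; "
                         "nothing left to model")
    out = ds.select_features([f for f, k in zip(ds.feature_names, keep) if k])
    report = ExclusionReport("missingness", ds.d, int(keep.sum()),
                             removed_ids=list(dropped), reasons=dropped)
    return out, report


def impute(ds: SurvivalDataset, strategy: str = "median",
           fit_rows=None) -> SurvivalDataset:
    """Fill missing cells with a per-feature statistic fit on ``fit_rows`` only.

    ``fit_rows`` defaults to all rows; pass the training-split indices to
    keep test rows out of the statistic. ``strategy`` is ``median`` or
    ``mean``.
    """
    if strategy not in ("median", "mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    fit_rows = np.arange(ds.n) if fit_rows is None else np.asarray(fit_rows)
    stat_fn = np.nanmedian if strategy == "median" else np.nanmean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stats = stat_fn(ds.X[fit_rows], axis=0)
    all_missing = np.isnan(stats)
    if all_missing.any():
        bad = [f for f, m in zip(ds.feature_names, all_missing) if m]
        raise ValueError(f"features entirely missing within fit rows: {bad}")
    out = ds.copy()
    mask = np.isnan(out.X)
    out.X[mask] = np.broadcast_to(stats, out.X.shape)[mask]
    return out


def run_pipeline(ds: SurvivalDataset, sd_k: float = 6.0, max_missing: float = 0.25,
                 strategy: str = "median", fit_rows=None):
    """Full preprocessing pass; returns the clean dataset and all reports."""
    ds1, r1 = drop_left_censored(ds)
    ds2, r2 = filter_outliers(ds1, k=sd_k)
    ds3, r3 = filter_features_by_missingness(ds2, max_missing=max_missing)
    ds4 = impute(ds3, strategy=strategy, fit_rows=fit_rows)
    return ds4, [r1, r2, r3]


def write_reports(reports, path) -> None:
    rows = []
    for r in reports:
        for rid in r.removed_ids:
            reason = r.reasons.get(rid, r.step)
            rows.append({"step": r.step, "id": rid, "reason": reason,
                         "n_in": r.n_in, "n_out": r.n_out})
    pd.DataFrame(rows, columns=["step", "id", "reason", "n_in", "n_out"]).to_csv(
        path, index=False)
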