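"""Synthetic censored-cohort generator with known ground truth.

Emulates the structure of a low-event-rate health-examination cohort:
standard-normal (optionally equicorrelated) biomarker covariates with
proportional-hazards effects, constant (exponential) baseline hazards
per task, administrative censoring at a fixed follow-up horizon, and
calendar-year time resolution (observed times are floored to whole
years). Missing cells and gross measurement outliers can be planted at
known positions so the preprocessing filters can be audited exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import SurvivalDataset


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic cohort.

    ``beta`` is the (d, K) matrix of true log-hazard coefficients;
    ``baseline_rate`` the per-task exponential event rate (events per
    person-year for a subject at covariate zero); ``followup_years`` the
    administrative censoring horizon. ``missing_rate`` / ``outlier_rate``
    plant missing cells and 8-SD outlier rows at recorded positions.
    """

    n: int = 2000
    d: int = 10
    beta: np.ndarray | None = None            # (d, K); default zeros, K=1
    baseline_rate: float | np.ndarray = 0.02
    followup_years: float = 10.0
    task_names: list = field(default_factory=lambda: ["event"])
    corr: float = 0.0
    weibull_shape: float | None = None        # None => exponential
    competing_risks: bool = False
    round_to_years: bool = True
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.d < 1:
            raise ValueError("n and d must be >= 1")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        for r in (self.missing_rate, self.outlier_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.beta is None:
            self.beta = np.zeros((self.d, len(self.task_names)))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.shape[0] != self.d:
            if self.beta.shape[1] == self.d:   # accept (K, d) transposed input
                self.beta = self.beta.T
            else:
                raise ValueError("beta must have d rows")
        if self.beta.shape[1] != len(self.task_names):
            raise ValueError("beta must have one column per task")

    @property
    def K(self) -> int:
        return len(self.task_names)


def _draw_times(rng, rate, eta, shape):
    """Event times with hazard rate*exp(eta); Weibull when shape given."""
    u = rng.random(eta.shape)
    scale = rate * np.exp(eta)
    if shape is None:
        return -np.log(u) / scale
    return (-np.log(u) / scale) ** (1.0 / shape)


def simulate_cohort(cfg: SimulationConfig):
    """Generate one cohort; returns ``(dataset, truth)``.

    ``truth`` records everything the generator knows and the models must
    recover: the coefficient matrix, the latent uncensored event times,
    and the planted outlier-row / missing-cell indices.
    """
    rng = np.random.default_rng(cfg.seed)
    X = rng.standard_normal((cfg.n, cfg.d))
    if cfg.corr > 0:
        shared = rng.standard_normal((cfg.n, 1))
        X = np.sqrt(1 - cfg.corr) * X + np.sqrt(cfg.corr) * shared

    rates = np.broadcast_to(np.asarray(cfg.baseline_rate, dtype=float), (cfg.K,))
    eta = X @ cfg.beta                                       # (n, K)
    latent = np.column_stack(
        [_draw_times(rng, rates[k], eta[:, k], cfg.weibull_shape)
         for k in range(cfg.K)])

    horizon = cfg.followup_years
    if cfg.competing_risks and cfg.K > 1:
        first = latent.min(axis=1)
        winner = latent.argmin(axis=1)
        observed = np.minimum(first, horizon)
        E = np.zeros((cfg.n, cfg.K), dtype=np.int8)
        had_event = first < horizon
        E[np.arange(cfg.n)[had_event], winner[had_event]] = 1
    else:
        E = (latent < horizon).astype(np.int8)
        # single follow-up clock: the per-subject observed time is the
        # earliest event (if any) else the horizon
        observed = np.where(E.any(axis=1), np.minimum(latent.min(axis=1), horizon),
                            horizon)
    T = np.floor(observed) if cfg.round_to_years else observed

    rate_emp = E.mean(axis=0)
    if np.all((rate_emp < 1e-4) | (rate_emp > 1 - 1e-4)):
        warnings.warn("degenerate benchmark: event rate ~0 or ~1 for every task")

    feature_names = [f"x{j}" for j in range(cfg.d)]
    ids = np.array([f"s{i:06d}" for i in range(cfg.n)])

    outlier_rows = np.array([], dtype=int)
    if cfg.outlier_rate > 0:
        n_out = int(round(cfg.outlier_rate * cfg.n))
        outlier_rows = rng.choice(cfg.n, size=n_out, replace=False)
        cols = rng.integers(0, cfg.d, size=n_out)
        # 8 SD from the mean: far beyond the 6-SD exclusion boundary
        X[outlier_rows, cols] = 8.0 * np.sign(rng.standard_normal(n_out) + 0.5)

    missing_cells = np.empty((0, 2), dtype=int)
    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n, cfg.d)) < cfg.missing_rate
        if cfg.outlier_rate > 0:
            mask[outlier_rows, cols] = False  # keep planted outliers observable
        missing_cells = np.argwhere(mask)
        X[mask] = np.nan

    ds = SurvivalDataset(ids, X, feature_names, T, E, list(cfg.task_names))
    truth = {"beta": cfg.beta.copy(), "latent_times": latent,
             "outlier_rows": np.sort(outlier_rows),
             "missing_cells": missing_cells, "config": cfg}
    return ds, truth


def calibrate_baseline_rate(target_event_rate: float, beta=None,
                            followup_years: float = 10.0, n_mc: int = 50_000,
                            seed: int = 0, tol: float = 1e-3,
                            d: int | None = None) -> float:
    """Baseline rate whose simulated event fraction hits the target.

    Monte-Carlo bisection with common random numbers, so the simulated
    event fraction is monotone in the rate and the bracket always
    closes. With ``beta`` zero (or None) the answer has the closed form
    ``-log(1 - target) / followup_years``.
    """
    if not 0 < target_event_rate < 1:
        raise ValueError("target event rate must lie strictly in (0, 1)")
    if beta is None or not np.any(np.asarray(beta)):
        return float(-np.log1p(-target_event_rate) / followup_years)
    beta = np.asarray(beta, dtype=float).reshape(-1)
    d = d or len(beta)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_mc, d))
    u = rng.random(n_mc)
    eta = X @ beta

    def frac(rate: float) -> float:
        times = -np.log(u) / (rate * np.exp(eta))
        return float(np.mean(times < followup_years))

    lo, hi = 1e-10, 1.0
    for _ in range(200):
        if frac(hi) >= target_event_rate:
            break
        hi *= 4.0
    else:
        raise RuntimeError("could not bracket the target event rate")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if abs(frac(mid) - target_event_rate) < tol:
            return float(mid)
        if frac(mid) < target_event_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
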