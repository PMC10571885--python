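"""Harrell's concordance index and run aggregation."""

from __future__ import annotations

import numpy as np


class ConcordanceUndefinedError(ValueError):
    """No acceptable pairs: the c-index does not exist for this sample."""


def concordance_index(r, T, E) -> float:
    """Harrell's c-index of risk scores ``r`` against censored outcomes.

    Over acceptable pairs (i, j) — ``E_i = 1`` and ``T_i < T_j`` — counts
    the pair concordant when ``r_i > r_j`` and half-concordant when
    ``r_i == r_j``; pairs tied on time are not compared. 0.5 is chance
    level, 1.0 perfect ranking.

    Raises :class:`ConcordanceUndefinedError` when no acceptable pair
    exists (e.g. all-censored data).
    """
    r = np.asarray(r, dtype=float).reshape(-1)
    T = np.asarray(T, dtype=float).reshape(-1)
    E = np.asarray(E, dtype=int).reshape(-1)
    if not (len(r) == len(T) == len(E)):
        raise ValueError("r, T, E must have equal length")
    acc = (E[:, None] == 1) & (T[:, None] < T[None, :])
    n_acc = int(acc.sum())
    if n_acc == 0:
        raise ConcordanceUndefinedError("no acceptable pairs in this sample")
    diff = r[:, None] - r[None, :]
    concordant = int((acc & (diff > 0)).sum())
    tied = int((acc & (diff == 0)).sum())
    return (concordant + 0.5 * tied) / n_acc


def mean_cindex(runs) -> tuple[float, float]:
    """Mean and sample SD of repeated c-index evaluations.

    A single run has no sample SD; 0.0 is returned for it.
    """
    runs = np.asarray(list(runs), dtype=float)
    if runs.size == 0:
        raise ValueError("no runs to aggregate")
    mean = float(runs.mean())
    sd = float(runs.std(ddof=1)) if runs.size > 1 else 0.0
    return mean, sd
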