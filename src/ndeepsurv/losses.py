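"""Composite survival training loss: Cox partial likelihood + ranking loss.

The networks are trained by minimising ``L1 + lambda * L2`` where

* ``L1`` is the negative log Breslow partial likelihood of the predicted
  risk scores ``r`` — shift-invariant in ``r``, defined only when at
  least one event is present, with risk sets ``R(t) = {j : T_j >= t}``;
* ``L2`` is an exponential ranking loss ``sum exp(-(r_i - r_j)/sigma)``
  over *acceptable pairs* — ordered pairs ``(i, j)`` where subject ``i``
  had an observed event strictly before subject ``j``'s observed time —
  pushing earlier-event subjects towards higher predicted risk.

All functions accept either an :class:`~ndeepsurv.autodiff.Tensor` (the
loss stays differentiable) or a plain array (a float is returned).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class NoEventsError(ValueError):
    """Partial likelihood is undefined without at least one event."""


def acceptable_pairs(T, E) -> list[tuple[int, int]]:
    """All ordered pairs (i, j), i != j, with E_i = 1 and T_i < T_j.

    Ties in observed time are not acceptable (strict inequality), so a
    pair of same-time events contributes nothing to L2 or the c-index.
    """
    T = np.asarray(T, dtype=float)
    E = np.asarray(E, dtype=int)
    ev, later = np.nonzero((E[:, None] == 1) & (T[:, None] < T[None, :]))
    return list(zip(ev.tolist(), later.tolist()))


def _as_tensor(r):
    if isinstance(r, Tensor):
        return r, True
    return Tensor(np.asarray(r, dtype=float)), False


def neg_log_partial_likelihood(r, T, E):
    """Negative log Breslow partial likelihood of risk scores ``r``.

    ``-sum_{i: E_i=1} [ r_i - log sum_{j: T_j >= T_i} exp(r_j) ]``,
    computed with a shift-stabilised log-sum-exp. Tied event times share
    the full risk-set denominator (Breslow convention).
    """
    r, was_tensor = _as_tensor(r)
    T = np.asarray(T, dtype=float)
    E = np.asarray(E, dtype=int)
    events = np.flatnonzero(E == 1)
    if events.size == 0:
        raise NoEventsError("no events: partial likelihood is undefined")
    at_risk = (T[None, :] >= T[events, None]).astype(float)  # (n_ev, n)
    shift = float(np.max(r.data))
    expr = (r - shift).exp().reshape(-1, 1)                  # (n, 1)
    log_denom = (Tensor(at_risk) @ expr).log() + shift       # (n_ev, 1)
    loss = log_denom.sum() - r[events].sum()
    return loss if was_tensor else loss.item()


def ranking_loss(r, T, E, sigma: float = 1.0):
    """Exponential pairwise ranking loss over acceptable pairs.

    Each acceptable pair (i, j) contributes ``exp(-(r_i - r_j) / sigma)``;
    equal risks contribute 1, a correctly ordered pair (r_i >> r_j)
    contributes ~0. Returns 0 when no acceptable pairs exist.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r, was_tensor = _as_tensor(r)
    T = np.asarray(T, dtype=float)
    E = np.asarray(E, dtype=int)
    events = np.flatnonzero(E == 1)
    later = (T[None, :] > T[events, None]).astype(float)     # (n_ev, n)
    if events.size == 0 or later.sum() == 0:
        zero = (r * 0.0).sum()
        return zero if was_tensor else 0.0
    shift = float(np.mean(r.data))
    up = ((r - shift) * (1.0 / sigma)).exp().reshape(-1, 1)      # exp(+r_j/s)
    down = ((r - shift) * (-1.0 / sigma)).exp()[events]          # exp(-r_i/s)
    loss = (down * (Tensor(later) @ up).reshape(-1)).sum()
    return loss if was_tensor else loss.item()


def total_loss(r, T, E, sigma: float = 1.0, lam: float = 1.0):
    """``L1 + lam * L2`` — the composite training objective (default lam=1)."""
    l1 = neg_log_partial_likelihood(r, T, E)
    if lam == 0:
        return l1
    return l1 + ranking_loss(r, T, E, sigma=sigma) * lam
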