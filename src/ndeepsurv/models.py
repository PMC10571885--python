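"""Survival models: recurrent hazard networks, MLP baselines, Cox PH.

Five model kinds share one training/evaluation interface:

``ndeep``
    Three stacked LSTM layers over the subject's covariate sequence plus
    one fully connected layer emitting a scalar hazard risk.
``mtl_ndeep``
    Multitask variant: a shared fully connected block feeds K
    task-specific LSTM stacks, each of which also receives the raw input
    through a residual connection.
``deepsurv``
    Feed-forward ReLU network (batch-norm / dropout / weight decay
    available) with a scalar risk head and no residual connection.
``deephit``
    Shared fully connected layers plus K task-specific sub-networks,
    each with an input residual connection, one risk per task.
``coxph``
    Linear Cox proportional-hazards baseline fit by Newton-Raphson on
    the Breslow partial likelihood.

All networks are trained by minibatch gradient descent on the composite
loss ``L1 + lambda L2`` with within-batch risk sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate
from .dataset import SequenceBatch, SurvivalDataset, to_sequences
from .losses import NoEventsError, total_loss
from .nn import MLP, Adam, Dropout, Linear, LSTMLayer, Module, seq_to_tensors

log = logging.getLogger(__name__)

#: The ten cancer-incidence tasks of the motivating cohort, in order.
TASKS_10 = ["thyroid", "gastric", "breast", "colorectal", "lung",
            "prostate", "liver", "kidney", "uterine_cervical", "lymphoma"]

#: Two five-site groups used for the DeepHit-style multitask model.
DEEPHIT_GROUPS = [TASKS_10[:5], TASKS_10[5:]]

#: Four smaller groups used for the multitask nDeep model.
MTL_NDEEP_GROUPS = [["thyroid", "gastric"], ["breast", "colorectal", "lung"],
                    ["prostate", "liver"], ["kidney", "uterine_cervical", "lymphoma"]]


# ---------------------------------------------------------------------------
# Reference LSTM cell (pure numpy, mathematical orientation)
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMParams:
    """One LSTM layer's weights in the mathematical orientation.

    Input matrices ``W_*`` are (h, d), recurrent matrices ``U_*`` are
    (h, h) — they multiply the previous hidden state, so they must be
    square — and biases are length h.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self):
        h, d = np.asarray(self.W_f).shape
        for g in "fioc":
            W, U, b = (np.asarray(getattr(self, f"{m}_{g}")) for m in "WUb")
            if W.shape != (h, d) or U.shape != (h, h) or b.shape != (h,):
                raise ValueError(f"inconsistent LSTM shapes for gate {g!r}")
            if not (np.isfinite(W).all() and np.isfinite(U).all()
                    and np.isfinite(b).all()):
                raise ValueError(f"non-finite LSTM parameters in gate {g!r}")
        self.h, self.d = h, d

    @classmethod
    def random(cls, h: int, d: int, rng: np.random.Generator) -> "LSTMParams":
        s = 1.0 / np.sqrt(max(d, 1))
        kw = {}
        for g in "fioc":
            kw[f"W_{g}"] = rng.uniform(-s, s, (h, d))
            kw[f"U_{g}"] = rng.uniform(-s, s, (h, h))
            kw[f"b_{g}"] = np.zeros(h)
        return cls(**kw)

    @classmethod
    def zeros(cls, h: int, d: int) -> "LSTMParams":
        kw = {}
        for g in "fioc":
            kw[f"W_{g}"] = np.zeros((h, d))
            kw[f"U_{g}"] = np.zeros((h, h))
            kw[f"b_{g}"] = np.zeros(h)
        return cls(**kw)


@dataclass
class LSTMState:
    """Hidden and cell state of one LSTM layer; initial state is zero."""

    h_t: np.ndarray
    c_t: np.ndarray

    @classmethod
    def initial(cls, h: int) -> "LSTMState":
        return cls(np.zeros(h), np.zeros(h))


def lstm_cell_forward(p: LSTMParams, x_t: np.ndarray, s: LSTMState) -> LSTMState:
    """One LSTM step on a single input vector.

    f_t = sigma(W_f x_t + U_f h + b_f), i_t and o_t alike,
    c~ = tanh(W_c x_t + U_c h + b_c), c_t = f_t*c + i_t*c~,
    h_t = o_t * tanh(c_t). Gate activations are logistic (codomain
    (0,1)); cell input and output activations are tanh (codomain (-1,1)).
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (p.d,):
        raise ValueError(f"expected input of shape ({p.d},), got {x_t.shape}")
    f = _sigmoid(p.W_f @ x_t + p.U_f @ s.h_t + p.b_f)
    i = _sigmoid(p.W_i @ x_t + p.U_i @ s.h_t + p.b_i)
    o = _sigmoid(p.W_o @ x_t + p.U_o @ s.h_t + p.b_o)
    c_tilde = np.tanh(p.W_c @ x_t + p.U_c @ s.h_t + p.b_c)
    c_t = f * s.c_t + i * c_tilde
    h_t = o * np.tanh(c_t)
    return LSTMState(h_t, c_t)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

VALID_KINDS = ("ndeep", "mtl_ndeep", "deepsurv", "deephit", "coxph")


@dataclass
class ModelSpec:
    """Architecture hyperparameters for one model.

    ``task_groups`` partitions the task names for multitask kinds; for a
    single-task model it is one group of one. ``residual`` controls how
    the raw input reaches task-specific blocks: ``"concat"`` (default,
    dimension-safe), ``"add"`` (requires matching widths), or ``"none"``
    (ablation).
    """

    kind: str = "ndeep"
    hidden: list = field(default_factory=lambda: [32])
    lstm_hidden: int = 32
    n_lstm_layers: int = 3
    n_steps: int = 4
    dropout: float = 0.0
    batch_norm: bool = False
    residual: str = "concat"
    shared_hidden: list = field(default_factory=lambda: [32])
    task_groups: list | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; valid: {VALID_KINDS}")
        if self.residual not in ("concat", "add", "none"):
            raise ValueError("residual must be 'concat', 'add' or 'none'")
        if self.task_groups is not None:
            flat = [t for g in self.task_groups for t in g]
            if len(flat) != len(set(flat)):
                raise ValueError("task_groups must not overlap")


def validate_task_groups(groups: list, task_names: list[str]) -> None:
    flat = [t for g in groups for t in g]
    if sorted(flat) != sorted(task_names):
        raise ValueError(f"task groups {groups} do not partition tasks {task_names}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class NDeepNet(Module):
    """Stacked-LSTM hazard network: LSTM layers + one FC risk head."""

    is_recurrent = True

    def __init__(self, d: int, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        h = spec.lstm_hidden
        self.lstm_layers = [LSTMLayer(d if i == 0 else h, h, rng)
                            for i in range(spec.n_lstm_layers)]
        self.dropout = Dropout(spec.dropout, rng)
        self.head = Linear(h, 1, rng)

    def __call__(self, seq: list[Tensor]) -> Tensor:
        for layer in self.lstm_layers:
            seq = layer(seq)
        last = self.dropout(seq[-1])
        return self.head(last).reshape(-1)


class DeepSurvNet(Module):
    """Feed-forward risk network; the only model without a residual path."""

    is_recurrent = False

    def __init__(self, d: int, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.body = MLP(d, list(spec.hidden), rng, dropout=spec.dropout,
                        batch_norm=spec.batch_norm)
        self.head = Linear(self.body.d_out, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.body(x)).reshape(-1)


def _residual_input(shared_out: Tensor, x: Tensor, mode: str) -> Tensor:
    if mode == "concat":
        return concatenate([shared_out, x], axis=-1)
    if mode == "add":
        if shared_out.shape[-1] != x.shape[-1]:
            raise ValueError("'add' residual requires shared width == input width")
        return shared_out + x
    return shared_out


class DeepHitNet(Module):
    """Shared FC layers + K task sub-networks, input residual to each head."""

    is_recurrent = False

    def __init__(self, d: int, n_tasks: int, spec: ModelSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.residual = spec.residual
        self.shared = MLP(d, list(spec.shared_hidden), rng, dropout=spec.dropout,
                          batch_norm=spec.batch_norm)
        head_in = self.shared.d_out + (d if spec.residual == "concat" else 0)
        self.heads = []
        for _ in range(n_tasks):
            body = MLP(head_in, list(spec.hidden), rng, dropout=spec.dropout)
            self.heads.append(body)
        self.outs = [Linear(self.heads[k].d_out, 1, rng) for k in range(n_tasks)]

    def __call__(self, x: Tensor) -> Tensor:
        s = self.shared(x)
        cols = []
        for body, out in zip(self.heads, self.outs):
            z = _residual_input(s, x, self.residual)
            cols.append(out(body(z)))
        return concatenate(cols, axis=-1)


class MTLNDeepNet(Module):
    """Shared FC block + K task-specific LSTM stacks with input residual.

    The shared block is applied step-wise (same weights at every step);
    each task block runs its own nDeep stack on the shared representation
    concatenated (or added) with the raw step input.
    """

    is_recurrent = True

    def __init__(self, d: int, n_tasks: int, spec: ModelSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.residual = spec.residual
        self.shared = MLP(d, list(spec.shared_hidden), rng, dropout=spec.dropout)
        block_in = self.shared.d_out + (d if spec.residual == "concat" else 0)
        self.blocks = []
        h = spec.lstm_hidden
        for _ in range(n_tasks):
            layers = [LSTMLayer(block_in if i == 0 else h, h, rng)
                      for i in range(spec.n_lstm_layers)]
            self.blocks.append(layers)
        self.outs = [Linear(h, 1, rng) for _ in range(n_tasks)]

    def parameters(self):
        params = super().parameters()
        for layers in self.blocks:
            for layer in layers:
                params.extend(layer.parameters())
        return params

    def train(self, mode: bool = True):
        super().train(mode)
        for layers in self.blocks:
            for layer in layers:
                layer.train(mode)
        return self

    def __call__(self, seq: list[Tensor]) -> Tensor:
        steps = [_residual_input(self.shared(x_t), x_t, self.residual)
                 for x_t in seq]
        cols = []
        for layers, out in zip(self.blocks, self.outs):
            s = steps
            for layer in layers:
                s = layer(s)
            cols.append(out(s[-1]))
        return concatenate(cols, axis=-1)


def build_model(spec: ModelSpec, d: int, n_tasks: int,
                rng: np.random.Generator) -> Module:
    if spec.kind == "ndeep":
        if n_tasks != 1:
            raise ValueError("ndeep is single-task; use mtl_ndeep for groups")
        return NDeepNet(d, spec, rng)
    if spec.kind == "deepsurv":
        if n_tasks != 1:
            raise ValueError("deepsurv is single-task")
        return DeepSurvNet(d, spec, rng)
    if spec.kind == "deephit":
        return DeepHitNet(d, n_tasks, spec, rng)
    if spec.kind == "mtl_ndeep":
        return MTLNDeepNet(d, n_tasks, spec, rng)
    raise ValueError(f"build_model does not handle kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Cox proportional hazards baseline
# ---------------------------------------------------------------------------

class CoxConvergenceError(RuntimeError):
    def __init__(self, message: str, beta: np.ndarray):
        super().__init__(message)
        self.beta = beta


@dataclass
class CoxPHModel:
    """Fitted linear Cox model; risk score is the linear predictor beta.x."""

    beta: np.ndarray
    feature_names: list[str]
    log_partial_likelihood: float
    n_iter: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta


def _breslow_ll_grad_hess(beta, X, T, E):
    """Log partial likelihood, gradient and information matrix (Breslow ties)."""
    n, d = X.shape
    eta = X @ beta
    # guard against overflow while keeping the likelihood exact up to shift
    shift = eta.max()
    w = np.exp(eta - shift)
    order = np.argsort(-T, kind="stable")
    Ts, Xs, Es, ws, etas = T[order], X[order], E[order], w[order], eta[order]
    ll, grad, hess = 0.0, np.zeros(d), np.zeros((d, d))
    S0, S1, S2 = 0.0, np.zeros(d), np.zeros((d, d))
    i = 0
    while i < n:
        j = i
        while j < n and Ts[j] == Ts[i]:
            j += 1
        Xg, wg = Xs[i:j], ws[i:j]
        S0 += wg.sum()
        S1 += wg @ Xg
        S2 += (Xg * wg[:, None]).T @ Xg
        ev = Es[i:j] == 1
        n_ev = int(ev.sum())
        if n_ev:
            m = S1 / S0
            ll += etas[i:j][ev].sum() - n_ev * (np.log(S0) + shift)
            grad += Xg[ev].sum(axis=0) - n_ev * m
            hess += n_ev * (S2 / S0 - np.outer(m, m))
        i = j
    return ll, grad, hess


def fit_cox_ph(ds, task=None, *, X=None, T=None, E=None, tol: float = 1e-6,
               max_iter: int = 100, max_beta_norm: float = 50.0) -> CoxPHModel:
    """Maximize the Breslow partial likelihood by damped Newton-Raphson.

    Accepts either a :class:`SurvivalDataset` plus a task name, or raw
    ``X``, ``T``, ``E`` arrays. Converges when the gradient norm drops
    below ``tol``; a diverging coefficient norm is reported as probable
    complete separation with a suggestion to regularize.
    """
    if ds is not None:
        if ds.has_missing():
            raise ValueError("Cox fit requires complete covariates; impute first")
        X = ds.X
        T = ds.T
        E = ds.events_for(task if task is not None else ds.task_names[0])
        names = list(ds.feature_names)
    else:
        X = np.asarray(X, dtype=float)
        T = np.asarray(T, dtype=float)
        E = np.asarray(E, dtype=int)
        names = [f"x{j}" for j in range(X.shape[1])]
    if E.sum() < 1:
        raise NoEventsError("Cox fit requires at least one event")

    d = X.shape[1]
    beta = np.zeros(d)
    ll, grad, hess = _breslow_ll_grad_hess(beta, X, T, E)
    it = 0
    n_events = int((E == 1).sum())
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            # a partial likelihood of ~1 means the linear predictor orders
            # every risk set perfectly: complete separation, beta diverges
            if ll > -1e-4 and n_events > 1:
                raise CoxConvergenceError(
                    "partial likelihood saturated at 1 (complete separation); "
                    "consider ridge-regularizing or removing the offending "
                    "feature", beta)
            return CoxPHModel(beta, names, float(ll), it - 1, True)
        try:
            step = np.linalg.solve(hess + 1e-9 * np.eye(d), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, g_new, h_new = _breslow_ll_grad_hess(cand, X, T, E)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.linalg.norm(beta) > max_beta_norm:
            raise CoxConvergenceError(
                "coefficients diverging (possible complete separation); "
                "consider ridge-regularizing or removing the offending feature",
                beta)
    if np.linalg.norm(grad) < tol:
        return CoxPHModel(beta, names, float(ll), it, True)
    raise CoxConvergenceError(
        f"Newton-Raphson did not converge in {max_iter} iterations "
        f"(|grad| = {np.linalg.norm(grad):.3g})", beta)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class LossConfig:
    """sigma scales the ranking loss; lam weights it against L1 (default: plain sum)."""

    sigma: float = 1.0
    lam: float = 1.0


@dataclass
class OptimizerConfig:
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    weight_decay: float = 0.0
    patience: int = 10
    full_batch: bool = False


@dataclass
class Scaler:
    """Feature standardiser fit on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean, sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class TrainedModel:
    """A fitted model plus the preprocessing needed to score new subjects."""

    def __init__(self, spec: ModelSpec, tasks: list[str], net=None,
                 cox_models: dict | None = None, scaler: Scaler | None = None,
                 loss_history=None, valid_history=None, seed: int | None = None):
        self.spec = spec
        self.tasks = list(tasks)
        self.net = net
        self.cox_models = cox_models
        self.scaler = scaler
        self.loss_history = loss_history or []
        self.valid_history = valid_history or []
        self.seed = seed

    def predict_risk(self, data, task: str | None = None) -> np.ndarray:
        """Risk scores for a dataset or raw covariate matrix.

        Returns shape (n,) for single-task models or when ``task`` is
        given; otherwise (n, K) with columns in ``self.tasks`` order.
        """
        X = data.X if isinstance(data, SurvivalDataset) else np.asarray(data, float)
        if self.spec.kind == "coxph":
            out = np.column_stack([self.cox_models[t].predict(X) for t in self.tasks])
        else:
            Xs = self.scaler.transform(X) if self.scaler is not None else X
            self.net.eval()
            if getattr(self.net, "is_recurrent", False):
                seq_data = np.repeat(Xs[:, None, :], self.spec.n_steps, axis=1)
                r = self.net(seq_to_tensors(seq_data))
            else:
                r = self.net(Tensor(Xs))
            out = r.data.reshape(X.shape[0], -1)
        if task is not None:
            return out[:, self.tasks.index(task)]
        return out[:, 0] if out.shape[1] == 1 else out


def _batch_loss(net, Xb, Tb, Eb, spec, loss_cfg):
    """Composite loss summed over the model's task columns, per-sample scaled."""
    if getattr(net, "is_recurrent", False):
        seq = seq_to_tensors(np.repeat(Xb[:, None, :], spec.n_steps, axis=1))
        r = net(seq)
    else:
        r = net(Tensor(Xb))
    n_tasks = Eb.shape[1]
    loss = None
    n_used = 0
    for k in range(n_tasks):
        if Eb[:, k].sum() == 0:
            continue
        rk = r if n_tasks == 1 and r.ndim == 1 else r.reshape(len(Xb), -1)[:, k]
        lk = total_loss(rk, Tb, Eb[:, k], sigma=loss_cfg.sigma, lam=loss_cfg.lam)
        loss = lk if loss is None else loss + lk
        n_used += 1
    if loss is None:
        return None
    return loss * (1.0 / len(Xb))


def train_model(spec: ModelSpec, ds: SurvivalDataset, tasks: list[str] | None = None,
                loss_cfg: LossConfig | None = None,
                opt_cfg: OptimizerConfig | None = None, seed: int = 0,
                valid_ds: SurvivalDataset | None = None,
                standardize: bool = True) -> TrainedModel:
    """Fit one model (of any kind) on a complete, preprocessed dataset.

    Training is fully reproducible from (spec, configs, seed): parameter
    initialisation, minibatch shuffling and dropout all draw from one
    seeded generator. With a validation set, the best-validation-loss
    weights are restored at the end (early stopping with ``patience``).
    """
    if ds.has_missing():
        raise ValueError("training data contains missing values; impute first")
    loss_cfg = loss_cfg or LossConfig()
    opt_cfg = opt_cfg or OptimizerConfig()
    tasks = list(tasks) if tasks is not None else (
        list(ds.task_names) if spec.kind in ("deephit", "mtl_ndeep")
        else [ds.task_names[0]])

    if spec.kind == "coxph":
        cox = {t: fit_cox_ph(ds, t) for t in tasks}
        return TrainedModel(spec, tasks, cox_models=cox, seed=seed)

    rng = np.random.default_rng(seed)
    scaler = Scaler.fit(ds.X) if standardize else None
    Xtr = scaler.transform(ds.X) if standardize else ds.X
    Etr = np.column_stack([ds.events_for(t) for t in tasks])
    net = build_model(spec, ds.d, len(tasks), rng)
    opt = Adam(net.parameters(), lr=opt_cfg.lr, weight_decay=opt_cfg.weight_decay)

    if valid_ds is not None:
        Xva = scaler.transform(valid_ds.X) if standardize else valid_ds.X
        Eva = np.column_stack([valid_ds.events_for(t) for t in tasks])

    n = ds.n
    batch = n if opt_cfg.full_batch else min(opt_cfg.batch_size, n)
    history, valid_history = [], []
    best_state, best_valid, since_best = None, np.inf, 0

    for epoch in range(opt_cfg.epochs):
        net.train()
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            loss = _batch_loss(net, Xtr[idx], ds.T[idx], Etr[idx], spec, loss_cfg)
            if loss is None:
                continue  # no events for any task in this minibatch
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    "loss became non-finite during training; "
                    "try a smaller learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))

        if valid_ds is not None:
            net.eval()
            vloss = _batch_loss(net, Xva, valid_ds.T, Eva, spec, loss_cfg)
            v = np.inf if vloss is None else vloss.item()
            valid_history.append(v)
            if v < best_valid - 1e-9:
                best_valid, since_best = v, 0
                best_state = [p.data.copy() for p in net.parameters()]
            else:
                since_best += 1
                if since_best >= opt_cfg.patience:
                    break

    if best_state is not None:
        for p, s in zip(net.parameters(), best_state):
            p.data[...] = s
    net.eval()
    return TrainedModel(spec, tasks, net=net, scaler=scaler,
                        loss_history=history, valid_history=valid_history,
                        seed=seed)


def ndeep_forward(spec: ModelSpec, batch: SequenceBatch,
                  rng: np.random.Generator | None = None, net: Module | None = None):
    """Functional forward pass of an (optionally freshly initialised) nDeep."""
    if net is None:
        net = NDeepNet(batch.d, spec, rng or np.random.default_rng(0))
    net.eval()
    return net(seq_to_tensors(batch.data)).data


def mtl_ndeep_forward(spec: ModelSpec, batch: SequenceBatch, n_tasks: int,
                      rng: np.random.Generator | None = None,
                      net: Module | None = None):
    if net is None:
        net = MTLNDeepNet(batch.d, n_tasks, spec, rng or np.random.default_rng(0))
    net.eval()
    return net(seq_to_tensors(batch.data)).data


def deepsurv_forward(spec: ModelSpec, X: np.ndarray,
                     rng: np.random.Generator | None = None,
                     net: Module | None = None):
    if net is None:
        net = DeepSurvNet(X.shape[1], spec, rng or np.random.default_rng(0))
    net.eval()
    return net(Tensor(np.asarray(X, float))).data


def deephit_like_forward(spec: ModelSpec, X: np.ndarray, n_tasks: int,
                         rng: np.random.Generator | None = None,
                         net: Module | None = None):
    if net is None:
        net = DeepHitNet(X.shape[1], n_tasks, spec, rng or np.random.default_rng(0))
    net.eval()
    return net(Tensor(np.asarray(X, float))).data
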