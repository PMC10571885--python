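"""Layers and an Adam optimizer built on the in-package autodiff.

Shapes follow the usual row-major convention: a batch is ``(n, d)`` and
linear weights are stored ``(d_in, d_out)``. The LSTM layer stores its
gate matrices transposed relative to :class:`~ndeepsurv.models.LSTMParams`
(which uses the mathematical ``(h, d)`` orientation); ``to_params`` /
``from_params`` convert between the two so the recurrence can be checked
against the reference cell function.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, relu, sigmoid, tanh


class Module:
    """Base class: parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask drawn from ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Feature-wise batch normalisation with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = ((x - Tensor(self.running_mean))
                    * Tensor((self.running_var + self.eps) ** -0.5))
        return xhat * self.gamma + self.beta


class MLP(Module):
    """ReLU feed-forward block with optional batch-norm and dropout."""

    def __init__(self, d_in: int, hidden: list[int], rng: np.random.Generator,
                 dropout: float = 0.0, batch_norm: bool = False):
        super().__init__()
        self.layers: list[Module] = []
        d = d_in
        for h in hidden:
            self.layers.append(Linear(d, h, rng))
            if batch_norm:
                self.layers.append(BatchNorm1d(h))
            self.layers.append(_ReLU())
            if dropout > 0:
                self.layers.append(Dropout(dropout, rng))
            d = h
        self.d_out = d

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return relu(x)


class LSTMLayer(Module):
    """One LSTM layer unrolled over a fixed-length sequence.

    Gates per step t (h_0 = c_0 = 0):

        f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
        i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
        o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
        c~  = tanh  (W_c x_t + U_c h_{t-1} + b_c)
        c_t = f_t * c_{t-1} + i_t * c~
        h_t = o_t * tanh(c_t)
    """

    GATES = ("f", "i", "o", "c")

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        s_in, s_rec = 1.0 / np.sqrt(d_in), 1.0 / np.sqrt(hidden)
        # stored (d_in, h) and (h, h) for row-major batches
        for g in self.GATES:
            setattr(self, f"W{g}", Tensor(rng.uniform(-s_in, s_in, (d_in, hidden)),
                                          requires_grad=True))
            setattr(self, f"U{g}", Tensor(rng.uniform(-s_rec, s_rec, (hidden, hidden)),
                                          requires_grad=True))
            setattr(self, f"b{g}", Tensor(np.zeros(hidden), requires_grad=True))

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        f = sigmoid(x_t @ self.Wf + h @ self.Uf + self.bf)
        i = sigmoid(x_t @ self.Wi + h @ self.Ui + self.bi)
        o = sigmoid(x_t @ self.Wo + h @ self.Uo + self.bo)
        c_tilde = tanh(x_t @ self.Wc + h @ self.Uc + self.bc)
        c_new = f * c + i * c_tilde
        h_new = o * tanh(c_new)
        return h_new, c_new

    def __call__(self, seq: list[Tensor]) -> list[Tensor]:
        """Run over a list of per-step (n, d) tensors; returns hidden states."""
        n = seq[0].shape[0]
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        outputs = []
        for x_t in seq:
            h, c = self.step(x_t, h, c)
            outputs.append(h)
        return outputs

    def to_params(self):
        """Export weights in the mathematical (h, d) orientation."""
        from .models import LSTMParams
        kw = {}
        for g in self.GATES:
            kw[f"W_{g}"] = getattr(self, f"W{g}").data.T.copy()
            kw[f"U_{g}"] = getattr(self, f"U{g}").data.T.copy()
            kw[f"b_{g}"] = getattr(self, f"b{g}").data.copy()
        return LSTMParams(**kw)

    def from_params(self, p) -> "LSTMLayer":
        for g in self.GATES:
            getattr(self, f"W{g}").data[...] = getattr(p, f"W_{g}").T
            getattr(self, f"U{g}").data[...] = getattr(p, f"U_{g}").T
            getattr(self, f"b{g}").data[...] = getattr(p, f"b_{g}")
        return self


class Adam:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def seq_to_tensors(data: np.ndarray) -> list[Tensor]:
    """Split an (n, steps, d) array into per-step (n, d) constant tensors."""
    return [Tensor(data[:, t, :]) for t in range(data.shape[1])]


__all__ = ["Module", "Linear", "Dropout", "BatchNorm1d", "MLP", "LSTMLayer",
           "Adam", "seq_to_tensors", "concatenate"]
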