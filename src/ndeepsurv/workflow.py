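"""Nested tuning and evaluation: splits, TPE search, bootstrap scoring, CV.

The benchmark protocol is an outer 5-fold cross-validation (each fold a
4:1 train/test split) repeated via bootstrap on the test side: within a
fold, a validation subset is sampled from the training rows (p = 0.2),
hyperparameters are tuned on it with a Tree-structured Parzen Estimator
(60 trials by default), the tuned model is refit on the fold's training
rows, and the held-out fold is scored 30 times on bootstrap resamples;
the reported c-index is the mean over resamples. All imputation
statistics are fit on training rows only, so no test row leaks into
preprocessing, tuning or training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset
from .metrics import ConcordanceUndefinedError, concordance_index, mean_cindex
from .models import (LossConfig, ModelSpec, OptimizerConfig, TrainedModel,
                     train_model, validate_task_groups)
from .preprocess import impute

log = logging.getLogger(__name__)


class SplitError(RuntimeError):
    """Could not produce a usable (event-containing) split."""


def _stratified_indices(E: np.ndarray, test_frac: float, rng) -> np.ndarray:
    """Boolean test mask, stratified on the 0/1 indicator ``E``."""
    test = np.zeros(len(E), dtype=bool)
    for value in (0, 1):
        idx = np.flatnonzero(E == value)
        if idx.size == 0:
            continue
        n_test = int(round(test_frac * idx.size))
        test[rng.choice(idx, size=n_test, replace=False)] = True
    return test


def split_train_test(ds: SurvivalDataset, ratio: float = 0.2, seed: int = 0,
                     task: str | None = None, max_redraw: int = 20):
    """Random 4:1 (by default) split, stratified by the target task's events.

    Redraws up to ``max_redraw`` times if either side ends up with zero
    events for the stratification task.
    """
    if ds.n < 10:
        raise ValueError("need at least 10 rows to split")
    E = ds.events_for(task) if task is not None else ds.E[:, 0]
    rng = np.random.default_rng(seed)
    for _ in range(max_redraw):
        test = _stratified_indices(E, ratio, rng)
        if E[~test].sum() > 0 and E[test].sum() > 0:
            return ds.subset(~test), ds.subset(test)
    raise SplitError("could not draw a split with events on both sides")


def sample_validation(train: SurvivalDataset, p: float = 0.2, seed: int = 0,
                      task: str | None = None, max_redraw: int = 20):
    """Carve a validation subset out of the training rows (probability p)."""
    if p == 0:
        log.warning("validation probability 0: empty validation set")
        return train, train.subset(np.zeros(train.n, dtype=bool))
    return split_train_test(train, ratio=p, seed=seed, task=task,
                            max_redraw=max_redraw)


def stratified_folds(ds: SurvivalDataset, folds: int, seed: int = 0,
                     task: str | None = None) -> list[np.ndarray]:
    """Partition row indices into event-stratified folds."""
    E = ds.events_for(task) if task is not None else ds.E[:, 0]
    rng = np.random.default_rng(seed)
    assignment = np.empty(ds.n, dtype=int)
    for value in (0, 1):
        idx = rng.permutation(np.flatnonzero(E == value))
        assignment[idx] = np.arange(idx.size) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


# ---------------------------------------------------------------------------
# Hyperparameter search (TPE)
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Named hyperparameter dimensions.

    Each entry maps a name to a spec tuple: ``("uniform", lo, hi)``,
    ``("loguniform", lo, hi)``, ``("int", lo, hi)`` or
    ``("choice", [options])``.
    """

    dims: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, dim in self.dims.items():
            kind = dim[0]
            if kind in ("uniform", "loguniform", "int"):
                lo, hi = dim[1], dim[2]
                if not lo < hi:
                    raise ValueError(f"{name}: bounds must be ordered")
                if kind == "loguniform" and lo <= 0:
                    raise ValueError(f"{name}: loguniform needs positive bounds")
            elif kind == "choice":
                if not dim[1]:
                    raise ValueError(f"{name}: empty choice list")
            else:
                raise ValueError(f"{name}: unknown dimension kind {kind!r}")


class TPESampler:
    """Tree-structured Parzen Estimator over a :class:`SearchSpace`.

    After ``n_startup`` random trials, observed trials are split at the
    ``gamma`` quantile of the objective into a "good" and a "bad" set;
    each numeric dimension gets a Gaussian kernel density per set, and
    the candidate maximising the density ratio l(x)/g(x) among
    ``n_candidates`` draws from the good density is proposed.
    Categorical dimensions use smoothed category frequencies.
    """

    def __init__(self, space: SearchSpace, seed: int = 0, n_startup: int = 10,
                 gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def _random_value(self, dim):
        kind = dim[0]
        if kind == "uniform":
            return float(self.rng.uniform(dim[1], dim[2]))
        if kind == "loguniform":
            return float(np.exp(self.rng.uniform(np.log(dim[1]), np.log(dim[2]))))
        if kind == "int":
            return int(self.rng.integers(dim[1], dim[2] + 1))
        return dim[1][self.rng.integers(len(dim[1]))]

    @staticmethod
    def _kde_logpdf(x, samples, lo, hi):
        samples = np.asarray(samples, dtype=float)
        bw = max(1.06 * samples.std() * samples.size ** -0.2, (hi - lo) * 0.01, 1e-12)
        z = (x - samples[:, None]) / bw
        return np.log(np.mean(np.exp(-0.5 * z * z) / (bw * np.sqrt(2 * np.pi)),
                              axis=0) + 1e-300)

    def suggest(self, history: list[tuple[dict, float]]) -> dict:
        """Propose parameters given (params, objective) history (maximised)."""
        if len(history) < self.n_startup:
            return {n: self._random_value(d) for n, d in self.space.dims.items()}
        scores = np.array([s for _, s in history])
        n_good = max(1, int(np.ceil(self.gamma * len(history))))
        good_idx = set(np.argsort(-scores)[:n_good].tolist())
        good = [history[i][0] for i in good_idx]
        bad = [history[i][0] for i in range(len(history)) if i not in good_idx]
        out = {}
        for name, dim in self.space.dims.items():
            kind = dim[0]
            if kind == "choice":
                options = dim[1]
                counts_g = np.array(
                    [1.0 + sum(p[name] == o for p in good) for o in options])
                counts_b = np.array(
                    [1.0 + sum(p[name] == o for p in bad) for o in options])
                ratio = (counts_g / counts_g.sum()) / (counts_b / counts_b.sum())
                probs = counts_g / counts_g.sum()
                cand = self.rng.choice(len(options), size=self.n_candidates, p=probs)
                out[name] = options[int(cand[np.argmax(ratio[cand])])]
                continue
            to_x = np.log if kind == "loguniform" else (lambda v: np.asarray(v, float))
            lo, hi = to_x(dim[1]), to_x(dim[2])
            gx = [float(to_x(p[name])) for p in good]
            bx = [float(to_x(p[name])) for p in bad] or gx
            bw = max(1.06 * np.std(gx) * max(len(gx), 2) ** -0.2, (hi - lo) * 0.05)
            cands = np.clip(self.rng.choice(gx, self.n_candidates)
                            + self.rng.normal(0, bw, self.n_candidates), lo, hi)
            score = (self._kde_logpdf(cands, gx, lo, hi)
                     - self._kde_logpdf(cands, bx, lo, hi))
            best = float(cands[np.argmax(score)])
            if kind == "loguniform":
                best = float(np.exp(best))
            out[name] = int(round(best)) if kind == "int" else best
        return out


@dataclass
class Trial:
    number: int
    params: dict
    value: float | None
    state: str = "ok"


def hyperparameter_search(space: SearchSpace, objective, n_trials: int = 60,
                          seed: int = 0, sampler: str = "tpe"):
    """Maximise ``objective(params)`` over the space; returns (best, trials).

    ``sampler`` is ``"tpe"`` (default) or ``"random"``. Failing trials
    (an exception from the objective) are logged and skipped; if every
    trial fails the full log is raised with the error.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    tpe = TPESampler(space, seed=seed)
    rng = np.random.default_rng(seed + 1)
    history: list[tuple[dict, float]] = []
    trials: list[Trial] = []
    for t in range(n_trials):
        if sampler == "tpe":
            params = tpe.suggest(history)
        else:
            params = {n: TPESampler(space, seed=int(rng.integers(2**31)))
                      ._random_value(d) for n, d in space.dims.items()}
        try:
            value = float(objective(params))
        except Exception as exc:  # noqa: BLE001 - trial failures are data
            log.warning("trial %d failed: %s", t, exc)
            trials.append(Trial(t, params, None, state=f"failed: {exc}"))
            continue
        history.append((params, value))
        trials.append(Trial(t, params, value))
    if not history:
        raise RuntimeError(f"all {n_trials} trials failed; log: {trials}")
    best_params, _ = max(history, key=lambda pv: pv[1])
    return best_params, trials


# ---------------------------------------------------------------------------
# Repeated evaluation and the cross-validated benchmark
# ---------------------------------------------------------------------------

def repeated_test_evaluation(model: TrainedModel, test: SurvivalDataset,
                             task: str, n_repeats: int = 30, seed: int = 0,
                             bootstrap: bool = True):
    """Score the model on ``n_repeats`` bootstrap resamples of the test set.

    Resamples with no acceptable pairs are skipped and logged; an error
    is raised only if every repeat is skipped. Returns
    ``(mean, sd, values)``.
    """
    if test.n == 0:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    risk = model.predict_risk(test, task=task)
    values, skipped = [], 0
    for _ in range(n_repeats):
        idx = (rng.integers(0, test.n, size=test.n) if bootstrap
               else np.arange(test.n))
        try:
            values.append(concordance_index(risk[idx], test.T[idx],
                                            test.events_for(task)[idx]))
        except ConcordanceUndefinedError:
            skipped += 1
    if not values:
        raise ConcordanceUndefinedError(
            f"all {n_repeats} bootstrap repeats had no acceptable pairs")
    if skipped:
        log.info("skipped %d/%d repeats with no acceptable pairs", skipped, n_repeats)
    mean, sd = mean_cindex(values)
    return mean, sd, values


@dataclass
class EvaluationReport:
    """Per-(model, task, fold, repeat) c-indices plus tuning metadata."""

    records: pd.DataFrame
    best_params: dict = field(default_factory=dict)
    folds: int = 0
    n_repeats: int = 0

    def summary(self) -> pd.DataFrame:
        return (self.records.groupby(["model", "task"])["cindex"]
                .agg(["mean", "std"]).reset_index())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def cross_validated_benchmark(ds: SurvivalDataset, specs: list[ModelSpec],
                              folds: int = 5, n_repeats: int = 30, seed: int = 0,
                              search_space: SearchSpace | None = None,
                              n_trials: int = 60,
                              loss_cfg: LossConfig | None = None,
                              opt_cfg: OptimizerConfig | None = None,
                              tasks: list[str] | None = None,
                              impute_strategy: str = "median") -> EvaluationReport:
    """Run the full nested benchmark for each model spec.

    Outer loop: event-stratified folds (each a 4:1 split at the default
    ``folds=5``). Inner loop per fold: validation sampling, optional TPE
    search (``search_space``), final training on the fold's training
    rows, bootstrap-repeated scoring on the held-out fold. Imputation
    statistics come from training rows only.
    """
    tasks = tasks or list(ds.task_names)
    rows = []
    best_params: dict = {}
    for spec in specs:
        if spec.task_groups is not None:
            validate_task_groups(spec.task_groups, tasks)
        groups = (spec.task_groups if spec.task_groups is not None
                  else ([tasks] if spec.kind in ("deephit", "mtl_ndeep", "coxph")
                        else [[t] for t in tasks]))
        for group in groups:
            fold_idx = stratified_folds(ds, folds, seed=seed, task=group[0])
            for f, test_rows in enumerate(fold_idx):
                train_rows = np.setdiff1d(np.arange(ds.n), test_rows)
                train = impute(ds.subset(train_rows), strategy=impute_strategy)
                test_raw = ds.subset(test_rows)
                # fill test cells with *training* statistics (leakage-free)
                test = (_impute_like(ds.subset(train_rows), test_raw,
                                     impute_strategy)
                        if test_raw.has_missing() else test_raw)
                fold_seed = seed * 1000 + f

                cfg_opt = opt_cfg or OptimizerConfig()
                cfg_loss = loss_cfg or LossConfig()
                if search_space is not None and spec.kind != "coxph":
                    sub_train, valid = sample_validation(
                        train, 0.2, seed=fold_seed, task=group[0])

                    def _objective(params, _spec=spec, _sub=sub_train,
                                   _val=valid, _group=group,
                                   _cl=cfg_loss, _co=cfg_opt, _fs=fold_seed):
                        sp, cl, co = _apply_params(_spec, _cl, _co, params)
                        m = train_model(sp, _sub, tasks=_group, loss_cfg=cl,
                                        opt_cfg=co, seed=_fs, valid_ds=_val)
                        vals = [concordance_index(m.predict_risk(_val, task=t),
                                                  _val.T, _val.events_for(t))
                                for t in _group]
                        return float(np.mean(vals))

                    params, _ = hyperparameter_search(
                        search_space, _objective, n_trials=n_trials,
                        seed=fold_seed)
                    best_params[(spec.kind, tuple(group), f)] = params
                    spec_f, cfg_loss, cfg_opt = _apply_params(
                        spec, cfg_loss, cfg_opt, params)
                else:
                    spec_f = spec

                model = train_model(spec_f, train, tasks=group, loss_cfg=cfg_loss,
                                    opt_cfg=cfg_opt, seed=fold_seed)
                for t in group:
                    mean, sd, values = repeated_test_evaluation(
                        model, test, t, n_repeats=n_repeats, seed=fold_seed)
                    for rep, v in enumerate(values):
                        rows.append({"model": spec.kind, "task": t, "fold": f,
                                     "repeat": rep, "cindex": v})
    records = pd.DataFrame(rows, columns=["model", "task", "fold", "repeat",
                                          "cindex"])
    return EvaluationReport(records, best_params=best_params, folds=folds,
                            n_repeats=n_repeats)


def _impute_like(train: SurvivalDataset, test: SurvivalDataset,
                 strategy: str) -> SurvivalDataset:
    """Fill test missing cells with statistics fit on the training split."""
    stat_fn = np.nanmedian if strategy == "median" else np.nanmean
    stats = stat_fn(train.X, axis=0)
    out = test.copy()
    mask = np.isnan(out.X)
    out.X[mask] = np.broadcast_to(stats, out.X.shape)[mask]
    return out


_SPEC_KEYS = {"lstm_hidden", "n_lstm_layers", "n_steps", "dropout", "hidden",
              "shared_hidden", "batch_norm", "residual"}
_LOSS_KEYS = {"sigma", "lam"}
_OPT_KEYS = {"lr", "batch_size", "epochs", "weight_decay", "patience"}


def _apply_params(spec: ModelSpec, loss_cfg: LossConfig, opt_cfg: OptimizerConfig,
                  params: dict):
    """Overlay searched hyperparameters onto spec / loss / optimizer configs."""
    import dataclasses
    sp = dataclasses.replace(spec)
    cl = dataclasses.replace(loss_cfg)
    co = dataclasses.replace(opt_cfg)
    for k, v in params.items():
        if k in _SPEC_KEYS:
            setattr(sp, k, v)
        elif k in _LOSS_KEYS:
            setattr(cl, k, v)
        elif k in _OPT_KEYS:
            setattr(co, k, int(v) if k in ("batch_size", "epochs", "patience") else v)
        else:
            raise KeyError(f"hyperparameter {k!r} matches no config field")
    return sp, cl, co
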