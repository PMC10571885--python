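"""Permutation feature importance scored by concordance-index drop.

For each feature, its column is shuffled (a fresh permutation per
repeat) while all other columns stay untouched; the importance score is
the baseline c-index minus the mean permuted c-index. Scores are not
additive and can be slightly negative for irrelevant features. By
default importance is computed on held-out data so the score reflects
generalisable reliance on the feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset
from .metrics import concordance_index
from .models import TrainedModel

#: Display grouping of the cohort biomarkers (heatmap separators).
FEATURE_GROUPS = {
    "demographic": ["AGE", "SEX"],
    "metabolic": ["WT", "HT", "BMI", "WC", "SBP", "DBP", "CHO", "HDL", "TG",
                  "LDL", "GLU", "PP"],
    "liver": ["ALB", "GLOBULIN", "AGR", "BIL", "DBIL", "ALP", "AST", "ALT",
              "GGTP"],
    "pulmonary": ["FVC", "FEV1"],
    "kidney": ["CREAT", "BUN", "SG", "PH", "CCR"],
    "pancreas": ["AMYLASE"],
}


@dataclass
class PFIMatrix:
    """feature x task matrix of mean c-index drops under permutation."""

    scores: pd.DataFrame          # index: feature names, columns: tasks
    repeats: int
    seed: int
    baseline: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.scores.to_csv(path)

    def top_features(self, task: str, k: int = 10) -> pd.Series:
        return self.scores[task].sort_values(ascending=False).head(k)


def permutation_importance(model: TrainedModel, ds: SurvivalDataset, task: str,
                           n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """One PFI column: per-feature mean c-index drop for one task."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if ds.has_missing():
        raise ValueError("impute before computing importance")
    rng = np.random.default_rng(seed)
    E = ds.events_for(task)
    baseline = concordance_index(model.predict_risk(ds.X, task=task), ds.T, E)
    scores = np.zeros(ds.d)
    for j in range(ds.d):
        drops = np.empty(n_repeats)
        Xp = ds.X.copy()
        for rep in range(n_repeats):
            Xp[:, j] = ds.X[rng.permutation(ds.n), j]
            drops[rep] = baseline - concordance_index(
                model.predict_risk(Xp, task=task), ds.T, E)
        scores[j] = drops.mean()
    return pd.Series(scores, index=ds.feature_names, name=task)


def pfi_matrix(model: TrainedModel, ds: SurvivalDataset,
               tasks: list[str] | None = None, n_repeats: int = 10,
               seed: int = 0) -> PFIMatrix:
    """PFI for every task the model predicts (or an explicit task list)."""
    tasks = tasks or list(model.tasks)
    cols, baseline = {}, {}
    for i, t in enumerate(tasks):
        cols[t] = permutation_importance(model, ds, t, n_repeats=n_repeats,
                                         seed=seed + i)
        baseline[t] = concordance_index(model.predict_risk(ds.X, task=t),
                                        ds.T, ds.events_for(t))
    return PFIMatrix(pd.DataFrame(cols), repeats=n_repeats, seed=seed,
                     baseline=baseline)


def plot_heatmap(pfi: PFIMatrix, path, groups: dict | None = None) -> None:
    """Optional convenience heatmap with feature-group separator lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = groups or FEATURE_GROUPS
    order = [f for fs in groups.values() for f in fs if f in pfi.scores.index]
    order += [f for f in pfi.scores.index if f not in order]
    data = pfi.scores.loc[order]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * data.shape[1],
                                    1 + 0.25 * data.shape[0]))
    im = ax.imshow(data.values, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(order)), order, fontsize=7)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45, ha="right")
    pos = 0
    for fs in groups.values():
        pos += sum(f in data.index for f in fs)
        if 0 < pos < len(order):
            ax.axhline(pos - 0.5, color="white", lw=1)
    fig.colorbar(im, ax=ax, label="c-index drop")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
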