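"""Feature selection: mutual-information filter and forward-backward wrapper.

The filter route scores each feature x by the plug-in mutual information
I(x; y) = H(y) - H(y | x) estimated from a histogram of x with round(sqrt(N))
equal-width bins over the observed range (natural log, so scores are in
nats), then ranks features by decreasing score.  MI is clipped at zero;
a constant feature has a single effective bin and scores exactly zero.

The wrapper route is the forward-backward search: starting from the empty
set, each step adds the feature whose inclusion most increases a criterion
(by default the balanced classification rate of a classifier on a
patient-grouped internal validation split), and from the third step onward
a backward pass may remove a previously selected feature if that strictly
improves the criterion.  The search stops when no addition strictly
improves the criterion or when ``max_features`` (default 10) is reached.
The criterion never sees the test patients: model selection uses held-out
*training* patients only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import bcr

__all__ = [
    "MIScore", "SelectionStep", "SelectionTrace",
    "histogram_mi", "rank_by_mi", "forward_backward",
    "make_grouped_bcr_criterion",
]


@dataclass
class MIScore:
    feature_name: str
    mi_nats: float
    n_bins: int


@dataclass
class SelectionStep:
    action: str  # "add" | "remove"
    feature_name: str
    criterion_value: float


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)          # accepted steps
    evaluations: list = field(default_factory=list)    # every candidate tried
    final_set: list = field(default_factory=list)

    def replay(self) -> list:
        s: list = []
        for step in self.steps:
            if step.action == "add":
                s.append(step.feature_name)
            else:
                s.remove(step.feature_name)
        return s


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def histogram_mi(x, y, n_bins: int | None = None, name: str = "") -> MIScore:
    """Histogram plug-in estimate of I(x; y) in nats.

    ``x`` is binned into ``round(sqrt(N))`` equal-width bins over
    [min(x), max(x)]; I = H(y) - sum_b p(b) H(y | b) from empirical
    frequencies, clipped at 0.  A constant ``x`` scores 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have the same length")
    if n < 4:
        raise ValueError("at least 4 samples are required")
    if n_bins is None:
        n_bins = int(round(np.sqrt(n)))
    _, y_codes = np.unique(y, return_inverse=True)
    k = y_codes.max() + 1
    span = x.max() - x.min()
    if span == 0:
        return MIScore(name, 0.0, 1)
    width = span / n_bins
    bins = np.minimum((x - x.min()) // width, n_bins - 1).astype(int)
    joint = np.zeros((n_bins, k))
    np.add.at(joint, (bins, y_codes), 1.0)
    h_y = _entropy(joint.sum(axis=0))
    p_b = joint.sum(axis=1) / n
    h_y_given_x = sum(
        p_b[b] * _entropy(joint[b]) for b in range(n_bins) if p_b[b] > 0
    )
    return MIScore(name, max(0.0, h_y - h_y_given_x), n_bins)


def rank_by_mi(matrix, y) -> pd.DataFrame:
    """Rank features by MI with the labels, descending; ties keep column order.

    ``matrix`` is a FeatureMatrix or a DataFrame (fully imputed).  Returns a
    DataFrame with columns rank, name, mi_nats, n_bins.
    """
    values = matrix.values if hasattr(matrix, "missing_mask") else matrix
    scores = [
        histogram_mi(values[c].to_numpy(), y, name=c) for c in values.columns
    ]
    mi = np.array([s.mi_nats for s in scores])
    order = np.argsort(-mi, kind="stable")
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "name": [scores[j].feature_name for j in order],
            "mi_nats": mi[order],
            "n_bins": [scores[j].n_bins for j in order],
        }
    )


def make_grouped_bcr_criterion(groups, n_folds: int = 4, seed: int = 0):
    """Criterion factory: mean BCR over patient-grouped internal folds.

    The distinct groups (patients) are shuffled once, deterministically
    from ``seed``, and partitioned into ``n_folds`` folds; the criterion
    fits the learner with each fold of patients held out in turn and
    returns the mean BCR over the held-out folds (each computed over the
    classes present there).  Model selection therefore never sees the test
    patients, and averaging over folds keeps the criterion fine-grained
    enough for the strict-improvement rule.
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("at least 2 patient groups are required")
    n_folds = min(n_folds, len(uniq))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_masks = [
        np.isin(groups, uniq[order[f::n_folds]]) for f in range(n_folds)
    ]

    def criterion(learner, X, y) -> float:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        scores = []
        for held in fold_masks:
            learner.fit(X[~held], y[~held])
            pred = learner.predict(X[held])
            scores.append(bcr(y[held], pred))
        return float(np.mean(scores))

    return criterion


def forward_backward(
    matrix, y, learner, criterion, max_features: int = 10
) -> SelectionTrace:
    """Forward-backward wrapper search over the feature columns.

    ``criterion(learner, X_subset, y)`` must be deterministic given the
    data.  Strict (>) improvement is required both to add and to remove,
    which guarantees termination.  A criterion failure aborts the search
    and returns the trace accumulated so far.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    values = matrix.values if hasattr(matrix, "missing_mask") else pd.DataFrame(matrix)
    y = np.asarray(y)
    names = list(values.columns)
    selected: list[str] = []
    current = -np.inf
    trace = SelectionTrace()

    def evaluate(subset) -> float:
        return float(criterion(learner, values[subset].to_numpy(), y))

    while len(selected) < max_features:
        best_feat, best_val = None, -np.inf
        try:
            for f in names:
                if f in selected:
                    continue
                v = evaluate(selected + [f])
                trace.evaluations.append(SelectionStep("add", f, v))
                if v > best_val:
                    best_feat, best_val = f, v
        except Exception:
            trace.final_set = list(selected)
            return trace
        if best_feat is None or not best_val > current:
            break
        selected.append(best_feat)
        current = best_val
        trace.steps.append(SelectionStep("add", best_feat, current))

        if len(selected) >= 3:
            best_rm, best_rm_val = None, current
            try:
                for g in list(selected):
                    v = evaluate([f for f in selected if f != g])
                    trace.evaluations.append(SelectionStep("remove", g, v))
                    if v > best_rm_val:
                        best_rm, best_rm_val = g, v
            except Exception:
                trace.final_set = list(selected)
                return trace
            if best_rm is not None:
                selected.remove(best_rm)
                current = best_rm_val
                trace.steps.append(SelectionStep("remove", best_rm, current))

    trace.final_set = list(selected)
    return trace
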