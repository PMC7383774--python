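"""Case-level k-fold cross-validation with a hard leakage guard.

Splits are made by CASE, never by frame: every frame of a clip shares its
case's fold, and each fold's model is trained only on the other folds'
cases. The guard that no case is ever predicted by a model that saw it in
training is an assertion, not a warning — a violated split is a bug, not a
quality issue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of case ids to folds."""

    k: int
    assignment: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if folds != set(range(self.k)):
            raise ValueError("assignment must use every fold index 0..k-1")

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f == fold)

    def fold_sizes(self) -> list[int]:
        return [len(self.fold_cases(f)) for f in range(self.k)]


class LeakageError(AssertionError):
    """A case was about to be predicted by a model trained on it."""


def make_folds(case_ids: Sequence[str], k: int = 6, seed: int = 0) -> FoldPlan:
    """Randomly partition cases into k near-equal folds (sizes differ <= 1)."""
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("case_ids must be unique")
    if k < 2 or k > len(ids):
        raise ValueError(f"k={k} must be in [2, n_cases={len(ids)}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[int(j)]: i % k for i, j in enumerate(perm)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def run_cv(
    cases: Mapping[str, object],
    plan: FoldPlan,
    train_fn: Callable[[dict, int], object],
    predict_fn: Callable[[object, object], object],
    metric_fn: Callable[[object, object], Mapping[str, float]] | None = None,
):
    """Train one fresh model per fold; predict each case exactly once.

    ``train_fn(train_cases, fold_index)`` returns a fitted model;
    ``predict_fn(model, case)`` returns that case's prediction;
    ``metric_fn(case, prediction)`` (optional) returns per-case metrics,
    which are averaged over cases in the returned summary.

    Returns ``(predictions, metric_means)`` where predictions maps case id
    to its held-out prediction.
    """
    ids = set(cases)
    if ids != set(plan.assignment):
        raise ValueError("plan does not cover exactly the provided cases")

    predictions: dict[str, object] = {}
    per_case_metrics: dict[str, Mapping[str, float]] = {}
    for fold in range(plan.k):
        held = plan.fold_cases(fold)
        train_ids = sorted(ids - set(held))
        model = train_fn({cid: cases[cid] for cid in train_ids}, fold)
        trained_on = frozenset(train_ids)
        for cid in held:
            if cid in trained_on:
                raise LeakageError(
                    f"case {cid!r} would be predicted by the model trained on it"
                )
            if cid in predictions:
                raise LeakageError(f"case {cid!r} predicted more than once")
            predictions[cid] = predict_fn(model, cases[cid])
            if metric_fn is not None:
                per_case_metrics[cid] = metric_fn(cases[cid], predictions[cid])

    metric_means: dict[str, float] = {}
    if metric_fn is not None and per_case_metrics:
        keys = sorted({k for m in per_case_metrics.values() for k in m})
        for key in keys:
            vals = [m[key] for m in per_case_metrics.values()
                    if key in m and np.isfinite(m[key])]
            metric_means[key] = float(np.mean(vals)) if vals else float("nan")
    return predictions, metric_means
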