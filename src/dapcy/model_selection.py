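"""Cross-validation split plans, accuracy scoring, and grid search over
the number of retained principal components."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .dapc_core import fit_dapc, predict
from .errors import (
    FoldError,
    ParameterError,
    ShapeError,
    StratificationError,
)
from .genotype_io import GenotypeMatrix, SampleLabels

__all__ = [
    "SplitPlan",
    "CVResult",
    "GridSearchResult",
    "make_split_plan",
    "accuracy",
    "cross_validate",
    "grid_search_pcs",
    "k_minus_one_pcs",
    "train_fraction_sweep",
]

SCHEMES = ("kfold", "stratified_kfold", "loocv")


@dataclass
class SplitPlan:
    scheme: str
    kcv: int
    seed: int | None
    folds: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        n = sum(len(t) for _, t in self.folds)
        all_test = np.concatenate([t for _, t in self.folds])
        if len(np.unique(all_test)) != n:
            raise ParameterError("test sets overlap")
        for train, test in self.folds:
            union = np.union1d(train, test)
            if len(union) != n or np.intersect1d(train, test).size:
                raise ParameterError("train/test pair does not partition samples")

    @property
    def n_samples(self) -> int:
        return sum(len(t) for _, t in self.folds)


@dataclass
class CVResult:
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    per_fold_predictions: list[tuple[np.ndarray, np.ndarray]]
    plan: SplitPlan
    n_pcs: int

    def __post_init__(self) -> None:
        if abs(self.mean_accuracy - float(np.mean(self.per_fold_accuracy))) > 1e-12:
            raise ParameterError("mean_accuracy inconsistent with folds")


@dataclass
class GridSearchResult:
    grid: list[int]
    table: list[dict]  # {'n_pcs', 'mean_accuracy', 'std_accuracy'}
    best_n_pcs: int
    cv_results: dict[int, CVResult] = field(default_factory=dict)


def _resolve_labels(labels, sample_ids=None) -> np.ndarray:
    if isinstance(labels, SampleLabels):
        if sample_ids is None:
            raise ParameterError("sample_ids required with SampleLabels")
        return labels.for_samples(sample_ids)
    return np.asarray(list(labels), dtype=object).astype(str).astype(object)


def make_split_plan(
    n: int,
    labels=None,
    scheme: str = "stratified_kfold",
    kcv: int = 10,
    seed: int | None = 0,
    sample_ids: Sequence[str] | None = None,
) -> SplitPlan:
    """Build a reproducible train/test fold plan.

    LOOCV ignores ``seed`` and ``kcv`` (each sample is its own test fold);
    the k-fold schemes shuffle with the given seed. Stratified folds keep
    per-fold class counts within one of proportional allocation and
    require every class to have at least ``kcv`` members.
    """
    if scheme not in SCHEMES:
        raise ParameterError(f"scheme must be one of {SCHEMES}")
    if scheme == "loocv":
        idx = np.arange(n)
        folds = [(np.delete(idx, i), np.array([i])) for i in range(n)]
        return SplitPlan(scheme="loocv", kcv=n, seed=None, folds=folds)
    if not 2 <= kcv <= n:
        raise ParameterError(f"kcv={kcv} out of range [2, {n}]")
    if scheme == "stratified_kfold":
        if labels is None:
            raise ParameterError("stratified scheme requires labels")
        y = _resolve_labels(labels, sample_ids)
        if len(y) != n:
            raise ShapeError("labels length does not match n")
        classes, counts = np.unique(y.astype(str), return_counts=True)
        too_small = classes[counts < kcv]
        if too_small.size:
            raise StratificationError(
                f"class {too_small[0]!r} has fewer than kcv={kcv} samples"
            )
        splitter = StratifiedKFold(n_splits=kcv, shuffle=True, random_state=seed)
        folds = [
            (train, test) for train, test in splitter.split(np.zeros(n), y.astype(str))
        ]
    else:
        splitter = KFold(n_splits=kcv, shuffle=True, random_state=seed)
        folds = [(train, test) for train, test in splitter.split(np.zeros(n))]
    return SplitPlan(scheme=scheme, kcv=kcv, seed=seed, folds=folds)


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of exact label matches."""
    t = np.asarray(list(true_labels), dtype=object)
    p = np.asarray(list(predicted_labels), dtype=object)
    if t.shape != p.shape:
        raise ShapeError("label vectors differ in length")
    if t.size == 0:
        raise ParameterError("empty label vectors")
    return float(np.mean(t.astype(str) == p.astype(str)))


def _take_rows(G, idx):
    if isinstance(G, GenotypeMatrix):
        return G.take_samples(idx)
    return G[idx]


def cross_validate(
    G,
    labels,
    n_pcs: int,
    plan: SplitPlan,
    fit_options: dict | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CVResult:
    """Leakage-free cross-validated accuracy of the DAPC classifier.

    For each fold the SVD (including its centering vector) and the
    discriminant model are fitted on the training fold only, then scored
    on the held-out fold.
    """
    fit_options = dict(fit_options or {})
    if isinstance(G, GenotypeMatrix) and sample_ids is None:
        sample_ids = G.sample_ids
    y = _resolve_labels(labels, sample_ids)
    n = len(y)
    if plan.n_samples != n:
        raise ShapeError("plan size does not match number of samples")
    all_classes = set(np.unique(y.astype(str)))

    accs = []
    preds = []
    for fold_no, (train, test) in enumerate(plan.folds):
        train_classes = set(np.unique(y[train].astype(str)))
        lost = all_classes - train_classes
        if lost:
            raise FoldError(
                f"fold {fold_no}: class {sorted(lost)[0]!r} absent from the "
                "training split; use the stratified scheme"
            )
        model = fit_dapc(_take_rows(G, train), y[train], n_pcs, **fit_options)
        pred = predict(model, _take_rows(G, test))
        accs.append(accuracy(y[test], pred))
        preds.append((test, pred))

    accs = np.array(accs)
    return CVResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=0)),
        per_fold_predictions=preds,
        plan=plan,
        n_pcs=n_pcs,
    )


def grid_search_pcs(
    G,
    labels,
    grid: Sequence[int],
    plan: SplitPlan,
    fit_options: dict | None = None,
    sample_ids: Sequence[str] | None = None,
) -> GridSearchResult:
    """Sweep candidate PC counts; keep the full accuracy table.

    Ties in mean accuracy resolve to the smallest candidate (parsimony).
    """
    grid = [int(v) for v in grid]
    if not grid:
        raise ParameterError("grid must be non-empty")
    table = []
    cv_results = {}
    for n_pcs in grid:
        try:
            res = cross_validate(
                G, labels, n_pcs, plan, fit_options, sample_ids=sample_ids
            )
        except (FoldError, ParameterError) as exc:
            raise type(exc)(f"n_pcs={n_pcs}: {exc}") from exc
        cv_results[n_pcs] = res
        table.append(
            {
                "n_pcs": n_pcs,
                "mean_accuracy": res.mean_accuracy,
                "std_accuracy": res.std_accuracy,
            }
        )
    best_acc = max(row["mean_accuracy"] for row in table)
    best_n_pcs = min(
        row["n_pcs"] for row in table if row["mean_accuracy"] == best_acc
    )
    return GridSearchResult(
        grid=grid, table=table, best_n_pcs=best_n_pcs, cv_results=cv_results
    )


def k_minus_one_pcs(k: int) -> int:
    """Retained-PC count under the k-1 criterion for k clusters."""
    if k < 2:
        raise ParameterError("k must be at least 2")
    return k - 1


def train_fraction_sweep(
    G,
    labels,
    fractions: Sequence[float],
    n_pcs: int,
    seed: int = 0,
    fit_options: dict | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[dict]:
    """Accuracy at a range of stratified train fractions.

    A convenience diagnostic: for each fraction, one stratified split is
    drawn, the model is fitted on the training part, and test accuracy is
    reported. Not a cross-validation scheme.
    """
    from sklearn.model_selection import train_test_split

    if isinstance(G, GenotypeMatrix) and sample_ids is None:
        sample_ids = G.sample_ids
    y = _resolve_labels(labels, sample_ids)
    rows = []
    for frac in fractions:
        if not 0 < frac < 1:
            raise ParameterError("fractions must lie in (0, 1)")
        train, test = train_test_split(
            np.arange(len(y)),
            train_size=frac,
            stratify=y.astype(str),
            random_state=seed,
        )
        model = fit_dapc(
            _take_rows(G, train), y[train], n_pcs, **(fit_options or {})
        )
        pred = predict(model, _take_rows(G, test))
        rows.append({"train_fraction": frac, "accuracy": accuracy(y[test], pred)})
    return rows
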