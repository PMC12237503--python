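"""De novo inference of genetic groups: K-means on principal-component
scores with SSE and silhouette evaluation across candidate k."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score as _sk_silhouette

from .errors import ParameterError
from .genotype_io import SampleLabels

__all__ = [
    "ClusterSolution",
    "KSweepResult",
    "fit_kmeans",
    "silhouette_score",
    "sweep_k",
    "labels_from_clusters",
    "suggest_n_pcs",
]


@dataclass
class ClusterSolution:
    k: int
    centroids: np.ndarray  # k x r
    assignments: np.ndarray  # cluster index per sample
    sse: float
    silhouette: float | None
    seed: int | None
    n_init: int

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ParameterError("sse must be non-negative")
        if self.silhouette is not None and not -1 <= self.silhouette <= 1:
            raise ParameterError("silhouette must lie in [-1, 1]")
        if self.assignments.size and self.assignments.max() >= self.k:
            raise ParameterError("assignment index out of range")

    def recompute_sse(self, scores: np.ndarray) -> float:
        """Sum of squared distances to assigned centroids (audit check)."""
        diffs = np.asarray(scores) - self.centroids[self.assignments]
        return float(np.sum(diffs**2))


@dataclass
class KSweepResult:
    table: list[dict]  # {'k', 'sse', 'silhouette'}
    selected_k: int | None
    selection_rule: str
    solutions: dict[int, ClusterSolution]


def fit_kmeans(
    scores: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_init: int = 10,
) -> ClusterSolution:
    """Best-of-``n_init`` Lloyd K-means with k-means++ seeding.

    Deterministic given ``(seed, n_init)``. The silhouette is attached
    when defined (2 <= k < n_samples), otherwise left as None.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ParameterError("scores must be 2-D")
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ParameterError(f"k={k} out of range [2, {n}]")
    if n_init < 1:
        raise ParameterError("n_init must be >= 1")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    sil = None
    if 2 <= k <= n - 1 and len(np.unique(km.labels_)) >= 2:
        sil = silhouette_score(X, km.labels_)
    return ClusterSolution(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        sse=float(km.inertia_),
        silhouette=sil,
        seed=seed,
        n_init=n_init,
    )


def silhouette_score(scores: np.ndarray, assignments) -> float:
    """Mean silhouette coefficient, (b - a) / max(a, b) per sample.

    Singleton clusters contribute 0 by the standard convention.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(assignments)
    if X.shape[0] != y.shape[0]:
        raise ParameterError("assignments length does not match scores")
    if X.shape[0] < 3:
        raise ParameterError("silhouette needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ParameterError("silhouette undefined for a single cluster")
    return float(_sk_silhouette(X, y))


def sweep_k(
    scores: np.ndarray,
    k_range: Sequence[int],
    seed: int | None = 0,
    n_init: int = 10,
    rule: str = "max_silhouette",
) -> KSweepResult:
    """Fit K-means over a sweep of k; always return the full table.

    Under ``max_silhouette`` the selected k attains the maximum mean
    silhouette (smallest k on ties); ``manual`` leaves selection to the
    user and reports only the table. SSE is reported for elbow inspection
    but never auto-thresholded.
    """
    if rule not in ("max_silhouette", "manual"):
        raise ParameterError("rule must be 'max_silhouette' or 'manual'")
    ks = sorted({int(k) for k in k_range})
    if not ks:
        raise ParameterError("k_range must be non-empty")
    table = []
    solutions = {}
    for k in ks:
        try:
            sol = fit_kmeans(scores, k, seed=seed, n_init=n_init)
        except ParameterError as exc:
            raise ParameterError(f"k={k}: {exc}") from exc
        solutions[k] = sol
        table.append({"k": k, "sse": sol.sse, "silhouette": sol.silhouette})
    selected = None
    if rule == "max_silhouette":
        scored = [row for row in table if row["silhouette"] is not None]
        if not scored:
            raise ParameterError("no candidate k has a defined silhouette")
        best = max(row["silhouette"] for row in scored)
        selected = min(row["k"] for row in scored if row["silhouette"] == best)
    return KSweepResult(
        table=table, selected_k=selected, selection_rule=rule, solutions=solutions
    )


def labels_from_clusters(
    solution: ClusterSolution,
    sample_ids: Sequence[str] | None = None,
) -> SampleLabels:
    """Turn cluster assignments into population labels for supervised steps."""
    n = len(solution.assignments)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    if len(sample_ids) != n:
        raise ParameterError("sample_ids length does not match assignments")
    mapping = {
        sid: f"cluster_{c}" for sid, c in zip(sample_ids, solution.assignments)
    }
    return SampleLabels(mapping=mapping)


def suggest_n_pcs(
    explained_variance_fraction: np.ndarray,
    threshold: float = 0.9,
    cap: int = 120,
) -> int:
    """Smallest component count reaching the cumulative-variance threshold.

    A documented heuristic (capped at ``cap``), used as the clustering
    default when the user does not fix the PC count.
    """
    frac = np.asarray(explained_variance_fraction, dtype=float)
    if frac.size == 0:
        raise ParameterError("empty explained-variance vector")
    cum = np.cumsum(frac)
    hit = np.flatnonzero(cum >= threshold)
    n = int(hit[0]) + 1 if hit.size else frac.size
    return min(n, cap)
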