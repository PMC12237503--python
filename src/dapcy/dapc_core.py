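"""The DAPC estimator: truncated-SVD reduction followed by linear
discriminant analysis on the retained components.

The reduction step never materializes a dense centered matrix: column-mean
centering is applied as a rank-one correction inside the matrix-vector
products of the sparse SVD, and again at transform time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, svds

from .errors import ParameterError, ShapeError, SingularScatterError
from .genotype_io import GenotypeMatrix, SampleLabels

__all__ = [
    "PCModel",
    "DAModel",
    "DAPCModel",
    "fit_truncated_svd",
    "transform_pcs",
    "fit_lda",
    "fit_dapc",
    "predict",
    "predict_proba",
    "discriminant_scores",
]

_RIDGE_GAMMA = 1e-6


@dataclass
class PCModel:
    """Fitted rank-r decomposition of the (optionally centered) dosage matrix."""

    r: int
    loadings: np.ndarray  # n_variants x r, orthonormal columns
    singular_values: np.ndarray  # non-increasing, positive
    explained_variance_fraction: np.ndarray
    center: np.ndarray | None
    centering_mode: str  # 'none' | 'implicit'

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(s) > 1e-10 * max(s[0], 1.0) if s.size else False):
            raise ParameterError("singular values must be non-increasing")
        if self.explained_variance_fraction.sum() > 1 + 1e-8:
            raise ParameterError("explained variance fractions sum above 1")
        if self.centering_mode not in ("none", "implicit"):
            raise ParameterError("centering_mode must be 'none' or 'implicit'")

    @property
    def n_variants(self) -> int:
        return self.loadings.shape[0]


@dataclass
class DAModel:
    """Fisher discriminant axes plus the shared-covariance Gaussian class model."""

    k: int
    class_labels: list[str]
    discriminant_axes: np.ndarray  # r x a, a <= min(k-1, r)
    class_means: np.ndarray  # k x r (principal-component space)
    class_priors: np.ndarray  # simplex
    pooled_within_scatter: np.ndarray  # r x r, SPD up to regularization

    def __post_init__(self) -> None:
        r = self.class_means.shape[1]
        a = self.discriminant_axes.shape[1]
        if a > min(self.k - 1, r):
            raise ParameterError("too many discriminant axes")
        if abs(self.class_priors.sum() - 1.0) > 1e-9:
            raise ParameterError("class priors must sum to 1")
        asym = np.abs(
            self.pooled_within_scatter - self.pooled_within_scatter.T
        ).max()
        if asym > 1e-10:
            raise ParameterError("pooled within-class scatter must be symmetric")

    @property
    def n_axes(self) -> int:
        return self.discriminant_axes.shape[1]


@dataclass
class DAPCModel:
    pc_model: PCModel
    da_model: DAModel
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pc_model.r != self.da_model.class_means.shape[1]:
            raise ShapeError(
                "PC model rank does not match discriminant feature dimension"
            )


def _as_matrix(G):
    """Accept a GenotypeMatrix, sparse matrix, or dense array."""
    if isinstance(G, GenotypeMatrix):
        if G.n_missing:
            raise ParameterError(
                "matrix has missing calls; run impute_missing first"
            )
        return G.dosages
    if sparse.issparse(G):
        return G.tocsr()
    return np.asarray(G, dtype=float)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def _randomized_svd_centered(X, center, r, rng, n_oversample=10, n_power=7):
    """Halko-style randomized SVD with the centering applied implicitly."""
    n, p = X.shape
    q = min(r + n_oversample, min(n, p))

    def right(M):  # (X - 1 c^T) @ M
        Y = np.asarray(X @ M)
        if center is not None:
            Y = Y - np.ones((n, 1)) @ (center @ M)[None, :]
        return Y

    def left(M):  # (X - 1 c^T)^T @ M
        Y = np.asarray(X.T @ M)
        if center is not None:
            Y = Y - center[:, None] @ M.sum(axis=0)[None, :]
        return Y

    Q = np.linalg.qr(right(rng.standard_normal((p, q))))[0]
    for _ in range(n_power):
        Q = np.linalg.qr(left(Q))[0]
        Q = np.linalg.qr(right(Q))[0]
    B = left(Q).T  # q x p
    _, s, vt = np.linalg.svd(B, full_matrices=False)
    return s[:r], vt[:r]


def fit_truncated_svd(
    G,
    r: int,
    centering_mode: str = "implicit",
    seed: int | None = None,
    solver: str = "exact",
) -> PCModel:
    """Top-r right singular vectors of the (column-centered) dosage matrix.

    Parameters
    ----------
    G : GenotypeMatrix or array-like
        Complete (no missing calls) samples x variants matrix.
    r : int
        Number of components; at most ``min(n, p)`` minus one when centering.
    centering_mode : {'implicit', 'none'}
        Implicit column-mean centering restores classical PCA semantics
        without densifying; 'none' decomposes the raw matrix.
    seed : int, optional
        Seeds the Lanczos start vector (and the randomized solver).
    solver : {'exact', 'randomized'}
        Exact ARPACK-style iteration by default; the randomized solver
        requires a seed.
    """
    X = _as_matrix(G)
    n, p = X.shape
    if centering_mode not in ("none", "implicit"):
        raise ParameterError("centering_mode must be 'none' or 'implicit'")
    if solver not in ("exact", "randomized"):
        raise ParameterError("solver must be 'exact' or 'randomized'")
    if solver == "randomized" and seed is None:
        raise ParameterError("randomized solver requires a seed")
    # column centering removes one dimension from the row space only
    max_r = min(n - (1 if centering_mode == "implicit" else 0), p)
    if not 1 <= r <= max_r:
        raise ParameterError(
            f"r={r} out of range [1, {max_r}] for a {n}x{p} matrix "
            f"with centering_mode={centering_mode!r}"
        )

    center = None
    if centering_mode == "implicit":
        center = np.asarray(X.mean(axis=0)).ravel()

    # total sum of squares of the (centered) matrix, computed sparsely
    if sparse.issparse(X):
        sq = float((X.multiply(X)).sum())
    else:
        sq = float((X * X).sum())
    if center is not None:
        total_ss = sq - n * float(center @ center)
    else:
        total_ss = sq
    total_ss = max(total_ss, 0.0)

    if total_ss <= 1e-12 * max(n * p, 1):
        warnings.warn(
            "matrix is (near-)constant after centering; no components returned",
            RuntimeWarning,
        )
        return PCModel(
            r=0,
            loadings=np.zeros((p, 0)),
            singular_values=np.zeros(0),
            explained_variance_fraction=np.zeros(0),
            center=center,
            centering_mode=centering_mode,
        )

    if r < min(n, p):
        if center is not None:
            c = center

            def matvec(v):
                v = np.asarray(v).ravel()
                return np.asarray(X @ v).ravel() - float(c @ v)

            def rmatvec(u):
                u = np.asarray(u).ravel()
                return np.asarray(X.T @ u).ravel() - c * float(u.sum())

            op = LinearOperator((n, p), matvec=matvec, rmatvec=rmatvec)
        else:
            op = X
        rng = np.random.default_rng(0 if seed is None else seed)
        if solver == "randomized":
            s, vt = _randomized_svd_centered(X, center, r, rng)
        else:
            _, s, vt = svds(op, k=r, v0=rng.standard_normal(min(n, p)))
        order = np.argsort(s)[::-1]
        s = s[order]
        loadings = vt[order].T
    else:
        Xd = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        if center is not None:
            Xd = Xd - center
        _, s_full, vt_full = np.linalg.svd(Xd, full_matrices=False)
        s = s_full[:r]
        loadings = vt_full[:r].T

    # drop numerically null components (rank deficiency)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    if not keep.all():
        warnings.warn(
            f"rank-deficient matrix: returning {int(keep.sum())} of {r} "
            "requested components",
            RuntimeWarning,
        )
        s = s[keep]
        loadings = loadings[:, keep]

    loadings = _fix_signs(np.asarray(loadings))
    frac = (s**2) / total_ss
    return PCModel(
        r=int(s.size),
        loadings=loadings,
        singular_values=s,
        explained_variance_fraction=frac,
        center=center,
        centering_mode=centering_mode,
    )


def transform_pcs(pc: PCModel, G) -> np.ndarray:
    """Project samples onto the retained components.

    Centering is applied implicitly: ``scores = G @ L - center @ L``.
    """
    X = _as_matrix(G)
    if X.shape[1] != pc.n_variants:
        raise ShapeError(
            f"matrix has {X.shape[1]} variants, model expects {pc.n_variants}"
        )
    scores = X @ pc.loadings
    scores = np.asarray(scores)
    if pc.center is not None:
        scores = scores - pc.center @ pc.loadings
    return scores


def _resolve_labels(labels, sample_ids=None) -> np.ndarray:
    if isinstance(labels, SampleLabels):
        if sample_ids is None:
            raise ParameterError(
                "sample_ids required when labels is a SampleLabels mapping"
            )
        return labels.for_samples(sample_ids)
    return np.asarray(list(labels), dtype=object)


def fit_lda(
    scores: np.ndarray,
    labels,
    sample_ids: Sequence[str] | None = None,
) -> DAModel:
    """Fisher discriminant analysis on component scores.

    Solves the generalized eigenproblem of between- over within-class
    scatter and keeps at most ``k - 1`` axes. Priors default to empirical
    class frequencies. A singular within-class scatter triggers one ridge
    retry (``gamma * trace(Sw)/r`` on the diagonal) before failing.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ShapeError("scores must be a 2-D sample x component array")
    y = _resolve_labels(labels, sample_ids)
    if len(y) != X.shape[0]:
        raise ShapeError("labels length does not match score rows")
    n, r = X.shape
    if r < 1:
        raise ParameterError("need at least one component")

    classes, y_idx = np.unique(y.astype(str), return_inverse=True)
    k = len(classes)
    if k < 2:
        raise ParameterError("supervised fit requires at least 2 classes")
    counts = np.bincount(y_idx, minlength=k)
    if counts.min() < 2:
        small = classes[np.argmin(counts)]
        raise SingularScatterError(
            f"class {small!r} has a single sample; within-class scatter is "
            "singular. Reduce the number of retained components or merge "
            "classes."
        )

    grand_mean = X.mean(axis=0)
    means = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
    Sw = np.zeros((r, r))
    for c in range(k):
        D = X[y_idx == c] - means[c]
        Sw += D.T @ D
    Sw /= n - k
    Sw = (Sw + Sw.T) / 2
    Sb = np.zeros((r, r))
    for c in range(k):
        d = (means[c] - grand_mean)[:, None]
        Sb += counts[c] * (d @ d.T)
    Sb = (Sb + Sb.T) / 2

    def _solve(Sw_reg):
        w, v = sla.eigh(Sb, Sw_reg)
        if not np.all(np.isfinite(w)):
            raise sla.LinAlgError("non-finite eigenvalues")
        return w, v

    try:
        eigvals, eigvecs = _solve(Sw)
    except sla.LinAlgError:
        ridge = _RIDGE_GAMMA * np.trace(Sw) / r
        try:
            eigvals, eigvecs = _solve(Sw + ridge * np.eye(r))
        except sla.LinAlgError as exc:
            raise SingularScatterError(
                "within-class scatter is singular even after ridge "
                "regularization; reduce the number of retained components"
            ) from exc

    a = min(k - 1, r)
    order = np.argsort(eigvals)[::-1][:a]
    axes = _fix_signs(eigvecs[:, order])

    return DAModel(
        k=k,
        class_labels=[str(c) for c in classes],
        discriminant_axes=axes,
        class_means=means,
        class_priors=counts / n,
        pooled_within_scatter=Sw,
    )


def fit_dapc(
    G,
    labels,
    n_pcs: int,
    sample_ids: Sequence[str] | None = None,
    centering_mode: str = "implicit",
    seed: int | None = None,
    solver: str = "exact",
) -> DAPCModel:
    """Full pipeline: truncated SVD then discriminant analysis."""
    if isinstance(G, GenotypeMatrix) and sample_ids is None:
        sample_ids = G.sample_ids
    pc = fit_truncated_svd(
        G, n_pcs, centering_mode=centering_mode, seed=seed, solver=solver
    )
    scores = transform_pcs(pc, G)
    da = fit_lda(scores, labels, sample_ids=sample_ids)
    X = _as_matrix(G)
    return DAPCModel(
        pc_model=pc,
        da_model=da,
        provenance={
            "n_samples": int(X.shape[0]),
            "n_variants": int(X.shape[1]),
            "n_pcs": int(pc.r),
            "centering_mode": centering_mode,
            "solver": solver,
            "seed": seed,
        },
    )


def _log_posteriors(da: DAModel, scores: np.ndarray) -> np.ndarray:
    """Unnormalized log membership under the shared-covariance Gaussian."""
    Sw = da.pooled_within_scatter
    try:
        factor = sla.cho_factor(Sw)

        def solve(M):
            return sla.cho_solve(factor, M)

    except sla.LinAlgError:
        ridge = _RIDGE_GAMMA * np.trace(Sw) / Sw.shape[0]
        factor = sla.cho_factor(Sw + ridge * np.eye(Sw.shape[0]))

        def solve(M):
            return sla.cho_solve(factor, M)

    A = solve(da.class_means.T)  # r x k
    lin = scores @ A
    quad = 0.5 * np.einsum("kr,rk->k", da.class_means, A)
    return lin - quad + np.log(da.class_priors)


def predict_proba(model: DAPCModel, G) -> np.ndarray:
    """Posterior membership probabilities, one simplex row per sample."""
    scores = transform_pcs(model.pc_model, G)
    logp = _log_posteriors(model.da_model, scores)
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def predict(model: DAPCModel, G) -> np.ndarray:
    """Most probable class label per sample (ties -> first in label order)."""
    probs = predict_proba(model, G)
    idx = np.argmax(probs, axis=1)
    labels = np.array(model.da_model.class_labels, dtype=object)
    return labels[idx]


def discriminant_scores(model: DAPCModel, G) -> np.ndarray:
    """Coordinates on the discriminant axes (for plotting)."""
    scores = transform_pcs(model.pc_model, G)
    return scores @ model.da_model.discriminant_axes
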