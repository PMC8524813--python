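"""Sample-level structure: scaling, PCA, binomial dissimilarity, PERMANOVA.

PCA is run on row-scaled (per-element z-scored) log2 FC values with samples
as observations, restricted upstream to autosomal elements.  Group structure
(karyotype, developmental stage) is tested with PERMANOVA on a binomial
dissimilarity matrix computed from the raw non-negative FC values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "scale_rows",
    "pca",
    "binomial_distance",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    data: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.data = np.maximum(d, 0.0)
        if len(self.labels) != d.shape[0]:
            raise ValueError("label count must match matrix size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


def scale_rows(matrix: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame | np.ndarray, list]:
    """Center each row to mean 0 and scale to unit variance (ddof=1).

    Zero-variance rows become all-zero and are returned in the flag list.
    Idempotent on already-scaled input.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd[flat] = 1.0
    Z = (X - mu) / sd
    Z[flat] = 0.0
    flagged = list(np.asarray(matrix.index if is_df else np.arange(X.shape[0]))[flat])
    if is_df:
        Z = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z, flagged


def pca(matrix: pd.DataFrame | np.ndarray, n_components: int | None = None):
    """SVD-based PCA with samples as rows (observations).

    Returns (scores, loadings, variance_explained).  variance_explained sums
    to 1 over the full rank; the sign of each component is fixed so that its
    largest-magnitude loading is positive (determinism).
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if n_components is None:
        n_components = rank if rank > 0 else 1
    n_components = min(n_components, max(rank, 1))
    total = (S**2).sum()
    var_exp = (S[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    if is_df:
        comp = [f"PC{i + 1}" for i in range(n_components)]
        scores = pd.DataFrame(scores, index=matrix.index, columns=comp)
        loadings = pd.DataFrame(loadings, index=matrix.columns, columns=comp)
    return scores, loadings, var_exp


def binomial_distance(matrix: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Binomial dissimilarity between sample rows of a non-negative matrix.

    For samples x, y and feature i with n_i = x_i + y_i:

        d(x, y) = sum_i [ x_i log(x_i/n_i) + y_i log(y_i/n_i) + n_i log 2 ] / n_i

    with 0 log 0 := 0 and features where n_i = 0 contributing 0.  This is the
    binomial index of ecological dissimilarity (the expected deviance of an
    even split of n_i between the two samples); it requires non-negative,
    count-like input, which the clamped log2 FC values satisfy.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("binomial distance requires non-negative input")
    labels = list(matrix.index) if is_df else [str(i) for i in range(X.shape[0])]
    m = X.shape[0]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = _binomial_pair(X[i], X[j])
    return DistanceMatrix(data=D, labels=labels)


def _binomial_pair(x: np.ndarray, y: np.ndarray) -> float:
    n = x + y
    mask = n > 0
    x, y, n = x[mask], y[mask], n[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / n), 0.0)
        ty = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / n), 0.0)
    terms = (tx + ty + n * math.log(2.0)) / n
    return float(np.maximum(terms, 0.0).sum())


def _pseudo_f(D2: np.ndarray, groups: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances via the Gower partition.

    SS_total = sum of squared distances / n; SS_within = the same computed
    within each group; F = (SS_among/(a-1)) / (SS_within/(n-a)).
    """
    n = D2.shape[0]
    uniq = np.unique(groups)
    a = len(uniq)
    ss_t = D2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    if ss_w <= 0:
        return math.inf if ss_a > 0 else 0.0
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    method: str = "random",
) -> tuple[float, float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns (pseudo-F, R2, p).  ``method="random"`` permutes sample labels
    ``n_perm`` times and reports p = (1 + #{F_perm >= F_obs}) / (1 + n_perm);
    ``method="exhaustive"`` enumerates every permutation of the sample order
    and reports the exact fraction with F_perm >= F_obs (identity included).
    """
    if isinstance(groups, (pd.Series, dict)):
        g = pd.Series(groups).loc[dist.labels].to_numpy()
    else:
        g = np.asarray(groups)
    if len(g) != len(dist.labels):
        raise ValueError("group vector length must match distance matrix")
    if len(np.unique(g)) < 2:
        raise ValueError("PERMANOVA requires >= 2 groups")
    D2 = dist.data**2
    n = D2.shape[0]
    f_obs = _pseudo_f(D2, g)
    ss_t = D2[np.triu_indices(n, 1)].sum() / n
    uniq = np.unique(g)
    ss_w = 0.0
    for gg in uniq:
        idx = np.flatnonzero(g == gg)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    r2 = (ss_t - ss_w) / ss_t if ss_t > 0 else 0.0

    if method == "exhaustive":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if _pseudo_f(D2, g[list(perm)]) >= f_obs - 1e-12:
                count += 1
        p = count / total
    elif method == "random":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if _pseudo_f(D2, rng.permutation(g)) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    else:
        raise ValueError("method must be 'random' or 'exhaustive'")
    return float(f_obs), float(r2), float(p)
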