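"""Comparison feature selectors: LASSO against the target, and mRMR ranking.

Both explore only feature–target associations (per block), unlike the
three-term sparse CCA which additionally couples the two blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import KFold

__all__ = [
    "RankedSelection",
    "lasso_select",
    "mutual_information",
    "mrmr_rank",
]


@dataclass
class RankedSelection:
    """mRMR output: features in selection order with their FS scores."""

    order: list[int]
    fs_scores: list[float]
    method: str
    k_requested: int

    def __post_init__(self) -> None:
        if len(self.order) != len(self.fs_scores):
            raise ValueError("order and fs_scores must have the same length")

    def top(self, k: int | None = None) -> list[int]:
        return self.order if k is None else self.order[:k]

    def above_threshold(self, threshold: float) -> list[int]:
        """Leading features whose FS score stays above ``threshold``."""
        out = []
        for idx, score in zip(self.order, self.fs_scores):
            if score <= threshold:
                break
            out.append(idx)
        return out


def lasso_select(F: np.ndarray, Z: np.ndarray, inner_cv_seed: int = 0) -> np.ndarray:
    """Indices with non-zero coefficients in an l1-penalized regression of Z on F.

    The penalty is chosen by internal 5-fold CV (minimum mean squared
    error) over 50 log-spaced values descending from the smallest
    penalty that zeroes every coefficient. An empty selection is a legal
    outcome.
    """
    F = np.asarray(F, dtype=float)
    Z = np.asarray(Z, dtype=float).ravel()
    if F.ndim != 2 or F.shape[0] != Z.size:
        raise ValueError("F must be n×m with n matching Z")
    n = F.shape[0]
    Zc = Z - Z.mean()
    alpha_max = np.max(np.abs(F.T @ Zc)) / n
    if alpha_max <= 0:
        return np.array([], dtype=int)
    alphas = np.geomspace(alpha_max, alpha_max * 1e-3, 50)
    cv = KFold(n_splits=5, shuffle=True, random_state=inner_cv_seed)
    model = LassoCV(alphas=alphas, cv=cv, max_iter=50000)
    model.fit(F, Z)
    # refit at the selected penalty on all rows; LassoCV already does this
    return np.flatnonzero(np.abs(model.coef_) > 0)


def _discretize(x: np.ndarray) -> np.ndarray:
    """3-level coding at mean ± 0.5·sd for continuous input; small-alphabet
    integer data (e.g. allele counts) is used as-is."""
    x = np.asarray(x, dtype=float).ravel()
    ints = np.all(np.isfinite(x)) and np.all(x == np.round(x))
    if ints and np.unique(x).size <= 5:
        return x.astype(int)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.zeros(x.size, dtype=int)
    codes = np.zeros(x.size, dtype=int)
    codes[x > mu + 0.5 * sd] = 2
    codes[(x >= mu - 0.5 * sd) & (x <= mu + 0.5 * sd)] = 1
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) on jointly discretized data."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    return float(mutual_info_score(_discretize(x), _discretize(y)))


def mrmr_rank(
    F: np.ndarray, Z: np.ndarray, k: int, use_redundancy: bool = True
) -> RankedSelection:
    """Greedy minimum-redundancy–maximum-relevance ranking (MID variant).

    The first feature maximizes relevance MI(f, Z); each subsequent
    feature maximizes FS = MI(f, Z) − mean_{s selected} MI(f, s). Ties
    break toward the lower feature index. With ``use_redundancy=False``
    the ranking degenerates to a plain sort by relevance.
    """
    F = np.asarray(F, dtype=float)
    Z = np.asarray(Z, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be at least 1")
    m = F.shape[1]
    if k > m:
        import warnings

        warnings.warn(f"k={k} exceeds the {m} available features; truncating")
        k = m
    codes = [_discretize(F[:, j]) for j in range(m)]
    z_codes = _discretize(Z)
    relevance = np.array([mutual_info_score(c, z_codes) for c in codes])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(m)
    remaining = set(range(m))
    for step in range(k):
        if step == 0 or not use_redundancy:
            fs = relevance.copy()
        else:
            fs = relevance - redundancy_sum / step
        cand = sorted(remaining)
        j_best = cand[int(np.argmax(fs[cand]))]  # argmax picks the first (lowest index) tie
        selected.append(j_best)
        scores.append(float(fs[j_best]))
        remaining.discard(j_best)
        mi_new = np.array([mutual_info_score(codes[j], codes[j_best]) for j in range(m)])
        redundancy_sum += mi_new
    return RankedSelection(order=selected, fs_scores=scores, method="mrmr-mid", k_requested=k)
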