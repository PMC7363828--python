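"""Fold construction, inner-CV penalty tuning, feature selection, nested-CV driver.

The tuning criterion is the mean, over inner validation folds, of the
average of the three held-out Pearson correlations

    (1/3) [ corr(Xᵢu₋ᵢ, Yᵢv₋ᵢ) + corr(Xᵢu₋ᵢ, Zᵢ) + corr(Yᵢv₋ᵢ, Zᵢ) ]

where (u₋ᵢ, v₋ᵢ) are fitted on everything except fold i. A held-out
projection with zero variance (over-shrunk penalties) contributes 0 to
its term, so such penalty pairs remain valid but unattractive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import lasso_select, mrmr_rank
from .data import Dataset, impute_and_standardize
from .prediction import (
    ModelMetrics,
    evaluate_fold,
    evaluate_models,
    mean_baseline,
    train_rf,
)
from .solver import (
    CanonicalSolution,
    OsSccaConfig,
    _fit_from_crossprods,
    _svd_init,
    fit_oscca,
)

__all__ = [
    "FoldSplit",
    "TuningResult",
    "NestedCvConfig",
    "FoldResult",
    "NestedCvResult",
    "make_folds",
    "default_lambda_grid",
    "cv_score",
    "tune_lambdas",
    "select_features",
    "consensus_features",
    "run_nested_cv",
]


@dataclass(frozen=True)
class FoldSplit:
    """Deterministic k-fold assignment; fold sizes differ by at most one."""

    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignment, minlength=self.k)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def folds(self):
        """Yield (train_idx, test_idx) per fold."""
        for i in range(self.k):
            test = np.flatnonzero(self.assignment == i)
            train = np.flatnonzero(self.assignment != i)
            yield train, test


def make_folds(
    n: int, k: int, seed: int = 0, stratify_on: np.ndarray | None = None
) -> FoldSplit:
    """Seeded balanced fold assignment, optionally quartile-stratified.

    With ``stratify_on``, subjects are sorted by the covariate and fold
    labels are dealt randomly within consecutive blocks of k, balancing
    the covariate across folds.
    """
    if not (2 <= k <= n):
        raise ValueError("need n >= k >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify_on is None:
        perm = rng.permutation(n)
        assignment[perm] = np.arange(n) % k
    else:
        values = np.asarray(stratify_on, dtype=float).ravel()
        if values.size != n:
            raise ValueError("stratify_on must have length n")
        order = np.argsort(values + 1e-12 * rng.standard_normal(n), kind="stable")
        for start in range(0, n, k):
            block = order[start : start + k]
            labels = rng.permutation(k)[: block.size]
            assignment[block] = labels
    return FoldSplit(k=k, assignment=assignment, seed=seed)


@dataclass
class TuningResult:
    """Grid of penalty pairs with their inner-CV scores and the chosen pair."""

    pairs: list[tuple[float, float]]
    mean_scores: np.ndarray
    per_fold_scores: np.ndarray  # n_pairs × k
    best_pair: tuple[float, float]
    rule: str


def _prepare_inner_folds(X, Y, Z, split: FoldSplit):
    """Per-fold training cross-products and standardized validation blocks."""
    preps = []
    for train, val in split.folds():
        if val.size < 3:
            raise ValueError("each validation fold needs at least 3 subjects")
        Xtr, xs = impute_and_standardize(X[train])
        Ytr, ys = impute_and_standardize(Y[train])
        Ztr, zs = impute_and_standardize(Z[train])
        Xva, _ = impute_and_standardize(X[val], xs)
        Yva, _ = impute_and_standardize(Y[val], ys)
        ztr = Ztr[:, 0]
        C = Xtr.T @ Ytr
        preps.append(
            {
                "C": C,
                "v_svd": _svd_init(C),
                "xz": Xtr.T @ ztr,
                "yz": Ytr.T @ ztr,
                "Xva": Xva,
                "Yva": Yva,
                "Zva": Z[val],
            }
        )
    return preps


def _corr_or_zero(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either side has zero variance."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _score_pair(preps, lambda_u, lambda_v, base: OsSccaConfig):
    """Mean validation score across inner folds for one penalty pair."""
    cfg = OsSccaConfig(
        lambda_u=lambda_u,
        lambda_v=lambda_v,
        w=base.w,
        max_iter=base.max_iter,
        tol=base.tol,
        init=base.init,
        seed=base.seed,
    )
    fold_scores = []
    any_nonzero = False
    for prep in preps:
        u, v, _, _, _ = _fit_from_crossprods(
            prep["C"], prep["xz"], prep["yz"], cfg, v_svd=prep["v_svd"]
        )
        if np.any(u) or np.any(v):
            any_nonzero = True
        xu = prep["Xva"] @ u
        yv = prep["Yva"] @ v
        z = prep["Zva"]
        score = (
            _corr_or_zero(xu, yv) + _corr_or_zero(xu, z) + _corr_or_zero(yv, z)
        ) / 3.0
        fold_scores.append(score)
    return np.array(fold_scores), any_nonzero


def cv_score(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    lambda_u: float,
    lambda_v: float,
    w: float = 1.0,
    inner_folds: FoldSplit | None = None,
    k: int = 5,
    seed: int = 0,
    base_config: OsSccaConfig | None = None,
) -> float:
    """Inner-CV tuning score for one (λ_u, λ_v) pair (mean over folds)."""
    X, Y, Z = np.asarray(X, float), np.asarray(Y, float), np.asarray(Z, float).ravel()
    split = inner_folds if inner_folds is not None else make_folds(X.shape[0], k, seed)
    base = base_config if base_config is not None else OsSccaConfig(w=w)
    if base.w != w:
        base = OsSccaConfig(
            w=w, max_iter=base.max_iter, tol=base.tol, init=base.init, seed=base.seed
        )
    preps = _prepare_inner_folds(X, Y, Z, split)
    fold_scores, _ = _score_pair(preps, lambda_u, lambda_v, base)
    return float(fold_scores.mean())


def default_lambda_grid(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    w: float = 1.0,
    num: int = 8,
    min_frac: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Data-adaptive log-spaced penalty grids spanning [min_frac·g*, g*].

    g* is the sup-norm of the initial block gradient; at λ = g* the
    first update already zeroes the corresponding loading vector.
    """
    from .solver import _svd_init, update_loading

    X, Y, Z = np.asarray(X, float), np.asarray(Y, float), np.asarray(Z, float).ravel()
    C = X.T @ Y
    xz = X.T @ Z
    yz = Y.T @ Z
    v0 = _svd_init(C)
    gu = C @ v0 + w * xz
    u0 = update_loading(gu, 0.0)
    gv = C.T @ u0 + w * yz
    gu_max = max(float(np.max(np.abs(gu))), 1e-12)
    gv_max = max(float(np.max(np.abs(gv))), 1e-12)
    return (
        np.geomspace(min_frac * gu_max, gu_max, num),
        np.geomspace(min_frac * gv_max, gv_max, num),
    )


def tune_lambdas(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    grid_u: np.ndarray,
    grid_v: np.ndarray,
    w: float = 1.0,
    k: int = 5,
    seed: int = 0,
    base_config: OsSccaConfig | None = None,
    rule: str = "mean-score",
) -> TuningResult:
    """Choose (λ_u, λ_v) on a grid by inner cross-validation.

    ``rule='mean-score'`` (default) picks the pair maximizing the score
    averaged over inner folds, ties broken toward the sparser model
    (larger λ_u + λ_v). ``rule='mean-score-1se'`` picks the sparsest
    pair whose mean score is within one standard error of the maximum
    (the usual parsimony rule; the mean score is often nearly flat in
    the penalties, so the plain argmax tends to over-select).
    ``rule='average-lambda'`` averages each fold's best pair — an
    alternative reading of choosing "the average as the
    hyperparameters".
    """
    if rule not in ("mean-score", "mean-score-1se", "average-lambda"):
        raise ValueError("rule must be 'mean-score', 'mean-score-1se' or 'average-lambda'")
    grid_u = np.atleast_1d(np.asarray(grid_u, dtype=float))
    grid_v = np.atleast_1d(np.asarray(grid_v, dtype=float))
    if grid_u.size == 0 or grid_v.size == 0:
        raise ValueError("penalty grids must be non-empty")
    X, Y, Z = np.asarray(X, float), np.asarray(Y, float), np.asarray(Z, float).ravel()
    split = make_folds(X.shape[0], k, seed)
    base = base_config if base_config is not None else OsSccaConfig(w=w)
    preps = _prepare_inner_folds(X, Y, Z, split)

    pairs = list(product(grid_u, grid_v))
    per_fold = np.zeros((len(pairs), split.k))
    degenerate = np.zeros(len(pairs), dtype=bool)
    for i, (lu, lv) in enumerate(pairs):
        scores, any_nonzero = _score_pair(preps, lu, lv, base)
        per_fold[i] = scores
        degenerate[i] = not any_nonzero
    if degenerate.all():
        raise ValueError(
            "every grid pair produced all-zero loadings; use a smaller penalty grid"
        )
    mean_scores = per_fold.mean(axis=1)

    def _argbest(scores: np.ndarray) -> int:
        best = scores.max()
        cand = [i for i in range(len(pairs)) if scores[i] >= best - 1e-12]
        return max(cand, key=lambda i: (pairs[i][0] + pairs[i][1], pairs[i]))

    if rule == "mean-score":
        best_pair = pairs[_argbest(mean_scores)]
    elif rule == "mean-score-1se":
        i_best = _argbest(mean_scores)
        se = per_fold[i_best].std(ddof=1) / np.sqrt(split.k)
        ok = np.flatnonzero(mean_scores >= mean_scores[i_best] - se)
        j = max(ok, key=lambda i: (pairs[i][0] + pairs[i][1], pairs[i]))
        best_pair = pairs[j]
    else:
        per_fold_best = [pairs[_argbest(per_fold[:, j])] for j in range(split.k)]
        best_pair = tuple(np.mean(per_fold_best, axis=0))
    return TuningResult(
        pairs=[(float(a), float(b)) for a, b in pairs],
        mean_scores=mean_scores,
        per_fold_scores=per_fold,
        best_pair=(float(best_pair[0]), float(best_pair[1])),
        rule=rule,
    )


def select_features(solution: CanonicalSolution) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the non-zero canonical loadings (imaging, genetic)."""
    return np.flatnonzero(solution.u != 0.0), np.flatnonzero(solution.v != 0.0)


def consensus_features(selections: list) -> list[int]:
    """Features selected in every fold, in original index order."""
    if not selections:
        raise ValueError("need at least one selection")
    common = set(int(i) for i in selections[0])
    for sel in selections[1:]:
        common &= set(int(i) for i in sel)
    return sorted(common)


# ---------------------------------------------------------------------------
# nested cross-validation driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NestedCvConfig:
    """Settings for the nested CV pipeline (defaults follow the study design:
    5 outer × 5 inner folds, w = 1, 500 regression trees)."""

    outer_k: int = 5
    inner_k: int = 5
    w: float = 1.0
    grid_size: int = 8
    grid_min_frac: float = 0.01
    max_iter: int = 100
    tol: float = 1e-6
    init: str = "cross-product-svd"
    n_trees: int = 500
    seed: int = 0
    tuning_rule: str = "mean-score"
    model_kinds: tuple[str, ...] = ("imaging", "genetic", "combined")
    baselines: tuple[str, ...] = ()
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("fold counts must be at least 2")
        bad = set(self.baselines) - {"lasso", "mrmr"}
        if bad:
            raise ValueError(f"unknown baselines: {sorted(bad)}")
        bad = set(self.model_kinds) - {"imaging", "genetic", "combined"}
        if bad:
            raise ValueError(f"unknown model kinds: {sorted(bad)}")


@dataclass
class FoldResult:
    fold_index: int
    test_idx: np.ndarray
    lambda_u: float
    lambda_v: float
    solution: CanonicalSolution
    imaging_selected: list[int]
    genetic_selected: list[int]
    metrics: dict[str, ModelMetrics]
    predictions: dict[str, np.ndarray]
    actual: np.ndarray
    baseline_selections: dict[str, dict[str, list[int]]] = field(default_factory=dict)


@dataclass
class NestedCvResult:
    folds: list[FoldResult]
    consensus_imaging: list[int]
    consensus_genetic: list[int]
    averaged: dict[str, ModelMetrics]
    config: NestedCvConfig
    imaging_names: list[str]
    variant_names: list[str]

    def to_dict(self) -> dict:
        def _m(m: ModelMetrics) -> dict:
            return {
                "pearson_r": m.pearson_r,
                "pearson_p": m.pearson_p,
                "rmse": m.rmse,
                "n_test": m.n_test,
            }

        return {
            "consensus_imaging": [self.imaging_names[i] for i in self.consensus_imaging],
            "consensus_genetic": [self.variant_names[i] for i in self.consensus_genetic],
            "averaged": {k: _m(m) for k, m in self.averaged.items()},
            "folds": [
                {
                    "fold": f.fold_index,
                    "lambda_u": f.lambda_u,
                    "lambda_v": f.lambda_v,
                    "imaging_selected": [self.imaging_names[i] for i in f.imaging_selected],
                    "genetic_selected": [self.variant_names[i] for i in f.genetic_selected],
                    "metrics": {k: _m(m) for k, m in f.metrics.items()},
                    "baseline_selections": f.baseline_selections,
                }
                for f in self.folds
            ],
            "config": {
                "outer_k": self.config.outer_k,
                "inner_k": self.config.inner_k,
                "w": self.config.w,
                "grid_size": self.config.grid_size,
                "grid_min_frac": self.config.grid_min_frac,
                "n_trees": self.config.n_trees,
                "seed": self.config.seed,
                "tuning_rule": self.config.tuning_rule,
                "model_kinds": list(self.config.model_kinds),
                "baselines": list(self.config.baselines),
                "rf_library_defaults": "scikit-learn RandomForestRegressor",
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for key, m in f.metrics.items():
                rows.append(
                    {
                        "fold": f.fold_index,
                        "model": key,
                        "pearson_r": m.pearson_r,
                        "pearson_p": m.pearson_p,
                        "rmse": m.rmse,
                        "n_test": m.n_test,
                    }
                )
        return pd.DataFrame(rows)

    def scatter_table(self) -> pd.DataFrame:
        """Per-subject (actual, predicted, fold, model) rows for prediction plots."""
        rows = []
        for f in self.folds:
            for key, pred in f.predictions.items():
                for a, p in zip(f.actual, pred):
                    rows.append(
                        {"model": key, "fold": f.fold_index, "actual": a, "predicted": p}
                    )
        return pd.DataFrame(rows)

    def write_outputs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "result": out / "nested_cv.json",
            "metrics": out / "fold_metrics.csv",
            "features": out / "selected_features.csv",
            "scatter": out / "prediction_scatter.csv",
        }
        self.to_json(paths["result"])
        self.metrics_table().to_csv(paths["metrics"], index=False)
        rows = []
        for f in self.folds:
            for i in f.imaging_selected:
                rows.append({"fold": f.fold_index, "block": "imaging", "index": i,
                             "name": self.imaging_names[i]})
            for i in f.genetic_selected:
                rows.append({"fold": f.fold_index, "block": "genetic", "index": i,
                             "name": self.variant_names[i]})
        pd.DataFrame(rows).to_csv(paths["features"], index=False)
        self.scatter_table().to_csv(paths["scatter"], index=False)
        return paths


def _undefined(kind: str, n_test: int) -> ModelMetrics:
    return ModelMetrics(pearson_r=None, pearson_p=None, rmse=None, n_test=n_test,
                        model_kind=kind)


def _fit_eval(kind, F_train, F_test, z_train, z_test, n_trees, seed, metrics, preds):
    """Train an RF on the selected columns and record test metrics."""
    if F_train.shape[1] == 0:
        warnings.warn(f"{kind}: empty feature set; metrics undefined for this fold")
        metrics[kind] = _undefined(kind, z_test.size)
        return
    model = train_rf(F_train, z_train, n_trees=n_trees, seed=seed)
    pred = model.predict(F_test)
    preds[kind] = pred
    metrics[kind] = evaluate_fold(z_test, pred, kind)


def run_nested_cv(dataset: Dataset, config: NestedCvConfig = NestedCvConfig()) -> NestedCvResult:
    """The full nested-CV pipeline on an aligned Dataset.

    For each outer fold: standardize on outer-train statistics, tune the
    penalties on inner folds, fit the sparse CCA, take the non-zero
    loadings as selected features, train random forests (imaging /
    genetic / combined) plus the mean-of-target baseline on outer-train,
    and evaluate on the held-out fold. Optionally runs the LASSO and
    mRMR comparison selectors on the same outer-train data, with the
    mRMR feature count matched to the sparse-CCA selection. Fully
    deterministic given ``config.seed``.
    """
    X, Y, Z = dataset.X, dataset.Y, dataset.Z
    outer = make_folds(
        dataset.n,
        config.outer_k,
        seed=config.seed,
        stratify_on=Z if config.stratify else None,
    )
    base = OsSccaConfig(
        w=config.w, max_iter=config.max_iter, tol=config.tol, init=config.init
    )
    fold_results: list[FoldResult] = []
    for f, (tr, te) in enumerate(outer.folds()):
        Xtr, xs = impute_and_standardize(X[tr])
        Ytr, ys = impute_and_standardize(Y[tr])
        Xte, _ = impute_and_standardize(X[te], xs)
        Yte, _ = impute_and_standardize(Y[te], ys)
        ztr, zte = Z[tr], Z[te]
        Ztr_s, _ = impute_and_standardize(ztr)
        ztr_s = Ztr_s[:, 0]

        grid_u, grid_v = default_lambda_grid(
            Xtr, Ytr, ztr_s, w=config.w, num=config.grid_size, min_frac=config.grid_min_frac
        )
        inner_seed = (config.seed * 7919 + 13 * f + 1) % 2**31
        tuning = tune_lambdas(
            X[tr], Y[tr], Z[tr], grid_u, grid_v,
            w=config.w, k=config.inner_k, seed=inner_seed,
            base_config=base, rule=config.tuning_rule,
        )
        lu, lv = tuning.best_pair
        cfg = OsSccaConfig(
            lambda_u=lu, lambda_v=lv, w=config.w,
            max_iter=config.max_iter, tol=config.tol, init=config.init,
        )
        solution = fit_oscca(
            Xtr, Ytr, ztr_s, cfg,
            imaging_names=dataset.imaging_names, variant_names=dataset.variant_names,
        )
        sel_x, sel_y = select_features(solution)

        metrics: dict[str, ModelMetrics] = {}
        preds: dict[str, np.ndarray] = {}
        rf_seed = (config.seed * 104729 + f) % 2**31
        blocks = {
            "imaging": (Xtr[:, sel_x], Xte[:, sel_x]),
            "genetic": (Ytr[:, sel_y], Yte[:, sel_y]),
            "combined": (
                np.hstack([Xtr[:, sel_x], Ytr[:, sel_y]]),
                np.hstack([Xte[:, sel_x], Yte[:, sel_y]]),
            ),
        }
        for kind in config.model_kinds:
            Ftr, Fte = blocks[kind]
            _fit_eval(f"oscca:{kind}", Ftr, Fte, ztr, zte, config.n_trees, rf_seed,
                      metrics, preds)

        baseline = mean_baseline(ztr)
        pred = baseline.predict(Xte)
        preds["baseline:mean"] = pred
        metrics["baseline:mean"] = evaluate_fold(zte, pred, "baseline:mean")

        baseline_selections: dict[str, dict[str, list[int]]] = {}
        if "lasso" in config.baselines:
            lx = lasso_select(Xtr, ztr, inner_cv_seed=inner_seed)
            ly = lasso_select(Ytr, ztr, inner_cv_seed=inner_seed + 1)
            baseline_selections["lasso"] = {
                "imaging": [int(i) for i in lx], "genetic": [int(i) for i in ly]
            }
            bl = {
                "imaging": (Xtr[:, lx], Xte[:, lx]),
                "genetic": (Ytr[:, ly], Yte[:, ly]),
                "combined": (
                    np.hstack([Xtr[:, lx], Ytr[:, ly]]),
                    np.hstack([Xte[:, lx], Yte[:, ly]]),
                ),
            }
            for kind in config.model_kinds:
                Ftr, Fte = bl[kind]
                _fit_eval(f"lasso:{kind}", Ftr, Fte, ztr, zte, config.n_trees,
                          rf_seed + 1, metrics, preds)
        if "mrmr" in config.baselines:
            # mRMR sees genotype counts on their native {0,1,2} scale
            # (missing calls imputed to the rounded training mode scale)
            col_mean = np.nanmean(Y[tr], axis=0)
            Ytr_counts = np.clip(
                np.round(np.where(np.isnan(Y[tr]), col_mean, Y[tr])), 0, 2
            )
            mx = mrmr_rank(Xtr, ztr, max(1, len(sel_x))).order if Xtr.shape[1] else []
            my = mrmr_rank(Ytr_counts, ztr, max(1, len(sel_y))).order if Ytr.shape[1] else []
            baseline_selections["mrmr"] = {
                "imaging": [int(i) for i in mx], "genetic": [int(i) for i in my]
            }
            bm = {
                "imaging": (Xtr[:, mx], Xte[:, mx]),
                "genetic": (Ytr[:, my], Yte[:, my]),
                "combined": (
                    np.hstack([Xtr[:, mx], Ytr[:, my]]),
                    np.hstack([Xte[:, mx], Yte[:, my]]),
                ),
            }
            for kind in config.model_kinds:
                Ftr, Fte = bm[kind]
                _fit_eval(f"mrmr:{kind}", Ftr, Fte, ztr, zte, config.n_trees,
                          rf_seed + 2, metrics, preds)

        fold_results.append(
            FoldResult(
                fold_index=f,
                test_idx=te,
                lambda_u=lu,
                lambda_v=lv,
                solution=solution,
                imaging_selected=[int(i) for i in sel_x],
                genetic_selected=[int(i) for i in sel_y],
                metrics=metrics,
                predictions=preds,
                actual=zte,
                baseline_selections=baseline_selections,
            )
        )

    averaged = evaluate_models([f.metrics for f in fold_results])
    return NestedCvResult(
        folds=fold_results,
        consensus_imaging=consensus_features([f.imaging_selected for f in fold_results]),
        consensus_genetic=consensus_features([f.genetic_selected for f in fold_results]),
        averaged=averaged,
        config=config,
        imaging_names=dataset.imaging_names,
        variant_names=dataset.variant_names,
    )
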