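"""Random-forest regression on selected features, evaluation metrics, mean baseline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ModelMetrics",
    "pearson",
    "rmse",
    "train_rf",
    "MeanPredictor",
    "mean_baseline",
    "evaluate_fold",
    "evaluate_models",
    "pooled_pearson",
]


@dataclass
class ModelMetrics:
    """Test-fold performance of one prediction model.

    ``pearson_r``/``pearson_p`` are ``None`` when the correlation is
    undefined (constant predictions or an empty feature set); RMSE is in
    target units (years for age at onset).
    """

    pearson_r: float | None
    pearson_p: float | None
    rmse: float | None
    n_test: int
    model_kind: str

    @property
    def defined(self) -> bool:
        return self.rmse is not None


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value.

    Raises on constant input rather than silently returning 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared prediction error."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size:
        raise ValueError("vectors must have equal length")
    if actual.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def train_rf(
    features: np.ndarray, targets: np.ndarray, n_trees: int = 500, seed: int = 0
) -> RandomForestRegressor:
    """Fit a random forest of regression trees (library defaults otherwise)."""
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float).ravel()
    if features.ndim != 2 or features.shape[1] < 1:
        raise ValueError("feature matrix must have at least one column")
    if features.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(features, targets)
    return model


class MeanPredictor:
    """Constant predictor: always the training-set mean of the target."""

    def __init__(self, mean: float):
        self.mean = float(mean)

    def predict(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F)
        n = F.shape[0] if F.ndim > 0 else 1
        return np.full(n, self.mean)


def mean_baseline(train_targets: np.ndarray) -> MeanPredictor:
    train_targets = np.asarray(train_targets, dtype=float).ravel()
    if train_targets.size == 0:
        raise ValueError("need at least one training target")
    return MeanPredictor(train_targets.mean())


def evaluate_fold(
    actual: np.ndarray, predicted: np.ndarray, model_kind: str
) -> ModelMetrics:
    """Metrics for one test fold; flags (rather than fakes) undefined correlations."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    try:
        r, p = pearson(actual, predicted)
    except ValueError:
        r, p = None, None
    return ModelMetrics(
        pearson_r=r,
        pearson_p=p,
        rmse=rmse(actual, predicted),
        n_test=actual.size,
        model_kind=model_kind,
    )


def evaluate_models(
    fold_metrics: list[dict[str, ModelMetrics]],
) -> dict[str, ModelMetrics]:
    """Average per-fold metrics arithmetically per model kind.

    Folds where a metric is undefined are excluded from that average
    (and counted via ``n_test`` of the remaining folds); a kind
    undefined in every fold is reported with ``None`` metrics. Averaging
    p-values across folds is a reporting convention, not a combined
    test.
    """
    if not fold_metrics:
        raise ValueError("need at least one fold")
    kinds: list[str] = []
    for fm in fold_metrics:
        for k in fm:
            if k not in kinds:
                kinds.append(k)
    out: dict[str, ModelMetrics] = {}
    for kind in kinds:
        entries = [fm[kind] for fm in fold_metrics if kind in fm]
        rs = [m.pearson_r for m in entries if m.pearson_r is not None]
        ps = [m.pearson_p for m in entries if m.pearson_p is not None]
        rmses = [m.rmse for m in entries if m.rmse is not None]
        out[kind] = ModelMetrics(
            pearson_r=float(np.mean(rs)) if rs else None,
            pearson_p=float(np.mean(ps)) if ps else None,
            rmse=float(np.mean(rmses)) if rmses else None,
            n_test=int(sum(m.n_test for m in entries)),
            model_kind=kind,
        )
    return out


def pooled_pearson(
    actuals: list[np.ndarray], predictions: list[np.ndarray]
) -> tuple[float, float]:
    """Correlation over predictions pooled across folds (reported separately,
    never substituted for the fold-averaged r)."""
    return pearson(np.concatenate(actuals), np.concatenate(predictions))
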