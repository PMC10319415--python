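"""Reference comparisons and seed-influence analyses.

Covers the group-average baselines, the three ridge-regression reference
models on channel-averaged pixel vectors, descriptive yield statistics
(moment-based skewness and Pearson kurtosis), and the per-plot
counterfactual analysis that predicts each test plot under every seed
combination to quantify the seed branch's influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge

from .errors import ConfigurationError, InvalidArgumentError
from .records import PlotRecord
from .train_eval import evaluate
from .yield_models import YieldModel

__all__ = [
    "CounterfactualResult", "average_all_baseline", "aver_seed_baseline",
    "reference_features", "lr_reference_model",
    "counterfactual_seed_analysis", "iqr_coverage",
    "describe_yield", "low_yield_sign_test",
]


# ------------------------------------------------------------ group averages

def average_all_baseline(train_yields, test_records) -> np.ndarray:
    """Predict the train-set mean yield for every test plot."""
    train_yields = np.asarray(train_yields, dtype=float)
    if train_yields.size == 0:
        raise InvalidArgumentError("empty train set")
    n_test = len(test_records)
    return np.full(n_test, train_yields.mean())


def aver_seed_baseline(train_records, test_records) -> np.ndarray:
    """Predict the train-mean yield of each test plot's seed combination.

    Combos unseen in training fall back to the global train mean.
    """
    if not train_records:
        raise InvalidArgumentError("empty train set")
    by_combo: dict[int, list[float]] = {}
    for r in train_records:
        by_combo.setdefault(r.combo_index, []).append(r.yield_kg_ha)
    global_mean = float(np.mean([r.yield_kg_ha for r in train_records]))
    means = {c: float(np.mean(v)) for c, v in by_combo.items()}
    return np.array([means.get(r.combo_index, global_mean)
                     for r in test_records])


# ------------------------------------------------------- linear reference LMs

def _image_feature(images, downsample: int = 1) -> np.ndarray:
    """Channel-average each pixel and flatten to a 1-D vector."""
    feats = []
    for img in images:
        gray = np.asarray(img, dtype=float).mean(axis=2)
        if downsample > 1:
            h, w = gray.shape
            gray = gray[:h - h % downsample, :w - w % downsample]
            gray = gray.reshape(h // downsample, downsample,
                                w // downsample, downsample).mean(axis=(1, 3))
        feats.append(gray.ravel())
    return np.concatenate(feats)


def reference_features(record: PlotRecord, variant: int, n_combos: int = 51,
                       downsample: int = 4) -> np.ndarray:
    """1-D input vector of the ridge reference models.

    variant 1: one-hot seed only; 2: + channel-averaged latest image;
    3: + channel-averaged images of all timestamps.
    """
    if variant not in (1, 2, 3):
        raise ConfigurationError(f"unknown variant {variant}; pick 1, 2 or 3")
    onehot = np.zeros(n_combos)
    onehot[record.combo_index] = 1.0
    if variant == 1:
        return onehot
    if variant == 2:
        return np.concatenate([
            onehot, _image_feature(record.images[-1:], downsample)])
    return np.concatenate([onehot, _image_feature(record.images, downsample)])


def lr_reference_model(records, train_idx, test_idx, variant: int,
                       n_combos: int = 51, alpha: float = 1.0,
                       downsample: int = 4):
    """Ridge-regression reference model; returns ``(MetricReport,
    predictions)`` on the test split."""
    if variant not in (1, 2, 3):
        raise ConfigurationError(f"unknown variant {variant}; pick 1, 2 or 3")

    X = np.stack([reference_features(records[i], variant, n_combos, downsample)
                  for i in np.concatenate([train_idx, test_idx])])
    X_tr, X_te = X[:len(train_idx)], X[len(train_idx):]
    y_tr = np.array([records[i].yield_kg_ha for i in train_idx])
    y_te = np.array([records[i].yield_kg_ha for i in test_idx])
    model = Ridge(alpha=alpha)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    return evaluate(y_te, pred), pred


# ------------------------------------------------------------- counterfactual

@dataclass
class CounterfactualResult:
    plot_id: int
    predictions: np.ndarray  # one prediction per combo index
    true_combo_index: int
    q1: float
    median: float
    q3: float
    iqr: float
    true_prediction: float
    status: str  # inside_iqr | outside_iqr | low_outlier

    @staticmethod
    def from_predictions(plot_id: int, predictions: np.ndarray,
                         true_combo_index: int) -> "CounterfactualResult":
        predictions = np.asarray(predictions, dtype=float)
        # linear-interpolation percentile rule
        q1, med, q3 = np.percentile(predictions, [25, 50, 75])
        iqr = q3 - q1
        true_pred = float(predictions[true_combo_index])
        if true_pred < q1 - 1.5 * iqr:
            status = "low_outlier"
        elif q1 <= true_pred <= q3:
            status = "inside_iqr"
        else:
            status = "outside_iqr"
        return CounterfactualResult(plot_id, predictions, true_combo_index,
                                    float(q1), float(med), float(q3),
                                    float(iqr), true_pred, status)


def counterfactual_seed_analysis(model: YieldModel, test_records,
                                 n_combos: int = 51,
                                 test_data: dict | None = None
                                 ) -> list[CounterfactualResult]:
    """Predict every test plot under all ``n_combos`` seed combinations.

    The images stay fixed; only the combo index is substituted (one true,
    the rest pseudo). The true-combo entry equals the ordinary forward
    pass bit-exactly.
    """
    if not getattr(model, "is_trained", False):
        raise InvalidArgumentError(
            "counterfactual analysis requires a trained model")
    if test_data is None:
        test_data = model.preprocess(test_records)
    results = []
    for i, rec in enumerate(test_records):
        data_i = {k: v[i:i + 1] for k, v in test_data.items()}
        # image branch once per plot; only the seed branch varies by combo
        v = model.image_representation(data_i, np.array([0]))
        preds = np.empty(n_combos)
        for combo in range(n_combos):
            raw = model.head_forward(v, np.array([combo])).numpy()[0]
            preds[combo] = raw * model.y_std + model.y_mean
        results.append(CounterfactualResult.from_predictions(
            rec.plot_id, preds, rec.combo_index))
    return results


def iqr_coverage(results: list[CounterfactualResult]):
    """(fraction_inside, fraction_outside, n_low_outliers) over plots."""
    if not results:
        raise InvalidArgumentError("empty result list")
    inside = sum(r.status == "inside_iqr" for r in results)
    low = sum(r.status == "low_outlier" for r in results)
    n = len(results)
    return inside / n, (n - inside) / n, low


def low_yield_sign_test(results: list[CounterfactualResult],
                        low_combo_indices) -> tuple[int, int, float]:
    """Sign test: do plots carrying designated low-yield combos sit below
    their counterfactual box median more often than chance?

    Returns (n_below, n_total, one-sided binomial p-value).
    """
    low = set(int(c) for c in low_combo_indices)
    sel = [r for r in results if r.true_combo_index in low]
    if not sel:
        raise InvalidArgumentError("no plots carry the designated combos")
    below = sum(r.true_prediction < r.median for r in sel)
    p = float(stats.binomtest(below, len(sel), 0.5,
                              alternative="greater").pvalue)
    return below, len(sel), p


# ---------------------------------------------------------------- descriptive

def describe_yield(yields) -> tuple[float, float]:
    """Moment-based skewness and Pearson (non-excess) kurtosis."""
    y = np.asarray(yields, dtype=float)
    if y.size < 4:
        raise InvalidArgumentError("need at least 4 samples")
    if np.var(y) == 0:
        raise InvalidArgumentError("zero variance")
    skew = float(stats.skew(y, bias=True))
    kurt = float(stats.kurtosis(y, fisher=False, bias=True))
    return skew, kurt
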