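"""Evaluation metrics, the benchmark harness, and classifier-comparison tests.

Covers three layers:

* per-run binary classification metrics and the out-of-sample forecast
  performance (accuracy restricted to cells outside the training set —
  for binary features every such cell lies outside the convex hull of the
  training data, so this measures genuine extrapolation);
* the benchmark summary over the synthetic design (median/IQR and mean/SD
  of each metric per training fraction);
* the nonparametric comparison machinery: Friedman test on per-dataset
  ranks and Holm step-down post-hoc z tests against a control classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import UNDEFINED, LabelTable, LabeledDataset, TreeStructure
from .synthetic import GeneratorConfig, benchmark_runs
from .trainer import FallbackPolicy, TrainResult, predict_codes, train

METRIC_NAMES = ("accuracy", "recall", "precision", "f1")


@dataclass(frozen=True)
class EvalReport:
    """Binary classification metrics plus determination coverage."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    coverage: float
    n_test: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "coverage": self.coverage,
            "n_test": self.n_test,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], coverage: float = 1.0
) -> EvalReport:
    """Accuracy, recall, precision and F1 with positive class 1.

    Zero-denominator conventions: precision/recall/F1 report 0 with a
    warning when undefined.
    """
    yt = np.asarray(y_true, dtype=np.int8)
    yp = np.asarray(y_pred, dtype=np.int8)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d sequences")
    if yt.size == 0:
        raise ValueError("cannot score an empty test set")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    accuracy = (tp + tn) / yt.size
    recall = _safe_ratio(tp, tp + fn, "recall")
    precision = _safe_ratio(tp, tp + fp, "precision")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
    return EvalReport(accuracy, recall, precision, f1, coverage, int(yt.size))


def evaluate_on_holdout(
    result: TrainResult,
    truth: LabelTable,
    fallback: FallbackPolicy = "majority",
    rng: np.random.Generator | None = None,
) -> EvalReport:
    """Score a trained model on all cells outside its training set."""
    if not truth.is_total:
        raise ValueError("evaluation requires a total ground-truth table")
    mask = np.ones(truth.n_cells, dtype=bool)
    mask[list(result.training_codes)] = False
    test_codes = np.nonzero(mask)[0]
    if test_codes.size == 0:
        raise ValueError("no cells outside the training set")
    y_true = truth.values()[test_codes]
    y_pred, determined = predict_codes(result, test_codes, fallback, rng)
    coverage = float(determined.mean())
    if fallback == "abstain":
        if not determined.any():
            raise ValueError("all test cells undetermined under fallback='abstain'")
        y_true, y_pred = y_true[determined], y_pred[determined]
    return classification_metrics(y_true, y_pred, coverage=coverage)


def out_of_sample_forecast(
    result: TrainResult,
    truth: LabelTable,
    fallback: FallbackPolicy = "majority",
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of non-training cells whose predicted label is correct.

    Under ``abstain`` the fraction is computed over the determined subset
    only (coverage is available from :func:`evaluate_on_holdout`).
    """
    return evaluate_on_holdout(result, truth, fallback, rng).accuracy


def table3_replication(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    fallback: FallbackPolicy = "majority",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full synthetic design and aggregate metrics per fraction.

    Returns ``(summary, runs)``: per-run metrics, and per-fraction
    median/IQR and mean/SD of each metric.  ``seed`` overrides the config's
    seed when given.
    """
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        from dataclasses import replace

        config = replace(config, seed=seed)
    rows = []
    for run in benchmark_runs(config):
        result = train(run.training)
        report = evaluate_on_holdout(result, run.truth, fallback)
        rows.append(
            {
                "d": run.structure.d,
                "blocks": "+".join(map(str, run.structure.block_sizes)),
                "fraction": run.fraction,
                "n_training": len(run.training),
                "conflicts": result.conflicts,
                **report.as_dict(),
            }
        )
    runs = pd.DataFrame(rows)
    records = []
    for fraction, grp in runs.groupby("fraction"):
        for metric in METRIC_NAMES:
            vals = grp[metric].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            records.append(
                {
                    "fraction": fraction,
                    "metric": metric,
                    "median": med,
                    "iqr": q3 - q1,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "n_runs": len(vals),
                }
            )
    summary = pd.DataFrame(records)
    return summary, runs


# -- rank-based classifier comparison --------------------------------------


@dataclass(frozen=True)
class RankMatrix:
    """Per-dataset classifier performances and their within-row ranks.

    Rank 1 is best (highest performance); ties receive average ranks, so
    every row sums to k(k+1)/2.
    """

    performances: np.ndarray  # (n_datasets, k)
    ranks: np.ndarray
    avg_ranks: np.ndarray
    classifiers: tuple[str, ...]

    @classmethod
    def from_performances(
        cls, performances: np.ndarray, classifiers: Sequence[str] | None = None
    ) -> "RankMatrix":
        perf = np.asarray(performances, dtype=float)
        if perf.ndim != 2 or perf.shape[0] < 1 or perf.shape[1] < 2:
            raise ValueError("performances must be (n_datasets >= 1, k >= 2)")
        names = (
            tuple(classifiers)
            if classifiers is not None
            else tuple(f"clf{j}" for j in range(perf.shape[1]))
        )
        if len(names) != perf.shape[1]:
            raise ValueError("one name per classifier column required")
        ranks = sps.rankdata(-perf, axis=1, method="average")
        return cls(perf, ranks, ranks.mean(axis=0), names)

    @property
    def n(self) -> int:
        return self.performances.shape[0]

    @property
    def k(self) -> int:
        return self.performances.shape[1]


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    reject: bool
    alpha: float


def chi_square_critical(alpha: float, df: int) -> float:
    """Upper-tail chi-square critical value."""
    return float(sps.chi2.isf(alpha, df))


def normal_critical(alpha: float) -> float:
    """Upper-tail standard-normal critical value."""
    return float(sps.norm.isf(alpha))


def friedman_test(ranks: RankMatrix, alpha: float = 0.001) -> FriedmanResult:
    """Classic Friedman chi-square test on average ranks.

    ``chi2_F = 12 n / (k (k+1)) * (sum_j Rbar_j^2 - k (k+1)^2 / 4)`` with
    ties handled through average ranks; the statistic is referred to the
    chi-square distribution with k - 1 degrees of freedom.
    """
    n, k = ranks.n, ranks.k
    if n < 2:
        raise ValueError("the Friedman test needs at least two datasets")
    rbar = ranks.avg_ranks
    statistic = 12.0 * n / (k * (k + 1)) * (float(np.sum(rbar**2)) - k * (k + 1) ** 2 / 4.0)
    statistic = max(statistic, 0.0)
    df = k - 1
    p_value = float(sps.chi2.sf(statistic, df))
    reject = statistic > chi_square_critical(alpha, df)
    return FriedmanResult(statistic, df, p_value, reject, alpha)


@dataclass(frozen=True)
class HolmComparison:
    classifier: str
    z: float
    p_raw: float
    p_holm: float
    reject: bool


def holm_posthoc(
    avg_ranks: Sequence[float],
    n: int,
    control_index: int = 0,
    alpha: float = 0.001,
    classifiers: Sequence[str] | None = None,
) -> list[HolmComparison]:
    """Holm step-down post-hoc z tests of every classifier against a control.

    ``z = |R_control - R_j| / sqrt(k (k+1) / (6 n))`` with two-sided normal
    raw p-values; adjusted p-values follow the Holm step-down rule over the
    k - 1 comparisons, and a comparison is rejected when the adjusted p
    falls below alpha or z exceeds the normal critical value.
    """
    rbar = np.asarray(avg_ranks, dtype=float)
    k = rbar.size
    if k < 2:
        raise ValueError("need at least two classifiers")
    if not 0 <= control_index < k:
        raise ValueError("control_index out of range")
    names = (
        tuple(classifiers)
        if classifiers is not None
        else tuple(f"clf{j}" for j in range(k))
    )
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    others = [j for j in range(k) if j != control_index]
    z = np.abs(rbar[control_index] - rbar[others]) / se
    p_raw = 2.0 * sps.norm.sf(z)
    order = np.argsort(p_raw)
    m = len(others)
    p_holm = np.empty(m)
    running = 0.0
    for rank_pos, idx in enumerate(order):
        running = max(running, (m - rank_pos) * p_raw[idx])
        p_holm[idx] = min(1.0, running)
    z_crit = normal_critical(alpha)
    return [
        HolmComparison(
            classifier=names[j],
            z=float(z[jj]),
            p_raw=float(p_raw[jj]),
            p_holm=float(p_holm[jj]),
            reject=bool(p_holm[jj] < alpha or z[jj] > z_crit),
        )
        for jj, j in enumerate(others)
    ]


# -- baseline harness ------------------------------------------------------


@dataclass(frozen=True)
class HarnessDataset:
    """One train/test split presented to every classifier adapter."""

    structure: TreeStructure
    training: LabeledDataset
    X_test: np.ndarray
    y_test: np.ndarray


Adapter = Callable[[HarnessDataset], np.ndarray]
"""A classifier adapter maps a dataset to test-set label predictions."""


def hybrid_adapter(fallback: FallbackPolicy = "majority") -> Adapter:
    """The conflict-graph learner exposed through the adapter interface."""

    def run(ds: HarnessDataset) -> np.ndarray:
        result = train(ds.training)
        weights = 1 << np.arange(ds.structure.d - 1, -1, -1, dtype=np.int64)
        codes = ds.X_test.astype(np.int64) @ weights
        labels, _ = predict_codes(result, codes, fallback)
        return labels

    return run


def constant_adapter(label: int) -> Adapter:
    """Dummy baseline predicting one class everywhere."""

    def run(ds: HarnessDataset) -> np.ndarray:
        return np.full(len(ds.y_test), label, dtype=np.int8)

    return run


def sklearn_adapter(estimator_factory: Callable[[], object]) -> Adapter:
    """Wrap any scikit-learn-style estimator (``fit``/``predict``)."""

    def run(ds: HarnessDataset) -> np.ndarray:
        est = estimator_factory()
        est.fit(ds.training.X, ds.training.y)
        return np.asarray(est.predict(ds.X_test), dtype=np.int8)

    return run


def baseline_harness(
    datasets: Sequence[HarnessDataset],
    classifiers: Mapping[str, Adapter],
) -> RankMatrix:
    """Accuracy of every registered classifier on every dataset, ranked."""
    if not classifiers:
        raise ValueError("no classifier adapters registered")
    names = tuple(classifiers)
    perf = np.zeros((len(datasets), len(names)))
    for row, ds in enumerate(datasets):
        for col, name in enumerate(names):
            y_pred = classifiers[name](ds)
            perf[row, col] = float(np.mean(y_pred == ds.y_test))
    return RankMatrix.from_performances(perf, names)
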