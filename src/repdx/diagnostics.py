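"""Discriminative-feature screening and the repeated equal-sampling
L1-logistic diagnostic harness.

The marker screen retains features passing a log fold-change threshold
and a rank-based AUC threshold between the two cohorts. The diagnostic
harness repeatedly (i) splits cases 80/20, (ii) samples controls equal in
number to the training cases, (iii) fits a cross-validated L1-penalized
logistic model on the training set, and (iv) evaluates on everything
held out, aggregating metrics over repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

CASE, CONTROL = "case", "control"


def feature_auc(
    values_case: Sequence[float], values_control: Sequence[float]
) -> float:
    """AUC = P(case > control) + 0.5 P(case == control), via midranks."""
    xc = np.asarray(values_case, dtype=float)
    xk = np.asarray(values_control, dtype=float)
    if xc.size == 0 or xk.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([xc, xk]))
    r_case = ranks[: xc.size].sum()
    u = r_case - xc.size * (xc.size + 1) / 2
    return float(u / (xc.size * xk.size))


def log_fold_change(
    mean_case: float, mean_control: float, pseudocount: float = 1e-4
) -> float:
    """Natural-log fold change with a pseudocount on both means."""
    if mean_case < 0 or mean_control < 0:
        raise ValueError("means must be non-negative")
    return math.log((mean_case + pseudocount) / (mean_control + pseudocount))


@dataclass(frozen=True)
class MarkerResult:
    feature: str
    log_fold_change: float
    auc: float
    direction: str  # up_in_case | up_in_control


def roc_marker_test(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    lfc_min: float = 0.25,
    auc_min: float = 0.7,
    pseudocount: float = 1e-4,
) -> list[MarkerResult]:
    """Screen every feature for |lfc| >= lfc_min and discriminative AUC
    (max of AUC and 1-AUC) > auc_min; sorted by discriminative AUC
    descending. ``labels`` maps sample_id -> 'case'/'control'."""
    ids = [s for s in matrix.index if s in labels]
    case_ids = [s for s in ids if labels[s] == CASE]
    ctrl_ids = [s for s in ids if labels[s] == CONTROL]
    if not case_ids or not ctrl_ids:
        raise ValueError("need samples from both classes")
    out: list[MarkerResult] = []
    xc_all = matrix.loc[case_ids].to_numpy(dtype=float)
    xk_all = matrix.loc[ctrl_ids].to_numpy(dtype=float)
    for j, feat in enumerate(matrix.columns):
        xc, xk = xc_all[:, j], xk_all[:, j]
        lfc = log_fold_change(xc.mean(), xk.mean(), pseudocount)
        auc = feature_auc(xc, xk)
        if abs(lfc) >= lfc_min and max(auc, 1 - auc) > auc_min:
            out.append(
                MarkerResult(
                    feature=str(feat),
                    log_fold_change=lfc,
                    auc=auc,
                    direction="up_in_case" if lfc > 0 else "up_in_control",
                )
            )
    out.sort(key=lambda m: (-max(m.auc, 1 - m.auc), m.feature))
    return out


@dataclass(frozen=True)
class SplitPlan:
    repeat_index: int
    seed: int
    train_case: tuple[str, ...]
    test_case: tuple[str, ...]
    train_control: tuple[str, ...]
    test_control: tuple[str, ...]


def split_cohorts(
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    repeat_index: int = 0,
) -> SplitPlan:
    """80/20 case split with equal-count control sampling.

    Training cases = ceil(train_fraction * n_case) cases drawn without
    replacement; training controls are an equally sized random subset of
    the controls. Everything else (both cohorts) is the test set. Set
    sizes depend only on the cohort sizes and fraction, never the seed.
    """
    case_ids = sorted(case_ids)
    control_ids = sorted(control_ids)
    if len(case_ids) < 2:
        raise ValueError("need at least 2 cases")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train_case = math.ceil(train_fraction * len(case_ids))
    if len(control_ids) < n_train_case:
        raise ValueError(
            f"need >= {n_train_case} controls, got {len(control_ids)}"
        )
    rng = np.random.default_rng(seed)
    train_case = sorted(
        rng.choice(case_ids, size=n_train_case, replace=False).tolist()
    )
    train_control = sorted(
        rng.choice(control_ids, size=n_train_case, replace=False).tolist()
    )
    return SplitPlan(
        repeat_index=repeat_index,
        seed=seed,
        train_case=tuple(train_case),
        test_case=tuple(s for s in case_ids if s not in set(train_case)),
        train_control=tuple(train_control),
        test_control=tuple(s for s in control_ids if s not in set(train_control)),
    )


@dataclass
class LassoModel:
    lambda_min: float
    intercept: float
    coefficients: dict[str, float]  # nonzero only, standardized scale
    cv_folds: int
    features: list[str] = field(default_factory=list)
    _mean: np.ndarray | None = None
    _std: np.ndarray | None = None
    _coef_full: np.ndarray | None = None

    def predict_proba(self, x: pd.DataFrame) -> np.ndarray:
        """Probability of the case class for each row of ``x``."""
        z = (x[self.features].to_numpy(dtype=float) - self._mean) / self._std
        logit = z @ self._coef_full + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))


def fit_lasso_cv(
    train_matrix: pd.DataFrame,
    train_labels: Mapping[str, str],
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 25,
) -> LassoModel:
    """Cross-validated L1-penalized binomial regression.

    Features are z-scored on the training set (zero-variance features get
    unit scale and therefore zero coefficient). The penalty minimizing
    mean cross-validated log loss is selected from a descending-lambda
    path; ``lambda_min`` is reported on the glmnet scale 1/(n*C). Folds
    are stratified; the fold count shrinks to the minority-class count
    when needed.
    """
    ids = [s for s in train_matrix.index if s in train_labels]
    y = np.array([1 if train_labels[s] == CASE else 0 for s in ids])
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    x = train_matrix.loc[ids].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    z = (x - mean) / std

    folds = min(n_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-2, 3, n_lambdas),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=5000,
        refit=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # scikit-learn >= 1.8 deprecation chatter about the l1 spelling;
        # liblinear + penalty='l1' is the fast path and stays supported
        # through the transition.
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(z, y)
    coef = clf.coef_.ravel()
    best_c = float(clf.C_[0])
    features = [str(c) for c in train_matrix.columns]
    nonzero = {f: float(w) for f, w in zip(features, coef) if w != 0.0}
    return LassoModel(
        lambda_min=1.0 / (best_c * len(ids)),
        intercept=float(clf.intercept_[0]),
        coefficients=nonzero,
        cv_folds=folds,
        features=features,
        _mean=mean,
        _std=std,
        _coef_full=coef,
    )


@dataclass(frozen=True)
class EvalMetrics:
    auc: float | None
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Threshold metrics from confusion counts."""
    n = tp + fn + tn + fp
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
    }


def evaluate_model(
    model: LassoModel,
    test_matrix: pd.DataFrame,
    test_labels: Mapping[str, str],
    threshold: float = 0.5,
) -> EvalMetrics:
    """Score the held-out set; AUC is None if only one class is present."""
    ids = [s for s in test_matrix.index if s in test_labels]
    y = np.array([1 if test_labels[s] == CASE else 0 for s in ids])
    prob = model.predict_proba(test_matrix.loc[ids])
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    m = confusion_metrics(tp, fn, tn, fp)
    auc = None
    if len(set(y)) == 2:
        auc = feature_auc(prob[y == 1], prob[y == 0])
    return EvalMetrics(auc=auc, **m)


@dataclass
class ClassifierReport:
    repeats: list[dict]
    aggregate: dict
    feature_frequency: dict[str, int]
    failures: list[dict]
    seeds: list[int]

    def as_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "aggregate": self.aggregate,
            "feature_frequency": self.feature_frequency,
            "failures": self.failures,
            "seeds": self.seeds,
        }


METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "precision")


def repeated_evaluation(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    n_repeats: int = 100,
    base_seed: int = 0,
    train_fraction: float = 0.8,
    n_folds: int = 10,
    threshold: float = 0.5,
) -> ClassifierReport:
    """Repeat split -> fit -> evaluate and aggregate over repeats.

    Repeat ``r`` uses seed ``base_seed + r``; all seeds are logged.
    Failed repeats are recorded and excluded from the aggregates.
    """
    ids = [s for s in matrix.index if s in labels]
    case_ids = [s for s in ids if labels[s] == CASE]
    ctrl_ids = [s for s in ids if labels[s] == CONTROL]
    repeats: list[dict] = []
    failures: list[dict] = []
    freq: dict[str, int] = {}
    seeds = [base_seed + r for r in range(n_repeats)]
    for r, seed in enumerate(seeds):
        try:
            plan = split_cohorts(
                case_ids, ctrl_ids, train_fraction, seed=seed, repeat_index=r
            )
            train_ids = list(plan.train_case) + list(plan.train_control)
            test_ids = list(plan.test_case) + list(plan.test_control)
            model = fit_lasso_cv(
                matrix.loc[train_ids], labels, n_folds=n_folds, seed=seed
            )
            metrics = evaluate_model(
                model, matrix.loc[test_ids], labels, threshold=threshold
            )
            for f in model.coefficients:
                freq[f] = freq.get(f, 0) + 1
            repeats.append(
                {
                    "repeat": r,
                    "seed": seed,
                    "n_train": len(train_ids),
                    "n_test": len(test_ids),
                    "n_selected": len(model.coefficients),
                    "lambda_min": model.lambda_min,
                    **metrics.as_dict(),
                }
            )
        except Exception as exc:  # recorded, not raised
            failures.append({"repeat": r, "seed": seed, "reason": str(exc)})
    aggregate: dict = {"n_repeats": len(repeats), "n_failures": len(failures)}
    for name in METRIC_NAMES:
        vals = [rep[name] for rep in repeats if rep[name] is not None]
        aggregate[f"{name}_mean"] = float(np.mean(vals)) if vals else None
        aggregate[f"{name}_sd"] = (
            float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        )
    return ClassifierReport(
        repeats=repeats,
        aggregate=aggregate,
        feature_frequency=dict(sorted(freq.items(), key=lambda kv: -kv[1])),
        failures=failures,
        seeds=seeds,
    )
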