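"""Recursive feature elimination with a random forest (RFE-RF).

The selector mirrors the classic caret-style resampled RFE: over repeated
stratified k-fold resamples of the training cohort, features are ranked by
random-forest importance on the resample's training part, the forest is
refit at each candidate subset size, and held-out accuracy is recorded.
The chosen subset size is, by default, the smallest size whose mean
cross-validated accuracy is within one standard error of the maximum
(exact-max mode available); the final forest is refit on the full training
cohort at that size.  AAH is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

__all__ = [
    "ConfusionMetrics",
    "SelectionResult",
    "DEFAULT_SUBSET_SIZES",
    "split_cohort",
    "rfe_rf",
    "evaluate_on_test",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "AAH"

#: Candidate subset sizes: dense below ~25 features, sparse above.
DEFAULT_SUBSET_SIZES: tuple[int, ...] = (
    *range(1, 16), 20, 25, 30, 40, 50, 75, 100, 178,
)

NAN = float("nan")


def _ratio(num: float, den: float) -> float:
    return num / den if den else NAN


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts plus the five derived proportions.

    Ratios with a zero denominator are NaN.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class SelectionResult:
    """Outcome of the RFE-RF selection on the training cohort."""

    subset_sizes: list[int]
    cv_accuracy_profile: pd.DataFrame  # columns: size, mean, sd
    best_size: int
    selected_features: list[str]
    final_model: RandomForestClassifier
    test_metrics: ConfusionMetrics | None = None
    ranking: list[str] = field(default_factory=list)  # full-train importance order

    @property
    def cv_accuracy_at_best(self) -> float:
        row = self.cv_accuracy_profile[
            self.cv_accuracy_profile["size"] == self.best_size
        ]
        return float(row["mean"].iloc[0])

    def to_json_dict(self) -> dict:
        out = {
            "subset_sizes": list(self.subset_sizes),
            "cv_accuracy_profile": self.cv_accuracy_profile.to_dict("records"),
            "best_size": self.best_size,
            "cv_accuracy_at_best": self.cv_accuracy_at_best,
            "selected_features": list(self.selected_features),
        }
        if self.test_metrics is not None:
            out["test_metrics"] = self.test_metrics.as_dict()
        return out


def _as_binary(labels) -> np.ndarray:
    """Map labels to 1 (AAH / positive) and 0 (control)."""
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == POSITIVE_LABEL).astype(int)
    return y.astype(int)


def split_cohort(
    features: pd.DataFrame,
    labels,
    test_size: float | int = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified train/test split, deterministic given the seed.

    ``test_size`` may be a fraction in (0, 1) or an explicit subject count
    (e.g. 17 to reproduce a 52/17 split of 69 subjects).
    """
    y = _as_binary(labels)
    if isinstance(test_size, float) and not (0.0 < test_size < 1.0):
        raise ValueError("test fraction must lie in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present before splitting")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, y, test_size=test_size, stratify=y, random_state=seed
    )
    return X_tr, X_te, y_tr, y_te


def _fit_forest(X, y, seed: int, n_trees: int) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def _importance_order(
    X: pd.DataFrame, y: np.ndarray, seed: int, n_trees: int,
    permutation: bool,
) -> list[str]:
    model = _fit_forest(X.to_numpy(), y, seed, n_trees)
    if permutation:
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(
            model, X.to_numpy(), y, n_repeats=5, random_state=seed
        ).importances_mean
    else:
        imp = model.feature_importances_
    order = np.argsort(imp, kind="stable")[::-1]
    return [X.columns[k] for k in order]


def rfe_rf(
    train: pd.DataFrame,
    labels,
    sizes: list[int] | tuple[int, ...] | None = None,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    one_se: bool = True,
    permutation_importance: bool = False,
) -> SelectionResult:
    """Resampled RFE-RF over the candidate subset sizes.

    Deterministic given ``seed``.  NaN-containing feature columns must be
    dropped by the caller beforehand (``ValueError`` otherwise).
    """
    X = train
    y = _as_binary(labels)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(
            f"feature table contains NaN columns {bad[:5]}... — drop or flag "
            "them before selection"
        )
    p = X.shape[1]
    if sizes is None:
        sizes = DEFAULT_SUBSET_SIZES
    sizes = sorted({min(s, p) for s in sizes if s >= 1})
    class_min = int(np.bincount(y, minlength=2).min())
    folds = min(cv_folds, class_min)
    if folds < cv_folds:
        logger.warning(
            "reducing cv folds from %d to %d (smallest class has %d subjects)",
            cv_folds, folds, class_min,
        )
    rng = np.random.SeedSequence(seed)
    fold_seed, rank_seeds_root, final_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(3)
    )
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=cv_repeats, random_state=fold_seed
    )
    n_resamples = folds * cv_repeats
    acc = np.zeros((n_resamples, len(sizes)))
    rank_seeds = np.random.SeedSequence(rank_seeds_root).spawn(n_resamples)
    for f, (tr_idx, te_idx) in enumerate(splitter.split(X, y)):
        X_tr, y_tr = X.iloc[tr_idx], y[tr_idx]
        X_te, y_te = X.iloc[te_idx], y[te_idx]
        sub_seeds = np.random.SeedSequence(
            int(rank_seeds[f].generate_state(1)[0] % (2**31))
        ).spawn(len(sizes) + 1)
        order = _importance_order(
            X_tr, y_tr,
            int(sub_seeds[0].generate_state(1)[0] % (2**31)),
            n_trees, permutation_importance,
        )
        for s_idx, size in enumerate(sizes):
            cols = order[:size]
            model = _fit_forest(
                X_tr[cols].to_numpy(), y_tr,
                int(sub_seeds[s_idx + 1].generate_state(1)[0] % (2**31)),
                n_trees,
            )
            pred = model.predict(X_te[cols].to_numpy())
            acc[f, s_idx] = float((pred == y_te).mean())

    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=1)
    profile = pd.DataFrame({"size": sizes, "mean": mean, "sd": sd})
    best_idx = int(np.argmax(mean))
    if one_se:
        se = sd[best_idx] / np.sqrt(n_resamples)
        within = np.nonzero(mean >= mean[best_idx] - se)[0]
        chosen = int(within[0])
        if chosen != best_idx:
            logger.info(
                "one-SE rule: size %d (mean %.3f) over exact max %d (%.3f)",
                sizes[chosen], mean[chosen], sizes[best_idx], mean[best_idx],
            )
        best_idx = chosen
    best_size = sizes[best_idx]

    ranking = _importance_order(
        X, y, final_seed, n_trees, permutation_importance
    )
    selected = ranking[:best_size]
    final_model = _fit_forest(X[selected].to_numpy(), y, final_seed, n_trees)
    return SelectionResult(
        subset_sizes=list(sizes),
        cv_accuracy_profile=profile,
        best_size=best_size,
        selected_features=selected,
        final_model=final_model,
        ranking=ranking,
    )


def evaluate_on_test(
    result: SelectionResult, test: pd.DataFrame, labels
) -> ConfusionMetrics:
    """Predict the held-out cohort with the final model; AAH is positive."""
    missing = [c for c in result.selected_features if c not in test.columns]
    if missing:
        raise ValueError(f"test table missing selected feature(s) {missing[:5]}")
    y = _as_binary(labels)
    pred = result.final_model.predict(
        test[result.selected_features].to_numpy()
    )
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    metrics = ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
    result.test_metrics = metrics
    return metrics
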