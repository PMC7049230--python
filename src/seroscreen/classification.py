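"""Random-forest discrimination of patients vs controls from NFI features.

Mirrors the single-split protocol of a serological biomarker evaluation:
the cohort is divided once into a training and a test set, a bagged-tree
ensemble is fitted on the training samples, and the held-out predictions
are summarized as a confusion matrix with sensitivity, specificity and
accuracy (reported as rounded percents, exact fractions retained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split as _sk_split

__all__ = [
    "SplitSpec",
    "ConfusionMetrics",
    "train_test_split",
    "fit_predict_forest",
    "confusion_metrics",
]

POSITIVE = "POAG"
NEGATIVE = "CTRL"


@dataclass
class SplitSpec:
    n_total: int
    n_train: int = 165
    n_test: int = 75
    stratify: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_train + self.n_test != self.n_total:
            raise ValueError(
                f"n_train + n_test = {self.n_train + self.n_test} does not "
                f"match cohort size {self.n_total}"
            )


def train_test_split(
    cohort: pd.DataFrame, spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Split sample ids into disjoint, exhaustive train/test sets.

    Reproducible for a fixed seed; stratified by the ``group`` column
    when ``spec.stratify`` (the default — a near-balanced test set is
    what a balanced cohort yields under stratification).
    """
    spec.validate()
    if len(cohort) != spec.n_total:
        raise ValueError(
            f"cohort has {len(cohort)} samples, spec expects {spec.n_total}"
        )
    ids = cohort["sample_id"].to_numpy()
    strat = cohort["group"].to_numpy() if spec.stratify else None
    train, test = _sk_split(
        ids,
        test_size=spec.n_test,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    return list(train), list(test)


def fit_predict_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    train_ids: list[str],
    test_ids: list[str],
    n_trees: int = 500,
    max_features: str | int | float = "sqrt",
    seed: int = 0,
) -> pd.Series:
    """Fit a random forest on the training ids, predict the test ids.

    ``features`` is the imputed NFI matrix (samples x targets; no missing
    values), ``labels`` the per-sample class.  Deterministic for a fixed
    seed.
    """
    y_train = labels.loc[train_ids]
    if y_train.nunique() < 2:
        raise ValueError("training set contains a single class")
    X_train = features.loc[train_ids]
    if X_train.isna().any().any() or features.loc[test_ids].isna().any().any():
        raise ValueError("features contain missing values; impute upstream")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=max_features, random_state=seed
    )
    forest.fit(X_train.to_numpy(), y_train.to_numpy())
    pred = forest.predict(features.loc[test_ids].to_numpy())
    return pd.Series(pred, index=test_ids, name="predicted")


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # percent, full precision
    specificity: float
    accuracy: float

    @property
    def rounded(self) -> tuple[int, int, int]:
        """(sensitivity, specificity, accuracy) as integer percents."""
        return (
            round(self.sensitivity),
            round(self.specificity),
            round(self.accuracy),
        )


def confusion_metrics(
    predicted: pd.Series | np.ndarray,
    observed: pd.Series | np.ndarray,
    positive: str = POSITIVE,
    negative: str = NEGATIVE,
) -> ConfusionMetrics:
    """Confusion counts and rates for a two-class prediction."""
    pred = np.asarray(predicted)
    obs = np.asarray(observed)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    allowed = {positive, negative}
    extra = (set(pred) | set(obs)) - allowed
    if extra:
        raise ValueError(f"unknown class label(s): {sorted(extra)}")
    tp = int(np.sum((pred == positive) & (obs == positive)))
    fn = int(np.sum((pred == negative) & (obs == positive)))
    tn = int(np.sum((pred == negative) & (obs == negative)))
    fp = int(np.sum((pred == positive) & (obs == negative)))
    total = tp + fn + tn + fp
    return ConfusionMetrics(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=100.0 * (tp + tn) / total if total else float("nan"),
    )
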