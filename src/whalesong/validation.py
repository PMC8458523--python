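"""Robustness check of a manual unit-type classification via the out-of-bag
(OOB) error of a bagged decision-tree ensemble.

The input is a numeric feature table (nominally 44 acoustic metrics per unit
exemplar) with a manual ``label`` column.  Each exemplar is scored by the
majority vote of the trees whose bootstrap sample did not contain it; the
OOB misclassification rate is the fraction of exemplars whose vote differs
from the manual label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = ["FeatureTable", "oob_error", "per_class_confusion"]


@dataclass
class FeatureTable:
    """Numeric features plus a manual label per unit exemplar."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        if self.labels.isna().any():
            raise ValueError("labels must not be missing")
        if not all(np.issubdtype(dt, np.number) for dt in self.features.dtypes):
            raise ValueError("all feature columns must be numeric")
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 classes")
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(
                f"classes with a single exemplar: {', '.join(map(str, thin.index))}"
            )

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = "label"
                 ) -> "FeatureTable":
        df = pd.read_csv(path)
        if label_column not in df.columns:
            raise ValueError(f"missing label column {label_column!r}")
        return cls(df.drop(columns=[label_column]), df[label_column])

    def to_csv(self, path: str | Path) -> None:
        out = self.features.copy()
        out["label"] = self.labels.to_numpy()
        out.to_csv(path, index=False)

    def canonical_order(self) -> "FeatureTable":
        """Sort rows by (label, feature values) so results are invariant to
        the row order of the input file."""
        df = self.features.copy()
        df["__label"] = self.labels.to_numpy()
        df = df.sort_values(
            ["__label"] + list(self.features.columns), kind="mergesort"
        ).reset_index(drop=True)
        return FeatureTable(df.drop(columns="__label"), df["__label"].rename("label"))


def _oob_votes(
    table: FeatureTable, n_trees: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(labels, predictions, valid mask, class order) from OOB votes."""
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    table = table.canonical_order()
    x = table.features.to_numpy(float)
    y = table.labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    votes = forest.oob_decision_function_
    valid = ~np.isnan(votes).any(axis=1)
    preds = np.empty(len(y), dtype=object)
    preds[valid] = forest.classes_[np.argmax(votes[valid], axis=1)]
    return y, preds, valid, forest.classes_


def oob_error(table: FeatureTable, n_trees: int = 500, seed: int = 0) -> float:
    """OOB misclassification rate in [0, 1].

    Deterministic for a fixed seed and invariant to input row order.
    Exemplars never left out of bag (vanishingly rare for >= 100 trees) are
    excluded from the denominator.
    """
    y, preds, valid, _ = _oob_votes(table, n_trees, seed)
    if not valid.any():
        raise RuntimeError("no exemplar received an OOB vote")
    return float(np.mean(preds[valid] != y[valid]))


def per_class_confusion(
    table: FeatureTable, n_trees: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Confusion matrix of OOB votes (rows: manual label, columns: vote).

    Row sums equal class sizes (minus any never-OOB exemplars), and
    trace / total = 1 - :func:`oob_error` for the same seed.
    """
    y, preds, valid, classes = _oob_votes(table, n_trees, seed)
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for truth, vote in zip(y[valid], preds[valid]):
        mat.loc[truth, vote] += 1
    mat.index.name = "manual"
    mat.columns.name = "oob_vote"
    return mat
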