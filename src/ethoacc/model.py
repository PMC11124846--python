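"""Ensemble-tree behavior classification and confusion-matrix metrics.

The modeling surface follows the Model/Results convention: a
:class:`BehaviorClassifier` is built from a feature table, ``fit``
returns a :class:`BehaviorClassifierResults` carrying the fitted forest,
its feature importances and a ``summary()`` table, and evaluation
produces a :class:`MetricsReport` with the confusion matrix and the
per-class rates

    sensitivity = TP / (TP + FN)        (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)

with overall accuracy = trace / total.  Rates whose denominator is zero
are reported as ``None`` (undefined), never as 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .behaviors import FULL, GroupingScheme
from .features import feature_columns

DEFAULT_HYPERPARAMS: Mapping[str, object] = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "max_depth": None,
    "min_samples_leaf": 1,
}


def group_labels(epochs: pd.DataFrame, scheme: GroupingScheme) -> pd.DataFrame:
    """Relabel the ``behavior`` column under a grouping scheme.

    Behaviors the scheme maps to ``None`` are dropped from the table.
    """
    out = epochs.copy()
    out["behavior"] = [scheme.apply(b) for b in out["behavior"]]
    return out[out["behavior"].notna()].reset_index(drop=True)


@dataclass(frozen=True)
class SplitSpec:
    """70/30 train/test split, stratified by (animal, label)."""

    train_fraction: float = 0.70
    stratify_by: tuple[str, ...] = ("animal_id", "behavior")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_train_test(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split.

    Within each stratum the train share is within one row of the target
    fraction.  Strata with a single row fall back to a global random
    assignment (with a warning).
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    keys = [k for k in spec.stratify_by if k in table.columns]
    train_idx: list[np.ndarray] = []
    singletons: list[int] = []
    groups = table.groupby(list(keys)).indices if keys else {"all": np.arange(len(table))}
    for _, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        idx = np.asarray(idx)
        if idx.size < 2:
            singletons.extend(idx.tolist())
            continue
        perm = rng.permutation(idx)
        n_train = int(round(spec.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(perm[:n_train])
    if singletons:
        warnings.warn(
            f"{len(singletons)} singleton strata assigned by a global draw", stacklevel=2
        )
        singles = np.asarray(singletons)
        pick = rng.random(singles.size) < spec.train_fraction
        train_idx.append(singles[pick])
    train_mask = np.zeros(len(table), dtype=bool)
    if train_idx:
        train_mask[np.concatenate(train_idx)] = True
    pos = np.arange(len(table))
    return (
        table.iloc[pos[train_mask]].reset_index(drop=True),
        table.iloc[pos[~train_mask]].reset_index(drop=True),
    )


@dataclass
class MetricsReport:
    """Confusion matrix plus overall and per-class performance."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true, columns = predicted
    accuracy: float
    sensitivity: Mapping[str, Optional[float]]
    specificity: Mapping[str, Optional[float]]
    precision: Mapping[str, Optional[float]]

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Optional[Sequence[str]] = None,
    ) -> "MetricsReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError(
                f"length mismatch: {y_true.size} true vs {y_pred.size} predicted labels"
            )
        if y_true.size == 0:
            raise ValueError("need at least one labeled instance")
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = tuple(classes)
        cm = confusion_matrix(y_true, y_pred, labels=list(classes))
        total = cm.sum()
        accuracy = float(np.trace(cm)) / total
        sens: dict[str, Optional[float]] = {}
        spec: dict[str, Optional[float]] = {}
        prec: dict[str, Optional[float]] = {}
        for i, c in enumerate(classes):
            tp = cm[i, i]
            fn = cm[i, :].sum() - tp
            fp = cm[:, i].sum() - tp
            tn = total - tp - fn - fp
            sens[c] = float(tp / (tp + fn)) if tp + fn > 0 else None
            spec[c] = float(tn / (tn + fp)) if tn + fp > 0 else None
            prec[c] = float(tp / (tp + fp)) if tp + fp > 0 else None
        undefined = [c for c in classes if sens[c] is None or prec[c] is None]
        if undefined:
            warnings.warn(
                f"metrics undefined (zero denominator) for classes {undefined}", stacklevel=2
            )
        return cls(classes, cm, accuracy, sens, spec, prec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
            }
        ).rename_axis("class")

    def to_json(self) -> str:
        def r(v):
            return None if v is None else round(v, 4)

        return json.dumps(
            {
                "classes": list(self.classes),
                "confusion": {
                    c: {p: int(self.confusion[i, j]) for j, p in enumerate(self.classes)}
                    for i, c in enumerate(self.classes)
                },
                "accuracy": r(self.accuracy),
                "sensitivity": {c: r(v) for c, v in self.sensitivity.items()},
                "specificity": {c: r(v) for c, v in self.specificity.items()},
                "precision": {c: r(v) for c, v in self.precision.items()},
            },
            indent=2,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def confusion_and_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Confusion matrix and accuracy/sensitivity/specificity/precision."""
    return MetricsReport.from_labels(y_true, y_pred, classes)


class BehaviorClassifier:
    """Ensemble-of-decision-trees behavior classifier on a feature table.

    Parameters
    ----------
    table
        Feature table with a ``behavior`` label column; key and label
        columns are excluded from the predictors automatically.
    scheme
        Optional grouping scheme applied to the labels before fitting.
    hyperparams
        Forest hyperparameters; defaults are 500 trees, sqrt(p) features
        per split and unlimited depth.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        scheme: GroupingScheme = FULL,
        label_col: str = "behavior",
        **hyperparams,
    ) -> None:
        if scheme is not FULL:
            table = group_labels(table, scheme)
        if label_col not in table.columns:
            raise ValueError(f"table has no label column {label_col!r}")
        self.table = table
        self.scheme = scheme
        self.label_col = label_col
        self.feature_names: list[str] = feature_columns(table)
        self.hyperparams = {**DEFAULT_HYPERPARAMS, **hyperparams}

        y = table[label_col]
        if y.nunique() < 2:
            raise ValueError("training data contain a single class; need at least two")
        X = table[self.feature_names].to_numpy(dtype=float)
        bad = [
            c
            for c, finite in zip(self.feature_names, np.isfinite(X).all(axis=0))
            if not finite
        ]
        if bad:
            raise ValueError(f"non-finite feature values in columns {bad}")
        self._X = X
        self._y = y.to_numpy()

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, scheme: GroupingScheme = FULL, **kw):
        return cls(table, scheme=scheme, **kw)

    def fit(self, seed: int = 0) -> "BehaviorClassifierResults":
        est = RandomForestClassifier(
            n_estimators=int(self.hyperparams["n_estimators"]),
            max_features=self.hyperparams["max_features"],
            max_depth=self.hyperparams["max_depth"],
            min_samples_leaf=int(self.hyperparams["min_samples_leaf"]),
            random_state=int(seed),
            n_jobs=1,
        )
        est.fit(self._X, self._y)
        return BehaviorClassifierResults(self, est, seed)


class BehaviorClassifierResults:
    """Fitted classifier: predictions, evaluation, importances, summary."""

    def __init__(self, model: Optional[BehaviorClassifier], estimator, seed: int) -> None:
        self.model = model
        self.estimator = estimator
        self.seed = seed
        if model is not None:
            self.feature_names = list(model.feature_names)
            self.scheme_name = model.scheme.name
        self.classes_: tuple[str, ...] = tuple(estimator.classes_)

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.estimator.feature_importances_, index=self.feature_names
        ).sort_values(ascending=False)

    def _check_schema(self, table: pd.DataFrame) -> np.ndarray:
        cols = feature_columns(table)
        if cols != self.feature_names:
            missing = [c for c in self.feature_names if c not in cols]
            extra = [c for c in cols if c not in self.feature_names]
            detail = []
            if missing:
                detail.append(f"missing {missing}")
            if extra:
                detail.append(f"unexpected {extra}")
            if not detail:
                detail.append(f"column order differs: got {cols[:5]}..., "
                              f"expected {self.feature_names[:5]}...")
            raise ValueError("feature schema mismatch: " + "; ".join(detail))
        return table[self.feature_names].to_numpy(dtype=float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if len(table) == 0:
            return np.array([], dtype=object)
        return self.estimator.predict(self._check_schema(table))

    def evaluate(self, table: pd.DataFrame, label_col: str = "behavior") -> MetricsReport:
        if self.model is not None and self.model.scheme is not FULL:
            scheme = self.model.scheme
            if not set(table[label_col]).issubset(scheme.groups):
                table = group_labels(table, scheme)
        y_pred = self.predict(table)
        return MetricsReport.from_labels(
            table[label_col].to_numpy(), y_pred, classes=self.classes_
        )

    def summary(self) -> str:
        hp = self.model.hyperparams if self.model is not None else {}
        lines = [
            "Behavior classifier (random forest)",
            "=" * 46,
            f"scheme:          {getattr(self, 'scheme_name', '?')}",
            f"classes:         {', '.join(self.classes_)}",
            f"n train rows:    {len(self.model.table) if self.model is not None else '?'}",
            f"n features:      {len(self.feature_names)}",
            f"trees:           {hp.get('n_estimators', '?')}",
            f"max features:    {hp.get('max_features', '?')}",
            f"seed:            {self.seed}",
            "",
            "top feature importances:",
        ]
        for name, v in self.feature_importances.head(8).items():
            lines.append(f"  {name:<22s} {v:6.3f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        joblib.dump(
            {
                "estimator": self.estimator,
                "feature_names": self.feature_names,
                "scheme_name": getattr(self, "scheme_name", None),
                "classes": list(self.classes_),
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "BehaviorClassifierResults":
        blob = joblib.load(path)
        out = cls(None, blob["estimator"], blob.get("seed", 0))
        out.feature_names = blob["feature_names"]
        out.scheme_name = blob.get("scheme_name")
        return out


def train_classifier(
    train: pd.DataFrame,
    hyperparams: Optional[Mapping[str, object]] = None,
    seed: int = 0,
) -> BehaviorClassifierResults:
    """Functional wrapper: build and fit a classifier on a training table."""
    return BehaviorClassifier(train, **(dict(hyperparams) if hyperparams else {})).fit(seed)


def predict(results: BehaviorClassifierResults, table: pd.DataFrame) -> np.ndarray:
    return results.predict(table)
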