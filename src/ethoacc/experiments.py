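"""The study's experiment orchestration.

Three experiments around the windowed-feature classifier:

* **window sweep** — re-extract features at smoothing windows from 1 to
  60 s, train and evaluate a classifier at each window, and find where
  the accuracy curve plateaus;
* **data reduction** — bootstrap a learning curve by structured
  subsampling (each animal keeps its original behavior composition) at
  a grid of retention proportions;
* **source comparison** — train and evaluate separately per observation
  source on size-matched subsets.

Curves are tidy DataFrames with one row per (x, metric, class):
``experiment, x, metric, class, scheme, mean, sd, stderr, n_replicates,
seed, config_hash``.  Every experiment is deterministic given its seed.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .behaviors import FULL, GroupingScheme
from .core import BehaviorBout, SignalFrame
from .features import WindowSpec, extract_features
from .ingest import join_labels_all
from .model import (
    BehaviorClassifier,
    MetricsReport,
    SplitSpec,
    group_labels,
    split_train_test,
)

#: Forest size used by the experiment loops.  The classifier's own
#: default (500 trees) is kept for single fits; the sweep and bootstrap
#: train hundreds of forests, and on well-separated behavior data the
#: out-of-bag error of a random forest is flat well below 100 trees, so
#: the experiment loops run 100-tree forests by default (overridable via
#: ``hyperparams``).
DESK_N_ESTIMATORS = 100

#: Desk-scale retention grid; the full study grid is 1..100%.
DESK_PROPORTIONS = (0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 1.00)

DEFAULT_WINDOWS = (1, 2, 5, 10, 15, 20, 30, 60)


@dataclass(frozen=True)
class ReductionSpec:
    """Grid and bootstrap size for the data-reduction experiment."""

    proportions: Sequence[float] = DESK_PROPORTIONS
    bootstrap_B: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < p <= 1 for p in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")


def _config_hash(**params) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:10]


def _metric_rows(report: MetricsReport):
    yield ("accuracy", "", report.accuracy)
    for name, table in (
        ("sensitivity", report.sensitivity),
        ("specificity", report.specificity),
        ("precision", report.precision),
    ):
        for cls, v in table.items():
            if v is not None:
                yield (name, cls, v)


def _aggregate(
    replicates: pd.DataFrame, experiment: str, scheme: str, seed: int, cfg: str
) -> pd.DataFrame:
    g = replicates.groupby(["x", "metric", "class"])["value"]
    curve = g.agg(mean="mean", sd=lambda v: v.std(ddof=0), n_replicates="count").reset_index()
    curve["stderr"] = curve["sd"] / np.sqrt(curve["n_replicates"])
    curve["experiment"] = experiment
    curve["scheme"] = scheme
    curve["seed"] = seed
    curve["config_hash"] = cfg
    return curve[
        ["experiment", "x", "metric", "class", "scheme", "mean", "sd", "stderr",
         "n_replicates", "seed", "config_hash"]
    ]


def _fit_and_score(
    table: pd.DataFrame,
    scheme: GroupingScheme,
    seed: int,
    hyperparams: Optional[Mapping[str, object]],
) -> MetricsReport:
    grouped = group_labels(table, scheme) if scheme is not FULL else table
    train, test = split_train_test(grouped, SplitSpec(seed=seed))
    hp = {"n_estimators": DESK_N_ESTIMATORS, **(hyperparams or {})}
    results = BehaviorClassifier(train, **hp).fit(seed)
    return results.evaluate(test)


def window_sweep(
    frames: Sequence[SignalFrame],
    epochs: pd.DataFrame,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    scheme: GroupingScheme = FULL,
    seed: int = 0,
    n_replicates: int = 1,
    hyperparams: Optional[Mapping[str, object]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/evaluate at each smoothing window; return (curve, replicates).

    For each window the features are re-extracted at 1-s epochs, split
    70/30 (stratified by animal and label), fitted and scored.
    Replicate ``r`` uses split/train seed ``seed + r``.
    """
    cfg = _config_hash(windows=tuple(windows), scheme=scheme.name, seed=seed,
                       n_replicates=n_replicates)
    rows = []
    for w in windows:
        tables = [
            extract_features(f, WindowSpec(window_s=int(w)), labels=epochs) for f in frames
        ]
        table = pd.concat([t for t in tables if len(t)], ignore_index=True) if any(
            len(t) for t in tables
        ) else pd.DataFrame()
        if len(table) == 0:
            warnings.warn(f"window {w}s produced an empty feature table; skipped",
                          stacklevel=2)
            continue
        for r in range(n_replicates):
            report = _fit_and_score(table, scheme, seed + r, hyperparams)
            rows.extend((w, r, m, c, v) for m, c, v in _metric_rows(report))
    replicates = pd.DataFrame(rows, columns=["x", "replicate", "metric", "class", "value"])
    return _aggregate(replicates, "window_sweep", scheme.name, seed, cfg), replicates


def sweep_feature_tables(
    frames: Sequence[SignalFrame],
    epochs: pd.DataFrame,
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> dict[int, pd.DataFrame]:
    """Pre-extract per-window feature tables (reusable across schemes)."""
    out: dict[int, pd.DataFrame] = {}
    for w in windows:
        tables = [
            extract_features(f, WindowSpec(window_s=int(w)), labels=epochs) for f in frames
        ]
        tables = [t for t in tables if len(t)]
        if tables:
            out[int(w)] = pd.concat(tables, ignore_index=True)
    return out


def window_sweep_from_tables(
    tables: Mapping[int, pd.DataFrame],
    scheme: GroupingScheme = FULL,
    seed: int = 0,
    n_replicates: int = 1,
    hyperparams: Optional[Mapping[str, object]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """As :func:`window_sweep` but over pre-extracted feature tables."""
    cfg = _config_hash(windows=tuple(tables), scheme=scheme.name, seed=seed,
                       n_replicates=n_replicates)
    rows = []
    for w in sorted(tables):
        for r in range(n_replicates):
            report = _fit_and_score(tables[w], scheme, seed + r, hyperparams)
            rows.extend((w, r, m, c, v) for m, c, v in _metric_rows(report))
    replicates = pd.DataFrame(rows, columns=["x", "replicate", "metric", "class", "value"])
    return _aggregate(replicates, "window_sweep", scheme.name, seed, cfg), replicates


def structured_subsample(table: pd.DataFrame, proportion: float, seed: int = 0) -> pd.DataFrame:
    """Subsample while preserving each animal's behavior composition.

    Within each (animal, behavior) cell, ``round(p * n_cell)`` rows
    (half-up) are retained without replacement.  ``p = 1`` returns the
    table unchanged.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    if proportion == 1.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _, idx in sorted(
        table.groupby(["animal_id", "behavior"]).indices.items(), key=lambda kv: str(kv[0])
    ):
        idx = np.asarray(idx)
        n_keep = int(math.floor(proportion * idx.size + 0.5))
        if n_keep:
            keep.append(rng.choice(idx, size=n_keep, replace=False))
    if not keep:
        return table.iloc[:0].copy()
    sel = np.sort(np.concatenate(keep))
    return table.iloc[sel].reset_index(drop=True)


def data_reduction_experiment(
    table: pd.DataFrame,
    spec: ReductionSpec = ReductionSpec(),
    scheme: GroupingScheme = FULL,
    hyperparams: Optional[Mapping[str, object]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap learning curve over retention proportions.

    For each proportion, ``bootstrap_B`` replicates of subsample →
    split → train → evaluate; the curve reports mean, sd and standard
    error per metric, and the full replicate table is returned.
    """
    cfg = _config_hash(proportions=tuple(spec.proportions), B=spec.bootstrap_B,
                       scheme=scheme.name, seed=spec.seed)
    rows = []
    for pi, p in enumerate(spec.proportions):
        for b in range(spec.bootstrap_B):
            rep_seed = spec.seed + 7919 * pi + b
            sub = structured_subsample(table, float(p), seed=rep_seed)
            grouped = group_labels(sub, scheme) if scheme is not FULL else sub
            if len(grouped) == 0 or grouped["behavior"].nunique() < 2:
                warnings.warn(
                    f"proportion {p} leaves fewer than two classes; skipped", stacklevel=2
                )
                rows = [row for row in rows if row[0] != p]
                break
            report = _fit_and_score(sub, scheme, rep_seed, hyperparams)
            rows.extend((p, b, m, c, v) for m, c, v in _metric_rows(report))
    replicates = pd.DataFrame(rows, columns=["x", "replicate", "metric", "class", "value"])
    return _aggregate(replicates, "data_reduction", scheme.name, spec.seed, cfg), replicates


def compare_sources(
    table: pd.DataFrame,
    scheme: GroupingScheme = FULL,
    seed: int = 0,
    n_replicates: int = 1,
    hyperparams: Optional[Mapping[str, object]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-source train/evaluate on size-matched subsets.

    The larger source is down-sampled to the smaller source's
    per-behavior counts so the comparison is not confounded by data
    volume.  Returns (per-source curve, deltas in_pasture − collar_video).
    """
    sources = sorted(set(table["source"]))
    if len(sources) < 2:
        raise ValueError(f"need both observation sources, found {sources}")
    cfg = _config_hash(scheme=scheme.name, seed=seed, n_replicates=n_replicates)
    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        matched = {}
        counts = table.groupby(["source", "behavior"])["epoch_utc"].count()
        for src in sources:
            parts = []
            for b in sorted(set(table["behavior"])):
                n = min(
                    int(counts.get((s, b), 0)) for s in sources
                )
                cell = table[(table["source"] == src) & (table["behavior"] == b)]
                if n and len(cell):
                    take = rng.choice(len(cell), size=min(n, len(cell)), replace=False)
                    parts.append(cell.iloc[np.sort(take)])
            matched[src] = pd.concat(parts, ignore_index=True)
        for src in sources:
            report = _fit_and_score(matched[src], scheme, seed + r, hyperparams)
            rows.extend((src, r, m, c, v) for m, c, v in _metric_rows(report))
    reps = pd.DataFrame(rows, columns=["x", "replicate", "metric", "class", "value"])
    curve = _aggregate(reps, "compare_sources", scheme.name, seed, cfg)
    wide = curve.pivot_table(index=["metric", "class"], columns="x", values="mean")
    deltas = (
        (wide.get("in_pasture") - wide.get("collar_video"))
        .rename("delta")
        .reset_index()
    )
    return curve, deltas


def plateau_detect(curve, metric: str = "accuracy", rel_tol: float = 0.01) -> float:
    """Smallest x whose mean metric is within ``rel_tol`` of the curve max.

    Accepts an experiment curve DataFrame (filtered to the overall row
    of ``metric``) or a pair of (x, y) sequences.
    """
    if isinstance(curve, pd.DataFrame):
        sub = curve[(curve["metric"] == metric) & (curve["class"] == "")]
        xs = sub["x"].to_numpy(dtype=float)
        ys = sub["mean"].to_numpy(dtype=float)
    else:
        xs, ys = (np.asarray(a, dtype=float) for a in curve)
    if xs.size == 0:
        raise ValueError("empty curve")
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    threshold = (1.0 - rel_tol) * ys.max()
    return float(xs[np.argmax(ys >= threshold)])


def synthetic_epoch_table(
    frames: Sequence[SignalFrame], schedule: Sequence[BehaviorBout]
) -> pd.DataFrame:
    """Ground-truth labeled epochs for a synthetic dataset."""
    return join_labels_all(frames, schedule)
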