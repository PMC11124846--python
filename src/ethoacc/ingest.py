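"""Reading, cleaning and time-aligning observation and sensor data.

Implements the study-design cleaning rules: 15-s collar-video clips in
which the animal switched behaviors are removed entirely; epochs whose
accelerometer signal contradicts the recorded behavior (for example a
"grazing" label over an upright, quiescent trace) are flagged by
configurable rules; and behavior bouts are joined to the nearest-in-time
GPS fix.

Epochs are integer UTC seconds; bouts are half-open intervals
[start, end) so boundaries never double-label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .behaviors import SOURCES, VocabularyError, normalize_label
from .core import VIDEO_CLIP_S, BehaviorBout, DataError, SignalFrame
from .features import STATIC_SPAN_S, compute_odba_vedba, static_dynamic_split

SIGNAL_COLUMNS = ("animal_id", "timestamp_utc", "ax_g", "ay_g", "az_g")
OBS_COLUMNS = ("animal_id", "start_utc", "end_utc", "behavior", "source")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


def _parse_time(col: pd.Series) -> np.ndarray:
    """Accept either numeric UTC seconds or ISO-8601 strings."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def read_signal_csv(path, max_gap_intervals: float = 2.0) -> list[SignalFrame]:
    """Read a collar acceleration CSV into validated signal frames.

    Rows are sorted by time per animal; a gap larger than
    ``max_gap_intervals`` sample intervals splits the recording into
    separate frames.  Duplicate or non-monotone timestamps raise a
    :class:`~ethoacc.core.DataError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    has_mag = all(c in df.columns for c in ("mx", "my", "mz"))
    frames: list[SignalFrame] = []
    for animal, sub in df.groupby("animal_id", sort=True):
        t = _parse_time(sub["timestamp_utc"])
        order = np.argsort(t, kind="stable")
        sub = sub.iloc[order]
        t = t[order]
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise DataError(
                f"{path}: duplicate or non-monotone timestamp for {animal} at sorted row {row}"
            )
        step = float(np.median(dt)) if dt.size else 1.0 / 40.0
        breaks = np.flatnonzero(dt > max_gap_intervals * step) + 1
        for chunk in np.split(np.arange(t.size), breaks):
            if chunk.size < 2:
                continue
            piece = sub.iloc[chunk]
            frames.append(
                SignalFrame(
                    animal_id=str(animal),
                    t=t[chunk],
                    ax=piece["ax_g"].to_numpy(float),
                    ay=piece["ay_g"].to_numpy(float),
                    az=piece["az_g"].to_numpy(float),
                    sample_rate=1.0 / step,
                    mx=piece["mx"].to_numpy(float) if has_mag else None,
                    my=piece["my"].to_numpy(float) if has_mag else None,
                    mz=piece["mz"].to_numpy(float) if has_mag else None,
                )
            )
    return frames


def read_observations(path) -> list[BehaviorBout]:
    """Read a behavior-observation CSV into validated, sorted bouts."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bouts: list[BehaviorBout] = []
    for _, row in df.iterrows():
        source = str(row["source"]).strip().lower()
        if source not in SOURCES:
            raise VocabularyError(f"unknown observation source {row['source']!r}")
        bouts.append(
            BehaviorBout(
                animal_id=str(row["animal_id"]),
                start_utc=float(_parse_time(pd.Series([row["start_utc"]]))[0]),
                end_utc=float(_parse_time(pd.Series([row["end_utc"]]))[0]),
                behavior=normalize_label(row["behavior"]),
                source=source,
                clip_id=str(row["clip_id"]) if "clip_id" in df.columns and pd.notna(row.get("clip_id")) else None,
            )
        )
    bouts.sort(key=lambda b: (b.animal_id, b.start_utc))
    for prev, cur in zip(bouts, bouts[1:]):
        if cur.animal_id == prev.animal_id and cur.start_utc < prev.end_utc - 1e-9:
            raise DataError(
                f"overlapping bouts for {cur.animal_id}: "
                f"[{prev.start_utc}, {prev.end_utc}) and [{cur.start_utc}, {cur.end_utc})"
            )
    return bouts


def _clip_groups(bouts: Sequence[BehaviorBout]) -> list[list[BehaviorBout]]:
    """Group collar-video bouts into 15-s clips.

    With explicit clip ids, grouping is by (animal, clip_id); otherwise
    each maximal temporally contiguous run of collar_video bouts is one
    clip (clips are an hour apart, so runs cannot merge).
    """
    groups: dict[tuple, list[BehaviorBout]] = {}
    anon: list[list[BehaviorBout]] = []
    ordered = sorted(bouts, key=lambda b: (b.animal_id, b.start_utc))
    current: list[BehaviorBout] = []
    for b in ordered:
        if b.clip_id is not None:
            groups.setdefault((b.animal_id, b.clip_id), []).append(b)
            continue
        if current and (
            b.animal_id != current[-1].animal_id
            or b.start_utc > current[-1].end_utc + 1e-9
        ):
            anon.append(current)
            current = []
        current.append(b)
    if current:
        anon.append(current)
    return list(groups.values()) + anon


def filter_video_clips(
    bouts: Sequence[BehaviorBout],
) -> tuple[list[BehaviorBout], list[BehaviorBout]]:
    """Remove collar-video clips during which the animal switched behavior.

    Any clip containing more than one distinct behavior is removed
    entirely; in-pasture bouts always pass through.  Returns
    ``(kept, removed)`` which partition the input.
    """
    kept = [b for b in bouts if b.source != "collar_video"]
    removed: list[BehaviorBout] = []
    for clip in _clip_groups([b for b in bouts if b.source == "collar_video"]):
        if len({b.behavior for b in clip}) > 1:
            removed.extend(clip)
        else:
            kept.extend(clip)
    kept.sort(key=lambda b: (b.animal_id, b.start_utc))
    removed.sort(key=lambda b: (b.animal_id, b.start_utc))
    return kept, removed


def join_labels(frame: SignalFrame, bouts: Sequence[BehaviorBout]) -> pd.DataFrame:
    """Label each whole epoch second covered by both the signal and a bout.

    An epoch second ``s`` is labeled when [s, s+1) lies inside the frame
    and inside one bout; seconds with signal but no bout are excluded.
    """
    t0, t1 = frame.t[0], frame.t[0] + frame.duration
    first_s = int(np.ceil(t0 - 1e-9))
    last_s = int(np.floor(t1 - 1 + 1e-9))
    rows = []
    for b in bouts:
        if b.animal_id != frame.animal_id:
            continue
        lo = max(first_s, int(np.ceil(b.start_utc - 1e-9)))
        hi = min(last_s, int(np.floor(b.end_utc - 1 + 1e-9)))
        for s in range(lo, hi + 1):
            rows.append((frame.animal_id, s, b.behavior, b.source))
    if not rows:
        warnings.warn(
            f"no temporal overlap between signal and bouts for {frame.animal_id}",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["animal_id", "epoch_utc", "behavior", "source"])
    out = pd.DataFrame(rows, columns=["animal_id", "epoch_utc", "behavior", "source"])
    return out.sort_values("epoch_utc", kind="stable").reset_index(drop=True)


def join_labels_all(
    frames: Sequence[SignalFrame], bouts: Sequence[BehaviorBout]
) -> pd.DataFrame:
    """Concatenate :func:`join_labels` over a set of frames."""
    tables = [join_labels(f, bouts) for f in frames]
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=["animal_id", "epoch_utc", "behavior", "source"])
    return pd.concat(tables, ignore_index=True)


@dataclass(frozen=True)
class MismatchRules:
    """Rule-based replacement for visual signal verification.

    A grazing epoch should show the head-down posture (static X near
    +1 g); a resting epoch should be quiescent (low VeDBA).  Thresholds
    of ``None`` disable a rule.
    """

    grazing_min_static_x: Optional[float] = 0.3
    resting_max_vedba: Optional[float] = 0.2
    window_s: float = 10.0

    @classmethod
    def disabled(cls) -> "MismatchRules":
        return cls(grazing_min_static_x=None, resting_max_vedba=None)


def flag_signal_mismatch(
    frame: SignalFrame,
    epochs: pd.DataFrame,
    rules: MismatchRules = MismatchRules(),
) -> pd.DataFrame:
    """Flag labeled epochs whose signal contradicts the recorded behavior.

    Returns the epoch table with boolean ``flagged`` and string
    ``flag_reason`` columns.  Statistics are centered means over
    ``rules.window_s`` around each epoch.
    """
    out = epochs.copy()
    out["flagged"] = False
    out["flag_reason"] = ""
    if rules.grazing_min_static_x is None and rules.resting_max_vedba is None:
        return out
    static, dynamic = static_dynamic_split(frame, STATIC_SPAN_S)
    _, vedba = compute_odba_vedba(
        dynamic["ax"].to_numpy(), dynamic["ay"].to_numpy(), dynamic["az"].to_numpy()
    )
    w = int(round(rules.window_s * frame.sample_rate))
    static_x = pd.Series(static["ax"]).rolling(w, center=True, min_periods=1).mean().to_numpy()
    vedba_m = pd.Series(vedba).rolling(w, center=True, min_periods=1).mean().to_numpy()
    idx = np.round((out["epoch_utc"].to_numpy() + 0.5 - frame.t[0]) * frame.sample_rate)
    idx = np.clip(idx.astype(int), 0, frame.n_samples - 1)
    same = out["animal_id"] == frame.animal_id
    if rules.grazing_min_static_x is not None:
        bad = same & (out["behavior"] == "grazing") & (static_x[idx] < rules.grazing_min_static_x)
        out.loc[bad, "flagged"] = True
        out.loc[bad, "flag_reason"] = "grazing_static_x_low"
    if rules.resting_max_vedba is not None:
        bad = same & (out["behavior"] == "resting") & (vedba_m[idx] > rules.resting_max_vedba)
        out.loc[bad, "flagged"] = True
        out.loc[bad, "flag_reason"] = "resting_vedba_high"
    return out


def nearest_gps_join(
    bouts: Sequence[BehaviorBout], fixes: pd.DataFrame
) -> pd.DataFrame:
    """Annotate each bout with its nearest-in-time GPS fix.

    The fix minimizing |fix time - bout midpoint| wins; exact ties go to
    the earlier fix.  ``fix_dt`` is the signed offset fix - midpoint.
    """
    have = set(fixes["animal_id"].astype(str))
    need = {b.animal_id for b in bouts}
    missing = sorted(need - have)
    if missing:
        raise DataError(f"no GPS fixes for animals {missing}")
    by_animal = {
        str(a): sub.sort_values("timestamp_utc", kind="stable")
        for a, sub in fixes.groupby("animal_id")
    }
    rows = []
    for b in bouts:
        sub = by_animal[b.animal_id]
        times = sub["timestamp_utc"].to_numpy(dtype=float)
        mid = b.midpoint
        j = int(np.searchsorted(times, mid))
        cands = [k for k in (j - 1, j) if 0 <= k < times.size]
        # earlier fix wins ties because candidates are scanned in time order
        best = min(cands, key=lambda k: abs(times[k] - mid))
        rows.append(
            (
                b.animal_id,
                b.start_utc,
                b.end_utc,
                b.behavior,
                b.source,
                float(sub["lon"].to_numpy()[best]),
                float(sub["lat"].to_numpy()[best]),
                float(times[best] - mid),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "start_utc", "end_utc", "behavior", "source", "lon", "lat", "fix_dt"],
    )


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EthogramSummary:
    """Second counts and percentage shares per behavior (and per source)."""

    overall: pd.DataFrame
    by_source: pd.DataFrame
    total_seconds: int

    def percent(self, behavior: str) -> float:
        row = self.overall.loc[self.overall["behavior"] == behavior, "percent"]
        if row.empty:
            raise KeyError(behavior)
        return float(row.iloc[0])


def summarize_ethogram(
    epochs_or_counts, total: Optional[int] = None
) -> EthogramSummary:
    """Summarize observed seconds and percentage share per behavior.

    Accepts either a labeled-epoch table or a mapping behavior -> second
    count.  ``total`` overrides the percentage denominator (useful when
    reproducing printed summaries whose total is stated separately);
    by default it is the sum of the counts.  Percentages are rounded
    half-away-from-zero at one decimal.
    """
    if isinstance(epochs_or_counts, Mapping):
        counts = {normalize_label(k): int(v) for k, v in epochs_or_counts.items()}
        by_source = pd.DataFrame(columns=["source", "behavior", "seconds", "percent"])
    else:
        epochs = epochs_or_counts
        if epochs is None or len(epochs) == 0:
            raise ValueError("cannot summarize an empty epoch table")
        counts = epochs.groupby("behavior")["epoch_utc"].count().to_dict()
        src = (
            epochs.groupby(["source", "behavior"])["epoch_utc"].count().reset_index()
        ).rename(columns={"epoch_utc": "seconds"})
        src["percent"] = [
            _round_half_up(100.0 * s / src.loc[src["source"] == row_src, "seconds"].sum())
            for row_src, s in zip(src["source"], src["seconds"])
        ]
        by_source = src
    denom = int(total) if total is not None else int(sum(counts.values()))
    if denom <= 0:
        raise ValueError("total must be positive")
    overall = pd.DataFrame(
        {
            "behavior": list(counts),
            "seconds": [counts[b] for b in counts],
        }
    ).sort_values("seconds", ascending=False, ignore_index=True)
    overall["percent"] = [_round_half_up(100.0 * s / denom) for s in overall["seconds"]]
    return EthogramSummary(overall, by_source, denom)


def seconds_to_hours(seconds: float, decimals: int = 1) -> float:
    """Convert seconds of observation to hours at the reporting precision."""
    return _round_half_up(seconds / 3600.0, decimals)
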