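"""Windowed feature extraction from raw collar signals.

The classifier consumes per-epoch (1 s) summary statistics of the raw
and dynamic acceleration.  For a smoothing window of ``w`` seconds and
trailing alignment, the epoch labeled second ``s`` summarizes the
``w * sample_rate`` samples in ``[s + 1 - w, s + 1)`` — the window ends
with the epoch's own second, so features are computable in real time.

Static acceleration is a centered running mean (gravity/posture);
dynamic acceleration is raw minus static.  From the dynamic channels:

    ODBA  = |dx| + |dy| + |dz|
    VeDBA = sqrt(dx^2 + dy^2 + dz^2)

which bound each other as VeDBA <= ODBA <= sqrt(3) * VeDBA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .core import DataError, MagnetometerTrace, SignalFrame

#: Default span of the centered running mean used for the static/dynamic
#: decomposition, seconds (biologging convention).
STATIC_SPAN_S = 2.0

KEY_COLUMNS = ("animal_id", "epoch_utc", "window_s")
LABEL_COLUMNS = ("behavior", "source")

_STATS = ("mean", "median", "sd", "min", "max")


@dataclass(frozen=True)
class WindowSpec:
    """Smoothing-window specification for per-epoch statistics."""

    window_s: int = 10
    epoch_step_s: int = 1
    alignment: str = "trailing"

    def __post_init__(self) -> None:
        if not 1 <= self.window_s <= 60:
            raise ValueError("window_s must lie in [1, 60]")
        if self.alignment not in ("trailing", "centered"):
            raise ValueError("alignment must be 'trailing' or 'centered'")


def static_dynamic_split(
    frame: SignalFrame, span_s: float = STATIC_SPAN_S
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split acceleration into static (posture) and dynamic components.

    Static is the centered running mean over ``span_s`` per axis, with
    edge windows shrunk to the available samples; dynamic is raw minus
    static exactly, so static + dynamic reconstructs the raw signal.
    """
    span = int(round(span_s * frame.sample_rate))
    if span < 2:
        raise ValueError(f"span of {span} samples is too short (need >= 2)")
    raw = pd.DataFrame({"ax": frame.ax, "ay": frame.ay, "az": frame.az})
    static = raw.rolling(span, center=True, min_periods=1).mean()
    dynamic = raw - static
    return static, dynamic


def butterworth_filter(
    channel: np.ndarray,
    kind: str,
    cutoff_hz: float,
    sample_rate: float,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filter of one channel.

    Because the filter runs forward and backward, the effective
    amplitude response is the squared magnitude of the analog design.
    """
    if kind not in ("low", "high"):
        raise ValueError("kind must be 'low' or 'high'")
    nyq = sample_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = _sig.butter(order, cutoff_hz, btype=kind, fs=sample_rate, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(channel, dtype=float))


def compute_odba_vedba(
    dx: np.ndarray, dy: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample overall (L1) and vectorial (L2) dynamic body acceleration."""
    dx, dy, dz = (np.asarray(a, dtype=float) for a in (dx, dy, dz))
    odba = np.abs(dx) + np.abs(dy) + np.abs(dz)
    vedba = np.sqrt(dx**2 + dy**2 + dz**2)
    return odba, vedba


def resample_magnetometry(mag: MagnetometerTrace, target_t: np.ndarray) -> pd.DataFrame:
    """Linearly interpolate magnetometry onto the acceleration time base.

    End values are held constant for target times beyond the
    magnetometer record (no extrapolation).
    """
    target_t = np.asarray(target_t, dtype=float)
    if target_t[0] > mag.t[-1] or target_t[-1] < mag.t[0]:
        raise DataError("magnetometer and acceleration time ranges are disjoint")
    return pd.DataFrame(
        {
            "mx": np.interp(target_t, mag.t, mag.mx),
            "my": np.interp(target_t, mag.t, mag.my),
            "mz": np.interp(target_t, mag.t, mag.mz),
        }
    )


def _window_stat_columns(rolled: dict[str, pd.core.window.Rolling], channels: Sequence[str]):
    cols = {}
    for ch in channels:
        r = rolled[ch]
        cols[f"mean_{ch}"] = r.mean()
        cols[f"median_{ch}"] = r.median()
        cols[f"sd_{ch}"] = r.std(ddof=0)  # population sd
        cols[f"min_{ch}"] = r.min()
        cols[f"max_{ch}"] = r.max()
    return cols


def window_features(
    frame: SignalFrame,
    dynamic: pd.DataFrame,
    odba: np.ndarray,
    vedba: np.ndarray,
    spec: WindowSpec,
    mag: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-epoch window statistics of all channels.

    Returns one row per whole epoch second whose window lies entirely
    inside the frame (partial edge windows are dropped).  Standard
    deviations are population (divisor N) statistics.
    """
    fs = frame.sample_rate
    w = int(round(spec.window_s * fs))
    n = frame.n_samples
    if w > n:
        warnings.warn(
            f"window of {spec.window_s}s exceeds frame of {n / fs:.1f}s; empty table",
            stacklevel=2,
        )
        return pd.DataFrame(columns=list(KEY_COLUMNS))

    chans = {
        "ax_g": frame.ax,
        "ay_g": frame.ay,
        "az_g": frame.az,
        "odba_g": np.asarray(odba, dtype=float),
        "vedba_g": np.asarray(vedba, dtype=float),
    }
    mag_cols: list[str] = []
    if mag is not None:
        for c in ("mx", "my", "mz"):
            chans[c] = np.asarray(mag[c], dtype=float)
            mag_cols.append(c)
    df = pd.DataFrame(chans)
    rolled = {ch: df[ch].rolling(w, min_periods=w) for ch in chans}
    stat_channels = ["ax_g", "ay_g", "az_g"] + mag_cols + ["odba_g", "vedba_g"]
    stats = pd.DataFrame(_window_stat_columns(rolled, stat_channels))

    # Epoch seconds: integer s with [s, s+1) inside the frame and the
    # window fully available.
    t0 = frame.t[0]
    first_s = int(np.ceil(t0 - 1e-9))
    last_s = int(np.floor(t0 + frame.duration - 1 + 1e-9))
    epochs = np.arange(first_s, last_s + 1)

    if spec.alignment == "trailing":
        # window [s + 1 - w_s, s + 1): last sample index of the window
        end_idx = np.round((epochs + 1 - t0) * fs).astype(int) - 1
    else:
        center = epochs + 0.5 - t0
        end_idx = np.round(center * fs + w / 2).astype(int) - 1
    valid = (end_idx - w + 1 >= 0) & (end_idx < n)
    epochs = epochs[valid]
    end_idx = end_idx[valid]
    if epochs.size == 0:
        warnings.warn("no complete windows fit inside the frame; empty table", stacklevel=2)
        return pd.DataFrame(columns=list(KEY_COLUMNS))

    # Raw snapshot at the last sample of the epoch's own second.
    snap_idx = np.round((epochs + 1 - t0) * fs).astype(int) - 1
    snap_idx = np.clip(snap_idx, 0, n - 1)

    out = {
        "animal_id": frame.animal_id,
        "epoch_utc": epochs,
        "window_s": spec.window_s,
        "ax_g": frame.ax[snap_idx],
        "ay_g": frame.ay[snap_idx],
        "az_g": frame.az[snap_idx],
    }
    for col in stats.columns:
        if col.split("_", 1)[1] in ("ax_g", "ay_g", "az_g"):
            out[col] = stats[col].to_numpy()[end_idx]
    out["dyn_ax_g"] = dynamic["ax"].to_numpy()[snap_idx]
    out["dyn_ay_g"] = dynamic["ay"].to_numpy()[snap_idx]
    out["dyn_az_g"] = dynamic["az"].to_numpy()[snap_idx]
    out["odba_g"] = chans["odba_g"][snap_idx]
    out["vedba_g"] = chans["vedba_g"][snap_idx]
    for ch in ("odba_g", "vedba_g"):
        for s in _STATS:
            out[f"{s}_{ch}"] = stats[f"{s}_{ch}"].to_numpy()[end_idx]
    if mag is not None:
        for c in mag_cols:
            out[c] = chans[c][snap_idx]
        for c in mag_cols:
            for s in _STATS:
                out[f"{s}_{c}"] = stats[f"{s}_{c}"].to_numpy()[end_idx]
    return pd.DataFrame(out)


def extract_features(
    frame: SignalFrame,
    spec: WindowSpec = WindowSpec(),
    labels: Optional[pd.DataFrame] = None,
    mag: Optional[MagnetometerTrace] = None,
    span_s: float = STATIC_SPAN_S,
) -> pd.DataFrame:
    """Full per-frame feature pipeline: split, DBA, window statistics.

    ``labels`` is a labeled-epoch table (animal_id, epoch_utc, behavior,
    source); when given, features are inner-joined to it so only labeled
    epochs are returned.
    """
    _, dynamic = static_dynamic_split(frame, span_s)
    odba, vedba = compute_odba_vedba(
        dynamic["ax"].to_numpy(), dynamic["ay"].to_numpy(), dynamic["az"].to_numpy()
    )
    mag_df = resample_magnetometry(mag, frame.t) if mag is not None else None
    table = window_features(frame, dynamic, odba, vedba, spec, mag_df)
    if labels is not None and len(table):
        table = table.merge(
            labels[["animal_id", "epoch_utc"] + [c for c in labels.columns if c in LABEL_COLUMNS]],
            on=["animal_id", "epoch_utc"],
            how="inner",
        )
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything but keys and labels)."""
    drop = set(KEY_COLUMNS) | set(LABEL_COLUMNS)
    return [c for c in table.columns if c not in drop]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV plus a sidecar JSON schema."""
    import pathlib

    path = pathlib.Path(path)
    table.to_csv(path, index=False)
    schema = {
        "window_s": sorted(int(w) for w in table["window_s"].unique()) if len(table) else [],
        "columns": list(table.columns),
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))
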