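"""Core data containers shared across the pipeline.

Axis convention (collar mounted upright): +X points forward, +Y right and
+Z down, so a resting animal reads +1 g on the Z axis.  This convention is
not universal in the biologging literature, so it is stated here once and
enforced by the synthetic generator and the signal-verification rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behaviors import normalize_label

#: Default accelerometer read rate, Hz.
ACCEL_RATE_HZ = 40.0
#: Default magnetometer read rate, Hz.
MAG_RATE_HZ = 10.0
#: GPS fix interval, seconds.
GPS_FIX_INTERVAL_S = 900.0
#: Duration of one collar video clip, seconds.
VIDEO_CLIP_S = 15.0


class DataError(ValueError):
    """Malformed sensor or observation data."""


@dataclass
class SignalFrame:
    """Uniformly sampled tri-axial acceleration for one animal.

    ``t`` holds UTC seconds; ``ax, ay, az`` hold acceleration in g.
    Optional magnetometer channels share the same time base (attach them
    via :func:`ethoacc.features.resample_magnetometry`).
    """

    animal_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = ACCEL_RATE_HZ
    mx: Optional[np.ndarray] = None
    my: Optional[np.ndarray] = None
    mz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("ax", "ay", "az"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise DataError(f"channel {name} length {arr.size} != t length {self.t.size}")
            setattr(self, name, arr)
        if self.t.size >= 2:
            dt = np.diff(self.t)
            step = 1.0 / self.sample_rate
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise DataError(f"timestamps not strictly increasing at row {bad + 1}")
            if not np.allclose(dt, step, atol=step * 0.01):
                raise DataError("timestamps not uniformly spaced at the stated sample rate")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Covered duration in seconds (one sample step past the last stamp)."""
        return self.n_samples / self.sample_rate

    @property
    def has_magnetometry(self) -> bool:
        return self.mx is not None and self.my is not None and self.mz is not None

    def accel(self) -> np.ndarray:
        """(n, 3) array of ax, ay, az."""
        return np.column_stack([self.ax, self.ay, self.az])

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp_utc": pd.to_datetime(self.t, unit="s", utc=True),
                "ax_g": self.ax,
                "ay_g": self.ay,
                "az_g": self.az,
            }
        )
        if self.has_magnetometry:
            out["mx"] = self.mx
            out["my"] = self.my
            out["mz"] = self.mz
        return out

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["timestamp_utc"] = df["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z"
        df.to_csv(path, index=False)


@dataclass
class MagnetometerTrace:
    """Tri-axial magnetometry (arbitrary units) on its own time base."""

    animal_id: str
    t: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    sample_rate: float = MAG_RATE_HZ


@dataclass(frozen=True)
class BehaviorBout:
    """A labeled interval of observed behavior, half-open [start_utc, end_utc)."""

    animal_id: str
    start_utc: float
    end_utc: float
    behavior: str
    source: str = "in_pasture"
    clip_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.end_utc > self.start_utc:
            raise DataError(
                f"bout end {self.end_utc} must exceed start {self.start_utc} "
                f"(animal {self.animal_id})"
            )
        object.__setattr__(self, "behavior", normalize_label(self.behavior))

    @property
    def duration(self) -> float:
        return self.end_utc - self.start_utc

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_utc + self.end_utc)


def bouts_to_dataframe(bouts: Sequence[BehaviorBout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [b.animal_id for b in bouts],
            "start_utc": [b.start_utc for b in bouts],
            "end_utc": [b.end_utc for b in bouts],
            "behavior": [b.behavior for b in bouts],
            "source": [b.source for b in bouts],
            "clip_id": [b.clip_id for b in bouts],
        }
    )


def write_bouts_csv(bouts: Sequence[BehaviorBout], path) -> None:
    df = bouts_to_dataframe(bouts)
    if df["clip_id"].isna().all():
        df = df.drop(columns="clip_id")
    df.to_csv(path, index=False)
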