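"""Time-series containers and their CSV formats.

``DecayCurve`` is the central exchange object: a (time, normalised
fluorescence) series, optionally with per-point SD and the number of axons
averaged.  ``RawTrace`` is the unprocessed per-axon record including the
pre/post-activation frames and the cumulative 488 nm exposure count used
for photobleach correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DecayCurve", "RawTrace"]


@dataclass
class DecayCurve:
    """A fluorescence decay series: times in seconds, dimensionless values."""

    times: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    n_axons: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd must match times in length")
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def normalized(self, reference_time: float | None = None) -> "DecayCurve":
        """Scale so the value at *reference_time* (default: first sample) is 1."""
        idx = 0 if reference_time is None else int(np.argmin(np.abs(self.times - reference_time)))
        ref = self.values[idx]
        if ref <= 0:
            raise ValueError("reference value must be positive to normalise")
        return DecayCurve(
            self.times.copy(),
            self.values / ref,
            None if self.sd is None else self.sd / ref,
            self.n_axons,
        )

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        data = {"time_s": self.times, "value": self.values}
        if self.sd is not None:
            data["sd"] = self.sd
        if self.n_axons is not None:
            data["n"] = np.full(len(self.times), self.n_axons, dtype=int)
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecayCurve":
        df = pd.read_csv(path)
        required = {"time_s", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: decay-curve CSV needs columns {sorted(required)}")
        return cls(
            df["time_s"].to_numpy(float),
            df["value"].to_numpy(float),
            df["sd"].to_numpy(float) if "sd" in df.columns else None,
            int(df["n"].iloc[0]) if "n" in df.columns else None,
        )


@dataclass
class RawTrace:
    """Per-axon intensity trace across the full imaging sequence.

    ``frame_labels`` are ``"pre"``, ``"post"`` and the post-activation
    minute marks as strings; ``times_s`` is NaN for the pre/post frames.
    ``exposure_index`` counts cumulative 488 nm fluorescence exposures
    (bright-field refocusing does not increment it).
    """

    frame_labels: list[str]
    times_s: np.ndarray
    intensities: np.ndarray
    exposure_index: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.exposure_index = np.asarray(self.exposure_index, dtype=float)
        n = len(self.frame_labels)
        if not (len(self.times_s) == len(self.intensities) == len(self.exposure_index) == n):
            raise ValueError("all RawTrace columns must have equal length")
        finite = self.exposure_index
        if np.any(np.diff(finite) < 0):
            raise ValueError("exposure_index must be non-decreasing")

    def timed_mask(self) -> np.ndarray:
        return np.isfinite(self.times_s)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "frame_label": self.frame_labels,
                "time_s": self.times_s,
                "intensity": self.intensities,
                "exposure_index": self.exposure_index.astype(int),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawTrace":
        df = pd.read_csv(path)
        required = {"frame_label", "time_s", "intensity", "exposure_index"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: raw-trace CSV needs columns {sorted(required)}")
        return cls(
            df["frame_label"].astype(str).tolist(),
            df["time_s"].to_numpy(float),
            df["intensity"].to_numpy(float),
            df["exposure_index"].to_numpy(float),
        )
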