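"""Time-intensity curves: the central measurement object.

A time-intensity curve (TIC) is the mean attenuation of one region of
interest (in Hounsfield units) sampled at each acquisition timepoint of a
dynamic contrast-enhanced CT series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CurveValidationError, InsufficientSamplesError

MIN_SAMPLES = 8


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Paired acquisition times (s) and mean ROI attenuation (HU).

    Parameters
    ----------
    times : array-like of float
        Acquisition times in seconds, strictly increasing, length >= 8.
    values : array-like of float
        Mean attenuation in HU at each time; finite, same length as times.
    roi_name : str
        Free-text ROI identifier, typically ``"tumor"`` or ``"pancreas"``.
    n_voxels : int or None
        Number of voxels averaged at each timepoint, when known.
    """

    times: np.ndarray
    values: np.ndarray
    roi_name: str = "roi"
    n_voxels: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise CurveValidationError(
                f"times and values must be 1-D of equal length, "
                f"got {t.shape} and {v.shape}"
            )
        if t.size < MIN_SAMPLES:
            raise InsufficientSamplesError(
                f"curve has {t.size} samples; at least {MIN_SAMPLES} required"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise CurveValidationError(
                "non-finite entries in curve; drop gaps before construction"
            )
        if np.any(np.diff(t) <= 0):
            raise CurveValidationError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times, "mean_hu": self.values})
        df["roi"] = self.roi_name
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the standard TIC CSV dialect: ``time_s,mean_hu,roi``."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roi_name: str | None = None
                 ) -> "TimeIntensityCurve":
        """Read a TIC CSV (header ``time_s,mean_hu[,roi]``)."""
        df = pd.read_csv(path)
        required = {"time_s", "mean_hu"}
        if not required.issubset(df.columns):
            raise CurveValidationError(
                f"TIC CSV {path} must contain columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        if roi_name is None:
            roi_name = str(df["roi"].iloc[0]) if "roi" in df.columns else "roi"
        return cls(df["time_s"].to_numpy(float),
                   df["mean_hu"].to_numpy(float), roi_name=roi_name)
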