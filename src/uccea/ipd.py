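"""Individual patient data (IPD) container shared across the package.

A single lightweight record-of-arrays holds right-censored time-to-event
data: observation times in months and an event flag (1 = event observed,
0 = right-censored).  Both simulated cohorts and pseudo-IPD reconstructed
from digitized Kaplan-Meier curves use this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IPD"]


@dataclass
class IPD:
    """Right-censored survival records.

    Parameters
    ----------
    times : array-like of float
        Observation times in months, strictly positive and finite.
    events : array-like of int
        1 if the event was observed at ``times[i]``, 0 if censored.
    label : str
        Free-form tag, e.g. ``"nivo_combo/OS"``.
    """

    times: np.ndarray
    events: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.size == 0:
            raise ValueError("IPD must contain at least one record")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have the same length")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite observation times")
        if np.any(self.times <= 0):
            raise ValueError("observation times must be strictly positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "IPD":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(), label)
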