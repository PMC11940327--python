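"""Data containers for cardiorespiratory recordings and derived event series.

Conventions used throughout the package:

* time is expressed in seconds from recording start,
* intervals are half-open ``[start, end)``,
* sample indexing is 0-based and channels share one uniform time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SignalRecording", "BreathSeries", "BeatSeries", "BaselineSummary"]


@dataclass
class SignalRecording:
    """Multichannel physiological recording on a uniform time base.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (the study protocol acquires at 1 kHz).
    flow : ndarray
        Expiratory airflow, L/s. Zero between expirations (one-way valve
        circuit measures expiration only).
    spo2 : ndarray
        Pulse-oximetry oxygen saturation, %.
    etco2 : ndarray, optional
        End-tidal CO2, mmHg.
    marker : ndarray, optional
        N2-administration on/off channel (0/1).
    beat_times : ndarray
        R-wave (beat) event times in seconds, strictly increasing.
    beat_ectopic_flags : ndarray of bool, optional
        Manual/annotated ectopic-beat flags aligned with ``beat_times``.
    n2_intervals : ndarray of shape (k, 2)
        Annotated N2 administration intervals ``[start, end)`` in seconds.
    """

    sample_rate: float
    flow: np.ndarray
    spo2: np.ndarray
    beat_times: np.ndarray
    etco2: Optional[np.ndarray] = None
    marker: Optional[np.ndarray] = None
    beat_ectopic_flags: Optional[np.ndarray] = None
    n2_intervals: Optional[np.ndarray] = None
    subject_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.etco2 is not None:
            self.etco2 = np.asarray(self.etco2, dtype=float)
        if self.marker is not None:
            self.marker = np.asarray(self.marker, dtype=float)
        if self.beat_ectopic_flags is not None:
            self.beat_ectopic_flags = np.asarray(self.beat_ectopic_flags, dtype=bool)
        if self.n2_intervals is not None:
            self.n2_intervals = np.asarray(self.n2_intervals, dtype=float).reshape(-1, 2)
        self.validate()

    def validate(self) -> None:
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        for name in ("spo2", "etco2", "marker"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != len(self.flow):
                raise ValidationError(f"channel {name!r} length differs from flow")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat_times must be strictly increasing")
        if self.spo2.size and (np.nanmin(self.spo2) < 0 or np.nanmax(self.spo2) > 100):
            raise ValidationError("spo2 must lie in [0, 100] %")
        if self.beat_ectopic_flags is not None and len(self.beat_ectopic_flags) != len(
            self.beat_times
        ):
            raise ValidationError("beat_ectopic_flags length differs from beat_times")

    @property
    def n_samples(self) -> int:
        return len(self.flow)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        """Uniform time base in seconds from recording start."""
        return np.arange(self.n_samples) / self.sample_rate

    def slice_indices(self, start: float, end: float) -> slice:
        """Sample slice covering the half-open time interval [start, end)."""
        i0 = int(np.ceil(start * self.sample_rate - 1e-9))
        i1 = int(np.ceil(end * self.sample_rate - 1e-9))
        return slice(max(i0, 0), min(max(i1, 0), self.n_samples))


@dataclass
class BreathSeries:
    """Per-breath event series: tidal volume, rate and minute ventilation.

    ``data`` columns: ``t_breath`` (expiration onset, s), ``vt`` (L),
    ``br`` (breaths/min, forward breath-to-breath period; the last breath
    inherits the previous period), ``vdot`` (L/min, = vt * br by
    construction).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"t_breath", "vt", "br", "vdot"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"BreathSeries missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["vt"] <= 0).any():
            raise ValidationError("tidal volumes must be positive")
        if len(self.data) and (self.data["br"] <= 0).any():
            raise ValidationError("breathing rates must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t_breath"].to_numpy()

    @property
    def vdot(self) -> np.ndarray:
        return self.data["vdot"].to_numpy()


@dataclass
class BeatSeries:
    """Per-beat event series with RR intervals and smoothed heart rate.

    ``data`` columns: ``t_beat`` (s), ``rr`` (s; NaN for the first beat),
    ``hr_raw`` (bpm, 60/rr; NaN where rr is not a physiological cycle,
    e.g. the interval spanning a removed ectopic), ``ectopic`` (bool
    flag), ``hr_smooth`` (bpm, 3-beat moving average; filled by
    :func:`chemoreflex.preprocess.smooth_hr`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"t_beat", "rr", "hr_raw", "ectopic"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"BeatSeries missing columns: {sorted(missing)}")
        t = self.data["t_beat"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t_beat"].to_numpy()

    @property
    def hr_smooth(self) -> np.ndarray:
        if "hr_smooth" not in self.data.columns:
            raise ValidationError("hr_smooth not computed; call smooth_hr first")
        return self.data["hr_smooth"].to_numpy()


@dataclass
class BaselineSummary:
    """Resting values averaged over the pre-test baseline window."""

    mean_vdot: float
    mean_hr: float
    mean_spo2: float
    mean_etco2: Optional[float]
    window: tuple = field(default=(0.0, 0.0))
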