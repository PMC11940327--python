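"""Event-level preprocessing: breath delineation, beat cleaning, baselines.

Turns raw channels into the event-indexed series the chemoreflex
estimator consumes: per-breath tidal volume / breathing rate /
instantaneous minute ventilation from the expiratory flow channel, and a
cleaned, 3-beat-smoothed beat-to-beat heart-rate series.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .recording import BaselineSummary, BeatSeries, BreathSeries, SignalRecording

__all__ = [
    "detect_breaths",
    "beats_from_times",
    "flag_ectopics",
    "remove_ectopics",
    "smooth_hr",
    "compute_baseline",
]

#: default breath-delineation parameters; the acquisition software's rule
#: is proprietary, so these are exposed and documented instead.
FLOW_THRESHOLD = 0.05  # L/s
MIN_BREATH_DURATION = 0.3  # s


def detect_breaths(
    recording: SignalRecording,
    flow_threshold: float = FLOW_THRESHOLD,
    min_duration: float = MIN_BREATH_DURATION,
) -> BreathSeries:
    """Delineate breaths on the expiratory flow channel.

    A breath is a maximal contiguous run of flow above ``flow_threshold``
    lasting at least ``min_duration``; its integration support is widened
    to the enclosing run of strictly positive flow so that threshold
    clipping does not bite into the tidal volume. Tidal volume is the
    trapezoidal integral of flow over that support; the instantaneous
    breathing rate of breath *i* uses the forward period
    ``60 / (t[i+1] - t[i])`` with the last breath inheriting the previous
    period; ``vdot = vt * br``.
    """
    if flow_threshold <= 0:
        raise ValidationError("flow_threshold must be positive")
    flow = recording.flow
    fs = recording.sample_rate
    pos = flow > 0
    above = flow > flow_threshold
    if not above.any():
        raise InsufficientDataError("no breaths detected: flow never exceeds threshold")

    # runs of positive flow
    d = np.diff(np.concatenate(([0], pos.astype(np.int8), [0])))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    min_samples = int(np.ceil(min_duration * fs))
    rows = []
    # cumulative sum of above-threshold mask lets us count per run cheaply
    cum_above = np.concatenate(([0], np.cumsum(above.astype(np.int64))))
    for i0, i1 in zip(run_starts, run_ends):
        if cum_above[i1] - cum_above[i0] < min_samples:
            continue
        vt = np.trapezoid(flow[i0:i1], dx=1.0 / fs)
        rows.append((i0 / fs, vt))
    if not rows:
        raise InsufficientDataError(
            "no breaths detected: no run above threshold lasts >= min_duration"
        )
    t = np.array([r[0] for r in rows])
    vt = np.array([r[1] for r in rows])
    periods = np.diff(t)
    if len(periods):
        periods = np.append(periods, periods[-1])  # last breath inherits
    else:
        periods = np.array([60.0 / 12.0])  # single breath: nominal period
    br = 60.0 / periods
    data = pd.DataFrame({"t_breath": t, "vt": vt, "br": br, "vdot": vt * br})
    return BreathSeries(data)


def beats_from_times(
    beat_times: np.ndarray, ectopic_flags: Optional[np.ndarray] = None
) -> BeatSeries:
    """Build a :class:`BeatSeries` from R-wave event times.

    RR of beat *i* is the backward interval ``t[i] - t[i-1]``; the first
    beat has no RR and carries NaN.
    """
    t = np.asarray(beat_times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise InsufficientDataError("need at least two beat times")
    rr = np.concatenate(([np.nan], np.diff(t)))
    flags = (
        np.zeros(len(t), dtype=bool)
        if ectopic_flags is None
        else np.asarray(ectopic_flags, dtype=bool)
    )
    data = pd.DataFrame(
        {"t_beat": t, "rr": rr, "hr_raw": 60.0 / rr, "ectopic": flags}
    )
    return BeatSeries(data)


def flag_ectopics(beats: BeatSeries, prematurity_threshold: float = 0.8) -> np.ndarray:
    """Flag premature beats by comparing each RR with its local median.

    A beat is flagged when its RR is shorter than
    ``prematurity_threshold`` times the median of the 11 RR intervals
    centred on it (fewer near the edges). Deterministic; the study used
    interactive vendor classification, for which this is the automated
    stand-in.
    """
    if len(beats) < 12:
        raise InsufficientDataError("ectopic flagging needs at least 12 beats")
    rr = beats.data["rr"].to_numpy()
    local_med = (
        pd.Series(rr).rolling(window=11, center=True, min_periods=5).median().to_numpy()
    )
    with np.errstate(invalid="ignore"):
        flags = rr < prematurity_threshold * local_med
    return np.nan_to_num(flags, nan=0.0).astype(bool)


def remove_ectopics(beats: BeatSeries, flags: Optional[np.ndarray] = None) -> BeatSeries:
    """Delete flagged ectopic beats and merge the disturbed RR intervals.

    The two intervals around a deleted beat merge into one recorded RR,
    but that merged interval is not a physiological cardiac cycle, so the
    beat closing it carries ``hr_raw = NaN`` and is excluded from
    smoothing and window statistics downstream.
    """
    if flags is None:
        flags = beats.data["ectopic"].to_numpy()
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(beats):
        raise ValidationError("flags must align with beats")
    if flags.all():
        raise ValidationError("all beats flagged ectopic; nothing left to analyse")
    if not flags.any():
        return BeatSeries(beats.data.copy().reset_index(drop=True))

    kept = beats.data.loc[~flags].reset_index(drop=True)
    t = kept["t_beat"].to_numpy()
    rr = np.concatenate(([np.nan], np.diff(t)))
    hr = 60.0 / rr
    # mark beats whose RR spans a deletion gap
    orig_idx = np.flatnonzero(~flags)
    post_gap = np.zeros(len(kept), dtype=bool)
    post_gap[1:] = np.diff(orig_idx) > 1
    hr[post_gap] = np.nan
    out = kept.copy()
    out["rr"] = rr
    out["hr_raw"] = hr
    out["ectopic"] = False
    return BeatSeries(out)


def smooth_hr(beats: BeatSeries) -> BeatSeries:
    """3-beat moving average of the beat-to-beat heart rate.

    ``hr_smooth[i]`` is the mean of the raw HR at beats ``i-1, i, i+1``;
    the first and last beats use the available 2-beat mean so that
    windows anchored near recording edges stay usable. NaN raw values
    (first beat, merged-gap beats) are ignored inside each window; a beat
    whose own raw HR is NaN keeps NaN.
    """
    if len(beats) < 3:
        raise InsufficientDataError("smoothing needs at least 3 beats")
    hr = beats.data["hr_raw"].to_numpy()
    sm = (
        pd.Series(hr).rolling(window=3, center=True, min_periods=1).mean().to_numpy()
    )
    sm[np.isnan(hr)] = np.nan
    out = beats.data.copy()
    out["hr_smooth"] = sm
    return BeatSeries(out)


def compute_baseline(
    recording: SignalRecording,
    breaths: BreathSeries,
    beats: BeatSeries,
    window_s: float = 600.0,
) -> BaselineSummary:
    """Resting values as the average of the pre-test baseline window.

    The window is the ``window_s`` seconds immediately preceding the
    first N2 administration (default 10 min). Minute ventilation is
    averaged over per-breath values, heart rate over per-beat smoothed
    values; SpO2 and etCO2 over samples.
    """
    if recording.n2_intervals is None or len(recording.n2_intervals) == 0:
        raise ValidationError("recording carries no N2 annotation intervals")
    first_start = float(recording.n2_intervals[0, 0])
    start = first_start - window_s
    if start < -1e-9:
        raise InsufficientDataError(
            f"baseline window needs {window_s:.0f} s of pre-test data but only "
            f"{first_start:.0f} s precede the first N2 administration"
        )
    sl = recording.slice_indices(start, first_start)
    bt = breaths.t
    in_b = (bt >= start) & (bt < first_start)
    if not in_b.any():
        raise InsufficientDataError("no breaths inside the baseline window")
    hr = (
        beats.data["hr_smooth"]
        if "hr_smooth" in beats.data.columns
        else beats.data["hr_raw"]
    ).to_numpy()
    tb = beats.t
    in_beat = (tb >= start) & (tb < first_start) & np.isfinite(hr)
    if not in_beat.any():
        raise InsufficientDataError("no beats inside the baseline window")
    return BaselineSummary(
        mean_vdot=float(breaths.vdot[in_b].mean()),
        mean_hr=float(hr[in_beat].mean()),
        mean_spo2=float(recording.spo2[sl].mean()),
        mean_etco2=(
            float(recording.etco2[sl].mean()) if recording.etco2 is not None else None
        ),
        window=(start, first_start),
    )
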