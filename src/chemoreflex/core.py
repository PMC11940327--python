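"""Chemoreflex sensitivity estimation from transient-hypoxia recordings.

For each N2-induced hypoxic episode two points are constructed per
response channel (minute ventilation or beat-to-beat heart rate):

* the *pre-hypoxic* point — mean SpO2 over the 60 s window immediately
  preceding the administration against the mean response over the same
  window;
* the *post-hypoxic* point — the SpO2 nadir (minimum within one minute
  after the administration ends) against the peak response inside a beat
  window running from 5 heartbeats before to 20 heartbeats after the
  nadir: the mean of the three largest consecutive per-breath minute
  ventilation values for the ventilatory channel, or the single highest
  3-beat-smoothed HR for the cardiac channel.

Pooling the points across episodes and regressing response on SpO2 gives
the hypoxic ventilatory response (HVR, L/min per % SpO2) or the HR slope
(bpm per %). Both are reported as slope *magnitudes*: the raw regression
slope is negative (response rises as SpO2 falls) and the published
convention is a positive sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, InsufficientDataError, ValidationError
from .preprocess import (
    beats_from_times,
    detect_breaths,
    flag_ectopics,
    remove_ectopics,
    smooth_hr,
)
from .recording import BeatSeries, BreathSeries, SignalRecording

__all__ = [
    "HypoxicEpisode",
    "ResponsePoint",
    "ChemoreflexResult",
    "segment_episodes",
    "pre_point",
    "post_point_ventilation",
    "post_point_hr",
    "fit_slope",
    "run_hvr",
    "run_hr_slope",
]

PRE_WINDOW_S = 60.0
NADIR_SEARCH_S = 60.0
BEATS_BEFORE_NADIR = 5
BEATS_AFTER_NADIR = 20
MIN_DESATURATION_PCT = 2.0  # episode-level QC: nadir must sit this far below pre-mean
MIN_EPISODES_DEFAULT = 3


@dataclass
class HypoxicEpisode:
    """One N2 administration with its nadir and validity bookkeeping."""

    index: int
    n2_start: float
    n2_end: float
    nadir_time: float = np.nan
    nadir_spo2: float = np.nan
    pre_spo2_mean: float = np.nan
    valid: bool = True
    reasons: List[str] = field(default_factory=list)

    def invalidate(self, reason: str) -> None:
        self.valid = False
        self.reasons.append(reason)


@dataclass
class ResponsePoint:
    """A single (SpO2, response) point entering the regression."""

    spo2: float
    response: float
    role: str  # "pre" | "post"
    episode: int
    truncated: bool = False


@dataclass
class ChemoreflexResult:
    """Fitted chemoreflex sensitivity with diagnostics.

    ``slope_magnitude`` is the positive sensitivity (−raw OLS slope when
    the raw slope is negative); a paradoxical positive raw slope yields a
    negative magnitude with a warning, never a clamp.
    """

    channel: str  # "ventilation" | "hr"
    slope_magnitude: float
    raw_ols_slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_episodes: int
    points: pd.DataFrame
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def units(self) -> str:
        return "L/min/SpO2%" if self.channel == "ventilation" else "bpm/SpO2%"


def segment_episodes(
    recording: SignalRecording,
    annotations: Optional[np.ndarray] = None,
    min_spacing: float = 180.0,
    min_desaturation: float = MIN_DESATURATION_PCT,
) -> List[HypoxicEpisode]:
    """Locate the SpO2 nadir of every annotated N2 administration.

    The nadir is the minimum SpO2 in the half-open window
    ``(n2_end, n2_end + 60]``; ties break toward the earlier time.
    Episodes violating the >= 3 min spacing rule or showing less than
    ``min_desaturation`` % drop below the pre-window SpO2 mean are
    flagged invalid with an explicit reason, never dropped silently.
    """
    if annotations is None:
        annotations = recording.n2_intervals
    if annotations is None or len(annotations) == 0:
        raise ValidationError("no N2 administration annotations provided")
    annotations = np.asarray(annotations, dtype=float).reshape(-1, 2)
    if np.any(np.diff(annotations[:, 0]) <= 0):
        raise ValidationError("N2 intervals must be sorted")
    if np.any(annotations[1:, 0] < annotations[:-1, 1]):
        raise ValidationError("N2 intervals must not overlap")

    fs = recording.sample_rate
    episodes: List[HypoxicEpisode] = []
    for k, (a, b) in enumerate(annotations):
        ep = HypoxicEpisode(index=k, n2_start=float(a), n2_end=float(b))
        if k > 0 and a - annotations[k - 1, 1] < min_spacing:
            ep.invalidate("spacing violation: gap to previous administration < 180 s")
        # half-open (b, b+60]: first sample strictly after b through b+60 incl.
        i0 = int(np.floor(b * fs)) + 1
        i1 = min(int(np.floor((b + NADIR_SEARCH_S) * fs)), recording.n_samples - 1)
        if i0 > i1:
            ep.invalidate("SpO2 channel missing over the nadir search window")
            episodes.append(ep)
            continue
        seg = recording.spo2[i0 : i1 + 1]
        if np.isnan(seg).all():
            ep.invalidate("SpO2 channel missing over the nadir search window")
            episodes.append(ep)
            continue
        j = int(np.nanargmin(seg))  # argmin returns the first minimum: earliest tie
        ep.nadir_time = (i0 + j) / fs
        ep.nadir_spo2 = float(seg[j])
        pre_sl = recording.slice_indices(a - PRE_WINDOW_S, a)
        if pre_sl.start >= 0 and a - PRE_WINDOW_S >= -1e-9:
            ep.pre_spo2_mean = float(recording.spo2[pre_sl].mean())
            if ep.pre_spo2_mean - ep.nadir_spo2 < min_desaturation:
                ep.invalidate("no desaturation: nadir within 2% of pre-window SpO2")
        episodes.append(ep)
    return episodes


def pre_point(
    episode: HypoxicEpisode,
    recording: SignalRecording,
    event_times: np.ndarray,
    event_values: np.ndarray,
) -> ResponsePoint:
    """Pre-hypoxic point: 60 s window means ending at the N2 start.

    ``event_times``/``event_values`` are the response events (per-breath
    minute ventilation or per-beat smoothed HR); events with NaN values
    are ignored.
    """
    start = episode.n2_start - PRE_WINDOW_S
    if start < -1e-9:
        raise InsufficientDataError(
            f"episode {episode.index}: pre-window truncated by recording start"
        )
    sl = recording.slice_indices(start, episode.n2_start)
    spo2 = float(recording.spo2[sl].mean())
    mask = (
        (event_times >= start)
        & (event_times < episode.n2_start)
        & np.isfinite(event_values)
    )
    if not mask.any():
        raise InsufficientDataError(
            f"episode {episode.index}: no response events in the pre-window"
        )
    return ResponsePoint(
        spo2=spo2,
        response=float(event_values[mask].mean()),
        role="pre",
        episode=episode.index,
    )


def _beat_window(
    episode: HypoxicEpisode, beat_times: np.ndarray
) -> tuple[float, float, bool]:
    """Window [t of 5th beat before nadir, t of 20th beat after nadir].

    Counted on the cleaned (post-ectopic-removal) beat series. Truncates
    to the available beats near recording edges and reports truncation.
    """
    n_before = int(np.searchsorted(beat_times, episode.nadir_time, side="left"))
    truncated = False
    lo = n_before - BEATS_BEFORE_NADIR
    if lo < 0:
        lo, truncated = 0, True
    hi = n_before + BEATS_AFTER_NADIR - 1
    if hi > len(beat_times) - 1:
        hi, truncated = len(beat_times) - 1, True
    if n_before >= len(beat_times) or hi < lo:
        raise InsufficientDataError(
            f"episode {episode.index}: no beats around the nadir"
        )
    return float(beat_times[lo]), float(beat_times[hi]), truncated


def best_consecutive_mean(values: np.ndarray, k: int = 3) -> float:
    """Maximum mean over all runs of ``k`` consecutive values."""
    values = np.asarray(values, dtype=float)
    if len(values) < k:
        raise InsufficientDataError(f"need at least {k} values")
    kernel = np.convolve(values, np.ones(k) / k, mode="valid")
    return float(kernel.max())


def post_point_ventilation(
    episode: HypoxicEpisode, breaths: BreathSeries, beats: BeatSeries
) -> ResponsePoint:
    """Post-hypoxic ventilation point at the SpO2 nadir.

    The response is the mean of the three largest *consecutive* breaths
    inside the nadir-anchored beat window.
    """
    w_lo, w_hi, truncated = _beat_window(episode, beats.t)
    bt = breaths.t
    mask = (bt >= w_lo) & (bt <= w_hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"episode {episode.index}: fewer than 3 breaths in the nadir window"
        )
    response = best_consecutive_mean(breaths.vdot[mask], k=3)
    return ResponsePoint(
        spo2=episode.nadir_spo2,
        response=response,
        role="post",
        episode=episode.index,
        truncated=truncated,
    )


def post_point_hr(episode: HypoxicEpisode, beats: BeatSeries) -> ResponsePoint:
    """Post-hypoxic HR point: highest smoothed HR in the nadir window."""
    w_lo, w_hi, truncated = _beat_window(episode, beats.t)
    tb = beats.t
    hr = beats.hr_smooth
    mask = (tb >= w_lo) & (tb <= w_hi) & np.isfinite(hr)
    if not mask.any():
        raise InsufficientDataError(
            f"episode {episode.index}: no retained beats in the nadir window"
        )
    vals = hr[mask]
    return ResponsePoint(
        spo2=episode.nadir_spo2,
        response=float(vals[np.argmax(vals)]),  # argmax: earliest tie wins
        role="post",
        episode=episode.index,
        truncated=truncated,
    )


def fit_slope(
    points: Sequence[ResponsePoint],
    channel: str,
    min_episodes: int = MIN_EPISODES_DEFAULT,
) -> ChemoreflexResult:
    """Pooled OLS of response on SpO2 across pre- and post-hypoxic points.

    Reports the slope magnitude (−raw slope), intercept, R² and the
    point table. A paradoxical positive raw slope is reported as a
    negative magnitude with a warning rather than clamped.
    """
    episodes = sorted({p.episode for p in points})
    if len(episodes) < min_episodes:
        raise InsufficientDataError(
            f"need >= {min_episodes} valid episodes to fit, got {len(episodes)}"
        )
    if len(episodes) < 4:
        warnings.warn(
            f"fitting {channel} slope on only {len(episodes)} episodes",
            stacklevel=2,
        )
    x = np.array([p.spo2 for p in points])
    y = np.array([p.response for p in points])
    if np.ptp(x) == 0:
        raise AnalysisError("all SpO2 values identical; slope undefined")
    if np.ptp(y) == 0:
        slope, intercept, r2 = 0.0, float(y[0]), 0.0
    else:
        res = sps.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    magnitude = -slope
    if slope > 1e-12:  # strictly positive beyond float noise
        warnings.warn(
            f"paradoxical {channel} response: raw slope positive "
            f"({slope:.4g}); reporting negative magnitude",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "episode": [p.episode for p in points],
            "role": [p.role for p in points],
            "spo2": x,
            "response": y,
            "truncated": [p.truncated for p in points],
        }
    )
    return ChemoreflexResult(
        channel=channel,
        slope_magnitude=float(magnitude),
        raw_ols_slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(points),
        n_episodes=len(episodes),
        points=table,
    )


def _prepare_beats(
    recording: SignalRecording, ectopic_flags: str | np.ndarray = "auto",
    af_flag_fraction: float = 0.2,
) -> BeatSeries:
    """Build, clean and smooth the beat series of a recording.

    ``ectopic_flags`` selects the flag source: ``"auto"`` (median-filter
    detector), ``"manual"`` (annotation carried by the recording, which
    takes precedence when present), or an explicit boolean array. A flag
    fraction above ``af_flag_fraction`` is treated as an irregular
    rhythm (e.g. atrial fibrillation) and refused, mirroring the
    protocol's exclusion of such recordings from HR analysis.
    """
    beats = beats_from_times(recording.beat_times)
    if isinstance(ectopic_flags, str):
        if ectopic_flags == "manual":
            if recording.beat_ectopic_flags is None:
                raise ValidationError("recording carries no manual ectopic flags")
            flags = recording.beat_ectopic_flags
        elif ectopic_flags == "auto":
            flags = flag_ectopics(beats)
        else:
            raise ValidationError(f"unknown ectopic flag source {ectopic_flags!r}")
    else:
        flags = np.asarray(ectopic_flags, dtype=bool)
    frac = float(np.mean(flags))
    if frac > af_flag_fraction:
        raise AnalysisError(
            f"irregular rhythm: {frac:.0%} of beats flagged ectopic "
            f"(> {af_flag_fraction:.0%}); HR analysis refused"
        )
    cleaned = remove_ectopics(beats, flags)
    return smooth_hr(cleaned)


def _run_channel(
    recording: SignalRecording,
    channel: str,
    annotations: Optional[np.ndarray],
    min_episodes: int,
    ectopic_flags: str | np.ndarray,
) -> ChemoreflexResult:
    breaths = detect_breaths(recording) if channel == "ventilation" else None
    # the irregular-rhythm refusal applies to the HR analysis only (the
    # ventilatory channel uses beats solely to delimit windows)
    af_gate = 0.2 if channel == "hr" else 1.1
    beats = _prepare_beats(recording, ectopic_flags, af_flag_fraction=af_gate)
    episodes = segment_episodes(recording, annotations)

    points: List[ResponsePoint] = []
    qc_rows = []
    for ep in episodes:
        row = {
            "episode": ep.index,
            "n2_start": ep.n2_start,
            "n2_end": ep.n2_end,
            "nadir_time": ep.nadir_time,
            "nadir_spo2": ep.nadir_spo2,
            "valid": ep.valid,
            "reason": "; ".join(ep.reasons),
            "used": False,
            "truncated_window": False,
        }
        if ep.valid:
            try:
                if channel == "ventilation":
                    pre = pre_point(ep, recording, breaths.t, breaths.vdot)
                    post = post_point_ventilation(ep, breaths, beats)
                else:
                    pre = pre_point(ep, recording, beats.t, beats.hr_smooth)
                    post = post_point_hr(ep, beats)
                points.extend([pre, post])
                row["used"] = True
                row["truncated_window"] = post.truncated
            except InsufficientDataError as exc:
                row["reason"] = str(exc)
        qc_rows.append(row)

    result = fit_slope(points, channel, min_episodes=min_episodes)
    result.qc = pd.DataFrame(qc_rows)
    return result


def run_hvr(
    recording: SignalRecording,
    annotations: Optional[np.ndarray] = None,
    min_episodes: int = MIN_EPISODES_DEFAULT,
    ectopic_flags: str | np.ndarray = "auto",
) -> ChemoreflexResult:
    """Full hypoxic-ventilatory-response pipeline for one recording."""
    return _run_channel(recording, "ventilation", annotations, min_episodes, ectopic_flags)


def run_hr_slope(
    recording: SignalRecording,
    annotations: Optional[np.ndarray] = None,
    min_episodes: int = MIN_EPISODES_DEFAULT,
    ectopic_flags: str | np.ndarray = "auto",
) -> ChemoreflexResult:
    """Full heart-rate-slope pipeline for one recording."""
    return _run_channel(recording, "hr", annotations, min_episodes, ectopic_flags)
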