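"""Synthetic transient-hypoxia test recordings with known chemoreflex gains.

The generator emulates the clinical protocol: repeated brief nitrogen
administrations into the breathing circuit produce stepwise arterial
desaturations; ventilation and heart rate respond linearly to the
desaturation with configurable gains ``Gv`` (L/min per % SpO2 drop) and
``Gh`` (bpm per %). Those gains are the ground-truth counterparts of the
HVR and HR-slope estimates produced downstream, so parameter recovery is
a meaningful end-to-end test.

Model summary
-------------
* SpO2 follows first-order decay toward a physiological floor while N2 is
  administered and first-order recovery afterwards, both shifted by a
  lung-to-earlobe circulation delay.
* The chemoreflex drive is the *peak-hold* of the desaturation
  ``D(t) = max(0, baseline_spo2 - SpO2(t))`` over the trailing
  ``response_hold_s`` seconds: a transient hypoxic stimulus produces a
  response sustained for ~15 s rather than an instantaneous one. This
  sustained-response model is what makes the nadir-anchored, max-type
  point construction of the estimator exact in the noiseless case.
* Per-breath minute ventilation ``V = baseline + Gv * D_hold + noise``;
  tidal volume and breathing rate are co-modulated so ``V = VT * BR``
  holds by construction. Per-beat ``HR = baseline + Gh * D_hold + noise``.
* Expiratory flow is rendered as one half-sine lobe per breath whose
  integral equals that breath's tidal volume.

All randomness flows from ``SynthConfig.seed`` through named substreams
(schedule, breaths, beats, ectopics, etco2 — in that order), so identical
configurations yield bit-identical recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .recording import SignalRecording

__all__ = [
    "SynthConfig",
    "AdminSchedule",
    "GroundTruth",
    "plan_n2_schedule",
    "simulate_subject",
    "render_expiratory_flow",
    "inject_ectopics",
]

# stream order is part of the reproducibility contract
_STREAMS = ("schedule", "breaths", "beats", "ectopics", "etco2")


@dataclass
class SynthConfig:
    """Configuration of one simulated transient-hypoxia test.

    Defaults reproduce the study conditions: 1 kHz acquisition, resting
    minute ventilation 11 L/min and heart rate 62 bpm (the cohort's
    resting means), SpO2 baseline 96 %, gains at the cohort's pre-
    intervention means (HVR 0.42 L/min/%, HR slope 0.26 bpm/%), 8
    administrations with >= 3 min spacing aiming at a ~70 % nadir.
    """

    seed: int = 0
    sample_rate: float = 1000.0
    baseline_spo2: float = 96.0
    baseline_ventilation: float = 11.0
    baseline_hr: float = 62.0
    baseline_br: float = 15.0
    ventilatory_gain: float = 0.42
    hr_gain: float = 0.26
    spo2_tau_fall: float = 30.0
    spo2_tau_recover: float = 20.0
    circulation_delay: float = 6.0
    spo2_floor: float = 60.0
    response_hold_s: float = 15.0
    noise_sd_ventilation: float = 0.5
    noise_sd_hr: float = 1.0
    noise_sd_etco2: float = 0.5
    etco2_baseline: float = 38.0
    ectopic_rate: float = 0.0
    n_admins: int = 8
    spacing_min: float = 180.0
    gap_jitter_s: float = 30.0
    target_nadir: float = 70.0
    min_admin_s: float = 5.0
    max_admin_s: float = 40.0
    staircase_step: float = 5.0
    pre_test_s: float = 600.0
    post_test_s: float = 120.0
    exp_fraction: float = 0.4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (4 <= self.n_admins <= 12):
            raise ConfigError(f"n_admins must be in [4, 12], got {self.n_admins}")
        if self.spacing_min < 180:
            raise ConfigError("spacing_min must be >= 180 s (>= 3 min room-air recovery)")
        if not (0 < self.target_nadir < self.baseline_spo2 <= 100):
            raise ConfigError("require 0 < target_nadir < baseline_spo2 <= 100")
        for name in ("spo2_tau_fall", "spo2_tau_recover", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.ventilatory_gain < 0 or self.hr_gain < 0:
            raise ConfigError("gains must be >= 0")
        if self.spo2_floor >= self.target_nadir:
            raise ConfigError("spo2_floor must lie below target_nadir")
        if not (0 < self.exp_fraction < 1):
            raise ConfigError("exp_fraction must lie in (0, 1)")
        if self.min_admin_s < 5 or self.max_admin_s > 40:
            raise ConfigError("administration durations must stay within [5, 40] s")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, deterministic substream of the root seed."""
        if stream not in _STREAMS:
            raise ConfigError(f"unknown RNG stream {stream!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        return np.random.default_rng(ss)

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class AdminSchedule:
    """Sorted, non-overlapping N2 administration intervals [start, end)."""

    intervals: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        for (a, b) in self.intervals:
            if not (b > a):
                raise ValidationError("administration intervals must have end > start")
        starts = [a for a, _ in self.intervals]
        if sorted(starts) != starts:
            raise ValidationError("administration intervals must be sorted")
        for (_, b0), (a1, _) in zip(self.intervals, self.intervals[1:]):
            if a1 < b0:
                raise ValidationError("administration intervals must not overlap")

    @property
    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals])

    @property
    def gaps(self) -> np.ndarray:
        """Room-air gaps between consecutive administrations (s)."""
        return np.array(
            [a1 - b0 for (_, b0), (a1, _) in zip(self.intervals, self.intervals[1:])]
        )

    @property
    def end(self) -> float:
        return self.intervals[-1][1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.intervals, dtype=float).reshape(-1, 2)


@dataclass
class GroundTruth:
    """What the generator actually did — the acceptance surface."""

    gv: float
    gh: float
    nadir_times: np.ndarray
    nadir_spo2: np.ndarray
    breath_log: pd.DataFrame  # t_breath, vt, br, vdot, t_exp
    beat_log: pd.DataFrame  # t_beat, ectopic

    def to_dict(self) -> dict:
        return {
            "gv": self.gv,
            "gh": self.gh,
            "nadir_times": list(map(float, self.nadir_times)),
            "nadir_spo2": list(map(float, self.nadir_spo2)),
            "breath_log": self.breath_log.to_dict(orient="list"),
            "beat_log": {
                "t_beat": self.beat_log["t_beat"].tolist(),
                "ectopic": self.beat_log["ectopic"].astype(int).tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        beat = pd.DataFrame(
            {
                "t_beat": d["beat_log"]["t_beat"],
                "ectopic": np.asarray(d["beat_log"]["ectopic"], dtype=bool),
            }
        )
        return cls(
            gv=d["gv"],
            gh=d["gh"],
            nadir_times=np.asarray(d["nadir_times"], dtype=float),
            nadir_spo2=np.asarray(d["nadir_spo2"], dtype=float),
            breath_log=pd.DataFrame(d["breath_log"]),
            beat_log=beat,
        )


def predicted_nadir(config: SynthConfig, duration: float) -> float:
    """SpO2 nadir the first-order desaturation model predicts for one bout.

    Starting from baseline, SpO2 decays toward the floor for ``duration``
    seconds, so the nadir is ``floor + (baseline - floor) * exp(-d/tau)``.
    """
    drop = config.baseline_spo2 - config.spo2_floor
    return config.spo2_floor + drop * float(np.exp(-duration / config.spo2_tau_fall))


def plan_n2_schedule(config: SynthConfig) -> AdminSchedule:
    """Plan the N2 administration staircase and its randomized tail.

    The first bout lasts 5 s; subsequent bouts grow by ``staircase_step``
    until the predicted nadir reaches ``target_nadir`` (or the 40 s cap),
    identifying the subject's maximum tolerated duration. Remaining bouts
    are drawn uniformly from [5 s, identified max] to spread the nadirs
    over a wide SpO2 range. Consecutive bouts are separated by at least
    ``spacing_min`` of room-air breathing.
    """
    rng = config.rng("schedule")
    durations: List[float] = []
    d = config.min_admin_s
    while len(durations) < config.n_admins:
        durations.append(d)
        if predicted_nadir(config, d) <= config.target_nadir or d >= config.max_admin_s:
            break
        d = min(d + config.staircase_step, config.max_admin_s)
    d_max = durations[-1]
    n_tail = config.n_admins - len(durations)
    if n_tail > 0:
        tail = rng.uniform(config.min_admin_s, d_max, size=n_tail)
        durations.extend(np.round(tail, 1))

    intervals: List[Tuple[float, float]] = []
    t = config.pre_test_s
    for dur in durations:
        intervals.append((t, t + dur))
        t = t + dur + config.spacing_min + rng.uniform(0.0, config.gap_jitter_s)
    return AdminSchedule(intervals)


class SaturationModel:
    """Piecewise-exponential SpO2 trajectory for a given admin schedule.

    Desaturation segments run over ``[start + delay, end + delay)`` for
    each N2 interval; recovery toward baseline follows until the next
    desaturation begins. The trajectory is continuous; each episode's
    nadir sits exactly at the end of its desaturation segment.
    """

    def __init__(self, schedule: AdminSchedule, config: SynthConfig):
        self.config = config
        delay = config.circulation_delay
        base = config.baseline_spo2
        floor = config.spo2_floor
        self.fall_start = np.array([a + delay for a, _ in schedule.intervals])
        self.fall_end = np.array([b + delay for _, b in schedule.intervals])
        s_start = np.empty(len(self.fall_start))
        s_nadir = np.empty(len(self.fall_start))
        s = base
        for k, (fs, fe) in enumerate(zip(self.fall_start, self.fall_end)):
            if k > 0:
                # recovery from previous nadir up to this fall start
                dt = fs - self.fall_end[k - 1]
                s = base + (s_nadir[k - 1] - base) * np.exp(-dt / config.spo2_tau_recover)
            s_start[k] = s
            s_nadir[k] = floor + (s - floor) * np.exp(-(fe - fs) / config.spo2_tau_fall)
        self.s_start = s_start
        self.s_nadir = s_nadir
        self._fall_start_list = self.fall_start.tolist()
        self._fall_end_list = self.fall_end.tolist()

    def spo2(self, t) -> np.ndarray:
        """Vectorized SpO2 (%) at times ``t`` (s)."""
        cfg = self.config
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, cfg.baseline_spo2)
        # which episode segment each time falls into
        k_fall = np.searchsorted(self.fall_start, t, side="right") - 1
        valid = k_fall >= 0
        if not np.any(valid):
            return out
        kf = np.clip(k_fall, 0, None)
        in_fall = valid & (t < self.fall_end[kf])
        in_rec = valid & ~in_fall
        if np.any(in_fall):
            k = kf[in_fall]
            out[in_fall] = cfg.spo2_floor + (self.s_start[k] - cfg.spo2_floor) * np.exp(
                -(t[in_fall] - self.fall_start[k]) / cfg.spo2_tau_fall
            )
        if np.any(in_rec):
            k = kf[in_rec]
            out[in_rec] = cfg.baseline_spo2 + (
                self.s_nadir[k] - cfg.baseline_spo2
            ) * np.exp(-(t[in_rec] - self.fall_end[k]) / cfg.spo2_tau_recover)
        return out

    def spo2_grid(self, n_samples: int, sample_rate: float) -> np.ndarray:
        """SpO2 sampled on the uniform grid, filled segment by segment.

        Equivalent to ``spo2(arange(n)/fs)`` but avoids per-sample
        segment lookup, which matters at 1 kHz over ~40 min.
        """
        cfg = self.config
        out = np.full(n_samples, cfg.baseline_spo2)
        n_ep = len(self.fall_start)
        for k in range(n_ep):
            i_fs = min(max(int(np.ceil(self.fall_start[k] * sample_rate)), 0), n_samples)
            i_fe = min(max(int(np.ceil(self.fall_end[k] * sample_rate)), 0), n_samples)
            i_next = (
                min(max(int(np.ceil(self.fall_start[k + 1] * sample_rate)), 0), n_samples)
                if k + 1 < n_ep
                else n_samples
            )
            if i_fe > i_fs:
                tt = np.arange(i_fs, i_fe) / sample_rate - self.fall_start[k]
                out[i_fs:i_fe] = cfg.spo2_floor + (
                    self.s_start[k] - cfg.spo2_floor
                ) * np.exp(-tt / cfg.spo2_tau_fall)
            if i_next > i_fe:
                tt = np.arange(i_fe, i_next) / sample_rate - self.fall_end[k]
                out[i_fe:i_next] = cfg.baseline_spo2 + (
                    self.s_nadir[k] - cfg.baseline_spo2
                ) * np.exp(-tt / cfg.spo2_tau_recover)
        return out

    def spo2_scalar(self, t: float) -> float:
        """Fast scalar SpO2 evaluation (event-generation hot path)."""
        import bisect
        import math

        cfg = self.config
        k = bisect.bisect_right(self._fall_start_list, t) - 1
        if k < 0:
            return cfg.baseline_spo2
        if t < self._fall_end_list[k]:
            return cfg.spo2_floor + (self.s_start[k] - cfg.spo2_floor) * math.exp(
                -(t - self._fall_start_list[k]) / cfg.spo2_tau_fall
            )
        return cfg.baseline_spo2 + (self.s_nadir[k] - cfg.baseline_spo2) * math.exp(
            -(t - self._fall_end_list[k]) / cfg.spo2_tau_recover
        )

    def desaturation_hold_scalar(self, t: float) -> float:
        """Fast scalar peak-hold desaturation (event-generation hot path)."""
        import bisect

        cfg = self.config
        base = cfg.baseline_spo2
        t_past = t - cfg.response_hold_s
        d = max(base - self.spo2_scalar(t), base - self.spo2_scalar(max(t_past, 0.0)))
        lo = bisect.bisect_left(self._fall_end_list, t_past)
        hi = bisect.bisect_right(self._fall_end_list, t)
        for k in range(lo, hi):
            d = max(d, base - self.s_nadir[k])
        return max(d, 0.0)

    def desaturation_hold(self, t) -> np.ndarray:
        """Peak-hold desaturation: max of D over [t - hold, t].

        SpO2 is piecewise monotone, so the maximum over the trailing
        window is attained at a window endpoint or at a nadir inside it.
        """
        cfg = self.config
        t = np.asarray(t, dtype=float)
        base = cfg.baseline_spo2
        d_now = base - self.spo2(t)
        d_past = base - self.spo2(np.maximum(t - cfg.response_hold_s, 0.0))
        # nadir inside the trailing window?
        lo = np.searchsorted(self.fall_end, t - cfg.response_hold_s, side="left")
        hi = np.searchsorted(self.fall_end, t, side="right")
        d_nadir = np.zeros_like(d_now)
        has = hi > lo
        if np.any(has):
            # deepest nadir in window (gaps >> hold, so at most one in practice)
            idx = np.where(has)[0]
            for i in idx:
                d_nadir[i] = base - self.s_nadir[lo[i]:hi[i]].min()
        return np.maximum.reduce([d_now, d_past, d_nadir, np.zeros_like(d_now)])


def _generate_breaths(
    config: SynthConfig, sat: SaturationModel, duration: float
) -> pd.DataFrame:
    """Breath-by-breath log: onset, VT, BR, V-dot and expiratory duration.

    Ventilation drive splits between rate and depth: BR scales with the
    square root of the ventilation ratio, VT carries the rest, so
    ``vdot = vt * br`` holds exactly.
    """
    rng = config.rng("breaths")
    rows = []
    t = 0.2
    base_v = config.baseline_ventilation
    while True:
        d = sat.desaturation_hold_scalar(t)
        vdot = base_v + config.ventilatory_gain * d
        if config.noise_sd_ventilation > 0:
            vdot += rng.normal(0.0, config.noise_sd_ventilation)
        else:
            rng.normal(0.0, 1.0)  # keep stream aligned across noise settings
        vdot = max(vdot, 0.2 * base_v)
        br = config.baseline_br * np.sqrt(vdot / base_v)
        vt = vdot / br
        period = 60.0 / br
        if t + period > duration:
            break
        rows.append((t, vt, br, vdot, config.exp_fraction * period))
        t += period
    return pd.DataFrame(rows, columns=["t_breath", "vt", "br", "vdot", "t_exp"])


def _generate_beats(
    config: SynthConfig, sat: SaturationModel, duration: float
) -> pd.DataFrame:
    rng = config.rng("beats")
    times = []
    t = 0.35
    while True:
        d = sat.desaturation_hold_scalar(t)
        hr = config.baseline_hr + config.hr_gain * d
        if config.noise_sd_hr > 0:
            hr += rng.normal(0.0, config.noise_sd_hr)
        else:
            rng.normal(0.0, 1.0)
        hr = max(hr, 25.0)
        rr = 60.0 / hr
        if t + rr > duration:
            break
        times.append(t)
        t += rr
    return pd.DataFrame({"t_beat": times, "ectopic": False})


def inject_ectopics(
    beat_log: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Turn a Poisson-drawn subset of beats into premature (ectopic) beats.

    An ectopic is modelled by advancing an existing beat to 60 % of its
    preceding RR interval; the following interval lengthens accordingly
    (compensatory pause), so the total beat-train duration is preserved.
    ``rate`` is in events per minute; rate 0 is a no-op.
    """
    if rate < 0:
        raise ValidationError("ectopic rate must be >= 0")
    out = beat_log.copy().reset_index(drop=True)
    if rate == 0 or len(out) < 4:
        return out
    t = out["t_beat"].to_numpy().copy()
    duration_min = (t[-1] - t[0]) / 60.0
    n = rng.poisson(rate * duration_min)
    if n == 0:
        return out
    candidates = np.arange(1, len(t) - 1)
    chosen = rng.choice(candidates, size=min(n, len(candidates)), replace=False)
    chosen = np.sort(chosen)
    # avoid adjacent picks: disturbed intervals must not overlap
    keep = [chosen[0]]
    for j in chosen[1:]:
        if j - keep[-1] >= 2:
            keep.append(j)
    flags = out["ectopic"].to_numpy().copy()
    for j in keep:
        rr_prev = t[j] - t[j - 1]
        t[j] = t[j - 1] + 0.6 * rr_prev
        flags[j] = True
    out["t_beat"] = t
    out["ectopic"] = flags
    return out


def render_expiratory_flow(
    breath_log: pd.DataFrame, sample_rate: float, n_samples: int
) -> np.ndarray:
    """Render a breath log as a sampled expiratory flow channel (L/s).

    Each breath becomes one half-sine lobe over ``[t, t + t_exp)`` with
    amplitude ``pi * vt / (2 * t_exp)``, whose time integral equals the
    breath's tidal volume; flow is zero between expirations.
    """
    flow = np.zeros(n_samples)
    if len(breath_log) == 0:
        return flow
    t = breath_log["t_breath"].to_numpy()
    vt = breath_log["vt"].to_numpy()
    t_exp = breath_log["t_exp"].to_numpy()
    if np.any(vt <= 0) or np.any(t_exp <= 0):
        raise ValidationError("breath log requires positive VT and expiratory times")
    if np.any(t[:-1] + t_exp[:-1] > t[1:] + 1e-12):
        raise ValidationError("overlapping breaths in breath log")
    for ti, vti, tei in zip(t, vt, t_exp):
        i0 = int(np.ceil(ti * sample_rate))
        i1 = int(np.floor((ti + tei) * sample_rate))
        i1 = min(i1, n_samples - 1)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1 + 1) / sample_rate
        amp = np.pi * vti / (2.0 * tei)
        flow[i0 : i1 + 1] = amp * np.sin(np.pi * (tt - ti) / tei)
    np.maximum(flow, 0.0, out=flow)
    return flow


def simulate_subject(
    config: SynthConfig, schedule: Optional[AdminSchedule] = None
) -> Tuple[SignalRecording, GroundTruth]:
    """Simulate one full transient-hypoxia test recording.

    Returns the multichannel recording (flow, SpO2, etCO2, N2 marker,
    beat times) and the ground truth (gains, per-episode nadirs, breath
    and beat logs). The recording spans a 10 min pre-test baseline, the
    administration schedule, and a 2 min tail.
    """
    if schedule is None:
        schedule = plan_n2_schedule(config)
    duration = schedule.end + config.post_test_s
    n_samples = int(round(duration * config.sample_rate))
    if schedule.end + config.circulation_delay >= duration:
        raise ValidationError("schedule extends past the recording span")

    sat = SaturationModel(schedule, config)
    breath_log = _generate_breaths(config, sat, duration)
    beat_log = _generate_beats(config, sat, duration)
    beat_log = inject_ectopics(beat_log, config.ectopic_rate, config.rng("ectopics"))

    flow = render_expiratory_flow(breath_log, config.sample_rate, n_samples)
    tgrid = np.arange(n_samples) / config.sample_rate
    spo2 = sat.spo2_grid(n_samples, config.sample_rate)
    rng_et = config.rng("etco2")
    etco2 = np.full(n_samples, config.etco2_baseline)
    if config.noise_sd_etco2 > 0:
        # slowly varying placeholder noise (one value per second, held)
        per_sec = rng_et.normal(0.0, config.noise_sd_etco2, size=int(np.ceil(duration)))
        etco2 += per_sec[np.minimum(tgrid.astype(int), len(per_sec) - 1)]
    marker = np.zeros(n_samples)
    for a, b in schedule.intervals:
        i0 = int(np.ceil(a * config.sample_rate - 1e-9))
        i1 = int(np.ceil(b * config.sample_rate - 1e-9))
        marker[i0:i1] = 1.0

    recording = SignalRecording(
        sample_rate=config.sample_rate,
        flow=flow,
        spo2=spo2,
        etco2=etco2,
        marker=marker,
        beat_times=beat_log["t_beat"].to_numpy(),
        beat_ectopic_flags=beat_log["ectopic"].to_numpy(),
        n2_intervals=schedule.as_array(),
    )
    truth = GroundTruth(
        gv=config.ventilatory_gain,
        gh=config.hr_gain,
        nadir_times=sat.fall_end.copy(),
        nadir_spo2=sat.s_nadir.copy(),
        breath_log=breath_log,
        beat_log=beat_log,
    )
    return recording, truth
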