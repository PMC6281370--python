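"""EMG-based behavioral-state scoring and twitch detection.

The scoring pipeline follows standard practice for infant rodents: the EMG is
rectified and smoothed (tau = 1 ms), a wake/sleep amplitude threshold is set
at the midpoint between the mean amplitude of representative high-tone and
atonia segments, runs of supra-/sub-threshold tone lasting at least 1 s
become wake/sleep bouts, myoclonic twitches are detected during sleep as
sharp transients exceeding 3x the mean atonia baseline, and each sleep bout
is split into behavioral quiescence (before its first twitch) and active
sleep (from the first twitch onward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .model import (
    AnalysisConfig,
    Bout,
    EventTrain,
    SampledSignal,
    Session,
    StateIntervals,
    ValidationError,
    log_stage,
)

__all__ = [
    "ThresholdEstimate",
    "TwitchDetection",
    "rectify_smooth",
    "estimate_threshold",
    "segment_states",
    "detect_twitches",
    "detect_wake_onsets",
    "score_session",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Midpoint wake/sleep threshold from representative tone segments."""

    mean_high: float
    mean_atonia: float
    threshold: float
    segments_high: tuple
    segments_atonia: tuple

    def __post_init__(self):
        if not self.mean_high > self.mean_atonia:
            raise ValidationError("threshold: mean_high must exceed mean_atonia")


@dataclass(frozen=True)
class TwitchDetection:
    muscle: str
    onsets: EventTrain
    baseline: float            #: mean rectified-smoothed amplitude during atonia
    multiplier: float          #: criterion, k x baseline


def rectify_smooth(signal: SampledSignal, tau: float,
                   kind: str = "exponential") -> SampledSignal:
    """Full-wave rectify, then smooth with a causal filter.

    ``exponential`` is a first-order RC filter, y[n] = a|x[n]| + (1-a)y[n-1]
    with a = 1 - exp(-dt/tau), whose step response is 1 - exp(-t/tau).
    ``boxcar`` is a trailing moving average of width tau.
    """
    if tau <= 0:
        raise ValidationError("rectify_smooth: tau must be > 0")
    x = np.abs(signal.samples)
    dt = 1.0 / signal.rate
    if kind == "exponential":
        a = 1.0 - np.exp(-dt / tau)
        y = lfilter([a], [1.0, -(1.0 - a)], x)
    elif kind == "boxcar":
        w = max(int(round(tau / dt)), 1)
        y = lfilter(np.full(w, 1.0 / w), [1.0], x)
    else:
        raise ValidationError(f"rectify_smooth: unknown kind {kind!r}")
    return SampledSignal(channel=signal.channel, rate=signal.rate,
                         samples=y, t0=signal.t0, rectified=True)


def _check_rectified(signal: SampledSignal, op: str) -> None:
    if not signal.rectified:
        raise ValidationError(f"{op}: expects a rectified signal")


def estimate_threshold(signal: SampledSignal, n_segments: int = 5,
                       seg_len: float = 1.0,
                       manual_segments: Optional[dict] = None) -> ThresholdEstimate:
    """Midpoint threshold from n representative segments per tone class.

    Automatic selection ranks non-overlapping ``seg_len`` windows by their
    median amplitude (the median is insensitive to brief twitch transients)
    and takes the top ``n_segments`` windows as high tone and the bottom
    ``n_segments`` as atonia; class means are then computed from all samples
    of the selected windows. ``manual_segments`` ({"high": [(s,e),...],
    "atonia": [...]}) overrides selection for exact reproduction of a manual
    choice.
    """
    _check_rectified(signal, "estimate_threshold")
    x, rate = signal.samples, signal.rate

    if manual_segments is not None:
        means = {}
        segs = {}
        for cls in ("high", "atonia"):
            ivs = sorted(manual_segments[cls])
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValidationError("estimate_threshold: manual segments overlap")
            samp = []
            for s, e in ivs:
                i0, i1 = int(round((s - signal.t0) * rate)), int(round((e - signal.t0) * rate))
                if i0 < 0 or i1 > x.size or i0 >= i1:
                    raise ValidationError(
                        f"estimate_threshold: manual segment ({s}, {e}) out of range")
                samp.append(x[i0:i1])
            means[cls] = float(np.concatenate(samp).mean())
            segs[cls] = tuple(ivs)
        if means["high"] <= means["atonia"]:
            raise ValidationError("estimate_threshold: cannot distinguish tone classes")
        return ThresholdEstimate(
            mean_high=means["high"], mean_atonia=means["atonia"],
            threshold=(means["high"] + means["atonia"]) / 2.0,
            segments_high=segs["high"], segments_atonia=segs["atonia"])

    w = int(round(seg_len * rate))
    n_win = x.size // w
    if n_win < 2 * n_segments:
        raise ValidationError(
            f"estimate_threshold: signal too short for 2x{n_segments} segments of {seg_len}s")
    wins = x[: n_win * w].reshape(n_win, w)
    order = np.argsort(np.median(wins, axis=1), kind="stable")
    lo_idx = order[:n_segments]
    hi_idx = order[-n_segments:]
    mean_atonia = float(wins[lo_idx].mean())
    mean_high = float(wins[hi_idx].mean())
    if not mean_high > mean_atonia * (1 + 1e-9):
        raise ValidationError("estimate_threshold: cannot distinguish tone classes")
    to_iv = lambda idx: tuple(
        (signal.t0 + i * w / rate, signal.t0 + (i + 1) * w / rate) for i in sorted(idx))
    return ThresholdEstimate(
        mean_high=mean_high, mean_atonia=mean_atonia,
        threshold=(mean_high + mean_atonia) / 2.0,
        segments_high=to_iv(hi_idx), segments_atonia=to_iv(lo_idx))


def _majority_filter(above: np.ndarray, width: int) -> np.ndarray:
    """Centered boolean majority vote (binary median filter).

    Debounces the threshold comparison: opposite-tone islands shorter than
    about half the window vanish, while a clean tone step keeps its boundary
    to within one sample. Partial windows at the edges use the actual
    window length.
    """
    if width <= 1:
        return above
    h = width // 2
    n = above.size
    cs = np.concatenate(([0], np.cumsum(above, dtype=np.int64)))
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    return (cs[hi] - cs[lo]) * 2 > (hi - lo)


def _tone_runs(signal: SampledSignal, threshold: float,
               min_bout: float) -> List[Tuple[float, float, bool]]:
    """Half-open (start, end, is_wake) runs after the minimum-bout merge.

    The supra-threshold mask is first debounced with a ``min_bout``-wide
    majority filter (removing noise dips within wake and twitch bumps within
    sleep); any remaining runs shorter than ``min_bout`` are merged into the
    preceding qualifying run, and leading short runs are absorbed into the
    first qualifying run.
    """
    above = _majority_filter(signal.samples > threshold,
                             int(round(min_bout * signal.rate)) | 1)
    edges = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [above.size]))
    runs = [(int(bounds[i]), int(bounds[i + 1]), bool(above[bounds[i]]))
            for i in range(bounds.size - 1)]

    min_n = min_bout * signal.rate - 0.5  # tolerate rounding at exact min_bout
    merged: List[List] = []
    for i0, i1, wake in runs:
        if i1 - i0 < min_n:
            if merged:
                merged[-1][1] = i1
            # leading short runs are absorbed into the first qualifying run
        else:
            if merged and merged[-1][2] == wake:
                merged[-1][1] = i1
            else:
                merged.append([0 if not merged else i0, i1, wake])
    if not merged:
        # no qualifying run at all: classify the whole span by majority tone
        merged = [[0, above.size, bool(above.mean() > 0.5)]]
    merged[-1][1] = above.size
    t0, rate = signal.t0, signal.rate
    return [(t0 + i0 / rate, t0 + i1 / rate, wake) for i0, i1, wake in merged]


def segment_states(signal: SampledSignal, twitch_trains: Sequence[EventTrain],
                   threshold: float, min_bout: float = 1.0) -> StateIntervals:
    """Tile the scored span with AW / BQ / AS intervals.

    Supra-threshold runs >= min_bout are AW; sub-threshold runs >= min_bout
    are sleep. Each sleep run is split at its first twitch (across all
    muscles) into BQ before and AS after; twitch-free sleep runs are BQ.
    """
    _check_rectified(signal, "segment_states")
    all_tw = np.sort(np.concatenate([t.times for t in twitch_trains])
                     ) if twitch_trains else np.empty(0)
    bouts: List[Bout] = []
    for start, end, wake in _tone_runs(signal, threshold, min_bout):
        if wake:
            bouts.append(Bout(start, end, "AW"))
            continue
        inside = all_tw[(all_tw >= start) & (all_tw < end)]
        if inside.size == 0:
            bouts.append(Bout(start, end, "BQ"))
        else:
            first = float(inside[0])
            if first > start:
                bouts.append(Bout(start, first, "BQ"))
            bouts.append(Bout(max(first, start), end, "AS"))
    return StateIntervals(tuple(bouts), threshold_used=threshold)


def detect_twitches(signal: SampledSignal, sleep_intervals: Sequence,
                    k: float = 3.0, refractory: float = 0.200) -> TwitchDetection:
    """Twitch onsets: first upward crossings of k x the atonia baseline.

    The baseline is the mean rectified-smoothed amplitude over the sleep
    (sub-threshold) intervals; onsets are rising-edge crossings of
    k x baseline inside those intervals, separated by at least ``refractory``.
    Supra-threshold (wake) epochs never contribute detections.
    """
    _check_rectified(signal, "detect_twitches")
    ivs = [(b.start, b.end) if isinstance(b, Bout) else (float(b[0]), float(b[1]))
           for b in sleep_intervals]
    if not ivs:
        raise ValidationError("detect_twitches: empty sleep mask")
    x, rate, t0 = signal.samples, signal.rate, signal.t0
    mask = np.zeros(x.size, dtype=bool)
    for s, e in ivs:
        i0 = max(int(round((s - t0) * rate)), 0)
        i1 = min(int(round((e - t0) * rate)), x.size)
        mask[i0:i1] = True
    if not mask.any():
        raise ValidationError("detect_twitches: sleep mask covers no samples")
    baseline = float(x[mask].mean())
    crit = k * baseline
    above = x >= crit
    rising = np.flatnonzero(above & ~np.roll(above, 1) & mask)
    if above.size and above[0] and mask[0]:
        rising = np.union1d(rising, [0])
    onsets: List[float] = []
    for i in rising:
        t = t0 + i / rate
        if not onsets or t - onsets[-1] >= refractory:
            onsets.append(t)
    duration = t0 + x.size / rate
    return TwitchDetection(
        muscle=signal.channel,
        onsets=EventTrain(f"twitch_{signal.channel}", np.asarray(onsets), duration),
        baseline=baseline, multiplier=k)


def detect_wake_onsets(signal: SampledSignal, states: StateIntervals,
                       threshold: float,
                       within_bout: bool = False,
                       min_gap: float = 1.0) -> EventTrain:
    """One movement onset per AW bout at its first supra-threshold crossing.

    With ``within_bout``, additional onsets are emitted at re-crossings that
    follow sub-threshold gaps shorter than ``min_gap`` inside the bout.
    """
    _check_rectified(signal, "detect_wake_onsets")
    x, rate, t0 = signal.samples, signal.rate, signal.t0
    above = x > threshold
    onsets: List[float] = []
    for b in states.bouts("AW"):
        i0 = max(int(round((b.start - t0) * rate)), 0)
        i1 = min(int(round((b.end - t0) * rate)), x.size)
        idx = np.flatnonzero(above[i0:i1])
        if idx.size == 0:
            continue
        onsets.append(t0 + (i0 + idx[0]) / rate)
        if within_bout:
            rel = above[i0:i1]
            rises = np.flatnonzero(rel & ~np.roll(rel, 1))
            falls = np.flatnonzero(~rel & np.roll(rel, 1))
            for r in rises[1:]:
                prev_fall = falls[falls < r]
                if prev_fall.size and (r - prev_fall[-1]) / rate < min_gap:
                    onsets.append(t0 + (i0 + r) / rate)
    duration = t0 + x.size / rate
    return EventTrain("wake_onset", np.asarray(sorted(set(onsets))), duration)


def score_session(session: Session, config: AnalysisConfig) -> Session:
    """Run the full scoring chain on one session, in place on a copy.

    Smooths every EMG channel, estimates the threshold on the configured
    state channel, detects per-muscle twitches within sleep, segments
    AW/BQ/AS and appends twitch and wake-onset event trains to the session.
    """
    channel = config.state_channel
    names = [s.channel for s in session.emg]
    if channel not in names:
        channel = names[0]
    smoothed = {s.channel: rectify_smooth(s, config.smooth_tau, config.smooth_kind)
                for s in session.emg}
    ref = smoothed[channel]
    est = estimate_threshold(ref, config.n_threshold_segments,
                             config.threshold_segment_len)
    # provisional sleep mask (no twitches yet): sub-threshold qualifying runs
    provisional = segment_states(ref, [], est.threshold, config.min_bout)
    sleep = provisional.bouts("BQ")
    detections = {}
    for name, sig in smoothed.items():
        if sleep:
            detections[name] = detect_twitches(
                sig, sleep, config.twitch_multiplier, config.twitch_refractory)
    twitch_trains = [d.onsets for d in detections.values()]
    states = segment_states(ref, twitch_trains, est.threshold, config.min_bout)
    wake_onsets = detect_wake_onsets(ref, states, est.threshold,
                                     config.wake_onsets_within_bout,
                                     config.min_bout)
    out = Session(
        id=session.id, duration=session.duration, emg=session.emg,
        spikes=session.spikes,
        events=[e for e in session.events
                if not e.label.startswith("twitch_") and e.label != "wake_onset"]
        + twitch_trains + [wake_onsets],
        states=states, group=session.group, ground_truth=session.ground_truth)
    log_stage("score_session", config,
              session=session.id, n_bouts=len(states),
              n_twitches=sum(len(t) for t in twitch_trains),
              n_wake_onsets=len(wake_onsets), threshold=round(est.threshold, 6))
    return out
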