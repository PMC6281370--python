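"""Shared data model for infant-rat sleep/wake electrophysiology sessions.

The analysis operates on three primitive time series, all referenced to a
common session clock that starts at 0 s:

* :class:`SampledSignal` -- an EMG channel (amplitude at a fixed rate),
* :class:`EventTrain`    -- discrete event onsets (twitches, wake onsets,
  exafferent stimulation marks),
* :class:`SpikeTrain`    -- sorted spike times of one unit.

Behavioral-state scoring produces :class:`StateIntervals`, a disjoint,
time-ordered tiling of the scored span with the three-state alphabet
AW (active wake), BQ (behavioral quiescence) and AS (active sleep).

:class:`AnalysisConfig` collects every numeric constant of the analysis in
one validated, hashable record so that each pipeline stage can log the exact
configuration it ran under.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "STATE_LABELS",
    "MUSCLE_ORDER",
    "SampledSignal",
    "EventTrain",
    "SpikeTrain",
    "Bout",
    "StateIntervals",
    "AnalysisConfig",
    "Session",
    "logger",
    "config_hash",
    "log_stage",
]

logger = logging.getLogger("precereb")

STATE_LABELS = ("AW", "BQ", "AS")

#: Canonical muscle ordering used for deterministic tie-breaks.
MUSCLE_ORDER = ("nuchal", "forelimb", "hindlimb")


class ValidationError(ValueError):
    """An in-memory object violates a data-model invariant."""


class FormatError(ValueError):
    """An interchange file is missing or malformed."""


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# primitive time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampledSignal:
    """One EMG channel sampled at a fixed rate.

    Amplitude is in arbitrary units; absolute scale is never interpreted.
    ``rectified`` records whether ``samples`` are a signed raw trace or a
    non-negative rectified (or rectified-and-smoothed) amplitude.
    """

    channel: str
    rate: float
    samples: np.ndarray
    t0: float = 0.0
    rectified: bool = False

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_f64(self.samples))
        if not (self.rate > 0):
            raise ValidationError(f"signal {self.channel!r}: rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError(f"signal {self.channel!r}: empty or non-1D samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"signal {self.channel!r}: non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class EventTrain:
    """Strictly increasing event onset times (s) with a label."""

    label: str
    times: np.ndarray
    session_duration: float

    def __post_init__(self):
        object.__setattr__(self, "times", _as_f64(self.times))
        t = self.times
        if t.ndim != 1:
            raise ValidationError(f"events {self.label!r}: times must be 1-D")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError(f"events {self.label!r}: times not strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.session_duration):
            raise ValidationError(
                f"events {self.label!r}: times outside [0, {self.session_duration}]"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) of one sorted unit (sorting happens upstream)."""

    unit_id: str
    times: np.ndarray
    structure: str = "other"
    quality_flags: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "times", _as_f64(self.times))
        object.__setattr__(self, "quality_flags", tuple(self.quality_flags))
        t = self.times
        if t.ndim != 1:
            raise ValidationError(f"unit {self.unit_id!r}: times must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError(f"unit {self.unit_id!r}: spike times not sorted")
        if t.size and t[0] < 0:
            raise ValidationError(f"unit {self.unit_id!r}: negative spike time")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Bout:
    """One half-open state interval [start, end)."""

    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StateIntervals:
    """Disjoint, time-ordered AW/BQ/AS intervals tiling the scored span."""

    intervals: tuple
    threshold_used: Optional[float] = None

    def __post_init__(self):
        ivs = tuple(
            b if isinstance(b, Bout) else Bout(float(b[0]), float(b[1]), str(b[2]))
            for b in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        prev_end = -np.inf
        for b in ivs:
            if not b.start < b.end:
                raise ValidationError(f"state interval [{b.start}, {b.end}) is empty")
            if b.start < prev_end - 1e-12:
                raise ValidationError("state intervals overlap or are out of order")
            if b.label not in STATE_LABELS:
                raise ValidationError(f"unknown state label {b.label!r}")
            prev_end = b.end

    def bouts(self, label: str) -> list:
        return [b for b in self.intervals if b.label == label]

    def time_in(self, label: str) -> float:
        return float(sum(b.duration for b in self.bouts(label)))

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Every numeric constant of the analysis, with field-standard defaults.

    Durations are in seconds, rates in Hz, amplitudes in the arbitrary EMG
    units of the input signals.
    """

    # EMG conditioning and state scoring
    smooth_tau: float = 0.001          #: rectify-smooth time constant
    smooth_kind: str = "exponential"   #: "exponential" (causal RC) or "boxcar"
    twitch_multiplier: float = 3.0     #: twitch criterion, k x atonia baseline
    twitch_refractory: float = 0.200   #: minimum separation of twitch onsets, per muscle
    min_bout: float = 1.0              #: minimum qualifying wake/sleep run
    n_threshold_segments: int = 5      #: representative 1-s segments per tone class
    threshold_segment_len: float = 1.0
    state_channel: str = "nuchal"      #: EMG channel used for state scoring
    wake_onsets_within_bout: bool = False

    # perievent histograms and jitter test
    psth_window: float = 1.0           #: total window, centered on the trigger
    bin_width: float = 0.010           #: 0.005 / 0.010 / 0.020 by analysis
    jitter_window: float = 0.500       #: interval-jitter cell width (Delta)
    n_surrogates: int = 1000
    band_alpha: float = 0.01           #: 0.01 for twitch analyses, 0.05 for MDJ/pooled
    cd_window: tuple = (-0.010, 0.010)
    premotor_window: tuple = (-0.500, -0.010)
    reafferent_window: tuple = (0.010, 0.500)
    reafferent_auc_window: tuple = (0.020, 0.200)
    pooled_smooth_tau: float = 0.010
    min_stim_events: int = 10
    stim_min_interval: float = 5.0

    # state-dependence classification
    state_alpha: float = 0.05
    bonferroni: bool = False
    min_paired_bouts: int = 5
    pairing: str = "cycle"             #: "cycle" (matched pairs) or "unpaired"

    # group comparison
    outlier_sd: float = 3.0
    auc_per_event: bool = True

    rng_seed: int = 0

    def __post_init__(self):
        for name in ("smooth_tau", "twitch_refractory", "min_bout", "psth_window",
                     "bin_width", "jitter_window", "pooled_smooth_tau",
                     "threshold_segment_len"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"config: {name} must be > 0")
        if not (0 < self.band_alpha < 1 and 0 < self.state_alpha < 1):
            raise ValidationError("config: alpha must lie in (0, 1)")
        if self.n_surrogates < 100:
            raise ValidationError("config: n_surrogates must be >= 100")
        if self.twitch_multiplier <= 1:
            raise ValidationError("config: twitch_multiplier must exceed 1")
        half = self.psth_window / 2
        for name in ("cd_window", "premotor_window", "reafferent_window",
                     "reafferent_auc_window"):
            lo, hi = getattr(self, name)
            if not (-half - 1e-12 <= lo < hi <= half + 1e-12):
                raise ValidationError(f"config: {name} must lie inside the PSTH window")
        if self.smooth_kind not in ("exponential", "boxcar"):
            raise ValidationError("config: smooth_kind must be exponential|boxcar")
        if self.pairing not in ("cycle", "unpaired"):
            raise ValidationError("config: pairing must be cycle|unpaired")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise FormatError(f"config: unknown fields {sorted(extra)}")
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kw)

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def config_hash(config: AnalysisConfig) -> str:
    """Short stable hash of a configuration, for run logs."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_stage(stage: str, config: Optional[AnalysisConfig] = None, **counts) -> None:
    """Log one pipeline stage with its config hash and bookkeeping counts.

    Exclusion counts (artifact units, outlier bouts, zero-peak units, ...)
    are always logged here rather than silently dropped, so reported n's are
    reproducible from the run log.
    """
    parts = [stage]
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    parts += [f"{k}={v}" for k, v in counts.items()]
    logger.info(" ".join(parts))


# ---------------------------------------------------------------------------
# session container
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """One recording session: EMG channels, sorted units, event marks.

    ``group`` carries the experimental group for cohort comparisons
    (e.g. "saline" | "apamin" | "none"). ``ground_truth`` is populated only
    for synthetic sessions.
    """

    id: str
    duration: float
    emg: list = field(default_factory=list)
    spikes: list = field(default_factory=list)
    events: list = field(default_factory=list)
    states: Optional[StateIntervals] = None
    group: str = "none"
    ground_truth: Optional[object] = None

    def __post_init__(self):
        if not (self.duration > 0):
            raise ValidationError(f"session {self.id!r}: duration must be > 0")
        for sig in self.emg:
            if sig.t0 + sig.duration > self.duration + 1e-6:
                raise ValidationError(
                    f"session {self.id!r}: signal {sig.channel!r} extends past duration"
                )
        for st in self.spikes:
            if len(st) and st.times[-1] > self.duration + 1e-9:
                raise ValidationError(
                    f"session {self.id!r}: unit {st.unit_id!r} spikes past duration"
                )
        for ev in self.events:
            if len(ev) and ev.times[-1] > self.duration + 1e-9:
                raise ValidationError(
                    f"session {self.id!r}: events {ev.label!r} past duration"
                )

    def emg_channel(self, channel: str) -> SampledSignal:
        for sig in self.emg:
            if sig.channel == channel:
                return sig
        raise KeyError(f"session {self.id!r}: no EMG channel {channel!r}")

    def event_train(self, label: str) -> EventTrain:
        for ev in self.events:
            if ev.label == label:
                return ev
        raise KeyError(f"session {self.id!r}: no event train {label!r}")
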