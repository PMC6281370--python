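"""Synthetic sleep/wake sessions with known ground truth.

Real infant-rat recordings pair EMG-defined behavioral states (active wake,
behavioral quiescence, active sleep) with precerebellar unit activity that is
both state-dependent and locked to myoclonic twitches. The generator emulates
exactly that statistical structure:

* states alternate AW -> BQ -> AS cycles with exponential bout durations;
* EMG amplitude is tonic during AW and near a low atonia baseline during
  BQ/AS, with brief high-amplitude transients injected at ground-truth twitch
  times (peak a configurable multiple of the atonia baseline);
* each unit is an inhomogeneous Poisson process whose rate is a per-state
  base rate plus Gaussian rate kernels locked to twitch onsets, optionally
  with a post-event plateau (the "apamin" archetype's prolonged tail).

Archetypes mirror the response classes the analysis must detect: ``cd`` (a
sharp corollary-discharge peak at twitch onset), ``motor`` (twitch-preceding),
``sensory`` (twitch-following reafference), ``motor+reafferent``,
``apamin_cd`` (sharp peak plus a 20-200 ms tail), and ``null`` (no locking).

Every draw flows through one :class:`numpy.random.Generator`, so a fixed seed
reproduces a session exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Bout,
    EventTrain,
    SampledSignal,
    Session,
    SpikeTrain,
    StateIntervals,
    ValidationError,
)

__all__ = [
    "UnitSpec",
    "SimConfig",
    "SyntheticGroundTruth",
    "simulate_states",
    "simulate_unit_spikes",
    "simulate_session",
    "simulate_null_pair",
    "poisson_train",
]

ARCHETYPES = ("cd", "motor", "sensory", "motor+reafferent", "apamin_cd", "null")

# Gaussian rate kernels (center s, sd s, gain Hz) per archetype; shapes chosen
# to produce a sharp +-10 ms peak (cd), a broad twitch-preceding bump (motor),
# a 10-50 ms twitch-following bump (sensory), and the cd peak plus a
# 20-200 ms plateau (apamin_cd).
_ARCHETYPE_KERNELS = {
    "cd": [(0.0, 0.004, 50.0)],
    "motor": [(-0.030, 0.020, 15.0)],
    "sensory": [(0.030, 0.012, 20.0)],
    "motor+reafferent": [(-0.030, 0.020, 15.0), (0.030, 0.012, 12.0)],
    "apamin_cd": [(0.0, 0.004, 50.0)],
    "null": [],
}
_ARCHETYPE_PLATEAU = {"apamin_cd": (0.020, 0.200, 4.0)}

#: Default per-state base rates (Hz): units here fire mostly during AS.
_DEFAULT_BASE = {"AS": 5.0, "AW": 1.5, "BQ": 1.0}


@dataclass(frozen=True)
class UnitSpec:
    """Generative description of one synthetic unit."""

    unit_id: str
    archetype: str = "null"
    base_rate_by_state: dict = field(default_factory=lambda: dict(_DEFAULT_BASE))
    event_kernels: tuple = ()          #: (center s, sd s, gain Hz) per kernel
    plateau: Optional[tuple] = None    #: (start s, end s, gain Hz) after each event
    trigger_muscle: str = "nuchal"
    structure: str = "IO"

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        for c, w, g in self.event_kernels:
            if w <= 0 or g < 0:
                raise ValidationError("kernel sd must be > 0 and gain >= 0")
            if abs(c) > 0.5:
                raise ValidationError("kernel center must lie within +-0.5 s")
        if self.plateau is not None:
            s, e, g = self.plateau
            if not (s < e) or g < 0:
                raise ValidationError("plateau must have start < end and gain >= 0")
        for v in self.base_rate_by_state.values():
            if v < 0:
                raise ValidationError("base rates must be >= 0")

    @classmethod
    def from_archetype(cls, archetype: str, unit_id: str, *,
                       gain_scale: float = 1.0, **kw) -> "UnitSpec":
        kernels = tuple((c, w, g * gain_scale)
                        for c, w, g in _ARCHETYPE_KERNELS[archetype])
        plateau = _ARCHETYPE_PLATEAU.get(archetype)
        if plateau is not None:
            s, e, g = plateau
            plateau = (s, e, g * gain_scale)
        return cls(unit_id=unit_id, archetype=archetype,
                   event_kernels=kernels, plateau=plateau, **kw)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic session.

    Defaults emulate a ~30-min head-fixed recording at 1 kHz EMG sampling
    with minute-scale sleep/wake cycling and frequent active-sleep twitching.
    """

    duration: float = 1800.0
    bout_means: dict = field(default_factory=lambda: {"AW": 30.0, "BQ": 15.0, "AS": 60.0})
    bout_floor: float = 2.0            #: minimum bout length drawn (s)
    twitch_rates: dict = field(default_factory=lambda: {
        "nuchal": 0.25, "forelimb": 0.15, "hindlimb": 0.08})  # events/s during AS
    twitch_refractory: float = 0.200   #: minimum separation per muscle (s)

    emg_rate: float = 1000.0
    atonia_level: float = 1.0          #: mean rectified amplitude during BQ/AS (a.u.)
    wake_level: float = 10.0           #: mean rectified amplitude during AW (a.u.)
    atonia_noise_sd: float = 0.2
    wake_noise_sd: float = 2.0
    twitch_amp_multiple: float = 8.0   #: transient peak, x atonia_level (must exceed k)
    twitch_duration: float = 0.060
    transient_shape: str = "halfsine"  #: "halfsine" | "rect"

    unit_specs: tuple = ()
    group: str = "none"
    seed: int = 0

    def __post_init__(self):
        if not (self.duration > 0 and self.emg_rate > 0):
            raise ValidationError("sim: duration and emg_rate must be > 0")
        for st, m in self.bout_means.items():
            if m <= 0:
                raise ValidationError(f"sim: bout mean for {st} must be > 0")
        for m, r in self.twitch_rates.items():
            if r < 0:
                raise ValidationError(f"sim: twitch rate for {m} must be >= 0")
        if self.twitch_amp_multiple <= 1:
            raise ValidationError("sim: twitch_amp_multiple must exceed 1")
        if self.wake_level <= self.atonia_level:
            raise ValidationError("sim: wake_level must exceed atonia_level")
        if self.transient_shape not in ("halfsine", "rect"):
            raise ValidationError("sim: transient_shape must be halfsine|rect")

    @classmethod
    def noise_free(cls, **kw) -> "SimConfig":
        """Deterministic-EMG preset: constant tone levels, one-sample-rise
        rectangular twitch transients. Spike trains remain stochastic."""
        kw.setdefault("atonia_noise_sd", 0.0)
        kw.setdefault("wake_noise_sd", 0.0)
        kw.setdefault("transient_shape", "rect")
        return cls(**kw)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth used to score the pipeline's recovery."""

    true_states: StateIntervals
    true_twitches: Dict[str, EventTrain]
    true_wake_onsets: EventTrain
    unit_specs: tuple
    atonia_baseline: float


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def poisson_train(rate: float, start: float, end: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times on [start, end)."""
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    span = end - start
    if span <= 0 or rate == 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return start + np.sort(rng.uniform(0.0, span, size=n))


def simulate_states(sim: SimConfig, rng: np.random.Generator) -> StateIntervals:
    """AW -> BQ -> AS cycles with exponential (floored) bout durations."""
    cycle = ("AW", "BQ", "AS")
    bouts, t, i = [], 0.0, 0
    while t < sim.duration:
        label = cycle[i % 3]
        d = max(rng.exponential(sim.bout_means[label]), sim.bout_floor)
        end = min(t + d, sim.duration)
        if end - t > 1e-9:
            bouts.append(Bout(t, end, label))
        t, i = end, i + 1
    return StateIntervals(tuple(bouts))


def _simulate_twitches(sim: SimConfig, states: StateIntervals,
                       rng: np.random.Generator) -> Dict[str, EventTrain]:
    """Per-muscle twitch trains confined to AS bouts.

    The first muscle's first twitch in each AS bout is placed exactly at the
    bout start: the scored AS boundary is defined by the first twitch of a
    sleep period, so this makes the generated state boundaries recoverable.
    """
    muscles = list(sim.twitch_rates)
    anchor = next((m for m in muscles if sim.twitch_rates[m] > 0), None)
    out = {m: [] for m in muscles}
    for bout in states.bouts("AS"):
        for m in muscles:
            rate = sim.twitch_rates[m]
            first_here = m == anchor and bout.duration > sim.twitch_duration
            times = []
            if first_here:
                times.append(bout.start)
            if rate > 0:
                t = bout.start
                while True:
                    t = t + rng.exponential(1.0 / rate)
                    if t >= bout.end:
                        break
                    if not times or t - times[-1] >= sim.twitch_refractory:
                        times.append(t)
            out[m].extend(times)
    return {
        m: EventTrain(f"twitch_{m}", np.asarray(sorted(ts)), sim.duration)
        for m, ts in out.items()
    }


def _transient(sim: SimConfig, n: int) -> np.ndarray:
    """Amplitude envelope of one twitch transient, peak normalized to 1."""
    if sim.transient_shape == "rect":
        return np.ones(n)
    return np.sin(np.pi * (np.arange(n) + 1) / (n + 1))


def _simulate_emg(sim: SimConfig, states: StateIntervals,
                  twitches: Dict[str, EventTrain],
                  rng: np.random.Generator) -> Dict[str, SampledSignal]:
    n = int(round(sim.duration * sim.emg_rate))
    base = np.full(n, sim.atonia_level)
    noise_sd = np.full(n, sim.atonia_noise_sd)
    for b in states.bouts("AW"):
        i0, i1 = int(round(b.start * sim.emg_rate)), int(round(b.end * sim.emg_rate))
        base[i0:i1] = sim.wake_level
        noise_sd[i0:i1] = sim.wake_noise_sd
    bump_len = max(int(round(sim.twitch_duration * sim.emg_rate)), 1)
    bump = (sim.twitch_amp_multiple - 1.0) * sim.atonia_level * _transient(sim, bump_len)

    out = {}
    for m, train in twitches.items():
        amp = base.copy()
        if sim.atonia_noise_sd > 0 or sim.wake_noise_sd > 0:
            amp = np.abs(amp + noise_sd * rng.standard_normal(n))
        for t in train.times:
            i0 = int(round(t * sim.emg_rate))
            i1 = min(i0 + bump_len, n)
            amp[i0:i1] += bump[: i1 - i0]
        out[m] = SampledSignal(channel=m, rate=sim.emg_rate, samples=amp,
                               rectified=True)
    return out


def simulate_unit_spikes(spec: UnitSpec, states: StateIntervals,
                         events: np.ndarray, duration: float,
                         rng: np.random.Generator) -> SpikeTrain:
    """Draw one unit's spikes: per-state homogeneous Poisson background plus
    event-locked Gaussian kernels and an optional post-event plateau.

    The superposition of independent Poisson components is itself an
    inhomogeneous Poisson process with the summed (non-negative) rate, so no
    thinning or clipping is needed.
    """
    parts = [np.empty(0)]
    for b in states.intervals:
        parts.append(poisson_train(spec.base_rate_by_state.get(b.label, 0.0),
                                   b.start, b.end, rng))
    events = np.asarray(events, dtype=float)
    for center, sd, gain in spec.event_kernels:
        mass = gain * sd * np.sqrt(2 * np.pi)  # expected spikes per event
        counts = rng.poisson(mass, size=events.size)
        tot = int(counts.sum())
        if tot:
            locs = np.repeat(events + center, counts)
            parts.append(locs + sd * rng.standard_normal(tot))
    if spec.plateau is not None:
        s, e, gain = spec.plateau
        counts = rng.poisson(gain * (e - s), size=events.size)
        tot = int(counts.sum())
        if tot:
            starts = np.repeat(events + s, counts)
            parts.append(starts + (e - s) * rng.uniform(size=tot))
    t = np.concatenate(parts)
    t = np.sort(t[(t >= 0) & (t < duration)])
    return SpikeTrain(unit_id=spec.unit_id, structure=spec.structure, times=t)


# ---------------------------------------------------------------------------
# top-level generators
# ---------------------------------------------------------------------------

def simulate_session(sim: SimConfig, session_id: str = "synthetic") -> Session:
    """Generate one complete session with ground truth populated."""
    rng = np.random.default_rng(sim.seed)
    states = simulate_states(sim, rng)
    twitches = _simulate_twitches(sim, states, rng)
    emg = _simulate_emg(sim, states, twitches, rng)
    wake_onsets = EventTrain(
        "wake_onset",
        np.asarray([b.start for b in states.bouts("AW")]),
        sim.duration,
    )
    spikes = []
    for spec in sim.unit_specs:
        ev = twitches.get(spec.trigger_muscle)
        ev_times = ev.times if ev is not None else np.empty(0)
        spikes.append(simulate_unit_spikes(spec, states, ev_times, sim.duration, rng))
    gt = SyntheticGroundTruth(
        true_states=states,
        true_twitches=twitches,
        true_wake_onsets=wake_onsets,
        unit_specs=tuple(sim.unit_specs),
        atonia_baseline=sim.atonia_level,
    )
    return Session(
        id=session_id,
        duration=sim.duration,
        emg=list(emg.values()),
        spikes=spikes,
        events=[],
        states=None,
        group=sim.group,
        ground_truth=gt,
    )


def simulate_null_pair(event_rate: float, spike_rate: float, duration: float,
                       seed_or_rng) -> Tuple[EventTrain, SpikeTrain]:
    """Independent homogeneous Poisson event and spike trains.

    The calibration harness for the jitter band: any apparent event locking
    in such a pair is a false positive.
    """
    if event_rate <= 0 or spike_rate < 0:
        raise ValidationError("rates must be positive (spike rate may be 0)")
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    ev = poisson_train(event_rate, 0.0, duration, rng)
    # strictly increasing is required of EventTrain; duplicate draws are
    # measure-zero but protect against them anyway
    ev = np.unique(ev)
    sp = poisson_train(spike_rate, 0.0, duration, rng)
    return (EventTrain("null_event", ev, duration),
            SpikeTrain("null_unit", sp))
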