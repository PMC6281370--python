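"""Perievent histograms, interval-jitter surrogates and simultaneous bands.

The central statistical question of the analysis is whether a unit's spiking
is locked to movement events (twitch onsets, wake-movement onsets, exafferent
stimulation) on a fine timescale. The test:

1. build the perievent time histogram (PSTH) of spike lags relative to the
   events (1-s window, 5/10/20-ms bins, 0 always a bin edge);
2. destroy fine-timescale locking while preserving coarse rate structure by
   *interval jitter*: partition the session into contiguous cells of width
   Delta (500 ms) and redraw each event uniformly within its cell, 1000
   times;
3. form *simultaneous* acceptance bands from the surrogate PSTHs, calibrated
   by a studentized-maximum statistic so that the probability that ANY bin
   of a null-consistent histogram escapes the bands is at most alpha — a
   multiple-comparison correction across bins;
4. classify units by which latency window contains breaching bins:
   twitch-preceding (< -10 ms, "motor"), +-10 ms (corollary discharge), or
   > +10 ms (reafferent).

Band calibration rests on exchangeability: under the null (no locking finer
than the jitter cell width), the observed event train is one more draw from
the cell-uniform law that generated the surrogates, so its studentized
maximum deviation is exchangeable with theirs and exceeds their
ceil((1-alpha)(S+1))-th order statistic with probability at most alpha.
See :func:`simultaneous_bands` for the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    AnalysisConfig,
    EventTrain,
    MUSCLE_ORDER,
    SpikeTrain,
    ValidationError,
    logger,
)

__all__ = [
    "Psth",
    "JitterBands",
    "ResponseClass",
    "build_psth",
    "jitter_surrogates",
    "jitter_surrogate_counts",
    "simultaneous_bands",
    "jitter_band_test",
    "classify_response",
    "select_strongest_muscle",
    "pool_units",
    "normalize_and_average",
    "smooth_psth",
    "area_under_curve",
    "evoked_response",
]


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Psth:
    """Perievent histogram: spike counts by lag bin, summed over events."""

    trigger: str
    edges: np.ndarray          #: bin edges (s) relative to the trigger; 0 is an edge
    counts: np.ndarray         #: spikes per bin, summed over events
    n_events: int
    unit_ids: tuple = ()
    n_truncated: int = 0       #: events whose window ran past a session edge

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.counts.size != self.edges.size - 1:
            raise ValidationError("psth: counts/edges size mismatch")
        if self.n_events <= 0:
            raise ValidationError("psth: n_events must be positive")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def rate(self) -> np.ndarray:
        """Counts converted to firing rate, Hz per bin."""
        return self.counts / (self.n_events * self.bin_width)

    @property
    def normalized(self) -> np.ndarray:
        """Rate divided by the peak rate (peak = 1; error if all-zero)."""
        peak = self.rate.max()
        if peak <= 0:
            raise ValidationError("psth: cannot normalize an all-zero histogram")
        return self.rate / peak


def _make_edges(window: float, bin_width: float) -> np.ndarray:
    half = window / 2.0
    n_half = half / bin_width
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValidationError(
            f"bin width {bin_width} must divide half the window {half} so 0 is an edge")
    n_half = int(round(n_half))
    return bin_width * np.arange(-n_half, n_half + 1)


def _lag_counts(spikes: np.ndarray, events: np.ndarray,
                edges: np.ndarray) -> np.ndarray:
    """Histogram of spike-minus-event lags over half-open bins, vectorized."""
    lo = np.searchsorted(spikes, events + edges[0], side="left")
    hi = np.searchsorted(spikes, events + edges[-1], side="left")
    n_per = hi - lo
    total = int(n_per.sum())
    nbins = edges.size - 1
    if total == 0:
        return np.zeros(nbins)
    # flat spike indices lo[i]..hi[i] for every event i
    flat = np.repeat(lo - np.concatenate(([0], np.cumsum(n_per)[:-1])), n_per) \
        + np.arange(total)
    lags = spikes[flat] - np.repeat(events, n_per)
    idx = np.searchsorted(edges, lags, side="right") - 1
    np.clip(idx, 0, nbins - 1, out=idx)
    return np.bincount(idx, minlength=nbins).astype(float)


def build_psth(spikes: SpikeTrain, events: EventTrain, window: float = 1.0,
               bin_width: float = 0.005, trigger: Optional[str] = None) -> Psth:
    """PSTH of ``spikes`` around ``events`` over a centered window.

    counts[b] = #{(s, e) : s - e in [edge_b, edge_{b+1})}. Events whose
    window extends past a session edge still contribute (their truncation is
    counted in ``n_truncated``). Empty event trains are an error rather than
    a zero histogram, to keep the rate view well defined.
    """
    if len(events) == 0:
        raise ValidationError(f"build_psth: event train {events.label!r} is empty")
    edges = _make_edges(window, bin_width)
    counts = _lag_counts(spikes.times, events.times, edges)
    half = window / 2.0
    n_trunc = int(np.sum((events.times < half)
                         | (events.times > events.session_duration - half)))
    return Psth(trigger=trigger or events.label, edges=edges, counts=counts,
                n_events=len(events), unit_ids=(spikes.unit_id,),
                n_truncated=n_trunc)


# ---------------------------------------------------------------------------
# interval jitter
# ---------------------------------------------------------------------------

def _jitter_matrix(events: EventTrain, delta: float, n_surrogates: int,
                   rng: np.random.Generator) -> np.ndarray:
    """(S, n_events) jittered times; each event uniform in its Delta-cell."""
    t = events.times
    cell_lo = np.floor(t / delta) * delta
    cell_hi = np.minimum(cell_lo + delta, events.session_duration)
    u = rng.uniform(size=(n_surrogates, t.size))
    return cell_lo + u * (cell_hi - cell_lo)


def jitter_surrogates(events: EventTrain, delta: float, n_surrogates: int,
                      seed_or_rng) -> List[EventTrain]:
    """Interval-jitter surrogate event trains.

    The session is partitioned into contiguous cells [k*Delta, (k+1)*Delta);
    each event is redrawn uniformly within its own cell, independently per
    surrogate, so the event count per cell (hence in total) is preserved
    exactly.
    """
    if delta <= 0:
        raise ValidationError("jitter_surrogates: delta must be > 0")
    if n_surrogates < 1:
        raise ValidationError("jitter_surrogates: need at least one surrogate")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    mat = _jitter_matrix(events, delta, n_surrogates, rng)
    out = []
    for row in np.sort(mat, axis=1):
        # ties between two jittered events are measure-zero; nudge if hit
        d = np.diff(row)
        if np.any(d <= 0):
            row = row + np.arange(row.size) * 1e-12
        out.append(EventTrain(events.label, row, events.session_duration))
    return out


def jitter_surrogate_counts(spikes: SpikeTrain, events: EventTrain,
                            edges: np.ndarray, delta: float,
                            n_surrogates: int,
                            rng: np.random.Generator) -> np.ndarray:
    """(S, n_bins) surrogate PSTH counts, computed without materializing
    surrogate event trains (the fast path used by the pipeline)."""
    spk = spikes.times
    mat = _jitter_matrix(events, delta, n_surrogates, rng)
    S, n_ev = mat.shape
    flat_ev = mat.ravel()
    lo = np.searchsorted(spk, flat_ev + edges[0], side="left")
    hi = np.searchsorted(spk, flat_ev + edges[-1], side="left")
    n_per = hi - lo
    total = int(n_per.sum())
    nbins = edges.size - 1
    if total == 0:
        return np.zeros((S, nbins))
    flat = np.repeat(lo - np.concatenate(([0], np.cumsum(n_per)[:-1])), n_per) \
        + np.arange(total)
    lags = spk[flat] - np.repeat(flat_ev, n_per)
    idx = np.searchsorted(edges, lags, side="right") - 1
    np.clip(idx, 0, nbins - 1, out=idx)
    surro = np.repeat(np.arange(S * n_ev, dtype=np.intp) // n_ev, n_per)
    counts = np.bincount(surro * nbins + idx, minlength=S * nbins)
    return counts.reshape(S, nbins).astype(float)


# ---------------------------------------------------------------------------
# simultaneous bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JitterBands:
    """Simultaneous acceptance bands from jitter surrogates (count scale)."""

    alpha: float
    n_surrogates: int
    delta: float
    upper: np.ndarray          #: per-bin upper band; breach = count > upper
    lower: np.ndarray          #: per-bin lower band; breach = count < lower
    surrogate_mean: np.ndarray
    q_crit: float              #: calibrated studentized-maximum quantile

    def breach_upper(self, counts: np.ndarray) -> np.ndarray:
        return np.asarray(counts) > self.upper

    def breach_lower(self, counts: np.ndarray) -> np.ndarray:
        return np.asarray(counts) < self.lower

    def any_breach(self, counts: np.ndarray) -> bool:
        return bool(self.breach_upper(counts).any()
                    or self.breach_lower(counts).any())


def _as_counts_matrix(surrogates) -> np.ndarray:
    if isinstance(surrogates, np.ndarray):
        return surrogates.astype(float)
    return np.vstack([s.counts for s in surrogates]).astype(float)


def simultaneous_bands(psth: Psth, surrogates, alpha: float,
                       analysis_span: Optional[Tuple[float, float]] = None,
                       delta: float = float("nan")) -> JitterBands:
    """Studentized-maximum-calibrated simultaneous bands.

    Per bin the surrogate counts give a mean mu_b and SD sigma_b; each
    surrogate is summarized by the scalar D_s = max_b |X_sb - mu_b| / sigma_b
    and the critical value q is the ceil((1-alpha)(S+1))-th smallest D_s.
    The bands are mu_b +/- q sigma_b, so the observed histogram breaches
    somewhere iff its own D exceeds q — a single scalar comparison that is
    exchangeable with the surrogate D's under the null, giving a family-wise
    breach probability <= alpha jointly over bins and both band sides.

    ``surrogates`` is either a list of surrogate :class:`Psth` (identical
    binning) or an (S, n_bins) count matrix. ``analysis_span`` restricts the
    family of bins under test (bands outside the span are +/- infinity and
    never breach); default is the full window.
    """
    X = _as_counts_matrix(surrogates)
    S, nbins = X.shape
    if nbins != psth.counts.size:
        raise ValidationError("simultaneous_bands: surrogate binning mismatch")
    k = int(np.ceil((1.0 - alpha) * (S + 1)))
    if S < int(np.ceil(1.0 / alpha)) or k > S:
        raise ValidationError(
            f"simultaneous_bands: too few surrogates ({S}) for alpha={alpha}")
    centers = psth.centers
    if analysis_span is None:
        span_mask = np.ones(nbins, dtype=bool)
    else:
        lo, hi = analysis_span
        span_mask = (centers > lo) & (centers < hi)
        if not span_mask.any():
            raise ValidationError("simultaneous_bands: analysis span contains no bins")
    Xs = X[:, span_mask]
    mu = Xs.mean(axis=0)
    sigma = Xs.std(axis=0)
    sigma_safe = np.where(sigma > 0, sigma, 1.0)
    D = np.max(np.abs(Xs - mu) / sigma_safe, axis=1)
    q = float(np.sort(D)[k - 1])
    upper = np.full(nbins, np.inf)
    lower = np.full(nbins, -np.inf)
    upper[span_mask] = mu + q * sigma
    lower[span_mask] = mu - q * sigma
    mean = np.zeros(nbins)
    mean[span_mask] = mu
    return JitterBands(alpha=alpha, n_surrogates=S, delta=delta,
                       upper=upper, lower=lower, surrogate_mean=mean, q_crit=q)


def jitter_band_test(spikes: SpikeTrain, events: EventTrain, *,
                     window: float = 1.0, bin_width: float = 0.010,
                     delta: float = 0.500, n_surrogates: int = 1000,
                     alpha: float = 0.01,
                     analysis_span: Optional[Tuple[float, float]] = None,
                     rng=None) -> Tuple[Psth, JitterBands]:
    """Observed PSTH plus its calibrated simultaneous bands, in one call."""
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    psth = build_psth(spikes, events, window, bin_width)
    X = jitter_surrogate_counts(spikes, events, psth.edges, delta,
                                n_surrogates, rng)
    bands = simultaneous_bands(psth, X, alpha, analysis_span, delta)
    return psth, bands


# ---------------------------------------------------------------------------
# latency-window classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseClass:
    """Which latency windows a unit's event-locked response occupies."""

    unit_id: str
    trigger: str
    significant_windows: frozenset      #: subset of {"premotor", "cd", "reafferent"}
    suppressed_windows: frozenset       #: windows with below-band bins
    primary_window: Optional[str]       #: window of the strongest breaching bin
    peak_lag: float                     #: center of the max-rate bin (s)
    first_breach_lag: Optional[float]   #: center of earliest breaching bin (s)
    muscle: Optional[str] = None

    @property
    def significant(self) -> bool:
        return bool(self.significant_windows)


def _window_bins(psth: Psth, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    eps = 1e-9
    return (psth.edges[:-1] >= lo - eps) & (psth.edges[1:] <= hi + eps)


def classify_response(psth: Psth, bands: JitterBands,
                      config: AnalysisConfig) -> ResponseClass:
    """Assign latency windows from band breaches.

    A window is significant iff at least one of its bins exceeds the upper
    band; below-band bins are flagged separately as suppression. The primary
    window is the one holding the largest above-band excess.
    """
    windows = {"premotor": config.premotor_window,
               "cd": config.cd_window,
               "reafferent": config.reafferent_window}
    up = bands.breach_upper(psth.counts)
    dn = bands.breach_lower(psth.counts)
    sig, supp = set(), set()
    centers = psth.centers
    best_excess, primary = -np.inf, None
    first_lag = None
    for name, win in windows.items():
        inb = _window_bins(psth, win)
        if np.any(up & inb):
            sig.add(name)
            excess = np.where(up & inb, psth.counts - bands.upper, -np.inf)
            i = int(np.argmax(excess))
            if excess[i] > best_excess:
                best_excess, primary = excess[i], name
        if np.any(dn & inb):
            supp.add(name)
    if up.any():
        first_lag = float(centers[np.flatnonzero(up)[0]])
    return ResponseClass(
        unit_id=psth.unit_ids[0] if psth.unit_ids else "",
        trigger=psth.trigger,
        significant_windows=frozenset(sig),
        suppressed_windows=frozenset(supp),
        primary_window=primary,
        peak_lag=float(centers[int(np.argmax(psth.counts))]),
        first_breach_lag=first_lag)


def select_strongest_muscle(per_muscle: Dict[str, Tuple[ResponseClass, Psth]]
                            ) -> Optional[str]:
    """Among muscles with a significant response, pick the one with the
    highest PSTH peak rate; ties break by total in-window count, then by the
    canonical muscle order. Returns None if no muscle is significant."""
    sig = {m: v for m, v in per_muscle.items() if v[0].significant}
    if not sig:
        return None

    def order_key(m: str) -> tuple:
        idx = MUSCLE_ORDER.index(m) if m in MUSCLE_ORDER else len(MUSCLE_ORDER)
        return (idx, m)

    def key(m: str) -> tuple:
        p = sig[m][1]
        return (-p.rate.max(), -p.counts.sum()) + order_key(m)

    chosen = min(sig, key=key)
    if len(sig) > 1:
        logger.info("select_strongest_muscle: chose %s among %s",
                    chosen, sorted(sig))
    return chosen


# ---------------------------------------------------------------------------
# pooling, normalization, smoothing, AUC
# ---------------------------------------------------------------------------

def pool_units(pairs: Sequence[Tuple[SpikeTrain, EventTrain]], *,
               window: float = 1.0, bin_width: float = 0.005,
               delta: float = 0.500, n_surrogates: int = 1000,
               alpha: float = 0.01, trigger: str = "pooled",
               rng=None) -> Tuple[Psth, JitterBands]:
    """Pool significant units: sum their PSTH counts and re-run the jitter
    test by jittering each unit's own events independently and summing the
    surrogate histograms."""
    if not pairs:
        raise ValidationError("pool_units: empty unit list")
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    edges = _make_edges(window, bin_width)
    counts = np.zeros(edges.size - 1)
    X = np.zeros((n_surrogates, edges.size - 1))
    n_events, unit_ids, n_trunc = 0, [], 0
    for spikes, events in pairs:
        p = build_psth(spikes, events, window, bin_width)
        counts += p.counts
        n_events += p.n_events
        n_trunc += p.n_truncated
        unit_ids.append(spikes.unit_id)
        X += jitter_surrogate_counts(spikes, events, edges, delta,
                                     n_surrogates, rng)
    pooled = Psth(trigger=trigger, edges=edges, counts=counts,
                  n_events=n_events, unit_ids=tuple(unit_ids),
                  n_truncated=n_trunc)
    bands = simultaneous_bands(pooled, X, alpha, None, delta)
    return pooled, bands


def normalize_and_average(psths: Sequence[Psth]
                          ) -> Tuple[np.ndarray, np.ndarray, int, list]:
    """Per-unit peak-normalized rates, averaged across units.

    Returns (mean, sem, n_used, excluded_unit_ids); units with a zero peak
    rate cannot be normalized and are excluded (and reported).
    """
    rows, excluded = [], []
    for p in psths:
        if p.rate.max() <= 0:
            excluded.append(p.unit_ids[0] if p.unit_ids else "?")
            continue
        rows.append(p.normalized)
    if not rows:
        raise ValidationError("normalize_and_average: all units have zero peak")
    M = np.vstack(rows)
    mean = M.mean(axis=0)
    sem = (M.std(axis=0, ddof=1) / np.sqrt(M.shape[0])
           if M.shape[0] > 1 else np.zeros(M.shape[1]))
    if excluded:
        logger.info("normalize_and_average: excluded zero-peak units %s", excluded)
    return mean, sem, M.shape[0], excluded


def smooth_psth(psth: Psth, tau: float = 0.010, causal: bool = False) -> np.ndarray:
    """Exponential-kernel smoothing of the rate view (mass preserving).

    Symmetric kernel exp(-|t|/tau) by default; ``causal`` uses exp(-t/tau)
    for t >= 0 only. The kernel is normalized to unit mass on the bin grid.
    """
    if tau <= 0:
        raise ValidationError("smooth_psth: tau must be > 0")
    bw = psth.bin_width
    half = max(int(np.ceil(6 * tau / bw)), 1)
    lags = np.arange(-half, half + 1) * bw
    if causal:
        k = np.where(lags >= 0, np.exp(-lags / tau), 0.0)
    else:
        k = np.exp(-np.abs(lags) / tau)
    k /= k.sum()
    return np.convolve(psth.rate, k, mode="same")


def area_under_curve(psth: Psth, window: Tuple[float, float],
                     per_event: bool = True) -> float:
    """Sum of histogram counts over a lag window aligned to bin edges.

    ``per_event`` divides by the number of trigger events so sessions with
    different twitch counts are comparable.
    """
    lo, hi = window
    eps = 1e-9
    for w in (lo, hi):
        k = (w - psth.edges[0]) / psth.bin_width
        if abs(k - round(k)) > 1e-6:
            raise ValidationError(
                f"area_under_curve: window bound {w} not aligned to bin edges")
    mask = _window_bins(psth, window)
    total = float(psth.counts[mask].sum())
    return total / psth.n_events if per_event else total


def evoked_response(spikes: SpikeTrain, stim_events: EventTrain, *,
                    bin_width: float = 0.020, window: float = 1.0,
                    delta: float = 0.500, n_surrogates: int = 1000,
                    alpha: float = 0.05, min_events: int = 10,
                    min_interval: float = 5.0,
                    rng=None) -> Tuple[Psth, JitterBands, Optional[float]]:
    """Exafferent-stimulation PSTH (20-ms bins) with response latency.

    Latency is the center of the first post-onset bin exceeding the upper
    band (None if no such bin). Stimulation intervals below ``min_interval``
    log a protocol-deviation warning.
    """
    if len(stim_events) < min_events:
        raise ValidationError(
            f"evoked_response: need >= {min_events} stimulations, got {len(stim_events)}")
    gaps = np.diff(stim_events.times)
    if gaps.size and gaps.min() < min_interval:
        logger.warning("evoked_response: %d stimulation intervals < %.1f s",
                       int(np.sum(gaps < min_interval)), min_interval)
    psth, bands = jitter_band_test(
        spikes, stim_events, window=window, bin_width=bin_width, delta=delta,
        n_surrogates=n_surrogates, alpha=alpha, rng=rng)
    up = bands.breach_upper(psth.counts) & (psth.edges[:-1] >= -1e-9)
    latency = float(psth.centers[np.flatnonzero(up)[0]]) if up.any() else None
    return psth, bands, latency
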