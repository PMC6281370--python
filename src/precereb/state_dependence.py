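"""State-dependent firing-rate classification (AS-on / AW-on / AS+AW-on).

Each unit's firing rate is computed per behavioral-state bout; bouts whose
rate deviates from their state's mean by more than 3 SD are excluded once
(this is rare, typically 0-2 bouts per unit); pairwise Wilcoxon matched-pairs
signed-rank tests across states then drive a decision table:

* AS-on:             AS significantly above both AW and BQ,
* AW-on:             AW significantly above both AS and BQ,
* AS+AW-on:          AS vs AW not significant, both significantly above BQ,
* state-independent: no significant ordering.

Bouts are paired by sleep-wake cycle index (the i-th AS bout with the i-th
AW bout, and so on), truncating to the shorter list; an unpaired
Mann-Whitney fallback is available for sessions without usable pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .model import (
    STATE_LABELS,
    SpikeTrain,
    StateIntervals,
    ValidationError,
    log_stage,
    logger,
)

__all__ = [
    "BoutRate",
    "StateRateProfile",
    "StateClass",
    "bout_rates",
    "classify_state",
]

_PAIRS = (("AS", "AW"), ("AS", "BQ"), ("AW", "BQ"))


@dataclass(frozen=True)
class BoutRate:
    index: int
    start: float
    duration: float
    count: int
    rate: float


@dataclass(frozen=True)
class StateRateProfile:
    unit_id: str
    rates: Dict[str, list]           #: state -> included BoutRate list
    excluded: Dict[str, list]        #: state -> excluded BoutRate list
    mean_rate: Dict[str, float]      #: unweighted mean of included bout rates

    def n_excluded(self) -> int:
        return sum(len(v) for v in self.excluded.values())


@dataclass(frozen=True)
class StateClass:
    unit_id: str
    label: str                       #: AS-on | AW-on | AS+AW-on | state-independent | indeterminate
    p_values: Dict[Tuple[str, str], float]
    alpha: float


def bout_rates(spikes: SpikeTrain, states: StateIntervals,
               outlier_sd: float = 3.0) -> StateRateProfile:
    """Per-bout firing rates with one-pass 3 SD outlier exclusion.

    Rates use half-open bout intervals [start, end). The exclusion
    criterion |rate - state mean| > outlier_sd x state SD (sample SD, ddof=1)
    is evaluated once on the full per-state distribution, never iterated.
    """
    t = spikes.times
    rates: Dict[str, List[BoutRate]] = {s: [] for s in STATE_LABELS}
    for i, b in enumerate(states.intervals):
        n = int(np.searchsorted(t, b.end, side="left")
                - np.searchsorted(t, b.start, side="left"))
        rates[b.label].append(BoutRate(i, b.start, b.duration, n, n / b.duration))
    kept: Dict[str, list] = {}
    excl: Dict[str, list] = {}
    means: Dict[str, float] = {}
    for s in STATE_LABELS:
        rs = rates[s]
        vals = np.array([r.rate for r in rs])
        if vals.size >= 2 and vals.std(ddof=1) > 0:
            lim = outlier_sd * vals.std(ddof=1)
            keep = np.abs(vals - vals.mean()) <= lim
        else:
            keep = np.ones(vals.size, dtype=bool)
        kept[s] = [r for r, k in zip(rs, keep) if k]
        excl[s] = [r for r, k in zip(rs, keep) if not k]
        means[s] = float(np.mean([r.rate for r in kept[s]])) if kept[s] else float("nan")
    prof = StateRateProfile(unit_id=spikes.unit_id, rates=kept,
                            excluded=excl, mean_rate=means)
    if prof.n_excluded():
        logger.info("bout_rates: unit %s excluded %d outlier bouts",
                    spikes.unit_id, prof.n_excluded())
    return prof


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; exact where ties permit."""
    d = a - b
    if np.all(d == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(a, b, method="exact").pvalue)
    except ValueError:  # zeros/ties: fall back to the normal approximation
        return float(stats.wilcoxon(a, b, method="approx").pvalue)


def classify_state(profile: StateRateProfile, pairing: str = "cycle",
                   alpha: float = 0.05, min_pairs: int = 5,
                   bonferroni: bool = False) -> StateClass:
    """Decision-table classification from pairwise rate comparisons.

    Significance requires both p < alpha and the mean paired difference in
    the stated direction; "AS > AW >= BQ" demands significance only of AS
    against each other state, not of AW against BQ.
    """
    thr = alpha / len(_PAIRS) if bonferroni else alpha
    pvals: Dict[Tuple[str, str], float] = {}
    greater: Dict[Tuple[str, str], bool] = {}
    usable = True
    for s1, s2 in _PAIRS:
        r1 = np.array([r.rate for r in profile.rates[s1]])
        r2 = np.array([r.rate for r in profile.rates[s2]])
        if pairing == "cycle":
            n = min(r1.size, r2.size)
            if n < min_pairs:
                usable = False
                pvals[(s1, s2)] = float("nan")
                continue
            p = _paired_p(r1[:n], r2[:n])
            diff = float(np.mean(r1[:n] - r2[:n]))
        elif pairing == "unpaired":
            if min(r1.size, r2.size) < 2:
                usable = False
                pvals[(s1, s2)] = float("nan")
                continue
            if np.ptp(np.concatenate([r1, r2])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(r1, r2, alternative="two-sided").pvalue)
            diff = float(r1.mean() - r2.mean())
        else:
            raise ValidationError(f"classify_state: unknown pairing {pairing!r}")
        pvals[(s1, s2)] = p
        greater[(s1, s2)] = p < thr and diff > 0

    if not usable:
        label = "indeterminate"
    else:
        as_aw = pvals[("AS", "AW")] < thr
        as_gt_aw = greater[("AS", "AW")]
        aw_gt_as = as_aw and not as_gt_aw
        if as_gt_aw and greater[("AS", "BQ")]:
            label = "AS-on"
        elif aw_gt_as and greater[("AW", "BQ")]:
            label = "AW-on"
        elif (not as_aw) and greater[("AS", "BQ")] and greater[("AW", "BQ")]:
            label = "AS+AW-on"
        else:
            label = "state-independent"
    return StateClass(unit_id=profile.unit_id, label=label,
                      p_values=pvals, alpha=thr)
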