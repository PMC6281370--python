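"""Two-group statistics and the saline-vs-apamin comparison pipeline.

SK-channel blockade in the inferior olive is expected to broaden the sharp
corollary-discharge peak that follows twitch onset without changing overall
responsiveness. The cohort comparison therefore runs, in order:

1. per-pup active-sleep time and twitches per minute of AS (Mann-Whitney);
2. per-unit AS firing rate (Mann-Whitney, 3 SD outlier exclusion);
3. per-unit twitch-triggered PSTHs (10-ms bins, 1-s window), peak-normalized
   and averaged within each group;
4. per-unit jitter significance; chi-squared tests on the proportion of
   significant units and on the proportion with a sharp +-10 ms peak;
5. pooled significant-unit PSTHs per group with simultaneous bands
   (alpha 0.05) and tau = 10 ms smoothing;
6. per-unit area under the curve in the +-10 ms and 20-200 ms windows
   (Mann-Whitney per window, 3 SD outlier exclusion).

Chi-squared tests are Pearson without continuity correction; rank tests are
two-sided with a tie-corrected normal Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import AnalysisConfig, Session, ValidationError, log_stage, logger
from .perievent import (
    area_under_curve,
    classify_response,
    jitter_band_test,
    normalize_and_average,
    pool_units,
    select_strongest_muscle,
    smooth_psth,
)
from .scoring import score_session

__all__ = [
    "ContingencyTable2x2",
    "TwoGroupResult",
    "chi_squared_2x2",
    "mann_whitney",
    "compare_apamin_pipeline",
    "GroupReport",
    "write_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (rows = groups, columns = outcome yes/no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency table: counts must be >= 0")
        if self.n == 0:
            raise ValidationError("contingency table: empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class TwoGroupResult:
    measure: str
    n: Tuple[int, int]
    medians: Tuple[float, float]
    means: Tuple[float, float]
    u: float
    z: float
    p: float
    excluded: Tuple[tuple, tuple]      #: outlier values removed per group


def chi_squared_2x2(table: ContingencyTable2x2) -> Tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table, WITHOUT continuity correction
    (the convention under which the reported group proportions reproduce).
    Returns (statistic, df=1, p)."""
    m = table.matrix
    if np.any(m.sum(axis=0) == 0) or np.any(m.sum(axis=1) == 0):
        raise ValidationError("chi_squared_2x2: degenerate margin (zero row/column)")
    stat, p, dof, _ = stats.chi2_contingency(m, correction=False)
    return float(stat), int(dof), float(p)


def _exclude_outliers(values: np.ndarray, outlier_sd: float) -> Tuple[np.ndarray, np.ndarray]:
    if values.size >= 2 and values.std(ddof=1) > 0:
        keep = np.abs(values - values.mean()) <= outlier_sd * values.std(ddof=1)
        return values[keep], values[~keep]
    return values, values[:0]


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 outlier_sd: float = 3.0,
                 measure: str = "") -> TwoGroupResult:
    """Mann-Whitney U with per-group 3 SD outlier exclusion.

    Outliers (beyond ``outlier_sd`` sample SDs of their own group) are
    removed once and logged. U is the statistic of the first group; Z is the
    tie-corrected normal deviate and p the two-sided normal p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, excl_a = _exclude_outliers(a, outlier_sd)
    b, excl_b = _exclude_outliers(b, outlier_sd)
    if a.size < 2 or b.size < 2:
        raise ValidationError("mann_whitney: need >= 2 values per group after exclusion")
    if excl_a.size or excl_b.size:
        logger.info("mann_whitney[%s]: excluded outliers %s | %s",
                    measure, excl_a.tolist(), excl_b.tolist())
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts ** 3 - t_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:          # all values identical in both groups
        z, p = 0.0, 1.0
    else:
        z = (u - mu) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return TwoGroupResult(
        measure=measure, n=(n1, n2),
        medians=(float(np.median(a)), float(np.median(b))),
        means=(float(a.mean()), float(b.mean())),
        u=u, z=float(z), p=min(p, 1.0),
        excluded=(tuple(excl_a), tuple(excl_b)))


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

@dataclass
class GroupReport:
    """Structured output of the two-group comparison."""

    groups: Tuple[str, str]
    behavior: pd.DataFrame               #: per-pup AS time and twitch rate
    behavior_tests: Dict[str, TwoGroupResult]
    unit_table: pd.DataFrame             #: per-unit rates, significance, AUC
    rate_test: Optional[TwoGroupResult]
    proportions: Dict[str, dict]         #: chi-squared results (or skip reasons)
    normalized_mean: Dict[str, pd.DataFrame]
    pooled: Dict[str, pd.DataFrame]
    auc_tests: Dict[str, Optional[TwoGroupResult]]
    log: List[str] = field(default_factory=list)


def _unit_jitter(spikes, twitch_trains, config, rng):
    """Per-muscle jitter tests for one unit; returns classifications, psths
    and the strongest significant muscle (None if none significant)."""
    per_muscle = {}
    for train in twitch_trains:
        if len(train) < 10:
            continue
        psth, bands = jitter_band_test(
            spikes, train, window=config.psth_window, bin_width=config.bin_width,
            delta=config.jitter_window, n_surrogates=config.n_surrogates,
            alpha=config.band_alpha, rng=rng)
        muscle = train.label.removeprefix("twitch_")
        rc = classify_response(psth, bands, config)
        per_muscle[muscle] = (rc, psth, bands, train)
    if not per_muscle:
        return None, None
    chosen = select_strongest_muscle(
        {m: (rc, p) for m, (rc, p, _, _) in per_muscle.items()})
    if chosen is None:
        # not significant anywhere: keep the highest-peak muscle for
        # descriptive histograms, flagged non-significant
        chosen = max(per_muscle, key=lambda m: per_muscle[m][1].rate.max())
        return chosen, per_muscle
    return chosen, per_muscle


def compare_apamin_pipeline(sessions: Sequence[Session],
                            config: AnalysisConfig,
                            groups: Tuple[str, str] = ("saline", "apamin")
                            ) -> GroupReport:
    """Run the full two-group battery on scored (or scorable) sessions."""
    ga, gb = groups
    by_group = {g: [s for s in sessions if s.group == g] for g in groups}
    for g, ss in by_group.items():
        if not ss:
            raise ValidationError(f"compare_apamin_pipeline: no sessions in group {g!r}")
    rng = np.random.default_rng(config.rng_seed)
    cfg = config.with_(band_alpha=0.05)   # pooled/apamin analyses use p < 0.05
    log: List[str] = []

    # --- 1. behavior: AS time and twitches per minute of AS, per pup
    beh_rows = []
    scored: Dict[str, list] = {g: [] for g in groups}
    for g in groups:
        for s in by_group[g]:
            sc = s if s.states is not None else score_session(s, cfg)
            scored[g].append(sc)
            as_time = sc.states.time_in("AS")
            n_tw = sum(len(e) for e in sc.events if e.label.startswith("twitch_"))
            beh_rows.append({
                "group": g, "session": sc.id, "as_time_s": as_time,
                "twitches_per_min_as": 60.0 * n_tw / as_time if as_time > 0 else np.nan,
            })
    behavior = pd.DataFrame(beh_rows)
    behavior_tests = {}
    for meas in ("as_time_s", "twitches_per_min_as"):
        va = behavior.loc[behavior.group == ga, meas].dropna().to_numpy()
        vb = behavior.loc[behavior.group == gb, meas].dropna().to_numpy()
        try:
            behavior_tests[meas] = mann_whitney(va, vb, np.inf, measure=meas)
        except ValidationError as e:
            log.append(f"behavior test {meas} skipped: {e}")

    # --- 2..6. per-unit measures
    unit_rows = []
    pooled_pairs: Dict[str, list] = {g: [] for g in groups}
    norm_psths: Dict[str, list] = {g: [] for g in groups}
    for g in groups:
        for sc in scored[g]:
            twitch_trains = [e for e in sc.events if e.label.startswith("twitch_")]
            as_bouts = sc.states.bouts("AS")
            as_dur = sum(b.duration for b in as_bouts)
            for spikes in sc.spikes:
                n_as = sum(
                    int(np.searchsorted(spikes.times, b.end)
                        - np.searchsorted(spikes.times, b.start))
                    for b in as_bouts)
                as_rate = n_as / as_dur if as_dur > 0 else np.nan
                chosen, per_muscle = _unit_jitter(spikes, twitch_trains, cfg, rng)
                if chosen is None:
                    log.append(f"unit {spikes.unit_id} ({sc.id}): no usable twitch "
                               "events; excluded from perievent analyses")
                    unit_rows.append({
                        "group": g, "session": sc.id, "unit": spikes.unit_id,
                        "as_rate_hz": as_rate, "muscle": None,
                        "significant": False, "sharp_peak": False,
                        "auc_cd": np.nan, "auc_tail": np.nan})
                    continue
                rc, psth, bands, train = per_muscle[chosen]
                significant = rc.significant
                sharp = "cd" in rc.significant_windows
                auc_cd = area_under_curve(psth, cfg.cd_window, cfg.auc_per_event)
                auc_tail = area_under_curve(psth, cfg.reafferent_auc_window,
                                            cfg.auc_per_event)
                unit_rows.append({
                    "group": g, "session": sc.id, "unit": spikes.unit_id,
                    "as_rate_hz": as_rate, "muscle": chosen,
                    "significant": significant, "sharp_peak": sharp,
                    "auc_cd": auc_cd, "auc_tail": auc_tail})
                norm_psths[g].append(psth)
                if significant:
                    pooled_pairs[g].append((spikes, train))
    units = pd.DataFrame(unit_rows)

    # --- 2. AS firing rate across groups
    rate_test = None
    try:
        rate_test = mann_whitney(
            units.loc[units.group == ga, "as_rate_hz"].dropna(),
            units.loc[units.group == gb, "as_rate_hz"].dropna(),
            cfg.outlier_sd, measure="as_rate_hz")
    except ValidationError as e:
        log.append(f"AS-rate test skipped: {e}")

    # --- 3. normalized mean PSTH per group
    normalized_mean = {}
    for g in groups:
        nz = [p for p in norm_psths[g] if p.rate.max() > 0]
        if nz:
            mean, sem, n_used, excl = normalize_and_average(nz)
            normalized_mean[g] = pd.DataFrame({
                "lag_s": nz[0].centers, "mean_norm_rate": mean, "sem": sem})
            if excl:
                log.append(f"group {g}: zero-peak units excluded from "
                           f"normalized average: {excl}")

    # --- 4. chi-squared on unit proportions
    proportions = {}
    for name, col in (("significant_units", "significant"),
                      ("sharp_peak_units", "sharp_peak")):
        counts = {}
        for g in groups:
            sub = units[(units.group == g) & units.muscle.notna()]
            counts[g] = (int(sub[col].sum()), int(len(sub)))
        ya, na_ = counts[ga]
        yb, nb_ = counts[gb]
        try:
            table = ContingencyTable2x2(ya, na_ - ya, yb, nb_ - yb)
            stat, dof, p = chi_squared_2x2(table)
            proportions[name] = {
                "counts": {ga: counts[ga], gb: counts[gb]},
                "chi2": stat, "df": dof, "p": p}
        except ValidationError as e:
            proportions[name] = {"counts": {ga: counts[ga], gb: counts[gb]},
                                 "skipped": str(e)}
            log.append(f"chi-squared {name} skipped: {e}")

    # --- 5. pooled significant-unit PSTHs with bands and smoothing
    pooled = {}
    for g in groups:
        if not pooled_pairs[g]:
            log.append(f"group {g}: no significant units to pool")
            continue
        pp, pb = pool_units(
            pooled_pairs[g], window=cfg.psth_window, bin_width=cfg.bin_width,
            delta=cfg.jitter_window, n_surrogates=cfg.n_surrogates,
            alpha=0.05, trigger=f"pooled_{g}", rng=rng)
        pooled[g] = pd.DataFrame({
            "lag_s": pp.centers, "count": pp.counts, "rate_hz": pp.rate,
            "smoothed_rate_hz": smooth_psth(pp, cfg.pooled_smooth_tau),
            "upper_band": pb.upper, "lower_band": pb.lower})

    # --- 6. AUC comparisons on significant units
    auc_tests: Dict[str, Optional[TwoGroupResult]] = {}
    sig = units[units.significant]
    for name, col in (("auc_cd", "auc_cd"), ("auc_tail", "auc_tail")):
        try:
            auc_tests[name] = mann_whitney(
                sig.loc[sig.group == ga, col].dropna(),
                sig.loc[sig.group == gb, col].dropna(),
                cfg.outlier_sd, measure=name)
        except ValidationError as e:
            auc_tests[name] = None
            log.append(f"AUC test {name} skipped: {e}")

    log_stage("compare_apamin_pipeline", cfg,
              n_sessions=len(sessions), n_units=len(units),
              n_significant=int(units.significant.sum()))
    return GroupReport(
        groups=groups, behavior=behavior, behavior_tests=behavior_tests,
        unit_table=units, rate_test=rate_test, proportions=proportions,
        normalized_mean=normalized_mean, pooled=pooled,
        auc_tests=auc_tests, log=log)


def write_report(report: GroupReport, outdir) -> List[str]:
    """Write a GroupReport as CSV tables plus a plain-text run log."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(name)

    save(report.behavior, "behavior.csv")
    save(report.unit_table, "units.csv")
    for g, df in report.normalized_mean.items():
        save(df, f"normalized_mean_{g}.csv")
    for g, df in report.pooled.items():
        save(df, f"pooled_{g}.csv")

    def tg(r: Optional[TwoGroupResult]) -> Optional[dict]:
        if r is None:
            return None
        return {"measure": r.measure, "n": list(r.n), "U": r.u, "Z": r.z,
                "p": r.p, "medians": list(r.medians),
                "excluded": [list(e) for e in r.excluded]}

    summary = {
        "groups": list(report.groups),
        "behavior_tests": {k: tg(v) for k, v in report.behavior_tests.items()},
        "as_rate_test": tg(report.rate_test),
        "proportions": report.proportions,
        "auc_tests": {k: tg(v) for k, v in report.auc_tests.items()},
        "log": report.log,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    written.append("summary.json")
    (out / "run.log").write_text("\n".join(report.log) + "\n")
    written.append("run.log")
    return written
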