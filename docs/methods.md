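# Methods

This note documents the models, procedures and numerical choices behind
`precereb`, in the order the pipeline runs.

## EMG conditioning and state scoring

EMG amplitude is treated as arbitrary units throughout; no absolute scale is
ever interpreted. The raw trace is full-wave rectified and smoothed with a
causal first-order exponential filter, `y[n] = a|x[n]| + (1-a)y[n-1]`,
`a = 1 - exp(-dt/τ)`, τ = 1 ms by default (a trailing boxcar of width τ is
available as an alternative). The filter is causal, so every step and
transient is detected at most one filtered sample late.

The wake/sleep threshold is the arithmetic midpoint between the mean
amplitude of *n* = 5 representative 1-s high-tone segments and *n* = 5
atonia segments. Historically this selection was manual; the automatic
selector ranks non-overlapping 1-s windows by their **median** amplitude and
takes the top/bottom five. The median is used for ranking (class means are
still computed from all samples of the selected windows) because a brief
twitch transient occupies only a few percent of a window and barely moves
its median, whereas it can drag a window's mean into the high-tone range.
A `manual_segments` override reproduces any manual choice exactly.

Supra-threshold runs ≥ 1 s are AW; sub-threshold runs ≥ 1 s are sleep.
The threshold comparison is first debounced with a centered 1-s boolean
majority (binary median) filter: single-sample noise dips during wake and
60-ms twitch bumps that cross the wake threshold both vanish, while a clean
tone step keeps its boundary to within one sample. Without this step,
noisy wake tone fragments into sub-1-s runs and entire wake bouts can be
absorbed into the neighboring sleep run by the minimum-bout merge. Any
runs still shorter than the 1-s minimum after debouncing are merged into
the preceding qualifying state (leading short runs join the first
qualifying run) — the minimum-bout rule is applied at segmentation time,
which is one of several defensible readings of a 1-s bout criterion; the
merge direction is a deliberate, logged choice. Each sleep run is split at its first detected twitch (across
all muscles) into BQ before and AS after; twitch-free sleep runs remain BQ.
This operationalizes "BQ is low tone interposed between AW and AS" as a
first-twitch boundary, which also makes the boundary recoverable exactly on
synthetic data.

Twitches are first upward crossings of *k* × (mean rectified-smoothed
amplitude during sub-threshold epochs), *k* = 3, restricted to sleep
intervals, separated by a per-muscle refractory period (default 200 ms; the
source analyses state no minimum separation). The onset is the crossing
time; whether amplitude is measured on the rectified-smoothed or raw trace
is not fixed by the original description, and the rectified-smoothed trace
is used. Wake-movement onsets are the first supra-threshold crossing of
each AW bout; additional within-bout re-crossings are available by config.

## State-dependence classification

Per-bout firing rates use half-open bout intervals. Bouts whose rate
deviates from their state's mean by more than 3 sample SDs are excluded
once (never iterated); at small bout counts this is deliberately a weak
filter — with five bouts at rates {1,1,1,1,100} Hz the extreme bout is
*retained* (mean 20.8, SD 44.3). Pairwise Wilcoxon matched-pairs
signed-rank tests (exact p where zeros/ties permit, normal approximation
otherwise) feed a decision table: AS-on requires AS significantly above
both AW and BQ (significance of AW vs BQ is *not* required); AW-on is
symmetric; AS+AW-on requires AS ≈ AW with both above BQ; anything else is
state-independent. Bouts are paired by sleep–wake cycle index (i-th AS
bout with i-th AW bout, truncated to the shorter list); the original
pairing is unstated, and an unpaired Mann–Whitney fallback is provided.
Alpha defaults to 0.05 per comparison, uncorrected (a Bonferroni flag
exists); units with fewer than five usable pairs are flagged
`indeterminate` rather than guessed.

## Perievent histograms and the jitter test

PSTHs accumulate spike-minus-event lags into half-open bins over a 1-s
window centered on the trigger; 0 is always a bin edge, so the ±10 ms
window comprises exactly the bins covering [−10, 0) and [0, +10) ms at 5-
or 10-ms widths. Events whose window crosses a session edge still
contribute (truncation is counted and logged). Empty event trains are an
error, not a zero histogram.

Interval jitter partitions the session into contiguous Δ = 500 ms cells and
redraws each event uniformly within its own cell, independently per
surrogate (S = 1000), preserving the per-cell event count exactly —
coarse rate structure survives, sub-Δ timing is destroyed.

Simultaneous bands are calibrated with a studentized-maximum statistic:
with per-bin surrogate mean μ_b and SD σ_b, each surrogate is summarized by
D_s = max_b |X_sb − μ_b| / σ_b, the critical value q is the
⌈(1−α)(S+1)⌉-th smallest D_s, and the bands are μ_b ± q σ_b. Under the
null the observed train is one more draw from the cell-uniform law, so its
D is exchangeable with the surrogates' and the probability that *any* bin
breaches either band is ≤ α jointly. A per-bin order-statistic
("pointwise quantile") construction was evaluated and rejected: with ~100
bins, two band sides and S = 1000, even bands at the pointwise surrogate
extremes are breached by a fresh null draw ~10–20% of the time, so no
pointwise rank can reach α = 0.01 at this problem size. The studentized-max
band's empirical family-wise error at the default settings is measured by
the acceptance suite (≤ 9/500 replicates). Bands can be restricted to a
declared analysis span; by default the full window is tested.

Classification: a latency window (premotor < −10 ms, CD ± 10 ms,
reafferent > +10 ms) is significant iff ≥ 1 of its bins exceeds the upper
band (no minimum bin count); below-band bins are flagged separately as
suppression. The *primary* window is the one containing the largest
above-band excess. When several muscles yield significant responses, the
muscle with the highest PSTH peak rate is kept (ties: total in-window
count, then the fixed order nuchal → forelimb → hindlimb, logged). Pooling
sums per-unit counts and per-unit surrogate histograms — each unit's own
events are jittered independently; jittering a concatenated event list
would ignore unit boundaries and was not used. α is 0.01 for twitch
analyses of IO/LRN units and 0.05 for midbrain and pooled group analyses,
carried in config.

Normalized averages divide each unit's rate by its peak (zero-peak units
are excluded and logged) before the across-unit mean ± SEM. Pooled
histograms are smoothed with a symmetric exponential kernel
(exp(−|t|/τ), τ = 10 ms, unit mass on the bin grid; a causal variant
exists). AUC sums per-event-normalized counts (counts / n_events) over a
window aligned to bin edges, so groups with different twitch counts are
comparable; a raw-count mode exists because the original description is
ambiguous on normalization. Bands are computed on counts; on rates they
would differ only by the constant factor 1/(n_events · bin width).

## Two-group battery

χ² tests on unit proportions are Pearson on the 2×2 table *without*
continuity correction — the convention is forced by the printed anchor
statistics (5/21 vs 11/18 gives 5.57; Yates would give 4.14). Rank tests
are two-sided Mann–Whitney U with a tie-corrected normal Z; per-group
values beyond 3 sample SDs are excluded once and logged. The cohort
pipeline runs, in order: per-pup AS time and twitches/min of AS; per-unit
AS firing rate; per-unit PSTHs (10-ms bins) with peak-normalized group
averages; per-unit jitter significance and the two proportion tests
(significant units; sharp ±10 ms peaks); pooled significant-unit PSTHs per
group (α = 0.05, τ = 10 ms smoothing); and per-unit AUC in the ±10 ms and
20–200 ms windows. Steps that a degenerate cohort cannot support (single
units, empty margins) are skipped with a logged reason rather than forced.

## Synthetic generator

The generator encodes the qualitative structure the analysis assumes, not a
biophysical model. States alternate AW → BQ → AS with exponential bout
durations (means 30/15/60 s; exponential is the simplest memoryless choice,
as no bout-length model is prescribed) floored at 2 s. Twitch trains are
per-muscle Poisson processes confined to AS (defaults 0.25/0.15/0.08
events/s for nuchal/forelimb/hindlimb — plausible for a week-old rat but
*placeholders*, not reported measurements) with a 200-ms refractory; the
first twitch of each AS bout is pinned to the bout start so the scored
BQ/AS boundary is recoverable. EMG is generated directly on the rectified
scale: atonia level 1.0 (a.u.), wake level 10.0, Gaussian amplitude noise
(SD 0.2 / 2.0), and half-sine twitch transients of 60 ms whose peak is 8×
the atonia level — comfortably above the 3× detection criterion by
construction. The `noise_free` preset removes amplitude noise and uses
rectangular (one-sample-rise) transients, making state boundaries and
twitch onsets recoverable to within one sample; that is the preset under
which scoring exactness is asserted, while precision/recall claims use the
noisy defaults.

Units are inhomogeneous Poisson processes built by superposing independent
Poisson components: per-state homogeneous background (defaults 5/1.5/1 Hz
in AS/AW/BQ), Gaussian rate kernels locked to twitch onsets, and an
optional uniform plateau. Archetype kernels (center, SD, gain): `cd`
(0 ms, 4 ms, 50 Hz), `motor` (−30 ms, 20 ms, 15 Hz), `sensory` (+30 ms,
12 ms, 20 Hz), `motor+reafferent` (both), `apamin_cd` = `cd` plus a 4-Hz
plateau over +20…+200 ms, `null` (none) — chosen once to reproduce the
qualitative histogram shapes of the response classes (sharp CD peak, broad
twitch-preceding bump, 10–50 ms reafferent bump, prolonged tail under SK
blockade). Superposition keeps every component rate non-negative, so no
clipping or thinning is needed and per-event kernel masses are exact.

What the generator does *not* emulate: real EMG spectra and
movement artifacts, spike-sorting errors and refractory violations,
unit–unit correlations, within-state rate drift, and wake movements with
structured kinematics. Passing tests therefore demonstrate that the
*analysis* recovers the structure it targets when that structure is
present, not that real recordings satisfy the generator's assumptions.

## Problem sizes and determinism

Every stochastic path flows through one `numpy.random.Generator`; a fixed
seed reproduces sessions, surrogates and reports byte-for-byte. The test
and acceptance suites use desk-scale problem sizes chosen to keep the full
run in minutes on one core: band calibration uses 500 null replicates of
600-s sessions (events 0.5/s, spikes 5/s); latency-window recovery uses
100 seeded runs per archetype with ~2100 triggers each; the cohort
experiment uses 50 replicates of 10 + 8 single-muscle pups (420-s sessions,
~2 units each). The cohort sessions use one EMG channel because the
group-level contrast (tail AUC) does not depend on cross-muscle selection;
multi-muscle selection is exercised by its own tests.

## Known limitations

- The studentized-max band assumes exchangeability of the observed train
  with its surrogates, which holds for event processes without sub-Δ rate
  structure; strong within-cell rate gradients would inflate breaches.
- The automatic threshold-segment selector biases the high-tone mean
  slightly upward (it takes the top-ranked windows); the effect on the
  midpoint is ≲ 5% at default noise and vanishes with manual segments.
- Cycle-index pairing of bouts is a heuristic; sessions with very uneven
  bout counts lose pairs to truncation.
- The 3 SD exclusion rules (bouts, group outliers) are intentionally weak
  at small n; they are reported, not optimized.
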