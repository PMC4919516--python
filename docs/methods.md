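# Methods

This note specifies the statistical procedures `aobt` implements, the
defaults it ships with and why, the behaviour of the synthetic-data
generator, and the places where the design was genuinely open.

## Data model

A *session* is one recording: a set of sorted single-unit spike trains
(strictly increasing spike times in seconds from session start), a trial
table of stimulus events (id, onset, offset, repeat index), and a stimulus
panel with exactly one designated solvent-control stimulus (Ringer's
solution in the emulated preparation). Stimulus epochs are 3–5 s
(validated, bounds configurable); every stimulus is expected to have at
least three repeats, enforced at analysis time per cell × stimulus rather
than at load time so that partial sessions remain inspectable. On disk a
session is a directory of plain-text files (`spikes.csv`, `cells.csv`,
`trials.csv`, `panel.json`, `meta.json`); floats are written with `%.17g`
and parsed in round-trip mode, so write∘read is the identity and output is
byte-stable.

## Response quantification

All windows are relative to stimulus onset, in seconds:

| window | extent | purpose |
|---|---|---|
| response | [+1, +5] (4 s) | rate scored as the response; the 1 s delay accommodates the dead volume of the stimulus line |
| baseline | [−5, 0] (5 s) | pre-stimulus reference rate |
| PSTH | [−5, +15], 1 s bins | display and rate-profile checks |

The per-trial response is ΔR = (count in response window)/4 − (count in
baseline window)/5, in Hz. Intervals are half-open `[t0, t1)`. Events whose
windows extend outside the recorded span are dropped (logged) and repeat
counts re-checked.

The baseline length is a design choice: the emulated protocol states only
"before stimulus delivery", and 5 s was adopted for symmetry with the
displayed PSTH pre-window. It is a field of `AnalysisWindows`.

## Significance calling and cell inclusion

A cell×stimulus pair is called *significant* iff

1. a two-sample Student's t-test (equal-variance; Welch available via
   `equal_var=False`) of the per-trial ΔR values against the same cell's
   control-stimulus ΔR values gives p < 0.05, **and**
2. the mean rate increase exceeds 1 Hz.

Two readings of the rate rule are implemented: on the mean ΔR (default,
`criterion="delta_r"`, the literal reading of "rate increase") or on the
mean absolute rate in the response window (`criterion="window_rate"`).
Pairs with fewer than three trials in either group are *unanalyzable*
(`None`), not non-responders. No multiple-testing correction is applied by
default — the emulated analysis uses a fixed per-comparison threshold — but
a Holm correction across stimuli is available (`holm=True`).

The control stimulus cannot be tested against itself, so "responded to the
control" is operationalized as a one-sample t-test of the control ΔR values
against zero plus the same 1 Hz rule. A cell is *included* iff it has at
least one significant non-control stimulus, a non-significant control, and
at least three complete trials for every tested stimulus; exclusion reasons
are recorded (`no response`, `control responsive`, `insufficient trials`).

Per-cell tuning curves are the mean-ΔR vectors normalized by the maximum
*absolute* mean ΔR over non-control stimuli, so the strongest response maps
to ±1 and inhibitory responses cannot exceed magnitude one. The absolute
value is a convention choice (heat maps span negative values and the
normalization convention is otherwise unstated); the control column is
excluded from the divisor.

For imaging series, the fluorescence response is the mean of the 3 stacks
after stimulus onset divided by the mean of the 3 stacks before it
(`compute_dff`), exactly as defined for GCaMP stack series.

## Population summaries

Within a comparison of two stimulus sets A and B, an included cell is
*exclusive-A* if it responds to ≥1 member of A and none of B (regardless of
the rest of the panel), *both* if it responds to members of both, and
*other* if it responds to neither (it responds to something else in the
battery — all included cells respond to something). Percentages are
reported to one decimal, rounded half away from zero, matching the printed
style of population figures. Venn-region counts are computed over the pool
of cells responding to at least one of the listed stimuli. The pairwise
co-response matrix entry (r, c) is 100·|responders to r and c|/|responders
to r|; rows with zero responders are undefined (NaN), never 0.

## Consensus mean-shift clustering

The clustering operates on the matrix of normalized tuning curves
(included cells × non-control stimuli):

1. **Base runs.** `n_runs` (default 1000, ≥100 enforced; hundreds to
   thousands are typical) independent k-means clusterings with random
   initialization and k drawn uniformly from `k_range` (default 2–12,
   capped at n−1). Random-k, random-init k-means is a standard way to build
   a non-deterministic base ensemble.
2. **Similarity.** `S[i, j]` = fraction of runs assigning cells i and j to
   the same cluster. S is symmetric with unit diagonal.
3. **Mean shift.** Flat-kernel mean shift on the *rows* of S (each cell
   described by its co-assignment profile). Labels are relabelled
   contiguously in order of first appearance. Deterministic given `seed`.

**Bandwidth.** The default bandwidth is Otsu's threshold applied to the
pairwise Euclidean distances between rows of S (`distance-gap`). The
rationale: for data with block structure, the row-distance distribution is
bimodal — small within-block, large between-block — and a flat-kernel mean
shift separates the blocks exactly when the bandwidth falls in the gap,
which is where Otsu's threshold lands by construction. The common
nearest-neighbour quantile heuristic is also available
(`bandwidth_method="quantile"`, default quantile 0.3), but it fails
whenever a cluster's population share is smaller than the quantile (the
k-th-neighbour average then crosses group boundaries and the estimate
swallows the separation), which planted-archetype benchmarks in the test
suite demonstrate. An explicit `bandwidth` overrides both.

The similarity matrix can be embedded by nonmetric MDS (dissimilarity
= 1 − S, 3 components by default, seeded; the stress value is returned).
Degenerate inputs (single cell, all-equal dissimilarities) produce a
zero-spread embedding with a warning.

We make no claim of reproducing any particular recorded population's
cluster count; the benchmark is recovery of planted archetypes (median
adjusted Rand ≥ 0.9 over 20 simulated 60-cell, 4-archetype sessions, which
the acceptance suite verifies — in practice it is 1.0).

## d′ and the population shuffle test

For one cell and two stimuli, d′ = |ΔR̄₁ − ΔR̄₂| / √((σ₁² + σ₂²)/2) with
sample variances (n−1). The absolute value makes d′ a non-negative
separability index. Both variances zero with equal means gives 0; with
unequal means d′ is undefined and raises.

The shuffle test builds `n_model` (default 100,000; the calibration
benchmarks use 10,000) model populations of the same size as the observed
one. Two resampling units are implemented, because the source description
("model cells are randomly assigned one of the normalized ΔR values from
each of the compared stimuli") does not yield a per-model-cell variance on
its own:

- `unit="trials"` (default): each model cell pairs the complete stimulus-1
  trial set of one uniformly drawn cell with the stimulus-2 trial set of an
  independently drawn cell (with replacement). This preserves each donor's
  across-trial variance and is the only reading under which per-model-cell
  d′ is directly computable.
- `unit="values"`: individual trial values are drawn with replacement from
  the stimulus-wise pooled set across cells — the single-value reading,
  with the variance then coming from the resampled set itself.

Each model population's d′ values are compared with the observed ones by a
two-group tie-corrected Kruskal–Wallis test; the reported fraction counts
model populations with p < 0.05 **and** model median below the observed
median ("statistically lower"). The Kruskal–Wallis computation is
vectorised across model populations (rank-based H statistic, χ² with 1 df);
the test suite verifies exact agreement with `scipy.stats.kruskal`,
including under ties.

d′ can be computed on normalized (default, matching the tuning analysis) or
raw ΔR. The calibration benchmarks use raw ΔR: per-cell normalization
divides both stimuli by a common per-cell constant, which preserves each
observed cell's d′ but makes cross-cell re-pairing mix scales, so only the
raw form is exactly exchangeable under the null.

## Synthetic-data generator

Spike trains are piecewise-constant-rate Poisson processes: rate λ0 outside
response windows and λ0 + Δ·g inside the 4 s response window of each event,
where Δ is the planted per-cell × per-stimulus effect and g is a per-trial
multiplicative log-normal jitter with unit mean (default s.d. 0.2). Rates
that would go negative are clipped to zero and logged. Defaults emulate the
recorded preparation: baseline rates drawn uniformly from 0.5–3 Hz, 5
trials per stimulus (≥3 enforced), 4 s stimulus epochs, 20 s between
onsets, block-randomized interleaved delivery (each stimulus exactly once
per block), and a control stimulus that never carries a planted effect.
The true across-trial ΔR variance of real recordings is unreported; the
jitter s.d. is the free parameter standing in for it and is exposed in the
config. Ground truth (the Δ map) is stored in session metadata, and
`ground_truth_tuning` thresholds it at the 1 Hz detection floor to give
every analysis stage an exact oracle.

What the generator does *not* emulate — temporal response shape (onset
transients, adaptation), bursting/refractoriness, slow drift, correlated
noise across cells, inhibitory responses, and control-stimulus
responders — bounds what passing tests show: they validate the statistical
machinery (windows, calling rule, clustering, d′/shuffle) under the stated
noise model, not robustness to every property of real recordings. The
analysis layer itself handles inhibitory ΔR and control responders even
though the generator never produces them.

## Benchmark problem sizes

The calibration and recovery benchmarks (test suite and
`scripts/acceptance.py`) use: 200-cell sessions for the caller
false-positive rate (600 null calls) and power; 200-cell populations with
10,000 model populations for shuffle-test calibration and the selectivity
sweep (0/2/5/10 Hz); and 20 × 60-cell 4-archetype sessions (Δ = 8 Hz, 300
base runs) for cluster recovery. These sizes give binomial/Monte-Carlo
error small relative to every threshold tested while keeping a full run in
tens of seconds.

## Known limitations

- The 1 Hz rule's two readings (ΔR vs absolute window rate) remain both
  available because the source phrasing is ambiguous; results can differ
  for cells with high spontaneous rates.
- The shuffle test's `values` mode is one constructive interpretation of
  single-value shuffling; no ground-truth reference exists for it.
- Mean-shift cluster *count* depends on the bandwidth; the distance-gap
  default is designed for block-structured similarity matrices and may
  over-merge when cluster separation is weak and the distance distribution
  unimodal.
- The t-test is applied to per-trial ΔR against control ΔR (not to raw
  window rates); with very low rates and few trials its normality
  assumption is rough — the 1 Hz rule is what keeps the false-positive
  rate of the joint call well below the nominal 5%.
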