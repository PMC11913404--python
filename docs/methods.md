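# Methods

This note documents the models and procedures the package implements, the
parameter choices behind them, what the synthetic generator does and does
not emulate, and the numerical conventions that make results reproducible
bit for bit.

## Behavioral segmentation

A session is an ordered stream of rewarded nose-pokes (rNP), non-rewarded
nose-pokes (nrNP), magazine entries (ME) and exits (MX) on a 10 ms grid.
nrNP events are retained in the stream but excluded before pairing, since
they do not occur in well-trained sessions and are not part of the analyzed
action sequence. Every adjacent pair of retained events whose types match
one of the five named transitions (rNP-ME, ME-MX, MX-rNP, rNP-rNP, MX-ME)
becomes a block; other pairs are counted in a diagnostics report and
skipped. Simultaneous timestamps keep file order (stable sort), and a
zero-duration pair is dropped with a warning because block velocity
BV = 1/(T_f − T_b) would be undefined.

Cycles are delimited by successive rNP-ME blocks. Two conventions are
defensible for the duration T(C): reward receipt to reward receipt
(ME completion → ME completion) or poke to poke. The package defaults to
the ME anchor — the routine is framed around reward-to-reward repetition —
and exposes `cycle_anchor="rNP"` for the alternative. A cycle's member
blocks are all blocks strictly between the delimiters plus the terminal
rNP-ME block, so a perfect routine cycle has exactly three member blocks
(ME-MX, MX-rNP, rNP-ME). Behavioral curves (choice proportions after rNP
and MX, blocks per cycle) use 10 equal-width session-elapsed bins by
default; the bin count is a parameter because no canonical width exists.

## Routine index

RI(C) = f(L / T(C)) with L = 60 s per minute, so the untransformed index is
the number of cycles per minute at the current pace. The transformation f
normalizes the index's distribution; candidates are linear, logarithmic,
reciprocal and square root. Each candidate is scored per subject by a
one-sample Kolmogorov–Smirnov distance computed Lilliefors-style: the
sample is standardized by its own mean and SD and compared against the
standard normal. The estimated-parameter reference is the right choice here
because the index's location and scale are arbitrary; the statistic is used
only as a relative normality score across transformations, never for
inference, so no null-distribution correction is needed. Group comparison
of each alternative against the square root uses paired t statistics with a
Dunnett-style adjustment implemented as sign-flip resampling of the
max-|t| over the three contrasts (10,000 resamples by default); plain
paired-t p-values are reported alongside. The selected transformation is
the arg-min of the group-mean K–S statistic.

## ΔF/F and signal quality

The baseline model is a sliding minimum of a sliding mean: F_AVG(t) is the
mean of F_RAW over the trailing 0.75 s window ending at t (23 frames at
30 fps, round-half-up), and F_BASELINE(t) is the minimum of F_AVG over the
3 s window ending at t inclusive (91 frames). Including the current frame
guarantees F_BASELINE ≤ F_AVG everywhere the window is full; leading frames
use whatever portion of each window exists (a `drop_partial` flag discards
them instead). ΔF/F = (F_RAW − F_BASELINE)/F_BASELINE. A centered averaging
window is available behind a flag, but the trailing (causal) form is the
default, consistent with a baseline defined over the preceding seconds.
One consequence worth knowing: on a slowly decaying trace the baseline sits
marginally above the current frame, so ΔF/F carries a small negative bias
bounded by the averaging-window length times the decay rate (≈ 2×10⁻⁴ for a
2000 s bleach constant).

Smoothing is an exponentially weighted moving window with time constant
τ = 0.2 s truncated at support ω = 1 s. The exact kernel equation of the
original acquisition software is not published, so the package reads the
two parameters as a causal truncated exponential, renormalized over the
available support (a symmetric variant is flag-selectable). A constant
input is a fixed point of the operator. Z-scoring uses the whole-session
mean and population SD of the smoothed ΔF/F.

Signal quality is an evoked-response SNR: the variance over time of the
across-trial mean trace divided by the mean within-trial residual variance.
This is a declared surrogate — no canonical formula exists for this
quantity — and it is always reported against a null built by independently
permuting timepoints within every trial (a circular-shift variant preserves
autocorrelation). Identical trials give an infinite SNR sentinel. All
permutation p-values in the package use the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n) and therefore never equal zero.

## Alignment

Event timestamps on the 10 ms grid map to the nearest 30 fps frame with
exact half-frame ties rounding down. Head-fixed alignment anchors rows at
the block's initial event (time axis 0…+w), tail-fixed at its terminal
event (−w…0); the default window w is half the mean block duration of the
type, which keeps adjacent alignments from overlapping. Window endpoints
are inclusive on the frame grid (a 1.5 s window spans 46 samples at
30 fps), and interval AUCs sum closed intervals of columns, so AUC values
are reproducible exactly. Blocks shorter than the window are retained —
their windows extend into adjacent behavior, matching the fixed-window
design — and rows whose window leaves the recording are dropped and logged.

## Regression and cluster inference

Per subject and block type, Y(:,t) is regressed by OLS on
[1, SE, BV, RI] independently at each timepoint (at least 8 blocks
required; pairwise covariate correlations above 0.9999 raise an error
naming the pair). RI is assigned to a block through its enclosing cycle;
blocks outside any cycle are excluded. Stacked across subjects, B_RI gets a
one-sample cluster-based permutation test: two-sided one-sample t at each
timepoint, cluster-forming α = 0.05 on the t critical value, cluster mass
Σ|t| over contiguous supra-threshold runs, and a max-mass null from random
sign flips of whole subject rows (10⁴ permutations by default). These three
choices — forming rule, mass statistic, sign-flip scheme — are the standard
construction for one-sample time-series inference and are all configurable.
The permutation pass is vectorized by the identity that sign flips leave
each column's sum of squares unchanged, so all permuted t statistics come
from one matrix product.

Post-hoc AUC regressions fit the same design to each subject's summed
activity over an identified interval; the N_S per-subject weights for each
covariate get a two-sided one-sample Wilcoxon signed-rank test, exact for
N_S ≤ 25 and normal-approximated with continuity correction above. Eleven
same-sign weights give the exact floor p = 2·(1/2)¹¹ ≈ 9.77×10⁻⁴. The
pre/post comparison averages activity in [−0.5, 0] and [0, 0.5] s around
rewarded magazine entry per block, then per subject, and applies a paired
Wilcoxon across subjects; identical windows return p = 1.

The shuffle-R² validation regresses each subject's behavioral curve
(choice proportions, blocks per cycle) on the same subject's routine-index
curve over shared occupied session-elapsed bins (R² = squared Pearson
correlation; flat curves are assigned R² = 0, and subjects with fewer than
3 shared bins are dropped). The null re-pairs behavior curves with routine
curves from other subjects; derangements (no self-pairing) are the default
because self-pairs would leak signal into the null, and a full-permutation
scheme is available.

## Mixed-model comparison

Four nested linear mixed models are fitted by maximum likelihood (not REML,
because the likelihood-ratio tests compare fixed-effect structures) with a
random subject intercept: RI only, RI+SE, RI+BV, and the full RI+SE+BV
model, each term entering as covariate + time + covariate:time with time a
single continuous regressor (the column-bin center in seconds). With this
parameterization the models carry 6/8/8/10 parameters (fixed effects plus
the random-intercept and residual variances), and each restricted model's
LR statistic 2·(LL_full − LL_r) is referred to χ² with the parameter-count
difference. The long table reduces each aligned matrix to a configurable
number of time bins (default 10) by averaging columns within a bin. A
random RI slope is a documented extension point; the default keeps the
random structure minimal so the LRT compares mean structures.

## Synthetic cohorts

The generator defines the study conditions under which the pipeline is
validated: 11 subjects, 3600 s sessions, 30 fps traces, 10 ms event grid.
Cycle durations follow T_k = T_min + (T_0 − T_min)·e^{−k/κ}·J_k with
T_0 = 150 s, T_min = 45 s, κ = 15 cycles and mean-one lognormal jitter
σ = 0.6 — about 40 reward cycles per hour with the wide trial-to-trial
scatter real operant behavior shows; the scatter also keeps the routine
index identifiable against session elapsed (r(RI, SE) ≈ 0.83 rather than
≈ 0.95 under small jitter). Non-routine blocks are inserted with
probabilities decaying logistically in session elapsed (repeated pokes
p₀ = 0.5, magazine re-entries p₀ = 0.45, midpoint 0.4, gain 4), which
reproduces the qualitative choice-proportion and blocks-per-cycle trends of
routine acquisition. Re-entries occur a median 6 s after the exit — the
animal wanders before returning — which also keeps the 3 s baseline
lookback of re-entry windows clear of the previous entry's transient; with
shorter gaps the sliding-minimum baseline becomes routine-correlated and
attenuates fitted effects, a coupling worth remembering with real data too.

Traces are bleaching drift e^{−t/3000 s} times
(1 + transients + effects + noise), with double-exponential transients
(rise 0.2 s, decay 1.5 s — a GCaMP6s-like shape, no claim of biophysical
fidelity) at every event (amplitudes 0.3/0.5/0.2 of baseline for
rNP/ME/MX, per-event lognormal jitter σ = 0.1), white multiplicative noise
SD 0.1, and per-subject lognormal random gains (σ = 0.2 amplitude, 0.1
baseline). Covariate effects multiply fluorescence in a window anchored at
a named event, linear in the covariate so ΔF/F-level effects are
approximately linear in it; the defaults inject routine-index effects
around every magazine entry in −0.5–0 s (amplitude 0.5 per unit RI) and
0–1.1 s (0.8), scaled by the RI of the cycle containing the entry. Under
these conditions the pipeline recovers the injected post-window β_RI to
within ~10–15% on the ΔF/F channel and detects both clusters in essentially
every cohort, while zero-effect cohorts produce significant clusters at
about the nominal 5% rate (measured 5/150 cohorts).

What the generator does **not** emulate: inter-day learning, isosbestic or
hemodynamic artifacts, correlated (pink) noise, movement artifacts,
astrocyte-specific kinetics beyond the kernel shape, and any circuit
mechanism. Passing tests therefore demonstrate the statistical machinery —
calibration, power, localization, recoverability — under a faithful data
*geometry*, not biological realism of the signals themselves. One honest
consequence of simulated duration distributions: the K–S transformation
selection frequently prefers the linear transform on generator cohorts,
and the square-root selection consistency is instead verified on cohorts
constructed so that √(L/T) is exactly normal.

## Numerical conventions and problem sizes

Window lengths convert to frame counts by round-half-up; all intervals are
closed on the frame grid. Every stochastic procedure takes an explicit
seed, reports it, and derives child seeds from numpy `SeedSequence`
spawning, so cohort simulation is bit-reproducible per subject. The test
suite and the acceptance script size their simulations for a single CPU:
1,000 random streams (300 in the script) for the segmentation oracle,
100 traces × 3,000 frames (30 in the script) for the ΔF/F oracle, 100 cohorts of 21 × 30 cycles for transformation
selection, 1,000 (tests) / 400 (script) null weight matrices for cluster
type-I error, 100 runs for power/localization, one effect cohort plus 40
zero-effect cohorts end to end, 100 (tests) / 50 (script) mixed-model
simulations, and 200/100 SNR simulations. Rate thresholds in the tests are
binomial tolerances of the targeted rates at those sizes (e.g. ≥ 36 of 40
clean null cohorts for a 95% clean rate).

## Limitations

- The cluster-forming threshold, mass statistic and permutation scheme are
  principled defaults, not uniquely determined by the problem; conclusions
  near threshold can shift under alternatives (all are config keys).
- The sliding-minimum baseline couples to event density; effects estimated
  inside ~3 s of dense event sequences are attenuated (quantified above for
  re-entries).
- MixedLM occasionally fails to converge on degenerate inputs; the
  comparison table marks such models rather than guessing.
- The SNR formula is a surrogate definition; only its shuffle-null
  calibration, not its absolute scale, should be interpreted.
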