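# routineform

Tools for quantifying **routine formation** in operant reward-seeking and
relating it to fiber-photometry Ca²⁺ dynamics.

When a food-restricted mouse works a fixed-ratio-1 schedule — one rewarded
nose-poke (rNP) delivers one reward in a magazine the animal then enters
(ME) and exits (MX) — its initially variable behavior condenses into a
stereotyped loop rNP → ME → MX → rNP. This package implements the full
analysis chain for such sessions:

1. **events** — parse timestamped event logs (10 ms grid) and segment them
   into *blocks* (transitions between adjacent events; five types, of which
   rNP-ME, ME-MX and MX-rNP are *cycle blocks*) and *cycles* (the stretch
   between successive rewarded magazine entries).
2. **routine** — the per-cycle *routine index* RI(C) = f(L / T(C)), with
   L = 60 s/min, T(C) the cycle duration and f a normalizing transformation
   (√ by default) selected by a Kolmogorov–Smirnov normality score across
   subjects with Dunnett-style paired comparisons.
3. **photometry** — ΔF/F from a sliding minimum-of-mean baseline
   (0.75 s trailing mean, 3 s trailing minimum), causal exponential
   smoothing (τ = 0.2 s, support ω = 1 s), whole-session z-scoring, and an
   evoked-response SNR with a timepoint-shuffle null.
4. **align** — head-/tail-fixed peri-event matrices Y ∈ ℝ^{K×T} (K blocks of
   one type × T frames at 30 fps; default window = half the mean block
   duration) and closed-interval AUCs.
5. **stats** — per-timepoint OLS
   `Y(:,t) = β₀(t) + β_SE(t)·SE + β_BV(t)·BV + β_RI(t)·RI`
   (SE = session elapsed, BV = block velocity = 1/duration, RI = the cycle's
   routine index), cluster-based permutation inference on the stacked
   subject matrix B_RI ∈ ℝ^{N_S×T} (sign-flip null, Σ|t| cluster mass),
   AUC regressions with one-sample Wilcoxon signed-rank tests, pre/post
   magazine-entry comparisons, subject-shuffled R² validation of the routine
   index, and nested linear-mixed-model likelihood-ratio tests
   (`Y ~ RI×Time [+ SE×Time] [+ BV×Time] + (1|subject)`, ML).
6. **synthetic** — a cohort generator with known ground truth: cycle
   durations shortening as `T_k = T_min + (T_0 − T_min)e^{−k/κ}` with
   lognormal jitter, non-routine block insertions decaying over the session,
   and traces built from bleaching drift × (1 + GCaMP6s-like transients +
   covariate-scaled effects + noise).
7. **cli / pipeline** — `routineform simulate|segment|routine|dff|run …`
   orchestration with YAML configs and reproducible JSON/CSV bundles.

## Worked example

```python
import routineform as rf

cfg = rf.SimulationConfig(n_subjects=11, seed=42)   # routine-tracking cohort
cohort = rf.simulate_cohort(cfg)
params = rf.AnalysisParams(n_perm=1000, seed=42)
analysis = rf.analyze_cohort(cohort.streams, cohort.traces, params)
print(analysis.summary())
```

prints

```
Cohort analysis: 11 subjects (0 excluded)
  selected RI transformation: linear
  pre: significant RI cluster [-0.467, +0.000] s, mass=148.8, p=0.0010, sign=+1
  post: significant RI cluster [+0.100, +1.500] s, mass=424.7, p=0.0010, sign=+1
  pre/post magazine-entry Wilcoxon p = 0.0010
  shuffle-R2 (p_rnp_me): mean R2 = 0.315, p = 0.3656
  shuffle-R2 (p_mx_rnp): mean R2 = 0.380, p = 0.2757
  shuffle-R2 (blocks_per_cycle): mean R2 = 0.512, p = 0.2288
```

The generator injected positive routine-index effects on the Ca²⁺ signal in
two windows around rewarded magazine entry (−0.5–0 s and 0–1.1 s); the
cluster-based permutation test recovers both as significant positive β_RI
clusters (`pre` is the tail-fixed rNP-ME alignment ending at the entry,
`post` the head-fixed ME-MX alignment starting there). The pre/post Wilcoxon
detects the net activity change across the entry. The K–S transformation
selection reports which candidate best normalizes this cohort's routine
index; on simulated duration distributions that is not always the square
root. The model-comparison table
(`analysis.model_comparison["post"].table`) reports DF/AIC/BIC/LL and the
likelihood-ratio test of each restricted mixed model against the full
RI+SE+BV model.

The same analysis runs from the shell on written files:

```bash
routineform simulate --out cohort/ --n-subjects 11 --seed 42
routineform run --config pipeline.yaml
```

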