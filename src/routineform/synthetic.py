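"""Synthetic operant sessions with paired photometry and known ground truth.

A simulated subject completes reward cycles whose durations shorten over the
session (routine formation): the k-th cycle lasts
``T_k = T_min + (T_0 − T_min)·exp(−k/κ)`` times a lognormal jitter.
Non-routine blocks (repeated nose-pokes, magazine re-entries) are inserted
with probabilities that decay logistically in session elapsed, so choice
proportions and blocks-per-cycle reproduce the qualitative trends of routine
acquisition.  The paired fluorescence trace is a slow bleaching drift
multiplied by ``1 + transients + noise``: every action event elicits a
GCaMP6s-like double-exponential transient, and configurable effect terms add
activity in a window around a named event whose amplitude is linear in a
behavioral covariate (e.g. the routine index), with per-subject random gain.
All draws are reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .events import EventStream, write_events
from .photometry import PhotometryTrace, write_trace


@dataclass
class RoutineSchedule:
    """Cycle-duration model T_k = T_min + (T_0 − T_min)·exp(−k/κ)·jitter."""

    t0: float = 150.0       # initial cycle duration, s
    t_min: float = 45.0     # asymptotic routine duration, s
    kappa: float = 15.0     # learning rate, cycles
    sigma: float = 0.6      # lognormal jitter SD (log scale), mean-one jitter

    def __post_init__(self) -> None:
        if self.t_min <= 0 or self.t0 < self.t_min:
            raise ValueError("need 0 < t_min <= t0")

    def mean_duration(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return self.t_min + (self.t0 - self.t_min) * np.exp(-k / self.kappa)

    def draw(self, k: int, rng: np.random.Generator) -> float:
        # mean-one lognormal jitter, so mean_duration() is the expectation
        jitter = (float(np.exp(rng.normal(-0.5 * self.sigma ** 2, self.sigma)))
                  if self.sigma > 0 else 1.0)
        return self.t_min + (self.t0 - self.t_min) * np.exp(-k / self.kappa) * jitter


@dataclass
class NonRoutineRates:
    """Insertion probabilities of non-cycle blocks, decaying in SE."""

    p_extra_poke: float = 0.5   # rNP-rNP insertion probability at SE = 0
    p_reentry: float = 0.45     # MX-ME insertion probability at SE = 0
    gain: float = 4.0           # logistic decay steepness
    midpoint: float = 0.4       # SE at which the rate halves

    def _decay(self, p0: float, se: float) -> float:
        return p0 / (1.0 + np.exp(self.gain * (se - self.midpoint)))

    def extra_poke(self, se: float) -> float:
        return self._decay(self.p_extra_poke, se)

    def reentry(self, se: float) -> float:
        return self._decay(self.p_reentry, se)


@dataclass
class TransientKernel:
    """Double-exponential Ca²⁺ transient shape, peak-normalized to 1."""

    rise: float = 0.2   # s
    decay: float = 1.5  # s

    def evaluate(self, lags) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        g = np.where(lags >= 0,
                     (1.0 - np.exp(-np.maximum(lags, 0) / self.rise))
                     * np.exp(-np.maximum(lags, 0) / self.decay), 0.0)
        # peak of (1-e^(-t/r))e^(-t/d) at t* = r·ln(1 + d/r)
        t_star = self.rise * np.log(1.0 + self.decay / self.rise)
        peak = (1.0 - np.exp(-t_star / self.rise)) * np.exp(-t_star / self.decay)
        return g / peak

    @property
    def support(self) -> float:
        return 6.0 * self.decay


@dataclass
class EffectSpec:
    """Event-locked activity scaling linearly with a behavioral covariate.

    ``window`` is relative to the named event; a window starting at or after
    the event uses the covariate of the cycle *beginning* there, a window
    before it uses the cycle *ending* there (relevant for ``ri``).  The
    effect waveform is the transient kernel with its onset at the window
    start, truncated to the window.
    """

    covariate: str = "ri"          # "ri" or "se"
    event: str = "ME"
    window: tuple = (0.0, 1.1)     # s relative to the event
    amplitude: float = 0.5         # fluorescence fraction per unit covariate


@dataclass
class PhotometryParams:
    fs: float = 30.0
    f0: float = 100.0
    bleach_tau: float = 3000.0     # s
    noise_sd: float = 0.1          # multiplicative white noise SD
    event_amplitudes: dict = field(
        default_factory=lambda: {"rNP": 0.3, "ME": 0.5, "MX": 0.2})
    amp_jitter_sd: float = 0.1     # per-transient lognormal jitter
    kernel: TransientKernel = field(default_factory=TransientKernel)
    effects: list = field(default_factory=lambda: [
        EffectSpec(covariate="ri", event="ME", window=(-0.5, 0.0), amplitude=0.5),
        EffectSpec(covariate="ri", event="ME", window=(0.0, 1.1), amplitude=0.8),
    ])


@dataclass
class SubjectEffects:
    """Per-subject lognormal random-effect SDs (log scale)."""

    amp_sd: float = 0.2
    f0_sd: float = 0.1


@dataclass
class SimulationConfig:
    n_subjects: int = 11
    session_duration: float = 3600.0
    resolution: float = 0.01
    schedule: RoutineSchedule = field(default_factory=RoutineSchedule)
    rates: NonRoutineRates = field(default_factory=NonRoutineRates)
    photometry: PhotometryParams = field(default_factory=PhotometryParams)
    subject_effects: SubjectEffects = field(default_factory=SubjectEffects)
    ri_transform_L: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule.t_min < 10 * self.resolution:
            raise ValueError("t_min too small for the event-time resolution")
        if self.session_duration <= 0 or self.resolution <= 0:
            raise ValueError("durations must be positive")


@dataclass
class GroundTruth:
    """Everything injected into one synthetic session."""

    subject_index: int
    cycle_target_durations: list
    cycle_actual_durations: list
    me_times: list
    effects: list                   # serialized EffectSpec dicts
    effect_covariates: list         # per ME, per effect: covariate value or None
    amp_multiplier: float
    f0_multiplier: float
    noise_sd: float
    seed_entropy: list

    def to_dict(self) -> dict:
        return asdict(self)


def _subject_rng(cfg: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, subject_index])


def _lognormal(rng, median, sigma):
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _simulate_events(cfg: SimulationConfig, rng: np.random.Generator):
    """Generate one session's event list plus cycle bookkeeping."""
    res = cfg.resolution
    dur = cfg.session_duration

    def q(t, prev):
        t = round(t / res) * res
        if prev is not None and t <= prev:
            t = prev + res
        return round(t, 10)

    events: list[tuple[float, str]] = []
    prev = None

    def emit(t, kind):
        nonlocal prev
        t = q(t, prev)
        events.append((t, kind))
        prev = t
        return t

    # cycle_starts[j] = time of the ME opening cycle j; target[j] its planned length
    me_times: list[float] = []
    targets: list[float] = []

    t_np = rng.uniform(5.0, 20.0)
    lat = _lognormal(rng, 1.2, 0.3)
    if t_np + lat >= dur:
        raise ValueError("session too short for a single cycle")
    t_np = emit(t_np, "rNP")
    me = emit(t_np + lat, "ME")
    me_times.append(me)

    k = 0
    while True:
        target = cfg.schedule.draw(k, rng)
        targets.append(target)
        planned_next_me = me_times[-1] + target
        # magazine dwell then exit
        mx_t = me + _lognormal(rng, 2.5, 0.3)
        if mx_t >= dur:
            break
        mx = emit(mx_t, "MX")
        # possible magazine re-entry (MX-ME + ME-MX non-routine blocks)
        se = mx / dur
        if rng.uniform() < cfg.rates.reentry(se):
            # the animal wanders before re-entering; the gap also clears the
            # baseline lookback of the previous entry's transient
            me2_t = mx + _lognormal(rng, 6.0, 0.3)
            mx2_t = me2_t + _lognormal(rng, 2.0, 0.3)
            if mx2_t >= dur:
                break
            emit(me2_t, "ME")
            mx = emit(mx2_t, "MX")
        # approach to the nose port, aiming at the planned cycle duration
        lat = _lognormal(rng, 1.2, 0.3)
        extra_gap = 0.0
        se = mx / dur
        do_extra = rng.uniform() < cfg.rates.extra_poke(se)
        if do_extra:
            extra_gap = _lognormal(rng, 1.5, 0.3)
        travel = planned_next_me - mx - lat - extra_gap
        if travel < 0.5:
            travel = 0.5
        t_np = mx + travel
        if t_np + extra_gap + lat >= dur:
            break
        t_np = emit(t_np, "rNP")
        if do_extra:
            t_np = emit(t_np + extra_gap, "rNP")
        me = emit(t_np + lat, "ME")
        me_times.append(me)
        k += 1
    actual = list(np.diff(me_times))
    return events, me_times, targets[:len(actual)], actual


def _ri(duration: float, L: float) -> float:
    return float(np.sqrt(L / duration))


def simulate_session(cfg: SimulationConfig, subject_index: int):
    """Simulate one subject-session.

    Returns ``(EventStream, PhotometryTrace, GroundTruth)``; identical
    config and subject index reproduce bit-identical outputs.
    """
    rng = _subject_rng(cfg, subject_index)
    amp_mult = float(np.exp(rng.normal(0.0, cfg.subject_effects.amp_sd)))
    f0_mult = float(np.exp(rng.normal(0.0, cfg.subject_effects.f0_sd)))

    events, me_times, targets, actual = _simulate_events(cfg, rng)
    times = np.array([t for t, _ in events])
    kinds = np.array([k for _, k in events], dtype=object)
    stream = EventStream(subject_id=f"sim{subject_index:02d}", times=times,
                         kinds=kinds, session_duration=cfg.session_duration,
                         resolution=cfg.resolution)

    p = cfg.photometry
    n = int(round(cfg.session_duration * p.fs)) + 1
    t_frames = np.arange(n) / p.fs
    s = np.zeros(n)
    kern_lags = np.arange(0, p.kernel.support, 1.0 / p.fs)
    kern = p.kernel.evaluate(kern_lags)

    def add(t_event, amp, window=None):
        """Add a transient; windowed effects have their onset at window start."""
        if amp == 0:
            return
        start = t_event + (window[0] if window is not None else 0.0)
        i0 = max(0, int(np.ceil(start * p.fs)))
        if window is not None:
            i1 = min(n, int(np.floor((t_event + window[1]) * p.fs + 1e-9)) + 1)
        else:
            i1 = min(n, i0 + kern.size)
        if i1 <= i0:
            return
        lags = np.arange(i0, i1) / p.fs - start  # from the effect onset
        s[i0:i1] += amp * p.kernel.evaluate(lags)

    # event-locked transients (amplitude jittered per event)
    for t_e, kind in events:
        base = p.event_amplitudes.get(kind, 0.0)
        if base:
            add(t_e, base * amp_mult
                * np.exp(rng.normal(0.0, p.amp_jitter_sd)))

    # covariate-scaled effects around every magazine entry (rewarded entries
    # delimit cycles; re-entries inherit the RI of the cycle containing them,
    # so all ME-MX blocks of a cycle carry the same per-unit-RI effect)
    rewarded = {t: j for j, t in enumerate(me_times)}

    def ri_for(t_e: float, pre_window: bool):
        j = rewarded.get(t_e)
        if j is not None:  # rewarded entry: cycle starting vs ending here
            j = j - 1 if pre_window else j
        else:              # re-entry: the cycle containing it
            j = int(np.searchsorted(me_times, t_e)) - 1
        if 0 <= j < len(actual):
            return _ri(actual[j], cfg.ri_transform_L)
        return None

    effect_covs = []
    for t_e, kind in events:
        if kind != "ME":
            continue
        per_event = []
        for eff in p.effects:
            if eff.event != "ME":
                per_event.append(None)
                continue
            if eff.covariate == "se":
                cov = t_e / cfg.session_duration
            elif eff.covariate == "ri":
                cov = ri_for(t_e, eff.window[0] < 0)
            else:
                raise ValueError(f"unsupported effect covariate {eff.covariate!r}")
            per_event.append(cov)
            if cov is not None:
                add(t_e, eff.amplitude * cov, window=eff.window)
        effect_covs.append({"time": t_e, "rewarded": t_e in rewarded,
                            "covariates": per_event})

    drift = np.exp(-t_frames / p.bleach_tau)
    noise = rng.normal(0.0, p.noise_sd, size=n)
    f_raw = p.f0 * f0_mult * drift * np.maximum(1.0 + s + noise, 0.05)
    trace = PhotometryTrace(f_raw=f_raw, fs=p.fs,
                            subject_id=stream.subject_id)

    truth = GroundTruth(
        subject_index=subject_index,
        cycle_target_durations=[float(x) for x in targets],
        cycle_actual_durations=[float(x) for x in actual],
        me_times=[float(x) for x in me_times],
        effects=[asdict(e) for e in p.effects],
        effect_covariates=effect_covs,
        amp_multiplier=amp_mult,
        f0_multiplier=f0_mult,
        noise_sd=p.noise_sd,
        seed_entropy=[cfg.seed, subject_index],
    )
    return stream, trace, truth


def effect_waveform(cfg: SimulationConfig, eff: EffectSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit-covariate effect waveform on the frame grid over its window.

    Returns event-relative lag times and the injected fluorescence fraction
    per unit covariate at each frame (kernel onset at the window start).
    """
    p = cfg.photometry
    lo = int(np.ceil(eff.window[0] * p.fs - 1e-9))
    hi = int(np.floor(eff.window[1] * p.fs + 1e-9))
    lags = np.arange(lo, hi + 1) / p.fs
    return lags, eff.amplitude * p.kernel.evaluate(lags - eff.window[0])


@dataclass
class Cohort:
    config: SimulationConfig
    streams: list
    traces: list
    ground_truths: list

    def write(self, outdir) -> None:
        """Write per-subject event/trace CSVs and the ground-truth manifest."""
        import os
        os.makedirs(outdir, exist_ok=True)
        for stream, trace in zip(self.streams, self.traces):
            write_events(stream, os.path.join(outdir, f"{stream.subject_id}_events.csv"))
            write_trace(trace, os.path.join(outdir, f"{trace.subject_id}_trace.csv"))
        manifest = {"n_subjects": self.config.n_subjects,
                    "seed": self.config.seed,
                    "subjects": [gt.to_dict() for gt in self.ground_truths]}
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate every subject of the configured cohort."""
    streams, traces, truths = [], [], []
    for i in range(cfg.n_subjects):
        stream, trace, truth = simulate_session(cfg, i)
        streams.append(stream)
        traces.append(trace)
        truths.append(truth)
    return Cohort(config=cfg, streams=streams, traces=traces,
                  ground_truths=truths)
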