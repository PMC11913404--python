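"""Fluorescence preprocessing: sliding-minimum ΔF/F, smoothing, z-scoring, SNR.

The baseline model is a minimum-of-mean: the raw trace is averaged over a
trailing 0.75 s window (F_AVG), the control signal F_BASELINE(t) is the
minimum of F_AVG over the 3 s window ending at t, and
ΔF/F(t) = (F_RAW(t) − F_BASELINE(t)) / F_BASELINE(t).  ΔF/F is then smoothed
with a causal truncated exponential kernel (time constant τ = 0.2 s, support
ω = 1 s) and z-scored against the whole-session mean and SD.  Signal quality
is scored by an evoked-response SNR with a timepoint-shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


class TraceFormatError(ValueError):
    """Raised for malformed or nonuniformly sampled trace files."""


@dataclass
class DffParams:
    """Window parameters of the ΔF/F computation, in seconds."""

    avg_window: float = 0.75
    baseline_lookback: float = 3.0
    tau: float = 0.2
    width: float = 1.0
    centered_avg: bool = False  # trailing (causal) by default
    drop_partial: bool = False  # use partial windows at the session start


def _frames(seconds: float, fs: float) -> int:
    """Round-half-up conversion of a window length to a frame count."""
    return max(1, int(np.floor(seconds * fs + 0.5)))


@dataclass
class PhotometryTrace:
    """Raw fluorescence and its derived channels for one subject-session."""

    f_raw: np.ndarray
    fs: float = 30.0
    subject_id: str = ""
    params: DffParams = None
    f_avg: np.ndarray | None = None
    f_baseline: np.ndarray | None = None
    dff: np.ndarray | None = None
    dff_smoothed: np.ndarray | None = None
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        if self.params is None:
            self.params = DffParams()
        if self.fs <= 0:
            raise TraceFormatError("frame rate must be positive")

    def __len__(self) -> int:
        return int(self.f_raw.size)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def channel(self, name: str) -> np.ndarray:
        out = getattr(self, name)
        if out is None:
            raise ValueError(f"channel {name!r} not computed yet")
        return out


def read_trace(path, subject_id: str | None = None,
               fs_tol: float = 1e-6) -> PhotometryTrace:
    """Read a headered ``time_s,f_raw`` CSV trace; sampling must be uniform."""
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns or "f_raw" not in df.columns:
        raise TraceFormatError(f"{path}: expected columns time_s,f_raw")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise TraceFormatError(f"{path}: need at least 2 frames")
    dt = np.diff(t)
    if np.ptp(dt) > fs_tol:
        raise TraceFormatError(f"{path}: nonuniform sampling")
    return PhotometryTrace(f_raw=df["f_raw"].to_numpy(float),
                           fs=1.0 / float(dt.mean()),
                           subject_id=subject_id or str(path))


def write_trace(trace: PhotometryTrace, path) -> None:
    """Write ``time_s,f_raw`` plus any computed derived channels as columns."""
    cols = {"time_s": trace.frame_times, "f_raw": trace.f_raw}
    for name in ("f_avg", "f_baseline", "dff", "dff_smoothed", "z"):
        ch = getattr(trace, name)
        if ch is not None:
            cols[name] = ch
    pd.DataFrame(cols).to_csv(path, index=False)


def compute_dff(trace: PhotometryTrace) -> PhotometryTrace:
    """Fill ``f_avg``, ``f_baseline`` and ``dff`` on a copy of the trace.

    F_AVG is the mean of F_RAW over the trailing ``avg_window`` ending at
    each frame; F_BASELINE is the minimum of F_AVG over the
    ``baseline_lookback`` window ending at the frame (inclusive, so
    F_BASELINE(t) ≤ F_AVG(t) wherever the window is full).  Leading frames
    use whatever portion of each window exists unless ``drop_partial``.
    """
    p = trace.params
    f = trace.f_raw
    if np.any(f <= 0):
        raise ValueError("f_raw must be strictly positive")
    n_avg = _frames(p.avg_window, trace.fs)
    if len(f) < n_avg:
        raise ValueError("trace shorter than the averaging window")
    n_base = _frames(p.baseline_lookback, trace.fs) + 1  # inclusive of t
    s = pd.Series(f)
    if p.centered_avg:
        f_avg = s.rolling(n_avg, min_periods=1, center=True).mean().to_numpy()
    else:
        f_avg = s.rolling(n_avg, min_periods=1).mean().to_numpy()
    f_baseline = pd.Series(f_avg).rolling(n_base, min_periods=1).min().to_numpy()
    dff = (f - f_baseline) / f_baseline
    if p.drop_partial:
        cut = n_avg + n_base - 2
        f_avg = f_avg.copy(); f_baseline = f_baseline.copy(); dff = dff.copy()
        f_avg[:n_avg - 1] = np.nan
        f_baseline[:cut] = np.nan
        dff[:cut] = np.nan
    return replace(trace, f_avg=f_avg, f_baseline=f_baseline, dff=dff)


def exponential_kernel(fs: float, tau: float, width: float,
                       symmetric: bool = False) -> np.ndarray:
    """Truncated exponential kernel: lag-0 first, support ``width`` seconds."""
    if tau <= 0 or width <= 0:
        raise ValueError("tau and width must be positive")
    n = _frames(width, fs)
    lags = np.arange(n + 1) / fs
    k = np.exp(-lags / tau)
    if symmetric:
        k = np.concatenate([k[:0:-1], k])
    return k


def smooth_exponential(x, fs: float, tau: float = 0.2, width: float = 1.0,
                       symmetric: bool = False) -> np.ndarray:
    """Exponentially weighted moving window, renormalized at the boundary.

    Causal by default: y(t) = Σ_{s≤t in window} e^{-(t−s)/τ} x(s) / Σ weights.
    A constant input is a fixed point of the operator.
    """
    x = np.asarray(x, dtype=float)
    k = exponential_kernel(fs, tau, width, symmetric=symmetric)
    n = x.size
    if symmetric:
        half = (k.size - 1) // 2
        num = np.convolve(x, k, mode="full")[half:half + n]
        den = np.convolve(np.ones(n), k, mode="full")[half:half + n]
    else:
        num = np.convolve(x, k, mode="full")[:n]
        den = np.convolve(np.ones(n), k, mode="full")[:n]
    return num / den


def zscore_session(x) -> np.ndarray:
    """Z-score against the whole-session mean and (population) SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero variance: cannot z-score")
    return (x - x.mean()) / sd


def preprocess(trace: PhotometryTrace) -> PhotometryTrace:
    """Full chain: ΔF/F → exponential smoothing → session z-score."""
    out = compute_dff(trace)
    sm = smooth_exponential(out.dff, out.fs, out.params.tau, out.params.width)
    return replace(out, dff_smoothed=sm, z=zscore_session(sm))


@dataclass
class SNRReport:
    """Evoked-response SNR against a timepoint-shuffle null."""

    snr_original: float
    snr_shuffled: np.ndarray
    p: float
    n_shuffles: int
    seed: int | None


def _evoked_snr(Y: np.ndarray) -> float:
    """Variance of the trial-mean trace over mean within-trial residual variance."""
    mean_trace = Y.mean(axis=0)
    signal = mean_trace.var()
    resid = (Y - mean_trace).var(axis=1).mean()
    if resid <= signal * 1e-12:
        if signal == 0:
            raise ValueError("degenerate trials: zero variance everywhere")
        return np.inf  # noiseless limit: identical trials
    return float(signal / resid)


def snr_shuffle_test(Y, n_shuffles: int = 1000,
                     seed: int | None = None,
                     method: str = "permute") -> SNRReport:
    """SNR of peri-event trials vs a null of timepoint-shuffled trials.

    Parameters
    ----------
    Y : (K trials × T timepoints) array of aligned activity
    method : {"permute", "circular"}
        Independent within-trial permutation of timepoints (default) or
        autocorrelation-preserving circular shifts.

    The p-value uses the add-one estimator and never equals 0.
    """
    Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
    if Y.shape[0] < 5 or Y.shape[1] < 10:
        raise ValueError("need >= 5 trials and >= 10 timepoints")
    snr0 = _evoked_snr(Y)
    rng = np.random.default_rng(seed)
    K, T = Y.shape
    if method == "permute":
        stack = rng.permuted(
            np.broadcast_to(Y, (n_shuffles, K, T)).copy(), axis=2)
    elif method == "circular":
        shifts = rng.integers(0, T, size=(n_shuffles, K))
        cols = (np.arange(T)[None, None, :] + shifts[:, :, None]) % T
        stack = np.take_along_axis(
            np.broadcast_to(Y, (n_shuffles, K, T)), cols, axis=2)
    else:
        raise ValueError("method must be 'permute' or 'circular'")
    mean_traces = stack.mean(axis=1)
    signal = mean_traces.var(axis=1)
    resid = (stack - mean_traces[:, None, :]).var(axis=2).mean(axis=1)
    snr_null = signal / resid
    p = (1.0 + np.sum(snr_null >= snr0)) / (1.0 + n_shuffles)
    return SNRReport(snr_original=snr0, snr_shuffled=snr_null, p=float(p),
                     n_shuffles=n_shuffles, seed=seed)
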