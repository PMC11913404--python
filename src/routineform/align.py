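"""Peri-event alignment of z-scored activity into block × timepoint matrices.

Blocks of one type are aligned either *head-fixed* (rows start at the
block's initial action event, time axis 0 … +window) or *tail-fixed* (rows
end at the terminal event, time axis −window … 0).  The default window is
half the mean block duration for the type, which keeps windows of adjacent
alignments from overlapping.  Event timestamps on the 10 ms behavioral grid
are mapped to the nearest 30 fps frame, ties rounding down; window endpoint
frames are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import Block
from .photometry import PhotometryTrace


@dataclass
class AlignedMatrix:
    """K blocks × T timepoints of peri-event activity."""

    Y: np.ndarray
    time_axis: np.ndarray
    mode: str
    window_length: float
    fs: float
    block_refs: list = field(default_factory=list)
    anchor_times: np.ndarray | None = None
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.Y.size and self.Y.shape[1] != self.time_axis.size:
            raise ValueError("Y columns must match the time axis")

    @property
    def K(self) -> int:
        return 0 if self.Y.size == 0 else self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.time_axis.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Y, columns=[f"{t:.6f}" for t in self.time_axis])
        df.insert(0, "anchor_time_s",
                  self.anchor_times if self.anchor_times is not None else np.nan)
        return df

    def sidecar(self) -> dict:
        return {
            "mode": self.mode,
            "window_length_s": self.window_length,
            "fs": self.fs,
            "n_rows": int(self.K),
            "anchor_times_s": (None if self.anchor_times is None
                               else [float(t) for t in self.anchor_times]),
            "dropped": list(self.dropped),
        }


def event_to_frame(t: float, fs: float) -> int:
    """Nearest-frame index for an event time; exact half-frame ties round down."""
    return int(np.ceil(t * fs - 0.5))


def _extract_rows(z: np.ndarray, fs: float, anchors, lo: int, hi: int):
    """Rows z[a+lo : a+hi] (inclusive) per anchor frame; out-of-range dropped."""
    rows, kept, dropped = [], [], []
    n = z.size
    for i, t in enumerate(anchors):
        a = event_to_frame(t, fs)
        if a + lo < 0 or a + hi >= n:
            dropped.append({"row": i, "anchor_time_s": float(t),
                            "reason": "window outside recording"})
            continue
        rows.append(z[a + lo:a + hi + 1])
        kept.append(i)
    Y = np.array(rows) if rows else np.empty((0, hi - lo + 1))
    return Y, kept, dropped


def _as_signal(z, fs):
    if isinstance(z, PhotometryTrace):
        return z.channel("z"), z.fs
    if fs is None:
        raise ValueError("fs required when passing a bare array")
    return np.asarray(z, dtype=float), float(fs)


def align_blocks(z, blocks: list[Block], mode: str = "head_fixed",
                 window_override: float | None = None,
                 fs: float | None = None, channel: str = "z") -> AlignedMatrix:
    """Build the aligned activity matrix for blocks of a single type.

    Parameters
    ----------
    z : PhotometryTrace or 1-D array
        Session signal; for a trace, ``channel`` selects the derived channel.
    blocks : blocks of one type, chronological
    mode : {"head_fixed", "tail_fixed"}
        Anchor rows at the block's initial (t_start) or terminal (t_end) event.
    window_override : seconds; default is half the mean block duration.
    """
    if isinstance(z, PhotometryTrace):
        sig, fs = z.channel(channel), z.fs
    else:
        sig, fs = _as_signal(z, fs)
    if not blocks:
        return AlignedMatrix(Y=np.empty((0, 0)), time_axis=np.empty(0),
                             mode=mode, window_length=0.0, fs=fs)
    types = {b.block_type for b in blocks}
    if len(types) > 1:
        raise ValueError(f"blocks must share one type, got {sorted(types)}")
    if mode not in ("head_fixed", "tail_fixed"):
        raise ValueError("mode must be 'head_fixed' or 'tail_fixed'")
    window = (window_override if window_override is not None
              else 0.5 * float(np.mean([b.duration for b in blocks])))
    n_win = max(1, int(np.floor(window * fs + 0.5)))
    if mode == "head_fixed":
        anchors = [b.t_start for b in blocks]
        lo, hi = 0, n_win
        time_axis = np.arange(0, n_win + 1) / fs
    else:
        anchors = [b.t_end for b in blocks]
        lo, hi = -n_win, 0
        time_axis = np.arange(-n_win, 1) / fs
    Y, kept, dropped = _extract_rows(sig, fs, anchors, lo, hi)
    if not kept:
        warnings.warn("no blocks survived alignment", stacklevel=2)
        return AlignedMatrix(Y=np.empty((0, time_axis.size)), time_axis=time_axis,
                             mode=mode, window_length=window, fs=fs,
                             dropped=dropped)
    return AlignedMatrix(
        Y=Y, time_axis=time_axis, mode=mode, window_length=window, fs=fs,
        block_refs=[blocks[i] for i in kept],
        anchor_times=np.array([anchors[i] for i in kept]), dropped=dropped)


def peri_event_matrix(z, event_times, pre: float, post: float,
                      fs: float | None = None,
                      channel: str = "z",
                      block_refs: list | None = None) -> AlignedMatrix:
    """Fixed [−pre, +post] windows around single events; 0 marks the event."""
    if isinstance(z, PhotometryTrace):
        sig, fs = z.channel(channel), z.fs
    else:
        sig, fs = _as_signal(z, fs)
    if pre < 0 or post < 0 or (pre == 0 and post == 0):
        raise ValueError("pre and post must be >= 0 and not both 0")
    n_pre = int(np.floor(pre * fs + 0.5))
    n_post = int(np.floor(post * fs + 0.5))
    time_axis = np.arange(-n_pre, n_post + 1) / fs
    Y, kept, dropped = _extract_rows(sig, fs, list(event_times), -n_pre, n_post)
    if not kept:
        warnings.warn("no events survived alignment", stacklevel=2)
    refs = ([block_refs[i] for i in kept] if block_refs is not None else [])
    return AlignedMatrix(
        Y=Y if Y.size else np.empty((0, time_axis.size)),
        time_axis=time_axis, mode="peri_event",
        window_length=pre + post, fs=fs, block_refs=refs,
        anchor_times=np.array([event_times[i] for i in kept]),
        dropped=dropped)


def interval_auc(M: AlignedMatrix, interval) -> np.ndarray:
    """Per-row sum of Y over columns with time in the closed interval [a, b]."""
    a, b = interval
    eps = 0.5 / M.fs * 1e-6 + 1e-9
    cols = (M.time_axis >= a - eps) & (M.time_axis <= b + eps)
    if not cols.any():
        raise ValueError(f"interval [{a}, {b}] selects no columns")
    return M.Y[:, cols].sum(axis=1)
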