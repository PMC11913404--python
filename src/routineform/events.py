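"""Behavioral event streams and their segmentation into blocks and cycles.

An operant session is a timestamped stream of four action events: rewarded
nose-poke (``rNP``), non-rewarded nose-poke (``nrNP``), magazine entry
(``ME``) and magazine exit (``MX``).  A *block* is the transition between two
adjacent retained events; five transition types occur in a fixed-ratio-1
session.  The three of them that are required to collect a reward
(rNP-ME, ME-MX, MX-rNP) are *cycle blocks*; rNP-rNP and MX-ME are
*non-cycle blocks*.  A *cycle* is the stretch of behavior between two
successive rewarded magazine entries, i.e. between adjacent rNP-ME blocks.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_KINDS = ("rNP", "nrNP", "ME", "MX")

#: the five named block types; order is (initial event, terminal event)
BLOCK_TYPES = ("rNP-ME", "ME-MX", "MX-rNP", "rNP-rNP", "MX-ME")
CYCLE_BLOCK_TYPES = frozenset({"rNP-ME", "ME-MX", "MX-rNP"})


class EventFormatError(ValueError):
    """Raised when an event log does not parse or violates stream invariants."""


class EmptyStreamError(ValueError):
    """Raised when an event log contains no events."""


@dataclass
class EventStream:
    """Ordered, timestamped action events of one session.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    times : ndarray of float
        Event times in seconds from session start, nondecreasing.
    kinds : ndarray of str
        Event codes, one of :data:`EVENT_KINDS`, same length as ``times``.
    session_duration : float
        Session duration ``T_S`` in seconds; at least the last event time.
    resolution : float
        Time grid of the acquisition system (default 10 ms).
    """

    subject_id: str
    times: np.ndarray
    kinds: np.ndarray
    session_duration: float
    resolution: float = 0.01

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.times.ndim != 1 or self.times.shape != self.kinds.shape:
            raise EventFormatError("times and kinds must be 1-D and congruent")
        if self.times.size == 0:
            raise EmptyStreamError(f"subject {self.subject_id}: no events")
        bad = set(self.kinds) - set(EVENT_KINDS)
        if bad:
            raise EventFormatError(f"unknown event codes {sorted(bad)}")
        if np.any(np.diff(self.times) < 0):
            raise EventFormatError("event times must be nondecreasing")
        if self.resolution <= 0:
            raise EventFormatError("resolution must be positive")
        if self.times[0] < 0 or self.times[-1] > self.session_duration + 1e-9:
            raise EventFormatError("event times must lie in [0, session_duration]")
        on_grid = np.abs(self.times / self.resolution
                         - np.round(self.times / self.resolution))
        if np.any(on_grid * self.resolution > 1e-9):
            raise EventFormatError(
                "event times must be integer multiples of the resolution")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def events(self) -> list[tuple[float, str]]:
        return list(zip(self.times.tolist(), self.kinds.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "event": self.kinds})


@dataclass
class Block:
    """One transition between two adjacent retained action events."""

    block_type: str
    t_start: float
    t_end: float
    session_duration: float

    def __post_init__(self) -> None:
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")
        if not self.t_end > self.t_start:
            raise ValueError("block must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def is_cycle_block(self) -> bool:
        return self.block_type in CYCLE_BLOCK_TYPES

    @property
    def session_elapsed(self) -> float:
        """SE = T_b / T_S, the fraction of the session already elapsed."""
        return self.t_start / self.session_duration

    @property
    def block_velocity(self) -> float:
        """BV = 1 / (T_f - T_b), the reciprocal block duration (1/s)."""
        return 1.0 / self.duration

    @property
    def initial_event(self) -> str:
        return self.block_type.split("-")[0]


@dataclass
class Cycle:
    """Blocks between two successive rewarded magazine entries.

    ``duration`` is the time between the two delimiting rNP-ME completions
    (ME anchor, the default) or initiations (rNP anchor).  ``blocks`` holds
    every block strictly between the delimiters plus the terminal rNP-ME
    block, so the minimal routine cycle (ME-MX, MX-rNP, rNP-ME) has
    ``n_blocks == 3``.  Any log containing a magazine exit between the
    delimiters yields at least two member blocks; only a degenerate log
    (ME followed immediately by rNP, no MX) reduces membership to the
    terminal block alone.
    """

    blocks: list[Block]
    duration: float
    t_start: float
    t_end: float
    index: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("cycle duration must be positive")
        if len(self.blocks) < 1:
            raise ValueError("a cycle contains at least its terminal block")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def session_elapsed(self) -> float:
        """SE of the cycle = SE of its first block."""
        return self.blocks[0].session_elapsed


@dataclass
class SegmentationDiagnostics:
    """Bookkeeping of what segmentation dropped or skipped."""

    n_events: int = 0
    n_nrnp_dropped: int = 0
    n_pairs_skipped: int = 0
    n_zero_duration_dropped: int = 0
    skipped_pair_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_nrnp_dropped": self.n_nrnp_dropped,
            "n_pairs_skipped": self.n_pairs_skipped,
            "n_zero_duration_dropped": self.n_zero_duration_dropped,
            "skipped_pair_counts": dict(self.skipped_pair_counts),
        }


_DURATION_HEADER = "# session_duration_s="


def read_events(path, subject_id: str | None = None,
                resolution: float = 0.01) -> EventStream:
    """Read a headered ``time_s,event`` CSV event log into an :class:`EventStream`.

    An optional comment line ``# session_duration_s=<float>`` declares the
    session duration; the stream's duration is the maximum of the declared
    value and the last event time.
    """
    declared = None
    rows = []
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith(_DURATION_HEADER):
            declared = float(line[len(_DURATION_HEADER):])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            rows.append(line)
    if not rows or rows == ["time_s,event"]:
        raise EmptyStreamError(f"{path}: no events")
    df = pd.read_csv(io.StringIO("\n".join(rows)))
    if list(df.columns) != ["time_s", "event"]:
        raise EventFormatError(f"{path}: expected columns time_s,event")
    bad = df.loc[~df["event"].isin(EVENT_KINDS)]
    if len(bad):
        row = bad.index[0] + 2  # header line + 1-based
        raise EventFormatError(
            f"{path}: unknown event code {bad['event'].iloc[0]!r} at row {row}")
    # stable sort: simultaneous timestamps keep file order
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    times = df["time_s"].to_numpy(float)
    duration = float(times[-1]) if declared is None else max(declared, float(times[-1]))
    return EventStream(
        subject_id=subject_id or str(path),
        times=times,
        kinds=df["event"].to_numpy(object),
        session_duration=duration,
        resolution=resolution,
    )


def write_events(stream: EventStream, path) -> None:
    """Write the event log in the same dialect :func:`read_events` reads."""
    with open(path, "w") as fh:
        fh.write(f"{_DURATION_HEADER}{stream.session_duration}\n")
        fh.write("time_s,event\n")
        for t, k in zip(stream.times, stream.kinds):
            fh.write(f"{t:.2f},{k}\n")


def segment_blocks(stream: EventStream, with_diagnostics: bool = False):
    """Segment a stream into blocks: one per adjacent pair of retained events.

    nrNP events are dropped before pairing.  Adjacent pairs whose
    (initial, terminal) kinds do not match one of the five named block types
    are skipped and counted; zero-duration pairs (simultaneous timestamps)
    are dropped with a warning because block velocity would be undefined.
    """
    diag = SegmentationDiagnostics(n_events=len(stream))
    keep = stream.kinds != "nrNP"
    diag.n_nrnp_dropped = int(np.sum(~keep))
    times = stream.times[keep]
    kinds = stream.kinds[keep]
    blocks: list[Block] = []
    for i in range(len(times) - 1):
        btype = f"{kinds[i]}-{kinds[i + 1]}"
        if btype not in BLOCK_TYPES:
            diag.n_pairs_skipped += 1
            diag.skipped_pair_counts[btype] = diag.skipped_pair_counts.get(btype, 0) + 1
            continue
        if times[i + 1] <= times[i]:
            diag.n_zero_duration_dropped += 1
            warnings.warn(
                f"dropped zero-duration {btype} block at t={times[i]:.2f}s",
                stacklevel=2)
            continue
        blocks.append(Block(btype, float(times[i]), float(times[i + 1]),
                            stream.session_duration))
    if with_diagnostics:
        return blocks, diag
    return blocks


def segment_cycles(blocks: list[Block], cycle_anchor: str = "ME") -> list[Cycle]:
    """Group blocks into cycles delimited by successive rNP-ME blocks.

    Parameters
    ----------
    blocks : list of Block
        Ordered by ``t_start`` (as produced by :func:`segment_blocks`).
    cycle_anchor : {"ME", "rNP"}
        Whether cycle duration runs between rNP-ME completions (magazine
        entries, default) or initiations (nose-pokes).
    """
    if cycle_anchor not in ("ME", "rNP"):
        raise ValueError("cycle_anchor must be 'ME' or 'rNP'")
    delim = [i for i, b in enumerate(blocks) if b.block_type == "rNP-ME"]
    cycles: list[Cycle] = []
    for c, (i, j) in enumerate(zip(delim[:-1], delim[1:])):
        members = blocks[i + 1:j + 1]  # strictly between, plus terminal rNP-ME
        if cycle_anchor == "ME":
            t0, t1 = blocks[i].t_end, blocks[j].t_end
        else:
            t0, t1 = blocks[i].t_start, blocks[j].t_start
        cycles.append(Cycle(blocks=members, duration=t1 - t0,
                            t_start=t0, t_end=t1, index=c))
    return cycles


def block_cycle_map(cycles: list[Cycle]) -> dict[int, Cycle]:
    """Map ``id(block) -> Cycle`` for every block belonging to a cycle."""
    mapping: dict[int, Cycle] = {}
    for cyc in cycles:
        for b in cyc.blocks:
            mapping[id(b)] = cyc
    return mapping


def _se_bins(n_bins: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_bins + 1)


def choice_proportions(blocks: list[Block], n_bins: int = 10) -> pd.DataFrame:
    """Per-SE-bin proportions of choosing the cycle block after rNP and MX.

    For blocks starting with rNP the competing types are rNP-ME (cycle) vs
    rNP-rNP; for MX-starts, MX-rNP vs MX-ME.  Empty bins carry NaN.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = _se_bins(n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame({
        "se_bin_center": centers,
        "p_rnp_me": np.nan, "n_rnp_starts": 0,
        "p_mx_rnp": np.nan, "n_mx_starts": 0,
    })
    if not blocks:
        return out
    se = np.array([b.session_elapsed for b in blocks])
    idx = np.clip(np.digitize(se, edges[1:-1]), 0, n_bins - 1)
    for k in range(n_bins):
        sub = [b for b, i in zip(blocks, idx) if i == k]
        rnp = [b for b in sub if b.initial_event == "rNP"]
        mx = [b for b in sub if b.initial_event == "MX"]
        if rnp:
            out.loc[k, "p_rnp_me"] = np.mean(
                [b.block_type == "rNP-ME" for b in rnp])
            out.loc[k, "n_rnp_starts"] = len(rnp)
        if mx:
            out.loc[k, "p_mx_rnp"] = np.mean(
                [b.block_type == "MX-rNP" for b in mx])
            out.loc[k, "n_mx_starts"] = len(mx)
    return out


def blocks_per_cycle_curve(cycles: list[Cycle], n_bins: int = 10) -> pd.DataFrame:
    """Mean number of blocks per cycle in each SE bin (cycle SE = first block's)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = _se_bins(n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame({"se_bin_center": centers,
                        "mean_n_blocks": np.nan, "n_cycles": 0})
    if not cycles:
        return out
    se = np.array([c.session_elapsed for c in cycles])
    nb = np.array([c.n_blocks for c in cycles], dtype=float)
    idx = np.clip(np.digitize(se, edges[1:-1]), 0, n_bins - 1)
    for k in range(n_bins):
        sel = idx == k
        if sel.any():
            out.loc[k, "mean_n_blocks"] = float(nb[sel].mean())
            out.loc[k, "n_cycles"] = int(sel.sum())
    return out
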