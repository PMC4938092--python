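"""Event-time datasets: reading, writing, validation, binning, segmentation.

A dataset holds, per channel, the onset times (seconds) of discrete call
events.  A channel is usually an individual bird, but after expansion by
call type it is an (individual, calltype) pair.  Call durations are not
modelled: onsets carry the timing information used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventDataset",
    "BinnedEvents",
    "read_events",
    "write_events",
    "bin_events",
    "split_segments",
    "expand_by_type",
]


class EventParseError(ValueError):
    """Raised when an event CSV cannot be parsed; carries a 1-based line number."""


@dataclass
class EventDataset:
    """Per-channel sorted event times with optional metadata.

    Parameters
    ----------
    channels : list of str
        Unique channel identifiers, in a fixed order.
    events : dict mapping channel -> ndarray of float
        Event onset times in seconds, non-decreasing, within [0, duration].
    duration : float
        Total observation span in seconds.
    metadata : dict
        Free-form; recognised keys include ``locations`` (channel -> location
        label), ``session`` (label), ``calltypes`` (channel -> (individual,
        calltype) after expansion), and ``seed`` (simulation provenance).
    """

    channels: list[str]
    events: dict[str, np.ndarray]
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel IDs must be unique")
        if not math.isfinite(self.duration) or self.duration < 0:
            raise ValueError(f"invalid duration {self.duration!r}")
        clean = {}
        for ch in self.channels:
            t = np.asarray(self.events.get(ch, ()), dtype=float)
            if t.size and (np.any(t < 0) or np.any(t > self.duration)):
                raise ValueError(f"channel {ch!r}: event times outside [0, duration]")
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"channel {ch!r}: event times not sorted")
            clean[ch] = t
        self.events = clean

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.events.values()))

    def counts(self) -> dict[str, int]:
        return {ch: len(self.events[ch]) for ch in self.channels}

    def rates(self) -> dict[str, float]:
        """Empirical event rate per channel, events/second."""
        if self.duration <= 0:
            raise ValueError("duration must be positive to compute rates")
        return {ch: len(self.events[ch]) / self.duration for ch in self.channels}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.channels:
            for t in self.events[ch]:
                rows.append((float(t), ch))
        df = pd.DataFrame(rows, columns=["time", "individual"])
        return df.sort_values("time", kind="stable").reset_index(drop=True)

    def equals(self, other: "EventDataset", atol: float = 0.0) -> bool:
        if self.channels != other.channels:
            return False
        if abs(self.duration - other.duration) > atol:
            return False
        for ch in self.channels:
            a, b = self.events[ch], other.events[ch]
            if len(a) != len(b):
                return False
            if len(a) and not np.allclose(a, b, atol=atol, rtol=0.0):
                return False
        return True


@dataclass
class BinnedEvents:
    """Events discretised onto a regular grid of half-open bins [kΔ, (k+1)Δ)."""

    channels: list[str]
    bin_width: float
    counts: np.ndarray  # (n_channels, n_bins) non-negative ints
    duration: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def read_events(
    path,
    *,
    duration: float | None = None,
    channels: Sequence[str] | None = None,
) -> EventDataset:
    """Read an event table CSV with columns ``time,individual[,calltype][,session]``.

    Lines beginning with ``#`` are ignored.  ``duration`` defaults to the
    maximum event time rounded up to the next whole second.  ``channels``
    declares the channel set (required to represent individuals with zero
    events, e.g. in a header-only file).
    """
    known = {"time", "individual", "calltype", "session"}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header = None
    rows = []  # (lineno, time, individual, calltype, session)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split(",")]
        if header is None:
            header = cells
            unknown = set(header) - known
            if unknown or "time" not in header or "individual" not in header:
                raise EventParseError(
                    f"line {lineno}: bad header {header!r}; expected columns "
                    "time,individual[,calltype][,session]"
                )
            continue
        if len(cells) != len(header):
            raise EventParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        rec = dict(zip(header, cells))
        try:
            t = float(rec["time"])
        except ValueError:
            raise EventParseError(f"line {lineno}: unparseable time {rec['time']!r}") from None
        if not math.isfinite(t) or t < 0:
            raise EventParseError(f"line {lineno}: negative or non-finite time {t}")
        rows.append((lineno, t, rec["individual"], rec.get("calltype"), rec.get("session")))
    if header is None:
        raise EventParseError("line 1: empty file, no header found")

    obs_channels = sorted({r[2] for r in rows})
    chans = list(channels) if channels is not None else obs_channels
    missing = set(obs_channels) - set(chans)
    if missing:
        raise EventParseError(f"events found for undeclared channels {sorted(missing)}")
    if duration is None:
        duration = math.ceil(max((r[1] for r in rows), default=0.0))
    ev = {ch: [] for ch in chans}
    sessions = set()
    for _, t, ind, _ctype, sess in rows:
        ev[ind].append(t)
        if sess:
            sessions.add(sess)
    meta: dict = {}
    if "calltype" in header:
        # store per-event types alongside times, keyed by channel
        types = {ch: [] for ch in chans}
        for _, t, ind, ctype, _ in rows:
            types[ind].append(ctype if ctype else "")
        # sort types together with times
        for ch in chans:
            order = np.argsort(ev[ch], kind="stable")
            types[ch] = [types[ch][k] for k in order]
        meta["event_types"] = types
    if sessions:
        meta["session"] = sorted(sessions)[0] if len(sessions) == 1 else sorted(sessions)
    events = {ch: np.sort(np.asarray(ev[ch], dtype=float)) for ch in chans}
    return EventDataset(channels=chans, events=events, duration=float(duration), metadata=meta)


def write_events(ds: EventDataset, path) -> None:
    """Write a dataset as CSV sorted by time, times at 6 decimal places."""
    types = ds.metadata.get("event_types")
    rows = []
    for ch in ds.channels:
        tlist = ds.events[ch]
        clist = types[ch] if types else [None] * len(tlist)
        for t, c in zip(tlist, clist):
            rows.append((float(t), ch, c))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        if types:
            fh.write("time,individual,calltype\n")
            for t, ch, c in rows:
                fh.write(f"{t:.6f},{ch},{c or ''}\n")
        else:
            fh.write("time,individual\n")
            for t, ch, _ in rows:
                fh.write(f"{t:.6f},{ch}\n")


def bin_events(ds: EventDataset, bin_width: float) -> BinnedEvents:
    """Discretise events onto half-open bins [kΔ, (k+1)Δ); counts are conserved."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, math.ceil(ds.duration / bin_width))
    counts = np.zeros((ds.n_channels, n_bins), dtype=np.int64)
    for ci, ch in enumerate(ds.channels):
        t = ds.events[ch]
        if not len(t):
            continue
        idx = np.floor(t / bin_width).astype(np.int64)
        # an event exactly at duration lands in the final bin
        idx = np.minimum(idx, n_bins - 1)
        np.add.at(counts[ci], idx, 1)
    return BinnedEvents(channels=list(ds.channels), bin_width=float(bin_width),
                        counts=counts, duration=float(ds.duration))


def split_segments(
    ds: EventDataset, seg_len: float, *, keep_partial: bool = False
) -> list[EventDataset]:
    """Cut a session into consecutive non-overlapping segments.

    Events are re-timed relative to each segment's start.  The trailing
    partial segment is dropped by default so that segment-level analyses
    compare like with like (set ``keep_partial`` to retain it).
    """
    if seg_len <= 0:
        raise ValueError("seg_len must be positive")
    n_full = int(ds.duration // seg_len)
    n_seg = n_full + (1 if keep_partial and ds.duration > n_full * seg_len else 0)
    out = []
    for k in range(n_seg):
        lo, hi = k * seg_len, (k + 1) * seg_len
        seg_dur = min(hi, ds.duration) - lo
        ev = {}
        for ch in ds.channels:
            t = ds.events[ch]
            m = (t >= lo) & (t < hi)
            ev[ch] = t[m] - lo
        meta = dict(ds.metadata)
        meta["segment_index"] = k
        meta["segment_start"] = lo
        out.append(EventDataset(list(ds.channels), ev, seg_dur, meta))
    return out


def expand_by_type(ds: EventDataset) -> EventDataset:
    """Split each individual's channel into one channel per observed call type.

    With n individuals and m call types this yields up to n*m channels, so a
    directed influence network over them has (n*m)^2 kernels.  The metadata
    key ``calltypes`` records the (individual, calltype) factorisation.
    """
    types = ds.metadata.get("event_types")
    if types is None:
        raise ValueError("expand_by_type requires call-type labels (metadata['event_types'])")
    new_channels: list[str] = []
    new_events: dict[str, np.ndarray] = {}
    factor: dict[str, tuple[str, str]] = {}
    observed_types = sorted({c for tl in types.values() for c in tl if c})
    for ch in ds.channels:
        tl = types[ch]
        if any(c == "" for c in tl):
            raise ValueError(f"channel {ch!r} has events with missing call-type labels")
        for ct in observed_types:
            times = np.asarray(
                [t for t, c in zip(ds.events[ch], tl) if c == ct], dtype=float
            )
            name = f"{ch}:{ct}"
            new_channels.append(name)
            new_events[name] = times
            factor[name] = (ch, ct)
    meta = dict(ds.metadata)
    meta.pop("event_types", None)
    meta["calltypes"] = factor
    return EventDataset(new_channels, new_events, ds.duration, meta)
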