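"""Reading, writing and segmenting CASAS-style annotated sensor event logs.

The on-disk dialect is one event per line, whitespace-delimited::

    2010-11-04 05:40:51.303739 M004 ON Bed_to_Toilet begin
    2010-11-04 05:40:52.342105 M005 OFF

Four mandatory fields (date, time, sensor ID, sensor status) and an
optional pair (activity name, ``begin``/``end`` marker).  CASAS files mix
tabs and spaces, so any run of whitespace delimits.

Segmentation turns the flat event stream into labelled activity
instances.  In a two-resident home activities overlap in time; every
event falling between a matched begin/end pair contributes to *all*
activities open at that moment, so one sensor firing can appear in two
instances' sequences.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "SensorEvent",
    "ActivityInstance",
    "ParseError",
    "parse_events",
    "segment_activities",
    "write_events",
]

_MARKERS = ("begin", "end")


class ParseError(ValueError):
    """A malformed line in an event log; carries the 1-based line number."""


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped sensor reading, optionally annotated with an activity.

    Attributes
    ----------
    d : datetime.date
        Calendar date of the event.
    t : datetime.time
        Time of day, sub-second precision preserved.
    s : str
        Sensor identifier, e.g. ``"M004"`` (motion) or ``"T001"``
        (temperature).
    ss : str
        Sensor status: ``"ON"``/``"OFF"`` for binary sensors, a numeric
        string for temperature readings.
    ar : str or None
        Activity name when the event marks an activity boundary.
    as_ : str or None
        Boundary marker, ``"begin"`` or ``"end"``; present iff ``ar`` is.
    line : int or None
        1-based source line number, retained for error reporting.
    """

    d: dt.date
    t: dt.time
    s: str
    ss: str
    ar: str | None = None
    as_: str | None = None
    line: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if (self.ar is None) != (self.as_ is None):
            raise ValueError(
                "activity name and begin/end marker must be both present "
                f"or both absent (got ar={self.ar!r}, as={self.as_!r})"
            )
        if self.as_ is not None and self.as_ not in _MARKERS:
            raise ValueError(f"activity marker must be 'begin' or 'end', got {self.as_!r}")

    @property
    def timestamp(self) -> dt.datetime:
        return dt.datetime.combine(self.d, self.t)


@dataclass(frozen=True)
class ActivityInstance:
    """One segmented activity: begin/end hours plus its sensor sequence.

    ``bt`` and ``et`` are the integer hour-of-day components of the first
    and last contributing event; ``sq`` is the ordered tuple of sensor IDs
    fired from the begin event through the end event inclusive.
    """

    bt: int
    et: int
    sq: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.sq:
            raise ValueError("activity sensor sequence must be non-empty")
        if not (0 <= self.bt <= 23 and 0 <= self.et <= 23):
            raise ValueError(f"bt/et must be hours in [0, 23], got ({self.bt}, {self.et})")

    def with_sq(self, sq: Sequence[str]) -> "ActivityInstance":
        return replace(self, sq=tuple(sq))


def _parse_line(raw: str, lineno: int) -> SensorEvent | None:
    fields = raw.split()
    if not fields:
        return None
    if len(fields) not in (4, 6):
        raise ParseError(
            f"line {lineno}: expected 4 or 6 whitespace-delimited fields, got {len(fields)}"
        )
    date_s, time_s, sensor, status = fields[:4]
    try:
        d = dt.date.fromisoformat(date_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: unparseable date {date_s!r}") from exc
    try:
        t = dt.time.fromisoformat(time_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: unparseable time {time_s!r}") from exc
    ar = as_ = None
    if len(fields) == 6:
        ar, as_ = fields[4], fields[5]
        if as_ not in _MARKERS:
            raise ParseError(
                f"line {lineno}: unknown activity marker {as_!r} (expected begin|end)"
            )
    return SensorEvent(d=d, t=t, s=sensor, ss=status, ar=ar, as_=as_, line=lineno)


def parse_events(
    stream: Iterable[str] | str,
    *,
    exclude_sensor_prefixes: Sequence[str] = (),
) -> list[SensorEvent]:
    """Parse a CASAS-style event log into a list of :class:`SensorEvent`.

    Parameters
    ----------
    stream
        A string or any iterable of lines (an open file works).
    exclude_sensor_prefixes
        Sensor-ID prefixes to drop, e.g. ``("T",)`` to exclude
        temperature sensors.  Nothing is excluded by default.

    Raises
    ------
    ParseError
        On a wrong field count, unparseable date/time, or an unknown
        begin/end marker, naming the offending line number.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    events: list[SensorEvent] = []
    prefixes = tuple(exclude_sensor_prefixes)
    for lineno, raw in enumerate(stream, start=1):
        ev = _parse_line(raw, lineno)
        if ev is None:
            continue
        if prefixes and ev.s.startswith(prefixes):
            continue
        events.append(ev)
    return events


def write_events(events: Iterable[SensorEvent]) -> str:
    """Serialize events back to the log dialect; inverse of :func:`parse_events`."""
    lines = []
    for ev in events:
        time_s = ev.t.isoformat()
        fields = [ev.d.isoformat(), time_s, ev.s, ev.ss]
        if ev.ar is not None:
            fields += [ev.ar, ev.as_]
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def segment_activities(events: Sequence[SensorEvent]) -> list[ActivityInstance]:
    """Segment an ordered event stream into labelled activity instances.

    For each matched ``(ar, begin) ... (ar, end)`` pair, emits one
    instance whose sequence contains the sensor of every event from the
    begin event through the end event inclusive, in stream order.  An
    event inside two concurrently open activities contributes to both.
    When the same activity name is open more than once, an ``end`` closes
    the earliest open instance.

    Unmatched ends and activities still open at end-of-stream are skipped
    with a warning.
    """
    open_by_label: dict[str, list[list[SensorEvent]]] = {}
    done: list[tuple[int, list[SensorEvent], str]] = []  # (begin order, events, label)
    order = 0
    begin_order: dict[int, int] = {}

    for ev in events:
        starts_here = ev.ar is not None and ev.as_ == "begin"
        if starts_here:
            bucket = open_by_label.setdefault(ev.ar, [])
            bucket.append([])
            begin_order[id(bucket[-1])] = order
            order += 1
        # the event joins every activity currently open (incl. one begun now)
        for spans in open_by_label.values():
            for span in spans:
                span.append(ev)
        if ev.ar is not None and ev.as_ == "end":
            spans = open_by_label.get(ev.ar, [])
            if not spans:
                warnings.warn(
                    f"'end' marker for {ev.ar!r} with no open activity "
                    f"(line {ev.line}); skipped",
                    stacklevel=2,
                )
                continue
            span = spans.pop(0)  # FIFO: earliest open instance closes first
            if not spans:
                del open_by_label[ev.ar]
            done.append((begin_order[id(span)], span, ev.ar))

    for label, spans in open_by_label.items():
        for _ in spans:
            warnings.warn(
                f"activity {label!r} still open at end of stream; incomplete "
                "instance skipped",
                stacklevel=2,
            )

    done.sort(key=lambda item: item[0])
    return [
        ActivityInstance(
            bt=span[0].t.hour,
            et=span[-1].t.hour,
            sq=tuple(ev.s for ev in span),
            label=label,
        )
        for _, span, label in done
    ]
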