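"""Sensor-importance table (SIA) and sequence de-noising.

In a two-resident home, the sensor sequence of one resident's activity is
polluted by events the co-resident triggers inside its time span.  The
de-noising step exploits a regularity: across the activities that *begin*
with a given sensor, the sensors genuinely belonging to the activity
recur in almost every instance, while interference sensors appear only
sporadically.

The SIA records, for each start sensor s0, the fraction of s0-initiated
activities in which each sensor occurs at least once (its *importance*).
De-noising then drops consecutive duplicate sensors and any sensor whose
importance does not exceed a threshold ``w``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from duoact.casas_io import ActivityInstance

__all__ = ["SIA", "DenoiseConfig", "build_sia", "denoise"]


@dataclass(frozen=True)
class SIA:
    """Two-level sensor-importance table.

    ``table[s0][s]`` is the fraction of training activities starting with
    sensor ``s0`` in which sensor ``s`` occurs at least once — a value in
    (0, 1]; sensors never co-occurring are simply absent (importance 0).
    ``fre[s0]`` counts the activities starting with ``s0``.
    """

    table: Mapping[str, Mapping[str, float]]
    fre: Mapping[str, int]

    def importance(self, start_sensor: str, sensor: str) -> float:
        """Importance of ``sensor`` among activities starting with ``start_sensor``."""
        return self.table.get(start_sensor, {}).get(sensor, 0.0)

    def to_json(self, **kwargs) -> str:
        """Serialize to a two-level JSON object for inspection."""
        payload = {
            "importance": {s0: dict(sorted(inner.items())) for s0, inner in self.table.items()},
            "frequency": dict(self.fre),
        }
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SIA":
        payload = json.loads(text)
        return cls(table=payload["importance"], fre=payload["frequency"])


@dataclass(frozen=True)
class DenoiseConfig:
    """De-noising parameters.

    Parameters
    ----------
    w : float
        Importance threshold in [0, 1): a sensor survives only if its
        importance is strictly greater than ``w``.  The default 0.25 sits
        below the smallest importance a sensor can have when it appears
        in half of a two-instance training class (0.5), so genuinely
        recurrent sensors survive while sporadic interference does not.
    dedup : {"consecutive", "global"}
        ``"consecutive"`` (default) removes an element equal to its
        immediately preceding kept element; ``"global"`` keeps only the
        first occurrence of each sensor.
    """

    w: float = 0.25
    dedup: Literal["consecutive", "global"] = "consecutive"

    def __post_init__(self) -> None:
        if not (0.0 <= self.w < 1.0):
            raise ValueError(f"threshold w must lie in [0, 1), got {self.w}")
        if self.dedup not in ("consecutive", "global"):
            raise ValueError(f"dedup must be 'consecutive' or 'global', got {self.dedup!r}")


def build_sia(sequences: Iterable[Sequence[str]]) -> SIA:
    """Build the sensor-importance table from training sensor sequences.

    For each start sensor s0 (first element of a sequence),
    ``importance[s0][s]`` = (number of s0-initiated sequences containing
    s at least once) / (number of s0-initiated sequences).

    Raises
    ------
    ValueError
        If any input sequence is empty.
    """
    presence: dict[str, dict[str, int]] = {}
    fre: dict[str, int] = {}
    for i, sq in enumerate(sequences):
        if len(sq) == 0:
            raise ValueError(f"sequence #{i} is empty; every sequence must be non-empty")
        s0 = sq[0]
        fre[s0] = fre.get(s0, 0) + 1
        counts = presence.setdefault(s0, {})
        for s in set(sq):
            counts[s] = counts.get(s, 0) + 1
    table = {
        s0: {s: cnt / fre[s0] for s, cnt in counts.items()}
        for s0, counts in presence.items()
    }
    return SIA(table=table, fre=fre)


def denoise(
    activity: ActivityInstance,
    sia: SIA,
    cfg: DenoiseConfig | None = None,
) -> ActivityInstance:
    """De-noise one activity's sensor sequence.

    A single in-order pass applies two rules jointly: an element is
    dropped if it equals the previously *kept* element (consecutive
    duplicate) or if its importance under the sequence's original start
    sensor is ≤ ``cfg.w``.  The start sensor itself always survives (its
    importance is 1 by construction); if filtering would empty the
    sequence, the original first element is retained.

    Begin/end hours and the label are unchanged.  A start sensor unseen
    in training yields a warning and importance 0 for every other
    element.
    """
    if cfg is None:
        cfg = DenoiseConfig()
    s0 = activity.sq[0]
    if s0 not in sia.table:
        warnings.warn(
            f"start sensor {s0!r} unseen in training SIA; treating all other "
            "sensors as importance 0",
            stacklevel=2,
        )
    row = sia.table.get(s0, {s0: 1.0})
    kept: list[str] = []
    seen: set[str] = set()
    for idx, s in enumerate(activity.sq):
        if idx == 0:
            kept.append(s)
            seen.add(s)
            continue
        if cfg.dedup == "consecutive":
            if kept and s == kept[-1]:
                continue
        else:
            if s in seen:
                continue
        if row.get(s, 0.0) > cfg.w:
            kept.append(s)
            seen.add(s)
    if not kept:  # unreachable with the always-kept start sensor; kept as a guard
        kept = [s0]
    return activity.with_sq(kept)
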