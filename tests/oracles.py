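"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately naive (memoised recursion, direct counting,
explicit interval membership) and shares no code with the library paths
it checks.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence


def edit_distance_recursive(
    sq1: Sequence[str], sq2: Sequence[str], substitution_cost: int = 2
) -> int:
    """Token edit distance by memoised recursion (ins/del 1, sub configurable)."""
    a, b = tuple(sq1), tuple(sq2)

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1)
        sub = d(i - 1, j - 1) + (0 if a[i - 1] == b[j - 1] else substitution_cost)
        return min(best, sub)

    return d(len(a), len(b))


def sia_by_counting(sequences: Sequence[Sequence[str]]) -> dict[str, dict[str, float]]:
    """Presence-count/divide construction of the sensor-importance table."""
    groups: dict[str, list[Sequence[str]]] = {}
    for sq in sequences:
        groups.setdefault(sq[0], []).append(sq)
    table: dict[str, dict[str, float]] = {}
    for s0, sqs in groups.items():
        sensors = {s for sq in sqs for s in sq}
        table[s0] = {
            s: sum(1 for sq in sqs if s in sq) / len(sqs) for s in sensors
        }
    return table


def denoise_by_rules(
    sq: Sequence[str], importance_row: dict[str, float], w: float
) -> list[str]:
    """Importance filter first, then consecutive-duplicate collapse."""
    filtered = [sq[0]] + [s for s in sq[1:] if importance_row.get(s, 0.0) > w]
    out: list[str] = []
    for s in filtered:
        if out and out[-1] == s:
            continue
        out.append(s)
    return out


def assign_events_to_intervals(
    events: Sequence[tuple[int, str | None, str | None]],
) -> dict[int, set[int]]:
    """Map event position -> set of open-activity instance ids.

    ``events`` is (position, activity-or-None, marker-or-None); instances
    are numbered in begin order.  Membership is inclusive of the begin
    and end events themselves.
    """
    open_ids: dict[str, list[int]] = {}
    member: dict[int, set[int]] = {}
    next_id = 0
    for pos, ar, marker in events:
        if ar is not None and marker == "begin":
            open_ids.setdefault(ar, []).append(next_id)
            next_id += 1
        member[pos] = {i for ids in open_ids.values() for i in ids}
        if ar is not None and marker == "end":
            open_ids[ar].pop(0)
            if not open_ids[ar]:
                del open_ids[ar]
    return member
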