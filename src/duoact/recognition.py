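"""Similarity scoring and top-n voting for activity recognition.

A test activity is compared to the training activities of its time
cluster with a hybrid similarity

    ratio = w1·(24 − |a.bt − t.bt|)/24
          + w1·(24 − |a.et − t.et|)/24
          + w2·LevRatio(a.sq, t.sq)

where the weights satisfy 2·w1 + w2 = 1 (so identical instances score
exactly 1) and 2·w1 ≤ w2 (the sensor sequence dominates).  LevRatio is
the normalised Levenshtein similarity

    LevRatio(sq1, sq2) = (|sq1| + |sq2| − ldist) / (|sq1| + |sq2|)

over whole sensor-ID tokens, with ldist the edit distance in which
insertions and deletions cost 1 and substitutions cost 2 — the one cost
convention under which the ratio is bounded in [0, 1] (it then equals the
fraction of tokens matched by a longest common subsequence, counted over
both sequences).

The label of the test activity is the majority vote of its top-n most
similar cluster mates; ties are broken by summed similarity, then by
lexicographic label order, so predictions are fully deterministic.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Literal, Sequence

from duoact.casas_io import ActivityInstance
from duoact.clustering import ClusterModel

__all__ = [
    "RecognitionConfig",
    "levenshtein_ratio",
    "similarity",
    "rank_neighbors",
    "recognize",
]

_EPS = 1e-9


@dataclass(frozen=True)
class RecognitionConfig:
    """Weights and vote count for similarity matching.

    ``w1`` weighs each of the two time terms (begin and end hour), ``w2``
    the sequence term; they must satisfy 2·w1 + w2 = 1 and 2·w1 ≤ w2.
    ``n`` is the number of nearest training instances that vote, and
    should stay below the number of activity classes.  Defaults
    w1 = 0.15, w2 = 0.7, n = 5.
    """

    w1: float = 0.15
    w2: float = 0.7
    n: int = 5
    substitution_cost: Literal[1, 2] = 2

    def __post_init__(self) -> None:
        if abs(2 * self.w1 + self.w2 - 1.0) > _EPS:
            raise ValueError(f"weights must satisfy 2*w1 + w2 = 1, got w1={self.w1}, w2={self.w2}")
        if 2 * self.w1 > self.w2 + _EPS:
            raise ValueError(f"weights must satisfy 2*w1 <= w2, got w1={self.w1}, w2={self.w2}")
        if self.n < 1:
            raise ValueError(f"vote count n must be >= 1, got {self.n}")
        if self.substitution_cost not in (1, 2):
            raise ValueError("substitution_cost must be 1 or 2")


def levenshtein_ratio(
    sq1: Sequence[str],
    sq2: Sequence[str],
    substitution_cost: int = 2,
) -> float:
    """Normalised token-level Levenshtein similarity in [0, 1].

    ``(|sq1| + |sq2| - ldist) / (|sq1| + |sq2|)`` with insertions and
    deletions costing 1 and substitutions ``substitution_cost``
    (default 2).  Tokens are whole sensor IDs, so "M004" and "M005" are
    simply unequal rather than partially matching characters.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if len(sq1) == 0 or len(sq2) == 0:
        raise ValueError("sequences must be non-empty")
    m, n = len(sq1), len(sq2)
    # single-row DP over tokens
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        a = sq1[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (0 if a == sq2[j - 1] else substitution_cost)
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, sub)
        prev = cur
    ldist = prev[n]
    total = m + n
    return (total - ldist) / total


def similarity(
    a: ActivityInstance,
    t: ActivityInstance,
    cfg: RecognitionConfig | None = None,
) -> float:
    """Hybrid time + sequence similarity between two activities.

    Symmetric, and bounded in [0, 1] whenever the config invariants hold;
    equals 1 exactly when the two instances share bt, et and sq.
    """
    if cfg is None:
        cfg = RecognitionConfig()
    time_term = (
        cfg.w1 * (24 - abs(a.bt - t.bt)) / 24
        + cfg.w1 * (24 - abs(a.et - t.et)) / 24
    )
    seq_term = cfg.w2 * levenshtein_ratio(a.sq, t.sq, cfg.substitution_cost)
    return time_term + seq_term


def rank_neighbors(
    train: Sequence[tuple[ActivityInstance, int]],
    model: ClusterModel,
    t: ActivityInstance,
    cfg: RecognitionConfig | None = None,
) -> list[tuple[ActivityInstance, float]]:
    """Training instances of t's time cluster, ranked by similarity (descending).

    Falls back to ranking over the whole training set, with a warning,
    when the predicted cluster holds no training instance.  Ranking ties
    are broken by label then sequence for determinism.
    """
    if cfg is None:
        cfg = RecognitionConfig()
    cluster = model.predict((t.bt, t.et))
    members = [a for a, c in train if c == cluster]
    if not members:
        warnings.warn(
            f"time cluster {cluster} holds no training instance; ranking over "
            "the full training set",
            stacklevel=2,
        )
        members = [a for a, _ in train]
    scored = [(a, similarity(a, t, cfg)) for a in members]
    scored.sort(key=lambda item: (-item[1], item[0].label, item[0].sq))
    return scored


def recognize(
    train: Sequence[tuple[ActivityInstance, int]],
    model: ClusterModel,
    t: ActivityInstance,
    cfg: RecognitionConfig | None = None,
) -> str:
    """Predict the label of ``t`` by top-n similarity voting in its time cluster.

    The majority label among the ``cfg.n`` most similar cluster mates
    wins; a vote tie goes to the label with the greater summed
    similarity, then to the lexicographically smaller label.  If the
    cluster holds fewer than n instances, all of them vote.
    """
    if cfg is None:
        cfg = RecognitionConfig()
    scored = rank_neighbors(train, model, t, cfg)
    top = scored[: cfg.n]
    votes: dict[str, int] = defaultdict(int)
    summed: dict[str, float] = defaultdict(float)
    for a, r in top:
        votes[a.label] += 1
        summed[a.label] += r
    return min(votes, key=lambda lb: (-votes[lb], -summed[lb], lb))
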