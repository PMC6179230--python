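"""Collaboration networks extracted from chat logs.

Each team becomes a directed weighted graph over its members.  The weight of
edge (i, j) — read "j responds to i" — accumulates time-decayed evidence over
all message pairs (p, q) where p is sent by i, q by j, and q falls in p's
response window:

    w_ij = sum over such pairs of exp(-rho * (q.time - p.time))

with decay rate rho (default 0.15 /s).  Zero-weight ordered pairs are absent
edges, not stored.  From the dense weighted network W we also derive sparse
unweighted networks by dropping a fraction of the lowest-weight edges (25%,
50% and 75% in the original analysis) and discarding the remaining weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import ChatLog
from .responses import DEFAULT_WINDOW, ResponseWindow, is_response_pair

__all__ = [
    "DEFAULT_DECAY_RATE",
    "CollaborationNetwork",
    "SparseNetwork",
    "build_weighted",
    "build_count_weighted",
    "sparsify",
]

DEFAULT_DECAY_RATE = 0.15  # per second


@dataclass
class CollaborationNetwork:
    """Directed weighted graph; ``weights[(i, j)]`` means j responds to i."""

    members: tuple[str, ...]
    weights: dict[tuple[str, str], float]
    decay_rate: float | None = DEFAULT_DECAY_RATE  # None for the count variant

    def __post_init__(self) -> None:
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError(f"self-loop on {i!r}")
            if not (math.isfinite(w) and w >= 0):
                raise ValueError(f"edge ({i}, {j}) has invalid weight {w}")
        member_set = set(self.members)
        for i, j in self.weights:
            if i not in member_set or j not in member_set:
                raise ValueError(f"edge ({i}, {j}) references unknown member")

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def weight(self, i: str, j: str) -> float:
        return self.weights.get((i, j), 0.0)


@dataclass
class SparseNetwork:
    """Unweighted directed graph obtained by thresholding a weighted network."""

    members: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    drop_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must lie in [0, 1)")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, i: str, j: str) -> float:
        return 1.0 if (i, j) in self.edges else 0.0


def _accumulate(log: ChatLog, window: ResponseWindow, term) -> dict[tuple[str, str], float]:
    weights: dict[tuple[str, str], float] = {}
    msgs = log.messages
    n = len(msgs)
    for a in range(n):
        p = msgs[a]
        for b in range(a + 1, n):
            q = msgs[b]
            if q.time - p.time > window.t2:
                break  # messages sorted: later ones are farther away
            if is_response_pair(p, q, window):
                key = (p.sender, q.sender)
                weights[key] = weights.get(key, 0.0) + term(q.time - p.time)
    return weights


def build_weighted(
    log: ChatLog,
    window: ResponseWindow = DEFAULT_WINDOW,
    rho: float = DEFAULT_DECAY_RATE,
) -> CollaborationNetwork:
    """Build the dense weighted collaboration network from a chat log.

    Members who never exchange qualifying message pairs have no incident
    edges.  Time-translation invariant: shifting all timestamps by a constant
    leaves the network unchanged.
    """
    if rho <= 0:
        raise ValueError("decay rate rho must be > 0")
    weights = _accumulate(log, window, lambda dt: math.exp(-rho * dt))
    return CollaborationNetwork(
        members=tuple(sorted(log.members)), weights=weights, decay_rate=rho
    )


def build_count_weighted(
    log: ChatLog, window: ResponseWindow = DEFAULT_WINDOW
) -> CollaborationNetwork:
    """Response-count variant: each qualifying pair contributes 1 instead of
    a decayed term.  Kept as a comparison baseline; the decayed weights give
    better predictive models downstream."""
    weights = _accumulate(log, window, lambda dt: 1.0)
    return CollaborationNetwork(
        members=tuple(sorted(log.members)), weights=weights, decay_rate=None
    )


def sparsify(network: CollaborationNetwork, drop_fraction: float) -> SparseNetwork:
    """Drop the floor(drop_fraction * |E|) lowest-weight edges, then weights.

    Ties are broken deterministically by sorting on (weight, source, target),
    which makes nested fractions produce nested edge sets:
    edges(S_75) ⊆ edges(S_50) ⊆ edges(S_25) ⊆ edges(W).
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    ranked = sorted(network.weights.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))
    n_drop = math.floor(drop_fraction * len(ranked))
    kept = frozenset(edge for edge, _ in ranked[n_drop:])
    return SparseNetwork(members=network.members, edges=kept, drop_fraction=drop_fraction)
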