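"""Efficiency, rivalry and friendly-rival classification of strategies.

Efficiency (self-cooperation): a strategy is efficient if mutual play of it
recovers full cooperation as the error rate vanishes.  Numerically we judge
the stationary self-cooperation level at ``e = 1e-4`` against a threshold of
0.99; the decision is insensitive to the threshold because self-cooperation
levels cluster either near 1 or well below it.

Rivalry (defensibility): a strategy is a rival if no co-player can obtain a
strictly higher long-term payoff at zero error, for any co-player strategy
and any initial state.  This is decided on a weighted directed graph over
the full-memory joint states: the focal player's move is fixed by its table,
the co-player's move is free, giving two outgoing edges per node.  Edge
weights carry the sign of the per-round payoff difference (focal minus
co-player): 0 when the new moves coincide, -1 when the focal player alone
cooperates, +1 when the co-player alone cooperates.  Only cycles contribute
to long-term payoffs, so the strategy is a rival iff the graph has no cycle
of negative total weight, which Floyd-Warshall detects via a negative
diagonal entry of the all-pairs shortest-path matrix.  The sign-preserving
weights make the verdict independent of the benefit ``b``.

A friendly rival (FR) is a strategy that is both efficient and a rival.
Batched (numpy-vectorized) versions of both tests are provided for census
work over tens of thousands of tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .payoff import GameParams, stationary, _geometry
from .strategy import Strategy, lift

__all__ = [
    "ClassLabel",
    "EFFICIENCY_ERROR_RATE",
    "EFFICIENCY_THRESHOLD",
    "is_efficient",
    "is_rival",
    "is_friendly_rival",
    "label",
    "rivalry_graph",
    "batch_self_cooperation",
    "batch_is_rival",
    "classify_tables",
]

EFFICIENCY_ERROR_RATE = 1e-4
EFFICIENCY_THRESHOLD = 0.99

_INF = 1e18

LABELS = ("FR", "non-FR efficient", "non-FR rival", "other")


@dataclass(frozen=True)
class ClassLabel:
    """Reporting category of a strategy: FR / non-FR efficient / non-FR rival / other."""

    efficient: bool
    rival: bool

    @property
    def label(self) -> str:
        if self.efficient and self.rival:
            return "FR"
        if self.efficient:
            return "non-FR efficient"
        if self.rival:
            return "non-FR rival"
        return "other"


def self_cooperation(s: Strategy, e: float = EFFICIENCY_ERROR_RATE) -> float:
    """Stationary self-play cooperation level ``gamma_pp`` at error rate ``e``."""
    return stationary(s, s, GameParams(b=2.0, e=e)).gamma_pq


def is_efficient(s: Strategy, threshold: float = EFFICIENCY_THRESHOLD) -> bool:
    """Self-cooperation at ``e = 1e-4`` above ``threshold`` (default 0.99)."""
    return self_cooperation(s) > threshold


def rivalry_graph(s: Strategy) -> np.ndarray:
    """Dense weight matrix of the rivalry graph (``_INF`` marks no edge).

    Nodes are the ``4**m`` joint states at the strategy's symmetric depth
    ``m = max(1, ma, mb)``; every node, including those unreachable from
    mutual cooperation, is kept because rivalry must hold from any initial
    state.
    """
    m = max(1, s.ma, s.mb)
    n, _, succ, _, _, _, _, _ = _geometry(m)
    acts = lift(s, m).state_table(m)
    rows = np.arange(n)
    W = np.full((n, n), _INF)
    for bb in (0, 1):
        tgt = np.where(acts == 1, succ[(1, bb)], succ[(0, bb)])
        # weight: focal C & co D -> -1 ; focal D & co C -> +1 ; tie -> 0
        w = np.where(acts == bb, 0.0, np.where(acts == 1, -1.0, 1.0))
        W[rows, tgt] = np.minimum(W[rows, tgt], w)
    return W


def _has_negative_cycle(W: np.ndarray) -> bool:
    """Floyd-Warshall negative-cycle check on a dense weight matrix."""
    d = W.copy()
    n = d.shape[0]
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
        if (np.diagonal(d) < 0).any():
            return True
    return False


def is_rival(s: Strategy) -> bool:
    """True iff the rivalry graph at zero error has no negative cycle."""
    return not _has_negative_cycle(rivalry_graph(s))


def is_friendly_rival(s: Strategy) -> bool:
    """Efficient and rival simultaneously."""
    return is_efficient(s) and is_rival(s)


@lru_cache(maxsize=None)
def _label_cached(key: tuple[int, int, int]) -> ClassLabel:
    s = Strategy(*key)
    return ClassLabel(efficient=is_efficient(s), rival=is_rival(s))


def label(s: Strategy) -> ClassLabel:
    """Classification of a strategy, memoized by canonical encoding."""
    return _label_cached(s.key)


# ---------------------------------------------------------------------------
# Batched classification over arrays of table bits (one shape at a time)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _shape_geometry(ma: int, mb: int):
    """State-space index maps for tables of shape ``(ma, mb)``."""
    m = max(1, ma, mb)
    n, swap, succ, coop_p, _, _, _, _ = _geometry(m)
    s = np.arange(n)
    a = (s >> m) & ((1 << ma) - 1)
    b = s & ((1 << mb) - 1)
    hidx = (a << mb) | b  # state -> history-profile index of the focal table
    return m, n, swap, succ, coop_p, hidx


def _state_actions(tables: np.ndarray, ma: int, mb: int) -> np.ndarray:
    """(B, n_states) uint8 action array for a batch of table bits."""
    _, _, _, _, _, hidx = _shape_geometry(ma, mb)
    t = np.asarray(tables, dtype=np.uint64)
    return ((t[:, None] >> hidx[None, :].astype(np.uint64)) & np.uint64(1)).astype(
        np.uint8
    )


def batch_self_cooperation(
    tables: np.ndarray,
    ma: int,
    mb: int,
    e: float = EFFICIENCY_ERROR_RATE,
    chunk: int = 4096,
) -> np.ndarray:
    """Self-play cooperation levels for a batch of same-shape tables.

    Builds the self-pair transition matrices for all tables at once and
    solves the stationary systems with one batched dense solve per chunk.
    """
    _, n, swap, succ, coop_p, _ = _shape_geometry(ma, mb)
    tables = np.asarray(tables, dtype=np.uint64)
    out = np.empty(len(tables))
    rows = np.arange(n)
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    for lo in range(0, len(tables), chunk):
        acts = _state_actions(tables[lo : lo + chunk], ma, mb).astype(float)
        pe = (1.0 - e) * acts + e * (1.0 - acts)
        qe = pe[:, swap]
        T = np.zeros((acts.shape[0], n, n))
        bidx = np.arange(acts.shape[0])[:, None]
        T[bidx, rows, succ[(1, 1)]] = pe * qe
        T[bidx, rows, succ[(1, 0)]] = pe * (1.0 - qe)
        T[bidx, rows, succ[(0, 1)]] = (1.0 - pe) * qe
        T[bidx, rows, succ[(0, 0)]] = (1.0 - pe) * (1.0 - qe)
        A = T.transpose(0, 2, 1) - np.eye(n)
        A[:, -1, :] = 1.0
        v = np.linalg.solve(A, np.broadcast_to(rhs[:, None], (acts.shape[0], n, 1)))
        out[lo : lo + chunk] = v[:, coop_p, 0].sum(axis=1)
    return out


def batch_is_rival(
    tables: np.ndarray, ma: int, mb: int, chunk: int = 4096
) -> np.ndarray:
    """Rivalry verdicts for a batch of same-shape tables (vectorized FW)."""
    _, n, _, succ, _, _ = _shape_geometry(ma, mb)
    tables = np.asarray(tables, dtype=np.uint64)
    out = np.empty(len(tables), dtype=bool)
    rows = np.arange(n)
    for lo in range(0, len(tables), chunk):
        acts = _state_actions(tables[lo : lo + chunk], ma, mb)
        B = acts.shape[0]
        d = np.full((B, n, n), _INF)
        bidx = np.arange(B)[:, None]
        for bb in (0, 1):
            # the two co-player moves lead to distinct targets, so plain
            # scatter assignment is safe
            tgt = np.where(acts == 1, succ[(1, bb)], succ[(0, bb)])
            w = np.where(acts == bb, 0.0, np.where(acts == 1, -1.0, 1.0))
            d[bidx, rows, tgt] = w
        for k in range(n):
            np.minimum(d, d[:, :, k, None] + d[:, k, None, :], out=d)
        neg = (np.diagonal(d, axis1=1, axis2=2) < 0).any(axis=1)
        out[lo : lo + chunk] = ~neg
    return out


def classify_tables(
    tables: np.ndarray, ma: int, mb: int, chunk: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """``(efficient, rival)`` boolean arrays for a batch of same-shape tables."""
    gamma = batch_self_cooperation(tables, ma, mb, chunk=chunk)
    eff = gamma > EFFICIENCY_THRESHOLD
    riv = batch_is_rival(tables, ma, mb, chunk=chunk)
    return eff, riv
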