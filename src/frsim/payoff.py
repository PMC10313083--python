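"""Long-term payoffs of a strategy pair in the repeated donation game.

With implementation error rate ``e`` each intended action is flipped
independently with probability ``e``, so a pure table ``p`` is effectively
played as ``(1 - e) p + e (1 - p)``.  When both players have finite memory
the sequence of rounds is a Markov chain over joint states
``s = (a << m) | b`` (focal player's last ``m`` moves ``a`` in the high
bits, co-player's ``b`` in the low bits, most recent move in bit 0).  For
``e > 0`` the chain is ergodic and has a unique stationary distribution
``v``; the cooperation level of the focal player is the stationary
probability that its most recent move is C, and the long-term payoff is

    pi_pq = b * gamma_qp - c * gamma_pq

with benefit ``b`` and cost ``c = 1``.  The state dimension is at most
``4**3 = 64``, so the stationary distribution is obtained by a dense linear
solve of ``v T = v`` with one equation replaced by the normalization.

:class:`PayoffCache` memoizes the scalar results per strategy pair; this is
what the evolution loops use, since the same resident pairs recur many
times while transient mutants are evaluated once and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .strategy import Strategy

__all__ = [
    "GameParams",
    "PairResult",
    "effective_strategy",
    "transition_matrix",
    "stationary",
    "payoff_matrix_entries",
    "PayoffCache",
]


@dataclass(frozen=True)
class GameParams:
    """Donation-game parameters: benefit ``b > 1``, cost 1, error rate ``e``."""

    b: float
    e: float
    c: float = 1.0

    def __post_init__(self):
        if not self.b > 1.0:
            raise ValueError(f"benefit b must exceed the unit cost, got b={self.b}")
        if not 0.0 < self.e < 0.5:
            raise ValueError(f"error rate must satisfy 0 < e < 0.5, got e={self.e}")


@dataclass
class PairResult:
    """Stationary outcome of one strategy pair.

    ``gamma_pq`` / ``gamma_qp`` are the two players' cooperation levels,
    ``pi_pq`` / ``pi_qp`` their long-term payoffs, and ``v`` the stationary
    distribution over joint states (first player's history in the high bits).
    """

    gamma_pq: float
    gamma_qp: float
    pi_pq: float
    pi_qp: float
    v: np.ndarray = field(repr=False)


@lru_cache(maxsize=8)
def _geometry(m: int):
    """Index arrays for the depth-``m`` joint state space (cached per m)."""
    n1 = 1 << m
    n = n1 * n1
    mask = n1 - 1
    s = np.arange(n)
    a = s >> m
    b = s & mask
    swap = (b << m) | a  # the co-player sees (its own history, focal history)
    succ = {}
    for aa in (0, 1):
        for bb in (0, 1):
            a2 = ((a << 1) & mask) | aa
            b2 = ((b << 1) & mask) | bb
            succ[(aa, bb)] = (a2 << m) | b2
    coop_p = (a & 1) == 1  # states whose most recent focal move is C
    coop_q = (b & 1) == 1
    rows = s
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    eye = np.eye(n)
    return n, swap, succ, coop_p, coop_q, rows, rhs, eye


def common_depth(p: Strategy, q: Strategy) -> int:
    """Smallest symmetric state depth accommodating both tables (>= 1)."""
    return max(1, p.ma, p.mb, q.ma, q.mb)


def effective_strategy(s: Strategy, e: float) -> np.ndarray:
    """Per-history cooperation probabilities ``(1 - e) p + e (1 - p)``."""
    if not 0.0 <= e < 1.0:
        raise ValueError(f"error rate must satisfy 0 <= e < 1, got {e}")
    p = s.actions().astype(float)
    return (1.0 - e) * p + e * (1.0 - p)


def _effective_states(s: Strategy, m: int, e: float) -> np.ndarray:
    """Effective cooperation probabilities on the depth-``m`` state space."""
    p = s.state_table(m).astype(float)
    return (1.0 - e) * p + e * (1.0 - p)


def _build_T(pe: np.ndarray, qe: np.ndarray, m: int) -> np.ndarray:
    """Transition matrix from the two players' effective cooperation vectors.

    ``qe`` must already be index-swapped to the focal player's state order.
    """
    n, _, succ, _, _, rows, _, _ = _geometry(m)
    T = np.zeros((n, n))
    T[rows, succ[(1, 1)]] = pe * qe
    T[rows, succ[(1, 0)]] = pe * (1.0 - qe)
    T[rows, succ[(0, 1)]] = (1.0 - pe) * qe
    T[rows, succ[(0, 0)]] = (1.0 - pe) * (1.0 - qe)
    return T


def _solve_v(T: np.ndarray, m: int) -> np.ndarray:
    """Solve ``v T = v``, ``sum(v) = 1`` by a dense linear solve."""
    n, _, _, _, _, _, rhs, eye = _geometry(m)
    A = T.T - eye
    A[-1, :] = 1.0
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - e > 0 is ergodic
        raise np.linalg.LinAlgError(
            f"singular pair chain (n={n}); stationary distribution requires e > 0"
        ) from exc


def _pair_gammas(pe: np.ndarray, qe_swapped: np.ndarray, m: int):
    """Cooperation levels ``(gamma_pq, gamma_qp)`` of a pair, fast path."""
    _, _, _, coop_p, coop_q, _, _, _ = _geometry(m)
    v = _solve_v(_build_T(pe, qe_swapped, m), m)
    return float(v[coop_p].sum()), float(v[coop_q].sum())


def transition_matrix(p: Strategy, q: Strategy, e: float) -> np.ndarray:
    """Row-stochastic transition matrix of the pair chain at error rate ``e``.

    Both tables are read on the common symmetric state space; ``q`` sees the
    state with the two history halves swapped.  An entry is zero unless the
    target state's older history equals the source state's history shifted
    by one round.
    """
    m = common_depth(p, q)
    _, swap, _, _, _, _, _, _ = _geometry(m)
    pe = _effective_states(p, m, e)
    qe = _effective_states(q, m, e)[swap]
    return _build_T(pe, qe, m)


def stationary(p: Strategy, q: Strategy, params: GameParams) -> PairResult:
    """Stationary distribution, cooperation levels and payoffs of a pair.

    Requires ``e > 0`` so the chain is ergodic and the stationary
    distribution unique (Perron-Frobenius).
    """
    m = common_depth(p, q)
    _, swap, _, coop_p, coop_q, _, _, _ = _geometry(m)
    pe = _effective_states(p, m, params.e)
    qe = _effective_states(q, m, params.e)[swap]
    v = _solve_v(_build_T(pe, qe, m), m)
    gamma_pq = float(v[coop_p].sum())
    gamma_qp = float(v[coop_q].sum())
    pi_pq = params.b * gamma_qp - params.c * gamma_pq
    pi_qp = params.b * gamma_pq - params.c * gamma_qp
    return PairResult(gamma_pq, gamma_qp, pi_pq, pi_qp, v)


def payoff_matrix_entries(
    p: Strategy, q: Strategy, params: GameParams, cache: "PayoffCache | None" = None
) -> tuple[float, float, float, float]:
    """The four long-term payoffs ``(pi_pp, pi_pq, pi_qp, pi_qq)``.

    These are exactly the quantities the fixation-probability formula
    consumes.  Pass a :class:`PayoffCache` to memoize across repeated pairs.
    """
    if cache is None:
        cache = PayoffCache(params)
    return cache.entries(p, q)


class PayoffCache:
    """Scalar payoff memoization keyed by canonical strategy encoding.

    ``self_payoff`` and ``cross`` persist their results (the resident set of
    an evolution run is small and recurs constantly), while
    ``mutant_entries`` computes a transient mutant's payoffs without storing
    anything for it.
    """

    def __init__(self, params: GameParams):
        self.params = params
        self._pe: dict = {}  # (key, m) -> effective cooperation vector
        self._self: dict = {}  # key -> (gamma_pp, pi_pp)
        self._pair: dict = {}  # (key_p, key_q) -> (pi_pq, pi_qp)

    def _pe_cached(self, s: Strategy, m: int) -> np.ndarray:
        k = (s.key, m)
        pe = self._pe.get(k)
        if pe is None:
            pe = _effective_states(s, m, self.params.e)
            self._pe[k] = pe
        return pe

    def self_payoff(self, s: Strategy) -> tuple[float, float]:
        """``(gamma_pp, pi_pp)`` of a strategy against itself (cached)."""
        k = s.key
        r = self._self.get(k)
        if r is None:
            m = max(1, s.ma, s.mb)
            _, swap, _, _, _, _, _, _ = _geometry(m)
            pe = self._pe_cached(s, m)
            g_pq, g_qp = _pair_gammas(pe, pe[swap], m)
            r = (g_pq, self.params.b * g_qp - self.params.c * g_pq)
            self._self[k] = r
        return r

    def cross(self, p: Strategy, q: Strategy) -> tuple[float, float]:
        """``(pi_pq, pi_qp)`` for an ordered pair (cached both ways)."""
        kp, kq = p.key, q.key
        if kp == kq:
            pi = self.self_payoff(p)[1]
            return pi, pi
        r = self._pair.get((kp, kq))
        if r is None:
            m = common_depth(p, q)
            _, swap, _, _, _, _, _, _ = _geometry(m)
            g_pq, g_qp = _pair_gammas(
                self._pe_cached(p, m), self._pe_cached(q, m)[swap], m
            )
            b, c = self.params.b, self.params.c
            r = (b * g_qp - c * g_pq, b * g_pq - c * g_qp)
            self._pair[(kp, kq)] = r
            self._pair[(kq, kp)] = (r[1], r[0])
        return r

    def entries(self, p: Strategy, q: Strategy) -> tuple[float, float, float, float]:
        """``(pi_pp, pi_pq, pi_qp, pi_qq)``, all cached."""
        pi_pq, pi_qp = self.cross(p, q)
        return self.self_payoff(p)[1], pi_pq, pi_qp, self.self_payoff(q)[1]

    def mutant_entries(
        self, x: Strategy, y: Strategy
    ) -> tuple[float, float, float, float]:
        """``(pi_xx, pi_xy, pi_yx, pi_yy)`` caching only the resident ``x``."""
        kx, ky = x.key, y.key
        if kx == ky:
            pi = self.self_payoff(x)[1]
            return pi, pi, pi, pi
        b, c, e = self.params.b, self.params.c, self.params.e
        m = common_depth(x, y)
        _, swap, _, _, _, _, _, _ = _geometry(m)
        pe_x = self._pe_cached(x, m)
        qe = _effective_states(y, m, e)
        g_xy, g_yx = _pair_gammas(pe_x, qe[swap], m)
        my = max(1, y.ma, y.mb)
        if my == m:
            pe_y = qe
        else:
            pe_y = _effective_states(y, my, e)
        _, swap_y, _, _, _, _, _, _ = _geometry(my)
        g_y1, g_y2 = _pair_gammas(pe_y, pe_y[swap_y], my)
        pi_yy = b * g_y2 - c * g_y1
        return (
            self.self_payoff(x)[1],
            b * g_yx - c * g_xy,
            b * g_xy - c * g_yx,
            pi_yy,
        )
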