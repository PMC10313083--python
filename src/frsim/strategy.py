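"""Deterministic memory-(m1, m2) strategies for the iterated donation game.

A strategy prescribes Cooperate or Defect as a function of the joint history
of the last few rounds: its own moves over the previous ``ma`` rounds and the
co-player's moves over the previous ``mb`` rounds.  With both depths bounded
by 3 the prescription is a finite lookup table, which we store bit-packed in
a single Python integer.

Encoding conventions (used everywhere in this package):

* ``C = 1``, ``D = 0``.
* A history profile is indexed by ``h = (own << mb) | co`` -- the player's
  own history occupies the high bits and the co-player's the low bits.
* Within each half, the *most recent* round sits in the lowest bit: bit
  ``t - 1`` of ``own`` is the action the player took ``t`` rounds ago.
* Bit ``h`` of ``Strategy.bits`` is the prescribed action for profile ``h``.

A table of shape ``(ma, mb)`` has ``2**(ma + mb)`` entries.  The *exact*
memory lengths ``(m1, m2)`` of a strategy may be smaller than the table
shape: e.g. Tit-for-Tat written as a memory-one 4-tuple only ever consults
the co-player's last move, so its exact memory is ``(0, 1)``.  Exact lengths
are found by a wildcard cascade: starting from the deepest round, test
whether any pair of profiles differing only in that round's own (resp.
co-player's) action receives different prescriptions; if not, that round is
irrelevant and the table is projected one level shallower before testing the
next round.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "Strategy",
    "MemoryLength",
    "compute_memory_lengths",
    "make_named",
    "memory_one",
    "lift",
    "PRESET_NAMES",
    "InvalidStrategyError",
]

MAX_DEPTH = 3


class InvalidStrategyError(ValueError):
    """Raised when a table is malformed or a name/serialization is unknown."""


@lru_cache(maxsize=64)
def _state_to_history(ma: int, mb: int, m: int) -> "np.ndarray":
    """Map depth-``m`` joint-state indices to shape-(ma, mb) profile indices."""
    s = np.arange(1 << (2 * m))
    a = (s >> m) & ((1 << ma) - 1)
    b = s & ((1 << mb) - 1)
    return (a << mb) | b


class MemoryLength(NamedTuple):
    """Exact memory lengths: own-history depth ``m1``, co-player depth ``m2``."""

    m1: int
    m2: int


class Strategy:
    """A pure strategy as a bit-packed lookup table of shape ``(ma, mb)``.

    Parameters
    ----------
    ma, mb
        Table depths for the player's own and the co-player's history,
        each in ``{0, 1, 2, 3}``.
    bits
        Integer whose bit ``h`` is the action (1 = C) prescribed for history
        profile ``h``; must satisfy ``0 <= bits < 2**(2**(ma + mb))``.

    Equality and hashing are defined on the *canonical* form -- the table
    projected down to its exact memory lengths -- so behaviourally identical
    strategies written at different depths compare equal.
    """

    __slots__ = ("ma", "mb", "bits", "_canon")

    def __init__(self, ma: int, mb: int, bits: int):
        if not (0 <= ma <= MAX_DEPTH and 0 <= mb <= MAX_DEPTH):
            raise InvalidStrategyError(f"table depths out of range: ({ma}, {mb})")
        n = 1 << (ma + mb)
        bits = int(bits)
        if not (0 <= bits < (1 << n)):
            raise InvalidStrategyError(
                f"table bits {bits!r} do not fit a {n}-entry table"
            )
        self.ma = ma
        self.mb = mb
        self.bits = bits
        self._canon = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_actions(cls, ma: int, mb: int, actions) -> "Strategy":
        """Build from a sequence of 0/1 actions indexed by history profile.

        ``actions[h]`` is the prescription for profile ``h``; any entry other
        than 0 or 1 is rejected (only pure strategies are representable).
        """
        n = 1 << (ma + mb)
        arr = np.asarray(list(actions))
        if arr.shape != (n,):
            raise InvalidStrategyError(
                f"expected {n} table entries for shape ({ma}, {mb}), "
                f"got shape {arr.shape}"
            )
        try:
            pure = np.isin(arr, (0, 1, True, False)).all()
        except TypeError:
            pure = False
        if not pure:
            raise InvalidStrategyError(
                "table entries must all be pure actions (0/1); "
                "probabilistic strategies are not representable"
            )
        packed = np.packbits(arr.astype(np.uint8), bitorder="little")
        return cls(ma, mb, int.from_bytes(packed.tobytes(), "little"))

    # -- basic accessors ------------------------------------------------------

    @property
    def n_histories(self) -> int:
        return 1 << (self.ma + self.mb)

    @property
    def m_cap(self) -> int:
        """Symmetric memory capacity: the larger of the two table depths."""
        return max(self.ma, self.mb)

    def action(self, h: int) -> int:
        """Prescribed action (1 = C) for history profile index ``h``."""
        return (self.bits >> h) & 1

    def action_at(self, own: int, co: int) -> int:
        """Prescribed action given own/co history bit patterns."""
        return (self.bits >> ((own << self.mb) | co)) & 1

    def actions(self) -> np.ndarray:
        """Table as a uint8 array indexed by history profile."""
        n = self.n_histories
        raw = self.bits.to_bytes((n + 7) // 8, "little")
        return np.unpackbits(np.frombuffer(raw, dtype=np.uint8), bitorder="little")[:n]

    def state_table(self, m: int) -> np.ndarray:
        """Actions on the symmetric depth-``m`` joint state space.

        State ``s = (a << m) | b`` holds the focal player's last ``m`` moves
        ``a`` (high bits) and the co-player's ``b`` (low bits); the strategy
        reads only the ``(ma, mb)`` most recent moves of each.
        """
        if m < self.ma or m < self.mb:
            raise InvalidStrategyError(
                f"state depth {m} below table shape ({self.ma}, {self.mb})"
            )
        return self.actions()[_state_to_history(self.ma, self.mb, m)]

    # -- canonicalization -----------------------------------------------------

    def memory_lengths(self) -> MemoryLength:
        return MemoryLength(self.canonical().ma, self.canonical().mb)

    def canonical(self) -> "Strategy":
        """The behaviourally identical table at exact memory shape."""
        if self._canon is None:
            arr = self.actions().reshape(1 << self.ma, 1 << self.mb)
            d1 = self.ma
            while d1 > 0:
                half = 1 << (d1 - 1)
                if np.array_equal(arr[:half], arr[half:]):
                    arr = arr[:half]
                    d1 -= 1
                else:
                    break
            d2 = self.mb
            while d2 > 0:
                half = 1 << (d2 - 1)
                if np.array_equal(arr[:, :half], arr[:, half:]):
                    arr = arr[:, :half]
                    d2 -= 1
                else:
                    break
            if d1 == self.ma and d2 == self.mb:
                canon = self
            else:
                canon = Strategy.from_actions(d1, d2, arr.reshape(-1))
            self._canon = canon
        return self._canon

    @property
    def key(self) -> tuple[int, int, int]:
        """Hashable canonical identity ``(m1, m2, bits)``."""
        c = self.canonical()
        return (c.ma, c.mb, c.bits)

    # -- serialization --------------------------------------------------------

    def to_text(self) -> str:
        """Serialize as ``"<m_cap>:<hex table bits>"`` at symmetric depth."""
        m = max(self.ma, self.mb)
        s = lift(self, m) if (self.ma != m or self.mb != m) else self
        return f"{m}:{s.bits:0{max(1, (1 << (2 * m)) // 4)}x}"

    @classmethod
    def from_text(cls, text: str) -> "Strategy":
        """Parse a preset name or the ``"<m_cap>:<hex>"`` literal form."""
        text = text.strip()
        if text.upper() in PRESETS:
            return make_named(text)
        try:
            head, _, tail = text.partition(":")
            m = int(head)
            bits = int(tail, 16)
        except ValueError as exc:
            raise InvalidStrategyError(f"cannot parse strategy {text!r}") from exc
        return cls(m, m, bits)

    # -- dunder ---------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Strategy):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"Strategy(ma={self.ma}, mb={self.mb}, bits={self.bits:#x})"


def compute_memory_lengths(s: Strategy) -> MemoryLength:
    """Exact memory lengths ``(m1, m2)`` of a strategy.

    ``m1`` is the deepest own round the prescription actually depends on, and
    ``m2`` the deepest co-player round, each found by the wildcard cascade
    from the table's depth downward (see module docstring).  Unconditional
    strategies get ``(0, 0)``; Tit-for-Tat gets ``(0, 1)``.
    """
    return s.memory_lengths()


def lift(s: Strategy, m_target: int) -> Strategy:
    """Re-express ``s`` on the symmetric depth-``m_target`` state space.

    The lifted table ignores the added history depth, so behaviour and exact
    memory lengths are unchanged.  ``m_target`` must be at least the exact
    memory length in each index.
    """
    c = s.canonical()
    if m_target < c.ma or m_target < c.mb:
        raise InvalidStrategyError(
            f"cannot lift to depth {m_target}: exact memory is ({c.ma}, {c.mb})"
        )
    if m_target > MAX_DEPTH:
        raise InvalidStrategyError(f"depth {m_target} exceeds the cap {MAX_DEPTH}")
    if s.ma == m_target and s.mb == m_target:
        return s
    acts = c.actions()[_state_to_history(c.ma, c.mb, m_target)]
    return Strategy.from_actions(m_target, m_target, acts)


def memory_one(p_cc: int, p_cd: int, p_dc: int, p_dd: int) -> Strategy:
    """Memory-one strategy from the conventional 4-tuple.

    ``p_ij`` is the (pure) cooperation prescription after the focal player
    played ``i`` and the co-player ``j`` in the previous round.
    """
    # profile h = (a1 << 1) | b1 with C = 1: h=3 is CC, h=2 CD, h=1 DC, h=0 DD
    return Strategy.from_actions(1, 1, [p_dd, p_dc, p_cd, p_cc])


PRESETS = {
    "ALLC": lambda: Strategy(0, 0, 1),
    "ALLD": lambda: Strategy(0, 0, 0),
    "TFT": lambda: memory_one(1, 0, 1, 0),
    "WSLS": lambda: memory_one(1, 0, 0, 1),
    "GRIM": lambda: memory_one(1, 0, 0, 0),
}

PRESET_NAMES = tuple(sorted(PRESETS))


def make_named(name: str) -> Strategy:
    """Return a canonical preset strategy (AllC, AllD, TFT, WSLS, GRIM)."""
    try:
        return PRESETS[name.upper()]()
    except KeyError:
        raise InvalidStrategyError(
            f"unknown strategy name {name!r}; known presets: {', '.join(PRESET_NAMES)}"
        ) from None


def enumerate_tables(ma: int, mb: int) -> Iterator[Strategy]:
    """All ``2**(2**(ma+mb))`` pure tables of a given shape (exact or not)."""
    for bits in range(1 << (1 << (ma + mb))):
        yield Strategy(ma, mb, bits)
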