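"""Counting, enumeration and sampling of exact memory-(m1, m2) classes.

``S(m1, m2)`` is the set of strategies whose *exact* memory lengths are
``(m1, m2)``; these classes are disjoint, and the memory-``m`` space
``S(m)`` is their union over ``m1, m2 <= m`` with ``|S(m)| = 2**(2**(2m))``.
A table on ``2**(m1+m2)`` histories belongs to the exact class iff its
prescription actually depends on the deepest own round (when ``m1 > 0``)
and the deepest co-player round (when ``m2 > 0``), which gives the
inclusion-exclusion count

    |S(m1,m2)| = N(m1,m2) - N(m1-1,m2) - N(m1,m2-1) + N(m1-1,m2-1)

with ``N(i,j) = 2**(2**(i+j))`` the number of tables of memory *at most*
``(i, j)`` (terms with a negative index are dropped).  For example there
are exactly 10 memory-(1,1) strategies.

Mutants are drawn by a two-step scheme: first ``m1`` and ``m2`` uniform on
``{0, ..., m}``, then a table uniform over the exact class (by rejection).
This gives short-memory strategies non-negligible weight and neutral-
selection mean memory lengths of ``(m/2, m/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np

from . import classify
from .strategy import Strategy, MAX_DEPTH

__all__ = [
    "count_exact",
    "count_at_most",
    "enumerate_exact",
    "exact_class_tables",
    "sample_mutant",
    "census",
    "CensusRow",
    "ENUMERATION_LIMIT",
]

# beyond m1 + m2 = 4 a superclass holds > 2**16 tables; enumeration refused
ENUMERATION_LIMIT = 4

_REJECTION_CAP = 10_000


def count_at_most(m1: int, m2: int) -> int:
    """Number of tables with memory at most ``(m1, m2)``: ``2**(2**(m1+m2))``."""
    if m1 < 0 or m2 < 0:
        raise ValueError(f"memory lengths must be non-negative, got ({m1}, {m2})")
    return 1 << (1 << (m1 + m2))


def count_exact(m1: int, m2: int) -> int:
    """Size of the exact class ``S(m1, m2)`` by inclusion-exclusion."""
    n = count_at_most(m1, m2)
    if m1 > 0:
        n -= count_at_most(m1 - 1, m2)
    if m2 > 0:
        n -= count_at_most(m1, m2 - 1)
    if m1 > 0 and m2 > 0:
        n += count_at_most(m1 - 1, m2 - 1)
    return n


@lru_cache(maxsize=64)
def _dep_masks(m1: int, m2: int) -> tuple[int, int, int, int]:
    """Bit-arithmetic helpers for the exact-memory test on shape (m1, m2).

    Returns ``(n_entries, half, co_shift, co_mask)``: a table ``t`` depends
    on its deepest own round iff its high and low halves differ (the deepest
    own action is the top bit of the history index), and on the deepest
    co-player round iff ``((t >> co_shift) ^ t)`` is nonzero on positions
    whose index has that bit clear.
    """
    n_hist = 1 << (m1 + m2)
    half = n_hist // 2
    if m2 > 0:
        d = m2 - 1
        co_shift = 1 << d
        co_mask = 0
        for i in range(n_hist):
            if not (i >> d) & 1:
                co_mask |= 1 << i
    else:
        co_shift = 0
        co_mask = 0
    return n_hist, half, co_shift, co_mask


def _is_exact(bits: int, m1: int, m2: int) -> bool:
    """True iff a shape-(m1, m2) table has exact memory (m1, m2)."""
    n_hist, half, co_shift, co_mask = _dep_masks(m1, m2)
    if m1 > 0:
        if (bits >> half) == (bits & ((1 << half) - 1)):
            return False
    if m2 > 0:
        if not (((bits >> co_shift) ^ bits) & co_mask):
            return False
    return True


def exact_class_tables(m1: int, m2: int) -> np.ndarray:
    """Table bits of every member of ``S(m1, m2)`` (requires m1+m2 <= 4).

    Returned as a uint64 array suitable for the batched classifiers.
    """
    if m1 + m2 > ENUMERATION_LIMIT:
        raise ValueError(
            f"class ({m1}, {m2}) holds {count_exact(m1, m2)} strategies; "
            f"exhaustive enumeration is limited to m1 + m2 <= {ENUMERATION_LIMIT} "
            "-- use sampling instead"
        )
    n_hist = 1 << (m1 + m2)
    tables = np.arange(1 << n_hist, dtype=np.uint64)
    keep = np.ones(len(tables), dtype=bool)
    if m1 > 0:
        half_bits = n_hist // 2
        low = tables & np.uint64((1 << half_bits) - 1)
        keep &= (tables >> np.uint64(half_bits)) != low
    if m2 > 0:
        _, _, co_shift, co_mask = _dep_masks(m1, m2)
        keep &= ((tables >> np.uint64(co_shift)) ^ tables) & np.uint64(co_mask) != 0
    return tables[keep]


def enumerate_exact(m1: int, m2: int) -> Iterator[Strategy]:
    """Yield every strategy of exact memory ``(m1, m2)`` once."""
    for bits in exact_class_tables(m1, m2):
        yield Strategy(m1, m2, int(bits))


def _sample_class_bits(m1: int, m2: int, rng: np.random.Generator) -> int:
    """Uniform table bits over the exact class ``S(m1, m2)`` by rejection."""
    n_hist = 1 << (m1 + m2)
    for _ in range(_REJECTION_CAP):
        bits = 0
        for _ in range(0, n_hist, 32):
            width = min(32, n_hist)
            bits = (bits << width) | int(rng.integers(0, 1 << width))
        if _is_exact(bits, m1, m2):
            return bits
    raise RuntimeError(  # pragma: no cover - acceptance prob is >= 10/16
        f"rejection sampling failed to hit class ({m1}, {m2}) "
        f"in {_REJECTION_CAP} draws"
    )


def sample_mutant_key(m: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Two-step mutant draw, returned as ``(m1, m2, bits)`` without wrapping."""
    if not 1 <= m <= MAX_DEPTH:
        raise ValueError(f"memory cap must be in 1..{MAX_DEPTH}, got {m}")
    m1 = int(rng.integers(0, m + 1))
    m2 = int(rng.integers(0, m + 1))
    return m1, m2, _sample_class_bits(m1, m2, rng)


def sample_mutant(m: int, rng: np.random.Generator) -> Strategy:
    """Draw a mutant: ``(m1, m2)`` uniform on ``{0..m}**2``, then a uniform
    member of the exact class ``S(m1, m2)``."""
    m1, m2, bits = sample_mutant_key(m, rng)
    return Strategy(m1, m2, bits)


class TwoStepSampler:
    """Buffered two-step mutant sampler for the Monte Carlo hot loops.

    Draws the same distribution as :func:`sample_mutant` -- ``(m1, m2)``
    uniform on ``{0..m}**2``, then uniform over the exact class -- but
    amortizes generator overhead by pre-drawing random numbers in blocks
    and by indexing directly into cached class tables where the class is
    small enough to enumerate (``m1 + m2 <= 4``); larger classes fall back
    to rejection sampling.
    """

    def __init__(self, m: int, rng: np.random.Generator, block: int = 8192):
        if not 1 <= m <= MAX_DEPTH:
            raise ValueError(f"memory cap must be in 1..{MAX_DEPTH}, got {m}")
        self.m = m
        self.rng = rng
        self.block = block
        self._classes: dict = {}
        for m1 in range(m + 1):
            for m2 in range(m + 1):
                if m1 + m2 <= ENUMERATION_LIMIT:
                    self._classes[(m1, m2)] = exact_class_tables(m1, m2).tolist()
        self._pos = block
        self._m1 = self._m2 = self._u = None

    def draw(self) -> tuple[int, int, int]:
        """Next mutant as ``(m1, m2, table_bits)``."""
        if self._pos == self.block:
            self._m1 = self.rng.integers(0, self.m + 1, size=self.block).tolist()
            self._m2 = self.rng.integers(0, self.m + 1, size=self.block).tolist()
            self._u = self.rng.random(size=self.block).tolist()
            self._pos = 0
        p = self._pos
        self._pos = p + 1
        m1 = self._m1[p]
        m2 = self._m2[p]
        cls = self._classes.get((m1, m2))
        if cls is not None:
            return m1, m2, cls[int(self._u[p] * len(cls))]
        return m1, m2, _sample_class_bits(m1, m2, self.rng)


@dataclass
class CensusRow:
    """Classification census of one exact memory class.

    Counts are exact when the class was enumerated exhaustively
    (``method == "exhaustive"``); otherwise the fractions are Monte Carlo
    estimates from ``n_samples`` uniform draws and ``n_fr`` is an estimate
    rather than an exact count.
    """

    m1: int
    m2: int
    n_total: int
    frac_efficient: float
    frac_rival: float
    frac_fr: float
    method: str
    n_samples: int

    @property
    def fr_wilson_interval(self) -> tuple[float, float]:
        """95% Wilson score interval for the FR fraction (sampled censuses)."""
        n = self.n_samples if self.method == "sampled" else self.n_total
        p = self.frac_fr
        if n == 0:
            return (0.0, 1.0)
        z = 1.959963984540054
        denom = 1.0 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        spread = z * np.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
        return (max(0.0, center - spread), min(1.0, center + spread))


def census(
    m1: int,
    m2: int,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
) -> CensusRow:
    """Classify an exact memory class, exhaustively when feasible.

    For ``m1 + m2 <= 4`` every member is enumerated and classified, giving
    exact fractions (including the FR count).  Larger classes are estimated
    from ``n_samples`` uniform draws; the FR fraction is then only a Monte
    Carlo estimate (FRs are so rare that its Wilson interval is wide).
    """
    n_total = count_exact(m1, m2)
    if m1 + m2 <= ENUMERATION_LIMIT:
        tables = exact_class_tables(m1, m2)
        eff, riv = classify.classify_tables(tables, m1, m2)
        n = len(tables)
        return CensusRow(
            m1, m2, n_total,
            float(eff.sum()) / n,
            float(riv.sum()) / n,
            float((eff & riv).sum()) / n,
            "exhaustive", n,
        )
    if rng is None:
        raise ValueError("a seeded numpy Generator is required for a sampled census")
    bits = np.array(
        [_sample_class_bits(m1, m2, rng) for _ in range(n_samples)], dtype=np.uint64
    )
    eff, riv = classify.classify_tables(bits, m1, m2, chunk=2048)
    return CensusRow(
        m1, m2, n_total,
        float(eff.sum()) / n_samples,
        float(riv.sum()) / n_samples,
        float((eff & riv).sum()) / n_samples,
        "sampled", n_samples,
    )
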