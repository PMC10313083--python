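"""Shared fixtures: named strategies and the exhaustive memory-2 scan.

The memory-2 scan (all 2**16 tables of shape (2, 2), i.e. every distinct
behaviour with both memory lengths at most 2) takes a few seconds and is
consumed by several classification and census tests, so it is computed once
per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from frsim import classify
from frsim.strategy import Strategy, make_named


@pytest.fixture(scope="session")
def named():
    return {name: make_named(name) for name in ("ALLC", "ALLD", "TFT", "WSLS", "GRIM")}


@pytest.fixture(scope="session")
def memory2_scan():
    """(tables, efficient, rival) over all 65536 shape-(2,2) tables."""
    tables = np.arange(1 << 16, dtype=np.uint64)
    eff, riv = classify.classify_tables(tables, 2, 2, chunk=8192)
    return tables, eff, riv


@pytest.fixture(scope="session")
def memory2_frs(memory2_scan):
    """The friendly-rival strategies of the memory-2 space."""
    tables, eff, riv = memory2_scan
    return [Strategy(2, 2, int(b)) for b in tables[eff & riv]]


def brute_memory_lengths(s: Strategy) -> tuple[int, int]:
    """Independent memory-length oracle: exhaustive pair comparison.

    ``m1`` is the smallest own depth ``d`` such that any two histories
    agreeing on the last ``d`` own moves (and all co-player moves) receive
    the same prescription; likewise ``m2`` for the co-player index.
    """
    arr = s.actions().reshape(1 << s.ma, 1 << s.mb)

    def min_depth(axis: int, full: int) -> int:
        for d in range(full + 1):
            ok = True
            for x in range(1 << full):
                for y in range(1 << full):
                    if (x ^ y) & ((1 << d) - 1):
                        continue
                    rows = (arr[x], arr[y]) if axis == 0 else (arr[:, x], arr[:, y])
                    if not np.array_equal(*rows):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return d
        return full

    return min_depth(0, s.ma), min_depth(1, s.mb)
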