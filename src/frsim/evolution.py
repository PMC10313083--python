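"""Small-mutation-limit evolutionary Monte Carlo over memory strategies.

Two population structures are supported:

* **Well-mixed** (size ``N``): in the small-mutation limit the population is
  a single resident strategy.  Each time step draws a mutant by the two-step
  sampler and replaces the resident with the fixation probability of the
  pairwise-comparison (Fermi) process,

      rho_{X->Y} = 1 / sum_{j=0}^{N-1} exp[ sigma_in * j *
          ((2N-j-3) pi_XX + (j+1) pi_XY - (2N-j-1) pi_YX - (j-1) pi_YY)
          / (2 (N-1)) ],

  whose j = 0 term is 1, so 0 < rho <= 1 and rho = 1/N when all four
  payoffs coincide (neutral drift).

* **Group-structured** (``M`` groups of size ``N``): intra-group dynamics is
  assumed fast, so each group is homogeneous and the state is one resident
  per group.  Each step picks a focal group (strategy X); with probability
  ``r`` a mutant Y is drawn and fixes with rho_{X->Y}; otherwise a random
  other group (strategy Y) is imitated with probability

      T_{X->Y} = f^out_{X->Y} * rho_{X->Y},

  where the out-group Fermi factor compares the two homogeneous-group
  self-payoffs (the groups never play each other directly).

Observables are streaming time-averages of resident properties after a
burn-in: self-cooperation level at the run's error rate, the disjoint class
fractions (FR / non-FR efficient / non-FR rival), and the exact memory
lengths.  Runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import classify
from .payoff import GameParams, PayoffCache
from .space import TwoStepSampler
from .strategy import Strategy

__all__ = [
    "WellMixedConfig",
    "GroupConfig",
    "Observables",
    "EvolutionResult",
    "fermi",
    "fixation_probability",
    "fixation_from_payoffs",
    "group_transition_probability",
    "run_well_mixed",
    "run_group_structured",
]

_EXP_CLAMP = 700.0


def _validate_game(b: float, e: float, m: int) -> None:
    if not b > 1.0:
        raise ValueError(f"benefit b must exceed the unit cost, got b={b}")
    if not 0.0 < e < 0.5:
        raise ValueError(f"error rate must satisfy 0 < e < 0.5, got e={e}")
    if not 1 <= m <= 3:
        raise ValueError(f"memory cap m must be in 1..3, got {m}")


def fermi(pi_x: float, pi_y: float, sigma: float) -> float:
    """Imitation probability ``1 / (1 + exp[sigma (pi_x - pi_y)])``.

    Equals 1/2 on a payoff tie and decreases in ``pi_x - pi_y``; the
    exponent is clamped at +-700 to avoid overflow at large selection
    strength.
    """
    z = sigma * (pi_x - pi_y)
    if z > _EXP_CLAMP:
        z = _EXP_CLAMP
    elif z < -_EXP_CLAMP:
        z = -_EXP_CLAMP
    return 1.0 / (1.0 + math.exp(z))


def fixation_from_payoffs(
    pi_xx: float, pi_xy: float, pi_yx: float, pi_yy: float, n: int, sigma: float
) -> float:
    """Fixation probability of one Y mutant in a homogeneous X group of size n.

    Closed form of the pairwise-comparison (Fermi) birth of a mutant lineage;
    see module docstring.  Reduces to ``1/n`` under neutrality and to
    ``1 / (1 + exp[sigma (pi_xy - pi_yx)])`` at ``n = 2``.
    """
    if n < 2:
        raise ValueError(f"group size must be at least 2, got {n}")
    denom = 2.0 * (n - 1)
    total = 1.0  # j = 0 term
    # the bracket (2N-j-3) pi_XX + (j+1) pi_XY - (2N-j-1) pi_YX - (j-1) pi_YY
    # is rewritten in terms of payoff differences so that exact ties cancel
    # exactly and neutrality yields rho = 1/N to the last bit
    d_xx = pi_xx - pi_yx
    d_xy = pi_xy - pi_yx
    d_yy = pi_yy - pi_yx
    for j in range(1, n):
        z = (
            sigma
            * j
            * ((2 * n - j - 3) * d_xx + (j + 1) * d_xy - (j - 1) * d_yy)
            / denom
        )
        if z > _EXP_CLAMP:
            z = _EXP_CLAMP
        elif z < -_EXP_CLAMP:
            z = -_EXP_CLAMP
        total += math.exp(z)
    return 1.0 / total


def fixation_probability(
    x: Strategy,
    y: Strategy,
    n: int,
    sigma_in: float,
    params: GameParams,
    cache: Optional[PayoffCache] = None,
) -> float:
    """Fixation probability rho_{X->Y} of a Y mutant in a group of X."""
    if cache is None:
        cache = PayoffCache(params)
    pi_xx, pi_xy, pi_yx, pi_yy = cache.entries(x, y)
    return fixation_from_payoffs(pi_xx, pi_xy, pi_yx, pi_yy, n, sigma_in)


@dataclass(frozen=True)
class WellMixedConfig:
    """Well-mixed run: population size ``N``, benefit ``b``, error ``e``,
    memory cap ``m``, selection strength ``sigma_in`` (default 30/(b-1)),
    ``steps`` total with the first ``burn_in`` discarded."""

    N: int
    b: float
    m: int
    e: float = 1e-6
    sigma_in: Optional[float] = None
    steps: int = 1_000_000
    burn_in: int = 100_000
    seed: int = 0
    thin: int = 1000

    def __post_init__(self):
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2, got {self.N}")
        if self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")
        _validate_game(self.b, self.e, self.m)

    @property
    def sigma(self) -> float:
        return 30.0 / (self.b - 1.0) if self.sigma_in is None else self.sigma_in


@dataclass(frozen=True)
class GroupConfig:
    """Group-structured run: ``M`` groups of size ``N``, relative mutation
    rate ``r``, out-group selection ``sigma_out`` (default 30/(b-1))."""

    M: int = 100
    N: int = 2
    b: float = 3.0
    m: int = 3
    e: float = 1e-6
    sigma_in: Optional[float] = None
    sigma_out: Optional[float] = None
    r: float = 1e-2
    steps: int = 10_000_000
    burn_in: Optional[int] = None
    seed: int = 0
    thin: int = 10_000
    init: Optional[tuple] = None  # initial residents; default: sampled

    def __post_init__(self):
        if self.init is not None and len(self.init) != self.M:
            raise ValueError(
                f"init must provide one resident per group ({self.M}), "
                f"got {len(self.init)}"
            )
        if self.M < 2:
            raise ValueError(f"number of groups M must be >= 2, got {self.M}")
        if self.N < 2:
            raise ValueError(f"group size N must be >= 2, got {self.N}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"relative mutation rate r must be in [0,1], got {self.r}")
        if self.burn_in is not None and self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")
        _validate_game(self.b, self.e, self.m)

    @property
    def sigma_in_value(self) -> float:
        return 30.0 / (self.b - 1.0) if self.sigma_in is None else self.sigma_in

    @property
    def sigma_out_value(self) -> float:
        return 30.0 / (self.b - 1.0) if self.sigma_out is None else self.sigma_out

    @property
    def burn_in_value(self) -> int:
        return self.steps // 10 if self.burn_in is None else self.burn_in


@dataclass
class Observables:
    """Streaming time-averages of resident properties after burn-in.

    ``frac_fr`` / ``frac_eff`` / ``frac_rival`` are the disjoint reporting
    buckets (FR, non-FR efficient, non-FR rival); their sum is at most 1,
    the remainder being strategies that are neither efficient nor rival.
    """

    mean_cooperation: float
    frac_fr: float
    frac_eff: float
    frac_rival: float
    mean_m1: float
    mean_m2: float
    steps_averaged: int

    def as_dict(self) -> dict:
        return {
            "mean_cooperation": self.mean_cooperation,
            "frac_fr": self.frac_fr,
            "frac_eff": self.frac_eff,
            "frac_rival": self.frac_rival,
            "mean_m1": self.mean_m1,
            "mean_m2": self.mean_m2,
            "steps_averaged": self.steps_averaged,
        }


@dataclass
class EvolutionResult:
    observables: Observables
    timeseries: pd.DataFrame = field(repr=False)


_SERIES_COLUMNS = [
    "t",
    "cooperation",
    "frac_fr",
    "frac_eff",
    "frac_rival",
    "mean_m1",
    "mean_m2",
]


class _StrategyStats:
    """Lazily computed per-strategy observables, cached by canonical key."""

    __slots__ = ("gamma", "fr", "eff", "riv", "m1", "m2")

    def __init__(self, strat: Strategy, gamma: float):
        lab = classify.label(strat)
        self.gamma = gamma
        self.fr = 1.0 if (lab.efficient and lab.rival) else 0.0
        self.eff = 1.0 if (lab.efficient and not lab.rival) else 0.0
        self.riv = 1.0 if (lab.rival and not lab.efficient) else 0.0
        m1, m2 = strat.memory_lengths()
        self.m1 = float(m1)
        self.m2 = float(m2)


def run_well_mixed(cfg: WellMixedConfig) -> EvolutionResult:
    """Single-resident Monte Carlo in the small-mutation limit."""
    params = GameParams(b=cfg.b, e=cfg.e)
    sigma = cfg.sigma
    rng = np.random.default_rng(cfg.seed)
    cache = PayoffCache(params)
    # small strategy spaces recur, so memoize every pair; in S(3) mutants
    # are almost surely novel and caching them would only burn memory
    entries = cache.entries if cfg.m <= 2 else cache.mutant_entries
    stats_cache: dict = {}

    def stats_for(s: Strategy) -> _StrategyStats:
        st = stats_cache.get(s.key)
        if st is None:
            st = _StrategyStats(s, cache.self_payoff(s)[0])
            stats_cache[s.key] = st
        return st

    sampler = TwoStepSampler(cfg.m, rng)
    resident = Strategy(*sampler.draw())
    res_stats = stats_for(resident)

    sums = [0.0] * 6
    series = []
    steps, burn_in, thin, n_pop = cfg.steps, cfg.burn_in, cfg.thin, cfg.N
    # payoff ties are resolved once per resident: the accept threshold for a
    # mutant is rho, drawn against a buffered uniform
    block = 1 << 14
    u_acc: list = []
    bpos = block
    for t in range(steps):
        if bpos == block:
            u_acc = rng.random(size=block).tolist()
            bpos = 0
        m1, m2, bits = sampler.draw()
        mutant = Strategy(m1, m2, bits)
        pi_xx, pi_xy, pi_yx, pi_yy = entries(resident, mutant)
        rho = fixation_from_payoffs(pi_xx, pi_xy, pi_yx, pi_yy, n_pop, sigma)
        if u_acc[bpos] < rho:
            resident = mutant
            res_stats = stats_for(resident)
        bpos += 1
        if t >= burn_in:
            sums[0] += res_stats.gamma
            sums[1] += res_stats.fr
            sums[2] += res_stats.eff
            sums[3] += res_stats.riv
            sums[4] += res_stats.m1
            sums[5] += res_stats.m2
        if thin and t % thin == 0:
            series.append(
                (
                    t,
                    res_stats.gamma,
                    res_stats.fr,
                    res_stats.eff,
                    res_stats.riv,
                    res_stats.m1,
                    res_stats.m2,
                )
            )
    n_avg = steps - burn_in
    obs = Observables(*(x / n_avg for x in sums), n_avg)
    return EvolutionResult(obs, pd.DataFrame(series, columns=_SERIES_COLUMNS))


def group_transition_probability(
    x: Strategy,
    y: Strategy,
    cfg: GroupConfig,
    params: Optional[GameParams] = None,
    cache: Optional[PayoffCache] = None,
) -> float:
    """Probability T_{X->Y} that a homogeneous X group adopts Y from a Y group.

    Product of the out-group Fermi factor (comparing the two groups'
    homogeneous self-payoffs) and the within-group fixation probability of
    the single convert.
    """
    if params is None:
        params = GameParams(b=cfg.b, e=cfg.e)
    if cache is None:
        cache = PayoffCache(params)
    pi_xx, pi_xy, pi_yx, pi_yy = cache.entries(x, y)
    f_out = fermi(pi_xx, pi_yy, cfg.sigma_out_value)
    rho = fixation_from_payoffs(pi_xx, pi_xy, pi_yx, pi_yy, cfg.N, cfg.sigma_in_value)
    return f_out * rho


def run_group_structured(cfg: GroupConfig) -> EvolutionResult:
    """Island-model Monte Carlo: one resident strategy per group.

    Per step: pick a focal group uniformly; with probability ``r`` attempt a
    mutant fixation, otherwise attempt out-group imitation of a uniformly
    chosen other group.  Observables average over groups and over time after
    burn-in.
    """
    params = GameParams(b=cfg.b, e=cfg.e)
    sigma_in = cfg.sigma_in_value
    sigma_out = cfg.sigma_out_value
    burn_in = cfg.burn_in_value
    rng = np.random.default_rng(cfg.seed)
    cache = PayoffCache(params)
    mut_entries = cache.entries if cfg.m <= 2 else cache.mutant_entries

    # residents are interned to small integer ids; all per-strategy data
    # lives in parallel lists indexed by id
    id_of: dict = {}
    strat_of: list = []
    stats_of: list = []

    def intern(s: Strategy) -> int:
        k = s.key
        i = id_of.get(k)
        if i is None:
            i = len(strat_of)
            id_of[k] = i
            strat_of.append(s)
            stats_of.append(_StrategyStats(s, cache.self_payoff(s)[0]))
        return i

    M, n_grp, r = cfg.M, cfg.N, cfg.r
    sampler = TwoStepSampler(cfg.m, rng)
    groups: list = []
    agg = [0.0] * 6
    for g in range(M):
        if cfg.init is not None:
            strat = cfg.init[g]
        else:
            strat = Strategy(*sampler.draw())
        i = intern(strat)
        groups.append(i)
        st = stats_of[i]
        agg[0] += st.gamma
        agg[1] += st.fr
        agg[2] += st.eff
        agg[3] += st.riv
        agg[4] += st.m1
        agg[5] += st.m2

    trans: dict = {}  # (id_x, id_y) -> T_{X->Y}
    sums = [0.0] * 6
    series = []
    steps, thin = cfg.steps, cfg.thin
    # the aggregate changes only on accepted replacements, so time-averages
    # are accumulated per constant segment rather than per step
    seg_start = burn_in
    next_series_t = 0

    def flush(upto: int):
        """Add the current aggregate over steps [seg_start, upto)."""
        nonlocal seg_start
        n = upto - seg_start
        if n > 0:
            sums[0] += agg[0] * n
            sums[1] += agg[1] * n
            sums[2] += agg[2] * n
            sums[3] += agg[3] * n
            sums[4] += agg[4] * n
            sums[5] += agg[5] * n
        seg_start = max(seg_start, upto)

    block = 1 << 16
    bpos = block
    u_focal = u_branch = u_other = u_acc = None
    for t in range(steps):
        if bpos == block:
            u_focal = rng.integers(0, M, size=block).tolist()
            u_branch = rng.random(size=block).tolist()
            u_other = rng.integers(0, M - 1, size=block).tolist()
            u_acc = rng.random(size=block).tolist()
            bpos = 0
        if thin and t == next_series_t:
            series.append((t, *(x / M for x in agg)))
            next_series_t += thin
        g = u_focal[bpos]
        ix = groups[g]
        iy = -1
        if u_branch[bpos] < r:
            # mutation: a mutant lineage either fixes in the group or dies out
            mutant = Strategy(*sampler.draw())
            pi_xx, pi_xy, pi_yx, pi_yy = mut_entries(strat_of[ix], mutant)
            rho = fixation_from_payoffs(pi_xx, pi_xy, pi_yx, pi_yy, n_grp, sigma_in)
            if u_acc[bpos] < rho:
                iy = intern(mutant)
        else:
            j = u_other[bpos]
            if j >= g:
                j += 1
            iy = groups[j]
            if iy != ix:
                tp = trans.get((ix, iy))
                if tp is None:
                    pi_xx, pi_xy, pi_yx, pi_yy = cache.entries(
                        strat_of[ix], strat_of[iy]
                    )
                    f_out = fermi(pi_xx, pi_yy, sigma_out)
                    rho = fixation_from_payoffs(
                        pi_xx, pi_xy, pi_yx, pi_yy, n_grp, sigma_in
                    )
                    tp = f_out * rho
                    trans[(ix, iy)] = tp
                if u_acc[bpos] >= tp:
                    iy = -1
            else:
                iy = -1
        bpos += 1
        if iy >= 0 and iy != ix:
            # the state after the event at step t counts from step t onward
            if t > burn_in:
                flush(t)
            groups[g] = iy
            so, sn = stats_of[ix], stats_of[iy]
            agg[0] += sn.gamma - so.gamma
            agg[1] += sn.fr - so.fr
            agg[2] += sn.eff - so.eff
            agg[3] += sn.riv - so.riv
            agg[4] += sn.m1 - so.m1
            agg[5] += sn.m2 - so.m2
    flush(steps)
    n_avg = steps - burn_in
    obs = Observables(*(x / (n_avg * M) for x in sums), n_avg)
    return EvolutionResult(obs, pd.DataFrame(series, columns=_SERIES_COLUMNS))
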