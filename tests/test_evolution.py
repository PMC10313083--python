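"""Fermi updating, fixation probabilities and the Monte Carlo engines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frsim.evolution import (
    GroupConfig,
    WellMixedConfig,
    fermi,
    fixation_from_payoffs,
    fixation_probability,
    group_transition_probability,
    run_group_structured,
    run_well_mixed,
)
from frsim.payoff import GameParams, PayoffCache
from frsim.space import TwoStepSampler, count_exact, exact_class_tables
from frsim.strategy import Strategy, make_named


@settings(derandomize=True, max_examples=200)
@given(
    a=st.floats(-50, 50),
    b=st.floats(-50, 50),
    sigma=st.floats(0, 1e4),
)
def test_fermi_properties(a, b, sigma):
    f = fermi(a, b, sigma)
    assert 0.0 <= f <= 1.0
    assert fermi(a, b, sigma) + fermi(b, a, sigma) == pytest.approx(1.0, abs=1e-12)
    if a == b:
        assert f == 0.5
    assert math.isfinite(fermi(a, b, 1e300))  # clamped, no overflow


def test_neutral_fixation_is_one_over_n():
    for n in (2, 3, 8, 64):
        assert fixation_from_payoffs(1.3, 1.3, 1.3, 1.3, n, sigma=7.0) == 1.0 / n


def test_fixation_reduces_to_fermi_at_n_two():
    rng = np.random.default_rng(0)
    for _ in range(50):
        pis = rng.normal(size=4)
        sigma = rng.uniform(0, 20)
        rho = fixation_from_payoffs(*pis, 2, sigma)
        assert rho == pytest.approx(fermi(pis[1], pis[2], sigma), rel=1e-12)


def _simulate_within_group_fixation(pi_xx, pi_xy, pi_yx, pi_yy, n, sigma, trials, rng):
    """Stochastic oracle: pairwise-comparison imitation inside one group.

    Starting from one Y mutant among n players, a random focal player
    imitates a random role model with the Fermi probability based on the
    composition-dependent fitnesses (average payoff against the other n-1
    group members).  Returns the fraction of trials in which Y fixed.
    """

    def fitness(k):
        # k = number of Y players
        fx = ((n - k - 1) * pi_xx + k * pi_xy) / (n - 1)
        fy = ((k - 1) * pi_yy + (n - k) * pi_yx) / (n - 1)
        return fx, fy

    fixed = 0
    for _ in range(trials):
        k = 1
        while 0 < k < n:
            i, j = rng.integers(0, n), rng.integers(0, n - 1)
            if j >= i:
                j += 1
            focal_y = i < k  # label players 0..k-1 as Y
            model_y = j < k
            if focal_y == model_y:
                continue
            fx, fy = fitness(k)
            if focal_y:
                if rng.random() < fermi(fy, fx, sigma):
                    k -= 1
            else:
                if rng.random() < fermi(fx, fy, sigma):
                    k += 1
        fixed += k == n
    return fixed / trials


def test_fixation_formula_matches_stochastic_oracle():
    """Closed-form fixation equals the simulated imitation process (3 sigma)."""
    rng = np.random.default_rng(123)
    trials = 40_000
    cases = [
        (1.0, -0.5, 2.0, 0.8, 1.0),  # mutant favoured
        (2.0, 2.0, 2.0, 2.0, 5.0),  # neutral
        (1.5, 0.3, 0.1, 0.2, 2.0),  # resident favoured
    ]
    for pi_xx, pi_xy, pi_yx, pi_yy, sigma in cases:
        rho = fixation_from_payoffs(pi_xx, pi_xy, pi_yx, pi_yy, 4, sigma)
        est = _simulate_within_group_fixation(
            pi_xx, pi_xy, pi_yx, pi_yy, 4, sigma, trials, rng
        )
        se = math.sqrt(max(rho * (1 - rho), 1e-6) / trials)
        assert abs(est - rho) <= 3 * se + 1e-4


def test_fixation_probability_from_strategies():
    params = GameParams(b=3.0, e=1e-6)
    wsls, alld = make_named("WSLS"), make_named("ALLD")
    # AllD invades a WSLS pair easily; WSLS cannot invade AllD
    rho_in = fixation_probability(wsls, alld, 2, 15.0, params)
    rho_out = fixation_probability(alld, wsls, 2, 15.0, params)
    assert rho_in > 0.99
    assert rho_out < 1e-6


def test_friendly_rivals_are_evolutionarily_robust(memory2_frs):
    """No mutant fixes in an FR population faster than neutral drift.

    Rivalry guarantees pi_YX <= pi_XY at zero error; with the probe error
    rate e the payoffs carry O(e) corrections, so the neutral bound 1/N
    holds up to a selection-scaled margin of sigma * (b + 1) * e.
    """
    params = GameParams(b=3.0, e=1e-6)
    sigma = 15.0
    tol = sigma * (params.b + 1.0) * params.e
    cache = PayoffCache(params)
    rng = np.random.default_rng(21)
    sampler = TwoStepSampler(3, rng)
    mutants = [Strategy(*sampler.draw()) for _ in range(1000)]
    for fr in memory2_frs[:2]:
        for n in (2, 8):
            for y in mutants[:500]:
                rho = fixation_probability(fr, y, n, sigma, params, cache)
                assert rho <= 1.0 / n + tol


def test_group_transition_probability_structure():
    cfg = GroupConfig(M=10, N=2, b=3.0, m=1, sigma_in=15.0, sigma_out=15.0)
    params = GameParams(b=3.0, e=1e-6)
    wsls, alld = make_named("WSLS"), make_named("ALLD")
    # identical groups: fermi factor 1/2 and neutral fixation 1/N
    t_same = group_transition_probability(wsls, wsls, cfg, params)
    assert t_same == pytest.approx(0.5 / cfg.N, rel=1e-12)
    # an AllD group is keen to imitate WSLS (higher group payoff), but the
    # lone convert is then exploited and almost never fixes
    cache = PayoffCache(params)
    t = group_transition_probability(alld, wsls, cfg, params, cache)
    pi_aa, _, _, _ = cache.entries(alld, alld)
    pi_ww, _, _, _ = cache.entries(wsls, wsls)
    f_out = fermi(pi_aa, pi_ww, 15.0)
    assert f_out > 0.99  # imitation pressure is strong
    assert t < f_out * (1.0 / cfg.N)  # ... but fixation suppresses it


def test_run_determinism():
    cfg = WellMixedConfig(N=8, b=6.0, m=1, steps=20_000, burn_in=2_000, seed=5)
    a, b = run_well_mixed(cfg), run_well_mixed(cfg)
    assert a.observables == b.observables
    assert a.timeseries.equals(b.timeseries)
    gcfg = GroupConfig(
        M=20, N=2, b=3.0, m=1, r=0.05, steps=20_000, burn_in=2_000, seed=5, thin=500
    )
    ga, gb = run_group_structured(gcfg), run_group_structured(gcfg)
    assert ga.observables == gb.observables
    assert ga.timeseries.equals(gb.timeseries)


def test_identical_residents_without_mutation_are_absorbing():
    wsls = make_named("WSLS")
    cfg = GroupConfig(
        M=2, N=2, b=3.0, m=1, r=0.0, steps=5_000, burn_in=500, seed=3,
        thin=100, init=(wsls, wsls),
    )
    res = run_group_structured(cfg)
    gamma = PayoffCache(GameParams(b=3.0, e=1e-6)).self_payoff(wsls)[0]
    assert res.observables.mean_cooperation == pytest.approx(gamma, abs=1e-12)
    assert np.allclose(res.timeseries["cooperation"], gamma, atol=1e-12)
    assert res.observables.frac_eff == 1.0


def _sampler_base_rates():
    """Exact class-bucket probabilities of the two-step sampler at m = 1."""
    from frsim import classify

    probs = {"fr": 0.0, "eff": 0.0, "riv": 0.0}
    for m1 in (0, 1):
        for m2 in (0, 1):
            tabs = exact_class_tables(m1, m2)
            w = 0.25 / len(tabs)
            for bits in tabs:
                lab = classify.label(Strategy(m1, m2, int(bits)))
                if lab.efficient and lab.rival:
                    probs["fr"] += w
                elif lab.efficient:
                    probs["eff"] += w
                elif lab.rival:
                    probs["riv"] += w
    return probs


def test_neutral_selection_recovers_sampler_base_rates():
    """sigma = 0: resident class fractions equal the mutant base rates.

    With zero selection strength every fixation probability is 1/N, so the
    resident chain is a resampling of the two-step mutant distribution; the
    time-averaged class fractions must match the exact base rates within
    3 standard errors across independent runs.
    """
    base = _sampler_base_rates()
    fracs = []
    for seed in range(10):
        cfg = WellMixedConfig(
            N=8, b=3.0, m=1, sigma_in=0.0, steps=30_000, burn_in=3_000, seed=seed,
            thin=0,
        )
        o = run_well_mixed(cfg).observables
        fracs.append((o.frac_eff, o.frac_rival))
    fracs = np.array(fracs)
    for idx, key in [(0, "eff"), (1, "riv")]:
        mean = fracs[:, idx].mean()
        se = fracs[:, idx].std(ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - base[key]) <= 3 * se + 0.01, key


def test_well_mixed_matches_exact_embedded_chain():
    """N = 2 memory-one dynamics agrees with the exactly solved 16-state chain.

    In S(1) the resident process is a Markov chain over the 16 behaviours
    with transition X -> Y at rate q(Y) rho_{X->Y}; its stationary
    distribution gives the exact long-run cooperation level, which the Monte
    Carlo estimate must reproduce.
    """
    params = GameParams(b=3.0, e=1e-6)
    cache = PayoffCache(params)
    sigma = 15.0
    strategies = []
    weights = []
    for m1 in (0, 1):
        for m2 in (0, 1):
            tabs = exact_class_tables(m1, m2)
            for bits in tabs:
                strategies.append(Strategy(m1, m2, int(bits)))
                weights.append(0.25 / len(tabs))
    weights = np.array(weights)
    n = len(strategies)
    P = np.zeros((n, n))
    for i, x in enumerate(strategies):
        for j, y in enumerate(strategies):
            if i == j:
                continue
            pi = cache.entries(x, y)
            P[i, j] = weights[j] * fixation_from_payoffs(*pi, 2, sigma)
        P[i, i] = 1.0 - P[i].sum()
    w, vl = np.linalg.eig(P.T)
    stat = np.real(vl[:, np.argmax(np.real(w))])
    stat = stat / stat.sum()
    exact_coop = sum(
        stat[i] * cache.self_payoff(s)[0] for i, s in enumerate(strategies)
    )

    estimates = []
    for seed in range(5):
        cfg = WellMixedConfig(
            N=2, b=3.0, m=1, sigma_in=sigma, steps=100_000, burn_in=10_000,
            seed=seed, thin=0,
        )
        estimates.append(run_well_mixed(cfg).observables.mean_cooperation)
    estimates = np.array(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - exact_coop) <= 3 * se + 0.02
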