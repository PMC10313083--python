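# frsim — friendly rivals in the iterated donation game

`frsim` is a research simulator for the evolution of cooperation by direct
reciprocity. It implements deterministic memory-(m₁, m₂) strategies for the
repeated donation game, classifies them as *efficient*, *rival* or
*friendly rival*, and runs small-mutation-limit evolutionary Monte Carlo in
well-mixed and group-structured (island-model) populations. It is aimed at
researchers in evolutionary game theory who want to study how memory length
and population structure interact to select cooperative strategies.

## The model

**Game.** In each round of the donation game a player may cooperate (pay
cost c = 1 to give the co-player benefit b > 1) or defect (do nothing).
Intended actions are flipped with a small implementation-error probability
e. A memory-(m₁, m₂) strategy prescribes C or D from the player's own last
m₁ moves and the co-player's last m₂ moves (m₁, m₂ ≤ 3); the pair play is a
Markov chain over joint histories whose stationary distribution **v** gives
each player's cooperation level γ and long-term payoff

π_pq = b·γ_qp − c·γ_pq.

**Strategy classes.**

* *Efficient* (self-cooperator): mutual play recovers full cooperation as
  e → 0; judged by γ_pp(e = 10⁻⁴) > 0.99.
* *Rival* (defensible/unbeatable): no co-player can ever obtain a strictly
  higher long-term payoff at e = 0, from any initial state. Decided by
  negative-cycle detection (Floyd–Warshall) on a weighted graph over joint
  states, where edge weights ±1/0 carry the sign of the per-round payoff
  difference.
* *Friendly rival (FR)*: both at once. FRs first appear at total memory
  m₁ + m₂ = 4 and make up only ~1.2×10⁻⁴ of the 2¹⁶ memory-2 strategies.

**Evolution.** In the small-mutation limit each (sub)population is a single
resident strategy. Mutants are drawn by a two-step scheme — (m₁, m₂)
uniform on {0..m}², then uniform within the exact class S(m₁, m₂) — and fix
with the pairwise-comparison (Fermi) probability

ρ_{X→Y} = 1 / Σ_{j=0}^{N−1} exp[σ_in·j·((2N−j−3)π_XX + (j+1)π_XY −
(2N−j−1)π_YX − (j−1)π_YY) / (2(N−1))].

In the group-structured population (M groups of size N) a focal group
either mutates (probability r) or imitates a random other group with
probability T_{X→Y} = f_out(π_XX, π_YY) · ρ_{X→Y}, where f_out is the Fermi
function with the out-group selection strength σ_out.

## Worked example

Classify Win-Stay-Lose-Shift and one of the eight memory-2 friendly rivals
(strategies are preset names or `"<m>:<hex table>"` literals):

```console
$ fr classify WSLS
{"strategy": "1:9", "m1": 1, "m2": 1, "efficient": true, "rival": false,
 "friendly_rival": false, "label": "non-FR efficient"}
$ fr classify 2:a296
{"strategy": "2:a296", "m1": 2, "m2": 2, "efficient": true, "rival": true,
 "friendly_rival": true, "label": "FR"}
```

WSLS recovers cooperation after an error (efficient) but is exploitable by
AllD (not a rival); the 16-bit table `a296` does both at once. Census of
the exact memory-(1,1) class — 10 strategies, of which 20% are efficient,
20% are rival, and none are FRs:

```console
$ fr census --m1 1 --m2 1
m1,m2,n_total,frac_efficient,frac_rival,frac_fr,method,n_samples
1,1,10,0.20000000000000001,0.20000000000000001,0,exhaustive,10
```

Evolution in a well-mixed population of N = 8 with memory-one strategies
and b = 6 (config in YAML; `seed` makes the run bit-reproducible):

```console
$ fr run-wellmixed --config wm.yaml --out results/
{"mean_cooperation": 0.9999970000062525, "frac_fr": 0.0, "frac_eff": 1.0,
 "frac_rival": 0.0, "mean_m1": 1.0, "mean_m2": 1.0, "steps_averaged": 180000}
```

The population sits at WSLS essentially the whole time (`frac_eff = 1`,
memory lengths (1,1)), and the time-averaged resident self-cooperation is
≈ 1 − 3e: full cooperation up to the error rate. `results/` receives
`summary.json`, `timeseries.csv` (t, cooperation, class fractions, memory
lengths) and `run.log`.

The library API mirrors the CLI: see `frsim.Strategy`, `frsim.stationary`,
`frsim.label`, `frsim.census`, `frsim.run_well_mixed`,
`frsim.run_group_structured`.

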