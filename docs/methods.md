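# Methods

This note records the model as implemented, the operational choices that a
reader cannot recover from the equations alone, and what the shipped
simulations do and do not establish.

## Strategies and encoding

A pure memory-(m₁, m₂) strategy is a lookup table over joint histories of
the player's own last m₁ moves and the co-player's last m₂ moves, with both
depths capped at 3. Tables are bit-packed into a single integer: C = 1,
history profile index h = (own << m₂) | co, most recent round in the lowest
bit of each half, and bit h of the table is the prescription for profile h.
Probabilistic tables are rejected at construction; the model is about pure
strategies, for which the friendly-rival property is even attainable (a
mixed strategy cannot be a strict rival at the defection states).

*Exact memory lengths* are computed by a wildcard cascade per index:
starting from the deepest round, test whether any two profiles differing
only in that round's action receive different prescriptions; if not,
project the table one level shallower and repeat. The test suite checks
this against an exhaustive pair-comparison oracle. Equality and hashing of
strategies go through the canonical (projected) form, so the same behaviour
written at different table depths is one strategy.

## Long-term payoffs

With implementation-error rate e each intended action flips independently
with probability e, so table p is effectively played as (1−e)p + e(1−p).
For two finite-memory players the round sequence is a Markov chain over at
most 4³ = 64 joint states; for e > 0 it is ergodic and its unique
stationary distribution is obtained by a dense linear solve of v·T = v with
one equation replaced by Σv = 1 (the state dimension never justifies
anything sparser). Cooperation levels are stationary marginals of the most
recent move; payoffs follow as π_pq = b·γ_qp − c·γ_pq with c = 1.

Strategy pairs of unequal depth are lifted to the common symmetric depth;
lifting provably leaves the stationary outcome, and the tests verify this
numerically to 1e-10. Downstream comparisons use an absolute tolerance of
1e-10.

## Classification

**Efficiency** is judged numerically: γ_pp at e = 10⁻⁴ greater than 0.99.
Across all 2¹⁶ memory-2 behaviours the two sides of the threshold are
separated by a wide margin (non-efficient strategies stay below 0.90;
efficient ones exceed 0.9976), and the verdict is unchanged when the probe
error rate is lowered to 10⁻⁵. One caveat: 214 of the 65 536 memory-2
behaviours have 1 − γ ≈ 15e, so a much stricter threshold (0.999) at
e = 10⁻⁴ would misjudge them even though γ → 1 as e → 0; 0.99 at e = 10⁻⁴
classifies all of them correctly.

**Rivalry** is decided at e = 0 on a directed weighted graph over the full
symmetric state space of the strategy (minimum depth 1). The focal player's
move is fixed by its table, the co-player's move is free — two outgoing
edges per node — and edge weights are the sign of the per-round payoff
difference: 0 on coinciding moves, −1 when only the focal player
cooperates, +1 when only the co-player does. Only cycles matter for
long-term payoffs, so the strategy is a rival iff no cycle has negative
total weight, detected by Floyd–Warshall via a negative diagonal entry
(early exit on first detection). Using sign weights rather than payoff
differences drops b from the computation, which is legitimate because the
verdict only depends on the sign structure as long as mutual cooperation is
socially optimal. All nodes are kept, including those unreachable from
mutual cooperation, because rivalry must hold from any initial state; the
verdict is representation-invariant under lifting (tested).

A friendly rival (FR) is efficient ∧ rival. Exhaustive classification of
the memory-2 space finds exactly 8 FRs (fraction 1.22×10⁻⁴), all with exact
memory (2, 2); no class with m₁ + m₂ ≤ 3 contains one.

For census work the classifiers are numpy-batched: transition matrices for
thousands of tables are assembled at once and solved with one batched
LAPACK call, and Floyd–Warshall runs vectorized over the batch. The full
memory-2 scan takes a few seconds.

## Strategy space and mutation

Exact classes S(m₁, m₂) are disjoint; their sizes follow by
inclusion–exclusion over the at-most counts N(i, j) = 2^(2^(i+j)), e.g.
|S(1,1)| = 16 − 4 − 4 + 2 = 10, verified against enumeration for every
class with m₁ + m₂ ≤ 4. Beyond that bound enumeration is refused (the
superclass exceeds 2¹⁶ tables) and census estimates come from uniform
sampling within the class, with a Wilson interval on the (rare) FR
fraction.

Mutants are drawn by the two-step scheme: (m₁, m₂) uniform on {0..m}², then
a uniform member of the exact class — by direct indexing where the class is
enumerated, by rejection sampling otherwise (acceptance probability is at
least 10/16 in the worst case, (1,1)). The scheme gives short-memory
strategies non-negligible weight and neutral-selection mean memory lengths
(m/2, m/2).

## Evolutionary dynamics

Both population types run in the small-mutation / fast-intra-group-dynamics
limit, so the state is one resident strategy (per group). Fermi exponents
are clamped at ±700 to avoid overflow at large selection strength. The
fixation bracket is evaluated in payoff-difference form,
(2N−j−3)(π_XX−π_YX) + (j+1)(π_XY−π_YX) − (j−1)(π_YY−π_YX), so exact payoff
ties cancel exactly and neutrality returns ρ = 1/N to the last bit. The
closed form is validated against a stochastic oracle that simulates the
within-group pairwise-comparison process with composition-dependent
fitnesses.

Defaults follow the study conditions: e = 10⁻⁶, σ_in = 30/(b−1), σ_out
selectable (same default), well-mixed runs of 10⁶ steps discarding 10⁵,
group runs with M = 100 groups of N = 2. Observables — resident
self-cooperation at the run's error rate, the disjoint class fractions
(FR / non-FR efficient / non-FR rival), and exact memory lengths — are
streamed as time-averages after burn-in; the group loop accumulates per
constant segment between accepted replacements, which is exact and keeps
the cost of 10⁸-step runs at a few minutes. Payoffs and class labels are
memoized per canonical strategy; payoffs of transient mutants (almost
surely novel in S(3)) are computed without being stored. Identical
configurations and seeds reproduce results bit-for-bit.

Evolutionary robustness of FRs (no mutant fixes faster than neutral drift)
holds at zero error; at the working error rate e the rival payoff guarantee
carries O(e) corrections, so the tests assert ρ ≤ 1/N + σ(b+1)e rather
than an absolute 1/N bound.

## Simulation scales and what they show

The shipped runs are desk-scale surrogates of much larger originals, chosen
as the smallest sizes at which the qualitative regime is unambiguous:

* Well-mixed S(1) (N = 8, b = 6): 10 runs × 10⁶ steps. The population
  parks at WSLS; cooperation ≈ 1.
* Well-mixed S(3): 5 runs × 2×10⁵ steps. Turnover among efficient
  strategies and their exploiters gives cooperation around 0.8.
* Group-structured S(3) (M = 100, N = 2, b = 3, r = 10⁻²): one run of 10⁸
  steps discarding 10⁷. An FR mutant is a rare event — the two-step sampler
  yields one with probability ≈ 2×10⁻⁵ per mutation, i.e. roughly one
  arrival per 10⁷ steps at r = 10⁻² — so shorter runs mostly measure the
  FR-free transient; 10⁸ steps is the scale at which arrivals are expected.

A caveat on the last point. FR dominance requires the relative mutation
rate to exceed the crossover at r ~ O(1/M): mutation must resupply rivals
fast enough to purge the tying efficient strategies that erode FR
populations by neutral drift. At M = 100 the prescribed r = 10⁻² sits *at*
that crossover rather than above it, and the simulations show exactly the
expected marginal behaviour: FR episodes arise, persist for ~10⁶–10⁷
steps, and are lost again to tying efficient strategies, so the long-run
cooperation level averages ≈ 0.85 (four seeds: 0.833–0.875, FR
time-fractions 0.05–0.27) rather than the ≈ 1 reached deep in the
FR-dominated regime (which at r = 10⁻² requires M ≈ 10³, an order of
magnitude beyond a desk run). Two controls confirm that the selection
mechanics — not the time scale — set this limit: at r = 0.1 ≫ 1/M with
M = 100 the same code gives cooperation 0.956 with FR fraction 0.87, and a
single seeded FR group takes over the population within ~5×10⁵ steps and
then holds cooperation at ≈ 0.997.

The synthetic dynamics emulate the model exactly rather than any empirical
data: there is no population structure beyond the island model, no
discounting, no mixed strategies, and no cost of memory. Passing tests
therefore establish internal correctness of the model's predictions, not
external validity for behavioural data.

## Known limitations

* Exact FR enumeration is only available where exhaustive classification is
  feasible (m₁ + m₂ ≤ 4); sampled censuses report FR fractions with wide
  intervals because FRs are so rare.
* The group model assumes homogeneous groups (two strategies at most,
  transiently); finite intra-group dynamics is folded into the fixation
  formula.
* Memory depths beyond 3 are out of scope (the state space and the table
  encodings are sized for 64 states).
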