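# Methods

## The model

`stgames` analyzes which populations of repeated-game strategies evolution
selects in symmetric 2×2 games. A game is normalized to R = 1 (mutual
cooperation) and P = 0 (mutual defection), leaving two parameters: S, the
payoff for cooperating against a defector, and T, the temptation for
defecting against a cooperator. The signs of S and T − 1 partition the
(S, T) plane into the Harmony game (S > 0, T < 1), Snowdrift (S > 0,
T > 1), the Prisoner's Dilemma (S < 0, T > 1) and the Stag Hunt (S < 0,
T < 1); the boundaries S = 0 and T = 1 are labeled as such and not forced
into a quadrant.

Players use memory-one strategies: the probability of cooperating depends
only on the previous round's outcome, indexed throughout in the fixed order
(CC, CD, DC, DD) — equivalently by the focal player's previous payoff
(R, S, T, P). We restrict to the 16 deterministic strategies, written as
4-bit codes (intended action after R, S, T, P; 1 = cooperate), perturbed by
an implementation error ε: each intended action is executed with
probability 1 − ε. This keeps every cooperation probability strictly inside
(0, 1), which makes every pair chain irreducible and regularizes strategies
(such as TFT) that are unstable against errors. ε defaults to 0.01 and is
restricted to (0, 1/2); results are not qualitatively sensitive to moderate
increases.

Win-stay lose-shift (WSLS) strategies repeat their previous action iff the
obtained payoff exceeded an aspiration level. With four distinct payoffs
there are three aspiration levels; we call the corresponding strategies
*ambitious* (content only with the top payoff), *balanced* (with the top
two), and *modest* (with anything but the worst). Their codes depend only
on the payoff ordering, hence change across the plane (e.g. in the typical
Prisoner's Dilemma ordering T > R > P > S they are 0001, 1001 = Pavlov and
1000 = GRIM; in the Harmony ordering R > S > T > P the balanced WSLS is
AllC). Ties in the payoffs make the construction undefined and raise an
error.

## Pair payoffs

Two memory-one strategies playing an infinitely repeated game form a
4-state Markov chain whose transition probabilities factorize into the two
players' cooperation probabilities (the opponent sees CD and DC swapped).
In the limit of no discounting the expected per-round payoff is v·(R,S,T,P)
with v the stationary distribution. v is computed by solving the linear
system (vM = v, Σv = 1) — a 4×4 solve is exact and deterministic, and is
cross-checked in the tests against long power iteration and against direct
Monte-Carlo play-outs of a million rounds. ε = 0 is allowed in this module
only (for limit checks); reducible chains produce a warning and one valid
stationary vector. The 16×16 matrix W of all ordered pair payoffs drives
everything downstream.

## Imitation dynamics

A well-mixed population of N individuals evolves by pairwise imitation: a
focal individual and an opponent are drawn without replacement, and the
focal one copies the opponent's strategy with probability
p = (1 + Δπ/Δπ_max)/2, where Δπ is the opponent's payoff excess. Payoffs
are expected payoffs against the self-excluded population mixture — the
replicator-consistent choice, which removes payoff-sampling noise. Δπ_max
is the global spread max(W) − min(W), so the imitation map is one fixed
linear function per game. Equal payoffs give p = 1/2, i.e. unbiased drift.

Direct simulation of this process wastes nearly all steps once the
population is dominated by one strategy. The rejection-free reformulation
samples only composition-changing events: the probability that some change
occurs in an elementary step is (N² − Σᵢnᵢ²)/(2N(N−1)) independently of
payoffs, each skipped stretch contributes its expected waiting time (the
reciprocal), and the executed jump is drawn from the conditional law
(replaced strategy from its marginal, copied strategy conditionally).
Observables are averaged with waiting-time weights, which reproduces the
direct process's time averages exactly; the tests verify the jump law
against exhaustive pair enumeration and the end-state distributions against
direct simulation.

### Stopping rule and quasi-stationarity

A run ends in one of three ways:

1. **Absorption** — the population becomes homogeneous.
2. **Statistical stationarity** — time-averaged composition over successive
   windows of 100·N elementary steps stops moving: `stable_windows` (= 4)
   consecutive window-to-window comparisons each within `tol_individuals`
   (default max(2, 0.02·N); quasi-stationary fluctuations grow like √N, so
   the tolerance is a population fraction rather than a fixed head count).
   Several consecutive quiet windows are required because slowly drifting
   near-neutral mixtures can pass a single comparison by chance but almost
   never several in a row before absorbing.
3. **Certified two-strategy well** — whenever only two strategies remain,
   their exact birth–death chain is analyzed (cheaply, cached): if the
   selection gradient points inward from both ends and the exact mean
   absorption time (computed in log space from per-state sojourns) exceeds
   the metastability scale, the run stops as quasi-stationary the moment
   the trajectory reaches the interior attractor, and reports the attractor
   composition. The metastability scale defaults to 20× the event budget in
   elementary steps: a state whose absorption a run could never witness is
   metastable relative to that run. This analytic path mirrors the way the
   method certifies mixed equilibria by fixation-time analysis, removes the
   main source of budget-exhausted runs, and makes repeated discoveries of
   the same well yield identical compositions.

Runs that exhaust the event budget without meeting any criterion are marked
inconclusive and are reported but never classified.

## Invasion graph

Sixteen homogeneous populations seed the graph. Every stable population is
invaded by every strategy absent from it: 5% of the population (at least
one individual) is converted to the invader and the dynamics is run to a
stopping condition, over 100 independent realizations per (node, invader)
pair. Outcomes are matched to existing nodes when they share the strategy
support and differ by at most 0.05 in max-norm composition (strategies
below 1% presence are dropped first); genuinely new mixed equilibria become
nodes and are invaded in turn, breadth-first, until closure (node cap 200
with an explicit warning if hit). Edges record empirical outcome fractions
over the conclusive realizations, labeled by the invading strategy.

## Markov analysis

The invasion graph induces a Markov chain over stable populations: with
invasion rate μ per step, the off-diagonal entry (a → b) is μ times the
mean outcome fraction over a's possible invaders (the division by the
invader count is a convention; all reported quantities are invariant to it
and to μ, which the tests verify across the admissible range). Outcome
fractions at or below 1/realizations — supported by a single realization —
are below the protocol's statistical resolution and are dropped by the
orchestrated analysis before assembly.

Recurrent classes are the sink strongly-connected components of the
positive-transition digraph; the rest is transient. Absorption
probabilities x[i][k] into each class solve (I − T)x = R·1ₖ on the
transient block; their unweighted mean over transient nodes X̄[k]
summarizes how reachable each class is, and per-class stationary vectors
are left eigenvector solves of the class submatrices. Conservation
(Σₖ x[i][k] = 1, Σπ = 1) is enforced to 1e-10.

## Fixation-probability alternative

The second scheme replaces simulated invasions by single-mutant fixation
probabilities. The two-strategy dynamics is a birth–death chain over the
mutant count; the fixation probability from one mutant uses the classical
absorption formula, accumulated in log space because strongly
counter-selected pairs have probabilities far below floating-point range.
The exact mean absorption time and an easy per-state sojourn lower bound
are provided, both log-space, for metastability certification. The
fixation chain has the 16 homogeneous populations as nodes, edge weights
ρ(resident → mutant), and contains no mixed node by construction.
Fixation probabilities below 0.1/N are pruned: near-neutral probabilities
cluster at the drift scale 1/N, so an absolute cutoff would change meaning
with N, whereas 0.1/N uniformly discards transitions an order of magnitude
below drift. (An absolute threshold can be supplied.)

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| ε | 0.01 | implementation error per action |
| N | 1000 (200 in the bundled experiments) | population size |
| invader fraction | 0.05 | share of residents converted per invasion |
| realizations | 100 | runs per (node, invader) |
| merge_tol / min_presence | 0.05 / 0.01 | node identification in fraction space |
| window, tol, stable_windows | 100·N, max(2, 0.02N), 4 | stationarity detection |
| event budget | 1e7 (2e5 in the bundled experiments) | accelerated events per run |
| metastable_time | 20 × budget | elementary steps; well certification |
| μ | 0.01 | invasion rate (immaterial to reported quantities) |
| prune threshold | 0.1/N | fixation-chain edge cutoff |

The bundled experiments (tests and the acceptance script) run at N = 200
with 100 realizations per invasion and an event budget of 2×10⁵, one
representative game per region: Harmony (0.5, 0.5), moderate- and
large-temptation Prisoner's Dilemma (−0.5, 1.5) and (−1.5, 2.5), and
high-S Snowdrift (2, 3). These sizes preserve all qualitative structure
(Pavlov's uniqueness in the moderate PD, AllC's dominance in Harmony,
GRIM/AllD in the large-temptation PD, anti-coordinating mixtures in
high-S Snowdrift) while each full per-game analysis completes in minutes
on one core.

## Numerical choices

- Stationary vectors: direct linear solves with the normalization row
  substituted; degenerate (reducible) cases fall back to least squares with
  a warning.
- Fixation products and absorption times: log-space cumulative sums and
  `logsumexp`; nothing overflows even for fixation probabilities ~e⁻³⁰⁰.
- Simulation kernels are numba-compiled; the RNG is explicitly seeded
  everywhere, per-point seeds derive deterministically from the master seed
  and (S, T), per-invasion streams from (node id, invader), and every
  trajectory records its seed.
- Initial invasion counts use largest-remainder apportionment so resident
  fractions survive integer rounding.

## What the experiments do and do not show

All experiments are self-generated — the model has no external data. The
bundled runs demonstrate the method's internal consistency (exact engines
vs independent oracles, accelerated vs direct dynamics, simulation vs
fixation schemes) and reproduce the qualitative evolutionary structure of
the four game regions at N = 200. They do not quantify finite-N effects:
absolute reach probabilities X̄ and the detailed composition of large
recurrent sets shift with N, invader fraction and realization count, and
weakly-selected transitions near the drift scale 1/N are resolved only up
to the 1/realizations sampling limit. Known limitations: three-or-more
strategy coexistences rely on the statistical stopping rule (no analytic
certificate); boundary games are classified but not given WSLS triples;
and the invasion protocol never re-invades a node with a strategy already
present in it.
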