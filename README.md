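# stgames

Evolutionary analysis of iterated symmetric 2×2 games played by noisy
deterministic memory-one strategies.

## The problem

Direct reciprocity — cooperation sustained by repeated interaction — is
usually studied through the iterated Prisoner's Dilemma, but the same
machinery applies to every symmetric 2×2 game. Normalizing the one-shot
payoffs to R = 1 (mutual cooperation) and P = 0 (mutual defection) leaves
two parameters, the sucker's payoff S and the temptation T, whose signs
split the (S, T) plane into the Harmony, Snowdrift, Prisoner's Dilemma and
Stag Hunt games. Players use memory-one strategies — 4-bit codes giving
the intended action after each previous-round outcome (CC, CD, DC, DD),
executed with error probability ε — which includes the classic strategies
AllC (1111), AllD (0000), TFT (1010), GRIM (1000) and Pavlov (1001).

Rather than following one noisy evolutionary trajectory, the package maps
the whole space of stable populations. For each game it:

1. computes the exact 16×16 expected payoff matrix from the stationary
   distribution of each pair's 4-state Markov chain (W_ij = v·(R,S,T,P));
2. simulates a finite-population pairwise-imitation process
   (p = (1 + Δπ/Δπ_max)/2), using an exact rejection-free acceleration
   with waiting-time-weighted averages;
3. systematically invades every stable population — homogeneous or
   quasi-stationary mixed — with every absent strategy, building a
   weighted **invasion graph** of outcomes;
4. treats that graph as a Markov chain and extracts its transient nodes,
   recurrent (sink) classes, absorption probabilities x and X̄, and
   within-class stationary vectors π — the evolutionarily relevant
   populations and how likely evolution is to reach each;
5. repeats the analysis with single-mutant fixation probabilities
   (ρ from the birth–death absorption formula, computed in log space) in
   place of simulations, which deliberately erases mixed equilibria and
   shows what they contribute.

It is written for researchers in evolutionary game theory and the
theoretical biology of cooperation. See `docs/methods.md` for the model,
the stopping rules and all tunable parameters.

## Worked example

Analyze a moderate-temptation Prisoner's Dilemma at population size 200:

```python
import stgames as sg

game = sg.Game(S=-0.5, T=1.5)
print(sg.classify_quadrant(game))      # PrisonersDilemma
print(sg.wsls_strategies(game))        # ambitious=0001, balanced=1001, modest=1000

config = sg.SweepConfig(
    invasion=sg.InvasionParams(
        N=200, realizations=100,
        stability=sg.StabilityConfig(event_budget=200_000),
    ),
    seed=1,
)
report = sg.analyze_game(game, config)
for cls, xbar in zip(report.simulation_decomposition.recurrent_classes,
                     report.simulation_decomposition.averaged_absorption):
    labels = [report.simulation_chain.node_labels[i] for i in cls]
    print(labels, f"reached with probability {xbar:.2f}")
```

Output:

```
PrisonersDilemma
WslsTriple(ambitious='0001', balanced='1001', modest='1000')
['1001'] reached with probability 1.00
```

The invasion graph's only recurrent class is the homogeneous Pavlov (1001)
population: every other stable population can be invaded along some path
that ends in Pavlov, and no strategy invades Pavlov — the balanced
win-stay lose-shift strategy is the unique evolutionary outcome here. The
fixation-probability chain (`report.fixation_decomposition`) gives the
same answer. At a high-S Snowdrift point such as (S, T) = (2, 3) the
recurrent structure instead contains anti-coordinating mixed equilibria
(supports like 0010+0011+1011 or 0100+0101+1101) that the fixation scheme
cannot represent.

The same pipeline is scriptable from the shell:

```bash
stgames payoffs --S -0.5 --T 1.5 --out out/
stgames invade  --S -0.5 --T 1.5 --N 200 --realizations 100 --event-budget 200000 --seed 1 --out out/
stgames fixation --S -0.5 --T 1.5 --N 200 --out out/
stgames sweep --N 200 --realizations 100 --event-budget 200000 --seed 1 --out sweep/
```

which writes the payoff matrix, node/edge tables, a GraphViz DOT export of
the invasion graph, and per-game summary tables (one row per recurrent
node with its within-class probability π and class reach probability X̄).

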