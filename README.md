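# zdgames

Zero-determinant strategy algebra, unbending-strategy classification, and
evolutionary dynamics for the iterated prisoner's dilemma (IPD).

## The problem

In the IPD with stage payoffs `T > R > P > S`, a *zero-determinant* (ZD)
player using a memory-one strategy can unilaterally enforce a linear
relation between the two long-run average payoffs,

    sX − O = χ (sY − O),

where `O ∈ [P, R]` is the baseline payoff, `χ ≥ 1` the extortion factor,
and a third parameter `φ > 0` normalizes the strategy vector

    p₁ = 1 − φ(R−O)(χ−1)         p₂ = 1 − φ[(T−O)χ + (O−S)]
    p₃ = φ[(O−S)χ + (T−O)]       p₄ = φ(O−P)(χ−1)

without affecting the relation. `O = P` gives the extortionate family,
`O = R` the generous one. Against a naive adapting opponent, extortion
looks unbeatable. But there exist fixed *unbending* strategies that turn
the tables: against them the extortioner's own payoff is independent of
its hidden knob `φ` and **strictly decreasing** in `χ`, so a
payoff-maximizing extortioner is driven to the fair limit `χ → 1` and an
equal split. Win-Stay-Lose-Shift, generous ZD players, and the
PSO Gambler `[1, 0.5217, 0, 0.1205]` are all unbending in the right
payoff regime, and the sign of `T + S − 2P` decides whether an
extortioner can even keep its payoff above `P`.

This package is for researchers in evolutionary game theory and direct
reciprocity who want those claims as running, tested code: exact long-run
payoffs for any memory-one pair (including reducible outcome chains), the
ZD admissibility algebra, numerical unbending classification and region
scans, deterministic gradient-learning dynamics, and finite-population
Moran dynamics in the rare-mutation limit.

## Worked example

```python
import numpy as np
from zdgames import (make_payoffs, ZDParams, zd_strategy, average_payoffs,
                     named_strategy, is_unbending, integrate_chi_learning,
                     LearningConfig)

game = make_payoffs(3, 0, 5, 1)                     # conventional IPD
ext = zd_strategy(ZDParams(O=1.0, chi=2.0, phi=0.1), game)
print("extortionate ZD:", ext)

pso = named_strategy("PSO_GAMBLER")
pair = average_payoffs(ext, pso, game)
print(f"vs PSO Gambler: sX={pair.sX:.4f}, sY={pair.sY:.4f}")

m = is_unbending(pso, game)
print("PSO Gambler unbending:", m.is_unbending, "| class A:", m.in_A)

gen = named_strategy("GENEROUS", game, chi=2.0)
traj = integrate_chi_learning(4.0, gen, game, LearningConfig(dt=0.05, steps=5000))
print(f"learned chi: {traj.states[-1][0]:.6f}, terminal sX={traj.payoffs[-1][0]:.4f}")
```

prints

```
extortionate ZD: [0.8 0.1 0.6 0. ]
vs PSO Gambler: sX=1.9939, sY=1.4969
PSO Gambler unbending: True | class A: True
learned chi: 1.000000, terminal sX=3.0000
```

The extortioner demanding a double share (`χ = 2`) earns about 2.0
against the PSO Gambler while conceding only 1.5 — but the Gambler is
unbending: the extortioner's payoff falls the harder it squeezes, so an
extortioner that adapts its own `χ` by gradient ascent on its payoff
slides all the way to the fair limit `χ = 1`, where both players earn the
full reward `R = 3`.

A CLI mirrors the library:

```sh
zdgames payoffs --p 0.8,0.1,0.6,0 --q 1,0,0,1 --payoffs 3,0,5,1
zdgames unbending classify --q 1,0.5217,0,0.1205 --payoffs 3,0,5,1
zdgames evolve abundance --strategies pso,gzd:2,tft,ezd:2 --N 100 --beta 1
```

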