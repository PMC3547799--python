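# punishnet

Evolutionary dynamics of **altruistic peer punishment on scale-free
networks**: a simulation and analysis pipeline for the question *when does
punishing defectors actually help cooperation?*

Cooperators and defectors populate the nodes of a Barabási–Albert network
and play one-shot social-dilemma games (Prisoner's Dilemma and Stag Hunt)
with their neighbors. With reward `R = 1` and mutual-defection payoff
`P = 0`, the game lives in the `(T, S)` plane (temptation × sucker's
payoff). A punishing cooperator pays a cost `q` per defecting partner to
inflict a fine `p` on it, so the effective payoff matrix is

|       | C     | D     |
|-------|-------|-------|
| **C** | 1     | S − q |
| **D** | T − p | 0     |

— punishment is exactly the translation `(T, S) → (T − p, S − q)`.
Strategies spread by imitation: a random player copies a random neighbor
with the Fermi pairwise-comparison probability
`W = 1/(1 + exp[β(P_x − P_y)])`, where payoffs are accumulated over all
interactions (hubs matter) and `β` is the intensity of selection. Each run
is iterated to fixation; averaging the 0/1 outcomes over many runs and
networks gives the cooperation level `x_ffc(T, S)`, and the **cooperation
index Ω** is the fraction of the rectangle `0 ≤ T ≤ 2, −1 ≤ S ≤ 0` where
`x_ffc > 0.5`.

The punchline the pipeline reproduces: on scale-free networks the 50%
cooperation boundary (the *edge-curve* λ) has tangent slope `σ(T)` bounded
between `σ₁ ≈ 0.31` and `σ₂ ≈ 0.77`, so whether punishment helps depends on
the cost-to-fine ratio: `q/p < σ₁` enlarges the cooperative region
everywhere, `q/p > σ₂` (even while `q < p`, i.e. still altruistic) shrinks
it, and in between the effect is mixed. The Ω-neutral line in the `(p, q)`
plane has slope ≈ 0.54. Punish — but not at all costs.

Intended for researchers in evolutionary game theory and social dynamics
who want a reproducible, seed-stable re-implementation of this experiment,
with analytic oracles to validate every moving part.

## Worked example

```python
import numpy as np
from punishnet import (
    GameParams, SweepConfig, generate_ba_network,
    estimate_xffc, imitation_probability, complete_graph_fixation,
)
from punishnet.geometry import classify_regime

net = generate_ba_network(n_nodes=500, m_links=2, seed=1)
print(f"network: {net.n_nodes} nodes, mean degree {net.mean_degree:.2f}, "
      f"max degree {net.degree.max()}")

# imitation probability for a payoff gap of 4 at beta = 0.25
print(f"W(adopt better neighbor) = {imitation_probability(0.0, 4.0, 0.25):.4f}")

# exact fixation probability of 3 cooperators on the complete graph K6
phi = complete_graph_fixation(6, 3, GameParams(T=0.5, S=-0.5, beta=0.25))
print(f"K6 fixation probability (exact) = {phi:.4f}")

# Monte-Carlo cooperation level at a Stag-Hunt point, with/without punishment
from dataclasses import replace
cfg = SweepConfig(n_networks=4, runs_per_point=100, network_size=500, root_seed=1)
x0 = estimate_xffc(0.8, -0.6, cfg)
x1 = estimate_xffc(0.8, -0.6, replace(cfg, p=0.1, q=0.0))
print(f"x_ffc(T=0.8, S=-0.6): {x0:.2f} without punishment, "
      f"{x1:.2f} with a free fine p=0.1")

print("regime(p=0.1, q=0.04):", classify_regime(0.1, 0.04, 0.31, 0.77))
```

prints

```
network: 500 nodes, mean degree 3.99, max degree 45
W(adopt better neighbor) = 0.7311
K6 fixation probability (exact) = 0.3466
x_ffc(T=0.8, S=-0.6): 0.39 without punishment, 0.56 with a free fine p=0.1
regime(p=0.1, q=0.04): mixed
```

Reading it: the generated network has the target mean degree 4 with a
45-neighbor hub; a neighbor 4 payoff units ahead is imitated 73% of the
time at `β = 0.25`; the birth–death oracle gives the exact fixation
probability the engine must reproduce; at a Stag-Hunt point just below the
edge-curve, a free fine (`q = 0`) lifts cooperation from losing (0.39) to
winning (0.56); and a cost/fine ratio of 0.4 sits between σ₁ and σ₂, where
punishment helps in some regions of the plane and harms in others.

## Command line

```bash
punishnet sweep  --seed 1 --out run          # x_ffc grid CSV + Ω manifest
punishnet curve  run_grid.csv                # edge-curve λ + (σ_min, σ_max)
punishnet pqscan --seed 1 --grid-step 0.1    # Ω(p,q) + separation slope
punishnet threestrat --runs 200              # 3-strategy batch (C, D, PC)
punishnet validate                           # oracle self-checks
```

All commands accept a flat TOML config (`--config`) mirroring
`SweepConfig`; flags override file values; every run writes a JSON manifest
with the exact config and seed, and re-running a manifest's config
reproduces its outputs byte for byte.

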