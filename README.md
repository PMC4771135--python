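# netdilemma

Evolutionary dynamics of cooperation in social dilemmas on complex
networks: well-mixed replicator analysis, an asynchronous individual-based
simulator with the Fermi update rule, model-network generators with
calibrated clustering and assortativity, and the cooperation index Λ.

## The problem

Natural selection favors defection in social dilemmas, yet cooperation is
everywhere — from replicating molecules to file-sharing networks.  One
influential explanation is population structure: when individuals interact
only with network neighbors, clusters of cooperators can assort and
persist.  This package implements three canonical dilemmas, each reduced
to a single cost-to-benefit ratio ρ = c/b:

* **donation game** (prisoner's dilemma class): π = [[1−ρ, −ρ], [1, 0]],
  ρ ∈ (0,1) — well-mixed populations always end in all-defect;
* **snowdrift game** (hawk-dove class): π = [[1−ρ/2, 1−ρ], [1, 0]],
  ρ ∈ (0,1) — cooperators and defectors coexist at p\* = (1−ρ)/(1−ρ/2);
* **sculling game** (coordination class): π = [[2−ρ, 1/2−ρ], [1/2, 0]],
  ρ ∈ (1/2, 3/2) — bistable, with separatrix p\* = ρ−1/2; for ρ > 1 it is
  a stag hunt.

On a network, individuals copy neighbors' strategies using the Fermi rule
p(i←j) = 1/(1+e^{−β(P_j−P_i)}), where payoffs come from single random
interactions with third-party neighbors.  Cooperation levels across games
and networks are compared through the **cooperation index**

Λ = 1/(B−A) ∫_A^B p̄∞(ρ) dρ ∈ [0, 1],

the normalized integral of the long-term cooperator fraction over the
game's whole ρ interval.  Well-mixed baselines: Λ = 0 (donation),
2 − ln 4 ≈ 0.614 (snowdrift), 1/2 (sculling from p0 = 1/2).  On sparse
networks cooperation survives beyond its well-mixed limits: the donation
game cooperates when 1/ρ > k̄−1 (so Λ ≈ 1/(k̄−1)), and the sculling game
when 1/(ρ−1) > k̄−1 (so Λ ≈ 1/(k̄−1) + 1/2).

## Worked example

Well-mixed baselines are analytic and instant:

```sh
$ netdilemma wellmixed --game snowdrift --lambda
Lambda(snowdrift, p0=0.5) = 0.613706
$ netdilemma wellmixed --game sculling --rho 0.9 --p0 0.5
pbar_inf(sculling, rho=0.9, p0=0.5) = 1.000000
```

Estimating Λ on a network runs the full individual-based model over a ρ
grid (here: desk scale, a random 4-regular graph on 1000 vertices, 2000
generations, 10 runs per ρ — a few seconds):

```sh
$ netdilemma lambda --game donation --type regular --n 1000 --k 4 \
      --generations 2000 --runs 10 --seed 1
Lambda(donation, regular, n=1000, k=4) = 0.3607 (var 0.000017)
$ netdilemma lambda --game sculling --type regular --n 1000 --k 4 \
      --generations 2000 --runs 10 --seed 1
Lambda(sculling, regular, n=1000, k=4) = 0.8545 (var 0.001983)
```

Network structure rescues cooperation: the donation game's index rises
from its well-mixed value 0 to ≈ 0.36, close to the mean-degree prediction
1/(k̄−1) = 1/3, and the sculling index lands near 1/(k̄−1) + 1/2 = 0.83.
The same library calls are available in Python:

```python
from netdilemma import GameSpec, SimConfig, random_regular, run_ensemble, long_term_mean

g = random_regular(1000, 20, seed=1)
cfg = SimConfig(generations=2000, p0=0.5, beta=1.0, runs=10, seed=1)
trajectories = run_ensemble(g, GameSpec("snowdrift", 0.75), cfg)
print(sum(long_term_mean(t) for t in trajectories) / 10)   # ≈ 0.45
```

Other subcommands: `netgen` (random regular / exponential /
Barabási–Albert / Holme–Kim with calibrated clustering / degree-preserving
rewiring with calibrated assortativity), `metrics` (k̄, C, r, degree
variance of an edge list), `simulate` (trajectory CSVs for a model network
or a user-supplied edge list), `sweep` (tidy CSVs plus a JSON manifest
over (network, ρ) grids), and `threshold-check` (empirical 50%-cooperation
boundary vs. the 1/ρ = k̄−1 prediction).

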