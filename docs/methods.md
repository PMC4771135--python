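# Methods

## Games

Three exemplar social dilemmas are modelled as symmetric 2×2 games with
strategies C (cooperate) and D (defect), each indexed by a single
cost-to-benefit ratio ρ = c/b.  Because the replicator dynamics is invariant
under affine transformations of the payoff matrix, every game is normalized
by dividing by the benefit b:

| game | α (C,C) | β (C,D) | γ (D,C) | δ (D,D) | ρ interval | class |
|---|---|---|---|---|---|---|
| donation | 1−ρ | −ρ | 1 | 0 | (0, 1) | prisoner's dilemma |
| snowdrift | 1−ρ/2 | 1−ρ | 1 | 0 | (0, 1) | hawk-dove |
| sculling | 2−ρ | 1/2−ρ | 1/2 | 0 | (1/2, 3/2) | coordination |

The ρ intervals are open and enforced strictly: the endpoint games are
degenerate (tied payoff entries), and classification of an arbitrary matrix
with ties returns `"degenerate"` rather than raising, so parameter sweeps
across a boundary never abort.  For the sculling game, (C,C) is always
payoff-dominant; it is risk-dominant for ρ < 1 and (D,D) is risk-dominant
for ρ > 1, so on (1, 3/2) the game is a stag hunt.

## Well-mixed replicator dynamics

The cooperator frequency p follows
ṗ = p(1−p)[p(α−γ) + (1−p)(β−δ)].
Equilibria are p = 0, p = 1, and the interior root of the bracket when it
lies in (0,1); stability is decided from the sign of the flow on either
side of each fixed point, which is robust at non-hyperbolic points where
the linearization vanishes.  The long-term state from an initial frequency
p0 is resolved analytically by locating p0's interval between equilibria
and following the sign of the flow; a numerical route (`method="ode"`,
LSODA with an |ṗ| < 1e−10 stopping event, horizon 1e6 time units) computes
the same limit independently and the two agree to 1e−6 in the tests.  The
sculling game's interior equilibrium p\* = ρ − 1/2 is a separatrix;
starting within 1e−12 of it is rejected with an error naming the
separatrix, because silently assigning a basin to a measure-zero initial
condition would be arbitrary.

The cooperation index
Λ = 1/(B−A) ∫ p̄∞(ρ) dρ
integrates the long-term cooperator fraction over the game's ρ interval
(A,B).  Closed forms in the well-mixed case: Λ = 0 (donation),
Λ = 2 − ln 4 ≈ 0.614 (snowdrift), Λ = p0 (sculling, since cooperation fixes
exactly when ρ < p0 + 1/2).  The quadrature route uses the composite
midpoint rule on a uniform interior grid (default 101 points), which avoids
evaluating at the excluded endpoints; its error for the snowdrift curve is
≈ 1.6e−5 at the default grid.  With p0 = 1/2 one sculling grid point falls
on the separatrix ρ = 1; that measure-zero point is assigned the mean of
the two basin attractors (0.5), which keeps the quadrature exact for the
step-function curve.

## Individual-based model on networks

Individuals occupy the vertices of an undirected simple graph with no
isolated vertices; the interaction and updating networks coincide.  One
elementary step: draw a focal individual i uniformly, a strategy model j
uniformly from N(i), an interaction partner k uniformly from N(i)\{j}, and
a partner l uniformly from N(j)\{i} (when i or j has a single neighbor the
exclusion is vacuous).  Payoffs are single-interaction values
P_i = π(s_i, s_k), P_j = π(s_j, s_l), recomputed fresh every step and never
accumulated.  The focal adopts s_j with probability
1/(1+exp(−β(P_j−P_i))) (Fermi rule, selection strength β) or
(P_j−P_i)₊/(P_max−P_min) (replicator rule, with P_max/P_min the extreme
entries of the payoff matrix — the attainable single-interaction payoffs,
since per-individual payoffs are undefined for unsampled individuals in an
asynchronous scheme).  A generation is n such steps (sampling with
replacement); the initial state places exactly round(p0·n) cooperators
uniformly at random, removing initial-condition binomial variance.

**Why the partner draws exclude the update pair.**  The design was
genuinely open: "a random neighbor k of i" can be read with or without
k = j allowed.  The two readings give qualitatively different dynamics.
With unconditioned draws, a defector being compared against a neighboring
cooperator is disproportionately scored on exploiting that very cooperator
(l = i yields P_j = π(D,C), the temptation payoff), and cooperation
collapses in the donation game for every ρ even at mean degree 4.  With
k ∈ N(i)\{j} and l ∈ N(j)\{i}, payoff comparisons are based on third-party
interactions, and the model reproduces the sharp cooperation/defection
threshold at 1/ρ ≈ k̄−1 for the donation game (measured transition between
ρ = 0.3 and 0.4 on k = 4 random regular networks, predicted 1/3) and its
sculling analogue 1/(ρ−1) ≈ k̄−1 (measured between 1.25 and 1.4, predicted
4/3).  Excluding only one of the two draws produces thresholds near
ρ ≈ 0.15–0.25 and is also rejected.  The both-exclusions scheme is
therefore the package's definition of the step.

Homogeneous populations are absorbing (no mutation); once a trajectory is
homogeneous the remaining generations are filled with the absorbing value
without further simulation, an optimization that is exact in distribution.
The generation loop is a numba-compiled kernel; a pure-Python kernel with
the identical algorithm is used when numba is unavailable.  The two kernels
are equal in distribution but not bit-identical, because their random
streams differ.  Each run r of an ensemble derives its stream seed as
(master_seed + r) mod (2³¹−1), recorded on the trajectory.

`flip_probability` computes the exact one-step change probability of a
focal vertex by marginalizing the draws analytically (the focal payoff
depends only on whether the sampled partner cooperates, giving a two-point
payoff distribution per model neighbor); the tests check it against
brute-force enumeration of all (i,j,k,l) draws on every ≤5-vertex graph and
against Monte-Carlo frequencies of the actual step.

## Networks

Generators (all returning simple graphs with vertex ids 0..n−1):

* **random regular** — uniform k-regular graph (configuration-model pairing
  with restarts, via networkx).
* **growing exponential** — clique seed on m+1 vertices, then uniform
  attachment of m edges per new vertex; mean degree → 2m, exponential
  degree tail.  (The growth variant — initial condition and fixed
  attachment count — was unspecified in the sources the model class comes
  from; the clique-seeded fixed-m variant is the package's choice.)
* **Barabási–Albert** — preferential attachment, heavy-tailed degrees.
* **Holme–Kim** — preferential attachment with a triad-formation step of
  probability P_t.  P_t is not exposed: the generator calibrates it by
  bisection (≤30 iterations, one pilot graph per iteration at the target
  size) until the realized mean local clustering is within 0.02 of the
  requested C ∈ [0, 0.6]; unreachable targets raise a calibration error
  reporting the achievable range.  C = 0 short-circuits to the identical
  BA growth path.
* **assortativity rewiring** — degree-preserving two-edge swaps re-pairing
  the four endpoints by degree, accepted only when they move the
  assortativity toward the target r ∈ [−0.3, 0.3] and never creating
  self-loops or multi-edges.  Since degrees are invariant under swaps, r is
  an affine function of Σ_edges k_u·k_v, which is tracked incrementally;
  the loop stops within 0.02 of the target or fails after a capped number
  of attempts (default 400·m).

The calibration tolerances (0.02 for both C and r) are fixed defaults,
overridable per call; the sweep manifest records realized metrics next to
targets so a calibration shortfall is never silent.

Metrics: k̄ = 2m/n exactly; C is the mean local clustering coefficient with
C_i := 0 for vertices of degree < 2 (the ratio is 0/0 there and this is the
standard convention); r is the Pearson degree correlation over edge ends,
computed from the per-edge degree-product sum, and reported as NaN for
regular graphs where its denominator vanishes (never as 0).  Edge lists are
two integer columns with `#` comments; labels are normalized to dense ids
on read with the original labels kept in `g.graph["original_labels"]`,
duplicate/reversed pairs collapse, self-loops are dropped with a summary
warning, and vertices left isolated by that drop are a validation error.

## Estimating p̄∞ and Λ from simulations

The long-term mean of a finite trajectory is the average of p_t over the
final half of the generations (burn-in fraction 0.5 by default).  The
averaging window was an open choice: donation and sculling trajectories
usually absorb (making the estimator window-independent), while snowdrift
fluctuates around a quasi-stationary level that a late window estimates
without transient bias.  Λ on a network integrates per-run p̄∞ curves over
a midpoint ρ grid (default 21 interior points at paper scale, 11 at desk
scale), computing the index per run and reporting the across-run mean and
population variance (the n convention, matching error bars reported as a
variance across runs).

## Scale presets and problem sizes

The `paper` preset is the published study condition: n = 10000, 10000
generations, β = 1, p0 = 0.5, 50 runs.  The `desk` preset — n = 1000, 2000
generations, 10 runs, identical code paths — is the package's default for
interactive work and is what the test suite and the acceptance script use;
it resolves the threshold locations to within one ρ-grid cell and the
snowdrift quasi-stationary level to ±0.005 across master seeds.  Whether
the network is regenerated for each run or one instance is reused is
configurable (`regenerate_network_per_run`); the default reuses one
instance.

## Known limitations

* Cooperation levels at desk scale carry finite-size noise of a few
  hundredths near sharp thresholds; boundary locations are bracketed, not
  resolved, by the default 11-point ρ grids.
* At mean degree 20 the simulated snowdrift quasi-stationary level at
  ρ = 0.75 is ≈ 0.455, slightly above the well-mixed attractor 0.4 it
  approaches as k̄ grows; the approach is from above and is still ≈ 0.05
  away at k̄ = 20 (at any n up to 10⁴), so tests that pin this level to
  0.4 ± 0.05 sit at the edge of the band.
* The model networks emulate degree heterogeneity, clustering and
  assortativity but none of the higher-order structure (communities,
  cores) of empirical graphs; results on model networks transfer to
  empirical edge lists only qualitatively.
* Separate interaction and updating networks, synchronous updating,
  mutation, and birth–death/imitation update rules are out of scope.
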