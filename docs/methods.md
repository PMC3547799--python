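# Methods

## Model

A population of `N` individuals occupies the nodes of a connected, simple,
undirected network and plays one-shot, two-player games with every network
neighbor. With the reward and mutual-defection payoffs normalized to
`R = 1`, `P = 0`, the game is parameterized by the temptation `T` and the
sucker's payoff `S`:

|           | C       | D       |
|-----------|---------|---------|
| **C**     | 1       | S − q   |
| **D**     | T − p   | 0       |

`T > 1, S < 0` is a Prisoner's Dilemma, `T < 1, S < 0` a Stag Hunt.
Cooperators here are *punishing* cooperators: against each defecting
partner they pay a cost `q` to inflict a fine `p` (altruistic punishment
when `p > q`). Punishment therefore acts purely as the translation
`(T, S) → (T − p, S − q)` of the effective game — an identity the code
treats as exact and exploits (below).

Evolution is asynchronous imitation with no mutation. An elementary step
draws a focal player `x` uniformly, a model `y` uniformly from `x`'s
neighborhood, and lets `x` copy `y`'s strategy with the pairwise-comparison
(Fermi) probability

    W(x ← y) = 1 / (1 + exp[β (P_x − P_y)]),

where `P_x`, `P_y` are payoffs *accumulated over all interactions* (never
divided by degree — accumulation is what lets hubs amass large payoffs and
drive the dynamics on heterogeneous networks) and `β ≥ 0` is the intensity
of selection. Without mutation the two monomorphic states absorb; every
run is iterated to fixation.

### Numerical choices in the update loop

- The Fermi exponent is clipped at ±700 before `exp`; at the payoff and β
  scales of interest `|β ΔP| < ~10²`, so the clip changes nothing
  observable and only prevents overflow for pathological inputs.
- Payoffs are cached and updated incrementally: a strategy flip of node `x`
  recomputes `P_x` and adjusts each neighbor's payoff by the matrix-entry
  difference. The cache is exact up to float addition order; nothing
  observable depends on it being a cache.
- When focal and model share a strategy no imitation draw is consumed (the
  state cannot change). The per-run draw order — initial-placement
  shuffle, then per step: focal, neighbor, and (only for discordant pairs)
  the adoption uniform — is fixed, which makes the translation identity
  testable bit-for-bit: runs at `(T, S, p, q)` and `(T − p, S − q, 0, 0)`
  with the same seed produce identical trajectories.
- Absorption safeguard: `max_steps = 5000 × N` elementary steps. Runs
  that hit the cap are *reported* as unabsorbed and excluded from `x_ffc`
  (which is defined only at fixation), never rounded to an outcome. At the
  default protocol fewer than ~0.5% of runs are affected, concentrated near
  the cooperation boundary.

## Population structures (the synthetic-data generator)

Scale-free networks are grown with the Barabási–Albert rule: start from a
complete graph on `m + 1` nodes and attach each new node with `m` edges to
distinct existing nodes, chosen with probability proportional to current
degree (sampling without replacement keeps the graph simple; the complete
seed keeps it connected and makes preferential attachment well defined
from the first step — the growth rule itself does not prescribe a seed
graph, so this convention is fixed here once). With `m = 2` the mean
degree approaches 4, and the degree distribution develops the
characteristic `k^−3` tail.

What the generator emulates: the degree heterogeneity (hubs), the
power-law tail, connectedness, and the mean degree of the study's
populations. What it does not emulate: degree correlations, clustering,
community structure, or any feature of *real* social networks beyond the
degree distribution — so passing tests support claims about BA-type
heterogeneity, not about empirical social graphs.

Initial conditions are maximally mixed: exactly `⌊N/2⌋` cooperators (or
thirds in the three-strategy variant, remainders assigned in label order
C, D, PC) placed by a uniform random permutation.

## Observables

- `x_ffc`: the average final fraction of cooperators — the mean of the
  0/1 fixation outcomes over many runs, each on its own network draw.
- `Ω` (cooperation index): the fraction of the rectangle
  `0 ≤ T ≤ 2, −1 ≤ S ≤ 0` with `x_ffc > 0.5`, estimated as the fraction of
  grid points (Riemann sum). The inequality is strict: ties and points
  with no absorbed runs count as non-cooperative. Well-mixed replicator
  dynamics gives `Ω = 0.25` (cooperators win exactly half of the Stag-Hunt
  quadrant from a 50/50 start); scale-free structure roughly doubles this.
- Edge-curve `λ`: the `x_ffc = 0.5` level set, extracted by marching
  squares (bilinear interpolation; longest connected component, ordered by
  increasing `T`). Its local tangent slope `σ(T)` is fitted by sliding-
  window least squares of `S` on `T`; `σ₁`/`σ₂` are the min/max over the
  curve interior (window-truncated ends excluded).
- Separation line: in the `(p, q)` plane, the contour `Ω(p, q) = Ω(0, 0)`
  fitted by a through-origin line `q = s·p` (the origin is exactly neutral
  by definition, hence the constraint). Both the fitted slope and the
  unweighted mean of `σ(T)` are reported; they agree only qualitatively and
  the package asserts nothing about their equality.

## Default protocol and parameter choices

| parameter | default | why |
|---|---|---|
| network size `N` | 500 | desk-scale stand-in for the original 10³; finite-size shift of Ω is within the Monte-Carlo tolerance |
| `m` (edges/new node) | 2 | mean degree ≈ 4 |
| networks per point | 10 | fresh draws average out single-network idiosyncrasies |
| runs per grid point | 200 | binomial SE of `x_ffc` ≈ 0.035 at the 0.5 level |
| β | 0.25 | the selection strength the study fixes (near-optimal for cooperation on scale-free networks without punishment); not weak selection |
| grid step | 0.05 | 41 × 21 points; resolves the edge-curve at desk cost |
| `max_steps` | 5000·N | see above |

The full-scale protocol (10³ nodes, 10² networks, 2.5×10⁴ runs per point)
is available through the same `SweepConfig`; nothing in the code is
specific to the scaled sizes. Networks are reused across grid points by
default (`reuse_networks`); per-point fresh batches are one flag away, and
at 10 networks × 20 runs each the difference is well inside the binomial
noise.

Seeding: every run's stream is keyed by `splitmix64(root_seed, i, j, run)`
on the grid indices, so sweeps are order-independent, reproducible, and a
grid point's result does not depend on which other points were evaluated.

## The p–q scan and the translation shortcut

Since punishment is exactly a translation, `Ω(p, q)` for all `(p, q)` on
the grid lattice is computed from a *single* punishment-free sweep on the
rectangle extended to `T ∈ [−p_max, 2]`, `S ∈ [−1 − q_max, 0]`, re-windowed
by index shifts. A direct re-simulation mode exists as a cross-check and
must agree exactly, seed for seed; to make that comparison float-exact the
direct mode evaluates the effective payoffs at the canonical extended-grid
coordinates (the same two floats the base sweep used) rather than
re-deriving them as `T − p`, which can differ in the last ulp depending on
the expression tree.

## Slope-window selection

On Monte-Carlo grids the contour points scatter around the true edge-curve
by roughly `δS = δx / |∂x/∂S|`, with `δx` the binomial standard error at
the 0.5 level and the gradient measured from the grid near the contour.
The OLS slope over a window spanning `w` grid columns of width `Δt`
carries a standard error of about `(δS/Δt)·sqrt(12/(w(w²−1)))`; with a
5-point window at the default protocol that is ≈ 0.2 — larger than the
σ₂ − σ₁ spread being measured, so the min/max of σ(T) would measure
sampling noise, not the curve. `choose_slope_window` therefore sizes the
window from the grid itself: smallest odd window with propagated slope SE
below 0.05 (window 11 at the default protocol; the resulting bounds are
stable across windows 9–15), capped at a quarter of the curve length so
genuine curvature is not smoothed away. Adjacent contour points share
grid vertices, so the grid column — not the contour point — is treated as
the unit of independent information. For clean (deterministic or
high-replication) fields the procedure falls back to the 5-point window,
which is also the plain `slope_along_curve` default.

## Independent references

Three oracles validate the engine without sharing code with it: the
closed-form replicator classifier (D wins the PD; in the SH, C wins from
1/2 iff the unstable equilibrium `x* = −S/(−S + 1 − T)` lies below 1/2,
i.e. iff `S > T − 1`, with the boundary assigned to D to match the strict
Ω inequality); the exact birth–death fixation probability on complete
graphs (transition ratio `γ_k = exp(β(π_D − π_C))`, product formula in log
space); and exhaustive 2^n-state chain solving on graphs with `n ≤ 10`.
The birth–death formula and the exhaustive solver agree to 10⁻¹⁰; the
engine agrees with both within three Monte-Carlo standard errors.

## Known limitations

- Degenerate parameter regions (e.g. grids entirely on one side of 0.5)
  yield empty edge-curves; callers receive an explicit empty/error result
  rather than an extrapolated curve.
- `x_ffc` near the boundary mixes genuinely slow coexistence with the step
  cap; the unabsorbed counts are reported per point so users can judge.
- The three-strategy variant is a qualitative check (monomorphic end
  states, hub-driven winner identity); no phase-plane statistics are
  computed for it.
- The weak-selection limit (separation slope → 1 as β → 0, i.e. any
  altruistic punishment helps once the network's role fades) is checked
  only as an ordering between two selection strengths at coarse scale,
  not as a quantitative limit.
- Anti-social punishment, pool punishment, and degree-preserving topology
  controls are out of scope.
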