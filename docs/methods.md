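# Methods

## Model and procedure

The package treats MVPA voxel selection as a wrapper optimization problem.
An instance is one stimulus block; its feature vector is the per-voxel GLM
β for that (run, condition); its label is the stimulus category.  A
candidate voxel subset `S` is scored by the cross-validated error of a
linear SVM restricted to `S`, folded into the scalar fitness
`f(S) = Error(S) / (N − |S|)`, minimized.  The denominator counts
eliminated features, so at equal error a smaller subset always scores at
least as well (monotonicity is property-tested).  `f` is undefined at
`|S| = N` and a classifier cannot be fit at `|S| = 0`; both receive a
sentinel `+inf` fitness.  A practical consequence on clean synthetic data:
once the inner-CV error of a subset reaches exactly zero, `f = 0`
regardless of size, and the run's global best freezes at the first
zero-error subset found — runs therefore end with compact subsets, and
coverage of a larger planted set comes from aggregating repeated runs, not
from any single run.

### Swarm dynamics

Positions live in `[0, 1]^N` and are decoded by a strict threshold
`x_j > θ` (θ default 0.95; the boundary value is excluded).  The velocity
update adds, per coordinate, inertia `ω·V`, a global-best pull weighted
`c1·r1`, a personal-best pull weighted `c2·r2`, and one pull per attractor
weighted `c3·r3`, followed by clamping to `±Vmax` and position clamping to
`[0, 1]` (velocity is left unchanged on clamping; reflection is out of
scope).  Random factors are drawn per coordinate, and per coordinate *and*
attractor for `r3`, which maximizes directional diversity of the attractor
pulls.

The hierarchy is rebuilt every iteration by a stable ascending sort on
current fitness (ties break to the lower particle index, making
hierarchies — and whole trajectories — deterministic for a fixed seed).
With `n` particles in `l` equal layers, top-layer particles take
same-layer particles with strictly better fitness as attractors; every
other particle takes the entire layer above.  With one layer, one particle
and `c3 = 0` the update degenerates exactly to standard PSO, which is
asserted coordinate-wise under shared random draws.

Behavior adaptation: a particle whose personal best has not improved for
`stagnation_limit` iterations (default 10), or that sits within
`crowding_epsilon·√N` (default 1e−3) of its nearest attractor, redraws its
behavior uniformly from {full update, cognitive-only (global-best term
dropped), social-only (personal-best term dropped), random
re-initialization}, excluding its current behavior, and resets its
stagnation counter.  A re-initializing particle redraws position and
velocity each iteration until its next switch, acting as a random-restart
scout.  This four-behavior pool is this package's own definition of the
heterogeneous behavior mechanism.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n` | 50 | population size |
| `layers` | 5 | hierarchy layers (10 particles per layer at defaults) |
| `c1` | 2.5 → 0.5 | global-best weight, linear in `t/n_t` (exploration → exploitation) |
| `c2` | 0.5 → 2.5 | personal-best weight, linear increasing |
| `c3` | 0.5 | attractor weight; kept small because up to `k` attractor terms sum |
| `ω` | 0.9 → 0.4 | inertia, linear decreasing (standard swarm practice) |
| `Vmax` | 0.2 | velocity clamp on the unit position range; with `c3 = 0.5` it keeps the attractor sum from dominating |
| `θ` | 0.95 | selection threshold, strict inequality |
| `patience` | 50 | stall length of the global best position that terminates a run |
| `n_t` | 500 | hard iteration cap (the stall rule is the operative criterion) |
| SVM `C` | 1 | linear kernel, one-vs-rest for K > 2, deterministic primal solver |

Initialization is uniform `[0, 1]` positions and uniform `[−0.1, 0.1]`
velocities.  All randomness in a run flows from one `numpy` generator
seeded by the config, so identical seeds give bit-identical runs.

### Nested evaluation protocol

The outer protocol holds out each of the 12 portions (fMRI runs when run
ids exist, otherwise 12 contiguous groups) once; selection sees only the
other 11.  Within a selection run, fitness is the mean SVM error over 20
random splits of the 11 training portions into 6 train / 5 test portions.
The splits are drawn once per run and reused for every subset, so fitness
differences between particles reflect the subsets rather than split noise,
and subsets are memoized so each is evaluated once.  On training pools
with a portion count other than 11 the 6/5 split generalizes
proportionally (e.g. 6/4 on 10 portions).  z-score standardization — of
the raw β columns and again of the Stage-II product columns — is always
fit on training rows only and applied to the holdout; a poisoned-holdout
test asserts that holdout rows cannot influence inner fitness, and a
label-permutation test that they cannot influence the selected sets.

### Two-stage interaction detection

Stage I repeats the selector 15 times (run `r` seeded `seed + r`, fresh
inner splits per run), counts per-feature selection frequency, and keeps
the top `N1 = ⌈1.05·N_avg⌉` (capped at `N`) by frequency, with ties broken
by descending mean global-best position value and then lowest index (the
multiplier is part of the method; the rounding and tie-breaks are this
package's choices).  Stage II forms all `N1(N1−1)/2` pairwise products of
the z-scored Stage-I columns, re-standardizes them, and applies the
identical repeat-rank-truncate mechanism.  Products of z-scored columns
make each product column an instance-level correlation contribution, which
is why a sign-coupled pair separates two classes whose marginals are
identical.

## Synthetic data: what it emulates, and what not

The additive generator plants class-dependent means (adjacent classes
`delta` apart, default 2, in noise-SD units) in a chosen feature subset;
the interaction generator draws planted pairs from bivariate normals with
correlation `+rho` in one class and `−rho` in the other (default 0.8), so
each marginal is exactly N(0, 1) in both classes and only the product
carries signal — Stage I is blind to it by construction and Stage II is
not.  Labels are balanced exactly across classes and the 12 portions
(round-robin).  The BOLD generator lays out 12 runs × 8 condition blocks
of 9 TRs at TR 2.5 s in seeded random order with 4 rest TRs between
blocks, pushes an N(0,1) condition-by-voxel β matrix through the
boxcar⊗HRF design, and adds Gaussian noise at a requested SNR (signal SD /
noise SD).

None of the generators model spatial voxel topology, temporal
autocorrelation, physiological drift or motion; passing tests demonstrate
that the machinery recovers the structures it targets under clean
conditions, not that it is robust to real scanner noise.

## Numerical and design choices

* HRF: gamma-density difference with SPM's canonical parameters (delays
  6/16 s, dispersions 1/1, peak:undershoot 6, 32 s kernel), sampled at the
  TR for design construction and normalized to unit peak; convolution at
  TR resolution (no microtime upsampling), adequate for 22.5 s blocks.
* β extraction is plain per-run OLS with an intercept; rank-deficient
  designs raise an error naming the collinear columns.  One β row per
  (run, condition) — block-level rather than TR-level instances.
* Constant columns z-score to zero rather than dividing by zero.
* Greedy forward/backward baselines use the same ratio fitness as the
  swarm methods (their criterion is otherwise unspecified), tie-breaking
  to the lowest feature index; backward's first sweep always removes at
  least one feature because the full set is sentinel-worst.
* Termination counts a stall as "global best position unchanged", and
  stops at ≥ 50 consecutive stalled iterations.
* The run-level RNG offsets used to derive evaluator and fold seeds are
  fixed constants recorded in the code; every report carries its seed and
  a config hash.

## Problem sizes in the test and acceptance runs

The exhaustive-oracle comparison uses 8 features × 60 instances over 10
portions (6/4 inner splits), where all 255 subsets can be enumerated with
the very evaluator the swarm uses, at the full 50-particle, patience-50
configuration.  The Stage-I recovery experiment uses the generator's
stated conditions (N = 100, 10 planted, δ = 2, K = 4, M = 240, 15 repeats)
with a reduced search budget per run (30 particles, 80-iteration cap,
patience 20, 5 inner splits); the Stage-II experiment (N = 30, 3 planted
pairs, ρ = 0.8, 5 seeded runs) evaluates one outer fold per run with 20
particles, a 50-iteration cap and 5 selection repeats, taking the full
30-feature set as the Stage-I output so the measured quantity isolates
interaction recovery.  These budgets are the package's own scaled working
sizes; the library defaults remain the full-scale settings above.

## Known limitations

* Fitness is degenerate at exactly zero inner-CV error (no further
  min-size pressure); on real, noisy data this regime is rarely reached.
* The behavior pool and its trigger thresholds are a declared
  re-interpretation of the heterogeneous-swarm idea, not a reimplementation
  of any specific published pool.
* `N1 = ⌈1.05·N_avg⌉` can exceed the number of features a single run ever
  selects when runs disagree strongly; the frequency ranking then pads the
  set with low-frequency features.
* The GLM omits drift and motion regressors; apply standard preprocessing
  upstream for real acquisitions.
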