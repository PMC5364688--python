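# Methods

## The model

oculofit implements a nonlinear-dynamics model of the horizontal saccadic
system: six coupled ODEs describing the oculomotor plant (gaze angle *g*,
eye velocity *v*), a leaky neural integrator *n*, two mutually inhibiting
excitatory burst neuron (EBN) populations *r* and *l*, and a resettable
motor-error integrator *m*:

```
dg/dt = v
dv/dt = -(1/T1 + 1/T2) v - g/(T1 T2) + n/(T1 T2) + (1/T1 + 1/T2)(r - l)
dn/dt = -n/TN + (r - l)
dr/dt = (1/ε)(-r - γ r l² + F(m))
dl/dt = (1/ε)(-l - γ l r² + F(-m))
dm/dt = -(r - l)
```

with the saturating burst nonlinearity

```
F(m) = α′(1 - e^(-m/β′))      m ≥ 0   (on-response)
F(m) = -(α/β) m e^(m/β)       m < 0   (off/braking response)
```

The plant time constants T1 = 0.15 s and T2 = 0.012 s and the integrator
time constant TN = 25 s are fixed physiological constants; the six
parameters {α, β, ε, γ, α′, β′} are free and are what the genetic
algorithm searches for.  The off-response brakes the eye at saccade end;
excessive braking is the model's route into nystagmus oscillations, so
α (braking magnitude, peaking at α/e at m = −β), β (braking range, deg)
and ε (EBN response time, s) control whether the model produces accurate
saccades, inaccurate saccades, or sustained oscillations.  γ sets the
mutual inhibition between the left/right EBN pools; α′ (spikes-scale
magnitude) and β′ (deg) shape the on-response, which saturates for large
motor errors and is consequently only weakly constrained by data —
fits recover α, β, ε, γ far more consistently than α′, β′.

A note on the velocity damping: some printed statements of this model
carry the coefficient −(1/T1 − 1/T2), which for T1 > T2 makes the plant an
unstable second-order system rather than the overdamped one it is
described as.  oculofit uses the overdamped form −(1/T1 + 1/T2) (plant
eigenvalues −1/T1, −1/T2) by default and exposes the alternative sign
behind the `printed_damping` flag so the two variants can be compared.

## Numerical integration

The EBN equations relax at rates of order 1/ε — up to 10^5 s^-1 at the
lower ε bound, and transiently far higher through the γ r l² terms — while
the plant and integrator evolve on 10^-2–10 s timescales, so the system
is stiff across most of the search box.  The production solver is LSODA
(via `scipy.integrate.odeint`) with an analytic Jacobian; both the
right-hand side and the Jacobian are numba-compiled, which makes a 6-s
integration cost ~10–20 ms rather than the ~0.1–1 s of a pure-Python
callback.  A fixed-step implicit-midpoint solver (A-stable, order 2;
Newton iteration with the analytic Jacobian, componentwise scaled
residual tolerance 1e-12, default test step 1e-5 s) is retained as a
fidelity cross-check: the two solvers agree on the post-transient gaze
trace of an oscillatory preset to better than 1e-3 deg.

Solver tolerances are role-dependent: target generation uses
rtol 1e-8/atol 1e-11, GA fitness evaluation rtol 1e-5/atol 1e-8.  The
objective noise induced by the looser setting is ~1e-4 deg, two orders of
magnitude below any threshold on which solutions are selected, and halves
the evaluation cost.  Trajectories are exposed on a uniform 2500 Hz
output mesh regardless of internal stepping, matching the mesh of
(upsampled) experimental targets.

## Fitness functions

Candidates are simulated from rest with a 1.5-deg displacement command
for 6 s.  The first 2.4 s are discarded as transient; the remaining gaze
trace is min-max normalised *for boundary detection only*, and local
minima with normalised value < 0.2 mark cycle boundaries (the threshold
rejects shallow ripple minima that do not terminate a cycle — a cycle
must contain its crest, so the 0.2 test is applied to the minima, not
used to trim the segment).  The un-normalised segment between the last
two boundary minima is the extracted cycle.

Nystagmus objectives: d_S is the RMS difference between the target cycle
and the simulated cycle time-rescaled to the target period and
cubic-resampled onto the target mesh, compared in degrees (not in
normalised units — this is what lets the shape objective alone drive
solutions to the correct amplitude, making a separate amplitude objective
redundant); d_P is the absolute difference of the *unscaled* periods.
Saccade objectives: one RMS velocity-profile difference per target
amplitude (5, 10, 20 deg by default), with the simulated velocity
evaluated directly on the target's mesh from onset to the target's end
point so lengths always agree.  Non-oscillatory candidates and failed
integrations receive 1e60 on every objective; such penalty vectors are
dominated by every finite vector and are purged by selection as soon as
any oscillatory solution exists.

## NSGA-II

The optimiser is an elitist NSGA-II: fast non-dominated sorting, crowding
distance, binary tournament on (rank, crowding), merge of parents and
offspring, truncation back to the population size.  Operator choices:

- **Heuristic crossover** (ratio R = 1.2): the child lies on the line
  through both parents, R of the way past the better one, clipped to the
  bounds.  R is the conventional default for this operator; it reaches
  good solutions at markedly smaller population sizes than intermediate
  (blend) crossover on these problems.
- **Adaptive feasible mutation**: a Gaussian step per parameter whose
  scale (initially 10% of each parameter's range) grows by 1.15× in
  generations where ≥ 20% of mutants reach a merged-population rank at
  least as good as their parent's, and shrinks by 0.85× otherwise,
  clamped to [1e-4, 0.5] of the range; steps are reflected at the bounds
  so every mutant is feasible.  This reproduces the documented behaviour
  of the closed-source "adaptive feasible" operator (direction-randomised,
  success-adaptive, always in bounds); the constants are this package's
  own choices.
- **Crowding space**: phenotype (objective space) by default; genotype
  (bound-normalised decision space) selectable.
- 80% of offspring come from crossover, 20% from mutation.

Runs are bit-reproducible from the seed.  Repeated decision vectors are
evaluated once per run (the objective maps are deterministic), which
saves substantial work once the population begins to concentrate.
Initial populations are uniform in the search box
1 ≤ α ≤ 1000, 0.1 ≤ β ≤ 60, 1e-5 ≤ ε ≤ 0.1, 0 ≤ γ ≤ 12 (extensible to
150), 50 ≤ α′ ≤ 1000, 0.1 ≤ β′ ≤ 60.

From a final front, one solution is selected by: smallest d_P
(`min_period`, the default for nystagmus — it consistently gives a good
shape fit as well), smallest Euclidean norm of the objective vector
(`min_norm`), or smallest single component (`best_objective`).  Ties are
broken lexicographically on the objective vector.

## Convergence metrics

The hypervolume indicator is H_I = 1 − H(F̂, y_R)/H(0, y_R), where
H(F̂, y_R) is the convex-hull volume between the estimated front and a
reference point y_R dominated by every front point (component-wise
maximum over all fronts being compared), and H(0, y_R) is the hypercuboid
spanned by the origin and y_R.  The hull's vertex set is every corner
obtained by replacing a subset of y_R's coordinates with a front point's
coordinates; in 2-D this is the same hull as "front + y_R + per-axis
projections through the front minima", and it is the set required for a
perfect single-point front at the origin to span the whole hypercuboid
(H_I = 0 ⇔ perfect simultaneous fit; H_I = 1 ⇔ the front carries no
volume).  The hull is an approximation to the dominated volume, not an
exact (WFG-style) hypervolume; a Monte-Carlo dominated-volume estimator
is used as an independent oracle in the tests and agrees with the hull
indicator in ordering.  Note that under NSGA-II the indicator is not
strictly monotone per generation: once the rank-0 set saturates the
population, crowding truncation may drop non-extreme front points,
causing fluctuations at the level of a single crowding gap (~1e-5 on the
toy problem) even though the front never genuinely degrades.

d_F̂ is the minimum Euclidean distance from the front to the objective
origin.  Across independent runs both metrics are summarised by mean,
sample SD (n−1) and coefficient of variation.

## UPO extraction

Real nystagmus is nonperiodic; a representative single cycle is obtained
as an (unstable) periodic orbit of the inter-cycle interval return map.
Stages, with defaults:

1. **Interval detection.** The gaze trace is differentiated (central
   differences) and lightly smoothed (20 ms moving average — position
   noise is amplified ~fs-fold by differentiation and would otherwise
   cause chatter crossings).  The velocity threshold defaults to half the
   median per-cycle fast-phase peak velocity, signed by the fast-phase
   direction — a deterministic reading of "roughly the middle of the fast
   phase".  Crossings are located with sub-sample linear interpolation; a
   crossing within 0.1 s of the previous one is treated as chatter and
   dropped.
2. **Delay embedding** of the interval sequence, w_k = (τ_k, …,
   τ_{k+d−1}), d = 2.
3. **So transform** G(w_n) = (I − DF(w_n))⁻¹(w_{n+1} − DF(w_n) w_n),
   which maps every point exactly onto the fixed point when the return
   map is linear.  DF is estimated per point by a least-squares local
   linear fit over the k = 8 nearest delay vectors (the neighbourhood
   scheme and k are this package's choices; an exact Jacobian can be
   supplied instead).  Points with I − DF singular to working precision
   (condition number > 1e12) are skipped with a logged count.
4. **Histogram peak.** Transformed points within a tube of diameter 0.5
   (interval units, i.e. seconds; perpendicular Euclidean distance) around
   the delay-space diagonal are projected onto the diagonal and binned at
   0.025 s with bin edges anchored at 0; the tallest bin's centre is the
   orbit period τ*, ties going to the smaller period.
5. **Cycle selection.** Among cycles whose interval is within 0.0125 s of
   τ*, the one with the smallest first-to-last gaze difference is chosen;
   three copies are concatenated and re-sectioned between two successive
   fast-phase onsets so the cycle starts at a fast phase, oriented with
   the fast phase rightward, and spline-upsampled 10× (250 → 2500 Hz).
   The reported cycle period lies on the recording's sample grid and is
   therefore within one coarse sample of the sub-sample crossing interval.

On noise-free periodic input the pipeline recovers the true period to one
sample; on jittered input (period SD 0.03 s, 100 cycles) it recovers the
mean period to within one histogram bin.

## Synthetic data

All fitting targets are generated from the model itself, so recovery of
known parameters can be verified end to end.  Oscillatory presets were
discovered by a seeded Latin-hypercube search of the default bounds (400
samples, seed 20), keeping parameter sets whose simulated cycle has
period in [0.1, 2] s and peak-to-peak amplitude in [0.5, 10] deg —
ranges typical of clinical nystagmus; seven verified presets are frozen
in `oculofit.synthetic.OSCILLATORY_PRESETS`.  The saccade preset
(α = 10, β = 4, ε = 0.004, γ = 5, α′ = 600, β′ = 9) produces accurate
saccades whose peak velocity increases with amplitude (main-sequence
behaviour).  Saccade targets end where the velocity falls and stays below
1 deg/s after its peak; the fitness module instead truncates comparisons
to the target's length, so this end-point convention only defines the
targets themselves.

Pseudo-experimental recordings concatenate jittered copies of a base
cycle: per-cycle lognormal time rescaling (period SD 0.03 s by default),
Gaussian amplitude scaling about the cycle mean (SD 5%), cubic resampling
to 250 Hz and additive Gaussian position noise (SD 0.02 deg, about four
times a typical recorder's quantisation resolution).  The generator
emulates cycle-to-cycle period/amplitude variability and measurement
noise; it does not emulate waveform-shape drift, blinks, baseline
sinusoidal oscillation, or slow gaze drifts, so passing tests demonstrate
correctness of the extraction machinery, not robustness to every clinical
artefact — recordings with blinks need upstream preprocessing.

## Problem sizes

The package's synthetic studies are run at desk scale: 4 independent
NSGA-II runs of population 200 × 40 generations per problem (roughly
8,000 model integrations per run after caching), rather than the
500–8000 × 100–200 populations a full study would use on parallel
hardware.  At this scale the nystagmus bi-objective fit recovers the
generating parameters' behaviour (d_P ≤ 0.01 s, d_S ≤ 5% of the target's
peak-to-peak amplitude) in at least 3 of 4 runs, and the saccade
tri-objective self-fit reaches every objective below 2% of the target's
peak velocity in at least 3 of 4 runs; α′ and β′ remain weakly
identifiable at every scale, so per-parameter CVs are reported but not
gated on.

## Known limitations

- The hull-based hypervolume under-estimates the dominated volume for
  strongly non-convex fronts; it is used as the convergence measure, with
  the Monte-Carlo estimator as a test oracle only.
- `batch_integrate` and multi-run experiments offer process-level
  parallelism (joblib); outputs are independent of the worker count.
- Only horizontal dynamics are modelled: no vertical/torsional
  components, no smooth-pursuit or vestibular subsystems, and no
  bifurcation-continuation tooling.
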