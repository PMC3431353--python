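# Methods

## Model

A cargo (radius r) moves along a one-dimensional coordinate x on a
microtubule, permanently linked to N_f plus-end-directed ("forward",
kinesin-2-like) and N_b minus-end-directed ("backward", cytoplasmic-
dynein-like) motors through independent elastic linkers.  Each motor is a
point-like head that, when engaged, occupies a lattice site x_j = j·Δx with
Δx = 8 nm.

**Linker force.**  A linker is slack within ±x0 of the cargo and Hookean in
the excess extension beyond it; the force on the cargo from motor i at
distance d_i = x_i − x_c is

    f_i = k (d_i − x0)   for d_i ≥ x0,
    f_i = 0              for |d_i| < x0,
    f_i = k (d_i + x0)   for d_i ≤ −x0,

always attractive toward the motor and continuous at |d_i| = x0.  Motors
with f_i ≠ 0 are *pulling* motors; the pulling state (q_f, q_b) counts them
per team, the attachment state (n_f, n_b) counts all engaged motors.  A
motor exactly at the slack boundary exerts zero force and is classified
non-pulling; because the force vanishes there the convention has no
dynamical consequence.

**Cargo dynamics.**  Overdamped Langevin equation

    dx_c/dt = (1/γ) Σ_i f_i + ξ(t),

with white noise of intensity k_B T / γ (fluctuation–dissipation) and
Stokes drag γ = 6π η r, η = n_γ · η_water.  Water viscosity is fixed at
1.0e-3 Pa·s, so the referential n_γ = 500, r = 500 nm give
γ = 4.712e-3 pN·s/nm and a free-cargo diffusivity k_B T/γ ≈ 880 nm²/s at
300 K — consistent with the simulated cargo speeds of a few hundred nm/s
under pN-scale forces.

**Motor kinetics.**  An engaged motor under load L_i (the reaction to f_i,
positive when opposing the motor's polarity: L_i = f_i for forward motors,
−f_i for backward ones) steps by +Δx in its own direction with rate

    p_step(L) = v(L)/Δx,   v(L) = v0 (1 − (L/F_s)^w)  for 0 ≤ L ≤ F_s,

v = 0 at or beyond stall and v = v0 for assisting loads (L < 0); no
backward steps exist.  The assisting-load cap is the minimal extension of
the force–velocity relation outside its stated domain.  It detaches with
rate ε·exp(|f_i|/F_d); the magnitude is used because the unbinding is
driven by the mechanical strain of the linkage regardless of sign.  A
detached motor re-engages with rate Π, uniformly at one of the lattice
sites strictly inside the slack zone (so a fresh linker is always relaxed;
27 sites for x0 = 110 nm, Δx = 8 nm).

A taut motor that is dragged beyond x0 + F_s/k carries a super-stall load,
cannot step, and acts as an elastic anchor until it detaches — the
mechanism behind both the low-velocity tug-of-war mode and the
high-velocity elastic-restitution segments.

## Integration

First-order Euler–Maruyama for the cargo combined with independent
Bernoulli thinning of each motor event within a step dt (default 1e-5 s;
supported range 1e-7–1e-5 s).  All forces and event probabilities are
evaluated on the state at the beginning of the step.  Step and detachment
draws of one motor are independent within a step; at dt = 1e-5 s every
per-event probability is below ~1e-3, so higher-order terms are
negligible.  A guard aborts and refines dt tenfold (restarting the
trajectory) if any per-event probability exceeds 0.1; with the shipped
parameter sets the guard never trips, because detachment removes a motor
long before its rate approaches 1e4/s.

Simulations start with all motors engaged at independently drawn relaxed
sites and the cargo at 0, run 20 s of simulated time, and stop early if
every motor is detached.  Trajectories are sampled every 0.01 s (cargo
position, per-motor flags and positions, derived state counts).  Each
trajectory consumes one RNG stream seeded from a deterministically spawned
child of the ensemble seed, so ensembles are reproducible, order-
independent, and prefix-stable.  The inner loop is numba-compiled; a plain
Python reference step with identical semantics backs the unit-level
oracles.

## Parameter sets

The referential set (RS) is the symmetric parameterization used for all
baseline results: N_f = N_b = 2, n_γ = 500, r = 500 nm, T = 300 K,
x0 = 110 nm, k = 0.02 pN/nm, v0 = 500 nm/s, w = 2, F_s = 6 pN, ε = 0.2/s,
F_d = 3 pN, Π = 2/s.  The stiff-linker variant changes only k to
0.3 pN/nm (the value measured for motors in vitro).  The dispersion set
("Set 1": Π_f = 3.5/s, Π_b = 2.2/s, ε_f = 0.08/s, ε_b = 0.07/s,
n_γ = 300) favours kinesin; the aggregation set ("Set 2": Π_f = 1.8/s,
Π_b = 2.2/s, ε_f = ε_b = 0.08/s, n_γ = 300) favours dynein.

The scaling transformation F_s→λF_s, F_d→βF_d, k→λk, γ→λγ (β ≈ √λ)
produces systems with near-identical dynamics at lower stall forces.  λ is
accepted on (0, 1] with a warning for λ ≤ 0.4 (outside the validated
range) and for β far from √λ; stiffness is scaled with λ like the forces
since no separate rule is stated, and per-species stiffness can be set
explicitly where a config requires it.

## Trajectory analysis

**Segmental velocities.**  Trajectories sampled at 0.01 s are split into
processive periods, each period is tiled with consecutive non-overlapping
40-point (0.4 s) windows, and a window is accepted if the ordinary-least-
squares slope of position on time exceeds 100 nm/s in magnitude with
|Pearson r| > 0.98.  The |r| (rather than signed r) makes the linearity
filter symmetric for backward segments.  The published selection procedure
for processive periods is not available; the implementation declares its
own rule: on a 0.1-s moving-average smoothed path, a period ends when
cumulative backtracking exceeds 60 nm, boundaries are trimmed to the local
extrema, and periods with net displacement under 100 nm are dropped.  All
thresholds are exposed as keyword arguments and in the `analysis` section
of config files.

**Histograms.**  Each accepted segment adds weight 1 to its velocity bin
(default bin width 55 nm/s, giving 4–5 bins per 250-nm/s mode; the
published bin-size criterion is not reproduced, and every quantity reported
here is insensitive to the choice).  Its forty per-sample attachment and
pulling states contribute fractional-occupancy weights (count/40), so the
state-resolved curves sum to the total bin-exactly — fractional occupancy
rather than majority vote preserves this partition identity.  The `max1`
mode rescales everything jointly so the distribution maximum equals 1.

**Spatial distributions and μ.**  For a velocity window, motor–cargo
offsets of attached motors are pooled over *every* sample of *every*
accepted forward-moving segment in the window.  μ is the quotient of
forward-team counts beyond +x0 over backward-team counts beyond −x0;
histograms are binned at 10 nm so ±x0 fall on bin edges and the
area-quotient and direct-count definitions agree exactly.

**Reversions.**  A long-term reversion is a sustained direction change:
on the 0.05-s smoothed path, alternating runs are delimited with a 250-nm
hysteresis threshold, and a run boundary counts as a reversion when the
following excursion covers ≥ 250 nm and lasts > 1 s.  Both thresholds are
configurable; the event count is non-increasing in each.

**Rise times.**  The slowing-down phase before a reversion is fitted with
x(t) = A (1 − exp(−t/t_r)) + c from its onset to the reversal extremum.
The onset — "where the path stops being linear" — is located on the
derivative: the run (plateau) velocity is the median of the 0.35-s
smoothed velocity over the first half of a ≤4-s lookback window, and the
onset is the last sample at which the smoothed velocity still reaches 80%
of it.  A residual-band criterion on the position (deviation from the
early-window line) was implemented first and rejected: on stochastic
trajectories the early window's own velocity wander sets the band width,
which either hides the sharp slowdowns of stiff-linker reversions inside
multi-second near-linear windows (the saturating-exponential fit then degenerates to a line,
t_r unbounded) or truncates the gradual ones; the two reversion shape
classes then become indistinguishable.  The velocity-threshold rule
recovers synthetic ground truth (exact for noiseless wave fixtures,
within ~10% at 5–10 nm noise across t_r = 0.1–0.75 s) and cleanly
separates a 300-ms wave from an 80-ms sharp stop under noise.  Fits are
flagged and excluded when the pre-reversal window is shorter than 0.6 s,
the plateau velocity is below 50 nm/s, the onset falls within 10 samples
of the reversal, or the fitted t_r exceeds 1.5× the fitted window (a
saturation not contained in the data is indistinguishable from a line; a
modest overhang is allowed because many simulated reversions are triggered
by a detachment before the slowdown fully saturates).

The ensemble statistic is the exponential-decay scale of the t_r
distribution: the distribution rises to a mode and decays exponentially,
so the characteristic value is the left-truncated-at-mode maximum-
likelihood scale (mean excess above the mode, mode located on a 0.1-s-bin
histogram), with a bootstrap standard error.  When the mode sits in the
first bin this is the plain exponential maximum-likelihood estimate.

**Multimodal fits.**  Velocity branches (forward, or backward folded onto
the positive axis), max-normalized, are fitted with a sum of four
Gaussians with free amplitudes, centers and widths, initialized at centers
m·250 nm/s with amplitudes read off the histogram; amplitudes are bounded
below by 0 and widths kept positive.  The exact published parameterization
is not reproduced, so the most general form is used; constrained variants
can be expressed through the initialization arguments.  A mode with
amplitude below 10% of the largest is degenerate; remaining centers closer
than 125 nm/s are merged when counting distinct modes, so a unimodal shape
split across two overlapping Gaussians is still counted once.  A2/A1 is
the amplitude quotient of the second to first *significant* mode in
ascending-center order, with the uncertainty propagated from the fit
covariance.

## Synthetic fixtures

The fixture generator produces objects with closed-form ground truth used
to validate the pipeline independently of the simulator: constant-velocity
lines (known slope), triangle waves (known split into two processive
periods), wave-shaped reversions with a velocity-continuous linear-to-
exponential approach (known onset and t_r), and four-Gaussian histograms
(known mixture parameters), each with optional Gaussian or Poisson noise.
These fixtures emulate the deterministic skeleton of real trajectories
only — they contain no stepping shot noise, no attachment/detachment
kinetics, and no velocity wander — so passing them demonstrates
correctness of the estimators, not robustness to every feature of real
tracking data.

## Problem sizes

The shipped analysis runs use reduced ensembles chosen so every
Monte-Carlo error sits well inside the corresponding published
uncertainty: 400 referential trajectories for the pulling-ratio and
rise-time statistics (the original study used 1000–4000), 250
stiff-linker, 300 per asymmetric set, 150 for the imbalance set.  The
mode-structure fit is the exception: in ensembles below ~1000
trajectories the third velocity mode is only a marginal shoulder and the
free-center four-Gaussian fit bistably spends its third component on the
second peak's shoulder (subsampling experiments put the fitted spacing at
195–270 nm/s for n = 700 but 220–262 nm/s for n = 1000), so the
referential histogram is pooled up to 1000 trajectories before fitting.
A progression-constrained variant (centers forced to an arithmetic
progression, `fit_mode_progression`) is provided but not used for the
headline spacing: it compromises the spacing downward to cover the
shoulder instead of resolving it.  The test suite uses smaller ensembles
with correspondingly widened Monte-Carlo margins.  All randomness derives
from a single seed through spawned child streams.

## Known limitations

- The processive-period selection and the histogram bin-size criterion are
  this package's own concretizations of procedures whose published
  descriptions are not available; both are configurable, and the reported
  quantities are insensitive to the bin size but not entirely to the
  selection thresholds.
- With one extra backward motor (2 vs 3) the model yields a strong but not
  near-total backward bias (~86% of segments versus the published ~98%);
  the minority forward segments are genuine ~1-s runs during which the
  backward team is depleted to about one attached motor.  See the
  state-decomposition note below.
- In the 350–550 nm/s window of the referential system the (1,0) pulling
  state carries slightly more weight than (2,0) (the published account
  attributes the ~500 nm/s mode mainly to (2,0)); both states peak there
  and the ordering is sensitive to how long a freshly attached motor needs
  to traverse the slack zone (~110 nm at a ~10–60 nm/s closure speed).
- The stiff-linker pulling ratio comes out near 6.5 rather than the
  published 4.8: backward anchors at k = 0.3 pN/nm detach within a few
  tens of ms of crossing the slack boundary, and their pooled sample count
  is correspondingly sensitive to that dwell time.
- Cargo rotation, three-dimensional geometry, microtubule obstacles,
  motor back-stepping, and fitting of motor parameters to experimental
  tracking data are out of scope.
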