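# tugofwar

Stochastic simulation and trajectory analysis of bidirectional cargo
transport along microtubules by two opposing teams of molecular motors
with loose elastic coupling — the regime relevant for organelles such as
melanosomes carried by kinesin-2 and cytoplasmic dynein in *Xenopus
laevis* melanophores.  It is aimed at researchers modelling intracellular
transport and at experimentalists who want to run the same segmental-
velocity, reversion and multimodal-fit analyses on their own tracking
data.

## Model

A cargo at position x_c obeys an overdamped Langevin equation,

    γ dx_c/dt = Σ_i f_i + γ ξ(t),      γ = 6π η r,

driven by the elastic linker forces f_i of all engaged motors and thermal
noise satisfying the fluctuation–dissipation relation.  Each motor walks
on an 8-nm lattice toward its own end of the microtubule with a
load-dependent rate v(L)/Δx, v(L) = v0 (1 − (L/F_s)^w), detaches with
rate ε exp(|f|/F_d), and re-engages with rate Π at a relaxed position
near the cargo.  Linkers are slack within ±x0 of the cargo: only motors
beyond that distance ("pulling" motors) exert force, which makes the
instantaneous velocity depend on the *pulling state* (q_f, q_b) rather
than on the number of engaged motors alone.  With the loosely coupled
referential parameters (k = 0.02 pN/nm, Table-style set exposed as
`referential_set()`), the model produces multimodal segmental-velocity
distributions with modes spaced ~250 nm/s apart, wave-shaped direction
reversions with characteristic rise times of a few hundred ms, and
velocities well above the single-motor zero-load speed; stiff linkers
(k = 0.3 pN/nm) collapse the distribution to a single mode and make
reversions abrupt.

The analysis pipeline mirrors standard single-particle-tracking practice:
trajectories sampled at 0.01 s are cut into processive periods, tiled
with 40-point windows accepted if |v| > 100 nm/s and |r| > 0.98, and the
resulting segmental velocities are histogrammed (with an exact
decomposition over motor states), fitted with four Gaussians, and scanned
for long-term reversions (≥ 250 nm, > 1 s) whose slowing-down phase is
fitted with x(t) = A(1 − e^(−t/t_r)) + c.  See `docs/methods.md` for the
full account.

## Worked example

```python
from tugofwar import (referential_set, simulate_ensemble,
                      segment_trajectories, branch_histogram,
                      fit_four_gaussians, count_modes, mode_spacing,
                      motor_spatial_distribution)

cfg = referential_set()                      # symmetric 2-vs-2 teams
trajs = simulate_ensemble(cfg, 150, base_seed=42)   # 150 x 20 s
segs = segment_trajectories(trajs)           # accepted 0.4-s segments

hist = branch_histogram(segs, direction=+1, bin_width=55.0)
fit = fit_four_gaussians(hist)
print("modes:", count_modes(fit), " spacing:", round(mode_spacing(fit)))

for name, window in {"I": (100, 300), "II": (350, 550),
                     "III": (700, 900)}.items():
    sd = motor_spatial_distribution(trajs, window, segments=segs)
    print(f"mu[{name}] = {sd.mu:.2f}")
```

Output from this exact run:

```
modes: 3  spacing: 279
mu[I] = 1.83
mu[II] = 4.32
mu[III] = 4.71
```

The velocity distribution is multimodal with modes ~250–280 nm/s apart.
μ is the ratio of pulling forward to pulling backward motors among
forward-moving segments in a velocity window: in the low-velocity region
I it is close to 2 — two kinesins dragging one dynein anchor, an active
tug-of-war — while in the fast regions the opposition has largely let
go.  Reversion rise times come from
`rise_time_statistics(collect_reversions(trajs))`, which on this
ensemble prints `t_r = 197 +/- 23 ms (93 events)`, versus
`t_r = 121 +/- 11 ms (99 events)` for the same system with
`cfg.with_stiffness(0.3)`; at the ensemble sizes of
`scripts/acceptance.py` the loose-linker value rises to ≈240 ms while
the stiff one stays near ≈110 ms — the wave-shaped versus abrupt
reversion contrast.

A command-line interface wraps the same stages:

```bash
tugofwar simulate --n-traj 100 --seed 1 --out ens.h5
tugofwar analyze segments --in ens.h5
tugofwar analyze reversions --in ens.h5
tugofwar reproduce spatial_mu --n-traj 300 --seed 1 --out out/
```

`analyze` also accepts a plain two-column CSV of (t, x) from any tracking
software; motor-state-resolved outputs are then unavailable.

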