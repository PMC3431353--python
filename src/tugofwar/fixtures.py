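"""Deterministic synthetic inputs with analytically known ground truth.

These generators produce toy trajectories and histograms whose true slope,
rise time or mixture parameters are known in closed form, so every stage of
the analysis pipeline (segmentation, reversion fitting, multimodal fitting)
can be exercised and validated independently of the stochastic simulator.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .engine import Trajectory

_KINDS = ("line", "triangle", "exp_reversion", "mixture_hist")


def make_fixture(kind: str, params: Optional[dict] = None,
                 seed: int = 0):
    """Dispatch on ``kind``; see the individual generators for parameters."""
    params = dict(params or {})
    if kind == "line":
        return line_trajectory(seed=seed, **params)
    if kind == "triangle":
        return triangle_trajectory(seed=seed, **params)
    if kind == "exp_reversion":
        return exp_reversion_trajectory(seed=seed, **params)
    if kind == "mixture_hist":
        return mixture_histogram(seed=seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {_KINDS}")


def line_trajectory(v: float = 400.0, duration: float = 4.0,
                    sample_dt: float = 0.01, noise: float = 0.0,
                    seed: int = 0) -> Trajectory:
    """Constant-velocity path ``x = v*t`` with optional i.i.d. noise (nm)."""
    t = np.arange(0.0, duration + 0.5 * sample_dt, sample_dt)
    x = v * t
    if noise > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise, size=len(t))
    return Trajectory.from_timeseries(t, x)


def triangle_trajectory(v: float = 400.0, half_period: float = 2.0,
                        n_periods: int = 1, sample_dt: float = 0.01,
                        noise: float = 0.0, seed: int = 0) -> Trajectory:
    """Forward for ``half_period`` s at +v, then backward at -v, repeated."""
    t = np.arange(0.0, 2 * n_periods * half_period + 0.5 * sample_dt,
                  sample_dt)
    phase = np.mod(t, 2 * half_period)
    x_cycle = np.where(phase <= half_period, v * phase,
                       v * (2 * half_period - phase))
    x = x_cycle  # net displacement per cycle is zero
    if noise > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise, size=len(t))
    return Trajectory.from_timeseries(t, x)


def exp_reversion_trajectory(
    v_pre: float = 500.0,
    t_pre: float = 2.0,
    t_r: float = 0.75,
    rise_mult: float = 4.0,
    v_back: float = 400.0,
    t_back: float = 1.5,
    sample_dt: float = 0.01,
    noise: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Wave-shaped reversion with a saturating-exponential slowing down.

    The path moves linearly at ``v_pre`` for ``t_pre`` s, then follows
    ``x = x_on + A*(1 - exp(-(t - t_on)/t_r))`` with ``A = v_pre * t_r`` so
    the velocity is continuous at the onset, and after ``rise_mult * t_r``
    seconds reverses into a linear backward phase at ``-v_back`` lasting
    ``t_back`` s.  Ground truth: rise time ``t_r``, onset at ``t_pre``.
    """
    A = v_pre * t_r
    t_rev = t_pre + rise_mult * t_r
    t_end = t_rev + t_back
    t = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    x = np.empty_like(t)
    pre = t <= t_pre
    x[pre] = v_pre * t[pre]
    x_on = v_pre * t_pre
    rise = (t > t_pre) & (t <= t_rev)
    x[rise] = x_on + A * (1.0 - np.exp(-(t[rise] - t_pre) / t_r))
    x_rev = x_on + A * (1.0 - np.exp(-(t_rev - t_pre) / t_r))
    back = t > t_rev
    x[back] = x_rev - v_back * (t[back] - t_rev)
    if noise > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise, size=len(t))
    return Trajectory.from_timeseries(t, x)


def mixture_histogram(
    amplitudes=(1.0, 0.6, 0.3, 0.15),
    centers=(250.0, 500.0, 750.0, 1000.0),
    sigmas=(80.0, 80.0, 80.0, 80.0),
    bin_width: float = 25.0,
    v_max: float = 1400.0,
    counts: Optional[float] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact (or Poisson-noised) multi-Gaussian histogram.

    Returns ``(bin_centers, weights)``.  With ``counts`` set, the exact
    curve is scaled so its maximum corresponds to that many histogram
    counts and Poisson noise is applied bin-wise.
    """
    x = np.arange(0.5 * bin_width, v_max, bin_width)
    y = np.zeros_like(x)
    for A, c, s in zip(amplitudes, centers, sigmas):
        y += A * np.exp(-((x - c) ** 2) / (2.0 * s * s))
    if counts is not None:
        lam = y / y.max() * counts
        y = np.random.default_rng(seed).poisson(lam).astype(float)
    return x, y
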