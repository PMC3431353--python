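"""Stochastic engine for cargo transport by two opposing motor teams.

The cargo obeys an overdamped Langevin equation driven by the elastic
linker forces of all attached motors plus thermal noise satisfying the
fluctuation-dissipation relation.  Attached motors step forward along the
8-nm microtubule lattice with a load-dependent rate, detach with a rate
growing exponentially in the linker force, and detached motors re-attach at
a relaxed lattice site near the cargo.  Integration is first-order
Euler-Maruyama for the cargo combined with independent Bernoulli thinning
of the motor events within each time step; a guard rejects time steps for
which any per-event probability leaves the first-order regime.

The inner loop is compiled with numba; :func:`advance` provides a plain
Python reference step with identical semantics for unit-level reasoning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import List, Optional

import numpy as np
from numba import njit

from .params import ModelConfig, MotorSpecies

#: largest per-event probability per time step still considered first-order
MAX_EVENT_PROB = 0.1

_STATUS_TMAX = 0
_STATUS_FULL_DETACH = 1
_STATUS_DT_TOO_LARGE = 2


class EngineError(RuntimeError):
    pass


class DtTooLargeError(EngineError):
    """An event probability per step exceeded the first-order guard."""


# ---------------------------------------------------------------------------
# elementary rates (array-friendly reference implementations)


def linker_force(d, k: float, x0: float):
    """Signed force the linker exerts on the cargo, pN.

    ``d = x_motor - x_cargo``.  Zero inside the slack zone ``|d| < x0``;
    outside, Hookean in the excess extension and always directed from the
    cargo toward the motor: ``k*(d - x0)`` for ``d >= x0`` and
    ``k*(d + x0)`` for ``d <= -x0``.  Continuous at ``|d| = x0``.
    """
    d = np.asarray(d, dtype=float)
    out = np.where(d >= x0, k * (d - x0), np.where(d <= -x0, k * (d + x0), 0.0))
    return out if out.ndim else float(out)


def stepping_rate(L, v0: float, Fs: float, w: float, dx: float):
    """Probability per unit time of an 8-nm step under load ``L`` (pN).

    The rate is ``v(L)/dx`` with the force-velocity relation
    ``v(L) = v0*(1 - (L/Fs)**w)`` for loads between 0 and the stall force.
    Loads at or above stall give rate 0; assisting loads (``L < 0``) are
    capped at the zero-load velocity.  No backward steps exist.
    """
    L = np.asarray(L, dtype=float)
    v = np.where(L <= 0.0, v0,
                 np.where(L >= Fs, 0.0, v0 * (1.0 - (np.abs(L) / Fs) ** w)))
    out = v / dx
    return out if out.ndim else float(out)


def detachment_rate(L, eps: float, Fd: float):
    """Probability per unit time of unbinding under load ``L`` (pN).

    ``eps * exp(|L|/Fd)``: the zero-load rate grows exponentially with the
    magnitude of the linker force.
    """
    L = np.asarray(L, dtype=float)
    out = eps * np.exp(np.abs(L) / Fd)
    return out if out.ndim else float(out)


def attachment_sites(x_c: float, x0: float, dx: float) -> np.ndarray:
    """Lattice sites strictly inside the slack zone around the cargo.

    A motor attaching at any of these exerts zero force immediately
    afterwards (relaxed-attachment rule).
    """
    jlo = int(math.floor((x_c - x0) / dx)) + 1
    while jlo * dx <= x_c - x0:
        jlo += 1
    jhi = int(math.ceil((x_c + x0) / dx)) - 1
    while jhi * dx >= x_c + x0:
        jhi -= 1
    if jhi < jlo:
        raise EngineError("no lattice site inside the slack zone")
    return dx * np.arange(jlo, jhi + 1, dtype=float)


# ---------------------------------------------------------------------------
# system state and reference step


@dataclass
class SystemState:
    """Instantaneous state: cargo position plus per-motor engagement.

    Motor ordering is forward team first, then backward team.  Attached
    motor positions lie on the lattice ``{j*dx}``; positions of detached
    motors are meaningless and kept only as storage.
    """

    t: float
    x_c: float
    attached: np.ndarray  # (M,) bool
    motor_x: np.ndarray   # (M,) float, nm
    polarity: np.ndarray  # (M,) int, +1/-1

    def copy(self) -> "SystemState":
        return SystemState(self.t, self.x_c, self.attached.copy(),
                           self.motor_x.copy(), self.polarity)

    def counts(self, cfg: ModelConfig):
        """(n_f, n_b, q_f, q_b): attached and pulling counts per team."""
        d = self.motor_x - self.x_c
        x0 = np.where(self.polarity > 0, cfg.forward.x0, cfg.backward.x0)
        pulling = self.attached & (np.abs(d) > x0)
        fwd = self.polarity > 0
        return (int(np.sum(self.attached & fwd)),
                int(np.sum(self.attached & ~fwd)),
                int(np.sum(pulling & fwd)),
                int(np.sum(pulling & ~fwd)))


def _species_of(cfg: ModelConfig, i: int) -> MotorSpecies:
    return cfg.forward if i < cfg.forward.count else cfg.backward


def initial_state(cfg: ModelConfig, rng: np.random.Generator) -> SystemState:
    """All motors engaged at independently drawn relaxed sites, cargo at 0."""
    M = cfg.forward.count + cfg.backward.count
    polarity = np.where(np.arange(M) < cfg.forward.count, 1, -1)
    motor_x = np.empty(M)
    for i in range(M):
        sp = _species_of(cfg, i)
        sites = attachment_sites(0.0, sp.x0, sp.dx)
        motor_x[i] = sites[rng.integers(len(sites))]
    return SystemState(0.0, 0.0, np.ones(M, bool), motor_x, polarity)


def motor_event_probabilities(state: SystemState, cfg: ModelConfig):
    """Per-motor event probabilities for one time step of ``cfg.dt``.

    Returns ``(p_step, p_detach, p_attach)`` arrays; entries are zero for
    the events unavailable in the motor's current engagement state.  Loads
    are the mechanical reactions to the linker forces: ``L_i = f_i`` for
    forward motors and ``L_i = -f_i`` for backward ones.
    """
    M = len(state.motor_x)
    p_step = np.zeros(M)
    p_det = np.zeros(M)
    p_att = np.zeros(M)
    for i in range(M):
        sp = _species_of(cfg, i)
        if state.attached[i]:
            f = linker_force(state.motor_x[i] - state.x_c, sp.k, sp.x0)
            L = f * sp.polarity
            p_step[i] = stepping_rate(L, sp.v0, sp.Fs, sp.w, sp.dx) * cfg.dt
            p_det[i] = detachment_rate(L, sp.eps, sp.Fd) * cfg.dt
        else:
            p_att[i] = sp.pi_att * cfg.dt
    return p_step, p_det, p_att


def advance(state: SystemState, cfg: ModelConfig,
            rng: np.random.Generator) -> SystemState:
    """One Euler-Maruyama + Bernoulli-thinning step (reference path).

    All forces and event probabilities are evaluated on the incoming state;
    step and detachment events of an attached motor are independent within
    the step, mirroring the compiled kernel exactly.
    """
    p_step, p_det, p_att = motor_event_probabilities(state, cfg)
    if max(p_step.max(initial=0.0), p_det.max(initial=0.0),
           p_att.max(initial=0.0)) > MAX_EVENT_PROB:
        raise DtTooLargeError(
            "an event probability per step exceeds "
            f"{MAX_EVENT_PROB}; reduce dt")
    new = state.copy()
    # cargo update from incoming forces
    F = 0.0
    for i in range(len(state.motor_x)):
        if state.attached[i]:
            sp = _species_of(cfg, i)
            F += linker_force(state.motor_x[i] - state.x_c, sp.k, sp.x0)
    gamma = cfg.env.gamma
    new.x_c = state.x_c + (F / gamma) * cfg.dt
    if cfg.thermal_noise:
        new.x_c += math.sqrt(2.0 * cfg.env.kBT * cfg.dt / gamma) * rng.standard_normal()
    # motor events
    for i in range(len(state.motor_x)):
        sp = _species_of(cfg, i)
        if state.attached[i]:
            if rng.random() < p_step[i]:
                new.motor_x[i] += sp.polarity * sp.dx
            if rng.random() < p_det[i]:
                new.attached[i] = False
        else:
            if rng.random() < p_att[i]:
                sites = attachment_sites(state.x_c, sp.x0, sp.dx)
                new.motor_x[i] = sites[int(rng.random() * len(sites))]
                new.attached[i] = True
    new.t = state.t + cfg.dt
    return new


# ---------------------------------------------------------------------------
# compiled kernel


@njit(cache=True)
def _draw_site(x_c, x0, dx):
    jlo = int(math.floor((x_c - x0) / dx)) + 1
    while jlo * dx <= x_c - x0:
        jlo += 1
    jhi = int(math.ceil((x_c + x0) / dx)) - 1
    while jhi * dx >= x_c + x0:
        jhi -= 1
    n = jhi - jlo + 1
    j = jlo + int(np.random.random() * n)
    if j > jhi:
        j = jhi
    return j * dx


@njit(cache=True)
def _run_kernel(seed, n_steps, sample_every, dt, gamma, noise_amp,
                pol, v0, Fs, w, eps, Fd, pi, k, x0, dx,
                stop_on_full_detach,
                xc_out, xm_out, att_out):
    np.random.seed(seed)
    M = pol.shape[0]
    x_c = 0.0
    xm = np.empty(M)
    att = np.empty(M, np.uint8)
    f = np.empty(M)
    for i in range(M):
        att[i] = 1
        xm[i] = _draw_site(x_c, x0[i], dx[i])
    xc_out[0] = x_c
    for i in range(M):
        att_out[0, i] = att[i]
        xm_out[0, i] = xm[i]
    n_rec = 1
    status = _STATUS_TMAX
    for step in range(1, n_steps + 1):
        # forces on cargo from the incoming state
        F = 0.0
        n_att = 0
        for i in range(M):
            if att[i] == 1:
                n_att += 1
                d = xm[i] - x_c
                if d >= x0[i]:
                    f[i] = k[i] * (d - x0[i])
                elif d <= -x0[i]:
                    f[i] = k[i] * (d + x0[i])
                else:
                    f[i] = 0.0
                F += f[i]
        if n_att == 0 and stop_on_full_detach:
            status = _STATUS_FULL_DETACH
            break
        # motor events (probabilities from incoming state)
        for i in range(M):
            if att[i] == 1:
                L = f[i] * pol[i]
                if L <= 0.0:
                    v = v0[i]
                elif L >= Fs[i]:
                    v = 0.0
                else:
                    v = v0[i] * (1.0 - (L / Fs[i]) ** w[i])
                p_step = v / dx[i] * dt
                p_det = eps[i] * math.exp(abs(f[i]) / Fd[i]) * dt
                if p_det > MAX_EVENT_PROB or p_step > MAX_EVENT_PROB:
                    status = _STATUS_DT_TOO_LARGE
                    break
                if np.random.random() < p_step:
                    xm[i] += pol[i] * dx[i]
                if np.random.random() < p_det:
                    att[i] = 0
            else:
                if np.random.random() < pi[i] * dt:
                    xm[i] = _draw_site(x_c, x0[i], dx[i])
                    att[i] = 1
        if status == _STATUS_DT_TOO_LARGE:
            break
        # cargo update
        x_c += (F / gamma) * dt
        if noise_amp > 0.0:
            x_c += noise_amp * np.random.normal(0.0, 1.0)
        if step % sample_every == 0:
            xc_out[n_rec] = x_c
            for i in range(M):
                att_out[n_rec, i] = att[i]
                xm_out[n_rec, i] = xm[i]
            n_rec += 1
    return n_rec, status


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Uniformly sampled cargo path with optional per-motor state.

    ``motor_x`` holds NaN while a motor is detached.  Per-sample team
    counts -- attached ``(n_f, n_b)`` and pulling ``(q_f, q_b)`` -- are
    derived lazily; a motor exactly at the slack boundary counts as
    non-pulling (it exerts zero force there).
    """

    t: np.ndarray
    x: np.ndarray
    attached: Optional[np.ndarray] = None    # (n, M) bool
    motor_x: Optional[np.ndarray] = None     # (n, M) float
    polarity: Optional[np.ndarray] = None    # (M,) int
    config: Optional[ModelConfig] = None
    seed: Optional[int] = None
    termination: str = "external"

    @property
    def sample_dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else float("nan")

    @property
    def has_motor_state(self) -> bool:
        return self.attached is not None and self.motor_x is not None

    @cached_property
    def _pulling(self) -> np.ndarray:
        x0 = np.where(self.polarity > 0, self.config.forward.x0,
                      self.config.backward.x0)
        d = self.motor_x - self.x[:, None]
        return self.attached & (np.abs(d) > x0[None, :])

    @cached_property
    def n_f(self) -> np.ndarray:
        return np.sum(self.attached[:, self.polarity > 0], axis=1)

    @cached_property
    def n_b(self) -> np.ndarray:
        return np.sum(self.attached[:, self.polarity < 0], axis=1)

    @cached_property
    def q_f(self) -> np.ndarray:
        return np.sum(self._pulling[:, self.polarity > 0], axis=1)

    @cached_property
    def q_b(self) -> np.ndarray:
        return np.sum(self._pulling[:, self.polarity < 0], axis=1)

    @classmethod
    def from_timeseries(cls, t, x) -> "Trajectory":
        """Wrap an externally supplied (time, position) series.

        Motor-state-resolved analyses are unavailable on such trajectories.
        """
        t = np.asarray(t, float)
        x = np.asarray(x, float)
        if t.ndim != 1 or t.shape != x.shape:
            raise ValueError("t and x must be matching 1-d arrays")
        return cls(t=t, x=x)


def simulate(cfg: ModelConfig, seed: Optional[int] = None) -> Trajectory:
    """Run one trajectory: all motors initially engaged, cargo at 0.

    The run lasts ``cfg.t_max`` seconds or until every motor is detached
    (when ``stop_on_full_detach`` is set).  If the first-order guard trips,
    the time step is refined tenfold and the run restarted, down to the
    smallest supported dt.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
    seed = int(seed) & 0xFFFFFFFF

    species = [cfg.forward] * cfg.forward.count + [cfg.backward] * cfg.backward.count
    M = len(species)
    if M == 0 and cfg.stop_on_full_detach:
        raise EngineError(
            "no motors configured; set stop_on_full_detach=False to "
            "simulate a free cargo")

    def arr(attr, dtype=float):
        return np.array([getattr(s, attr) for s in species], dtype=dtype)

    pol = arr("polarity", np.int64)
    dt = cfg.dt
    sample_every = int(round(cfg.sample_dt / dt))
    while True:
        n_steps = int(round(cfg.t_max / dt))
        noise_amp = (math.sqrt(2.0 * cfg.env.kBT * dt / cfg.env.gamma)
                     if cfg.thermal_noise else 0.0)
        # attachment probabilities are state-independent: guard them up front
        if M and max(s.pi_att for s in species) * dt > MAX_EVENT_PROB:
            raise DtTooLargeError("pi_att*dt exceeds the first-order guard")
        n_samples = n_steps // sample_every + 1
        xc_out = np.empty(n_samples)
        xm_out = np.empty((n_samples, M))
        att_out = np.empty((n_samples, M), np.uint8)
        n_rec, status = _run_kernel(
            seed, n_steps, sample_every, dt, cfg.env.gamma, noise_amp,
            pol, arr("v0"), arr("Fs"), arr("w"), arr("eps"), arr("Fd"),
            arr("pi_att"), arr("k"), arr("x0"), arr("dx"),
            cfg.stop_on_full_detach, xc_out, xm_out, att_out)
        if status != _STATUS_DT_TOO_LARGE:
            break
        if dt / 10.0 < 1.0e-7 - 1e-12:
            raise DtTooLargeError(
                "event probabilities exceed the first-order guard even at "
                "the smallest supported dt")
        dt /= 10.0
        sample_every *= 10
    att = att_out[:n_rec].astype(bool)
    xm = xm_out[:n_rec].copy()
    xm[~att] = np.nan
    return Trajectory(
        t=np.arange(n_rec) * cfg.sample_dt,
        x=xc_out[:n_rec].copy(),
        attached=att,
        motor_x=xm,
        polarity=pol,
        config=cfg,
        seed=seed,
        termination="full_detach" if status == _STATUS_FULL_DETACH else "t_max",
    )


def ensemble_seeds(base_seed: int, n_traj: int) -> np.ndarray:
    """Deterministic, order-independent per-trajectory seeds (< 2**31)."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n_traj, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def simulate_ensemble(cfg: ModelConfig, n_traj: int, base_seed: int,
                      progress=None) -> List[Trajectory]:
    """Independent trajectories with one RNG stream each.

    Seeds are spawned deterministically from ``base_seed``, so the first
    ``n`` trajectories of a larger ensemble coincide with a smaller one and
    results do not depend on execution order.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    seeds = ensemble_seeds(base_seed, n_traj)
    out = []
    for i, s in enumerate(seeds):
        out.append(simulate(cfg, seed=int(s)))
        if progress is not None:
            progress(i + 1, n_traj)
    return out
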