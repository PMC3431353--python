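"""Engine: elementary rates, one-step dynamics, and stochastic invariants."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from tugofwar.engine import (DtTooLargeError, SystemState, Trajectory, advance,
                             attachment_sites, detachment_rate, initial_state,
                             linker_force, motor_event_probabilities, simulate,
                             simulate_ensemble, stepping_rate)
from tugofwar.params import MotorSpecies, referential_set


class TestLinkerForce:
    @pytest.mark.parametrize("d, expected", [
        (50.0, 0.0),              # inside the slack zone
        (110.0, 0.0),             # continuous at the boundary
        (-110.0, 0.0),
        (285.0, 3.5),             # 0.02*(285-110)
        (-285.0, -3.5),           # attractive toward a motor behind the cargo
    ])
    def test_values(self, d, expected):
        assert linker_force(d, k=0.02, x0=110.0) == pytest.approx(expected)

    def test_continuity_at_boundary(self):
        eps = 1e-9
        for sign in (1, -1):
            lo = linker_force(sign * (110.0 - eps), 0.02, 110.0)
            hi = linker_force(sign * (110.0 + eps), 0.02, 110.0)
            assert abs(hi - lo) < 1e-9

    def test_vectorized(self):
        d = np.array([-300.0, 0.0, 300.0])
        np.testing.assert_allclose(linker_force(d, 0.02, 110.0),
                                   [-3.8, 0.0, 3.8])


class TestSteppingRate:
    def test_zero_load_is_v0_over_dx(self):
        assert stepping_rate(0.0, 500.0, 6.0, 2.0, 8.0) == pytest.approx(62.5)

    def test_stall(self):
        assert stepping_rate(6.0, 500.0, 6.0, 2.0, 8.0) == 0.0
        assert stepping_rate(9.0, 500.0, 6.0, 2.0, 8.0) == 0.0

    def test_half_stall(self):
        # 500*(1-(3/6)^2)/8 = 46.875
        assert stepping_rate(3.0, 500.0, 6.0, 2.0, 8.0) == pytest.approx(46.875)

    def test_assisting_load_capped(self):
        assert stepping_rate(-4.0, 500.0, 6.0, 2.0, 8.0) == pytest.approx(62.5)

    def test_monotone_in_opposing_load(self):
        L = np.linspace(0, 6, 50)
        r = stepping_rate(L, 500.0, 6.0, 2.0, 8.0)
        assert np.all(np.diff(r) <= 1e-12)


class TestDetachmentRate:
    @pytest.mark.parametrize("L, expected", [
        (0.0, 0.2),
        (3.0, 0.2 * math.e),
        (-3.0, 0.2 * math.e),      # magnitude of the load
        (6.0, 0.2 * math.e ** 2),
    ])
    def test_values(self, L, expected):
        assert detachment_rate(L, 0.2, 3.0) == pytest.approx(expected)


class TestAttachment:
    def test_site_enumeration(self):
        # |8j| < 110  =>  j in -13..13, 27 sites
        sites = attachment_sites(0.0, 110.0, 8.0)
        assert len(sites) == 27
        assert sites[0] == -104.0 and sites[-1] == 104.0
        assert np.all(np.abs(sites) < 110.0)

    def test_attachment_is_relaxed(self):
        """Any freshly attached motor exerts zero force on the cargo."""
        rng = np.random.default_rng(3)
        for x_c in rng.uniform(-1e4, 1e4, size=50):
            sites = attachment_sites(x_c, 110.0, 8.0)
            assert np.all(linker_force(sites - x_c, 0.02, 110.0) == 0.0)
            # sites lie on the lattice
            assert np.allclose(sites / 8.0, np.round(sites / 8.0))

    def test_mean_waiting_time(self):
        """With pi = 2/s the attach waiting time is exponential, mean 0.5 s."""
        cfg = referential_set()
        dt = cfg.dt
        p = cfg.forward.pi_att * dt
        rng = np.random.default_rng(11)
        n = 3000
        waits = rng.geometric(p, size=n) * dt  # Bernoulli-thinning model
        # the thinned process must agree with the exponential oracle
        assert np.mean(waits) == pytest.approx(0.5, rel=4.0 / math.sqrt(n))


def _one_motor_state(cfg, d):
    """Single forward motor at distance d from a cargo at 0."""
    return SystemState(t=0.0, x_c=0.0, attached=np.array([True]),
                       motor_x=np.array([float(d)]),
                       polarity=np.array([1]))


def _single_motor_cfg(**motor_kwargs):
    cfg = referential_set()
    fwd = replace(cfg.forward, count=1, **motor_kwargs)
    bwd = replace(cfg.backward, count=0)
    return replace(cfg, forward=fwd, backward=bwd)


class TestOneStepProbabilities:
    def test_matches_enumeration_oracle(self):
        """One-dt outcome probabilities equal brute-force enumeration.

        For a single attached motor the four outcomes (step or not) x
        (detach or not) have probabilities given directly by the rate
        formulas; the engine's per-motor event probabilities must compose
        to exactly the same numbers.
        """
        cfg = _single_motor_cfg()
        state = _one_motor_state(cfg, 150.0)
        p_step, p_det, _ = motor_event_probabilities(state, cfg)
        # oracle from first principles
        f = 0.02 * (150.0 - 110.0)
        v = 500.0 * (1.0 - (f / 6.0) ** 2)
        ps = v / 8.0 * cfg.dt
        pd = 0.2 * math.exp(f / 3.0) * cfg.dt
        outcomes = {}
        for step, det in itertools.product([0, 1], repeat=2):
            prob = (ps if step else 1 - ps) * (pd if det else 1 - pd)
            outcomes[(step, det)] = prob
        assert sum(outcomes.values()) == pytest.approx(1.0, abs=1e-14)
        impl = {}
        for step, det in outcomes:
            impl[(step, det)] = ((p_step[0] if step else 1 - p_step[0])
                                 * (p_det[0] if det else 1 - p_det[0]))
        for key in outcomes:
            assert impl[key] == pytest.approx(outcomes[key], abs=1e-10)

    def test_two_motor_chain_matches_transition_matrix(self):
        """Frozen-cargo two-motor chain equals exhaustive propagation.

        One forward and one backward motor, cargo immobile: the per-step
        engagement dynamics is a 4-state Markov chain whose transition
        matrix follows from the attach/detach formulas.  Propagating the
        engine's per-motor probabilities for k steps must match an
        independent enumeration over all event sequences.
        """
        cfg = referential_set()
        fwd = replace(cfg.forward, count=1)
        bwd = replace(cfg.backward, count=1)
        cfg = replace(cfg, forward=fwd, backward=bwd)
        d_f, d_b = 150.0, -130.0  # fixed motor positions, cargo frozen at 0
        pols = [1, -1]
        species = [fwd, bwd]
        ds = [d_f, d_b]

        def event_probs(att):
            """(p_gain, p_lose) per motor from the engine's formulas."""
            state = SystemState(0.0, 0.0, np.array(att, bool),
                                np.array(ds), np.array(pols))
            p_step, p_det, p_att = motor_event_probabilities(state, cfg)
            return [(p_att[i], p_det[i]) for i in range(2)]

        # engine route: one-step 4x4 matrix from the engine probabilities
        states = list(itertools.product([0, 1], repeat=2))
        T = np.zeros((4, 4))
        for a, s_from in enumerate(states):
            probs = event_probs(s_from)
            for b, s_to in enumerate(states):
                p = 1.0
                for i in range(2):
                    p_gain, p_lose = probs[i]
                    if s_from[i] == 1:
                        p *= p_lose if s_to[i] == 0 else 1 - p_lose
                    else:
                        p *= p_gain if s_to[i] == 1 else 1 - p_gain
                T[a, b] = p
        start = np.zeros(4)
        start[states.index((1, 1))] = 1.0
        k = 3
        impl = start @ np.linalg.matrix_power(T, k)

        # oracle route: enumerate every k-step event sequence from the
        # closed-form rates (written out independently of the engine)
        def rates(att, i):
            sp = species[i]
            if att:
                f = sp.k * (abs(ds[i]) - sp.x0) * (1 if ds[i] > 0 else -1)
                return sp.eps * math.exp(abs(f) / sp.Fd) * cfg.dt
            return sp.pi_att * cfg.dt

        oracle = np.zeros(4)

        def recurse(att, prob, depth):
            if depth == k:
                oracle[states.index(att)] += prob
                return
            for flip0 in (0, 1):
                for flip1 in (0, 1):
                    p = prob
                    new = list(att)
                    for i, flip in enumerate((flip0, flip1)):
                        pe = rates(att[i], i)
                        if flip:
                            p *= pe
                            new[i] = 1 - new[i]
                        else:
                            p *= 1 - pe
                    recurse(tuple(new), p, depth + 1)

        recurse((1, 1), 1.0, 0)
        np.testing.assert_allclose(impl, oracle, atol=1e-10)

    def test_dt_guard(self):
        cfg = _single_motor_cfg(eps=2e4)
        state = _one_motor_state(cfg, 0.0)
        with pytest.raises(DtTooLargeError):
            advance(state, cfg, np.random.default_rng(0))


class TestStallAnchor:
    def test_motor_never_advances_at_stall(self):
        """Beyond x0 + Fs/k the load exceeds the stall force: no steps.

        The motor acts as an elastic anchor; over many steps with a pinned
        cargo its position never changes (detachment is disabled to
        isolate stepping).
        """
        cfg = _single_motor_cfg(eps=0.0, pi_att=0.0)
        stall_d = cfg.forward.x0 + cfg.forward.Fs / cfg.forward.k
        state = _one_motor_state(cfg, stall_d + 1.0)
        # pin the cargo with an effectively infinite drag, no noise
        heavy = replace(cfg, env=replace(cfg.env, n_gamma=1e12),
                        thermal_noise=False)
        rng = np.random.default_rng(5)
        x_start = state.motor_x[0]
        for _ in range(2000):
            state = advance(state, heavy, rng)
        assert state.motor_x[0] == x_start

    def test_stepping_rate_zero_at_stall_distance(self):
        cfg = referential_set().forward
        L = cfg.k * ((cfg.x0 + cfg.Fs / cfg.k) - cfg.x0)
        assert L == pytest.approx(cfg.Fs)
        assert stepping_rate(L, cfg.v0, cfg.Fs, cfg.w, cfg.dx) == 0.0


class TestSimulate:
    def test_deterministic_given_seed(self, rs_config):
        a = simulate(rs_config.replace(t_max=1.0), seed=123)
        b = simulate(rs_config.replace(t_max=1.0), seed=123)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.motor_x, b.motor_x)

    def test_sampling_grid(self, rs_config):
        tr = simulate(rs_config.replace(t_max=1.0), seed=1)
        dt = np.diff(tr.t)
        np.testing.assert_allclose(dt, 0.01, atol=1e-12)

    def test_lattice_invariant(self, rs_config):
        """Attached motor positions always lie on the 8-nm lattice."""
        tr = simulate(rs_config.replace(t_max=2.0), seed=77)
        xm = tr.motor_x[tr.attached]
        np.testing.assert_allclose(xm / 8.0, np.round(xm / 8.0), atol=1e-9)

    def test_counts_are_consistent(self, rs_config):
        tr = simulate(rs_config.replace(t_max=2.0), seed=99)
        assert np.all(tr.q_f <= tr.n_f) and np.all(tr.n_f <= 2)
        assert np.all(tr.q_b <= tr.n_b) and np.all(tr.n_b <= 2)

    def test_full_detach_termination(self, rs_config):
        cfg = rs_config.replace(
            forward=replace(rs_config.forward, pi_att=0.0, eps=50.0),
            backward=replace(rs_config.backward, pi_att=0.0, eps=50.0))
        tr = simulate(cfg, seed=4)
        assert tr.termination == "full_detach"
        assert tr.t[-1] < cfg.t_max

    def test_ensemble_prefix_property(self, rs_config):
        cfg = rs_config.replace(t_max=0.5)
        small = simulate_ensemble(cfg, 2, base_seed=5)
        large = simulate_ensemble(cfg, 4, base_seed=5)
        for a, b in zip(small, large):
            np.testing.assert_array_equal(a.x, b.x)
        # pairwise distinct
        assert not np.array_equal(large[0].x, large[1].x)


class TestFluctuationDissipation:
    def test_free_cargo_msd(self):
        """Free-cargo MSD follows 2*(kBT/gamma)*t within 5%."""
        cfg = referential_set().replace(
            forward=replace(referential_set().forward, count=0),
            backward=replace(referential_set().backward, count=0),
            t_max=0.5, stop_on_full_detach=False)
        n = 1000
        trajs = simulate_ensemble(cfg, n, base_seed=2024)
        X = np.stack([t.x for t in trajs])
        D = cfg.env.kBT / cfg.env.gamma
        lags = np.arange(5, 30, 5)  # 0.05-0.25 s
        msd = np.array([np.mean((X[:, L:] - X[:, :-L]) ** 2) for L in lags])
        t = lags * cfg.sample_dt
        slope = np.sum(msd * t) / np.sum(t * t)  # through-origin fit
        assert slope == pytest.approx(2.0 * D, rel=0.05)
        # and bin-wise agreement at the same tolerance
        np.testing.assert_allclose(msd, 2.0 * D * t, rtol=0.05)


class TestEventRates:
    def test_detach_and_attach_frequencies(self):
        """Zero-load engagement kinetics match the configured rates.

        A single motor far from stall with the cargo pinned flips between
        attached and detached as a two-state Markov process with rates
        eps and pi; empirical dwell-based rate estimates must agree within
        Monte-Carlo error.
        """
        cfg = _single_motor_cfg(eps=1.0, pi_att=2.0, k=1e-9)  # force-free
        cfg = replace(cfg, env=replace(cfg.env, n_gamma=1e10),
                      thermal_noise=False, stop_on_full_detach=False,
                      t_max=20.0)
        flips_to_det = 0
        att_time = 0.0
        det_time = 0.0
        for s in range(30):
            tr = simulate(cfg, seed=1000 + s)
            att = tr.attached[:, 0]
            att_time += att.sum() * cfg.sample_dt
            det_time += (~att).sum() * cfg.sample_dt
            flips_to_det += np.sum(att[:-1] & ~att[1:])
        eps_hat = flips_to_det / att_time
        # Poisson counting error ~ 1/sqrt(N)
        err = 4.0 / math.sqrt(flips_to_det)
        assert eps_hat == pytest.approx(1.0, rel=err)
        # stationary occupancy pi/(pi+eps) = 2/3
        occ = att_time / (att_time + det_time)
        assert occ == pytest.approx(2.0 / 3.0, abs=0.03)


class TestTrajectoryContainer:
    def test_from_timeseries_rejects_mismatch(self):
        with pytest.raises(ValueError):
            Trajectory.from_timeseries([0.0, 1.0], [0.0])

    def test_plain_series_has_no_motor_state(self):
        tr = Trajectory.from_timeseries([0.0, 0.01], [0.0, 5.0])
        assert not tr.has_motor_state
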