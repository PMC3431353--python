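"""Detection and characterization of long-term direction reversions.

A long-term reversion is a sustained change of travel direction in which
the cargo travels back at least 250 nm over more than 1 s.  For reversions
preceded by a gradual slowing-down ("wave-shaped" reversions), the position
just before the reversal point follows a saturating exponential

    x(t) = A * (1 - exp(-t/t_r)) + c,

whose time constant t_r (the rise time) characterizes how slowly the
winning team is brought to a halt by the opposing one.  The onset of the
slowing-down phase is located as the point where the path stops being
predicted by the constant-velocity fit of the earlier part of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .engine import Trajectory
from .segmentation import _smooth, _split_runs

#: default detection thresholds: backtrack displacement (nm) and duration (s)
MIN_BACKTRACK = 250.0
MIN_DURATION = 1.0


@dataclass
class ReversionEvent:
    """One detected long-term reversion, optionally with a fitted rise time."""

    rev_idx: int             # sample index of the reversal extremum
    rev_t: float             # time of the reversal, s
    rev_x: float             # cargo position at the reversal, nm
    direction: int           # +1: forward run reverting to backward motion
    pre_start: int           # first sample of the preceding run
    back_end: int            # last sample of the back excursion
    back_displacement: float  # magnitude of the back travel, nm
    back_duration: float     # duration of the back travel, s
    traj: Optional[Trajectory] = field(default=None, repr=False)
    # fit results
    fitted: bool = False
    ok: bool = False
    message: str = ""
    onset_idx: Optional[int] = None
    A: float = float("nan")          # nm
    t_r: float = float("nan")        # s
    offset: float = float("nan")     # nm
    resid_rms: float = float("nan")  # nm


def detect_reversions(
    traj: Trajectory,
    min_backtrack: float = MIN_BACKTRACK,
    min_duration: float = MIN_DURATION,
    smooth_window: float = 0.05,
) -> List[ReversionEvent]:
    """Locate long-term reversions on the smoothed path.

    The path is split into alternating runs with a hysteresis threshold of
    ``min_backtrack``; every run boundary whose following run lasts longer
    than ``min_duration`` is a reversion at the boundary extremum.  Events
    are non-overlapping by construction, and the detected count is
    non-increasing in both thresholds.
    """
    n = len(traj.x)
    if n < 3:
        return []
    w = max(1, int(round(smooth_window / traj.sample_dt)))
    xs = _smooth(traj.x, w)
    runs = _split_runs(xs, min_backtrack)
    events: List[ReversionEvent] = []
    for prev, nxt in zip(runs[:-1], runs[1:]):
        b0, b1, bdir = nxt
        duration = traj.t[b1] - traj.t[b0]
        displacement = abs(xs[b1] - xs[b0])
        if duration <= min_duration or displacement < min_backtrack:
            continue
        events.append(ReversionEvent(
            rev_idx=prev[1], rev_t=float(traj.t[prev[1]]),
            rev_x=float(traj.x[prev[1]]), direction=prev[2],
            pre_start=prev[0], back_end=b1,
            back_displacement=float(displacement),
            back_duration=float(duration), traj=traj))
    return events


def fit_saturating_exponential(t: np.ndarray, x: np.ndarray,
                               p0: Optional[Tuple[float, float, float]] = None):
    """Least-squares fit of ``x = A*(1 - exp(-t/t_r)) + c``.

    ``t`` is measured from the start of the fitted window.  Returns
    ``(A, t_r, c), perr`` with per-parameter standard errors from the fit
    covariance; raises ``RuntimeError`` on non-convergence.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)

    def model(tt, A, t_r, c):
        return A * (1.0 - np.exp(-tt / t_r)) + c

    if p0 is None:
        span = x[-1] - x[0]
        p0 = (max(1.2 * span, 1e-3), max(t[-1] / 3.0, 1e-3), x[0])
    popt, pcov = curve_fit(
        model, t, x, p0=p0,
        bounds=([0.0, 1e-5, -np.inf], [np.inf, 1e3, np.inf]),
        maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return tuple(popt), perr


def fit_rise_time(
    event: ReversionEvent,
    traj: Optional[Trajectory] = None,
    max_lookback: float = 4.0,
    velocity_smooth: float = 0.35,
    velocity_frac: float = 0.8,
    min_run_velocity: float = 50.0,
    min_fit_samples: int = 10,
    min_pre_samples: int = 60,
    resolve_mult: float = 1.5,
) -> ReversionEvent:
    """Fit the slowing-down phase of one reversion (in place).

    The pre-reversal window is the preceding run, limited to the last
    ``max_lookback`` seconds.  The onset of the slowing-down phase is where
    the path stops following its constant-velocity trend, located on the
    smoothed velocity: the run (plateau) velocity is estimated as the
    median of the ``velocity_smooth``-second-smoothed velocity over the
    first half of the window, and the onset is the last sample at which
    the smoothed velocity still reaches ``velocity_frac`` of it.  From the
    onset to the reversal point the saturating exponential is fitted by
    least squares.  Events without a resolvable slowing-down phase --
    onset within ``min_fit_samples`` of the reversal, no plateau, or a
    fitted ``t_r`` exceeding ``resolve_mult`` times the fitted window
    (saturation not contained in the data) -- are flagged and excluded
    from statistics.
    """
    tr = traj if traj is not None else event.traj
    if tr is None:
        raise ValueError("event has no trajectory attached")
    event.fitted = True
    dt = tr.sample_dt
    i1 = event.rev_idx
    i0 = max(event.pre_start, i1 - int(round(max_lookback / dt)))
    n = i1 - i0 + 1
    if n < min_pre_samples:
        event.ok = False
        event.message = "pre-reversal window too short"
        return event
    t = tr.t[i0:i1 + 1]
    s = event.direction * tr.x[i0:i1 + 1]  # increasing during the run
    w = max(1, int(round(velocity_smooth / dt)))
    vs = np.gradient(_smooth(s, w), dt)
    v_run = float(np.median(vs[:max(n // 2, 20)]))
    if v_run < min_run_velocity:
        event.ok = False
        event.message = "no constant-velocity approach"
        return event
    above = np.nonzero(vs[:n - 1] >= velocity_frac * v_run)[0]
    onset = int(above[-1]) if len(above) else 0
    event.onset_idx = i0 + onset
    if n - 1 - onset < min_fit_samples:
        event.ok = False
        event.message = "no slowing-down phase (onset at reversal)"
        return event
    tt = t[onset:] - t[onset]
    xx = s[onset:]
    try:
        (A, t_r, c), _ = fit_saturating_exponential(tt, xx)
    except (RuntimeError, ValueError) as exc:
        event.ok = False
        event.message = f"fit did not converge: {exc}"
        return event
    event.A = float(A)
    event.t_r = float(t_r)
    event.offset = float(c) * event.direction
    pred = A * (1.0 - np.exp(-tt / t_r)) + c
    event.resid_rms = float(np.sqrt(np.mean((xx - pred) ** 2)))
    if t_r > resolve_mult * tt[-1]:
        event.ok = False
        event.message = "saturation not resolved within the window"
        return event
    event.ok = True
    event.message = "ok"
    return event


@dataclass
class RiseTimeStats:
    """Characteristic rise time of an event ensemble."""

    scale_ms: float          # exponential-decay scale of the t_r distribution
    err_ms: float            # bootstrap standard error
    n_events: int

    def __str__(self) -> str:
        return (f"t_r = {self.scale_ms:.0f} +/- {self.err_ms:.0f} ms "
                f"({self.n_events} events)")


def _exp_decay_scale(t_r: np.ndarray, mode_bin: float) -> float:
    """Decay scale of a distribution rising to a mode then decaying.

    Locates the mode on a coarse histogram and applies the left-truncated
    exponential maximum-likelihood estimate above it (for an exponential
    tail, ``scale = mean(t - t_mode | t >= t_mode)``); with the mode in the
    first bin this reduces to the plain exponential MLE, the sample mean.
    """
    h, edges = np.histogram(t_r, bins=np.arange(0.0, t_r.max() + mode_bin,
                                                mode_bin))
    t_mode = edges[int(np.argmax(h))]
    tail = t_r[t_r >= t_mode]
    return float(np.mean(tail - t_mode))


def rise_time_statistics(events: Sequence[ReversionEvent],
                         min_events: int = 20,
                         n_boot: int = 500,
                         seed: int = 0,
                         mode_bin: float = 0.1) -> RiseTimeStats:
    """Exponential-decay scale of the fitted rise times, with bootstrap error.

    The rise-time distribution decays exponentially beyond its mode; the
    characteristic value reported is the maximum-likelihood decay scale of
    that tail (see :func:`_exp_decay_scale`).  Only successfully fitted
    events enter; fewer than ``min_events`` of them is an error.
    """
    t_r = np.array([e.t_r for e in events if e.fitted and e.ok and e.t_r > 0])
    if len(t_r) < min_events:
        raise ValueError(
            f"only {len(t_r)} usable events (< {min_events}); "
            "no reliable estimate")
    rng = np.random.default_rng(seed)
    scale = _exp_decay_scale(t_r, mode_bin)
    boots = np.array([
        _exp_decay_scale(rng.choice(t_r, size=len(t_r), replace=True),
                         mode_bin)
        for _ in range(n_boot)])
    return RiseTimeStats(scale_ms=1e3 * scale,
                         err_ms=1e3 * float(np.std(boots)),
                         n_events=len(t_r))


def collect_reversions(trajs: Iterable[Trajectory],
                       fit: bool = True,
                       analysis=None,
                       **detect_kwargs) -> List[ReversionEvent]:
    """Detect (and optionally fit) reversions over an ensemble.

    ``analysis`` may be an :class:`~tugofwar.params.AnalysisOptions`
    carrying the detection and onset thresholds; keyword arguments go to
    :func:`detect_reversions` directly.
    """
    if analysis is not None:
        detect_kwargs = dict(min_backtrack=analysis.min_backtrack,
                             min_duration=analysis.min_duration,
                             smooth_window=analysis.reversion_smooth)
        fit_kwargs = dict(velocity_smooth=analysis.velocity_smooth,
                          velocity_frac=analysis.velocity_frac,
                          resolve_mult=analysis.resolve_mult)
    else:
        fit_kwargs = {}
    events: List[ReversionEvent] = []
    for tr in trajs:
        for ev in detect_reversions(tr, **detect_kwargs):
            if fit:
                fit_rise_time(ev, **fit_kwargs)
            events.append(ev)
    return events


def forward_detachment_precedes(event: ReversionEvent,
                                window: float = 0.3) -> bool:
    """Whether a motor of the winning team detached just before the reversal.

    For a forward-to-backward reversion the trigger is the detachment of a
    forward motor (and symmetrically for the opposite direction): the
    elastic restitution of the remaining opposing linkers then snaps the
    cargo back.  Checks for a drop of the winning team's attached count
    within ``window`` seconds around the reversal point.
    """
    tr = event.traj
    if tr is None or not tr.has_motor_state:
        raise ValueError("event lacks motor-state information")
    counts = tr.n_f if event.direction > 0 else tr.n_b
    half = int(round(window / tr.sample_dt))
    lo = max(0, event.rev_idx - half)
    hi = min(len(counts) - 1, event.rev_idx + half)
    c = np.asarray(counts[lo:hi + 1])
    return bool((np.diff(c) < 0).any())
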