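"""Segmental-velocity analysis of cargo trajectories.

Trajectories sampled at 0.01 s are first split into periods of processive
single-direction motion, each period is tiled with consecutive 40-point
(0.4 s) windows, and the windows passing the speed and linearity filters
(|v| > 100 nm/s, |Pearson r| > 0.98) become the segmental velocities.
Because each accepted segment carries forty per-sample attachment and
pulling states, the velocity histogram can be decomposed exactly into the
contributions of the individual motor states; pooled motor positions over
segments in a chosen velocity window give the spatial distributions around
the cargo and the pulling-motor ratio mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .engine import Trajectory

#: samples per segment (0.4 s at the 0.01-s sampling of the pipeline)
SEGMENT_LENGTH = 40
#: speed filter, nm/s
MIN_SPEED = 100.0
#: linearity filter on |Pearson r| of position vs time
MIN_CORR = 0.98


def _smooth(x: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return x
    return uniform_filter1d(x, size=window_samples, mode="nearest")


def _split_runs(xs: np.ndarray, tol: float) -> List[Tuple[int, int, int]]:
    """Split a path into alternating monotone runs by hysteresis.

    A run in one direction ends once the path backtracks more than ``tol``
    from its running extremum; boundaries are trimmed to the extrema.
    Returns ``(start, end, direction)`` with inclusive extremum indices.
    """
    n = len(xs)
    runs: List[Tuple[int, int, int]] = []
    if n < 2:
        return runs
    dirn = 0
    start = imax = imin = 0
    for i in range(1, n):
        if xs[i] >= xs[imax]:
            imax = i
        if xs[i] <= xs[imin]:
            imin = i
        if dirn == 0:
            if xs[i] <= xs[imax] - tol:
                dirn = -1
                start = imax
                imin = i
            elif xs[i] >= xs[imin] + tol:
                dirn = 1
                start = imin
                imax = i
        elif dirn == 1:
            if xs[i] <= xs[imax] - tol:
                runs.append((start, imax, 1))
                dirn, start = -1, imax
                imin = i
        else:
            if xs[i] >= xs[imin] + tol:
                runs.append((start, imin, -1))
                dirn, start = 1, imin
                imax = i
    if dirn == 1:
        runs.append((start, imax, 1))
    elif dirn == -1:
        runs.append((start, imin, -1))
    return runs


def select_processive_periods(
    traj: Trajectory,
    min_run: float = 100.0,
    backtrack_tol: float = 60.0,
    smooth_window: float = 0.1,
) -> List[Tuple[int, int]]:
    """Maximal single-direction processive intervals of a trajectory.

    The path is smoothed with a ``smooth_window``-second moving average and
    cut wherever cumulative backtracking exceeds ``backtrack_tol`` nm;
    interval boundaries are trimmed to the local extrema and intervals with
    net displacement below ``min_run`` nm are dropped.  Returned intervals
    are half-open index ranges into the original samples and do not overlap.
    """
    n = len(traj.x)
    if n < SEGMENT_LENGTH:
        return []
    w = max(1, int(round(smooth_window / traj.sample_dt)))
    xs = _smooth(traj.x, w)
    out = []
    for start, end, _ in _split_runs(xs, backtrack_tol):
        if abs(xs[end] - xs[start]) >= min_run:
            out.append((start, end + 1))
    return out


@dataclass
class Segment:
    """A 40-point constant-velocity window of a trajectory."""

    start: int               # index of the first sample in the source trajectory
    t0: float                # time of the first sample, s
    v: float                 # fitted slope, nm/s
    corr: float              # Pearson r of position vs time
    direction: int           # sign of v
    n_pairs: Optional[np.ndarray] = None  # (40, 2) attached (n_f, n_b)
    q_pairs: Optional[np.ndarray] = None  # (40, 2) pulling (q_f, q_b)
    traj: Optional[Trajectory] = field(default=None, repr=False)


def extract_segments(
    traj: Trajectory,
    intervals: Optional[Sequence[Tuple[int, int]]] = None,
    seg_len: int = SEGMENT_LENGTH,
    min_speed: float = MIN_SPEED,
    min_corr: float = MIN_CORR,
) -> List[Segment]:
    """Tile processive intervals with non-overlapping fitted windows.

    The slope and correlation come from ordinary least squares of position
    on time over each ``seg_len``-sample window; windows failing the speed
    or linearity filter and residual tails shorter than one window are
    discarded.
    """
    if intervals is None:
        intervals = select_processive_periods(traj)
    segments: List[Segment] = []
    t, x = traj.t, traj.x
    has_state = traj.has_motor_state
    if has_state:
        n_f, n_b, q_f, q_b = traj.n_f, traj.n_b, traj.q_f, traj.q_b
    for i0, i1 in intervals:
        for s in range(i0, i1 - seg_len + 1, seg_len):
            tw = t[s:s + seg_len]
            xw = x[s:s + seg_len]
            tc = tw - tw.mean()
            xc = xw - xw.mean()
            stt = float(np.dot(tc, tc))
            sxx = float(np.dot(xc, xc))
            stx = float(np.dot(tc, xc))
            v = stx / stt
            corr = stx / np.sqrt(stt * sxx) if sxx > 0 else 0.0
            if abs(v) <= min_speed or abs(corr) <= min_corr:
                continue
            seg = Segment(start=s, t0=float(tw[0]), v=float(v),
                          corr=float(corr), direction=int(np.sign(v)),
                          traj=traj)
            if has_state:
                seg.n_pairs = np.stack(
                    [n_f[s:s + seg_len], n_b[s:s + seg_len]], axis=1)
                seg.q_pairs = np.stack(
                    [q_f[s:s + seg_len], q_b[s:s + seg_len]], axis=1)
            segments.append(seg)
    return segments


def segment_trajectories(trajs: Iterable[Trajectory], analysis=None,
                         **kwargs) -> List[Segment]:
    """Convenience: select periods and extract segments over an ensemble.

    ``analysis`` may be an :class:`~tugofwar.params.AnalysisOptions`
    carrying all selection and filter thresholds (e.g. from a config
    file's ``analysis:`` section); keyword arguments address
    :func:`extract_segments` directly.
    """
    out: List[Segment] = []
    for tr in trajs:
        if analysis is not None:
            intervals = select_processive_periods(
                tr, min_run=analysis.min_run,
                backtrack_tol=analysis.backtrack_tol,
                smooth_window=analysis.smooth_window)
            out.extend(extract_segments(
                tr, intervals, min_speed=analysis.min_speed,
                min_corr=analysis.min_corr))
        else:
            out.extend(extract_segments(tr, **kwargs))
    return out


# ---------------------------------------------------------------------------
# velocity histograms


@dataclass
class StateResolvedHistogram:
    """Velocity histogram with exact per-motor-state decomposition.

    Each segment contributes weight 1 to its velocity bin; its per-state
    contributions are weighted by the fractional occupancy of each state
    over the 40 samples, so the state-resolved curves sum bin-wise to the
    total.
    """

    edges: np.ndarray
    total: np.ndarray
    per_pulling: Dict[Tuple[int, int], np.ndarray]
    per_attach: Dict[Tuple[int, int], np.ndarray]
    mode: str = "count"
    empty: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def velocity_histogram(
    segments: Sequence[Segment],
    bin_width: float = 55.0,
    mode: str = "count",
    speeds: bool = False,
) -> StateResolvedHistogram:
    """Build the segmental-velocity histogram with state decomposition.

    ``mode='max1'`` rescales all curves jointly so the global maximum of
    the total histogram equals 1.  With ``speeds=True`` the histogram is
    built over |v| (used for fitting one branch folded onto the positive
    axis).
    """
    if mode not in ("count", "max1"):
        raise ValueError("mode must be 'count' or 'max1'")
    vs = np.array([abs(s.v) if speeds else s.v for s in segments], float)
    if len(vs) == 0:
        return StateResolvedHistogram(
            edges=np.array([0.0, bin_width]), total=np.zeros(1),
            per_pulling={}, per_attach={}, mode=mode, empty=True)
    lo = np.floor(vs.min() / bin_width)
    hi = np.ceil(vs.max() / bin_width)
    if hi <= lo:
        hi = lo + 1
    edges = bin_width * np.arange(lo, hi + 1)
    nbins = len(edges) - 1
    total = np.zeros(nbins)
    per_pull: Dict[Tuple[int, int], np.ndarray] = {}
    per_att: Dict[Tuple[int, int], np.ndarray] = {}
    idx = np.clip(np.searchsorted(edges, vs, side="right") - 1, 0, nbins - 1)
    for seg, b in zip(segments, idx):
        total[b] += 1.0
        for pairs, accum in ((seg.q_pairs, per_pull), (seg.n_pairs, per_att)):
            if pairs is None:
                continue
            states, counts = np.unique(pairs, axis=0, return_counts=True)
            for st, c in zip(states, counts):
                key = (int(st[0]), int(st[1]))
                if key not in accum:
                    accum[key] = np.zeros(nbins)
                accum[key][b] += c / len(pairs)
    hist = StateResolvedHistogram(edges=edges, total=total,
                                  per_pulling=per_pull, per_attach=per_att,
                                  mode=mode)
    if mode == "max1":
        scale = total.max()
        if scale > 0:
            hist.total = total / scale
            hist.per_pulling = {k: v / scale for k, v in per_pull.items()}
            hist.per_attach = {k: v / scale for k, v in per_att.items()}
    return hist


def branch_histogram(segments: Sequence[Segment], direction: int,
                     bin_width: float = 55.0,
                     mode: str = "max1") -> StateResolvedHistogram:
    """Histogram of one velocity branch folded onto the positive axis."""
    subset = [s for s in segments if s.direction == direction]
    return velocity_histogram(subset, bin_width=bin_width, mode=mode,
                              speeds=True)


def dominant_pulling_state(hist: StateResolvedHistogram,
                           vmin: float, vmax: float) -> Tuple[int, int]:
    """Pulling state with the largest summed contribution in [vmin, vmax]."""
    c = hist.centers
    sel = (c >= vmin) & (c <= vmax)
    if not sel.any() or not hist.per_pulling:
        raise ValueError("window contains no bins or histogram lacks states")
    weights = {k: float(v[sel].sum()) for k, v in hist.per_pulling.items()}
    return max(weights, key=weights.get)


def backward_fraction(segments: Sequence[Segment]) -> float:
    """Fraction of accepted segments with negative velocity."""
    if len(segments) == 0:
        raise ValueError("no segments")
    return sum(1 for s in segments if s.v < 0) / len(segments)


# ---------------------------------------------------------------------------
# spatial motor distributions and mu


@dataclass
class SpatialDistribution:
    """Pooled motor positions relative to the cargo for one velocity window.

    ``mu`` is the area quotient of the forward-team histogram beyond
    ``+x0`` over the backward-team histogram beyond ``-x0``; because the
    histograms are pure sample counts with an edge at ``±x0``, this equals
    the quotient of the directional pulling-sample counts.
    """

    edges: np.ndarray
    forward: np.ndarray          # normalized density, forward team
    backward: np.ndarray         # normalized density, backward team
    n_forward_pulling: int       # forward-team samples with d > +x0
    n_backward_pulling: int      # backward-team samples with d < -x0
    n_segments: int
    x0: float

    @property
    def mu(self) -> float:
        if self.n_backward_pulling == 0:
            return float("inf")
        return self.n_forward_pulling / self.n_backward_pulling

    @property
    def defined(self) -> bool:
        return self.n_segments > 0 and self.n_backward_pulling > 0


def pool_motor_offsets(segments: Sequence[Segment],
                       vmin: float, vmax: float):
    """Per-team motor-cargo offsets pooled over forward segments in window.

    Follows the convention that only segments with positive velocity in
    ``[vmin, vmax]`` contribute, and every sample of each accepted segment
    is pooled.
    """
    d_fwd, d_bwd = [], []
    n_used = 0
    for seg in segments:
        if seg.v < vmin or seg.v > vmax or seg.direction < 0:
            continue
        tr = seg.traj
        if tr is None or not tr.has_motor_state:
            continue
        sl = slice(seg.start, seg.start + SEGMENT_LENGTH)
        d = tr.motor_x[sl] - tr.x[sl][:, None]
        att = tr.attached[sl]
        fwd = tr.polarity > 0
        d_fwd.append(d[:, fwd][att[:, fwd]])
        d_bwd.append(d[:, ~fwd][att[:, ~fwd]])
        n_used += 1
    cat = lambda lst: np.concatenate(lst) if lst else np.empty(0)
    return cat(d_fwd), cat(d_bwd), n_used


def motor_spatial_distribution(
    trajectories: Iterable[Trajectory],
    velocity_window: Tuple[float, float],
    bin_width: float = 10.0,
    segments: Optional[Sequence[Segment]] = None,
) -> SpatialDistribution:
    """Spatial distribution of motors around the cargo, and mu.

    Pools attached-motor positions relative to the cargo over all samples
    of accepted forward-moving segments whose velocity lies in the window;
    histograms are normalized to unit area per team.  ``bin_width`` should
    divide ``x0`` so the slack boundary falls on a bin edge.
    """
    if segments is None:
        segments = segment_trajectories(list(trajectories))
    vmin, vmax = velocity_window
    d_fwd, d_bwd, n_used = pool_motor_offsets(segments, vmin, vmax)
    some = [s for s in segments if s.traj is not None and s.traj.config]
    x0 = some[0].traj.config.forward.x0 if some else 110.0
    alld = np.concatenate([d_fwd, d_bwd]) if (len(d_fwd) + len(d_bwd)) else np.zeros(1)
    span = max(abs(alld.min()), abs(alld.max()), x0) + bin_width
    m = int(np.ceil(span / bin_width))
    edges = bin_width * np.arange(-m, m + 1)

    def _norm_hist(d):
        h, _ = np.histogram(d, bins=edges)
        area = h.sum() * bin_width
        return h / area if area > 0 else h.astype(float)

    return SpatialDistribution(
        edges=edges,
        forward=_norm_hist(d_fwd),
        backward=_norm_hist(d_bwd),
        n_forward_pulling=int(np.sum(d_fwd > x0)),
        n_backward_pulling=int(np.sum(d_bwd < -x0)),
        n_segments=n_used,
        x0=x0,
    )
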