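"""Four-Gaussian fits of multimodal segmental-velocity distributions.

The segmental-velocity histograms of loosely coupled tug-of-war transport
show local maxima at roughly integer multiples of ~250 nm/s.  Following
the standard treatment of such distributions, each branch (forward or
backward, folded onto the positive axis and max-normalized) is fitted with
a sum of four Gaussians

    H(v) = sum_m A_m * exp(-(v - c_m)^2 / (2 sigma_m^2)),   m = 1..4,

with free amplitudes, centers and widths; the amplitude ratio of the
second to the first mode, A2/A1, summarizes the relative weight of
two-motor versus one-motor transport.  Modes are initialized on a 250 nm/s
grid; a mode whose fitted amplitude collapses to ~0 is degenerate, and a
distribution whose significant modes merge into one cluster is unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from .segmentation import StateResolvedHistogram

#: default initialization spacing of the mode centers, nm/s
INIT_SPACING = 250.0


class FitError(RuntimeError):
    """Non-convergent multimodal fit; carries the initialization used."""

    def __init__(self, message: str, p0=None):
        super().__init__(message)
        self.p0 = p0


@dataclass
class MultiGaussFit:
    """Result of a multi-Gaussian histogram fit, modes sorted by center."""

    amplitudes: np.ndarray   # (m,)
    centers: np.ndarray      # (m,) nm/s
    sigmas: np.ndarray       # (m,) nm/s
    cov: Optional[np.ndarray]  # (3m, 3m) in (A1..Am, c1..cm, s1..sm) order
    resid_norm: float
    n_modes: int = 4
    x_range: Tuple[float, float] = (0.0, 1500.0)  # fitted data range
    center_bounds: Optional[np.ndarray] = None    # (m, 2) allowed intervals

    def __call__(self, v) -> np.ndarray:
        v = np.asarray(v, float)
        out = np.zeros_like(v)
        for A, c, s in zip(self.amplitudes, self.centers, self.sigmas):
            out += A * np.exp(-((v - c) ** 2) / (2.0 * s * s))
        return out

    def amplitude_error(self, m: int) -> float:
        """Standard error of amplitude ``m`` (1-based), NaN if unknown."""
        if self.cov is None:
            return float("nan")
        return float(np.sqrt(self.cov[m - 1, m - 1]))


def _mixture(v, *params):
    m = len(params) // 3
    A = params[:m]
    c = params[m:2 * m]
    s = params[2 * m:]
    out = np.zeros_like(v)
    for i in range(m):
        out = out + A[i] * np.exp(-((v - c[i]) ** 2) / (2.0 * s[i] * s[i]))
    return out


def fit_four_gaussians(
    hist: Union[StateResolvedHistogram, Tuple[np.ndarray, np.ndarray]],
    init_centers: Optional[Sequence[float]] = None,
    init_spacing: float = INIT_SPACING,
    n_modes: int = 4,
    min_bins: int = 12,
) -> MultiGaussFit:
    """Fit a sum of ``n_modes`` Gaussians to a velocity histogram.

    Accepts a :class:`StateResolvedHistogram` or a ``(centers, weights)``
    pair.  The histogram is max-normalized before fitting, making the
    amplitudes scale-free; by default mode centers start at multiples of
    ``init_spacing`` with amplitudes read off the histogram there.  Bounds
    keep amplitudes non-negative and widths positive.  A mode whose fitted
    amplitude is ~0 is reported as degenerate, not an error.
    """
    if isinstance(hist, StateResolvedHistogram):
        x, y = hist.centers, hist.total
    else:
        x, y = np.asarray(hist[0], float), np.asarray(hist[1], float)
    nz = np.count_nonzero(y)
    if nz < min_bins:
        raise ValueError(
            f"histogram has {nz} non-empty bins; need >= {min_bins}")
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("histogram is empty")
    y = y / ymax

    if init_centers is None:
        init_centers = init_spacing * np.arange(1, n_modes + 1)
    init_centers = np.asarray(init_centers, float)
    if len(init_centers) != n_modes:
        raise ValueError("init_centers length must equal n_modes")
    amp0 = np.array([max(float(np.interp(c, x, y)), 1e-3)
                     for c in init_centers])
    sig0 = np.full(n_modes, 0.35 * init_spacing)
    p0 = np.concatenate([amp0, init_centers, sig0])
    span = x.max() - x.min()
    dx = float(x[1] - x[0]) if len(x) > 1 else 1.0
    # Identifiability bounds: each center moves at most half the mode
    # spacing from its initialization (so two components cannot pile onto
    # one peak while another peak goes unmodelled), centers stay inside
    # the data range (a mode outside it is not a mode of the data), and
    # widths stay between sub-bin scale and a fraction of the span so no
    # Gaussian can act as a flat pedestal.
    sig_hi = max(0.35 * span, 3.0 * dx)
    half = 0.5 * init_spacing
    init_centers = np.clip(init_centers, x.min(), x.max())
    p0 = np.concatenate([amp0, init_centers, np.minimum(sig0, sig_hi)])
    c_lo = np.maximum(init_centers - half, x.min())
    c_hi = np.minimum(init_centers + half, x.max())
    c_hi = np.maximum(c_hi, c_lo + 1e-6)
    lo = np.concatenate([np.zeros(n_modes), c_lo,
                         np.full(n_modes, max(0.5 * dx, 1.0))])
    hi = np.concatenate([np.full(n_modes, 2.0), c_hi,
                         np.full(n_modes, sig_hi)])
    try:
        popt, pcov = curve_fit(_mixture, x, y, p0=p0, bounds=(lo, hi),
                               maxfev=50000)
    except RuntimeError as exc:
        raise FitError(f"four-Gaussian fit did not converge: {exc}", p0=p0)
    A = popt[:n_modes]
    c = popt[n_modes:2 * n_modes]
    s = popt[2 * n_modes:]
    order = np.argsort(c)
    perm = np.concatenate([order, order + n_modes, order + 2 * n_modes])
    cov = pcov[np.ix_(perm, perm)] if pcov is not None else None
    resid = y - _mixture(x, *popt)
    return MultiGaussFit(amplitudes=A[order], centers=c[order],
                         sigmas=s[order], cov=cov,
                         resid_norm=float(np.sqrt(np.sum(resid ** 2))),
                         n_modes=n_modes,
                         x_range=(float(x.min()), float(x.max())),
                         center_bounds=np.stack([c_lo, c_hi], axis=1)[order])


def fit_mode_progression(
    hist: Union[StateResolvedHistogram, Tuple[np.ndarray, np.ndarray]],
    n_modes: int = 4,
    init_spacing: float = INIT_SPACING,
    min_bins: int = 12,
) -> MultiGaussFit:
    """Fit Gaussians whose centers form an arithmetic progression.

    Model: sum of ``n_modes`` Gaussians with centers ``c1 + (m-1)*delta``,
    free amplitudes and widths.  This is the estimator of the *common*
    spacing of the velocity modes: unlike the fully free fit it cannot
    spend two components on one peak-plus-shoulder, so ``delta`` is pinned
    by the strong low-order modes even when the third mode is only a
    marginal shoulder in a finite ensemble.  The spacing is
    ``np.diff(result.centers)[0]``.
    """
    if isinstance(hist, StateResolvedHistogram):
        x, y = hist.centers, hist.total
    else:
        x, y = np.asarray(hist[0], float), np.asarray(hist[1], float)
    if np.count_nonzero(y) < min_bins:
        raise ValueError("histogram too sparse for a progression fit")
    y = y / y.max()
    dx = float(x[1] - x[0]) if len(x) > 1 else 1.0
    span = x.max() - x.min()
    sig_hi = max(0.35 * span, 3.0 * dx)

    def model(v, *p):
        A = p[:n_modes]
        c1, delta = p[n_modes], p[n_modes + 1]
        s = p[n_modes + 2:]
        out = np.zeros_like(v)
        for m in range(n_modes):
            c = c1 + m * delta
            out = out + A[m] * np.exp(-((v - c) ** 2) / (2.0 * s[m] * s[m]))
        return out

    amp0 = [max(float(np.interp(init_spacing * (m + 1), x, y)), 1e-3)
            for m in range(n_modes)]
    p0 = np.concatenate([amp0, [init_spacing, init_spacing],
                         np.full(n_modes, min(0.35 * init_spacing, sig_hi))])
    lo = np.concatenate([np.zeros(n_modes),
                         [0.5 * init_spacing, 0.5 * init_spacing],
                         np.full(n_modes, max(0.5 * dx, 1.0))])
    hi = np.concatenate([np.full(n_modes, 2.0),
                         [1.5 * init_spacing, 1.5 * init_spacing],
                         np.full(n_modes, sig_hi)])
    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, bounds=(lo, hi),
                               maxfev=50000)
    except RuntimeError as exc:
        raise FitError(f"progression fit did not converge: {exc}", p0=p0)
    A = np.asarray(popt[:n_modes])
    c1, delta = popt[n_modes], popt[n_modes + 1]
    s = np.asarray(popt[n_modes + 2:])
    centers = c1 + delta * np.arange(n_modes)
    resid = y - model(x, *popt)
    return MultiGaussFit(amplitudes=A, centers=centers, sigmas=s, cov=None,
                         resid_norm=float(np.sqrt(np.sum(resid ** 2))),
                         n_modes=n_modes,
                         x_range=(float(x.min()), float(x.max())))


def amplitude_ratio(fit: MultiGaussFit, i: int = 2, j: int = 1,
                    significant: bool = True,
                    amp_frac: float = 0.05) -> Tuple[float, float]:
    """Amplitude ratio ``A_i / A_j`` of two modes with propagated error.

    Modes are numbered from 1 in order of ascending center.  With
    ``significant=True`` (default) the numbering runs over non-degenerate
    modes only, so the "first" and "second" peaks are the first two actually
    present in the distribution.  Returns ``(ratio, stderr)``; a degenerate
    denominator yields ``(nan, nan)``.
    """
    if significant:
        idx = [m for m in range(fit.n_modes)
               if fit.amplitudes[m] >= amp_frac * fit.amplitudes.max()]
    else:
        idx = list(range(fit.n_modes))
    if i > len(idx) or j > len(idx) or i < 1 or j < 1:
        return float("nan"), float("nan")
    ii, jj = idx[i - 1], idx[j - 1]
    Ai, Aj = fit.amplitudes[ii], fit.amplitudes[jj]
    if Aj <= amp_frac * fit.amplitudes.max():
        return float("nan"), float("nan")
    ratio = Ai / Aj
    if fit.cov is None:
        return float(ratio), float("nan")
    var_i = fit.cov[ii, ii]
    var_j = fit.cov[jj, jj]
    cov_ij = fit.cov[ii, jj]
    var = (ratio ** 2) * (var_i / Ai ** 2 + var_j / Aj ** 2
                          - 2.0 * cov_ij / (Ai * Aj))
    return float(ratio), float(np.sqrt(max(var, 0.0)))


def significant_modes(fit: MultiGaussFit, amp_frac: float = 0.1,
                      bound_tol: float = 0.5) -> np.ndarray:
    """Indices (0-based) of resolved modes.

    A mode counts as resolved when its amplitude reaches ``amp_frac`` of
    the largest one and its center lies strictly inside its allowed
    interval: a center pinned at a constraint boundary (within
    ``bound_tol`` nm/s) is the optimizer parking an unneeded component
    against a bound, not a mode located by the data.
    """
    keep = fit.amplitudes >= amp_frac * fit.amplitudes.max()
    if fit.center_bounds is not None:
        interior = ((fit.centers > fit.center_bounds[:, 0] + bound_tol)
                    & (fit.centers < fit.center_bounds[:, 1] - bound_tol))
        keep &= interior
    return np.nonzero(keep)[0]


def count_modes(fit: MultiGaussFit, amp_frac: float = 0.1,
                grid_points: int = 2000) -> int:
    """Number of local maxima of the fitted curve over the data range.

    Counting maxima of the mixture itself (rather than non-degenerate
    component Gaussians) makes the answer parameter-free: a unimodal
    shape decomposed into overlapping Gaussians still has a single hump,
    while genuinely separated modes each produce one.  Maxima below
    ``amp_frac`` of the global maximum are ignored.
    """
    v = np.linspace(fit.x_range[0], fit.x_range[1], grid_points)
    y = fit(v)
    if y.max() <= 0:
        return 0
    interior = (y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:])
    peaks = np.nonzero(interior)[0] + 1
    # endpoints count when the curve falls away from them
    if y[0] > y[1]:
        peaks = np.concatenate([[0], peaks])
    if y[-1] > y[-2]:
        peaks = np.concatenate([peaks, [len(y) - 1]])
    return int(np.sum(y[peaks] >= amp_frac * y.max()))


def mode_spacing(fit: MultiGaussFit, amp_frac: float = 0.1) -> float:
    """Mean spacing between consecutive significant mode centers, nm/s."""
    idx = significant_modes(fit, amp_frac)
    if len(idx) < 2:
        return float("nan")
    centers = np.sort(fit.centers[idx])
    return float(np.mean(np.diff(centers)))
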