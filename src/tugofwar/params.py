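"""Model parameterization for tug-of-war cargo transport.

Two teams of opposite-polarity motors (kinesin-like "forward", dynein-like
"backward") are permanently linked to a single cargo through independent
elastic linkers.  All single-motor parameters, the environment (viscous drag
and thermal energy), and the numerical settings of a simulation live here,
together with the canonical parameter sets used throughout and the
stall-force scaling transformation.

Units are fixed package-wide: lengths in nm, forces in pN, times in s,
stiffness in pN/nm, drag in pN·s/nm, energies in pN·nm.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import yaml

#: viscosity of water, Pa·s; reference point of the dimensionless viscosity
ETA_WATER = 1.0e-3

#: Boltzmann constant in pN·nm/K
KB = 1.380649e-2

#: conversion: 1 Pa·s = 1e-6 pN·s/nm²
_PAS_TO_PN_S_PER_NM2 = 1.0e-6


class ParameterError(ValueError):
    """Invalid model parameter; carries the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


@dataclass(frozen=True)
class MotorSpecies:
    """Single-motor parameters for one polarity.

    Parameters
    ----------
    polarity : int
        +1 for plus-end-directed (forward) motors, -1 for minus-end-directed.
    count : int
        Number of motors of this species permanently linked to the cargo.
    v0 : float
        Zero-load stepping velocity, nm/s.
    Fs : float
        Stall force, pN; stepping velocity reaches zero at this load.
    w : float
        Exponent of the force-velocity nonlinearity.
    eps : float
        Zero-load detachment rate, 1/s.
    Fd : float
        Detachment force, pN; load scale of the exponential unbinding rate.
    pi_att : float
        Attachment rate of a detached motor, 1/s.
    k : float
        Stiffness of the motor-cargo linker, pN/nm.
    x0 : float
        Slack half-width of the linker, nm; the linker exerts no force while
        the motor is within ``x0`` of the cargo.
    dx : float
        Step length on the microtubule lattice, nm.
    """

    polarity: int
    count: int
    v0: float = 500.0
    Fs: float = 6.0
    w: float = 2.0
    eps: float = 0.2
    Fd: float = 3.0
    pi_att: float = 2.0
    k: float = 0.02
    x0: float = 110.0
    dx: float = 8.0

    def validate(self, prefix: str = "motor") -> None:
        if self.polarity not in (1, -1):
            raise ParameterError(f"{prefix}.polarity", "must be +1 or -1")
        if self.count < 0:
            raise ParameterError(f"{prefix}.count", "must be >= 0")
        for name, positive in [
            ("v0", True), ("Fs", True), ("w", True), ("Fd", True),
            ("k", True), ("x0", True), ("dx", True),
            ("eps", False), ("pi_att", False),
        ]:
            val = getattr(self, name)
            if positive and not val > 0:
                raise ParameterError(f"{prefix}.{name}", "must be > 0")
            if not positive and val < 0:
                raise ParameterError(f"{prefix}.{name}", "must be >= 0")


@dataclass(frozen=True)
class Environment:
    """Cargo environment: viscous drag via Stokes' law and thermal energy.

    ``n_gamma`` is the medium viscosity in units of the viscosity of water;
    the drag follows gamma = 6*pi*eta*r with eta = n_gamma * eta_water.
    """

    n_gamma: float = 500.0
    r: float = 500.0
    T: float = 300.0

    @property
    def eta(self) -> float:
        """Medium viscosity, Pa·s."""
        return self.n_gamma * ETA_WATER

    @property
    def gamma(self) -> float:
        """Viscous drag coefficient, pN·s/nm."""
        return 6.0 * math.pi * self.eta * _PAS_TO_PN_S_PER_NM2 * self.r

    @property
    def kBT(self) -> float:
        """Thermal energy, pN·nm."""
        return KB * self.T

    def validate(self) -> None:
        for name in ("n_gamma", "r", "T"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"environment.{name}", "must be > 0")


@dataclass(frozen=True)
class AnalysisOptions:
    """Thresholds of the trajectory-analysis pipeline.

    Every value defaults to the pipeline's canonical setting; configs may
    override them under an ``analysis:`` section.  Units: nm, nm/s, s.
    """

    min_run: float = 100.0        # minimum net displacement of a period, nm
    backtrack_tol: float = 60.0   # hysteresis ending a processive period, nm
    smooth_window: float = 0.1    # period-selection smoothing, s
    min_speed: float = 100.0      # segment speed filter, nm/s
    min_corr: float = 0.98        # segment |Pearson r| filter
    bin_width: float = 55.0       # velocity histogram bin, nm/s
    min_backtrack: float = 250.0  # long-term reversion displacement, nm
    min_duration: float = 1.0     # long-term reversion duration, s
    reversion_smooth: float = 0.05   # reversion-detection smoothing, s
    velocity_smooth: float = 0.35    # rise-time onset velocity smoothing, s
    velocity_frac: float = 0.8       # onset threshold, fraction of v_run
    resolve_mult: float = 1.5        # max fitted t_r per window length
    init_spacing: float = 250.0      # multimodal-fit mode initialization, nm/s

    def validate(self) -> None:
        for name in ("min_run", "backtrack_tol", "smooth_window",
                     "min_speed", "bin_width", "min_backtrack",
                     "min_duration", "reversion_smooth", "velocity_smooth",
                     "resolve_mult", "init_spacing"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"analysis.{name}", "must be > 0")
        if not 0.0 < self.min_corr < 1.0:
            raise ParameterError("analysis.min_corr", "must lie in (0, 1)")
        if not 0.0 < self.velocity_frac <= 1.0:
            raise ParameterError("analysis.velocity_frac",
                                 "must lie in (0, 1]")


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of one simulation run."""

    forward: MotorSpecies
    backward: MotorSpecies
    env: Environment = Environment()
    dt: float = 1.0e-5
    t_max: float = 20.0
    sample_dt: float = 0.01
    seed: Optional[int] = None
    stop_on_full_detach: bool = True
    thermal_noise: bool = True
    analysis: AnalysisOptions = AnalysisOptions()

    def validate(self) -> None:
        self.forward.validate("forward")
        self.backward.validate("backward")
        self.env.validate()
        self.analysis.validate()
        if self.forward.polarity != 1:
            raise ParameterError("forward.polarity", "must be +1")
        if self.backward.polarity != -1:
            raise ParameterError("backward.polarity", "must be -1")
        if not (1.0e-7 <= self.dt <= 1.0e-5):
            raise ParameterError("dt", "must lie in [1e-7, 1e-5] s")
        if self.sample_dt < 100.0 * self.dt:
            raise ParameterError("sample_dt", "must be >= 100*dt")
        if not self.t_max > 0:
            raise ParameterError("t_max", "must be > 0")

    def replace(self, **changes) -> "ModelConfig":
        """Return a copy with the given top-level fields replaced."""
        return replace(self, **changes)

    def with_stiffness(self, k: float) -> "ModelConfig":
        """Copy with the linker stiffness of both species set to ``k``."""
        return replace(
            self,
            forward=replace(self.forward, k=k),
            backward=replace(self.backward, k=k),
        )


def referential_set(seed: Optional[int] = None, **numerics) -> ModelConfig:
    """The symmetric referential parameter set (RS).

    Two motors per team; both species share v0 = 500 nm/s, Fs = 6 pN, w = 2,
    eps = 0.2/s, Fd = 3 pN, pi = 2/s, k = 0.02 pN/nm, x0 = 110 nm and differ
    only in polarity.  Environment: n_gamma = 500, r = 500 nm, T = 300 K.
    """
    cfg = ModelConfig(
        forward=MotorSpecies(polarity=1, count=2),
        backward=MotorSpecies(polarity=-1, count=2),
        env=Environment(n_gamma=500.0, r=500.0, T=300.0),
        seed=seed,
        **numerics,
    )
    cfg.validate()
    return cfg


def dispersion_set(seed: Optional[int] = None, **numerics) -> ModelConfig:
    """Asymmetric rate set modelling the dispersion regime (Set 1).

    Kinesin-favoured: pi_f = 3.5/s > pi_b = 2.2/s, eps_f = 0.08/s,
    eps_b = 0.07/s, n_gamma = 300; everything else as the referential set.
    """
    rs = referential_set(seed=seed, **numerics)
    return replace(
        rs,
        forward=replace(rs.forward, pi_att=3.5, eps=0.08),
        backward=replace(rs.backward, pi_att=2.2, eps=0.07),
        env=replace(rs.env, n_gamma=300.0),
    )


def aggregation_set(seed: Optional[int] = None, **numerics) -> ModelConfig:
    """Asymmetric rate set modelling the aggregation regime (Set 2).

    Dynein-favoured: pi_f = 1.8/s < pi_b = 2.2/s, eps_f = eps_b = 0.08/s,
    n_gamma = 300; everything else as the referential set.
    """
    rs = referential_set(seed=seed, **numerics)
    return replace(
        rs,
        forward=replace(rs.forward, pi_att=1.8, eps=0.08),
        backward=replace(rs.backward, pi_att=2.2, eps=0.08),
        env=replace(rs.env, n_gamma=300.0),
    )


def scale_parameters(cfg: ModelConfig, lam: float, beta: float) -> ModelConfig:
    """Apply the approximate dynamical-invariance scaling.

    The transformation Fs -> lam*Fs, Fd -> beta*Fd, k -> lam*k together with
    gamma -> lam*gamma (realized by scaling the dimensionless viscosity)
    yields a system whose dynamics closely mirrors the original, for lam in
    roughly (0.4, 1] and beta of order sqrt(lam).  It is used to explore
    lower stall forces without re-tuning every other parameter.
    """
    if not (0.0 < lam <= 1.0):
        raise ParameterError("lam", "must lie in (0, 1]")
    if lam <= 0.4:
        warnings.warn(
            f"lam={lam} is outside the validated range (0.4, 1]; scaled "
            "dynamics may no longer mirror the original", stacklevel=2)
    root = math.sqrt(lam)
    if abs(beta - root) / root > 0.3:
        warnings.warn(
            f"beta={beta} is far from sqrt(lam)={root:.3f}; the scaling "
            "is only expected to hold for beta ~ sqrt(lam)", stacklevel=2)

    def _scale(m: MotorSpecies) -> MotorSpecies:
        return replace(m, Fs=lam * m.Fs, Fd=beta * m.Fd, k=lam * m.k)

    return replace(
        cfg,
        forward=_scale(cfg.forward),
        backward=_scale(cfg.backward),
        env=replace(cfg.env, n_gamma=lam * cfg.env.n_gamma),
    )


# ---------------------------------------------------------------------------
# config file round-trip


def config_to_dict(cfg: ModelConfig) -> dict:
    d = {
        "forward": dataclasses.asdict(cfg.forward),
        "backward": dataclasses.asdict(cfg.backward),
        "environment": dataclasses.asdict(cfg.env),
        "analysis": dataclasses.asdict(cfg.analysis),
        "numerics": {
            "dt": cfg.dt,
            "t_max": cfg.t_max,
            "sample_dt": cfg.sample_dt,
            "seed": cfg.seed,
            "stop_on_full_detach": cfg.stop_on_full_detach,
            "thermal_noise": cfg.thermal_noise,
        },
    }
    return d


def config_from_dict(d: dict) -> ModelConfig:
    try:
        fwd = MotorSpecies(**d["forward"])
        bwd = MotorSpecies(**d["backward"])
        env = Environment(**d.get("environment", {}))
        ana = AnalysisOptions(**d.get("analysis", {}))
        num = dict(d.get("numerics", {}))
    except TypeError as exc:
        raise ParameterError("<config>", f"unknown or missing key ({exc})")
    cfg = ModelConfig(forward=fwd, backward=bwd, env=env, analysis=ana, **num)
    cfg.validate()
    return cfg


def load_config(path) -> ModelConfig:
    """Load and validate a YAML model configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParameterError("<config>", "top level must be a mapping")
    return config_from_dict(d)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
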