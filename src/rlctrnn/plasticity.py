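"""Reward-modulated sinusoidal parameter fluctuations.

Any scalar parameter of the network (a synaptic weight or a bias) can be made
*plastic*: instead of holding a fixed value it fluctuates sinusoidally around
a slowly-moving "true center" C with amplitude A,

    p(t) = C + A * sin(2*pi*(t - t_k) / T_k),        t_k <= t < t_k + T_k,

emulating the ongoing variation of effective synaptic strength produced by
receptor trafficking.  Each time the fluctuation completes a cycle (crosses
its center while increasing) a new period T_k is drawn from a clamped
Gaussian.  A single global reward signal R(t) drives learning:

    dC/dt =  alpha * (p(t) - C) * R(t)      (learning rate alpha)
    dA/dt = -beta * R(t)                    (convergence rate beta)

Positive reward pulls the center toward the current displacement and shrinks
the amplitude (exploit); negative reward pushes the center away and grows the
amplitude (explore); zero reward leaves both untouched.

Two implementations share these formulas: :class:`FluctuatingScalar` with
per-scalar functions (the reference, convenient for inspection), and
:class:`FluctuationArray`, which advances a whole batch of plastic parameters
in lock-step and is what the trial runner uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .ctrnn import NetworkParameters

__all__ = [
    "FluctuationConfig",
    "FluctuatingScalar",
    "FluctuationArray",
    "PlasticNetwork",
    "sample_period",
    "fluctuation_value",
    "advance_fluctuation",
    "apply_reward",
    "effective_parameters",
]


@dataclass(frozen=True)
class FluctuationConfig:
    """Metaparameters of the fluctuation learning rule.

    Parameters
    ----------
    learning_rate : float
        alpha, per second; gain on the center update dC/dt = alpha*(p-C)*R.
    convergence_rate : float
        beta, per second; gain on the amplitude update dA/dt = -beta*R.
    init_flux : float
        Initial fluctuation amplitude A(0) (half-range; peak-to-peak is 2A).
    period_min, period_max : float
        Bounds of the fluctuation period, seconds.  By default the maximum is
        double the minimum.
    period_mean, period_sd : float
        mu and omega of the Gaussian the period is drawn from before
        clamping.  Defaults: mu = 1.5*period_min, omega = 0.5*period_min,
        which puts both bounds one standard deviation from the mean.
    value_bounds : (float, float)
        Closed interval the effective parameter value (and its center) is
        clamped to.
    amplitude_max : float
        Upper bound for the amplitude; the lower bound is 0.
    """

    learning_rate: float = 1.0
    convergence_rate: float = 3.0
    init_flux: float = 4.0
    period_min: float = 2.0
    period_max: Optional[float] = None
    period_mean: Optional[float] = None
    period_sd: Optional[float] = None
    value_bounds: tuple[float, float] = (-16.0, 16.0)
    amplitude_max: float = 16.0

    def __post_init__(self):
        if self.learning_rate < 0 or self.convergence_rate < 0:
            raise ValueError("learning_rate and convergence_rate must be >= 0")
        if self.init_flux < 0:
            raise ValueError("init_flux must be >= 0")
        if self.period_min <= 0:
            raise ValueError("period_min must be positive")
        if self.period_max is None:
            object.__setattr__(self, "period_max", 2.0 * self.period_min)
        if self.period_min > self.period_max:
            raise ValueError("period_min must not exceed period_max")
        if self.period_mean is None:
            object.__setattr__(self, "period_mean", 1.5 * self.period_min)
        if self.period_sd is None:
            object.__setattr__(self, "period_sd", 0.5 * self.period_min)
        if self.period_sd < 0:
            raise ValueError("period_sd must be >= 0")
        lo, hi = self.value_bounds
        if not lo < hi:
            raise ValueError("value_bounds must be a non-empty interval")
        if self.amplitude_max < 0:
            raise ValueError("amplitude_max must be >= 0")


@dataclass
class FluctuatingScalar:
    """One plastic parameter: center, amplitude, and current-period bookkeeping."""

    center: float
    amplitude: float
    period: float
    period_start: float = 0.0
    value_bounds: tuple[float, float] = (-16.0, 16.0)
    amplitude_bounds: tuple[float, float] = (0.0, 16.0)

    @classmethod
    def from_config(
        cls, center: float, config: FluctuationConfig, rng: np.random.Generator, t0: float = 0.0
    ) -> "FluctuatingScalar":
        """Start a fresh fluctuation at phase 0 (value = center) at time t0."""
        return cls(
            center=float(center),
            amplitude=float(config.init_flux),
            period=sample_period(config, rng),
            period_start=t0,
            value_bounds=config.value_bounds,
            amplitude_bounds=(0.0, config.amplitude_max),
        )


def sample_period(config: FluctuationConfig, rng: np.random.Generator) -> float:
    """Draw a fluctuation period from N(mu, omega^2), clamped to its bounds."""
    draw = rng.normal(config.period_mean, config.period_sd)
    return float(np.clip(draw, config.period_min, config.period_max))


def fluctuation_value(fs: FluctuatingScalar, t: float) -> float:
    """Effective parameter value at time ``t`` within the current period."""
    if not (fs.period_start <= t < fs.period_start + fs.period + 1e-12):
        raise ValueError(
            f"t={t} outside current period [{fs.period_start}, {fs.period_start + fs.period})"
        )
    raw = fs.center + fs.amplitude * np.sin(2.0 * np.pi * (t - fs.period_start) / fs.period)
    return float(np.clip(raw, *fs.value_bounds))


def advance_fluctuation(
    fs: FluctuatingScalar, t: float, dt: float, config: FluctuationConfig, rng: np.random.Generator
) -> FluctuatingScalar:
    """Resample the period if the step from t to t+dt completes the cycle.

    The cycle completes at the upward center-crossing, i.e. when t + dt
    reaches period_start + period; the new period starts exactly there.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t + dt >= fs.period_start + fs.period:
        return replace(
            fs,
            period_start=fs.period_start + fs.period,
            period=sample_period(config, rng),
        )
    return fs


def apply_reward(
    fs: FluctuatingScalar, p_now: float, reward: float, config: FluctuationConfig, dt: float
) -> FluctuatingScalar:
    """One Euler step of the center and amplitude updates under reward R.

    C <- clamp(C + dt*alpha*(p_now - C)*R) ; A <- clamp(A - dt*beta*R).
    """
    c = fs.center + dt * config.learning_rate * (p_now - fs.center) * reward
    a = fs.amplitude - dt * config.convergence_rate * reward
    return replace(
        fs,
        center=float(np.clip(c, *fs.value_bounds)),
        amplitude=float(np.clip(a, *fs.amplitude_bounds)),
    )


class FluctuationArray:
    """A batch of independent fluctuating scalars advanced in lock-step.

    All arrays have a common shape (typically ``(B, N, N)`` for the plastic
    weights of B concurrently-simulated networks, or ``(B, N)`` for biases).
    Each entry keeps its own period and phase; one shared RNG supplies the
    period draws, so a run is reproducible given the seed.
    """

    def __init__(
        self,
        centers: np.ndarray,
        config: FluctuationConfig,
        rng: np.random.Generator,
        t0: float = 0.0,
    ):
        self.config = config
        self.centers = np.array(centers, dtype=float)
        shape = self.centers.shape
        self.amplitudes = np.full(shape, float(config.init_flux))
        self.periods = np.clip(
            rng.normal(config.period_mean, config.period_sd, size=shape),
            config.period_min,
            config.period_max,
        )
        self.period_starts = np.full(shape, float(t0))
        self._rng = rng

    def values(self, t: float) -> np.ndarray:
        """Effective values at time t, clamped to the value bounds."""
        raw = self.centers + self.amplitudes * np.sin(
            2.0 * np.pi * (t - self.period_starts) / self.periods
        )
        return np.clip(raw, *self.config.value_bounds)

    def advance(self, t: float, dt: float) -> None:
        """Resample periods for entries whose cycle completes within the step."""
        done = t + dt >= self.period_starts + self.periods
        n = int(np.count_nonzero(done))
        if n:
            self.period_starts[done] += self.periods[done]
            draws = self._rng.normal(self.config.period_mean, self.config.period_sd, size=n)
            self.periods[done] = np.clip(
                draws, self.config.period_min, self.config.period_max
            )

    def apply_reward(self, values: np.ndarray, reward: np.ndarray | float, dt: float) -> None:
        """Vectorized center/amplitude update; ``reward`` broadcasts over entries."""
        cfg = self.config
        self.centers += dt * cfg.learning_rate * (values - self.centers) * np.asarray(reward)
        np.clip(self.centers, *cfg.value_bounds, out=self.centers)
        self.amplitudes -= dt * cfg.convergence_rate * np.asarray(reward)
        np.clip(self.amplitudes, 0.0, cfg.amplitude_max, out=self.amplitudes)


@dataclass
class PlasticNetwork:
    """A base network whose weights (and optionally biases) fluctuate.

    ``plastic_weight_mask`` selects which weight entries are plastic (all by
    default); centers are initialized to the base values, so at construction
    the effective network equals the base network.
    """

    base: NetworkParameters
    config: FluctuationConfig
    rng: np.random.Generator
    plastic_biases: bool = False
    plastic_weight_mask: Optional[np.ndarray] = None
    t0: float = 0.0
    weights_flux: FluctuationArray = field(init=False)
    biases_flux: Optional[FluctuationArray] = field(init=False, default=None)

    def __post_init__(self):
        if self.plastic_weight_mask is None:
            self.plastic_weight_mask = np.ones_like(self.base.weights, dtype=bool)
        self.weights_flux = FluctuationArray(self.base.weights, self.config, self.rng, self.t0)
        if self.plastic_biases:
            self.biases_flux = FluctuationArray(self.base.biases, self.config, self.rng, self.t0)

    def advance(self, t: float, dt: float) -> None:
        self.weights_flux.advance(t, dt)
        if self.biases_flux is not None:
            self.biases_flux.advance(t, dt)

    def effective(self, t: float) -> NetworkParameters:
        return effective_parameters(self, t)

    def apply_reward(self, t: float, reward: float, dt: float) -> None:
        mask = self.plastic_weight_mask
        wvals = self.weights_flux.values(t)
        # frozen (non-plastic) entries receive no update: zero their reward
        r = np.where(mask, reward, 0.0)
        self.weights_flux.apply_reward(wvals, r, dt)
        if self.biases_flux is not None:
            self.biases_flux.apply_reward(self.biases_flux.values(t), reward, dt)


def effective_parameters(net: PlasticNetwork, t: float) -> NetworkParameters:
    """Base parameters with every plastic entry replaced by its value at t."""
    w = np.where(net.plastic_weight_mask, net.weights_flux.values(t), net.base.weights)
    b = net.biases_flux.values(t) if net.biases_flux is not None else net.base.biases
    return NetworkParameters(weights=w, biases=b, time_constants=net.base.time_constants)
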