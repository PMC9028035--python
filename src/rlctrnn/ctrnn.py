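"""Continuous-time recurrent neural network (CTRNN) dynamics.

Each of the N neurons obeys the first-order state equation

    tau_i dy_i/dt = -y_i + sum_j w_ji * sigma(y_j + theta_j)

where ``w_ji`` is the connection weight *from* neuron j *to* neuron i,
``theta_j`` is the bias of neuron j, ``tau_i`` the membrane time constant
(seconds), and ``sigma`` the standard logistic function.  Injected current is
not modelled.  Integration is fixed-step explicit Euler.

Weight-matrix orientation
-------------------------
``weights[j, i]`` is the weight of the connection **from neuron j to neuron
i** (row = presynaptic, column = postsynaptic).  The net input to neuron i is
therefore ``outputs @ weights`` taken column-wise.  The same row-major
``w[j][i]`` convention is used in the JSON serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "NetworkParameters",
    "NetworkState",
    "SimulationConfig",
    "SimulationError",
    "logistic",
    "neuron_outputs",
    "euler_step",
    "simulate",
    "simulate_outputs_batch",
    "trace_to_csv",
]

#: abort the integration when any |y| exceeds this (diverging trajectory)
STATE_OVERFLOW_LIMIT = 1e6


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite or overflowing state."""


def logistic(x):
    """Standard logistic activation sigma(x) = 1 / (1 + exp(-x)).

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    Output lies strictly inside (0, 1) for finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("logistic: input must be finite")
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class NetworkParameters:
    """Static description of an N-neuron CTRNN.

    Parameters
    ----------
    weights : (N, N) array
        ``weights[j, i]`` is the connection from neuron j to neuron i.
    biases : (N,) array
        Bias ``theta_j`` added to the state before the activation.
    time_constants : (N,) array
        Membrane time constants ``tau_i`` in seconds; strictly positive.
    """

    weights: np.ndarray
    biases: np.ndarray
    time_constants: np.ndarray

    def __post_init__(self):
        w = np.array(self.weights, dtype=float)
        b = np.array(self.biases, dtype=float)
        tau = np.array(self.time_constants, dtype=float)
        n = b.shape[0]
        if w.shape != (n, n):
            raise ValueError(f"weights must be ({n}, {n}), got {w.shape}")
        if tau.shape != (n,):
            raise ValueError(f"time_constants must have length {n}")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b)) and np.all(np.isfinite(tau))):
            raise ValueError("network parameters must be finite")
        if np.any(tau <= 0):
            raise ValueError("time_constants must be strictly positive")
        w.setflags(write=False)
        b.setflags(write=False)
        tau.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "biases", b)
        object.__setattr__(self, "time_constants", tau)

    @property
    def n_neurons(self) -> int:
        return self.biases.shape[0]

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "time_constants": self.time_constants.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParameters":
        net = cls(
            weights=np.asarray(d["weights"], dtype=float),
            biases=np.asarray(d["biases"], dtype=float),
            time_constants=np.asarray(d["time_constants"], dtype=float),
        )
        if "n_neurons" in d and int(d["n_neurons"]) != net.n_neurons:
            raise ValueError("n_neurons inconsistent with array shapes")
        return net

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class NetworkState:
    """Instantaneous neuron states ``y`` and the simulation clock ``t``."""

    y: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.y = np.array(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("neuron states must be finite")
        if self.t < 0:
            raise ValueError("time must be non-negative")

    @classmethod
    def zeros(cls, n: int) -> "NetworkState":
        return cls(y=np.zeros(n), t=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step integration settings: step ``dt`` and total ``duration`` (s)."""

    dt: float = 0.01
    duration: float = 10.0

    def __post_init__(self):
        if not (0 < self.dt <= 0.1):
            raise ValueError("dt must lie in (0, 0.1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def neuron_outputs(state: NetworkState, params: NetworkParameters) -> np.ndarray:
    """Neuron outputs o_j = sigma(y_j + theta_j), each strictly inside (0, 1)."""
    if state.y.shape != params.biases.shape:
        raise ValueError("state and parameters have inconsistent dimensions")
    return logistic(state.y + params.biases)


def euler_step(state: NetworkState, params: NetworkParameters, dt: float) -> NetworkState:
    """Advance the network one explicit-Euler step of size ``dt`` (seconds).

    Returns a new :class:`NetworkState`; the inputs are not modified.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    o = neuron_outputs(state, params)
    y_new = state.y + (dt / params.time_constants) * (-state.y + o @ params.weights)
    if not np.all(np.isfinite(y_new)) or np.any(np.abs(y_new) > STATE_OVERFLOW_LIMIT):
        raise SimulationError(
            f"state overflow at t={state.t + dt:.4f} s (|y| > {STATE_OVERFLOW_LIMIT:g})"
        )
    return NetworkState(y=y_new, t=state.t + dt)


def simulate(
    params: NetworkParameters,
    config: SimulationConfig,
    initial_state: NetworkState | None = None,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Integrate the network and return the trace [(t, y, outputs), ...].

    The trace has ``duration/dt + 1`` samples and includes the initial point.
    """
    state = initial_state if initial_state is not None else NetworkState.zeros(params.n_neurons)
    trace = [(state.t, state.y.copy(), neuron_outputs(state, params))]
    for _ in range(config.n_steps):
        state = euler_step(state, params, config.dt)
        trace.append((state.t, state.y.copy(), neuron_outputs(state, params)))
    return trace


def simulate_outputs_batch(
    weights: np.ndarray,
    biases: np.ndarray,
    time_constants: np.ndarray,
    dt: float,
    n_steps: int,
    y0: np.ndarray | None = None,
) -> Iterator[np.ndarray]:
    """Step a batch of B same-size networks, yielding outputs each step.

    ``weights`` is (B, N, N) with the same from->to orientation as
    :class:`NetworkParameters`; ``biases`` (B, N); ``time_constants`` (N,) or
    (B, N).  Yields the (B, N) output array n_steps + 1 times (initial point
    included).  Used by the fitness and landscape evaluators, where thousands
    of candidate networks are integrated in lock-step.
    """
    B, N = biases.shape
    y = np.zeros((B, N)) if y0 is None else np.array(y0, dtype=float)
    rate = dt / np.asarray(time_constants, dtype=float)
    o = 1.0 / (1.0 + np.exp(-(y + biases)))
    yield o
    for k in range(n_steps):
        y += rate * (-y + np.einsum("bj,bji->bi", o, weights))
        if not np.all(np.abs(y) <= STATE_OVERFLOW_LIMIT):
            raise SimulationError(f"state overflow at step {k + 1}")
        o = 1.0 / (1.0 + np.exp(-(y + biases)))
        yield o


def trace_to_csv(trace: Sequence[tuple[float, np.ndarray, np.ndarray]], path: str | Path) -> None:
    """Write a simulation trace as CSV with header t, y_1..y_N, o_1..o_N."""
    n = len(trace[0][1])
    header = ["t"] + [f"y_{i + 1}" for i in range(n)] + [f"o_{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for t, y, o in trace:
            row = [f"{t:.6f}"] + [f"{v:.9g}" for v in y] + [f"{v:.9g}" for v in o]
            fh.write(",".join(row) + "\n")
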