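"""Rhythmic pattern-generation performance, running average, reward, fitness.

The task is central pattern generation: with no input, a network is rewarded
for continually changing its outputs.  Instantaneous performance is the
per-neuron mean absolute output change, expressed as a rate:

    P(t) = ( sum_j |o_j(t) - o_j(t - dt)| / N ) / dt       [1/s]

Dividing by the integration step makes P comparable across step sizes; only a
network that keeps raising and lowering its outputs (i.e. oscillates) can
sustain a high P, since moving in one direction saturates the logistic.

The reward is a reward-prediction-error-like signal: the difference between
the instantaneous performance and its sliding-window running average,

    R(t) = P(t) - P_r(t),

positive when the network is doing better than it recently has.

For the baseline searchers and landscape plots, a network's *fitness* is the
mean of P over a fixed evaluation from the zero state, either including the
initial transient or only counting output changes after a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctrnn import NetworkParameters, SimulationError

__all__ = [
    "PerformanceTracker",
    "FitnessSpec",
    "instantaneous_performance",
    "evaluate_fitness",
    "evaluate_fitness_batch",
]


def instantaneous_performance(
    outputs_prev: np.ndarray, outputs_now: np.ndarray, dt: float
) -> float:
    """Per-neuron mean absolute output change per second between two steps."""
    outputs_prev = np.asarray(outputs_prev, dtype=float)
    outputs_now = np.asarray(outputs_now, dtype=float)
    if outputs_prev.shape != outputs_now.shape:
        raise ValueError("output vectors must have equal length")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.mean(np.abs(outputs_now - outputs_prev)) / dt)


class PerformanceTracker:
    """Sliding-window running average of performance and the reward signal.

    The window is ``window_seconds`` of simulated time (``window_seconds/dt``
    samples).  While the buffer is filling the average is taken over the
    samples present, which keeps the reward near zero at onset instead of
    producing a spurious positive spike.  Supports a batch dimension so B
    concurrent trials can share one tracker.
    """

    def __init__(self, window_seconds: float, dt: float, batch: int = 1):
        if window_seconds <= 0 or dt <= 0:
            raise ValueError("window_seconds and dt must be positive")
        self.window_seconds = float(window_seconds)
        self.dt = float(dt)
        self._size = max(1, int(round(window_seconds / dt)))
        self._buf = np.zeros((batch, self._size))
        self._idx = 0
        self._count = 0
        self._sum = np.zeros(batch)
        self.perf_now = np.zeros(batch)
        self.perf_avg = np.zeros(batch)
        self.reward = np.zeros(batch)

    @property
    def window_size(self) -> int:
        """Window length in samples."""
        return self._size

    def update(self, perf) -> np.ndarray:
        """Push one performance sample (scalar or length-B) and return reward."""
        perf = np.atleast_1d(np.asarray(perf, dtype=float))
        if self._count >= self._size:
            self._sum -= self._buf[:, self._idx]
        self._buf[:, self._idx] = perf
        self._sum += perf
        self._idx += 1
        self._count = min(self._count + 1, self._size)
        if self._idx == self._size:
            self._idx = 0
            # periodic exact refresh bounds round-off drift of the running sum
            self._sum = self._buf.sum(axis=1)
        self.perf_now = perf
        self.perf_avg = self._sum / self._count
        self.reward = self.perf_now - self.perf_avg
        return self.reward


@dataclass(frozen=True)
class FitnessSpec:
    """How to score a network: evaluation length and transient handling.

    ``transient_policy`` is "include-all" (every step counts, the paper-style
    10 s metric) or "exclude-before-cutoff" (only output changes after
    ``transient_cutoff`` seconds count, which ignores transient activity).
    """

    eval_duration: float = 10.0
    transient_policy: str = "include-all"
    transient_cutoff: float = 250.0
    dt: float = 0.01

    def __post_init__(self):
        if self.eval_duration <= 0:
            raise ValueError("eval_duration must be positive")
        if self.transient_policy not in ("include-all", "exclude-before-cutoff"):
            raise ValueError(f"unknown transient_policy {self.transient_policy!r}")
        if (
            self.transient_policy == "exclude-before-cutoff"
            and not (0 < self.transient_cutoff < self.eval_duration)
        ):
            raise ValueError("transient_cutoff must lie inside the evaluation window")


def evaluate_fitness_batch(
    weights: np.ndarray,
    biases: np.ndarray,
    time_constants: np.ndarray,
    spec: FitnessSpec,
    y0: np.ndarray | None = None,
    return_final_state: bool = False,
):
    """Fitness of B same-size networks simulated in lock-step from ``y0``.

    Returns the length-B vector of mean instantaneous performance over the
    included interval (and, if requested, the final neuron states, which the
    carry-over evaluation policy of the baseline searchers needs).  ``y0``
    defaults to the zero state.
    """
    dt = spec.dt
    n_steps = int(round(spec.eval_duration / dt))
    skip = (
        int(round(spec.transient_cutoff / dt))
        if spec.transient_policy == "exclude-before-cutoff"
        else 0
    )
    B, N = biases.shape
    y = np.zeros((B, N)) if y0 is None else np.array(y0, dtype=float)
    rate = dt / np.asarray(time_constants, dtype=float)
    total = np.zeros(B)
    o = 1.0 / (1.0 + np.exp(-(y + biases)))
    for k in range(1, n_steps + 1):
        y += rate * (-y + np.einsum("bj,bji->bi", o, weights))
        if not np.all(np.abs(y) <= 1e6):
            raise SimulationError(f"state overflow at step {k}")
        o_new = 1.0 / (1.0 + np.exp(-(y + biases)))
        if k > skip:
            total += np.abs(o_new - o).mean(axis=1)
        o = o_new
    fitness = total / ((n_steps - skip) * dt)
    if return_final_state:
        return fitness, y
    return fitness


def evaluate_fitness(params: NetworkParameters, spec: FitnessSpec) -> float:
    """Fitness of one network from the zero initial state (see the batch form)."""
    return float(
        evaluate_fitness_batch(
            params.weights[None], params.biases[None], params.time_constants, spec
        )[0]
    )
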