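"""Learning strategies: the online RL trial and two baseline searchers.

The RL-CTRNN learns *online*: every plastic parameter fluctuates continuously
while the network runs, and a single global reward signal — instantaneous
performance minus its running average — nudges all fluctuation centers and
amplitudes at every integration step.  The two baselines, a random walker and
a hill climber, instead take discrete steps in weight space and score each
candidate with a short offline fitness evaluation; their iteration axis is
mapped onto simulated seconds through the evaluation length so all three
strategies can share a time axis.

All strategies run many seeded repetitions; the trial engine advances a whole
batch of runs in lock-step with vectorized array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ctrnn import NetworkParameters, SimulationError
from .plasticity import FluctuationArray, FluctuationConfig
from .reward import FitnessSpec, PerformanceTracker, evaluate_fitness_batch

__all__ = [
    "RLTrialConfig",
    "WalkerConfig",
    "TrialTrace",
    "RLBatchResult",
    "WalkResult",
    "run_rl_trial",
    "run_rl_trials",
    "random_walk",
    "hill_climb",
    "budget_alignment",
]

#: a run counts as converged once its mean amplitude stays below this ...
#: (the reward keeps oscillating with the learned rhythm, so the amplitude
#: jitters above its floor by ~beta*|R| even after learning has finished)
CONVERGENCE_AMPLITUDE = 0.25
#: ... for this many consecutive simulated seconds
CONVERGENCE_HOLD_SECONDS = 100.0


@dataclass(frozen=True)
class RLTrialConfig:
    """Settings for one online learning trial.

    ``transient`` seconds of warm-up let the network dynamics (and the
    running-average buffer) settle before reward is allowed to move centers
    and amplitudes; fluctuations themselves run from t = 0.  With
    ``plastic_biases`` the biases fluctuate and learn under the same rule and
    metaparameters as the weights.  ``invert_reward`` flips the sign of the
    reward fed to the update rule (for comparison runs; the default sign
    implements exploit-on-improvement).
    """

    fluctuation: FluctuationConfig = field(default_factory=FluctuationConfig)
    window_seconds: float = 10.0
    dt: float = 0.01
    duration: float = 2000.0
    transient: float = 100.0
    plastic_biases: bool = False
    invert_reward: bool = False
    record_every: float = 1.0

    def __post_init__(self):
        if self.duration <= self.transient:
            raise ValueError("duration must exceed the warm-up transient")
        if self.dt <= 0 or self.record_every <= 0:
            raise ValueError("dt and record_every must be positive")


@dataclass(frozen=True)
class WalkerConfig:
    """Settings for the random-walk and hill-climbing baselines.

    Each iteration perturbs every walked weight by an independent draw from
    Uniform(-mutation_size, +mutation_size) and scores the candidate with
    ``eval``.  ``state_policy`` "reset-to-zero" starts every evaluation from
    the zero state; "carry-over" starts from wherever the previous accepted
    evaluation left the neurons.
    """

    mutation_size: float = 8.0
    eval: FitnessSpec = field(default_factory=FitnessSpec)
    iterations: int = 200
    state_policy: str = "reset-to-zero"
    clip_bounds: tuple[float, float] = (-16.0, 16.0)

    def __post_init__(self):
        if self.mutation_size < 0:
            raise ValueError("mutation_size must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.state_policy not in ("reset-to-zero", "carry-over"):
            raise ValueError(f"unknown state_policy {self.state_policy!r}")


@dataclass
class TrialTrace:
    """Recorded time series of one RL learning trial.

    Arrays are sampled every ``record_every`` seconds.  ``weight_centers``
    etc. have shape (T, N, N); bias arrays are None when biases are static.
    ``final_perf_avg`` is the running-average performance at the end of the
    trial and ``convergence_time`` the first time the mean fluctuation
    amplitude stayed below the convergence threshold for the required hold
    (NaN if it never did).
    """

    t: np.ndarray
    perf_now: np.ndarray
    perf_avg: np.ndarray
    reward: np.ndarray
    weight_centers: np.ndarray
    weight_values: np.ndarray
    weight_amplitudes: np.ndarray
    bias_centers: Optional[np.ndarray]
    bias_values: Optional[np.ndarray]
    bias_amplitudes: Optional[np.ndarray]
    final_params: NetworkParameters
    final_perf_avg: float
    convergence_time: float

    def to_csv(self, path) -> None:
        """Dump the per-sample series (performance, reward, per-weight C/value/A)."""
        n = self.weight_centers.shape[1]
        cols = ["t", "perf_now", "perf_avg", "reward"]
        mats = [self.t, self.perf_now, self.perf_avg, self.reward]
        for j in range(n):
            for i in range(n):
                cols += [f"C_w{j}{i}", f"p_w{j}{i}", f"A_w{j}{i}"]
        flat = np.column_stack(
            [np.asarray(m) for m in mats]
            + [
                arr[:, j, i]
                for j in range(n)
                for i in range(n)
                for arr in (self.weight_centers, self.weight_values, self.weight_amplitudes)
            ]
        )
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            np.savetxt(fh, flat, delimiter=",", fmt="%.9g")


@dataclass
class RLBatchResult:
    """Vectorized result of B lock-step RL trials (leading axis = run)."""

    t: np.ndarray                       # (T,)
    perf_now: np.ndarray                # (T, B)
    perf_avg: np.ndarray                # (T, B)
    reward: np.ndarray                  # (T, B)
    weight_centers: np.ndarray          # (T, B, N, N)
    weight_values: np.ndarray           # (T, B, N, N)
    weight_amplitudes: np.ndarray       # (T, B, N, N)
    bias_centers: Optional[np.ndarray]  # (T, B, N)
    bias_values: Optional[np.ndarray]
    bias_amplitudes: Optional[np.ndarray]
    final_weights: np.ndarray           # (B, N, N) effective at trial end
    final_biases: np.ndarray            # (B, N)
    time_constants: np.ndarray          # (N,)
    final_perf_avg: np.ndarray          # (B,)
    convergence_time: np.ndarray        # (B,), NaN where never converged

    @property
    def n_runs(self) -> int:
        return self.perf_now.shape[1]

    def mean_amplitude(self) -> np.ndarray:
        """(T, B) mean fluctuation amplitude over all plastic parameters."""
        amp = self.weight_amplitudes.mean(axis=(2, 3))
        if self.bias_amplitudes is not None:
            n2 = self.weight_amplitudes.shape[2] ** 2
            nb = self.bias_amplitudes.shape[2]
            amp = (amp * n2 + self.bias_amplitudes.mean(axis=2) * nb) / (n2 + nb)
        return amp

    def center_path_lengths(self) -> np.ndarray:
        """(B,) Euclidean path length of the weight-center trajectory."""
        d = np.diff(self.weight_centers, axis=0)
        return np.sqrt((d**2).sum(axis=(2, 3))).sum(axis=0)

    def amplitude_halving_times(self) -> np.ndarray:
        """(B,) first time each run's mean amplitude fell below half its
        initial value (NaN if never).  A jitter-robust measure of how fast
        exploration is annealed, useful where the latching convergence
        detector is confounded by the reward-driven amplitude jitter."""
        amp = self.mean_amplitude()
        out = np.full(self.n_runs, np.nan)
        for b in range(self.n_runs):
            hit = np.flatnonzero(amp[:, b] < 0.5 * amp[0, b])
            if hit.size:
                out[b] = self.t[hit[0]]
        return out

    def extract(self, run: int) -> TrialTrace:
        """Single-run view as a :class:`TrialTrace`."""
        b = run
        return TrialTrace(
            t=self.t,
            perf_now=self.perf_now[:, b],
            perf_avg=self.perf_avg[:, b],
            reward=self.reward[:, b],
            weight_centers=self.weight_centers[:, b],
            weight_values=self.weight_values[:, b],
            weight_amplitudes=self.weight_amplitudes[:, b],
            bias_centers=None if self.bias_centers is None else self.bias_centers[:, b],
            bias_values=None if self.bias_values is None else self.bias_values[:, b],
            bias_amplitudes=None if self.bias_amplitudes is None else self.bias_amplitudes[:, b],
            final_params=NetworkParameters(
                weights=self.final_weights[b],
                biases=self.final_biases[b],
                time_constants=self.time_constants,
            ),
            final_perf_avg=float(self.final_perf_avg[b]),
            convergence_time=float(self.convergence_time[b]),
        )


def run_rl_trials(
    starts: Sequence[NetworkParameters] | NetworkParameters,
    config: RLTrialConfig,
    seed: int,
    n_runs: Optional[int] = None,
) -> RLBatchResult:
    """Run B online learning trials in lock-step and return the batch result.

    ``starts`` is either one network (replicated ``n_runs`` times; the runs
    then differ only through their independent period draws) or a sequence of
    same-size networks, one per run.  All randomness comes from ``seed``.
    """
    if isinstance(starts, NetworkParameters):
        starts = [starts] * (n_runs if n_runs is not None else 1)
    starts = list(starts)
    B = len(starts)
    N = starts[0].n_neurons
    tau = starts[0].time_constants
    for s in starts:
        if s.n_neurons != N or not np.array_equal(s.time_constants, tau):
            raise ValueError("all start networks must share size and time constants")

    rng = np.random.default_rng(seed)
    cfg = config.fluctuation
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    rec_stride = max(1, int(round(config.record_every / dt)))
    n_rec = n_steps // rec_stride + 1

    w_flux = FluctuationArray(np.stack([s.weights for s in starts]), cfg, rng)
    b_flux = (
        FluctuationArray(np.stack([s.biases for s in starts]), cfg, rng)
        if config.plastic_biases
        else None
    )
    base_biases = np.stack([s.biases for s in starts])
    rate = dt / tau

    tracker = PerformanceTracker(config.window_seconds, dt, batch=B)
    y = np.zeros((B, N))
    o_prev = 1.0 / (1.0 + np.exp(-(y + (b_flux.values(0.0) if b_flux else base_biases))))

    rec_t = np.zeros(n_rec)
    rec_perf = np.zeros((n_rec, B))
    rec_avg = np.zeros((n_rec, B))
    rec_rwd = np.zeros((n_rec, B))
    rec_wc = np.zeros((n_rec, B, N, N))
    rec_wv = np.zeros((n_rec, B, N, N))
    rec_wa = np.zeros((n_rec, B, N, N))
    rec_bc = np.zeros((n_rec, B, N)) if b_flux else None
    rec_bv = np.zeros((n_rec, B, N)) if b_flux else None
    rec_ba = np.zeros((n_rec, B, N)) if b_flux else None

    def record(idx, t):
        rec_t[idx] = t
        rec_perf[idx] = tracker.perf_now
        rec_avg[idx] = tracker.perf_avg
        rec_rwd[idx] = tracker.reward
        rec_wc[idx] = w_flux.centers
        rec_wv[idx] = w_flux.values(t)
        rec_wa[idx] = w_flux.amplitudes
        if b_flux is not None:
            rec_bc[idx] = b_flux.centers
            rec_bv[idx] = b_flux.values(t)
            rec_ba[idx] = b_flux.amplitudes

    record(0, 0.0)
    rec_idx = 1

    # convergence = trailing CONVERGENCE_HOLD_SECONDS mean of the mean
    # amplitude below threshold (the instantaneous amplitude keeps jittering
    # with the reward, so a pointwise criterion would never latch)
    hold_steps = int(round(CONVERGENCE_HOLD_SECONDS / dt))
    amp_ring = np.zeros((B, hold_steps))
    amp_sum = np.zeros(B)
    ring_idx = 0
    conv_time = np.full(B, np.nan)
    n_params = N * N + (N if b_flux else 0)

    sign = -1.0 if config.invert_reward else 1.0
    for k in range(n_steps):
        t = k * dt
        t_next = t + dt
        w_flux.advance(t, dt)
        w_now = w_flux.values(t_next)
        if b_flux is not None:
            b_flux.advance(t, dt)
            b_now = b_flux.values(t_next)
        else:
            b_now = base_biases
        y += rate * (-y + np.einsum("bj,bji->bi", o_prev, w_now))
        if not np.all(np.abs(y) <= 1e6):
            raise SimulationError(f"state overflow at step {k + 1} (t={t_next:.2f} s)")
        o = 1.0 / (1.0 + np.exp(-(y + b_now)))
        perf = np.abs(o - o_prev).mean(axis=1) / dt
        o_prev = o
        reward = tracker.update(perf)
        if t_next > config.transient:
            r = sign * reward
            w_flux.apply_reward(w_now, r[:, None, None], dt)
            if b_flux is not None:
                b_flux.apply_reward(b_now, r[:, None], dt)
        # convergence bookkeeping on the mean amplitude across plastic params
        amp = w_flux.amplitudes.sum(axis=(1, 2))
        if b_flux is not None:
            amp = amp + b_flux.amplitudes.sum(axis=1)
        amp /= n_params
        amp_sum += amp - amp_ring[:, ring_idx]
        amp_ring[:, ring_idx] = amp
        ring_idx += 1
        if ring_idx == hold_steps:
            ring_idx = 0
        if k + 1 >= hold_steps:
            newly = (amp_sum / hold_steps < CONVERGENCE_AMPLITUDE) & np.isnan(conv_time)
            conv_time[newly] = t_next
        if (k + 1) % rec_stride == 0:
            record(rec_idx, t_next)
            rec_idx += 1

    t_end = n_steps * dt
    return RLBatchResult(
        t=rec_t[:rec_idx],
        perf_now=rec_perf[:rec_idx],
        perf_avg=rec_avg[:rec_idx],
        reward=rec_rwd[:rec_idx],
        weight_centers=rec_wc[:rec_idx],
        weight_values=rec_wv[:rec_idx],
        weight_amplitudes=rec_wa[:rec_idx],
        bias_centers=None if rec_bc is None else rec_bc[:rec_idx],
        bias_values=None if rec_bv is None else rec_bv[:rec_idx],
        bias_amplitudes=None if rec_ba is None else rec_ba[:rec_idx],
        final_weights=w_flux.values(t_end),
        final_biases=b_flux.values(t_end) if b_flux else base_biases,
        time_constants=tau,
        final_perf_avg=tracker.perf_avg.copy(),
        convergence_time=conv_time,
    )


def run_rl_trial(start: NetworkParameters, config: RLTrialConfig, seed: int) -> TrialTrace:
    """Run one online learning trial (batch of one) and return its trace."""
    return run_rl_trials(start, config, seed, n_runs=1).extract(0)


@dataclass
class WalkResult:
    """Result of a batch of baseline searches (leading axis = iteration)."""

    fitness: np.ndarray        # (iterations+1, B) best-so-far (RW) / accepted (HC)
    best_weights: np.ndarray   # (B, N, N)
    time_axis: np.ndarray      # (iterations+1,) simulated seconds spent evaluating

    @property
    def final_fitness(self) -> np.ndarray:
        return self.fitness[-1]


def _walk_setup(start: NetworkParameters, config: WalkerConfig, n_runs: int):
    B = n_runs
    N = start.n_neurons
    w = np.broadcast_to(start.weights, (B, N, N)).copy()
    b = np.broadcast_to(start.biases, (B, N)).copy()
    f0 = evaluate_fitness_batch(w, b, start.time_constants, config.eval)
    return w, b, f0


def random_walk(
    start: NetworkParameters, config: WalkerConfig, seed: int, n_runs: int = 1
) -> WalkResult:
    """Unconditional random walk through weight space, best-so-far reported.

    Every iteration moves *all* weights by independent uniform draws from the
    current position (the walk never reverts); the reported curve is the
    running maximum of the fitness encountered.
    """
    rng = np.random.default_rng(seed)
    w, b, f = _walk_setup(start, config, n_runs)
    m = config.mutation_size
    best = f.copy()
    best_w = w.copy()
    curve = [best.copy()]
    y = np.zeros_like(b)
    for _ in range(config.iterations):
        w += rng.uniform(-m, m, size=w.shape)
        np.clip(w, *config.clip_bounds, out=w)
        y0 = y if config.state_policy == "carry-over" else None
        f, y = evaluate_fitness_batch(
            w, b, start.time_constants, config.eval, y0=y0, return_final_state=True
        )
        improved = f > best
        best = np.maximum(best, f)
        best_w[improved] = w[improved]
        curve.append(best.copy())
    axis = budget_alignment(config.iterations, config.eval.eval_duration)
    return WalkResult(fitness=np.array(curve), best_weights=best_w, time_axis=axis)


def hill_climb(
    start: NetworkParameters, config: WalkerConfig, seed: int, n_runs: int = 1
) -> WalkResult:
    """Hill climber: a proposed step is kept only if fitness does not drop.

    With the default reset-to-zero policy every candidate is scored from the
    consistent zero state; with carry-over the evaluation starts from the end
    state of the previously accepted evaluation, which mimics the RL-CTRNN's
    ongoing dynamics and is known to hurt the climber.
    """
    rng = np.random.default_rng(seed)
    w, b, f = _walk_setup(start, config, n_runs)
    m = config.mutation_size
    curve = [f.copy()]
    y = np.zeros_like(b)
    for _ in range(config.iterations):
        cand = np.clip(w + rng.uniform(-m, m, size=w.shape), *config.clip_bounds)
        y0 = y if config.state_policy == "carry-over" else None
        f_new, y_new = evaluate_fitness_batch(
            cand, b, start.time_constants, config.eval, y0=y0, return_final_state=True
        )
        accept = f_new >= f
        w[accept] = cand[accept]
        f = np.where(accept, f_new, f)
        if config.state_policy == "carry-over":
            y[accept] = y_new[accept]
        curve.append(f.copy())
    axis = budget_alignment(config.iterations, config.eval.eval_duration)
    return WalkResult(fitness=np.array(curve), best_weights=w, time_axis=axis)


def budget_alignment(walker_iterations: int, eval_duration: float) -> np.ndarray:
    """Map iteration k to k * eval_duration simulated seconds (shared x-axis)."""
    if walker_iterations < 0 or eval_duration <= 0:
        raise ValueError("iterations must be >= 0 and eval_duration positive")
    return np.arange(walker_iterations + 1) * eval_duration
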