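"""Experiment suites: landscape slices, distance sweeps, metaparameter
sweeps, and network-size scaling.

Each experiment is fully determined by its config and a master seed: per-run
seeds are spawned deterministically from (master seed, run index) via
``numpy.random.SeedSequence``, so results are reproducible and individual
runs can be re-executed in isolation.  Results are returned as pandas
DataFrames, one row per run or grid cell, ready to be written as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ctrnn import NetworkParameters
from .evolve import random_network
from .learners import RLTrialConfig, run_rl_trials
from .plasticity import FluctuationConfig
from .reward import FitnessSpec, evaluate_fitness_batch

__all__ = [
    "GridSpec",
    "SweepSpec",
    "landscape_slice",
    "distance_sweep",
    "bin_by_distance",
    "metaparameter_sweep",
    "size_scaling",
]

#: distance decades used when summarizing sweep results, open-ended at the top
DISTANCE_BIN_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over a set of weight entries.

    ``dims`` lists the varied entries as (j, i) index pairs into the weight
    matrix; ``ranges`` gives one (lo, hi, step) triple per dimension.  Grid
    values are lo, lo+step, ..., hi inclusive.
    """

    dims: tuple[tuple[int, int], ...]
    ranges: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if len(self.dims) != len(self.ranges):
            raise ValueError("dims and ranges must have equal length")
        for lo, hi, step in self.ranges:
            if step <= 0 or hi < lo:
                raise ValueError("each range needs lo <= hi and step > 0")

    def axis(self, d: int) -> np.ndarray:
        lo, hi, step = self.ranges[d]
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    @property
    def cardinality(self) -> int:
        out = 1
        for d in range(len(self.dims)):
            out *= len(self.axis(d))
        return out

    def enumerate_weights(self, base: NetworkParameters) -> np.ndarray:
        """(cardinality, N, N) weight matrices: base with grid values filled in."""
        axes = [self.axis(d) for d in range(len(self.dims))]
        mesh = np.meshgrid(*axes, indexing="ij")
        combos = np.stack([m.ravel() for m in mesh], axis=1)  # (M, D)
        w = np.broadcast_to(base.weights, (combos.shape[0],) + base.weights.shape).copy()
        for d, (j, i) in enumerate(self.dims):
            w[:, j, i] = combos[:, d]
        return w


def landscape_slice(
    base: NetworkParameters,
    dims: tuple[tuple[int, int], tuple[int, int]],
    grid: GridSpec | None = None,
    metric: FitnessSpec | None = None,
) -> pd.DataFrame:
    """Fitness over a two-weight slice of parameter space.

    Returns a DataFrame with columns (param1, param2, fitness), one row per
    grid cell, with all other parameters held at ``base``.  The default grid
    spans [-16, 16] at step 1 in both varied weights.
    """
    if grid is None:
        grid = GridSpec(dims=dims, ranges=((-16, 16, 1.0), (-16, 16, 1.0)))
    elif tuple(grid.dims) != tuple(dims):
        grid = replace(grid, dims=tuple(dims))
    if len(grid.dims) != 2:
        raise ValueError("a landscape slice varies exactly two weights")
    metric = metric or FitnessSpec()
    w = grid.enumerate_weights(base)
    B = w.shape[0]
    biases = np.broadcast_to(base.biases, (B, base.n_neurons)).copy()
    fit = evaluate_fitness_batch(w, biases, base.time_constants, metric)
    (j1, i1), (j2, i2) = grid.dims
    return pd.DataFrame(
        {"param1": w[:, j1, i1], "param2": w[:, j2, i2], "fitness": fit}
    )


def bin_by_distance(distances: np.ndarray, edges: Sequence[float] = DISTANCE_BIN_EDGES):
    """Assign each distance to a decade bin; the last bin is open-ended.

    Returns (labels, bin_index): e.g. edges (0,10,...,50) produce labels
    '0-10', ..., '40-50', '50+'.  Bins are disjoint and exhaustive.
    """
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges[1:], distances, side="right")
    labels = [f"{edges[k]:g}-{edges[k + 1]:g}" for k in range(len(edges) - 1)]
    labels.append(f"{edges[-1]:g}+")
    return labels, idx


def distance_sweep(
    known_good: NetworkParameters,
    grid: GridSpec,
    trial: RLTrialConfig,
    seed: int,
) -> pd.DataFrame:
    """One RL trial from every grid configuration, tabulated against distance.

    Each start's Euclidean distance to ``known_good`` is measured over the
    varied weights.  Returns columns (start_id, distance, distance_bin,
    final_perf_avg, convergence_time); runs that overflow are recorded as NaN
    rather than aborting the sweep.  All trials run in one lock-step batch.
    """
    w = grid.enumerate_weights(known_good)
    M = w.shape[0]
    starts = [
        NetworkParameters(
            weights=w[m], biases=known_good.biases, time_constants=known_good.time_constants
        )
        for m in range(M)
    ]
    good = np.array([known_good.weights[j, i] for j, i in grid.dims])
    varied = np.stack([[w[m, j, i] for j, i in grid.dims] for m in range(M)])
    dist = np.linalg.norm(varied - good, axis=1)
    labels, bins = bin_by_distance(dist)

    res = run_rl_trials(starts, trial, seed=seed)
    return pd.DataFrame(
        {
            "start_id": np.arange(M),
            "distance": dist,
            "distance_bin": [labels[b] for b in bins],
            "final_perf_avg": res.final_perf_avg,
            "convergence_time": res.convergence_time,
        }
    )


SWEEPABLE = ("init_flux", "convergence_rate", "period_min", "window_seconds")


@dataclass(frozen=True)
class SweepSpec:
    """One-metaparameter sweep: which knob, its values, runs per value."""

    which: str
    values: tuple[float, ...]
    runs_per_value: int = 10
    base: RLTrialConfig = field(default_factory=RLTrialConfig)

    def __post_init__(self):
        if self.which not in SWEEPABLE:
            raise ValueError(f"which must be one of {SWEEPABLE}")
        if not self.values:
            raise ValueError("values must be non-empty")
        if self.runs_per_value < 1:
            raise ValueError("runs_per_value must be >= 1")

    def config_for(self, value: float) -> RLTrialConfig:
        if self.which == "window_seconds":
            return replace(self.base, window_seconds=value)
        old = self.base.fluctuation
        if self.which == "period_min":
            # the period-distribution settings (mean, sd, max) follow the minimum
            fluct = FluctuationConfig(
                learning_rate=old.learning_rate,
                convergence_rate=old.convergence_rate,
                init_flux=old.init_flux,
                period_min=value,
                value_bounds=old.value_bounds,
                amplitude_max=old.amplitude_max,
            )
        else:
            fluct = replace(old, **{self.which: value})
        return replace(self.base, fluctuation=fluct)


def metaparameter_sweep(
    start: NetworkParameters, spec: SweepSpec, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Seeded trials for each metaparameter value, plus aggregated curves.

    Returns ``(summary, curves)``.  ``summary`` has one row per run with the
    metaparameter value, final running-average performance, convergence time,
    and weight-center path length.  ``curves[value]`` holds the per-value
    mean +/- standard-error learning and amplitude curves over time.
    """
    rows = []
    curves: dict = {}
    children = np.random.SeedSequence(seed).spawn(len(spec.values))
    for v, child in zip(spec.values, children):
        cfg = spec.config_for(v)
        run_seed = int(child.generate_state(1)[0] % (2**31))
        res = run_rl_trials(start, cfg, seed=run_seed, n_runs=spec.runs_per_value)
        path = res.center_path_lengths()
        halving = res.amplitude_halving_times()
        B = res.n_runs
        for b in range(B):
            rows.append(
                {
                    spec.which: v,
                    "run": b,
                    "final_perf_avg": res.final_perf_avg[b],
                    "convergence_time": res.convergence_time[b],
                    "amp_halving_time": halving[b],
                    "path_length": path[b],
                }
            )
        amp = res.mean_amplitude()

        def _se(a):
            if B < 2:
                return np.zeros(a.shape[0])
            return a.std(axis=1, ddof=1) / np.sqrt(B)

        curves[v] = pd.DataFrame(
            {
                "t": res.t,
                "perf_avg_mean": res.perf_avg.mean(axis=1),
                "perf_avg_se": _se(res.perf_avg),
                "amplitude_mean": amp.mean(axis=1),
                "amplitude_se": _se(amp),
            }
        )
    return pd.DataFrame(rows), curves


def size_scaling(
    sizes: Sequence[int],
    n_starts: int,
    trial: RLTrialConfig,
    seed: int,
    bounds: tuple[float, float] = (-16.0, 16.0),
) -> tuple[pd.DataFrame, dict]:
    """Learning from random starts across network sizes, same metaparameters.

    For every size, ``n_starts`` random all-to-all networks (weights and
    biases uniform in ``bounds``, tau = 1) are trained with weights *and*
    biases plastic.  Returns (summary DataFrame with one row per run, curves
    keyed by size with the mean learning curve over runs).
    """
    if any(s < 2 for s in sizes):
        raise ValueError("network sizes must be >= 2")
    trial = replace(trial, plastic_biases=True)
    rows = []
    curves: dict = {}
    top = np.random.SeedSequence(seed).spawn(len(sizes))
    for size, child in zip(sizes, top):
        start_seeds = child.generate_state(n_starts + 1) % (2**31)
        starts = [random_network(size, bounds, seed=int(s)) for s in start_seeds[:-1]]
        res = run_rl_trials(starts, trial, seed=int(start_seeds[-1]))
        for b in range(n_starts):
            rows.append(
                {
                    "size": size,
                    "run": b,
                    "n_parameters": size * size + size,
                    "final_perf_avg": res.final_perf_avg[b],
                    "convergence_time": res.convergence_time[b],
                }
            )
        curves[size] = pd.DataFrame(
            {"t": res.t, "perf_avg_mean": res.perf_avg.mean(axis=1)}
        )
    return pd.DataFrame(rows), curves
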