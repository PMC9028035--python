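"""Seed networks for the learning experiments.

The learning task must be solvable by weight changes alone, so a
high-performing two-neuron oscillator is first evolved with a microbial
genetic algorithm (steady-state GA: pairwise tournament, the loser is
gene-wise overwritten by the winner with some probability, then mutated).
Perturbed copies of that oscillator at controlled weight-space distances and
fully random networks then provide starting configurations of graded
difficulty.  Time constants are fixed at 1.0 throughout — they only rescale
time, not the attainable dynamics.

A canonical evolved oscillator is shipped with the package
(``data/evolved_oscillator_2n.json``) so downstream experiments and tests do
not have to re-run the GA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .ctrnn import NetworkParameters
from .reward import FitnessSpec, evaluate_fitness_batch

__all__ = [
    "GAConfig",
    "PerturbationSpec",
    "microbial_ga",
    "perturb_weights",
    "random_network",
    "load_evolved_oscillator",
]


@dataclass(frozen=True)
class GAConfig:
    """Microbial GA settings; a genotype is [weights row-major, biases]."""

    n_neurons: int = 2
    population_size: int = 50
    generations: int = 2000            # number of pairwise tournaments
    recombination_prob: float = 0.5    # per-gene probability loser copies winner
    mutation_sd: float = 1.0           # per-gene Gaussian mutation, applied to loser
    gene_bounds: tuple[float, float] = (-16.0, 16.0)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)

    def __post_init__(self):
        if not 0 <= self.recombination_prob <= 1:
            raise ValueError("recombination_prob must be in [0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")


def _decode(genome: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    return genome[: n * n].reshape(n, n), genome[n * n :]


def microbial_ga(config: GAConfig, seed: int) -> tuple[NetworkParameters, np.ndarray]:
    """Evolve a network; returns (best network, best-fitness-so-far history).

    All time constants are fixed at 1.0.  The history has one entry per
    tournament and is non-decreasing (best-so-far bookkeeping).
    """
    rng = np.random.default_rng(seed)
    n = config.n_neurons
    n_genes = n * n + n
    lo, hi = config.gene_bounds
    tau = np.ones(n)

    pop = rng.uniform(lo, hi, size=(config.population_size, n_genes))
    w = pop[:, : n * n].reshape(-1, n, n)
    b = pop[:, n * n :]
    fit = evaluate_fitness_batch(w, b, tau, config.fitness)

    best_idx = int(np.argmax(fit))
    best_genome = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = np.empty(config.generations)

    for g in range(config.generations):
        i, j = rng.choice(config.population_size, size=2, replace=False)
        if fit[i] >= fit[j]:
            winner, loser = i, j
        else:
            winner, loser = j, i
        copy_mask = rng.random(n_genes) < config.recombination_prob
        pop[loser, copy_mask] = pop[winner, copy_mask]
        pop[loser] += rng.normal(0.0, config.mutation_sd, size=n_genes)
        np.clip(pop[loser], lo, hi, out=pop[loser])
        wl, bl = _decode(pop[loser], n)
        fit[loser] = evaluate_fitness_batch(wl[None], bl[None], tau, config.fitness)[0]
        if fit[loser] > best_fit:
            best_fit = float(fit[loser])
            best_genome = pop[loser].copy()
        history[g] = best_fit

    wb, bb = _decode(best_genome, n)
    return NetworkParameters(weights=wb, biases=bb, time_constants=tau), history


@dataclass(frozen=True)
class PerturbationSpec:
    """How to displace a network's weights.

    modes: "gaussian" (sd = magnitude), "uniform" (± magnitude), and
    "exact-distance" (a random direction scaled so the Euclidean displacement
    over the chosen weights equals ``magnitude`` before clamping).
    ``n_weights`` entries are chosen at random without replacement (all, if
    None).
    """

    magnitude: float = 1.0
    n_weights: int | None = None
    mode: str = "gaussian"
    clip_bounds: tuple[float, float] = (-16.0, 16.0)

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.mode not in ("gaussian", "uniform", "exact-distance"):
            raise ValueError(f"unknown mode {self.mode!r}")


def perturb_weights(
    net: NetworkParameters, spec: PerturbationSpec, seed: int
) -> NetworkParameters:
    """Return a copy of ``net`` with selected weights displaced per ``spec``."""
    rng = np.random.default_rng(seed)
    n = net.n_neurons
    total = n * n
    k = total if spec.n_weights is None else int(spec.n_weights)
    if not 0 <= k <= total:
        raise ValueError(f"n_weights must be in [0, {total}]")
    idx = rng.choice(total, size=k, replace=False)
    flat = net.weights.flatten()

    if spec.mode == "gaussian":
        delta = rng.normal(0.0, spec.magnitude, size=k)
    elif spec.mode == "uniform":
        delta = rng.uniform(-spec.magnitude, spec.magnitude, size=k)
    else:  # exact-distance
        direction = rng.normal(size=k)
        norm = np.linalg.norm(direction)
        if norm == 0:
            direction = np.ones(k)
            norm = np.sqrt(k)
        delta = direction / norm * spec.magnitude

    flat[idx] += delta
    clipped = np.clip(flat, *spec.clip_bounds)
    if spec.mode == "exact-distance" and not np.allclose(clipped, flat, atol=1e-12):
        offending = np.flatnonzero(clipped != flat)
        raise ValueError(
            f"exact-distance perturbation infeasible: weights {offending.tolist()} "
            f"hit bounds {spec.clip_bounds}"
        )
    return NetworkParameters(
        weights=clipped.reshape(n, n),
        biases=net.biases,
        time_constants=net.time_constants,
    )


def random_network(
    n: int, bounds: tuple[float, float] = (-16.0, 16.0), seed: int | None = None
) -> NetworkParameters:
    """All-to-all network with Uniform(bounds) weights and biases, tau = 1."""
    if n < 1:
        raise ValueError("network size must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    return NetworkParameters(
        weights=rng.uniform(lo, hi, size=(n, n)),
        biases=rng.uniform(lo, hi, size=n),
        time_constants=np.ones(n),
    )


def load_evolved_oscillator() -> NetworkParameters:
    """The canonical evolved two-neuron oscillator shipped with the package."""
    text = resources.files("rlctrnn.data").joinpath("evolved_oscillator_2n.json").read_text()
    return NetworkParameters.from_dict(json.loads(text))
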