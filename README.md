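# rlctrnn

Online reinforcement learning for continuous-time recurrent neural networks
(CTRNNs) on a central pattern generation task, with reward-modulated
sinusoidal parameter fluctuations, baseline stochastic searchers, and the
experiment suites built around them.

## The problem

CTRNNs are the workhorse dynamical model of computational neuroethology:
each neuron's state obeys

    τᵢ ẏᵢ = −yᵢ + Σⱼ wⱼᵢ σ(yⱼ + θⱼ),        oⱼ = σ(yⱼ + θⱼ),

with logistic activation σ, recurrent weights wⱼᵢ (from neuron *j* to neuron
*i*), biases θ, and time constants τ. These networks are usually configured
by offline stochastic search (evolutionary algorithms); this package instead
implements a biologically motivated *lifetime* learning rule. Each plastic
parameter p (a weight or bias) fluctuates sinusoidally around a slowly
learned "true center" C — emulating receptor-trafficking-driven variation of
effective synaptic strength:

    p(t) = C + A·sin(2π(t − tₖ)/Tₖ),

with the period Tₖ redrawn from a clamped Gaussian at every upward
center-crossing. A single global reward signal drives all parameters at
once:

    Ċ = α (p(t) − C) R(t),          Ȧ = −β R(t).

Positive reward pulls each center toward its current displacement and
shrinks the fluctuation amplitude (exploit); negative reward does the
opposite (explore). The task is rhythmic pattern generation: instantaneous
performance P(t) is the per-neuron mean absolute output change per second,
its sliding-window running average P_r(t) is the reward baseline, and
R(t) = P(t) − P_r(t) — a reward-prediction-error-like signal that is positive
exactly when the circuit is doing better than it recently has. Only a
network that keeps raising and lowering its outputs — an oscillator —
sustains high performance.

The package also provides the supporting cast: a microbial GA that evolves
high-performing seed oscillators, controlled weight perturbations, fitness
landscapes under transient-including and transient-excluding metrics,
hill-climbing and random-walk baselines at matched exploration budgets, and
sweeps over the learning rule's metaparameters and network sizes.

## Worked example

```python
import rlctrnn as r

osc = r.load_evolved_oscillator()                  # committed 2-neuron CPG
print("oscillator fitness (10 s):", round(r.evaluate_fitness(osc, r.FitnessSpec()), 3))

start = r.perturb_weights(                          # displace it by distance 8
    osc, r.PerturbationSpec(magnitude=8.0, mode="exact-distance"), seed=0)
print("perturbed start fitness:", round(r.evaluate_fitness(start, r.FitnessSpec()), 3))

trace = r.run_rl_trial(start, r.RLTrialConfig(duration=2000.0), seed=1)
print("final running-average performance:", round(trace.final_perf_avg, 3))
print("converged at t =", trace.convergence_time, "s")
```

prints

```
oscillator fitness (10 s): 0.712
perturbed start fitness: 0.133
final running-average performance: 0.788
converged at t = 832.82 s
```

The evolved oscillator scores 0.712 (mean |output change| per neuron per
second over a 10 s evaluation); the perturbation knocks it down to 0.133;
the online learning trial recovers full oscillation within the 2,000 s
budget, annealing its fluctuation amplitude until the convergence detector
latches at t ≈ 833 s. Fitness and performance are rates (1/s) throughout.

The same operations are exposed on the command line:

```
rlctrnn evolve --seed 11 --outdir out/              # evolve a seed oscillator
rlctrnn run-rl out/evolved_network.json --seed 1 --outdir out/ --trace --plot
rlctrnn landscape out/evolved_network.json --outdir out/
rlctrnn distance-sweep out/evolved_network.json --seed 7 --outdir out/
rlctrnn sweep ... | rlctrnn scaling ... | rlctrnn run-hc ... | rlctrnn run-rw ...
```

Experiment outputs are CSV tables plus JSON summaries; `--trace` adds
per-step trace CSVs and `--plot` basic learning-curve/trajectory PNGs.

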