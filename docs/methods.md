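# Methods

## Model

Each of the N neurons follows the standard CTRNN state equation
τᵢẏᵢ = −yᵢ + Σⱼ wⱼᵢ σ(yⱼ + θⱼ) with logistic activation and no injected
current (the injected-current term is omitted from the implementation
surface entirely). `weights[j, i]` is the connection *from* j *to* i; the
JSON serialization uses the same row-major orientation. Integration is
explicit Euler at a fixed step, dt = 0.01 s by default. Euler is the
community default for this model family and the dynamics of interest
(relaxation-oscillator limit cycles with τ = 1 s) are far from the step's
stability limit; dt is exposed in every config for convergence checks.
Initial neuron states are zero everywhere — trials, fitness evaluations,
and baseline-search evaluations all start from the consistent zero state
unless a carry-over policy is explicitly selected. The integrator aborts
with a diagnostic if any |y| exceeds 10⁶ rather than emitting NaN traces.

## Plasticity rule

A plastic parameter fluctuates as p(t) = C + A·sin(2π(t − tₖ)/Tₖ) and is
clamped to the value bounds. A is the *half-range* of the fluctuation
(peak-to-peak = 2A); the config knob `init_flux` sets A(0). When a
fluctuation completes a cycle (crosses its center moving upward), a new
period is drawn from N(μ, ω²) and clamped to [period_min, period_max].
The period distribution is parameterized by its minimum: μ = 1.5·period_min
and ω = 0.5·period_min with period_max = 2·period_min, which places both
bounds one standard deviation from the mean; μ and ω can also be set
directly, since the minimum-period description admits more than one reading
(ω vs ω² subtracted from the mean). Draws are clamped, not rejected — the
bias at these settings is negligible and is covered by a clamped-moment
test against numerical integration.

Reward updates are forward-Euler with the same clock as the network:
C ← clamp(C + dt·α·(p − C)·R) and A ← clamp(A − dt·β·R, [0, A_max]).
The reward sign is chosen so that *improvement shrinks exploration*:
R = P − P_r (positive when the circuit currently outperforms its recent
average). An `invert_reward` flag restores the opposite convention for
comparison runs. Every plastic parameter keeps its own period and phase;
all begin a fresh period (phase 0, value = center) at trial onset, so the
initial effective network equals the configured network; one global reward
drives all updates. Value bounds default to ±16 and A_max to 16, keeping
exploration inside the studied region of weight space.

## Task, reward, fitness

Instantaneous performance is the per-neuron mean absolute output change
*per second*: P(t) = (Σⱼ|oⱼ(t) − oⱼ(t − dt)|/N)/dt. Dividing by dt makes P
a rate that is comparable across step sizes; note that absolute performance
numbers therefore scale differently from any convention that reports the
raw per-step difference. The running average P_r is a simple (unweighted)
sliding-window mean over Z seconds of simulated time (Z/dt samples);
while the buffer fills, the mean is taken over the samples present, which
avoids a spurious positive reward spike at onset. During the first 100 s
of a trial (the warm-up transient), performance is tracked but
reward-driven updates to C and A are disabled.

Offline *fitness* — used by the baseline searchers, the GA, and landscape
plots — is the mean of P over an evaluation from the zero state, either
over the whole evaluation (`include-all`, 10 s default) or counting only
output changes after a cutoff (`exclude-before-cutoff`, 300 s evaluation
with a 250 s cutoff by default). The first metric credits transient
activity and produces a broader, more navigable landscape; the second
isolates sustained oscillation.

## Learning strategies

The RL trial advances fluctuations, builds the effective network, steps the
dynamics, updates the tracker, and applies the reward to every plastic
parameter — all at each dt. Batches of trials run in lock-step as array
operations (leading axis = run); a scalar-loop reference implementation is
kept in the test suite and the two are required to agree to 1e−9.

The baselines perturb *all* walked weights each iteration by independent
Uniform(−m, m) draws, m = 8 by default. The random walker never reverts and
reports the best fitness seen; the hill climber accepts a step iff fitness
does not drop (ties accepted). Its default evaluation resets the neuron
state to zero; the `carry-over` policy instead starts each evaluation from
the end state of the previously accepted one, which makes its fitness
comparisons inconsistent and degrades the search — when comparing policies
we re-score final networks from the zero state, since carry-over's own
accepted-fitness scale (no reset transient) is not comparable. Walker
iterations map onto simulated seconds as k·(evaluation length) so all
strategies share a time axis.

## Metaparameter defaults

| knob | default | units | why |
|---|---|---|---|
| dt | 0.01 | s | stability margin for τ = 1 dynamics; exposed everywhere |
| α (learning rate) | 1.0 | 1/s | calibrated once (below) |
| β (convergence rate) | 3.0 | 1/s | calibrated once (below) |
| init_flux A(0) | 4.0 | — | half-range used in the strategy comparison |
| period_min | 2.0 | s | calibrated once; max = 4 s, μ = 3 s, ω = 1 s |
| window Z | 10.0 | s | mid-range of the regime where learning is reliable |
| warm-up | 100 | s | transient dissipation before reward flows |
| value bounds | ±16 | — | the studied weight/bias space |
| mutation m (HC/RW) | 8 | — | matched exploration rate vs init_flux 4 |

α and β are not derivable from first principles; they were fixed by a single
calibration pass on the two-neuron task from a distance-8 perturbed start
before any test was frozen, and not revisited. The total amplitude annealed
over a learning episode is ≈ β·(window lag)·ΔP ≈ β·(Z/2)·ΔP, so with
ΔP ≈ 0.6/s and Z = 10 s, β ≳ 1.5 is needed to anneal A(0) = 4 to its floor;
β = 3 does so reliably (convergence at 200–900 s depending on start
distance) while β = 6 anneals fastest but degrades final performance and
β ≤ 1 fails to converge within 2,000 s — the premature-convergence /
no-convergence trade-off the sweep suites quantify.

## Convergence detection

The reward keeps oscillating with the learned rhythm (P itself oscillates
around P_r at the circuit's frequency), so the amplitude performs a
reflected random walk just above its zero floor with excursion scale ∝ β.
A pointwise "amplitude below threshold for 100 s" criterion therefore never
latches. Convergence is instead declared when the *trailing 100 s mean* of
the mean plastic-parameter amplitude first falls below 0.25, which matches
the visual flattening of amplitude traces under the default β. For
comparisons *across* β values even this is confounded (the jitter floor
scales with β), so the sweep suite additionally reports a per-run
*amplitude halving time* — the first time a run's mean amplitude falls
below half its initial value — as the annealing-speed statistic.

## Seed networks

A two-neuron oscillator is evolved by a microbial GA (population 50,
2,000 pairwise tournaments, per-gene recombination probability 0.5,
per-gene Gaussian mutation sd 1.0, genes = 4 weights + 2 biases in ±16,
10 s include-transient fitness, τ fixed at 1.0). These GA settings are
chosen for reliability on the two-neuron task, not to match any particular
published genotype; the canonical result (seed 11) is committed as
`data/evolved_oscillator_2n.json` — 10 s fitness 0.712, sustained
post-250 s fitness 0.692 — so experiments and tests are reproducible
without re-running the GA. Perturbations displace a chosen number of
weights in gaussian, uniform, or exact-distance mode (a random direction
scaled to an exact Euclidean displacement); displacements that would be
clipped by the ±16 bounds make exact-distance mode raise rather than
silently shrink the distance. Note the committed oscillator has two weights
saturated at ±16, so some exact-distance directions are infeasible by
construction.

## Experiment suites and the sizes used

Every suite derives per-run seeds from a master seed via
`numpy.random.SeedSequence`, so outputs are byte-reproducible. The shipped
defaults are deliberately scaled down so the whole battery runs in minutes
on one CPU; the full-scale settings (e.g. the 6,561-configuration ×
10,000 s distance sweep) are expressible with the same configs and take
hours:

- strategy comparison: 30 runs per strategy from one distance-8 perturbed
  start, 2,000 s budget (200 × 10 s evaluations for HC/RW);
- distance sweep: 3 samples per weight dimension (81 starts), 2,000 s
  trials, distances binned in decades with an open 50+ bin;
- metaparameter sweeps: 10 runs per value; init_flux {0.5, 2, 4, 8},
  convergence rate {1, 3, 6}, period_min {0.5, 2, 8}, window {2, 10, 20};
  "success" = converged and final running-average performance above half
  the seed oscillator's fitness;
- landscape slices: 33 × 33 over the two self-connections at step 1,
  under both fitness metrics;
- size scaling: sizes {2, 5, 10}, 10 random starts each, 3,000 s, weights
  *and* biases plastic with identical metaparameters across sizes.

## What the generated data does and does not show

All inputs are internally generated (evolved, perturbed, or uniform-random
networks); there is no external data. Passing tests show that the learning
rule recovers and discovers oscillators across starting distances, network
sizes, and metaparameter ranges *for this task family and these bounds*.
They do not speak to sensory-driven tasks, embodied closed-loop behavior,
non-sinusoidal fluctuation waveforms, per-parameter reward signals, or
evolution of the rule's metaparameters, all of which are out of scope.

## Numerical choices and known limitations

- Performance is reported as a rate (1/s); comparisons with per-step
  conventions require multiplying by dt.
- The running-average buffer keeps an incremental sum refreshed exactly at
  every full wrap, bounding float drift over 10⁶-step trials.
- Ties in the hill climber are accepted; the random walker's best-so-far
  curve is non-decreasing by construction.
- Fluctuation phases advance by period bookkeeping, not accumulated angle,
  so a cycle boundary within a step resamples exactly once.
- With 30 seeds from the common start, the per-timepoint standard error of
  the mean weight-center trajectory is 7–16% of the trajectory range per
  weight — the mean path is coherent but individual runs diverge more than
  a "vanishing SE" idealization; independent per-parameter period draws are
  the main source of dispersion.
- Batched runs share one RNG stream: results are reproducible given (seed,
  batch composition), but a run extracted from a batch is not bit-identical
  to the same start re-run alone with the same seed.
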