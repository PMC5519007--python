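# prls-evosim

An agent-based evolutionary simulator of life-history resource allocation,
built to study when **menopause** and an extensive **post-reproductive
lifespan (PRLS)** can emerge as evolved strategies. It is aimed at
evolutionary biologists and behavioural ecologists who want to probe the
Maternal Hypothesis, the Grandmother Hypothesis, and the Embodied Capital
Model in a single controllable system.

## The model in brief

A population of asexual individuals shares a limited resource flow (20,000
units/tick). Each individual is controlled by a heritable multilayer
perceptron (14 inputs, 5 hidden units, 11 outputs, logistic activations,
141 weights) that divides its per-tick income among somatic/cognitive
growth and maintenance, survival, direct reproduction, and care for up to
five children. Physiology follows an embodied-capital model: productivity
is Cobb–Douglas in a somatic factor `K = Q_soma·q_soma` and a cognitive
factor `C = Q_cog·q_cog·β·∫ Q_cog·q_cog dt` (delayed returns on early brain
investment), squashed through a scaled sigmoid with slope γ1 and inflexion
γ2; capital quality degrades at rate δ and is repaired by maintenance;
survival per tick is a scaled sigmoid (σ1, σ2) of the resources invested in
it, with s(0) = 0. Weights mutate at 1/141 per weight per birth (10%
uniform redraws on [−10, 10], 90% N(0, 0.01) jitter). Five ecological
parameters (α, β, γ2, δ, σ2) define the niche; the shipped default is EP*
(α = 0.91, β = 0.47, γ2 = 157, δ = 0.87, σ2 = 27), the combination that
maximizes evolved PRLS. PRLS is measured as mean(death − last reproduction)
over individuals born and dead within the final 2,000 ticks.

See `docs/methods.md` for the full model description, parameter table,
design choices, and known limitations (including an honest account of the
evolved equilibrium this implementation reaches under EP*).

## Worked example

```python
from prls_evosim import SimConfig, run, measure_prls

cfg = SimConfig(initial_population=200, duration=2000, seed=42)  # EP* ecology
history = run(cfg)
prls = measure_prls(history, window=500)
print(f"population at end: {history.pop_size[-1]}")
print(f"individuals ever born: {len(history.records['birth'])}")
print(f"mean PRLS (final 500-tick cohort): {prls.mean:.2f} "
      f"(sd {prls.sd:.2f}, n={prls.n})")
```

prints

```
population at end: 130
individuals ever born: 105564
mean PRLS (final 500-tick cohort): 1.00 (sd 0.05, n=6112)
```

Reading: under EP* the resource pool sustains a standing population of
~130; over 2,000 ticks about 10⁵ individuals are born; and the evolved
population here reproduces up to the tick before death (PRLS ≈ 1), i.e.
this run has *not* evolved menopause — see the methods note for why that
equilibrium arises and what would be expected instead.

## Experiments

Each experiment is a library function (`prls_evosim.experiments`) and a CLI
subcommand emitting tidy CSV/JSON plus a reproducibility manifest:

```bash
prls-evosim sweep    --config configs/epstar.yaml --seed 1 --out results/sweep
prls-evosim maximize --config configs/epstar.yaml --seed 1 --out results/ga
prls-evosim variant  --config configs/epstar.yaml --seed 1 --variant no_grandmothering --out results/v
prls-evosim describe --config configs/epstar.yaml --seed 1 --weights results/ga/best_weights.json --out results/d
prls-evosim cost     --config configs/epstar.yaml --seed 1 --condition 1 --weights results/ga/best_weights.json --out results/c1
```

* `sweep` — random draws of the five ecological parameters, one
  evolutionary run each, PRLS per draw.
* `maximize` — real-coded elitist GA over the parameter space; fitness is
  the evolved PRLS of a fresh run; emits the optimum and the evolved modal
  strategy.
* `variant` — ablations: `no_grandmothering` (care to already-reproduced
  children removed), `no_delayed_cognition` (no skill integral),
  `sibling_transfers` (extended 171-weight network).
* `describe` — homogeneous mutation-free run of a fixed strategy with
  per-age life-history traces.
* `cost` — heritable-condition analysis in populations with a fixed
  strategy: forced death (condition 1) or one forced extra birth
  (condition 2) at the age of menopause, lineages tracked over ten
  generations with exact binomial and Welch t-tests.

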