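# Methods

## The model

`prls-evosim` simulates the evolution of life-history allocation decisions
in a one-sex, asexual population of individuals controlled by heritable
artificial neural networks. The scientific question it addresses is under
which ecological conditions *menopause* — the permanent cessation of direct
reproduction well before death — and an extensive *post-reproductive
lifespan* (PRLS) can emerge as evolved allocation strategies rather than
hard-coded constraints, discriminating among the Maternal Hypothesis,
the Grandmother Hypothesis, and the Embodied Capital Model.

### State

Each individual carries two embodied capitals, somatic and cognitive, each
with quantity `Q` and non-degraded part `Qf` (quality `q = Qf/Q ∈ [0,1]`,
0 when `Q = 0`), plus a running *skill integral* — the sum over its life of
`Q_cog · q_cog` — representing the accumulated returns of past cognitive
investment.

### Production

The somatic factor is `K = Q_soma · q_soma`; the cognitive factor is
`C = Q_cog · q_cog · β · skill_integral` in the full model (the *delayed
benefits* of early cognitive investment) or `C = Q_cog · q_cog` under the
delayed-cognition ablation. Productivity combines the factors through a
Cobb–Douglas function with skill intensiveness `α`:

    P = K^(1−α) · C^α,   with P = 0 whenever K = 0 or C = 0.

A zero factor cannot be compensated by the other. The variant form
`K^(α−1) · C^α` (which makes productivity decrease in somatic capital, at
odds with the meaning of α as a relative-importance weight) is available
via `cobb_douglas_exponent = "as_printed"`; the default is the standard
constant-returns form. `P` is then squashed through a scaled logistic

    f(x) = (expit(s·(x−m)) − expit(−s·m)) · (1 + e^(−s·m))

with slope `γ1` and inflexion `γ2`, which is exactly 0 at 0 and tends to 1,
giving the scaled productivity `P′`. Each tick a pool of 20,000 resource
units is divided among individuals proportionally to `P′` (nothing flows
when every `P′` is 0).

### Capital dynamics

Per tick, with growth `g` and maintenance `m` investments and degradation
rate `δ` (shared by both capitals):

    Q'  = Q + g
    Qf' = clamp(Qf + g − Q'·δ + m, 0, Q')

New tissue is pristine (a completion choice: the depletion rule alone
does not say how grown tissue enters the quality ledger). The skill integral advances once per tick with the
post-update `Q_cog · q_cog`; production at tick *t* therefore uses the
integral through *t−1*.

### Survival

The probability of surviving a tick is the same scaled sigmoid applied to
the resources `I_s` invested in survival, with slope `σ1` and inflexion
`σ2`: `s(0) = 0` (an individual with no income dies with certainty) and
`s < 1` always. Mortality is purely a consequence of allocation; there is
no extrinsic hazard.

### The controller

Allocation decisions come from a fully connected perceptron: 14 inputs
(own `Q_soma, q_soma, Q_cog, q_cog`; five child-presence flags; five child
productivities each divided by that child's number of living children + 1 —
the grandchild signal), one hidden layer of 5 logistic units, and 11
logistic outputs normalized to sum to 1: somatic growth, somatic
maintenance, cognitive growth, cognitive maintenance, survival, direct
reproduction, and care for each of the five child slots. Both layers have
a bias unit — only then does the architecture arithmetic give the canonical
141 weights ((14+1)·5 + (5+1)·11). Initial weights are i.i.d. uniform on
[−10, 10]. Offspring inherit weights with per-weight mutation probability
1/141: a mutating weight is redrawn uniformly on [−10, 10] with probability
0.1 ("strong") or jittered with N(0, 0.01) noise ("weak", unclipped —
only initial draws and strong mutations are bounded).

### The tick

All perceptions are taken from the start-of-tick state (synchronous
update). Individuals are then processed in ascending generation depth, so
a mother's realized income — and whether she dies this tick — is known
before her children receive transfers: an individual who dies transfers
nothing that tick. Within an individual's turn: income (environmental
share + maternal transfers + any pending endowment) is split by the
normalized network outputs; growth and capital dynamics apply; survival is
drawn; survivors with more than `birth_threshold` resources allocated to
direct reproduction and a free child slot give birth (newborns occupy the
lowest free slot, receive exactly the reproduction allocation, perceive
all-zero inputs, and cannot themselves reproduce in their birth tick);
care is routed per slot to children born before this tick. Fractions
allocated to empty or just-filled slots are forfeited — the cost of a
poorly tuned strategy. Founders are age-0 newborns at tick 0 with a
200-unit endowment allocated through their own network.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| α | skill intensiveness | 0.91 | EP* |
| β | rate of skills acquisition | 0.47 | EP* |
| γ2 | productivity-sigmoid inflexion ("difficulty") | 157 | EP* |
| δ | capital degradation rate | 0.87 | EP* |
| σ2 | survival-sigmoid inflexion ("dangerousness") | 27 | EP* |
| γ1, σ1 | sigmoid slopes | 0.1 | free parameters of this implementation; of order 1/inflexion so the sigmoids stay non-degenerate over the [0, 200] inflexion range; every result reports the values used |
| pool | resource flow per tick | 20,000 | sets carrying capacity |
| n₀, T | founders, duration | 1,000 / 10,000 | study conditions |
| endowment | founders' tick-0 resources | 200 | |
| ε_birth | min. reproduction spend for a birth | 1.0 | see below |

The default ecology *is* the EP* preset — the parameter combination that
maximizes evolved PRLS (`configs/epstar.yaml`).

**Birth threshold.** Logistic outputs are strictly positive, so a literal
"any positive allocation triggers a birth" rule would make every individual
with income and a free slot give birth every single tick, pinning
last-reproduction to the tick before death and PRLS to ≈0 by construction —
incompatible with the life histories this model is meant to admit (few,
well-spaced births under EP*). We therefore require at least one resource unit behind a birth; under
EP* a child endowed with less than one unit has a <1% chance of surviving
its first tick, so the threshold only gates structurally hopeless births.
It is configurable (`birth_threshold`).

## Experiments

* **Parameter sweep** (`experiments.parameter_sweep`): α, β, δ ~ U[0,1],
  γ2, σ2 ~ U[0,200], one evolutionary run per draw (100 by default), mean
  PRLS of the cohort born and dead in the final 2,000 ticks. Extinct
  replicates are flagged, not silently dropped.
* **PRLS maximization** (`experiments.maximize_prls`): a real-coded
  elitist GA over the five parameters (rank-proportional selection, uniform
  per-gene crossover, 0.1 random-reset mutation; 40 candidates × 30
  generations by default — the search hyper-parameters are ours). Fitness
  of a candidate is the evolved PRLS of a fresh run; the evolved "best
  weights" are the modal strategy of the best run's final population.
* **Strategy description** (`experiments.describe_strategy`): homogeneous,
  mutation-free population with fixed weights; per-age traces of capitals,
  qualities, allocations and reproductive events.
* **Ablations** (`experiments.run_variant`): `no_grandmothering` zeroes the
  care outputs aimed at children who have already reproduced (zeroed before
  normalization, so the remaining outputs are renormalized — the option is
  removed without imposing a dead-weight loss); `no_delayed_cognition`
  drops the integral term and β from the cognitive factor;
  `sibling_transfers` appends five outputs transferring to siblings (171
  weights; transfers land in the recipient's next-tick income to avoid
  within-generation circularity; orphans neither send nor receive).
* **Cost analysis** (`experiments.cost_analysis`): homogeneous mutation-free
  populations; at the apply tick every living individual is tagged
  generation 0 and a seeded random half receives a heritable condition.
  Condition 1 forces death at the menopause age (estimated, unless given,
  as the rounded mean age at last reproduction over completed burn-in
  lives); condition 2 forces one additional reproductive event at that age
  by diverting the same absolute amount as the previous birth, scaling the
  other allocations down proportionally; condition 3 is a sham tag used as
  a type-I control. Descendants inherit the tag with the generation
  incremented. Frequencies are tested against 0.5 with exact two-sided
  binomial tests on pooled counts; survival-to-reproduction, fertility and
  lifespan contrasts use two-sided Welch t-tests across population means
  (the R default behind the source's t-test).

Reproducibility: each stochastic component (strategy initialization,
mutation, survival, condition assignment) draws from its own named RNG
stream derived from the master seed, so matched-seed ablation contrasts
share founders and survival draws; every run is bit-reproducible from its
manifest.

## What the simulations do and do not show

The generator *is* the study system here — there is no external data. The
test suite exercises the machinery at the stated scales plus small
deterministic micro-scenarios; passing tests certify the mechanics
(conservation, transfer ordering, ablation semantics, statistics), not that
any particular strategy is optimal for real organisms.

**Known limitation — the evolved equilibrium.** Under EP* with this
implementation, evolution from random strategies settles into a
"birth-spam" equilibrium: adults give birth to cheap children nearly every
tick, most of whom die young, and measured PRLS is ≈1 time unit instead of
the reference value of ≈22 for this parameterization. Menopausal strategies are representable (normalized
logistic outputs can be driven far below any positive birth threshold, and
reproduction can be conditioned on child presence), but selection does not
reach them: a viable child needs on the order of σ2 resources per tick of
sustained maternal care for the ~15+ ticks it takes to become productive,
and starting from the spam equilibrium there is no fitness gradient into
such coordinated care — a fitness valley. This persists across seeds,
birth thresholds (1–50), slope settings (γ1, σ1 ∈ 0.1–2), and an
alternative output-layer reading in which allocations can be exactly zero
(that variant tends to immediate extinction, as half of random founders
allocate nothing to survival). Because the sigmoid slopes and search
settings are free parameters, we report the computed quantities as they
are rather than calibrating them toward the reference values; the ablation and
cost-analysis pipelines remain fully functional and are exercised with the
strategies that do evolve.

## Numerical choices

* Logistic functions via `scipy.special.expit`; the scaled sigmoid is
  computed in the overflow-safe form given above and is exactly 0 at 0.
* `0^0`-type corners of the Cobb–Douglas: any zero factor ⇒ P = 0.
* Quality clamps: `Qf ∈ [0, Q]` after every update.
* Survival probabilities are clipped to [0, 1]; death occurs when the
  uniform draw is ≥ s, so s = 0 kills with certainty.
* Child slots: lowest-index free slot, never compacted; a freed slot is
  reusable the next tick.
* Population state is stored as columns of NumPy arrays with recycled
  rows; environmental shares, care and pending income are consumed on
  read so a recycled row can never inherit the previous occupant's income.
* Problem sizes in the test suite: the emergence check runs the full
  1,000 × 10,000 study; the ablation contrast uses 200 × 2,000 with 10
  matched seeds and the cost analysis 10 populations of 200 over 4,000
  ticks — scales at which each pipeline's qualitative behaviour is stable
  across seeds.
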