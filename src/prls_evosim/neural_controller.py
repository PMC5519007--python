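"""The heritable allocation policy: a fully connected multilayer perceptron.

Each individual carries a flat vector of synaptic weights encoding a
14-input / 5-hidden / 11-output perceptron with logistic activations at both
layers and one bias unit per layer:

* input -> hidden block: (14 inputs + 1 bias) x 5 hidden = 75 weights,
* hidden -> output block: (5 hidden + 1 bias) x 11 outputs = 66 weights,

for 141 weights in total.  The sibling-transfer model variant appends 5 more
outputs (16 outputs, 171 weights).

The 14 inputs (the :class:`Perception`) are the individual's own somatic and
cognitive capital quantities and qualities (inputs 1-4), one presence flag
per child slot (5-9), and each child's scaled productivity divided by the
child's own number of children plus one (10-14) — the grandchild signal.

The 11 outputs are allocation fractions for: somatic growth, somatic
maintenance, cognitive growth, cognitive maintenance, survival, direct
reproduction, and care for each of the five child slots.  Raw logistic
outputs are divided by their sum so the fractions total exactly 1.

Weights are inherited with per-weight mutation probability 1/n_weights;
a mutating weight is redrawn uniformly on [-10, 10] with probability 0.1
("strong") or perturbed by N(0, 0.01) noise with probability 0.9 ("weak").
Weak mutations are not clipped: only initial draws and strong mutations are
bounded by [-10, 10].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

N_INPUTS = 14
N_HIDDEN = 5
N_OUTPUTS = 11
N_OUTPUTS_SIBLING = 16

WEIGHT_LOW, WEIGHT_HIGH = -10.0, 10.0
P_STRONG = 0.1          # probability a mutation is a uniform redraw
WEAK_SD = 0.01          # s.d. of the weak (Gaussian) mutation

# Output indices, fixed ordering (ordering version 1).
OUT_SOMA_GROWTH = 0
OUT_SOMA_MAINT = 1
OUT_COG_GROWTH = 2
OUT_COG_MAINT = 3
OUT_SURVIVAL = 4
OUT_REPRO = 5
OUT_CARE = slice(6, 11)        # care for child slots 0..4
OUT_SIBLING = slice(11, 16)    # sibling-transfer outputs (variant only)

ORDERING_VERSION = 1


def n_weights(n_outputs: int = N_OUTPUTS) -> int:
    """Total weight count: (14+1)*5 input block + (5+1)*n_outputs output block."""
    return (N_INPUTS + 1) * N_HIDDEN + (N_HIDDEN + 1) * n_outputs


#: Weight count of the base (11-output) architecture.
N_WEIGHTS = n_weights()           # 141
N_WEIGHTS_SIBLING = n_weights(N_OUTPUTS_SIBLING)  # 171

_IN_BLOCK = (N_INPUTS + 1) * N_HIDDEN  # 75


def n_outputs_of(weights: np.ndarray) -> int:
    """Infer the output count from a weight vector's length."""
    rem = len(weights) - _IN_BLOCK
    if rem <= 0 or rem % (N_HIDDEN + 1):
        raise ValueError(f"weight vector of length {len(weights)} does not match "
                         f"the {N_INPUTS}-{N_HIDDEN}-K architecture")
    return rem // (N_HIDDEN + 1)


@dataclass
class Perception:
    """The 14 sensory inputs of one individual at one tick."""

    soma_qty: float = 0.0
    soma_qual: float = 0.0
    cog_qty: float = 0.0
    cog_qual: float = 0.0
    child_present: Sequence[float] = field(default_factory=lambda: [0.0] * 5)
    child_prod_corrected: Sequence[float] = field(default_factory=lambda: [0.0] * 5)

    def to_array(self) -> np.ndarray:
        x = np.empty(N_INPUTS)
        x[0], x[1], x[2], x[3] = (
            self.soma_qty, self.soma_qual, self.cog_qty, self.cog_qual)
        x[4:9] = self.child_present
        x[9:14] = self.child_prod_corrected
        return x


def init_strategy(rng: np.random.Generator, n_outputs: int = N_OUTPUTS) -> np.ndarray:
    """Draw a fresh strategy: i.i.d. uniform weights on [-10, 10]."""
    return rng.uniform(WEIGHT_LOW, WEIGHT_HIGH, size=n_weights(n_outputs))


def init_strategies(rng: np.random.Generator, n: int,
                    n_outputs: int = N_OUTPUTS) -> np.ndarray:
    """Draw ``n`` independent strategies as an (n, n_weights) matrix."""
    return rng.uniform(WEIGHT_LOW, WEIGHT_HIGH, size=(n, n_weights(n_outputs)))


def split_weights(weights: np.ndarray) -> tuple:
    """Split a flat weight vector into (W1, W2).

    W1 has shape (15, 5): rows are the 14 inputs then the input-layer bias;
    W2 has shape (6, K): rows are the 5 hidden units then the hidden-layer
    bias; columns index hidden units / outputs respectively.
    """
    weights = np.asarray(weights, dtype=float)
    K = n_outputs_of(weights)
    W1 = weights[:_IN_BLOCK].reshape(N_INPUTS + 1, N_HIDDEN)
    W2 = weights[_IN_BLOCK:].reshape(N_HIDDEN + 1, K)
    return W1, W2


def decide(weights: np.ndarray, perception) -> np.ndarray:
    """Forward pass: perception -> normalized allocation fractions.

    Pure and deterministic.  Raises ValueError on non-finite perception
    (a corrupted state upstream).
    """
    if isinstance(perception, Perception):
        x = perception.to_array()
    else:
        x = np.asarray(perception, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite perception: corrupted individual state")
    W1, W2 = split_weights(weights)
    h = expit(x @ W1[:-1] + W1[-1])
    raw = expit(h @ W2[:-1] + W2[-1])
    return raw / raw.sum()


def decide_batch(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass for per-individual weights.

    ``weights``: (n, n_weights) — one strategy per row; ``X``: (n, 14)
    perceptions.  Returns (n, K) allocation fractions, each row summing to 1.
    """
    weights = np.asarray(weights, dtype=float)
    X = np.asarray(X, dtype=float)
    n = weights.shape[0]
    K = n_outputs_of(weights[0]) if n else N_OUTPUTS
    W1 = weights[:, :_IN_BLOCK].reshape(n, N_INPUTS + 1, N_HIDDEN)
    W2 = weights[:, _IN_BLOCK:].reshape(n, N_HIDDEN + 1, K)
    h = expit(np.einsum("ni,nij->nj", X, W1[:, :-1]) + W1[:, -1])
    raw = expit(np.einsum("ni,nij->nj", h, W2[:, :-1]) + W2[:, -1])
    return raw / raw.sum(axis=1, keepdims=True)


def mutate(parent: np.ndarray, rng: np.random.Generator,
           mutation_prob: Optional[float] = None) -> np.ndarray:
    """Return a mutated copy of ``parent``.

    Each weight mutates independently with probability 1/n_weights (or the
    supplied ``mutation_prob``).  A mutating weight is redrawn uniformly on
    [-10, 10] with probability 0.1, else jittered by N(0, 0.01) noise.
    """
    return mutate_batch(parent[None, :], rng, mutation_prob)[0]


def mutate_batch(parents: np.ndarray, rng: np.random.Generator,
                 mutation_prob: Optional[float] = None) -> np.ndarray:
    """Vectorized :func:`mutate` over an (n, n_weights) matrix of parents."""
    parents = np.asarray(parents, dtype=float)
    n, L = parents.shape
    p = (1.0 / L) if mutation_prob is None else mutation_prob
    child = parents.copy()
    if p <= 0.0 or n == 0:
        return child
    mut = rng.random((n, L)) < p
    strong = rng.random((n, L)) < P_STRONG
    uni = rng.uniform(WEIGHT_LOW, WEIGHT_HIGH, size=(n, L))
    weak = child + rng.normal(0.0, WEAK_SD, size=(n, L))
    child = np.where(mut & strong, uni, np.where(mut & ~strong, weak, child))
    return child


def strategy_to_json(weights: np.ndarray) -> str:
    """Serialize a strategy with its block partition and ordering version."""
    weights = np.asarray(weights, dtype=float)
    K = n_outputs_of(weights)
    return json.dumps({
        "ordering_version": ORDERING_VERSION,
        "n_inputs": N_INPUTS,
        "n_hidden": N_HIDDEN,
        "n_outputs": K,
        "partition": [_IN_BLOCK, len(weights) - _IN_BLOCK],
        "weights": weights.tolist(),
    })


def strategy_from_json(text: str) -> np.ndarray:
    d = json.loads(text)
    w = np.asarray(d["weights"], dtype=float)
    if len(w) != sum(d["partition"]):
        raise ValueError("strategy partition does not match weight count")
    n_outputs_of(w)  # validates length
    return w


def strategy_to_csv(weights: np.ndarray) -> str:
    """One weight per line, with a header comment recording the block
    partition and ordering version."""
    weights = np.asarray(weights, dtype=float)
    K = n_outputs_of(weights)
    header = (f"# ordering_version={ORDERING_VERSION} "
              f"partition={_IN_BLOCK}+{len(weights) - _IN_BLOCK} "
              f"architecture={N_INPUTS}-{N_HIDDEN}-{K}\n")
    return header + "weight\n" + "\n".join(repr(float(w)) for w in weights) + "\n"


def strategy_from_csv(text: str) -> np.ndarray:
    lines = [ln for ln in text.splitlines()
             if ln and not ln.startswith("#") and ln != "weight"]
    w = np.array([float(ln) for ln in lines])
    n_outputs_of(w)  # validates length
    return w
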