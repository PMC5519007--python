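"""Embodied-capital physiology: production, capital dynamics and survival.

An individual is described by two *embodied capitals* — somatic (muscles,
digestive organs, ...) and cognitive (brain tissue) — each with a quantity
``Q`` and a quality ``q = Qf/Q`` in [0, 1], where ``Qf`` is the non-degraded
part of the capital.  Productivity, the ability to extract resources from a
shared environmental pool, combines a somatic factor ``K`` and a cognitive
factor ``C`` through a Cobb–Douglas production function whose exponent
``alpha`` ("skill intensiveness of the foraging niche") sets the relative
importance of skills over strength.  The cognitive factor carries *delayed
benefits*: it is multiplied by the running integral of past cognitive state,
so early investment in brain tissue pays off later — the core assumption of
the Embodied Capital Model.

Raw productivity and the resources allocated to survival are both squashed
through a scaled logistic sigmoid that is exactly 0 at 0 and tends to 1 at
infinity, modelling the age profile of foraging efficiency and the
diminishing returns of survival investment respectively.

All functions accept scalars or NumPy arrays and broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
from scipy.special import expit

ArrayLike = Union[float, np.ndarray]


class ConfigError(ValueError):
    """A configuration value is outside its documented domain."""


class StateError(RuntimeError):
    """An individual's physiological state is corrupted (e.g. negative capital)."""


@dataclass
class EcologicalParams:
    """The ecological niche: five evolvable parameters plus sigmoid slopes.

    Parameters
    ----------
    alpha : float in [0, 1]
        Skill intensiveness of the foraging niche — Cobb–Douglas weight of the
        cognitive factor in productivity.
    beta : float in [0, 1]
        Rate of skills acquisition, scaling the delayed-benefit integral of
        the cognitive factor.
    gamma1 : float > 0
        Slope of the productivity sigmoid at its inflexion point.
    gamma2 : float in [0, 200]
        Abscissa of the productivity-sigmoid inflexion — difficulty of
        acquiring resources in the environment.
    delta : float in (0, 1)
        Per-tick degradation rate of capital quality, shared by the somatic
        and cognitive capitals.
    sigma1 : float > 0
        Slope of the survival sigmoid at its inflexion point.
    sigma2 : float in [0, 200]
        Abscissa of the survival-sigmoid inflexion — dangerousness of the
        environment.
    resource_pool : float > 0
        Units of resources flowing into the environment per tick, divided
        among individuals proportionally to their (scaled) productivity.
    cobb_douglas_exponent : {"standard", "as_printed"}
        "standard" uses P = K**(1-alpha) * C**alpha (constant-returns
        Cobb–Douglas, the default); "as_printed" uses K**(alpha-1) * C**alpha.

    The default values are the EP* preset: the parameter combination under
    which menopause and the longest post-reproductive lifespan evolve.
    """

    alpha: float = 0.91
    beta: float = 0.47
    gamma1: float = 0.1
    gamma2: float = 157.0
    delta: float = 0.87
    sigma1: float = 0.1
    sigma2: float = 27.0
    resource_pool: float = 20_000.0
    cobb_douglas_exponent: str = "standard"

    def validate(self) -> "EcologicalParams":
        """Raise :class:`ConfigError` naming the offending field if any value
        is outside its documented domain; return self otherwise."""
        checks = [
            ("ecological.alpha", 0.0 <= self.alpha <= 1.0, "must be in [0, 1]"),
            ("ecological.beta", 0.0 <= self.beta <= 1.0, "must be in [0, 1]"),
            ("ecological.gamma1", self.gamma1 > 0.0, "must be > 0"),
            ("ecological.gamma2", 0.0 <= self.gamma2 <= 200.0, "must be in [0, 200]"),
            ("ecological.delta", 0.0 < self.delta < 1.0, "must be in (0, 1)"),
            ("ecological.sigma1", self.sigma1 > 0.0, "must be > 0"),
            ("ecological.sigma2", 0.0 <= self.sigma2 <= 200.0, "must be in [0, 200]"),
            ("ecological.resource_pool", self.resource_pool >= 0.0, "must be >= 0"),
            (
                "ecological.cobb_douglas_exponent",
                self.cobb_douglas_exponent in ("standard", "as_printed"),
                'must be "standard" or "as_printed"',
            ),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigError(f"{name} {msg} (got {getattr(self, name.split('.')[1])!r})")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EcologicalParams":
        return cls(**d).validate()


#: The ecological parameter combination maximizing evolved post-reproductive
#: lifespan (alpha=0.91, beta=0.47, gamma2=157, delta=0.87, sigma2=27).
EP_STAR = EcologicalParams()


@dataclass
class CapitalState:
    """Scalar capital state of one individual (convenience container for
    single-agent computations and test fixtures; the population engine keeps
    these as columns of arrays)."""

    Q_soma: float = 0.0
    Qf_soma: float = 0.0
    Q_cog: float = 0.0
    Qf_cog: float = 0.0
    skill_integral: float = 0.0

    @property
    def q_soma(self) -> float:
        return quality(self.Q_soma, self.Qf_soma)

    @property
    def q_cog(self) -> float:
        return quality(self.Q_cog, self.Qf_cog)


def quality(Q: ArrayLike, Qf: ArrayLike) -> ArrayLike:
    """Capital quality q = Qf / Q, defined as 0 where Q == 0."""
    Q = np.asarray(Q, dtype=float)
    Qf = np.asarray(Qf, dtype=float)
    out = np.divide(Qf, Q, out=np.zeros_like(Qf, dtype=float), where=Q > 0)
    return out if out.ndim else float(out)


def somatic_factor(c: CapitalState) -> float:
    """Somatic production factor K = Q_soma * q_soma = Qf_soma."""
    if c.Q_soma < 0 or c.Qf_soma < 0:
        raise StateError(f"negative somatic capital: Q={c.Q_soma}, Qf={c.Qf_soma}")
    if c.Q_soma == 0:
        return 0.0
    return c.Q_soma * (c.Qf_soma / c.Q_soma)


def cognitive_factor(
    c: CapitalState, beta: float, delayed_benefits: bool = True
) -> float:
    """Cognitive production factor.

    With delayed benefits (full model): C = Q_cog * q_cog * beta * skill_integral,
    where skill_integral is the running sum of past Q_cog * q_cog.  With the
    ablation (cognitive resources undifferentiated from somatic ones):
    C = Q_cog * q_cog.
    """
    present = c.Q_cog * c.q_cog
    if delayed_benefits:
        return present * beta * c.skill_integral
    return present


def raw_productivity(
    K: ArrayLike, C: ArrayLike, alpha: float, exponent: str = "standard"
) -> ArrayLike:
    """Cobb–Douglas productivity of the somatic and cognitive factors.

    P = K**(1-alpha) * C**alpha ("standard", default) or
    P = K**(alpha-1) * C**alpha ("as_printed").  A zero factor forces P = 0:
    total compensation of one capital by the other is impossible.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"ecological.alpha must be in [0, 1] (got {alpha!r})")
    if exponent not in ("standard", "as_printed"):
        raise ConfigError(f"unknown cobb_douglas_exponent {exponent!r}")
    K = np.asarray(K, dtype=float)
    C = np.asarray(C, dtype=float)
    k_exp = (1.0 - alpha) if exponent == "standard" else (alpha - 1.0)
    pos = (K > 0) & (C > 0)
    # Evaluate on safe operands only; any zero factor forces P = 0.
    Ksafe = np.where(pos, K, 1.0)
    Csafe = np.where(pos, C, 1.0)
    P = np.where(pos, Ksafe**k_exp * Csafe**alpha, 0.0)
    return P if P.ndim else float(P)


def scaled_sigmoid(x: ArrayLike, slope: float, inflexion: float) -> ArrayLike:
    """Logistic sigmoid rescaled so f(0) = 0 exactly and f(x) -> 1 as x -> inf.

    f(x) = (1/(1+exp(slope*(inflexion-x))) - 1/(1+exp(slope*inflexion)))
           * (1+exp(slope*inflexion)) / exp(slope*inflexion)

    computed stably as (expit(slope*(x-inflexion)) - expit(-slope*inflexion))
    * (1 + exp(-slope*inflexion)).  Strictly increasing on x >= 0.
    """
    if slope <= 0:
        raise ConfigError(f"sigmoid slope must be > 0 (got {slope!r})")
    x = np.asarray(x, dtype=float)
    a, b = float(slope), float(inflexion)
    out = (expit(a * (x - b)) - expit(-a * b)) * (1.0 + np.exp(-a * b))
    return out if out.ndim else float(out)


def survival_prob(I_s: ArrayLike, sigma1: float, sigma2: float) -> ArrayLike:
    """Per-tick survival probability from resources invested in survival.

    s = scaled_sigmoid(I_s, sigma1, sigma2); s = 0 at I_s = 0, s < 1 always.
    """
    return np.clip(scaled_sigmoid(I_s, sigma1, sigma2), 0.0, 1.0)


def update_capital(
    Q: ArrayLike,
    Qf: ArrayLike,
    growth: ArrayLike,
    maintenance: ArrayLike,
    delta: float,
) -> tuple:
    """One tick of capital dynamics: growth, degradation and repair.

    New tissue is pristine (added to both Q and Qf); the non-degraded part
    then loses Q'*delta and gains the maintenance investment, clamped to
    [0, Q'] so quality stays in [0, 1]:

        Q'  = Q + growth
        Qf' = clamp(Qf + growth - Q'*delta + maintenance, 0, Q')
    """
    Q = np.asarray(Q, dtype=float)
    Qf = np.asarray(Qf, dtype=float)
    Qn = Q + growth
    Qfn = np.clip(Qf + growth - Qn * delta + maintenance, 0.0, Qn)
    if Qn.ndim:
        return Qn, Qfn
    return float(Qn), float(Qfn)
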