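"""The four computational experiments and their statistics.

* :func:`parameter_sweep` — random draws of the five ecological parameters,
  one evolutionary run each, PRLS of the final cohort (the correlation
  screen).
* :func:`maximize_prls` — a real-coded genetic algorithm over the ecological
  parameter space whose fitness is the evolved PRLS of a fresh run; yields
  the optimum EP* and the associated evolved ("best") synaptic weights.
* :func:`describe_strategy` — a homogeneous, mutation-free population with a
  fixed strategy, traced age-by-age.
* :func:`run_variant` — the model ablations: no grand-mothering, no delayed
  cognitive benefits, sibling transfers.
* :func:`cost_analysis` — heritable-condition experiment in populations
  where menopause has already evolved: condition 1 forces death at the age
  of menopause, condition 2 forces one additional reproductive event there;
  lineages are tracked for ten generations and compared to controls with
  exact binomial and Welch t-tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import population_engine as pe
from .physiology import ConfigError, EcologicalParams
from .population_engine import (
    PopulationHistory,
    PRLSResult,
    SimConfig,
    measure_prls,
)

#: Ecological-parameter bounds of the search space: alpha, beta, delta on
#: [0, 1]; gamma2, sigma2 on [0, 200].
SWEEP_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 1.0),
    "gamma2": (0.0, 200.0),
    "delta": (0.0, 1.0),
    "sigma2": (0.0, 200.0),
}
_PARAM_ORDER = ("alpha", "beta", "gamma2", "delta", "sigma2")

VARIANTS = {
    "full": {},
    "no_grandmothering": {"grandmothering_enabled": False},
    "no_delayed_cognition": {"delayed_benefits_enabled": False},
    "sibling_transfers": {"sibling_transfers_enabled": True},
}


def derive_seed(master: int, *keys) -> int:
    """Stable sub-seed (< 2^31) from a master seed and arbitrary keys."""
    text = ":".join([str(master), *map(str, keys)])
    return zlib.crc32(text.encode("utf8")) & 0x7FFFFFFF


def _with_params(config: SimConfig, values: dict, seed: int, **overrides) -> SimConfig:
    eco = dc_replace(config.ecological, **values)
    return dc_replace(config, ecological=eco, seed=seed, **overrides)


# -- statistics --------------------------------------------------------------

def binomial_frequency_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for k successes in n trials."""
    if n < 1:
        raise ValueError("binomial test requires n >= 1")
    return float(stats.binomtest(int(k), int(n), p0).pvalue)


def two_sample_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Welch two-sample t-test p-value (NaN if degenerate)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("t-test requires non-empty groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


# -- 1. parameter sweep ------------------------------------------------------

def parameter_sweep(n_reps: int = 100,
                    base_config: Optional[SimConfig] = None,
                    seed: int = 0,
                    bounds: Optional[dict] = None) -> pd.DataFrame:
    """Draw random ecological parameters ``n_reps`` times and evolve one
    population per draw.

    Returns one row per replicate: the five parameters, the simulation seed,
    the final-cohort mean PRLS (NaN where undefined) and a population-
    collapse flag.
    """
    base = base_config or SimConfig()
    bounds = bounds or SWEEP_BOUNDS
    rng = np.random.Generator(np.random.PCG64(derive_seed(seed, "sweep_params")))
    rows = []
    for i in range(n_reps):
        values = {k: rng.uniform(*bounds[k]) for k in _PARAM_ORDER}
        sim_seed = derive_seed(seed, "sweep_rep", i)
        cfg = _with_params(base, values, sim_seed)
        history = pe.run(cfg)
        prls = measure_prls(history)
        rows.append({**values, "seed": sim_seed, "mean_prls": prls.mean,
                     "sd_prls": prls.sd, "n": prls.n,
                     "collapsed": bool(history.extinct or prls.undefined)})
    return pd.DataFrame(rows)


# -- 2. PRLS maximization (genetic algorithm) --------------------------------

@dataclass
class MaximizationResult:
    best_params: EcologicalParams
    best_weights: np.ndarray
    best_weights_share: float
    mean_prls: float
    n: int
    trajectory: pd.DataFrame        # per GA generation
    evaluations: pd.DataFrame       # every (candidate, fitness) evaluated


def _fitness(values: dict, base: SimConfig, sim_seed: int) -> tuple:
    cfg = _with_params(base, values, sim_seed)
    history = pe.run(cfg)
    prls = measure_prls(history)
    fit = 0.0 if prls.undefined else prls.mean
    return fit, prls, history


def maximize_prls(base_config: Optional[SimConfig] = None,
                  ga_pop: int = 40,
                  ga_gens: int = 30,
                  elitism: int = 2,
                  mutation_chance: float = 0.1,
                  seed: int = 0,
                  bounds: Optional[dict] = None,
                  initial_candidates: Optional[np.ndarray] = None,
                  fitness_fn=None) -> MaximizationResult:
    """Real-coded genetic algorithm over (alpha, beta, gamma2, delta, sigma2).

    A candidate's fitness is the mean final-cohort PRLS of a fresh
    evolutionary run under those parameters (0 where undefined).  Elitist:
    the ``elitism`` best candidates survive unchanged, so the best recorded
    fitness is non-decreasing.  Offspring take each gene from either parent
    uniformly; each gene is redrawn uniformly within bounds with probability
    ``mutation_chance``.

    ``fitness_fn(values: dict, seed: int) -> float`` replaces the
    simulation-based objective when supplied (used to exercise the search
    itself on cheap deterministic surrogates); in that case no evolved
    weights exist and ``best_weights`` is None.
    """
    base = base_config or SimConfig()
    bounds = bounds or SWEEP_BOUNDS
    lo = np.array([bounds[k][0] for k in _PARAM_ORDER])
    hi = np.array([bounds[k][1] for k in _PARAM_ORDER])
    rng = np.random.Generator(np.random.PCG64(derive_seed(seed, "ga")))

    if initial_candidates is not None:
        pop = np.array(initial_candidates, dtype=float).reshape(-1, len(_PARAM_ORDER))
        ga_pop = len(pop)
    else:
        pop = rng.uniform(lo, hi, size=(ga_pop, len(lo)))

    elitism = min(elitism, ga_pop)
    eval_rows, traj_rows = [], []
    best_vec, best_fit, best_seed = None, -np.inf, None

    def evaluate(generation: int, vectors: np.ndarray) -> np.ndarray:
        nonlocal best_vec, best_fit, best_seed
        fits = np.empty(len(vectors))
        for j, v in enumerate(vectors):
            values = dict(zip(_PARAM_ORDER, v))
            sim_seed = derive_seed(seed, "ga_eval", generation, j)
            if fitness_fn is not None:
                fit, n_eval = float(fitness_fn(values, sim_seed)), 0
            else:
                fit, prls, _ = _fitness(values, base, sim_seed)
                n_eval = prls.n
            fits[j] = fit
            eval_rows.append({"generation": generation, "candidate": j,
                              **values, "sim_seed": sim_seed, "fitness": fit,
                              "n": n_eval})
            if fit > best_fit:
                best_vec, best_fit, best_seed = v.copy(), fit, sim_seed
        return fits

    fits = evaluate(0, pop)
    traj_rows.append({"generation": 0, "best_fitness": float(fits.max()),
                      "mean_fitness": float(fits.mean()),
                      "best_so_far": float(best_fit)})

    for g in range(1, ga_gens + 1):
        order = np.argsort(-fits)
        pop, fits = pop[order], fits[order]
        # rank-proportional parent selection
        ranks = np.arange(ga_pop, 0, -1, dtype=float)
        p_sel = ranks / ranks.sum()
        n_off = ga_pop - elitism
        pa = rng.choice(ga_pop, size=n_off, p=p_sel)
        pb = rng.choice(ga_pop, size=n_off, p=p_sel)
        take_a = rng.random((n_off, len(lo))) < 0.5
        off = np.where(take_a, pop[pa], pop[pb])
        mut = rng.random(off.shape) < mutation_chance
        off = np.where(mut, rng.uniform(lo, hi, size=off.shape), off)
        off_fits = evaluate(g, off)
        pop = np.vstack([pop[:elitism], off])
        fits = np.concatenate([fits[:elitism], off_fits])
        traj_rows.append({"generation": g, "best_fitness": float(fits.max()),
                          "mean_fitness": float(fits.mean()),
                          "best_so_far": float(best_fit)})

    values = dict(zip(_PARAM_ORDER, best_vec))
    best_params = dc_replace(base.ecological, **values)
    if fitness_fn is not None:
        return MaximizationResult(
            best_params=best_params, best_weights=None, best_weights_share=np.nan,
            mean_prls=best_fit, n=0,
            trajectory=pd.DataFrame(traj_rows), evaluations=pd.DataFrame(eval_rows))
    # Re-run the best (same seed -> identical history) to recover the evolved
    # modal strategy of its final population.
    _, prls, history = _fitness(values, base, best_seed)
    if history.final_weights is not None and len(history.final_weights):
        weights, share = history.modal_strategy()
    else:  # best run ended extinct: no evolved strategy to report
        weights, share = None, np.nan
    return MaximizationResult(
        best_params=best_params, best_weights=weights, best_weights_share=share,
        mean_prls=prls.mean, n=prls.n,
        trajectory=pd.DataFrame(traj_rows), evaluations=pd.DataFrame(eval_rows))


# -- 3. strategy description + ablations -------------------------------------

@dataclass
class DescribeResult:
    trace: pd.DataFrame
    mean_prls: float
    sd_prls: float
    n: int
    strategy_share: float
    menopause_like_age: Optional[float]  # mean age at last reproduction
    history: PopulationHistory


def describe_strategy(weights: np.ndarray,
                      params: Optional[EcologicalParams] = None,
                      seed: int = 0,
                      base_config: Optional[SimConfig] = None,
                      trace_max: int = 50) -> DescribeResult:
    """Run a homogeneous, mutation-free population with a fixed strategy and
    return the realized life-history trace of final-cohort individuals.

    The trace is a tidy per-(individual, age) table of capitals, qualities,
    allocation fractions, survival probability and reproductive events.
    """
    base = base_config or SimConfig()
    if params is not None:
        base = dc_replace(base, ecological=params)
    cfg = dc_replace(
        base, founder_weights=np.asarray(weights, dtype=float),
        mutation_enabled=False, seed=seed,
        trace_start=max(0, base.duration - 2000), trace_max=trace_max)
    history = pe.run(cfg)
    prls = measure_prls(history)
    rows = []
    for uid, entries in (history.traces or {}).items():
        for e in entries:
            rows.append({"uid": uid, **e})
    trace = pd.DataFrame(rows)
    r = history.records
    done = (r["death"] >= 0) & (r["last_repro"] >= 0)
    men_age = float(np.mean(r["last_repro"][done] - r["birth"][done])) \
        if done.any() else None
    return DescribeResult(trace=trace, mean_prls=prls.mean, sd_prls=prls.sd,
                          n=prls.n, strategy_share=history.strategy_share(),
                          menopause_like_age=men_age, history=history)


def run_variant(variant: str, config: Optional[SimConfig] = None,
                seed: int = 0) -> tuple:
    """Run one model variant under otherwise identical configuration.

    Variants: ``full``, ``no_grandmothering`` (care to already-reproduced
    children removed), ``no_delayed_cognition`` (cognitive factor loses the
    skill integral and beta), ``sibling_transfers`` (5 extra transfer
    outputs).  Returns ``(history, PRLSResult)``.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from "
                          f"{sorted(VARIANTS)}")
    base = config or SimConfig()
    cfg = dc_replace(base, seed=seed, **VARIANTS[variant])
    if cfg.sibling_transfers_enabled and cfg.founder_weights is not None:
        raise ConfigError("sibling_transfers changes the architecture; "
                          "founder_weights cannot be reused")
    history = pe.run(cfg)
    return history, measure_prls(history)


# -- 4. cost analysis --------------------------------------------------------

@dataclass
class CostAnalysisResult:
    condition: int
    n_pops: int
    menopause_age: Optional[int]
    per_generation: pd.DataFrame
    lifespan_conditioned: float
    lifespan_control: float
    lifespan_p_value: float
    forced_child_survival: float
    other_child_survival: float
    per_population: pd.DataFrame


def cost_analysis(condition: int,
                  n_pops: int = 100,
                  weights: Optional[np.ndarray] = None,
                  params: Optional[EcologicalParams] = None,
                  seed: int = 0,
                  base_config: Optional[SimConfig] = None,
                  apply_tick: Optional[int] = None,
                  duration: Optional[int] = None,
                  menopause_age: Optional[int] = None,
                  generations: int = 10) -> CostAnalysisResult:
    """Heritable-condition experiment in populations with evolved menopause.

    Each of ``n_pops`` homogeneous, mutation-free populations runs under the
    given parameters; at ``apply_tick`` a random half of the living
    individuals is tagged (generation 0) with the condition, which their
    descendants inherit with an incremented generation tag.  Condition 1
    forces death at the age of menopause; condition 2 forces one additional
    reproductive event there (diverting the resources of the previous
    birth); condition 3 is a sham tag with no phenotypic effect (a type-I
    control of the pipeline).

    Per generation 0..``generations``: the frequency of conditioned
    individuals (exact binomial test against 0.5 on pooled counts) and the
    survival-to-reproduction / fertility contrasts versus tagged controls
    (Welch t-tests across population means).
    """
    if condition not in (1, 2, 3):
        raise ConfigError(f"condition must be 1, 2 or 3 (got {condition!r})")
    base = base_config or SimConfig()
    if params is not None:
        base = dc_replace(base, ecological=params)
    if weights is None:
        if base.founder_weights is None:
            raise ConfigError("cost_analysis requires evolved weights")
        weights = base.founder_weights
    duration = duration if duration is not None else 2 * base.duration
    apply_tick = apply_tick if apply_tick is not None else duration // 2

    pop_rows = []
    men_ages = []
    pooled = []  # per-pop record arrays for forced-child statistics
    for p in range(n_pops):
        cfg = dc_replace(
            base, founder_weights=np.asarray(weights, dtype=float),
            mutation_enabled=False, condition=condition,
            condition_apply_tick=apply_tick, duration=duration,
            menopause_age=menopause_age,
            seed=derive_seed(seed, "cost_pop", condition, p))
        history = pe.run(cfg)
        men_ages.append(history.menopause_age_used)
        r = history.records
        done = r["death"] >= 0
        pooled.append({k: r[k] for k in
                       ("death", "gen", "condition", "n_repro", "forced_birth")})
        for g in range(generations + 1):
            in_g = (r["gen"] == g) & done
            cond_m = in_g & (r["condition"] == condition)
            ctrl_m = in_g & (r["condition"] == 0)
            k, m = int(cond_m.sum()), int(ctrl_m.sum())
            row = {"population": p, "generation": g, "n_cond": k, "n_ctrl": m}
            row["frequency"] = k / (k + m) if (k + m) else np.nan
            for label, mask in (("cond", cond_m), ("ctrl", ctrl_m)):
                if mask.any():
                    row[f"surv_{label}"] = float((r["n_repro"][mask] > 0).mean())
                    row[f"fert_{label}"] = float(r["n_repro"][mask].mean())
                    row[f"life_{label}"] = float(
                        (r["death"][mask] - r["birth"][mask]).mean())
                else:
                    row[f"surv_{label}"] = np.nan
                    row[f"fert_{label}"] = np.nan
                    row[f"life_{label}"] = np.nan
            pop_rows.append(row)
    per_pop = pd.DataFrame(pop_rows)

    gen_rows = []
    for g in range(generations + 1):
        sub = per_pop[per_pop["generation"] == g]
        k = int(sub["n_cond"].sum())
        n = int((sub["n_cond"] + sub["n_ctrl"]).sum())
        row = {"generation": g,
               "frequency": k / n if n else np.nan,
               "n_cond": k, "n_total": n,
               "binom_p": binomial_frequency_test(k, n) if n else np.nan}
        for metric in ("surv", "fert", "life"):
            a = sub[f"{metric}_cond"].dropna()
            b = sub[f"{metric}_ctrl"].dropna()
            row[f"{metric}_cond_mean"] = float(a.mean()) if len(a) else np.nan
            row[f"{metric}_ctrl_mean"] = float(b.mean()) if len(b) else np.nan
            row[f"{metric}_p"] = (two_sample_t_test(a, b)
                                  if len(a) > 1 and len(b) > 1 else np.nan)
        gen_rows.append(row)
    per_generation = pd.DataFrame(gen_rows)

    # Lifespan contrast among the directly manipulated cohort (generation 0).
    g0 = per_pop[per_pop["generation"] == 0]
    life_a = g0["life_cond"].dropna()
    life_b = g0["life_ctrl"].dropna()
    life_p = two_sample_t_test(life_a, life_b) if len(life_a) > 1 and len(life_b) > 1 \
        else np.nan

    # Survival of the forced last child versus other first-generation
    # children of conditioned mothers (condition 2 only).
    forced_surv, other_surv = np.nan, np.nan
    if condition == 2:
        fvals, ovals = [], []
        for r in pooled:
            done = r["death"] >= 0
            g1_cond = done & (r["gen"] == 1) & (r["condition"] == condition)
            forced = g1_cond & r["forced_birth"]
            other = g1_cond & ~r["forced_birth"]
            if forced.any():
                fvals.append(float((r["n_repro"][forced] > 0).mean()))
            if other.any():
                ovals.append(float((r["n_repro"][other] > 0).mean()))
        forced_surv = float(np.mean(fvals)) if fvals else np.nan
        other_surv = float(np.mean(ovals)) if ovals else np.nan

    men = [m for m in men_ages if m is not None]
    return CostAnalysisResult(
        condition=condition, n_pops=n_pops,
        menopause_age=int(round(np.mean(men))) if men else None,
        per_generation=per_generation,
        lifespan_conditioned=float(life_a.mean()) if len(life_a) else np.nan,
        lifespan_control=float(life_b.mean()) if len(life_b) else np.nan,
        lifespan_p_value=life_p,
        forced_child_survival=forced_surv,
        other_child_survival=other_surv,
        per_population=per_pop)
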