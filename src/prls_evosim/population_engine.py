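"""Per-tick life cycle of a population of ANN-controlled individuals.

Each time unit, for every living individual: (1) allocation fractions are
computed from the start-of-tick perception (synchronous update); (2) the
environmental resource pool is divided proportionally to scaled
productivity; (3) maternal transfers (the direct-reproduction endowment for
age-0 children, care allocations for older ones) are added — an individual
who dies this tick transfers nothing; (4) growth allocations are added to
capital quantities; (5) capital quality degrades and is repaired by
maintenance, and the skill integral advances; (6) survival is a Bernoulli
draw on the scaled sigmoid of resources allocated to survival; (7) an
individual whose direct-reproduction allocation exceeds the birth threshold
and who has a free child slot gives birth to a (possibly mutated) copy of
its strategy, endowed with exactly that allocation; (8) care transfers are
routed per child slot.

Mothers are always created before their children, so transfers resolve
within a tick by processing individuals in ascending generation depth:
a mother's income (and death) is fully known before her children receive
their transfers.  Newborns join the population at depth mother+1, perceive
all-zero inputs, spend their endowment the same tick, and cannot themselves
give birth until the next tick.

The engine stores the population as columns of NumPy arrays with recycled
rows; a compact per-individual event log (:class:`PopulationHistory`) is
kept for demographic analysis.
"""

from __future__ import annotations

import zlib
from bisect import insort
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import numpy as np

from . import neural_controller as nc
from . import physiology as ph
from .physiology import EcologicalParams, ConfigError

RNG_STREAM_NAMES = ("strategy_init", "mutation", "survival", "condition")

# condition tags
COND_NONE = 0
COND_DEATH_AT_MENOPAUSE = 1      # condition 1: forced death at menopause age
COND_EXTRA_BIRTH = 2             # condition 2: one forced extra reproduction
COND_SHAM = 3                    # tag inherited, no phenotypic effect


@dataclass
class SimConfig:
    """Complete configuration of one simulation run."""

    ecological: EcologicalParams = field(default_factory=EcologicalParams)
    initial_population: int = 1000
    duration: int = 10_000
    initial_endowment: float = 200.0
    grandmothering_enabled: bool = True
    delayed_benefits_enabled: bool = True
    sibling_transfers_enabled: bool = False
    mutation_enabled: bool = True
    # Minimum absolute resources routed to direct reproduction for a birth to
    # occur.  Logistic outputs are strictly positive, so a zero threshold
    # would trigger a (doomed) birth every tick; one resource unit gates only
    # births whose endowment gives the child a <1% per-tick survival chance
    # under EP*-like environments.
    birth_threshold: float = 1.0
    # Child-productivity inputs use scaled productivity P' (default) or raw P.
    child_productivity_scaled: bool = True
    founder_weights: Optional[np.ndarray] = None  # (L,) homogeneous or (n, L)
    # Heritable experimental condition (cost analysis).
    condition: int = COND_NONE
    condition_apply_tick: Optional[int] = None
    menopause_age: Optional[int] = None  # estimated at apply time if None
    # Full life-history traces for the first `trace_max` individuals born at
    # or after `trace_start` (None disables tracing).
    trace_start: Optional[int] = None
    trace_max: int = 50
    seed: Optional[int] = None

    def validate(self) -> "SimConfig":
        self.ecological.validate()
        checks = [
            ("initial_population", self.initial_population > 0, "must be > 0"),
            ("duration", self.duration >= 0, "must be >= 0"),
            ("initial_endowment", self.initial_endowment >= 0, "must be >= 0"),
            ("birth_threshold", self.birth_threshold >= 0, "must be >= 0"),
            ("condition", self.condition in (0, 1, 2, 3), "must be 0, 1, 2 or 3"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigError(f"{name} {msg} (got {getattr(self, name)!r})")
        if self.condition != COND_NONE and self.condition_apply_tick is None:
            raise ConfigError("condition_apply_tick is required when condition != 0")
        return self

    @property
    def n_outputs(self) -> int:
        return nc.N_OUTPUTS_SIBLING if self.sibling_transfers_enabled else nc.N_OUTPUTS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ecological"] = self.ecological.to_dict()
        fw = d.pop("founder_weights")
        d["founder_weights"] = None if fw is None else np.asarray(fw).tolist()
        return d


@dataclass
class Individual:
    """Read-only snapshot of one living individual (testing/introspection)."""

    id: int
    mother_id: int
    birth_tick: int
    age: int
    capitals: ph.CapitalState
    child_slots: list
    n_repro: int
    last_repro_tick: int
    condition_tag: int
    generation_tag: int
    alive: bool


class _Recorder:
    """Growing columnar event log, one row per individual ever born."""

    _SPEC = [
        ("mother_uid", np.int64), ("birth", np.int32), ("death", np.int32),
        ("n_repro", np.int32), ("last_repro", np.int32), ("first_repro", np.int32),
        ("condition", np.int8), ("gen", np.int16), ("forced_birth", bool),
        ("whash", np.uint32),
    ]

    def __init__(self, capacity: int = 4096):
        self.n = 0
        self._cap = capacity
        self.cols = {name: np.zeros(capacity, dtype=dt) for name, dt in self._SPEC}

    def _grow(self, need: int) -> None:
        while self._cap < need:
            self._cap *= 2
        for k, v in self.cols.items():
            new = np.zeros(self._cap, dtype=v.dtype)
            new[: self.n] = v[: self.n]
            self.cols[k] = new

    def append(self, k: int, **values) -> np.ndarray:
        """Append k rows; returns the new uids."""
        if self.n + k > self._cap:
            self._grow(self.n + k)
        uids = np.arange(self.n, self.n + k)
        for name, _ in self._SPEC:
            self.cols[name][uids] = values[name]
        self.n += k
        return uids

    def finalize(self) -> Dict[str, np.ndarray]:
        return {k: v[: self.n].copy() for k, v in self.cols.items()}


@dataclass
class PRLSResult:
    """Mean post-reproductive lifespan of a cohort (undefined if no eligible
    individual reproduced)."""

    mean: float
    sd: float
    n: int
    n_nonreproducing: int
    undefined: bool


@dataclass
class PopulationHistory:
    """Event log of a finished run: one record per individual ever born, the
    per-tick population size, and optional full traces."""

    records: Dict[str, np.ndarray]
    pop_size: np.ndarray
    births_per_tick: np.ndarray
    deaths_per_tick: np.ndarray
    duration: int
    ticks_run: int
    extinct: bool
    config: dict
    menopause_age_used: Optional[int] = None
    traces: Optional[dict] = None
    final_weights: Optional[np.ndarray] = None  # strategies alive at the end

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.records)
        df.insert(0, "uid", np.arange(len(df)))
        return df

    def modal_strategy(self) -> tuple:
        """(weights, share): the most frequent final-population strategy and
        the fraction of the final population carrying it."""
        if self.final_weights is None or not len(self.final_weights):
            raise ValueError("no surviving individuals: modal strategy undefined")
        hashes = np.array([zlib.crc32(w.tobytes()) for w in self.final_weights],
                         dtype=np.uint64)
        vals, counts = np.unique(hashes, return_counts=True)
        top = vals[np.argmax(counts)]
        idx = int(np.flatnonzero(hashes == top)[0])
        return self.final_weights[idx].copy(), counts.max() / len(hashes)

    def strategy_share(self, window: int = 2000) -> float:
        """Fraction of the born-and-died final-window cohort sharing the
        modal strategy (by weight-vector hash)."""
        r = self.records
        t1 = self.ticks_run
        sel = (r["birth"] >= t1 - window) & (r["death"] >= 0)
        h = r["whash"][sel]
        if not len(h):
            return float("nan")
        _, counts = np.unique(h, return_counts=True)
        return counts.max() / len(h)


def divide_resources(scaled_productivity: np.ndarray, pool: float) -> np.ndarray:
    """Split the per-tick pool proportionally to scaled productivity.

    Individuals with P' = 0 receive nothing; if every P' is 0, nobody
    receives environmental resources.
    """
    p = np.asarray(scaled_productivity, dtype=float)
    total = p.sum()
    if total <= 0.0 or pool <= 0.0:
        return np.zeros_like(p)
    return pool * (p / total)


class _Arena:
    """Struct-of-arrays store for living individuals; rows are recycled."""

    def __init__(self, capacity: int, n_weights: int):
        self.cap = capacity
        self.nw = n_weights
        self.alive = np.zeros(capacity, dtype=bool)
        self.uid = np.full(capacity, -1, dtype=np.int64)
        self.birth = np.zeros(capacity, dtype=np.int64)
        self.depth = np.zeros(capacity, dtype=np.int64)
        self.mother = np.full(capacity, -1, dtype=np.int64)       # arena row
        self.slot_in_mother = np.zeros(capacity, dtype=np.int64)
        self.weights = np.zeros((capacity, n_weights))
        self.Qs = np.zeros(capacity)
        self.Qfs = np.zeros(capacity)
        self.Qc = np.zeros(capacity)
        self.Qfc = np.zeros(capacity)
        self.skill = np.zeros(capacity)
        self.children = np.full((capacity, 5), -1, dtype=np.int64)
        self.n_repro = np.zeros(capacity, dtype=np.int64)
        self.last_repro = np.full(capacity, -1, dtype=np.int64)
        self.first_repro = np.full(capacity, -1, dtype=np.int64)
        self.last_birth_spend = np.zeros(capacity)
        self.pending = np.zeros(capacity)   # endowment / delayed transfers
        self.condition = np.zeros(capacity, dtype=np.int8)
        self.gen = np.full(capacity, -1, dtype=np.int16)
        self.free: list = list(range(capacity - 1, -1, -1))

    def grow(self, need: int) -> None:
        old = self.cap
        while self.cap < need:
            self.cap *= 2
        for name in ("alive", "uid", "birth", "depth", "mother", "slot_in_mother",
                     "Qs", "Qfs", "Qc", "Qfc", "skill", "n_repro", "last_repro",
                     "first_repro", "last_birth_spend", "pending", "condition",
                     "gen"):
            arr = getattr(self, name)
            new = np.zeros(self.cap, dtype=arr.dtype)
            new[:old] = arr
            setattr(self, name, new)
        for name, fillshape in (("weights", (self.cap, self.nw)),
                                ("children", (self.cap, 5))):
            arr = getattr(self, name)
            new = np.full(fillshape, -1, dtype=arr.dtype) if name == "children" \
                else np.zeros(fillshape)
            new[:old] = arr
            setattr(self, name, new)
        self.free.extend(range(self.cap - 1, old - 1, -1))

    def take_rows(self, k: int) -> np.ndarray:
        if len(self.free) < k:
            used = self.cap - len(self.free)
            self.grow(max(self.cap * 2, used + k))
        rows = np.array([self.free.pop() for _ in range(k)], dtype=np.int64)
        return rows


class Engine:
    """Stepwise simulator.  Use :func:`run` for whole runs."""

    def __init__(self, config: SimConfig, rngs: Optional[dict] = None):
        config.validate()
        self.config = config
        self.eco = config.ecological
        if rngs is None:
            from .cli_io import seed_streams

            rngs = seed_streams(config.seed if config.seed is not None else 0,
                                RNG_STREAM_NAMES)
        self.rngs = rngs
        self.tick = 0
        self.K = config.n_outputs
        self.nw = nc.n_weights(self.K)
        n0 = config.initial_population
        cap = max(1024, 4 * n0)
        self.arena = _Arena(cap, self.nw)
        self.rec = _Recorder(max(4096, 2 * n0))
        self._alloc = np.zeros((cap, self.K))
        self._pop_size: list = []
        self._births: list = []
        self._deaths: list = []
        self.extinct = False
        self.menopause_age_used: Optional[int] = config.menopause_age
        self._traces: Optional[dict] = {} if config.trace_start is not None else None
        self._trace_rows: dict = {}
        self._audit = False
        self.audit_log: list = []
        self._spawn_founders()

    # -- setup ---------------------------------------------------------------

    def _founder_strategies(self, n: int) -> np.ndarray:
        fw = self.config.founder_weights
        if fw is None:
            return nc.init_strategies(self.rngs["strategy_init"], n, self.K)
        fw = np.asarray(fw, dtype=float)
        if fw.ndim == 1:
            return np.tile(fw, (n, 1))
        return fw.copy()

    def _spawn_founders(self) -> None:
        n = self.config.initial_population
        W = self._founder_strategies(n)
        if W.shape != (n, self.nw):
            raise ConfigError(
                f"founder_weights shape {W.shape} does not match "
                f"({n}, {self.nw})")
        rows = self.arena.take_rows(n)
        self._register_births(rows, W, mother_rows=None, endowment=np.full(
            n, self.config.initial_endowment), tick=0, forced=False)

    def _register_births(self, rows, W, mother_rows, endowment, tick, forced):
        a = self.arena
        if self._alloc.shape[0] < a.cap:
            new = np.zeros((a.cap, self.K))
            new[: self._alloc.shape[0]] = self._alloc
            self._alloc = new
        k = len(rows)
        a.alive[rows] = True
        a.birth[rows] = tick
        a.weights[rows] = W
        for name in ("Qs", "Qfs", "Qc", "Qfc", "skill", "last_birth_spend"):
            getattr(a, name)[rows] = 0.0
        a.children[rows] = -1
        a.n_repro[rows] = 0
        a.last_repro[rows] = -1
        a.first_repro[rows] = -1
        a.pending[rows] = endowment
        if mother_rows is None:
            a.depth[rows] = 0
            a.mother[rows] = -1
            a.slot_in_mother[rows] = -1
            a.condition[rows] = COND_NONE
            a.gen[rows] = -1
            mother_uids = np.full(k, -1, dtype=np.int64)
        else:
            a.depth[rows] = a.depth[mother_rows] + 1
            a.mother[rows] = mother_rows
            a.condition[rows] = a.condition[mother_rows]
            g = a.gen[mother_rows]
            a.gen[rows] = np.where(g >= 0, g + 1, -1)
            mother_uids = a.uid[mother_rows]
        whash = np.fromiter(
            (zlib.crc32(W[i].tobytes()) for i in range(k)), dtype=np.uint32,
            count=k)
        uids = self.rec.append(
            k, mother_uid=mother_uids, birth=tick, death=-1, n_repro=0,
            last_repro=-1, first_repro=-1, condition=a.condition[rows],
            gen=a.gen[rows], forced_birth=forced, whash=whash)
        a.uid[rows] = uids
        if self._traces is not None and tick >= self.config.trace_start:
            for r in rows:
                if len(self._traces) >= self.config.trace_max:
                    break
                u = int(a.uid[r])
                self._traces[u] = []
                self._trace_rows[int(r)] = u

    # -- introspection -------------------------------------------------------

    def living_rows(self) -> np.ndarray:
        return np.flatnonzero(self.arena.alive)

    def perceive(self, row: int) -> nc.Perception:
        """Build the Perception of one living individual from current state."""
        a = self.arena
        if not a.alive[row]:
            raise ValueError("cannot perceive a dead individual")
        rows = self.living_rows()
        _, prod = self._scaled_productivity(rows)
        prod_full = np.zeros(a.cap)
        prod_full[rows] = prod
        flags, prods = self._child_inputs(np.array([row]), prod_full)
        return nc.Perception(
            soma_qty=float(a.Qs[row]),
            soma_qual=float(ph.quality(a.Qs[row], a.Qfs[row])),
            cog_qty=float(a.Qc[row]),
            cog_qual=float(ph.quality(a.Qc[row], a.Qfc[row])),
            child_present=flags[0].tolist(),
            child_prod_corrected=prods[0].tolist(),
        )

    def snapshot(self, row: int) -> Individual:
        a = self.arena
        return Individual(
            id=int(a.uid[row]),
            mother_id=int(a.uid[a.mother[row]]) if a.mother[row] >= 0 else -1,
            birth_tick=int(a.birth[row]), age=self.tick - int(a.birth[row]),
            capitals=ph.CapitalState(float(a.Qs[row]), float(a.Qfs[row]),
                                     float(a.Qc[row]), float(a.Qfc[row]),
                                     float(a.skill[row])),
            child_slots=[int(c) if c >= 0 else None for c in a.children[row]],
            n_repro=int(a.n_repro[row]), last_repro_tick=int(a.last_repro[row]),
            condition_tag=int(a.condition[row]),
            generation_tag=int(a.gen[row]), alive=bool(a.alive[row]))

    # -- per-tick pieces -----------------------------------------------------

    def _scaled_productivity(self, rows: np.ndarray) -> np.ndarray:
        a, e = self.arena, self.eco
        K = a.Qfs[rows]  # Q * (Qf/Q) = Qf
        qc = ph.quality(a.Qc[rows], a.Qfc[rows])
        present = a.Qc[rows] * qc
        if self.config.delayed_benefits_enabled:
            C = present * e.beta * a.skill[rows]
        else:
            C = present
        P = ph.raw_productivity(K, C, e.alpha, e.cobb_douglas_exponent)
        pp = ph.scaled_sigmoid(P, e.gamma1, e.gamma2)
        return pp, (pp if self.config.child_productivity_scaled else P)

    def _child_inputs(self, rows: np.ndarray, prod_full: np.ndarray) -> tuple:
        a = self.arena
        ch = a.children[rows]
        occ = ch >= 0
        flags = occ.astype(float)
        prods = np.zeros_like(flags)
        if occ.any():
            c = ch[occ]
            nliv = (a.children[c] >= 0).sum(axis=1)
            prods[occ] = prod_full[c] / (nliv + 1.0)
        return flags, prods

    def _decide_all(self, rows, pp_full, prod_full):
        a = self.arena
        X = np.empty((len(rows), nc.N_INPUTS))
        X[:, 0] = a.Qs[rows]
        X[:, 1] = ph.quality(a.Qs[rows], a.Qfs[rows])
        X[:, 2] = a.Qc[rows]
        X[:, 3] = ph.quality(a.Qc[rows], a.Qfc[rows])
        flags, prods = self._child_inputs(rows, prod_full)
        X[:, 4:9] = flags
        X[:, 9:14] = prods
        alloc = nc.decide_batch(a.weights[rows], X)
        if not self.config.grandmothering_enabled:
            # Zero care aimed at children who already reproduced, renormalize.
            ch = a.children[rows]
            occ = ch >= 0
            reproduced = np.zeros_like(occ)
            if occ.any():
                reproduced[occ] = a.n_repro[ch[occ]] > 0
            care = alloc[:, nc.OUT_CARE]
            care[reproduced] = 0.0
            alloc /= alloc.sum(axis=1, keepdims=True)
        self._alloc[rows] = alloc

    def _apply_condition_tags(self) -> None:
        """At the apply tick: tag every living individual generation 0 and
        give a random half the heritable condition."""
        a = self.arena
        rows = self.living_rows()
        a.gen[rows] = 0
        self.rec.cols["gen"][a.uid[rows]] = 0
        half = self.rngs["condition"].random(len(rows)) < 0.5
        a.condition[rows[half]] = self.config.condition
        self.rec.cols["condition"][a.uid[rows[half]]] = self.config.condition
        if self.menopause_age_used is None and self.config.condition in (
                COND_DEATH_AT_MENOPAUSE, COND_EXTRA_BIRTH):
            self.menopause_age_used = self._estimate_menopause_age()

    def _estimate_menopause_age(self) -> int:
        """Rounded mean age at last reproduction among completed lives of the
        pre-apply burn-in (second half of it, to skip transients)."""
        r = self.rec
        n = r.n
        death = r.cols["death"][:n]
        birth = r.cols["birth"][:n]
        last = r.cols["last_repro"][:n]
        lo = self.tick // 2
        sel = (death >= 0) & (last >= 0) & (birth >= lo)
        if not sel.any():
            raise RuntimeError("cannot estimate menopause age: no completed "
                               "reproducing lives in the burn-in window")
        return int(round(float(np.mean(last[sel] - birth[sel]))))

    def _kill(self, rows: np.ndarray, t: int) -> None:
        a = self.arena
        uids = a.uid[rows]
        self.rec.cols["death"][uids] = t
        self.rec.cols["n_repro"][uids] = a.n_repro[rows]
        self.rec.cols["last_repro"][uids] = a.last_repro[rows]
        self.rec.cols["first_repro"][uids] = a.first_repro[rows]
        # free our slot in the mother's household
        m = a.mother[rows]
        has_m = m >= 0
        if has_m.any():
            mm = m[has_m]
            live_m = a.alive[mm]
            if live_m.any():
                a.children[mm[live_m], a.slot_in_mother[rows[has_m]][live_m]] = -1
        # orphan our children
        ch = a.children[rows]
        kids = ch[ch >= 0]
        if len(kids):
            a.mother[kids] = -1
        a.children[rows] = -1
        a.alive[rows] = False
        a.pending[rows] = 0.0
        for r in rows:
            ri = int(r)
            if ri in self._trace_rows:
                del self._trace_rows[ri]
            a.free.append(ri)

    # -- the tick ------------------------------------------------------------

    def step(self) -> None:
        """Advance the whole population by one time unit."""
        t = self.tick
        cfg = self.config
        a = self.arena
        rng_s = self.rngs["survival"]

        if cfg.condition != COND_NONE and t == cfg.condition_apply_tick:
            self._apply_condition_tags()

        births_this_tick = 0
        deaths_this_tick = 0

        # Condition 1: forced death at menopause age, before any allocation.
        if cfg.condition == COND_DEATH_AT_MENOPAUSE and \
                self.menopause_age_used is not None and \
                cfg.condition_apply_tick is not None and \
                t >= cfg.condition_apply_tick:
            rows = self.living_rows()
            doomed = rows[(a.condition[rows] == COND_DEATH_AT_MENOPAUSE)
                          & (t - a.birth[rows] == self.menopause_age_used)]
            if len(doomed):
                self._kill(doomed, t)
                deaths_this_tick += len(doomed)

        rows = self.living_rows()
        if not len(rows):
            self.extinct = True
            self._pop_size.append(0)
            self._births.append(births_this_tick)
            self._deaths.append(deaths_this_tick)
            self.tick += 1
            return

        # Phase A: synchronous perception + allocation from start-of-tick state.
        pp, prod_for_inputs = self._scaled_productivity(rows)
        pp_full = np.zeros(a.cap)
        pp_full[rows] = pp
        prod_full = np.zeros(a.cap)
        prod_full[rows] = prod_for_inputs
        self._decide_all(rows, pp_full, prod_full)

        env_full = np.zeros(a.cap)
        env_full[rows] = divide_resources(pp, self.eco.resource_pool)

        care_in = np.zeros(a.cap)

        # Phase B: process in ascending generation depth.
        groups: Dict[int, list] = {}
        for d in np.unique(a.depth[rows]):
            groups[int(d)] = [rows[a.depth[rows] == d]]
        order = sorted(groups)
        i = 0
        while i < len(order):
            d = order[i]
            r = np.concatenate(groups[d]) if len(groups[d]) > 1 else groups[d][0]
            i += 1
            env_level = env_full[r]
            income = env_level + care_in[r] + a.pending[r]
            if self._audit:
                self.audit_log.append({
                    "tick": t, "depth": d, "income": float(income.sum()),
                    "env": float(env_level.sum()),
                })
            # consume on read: a row freed and recycled for a newborn later
            # this tick must not re-deliver the previous occupant's share
            env_full[r] = 0.0
            care_in[r] = 0.0
            a.pending[r] = 0.0
            frac = self._alloc[r]

            # Condition 2: divert the previous birth's spend to reproduction.
            forced_mask = np.zeros(len(r), dtype=bool)
            if cfg.condition == COND_EXTRA_BIRTH and \
                    self.menopause_age_used is not None and \
                    cfg.condition_apply_tick is not None and \
                    t >= cfg.condition_apply_tick:
                forced_mask = ((a.condition[r] == COND_EXTRA_BIRTH)
                               & (t - a.birth[r] == self.menopause_age_used)
                               & (a.last_birth_spend[r] > 0.0))
                if forced_mask.any():
                    frac = frac.copy()
                    fi = np.flatnonzero(forced_mask)
                    amt = np.minimum(a.last_birth_spend[r[fi]],
                                     income[fi])
                    inc = income[fi]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        share = np.where(inc > 0, amt / np.maximum(inc, 1e-300), 0.0)
                    other = 1.0 - frac[fi, nc.OUT_REPRO]
                    scale = np.where(other > 0, (1.0 - share) / np.maximum(other, 1e-300), 0.0)
                    frac[fi] *= scale[:, None]
                    frac[fi, nc.OUT_REPRO] = share

            absr = frac * income[:, None]
            if self._audit:
                self.audit_log[-1]["allocated"] = float(absr.sum())

            # growth + capital dynamics + skill integral
            a.Qs[r], a.Qfs[r] = ph.update_capital(
                a.Qs[r], a.Qfs[r], absr[:, nc.OUT_SOMA_GROWTH],
                absr[:, nc.OUT_SOMA_MAINT], self.eco.delta)
            a.Qc[r], a.Qfc[r] = ph.update_capital(
                a.Qc[r], a.Qfc[r], absr[:, nc.OUT_COG_GROWTH],
                absr[:, nc.OUT_COG_MAINT], self.eco.delta)
            a.skill[r] += a.Qc[r] * ph.quality(a.Qc[r], a.Qfc[r])

            # survival draw
            s = ph.survival_prob(absr[:, nc.OUT_SURVIVAL],
                                 self.eco.sigma1, self.eco.sigma2)
            u = rng_s.random(len(r))
            died = u >= s
            if died.any():
                self._kill(r[died], t)
                deaths_this_tick += int(died.sum())
            alive_mask = ~died
            sr = r[alive_mask]
            s_absr = absr[alive_mask]
            s_forced = forced_mask[alive_mask]

            if self._traces is not None and len(sr):
                self._record_traces(sr, t, env_full, care_in, s_absr, s[alive_mask])

            if not len(sr):
                continue

            # reproduction
            repro_res = s_absr[:, nc.OUT_REPRO]
            free_slot = (a.children[sr] >= 0).sum(axis=1) < 5
            eligible = ((repro_res > cfg.birth_threshold)
                        | (s_forced & (repro_res > 0.0))) \
                & (a.birth[sr] < t) & free_slot
            if eligible.any():
                mothers = sr[eligible]
                endow = repro_res[eligible]
                forced_flags = s_forced[eligible]
                W = a.weights[mothers]
                if cfg.mutation_enabled:
                    W = nc.mutate_batch(W, self.rngs["mutation"])
                newrows = self.arena.take_rows(len(mothers))
                slot = np.argmax(a.children[mothers] == -1, axis=1)
                a.children[mothers, slot] = newrows
                a.n_repro[mothers] += 1
                a.last_repro[mothers] = t
                a.first_repro[mothers] = np.where(
                    a.first_repro[mothers] < 0, t, a.first_repro[mothers])
                a.last_birth_spend[mothers] = endow
                self._register_births(newrows, W, mothers, endow, t,
                                      forced=forced_flags)
                a.slot_in_mother[newrows] = slot
                births_this_tick += len(mothers)
                # newborn allocations: all-zero perception
                self._alloc[newrows] = nc.decide_batch(
                    a.weights[newrows], np.zeros((len(newrows), nc.N_INPUTS)))
                nd = d + 1
                if nd in groups:
                    groups[nd].append(newrows)
                else:
                    groups[nd] = [newrows]
                    insort(order, nd)

            # care transfers to children alive since before this tick
            ch = a.children[sr]
            valid = (ch >= 0)
            if valid.any():
                older = np.zeros_like(valid)
                older[valid] = a.birth[ch[valid]] < t
                amounts = s_absr[:, nc.OUT_CARE]
                np.add.at(care_in, ch[older], amounts[older])

            # sibling transfers (variant): delivered into next-tick income
            if cfg.sibling_transfers_enabled:
                m = a.mother[sr]
                has_m = m >= 0
                if has_m.any():
                    senders = np.flatnonzero(has_m)
                    sib = a.children[m[has_m]]           # (k, 5)
                    amounts = s_absr[senders][:, nc.OUT_SIBLING]
                    ok = (sib >= 0) & (sib != sr[senders][:, None])
                    ok &= np.where(sib >= 0, a.alive[np.maximum(sib, 0)], False)
                    ok &= np.where(sib >= 0, a.birth[np.maximum(sib, 0)] < t, False)
                    np.add.at(a.pending, sib[ok], amounts[ok])

        self._pop_size.append(int(a.alive.sum()))
        self._births.append(births_this_tick)
        self._deaths.append(deaths_this_tick)
        self.tick += 1

    def _record_traces(self, sr, t, env_full, care_in, absr, s):
        a = self.arena
        for j, r in enumerate(sr):
            ri = int(r)
            u = self._trace_rows.get(ri)
            if u is None:
                continue
            self._traces[u].append({
                "tick": t, "age": int(t - a.birth[r]),
                "income": float(absr[j].sum()),
                "Q_soma": float(a.Qs[r]), "q_soma": float(ph.quality(a.Qs[r], a.Qfs[r])),
                "Q_cog": float(a.Qc[r]), "q_cog": float(ph.quality(a.Qc[r], a.Qfc[r])),
                "skill_integral": float(a.skill[r]),
                "survival_prob": float(s[j]),
                "gave_birth": bool(a.last_repro[r] == t),
                **{f"alloc_{k}": float(absr[j, k] / absr[j].sum()) if absr[j].sum() > 0
                   else float("nan") for k in range(self.K)},
            })

    # -- whole runs ----------------------------------------------------------

    def run(self) -> PopulationHistory:
        for _ in range(self.config.duration):
            self.step()
            if self.extinct:
                break
        return self.finalize()

    def finalize(self) -> PopulationHistory:
        a = self.arena
        rows = self.living_rows()
        uids = a.uid[rows]
        self.rec.cols["n_repro"][uids] = a.n_repro[rows]
        self.rec.cols["last_repro"][uids] = a.last_repro[rows]
        self.rec.cols["first_repro"][uids] = a.first_repro[rows]
        traces = None
        if self._traces is not None:
            traces = {u: rows_ for u, rows_ in self._traces.items() if rows_}
        return PopulationHistory(
            records=self.rec.finalize(),
            pop_size=np.asarray(self._pop_size, dtype=np.int64),
            births_per_tick=np.asarray(self._births, dtype=np.int64),
            deaths_per_tick=np.asarray(self._deaths, dtype=np.int64),
            duration=self.config.duration,
            ticks_run=self.tick,
            extinct=self.extinct,
            config=self.config.to_dict(),
            menopause_age_used=self.menopause_age_used,
            traces=traces,
            final_weights=a.weights[rows].copy(),
        )


def run(config: SimConfig, rngs: Optional[dict] = None) -> PopulationHistory:
    """Run a full simulation; reproducible given ``config.seed`` (or ``rngs``)."""
    return Engine(config, rngs).run()


# -- demographic metrics -----------------------------------------------------

def measure_prls(history: PopulationHistory, window: int = 2000) -> PRLSResult:
    """Mean post-reproductive lifespan over individuals born and dead within
    the final ``window`` ticks who reproduced at least once.

    PRLS_i = death_tick - last_reproduction_tick.  Non-reproducers are
    excluded (their last reproduction is undefined) and counted separately.
    An empty eligible set yields an undefined (NaN) result, not 0.
    """
    r = history.records
    t1 = history.ticks_run
    t0 = t1 - window
    cohort = (r["birth"] >= t0) & (r["death"] >= 0) & (r["death"] <= t1)
    reproduced = cohort & (r["last_repro"] >= 0)
    vals = (r["death"][reproduced] - r["last_repro"][reproduced]).astype(float)
    n = len(vals)
    n_excl = int(cohort.sum()) - n
    if n == 0:
        return PRLSResult(float("nan"), float("nan"), 0, n_excl, True)
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return PRLSResult(float(np.mean(vals)), sd, n, n_excl, False)


def measure_demographics(history: PopulationHistory,
                         by: tuple = ("condition", "gen"),
                         completed_only: bool = True):
    """Fertility, survival-to-reproduction and lifespan per group.

    Groups by the record columns in ``by`` (default: condition tag and
    generation tag).  With ``completed_only`` (default), only individuals
    whose death is recorded enter the lifespan and fertility means, so
    right-censored lives do not bias them.  Returns a tidy DataFrame; empty
    groups simply do not appear.
    """
    import pandas as pd

    df = history.to_dataframe()
    if completed_only:
        df = df[df["death"] >= 0].copy()
    if df.empty:
        return pd.DataFrame(columns=[*by, "n", "fertility_mean",
                                     "survival_to_repro", "lifespan_mean"])
    df["fertility"] = df["n_repro"]
    df["survived_to_repro"] = (df["n_repro"] > 0).astype(float)
    df["lifespan"] = df["death"] - df["birth"]
    out = (df.groupby(list(by))
             .agg(n=("uid", "size"),
                  fertility_mean=("fertility", "mean"),
                  survival_to_repro=("survived_to_repro", "mean"),
                  lifespan_mean=("lifespan", "mean"))
             .reset_index())
    return out
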