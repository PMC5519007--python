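"""Life-cycle engine: perception, resource division, transfers, demography."""

import numpy as np
import pytest

from prls_evosim import physiology as ph
from prls_evosim import neural_controller as nc
from prls_evosim.cli_io import make_fixture
from prls_evosim.population_engine import (
    Engine,
    PopulationHistory,
    SimConfig,
    divide_resources,
    measure_demographics,
    measure_prls,
)


class _FixedRng:
    """Survival-stream stub: .random(n) pops scripted batches (1.0 = die,
    0.0 = survive), then repeats the last batch value."""

    def __init__(self, batches):
        self.batches = list(batches)

    def random(self, n):
        v = self.batches.pop(0) if self.batches else self.last
        self.last = v
        return np.full(n, float(v))


def _stub_streams(survival_batches=(0.0,)):
    r = np.random.default_rng(0)
    return {"strategy_init": r, "mutation": np.random.default_rng(1),
            "survival": _FixedRng(survival_batches),
            "condition": np.random.default_rng(2)}


class TestPerception:
    def test_newborn_perceives_all_zeros(self):
        fx = make_fixture("single_agent")
        p = fx.engine.perceive(fx.rows["agent"])
        assert not any(p.to_array())

    def test_child_productivity_corrected_by_grandchildren(self):
        """A child who has one child of her own contributes P'/2 to the
        grandmother's input (division by number of children + 1)."""
        fx = make_fixture("grandmother_triplet")
        eng, rows = fx.engine, fx.rows
        a = eng.arena
        child = rows["child"]
        c = ph.CapitalState(a.Qs[child], a.Qfs[child], a.Qc[child],
                            a.Qfc[child], a.skill[child])
        P = ph.raw_productivity(ph.somatic_factor(c),
                                ph.cognitive_factor(c, eng.eco.beta),
                                eng.eco.alpha)
        expected = ph.scaled_sigmoid(P, eng.eco.gamma1, eng.eco.gamma2) / 2.0
        p = eng.perceive(rows["grandmother"])
        assert p.child_present == [1.0, 0.0, 0.0, 0.0, 0.0]
        assert p.child_prod_corrected[0] == pytest.approx(expected)
        assert expected > 0

    def test_dead_child_slot_reads_zero(self):
        fx = make_fixture("mother_two_children")
        eng, rows = fx.engine, fx.rows
        eng._kill(np.array([rows["child1"]]), t=0)
        p = eng.perceive(rows["mother"])
        assert p.child_present == [1.0, 0.0, 0.0, 0.0, 0.0]
        assert p.child_prod_corrected[1] == 0.0


class TestDivideResources:
    def test_single_producer_takes_whole_pool(self):
        np.testing.assert_allclose(divide_resources(np.array([0.4]), 20000),
                                   [20000.0])

    def test_proportional_shares(self):
        np.testing.assert_allclose(
            divide_resources(np.array([0.1, 0.3]), 20000), [5000.0, 15000.0])

    def test_no_producers_no_flow(self):
        assert not divide_resources(np.array([0.0, 0.0]), 20000).any()


class TestTransfersAndConservation:
    def _two_gen_engine(self, survival_batches):
        fx = make_fixture("mother_two_children")
        eng = fx.engine
        eng.rngs = _stub_streams(survival_batches)
        eng.tick = 1  # children count as born before this tick
        eng.config.birth_threshold = 1e9  # no new births in this scenario
        a = eng.arena
        a.pending[fx.rows["mother"]] = 110.0
        for c in (fx.rows["child0"], fx.rows["child1"]):
            a.Qs[c] = a.Qfs[c] = 0.0  # dependent: no environmental share
            a.pending[c] = 60.0
        eng._audit = True
        return eng, fx.rows

    def test_living_mother_transfers_care(self):
        eng, rows = self._two_gen_engine(survival_batches=[0.0])
        eng.step()
        # mother has no cognitive capital so no env share: income = 110,
        # each child receives 1/11 of it in care on top of its own 60
        by_depth = {e["depth"]: e for e in eng.audit_log}
        assert by_depth[0]["income"] == pytest.approx(110.0)
        assert by_depth[1]["income"] == pytest.approx(120.0 + 2 * 110.0 / 11.0)

    def test_dying_mother_withholds_transfers(self):
        """A mother who dies this tick allocates nothing to her children."""
        eng, rows = self._two_gen_engine(survival_batches=[1.0, 0.0])
        eng.step()
        by_depth = {e["depth"]: e for e in eng.audit_log}
        assert by_depth[1]["income"] == pytest.approx(120.0)
        assert not eng.arena.alive[rows["mother"]]
        assert eng.arena.alive[rows["child0"]]

    def test_resources_fully_allocated(self, small_config):
        """Every living individual's absolute allocations sum to exactly its
        income, and per-tick environmental outflow equals the pool whenever
        someone is productive."""
        eng = Engine(small_config)
        eng._audit = True
        for _ in range(60):
            eng.step()
        assert eng.audit_log
        per_tick_env = {}
        for e in eng.audit_log:
            assert e["allocated"] == pytest.approx(e["income"], rel=1e-9)
            per_tick_env[e["tick"]] = per_tick_env.get(e["tick"], 0) + e["env"]
        pool = small_config.ecological.resource_pool
        productive_ticks = [t for t, v in per_tick_env.items() if v > 0]
        assert productive_ticks
        for t in productive_ticks:
            assert per_tick_env[t] == pytest.approx(pool, rel=1e-9)


def _solo_mother_engine(benign_ecology):
    """One zero-weight founder in a gentle environment, fed a steady income."""
    cfg = SimConfig(ecological=benign_ecology, initial_population=1,
                    duration=0, mutation_enabled=False, seed=0,
                    founder_weights=np.zeros(nc.N_WEIGHTS))
    eng = Engine(cfg, rngs=_stub_streams([0.0]))
    return eng


class TestFamilyBookkeeping:
    def test_never_more_than_five_children_and_slot_reuse(self, benign_ecology):
        eng = _solo_mother_engine(benign_ecology)
        a, m = eng.arena, 0
        for _ in range(8):
            a.pending[m] += 110.0  # steady personal income
            eng.step()
        assert (a.children[m] >= 0).sum() == 5
        assert a.n_repro[m] == 5  # births stop once all slots are full
        # free a slot: its reuse allows exactly one more birth
        victim = a.children[m, 2]
        eng._kill(np.array([victim]), t=eng.tick)
        a.pending[m] += 110.0
        eng.step()
        assert a.n_repro[m] == 6
        assert (a.children[m] >= 0).sum() == 5

    def test_newborn_cannot_give_birth_same_tick(self, benign_ecology):
        eng = _solo_mother_engine(benign_ecology)
        eng.arena.pending[0] += 1100.0
        eng.step()           # tick 0: founders never reproduce at age 0
        assert eng.rec.n == 1
        eng.arena.pending[0] += 1100.0
        eng.step()           # tick 1: one birth; the 100-unit newborn would
        assert eng.rec.n == 2  # itself qualify, but not in its birth tick


class TestRunContract:
    def test_duration_zero_keeps_only_founders(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, duration=0)
        h = Engine(cfg).run()
        assert len(h.records["birth"]) == cfg.initial_population
        assert (h.records["death"] == -1).all()

    def test_seeded_bit_reproducibility(self, small_config):
        h1 = Engine(small_config).run()
        h2 = Engine(small_config).run()
        for k in h1.records:
            np.testing.assert_array_equal(h1.records[k], h2.records[k])
        np.testing.assert_array_equal(h1.pop_size, h2.pop_size)

    def test_zero_pool_leads_to_extinction(self, small_config):
        import dataclasses

        eco = dataclasses.replace(small_config.ecological, resource_pool=0.0)
        cfg = dataclasses.replace(small_config, ecological=eco, duration=400)
        h = Engine(cfg).run()
        assert h.extinct
        assert h.pop_size[-1] == 0

    def test_grandmothering_ablation_zeroes_care_to_reproduced_children(self):
        import dataclasses

        for enabled in (True, False):
            fx = make_fixture("grandmother_triplet")
            eng = fx.engine
            eng.config = dataclasses.replace(eng.config,
                                             grandmothering_enabled=enabled)
            eng.rngs = _stub_streams([0.0])
            eng.arena.pending[fx.rows["grandmother"]] = 50.0
            eng.arena.pending[fx.rows["child"]] = 50.0
            eng.arena.pending[fx.rows["grandchild"]] = 50.0
            eng.step()
            care0 = eng._alloc[fx.rows["grandmother"], nc.OUT_CARE][0]
            if enabled:
                assert care0 > 0
            else:
                assert care0 == 0.0
                # remaining fractions renormalized
                assert eng._alloc[fx.rows["grandmother"]].sum() == \
                    pytest.approx(1.0)


def _toy_history(records, ticks_run=100):
    n = len(records["birth"])
    base = {
        "mother_uid": np.full(n, -1, dtype=np.int64),
        "condition": np.zeros(n, dtype=np.int8),
        "gen": np.full(n, -1, dtype=np.int16),
        "forced_birth": np.zeros(n, dtype=bool),
        "whash": np.zeros(n, dtype=np.uint32),
        "first_repro": np.full(n, -1, dtype=np.int32),
        "n_repro": np.zeros(n, dtype=np.int32),
    }
    base.update({k: np.asarray(v) for k, v in records.items()})
    return PopulationHistory(
        records=base, pop_size=np.zeros(ticks_run, dtype=np.int64),
        births_per_tick=np.zeros(ticks_run, dtype=np.int64),
        deaths_per_tick=np.zeros(ticks_run, dtype=np.int64),
        duration=ticks_run, ticks_run=ticks_run, extinct=False, config={})


class TestMeasurePRLS:
    def test_interval_between_last_birth_and_death(self):
        h = _toy_history({
            "birth": [10, 12, 20, 30],
            "death": [47, 40, -1, 90],     # third alive, excluded
            "last_repro": [28, 40, 25, 60],
            "n_repro": [2, 1, 1, 3],
        })
        res = measure_prls(h, window=100)
        # eligible: 47-28=19, 40-40=0 (death on last birth), 90-60=30;
        # the alive-at-end individual is excluded
        assert res.n == 3
        assert res.mean == pytest.approx((19 + 0 + 30) / 3)
        assert not res.undefined

    def test_nonreproducers_are_excluded_and_counted(self):
        h = _toy_history({
            "birth": [10, 12], "death": [30, 35],
            "last_repro": [-1, 20], "n_repro": [0, 1],
        })
        res = measure_prls(h, window=100)
        assert (res.n, res.n_nonreproducing) == (1, 1)
        assert res.mean == pytest.approx(15.0)

    def test_window_excludes_earlier_births(self):
        h = _toy_history({
            "birth": [10, 60], "death": [80, 90],
            "last_repro": [70, 80], "n_repro": [1, 1],
        })
        res = measure_prls(h, window=50)
        assert res.n == 1
        assert res.mean == pytest.approx(10.0)

    def test_empty_cohort_is_undefined_not_zero(self):
        h = _toy_history({"birth": [], "death": [], "last_repro": [],
                          "n_repro": []})
        res = measure_prls(h, window=50)
        assert res.undefined
        assert np.isnan(res.mean)


class TestMeasureDemographics:
    def test_group_metrics(self):
        h = _toy_history({
            "birth": [0, 0, 0, 0], "death": [10, 20, 30, 40],
            "last_repro": [5, -1, 25, -1], "n_repro": [2, 0, 3, 1],
            "gen": np.array([0, 0, 0, 0], dtype=np.int16),
            "condition": np.array([0, 0, 0, 0], dtype=np.int8),
        })
        df = measure_demographics(h)
        row = df.iloc[0]
        assert row["n"] == 4
        assert row["fertility_mean"] == pytest.approx(1.5)
        assert row["survival_to_repro"] == pytest.approx(0.75)
        assert row["lifespan_mean"] == pytest.approx(25.0)

    def test_mean_fertility_example(self):
        h = _toy_history({
            "birth": [0, 0, 0], "death": [9, 9, 9],
            "last_repro": [5, 5, 5], "n_repro": [2, 3, 1],
        })
        df = measure_demographics(h, by=("condition",))
        assert df.iloc[0]["fertility_mean"] == pytest.approx(2.0)

    def test_empty_history_yields_empty_frame(self):
        h = _toy_history({"birth": [], "death": [], "last_repro": [],
                          "n_repro": []})
        assert measure_demographics(h).empty
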