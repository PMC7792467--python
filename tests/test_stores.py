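"""Working-memory store dynamics: growth, decay, capacity, maintenance."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from wmdec.knowledge import load_dltm
from wmdec.params import (ModelParameters, grow, decay, gauss_duration,
                          rehearsal_duration, revival_duration)
from wmdec.stores import (EpisodicBuffer, EpisodicLTM, ExecutiveMemory,
                          PhonologicalLoop, RecallProcess, RefreshProcess,
                          TaskAction, VisuospatialMemory, enforce_capacity)


class TestGrowDecay:
    def test_growth_closed_form(self):
        assert grow(0.25, 0.02) == pytest.approx(0.265)
        assert grow(0.0, 0.001) == pytest.approx(0.001)

    def test_growth_fixed_point_at_one(self):
        assert grow(1.0, 0.02) == 1.0

    def test_decay_closed_form(self):
        assert decay(0.8, 0.75) == pytest.approx(0.6)
        assert decay(0.0, 0.989) == 0.0

    def test_hundred_cycles_of_phonological_decay(self):
        a = 1.0
        for _ in range(100):
            a = decay(a, 0.989)
        assert a == pytest.approx(0.989 ** 100)
        assert a == pytest.approx(0.3313, abs=5e-4)

    @given(a=st.floats(0, 1), steps=st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_activation_stays_in_unit_interval(self, a, steps):
        r = random.Random(steps)
        for _ in range(steps):
            op = r.choice(["g", "d"])
            a = grow(a, 0.02) if op == "g" else decay(a, 0.95)
            assert 0.0 <= a <= 1.0


class TestDurations:
    def test_gaussian_duration_rounds_and_floors(self, rng):
        assert gauss_duration(rng, 20.0, 0.0) == 20
        assert gauss_duration(rng, -5.0, 0.0) == 1

    def test_rehearsal_duration_formula(self, rng):
        # d = 0.9 sqrt(n) t_s at r = 0
        class Zero(random.Random):
            def gauss(self, a, b):
                return 0.0
        z = Zero()
        assert rehearsal_duration(z, 1, 50) == 45
        assert rehearsal_duration(z, 4, 50) == 90

    def test_revival_duration_formula(self):
        class Zero(random.Random):
            def gauss(self, a, b):
                return 0.0
        assert revival_duration(Zero()) == 25


class TestCapacity:
    def _run(self, acts, protected, C):
        vals = list(acts)

        def setter(i, v):
            vals[i] = v
        enforce_capacity(list(acts), protected, C, setter)
        return vals

    def test_current_episode_items_rescaled_in_step_two(self):
        vals = self._run([1.0, 1.0, 1.0], [True] * 3, 2.9)
        assert vals == pytest.approx([2.9 / 3] * 3)
        assert sum(vals) == pytest.approx(2.9)

    def test_under_capacity_unchanged(self):
        vals = self._run([1.0, 1.5], [True, True], 2.9)
        assert vals == [1.0, 1.5]

    def test_old_item_pays_first_then_everyone(self):
        # one old item plus two current ones, hand-worked two-step case
        vals = self._run([1.0, 1.0, 1.0], [False, True, True], 2.9)
        f1 = 2.9 / 3.0
        step1 = [f1, 1.0, 1.0]
        f2 = 2.9 / sum(step1)
        assert vals == pytest.approx([x * f2 for x in step1])
        assert sum(vals) == pytest.approx(2.9)

    @given(acts=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12),
           flags=st.lists(st.booleans(), min_size=12, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_post_sum_never_exceeds_capacity(self, acts, flags):
        C = 2.9
        vals = self._run(acts, flags[:len(acts)], C)
        assert sum(vals) <= C + 1e-9
        if sum(acts) > C:
            assert sum(vals) == pytest.approx(C, abs=1e-6)


class TestEpisodicBuffer:
    def _eb(self, params, small_dltm):
        return EpisodicBuffer(params, small_dltm)

    def test_new_instance_starts_at_phi(self, params, small_dltm, rng):
        eb = self._eb(params, small_dltm)
        inst = eb.begin_instance("D9", "OBJECT", None, 0, 0, rng)
        assert inst.activation == pytest.approx(params.phi)
        assert inst.pending

    def test_creation_duration_near_twenty_cycles(self, params, small_dltm):
        durations = []
        for seed in range(200):
            eb = self._eb(params, small_dltm)
            r = random.Random(seed)
            inst = eb.begin_instance("D9", "OBJECT", None, 0, 0, r)
            durations.append(inst.complete_cycle)
        mean = sum(durations) / len(durations)
        assert 18 < mean < 22          # d = 20 + 4r

    def test_unknown_name_rejected(self, params, small_dltm, rng):
        eb = self._eb(params, small_dltm)
        with pytest.raises(KeyError):
            eb.begin_instance("GHOST", "OBJECT", None, 0, 0, rng)

    def test_opposed_pending_instances_inhibit_each_other(self, params,
                                                          small_dltm, rng):
        eb = self._eb(params, small_dltm)
        a = eb.begin_instance("SMALL", "CLASS", None, 0, 0, rng)
        b = eb.begin_instance("LARGE", "CLASS", None, 0, 0, rng)
        a.activation = b.activation = 0.5
        eb.step_pending(1)
        expected = grow(0.5, params.alpha) * params.beta
        assert a.activation == pytest.approx(expected)
        assert b.activation == pytest.approx(expected)

    def test_access_rule_open_above_half(self, params, small_dltm, rng):
        eb = self._eb(params, small_dltm)
        inst = eb.begin_instance("D9", "OBJECT", None, 0, 0, rng)
        inst.pending = False
        inst.activation = 0.6
        for r in (0.01, 0.5, 0.99):
            eb.set_access(r)
            assert inst.access

    def test_access_step_function_below_half(self, params, small_dltm, rng):
        eb = self._eb(params, small_dltm)
        inst = eb.begin_instance("D9", "OBJECT", None, 0, 0, rng)
        inst.pending = False
        inst.activation = 0.2
        eb.set_access(0.3)      # 0.2 >= 0.15 -> OPEN
        assert inst.access
        eb.set_access(0.9)      # 0.2 < 0.45 -> CLOSED
        assert not inst.access

    def test_chunk_formation_inhibits_components(self, params, small_dltm,
                                                 rng):
        eb = self._eb(params, small_dltm)
        items = []
        for name in ("D9", "D2"):
            i = eb.begin_instance(name, "OBJECT", None, 0, 0, rng,
                                  mark="TBR")
            i.pending = False
            i.activation = 0.8
            items.append(i)
        chunk = eb.form_chunk(items, 0, 10, rng)
        assert chunk.mark == "TBR" and chunk.type == "CHUNK"
        assert len(chunk.components) == 2
        for i in items:
            assert i.activation == pytest.approx(0.8 * params.tau)
            assert i.mark == "OFF"

    def test_chunk_needs_two_components(self, params, small_dltm, rng):
        eb = self._eb(params, small_dltm)
        i = eb.begin_instance("D9", "OBJECT", None, 0, 0, rng, mark="TBR")
        with pytest.raises(ValueError):
            eb.form_chunk([i], 0, 0, rng)


class TestPhonologicalLoop:
    def test_loop_is_circular(self, params):
        pl = PhonologicalLoop(params)
        a = pl.insert("WA")
        assert a.next is a                      # singleton points to itself
        b = pl.insert("WB")
        c = pl.insert("WC")
        assert a.next is b and b.next is c and c.next is a

    def test_loop_integrity_under_random_edits(self, params, rng):
        pl = PhonologicalLoop(params)
        names = iter(f"T{i}" for i in range(1000))
        for _ in range(300):
            if pl.traces and rng.random() < 0.4:
                pl.remove(rng.choice(pl.traces))
            else:
                pl.insert(next(names))
            if pl.traces:
                seen, t = [], pl.traces[0]
                for _ in range(len(pl.traces)):
                    seen.append(t)
                    t = t.next
                assert t is pl.traces[0]
                assert len(set(map(id, seen))) == len(pl.traces)

    def test_decay_only_trace_matches_closed_form(self, params):
        pl = PhonologicalLoop(params)
        t = pl.insert("WA")
        for n in range(1, 10_001):
            pl.decay_step()
            assert t.activation == pytest.approx(params.delta ** n,
                                                 rel=1e-12)

    def test_pl_access_threshold(self, params):
        pl = PhonologicalLoop(params)
        t = pl.insert("WA")
        t.activation = 0.37     # above max of (0.6 r)^2 = 0.36
        for r in (0.1, 0.5, 1.0):
            pl.set_access(r)
            assert t.access
        t.activation = 0.1
        pl.set_access(1.0)      # threshold 0.36
        assert not t.access

    def test_rehearsal_keeps_trace_above_decay_only(self, params, rng):
        from wmdec.stores import RehearseProcess
        pl = PhonologicalLoop(params)
        t = pl.insert("WA", syllables=1)
        reh = RehearseProcess(params)
        reh.enabled = True
        passive = 1.0
        floor_ok = True
        for cyc in range(1500):
            pl.decay_step()
            passive = decay(passive, params.delta)
            reh.step(pl, cyc, rng)
            if cyc > 200 and t.activation <= passive:
                floor_ok = False
        assert floor_ok
        # steady-state band for a 1-syllable item: acts every ~45 cycles,
        # fixed point around 0.13-0.25, far above the decayed-out trace
        assert t.activation > 0.1 > passive


class TestVisuospatial:
    def test_one_trace_per_cell(self, params):
        vsm = VisuospatialMemory(params)
        vsm.insert("X", (1, 1))
        with pytest.raises(ValueError):
            vsm.insert("Y", (1, 1))

    def test_decay_rate(self, params):
        vsm = VisuospatialMemory(params)
        t = vsm.insert("X", (2, 2))
        vsm.decay_step()
        assert t.activation == pytest.approx(params.sigma)


class TestRefreshment:
    def _eb_with_tbr(self, params, small_dltm, rng, stamps):
        eb = EpisodicBuffer(params, small_dltm)
        out = []
        for k, ts in enumerate(stamps):
            i = eb.begin_instance(["D9", "D2", "CMAG"][k % 3], "OBJECT",
                                  None, 0, 0, rng, mark="TBR")
            i.pending = False
            i.timestamp = ts
            i.activation = 0.25
            out.append(i)
        return eb, out

    def test_no_tbr_traces_means_no_refresh(self, params, small_dltm, rng):
        eb = EpisodicBuffer(params, small_dltm)
        rf = RefreshProcess(params)
        rf.enabled = True
        assert rf.step(eb, 0) is None

    def test_rotation_is_oldest_first_round_robin(self, params, small_dltm,
                                                  rng):
        eb, items = self._eb_with_tbr(params, small_dltm, rng, [10, 20, 30])
        rf = RefreshProcess(params)
        rf.enabled = True
        visited = []
        for cyc in range(30):
            t = rf.step(eb, cyc)
            if t is not None and (not visited or visited[-1] is not t):
                visited.append(t)
        stamps = [t.timestamp for t in visited]
        assert stamps[:3] == [10, 20, 30]
        assert stamps[3] == 10      # wraps around

    def test_refresh_act_applies_one_growth_increment(self, params,
                                                      small_dltm, rng):
        eb, (item,) = self._eb_with_tbr(params, small_dltm, rng, [5])
        rf = RefreshProcess(params)
        rf.enabled = True
        a0 = item.activation
        for cyc in range(params.refresh_dwell):
            rf.step(eb, cyc)
        assert item.activation == pytest.approx(grow(a0, params.alpha))

    def test_worked_trajectory_band(self, params, small_dltm, rng):
        # solo refreshment from 0.25 reaches 0.50-0.62 after 67 cycles
        eb, (item,) = self._eb_with_tbr(params, small_dltm, rng, [5])
        rf = RefreshProcess(params)
        rf.enabled = True
        for cyc in range(67):
            rf.step(eb, cyc)
        assert 0.50 <= item.activation <= 0.62

    def test_hold_suspends_refreshment(self, params, small_dltm, rng):
        eb, (item,) = self._eb_with_tbr(params, small_dltm, rng, [5])
        rf = RefreshProcess(params)
        rf.enabled = True
        rf.hold = True
        for cyc in range(30):
            assert rf.step(eb, cyc) is None
        assert item.activation == 0.25


class TestConsolidation:
    def test_first_consolidation_cycle(self, params):
        eltm = EpisodicLTM(params)
        t = eltm.consolidate("WZ", 0, 100)
        assert t.strength == pytest.approx(0.001)

    def test_saturating_growth(self, params):
        eltm = EpisodicLTM(params)
        for _ in range(161):
            eltm.consolidate("WZ", 0, 0)
        # matches the narrated ~0.15 after ~160 refreshed cycles
        assert eltm.get("WZ", 0).strength == pytest.approx(
            1 - 0.999 ** 161, rel=1e-9)
        assert 0.12 < eltm.get("WZ", 0).strength < 0.18

    def test_step_retrieval_rule(self, params):
        eltm = EpisodicLTM(params)
        for _ in range(300):
            eltm.consolidate("WZ", 0, 0)
        s = eltm.get("WZ", 0).strength
        assert eltm.retrieve("WZ", 0, s / 0.5 - 1e-9)
        assert not eltm.retrieve("WZ", 0, s / 0.5 + 1e-3)
        assert not eltm.retrieve("GHOST", 0, 0.0)


class TestExecutiveMemory:
    def test_dominant_requires_access(self, params, rng):
        em = ExecutiveMemory(params)
        ts = em.instantiate("MAGTS", 0, rng)
        ts.pending = False
        ts.activation = 0.9
        ts.access = False
        assert em.dominant() is None
        ts.access = True
        assert em.dominant() is ts

    def test_capacity_counts_components(self, params, rng):
        em = ExecutiveMemory(params)
        ts = em.instantiate("MEMTS", 0, rng,
                            defaults={f"K{i}": i for i in range(6)})
        ts.pending = False
        assert em.total_activation() == pytest.approx(
            ts.activation + 6 * ExecutiveMemory.COMPONENT_LOAD)

    def test_demotion_clears_dominance(self, params, rng):
        em = ExecutiveMemory(params)
        ts = em.instantiate("MAGTS", 0, rng)
        ts.pending = False
        ts.access = True
        a0 = ts.activation
        em.demote(ts)
        assert ts.mode == "DEMOTED"
        assert ts.activation == pytest.approx(a0 * params.tau)
        assert em.dominant() is None


class TestRecall:
    def _setup(self, params, small_dltm, rng, names, access=True):
        eb = EpisodicBuffer(params, small_dltm)
        for k, n in enumerate(names):
            i = eb.begin_instance(n, "OBJECT", None, k, 0, rng, mark="TBR")
            i.pending = False
            i.timestamp = k * 100
            i.activation = 0.9
            i.access = access
        act = TaskAction(name="RETRIEVE", status="ON")
        return eb, RecallProcess(params, act)

    def test_recall_in_presentation_order(self, params, small_dltm, rng):
        eb, rec = self._setup(params, small_dltm, rng, ["D9", "D2", "CMAG"])
        eltm = EpisodicLTM(params)
        pl, vsm = PhonologicalLoop(params), VisuospatialMemory(params)
        for cyc in range(600):
            eb.set_access(0.0)
            rec.step(eb, pl, vsm, eltm, cyc, rng)
            if rec.action.status == "DONE":
                break
        assert rec.recalled_sequence() == ["D9", "D2", "CMAG"]
        assert rec.action.status == "DONE"

    def test_empty_tbr_set_finishes_immediately(self, params, small_dltm,
                                                rng):
        eb = EpisodicBuffer(params, small_dltm)
        rec = RecallProcess(params, TaskAction(name="RETRIEVE", status="ON"))
        rec.step(eb, None, None, EpisodicLTM(params), 0, rng)
        assert rec.action.status == "DONE"

    def test_inaccessible_item_skipped_after_three_failures(self, params,
                                                            small_dltm, rng):
        eb, rec = self._setup(params, small_dltm, rng, ["D9", "D2"])
        first = eb.instances[0]
        first.activation = 0.0      # never accessible; rejection inhibits it
        eltm = EpisodicLTM(params)
        for cyc in range(800):
            for i in eb.instances:
                i.access = i.activation > 0.5
            rec.step(eb, None, None, eltm, cyc, rng)
            if rec.action.status == "DONE":
                break
        assert rec.failures == ["D9"]
        assert rec.recalled_sequence() == ["D2"]
        assert first.recall_status == "FAILED"
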