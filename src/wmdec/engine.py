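"""The procedural loop: one 10-ms cycle executing twelve ordered steps.

Parallel operation of the memory modules is emulated by partitioning time
into 10-ms slices; everything inside a slice counts as simultaneous, and a
fixed within-cycle order prevents information leaking between slices:

 1. stage a ready response;
 2. sensory/phonological/visual decay, capacity checks in EB and EM;
 3. a rehearsal step;  4. a revival step;
 5. consolidation of the currently refreshed trace;
 6. response-tendency increments (random walk);
 7. access flags in every store;  8. fixation and focus;
 9. sensory update from the environment;
10. episodic-buffer flag sync (EXT -> INT when the source is gone);
11. match all non-active production rules, select one for execution;
12. deliver a staged response to the environment.

Rule actions are scheduled: a duration-d rule selected at cycle c completes
(and takes effect) at c + d - 1; an action whose object is busy to another
rule waits in a FIFO queue for that object and then runs its full duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

from . import knowledge
from .knowledge import (LearningConfig, ProductionRule, compile_condition,
                        evaluate_condition, select_rule,
                        update_rule_strength, create_association_rule)
from .params import ModelParameters, gauss_duration
from .perception import (EchoicSlot, GazeState, IconicStore, MotorState,
                         adjust_threshold, raise_feedback,
                         step_response_competition, update_gaze)
from .stores import (EpisodicBuffer, EpisodicLTM, ExecutiveMemory,
                     PhonologicalLoop, RecallProcess, RefreshProcess,
                     RehearseProcess, ReviveProcess, TaskAction,
                     VisuospatialMemory)

RNG_STREAMS = ("durations", "access", "gaze", "motor", "drift", "rules",
               "recall", "misc")


@dataclass
class TaskSchema:
    """Instruction-level description of one task (available via tskinstr)."""

    name: str                       # task-set name, e.g. MAGTS
    goal: str = ""                  # e.g. MAG
    cue: str = ""                   # e.g. CMAG
    modality: str = "MANUAL"        # response modality
    category_class: str = ""        # e.g. MAGCAT
    classify_by: str = "prop"       # "prop" or "location"
    object_class: str = ""          # restrict to a stimulus class; "@DIM"
                                    # resolves through the DIM parameter
    mappings: dict = field(default_factory=dict)   # category -> response
    defaults: dict = field(default_factory=dict)   # task-set parameters
    memory: bool = False


@dataclass
class ActiveExecution:
    rule: ProductionRule
    bindings: dict
    lock: tuple | None
    start: int
    completion: int


class ConfigurationError(RuntimeError):
    pass


def _lock_for(action, bindings):
    """The busy-lock key an action claims, or None for unlocked actions."""
    fn = action.function
    if fn in ("mkinst", "mkgoal", "mkmemo"):
        name = bindings.get(action.args[0], action.args[0])
        return ("eb", name)
    if fn in ("execute", "do", "unblock", "motorinit"):
        return ("motor",)
    if fn in ("loadts", "demts", "boostts", "addmaps", "setpar", "loadact"):
        name = bindings.get(action.args[0], action.args[0])
        return ("ts", name)
    if fn.startswith("learn") or fn in ("inhibitresponse", "clearfeedback",
                                        "disband"):
        return ("learn",)
    return None


class Engine:
    """Complete system state plus the per-cycle procedural loop."""

    def __init__(self, dltm, rules, params: ModelParameters, schemas,
                 seed: int, env, log_events=False):
        self.dltm = dltm
        self.rules: list[ProductionRule] = list(rules)
        self.params = params
        self.schemas: dict[str, TaskSchema] = dict(schemas)
        self.env = env
        self.log_events = log_events
        self.log: list[tuple] = []

        base = Random(seed)
        self.rng = {name: Random(base.randrange(1 << 30))
                    for name in RNG_STREAMS}

        self.cycle = 0
        self.episode = 0
        self.ism = IconicStore()
        self.esm = EchoicSlot()
        self.eb = EpisodicBuffer(params, dltm)
        self.pl = PhonologicalLoop(params)
        self.vsm = VisuospatialMemory(params)
        self.em = ExecutiveMemory(params)
        self.eltm = EpisodicLTM(params)
        self.gaze = GazeState()
        self.motor = MotorState(threshold=params.theta)
        self.refresh = RefreshProcess(params)
        self.rehearse = RehearseProcess(params)
        self.revive = ReviveProcess(params)
        self.recall: RecallProcess | None = None
        self.internal_events: list = []
        self.staged_response = None
        self.active: list[ActiveExecution] = []
        self.queued: list[ActiveExecution] = []
        self.locks: dict[tuple, ActiveExecution] = {}
        self.learn_stage = 0
        self.learn_cfg = LearningConfig(eta=params.eta,
                                        new_rule_strength=params.new_rule_strength,
                                        new_rule_duration=params.new_rule_duration)
        self.selected_this_episode: list[ProductionRule] = []
        self.trial_target: str | None = None
        self.refreshed_trace = None
        self.list_ended = False       # presentation phase over (chunking)
        self._registry = dict(PREDICATES)
        self._actions = dict(ACTIONS)
        self._area = self.gaze.fixated_area()
        self._cycle_cache: dict = {}

    # -- logging -----------------------------------------------------------

    def emit(self, module, event, details=""):
        if self.log_events:
            self.log.append((self.cycle, module, event, details))

    def trace_text(self):
        return "\n".join(f"{c}\t{m}\t{e}\t{d}" for (c, m, e, d) in self.log)

    # -- schema helpers ----------------------------------------------------

    def schema_for_ts(self, ts_name):
        return self.schemas.get(ts_name)

    def schema_for_goal(self, goal):
        for s in self.schemas.values():
            if s.goal == goal:
                return s
        return None

    # -- the twelve steps --------------------------------------------------

    def run_cycle(self):
        self.cycle += 1
        c = self.cycle
        p = self.params

        # 1. stage a ready response
        if self.motor.emitted is not None and self.staged_response is None:
            self.staged_response = self.motor.emitted
            self.motor.emitted = None

        # 2. decay + growth + capacity enforcement
        self.ism.step()
        self.esm.step()
        self.pl.decay_step()
        self.vsm.decay_step()
        self.eb.step_pending(c)
        self.em.step_pending(c, opposed=self.dltm.opposites)
        self.eb.enforce_capacity(self.episode)
        self.em.enforce_capacity()
        self.eb.prune()
        self.em.prune()

        # 3./4. rehearsal and revival steps
        self.rehearse.step(self.pl, c, self.rng["recall"])
        self.revive.step(self.vsm, c, self.rng["recall"])
        self.refreshed_trace = self.refresh.step(self.eb, c)

        # 5. consolidation of the refreshed trace
        if self.refreshed_trace is not None:
            t = self.refreshed_trace
            trace = self.eltm.consolidate(t.name, t.episode, c,
                                          location=t.location)
            t.eltm_link = trace

        # retrieval stepping (rule-initiated action; paced here so recall
        # progresses once per cycle like the other store processes)
        if self.recall is not None:
            self.recall.episode = self.episode
            self.recall.step(self.eb, self.pl, self.vsm, self.eltm, c,
                             self.rng["recall"],
                             maintenance_mode=self._maintenance_mode())

        # 6. response tendencies (random walk); paused while an emission
        # is still in flight to the environment
        if self.motor.emitted is None and self.staged_response is None:
            step_response_competition(self.motor, p, self.rng["drift"], c)

        # 7. access flags (one fresh uniform draw per store)
        r = self.rng["access"]
        self.eb.set_access(r.random())
        self.pl.set_access(r.random())
        self.vsm.set_access(r.random())
        self.em.set_access(r.random())

        # 8. fixation and focus
        update_gaze(self.gaze, self.ism, self.rng["gaze"], c)
        self._area = self.gaze.fixated_area()
        self._cycle_cache.clear()

        # 9. sensory update from the environment
        self._sensory_update(c)

        # 10. EB flag sync
        self.eb.sync_flags(lambda name: not self.ism.present(name)
                           and self.esm.name != name)

        # 11. rule completion, matching and selection
        self._finish_executions(c)
        self._match_and_select(c)

        # 12. deliver a staged response
        if self.staged_response is not None:
            self._deliver_response(c)

        self._expire_internal_events(c)
        return self

    def run_until(self, stop=None, max_cycles=10000):
        """Run cycles until `stop(engine)` is true or `max_cycles` elapse.

        Returns (engine, timed_out).
        """
        start = self.cycle
        while self.cycle - start < max_cycles:
            self.run_cycle()
            if stop is not None and stop(self):
                return self, False
        if stop is not None:
            self.emit("engine", "timeout", f"after {max_cycles} cycles")
            return self, True
        return self, False

    # -- internals ---------------------------------------------------------

    def _maintenance_mode(self):
        ts = self.em.get("MEMTS")
        if ts is None:
            return "RF"
        return ts.get_parameter("MAINT", "RF")

    def _sensory_update(self, c):
        saccading = self.gaze.status == "SACCADE"
        for e in self.env.deliverable(c):
            if e.modality == "AUD":
                self.esm.put(e.name)
                e.registered = True
            elif not saccading:
                self.ism.put(e.name, e.position, e.colour)
                e.registered = True
        for e in self.env.expired(c):
            if e.modality == "AUD":
                self.esm.end_stream()
            elif e.position is not None:
                self.ism.clear(e.position)
            e.cleared = True
        self.env.gc(c)

    def _finish_executions(self, c):
        done = [ae for ae in self.active if ae.completion <= c]
        self._just_finished = {ae.rule for ae in done}
        for ae in done:
            self.active.remove(ae)
            if ae.lock is not None and self.locks.get(ae.lock) is ae:
                del self.locks[ae.lock]
            self._run_action(ae)
        # queued executions start the cycle after their lock frees and then
        # run their full duration
        still = []
        for ae in self.queued:
            if ae.lock not in self.locks:
                self.locks[ae.lock] = ae
                ae.start = c + 1
                ae.completion = c + ae.rule.duration
                self.active.append(ae)
            else:
                still.append(ae)
        self.queued = still

    def _match_and_select(self, c):
        active_rules = {ae.rule for ae in self.active}
        active_rules.update(ae.rule for ae in self.queued)
        active_rules.update(getattr(self, "_just_finished", ()))
        # cheap gates: most rules key on new sensory input, trial feedback
        # or (for learned associations) an accessible stimulus
        has_new = (bool(self.ism.new_items(self._area))
                   or self.esm.flag in ("NEW", "CHANGE"))
        learning = self.learn_stage > 0 or self.feedback_event() is not None
        has_obj = any(i.type == "OBJECT" and i.access and not i.pending
                      and i.mark == "ON" for i in self.eb.instances)
        matches = []
        for rule in self.rules:
            if rule in active_rules:
                continue
            first = rule.condition[0].function
            if not has_new and first in ("newcnt", "isnew"):
                continue
            if not learning and first in ("feedback", "learnstage"):
                continue
            if not has_obj and rule.name.startswith("assoc-"):
                continue
            ev = rule.__dict__.get("_eval")
            if ev is None:
                ev = compile_condition(rule, self._registry)
                rule.__dict__["_eval"] = ev
            bindings = ev(self)
            if bindings is not None:
                matches.append((rule, bindings))
        chosen = select_rule(matches, active_rules, self.rng["rules"])
        if chosen is None:
            return
        rule, bindings = chosen
        self.selected_this_episode.append(rule)
        lock = _lock_for(rule.action, bindings)
        ae = ActiveExecution(rule=rule, bindings=bindings, lock=lock,
                             start=c, completion=c + rule.duration - 1)
        if lock is not None and lock in self.locks:
            self.queued.append(ae)      # FIFO wait for the busy object
            self.emit("engine", "queued", rule.name)
        else:
            if lock is not None:
                self.locks[lock] = ae
            self.active.append(ae)
            self.emit("engine", "select", rule.name)

    def _run_action(self, ae: ActiveExecution):
        fn = self._actions.get(ae.rule.action.function)
        if fn is None:
            raise ConfigurationError(
                f"rule {ae.rule.name}: action {ae.rule.action.function!r} "
                "is not registered")
        args = [ae.bindings.get(a, a) for a in ae.rule.action.args]
        fn(self, *args)

    def _deliver_response(self, c):
        response = self.staged_response
        self.staged_response = None
        intent = self.motor.get_stream("intentional")
        intended = intent.response if intent is not None else None
        self.motor.status = "DONE"
        self.emit("motor", "response", response)
        record = self.env.on_response(response, c)
        fb = raise_feedback(response, intended, c)
        self.internal_events.append(fb)
        adjust_threshold(self.motor, fb.evaluation, self.params)
        if record is not None:
            record.condition.setdefault("evaluation", fb.evaluation)

    def _expire_internal_events(self, c):
        self.internal_events = [e for e in self.internal_events
                                if e.in_use and e.end >= c]

    # -- trial housekeeping (driven by the learn rules or the runner) ------

    def end_trial(self, purge_memory=False):
        """Advance the episode and discard trial-local traces."""
        transient = {"OBJECT", "CLASS", "RESPONSE", "BIND", "CUE"}
        if purge_memory:
            transient = transient | {"CHUNK"}
        for inst in self.eb.instances:
            if inst.type in transient and inst.mark != "TBR":
                inst.flag = "DONE"
                inst.mark = "OFF"
            elif purge_memory and inst.mark in ("TBR", "OFF"):
                inst.flag = "DONE"
                inst.mark = "OFF"
        self.motor.clear()
        self.motor.modality = "NONE"
        self.motor.status = "BLOCKED"
        self.internal_events = []
        self.learn_stage = 0
        self.selected_this_episode = []
        self.trial_target = None
        self.list_ended = False
        if purge_memory:
            self.refresh.enabled = False
            self.refresh.current = None
            self.refresh.last_timestamp = -1
            self.recall = None
            ts = self.em.get("MEMTS")
            if ts is not None:
                ts.actions.clear()
                ts.set_parameter("MAINT", "NORF")
                ts.set_parameter("RECALL", "OFF")
        self.episode += 1

    def feedback_event(self):
        for e in self.internal_events:
            if e.name == "FEEDBACK" and e.in_use:
                return e
        return None


# ---------------------------------------------------------------------------
# Predicate vocabulary
# ---------------------------------------------------------------------------

PREDICATES: dict = {}
ACTIONS: dict = {}


def predicate(name):
    def deco(fn):
        PREDICATES[name] = fn
        return fn
    return deco


def action(name):
    def deco(fn):
        ACTIONS[name] = fn
        return fn
    return deco


def _wild(value):
    return value in ("ANY", "NOLOC", "0", None)


@predicate("newcnt")
def p_newcnt(e: Engine, store="ISM"):
    if store == "ESM":
        return 1 if e.esm.flag in ("NEW", "CHANGE") else 0
    return len(e.ism.new_items(e._area))


@predicate("isnew")
def p_isnew(e: Engine, store="ISM", category="ANY"):
    if store == "ESM":
        if e.esm.flag in ("NEW", "CHANGE"):
            if _wild(category) or e.dltm.is_a(e.esm.name, category):
                return e.esm.name
        return False
    for pos, cell in e.ism.new_items(e._area):
        if _wild(category) or e.dltm.is_a(cell.name, category):
            return cell.name
    return False


@predicate("ltmhas")
def p_ltmhas(e: Engine, name, prop):
    node = e.dltm.get(name)
    return node is not None and node.has_link("PROP", prop)


@predicate("ltmsup")
def p_ltmsup(e: Engine, name, category):
    node = e.dltm.get(name)
    return node is not None and node.has_link("SUP", category)


@predicate("ltmprop")
def p_ltmprop(e: Engine, name, of_class):
    return e.dltm.prop(name, of_class) or False


@predicate("ineb")
def p_ineb(e: Engine, name="ANY", type_="ANY", mark="ANY"):
    for i in e.eb.instances:
        if i.flag == "DONE" or i.mark == "OFF":
            continue
        if not _wild(name) and i.name != name:
            continue
        if not _wild(type_) and i.type != type_:
            continue
        if not _wild(mark) and i.mark != mark:
            continue
        return i.name
    return False


@predicate("ebacc")
def p_ebacc(e: Engine, name="ANY", type_="ANY", mark="ANY"):
    for i in e.eb.instances:
        if i.pending or not i.access or i.flag == "DONE" or i.mark == "OFF":
            continue
        if not _wild(name) and i.name != name:
            continue
        if not _wild(type_) and i.type != type_:
            continue
        if not _wild(mark) and i.mark != mark:
            continue
        return i.name
    return False


@predicate("ineb_other")
def p_ineb_other(e: Engine, name, type_):
    """A completed, still-active instance of `type_` with a different name."""
    for i in e.eb.instances:
        if i.pending or i.flag == "DONE" or i.mark == "OFF":
            continue
        if i.type == type_ and i.name != name:
            return i.name
    return False


@predicate("ineb_opp")
def p_ineb_opp(e: Engine, name, type_):
    """A still-active instance of `type_` opposed (OPP-linked) to `name`."""
    opps = set(e.dltm.opposites(name))
    if not opps:
        return False
    for i in e.eb.instances:
        if i.flag == "DONE" or i.mark == "OFF":
            continue
        if i.type == type_ and i.name in opps:
            return i.name
    return False


@predicate("objcolour")
def p_objcolour(e: Engine, name):
    for cell in e.ism.cells.values():
        if cell.name == name and cell.flag not in ("GONE", "EMPTY"):
            return cell.colour
    return False


@predicate("oldepisode")
def p_oldepisode(e: Engine, name):
    inst = e.eb.get(name)
    return inst is not None and not inst.pending \
        and inst.episode != e.episode


@predicate("recallheld")
def p_recallheld(e: Engine):
    return e.recall is not None and e.recall.action.status == "HOLD"


@predicate("lastrecall")
def p_lastrecall(e: Engine):
    if e.recall is None or not e.recall.outputs:
        return False
    return e.recall.outputs[-1][0]


@predicate("domts")
def p_domts(e: Engine):
    cache = e._cycle_cache
    if "domts" in cache:
        return cache["domts"]
    ts = e.em.dominant()
    result = ts.name if ts is not None else False
    cache["domts"] = result
    return result


@predicate("tsacc")
def p_tsacc(e: Engine, name):
    ts = e.em.get(name)
    return (ts is not None and ts.mode == "ACTIVE" and not ts.pending
            and ts.access)


@predicate("inem")
def p_inem(e: Engine, name):
    ts = e.em.get(name)
    return ts is not None and ts.mode == "ACTIVE"


@predicate("inem_opp")
def p_inem_opp(e: Engine, name):
    """An active task set opposed (OPP-linked in dLTM) to `name`."""
    for opp in e.dltm.opposites(name):
        ts = e.em.get(opp)
        if ts is not None and ts.mode == "ACTIVE" and not ts.pending:
            return opp
    return False


@predicate("tsloc")
def p_tsloc(e: Engine, name):
    schema = e.schema_for_ts(name)
    return schema is not None and schema.classify_by == "location"


@predicate("tshasmaps")
def p_tshasmaps(e: Engine, name):
    """True when the task set's full mapping list has been uploaded."""
    ts = e.em.get(name)
    if ts is None or not ts.mappings:
        return False
    schema = e.schema_for_ts(name)
    if schema is None:
        return bool(ts.mappings)
    return len(ts.mappings) >= len(schema.mappings)


@predicate("tspar")
def p_tspar(e: Engine, name, key):
    ts = e.em.get(name)
    if ts is None:
        return False
    return ts.get_parameter(key, False)


@predicate("hasact")
def p_hasact(e: Engine, name, act_name):
    ts = e.em.get(name)
    return ts is not None and act_name in ts.actions


@predicate("anytaskgoal")
def p_anytaskgoal(e: Engine):
    """Most recent task-set goal instance, accessible or not."""
    cache = e._cycle_cache
    if "anytaskgoal" in cache:
        return cache["anytaskgoal"]
    result = False
    for i in reversed(e.eb.instances):
        if (i.type == "GOAL" and not i.pending
                and i.flag != "DONE" and i.mark != "OFF"
                and e.dltm.prop(i.name, "TSKSET")):
            result = i.name
            break
    cache["anytaskgoal"] = result
    return result


@predicate("taskobj_loc")
def p_taskobj_loc(e: Engine, ts_name):
    """Like taskobj, but a still-forming object qualifies: its position is
    represented from the moment the trace is laid down."""
    required = _object_filter(e, ts_name)
    if required is None:
        return False
    for i in e.eb.instances:
        if (i.type == "OBJECT" and i.flag != "DONE" and i.mark == "ON"
                and i.location is not None):
            if not required or e.dltm.is_a(i.name, required):
                return i.name
    return False


@predicate("taskgoal")
def p_taskgoal(e: Engine):
    """Most recent accessible goal instance that names a regular task set."""
    cache = e._cycle_cache
    if "taskgoal" in cache:
        return cache["taskgoal"]
    result = False
    for i in reversed(e.eb.instances):
        if (i.type == "GOAL" and not i.pending and i.access
                and i.flag != "DONE" and i.mark != "OFF"
                and e.dltm.prop(i.name, "TSKSET")):
            result = i.name
            break
    cache["taskgoal"] = result
    return result


_DIM_CLASSES = {"DIGDIM": "DIGIT", "NUMDIM": "NUMWORD"}


def _object_filter(e: Engine, ts_name):
    schema = e.schema_for_ts(ts_name)
    if schema is None:
        return None
    required = schema.object_class
    if required == "@DIM":
        ts = e.em.get(ts_name)
        dim = ts.get_parameter("DIM") if ts is not None else None
        required = _DIM_CLASSES.get(dim)
        if required is None:
            return None
    return required or ""


@predicate("taskobj")
def p_taskobj(e: Engine, ts_name):
    """Accessible OBJECT instance the task set's stimulus filter accepts."""
    required = _object_filter(e, ts_name)
    if required is None:
        return False
    for i in e.eb.instances:
        if (i.type == "OBJECT" and not i.pending and i.access
                and i.flag != "DONE" and i.mark == "ON"):
            if not required or e.dltm.is_a(i.name, required):
                return i.name
    return False


@predicate("classof")
def p_classof(e: Engine, ts_name, obj_name):
    schema = e.schema_for_ts(ts_name)
    if schema is None or not schema.category_class:
        return False
    required = schema.object_class
    if required == "@DIM":
        ts = e.em.get(ts_name)
        dim = ts.get_parameter("DIM") if ts is not None else None
        required = _DIM_CLASSES.get(dim, "")
        if not required:
            return False
    if required and not e.dltm.is_a(obj_name, required):
        return False
    if schema.classify_by == "location":
        inst = e.eb.get(obj_name)
        if inst is None or inst.location is None:
            return False
        return "ABOVE" if inst.location[1] < 4 else "BELOW"
    return e.dltm.prop(obj_name, schema.category_class) or False


@predicate("mapof")
def p_mapof(e: Engine, ts_name, category):
    ts = e.em.get(ts_name)
    if ts is None:
        return False
    entry = ts.mappings.get(category)
    return entry[0] if entry is not None else False


@predicate("tskinstr")
def p_tskinstr(e: Engine, ts_name, key):
    schema = e.schema_for_ts(ts_name)
    if schema is None:
        return False
    if key == "GOAL":
        return schema.goal
    if key == "MODALITY":
        return schema.modality
    return schema.defaults.get(key, False)


@predicate("gamsget")
def p_gamsget(e: Engine, key="STATUS"):
    if key == "STATUS":
        return "NONE" if e.motor.modality == "NONE" else e.motor.status
    if key == "MODALITY":
        return e.motor.modality
    if key == "THRESHOLD":
        return e.motor.threshold
    return False


@predicate("motorstat")
def p_motorstat(e: Engine):
    return "NONE" if e.motor.modality == "NONE" else e.motor.status


@predicate("feedback")
def p_feedback(e: Engine, evaluation="ANY"):
    ev = e.feedback_event()
    if ev is None:
        return False
    if _wild(evaluation) or ev.evaluation == evaluation:
        return ev.evaluation
    return False


@predicate("learnstage")
def p_learnstage(e: Engine, k):
    return e.learn_stage == int(k)


@predicate("bindacc")
def p_bindacc(e: Engine):
    for i in e.eb.instances:
        if (i.type == "BIND" and not i.pending and i.access
                and i.flag != "DONE" and i.mark != "OFF"):
            return i.name
    return False


@predicate("bindhas")
def p_bindhas(e: Engine, type_):
    for i in e.eb.instances:
        if i.type == "BIND" and i.flag != "DONE" and i.mark != "OFF":
            return any(c.type == type_ for c in i.components)
    return False


@predicate("bindresp")
def p_bindresp(e: Engine):
    for i in e.eb.instances:
        if i.type == "BIND" and i.flag != "DONE" and i.mark != "OFF":
            for c in i.components:
                if c.type == "RESPONSE":
                    return c.name
    return False


@predicate("stream")
def p_stream(e: Engine, which):
    t = e.motor.get_stream(which)
    return t.response if t is not None else False


@predicate("objpresent")
def p_objpresent(e: Engine, category="TARGET"):
    for cell in e.ism.cells.values():
        if cell.flag in ("GONE", "EMPTY"):
            continue
        if e.dltm.is_a(cell.name, category):
            return cell.name
    return False


@predicate("coord")
def p_coord(e: Engine, name="DUAL"):
    for i in e.eb.instances:
        if i.type == "COORD" and (name == "ANY" or i.name == name) \
                and i.flag != "DONE":
            return i.name
    return False


@predicate("rfon")
def p_rfon(e: Engine):
    return e.refresh.enabled and not e.refresh.hold


@predicate("rfheld")
def p_rfheld(e: Engine):
    return e.refresh.enabled and e.refresh.hold


@predicate("anytbr")
def p_anytbr(e: Engine):
    return any(i.mark == "TBR" and not i.pending for i in e.eb.instances)


@predicate("taskopen")
def p_taskopen(e: Engine):
    rec = e.env.open_trial
    return rec is not None and rec.condition.get("kind") == "task"


@predicate("canchunk")
def p_canchunk(e: Engine):
    ts = e.em.get("MEMTS")
    if ts is None:
        return False
    L0 = int(ts.get_parameter("L0", 0) or 0)
    if L0 < 2:
        return False
    free = [i for i in e.eb.instances
            if i.mark == "TBR" and not i.pending and i.type != "CHUNK"]
    if len(free) >= L0:
        return True
    return e.list_ended and len(free) >= 2


@predicate("recallstat")
def p_recallstat(e: Engine, status):
    ts = e.em.get("MEMTS")
    if ts is None:
        return False
    act = ts.actions.get("RETRIEVE")
    return act is not None and act.status == status


# ---------------------------------------------------------------------------
# Action vocabulary
# ---------------------------------------------------------------------------

def _ism_location(e: Engine, name):
    for pos, cell in e.ism.cells.items():
        if cell.name == name and cell.flag not in ("GONE", "EMPTY"):
            return pos
    return None


@action("noop")
def a_noop(e: Engine, *args):
    pass


@action("mkinst")
def a_mkinst(e: Engine, name, type_="OBJECT", mark="ON"):
    loc = _ism_location(e, name)
    flag = "EXT" if (loc is not None or e.esm.name == name) else "INT"
    inst = e.eb.begin_instance(name, type_, loc, e.episode, e.cycle,
                               e.rng["durations"], mark=mark, flag=flag)
    if loc is not None:
        e.ism.seen(loc)
    if e.esm.name == name and e.esm.flag in ("NEW", "CHANGE"):
        e.esm.seen()
    if type_ == "OBJECT":
        e.trial_target = name
    e.emit("eb", "instance", f"{name}/{type_}")
    return inst


@action("mkgoal")
def a_mkgoal(e: Engine, name):
    inst = e.eb.begin_instance(name, "GOAL", None, e.episode, e.cycle,
                               e.rng["durations"], mark="ON", flag="INT")
    e.emit("eb", "goal", name)
    return inst


@action("mkmemo")
def a_mkmemo(e: Engine, name):
    loc = _ism_location(e, name)
    # each presentation opens a new episode: earlier list items lose their
    # capacity protection against the trace now being built
    e.episode += 1
    inst = e.eb.begin_instance(name, "OBJECT", loc, e.episode, e.cycle,
                               e.rng["durations"], mark="TBR", flag="EXT")
    if loc is not None:
        e.ism.seen(loc)
    e.emit("eb", "memo", name)
    return inst


@action("mkcoord")
def a_mkcoord(e: Engine, name="DUAL"):
    inst = e.eb.begin_instance(name, "COORD", None, e.episode, e.cycle,
                               e.rng["durations"], mark="ON", flag="INT")
    e.emit("eb", "coord", name)
    return inst


@action("renew")
def a_renew(e: Engine, name):
    """Re-create a still-present trace into the current episode.

    The trace re-enters a short creation phase (re-creation duration) during
    which its activation grows again, like any instance being built.
    """
    inst = e.eb.get(name)
    if inst is None or inst.pending:
        return
    p = e.params
    d = gauss_duration(e.rng["durations"], p.recreate_mean, p.recreate_sd)
    d = max(1, d // 2)    # the trace is present and active: renewal is
                          # cheaper than re-creating a discarded one
    floor = 1.0 - (1.0 - p.phi) * (1.0 - p.alpha) ** max(0, 20 - d)
    inst.episode = e.episode
    inst.activation = max(inst.activation, floor)
    inst.pending = True
    inst.complete_cycle = e.cycle + d
    e.emit("eb", "renew", name)


@action("inhibit")
def a_inhibit(e: Engine, name):
    inst = e.eb.get(name)
    if inst is not None:
        e.eb.inhibit(inst)
        inst.mark = "OFF"
        e.emit("eb", "inhibit", name)


@action("loadts")
def a_loadts(e: Engine, name):
    schema = e.schema_for_ts(name)
    if schema is None:
        raise ConfigurationError(f"no task instructions for {name!r}")
    ts = e.em.instantiate(name, e.cycle, e.rng["durations"],
                          defaults=schema.defaults)
    e.emit("em", "taskset", name)
    return ts


@action("demts")
def a_demts(e: Engine, name):
    """Displace a task set: it loses activation and its configuration
    (mappings), which must be re-uploaded when the set is next engaged —
    the source of the residual switch cost."""
    ts = e.em.get(name)
    if ts is not None and ts.mode == "ACTIVE":
        e.em.demote(ts)
        ts.mappings.clear()
        e.emit("em", "demote", name)


@action("boostts")
def a_boostts(e: Engine, name):
    """Re-energise an existing task set so it can regain dominance."""
    ts = e.em.get(name)
    if ts is None:
        return
    ts.mode = "ACTIVE"
    ts.activation = max(ts.activation, e.params.phi)
    ts.pending = True
    ts.complete_cycle = e.cycle + gauss_duration(
        e.rng["durations"], e.params.recreate_mean, e.params.recreate_sd)
    e.emit("em", "boost", name)


@action("addmaps")
def a_addmaps(e: Engine, name):
    """Upload the next missing category-response mapping (one per firing)."""
    schema = e.schema_for_ts(name)
    ts = e.em.get(name)
    if schema is None or ts is None:
        return
    for category, response in schema.mappings.items():
        if category not in ts.mappings:
            ts.add_mapping(category, response)
            e.emit("em", "mapping", f"{name}:{category}-{response}")
            return


@action("setpar")
def a_setpar(e: Engine, name, key, value):
    ts = e.em.get(name)
    if ts is None:
        return
    if key not in ts.parameters:
        schema = e.schema_for_ts(name)
        if schema is not None and key not in schema.defaults:
            raise ConfigurationError(
                f"task set {name}: unknown parameter {key!r}")
    ts.set_parameter(key, value)
    e.emit("em", "param", f"{name}.{key}={value}")
    if name == "MEMTS":
        if key == "MAINT":
            pass
        if key == "RECALL" and value == "ON":
            pass


@action("loadact")
def a_loadact(e: Engine, name, act_name):
    ts = e.em.get(name)
    if ts is None:
        return
    if act_name in ts.actions:
        return
    act = TaskAction(name=act_name, status="ON")
    ts.actions[act_name] = act
    if act_name == "REFRESH":
        e.refresh.enabled = True
        e.refresh.schedule = str(ts.get_parameter("DREF", "ALL"))
    elif act_name == "RETRIEVE":
        kind = str(ts.get_parameter("TSPAN", "sequential"))
        act.task_kind = kind
        e.recall = RecallProcess(e.params, act)
    e.emit("em", "action", f"{name}.{act_name}")


@action("holdrf")
def a_holdrf(e: Engine):
    e.refresh.hold = True
    # the coordination instance is kept active throughout dual-task trials
    for i in e.eb.instances:
        if i.type == "COORD" and i.flag != "DONE" and i.mark != "OFF":
            i.episode = e.episode
            if i.activation < 0.5:
                i.activation = 0.5
    e.emit("em", "refresh-hold", "")


@action("resumerf")
def a_resumerf(e: Engine):
    e.refresh.hold = False
    e.emit("em", "refresh-resume", "")


@action("motorinit")
def a_motorinit(e: Engine, ts_name):
    ts = e.em.get(ts_name)
    modality = "MANUAL"
    if ts is not None:
        modality = str(ts.get_parameter("RSPMOD", "MANUAL"))
    e.motor.init(modality, e.params)
    e.emit("motor", "init", modality)


@action("unblock")
def a_unblock(e: Engine):
    if e.motor.modality != "NONE" and e.motor.status == "BLOCKED":
        e.motor.status = "UNBLOCK"
        e.emit("motor", "unblock", "")


@action("mkbind")
def a_mkbind(e: Engine, goal, obj, category):
    parts = [e.eb.get(goal), e.eb.get(obj), e.eb.get(category)]
    if any(x is None for x in parts):
        return
    name = f"B-{goal}-{obj}"
    if name not in e.dltm.nodes:
        from .knowledge import Node
        e.dltm.add_node(Node(name=name))
    inst = e.eb.begin_instance(name, "BIND", None, e.episode, e.cycle,
                               e.rng["durations"], mark="ON", flag="INT")
    inst.components = [x for x in parts if x is not None]
    e.emit("eb", "bind", name)
    return inst


@action("addbind")
def a_addbind(e: Engine, name):
    comp = e.eb.get(name)
    if comp is None:
        return
    for i in e.eb.instances:
        if i.type == "BIND" and i.flag != "DONE" and i.mark != "OFF":
            if comp not in i.components:
                i.components.append(comp)
                e.emit("eb", "bind-add", name)
            return


@action("execute")
def a_execute(e: Engine, response):
    e.motor.start("intentional", response)
    e.emit("motor", "execute", response)


@action("do")
def a_do(e: Engine, response):
    e.motor.start("automatic", response)
    e.emit("motor", "do", response)


@action("learnstrengths")
def a_learnstrengths(e: Engine):
    fb = e.feedback_event()
    outcome = "positive" if fb is not None and fb.evaluation == "CORRECT" \
        else "negative"
    for rule in set(e.selected_this_episode):
        update_rule_strength(rule, outcome, e.learn_cfg)
    e.learn_stage = 1
    e.emit("learn", "strengths", outcome)


@action("learnassoc")
def a_learnassoc(e: Engine):
    fb = e.feedback_event()
    if (fb is not None and fb.evaluation == "CORRECT"
            and e.trial_target is not None):
        new = create_association_rule(e.trial_target, fb.last_response,
                                      e.learn_cfg, e.rules)
        if new is not None:
            e.rules.append(new)
            e.emit("learn", "association", new.name)
    e.learn_stage = 2


@action("inhibitresponse")
def a_inhibitresponse(e: Engine):
    for i in e.eb.instances:
        if i.type == "RESPONSE" and i.flag != "DONE":
            e.eb.inhibit(i)
    e.motor.clear()
    e.learn_stage = 3
    e.emit("learn", "inhibit-response", "")


@action("clearfeedback")
def a_clearfeedback(e: Engine):
    for ev in e.internal_events:
        if ev.name == "FEEDBACK":
            ev.in_use = False
    e.learn_stage = 4
    e.emit("learn", "clear-feedback", "")


@action("disband")
def a_disband(e: Engine):
    for i in e.eb.instances:
        if i.type == "BIND" and i.flag != "DONE":
            for c in i.components:
                if c.type in ("OBJECT", "CLASS", "RESPONSE"):
                    e.eb.inhibit(c)
            i.flag = "DONE"
            i.mark = "OFF"
    e.emit("learn", "disband", "")
    e.end_trial()


@action("formchunk")
def a_formchunk(e: Engine):
    ts = e.em.get("MEMTS")
    if ts is None:
        return
    L0 = int(ts.get_parameter("L0", 0) or 0)
    free = [i for i in e.eb.instances
            if i.mark == "TBR" and not i.pending and i.type != "CHUNK"]
    free.sort(key=lambda i: i.timestamp)
    if len(free) >= L0 >= 2:
        comps = free[:L0]
    elif e.list_ended and len(free) >= 2:
        comps = free
    else:
        return
    chunk = e.eb.form_chunk(comps, e.episode, e.cycle, e.rng["durations"])
    e.emit("eb", "chunk", chunk.name)


@action("startrecall")
def a_startrecall(e: Engine):
    ts = e.em.get("MEMTS")
    if ts is None or e.recall is None:
        return
    e.recall.action.status = "ON"
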