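"""Working-memory stores and their activation dynamics.

Four limited-capacity stores — the episodic buffer (EB), the phonological
loop (PL), visuospatial memory (VSM) and executive memory (EM) — plus the
episodic long-term store (eLTM).  All dynamics are per 10-ms cycle:
saturating growth ``a + (1-a)*rate``, multiplicative decay ``a*rate``,
mutual lateral inhibition between opposed traces, and two-step rescaling
when the summed activation of EB or EM exceeds its capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random

from .params import (ModelParameters, grow, decay, gauss_duration,
                     rehearsal_duration, revival_duration)

GRID = 9  # side of the square spatial matrix shared by ISM and VSM

EB_TYPES = ("GOAL", "COORD", "CUE", "OBJECT", "CLASS", "RESPONSE", "CHUNK", "BIND")


class EBInstance:
    """An episodic-buffer trace; the model's central currency.

    Creation takes ``d = 20 + 4r`` cycles during which activation grows from
    phi; a pending instance is invisible to most rules until creation
    completes.  Completed instances do not decay; they are lost only through
    capacity competition or explicit inhibition.
    """

    __slots__ = ("name", "type", "location", "episode", "timestamp", "busy",
                 "access", "flag", "mark", "activation", "vsm_link", "pl_link",
                 "eltm_link", "recall_status", "components", "pending",
                 "complete_cycle", "source")

    def __init__(self, name, type_, location, episode, cycle, activation,
                 complete_cycle, mark="ON", flag="EXT", source=None):
        self.name = name
        self.type = type_
        self.location = location
        self.episode = episode
        self.timestamp = complete_cycle
        self.busy = 0
        self.access = False
        self.flag = flag
        self.mark = mark
        self.activation = activation
        self.vsm_link = 0
        self.pl_link = 0
        self.eltm_link = 0
        self.recall_status = None
        self.components = []
        self.pending = True
        self.complete_cycle = complete_cycle
        self.source = source if source is not None else name

    def __repr__(self):  # pragma: no cover - debugging aid
        state = "pending" if self.pending else "ok"
        return (f"<EB {self.name} {self.type} a={self.activation:.3f} "
                f"{self.mark}/{self.flag} {state}>")


def enforce_capacity(activations, protected, capacity, set_activation,
                     eps=1e-9):
    """Two-step capacity rescaling shared by EB and EM.

    ``activations`` is a list of current values, ``protected`` flags items
    created in the current episode and not yet discarded.  Step 1 scales only
    unprotected items by C/sum; step 2, if the sum still exceeds C, rescales
    everything by the recomputed fraction.  Returns the new values.
    """
    total = sum(activations)
    if total <= capacity + eps or total <= 0.0:
        return activations
    f = capacity / total
    new = [a if prot else a * f
           for a, prot in zip(activations, protected)]
    total = sum(new)
    if total > capacity + eps:
        f = capacity / total
        new = [a * f for a in new]
    for i, a in enumerate(new):
        set_activation(i, a)
    return new


class EpisodicBuffer:
    """The multimodal episodic buffer with capacity C (default 2.9)."""

    def __init__(self, params: ModelParameters, dltm):
        self.params = params
        self.dltm = dltm
        self.instances: list[EBInstance] = []
        self.familiar: dict[str, int] = {}   # name -> cycle last discarded
        self.recreate_horizon = 5000

    # -- creation ----------------------------------------------------------

    def begin_instance(self, name, type_, location, episode, cycle,
                       rng: Random, mark="ON", flag="EXT", source=None):
        """Start creating an instance; returns the pending trace.

        A re-creation of a recently discarded trace of the same name is
        faster than a brand-new one.
        """
        if name not in self.dltm:
            raise KeyError(f"unknown declarative node {name!r}")
        p = self.params
        seen = self.familiar.get(name)
        if seen is not None and cycle - seen <= self.recreate_horizon:
            d = gauss_duration(rng, p.recreate_mean, p.recreate_sd)
            # a re-created trace resumes part-built: it completes at the
            # same activation level a full creation would reach
            a0 = 1.0 - (1.0 - p.phi) * (1.0 - p.alpha) ** max(0, 20 - d)
        else:
            d = gauss_duration(rng, 20.0, 4.0)
            a0 = p.phi
        inst = EBInstance(name, type_, location, episode, cycle,
                          a0, cycle + d, mark=mark, flag=flag, source=source)
        self.instances.append(inst)
        self.familiar[name] = cycle
        return inst

    def step_pending(self, cycle):
        """Growth of pending instances plus mutual lateral inhibition."""
        p = self.params
        pend = [i for i in self.instances if i.pending]
        if pend:
            inhibited: set[int] = set()
            for inst in pend:
                inst.activation = grow(inst.activation, p.alpha)
                for opp in self.dltm.opposites(inst.name):
                    for other in self.instances:
                        if other.name == opp and other.mark != "OFF":
                            inhibited.add(id(inst))
                            inhibited.add(id(other))
            for inst in self.instances:
                if id(inst) in inhibited:
                    inst.activation = decay(inst.activation, p.beta)
            for inst in pend:
                if cycle >= inst.complete_cycle:
                    inst.pending = False
                    inst.timestamp = cycle

    # -- queries -----------------------------------------------------------

    def find(self, name=None, type_=None, mark=None, include_pending=True,
             include_done=False):
        out = []
        for i in self.instances:
            if i.pending and not include_pending:
                continue
            if not include_done and (i.flag == "DONE" or i.mark == "OFF"):
                continue
            if name is not None and i.name != name:
                continue
            if type_ is not None and i.type != type_:
                continue
            if mark is not None and i.mark != mark:
                continue
            out.append(i)
        return out

    def accessible(self, name=None, type_=None, mark=None):
        return [i for i in self.find(name, type_, mark, include_pending=False)
                if i.access]

    def get(self, name):
        for i in self.instances:
            if i.name == name and i.flag != "DONE":
                return i
        return None

    def total_activation(self):
        return sum(i.activation for i in self.instances)

    # -- dynamics ----------------------------------------------------------

    def enforce_capacity(self, episode):
        items = self.instances
        if not items:
            return
        protected = [(i.episode == episode and i.flag != "DONE"
                      and i.mark != "OFF") for i in items]
        acts = [i.activation for i in items]

        def setter(idx, val):
            items[idx].activation = val
        enforce_capacity(acts, protected, self.params.eb_capacity, setter)

    def inhibit(self, inst: EBInstance):
        inst.activation = decay(inst.activation, self.params.tau)

    def set_access(self, r: float):
        for i in self.instances:
            a = i.activation
            i.access = (not i.pending) and (a > 0.5 or a >= 0.5 * r)

    def sync_flags(self, source_gone):
        """Flip EXT traces to INT when their sensory source is gone."""
        for i in self.instances:
            if i.flag == "EXT" and source_gone(i.source):
                i.flag = "INT"

    def prune(self):
        """Remove traces that no longer compete for capacity.

        Traces flagged DONE (deliberately discarded at trial cleanup) drop
        immediately, so the next episode's instances grow into freed slack.
        Traces merely switched OFF (inhibited, or already recalled) linger
        and keep holding capacity until the squeeze grinds them down.
        """
        floor = self.params.prune_floor
        linger = self.params.discard_decay
        keep = []
        for i in self.instances:
            if i.busy:
                keep.append(i)
                continue
            if i.flag == "DONE":
                continue
            if i.mark == "OFF":
                i.activation *= linger   # inhibited traces fade passively
                if i.activation < floor:
                    continue
            keep.append(i)
        self.instances = keep

    # -- chunking ----------------------------------------------------------

    def form_chunk(self, components, episode, cycle, rng: Random,
                   name=None):
        """Combine >= 2 consecutive TBR instances into a CHUNK trace.

        Components are inhibited (rate tau) and lose their TBR mark; the
        chunk itself is marked TBR and is created like any instance.
        """
        if len(components) < 2:
            raise ValueError("a chunk needs at least two components")
        name = name or "+".join(c.name for c in components)
        if name not in self.dltm.nodes:
            # chunks name composite entries; register them on the fly
            from .knowledge import Node
            syl = sum(self.dltm[c.name].syllables for c in components)
            self.dltm.add_node(Node(name=name, syllables=syl))
        chunk = self.begin_instance(name, "CHUNK", None, episode, cycle, rng,
                                    mark="TBR", flag="INT")
        chunk.timestamp = min(c.timestamp for c in components)
        chunk.components = list(components)
        for c in components:
            self.inhibit(c)
            c.mark = "OFF"
        return chunk


# ---------------------------------------------------------------------------
# Phonological loop
# ---------------------------------------------------------------------------

@dataclass
class PLTrace:
    name: str
    eb_link: object = None
    access: bool = False
    syllables: int = 1
    activation: float = 1.0
    next: "PLTrace" = None  # circular


class PhonologicalLoop:
    """Circular list of phonological traces supporting rehearsal."""

    def __init__(self, params: ModelParameters):
        self.params = params
        self.traces: list[PLTrace] = []

    def insert(self, name, syllables=1, eb_link=None):
        t = PLTrace(name=name, syllables=syllables, eb_link=eb_link,
                    activation=1.0)
        self.traces.append(t)
        self._relink()
        return t

    def remove(self, trace):
        self.traces.remove(trace)
        self._relink()

    def _relink(self):
        n = len(self.traces)
        for i, t in enumerate(self.traces):
            t.next = self.traces[(i + 1) % n]

    def decay_step(self):
        d = self.params.delta
        for t in self.traces:
            t.activation = decay(t.activation, d)

    def set_access(self, r: float):
        thr = (0.6 * r) ** 2
        for t in self.traces:
            t.access = t.activation >= thr

    def __len__(self):
        return len(self.traces)


# ---------------------------------------------------------------------------
# Visuospatial memory
# ---------------------------------------------------------------------------

@dataclass
class VSMTrace:
    name: str
    type: str = "SHAPE"       # WORD-SYMBOL or SHAPE
    flag: str = "EXT"
    colour: str = "BLACK"
    activation: float = 1.0
    eb_link: object = None
    coords: tuple = (0, 0)
    next_in_sequence: object = 0
    access: bool = False


class VisuospatialMemory:
    """Grid-bound visual traces; decay countered by revival."""

    def __init__(self, params: ModelParameters):
        self.params = params
        self.traces: dict[tuple, VSMTrace] = {}

    def insert(self, name, coords, type_="SHAPE", colour="BLACK", eb_link=None):
        if coords in self.traces:
            raise ValueError(f"VSM cell {coords} already occupied")
        t = VSMTrace(name=name, coords=coords, type=type_, colour=colour,
                     eb_link=eb_link)
        self.traces[coords] = t
        return t

    def remove(self, trace):
        self.traces.pop(trace.coords, None)

    def decay_step(self):
        s = self.params.sigma
        for t in self.traces.values():
            t.activation = decay(t.activation, s)

    def set_access(self, r: float):
        for t in self.traces.values():
            a = t.activation
            t.access = a > 0.5 or a >= 0.5 * r

    def __len__(self):
        return len(self.traces)


# ---------------------------------------------------------------------------
# Executive memory
# ---------------------------------------------------------------------------

@dataclass
class TaskAction:
    """Progress bookkeeping for one task-set action (e.g. retrieval)."""

    name: str
    access: str = "AWAKE"          # AWAKE or SLEEP
    status: str = "EMPTY"          # EMPTY, ON, HOLD, FREE, DONE
    object_type: str = "WORD"
    task_kind: str = "sequential"
    pl_target: object = 0
    pl_fails: int = 0
    vsm_target: object = 0
    vsm_fails: int = 0
    eb_target: object = 0
    eb_fails: int = 0
    reference_age: int = 0
    match_count: int = 0
    tbr_count: int = 0
    action_count: int = 0
    completion_cycle: int = 0


@dataclass
class TaskSet:
    """Executive-memory structure configuring one goal-directed task."""

    name: str
    activation: float = 0.25
    access: bool = False
    timestamp: int = 0
    busy: str = "OFF"
    mode: str = "ACTIVE"          # ACTIVE or DEMOTED
    parameters: dict = field(default_factory=dict)   # key -> [value, strength]
    mappings: dict = field(default_factory=dict)     # category -> (response, s)
    actions: dict = field(default_factory=dict)      # name -> TaskAction
    pending: bool = True
    complete_cycle: int = 0

    def set_parameter(self, key, value, strength=0.25):
        if key not in self.parameters:
            self.parameters[key] = [value, strength]
        else:
            self.parameters[key][0] = value

    def get_parameter(self, key, default=None):
        entry = self.parameters.get(key)
        return entry[0] if entry is not None else default

    def add_mapping(self, category, response, strength=0.25):
        self.mappings[category] = (response, strength)

    def component_count(self):
        return len(self.parameters) + len(self.mappings) + len(self.actions)


class ExecutiveMemory:
    """Task sets plus their components under a shared capacity C (default 5).

    Each parameter, mapping or action contributes a fixed component load so
    that juggling several richly configured task sets saturates the store.
    """

    COMPONENT_LOAD = 0.2

    def __init__(self, params: ModelParameters):
        self.params = params
        self.task_sets: list[TaskSet] = []

    def instantiate(self, name, cycle, rng: Random, defaults=None,
                    mappings=None, mode="ACTIVE"):
        existing = self.get(name)
        if existing is not None and existing.mode == "DEMOTED":
            # revival of a demoted task set: resumes part-built
            p = self.params
            d = gauss_duration(rng, p.recreate_mean, p.recreate_sd)
            floor = 1.0 - (1.0 - p.phi) * (1.0 - p.alpha) ** max(0, 20 - d)
            existing.mode = "ACTIVE"
            existing.activation = max(existing.activation, floor)
            existing.pending = True
            existing.complete_cycle = cycle + d
            existing.timestamp = cycle
            return existing
        ts = TaskSet(name=name, activation=self.params.phi, timestamp=cycle,
                     mode=mode)
        ts.complete_cycle = cycle + gauss_duration(rng, 20.0, 4.0)
        for key, value in (defaults or {}).items():
            ts.set_parameter(key, value)
        for cat, resp in (mappings or {}).items():
            ts.add_mapping(cat, resp)
        self.task_sets.append(ts)
        return ts

    def get(self, name):
        for ts in self.task_sets:
            if ts.name == name:
                return ts
        return None

    def active(self):
        return [ts for ts in self.task_sets if ts.mode == "ACTIVE"]

    def dominant(self, require_access=True):
        """The accessible task set with the highest activation, or None."""
        best = None
        for ts in self.active():
            if ts.pending:
                continue
            if require_access and not ts.access:
                continue
            if best is None or ts.activation > best.activation:
                best = ts
        return best

    def demote(self, ts: TaskSet):
        ts.mode = "DEMOTED"
        ts.activation = decay(ts.activation, self.params.tau)

    def step_pending(self, cycle, opposed=None):
        """Activation growth of loading task sets + mutual lateral inhibition.

        While a task set is loading, it and any opposed task set (active or
        recently demoted) inhibit each other, so a set that repeatedly loses
        the competition keeps losing ground.
        """
        p = self.params
        pend = [ts for ts in self.task_sets if ts.pending]
        if not pend:
            return
        for ts in pend:
            ts.activation = grow(ts.activation, p.alpha)
        inhibit = set()
        for ts in pend:
            if ts.mode != "ACTIVE":
                continue
            rivals = set(opposed(ts.name)) if opposed is not None else None
            for other in self.task_sets:
                if other is ts:
                    continue
                if rivals is None:
                    if other.mode != "ACTIVE":
                        continue
                elif other.name not in rivals:
                    continue
                inhibit.add(id(ts))
                inhibit.add(id(other))
        for ts in self.task_sets:
            if id(ts) in inhibit:
                ts.activation = decay(ts.activation, p.beta)
        for ts in pend:
            if cycle >= ts.complete_cycle:
                ts.pending = False

    def total_activation(self):
        return sum(ts.activation + self.COMPONENT_LOAD * ts.component_count()
                   for ts in self.task_sets)

    def enforce_capacity(self):
        tss = self.task_sets
        if not tss:
            return
        comp = [self.COMPONENT_LOAD * ts.component_count() for ts in tss]
        acts = [ts.activation + c for ts, c in zip(tss, comp)]
        protected = [ts.mode == "ACTIVE" for ts in tss]

        def setter(idx, val):
            tss[idx].activation = max(0.0, val - comp[idx])
        enforce_capacity(acts, protected, self.params.em_capacity, setter)

    def set_access(self, r: float):
        for ts in self.task_sets:
            a = ts.activation
            ts.access = (not ts.pending) and (a > 0.5 or a >= 0.5 * r)

    def prune(self):
        floor = self.params.prune_floor
        self.task_sets = [ts for ts in self.task_sets
                          if not (ts.mode == "DEMOTED"
                                  and ts.activation < floor)]


# ---------------------------------------------------------------------------
# Episodic long-term memory
# ---------------------------------------------------------------------------

@dataclass
class ELTMTrace:
    name: str
    episode: int = 0
    timestamp: int = 0
    position: int = 0
    strength: float = 0.0
    location: tuple | None = None


class EpisodicLTM:
    """Slow consolidation store fed by refreshed episodic-buffer traces."""

    def __init__(self, params: ModelParameters):
        self.params = params
        self.traces: dict[tuple, ELTMTrace] = {}

    def consolidate(self, name, episode, cycle, position=0, location=None):
        key = (name, episode)
        trace = self.traces.get(key)
        if trace is None:
            trace = ELTMTrace(name=name, episode=episode, timestamp=cycle,
                              position=position, location=location)
            self.traces[key] = trace
        trace.strength = grow(trace.strength, self.params.kappa)
        return trace

    def get(self, name, episode):
        return self.traces.get((name, episode))

    def retrieve(self, name, episode, r: float):
        """Step-rule access: success when strength >= 0.5 r."""
        trace = self.traces.get((name, episode))
        if trace is None:
            return False
        return trace.strength >= 0.5 * r


# ---------------------------------------------------------------------------
# Maintenance processes: refreshment, rehearsal, revival
# ---------------------------------------------------------------------------

class RefreshProcess:
    """Attentional refreshment of TBR episodic-buffer traces.

    One refresh act dwells on a trace for ``refresh_dwell`` cycles and ends
    with one saturating-growth increment (rate alpha); moving to the next
    trace costs ``refresh_switch`` cycles.  Rotation is oldest-first round
    robin within the schedule-eligible set.  The trace being dwelt on is the
    one consolidated into eLTM that cycle.
    """

    def __init__(self, params: ModelParameters):
        self.params = params
        self.enabled = False
        self.hold = False
        self.schedule = "ALL"
        self.current: EBInstance | None = None
        self.dwell_left = 0
        self.switch_left = 0
        self.last_timestamp = -1

    def eligible(self, eb: EpisodicBuffer):
        items = [i for i in eb.instances
                 if i.mark == "TBR" and not i.pending]
        items.sort(key=lambda i: i.timestamp)
        sched = self.schedule
        if sched == "ALL" or not items:
            return items
        if sched.startswith("OLD"):
            k = int(sched[3:] or 1)
            return items[:k]
        if sched.startswith("NEW"):
            k = int(sched[3:] or 1)
            return items[-k:]
        return items

    def step(self, eb: EpisodicBuffer, cycle):
        """Advance one cycle; returns the trace being refreshed, if any."""
        if not self.enabled or self.hold:
            return None
        if self.switch_left > 0:
            self.switch_left -= 1
            return None
        if self.current is not None:
            if self.current.mark != "TBR" or self.current not in eb.instances:
                self.current = None
                self.dwell_left = 0
        if self.current is None:
            items = self.eligible(eb)
            if not items:
                return None
            nxt = None
            for inst in items:
                if inst.timestamp > self.last_timestamp:
                    nxt = inst
                    break
            if nxt is None:
                nxt = items[0]
            self.current = nxt
            self.last_timestamp = nxt.timestamp
            self.dwell_left = self.params.refresh_dwell
        trace = self.current
        self.dwell_left -= 1
        if self.dwell_left <= 0:
            trace.activation = grow(trace.activation, self.params.alpha)
            self.current = None
            self.switch_left = self.params.refresh_switch
        return trace


class RehearseProcess:
    """Subvocal rehearsal around the phonological loop."""

    def __init__(self, params: ModelParameters):
        self.params = params
        self.enabled = False
        self.hold = False
        self.current: PLTrace | None = None
        self.left = 0

    def step(self, pl: PhonologicalLoop, cycle, rng: Random):
        if not self.enabled or self.hold or not pl.traces:
            return None
        if self.current is None or self.current not in pl.traces:
            self.current = pl.traces[0]
            self.left = rehearsal_duration(rng, self.current.syllables,
                                           self.params.syllable_cycles)
        trace = self.current
        self.left -= 1
        if self.left <= 0:
            trace.activation = grow(trace.activation, self.params.rho)
            self.current = trace.next
            self.left = rehearsal_duration(rng, self.current.syllables,
                                           self.params.syllable_cycles)
        return trace


class ReviveProcess:
    """Revival of visuospatial traces linked to TBR instances."""

    def __init__(self, params: ModelParameters):
        self.params = params
        self.enabled = False
        self.hold = False
        self.current: VSMTrace | None = None
        self.left = 0
        self.index = 0

    def step(self, vsm: VisuospatialMemory, cycle, rng: Random):
        if not self.enabled or self.hold or not vsm.traces:
            return None
        traces = [t for t in vsm.traces.values()
                  if t.eb_link is None or getattr(t.eb_link, "mark", "TBR") == "TBR"]
        if not traces:
            return None
        if self.current is None or self.current not in traces:
            self.index %= len(traces)
            self.current = traces[self.index]
            self.left = revival_duration(rng)
        trace = self.current
        self.left -= 1
        if self.left <= 0:
            trace.activation = grow(trace.activation, self.params.rho)
            self.index = (self.index + 1) % len(traces)
            self.current = None
        return trace


# ---------------------------------------------------------------------------
# Retrieval (serial recall) process
# ---------------------------------------------------------------------------

class RecallProcess:
    """Serial recall driven by a retrieval task action.

    The next item is the oldest not-yet-recalled TBR trace.  Access is tried
    in the store matching the maintenance mode (VSM if revival, PL if
    rehearsal, else EB), retrying every few cycles; after three failures the
    eLTM trace is tried once, and if that also fails the item is skipped and
    a failure recorded.  Successful items are spoken/written out over an
    output dwell; chunks unpack into their components in order.
    """

    def __init__(self, params: ModelParameters, action: TaskAction):
        self.params = params
        self.action = action
        self.phase = "LOCATE"
        self.current: EBInstance | None = None
        self.fails = 0
        self.wait_until = 0
        self.output_queue: list[str] = []
        self.outputs: list[tuple] = []     # (symbol, cycle)
        self.failures: list[str] = []
        self.attempted: set[int] = set()
        self.on_output = None              # callback(symbol, cycle)
        self.episode = 0
        self._speaking: list[tuple] = []   # (response instance, end cycle)

    def _locate(self, eb: EpisodicBuffer):
        best = None
        for inst in eb.instances:
            if inst.mark != "TBR" or inst.pending:
                continue
            if id(inst) in self.attempted:
                continue
            if best is None or inst.timestamp < best.timestamp:
                best = inst
        return best

    def _output_duration(self, symbol, eb, rng):
        node = eb.dltm.get(symbol)
        syl = max(1, node.syllables if node is not None else 1)
        return max(5, int(round(0.6 * self.params.syllable_cycles
                                * math.sqrt(syl) + rng.gauss(0.0, 1.0))))

    def step(self, eb: EpisodicBuffer, pl, vsm, eltm, cycle, rng: Random,
             maintenance_mode="RF"):
        act = self.action
        for inst, end in list(self._speaking):
            if cycle >= end:
                # spoken; the articulated trace lingers inhibited
                inst.mark = "OFF"
                self._speaking.remove((inst, end))
        if act.status != "ON":
            return
        if cycle < self.wait_until:
            return
        if self.output_queue:
            symbol = self.output_queue.pop(0)
            self._emit(symbol, eb, cycle, rng)
            return
        if self.phase == "LOCATE":
            inst = self._locate(eb)
            if inst is None:
                act.status = "DONE"
                act.completion_cycle = cycle
                return
            self.current = inst
            self.fails = 0
            self.phase = "ACCESS"
            act.eb_target = inst
            act.reference_age = cycle - inst.timestamp
        if self.phase == "ACCESS":
            inst = self.current
            ok = False
            if maintenance_mode == "RV" and inst.vsm_link:
                ok = inst.vsm_link.access
            elif maintenance_mode == "RH" and inst.pl_link:
                ok = inst.pl_link.access
            else:
                ok = inst.access
            if ok:
                self.attempted.add(id(inst))
                inst.mark = "OFF"
                inst.recall_status = "RECALLED"
                act.match_count += 1
                if inst.type == "CHUNK" and inst.components:
                    names = [c.name for c in inst.components]
                    self._emit(names[0], eb, cycle, rng)
                    self.output_queue = names[1:]
                else:
                    self._emit(inst.name, eb, cycle, rng)
                return
            self.fails += 1
            act.eb_fails += 1
            # a failed access is a rejection: the candidate is inhibited
            inst.activation *= self.params.tau
            if self.fails >= self.params.max_item_failures:
                # last resort: episodic LTM
                r = rng.random()
                if eltm.retrieve(inst.name, inst.episode, r):
                    self.attempted.add(id(inst))
                    inst.mark = "OFF"
                    inst.recall_status = "RECALLED-ELTM"
                    if inst.type == "CHUNK" and inst.components:
                        names = [c.name for c in inst.components]
                        self._emit(names[0], eb, cycle, rng)
                        self.output_queue = names[1:]
                    else:
                        self._emit(inst.name, eb, cycle, rng)
                    return
                self.attempted.add(id(inst))
                inst.mark = "OFF"
                inst.recall_status = "FAILED"
                self.failures.append(inst.name)
                self.current = None
                self.phase = "LOCATE"
                self.wait_until = cycle + 2
                return
            self.wait_until = cycle + self.params.access_retry

    def _emit(self, symbol, eb, cycle, rng):
        dur = self._output_duration(symbol, eb, rng)
        # speaking the item instantiates the response in the buffer, which
        # competes for capacity with the traces still awaiting recall
        spoken = eb.begin_instance(symbol, "RESPONSE", None, self.episode,
                                   cycle, rng, mark="ON", flag="INT")
        self._speaking.append((spoken, cycle + dur))
        self.outputs.append((symbol, cycle + dur))
        self.action.action_count += 1
        self.wait_until = cycle + dur + 2
        self.phase = "LOCATE"
        self.current = None
        if self.on_output is not None:
            self.on_output(symbol, cycle + dur)
        if self.action.task_kind == "alternating":
            self.action.status = "HOLD"

    def recalled_sequence(self):
        return [s for (s, _) in self.outputs]
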