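"""Builders and runners for the five simulation studies.

Study 1 — cued task switching (magnitude/parity/form on digits and digit
words, cue-target intervals 0-900 ms).
Study 2 — task and dimension switching (hierarchical vs combined task-set
organisation).
Study 3 — complex span with embedded parity or location judgments (burst
sizes 4/6/8 in a fixed maintenance interval).
Study 4 — memory span versus task span for ordered task-name lists, with
chunking disabled or limited to chunks of two or three.
Study 5 — serial recall with strictly timed embedded digit-task lists
(single vs alternating; few vs many switches; Brown-Peterson variant).

Rule sets and declarative networks are data fixtures; the builders here
assemble them with the study-specific stimulus lexicon and timing constants
and drive the engine trial by trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

import pandas as pd

from .engine import Engine, TaskSchema
from .environment import Environment, ScheduledEvent, TrialRecord
from .knowledge import load_dltm, parse_rules
from .params import ModelParameters, sample_subject
from .rulesets import load_text

WORD_SYLLABLES = {1: 1, 2: 1, 3: 1, 4: 1, 5: 1, 6: 1, 7: 2, 8: 1, 9: 1}

CROSS_POS = (4, 4)
CUE_POS = (4, 3)
TARGET_POS = (4, 5)
ABOVE_POS = (4, 2)
BELOW_POS = (4, 6)


# ---------------------------------------------------------------------------
# Lexicon builders (declarative-network text fragments)
# ---------------------------------------------------------------------------

def digit_nodes(values, pivot=5, words=True):
    lines = []
    for v in values:
        mag = "SMALL" if v < pivot else "LARGE"
        par = "ODD" if v % 2 else "EVEN"
        lines.append(f"D{v} syllables=1 link=SUP:DIGIT link=SUP:TARGET "
                     f"link=PROP:{mag} link=PROP:{par} link=PROP:DIG")
        if words:
            syl = WORD_SYLLABLES[v]
            lines.append(f"W{v} syllables={syl} link=SUP:NUMWORD "
                         f"link=SUP:TARGET link=PROP:{mag} link=PROP:{par} "
                         f"link=PROP:WRD")
    return "\n".join(lines)


def letter_nodes(names):
    return "\n".join(f"{n} syllables=1 link=SUP:LETTER link=SUP:MEMITEM"
                     for n in names)


def task_triad_nodes(triads, cue_props=None):
    """Cue/goal/task-set nodes with pairwise opposition within each tier.

    `triads` is a list of (cue, goal, ts) tuples; `cue_props` maps a cue to
    extra PROP targets (e.g. an attended-dimension node).
    """
    cue_props = cue_props or {}
    cues = [t[0] for t in triads if t[0]]
    goals = [t[1] for t in triads]
    tss = [t[2] for t in triads]
    lines = []
    for cue, goal, ts in triads:
        if cue:
            opp = " ".join(f"link=OPP:{c}" for c in cues if c != cue)
            props = " ".join(f"link=PROP:{p}" for p in
                             [goal] + list(cue_props.get(cue, [])))
            lines.append(f"{cue} syllables=1 link=SUP:CUE {props} {opp}")
        gopp = " ".join(f"link=OPP:{g}" for g in goals if g != goal)
        lines.append(f"{goal} syllables=1 link=SUP:GOAL link=PROP:{ts} {gopp}")
        topp = " ".join(f"link=OPP:{t}" for t in tss if t != ts)
        lines.append(f"{ts} link=SUP:TSKSET {topp}")
    return "\n".join(lines)


def memoranda_task_names(triads):
    """Recallable task-name words pointing at the task goals (task span)."""
    return "\n".join(
        f"T{goal} syllables=1 link=SUP:MEMITEM link=PROP:{goal}"
        for (_, goal, _) in triads)


MAG_SCHEMA = dict(category_class="MAGCAT",
                  mappings={"SMALL": "LEFT", "LARGE": "RIGHT"})
PAR_SCHEMA = dict(category_class="PARCAT",
                  mappings={"ODD": "LEFT", "EVEN": "RIGHT"})
FRM_SCHEMA = dict(category_class="FRMCAT",
                  mappings={"DIG": "LEFT", "WRD": "RIGHT"})
LOC_SCHEMA = dict(category_class="LOCCAT", classify_by="location",
                  mappings={"ABOVE": "LEFT", "BELOW": "RIGHT"})

JUDGE_DEFAULTS = {"RSPMOD": "MANUAL", "RSPCTL": "BLOCKED"}


def make_schema(name, goal, cue, spec, object_class="", extra_defaults=None):
    defaults = dict(JUDGE_DEFAULTS)
    defaults.update(extra_defaults or {})
    return TaskSchema(name=name, goal=goal, cue=cue,
                      category_class=spec["category_class"],
                      classify_by=spec.get("classify_by", "prop"),
                      object_class=object_class,
                      mappings=dict(spec["mappings"]),
                      defaults=defaults)


def memory_schema(chunk_size=0, dref="ALL", task_span=False):
    defaults = {"MEMMOD": "ORAL", "RSPMOD": "NONE", "MAINT": "NORF",
                "RECALL": "OFF", "L0": chunk_size, "DREF": dref,
                "TSPAN": "alternating" if task_span else "sequential"}
    return TaskSchema(name="MEMTS", goal="MEM", cue="CMEM", modality="NONE",
                      defaults=defaults, memory=True)


# ---------------------------------------------------------------------------
# Designs and engine assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    study: str
    variant: str = ""
    n_subjects: int = 0
    factors: dict = field(default_factory=dict)
    dltm_text: str = ""
    rules_texts: list = field(default_factory=list)
    schemas: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)
    base_params: ModelParameters = field(default_factory=ModelParameters)


def make_engine(design: StudyDesign, params, seed, log=False) -> Engine:
    dltm = load_dltm(design.dltm_text)
    rules = []
    for text in design.rules_texts:
        rules.extend(parse_rules(text))
    return Engine(dltm, rules, params, design.schemas, seed, Environment(),
                  log_events=log)


def subject_params(design: StudyDesign, sid, seed):
    spec = sample_subject(sid, seed, design.base_params)
    return spec, spec.apply(design.base_params)


def _subject_seeds(master_seed, n):
    rng = Random(master_seed)
    return [rng.randrange(1 << 30) for _ in range(n)]


# ---------------------------------------------------------------------------
# Shared trial drivers
# ---------------------------------------------------------------------------

def expected_response(engine: Engine, schema: TaskSchema, target, pos=None):
    if schema.classify_by == "location":
        category = "ABOVE" if pos is not None and pos[1] < 4 else "BELOW"
    else:
        category = engine.dltm.prop(target, schema.category_class)
    return schema.mappings.get(category)


def _settle_trial(engine: Engine, iti):
    """Run the inter-trial interval, letting the learn rules finish."""
    for _ in range(iti):
        engine.run_cycle()
    if engine.learn_stage != 0 or engine.feedback_event() is not None:
        engine.run_until(lambda e: e.learn_stage == 0
                         and e.feedback_event() is None, max_cycles=40)
    if engine.learn_stage != 0:
        engine.end_trial()


def run_cued_trial(engine: Engine, schema: TaskSchema, target, cti_cycles,
                   condition, trial_index=0, window=300, iti=50,
                   with_cross=True):
    """One cued categorisation trial (fixation, cue, target, response)."""
    env = engine.env
    t0 = engine.cycle + 2
    cue_on = t0 + (50 if with_cross else 0)
    tgt_on = cue_on + cti_cycles
    if with_cross:
        env.add_event(ScheduledEvent("CROSS", position=CROSS_POS, start=t0,
                                     duration=50))
    env.add_event(ScheduledEvent(schema.cue, position=CUE_POS, start=cue_on,
                                 duration=window + cti_cycles,
                                 until_response=True, role="cue"))
    env.add_event(ScheduledEvent(target, position=TARGET_POS, start=tgt_on,
                                 duration=window, until_response=True,
                                 role="target"))
    rec = TrialRecord(trial=trial_index, condition=dict(condition),
                      target=target, onset=tgt_on)
    env.open(rec, expected_response(engine, schema, target))
    budget = (tgt_on - engine.cycle) + window + 10
    engine.run_until(lambda e: e.env.trial_done, max_cycles=budget)
    if not env.trial_done:
        env.on_timeout(engine.cycle)
        engine.end_trial()
    _settle_trial(engine, iti)
    return env.records[-1]


def run_embedded_judgment(engine: Engine, schema: TaskSchema, target, pos,
                          window, colour="BLACK", condition=None, iti=0):
    """One embedded judgment (no cue/cross; goal is already in place)."""
    env = engine.env
    onset = engine.cycle + 1
    env.add_event(ScheduledEvent(target, colour=colour, position=pos,
                                 start=onset, duration=window,
                                 until_response=True, role="target"))
    cond = dict(condition or {})
    cond["kind"] = "task"
    rec = TrialRecord(trial=0, condition=cond, target=target, onset=onset)
    env.open(rec, expected_response(engine, schema, target, pos))
    engine.run_until(lambda e: e.env.trial_done, max_cycles=window + 5)
    if not env.trial_done:
        env.on_timeout(engine.cycle)
        engine.end_trial()
    if iti:
        _settle_trial(engine, iti)
    return env.records[-1]


def begin_memory_series(engine: Engine, dual=False, setup_budget=220):
    """Present the memorisation cue and wait for refreshment to come up."""
    env = engine.env
    t0 = engine.cycle + 2
    env.add_event(ScheduledEvent("CMEM", position=CUE_POS, start=t0,
                                 duration=50, role="cue"))
    if dual:
        inst = engine.eb.begin_instance("DUAL", "COORD", None, engine.episode,
                                        engine.cycle, engine.rng["durations"],
                                        mark="ON", flag="INT")
        inst.pending = False
        inst.activation = 0.5   # standing coordination load
    engine.run_until(lambda e: e.refresh.enabled, max_cycles=setup_budget)


def finish_memory_series(engine: Engine, presented, condition,
                         recall_window=None, settle=30):
    """Present the recall cue, collect the output, close the series.

    Dual-task coordination ends with the processing phase: the COORD
    instance is released when recall is called for.
    """
    env = engine.env
    engine.list_ended = True
    for inst in engine.eb.instances:
        if inst.type == "COORD":
            inst.flag = "DONE"
            inst.mark = "OFF"
    engine.refresh.hold = False
    t0 = engine.cycle + 2
    env.add_event(ScheduledEvent("CRCL", position=CUE_POS, start=t0,
                                 duration=60, role="recall-cue"))
    budget = recall_window or (len(presented) * 220 + 2500)
    deadline = t0 + budget
    engine.run_until(lambda e: (e.recall is not None
                                and e.recall.action.status == "DONE")
                     or e.cycle >= deadline,
                     max_cycles=budget + 80)
    outputs = []
    if engine.recall is not None:
        outputs = [s for (s, c) in engine.recall.outputs if c <= deadline]
    rec = TrialRecord(trial=condition.get("series", 0),
                      condition=dict(condition))
    env.close_recall_trial(outputs, presented, engine.cycle, rec)
    engine.end_trial(purge_memory=True)
    for inst in engine.eb.instances:
        if inst.type == "COORD":
            inst.flag = "DONE"
            inst.mark = "OFF"
    for _ in range(settle):
        engine.run_cycle()
    return rec


# ---------------------------------------------------------------------------
# Study 1 — task switch cost and preparation
# ---------------------------------------------------------------------------

STUDY1_TRIADS = [("CMAG", "MAG", "MAGTS"),
                 ("CPAR", "PAR", "PARTS"),
                 ("CFRM", "FRM", "FRMTS")]


def build_study1(n_subjects=30) -> StudyDesign:
    values = [v for v in range(1, 10) if v != 5]
    dltm = "\n".join([load_text("standard.dltm"),
                      task_triad_nodes(STUDY1_TRIADS),
                      digit_nodes(values, pivot=5, words=True)])
    schemas = {
        "MAGTS": make_schema("MAGTS", "MAG", "CMAG", MAG_SCHEMA),
        "PARTS": make_schema("PARTS", "PAR", "CPAR", PAR_SCHEMA),
        "FRMTS": make_schema("FRMTS", "FRM", "CFRM", FRM_SCHEMA),
    }
    targets = [f"D{v}" for v in values] + [f"W{v}" for v in values]
    return StudyDesign(
        study="1", n_subjects=n_subjects,
        factors={"tasks": ["MAG", "PAR", "FRM"], "targets": targets,
                 "ctis_ms": list(range(0, 1000, 100))},
        dltm_text=dltm,
        rules_texts=[load_text("categorisation.rules")],
        schemas=schemas,
        timing={"window": 300, "iti": 50})


def study1_trials(design: StudyDesign, rng: Random):
    trials = [(task, target, cti)
              for task in design.factors["tasks"]
              for target in design.factors["targets"]
              for cti in design.factors["ctis_ms"]]
    rng.shuffle(trials)
    return trials


def run_study1_subject(design: StudyDesign, sid, seed, trials=None):
    spec, params = subject_params(design, sid, seed)
    engine = make_engine(design, params, seed)
    rng = Random(seed + 17)
    trials = trials if trials is not None else study1_trials(design, rng)
    schema_by_goal = {s.goal: s for s in design.schemas.values()}
    prev = None
    rows = []
    for i, (task, target, cti) in enumerate(trials):
        schema = schema_by_goal[task]
        cond = {"subject": sid, "task": task, "cti": cti,
                "transition": "first" if prev is None
                else ("repeat" if task == prev else "switch")}
        rec = run_cued_trial(engine, schema, target, cti // 10, cond,
                             trial_index=i,
                             window=design.timing["window"],
                             iti=design.timing["iti"])
        rows.append(rec.as_row())
        prev = task
    return pd.DataFrame(rows)


def run_study1(design: StudyDesign, seed, n_subjects=None,
               trials_per_subject=None):
    n = n_subjects or design.n_subjects
    frames = []
    for sid, sseed in enumerate(_subject_seeds(seed, n), start=1):
        rng = Random(sseed + 17)
        trials = study1_trials(design, rng)
        if trials_per_subject:
            trials = trials[:trials_per_subject]
        frames.append(run_study1_subject(design, sid, sseed, trials))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Study 2 — task and dimension switching
# ---------------------------------------------------------------------------

def build_study2(variant="combined", n_subjects=20) -> StudyDesign:
    values = [2, 3, 5, 6]
    stim = digit_nodes(values, pivot=4, words=True)
    if variant == "combined":
        triads = [("CMAG", "MAG", "MAGTS"), ("CMAGN", "MAGN", "MAGNTS"),
                  ("CPAR", "PAR", "PARTS"), ("CPARN", "PARN", "PARNTS")]
        dltm = "\n".join([load_text("standard.dltm"),
                          task_triad_nodes(triads), stim])
        schemas = {
            "MAGTS": make_schema("MAGTS", "MAG", "CMAG", MAG_SCHEMA, "DIGIT"),
            "MAGNTS": make_schema("MAGNTS", "MAGN", "CMAGN", MAG_SCHEMA,
                                  "NUMWORD"),
            "PARTS": make_schema("PARTS", "PAR", "CPAR", PAR_SCHEMA, "DIGIT"),
            "PARNTS": make_schema("PARNTS", "PARN", "CPARN", PAR_SCHEMA,
                                  "NUMWORD"),
        }
        rules = [load_text("categorisation.rules")]
    elif variant == "hierarchical":
        triads = [("CMAG", "MAG", "MAGTS"), ("CPAR", "PAR", "PARTS")]
        extra = [("CMAGN", "MAG", "MAGTS"), ("CPARN", "PAR", "PARTS")]
        cue_lines = []
        all_cues = ["CMAG", "CMAGN", "CPAR", "CPARN"]
        dim_of = {"CMAG": "DIGDIM", "CMAGN": "NUMDIM",
                  "CPAR": "DIGDIM", "CPARN": "NUMDIM"}
        goal_of = {"CMAG": "MAG", "CMAGN": "MAG",
                   "CPAR": "PAR", "CPARN": "PAR"}
        for cue in all_cues:
            opp = " ".join(f"link=OPP:{c}" for c in all_cues if c != cue)
            cue_lines.append(
                f"{cue} syllables=1 link=SUP:CUE link=PROP:{goal_of[cue]} "
                f"link=PROP:{dim_of[cue]} {opp}")
        goal_ts = ("MAG syllables=1 link=SUP:GOAL link=PROP:MAGTS link=OPP:PAR\n"
                   "PAR syllables=1 link=SUP:GOAL link=PROP:PARTS\n"
                   "MAGTS link=SUP:TSKSET link=OPP:PARTS\n"
                   "PARTS link=SUP:TSKSET")
        dltm = "\n".join([load_text("standard.dltm"),
                          "\n".join(cue_lines), goal_ts, stim])
        schemas = {
            "MAGTS": make_schema("MAGTS", "MAG", "CMAG", MAG_SCHEMA, "@DIM",
                                 {"DIM": "DIGDIM"}),
            "PARTS": make_schema("PARTS", "PAR", "CPAR", PAR_SCHEMA, "@DIM",
                                 {"DIM": "DIGDIM"}),
        }
        rules = [load_text("categorisation.rules"),
                 load_text("dimension.rules")]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return StudyDesign(
        study="2", variant=variant, n_subjects=n_subjects,
        factors={"cues": ["CMAG", "CMAGN", "CPAR", "CPARN"],
                 "values": values},
        dltm_text=dltm, rules_texts=rules, schemas=schemas,
        timing={"window": 350, "iti": 50})


#: cue -> (task, dimension)
CUE_FACTORS = {"CMAG": ("MAG", "DIG"), "CMAGN": ("MAG", "NUM"),
               "CPAR": ("PAR", "DIG"), "CPARN": ("PAR", "NUM")}


def run_study2_subject(design: StudyDesign, sid, seed, ctis_ms=(0,),
                       n_trials=96):
    spec, params = subject_params(design, sid, seed)
    engine = make_engine(design, params, seed)
    rng = Random(seed + 31)
    cues = design.factors["cues"]
    values = design.factors["values"]
    rows = []
    prev = None
    for i in range(n_trials):
        cue = cues[rng.randrange(4)]
        cti = ctis_ms[rng.randrange(len(ctis_ms))]
        dv, wv = rng.choice(values), rng.choice(values)
        task, dim = CUE_FACTORS[cue]
        if design.variant == "combined":
            goal = {"CMAG": "MAG", "CMAGN": "MAGN",
                    "CPAR": "PAR", "CPARN": "PARN"}[cue]
            schema = next(s for s in design.schemas.values()
                          if s.goal == goal)
        else:
            schema = next(s for s in design.schemas.values()
                          if s.goal == task)
        target = f"D{dv}" if dim == "DIG" else f"W{wv}"
        cond = {"subject": sid, "cue": cue, "task": task, "dim": dim,
                "cti": cti}
        if prev is not None:
            cond["task_trans"] = "rep" if task == prev[0] else "sw"
            cond["dim_trans"] = "rep" if dim == prev[1] else "sw"
        env = engine.env
        t0 = engine.cycle + 2
        cue_on = t0 + 50
        tgt_on = cue_on + cti // 10
        window = design.timing["window"]
        env.add_event(ScheduledEvent("CROSS", position=CROSS_POS, start=t0,
                                     duration=50))
        env.add_event(ScheduledEvent(cue, position=CUE_POS, start=cue_on,
                                     duration=window + cti // 10,
                                     until_response=True, role="cue"))
        env.add_event(ScheduledEvent(f"D{dv}", position=(3, 4), start=tgt_on,
                                     duration=window, until_response=True,
                                     role="target"))
        env.add_event(ScheduledEvent(f"W{wv}", position=(5, 4), start=tgt_on,
                                     duration=window, until_response=True,
                                     role="target"))
        rec = TrialRecord(trial=i, condition=cond, target=target,
                          onset=tgt_on)
        env.open(rec, expected_response(engine, schema, target))
        engine.run_until(lambda e: e.env.trial_done,
                         max_cycles=(tgt_on - engine.cycle) + window + 10)
        if not env.trial_done:
            env.on_timeout(engine.cycle)
            engine.end_trial()
        _settle_trial(engine, design.timing["iti"])
        rows.append(env.records[-1].as_row())
        prev = (task, dim)
    return pd.DataFrame(rows)


def run_study2(design: StudyDesign, seed, n_subjects=None, ctis_ms=(0,),
               n_trials=96):
    n = n_subjects or design.n_subjects
    frames = [run_study2_subject(design, sid, sseed, ctis_ms, n_trials)
              for sid, sseed in enumerate(_subject_seeds(seed, n), start=1)]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Study 3 — complex span under cognitive load
# ---------------------------------------------------------------------------

#: burst size -> (digit on, digit off) in cycles
BURST_TIMING = {4: (107, 53), 6: (71, 36), 8: (53, 27)}

LETTERS_20 = ["WB", "WC", "WD", "WF", "WG", "WH", "WJ", "WK", "WL", "WM",
              "WN", "WP", "WQ", "WR", "WS", "WT", "WV", "WX", "WY", "WZ"]


def build_study3(n_per_cell=16) -> StudyDesign:
    values = [v for v in range(1, 10) if v != 5]
    triads = [("CPAR", "PAR", "PARTS"), ("CLOC", "LOC", "LOCTS")]
    dltm = "\n".join([load_text("standard.dltm"),
                      task_triad_nodes(triads),
                      digit_nodes(values, pivot=5, words=False),
                      letter_nodes(LETTERS_20)])
    schemas = {
        "PARTS": make_schema("PARTS", "PAR", "CPAR", PAR_SCHEMA),
        "LOCTS": make_schema("LOCTS", "LOC", "CLOC", LOC_SCHEMA),
        "MEMTS": memory_schema(),
    }
    return StudyDesign(
        study="3", n_subjects=n_per_cell * 6,
        factors={"tasks": ["parity", "location"], "bursts": [4, 6, 8],
                 "lengths": list(range(1, 8)), "series_per_length": 3,
                 "n_per_cell": n_per_cell},
        dltm_text=dltm,
        rules_texts=[load_text("categorisation.rules"),
                     load_text("location.rules"),
                     load_text("memory.rules"), load_text("dual.rules"),
                     load_text("fixedtask.rules")],
        schemas=schemas,
        timing={"letter_on": 150, "letter_gap": 50, "practice": 4})


def run_study3_subject(design: StudyDesign, sid, seed, task, burst,
                       lengths=None, series_per_length=None):
    spec, params = subject_params(design, sid, seed)
    engine = make_engine(design, params, seed)
    rng = Random(seed + 7)
    schema = design.schemas["PARTS" if task == "parity" else "LOCTS"]
    values = [v for v in range(1, 10) if v != 5]
    on, off = BURST_TIMING[burst]
    # single-task practice (also loads the judgment goal and task set)
    for k in range(design.timing["practice"]):
        digit = f"D{rng.choice(values)}"
        pos = ABOVE_POS if rng.random() < 0.5 else BELOW_POS
        run_cued_trial(engine, schema, digit, 50,
                       {"subject": sid, "phase": "practice", "kind": "task"},
                       window=300, iti=30, with_cross=(k == 0))
    lengths = lengths or design.factors["lengths"]
    reps = series_per_length or design.factors["series_per_length"]
    series_rows, digit_rows = [], []
    series_ix = 0
    for rep in range(reps):
        for length in lengths:
            letters = rng.sample(LETTERS_20, length)
            begin_memory_series(engine, dual=True)
            burst_times = []
            for li, letter in enumerate(letters):
                t_letter = engine.cycle + 2
                engine.env.add_event(ScheduledEvent(
                    letter, position=CROSS_POS, start=t_letter,
                    duration=design.timing["letter_on"], role="memo"))
                engine.run_until(
                    lambda e: e.cycle >= t_letter
                    + design.timing["letter_on"]
                    + design.timing["letter_gap"], max_cycles=100000)
                occupied = 0
                for d in range(burst):
                    digit = f"D{rng.choice(values)}"
                    pos = ABOVE_POS if rng.random() < 0.5 else BELOW_POS
                    t_d = engine.cycle
                    rec = run_embedded_judgment(
                        engine, schema, digit, pos, window=on + off - 2,
                        condition={"subject": sid, "task": task,
                                   "burst": burst, "length": length,
                                   "phase": "dual"})
                    if rec.response != "TIMEOUT":
                        occupied += rec.response_cycle - rec.onset
                    else:
                        occupied += on + off - 2
                    digit_rows.append(rec.as_row())
                    slot_end = t_d + on + off
                    if engine.cycle < slot_end:
                        engine.run_until(lambda e: e.cycle >= slot_end,
                                         max_cycles=on + off + 5)
                burst_times.append(occupied)
            series_ix += 1
            mean_occ = sum(burst_times) / len(burst_times)
            rec = finish_memory_series(
                engine, letters,
                {"subject": sid, "task": task, "burst": burst,
                 "length": length, "series": series_ix,
                 "occupied_ms": mean_occ * 10.0},
                recall_window=length * 80 + 150)
            series_rows.append(rec.as_row())
    return pd.DataFrame(series_rows), pd.DataFrame(digit_rows)


def run_study3(design: StudyDesign, seed, n_per_cell=None, lengths=None,
               series_per_length=None):
    n = n_per_cell or design.factors["n_per_cell"]
    cells = [(task, burst) for task in design.factors["tasks"]
             for burst in design.factors["bursts"]]
    seeds = _subject_seeds(seed, n * len(cells))
    series_frames, digit_frames = [], []
    sid = 0
    for (task, burst) in cells:
        for _ in range(n):
            sid += 1
            s, d = run_study3_subject(design, sid, seeds[sid - 1], task,
                                      burst, lengths, series_per_length)
            series_frames.append(s)
            digit_frames.append(d)
    return (pd.concat(series_frames, ignore_index=True),
            pd.concat(digit_frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Study 4 — memory span versus task span
# ---------------------------------------------------------------------------

LIST_LENGTHS = {"2468": [2, 4, 6, 8], "2369": [2, 3, 6, 9]}


def build_study4(chunking=0, n_subjects=32) -> StudyDesign:
    values = [v for v in range(1, 10) if v != 5]
    dltm = "\n".join([load_text("standard.dltm"),
                      task_triad_nodes(STUDY1_TRIADS),
                      memoranda_task_names(STUDY1_TRIADS),
                      digit_nodes(values, pivot=5, words=True)])
    schemas = {
        "MAGTS": make_schema("MAGTS", "MAG", "CMAG", MAG_SCHEMA),
        "PARTS": make_schema("PARTS", "PAR", "CPAR", PAR_SCHEMA),
        "FRMTS": make_schema("FRMTS", "FRM", "CFRM", FRM_SCHEMA),
        "MEMTS": memory_schema(chunk_size=chunking),
    }
    return StudyDesign(
        study="4", variant=f"L{chunking}", n_subjects=n_subjects,
        factors={"list_types": ["2468", "2369"], "rsis_ms": [100, 1000],
                 "sequences": 48, "chunking": chunking},
        dltm_text=dltm,
        rules_texts=[load_text("categorisation.rules"),
                     load_text("memory.rules"), load_text("dual.rules"),
                     load_text("taskspan.rules")],
        schemas=schemas,
        timing={"memo_on": 100, "exec_window": 300})


def task_name_list(length, rng: Random):
    """Random task names, all three used before any repeats."""
    names = ["TMAG", "TPAR", "TFRM"]
    out = []
    while len(out) < length:
        block = names[:]
        rng.shuffle(block)
        if out and block[0] == out[-1]:
            block[0], block[1] = block[1], block[0]
        out.extend(block)
    return out[:length]


def run_study4_block(engine: Engine, design, sid, rng, span_type, list_type,
                     rsi_cycles, reps):
    lengths = LIST_LENGTHS[list_type]
    values = [v for v in range(1, 10) if v != 5]
    goal_of = {"TMAG": "MAG", "TPAR": "PAR", "TFRM": "FRM"}
    schema_of = {"MAG": design.schemas["MAGTS"],
                 "PAR": design.schemas["PARTS"],
                 "FRM": design.schemas["FRMTS"]}
    rows = []
    series_ix = 0
    for rep in range(reps):
        for length in lengths:
            names = task_name_list(length, rng)
            series_ix += 1
            begin_memory_series(engine, dual=False)
            for name in names:
                t0 = engine.cycle + 2
                engine.env.add_event(ScheduledEvent(
                    name, position=CROSS_POS, start=t0,
                    duration=design.timing["memo_on"], role="memo"))
                engine.run_until(
                    lambda e: e.cycle >= t0 + design.timing["memo_on"]
                    + rsi_cycles, max_cycles=100000)
            cond = {"subject": sid, "span_type": span_type,
                    "list_type": list_type, "length": length,
                    "series": series_ix}
            if span_type == "memory":
                rec = finish_memory_series(engine, names, cond)
                rows.append(rec.as_row())
            else:
                rec = _run_task_span_test(engine, design, names, cond, rng,
                                          values, goal_of, schema_of)
                rows.append(rec.as_row())
    return pd.DataFrame(rows)


def _run_task_span_test(engine: Engine, design, names, cond, rng, values,
                        goal_of, schema_of):
    """Recall alternating with execution: each recalled name is applied to
    a waiting target; the retrieval action resumes after the response."""
    env = engine.env
    engine.list_ended = True
    t0 = engine.cycle + 2
    env.add_event(ScheduledEvent("CRCL", position=CUE_POS, start=t0,
                                 duration=60, role="recall-cue"))
    exec_ok: list[bool] = []
    budget = len(names) * 900 + 3000
    deadline = engine.cycle + budget
    while engine.cycle < deadline:
        engine.run_until(
            lambda e: e.recall is not None
            and e.recall.action.status in ("DONE", "HOLD"),
            max_cycles=deadline - engine.cycle)
        if engine.recall is None or engine.recall.action.status == "DONE":
            break
        if engine.recall.action.status != "HOLD":
            break
        recalled = engine.recall.outputs[-1][0]
        goal = goal_of.get(recalled)
        target = f"D{rng.choice(values)}" if rng.random() < 0.5 \
            else f"W{rng.choice(values)}"
        if goal is None:
            exec_ok.append(False)
        else:
            schema = schema_of[goal]
            rec = run_embedded_judgment(
                engine, schema, target, TARGET_POS,
                window=design.timing["exec_window"],
                condition={"phase": "taskspan"}, iti=40)
            exec_ok.append(bool(rec.correct))
        if engine.recall is not None \
                and engine.recall.action.status == "HOLD":
            engine.recall.action.status = "ON"
    outputs = []
    if engine.recall is not None:
        outputs = engine.recall.recalled_sequence()
    rec = TrialRecord(trial=cond.get("series", 0), condition=dict(cond))
    env.close_recall_trial(outputs, names, engine.cycle, rec)
    # a position counts only when the right task was recalled AND executed
    rec.position_correct = [ok and (i < len(exec_ok) and exec_ok[i])
                            for i, ok in enumerate(rec.position_correct)]
    engine.end_trial(purge_memory=True)
    for _ in range(30):
        engine.run_cycle()
    return rec


def run_study4_subject(design: StudyDesign, sid, seed, list_type, rsi_ms,
                       reps=6, order=("memory", "task")):
    spec, params = subject_params(design, sid, seed)
    rng = Random(seed + 13)
    rows = []
    for span_type in order:
        task_span = span_type == "task"
        schemas = dict(design.schemas)
        schemas["MEMTS"] = memory_schema(
            chunk_size=design.factors["chunking"], task_span=task_span)
        block_design = StudyDesign(
            study="4", variant=design.variant, dltm_text=design.dltm_text,
            rules_texts=design.rules_texts, schemas=schemas,
            timing=design.timing, factors=design.factors,
            base_params=design.base_params)
        engine = make_engine(block_design, params, seed + (1 if task_span
                                                           else 0))
        rows.append(run_study4_block(engine, block_design, sid, rng,
                                     span_type, list_type, rsi_ms // 10,
                                     reps))
    return pd.concat(rows, ignore_index=True)


def run_study4(design: StudyDesign, seed, n_subjects=None, reps=6,
               list_types=None, rsis_ms=None):
    n = n_subjects or design.n_subjects
    list_types = list_types or design.factors["list_types"]
    rsis = rsis_ms or design.factors["rsis_ms"]
    seeds = _subject_seeds(seed, n)
    frames = []
    for sid, sseed in enumerate(seeds, start=1):
        list_type = list_types[(sid - 1) % len(list_types)]
        rsi = rsis[((sid - 1) // len(list_types)) % len(rsis)]
        order = ("memory", "task") if sid % 2 else ("task", "memory")
        df = run_study4_subject(design, sid, sseed, list_type, rsi,
                                reps=reps, order=order)
        df["rsi"] = rsi
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Study 5 — task switching inside a serial-recall task
# ---------------------------------------------------------------------------

CONSONANTS = ["WB", "WC", "WD", "WF", "WG", "WH", "WJ", "WK", "WL", "WM",
              "WN", "WP", "WR", "WS", "WT", "WV", "WX", "WZ"]


def build_study5(exp=1, n_subjects=32) -> StudyDesign:
    values = [v for v in range(1, 10) if v != 5]
    triads = [("CMAG", "MAG", "MAGTS"), ("CPAR", "PAR", "PARTS")]
    dltm = "\n".join([load_text("standard.dltm"),
                      task_triad_nodes(triads),
                      digit_nodes(values, pivot=5, words=False),
                      letter_nodes(CONSONANTS)])
    schemas = {
        "MAGTS": make_schema("MAGTS", "MAG", "CMAG", MAG_SCHEMA),
        "PARTS": make_schema("PARTS", "PAR", "CPAR", PAR_SCHEMA),
        "MEMTS": memory_schema(),
    }
    base = ModelParameters(theta=0.40)   # strict timing: lowered threshold
    lengths = list(range(3, 9)) if exp == 3 else list(range(3, 7))
    return StudyDesign(
        study="5", variant=f"exp{exp}", n_subjects=n_subjects,
        factors={"exp": exp, "lengths": lengths, "tasks_per_list": 8,
                 "inter_digit": 120},
        dltm_text=dltm,
        rules_texts=[load_text("categorisation.rules"),
                     load_text("memory.rules"), load_text("dual.rules"),
                     load_text("colourcue.rules")],
        schemas=schemas, base_params=base,
        timing={"letter_on": 100, "letter_gap": 20, "digit_on": 100,
                "digit_off": 20, "practice": 4})


def colour_sequence(exp, list_kind, n_tasks, rng: Random):
    """Colour (task) sequence for one embedded task list."""
    if list_kind == "single":
        col = "RED" if rng.random() < 0.5 else "BLUE"
        return [col] * n_tasks
    if list_kind == "alternating":
        first = "RED" if rng.random() < 0.5 else "BLUE"
        other = "BLUE" if first == "RED" else "RED"
        return [first if i % 2 == 0 else other for i in range(n_tasks)]
    # few (2-3) or many (5-6) switches at random positions
    k = rng.choice([2, 3]) if list_kind == "few" else rng.choice([5, 6])
    gaps = rng.sample(range(1, n_tasks), k)
    seq = []
    col = "RED" if rng.random() < 0.5 else "BLUE"
    for i in range(n_tasks):
        if i in gaps:
            col = "BLUE" if col == "RED" else "RED"
        seq.append(col)
    return seq


def _run_digit_list(engine, design, schemas, colours, rng, values, cond):
    on, off = design.timing["digit_on"], design.timing["digit_off"]
    slot = design.factors["inter_digit"]
    for colour in colours:
        digit = f"D{rng.choice(values)}"
        schema = schemas["MAGTS" if colour == "RED" else "PARTS"]
        t_d = engine.cycle
        run_embedded_judgment(engine, schema, digit, TARGET_POS,
                              window=slot - 10, colour=colour,
                              condition=cond)
        slot_end = t_d + slot
        if engine.cycle < slot_end:
            engine.run_until(lambda e: e.cycle >= slot_end,
                             max_cycles=slot + 5)


def run_study5_subject(design: StudyDesign, sid, seed, list_kinds,
                       reps_per_length=1):
    spec, params = subject_params(design, sid, seed)
    engine = make_engine(design, params, seed)
    rng = Random(seed + 23)
    values = [v for v in range(1, 10) if v != 5]
    exp = design.factors["exp"]
    n_tasks = design.factors["tasks_per_list"]
    # colour-cued practice digits (loads both judgment task sets)
    for _ in range(design.timing["practice"]):
        colour = "RED" if rng.random() < 0.5 else "BLUE"
        schema = design.schemas["MAGTS" if colour == "RED" else "PARTS"]
        run_embedded_judgment(engine, schema, f"D{rng.choice(values)}",
                              TARGET_POS, window=250, colour=colour, iti=25)
    rows = []
    series_ix = 0
    for rep in range(reps_per_length):
        for length in design.factors["lengths"]:
            for kind in list_kinds:
                series_ix += 1
                letters = rng.sample(CONSONANTS, length)
                begin_memory_series(engine, dual=True)
                cond = {"subject": sid, "exp": exp, "list_kind": kind,
                        "length": length, "series": series_ix}
                if exp == 3:
                    for letter in letters:
                        t0 = engine.cycle + 2
                        engine.env.add_event(ScheduledEvent(
                            letter, position=CROSS_POS, start=t0,
                            duration=design.timing["letter_on"],
                            role="memo"))
                        engine.run_until(
                            lambda e: e.cycle >= t0
                            + design.timing["letter_on"]
                            + design.timing["letter_gap"],
                            max_cycles=100000)
                    for _ in range(4):
                        colours = colour_sequence(exp, kind, n_tasks, rng)
                        _run_digit_list(engine, design, design.schemas,
                                        colours, rng, values,
                                        {**cond, "kind": "task"})
                else:
                    for letter in letters:
                        t0 = engine.cycle + 2
                        engine.env.add_event(ScheduledEvent(
                            letter, position=CROSS_POS, start=t0,
                            duration=design.timing["letter_on"],
                            role="memo"))
                        engine.run_until(
                            lambda e: e.cycle >= t0
                            + design.timing["letter_on"]
                            + design.timing["letter_gap"],
                            max_cycles=100000)
                        colours = colour_sequence(exp, kind, n_tasks, rng)
                        _run_digit_list(engine, design, design.schemas,
                                        colours, rng, values,
                                        {**cond, "kind": "task"})
                rec = finish_memory_series(
                    engine, letters, cond,
                    recall_window=length * 90 + 200)
                rows.append(rec.as_row())
    return pd.DataFrame(rows)


def run_study5(design: StudyDesign, seed, n_subjects=None,
               reps_per_length=1):
    exp = design.factors["exp"]
    kinds = {1: ["single", "alternating"],
             2: ["few", "many"],
             3: ["few", "many"]}[exp]
    n = n_subjects or design.n_subjects
    frames = [run_study5_subject(design, sid, sseed, kinds, reps_per_length)
              for sid, sseed in enumerate(_subject_seeds(seed, n), start=1)]
    return pd.concat(frames, ignore_index=True)
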