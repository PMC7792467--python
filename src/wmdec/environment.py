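"""The simulated experimental environment.

Trials are lists of scheduled events (a fixation cross, cues, targets,
memoranda, empty intervals).  An event runs from ``start`` for ``duration``
cycles up to and including ``start + duration - 1``.  Events that wait for a
response keep a planned window; when the response arrives their registered
end is the response cycle and their registered duration is ``end - start``,
and all later events are shifted to begin right after the response.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field


@dataclass
class ScheduledEvent:
    name: str
    colour: str = "BLACK"
    modality: str = "VSP"          # VSP or AUD
    position: tuple | None = None  # grid coordinate, VSP only
    start: int = 0
    duration: int = 1
    end: int = 0
    until_response: bool = False   # cue/target terminated by the response
    role: str = ""                 # cue / target / memo / recall-cue / other
    registered: bool = False       # delivered into sensory memory
    cleared: bool = False

    def __post_init__(self):
        if self.duration < 1:
            raise ScheduleError(f"event {self.name}: duration must be >= 1")
        if not self.end:
            self.end = self.start + self.duration - 1
        if self.end < self.start:
            raise ScheduleError(f"event {self.name}: end precedes start")


class ScheduleError(ValueError):
    pass


@dataclass
class TrialRecord:
    trial: int
    condition: dict = field(default_factory=dict)
    target: str = ""
    onset: int = 0
    response: str = "TIMEOUT"
    response_cycle: int = -1
    rt_ms: float = float("nan")
    correct: bool = False
    recall_output: list = field(default_factory=list)
    presented: list = field(default_factory=list)
    position_correct: list = field(default_factory=list)

    def as_row(self):
        row = dict(self.condition)
        row.update(trial=self.trial, target=self.target, onset=self.onset,
                   response=self.response, response_cycle=self.response_cycle,
                   rt_ms=self.rt_ms, correct=int(self.correct),
                   recall_output="|".join(self.recall_output),
                   presented="|".join(self.presented),
                   span=sum(self.position_correct),
                   list_correct=int(bool(self.position_correct)
                                    and all(self.position_correct)))
        return row


def current_stimuli(events, cycle):
    """Events active at `cycle` (start <= cycle <= end)."""
    active = [e for e in events if e.start <= cycle <= e.end]
    by_pos = {}
    for e in active:
        if e.modality == "VSP" and e.position is not None:
            if e.position in by_pos:
                raise ScheduleError(
                    f"overlapping visual events at {e.position} @ cycle {cycle}")
            by_pos[e.position] = e
    return active


def register_response(events, response_cycle):
    """Adapt a schedule after a response (printed-arithmetic convention).

    Response-terminated events get ``end = response_cycle`` and
    ``duration = end - start``; later events are shifted to start at
    ``response_cycle + 1`` with their planned durations.
    """
    adapted = []
    for e in events:
        if e.until_response and e.start <= response_cycle <= e.end:
            e.end = response_cycle
            e.duration = e.end - e.start
            e.until_response = False
            adapted.append(e)
        elif e.start > response_cycle:
            shift = response_cycle + 1 - e.start
            e.start += shift
            e.end = e.start + e.duration - 1
    return adapted


def score_recall(output, presented):
    """Positional scoring: position i correct iff output[i] == presented[i]."""
    correct = []
    for i, item in enumerate(presented):
        correct.append(i < len(output) and output[i] == item)
    return correct


class Environment:
    """Mutable event schedule plus per-trial response bookkeeping."""

    def __init__(self):
        self.events: list[ScheduledEvent] = []
        self.records: list[TrialRecord] = []
        self.open_trial: TrialRecord | None = None
        self.trial_mapping: dict = {}     # response evaluation for open trial
        self.trial_done = False
        self.stray_responses: list = []

    # -- schedule management ----------------------------------------------

    def add_event(self, event: ScheduledEvent):
        self.events.append(event)
        return event

    def open(self, record: TrialRecord, correct_response=None):
        self.open_trial = record
        self.trial_mapping = {"correct": correct_response}
        self.trial_done = False

    def active(self, cycle):
        return current_stimuli(self.events, cycle)

    def deliverable(self, cycle):
        """Visual/auditory events that should enter sensory memory now."""
        return [e for e in self.events
                if not e.registered and e.start <= cycle <= e.end]

    def expired(self, cycle):
        return [e for e in self.events
                if not e.cleared and e.end < cycle]

    def gc(self, cycle):
        self.events = [e for e in self.events if e.end >= cycle - 5]

    # -- response handling -------------------------------------------------

    def on_response(self, response, cycle):
        rec = self.open_trial
        if rec is None:
            self.stray_responses.append((response, cycle))
            return None
        register_response(self.events, cycle)
        rec.response = response
        rec.response_cycle = cycle
        rec.rt_ms = (cycle - rec.onset) * 10.0
        expected = self.trial_mapping.get("correct")
        rec.correct = (expected is not None and response == expected)
        self.trial_done = True
        self.open_trial = None
        self.records.append(rec)
        return rec

    def on_timeout(self, cycle):
        rec = self.open_trial
        if rec is None:
            return None
        rec.response = "TIMEOUT"
        rec.response_cycle = cycle
        rec.correct = False
        self.trial_done = True
        self.open_trial = None
        self.records.append(rec)
        return rec

    def close_recall_trial(self, output, presented, cycle, record):
        record.recall_output = list(output)
        record.presented = list(presented)
        record.position_correct = score_recall(output, presented)
        record.response_cycle = cycle
        self.records.append(record)
        self.trial_done = True
        return record


SCHEDULE_COLUMNS = ["NAME", "COLOUR", "MODALITY", "POSITION", "START",
                    "DURATION", "END"]


def events_to_csv(events) -> str:
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(SCHEDULE_COLUMNS)
    for e in events:
        pos = f"{e.position[0]},{e.position[1]}" if e.position else ""
        w.writerow([e.name, e.colour, e.modality, pos,
                    e.start, e.duration, e.end])
    return buf.getvalue()


def events_from_csv(text) -> list:
    rd = csv.DictReader(io.StringIO(text))
    out = []
    for row in rd:
        pos = None
        if row.get("POSITION"):
            x, _, y = row["POSITION"].partition(",")
            pos = (int(x), int(y))
        ev = ScheduledEvent(
            name=row["NAME"], colour=row.get("COLOUR", "BLACK"),
            modality=row.get("MODALITY", "VSP"), position=pos,
            start=int(row["START"]), duration=int(row["DURATION"]))
        if row.get("END"):
            ev.end = int(row["END"])
        out.append(ev)
    return out
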