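"""Sensory registers, gaze control, and motor response competition.

Visual input lands in a 9x9 iconic store (one object per cell, NEW/CHANGE/
FADE/GONE flags), auditory input in a single echoic slot.  Only the fixated
cell and its eight neighbours are perceivable; events elsewhere trigger a
saccade (3-6 cycles, distance dependent) during which no visual change is
registered.  Responses race to a threshold as noisy accumulators: an
intentional stream (drift zeta) versus an automatic stream (slower drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

from .params import ModelParameters

GRID = 9


@dataclass
class IconicCell:
    name: str = ""
    flag: str = "EMPTY"    # EMPTY, NEW, CHANGE, FADE, GONE
    colour: str = ""
    strength: float = 0.0


class IconicStore:
    """9x9 iconic sensory memory; at most one object per cell."""

    FADE_AFTER = 20       # cycles after which a static object starts to fade
    GONE_AFTER = 30       # cycles GONE persists before the cell empties

    def __init__(self):
        self.cells: dict[tuple, IconicCell] = {}
        self._ages: dict[tuple, int] = {}

    def put(self, name, pos, colour="BLACK"):
        cell = self.cells.get(pos)
        if cell is None or cell.flag in ("EMPTY", "GONE"):
            self.cells[pos] = IconicCell(name=name, flag="NEW", colour=colour,
                                         strength=1.0)
        else:
            cell.name, cell.flag, cell.colour = name, "CHANGE", colour
            cell.strength = 1.0
        self._ages[pos] = 0

    def clear(self, pos):
        cell = self.cells.get(pos)
        if cell is not None and cell.flag not in ("EMPTY", "GONE"):
            cell.flag = "GONE"
            self._ages[pos] = 0

    def step(self):
        for pos, cell in list(self.cells.items()):
            age = self._ages.get(pos, 0) + 1
            self._ages[pos] = age
            if cell.flag in ("NEW", "CHANGE") and age > self.FADE_AFTER:
                cell.flag = "FADE"
            elif cell.flag == "GONE" and age > self.GONE_AFTER:
                del self.cells[pos]
                del self._ages[pos]
            if cell.flag == "FADE":
                cell.strength *= 0.97

    def seen(self, pos):
        """Mark an object as attended (no longer NEW/CHANGE)."""
        cell = self.cells.get(pos)
        if cell is not None and cell.flag in ("NEW", "CHANGE"):
            cell.flag = "FADE"
            self._ages[pos] = self.FADE_AFTER

    def present(self, name):
        return any(c.name == name and c.flag not in ("GONE", "EMPTY")
                   for c in self.cells.values())

    def new_items(self, area=None):
        out = []
        for pos, cell in self.cells.items():
            if cell.flag in ("NEW", "CHANGE"):
                if area is None or pos in area:
                    out.append((pos, cell))
        out.sort(key=lambda pc: pc[0])
        return out


@dataclass
class EchoicSlot:
    """Single-slot echoic sensory memory (one auditory location)."""

    name: str = ""
    flag: str = "EMPTY"    # BUSY, NEW, CHANGE, FADE, GONE (or EMPTY)
    strength: float = 0.0
    _age: int = 0

    GONE_AFTER = 150       # 1.5 s after stream end

    def put(self, name):
        if self.flag in ("EMPTY", "GONE"):
            self.flag = "NEW"
        else:
            self.flag = "CHANGE"
        self.name = name
        self.strength = 1.0
        self._age = 0

    def end_stream(self):
        if self.flag not in ("EMPTY",):
            self.flag = "FADE"
            self._age = 0

    def step(self):
        self._age += 1
        if self.flag == "FADE" and self._age > self.GONE_AFTER:
            self.flag = "GONE"

    def seen(self):
        if self.flag in ("NEW", "CHANGE"):
            self.flag = "FADE"
            self._age = 0


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------

def chebyshev(a, b):
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


@dataclass
class GazeState:
    """Fixation point, drift timer, and saccade programming."""

    status: str = "FIXATION"   # FIXATION, PREP_RANDOM, PREP_STIMULUS, SACCADE
    fixation: tuple = (4, 4)
    next: tuple = (4, 4)
    saccade_left: int = 0
    distance: int = 0
    fixation_left: int = 20
    home: tuple = (4, 4)       # display region the drift stays tethered to

    def fixated_area(self):
        fx, fy = self.fixation
        return {(fx + dx, fy + dy)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                if 0 <= fx + dx < GRID and 0 <= fy + dy < GRID}


def saccade_duration(distance: int) -> int:
    """3-6 cycles depending on distance (clamped)."""
    return min(6, max(3, 2 + distance))


def update_gaze(gaze: GazeState, ism: IconicStore, rng: Random, cycle: int):
    """Per-cycle gaze control: saccade execution, stimulus capture, drift."""
    if gaze.status == "SACCADE":
        gaze.saccade_left -= 1
        if gaze.saccade_left <= 0:
            gaze.fixation = gaze.next
            gaze.status = "FIXATION"
            gaze.fixation_left = max(1, int(round(20 + 3 * rng.gauss(0.0, 1.0))))
        return
    area = gaze.fixated_area()
    outside = [pos for pos, cell in ism.cells.items()
               if cell.flag in ("NEW", "CHANGE") and pos not in area]
    if outside:
        target = min(outside, key=lambda p: chebyshev(p, gaze.fixation))
        gaze.next = target
        gaze.home = target
        gaze.distance = chebyshev(target, gaze.fixation)
        gaze.saccade_left = saccade_duration(gaze.distance)
        gaze.status = "SACCADE"
        return
    gaze.fixation_left -= 1
    if gaze.fixation_left <= 0:
        fx, fy = gaze.fixation
        moves = [(fx + dx, fy + dy)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 if (dx, dy) != (0, 0)
                 and 0 <= fx + dx < GRID and 0 <= fy + dy < GRID]
        # the drift random-walks but stays tethered to the display region
        tethered = [p for p in moves if chebyshev(p, gaze.home) <= 1]
        if tethered:
            moves = tethered
        gaze.next = moves[rng.randrange(len(moves))]
        gaze.distance = 1
        gaze.saccade_left = saccade_duration(1)
        gaze.status = "SACCADE"


# ---------------------------------------------------------------------------
# Motor system
# ---------------------------------------------------------------------------

@dataclass
class Tendency:
    stream: str               # "intentional" or "automatic"
    response: str
    activation: float = 0.0


@dataclass
class MotorState:
    """Response preparation and the random-walk race to threshold."""

    modality: str = "NONE"      # NONE, ORAL, MANUAL
    status: str = "BLOCKED"     # BLOCKED, UNBLOCK, DONE
    threshold: float = 0.50
    last_change_episode: int = -1
    sat_parameter: str = "NEUTRAL"
    sat_strength: float = 0.25
    tendencies: list = field(default_factory=list)
    emitted: str | None = None
    emitted_cycle: int = -1
    consecutive_correct: int = 0
    suppressed: list = field(default_factory=list)

    def init(self, modality, params: ModelParameters):
        self.modality = modality
        self.status = "BLOCKED"

    def get_stream(self, stream):
        for t in self.tendencies:
            if t.stream == stream:
                return t
        return None

    def start(self, stream, response):
        t = self.get_stream(stream)
        if t is None:
            self.tendencies.append(Tendency(stream=stream, response=response))
        elif t.response != response:
            t.response = response
            t.activation = 0.0

    def clear(self):
        self.tendencies = []
        self.emitted = None


def step_response_competition(motor: MotorState, params: ModelParameters,
                              rng: Random, cycle: int):
    """One cycle of the race; emits the first tendency to cross threshold.

    Each tendency gains ``lambda*r + zeta_k`` per cycle (r ~ N(0,1)); on a
    within-cycle tie the intentional stream wins.  An emission attempted
    while the motor system is BLOCKED is suppressed and logged.
    """
    if not motor.tendencies or motor.status == "DONE":
        return None
    crossed = []
    for t in motor.tendencies:
        drift = params.zeta if t.stream == "intentional" else params.zeta_auto
        t.activation += params.lam * rng.gauss(0.0, 1.0) + drift
        if t.activation < 0.0:
            t.activation = 0.0
        if t.activation >= motor.threshold:
            crossed.append(t)
    if not crossed:
        return None
    crossed.sort(key=lambda t: 0 if t.stream == "intentional" else 1)
    winner = crossed[0]
    if motor.status == "BLOCKED":
        motor.suppressed.append((winner.response, cycle))
        winner.activation = 0.0
        return None
    motor.emitted = winner.response
    motor.emitted_cycle = cycle
    return winner


def adjust_threshold(motor: MotorState, evaluation: str,
                     params: ModelParameters):
    """Speed-accuracy control: lower after sustained success, raise on error."""
    if evaluation == "CORRECT":
        motor.consecutive_correct += 1
        if motor.consecutive_correct >= params.theta_k:
            motor.threshold = max(params.theta_low,
                                  motor.threshold - params.theta_step_down)
            motor.consecutive_correct = 0
    else:
        motor.consecutive_correct = 0
        motor.threshold = min(params.theta_high,
                              motor.threshold + params.theta_step_up)
    return motor.threshold


@dataclass
class InternalEvent:
    """Temporary internal stimulus event (e.g. response feedback)."""

    name: str = "NONE"
    in_use: bool = False
    start: int = 0
    end: int = 0
    last_response: str = ""
    evaluation: str = ""       # CORRECT or ERROR


def raise_feedback(emitted: str, intended: str | None, cycle: int,
                   horizon: int = 200) -> InternalEvent:
    """CORRECT iff the emitted response matches the intentional stream's."""
    evaluation = "CORRECT" if (intended is not None
                               and emitted == intended) else "ERROR"
    return InternalEvent(name="FEEDBACK", in_use=True, start=cycle,
                         end=cycle + horizon, last_response=emitted,
                         evaluation=evaluation)
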