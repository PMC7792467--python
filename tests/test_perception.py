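"""Sensory registers, gaze control, and motor response competition."""

import math
import random

import pytest

from wmdec.params import ModelParameters
from wmdec.perception import (EchoicSlot, GazeState, IconicStore, MotorState,
                              adjust_threshold, chebyshev, raise_feedback,
                              saccade_duration, step_response_competition,
                              update_gaze)


class FixedGauss(random.Random):
    """Deterministic stand-in: gauss() always returns a preset value."""

    def __init__(self, value=0.0, seed=0):
        super().__init__(seed)
        self.value = value

    def gauss(self, mu, sigma):
        return self.value


class TestIconic:
    def test_one_object_per_cell_with_change_flag(self):
        ism = IconicStore()
        ism.put("A", (1, 1))
        assert ism.cells[(1, 1)].flag == "NEW"
        ism.put("B", (1, 1))
        assert ism.cells[(1, 1)].name == "B"
        assert ism.cells[(1, 1)].flag == "CHANGE"

    def test_flag_sequence_new_fade_gone_empty(self):
        ism = IconicStore()
        ism.put("A", (0, 0))
        for _ in range(IconicStore.FADE_AFTER + 1):
            ism.step()
        assert ism.cells[(0, 0)].flag == "FADE"
        ism.clear((0, 0))
        assert ism.cells[(0, 0)].flag == "GONE"
        for _ in range(IconicStore.GONE_AFTER + 1):
            ism.step()
        assert (0, 0) not in ism.cells


class TestEchoic:
    def test_gone_150_cycles_after_stream_end(self):
        esm = EchoicSlot()
        esm.put("TONE")
        esm.end_stream()
        for _ in range(150):
            esm.step()
        assert esm.flag == "FADE"
        esm.step()
        assert esm.flag == "GONE"


class TestGaze:
    def test_saccade_duration_clamped_3_to_6(self):
        assert saccade_duration(0) == 3
        assert saccade_duration(1) == 3
        assert saccade_duration(2) == 4
        assert saccade_duration(4) == 6
        assert saccade_duration(8) == 6

    def test_neighbour_event_needs_no_saccade(self):
        gaze = GazeState(fixation=(4, 4), fixation_left=50)
        ism = IconicStore()
        ism.put("A", (4, 5))
        update_gaze(gaze, ism, random.Random(0), 0)
        assert gaze.status == "FIXATION"

    def test_outside_event_triggers_stimulus_saccade(self):
        gaze = GazeState(fixation=(4, 4), fixation_left=50)
        ism = IconicStore()
        ism.put("A", (8, 8))
        update_gaze(gaze, ism, random.Random(0), 0)
        assert gaze.status == "SACCADE"
        assert gaze.next == (8, 8)
        assert gaze.saccade_left == saccade_duration(chebyshev((8, 8),
                                                              (4, 4)))

    def test_drift_after_20_cycles_at_r0(self):
        gaze = GazeState(fixation=(4, 4), fixation_left=20)
        ism = IconicStore()
        rng = FixedGauss(0.0)
        for cyc in range(19):
            update_gaze(gaze, ism, rng, cyc)
            assert gaze.status == "FIXATION"
        update_gaze(gaze, ism, rng, 20)
        assert gaze.status == "SACCADE"
        assert chebyshev(gaze.next, (4, 4)) == 1

    def test_no_visual_intake_during_saccade(self):
        # engine contract: delivery is deferred while status is SACCADE;
        # here we check that the saccade lasts its programmed duration
        gaze = GazeState(fixation=(0, 0), fixation_left=50)
        ism = IconicStore()
        ism.put("A", (5, 5))
        rng = random.Random(0)
        update_gaze(gaze, ism, rng, 0)
        d = gaze.saccade_left
        for k in range(d):
            assert gaze.status == "SACCADE"
            update_gaze(gaze, ism, rng, k + 1)
        assert gaze.status == "FIXATION"
        assert gaze.fixation == (5, 5)


class TestResponseCompetition:
    def test_noiseless_crossing_time_formula(self):
        # with lambda = 0 the crossing cycle is ceil(theta / zeta)
        p = ModelParameters(lam=0.0, zeta=0.015, theta=0.50)
        motor = MotorState(status="UNBLOCK", threshold=0.50)
        motor.start("intentional", "RIGHT")
        rng = FixedGauss(0.0)
        for cyc in range(1, 200):
            if step_response_competition(motor, p, rng, cyc):
                break
        assert cyc == math.ceil(0.5 / 0.015) == 34

    def test_automatic_stream_formula(self):
        p = ModelParameters(lam=0.0, zeta_auto=0.004, theta=0.50)
        motor = MotorState(status="UNBLOCK", threshold=0.50)
        motor.start("automatic", "LEFT")
        rng = FixedGauss(0.0)
        for cyc in range(1, 300):
            if step_response_competition(motor, p, rng, cyc):
                break
        assert cyc == math.ceil(0.5 / 0.004) == 125

    @pytest.mark.parametrize("theta,zeta", [(0.4, 0.01), (0.6, 0.02),
                                            (0.47, 0.013)])
    def test_crossing_formula_oracle(self, theta, zeta):
        p = ModelParameters(lam=0.0, zeta=zeta, theta=theta)
        motor = MotorState(status="UNBLOCK", threshold=theta)
        motor.start("intentional", "R")
        rng = FixedGauss(0.0)
        for cyc in range(1, 500):
            if step_response_competition(motor, p, rng, cyc):
                break
        assert cyc == math.ceil(theta / zeta)

    def test_no_tendencies_no_emission(self):
        motor = MotorState(status="UNBLOCK")
        assert step_response_competition(motor, ModelParameters(),
                                         random.Random(0), 0) is None

    def test_blocked_emission_suppressed_and_logged(self):
        p = ModelParameters(lam=0.0)
        motor = MotorState(status="BLOCKED", threshold=0.01)
        motor.start("intentional", "R")
        step_response_competition(motor, p, FixedGauss(0.0), 5)
        assert motor.emitted is None
        assert motor.suppressed == [("R", 5)]

    def test_tie_goes_to_intentional(self):
        p = ModelParameters(lam=0.0, zeta=0.5, zeta_auto=0.5)
        motor = MotorState(status="UNBLOCK", threshold=0.4)
        motor.start("automatic", "A")
        motor.start("intentional", "I")
        winner = step_response_competition(motor, p, FixedGauss(0.0), 1)
        assert winner.stream == "intentional"

    def test_probability_automatic_wins_grows_with_intentional_delay(self):
        p = ModelParameters()
        wins = []
        for delay in (0, 40, 80):
            auto_wins = 0
            for trial in range(2000):
                rng = random.Random(1000 * delay + trial)
                motor = MotorState(status="UNBLOCK", threshold=0.5)
                motor.start("automatic", "A")
                emitted = None
                for cyc in range(1, 400):
                    if cyc == delay + 1:
                        motor.start("intentional", "I")
                    w = step_response_competition(motor, p, rng, cyc)
                    if w is not None:
                        emitted = w
                        break
                if emitted is not None and emitted.stream == "automatic":
                    auto_wins += 1
            wins.append(auto_wins)
        assert wins[0] < wins[1] < wins[2]


class TestThresholdControl:
    def test_error_raises_threshold(self):
        p = ModelParameters()
        m = MotorState(threshold=0.50)
        assert adjust_threshold(m, "ERROR", p) == pytest.approx(0.52)

    def test_five_corrects_lower_threshold(self):
        p = ModelParameters()
        m = MotorState(threshold=0.50)
        for _ in range(5):
            adjust_threshold(m, "CORRECT", p)
        assert m.threshold == pytest.approx(0.49)

    def test_floor_at_table_low_bound(self):
        p = ModelParameters()
        m = MotorState(threshold=0.40)
        for _ in range(10):
            adjust_threshold(m, "CORRECT", p)
        assert m.threshold == pytest.approx(0.40)

    def test_ceiling_at_table_high_bound(self):
        p = ModelParameters()
        m = MotorState(threshold=0.59)
        adjust_threshold(m, "ERROR", p)
        adjust_threshold(m, "ERROR", p)
        assert m.threshold == pytest.approx(0.60)


class TestFeedback:
    def test_correct_iff_emitted_matches_intended(self):
        assert raise_feedback("RIGHT", "RIGHT", 0).evaluation == "CORRECT"
        assert raise_feedback("LEFT", "RIGHT", 0).evaluation == "ERROR"

    def test_automatic_only_emission_is_error(self):
        assert raise_feedback("RIGHT", None, 0).evaluation == "ERROR"
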