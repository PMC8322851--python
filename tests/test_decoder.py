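"""Finite-state decoder: command/broadcast tables, debouncing, the 5 s
deadline, gripper safety, and reachability of exactly 8 commands and
12 broadcast strings."""

import itertools

import numpy as np
import pytest

import myoface as mf
from myoface.decoder import (
    AXIS_COMMANDS,
    BROADCASTS,
    COMMANDS,
    DecoderConfig,
    FsmDecoder,
    SELECTOR_OF_LABEL,
    decode_stream,
)
from myoface.types import LABELS, MOVEMENTS, REST

LOW_POSE = (50.0, 0.0, 5.0)     # over desktop, under the 10 cm gripper limit
HIGH_POSE = (50.0, 0.0, 50.0)

#: the canonical two-action sequence for each of the 8 commands
CANONICAL = {
    "+X": ("REBO", "LEb"), "-X": ("REBO", "Bk"),
    "+Y": ("LEBO", "LEb"), "-Y": ("LEBO", "Bk"),
    "+Z": ("TMR", "LEb"), "-Z": ("TMR", "Bk"),
    "close_gripper": ("TML", "LEb"), "open_gripper": ("TML", "Bk"),
}


def run_labels(labels, pose=LOW_POSE, config=None):
    dec = FsmDecoder(config or DecoderConfig())
    cmds, bcs, refs = [], [], []
    for i, lab in enumerate(labels):
        c, b, r = dec.step(lab, i * 0.05, pose)
        cmds += c
        bcs += b
        refs += r
    return cmds, bcs, refs


def two_action(first, second, hold=8, tail=8):
    return [first] * 5 + [second] * hold + [REST] * tail


class TestCommandTable:
    @pytest.mark.parametrize("command,pair", sorted(CANONICAL.items()))
    def test_canonical_sequences(self, command, pair):
        first, second = pair
        cmds, bcs, _ = run_labels(two_action(first, second))
        assert cmds[0].command == command
        if command in AXIS_COMMANDS:
            assert [c.lifecycle for c in cmds] == (
                ["start"] + ["continue"] * (len(cmds) - 2) + ["stop"]
            )
        else:
            assert [c.lifecycle for c in cmds] == ["pulse"]

    def test_broadcast_pairs(self):
        cmds, bcs, _ = run_labels(two_action("REBO", "LEb"))
        assert [b.text for b in bcs] == ["Left or right", "Left"]
        cmds, bcs, _ = run_labels(two_action("LEBO", "Bk"))
        assert [b.text for b in bcs] == ["Forward or back", "Forward"]
        cmds, bcs, _ = run_labels(two_action("TML", "LEb"))
        assert [b.text for b in bcs] == ["Gripper", "Close"]

    def test_swap_gripper_convention(self):
        cfg = DecoderConfig(swap_gripper_direction=True)
        cmds, bcs, _ = run_labels(two_action("TML", "Bk"), config=cfg)
        assert cmds[0].command == "close_gripper"
        assert [b.text for b in bcs] == ["Gripper", "Open"]

    def test_exactly_eight_commands_and_twelve_broadcasts(self):
        seen_cmds, seen_bcs = set(), set()
        for first, second in CANONICAL.values():
            cmds, bcs, _ = run_labels(two_action(first, second))
            seen_cmds |= {c.command for c in cmds}
            seen_bcs |= {b.text for b in bcs}
        assert seen_cmds == set(COMMANDS) and len(COMMANDS) == 8
        assert seen_bcs == set(BROADCASTS) and len(set(BROADCASTS)) == 12


class TestTransitionAudit:
    def test_exhaustive_state_label_audit(self):
        """Every reachable (stage, pending, label) pair emits only the
        table-prescribed command/broadcast — nothing else is reachable."""
        for selector, label in itertools.product(SELECTOR_OF_LABEL, LABELS):
            dec = FsmDecoder(DecoderConfig())
            # drive to stage 1 with `selector` pending
            for i in range(5):
                dec.step(selector, i * 0.05, LOW_POSE)
            assert dec.state.stage == 1
            c, b, r = dec.step(label, 0.3, LOW_POSE)
            pending = SELECTOR_OF_LABEL[selector]
            if label in ("LEb", "Bk"):
                if pending == "Gripper":
                    expected = (
                        "close_gripper" if label == "LEb" else "open_gripper"
                    )
                    assert [x.command for x in c] == [expected]
                    assert dec.state.stage == 0
                else:
                    sign = "+" if label == "LEb" else "-"
                    assert [x.command for x in c] == [sign + pending]
                    assert dec.state.stage == 2
                assert len(b) == 1 and b[0].text in BROADCASTS
            else:
                assert c == [] and b == []

    def test_stage0_emits_nothing_but_selector_broadcasts(self):
        for label in MOVEMENTS:
            cmds, bcs, _ = run_labels([label] * 5)
            assert cmds == []
            if label in SELECTOR_OF_LABEL:
                assert len(bcs) == 1
            else:
                assert bcs == []  # LEb/Bk alone select nothing

    def test_unknown_label_rejected(self):
        dec = FsmDecoder()
        with pytest.raises(ValueError):
            dec.step("WINK", 0.0, LOW_POSE)


class TestDebounceAndDeadline:
    def test_short_runs_do_not_select(self):
        cmds, bcs, _ = run_labels(["REBO"] * 4 + [REST] * 10)
        assert cmds == [] and bcs == []

    def test_interrupted_run_restarts(self):
        cmds, bcs, _ = run_labels(["REBO", "REBO", REST, "REBO", "REBO", "REBO"])
        assert bcs == []  # never 5 consecutive

    def test_late_second_action_ignored(self):
        # 6 s of rest after selection, then the direction action
        labels = ["LEBO"] * 5 + [REST] * 120 + ["Bk"] * 8 + [REST] * 8
        cmds, bcs, refs = run_labels(labels)
        assert [b.text for b in bcs] == ["Forward or back"]
        assert cmds == []

    def test_held_action_outlives_deadline(self):
        # hold-to-move keeps refreshing its own validity
        labels = ["TMR"] * 5 + ["LEb"] * 150 + [REST] * 8
        cmds, _, _ = run_labels(labels)
        assert cmds[0].command == "+Z" and cmds[0].lifecycle == "start"
        assert cmds[-1].lifecycle == "stop"
        assert sum(c.lifecycle == "continue" for c in cmds) == 149 + 4

    def test_rest_hysteresis_bridges_short_gaps(self):
        labels = ["REBO"] * 5 + ["LEb"] * 6 + [REST] * 2 + ["LEb"] * 6 + [REST] * 8
        cmds, _, _ = run_labels(labels)
        stops = [c for c in cmds if c.lifecycle == "stop"]
        assert len(stops) == 1  # the 2-window gap does not stop the motion

    def test_different_action_stops_motion(self):
        labels = ["REBO"] * 5 + ["LEb"] * 6 + ["Bk"] * 2
        cmds, _, _ = run_labels(labels)
        assert cmds[-1].lifecycle == "stop"


class TestGripperSafety:
    def test_high_gripper_refused(self):
        cmds, bcs, refs = run_labels(two_action("TML", "LEb"), pose=HIGH_POSE)
        assert cmds == []
        assert [b.text for b in bcs] == ["Gripper"]  # no Close confirmation
        assert len(refs) == 1 and "refused" in refs[0].reason

    def test_off_desktop_refused(self):
        cfg = DecoderConfig(desktop_rect=((20.0, 120.0), (-70.0, 100.0)))
        cmds, _, refs = run_labels(
            two_action("TML", "Bk"), pose=(0.0, 0.0, 5.0), config=cfg
        )
        assert cmds == [] and len(refs) == 1

    def test_safety_over_random_streams(self):
        """No gripper command is ever emitted above the z limit."""
        rng = np.random.default_rng(99)
        labels = list(LABELS)
        for trial in range(20):
            z = float(rng.uniform(0, 120))
            dec = FsmDecoder(DecoderConfig())
            for i in range(400):
                lab = labels[rng.integers(len(labels))]
                c, _, _ = dec.step(lab, i * 0.05, (50.0, 0.0, z))
                for ev in c:
                    if ev.command in ("close_gripper", "open_gripper"):
                        assert z < 10.0


class TestDecodeStream:
    def test_all_rest_is_silent(self):
        log = decode_stream([(i * 0.05, REST) for i in range(100)])
        assert log == []

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        labels = [
            (i * 0.05, LABELS[rng.integers(len(LABELS))]) for i in range(300)
        ]
        assert decode_stream(labels) == decode_stream(labels)

    def test_stop_always_follows_start(self):
        rng = np.random.default_rng(17)
        labels = [
            (i * 0.05, LABELS[rng.integers(len(LABELS))]) for i in range(2000)
        ]
        log = decode_stream(labels)
        active = None
        for ev in log:
            if ev["kind"] != "command":
                continue
            cmd, life = ev["payload"]["command"], ev["payload"]["lifecycle"]
            if life == "start":
                assert active is None
                active = cmd
            elif life in ("continue", "stop"):
                assert active == cmd
                if life == "stop":
                    active = None
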