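"""Two-stage finite-state intent decoder.

Window-level movement predictions are debounced and folded into arm
commands in two stages:

* **Stage 0 — axis selection.**  A debounced run of one of the four
  selector movements picks what to control: REBO selects the X axis,
  LEBO the Y axis, TMR the Z axis, and TML the gripper.  The matching
  audio broadcast ("Left or right", "Forward or back", "Up or down",
  "Gripper") is emitted and a 5 s deadline starts.
* **Stage 1/2 — direction.**  Within the deadline, LEb picks the
  positive direction of the pending axis and Bk the negative one
  (+X is the user's left, −Y is forward, +Z is up).  Axis motion is
  hold-to-move: it starts on the first direction window, continues
  while the direction movement persists, and stops once REST has been
  seen for a debounce period (shorter REST gaps are bridged so single
  misclassified windows do not stutter the arm).  The gripper is
  momentary and self-latching: LEb closes, Bk opens, and the command is
  only honoured when the gripper sits over the desktop below the 10 cm
  safety height — otherwise a refusal is logged.

A second action arriving after the deadline is ignored and the decoder
falls back to stage 0; while a direction movement is held, it is its
own licence to continue (the deadline refreshes on every non-REST
direction window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .types import LABELS, REST

__all__ = [
    "COMMANDS",
    "AXIS_COMMANDS",
    "GRIPPER_COMMANDS",
    "BROADCASTS",
    "SELECTOR_OF_LABEL",
    "DecoderConfig",
    "CommandEvent",
    "BroadcastEvent",
    "RefusalEvent",
    "FsmDecoder",
    "decode_stream",
]

logger = logging.getLogger(__name__)

AXIS_COMMANDS: tuple[str, ...] = ("+X", "-X", "+Y", "-Y", "+Z", "-Z")
GRIPPER_COMMANDS: tuple[str, ...] = ("close_gripper", "open_gripper")
#: the eight arm commands
COMMANDS: tuple[str, ...] = AXIS_COMMANDS + GRIPPER_COMMANDS

#: stage-0 selector movement -> controlled axis
SELECTOR_OF_LABEL: dict[str, str] = {
    "REBO": "X",
    "LEBO": "Y",
    "TMR": "Z",
    "TML": "Gripper",
}

#: broadcast after the first (selector) movement is recognised
FIRST_BROADCAST: dict[str, str] = {
    "X": "Left or right",
    "Y": "Forward or back",
    "Z": "Up or down",
    "Gripper": "Gripper",
}

#: broadcast after the second (direction) movement
SECOND_BROADCAST: dict[tuple[str, str], str] = {
    ("X", "LEb"): "Left", ("X", "Bk"): "Right",
    ("Y", "LEb"): "Back", ("Y", "Bk"): "Forward",
    ("Z", "LEb"): "Up", ("Z", "Bk"): "Down",
    ("Gripper", "LEb"): "Close", ("Gripper", "Bk"): "Open",
}

#: axis motion command for (pending axis, direction movement);
#: +X is the user's left and -Y is forward, so LEb (positive) on X
#: broadcasts "Left" and Bk (negative) on Y broadcasts "Forward"
AXIS_COMMAND_OF: dict[tuple[str, str], str] = {
    ("X", "LEb"): "+X", ("X", "Bk"): "-X",
    ("Y", "LEb"): "+Y", ("Y", "Bk"): "-Y",
    ("Z", "LEb"): "+Z", ("Z", "Bk"): "-Z",
}

#: the full 12-string broadcast vocabulary
BROADCASTS: tuple[str, ...] = tuple(FIRST_BROADCAST.values()) + tuple(
    SECOND_BROADCAST.values()
)


@dataclass(frozen=True)
class DecoderConfig:
    second_action_timeout_s: float = 5.0
    debounce_windows: int = 5          # ~250 ms at the 50 ms window step
    window_step_ms: float = 50.0
    gripper_z_limit_cm: float = 10.0
    rest_stop_windows: int | None = None  # default: same as debounce_windows
    #: desktop rectangle ((x0, x1), (y0, y1)) for the gripper guard;
    #: None disables the over-desktop part of the guard
    desktop_rect: tuple[tuple[float, float], tuple[float, float]] | None = None
    #: flip to the text convention Bk=close / LEb=open
    swap_gripper_direction: bool = False

    def __post_init__(self) -> None:
        if self.second_action_timeout_s <= 0:
            raise ValueError("timeout must be positive")
        if self.debounce_windows < 1:
            raise ValueError("debounce_windows must be >= 1")

    @property
    def stop_windows(self) -> int:
        return (
            self.debounce_windows
            if self.rest_stop_windows is None
            else self.rest_stop_windows
        )


@dataclass
class CommandEvent:
    command: str               # one of COMMANDS
    lifecycle: str             # start | continue | stop (axis), pulse (gripper)
    time_s: float


@dataclass
class BroadcastEvent:
    text: str                  # one of BROADCASTS
    time_s: float


@dataclass
class RefusalEvent:
    reason: str
    time_s: float


def _pose_xyz(pose) -> tuple[float, float, float]:
    if pose is None:
        return (0.0, 0.0, 0.0)
    if hasattr(pose, "x"):
        return (float(pose.x), float(pose.y), float(pose.z))
    x, y, z = pose
    return (float(x), float(y), float(z))


@dataclass
class _State:
    stage: int = 0
    pending: str | None = None         # X | Y | Z | Gripper
    deadline_s: float | None = None
    motion: str | None = None          # active axis command
    motion_label: str | None = None    # movement that holds the motion
    rest_run: int = 0
    deb_label: str | None = None
    deb_count: int = 0


class FsmDecoder:
    """Stateful two-stage decoder; one :meth:`step` per prediction window."""

    def __init__(self, config: DecoderConfig = DecoderConfig()) -> None:
        self.config = config
        self.state = _State()

    # -- helpers -----------------------------------------------------------
    def _reset(self) -> None:
        self.state = _State()

    def _over_desktop(self, x: float, y: float) -> bool:
        rect = self.config.desktop_rect
        if rect is None:
            return True
        (x0, x1), (y0, y1) = rect
        return x0 <= x <= x1 and y0 <= y <= y1

    def _gripper_command(self, label: str) -> str:
        close_label = "Bk" if self.config.swap_gripper_direction else "LEb"
        return "close_gripper" if label == close_label else "open_gripper"

    # -- the transition function ------------------------------------------
    def step(
        self, predicted_label: str, now_s: float, arm_pose=None
    ) -> tuple[list[CommandEvent], list[BroadcastEvent], list[RefusalEvent]]:
        """Consume one window prediction; emit commands and broadcasts."""
        if predicted_label not in LABELS:
            raise ValueError(f"unknown label {predicted_label!r}")
        st = self.state
        cfg = self.config
        commands: list[CommandEvent] = []
        broadcasts: list[BroadcastEvent] = []
        refusals: list[RefusalEvent] = []

        if st.stage == 0:
            if predicted_label == REST:
                st.deb_label, st.deb_count = None, 0
                return commands, broadcasts, refusals
            if predicted_label == st.deb_label:
                st.deb_count += 1
            else:
                st.deb_label, st.deb_count = predicted_label, 1
            if st.deb_count >= cfg.debounce_windows:
                if predicted_label in SELECTOR_OF_LABEL:
                    st.pending = SELECTOR_OF_LABEL[predicted_label]
                    st.stage = 1
                    st.deadline_s = now_s + cfg.second_action_timeout_s
                    broadcasts.append(
                        BroadcastEvent(FIRST_BROADCAST[st.pending], now_s)
                    )
                # a debounced LEb/Bk with nothing pending selects no axis
                st.deb_label, st.deb_count = None, 0
            return commands, broadcasts, refusals

        if st.stage == 1:
            expired = st.deadline_s is not None and now_s > st.deadline_s
            if predicted_label in ("LEb", "Bk"):
                if expired:
                    refusals.append(
                        RefusalEvent("second action after the 5 s deadline", now_s)
                    )
                    logger.info("second action at %.2f s ignored: deadline", now_s)
                    self._reset()
                    return commands, broadcasts, refusals
                pending = st.pending
                assert pending is not None
                if pending == "Gripper":
                    cmd = self._gripper_command(predicted_label)
                    x, y, z = _pose_xyz(arm_pose)
                    if z < cfg.gripper_z_limit_cm and self._over_desktop(x, y):
                        broadcasts.append(
                            BroadcastEvent(
                                SECOND_BROADCAST[(pending, predicted_label)], now_s
                            )
                        )
                        commands.append(CommandEvent(cmd, "pulse", now_s))
                    else:
                        refusals.append(
                            RefusalEvent(
                                f"{cmd} refused: gripper at z={z:.1f} cm "
                                "not over the desktop below the safety height",
                                now_s,
                            )
                        )
                        logger.warning("gripper command refused at %.2f s", now_s)
                    self._reset()
                else:
                    broadcasts.append(
                        BroadcastEvent(
                            SECOND_BROADCAST[(pending, predicted_label)], now_s
                        )
                    )
                    cmd = AXIS_COMMAND_OF[(pending, predicted_label)]
                    commands.append(CommandEvent(cmd, "start", now_s))
                    st.motion = cmd
                    st.motion_label = predicted_label
                    st.stage = 2
                    st.rest_run = 0
                    st.deadline_s = now_s + cfg.second_action_timeout_s
            elif expired:
                self._reset()
                if predicted_label != REST:
                    # the new selector run may begin immediately
                    self.state.deb_label = predicted_label
                    self.state.deb_count = 1
            # selector labels inside the deadline are ignored
            return commands, broadcasts, refusals

        # stage 2: axis motion active
        assert st.motion is not None
        if predicted_label == st.motion_label:
            st.rest_run = 0
            st.deadline_s = now_s + cfg.second_action_timeout_s
            commands.append(CommandEvent(st.motion, "continue", now_s))
        elif predicted_label == REST:
            st.rest_run += 1
            if st.rest_run >= cfg.stop_windows:
                commands.append(CommandEvent(st.motion, "stop", now_s))
                self._reset()
            else:
                # bridge short misclassification gaps
                commands.append(CommandEvent(st.motion, "continue", now_s))
        else:
            commands.append(CommandEvent(st.motion, "stop", now_s))
            self._reset()
            self.state.deb_label = predicted_label
            self.state.deb_count = 1
        return commands, broadcasts, refusals


def decode_stream(
    window_predictions: Iterable[tuple[float, str]],
    config: DecoderConfig = DecoderConfig(),
    arm_pose_provider: Callable[[float], Sequence[float]] | None = None,
) -> list[dict]:
    """Fold :meth:`FsmDecoder.step` over a timed label sequence.

    Returns the full event log as dicts with keys ``time_s``, ``kind``
    (``command`` / ``broadcast`` / ``refusal``) and ``payload``.
    """
    dec = FsmDecoder(config)
    log: list[dict] = []
    for t, label in window_predictions:
        pose = arm_pose_provider(t) if arm_pose_provider is not None else None
        commands, broadcasts, refusals = dec.step(label, t, pose)
        for c in commands:
            log.append(
                {
                    "time_s": c.time_s,
                    "kind": "command",
                    "payload": {"command": c.command, "lifecycle": c.lifecycle},
                }
            )
        for b in broadcasts:
            log.append({"time_s": b.time_s, "kind": "broadcast", "payload": b.text})
        for r in refusals:
            log.append({"time_s": r.time_s, "kind": "refusal", "payload": r.reason})
    return log
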