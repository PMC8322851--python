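"""End-to-end glue: offline training and the closed control loop.

The closed loop reproduces the online architecture of the interface at
each 50 ms tick:

1. a scripted *intent policy* (standing in for the user) chooses which
   facial movement to make, watching the simulated arm and listening to
   the decoder's broadcasts — the same visual and audio feedback a real
   user has;
2. the synthetic generator produces the next 50 ms of raw fEMG for that
   movement, with filter state carried across ticks;
3. the streaming preprocessor applies the notch + band-pass chain;
4. the newest 200 ms window is turned into the elected feature row and
   classified;
5. the finite-state decoder debounces the prediction into arm commands;
6. the arm simulator integrates the commands and updates the task.

The loop ends when the drinking task completes or a timeout elapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .armsim import DrinkTaskSim, TaskLog, TaskScenario, Workspace
from .decoder import DecoderConfig, FsmDecoder
from .features import EF_FEATURES, FeatureMatrix, feature_row
from .model_eval import make_registry
from .preprocess import FilterSpec, StreamingPreprocessor
from .synth import CrosstalkProfile, StreamingSynth
from .types import REST

__all__ = [
    "train_classifier",
    "build_drink_plan",
    "IntentPolicy",
    "ClosedLoopResult",
    "run_closed_loop",
]

#: controlled axis -> stage-0 selector movement
LABEL_OF_SELECTOR = {"X": "REBO", "Y": "LEBO", "Z": "TMR", "Gripper": "TML"}


def train_classifier(
    matrix: FeatureMatrix, model_name: str = "GBC", seed: int = 0
):
    """Fit one registry classifier on a full design matrix."""
    est = make_registry(seed)[model_name]
    est.fit(matrix.X.to_numpy(), matrix.y)
    return est


# ---------------------------------------------------------------------------
# scripted intent
# ---------------------------------------------------------------------------

def build_drink_plan(
    scenario: TaskScenario, workspace: Workspace = Workspace()
) -> list[tuple]:
    """Step list for the three-stage drinking task.

    Steps are ``("move", axis, target_cm)``, ``("grip", "close"|"open")``
    and ``("dwell", seconds)``; targets follow the scripted button
    policy (grasp height 8 cm, carry height inside the mouth window).
    """
    cx, cy = scenario.cup_position
    mouth_x = float(np.mean(workspace.mouth_x))
    mouth_y = workspace.mouth_y_max - 2.0
    return [
        ("move", "Z", 8.0),
        ("move", "X", cx),
        ("move", "Y", cy),
        ("grip", "close"),
        ("move", "Z", 70.0),
        ("move", "X", mouth_x),
        ("move", "Y", mouth_y),
        ("dwell", 1.5),
        ("move", "Y", cy),
        ("move", "X", cx),
        ("move", "Z", 8.0),
        ("grip", "open"),
    ]


_AXIS_IDX = {"X": 0, "Y": 1, "Z": 2}


class IntentPolicy:
    """Scripted user: turns a drink plan into a facial movement per tick.

    For a move step the policy performs the axis-selector movement until
    it hears the selection broadcast, then holds the direction movement
    (LEb toward positive, Bk toward negative) until the arm is within
    ``lead_cm`` of the target — the lead compensates the decoder's stop
    latency — then rests so the decoder returns to stage 0.  Gripper
    steps are momentary; the confirmation broadcast advances the plan.
    """

    def __init__(
        self,
        plan: Sequence[tuple],
        dt_s: float = 0.05,
        lead_cm: float = 1.0,
        settle_s: float = 0.7,
        grip_hold_s: float = 0.4,
    ) -> None:
        self.plan = list(plan)
        self.dt = dt_s
        self.lead = lead_cm
        self.settle_ticks = int(round(settle_s / dt_s))
        self.grip_hold_ticks = int(round(grip_hold_s / dt_s))
        self.step_idx = 0
        self.phase = "select"
        self._direction: str | None = None
        self._counter = 0

    @property
    def done(self) -> bool:
        return self.step_idx >= len(self.plan)

    def _advance(self) -> None:
        self.step_idx += 1
        self.phase = "select"
        self._direction = None
        self._counter = 0

    def next_label(self, arm, heard: Sequence[str]) -> str:
        """Facial movement for this tick given the arm pose and the
        broadcasts heard since the last tick."""
        if self.done:
            return REST
        step = self.plan[self.step_idx]

        if step[0] == "dwell":
            self._counter += 1
            if self._counter >= int(round(step[1] / self.dt)):
                self._advance()
            return REST

        if step[0] == "move":
            _, axis, target = step
            pos = float(arm.position[_AXIS_IDX[axis]])
            err = target - pos
            if self.phase == "select":
                if abs(err) <= self.lead:
                    self._advance()          # already close enough
                    return REST
                if any(h in ("Left or right", "Forward or back", "Up or down")
                       for h in heard):
                    self.phase = "direct"
                    self._direction = "LEb" if err > 0 else "Bk"
                    return self._direction
                return LABEL_OF_SELECTOR[axis]
            if self.phase == "direct":
                assert self._direction is not None
                moved_past = (err <= 0) if self._direction == "LEb" else (err >= 0)
                if abs(err) <= self.lead or moved_past:
                    self.phase = "settle"
                    self._counter = 0
                    return REST
                return self._direction
            # settle: rest until the decoder has stopped and reset
            self._counter += 1
            if self._counter >= self.settle_ticks:
                self._advance()
            return REST

        # gripper step
        _, action = step
        if self.phase == "select":
            if "Gripper" in heard:
                self.phase = "direct"
                self._counter = 0
                return "LEb" if action == "close" else "Bk"
            return LABEL_OF_SELECTOR["Gripper"]
        if self.phase == "direct":
            if ("Close" in heard) or ("Open" in heard):
                self.phase = "settle"
                self._counter = 0
                return REST
            self._counter += 1
            if self._counter > 4 * self.grip_hold_ticks:
                # confirmation never came (refusal?) — retry from selection
                self.phase = "select"
                return REST
            return "LEb" if action == "close" else "Bk"
        self._counter += 1
        if self._counter >= self.settle_ticks:
            self._advance()
        return REST


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

@dataclass
class ClosedLoopResult:
    task: TaskLog
    events: list[dict] = field(default_factory=list)
    n_ticks: int = 0
    prediction_accuracy: float = float("nan")


def run_closed_loop(
    classifier,
    profile: CrosstalkProfile,
    scenario: TaskScenario,
    workspace: Workspace = Workspace(),
    decoder_config: DecoderConfig | None = None,
    filter_spec: FilterSpec = FilterSpec(),
    seed: int = 0,
    sampling_rate_hz: float = 1000.0,
    window_ms: float = 200.0,
    timeout_s: float = 900.0,
    features: Sequence[str] = EF_FEATURES,
) -> ClosedLoopResult:
    """Simulate one fEMG-controlled drinking task end to end.

    ``classifier`` must map the elected feature row (channel-major) to a
    movement label — typically the gradient-boosting model trained on
    the synthetic acquisition.  Deterministic for a fixed seed.
    """
    dt = 0.05
    step_n = int(round(dt * sampling_rate_hz))
    win_n = int(round(window_ms / 1000.0 * sampling_rate_hz))
    if decoder_config is None:
        decoder_config = DecoderConfig(
            desktop_rect=(workspace.desktop_x, workspace.desktop_y)
        )
    elif decoder_config.desktop_rect is None:
        decoder_config = replace(
            decoder_config,
            desktop_rect=(workspace.desktop_x, workspace.desktop_y),
        )

    synth = StreamingSynth(profile, sampling_rate_hz, seed)
    pre = StreamingPreprocessor(filter_spec, sampling_rate_hz)
    decoder = FsmDecoder(decoder_config)
    sim = DrinkTaskSim(scenario, workspace)
    policy = IntentPolicy(build_drink_plan(scenario, workspace), dt_s=dt)

    buffer = np.zeros((0, 6))
    heard: list[str] = []
    events: list[dict] = []
    hits = total = 0
    t = 0.0
    n_ticks = 0

    while t < timeout_s:
        intent = policy.next_label(sim.arm, heard)
        chunk = pre.process(synth.tick(intent, step_n))
        buffer = np.vstack([buffer, chunk])[-win_n:]

        if buffer.shape[0] >= win_n:
            row = feature_row(buffer, features)
            pred = str(classifier.predict(row[None, :])[0])
            hits += pred == intent
            total += 1
        else:
            pred = REST

        commands, broadcasts, refusals = decoder.step(pred, t, sim.arm)
        heard = [b.text for b in broadcasts]
        apply_now = [
            c.command for c in commands if c.lifecycle in ("start", "continue", "pulse")
        ]
        sim.step(apply_now, dt)

        for c in commands:
            if c.lifecycle != "continue":
                events.append(
                    {"time_s": c.time_s, "kind": "command",
                     "payload": {"command": c.command, "lifecycle": c.lifecycle}}
                )
        for b in broadcasts:
            events.append({"time_s": b.time_s, "kind": "broadcast", "payload": b.text})
        for r in refusals:
            events.append({"time_s": r.time_s, "kind": "refusal", "payload": r.reason})

        t += dt
        n_ticks += 1
        if sim.completed and policy.done:
            break

    return ClosedLoopResult(
        task=sim.task_log(timed_out=not sim.completed),
        events=events,
        n_ticks=n_ticks,
        prediction_accuracy=hits / total if total else float("nan"),
    )
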