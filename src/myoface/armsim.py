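"""Kinematic point model of the robotic-arm end effector and the
drinking-task scenario.

The gripper is a point moving at a constant 3 cm/s along one Cartesian
axis at a time inside a cuboid workspace (X [20, 120], Y [−70, 100],
Z [5, 120] cm).  The X-Y projection may not leave the desktop except
across its +Y edge, which may be overhung by up to 30 cm so the cup can
reach the user's mouth.  Joint-space kinematics are out of scope — the
real arm's API does that mapping.

A drinking task has three stages: reach and grasp the cup on its
saucer, carry it to the mouth zone and dwell there, then return it to
the saucer and release.  Task time runs from the first gripper motion
until the cup is back on the saucer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decoder import AXIS_COMMANDS, COMMANDS

__all__ = [
    "Workspace",
    "ArmState",
    "TaskScenario",
    "TaskLog",
    "make_scenario",
    "apply_command",
    "DrinkTaskSim",
    "scripted_drink_policy",
    "scripted_path_length_cm",
    "run_task",
]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass(frozen=True)
class Workspace:
    x_range: tuple[float, float] = (20.0, 120.0)
    y_range: tuple[float, float] = (-70.0, 100.0)
    z_range: tuple[float, float] = (5.0, 120.0)
    #: desktop rectangle in X-Y (the workspace footprint by default)
    desktop_x: tuple[float, float] = (20.0, 120.0)
    desktop_y: tuple[float, float] = (-70.0, 100.0)
    #: +Y overhang reachable only through the mouth window
    mouth_y_max: float = 130.0
    mouth_x: tuple[float, float] = (55.0, 85.0)
    mouth_z: tuple[float, float] = (60.0, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.x_range, self.y_range, self.z_range):
            if not lo < hi:
                raise ValueError("workspace ranges must be non-degenerate")
        if self.mouth_y_max - self.y_range[1] > 30.0:
            raise ValueError("mouth-zone overhang must not exceed 30 cm")

    def desktop_contains(self, x: float, y: float) -> bool:
        return (
            self.desktop_x[0] <= x <= self.desktop_x[1]
            and self.desktop_y[0] <= y <= self.desktop_y[1]
        )

    def in_mouth_window(self, x: float, z: float) -> bool:
        return (
            self.mouth_x[0] <= x <= self.mouth_x[1]
            and self.mouth_z[0] <= z <= self.mouth_z[1]
        )

    def in_mouth_zone(self, x: float, y: float, z: float) -> bool:
        return y > self.y_range[1] and self.in_mouth_window(x, z)

    def y_max_at(self, x: float, z: float) -> float:
        return self.mouth_y_max if self.in_mouth_window(x, z) else self.y_range[1]

    def move(self, pos: np.ndarray, axis: int, delta: float) -> np.ndarray:
        """One single-axis translation with workspace limits.

        The moved coordinate is clipped to its admissible range (for Y
        that range depends on whether the X-Z position is inside the
        mouth window).  An X or Z move that would strand the arm in the
        +Y overhang outside the mouth window is blocked outright — the
        end effector never jumps.
        """
        new = pos.copy()
        new[axis] += delta
        if axis == 0:
            new[0] = float(np.clip(new[0], *self.x_range))
        elif axis == 2:
            new[2] = float(np.clip(new[2], *self.z_range))
        else:
            new[1] = float(
                np.clip(new[1], self.y_range[0], self.y_max_at(new[0], new[2]))
            )
        if new[1] > self.y_range[1] and not self.in_mouth_window(new[0], new[2]):
            return pos.copy()
        return new


@dataclass
class ArmState:
    position: np.ndarray                  # (x, y, z) cm
    speed_cm_s: float = 3.0
    gripper: str = "open"                 # open | closed
    holding_cup: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.gripper not in ("open", "closed"):
            raise ValueError("gripper must be 'open' or 'closed'")
        if self.holding_cup and self.gripper != "closed":
            raise ValueError("holding the cup requires a closed gripper")

    @property
    def x(self) -> float:
        return float(self.position[0])

    @property
    def y(self) -> float:
        return float(self.position[1])

    @property
    def z(self) -> float:
        return float(self.position[2])


@dataclass(frozen=True)
class TaskScenario:
    """Geometry of one randomized drinking task."""

    cup_position: tuple[float, float]         # X-Y on the saucer
    gripper_start: tuple[float, float, float]
    saucer_center: tuple[float, float, float] = (90.0, 45.0, 0.0)
    saucer_size: tuple[float, float] = (30.0, 15.0)
    cup_diameter: float = 7.5
    cup_height: float = 13.0
    seed: int | None = None

    def __post_init__(self) -> None:
        cx, cy = self.cup_position
        if not (
            abs(cx - self.saucer_center[0]) <= self.saucer_size[0] / 2
            and abs(cy - self.saucer_center[1]) <= self.saucer_size[1] / 2
        ):
            raise ValueError("cup must sit on the saucer")

    def on_saucer(self, x: float, y: float) -> bool:
        return (
            abs(x - self.saucer_center[0]) <= self.saucer_size[0] / 2
            and abs(y - self.saucer_center[1]) <= self.saucer_size[1] / 2
        )


def make_scenario(seed: int, workspace: Workspace = Workspace()) -> TaskScenario:
    """Seeded random task: cup anywhere on the saucer (inset by its
    radius), gripper start at (x_i, −45, z_i) with x_i, z_i uniform in
    the workspace ranges."""
    rng = np.random.default_rng(seed)
    sc = TaskScenario.__dataclass_fields__
    center = sc["saucer_center"].default
    size = sc["saucer_size"].default
    r = sc["cup_diameter"].default / 2
    cup = (
        rng.uniform(center[0] - size[0] / 2 + r, center[0] + size[0] / 2 - r),
        rng.uniform(center[1] - size[1] / 2 + r, center[1] + size[1] / 2 - r),
    )
    start = (
        rng.uniform(*workspace.x_range),
        -45.0,
        rng.uniform(*workspace.z_range),
    )
    return TaskScenario(cup_position=cup, gripper_start=start, seed=seed)


def apply_command(
    arm: ArmState,
    command: str,
    dt_s: float,
    workspace: Workspace = Workspace(),
) -> ArmState:
    """Pure end-effector kinematics: translate 3·dt cm along the signed
    axis (clamped to the workspace) or switch the gripper state."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}")
    if command in AXIS_COMMANDS:
        sign = 1.0 if command[0] == "+" else -1.0
        axis = _AXIS_INDEX[command[1]]
        new = workspace.move(arm.position, axis, sign * arm.speed_cm_s * dt_s)
        return replace(arm, position=new)
    if command == "close_gripper":
        return replace(arm, gripper="closed")
    # opening drops whatever is held
    return replace(arm, gripper="open", holding_cup=False)


@dataclass
class TaskLog:
    completed: bool
    elapsed_s: float | None            # first motion -> cup back on saucer
    stage_times_s: dict[str, float]    # grasp / drink / release timestamps
    timed_out: bool
    events: list[dict] = field(default_factory=list)


class DrinkTaskSim:
    """Closed-loop drinking-task world: arm, cup, saucer, mouth zone.

    Call :meth:`step` once per control tick with the commands to apply.
    The cup is always in exactly one of three places: on the saucer, in
    the closed gripper, or dropped (task failure).
    """

    GRASP_RADIUS_CM = 5.0       # cup radius + clearance of the soft gripper
    DRINK_DWELL_S = 1.0

    def __init__(
        self,
        scenario: TaskScenario,
        workspace: Workspace = Workspace(),
    ) -> None:
        self.scenario = scenario
        self.workspace = workspace
        self.arm = ArmState(position=np.array(scenario.gripper_start))
        self.cup_xy = tuple(scenario.cup_position)
        self.cup_state = "on_saucer"      # on_saucer | held | dropped
        self.t = 0.0
        self.first_move_t: float | None = None
        self.grasp_t: float | None = None
        self.mouth_dwell = 0.0
        self.drink_t: float | None = None
        self.release_t: float | None = None

    # -- queries -----------------------------------------------------------
    @property
    def pose(self) -> ArmState:
        return self.arm

    @property
    def completed(self) -> bool:
        return self.release_t is not None

    def _near_cup(self) -> bool:
        dx = self.arm.x - self.cup_xy[0]
        dy = self.arm.y - self.cup_xy[1]
        return (
            float(np.hypot(dx, dy)) <= self.GRASP_RADIUS_CM
            and self.arm.z <= self.scenario.cup_height
        )

    # -- dynamics ----------------------------------------------------------
    def step(self, commands: list[str], dt_s: float) -> None:
        """Apply this tick's commands, then advance task bookkeeping."""
        for cmd in commands:
            if cmd in AXIS_COMMANDS:
                before = self.arm.position.copy()
                self.arm = apply_command(self.arm, cmd, dt_s, self.workspace)
                if self.first_move_t is None and not np.array_equal(
                    before, self.arm.position
                ):
                    self.first_move_t = self.t
            elif cmd == "close_gripper":
                self.arm = apply_command(self.arm, cmd, dt_s, self.workspace)
                if self.cup_state == "on_saucer" and self._near_cup():
                    self.cup_state = "held"
                    self.arm.holding_cup = True
                    if self.grasp_t is None:
                        self.grasp_t = self.t
            elif cmd == "open_gripper":
                was_holding = self.cup_state == "held"
                self.arm = apply_command(self.arm, cmd, dt_s, self.workspace)
                if was_holding:
                    x, y = self.arm.x, self.arm.y
                    if self.scenario.on_saucer(x, y):
                        self.cup_state = "on_saucer"
                        self.cup_xy = (x, y)
                        if self.drink_t is not None and self.release_t is None:
                            self.release_t = self.t + dt_s
                    else:
                        self.cup_state = "dropped"
            elif cmd is not None:
                raise ValueError(f"unknown command {cmd!r}")

        if self.cup_state == "held":
            ws = self.workspace
            if ws.in_mouth_zone(self.arm.x, self.arm.y, self.arm.z):
                self.mouth_dwell += dt_s
                if self.drink_t is None and self.mouth_dwell >= self.DRINK_DWELL_S:
                    self.drink_t = self.t
        self.t += dt_s

    def task_log(self, timed_out: bool = False) -> TaskLog:
        elapsed = None
        if self.completed and self.first_move_t is not None:
            elapsed = self.release_t - self.first_move_t
        stages = {}
        if self.grasp_t is not None:
            stages["grasp"] = self.grasp_t
        if self.drink_t is not None:
            stages["drink"] = self.drink_t
        if self.release_t is not None:
            stages["release"] = self.release_t
        return TaskLog(
            completed=self.completed,
            elapsed_s=elapsed,
            stage_times_s=stages,
            timed_out=timed_out,
        )


# ---------------------------------------------------------------------------
# scripted (virtual-button) policy
# ---------------------------------------------------------------------------

GRASP_Z_CM = 8.0          # grasp/release height, below the 10 cm safety limit
CARRY_Z_CM = 70.0         # inside the mouth-window z band


def scripted_drink_policy(
    scenario: TaskScenario, workspace: Workspace = Workspace()
) -> list[tuple[str | None, float]]:
    """Timed button presses that solve a scenario optimally.

    Axis legs move one coordinate at a time at 3 cm/s (durations are
    leg length / speed); the mouth dwell is a short idle hold.
    """
    speed = 3.0
    cx, cy = scenario.cup_position
    mouth_x = float(np.mean(workspace.mouth_x))
    mouth_y = workspace.mouth_y_max - 2.0
    x0, y0, z0 = scenario.gripper_start

    def leg(axis: str, frm: float, to: float) -> tuple[str | None, float]:
        d = to - frm
        if abs(d) < 1e-9:
            return (None, 0.0)
        return (("+" if d > 0 else "-") + axis, abs(d) / speed)

    plan = [
        leg("Z", z0, GRASP_Z_CM),
        leg("X", x0, cx),
        leg("Y", y0, cy),
        ("close_gripper", 0.05),
        leg("Z", GRASP_Z_CM, CARRY_Z_CM),
        leg("X", cx, mouth_x),
        leg("Y", cy, mouth_y),
        (None, DrinkTaskSim.DRINK_DWELL_S + 0.2),   # drink
        leg("Y", mouth_y, cy),
        leg("X", mouth_x, cx),
        leg("Z", CARRY_Z_CM, GRASP_Z_CM),
        ("open_gripper", 0.05),
    ]
    return [(c, d) for c, d in plan if d > 0]


def scripted_path_length_cm(
    scenario: TaskScenario, workspace: Workspace = Workspace()
) -> float:
    """Total axis-aligned travel of the scripted policy."""
    return 3.0 * sum(
        d for c, d in scripted_drink_policy(scenario, workspace)
        if c in AXIS_COMMANDS
    )


def run_task(
    scenario: TaskScenario,
    command_source: list[tuple[str | None, float]],
    timeout_s: float = 600.0,
    workspace: Workspace = Workspace(),
    dt_s: float = 0.05,
) -> TaskLog:
    """Drive a scenario from a timed command list (a scripted policy or a
    decoder's command log flattened to hold durations).

    On timeout the partial log is returned with ``timed_out=True``.
    """
    sim = DrinkTaskSim(scenario, workspace)
    for cmd, duration in command_source:
        n_ticks = max(1, int(round(duration / dt_s)))
        for _ in range(n_ticks):
            if sim.t >= timeout_s:
                return sim.task_log(timed_out=True)
            sim.step([] if cmd is None else [cmd], dt_s)
            if sim.completed:
                return sim.task_log()
    return sim.task_log(timed_out=not sim.completed)
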