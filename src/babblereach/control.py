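"""Post-training experiments: one-step transformation tests and reaching.

After babbling, the trained pair of networks is probed three ways:

* ``test_forward`` — from a settled internal state, feed each of a grid of
  motor commands once and compare the decoded visual prediction with the
  hand position the arm actually reaches;

* ``test_inverse`` — feed visual positions that are *not* the hand (i.e.
  targets) and decode the postdicted motor command: the network treats the
  target as "where the hand ended up" and emits the command that would have
  brought it there;

* ``reach`` — close the loop: the inverse output population is fed straight
  back into the forward network as the motor input while its decoded value
  drives the physical arm.  Hand vision is never input during the loop (the
  visual input to the forward network is the zero vector, the same
  convention as an unavailable observation during babbling), so this is a
  movement performed in the dark, steered entirely by the internal forward
  prediction held in the hidden state.  Reaching emerges although the
  networks were only ever trained on single random movements with no
  notion of a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arm as arm_mod
from .arm import ArmConfig, HandPosition, MotorCommand, apply_command, forward_kinematics
from .coding import TuningGrid, decode_activations
from .networks import ModelParams, forward_step, initial_state, inverse_step

__all__ = [
    "ReachSpec",
    "TrajectoryStep",
    "Trajectory",
    "DEFAULT_TARGET_AZIMUTHS",
    "default_command_grid",
    "default_targets",
    "initialize_state",
    "test_forward",
    "test_inverse",
    "reach",
]

#: Azimuths of the seven reach targets, degrees (evenly spaced, symmetric).
DEFAULT_TARGET_AZIMUTHS = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)


def default_command_grid(values=(-20.0, -10.0, 0.0, 10.0, 20.0)) -> list[MotorCommand]:
    """The 25 test commands: all combinations of the 5 displacements per joint."""
    return [MotorCommand(da, db) for da in values for db in values]


def default_targets(
    distance: float, azimuths=DEFAULT_TARGET_AZIMUTHS
) -> list[HandPosition]:
    """Targets at one distance spanning the azimuth range."""
    return [HandPosition(r=float(distance), theta=float(az)) for az in azimuths]


@dataclass(frozen=True)
class ReachSpec:
    """One reaching run: posture, target, loop length, settling length."""

    target: HandPosition
    initial_posture: ArmConfig = ArmConfig(20.0, 40.0)
    n_loop: int = 4
    init_iterations: int = 20

    def __post_init__(self) -> None:
        if self.n_loop < 0:
            raise ValueError(f"n_loop must be >= 0, got {self.n_loop}")
        if self.init_iterations < 1:
            raise ValueError(
                f"init_iterations must be >= 1, got {self.init_iterations}"
            )


@dataclass(frozen=True)
class TrajectoryStep:
    step: int
    config: ArmConfig
    hand: HandPosition
    predicted: HandPosition | None  # decoded forward prediction, None at step 0
    command: MotorCommand | None    # decoded command that produced this posture


@dataclass(frozen=True)
class Trajectory:
    """Ordered record of one reaching run; step 0 is the initial posture."""

    spec: ReachSpec
    steps: tuple[TrajectoryStep, ...]

    @property
    def final_hand(self) -> HandPosition:
        return self.steps[-1].hand

    def distances_to_target(self) -> np.ndarray:
        """Cartesian hand-target distance at every step."""
        t = self.spec.target
        return np.array(
            [np.hypot(s.hand.x - t.x, s.hand.y - t.y) for s in self.steps]
        )

    def to_frame(self) -> pd.DataFrame:
        t = self.spec.target
        rows = []
        for s in self.steps:
            rows.append(
                {
                    "step": s.step,
                    "alpha": s.config.alpha,
                    "beta": s.config.beta,
                    "x": s.hand.x,
                    "y": s.hand.y,
                    "r": s.hand.r,
                    "theta": s.hand.theta,
                    "target_x": t.x,
                    "target_y": t.y,
                    "d_alpha": np.nan if s.command is None else s.command.d_alpha,
                    "d_beta": np.nan if s.command is None else s.command.d_beta,
                }
            )
        return pd.DataFrame(rows)


def initialize_state(
    params: ModelParams,
    motor_grid: TuningGrid,
    visual_grid: TuningGrid,
    initial_position: HandPosition,
    n: int = 20,
) -> np.ndarray:
    """Settle the forward hidden state onto an internal representation of
    ``initial_position`` by iterating the forward network ``n`` times with
    vision fixed to that position and the motor command fixed to zero."""
    y_act = visual_grid.activations(initial_position.as_array())
    u_act = motor_grid.activations((0.0, 0.0))
    h = initial_state(params.sizes, params.dtype)
    for _ in range(n):
        h, _ = forward_step(params, u_act, y_act, h)
    return h


def test_forward(
    params: ModelParams,
    motor_grid: TuningGrid,
    visual_grid: TuningGrid,
    initial: ArmConfig = ArmConfig(30.0, 60.0),
    commands: list[MotorCommand] | None = None,
    init_iterations: int = 20,
) -> list[tuple[MotorCommand, HandPosition, HandPosition]]:
    """One-step forward test: per command, (command, actual, predicted).

    The state is settled on the initial hand position; each command is then
    propagated once with vision still fixed to the initial position, and the
    output population is decoded to a predicted polar position.
    """
    if commands is None:
        commands = default_command_grid()
    pos0 = forward_kinematics(initial)
    h0 = initialize_state(params, motor_grid, visual_grid, pos0, init_iterations)
    y0_act = visual_grid.activations(pos0.as_array())
    out = []
    for cmd in commands:
        u_act = motor_grid.activations((cmd.d_alpha, cmd.d_beta))
        _, y_pred = forward_step(params, u_act, y0_act, h0)
        pred = decode_activations(np.asarray(y_pred, dtype=float), visual_grid)
        actual = forward_kinematics(apply_command(initial, cmd))
        out.append((cmd, actual, HandPosition(r=pred[0], theta=pred[1])))
    return out


def test_inverse(
    params: ModelParams,
    motor_grid: TuningGrid,
    visual_grid: TuningGrid,
    initial: ArmConfig = ArmConfig(30.0, 60.0),
    targets: list[HandPosition] | None = None,
    init_iterations: int = 20,
) -> list[tuple[HandPosition, MotorCommand]]:
    """One-step inverse test: per target, the decoded motor command.

    Targets default to the positions reached from the initial posture by the
    25-command grid.  The target's population code plays the role of "the
    hand position after the movement"; the decoded output is the command the
    network believes produced it.
    """
    if targets is None:
        targets = [
            forward_kinematics(apply_command(initial, cmd))
            for cmd in default_command_grid()
        ]
    pos0 = forward_kinematics(initial)
    h0 = initialize_state(params, motor_grid, visual_grid, pos0, init_iterations)
    out = []
    for tgt in targets:
        u_post = inverse_step(params, visual_grid.activations(tgt.as_array()), h0)
        dec = decode_activations(np.asarray(u_post, dtype=float), motor_grid)
        out.append((tgt, MotorCommand(d_alpha=dec[0], d_beta=dec[1])))
    return out


def reach(
    params: ModelParams,
    motor_grid: TuningGrid,
    visual_grid: TuningGrid,
    spec: ReachSpec,
    reencode_motor: bool = False,
) -> Trajectory:
    """Closed-loop reaching toward a visual target without hand vision.

    Per loop iteration: (1) the inverse network postdicts a motor population
    u* from the target's code and the current hidden state; (2) the decoded
    u* moves the physical arm; (3) the forward network consumes u* (the raw
    population by default; ``reencode_motor=True`` re-encodes the decoded
    command instead) with zeroed visual input, updating the hidden state.
    The actual hand position is recorded for analysis but never encoded or
    fed back — vision of the hand plays no role in the loop.
    """
    pos0 = forward_kinematics(spec.initial_posture)
    h = initialize_state(
        params, motor_grid, visual_grid, pos0, spec.init_iterations
    )
    target_act = visual_grid.activations(spec.target.as_array())
    config = spec.initial_posture
    steps = [TrajectoryStep(0, config, pos0, None, None)]
    for k in range(spec.n_loop):
        u_post = inverse_step(params, target_act, h)
        dec = decode_activations(np.asarray(u_post, dtype=float), motor_grid)
        cmd = MotorCommand(d_alpha=float(dec[0]), d_beta=float(dec[1]))
        config = apply_command(config, cmd)
        motor_in = (
            motor_grid.activations((cmd.d_alpha, cmd.d_beta))
            if reencode_motor
            else u_post
        )
        h, y_pred = forward_step(params, motor_in, None, h)
        pred = decode_activations(np.asarray(y_pred, dtype=float), visual_grid)
        steps.append(
            TrajectoryStep(
                step=k + 1,
                config=config,
                hand=forward_kinematics(config),
                predicted=HandPosition(r=pred[0], theta=pred[1]),
                command=cmd,
            )
        )
    return Trajectory(spec=spec, steps=tuple(steps))
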