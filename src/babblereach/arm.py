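"""Planar two-joint arm plant.

The arm is a shoulder-centered pair of unit-length segments moving in the
horizontal plane.  The shoulder angle ``alpha`` is measured counterclockwise
from the rightward (+x) body axis; ``beta`` is the interior elbow angle, with
180 degrees meaning full extension, so the forearm points along
``alpha + 180 - beta``.  Both joints travel in [0, 180] degrees and commands
that would push a joint past an edge simply stop there.

Vision reports the hand in body-centered polar coordinates: distance ``r``
from the shoulder (= body center; body width is neglected) and azimuth
``theta`` measured from the straight-ahead (+y) axis, positive toward the
modeled (right) arm's side.  All angles are degrees end to end; radians only
appear inside trigonometric calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JOINT_RANGE",
    "COMMAND_RANGE",
    "ArmConfig",
    "MotorCommand",
    "HandPosition",
    "InvalidConfigurationError",
    "forward_kinematics",
    "apply_command",
    "sample_babble",
]

#: Travel range of each joint, degrees.
JOINT_RANGE = (0.0, 180.0)

#: Range of each joint-displacement command during babbling, degrees.
COMMAND_RANGE = (-20.0, 20.0)


class InvalidConfigurationError(ValueError):
    """Raised when an arm configuration violates its joint-range invariants."""


@dataclass(frozen=True)
class ArmConfig:
    """Joint configuration (alpha, beta) of the two-link arm, degrees."""

    alpha: float
    beta: float
    segment_length: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = JOINT_RANGE
        if not (lo <= self.alpha <= hi and lo <= self.beta <= hi):
            raise InvalidConfigurationError(
                f"joint angles ({self.alpha}, {self.beta}) outside [{lo}, {hi}]"
            )
        if not self.segment_length > 0:
            raise InvalidConfigurationError(
                f"segment_length must be positive, got {self.segment_length}"
            )


@dataclass(frozen=True)
class MotorCommand:
    """Joint displacement (d_alpha, d_beta), degrees per step."""

    d_alpha: float
    d_beta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d_alpha, self.d_beta], dtype=float)


@dataclass(frozen=True)
class HandPosition:
    """Body-centered polar hand position; Cartesian view derived.

    ``x`` points rightward (toward the modeled arm's side), ``y`` straight
    ahead; ``(x, y) = (r sin(theta), r cos(theta))``.
    """

    r: float
    theta: float

    @property
    def x(self) -> float:
        return self.r * math.sin(math.radians(self.theta))

    @property
    def y(self) -> float:
        return self.r * math.cos(math.radians(self.theta))

    @classmethod
    def from_cartesian(cls, x: float, y: float) -> "HandPosition":
        # atan2(x, y): azimuth from the +y axis, signed toward +x; behind-body
        # positions come out with |theta| > 90 (vision is never clipped).
        return cls(r=math.hypot(x, y), theta=math.degrees(math.atan2(x, y)))

    def as_array(self) -> np.ndarray:
        """Polar vector (r, theta) as consumed by the visual population code."""
        return np.array([self.r, self.theta], dtype=float)


def forward_kinematics(config: ArmConfig) -> HandPosition:
    """Hand position of a joint configuration.

    Shoulder at the origin; elbow at ``L (cos a, sin a)``; hand at
    ``elbow + L (cos(a + 180 - b), sin(a + 180 - b))``.  With unit segments,
    ``(alpha, beta) = (30, 60)`` puts the hand at Cartesian (0, 1), i.e.
    polar (r, theta) = (1, 0); full extension (beta = 180) reaches r = 2.
    """
    a = math.radians(config.alpha)
    f = math.radians(config.alpha + 180.0 - config.beta)
    L = config.segment_length
    x = L * (math.cos(a) + math.cos(f))
    y = L * (math.sin(a) + math.sin(f))
    return HandPosition.from_cartesian(x, y)


def apply_command(config: ArmConfig, cmd: MotorCommand) -> ArmConfig:
    """Displace both joints, stopping each independently at the range edge."""
    lo, hi = JOINT_RANGE
    return ArmConfig(
        alpha=min(hi, max(lo, config.alpha + cmd.d_alpha)),
        beta=min(hi, max(lo, config.beta + cmd.d_beta)),
        segment_length=config.segment_length,
    )


def sample_babble(
    rng: np.random.Generator,
    low: float = COMMAND_RANGE[0],
    high: float = COMMAND_RANGE[1],
) -> MotorCommand:
    """Draw one babbling command, each joint i.i.d. Uniform(low, high)."""
    d = rng.uniform(low, high, size=2)
    return MotorCommand(d_alpha=float(d[0]), d_beta=float(d[1]))
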