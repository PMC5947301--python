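"""Motor-babbling learning loop.

The model learns with no targets and no teacher other than its own body:
at every step a random joint-displacement command (each joint i.i.d.
Uniform(-20, 20) degrees) moves the arm, and — whenever the hand happens to
be looked at, which occurs with probability ``visual_availability`` per
step — the observed post-movement hand position serves simultaneously as
the forward network's teacher and, paired with the babbled command, as the
inverse network's training example.  When the hand is not observed the step
still happens (the forward network runs on its efference copy and recurrent
context alone) but neither network is updated; these gaps are what force
the hidden layer to maintain an internal estimate of the hand position.

Babbling is one continuous random walk: joints clip at their range edges
and the posture is never reset by default (optional episodic resets clear
the hidden state as well).  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arm import ArmConfig, MotorCommand, apply_command, forward_kinematics
from .coding import TuningGrid, decode_activations, motor_grid, visual_grid
from .control import default_command_grid, initialize_state
from .networks import (
    LayerSizes,
    ModelParams,
    forward_step,
    initial_state,
    inverse_step,
    update_forward,
    update_inverse,
)

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "DivergenceError",
    "grids_from_config",
    "train",
    "default_probe_set",
    "evaluate_probe",
]

_BLOCK = 10_000  # babbling commands are drawn from the RNG in fixed blocks


class DivergenceError(RuntimeError):
    """Raised when network weights become non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    """All knobs of the babbling run.  The defaults are the study conditions:
    100/200/400 units, 10x10 and 10x20 preferred grids covering twice the
    definition ranges, command range +-20 deg, visual range [0,3] x
    [-90,90], joints [0,180], learning rate 0.05, visual availability 0.8,
    1,200,000 iterations."""

    eta: float = 0.05
    n_iterations: int = 1_200_000
    visual_availability: float = 0.8
    motor_range: tuple[float, float] = (-20.0, 20.0)
    visual_distance_range: tuple[float, float] = (0.0, 3.0)
    visual_azimuth_range: tuple[float, float] = (-90.0, 90.0)
    joint_range: tuple[float, float] = (0.0, 180.0)
    motor_units_per_dim: tuple[int, int] = (10, 10)
    visual_units_per_dim: tuple[int, int] = (10, 20)
    hidden_units: int = 400
    segment_length: float = 1.0
    grid_coverage: float = 2.0
    init_scale: float = 0.1
    dtype: str = "float32"
    seed: int = 0
    checkpoint_every: int | None = None  # default: n_iterations // 20
    episode_reset_every: int | None = None

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if not 0.0 <= self.visual_availability <= 1.0:
            raise ValueError(
                f"visual_availability must be in [0, 1], got {self.visual_availability}"
            )
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if np.dtype(self.dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
            raise ValueError(f"dtype must be float32 or float64, got {self.dtype}")

    @property
    def layer_sizes(self) -> LayerSizes:
        return LayerSizes(
            motor=self.motor_units_per_dim[0] * self.motor_units_per_dim[1],
            visual=self.visual_units_per_dim[0] * self.visual_units_per_dim[1],
            hidden=self.hidden_units,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def grids_from_config(config: TrainConfig) -> tuple[TuningGrid, TuningGrid]:
    """The (motor, visual) tuning grids a config describes."""
    return (
        motor_grid(
            command_range=config.motor_range,
            n_per_dim=config.motor_units_per_dim,
            coverage=config.grid_coverage,
        ),
        visual_grid(
            distance_range=config.visual_distance_range,
            azimuth_range=config.visual_azimuth_range,
            n_per_dim=config.visual_units_per_dim,
            coverage=config.grid_coverage,
        ),
    )


@dataclass
class TrainingLog:
    """Per-checkpoint probe metrics and weight norms."""

    records: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append(record)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def first(self) -> dict:
        return self.records[0]

    @property
    def last(self) -> dict:
        return self.records[-1]


def default_probe_set(
    posture: ArmConfig = ArmConfig(30.0, 60.0),
) -> list[tuple[ArmConfig, MotorCommand]]:
    """The fixed 25-probe grid used for checkpoint metrics (the one-step
    test grid: all combinations of {-20,-10,0,10,20} per joint)."""
    return [(posture, cmd) for cmd in default_command_grid()]


def evaluate_probe(
    params: ModelParams,
    probes: list[tuple[ArmConfig, MotorCommand]],
    motor: TuningGrid,
    visual: TuningGrid,
    init_iterations: int = 20,
) -> dict:
    """Decoded one-step accuracy of both transformations on a probe set.

    Per probe (posture, command): the forward network's decoded prediction
    is compared with the true post-movement hand position (Euclidean error
    in Cartesian space), and the inverse network's decoded command for the
    true post-movement position is compared with the probe command
    (per-joint absolute error in degrees) and with the required movement
    direction (cosine between the hand displacement the decoded command
    actually produces and the posture-to-target direction; zero-displacement
    probes are excluded from the cosine).
    """
    if not probes:
        raise ValueError("probe set is empty")
    fwd_err: list[float] = []
    inv_joint_err: list[float] = []
    inv_cos: list[float] = []
    # settle the state once per distinct posture
    h_cache: dict[tuple[float, float, float], np.ndarray] = {}
    for posture, cmd in probes:
        key = (posture.alpha, posture.beta, posture.segment_length)
        pos0 = forward_kinematics(posture)
        if key not in h_cache:
            h_cache[key] = initialize_state(
                params, motor, visual, pos0, init_iterations
            )
        h0 = h_cache[key]
        actual = forward_kinematics(apply_command(posture, cmd))
        # forward: predict the consequence of cmd
        u_act = motor.activations((cmd.d_alpha, cmd.d_beta))
        y0_act = visual.activations(pos0.as_array())
        _, y_pred = forward_step(params, u_act, y0_act, h0)
        pred = decode_activations(np.asarray(y_pred, dtype=float), visual)
        px = pred[0] * math.sin(math.radians(pred[1]))
        py = pred[0] * math.cos(math.radians(pred[1]))
        fwd_err.append(math.hypot(px - actual.x, py - actual.y))
        # inverse: postdict the command that reaches `actual`
        u_post = inverse_step(params, visual.activations(actual.as_array()), h0)
        dec = decode_activations(np.asarray(u_post, dtype=float), motor)
        inv_joint_err.append(
            0.5 * (abs(dec[0] - cmd.d_alpha) + abs(dec[1] - cmd.d_beta))
        )
        moved = forward_kinematics(
            apply_command(posture, MotorCommand(float(dec[0]), float(dec[1])))
        )
        need = np.array([actual.x - pos0.x, actual.y - pos0.y])
        got = np.array([moved.x - pos0.x, moved.y - pos0.y])
        if np.linalg.norm(need) > 1e-12 and np.linalg.norm(got) > 1e-12:
            inv_cos.append(
                float(need @ got / (np.linalg.norm(need) * np.linalg.norm(got)))
            )
    q = lambda v: np.quantile(np.asarray(v), [0.25, 0.5, 0.75])
    fwd_q = q(fwd_err)
    return {
        "forward_error_mean": float(np.mean(fwd_err)),
        "forward_error_q25": float(fwd_q[0]),
        "forward_error_q50": float(fwd_q[1]),
        "forward_error_q75": float(fwd_q[2]),
        "inverse_joint_error_mean": float(np.mean(inv_joint_err)),
        "inverse_direction_cosine_mean": float(np.mean(inv_cos)) if inv_cos else float("nan"),
    }


def _check_finite(params: ModelParams, iteration: int) -> None:
    for name in ModelParams.FORWARD_FIELDS + ModelParams.INVERSE_FIELDS:
        if not np.all(np.isfinite(getattr(params, name))):
            raise DivergenceError(
                f"non-finite weights in {name} at iteration {iteration}"
            )


def train(
    config: TrainConfig,
    progress: bool = False,
) -> tuple[ModelParams, TrainingLog]:
    """Run the babbling loop; returns trained weights and the checkpoint log.

    Per iteration: sample a command, move the (clipping) arm, draw visual
    availability, propagate the forward network with the previous step's
    observation (zeros if it was unobserved), and — only if the new position
    is observed — apply one forward update (teacher: the observed position's
    code) and one inverse update (inputs: that code and the pre-movement
    hidden state; teacher: the babbled command's code).  The hidden state
    always carries over.  (seed, config) fully determine the result.
    """
    rng = np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype)
    params = ModelParams.initialize(
        config.layer_sizes, rng, scale=config.init_scale, dtype=dtype
    )
    motor, visual = grids_from_config(config)
    probes = default_probe_set()
    log = TrainingLog()
    ckpt = config.checkpoint_every or max(1, config.n_iterations // 20)

    jlo, jhi = config.joint_range
    clo, chi = config.motor_range
    alpha = float(rng.uniform(jlo, jhi))
    beta = float(rng.uniform(jlo, jhi))
    L = config.segment_length
    h = initial_state(config.layer_sizes, dtype)
    avail = config.visual_availability
    eta = config.eta

    def observe() -> np.ndarray:
        a = math.radians(alpha)
        f = math.radians(alpha + 180.0 - beta)
        x = L * (math.cos(a) + math.cos(f))
        y = L * (math.sin(a) + math.sin(f))
        r = math.hypot(x, y)
        th = math.degrees(math.atan2(x, y))
        return np.asarray(visual.activations((r, th)), dtype=dtype)

    # the step-0 view of the hand, subject to the same availability rate
    y_prev = observe() if (avail > 0 and rng.random() < avail) else None

    done = 0
    while done < config.n_iterations:
        n = min(_BLOCK, config.n_iterations - done)
        cmds = rng.uniform(clo, chi, size=(n, 2))
        seen = rng.random(n) < avail
        for i in range(n):
            it = done + i + 1
            da, db = cmds[i, 0], cmds[i, 1]
            alpha = min(jhi, max(jlo, alpha + da))
            beta = min(jhi, max(jlo, beta + db))
            u_act = np.asarray(motor.activations((da, db)), dtype=dtype)
            h_new, y_pred = forward_step(params, u_act, y_prev, h)
            if seen[i]:
                y_next = observe()
                update_forward(
                    params, u_act, y_prev, h, y_next, eta, cache=(h_new, y_pred)
                )
                # The inverse receives the hidden state as it stood when the
                # command was issued — the internal representation of the hand
                # position *before* the movement.  Feeding the post-command
                # hidden instead would let the inverse short-circuit into a
                # readout of the command it is supposed to infer.
                update_inverse(params, y_next, h, u_act, eta)
                y_prev = y_next
            else:
                y_prev = None
            h = h_new
            if config.episode_reset_every and it % config.episode_reset_every == 0:
                alpha = float(rng.uniform(jlo, jhi))
                beta = float(rng.uniform(jlo, jhi))
                h = initial_state(config.layer_sizes, dtype)
                y_prev = observe() if (avail > 0 and rng.random() < avail) else None
            if it % ckpt == 0 or it == config.n_iterations:
                _check_finite(params, it)
                metrics = evaluate_probe(params, probes, motor, visual)
                log.append(
                    iteration=it,
                    **metrics,
                    forward_weight_norm=float(
                        np.sqrt(
                            sum(
                                float((getattr(params, f) ** 2).sum())
                                for f in ModelParams.FORWARD_FIELDS
                            )
                        )
                    ),
                    inverse_weight_norm=float(
                        np.sqrt(
                            sum(
                                float((getattr(params, f) ** 2).sum())
                                for f in ModelParams.INVERSE_FIELDS
                            )
                        )
                    ),
                )
                if progress:
                    print(
                        f"[babblereach] iter {it}/{config.n_iterations} "
                        f"fwd_err={metrics['forward_error_mean']:.4f} "
                        f"inv_cos={metrics['inverse_direction_cosine_mean']:.3f}"
                    )
        done += n
    return params, log
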