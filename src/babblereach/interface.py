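"""Configuration, model serialization, and the experiment-suite driver.

Configuration is a plain YAML file mirroring :class:`RunConfig`'s nested
sections (``arm``, ``coding``, ``network``, ``training``, ``experiments``,
``output``); an empty file yields the full default study conditions.
Unknown keys are rejected and every validation failure names the offending
field.

``run_paper_suite`` ties everything together: it trains a model (or loads
one), runs the one-step forward and inverse tests and the within-reach and
out-of-reach reaching loops, writes all tables as CSV (degrees and
arm-segment units, 6 decimal places), optionally renders summary plots, and
returns a machine-readable report of the headline metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arm import ArmConfig, HandPosition
from .coding import TuningGrid
from .control import (
    DEFAULT_TARGET_AZIMUTHS,
    ReachSpec,
    Trajectory,
    default_targets,
    reach,
    test_forward,
    test_inverse,
)
from .networks import LayerSizes, ModelParams
from .training import (
    TrainConfig,
    TrainingLog,
    default_probe_set,
    evaluate_probe,
    grids_from_config,
    train,
)

__all__ = [
    "ConfigError",
    "ArmSection",
    "CodingSection",
    "NetworkSection",
    "TrainingSection",
    "ExperimentsSection",
    "OutputSection",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "save_model",
    "load_model",
    "run_paper_suite",
]

_CSV_FLOAT = "%.6f"


class ConfigError(ValueError):
    """Raised for unreadable, malformed, or invalid configuration input."""


@dataclass(frozen=True)
class ArmSection:
    segment_length: float = 1.0
    joint_range: tuple[float, float] = (0.0, 180.0)


@dataclass(frozen=True)
class CodingSection:
    motor_units_per_dim: tuple[int, int] = (10, 10)
    visual_units_per_dim: tuple[int, int] = (10, 20)
    grid_coverage: float = 2.0


@dataclass(frozen=True)
class NetworkSection:
    hidden_units: int = 400
    init_scale: float = 0.1
    dtype: str = "float32"


@dataclass(frozen=True)
class TrainingSection:
    eta: float = 0.05
    n_iterations: int = 1_200_000
    visual_availability: float = 0.8
    motor_range: tuple[float, float] = (-20.0, 20.0)
    visual_distance_range: tuple[float, float] = (0.0, 3.0)
    visual_azimuth_range: tuple[float, float] = (-90.0, 90.0)
    seed: int = 0
    checkpoint_every: int | None = None
    episode_reset_every: int | None = None


@dataclass(frozen=True)
class ExperimentsSection:
    test_posture: tuple[float, float] = (30.0, 60.0)
    reach_posture: tuple[float, float] = (20.0, 40.0)
    target_azimuths: tuple[float, ...] = DEFAULT_TARGET_AZIMUTHS
    within_reach_distance: float = 2.0
    within_reach_loops: int = 4
    out_of_reach_distance: float = 3.0
    out_of_reach_loops: int = 7
    init_iterations: int = 20


@dataclass(frozen=True)
class OutputSection:
    directory: str = "results"
    plots: bool = False


@dataclass(frozen=True)
class RunConfig:
    arm: ArmSection = field(default_factory=ArmSection)
    coding: CodingSection = field(default_factory=CodingSection)
    network: NetworkSection = field(default_factory=NetworkSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    experiments: ExperimentsSection = field(default_factory=ExperimentsSection)
    output: OutputSection = field(default_factory=OutputSection)

    def to_train_config(self, seed: int | None = None) -> TrainConfig:
        t = self.training
        try:
            return TrainConfig(
                eta=t.eta,
                n_iterations=t.n_iterations,
                visual_availability=t.visual_availability,
                motor_range=t.motor_range,
                visual_distance_range=t.visual_distance_range,
                visual_azimuth_range=t.visual_azimuth_range,
                joint_range=self.arm.joint_range,
                motor_units_per_dim=self.coding.motor_units_per_dim,
                visual_units_per_dim=self.coding.visual_units_per_dim,
                hidden_units=self.network.hidden_units,
                segment_length=self.arm.segment_length,
                grid_coverage=self.coding.grid_coverage,
                init_scale=self.network.init_scale,
                dtype=self.network.dtype,
                seed=t.seed if seed is None else int(seed),
                checkpoint_every=t.checkpoint_every,
                episode_reset_every=t.episode_reset_every,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


def _build_dataclass(cls, data: dict, path: str):
    """Recursively fill ``cls`` from a dict, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path or cls.__name__}' must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{path or 'top level'}'"
        )
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        here = f"{path}.{name}" if path else name
        if is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type.endswith("Section")
        ):
            sub_cls = f.default_factory() .__class__  # type: ignore[misc]
            kwargs[name] = _build_dataclass(sub_cls, value, here)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{path or 'top level'}': {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` or an empty file gives the
    full defaults.  Unknown keys and invalid values raise :class:`ConfigError`
    naming the field; the resulting training section is validated eagerly."""
    if path is None:
        cfg = RunConfig()
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            data = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {p}: {exc}") from exc
        cfg = _build_dataclass(RunConfig, data or {}, "")
    cfg.to_train_config()  # validate eagerly so bad values fail at load time
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain_dict(config), sort_keys=False))


def _as_plain_dict(obj):
    if is_dataclass(obj):
        return {f.name: _as_plain_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain_dict(v) for v in obj]
    return obj


def config_hash(config: RunConfig | TrainConfig) -> str:
    """Stable short hash identifying a configuration."""
    if isinstance(config, TrainConfig):
        payload = config.to_dict()
    else:
        payload = _as_plain_dict(config)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# model files

_MODEL_FORMAT = 1


def save_model(
    path: str | Path,
    params: ModelParams,
    config: TrainConfig,
    n_iterations_done: int | None = None,
) -> None:
    """Write weights plus a self-describing header (grids, sizes, config,
    seed, iteration count) to an ``.npz`` container."""
    motor, visual = grids_from_config(config)
    meta = {
        "format": _MODEL_FORMAT,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_iterations_done": (
            config.n_iterations if n_iterations_done is None else n_iterations_done
        ),
        "layer_sizes": dataclasses.asdict(config.layer_sizes),
        "motor_grid": motor.to_dict(),
        "visual_grid": visual.to_dict(),
    }
    arrays = {
        name: getattr(params, name)
        for name in ModelParams.FORWARD_FIELDS + ModelParams.INVERSE_FIELDS
    }
    np.savez(Path(path), meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> tuple[ModelParams, TrainConfig, dict]:
    """Load a model file; returns (params, config, metadata)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format") != _MODEL_FORMAT:
            raise ValueError(f"unsupported model-file format: {meta.get('format')}")
        arrays = {
            name: np.asfortranarray(data[name])
            for name in ModelParams.FORWARD_FIELDS + ModelParams.INVERSE_FIELDS
        }
    cfg_dict = meta["config"]
    for key in (
        "motor_range",
        "visual_distance_range",
        "visual_azimuth_range",
        "joint_range",
        "motor_units_per_dim",
        "visual_units_per_dim",
    ):
        cfg_dict[key] = tuple(cfg_dict[key])
    return ModelParams(**arrays), TrainConfig(**cfg_dict), meta


# ---------------------------------------------------------------------------
# the experiment suite

def _forward_table(results) -> pd.DataFrame:
    rows = []
    for cmd, actual, predicted in results:
        rows.append(
            {
                "d_alpha": cmd.d_alpha,
                "d_beta": cmd.d_beta,
                "actual_x": actual.x,
                "actual_y": actual.y,
                "actual_r": actual.r,
                "actual_theta": actual.theta,
                "predicted_x": predicted.x,
                "predicted_y": predicted.y,
                "predicted_r": predicted.r,
                "predicted_theta": predicted.theta,
                "error": float(
                    np.hypot(predicted.x - actual.x, predicted.y - actual.y)
                ),
            }
        )
    return pd.DataFrame(rows)


def _inverse_table(results, initial_pos: HandPosition) -> pd.DataFrame:
    rows = []
    for target, cmd in results:
        rows.append(
            {
                "target_x": target.x,
                "target_y": target.y,
                "target_r": target.r,
                "target_theta": target.theta,
                "d_alpha": cmd.d_alpha,
                "d_beta": cmd.d_beta,
                "initial_x": initial_pos.x,
                "initial_y": initial_pos.y,
            }
        )
    return pd.DataFrame(rows)


def _reach_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    frames = []
    for traj in trajectories:
        f = traj.to_frame()
        f.insert(0, "target_theta", traj.spec.target.theta)
        f.insert(0, "target_r", traj.spec.target.r)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def reach_summary(trajectories: list[Trajectory]) -> dict:
    """Headline reaching metrics over a set of runs toward one distance."""
    init_d = np.array([t.distances_to_target()[0] for t in trajectories])
    final_d = np.array([t.distances_to_target()[-1] for t in trajectories])
    azim = np.array([t.spec.target.theta for t in trajectories])
    final_r = np.array([t.final_hand.r for t in trajectories])
    final_theta = np.array([t.final_hand.theta for t in trajectories])
    ipsi = azim > 0
    contra = azim < 0
    lateral = np.abs(azim) >= 60.0
    return {
        "mean_initial_distance": float(init_d.mean()),
        "mean_final_distance": float(final_d.mean()),
        "mean_final_distance_ipsilateral": float(final_d[ipsi].mean())
        if ipsi.any()
        else float("nan"),
        "mean_final_distance_contralateral": float(final_d[contra].mean())
        if contra.any()
        else float("nan"),
        "min_final_r": float(final_r.min()),
        "mean_final_r": float(final_r.mean()),
        "lateral_azimuth_sign_agreement": float(
            np.mean(np.sign(final_theta[lateral]) == np.sign(azim[lateral]))
        )
        if lateral.any()
        else float("nan"),
    }


def run_paper_suite(
    config: RunConfig,
    seed: int | None = None,
    outdir: str | Path | None = None,
    model_path: str | Path | None = None,
    progress: bool = False,
) -> dict:
    """Train (or load) a model and run the full experiment battery.

    Writes ``training_log.csv``, ``forward_test.csv``, ``inverse_test.csv``,
    ``reach_within.csv``, ``reach_beyond.csv``, ``model.npz`` and
    ``report.json`` under ``outdir`` (default: the config's output
    directory), plus summary plots when enabled.  Returns the report dict.
    """
    out = Path(outdir if outdir is not None else config.output.directory)
    out.mkdir(parents=True, exist_ok=True)

    if model_path is not None:
        params, tc, _meta = load_model(model_path)
        log = TrainingLog()
    else:
        tc = config.to_train_config(seed=seed)
        params, log = train(tc, progress=progress)
    motor, visual = grids_from_config(tc)
    exp = config.experiments

    test_posture = ArmConfig(*exp.test_posture, segment_length=tc.segment_length)
    reach_posture = ArmConfig(*exp.reach_posture, segment_length=tc.segment_length)
    from .arm import forward_kinematics  # local import to avoid cycle at top

    fwd = test_forward(
        params, motor, visual, initial=test_posture,
        init_iterations=exp.init_iterations,
    )
    inv = test_inverse(
        params, motor, visual, initial=test_posture,
        init_iterations=exp.init_iterations,
    )
    within = [
        reach(
            params, motor, visual,
            ReachSpec(
                target=t, initial_posture=reach_posture,
                n_loop=exp.within_reach_loops,
                init_iterations=exp.init_iterations,
            ),
        )
        for t in default_targets(exp.within_reach_distance, exp.target_azimuths)
    ]
    beyond = [
        reach(
            params, motor, visual,
            ReachSpec(
                target=t, initial_posture=reach_posture,
                n_loop=exp.out_of_reach_loops,
                init_iterations=exp.init_iterations,
            ),
        )
        for t in default_targets(exp.out_of_reach_distance, exp.target_azimuths)
    ]

    fwd_table = _forward_table(fwd)
    inv_table = _inverse_table(inv, forward_kinematics(test_posture))
    within_table = _reach_table(within)
    beyond_table = _reach_table(beyond)

    fwd_table.to_csv(out / "forward_test.csv", index=False, float_format=_CSV_FLOAT)
    inv_table.to_csv(out / "inverse_test.csv", index=False, float_format=_CSV_FLOAT)
    within_table.to_csv(out / "reach_within.csv", index=False, float_format=_CSV_FLOAT)
    beyond_table.to_csv(out / "reach_beyond.csv", index=False, float_format=_CSV_FLOAT)
    log.to_frame().to_csv(out / "training_log.csv", index=False, float_format=_CSV_FLOAT)
    save_model(out / "model.npz", params, tc)

    probe_metrics = evaluate_probe(
        params, default_probe_set(test_posture), motor, visual,
        init_iterations=exp.init_iterations,
    )
    report = {
        "seed": tc.seed,
        "config_hash": config_hash(tc),
        "n_iterations": tc.n_iterations,
        "probe": probe_metrics,
        "forward_test_mean_error": float(fwd_table["error"].mean()),
        "reach_within": reach_summary(within),
        "reach_beyond": reach_summary(beyond),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))

    if config.output.plots:
        _render_plots(out, fwd_table, inv_table, within_table, beyond_table)
    return report


def _render_plots(out: Path, fwd, inv, within, beyond) -> None:
    """Optional side outputs: scatter/trajectory summaries of the tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(fwd["actual_x"], fwd["actual_y"], s=18, c="k", label="actual")
    ax.scatter(
        fwd["predicted_x"], fwd["predicted_y"],
        s=40, facecolors="none", edgecolors="k", label="predicted",
    )
    ax.set_xlabel("x"); ax.set_ylabel("y"); ax.legend()
    ax.set_title("one-step forward test")
    fig.savefig(out / "forward_test.png", dpi=120); plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        inv["target_x"], inv["target_y"],
        s=40, facecolors="none", edgecolors="k", label="target",
    )
    ax.quiver(
        inv["initial_x"], inv["initial_y"],
        inv["target_x"] - inv["initial_x"], inv["target_y"] - inv["initial_y"],
        angles="xy", scale_units="xy", scale=1, width=0.003, alpha=0.4,
    )
    ax.set_xlabel("x"); ax.set_ylabel("y")
    ax.set_title("one-step inverse test targets")
    fig.savefig(out / "inverse_test.png", dpi=120); plt.close(fig)

    for name, table in (("reach_within", within), ("reach_beyond", beyond)):
        fig, ax = plt.subplots(figsize=(5, 5))
        for theta, traj in table.groupby("target_theta"):
            ax.plot(traj["x"], traj["y"], "o-", ms=3)
            ax.plot(
                traj["target_x"].iloc[0], traj["target_y"].iloc[0], "*", ms=10
            )
        ax.set_xlabel("x"); ax.set_ylabel("y"); ax.set_title(name)
        fig.savefig(out / f"{name}.png", dpi=120); plt.close(fig)
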