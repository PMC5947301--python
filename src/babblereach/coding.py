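"""Broadly tuned population place codes for 2-D motor and visual vectors.

A :class:`TuningGrid` lays the units' preferred vectors on a regular lattice
that spans, per dimension, twice the length of the definition range, centered
on its midpoint.  The out-of-range preferred vectors let the population
represent inputs at the edge of the range: without them every unit responding
to an edge input prefers a more central value, so the decoded vector shifts
toward the center.

Each unit's tuning curve is a truncated cosine per dimension, combined
multiplicatively:

    g(delta; w) = cos(90 deg * delta / w)   if |delta| < w, else 0
    activation_i = g(v_0 - p_i0; w_0) * g(v_1 - p_i1; w_1)

so activation is 1 exactly at the preferred vector, falls off smoothly, and
is 0 once the offset reaches the half-width ``w`` in either dimension.  The
visual azimuth half-width is 90 degrees (broad sensitivity); the remaining
half-widths follow the same "half the definition-range length" rule
(distance: 1.5 arm units, motor: 20 degrees per joint).

Decoding is the standard population-vector readout: the activation-weighted
center of gravity of the preferred vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TuningGrid",
    "PopulationCode",
    "GridConfigurationError",
    "UndecodableCodeError",
    "build_grid",
    "motor_grid",
    "visual_grid",
    "encode",
    "decode",
]


class GridConfigurationError(ValueError):
    """Raised for non-positive unit counts or inverted definition ranges."""


class UndecodableCodeError(ValueError):
    """Raised when decoding an all-zero population."""


@dataclass(frozen=True, eq=False)
class TuningGrid:
    """Regular 2-D lattice of preferred vectors with per-dimension tuning.

    ``axes[d]`` holds the sorted preferred values along dimension ``d``; the
    full lattice is their Cartesian product in C order (dimension 0 major).
    """

    axes: tuple[np.ndarray, np.ndarray]
    half_width: tuple[float, float]
    definition_range: tuple[tuple[float, float], tuple[float, float]]
    dim_names: tuple[str, str]

    @property
    def n_per_dim(self) -> tuple[int, int]:
        return (len(self.axes[0]), len(self.axes[1]))

    @property
    def n_units(self) -> int:
        return len(self.axes[0]) * len(self.axes[1])

    @property
    def preferred(self) -> np.ndarray:
        """(n_units, 2) array of preferred vectors, C-order of the lattice."""
        g0, g1 = np.meshgrid(self.axes[0], self.axes[1], indexing="ij")
        return np.column_stack([g0.ravel(), g1.ravel()])

    @property
    def spacing(self) -> tuple[float, float]:
        """Lattice spacing per dimension."""
        return (
            float(self.axes[0][1] - self.axes[0][0]),
            float(self.axes[1][1] - self.axes[1][0]),
        )

    def activations(self, v: Sequence[float]) -> np.ndarray:
        """Raw activation vector for input ``v`` (separable truncated cosine)."""
        parts = []
        for d in range(2):
            delta = float(v[d]) - self.axes[d]
            w = self.half_width[d]
            resp = np.cos((np.pi / 2.0) * delta / w)
            resp[np.abs(delta) >= w] = 0.0
            parts.append(resp)
        return np.outer(parts[0], parts[1]).ravel()

    def to_dict(self) -> dict:
        """JSON-serializable description (for self-describing model files)."""
        return {
            "axes": [a.tolist() for a in self.axes],
            "half_width": list(self.half_width),
            "definition_range": [list(r) for r in self.definition_range],
            "dim_names": list(self.dim_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TuningGrid":
        return cls(
            axes=tuple(np.asarray(a, dtype=float) for a in d["axes"]),
            half_width=tuple(d["half_width"]),
            definition_range=tuple(tuple(r) for r in d["definition_range"]),
            dim_names=tuple(d["dim_names"]),
        )


@dataclass(frozen=True, eq=False)
class PopulationCode:
    """Activation vector in [0, 1] over a :class:`TuningGrid`."""

    activations: np.ndarray
    grid: TuningGrid

    def __post_init__(self) -> None:
        a = self.activations
        if a.shape != (self.grid.n_units,):
            raise ValueError(
                f"activation length {a.shape} does not match grid "
                f"({self.grid.n_units} units)"
            )


def build_grid(
    definition_range: Sequence[Sequence[float]],
    n_per_dim: Sequence[int],
    half_width: Sequence[float],
    dim_names: Sequence[str] = ("dim0", "dim1"),
    coverage: float = 2.0,
) -> TuningGrid:
    """Build a lattice spanning ``coverage`` times the definition range.

    With the default ``coverage=2`` the preferred values run from
    ``mid - span`` to ``mid + span`` where ``span`` is the full
    definition-range length, endpoints included.  ``coverage=1`` gives a
    non-doubled control grid (useful for quantifying edge bias).
    """
    axes = []
    for d in range(2):
        lo, hi = (float(definition_range[d][0]), float(definition_range[d][1]))
        n = int(n_per_dim[d])
        if n < 2:
            raise GridConfigurationError(f"n_per_dim[{d}] must be >= 2, got {n}")
        if not hi > lo:
            raise GridConfigurationError(
                f"definition_range[{d}] = ({lo}, {hi}) is degenerate or inverted"
            )
        if not half_width[d] > 0:
            raise GridConfigurationError(
                f"half_width[{d}] must be positive, got {half_width[d]}"
            )
        mid = 0.5 * (lo + hi)
        half_span = 0.5 * (hi - lo) * coverage
        axes.append(np.linspace(mid - half_span, mid + half_span, n))
    return TuningGrid(
        axes=(axes[0], axes[1]),
        half_width=(float(half_width[0]), float(half_width[1])),
        definition_range=(
            (float(definition_range[0][0]), float(definition_range[0][1])),
            (float(definition_range[1][0]), float(definition_range[1][1])),
        ),
        dim_names=(str(dim_names[0]), str(dim_names[1])),
    )


def motor_grid(
    command_range: Sequence[float] = (-20.0, 20.0),
    n_per_dim: Sequence[int] = (10, 10),
    half_width: Sequence[float] | None = None,
    coverage: float = 2.0,
) -> TuningGrid:
    """Default motor grid: 10 x 10 preferred displacements over the doubled
    command range [-40, 40] per joint, half-width 20 degrees per joint."""
    if half_width is None:
        w = 0.5 * (command_range[1] - command_range[0])
        half_width = (w, w)
    return build_grid(
        definition_range=(command_range, command_range),
        n_per_dim=n_per_dim,
        half_width=half_width,
        dim_names=("d_alpha", "d_beta"),
        coverage=coverage,
    )


def visual_grid(
    distance_range: Sequence[float] = (0.0, 3.0),
    azimuth_range: Sequence[float] = (-90.0, 90.0),
    n_per_dim: Sequence[int] = (10, 20),
    half_width: Sequence[float] | None = None,
    coverage: float = 2.0,
) -> TuningGrid:
    """Default visual grid: 10 preferred distances x 20 preferred azimuths
    over the doubled ranges [-1.5, 4.5] x [-180, 180], half-widths
    1.5 arm units and 90 degrees."""
    if half_width is None:
        half_width = (0.5 * (distance_range[1] - distance_range[0]), 90.0)
    return build_grid(
        definition_range=(distance_range, azimuth_range),
        n_per_dim=n_per_dim,
        half_width=half_width,
        dim_names=("distance", "azimuth"),
        coverage=coverage,
    )


def encode(v: Sequence[float], grid: TuningGrid) -> PopulationCode:
    """Encode a 2-D vector as a population of broadly tuned activations.

    ``v`` may lie outside the definition range (e.g. behind-body azimuths);
    far-out inputs simply activate few or no units.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"cannot encode non-finite vector {v!r}")
    return PopulationCode(activations=grid.activations(v), grid=grid)


def decode(code: PopulationCode) -> np.ndarray:
    """Center-of-gravity readout: sum_i a_i p_i / sum_i a_i."""
    return decode_activations(code.activations, code.grid)


def decode_activations(activations: np.ndarray, grid: TuningGrid) -> np.ndarray:
    """Decode a raw activation vector over ``grid`` (array-level fast path)."""
    total = float(activations.sum())
    if total <= 0.0:
        raise UndecodableCodeError("population is all-zero; nothing to decode")
    n0, n1 = grid.n_per_dim
    a = np.asarray(activations, dtype=float).reshape(n0, n1)
    v0 = float(a.sum(axis=1) @ grid.axes[0]) / total
    v1 = float(a.sum(axis=0) @ grid.axes[1]) / total
    return np.array([v0, v1])
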