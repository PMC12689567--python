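"""PMC surface and radar exports.

A policy's nine dimension scores are arranged row-major into a 3x3 surface
matrix

    [[X1, X2, X3],
     [X4, X5, X6],
     [X7, X8, X9]]

and rendered as a 3D surface: convex regions mark strong dimensions,
concave regions weak ones.  Only the qualitative convex/concave reading
matters, so the smooth rendering uses shape-preserving tensor-product PCHIP
interpolation, which passes exactly through the nine control values and
never overshoots their range.  A "tile" mode (nearest-neighbour, no
interpolation) is also exposed.  The radar export carries the dimension
averages with a configurable low-score flag (default threshold 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .engine import EvaluationResult, PolicyScoreCard
from .rounding import round_half_up

__all__ = [
    "SurfaceMatrix",
    "surface_matrix",
    "average_surface",
    "export_surface_grid",
    "radar_data",
]

_GRID_SHAPE = (3, 3)


@dataclass(frozen=True)
class SurfaceMatrix:
    """3x3 row-major arrangement of the nine dimension scores."""

    values: np.ndarray  # float, shape (3, 3)
    codes: tuple[tuple[str, ...], ...]
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != _GRID_SHAPE:
            raise ValueError(f"surface must be 3x3, got {vals.shape}")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("surface entries must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def display(self) -> list[list[float]]:
        return [[round_half_up(v) for v in row] for row in self.values]


def _arrange(values: dict[str, Fraction | float], label: str) -> SurfaceMatrix:
    codes = list(values)
    if len(codes) != 9:
        raise ValueError(f"need 9 dimension scores, got {len(codes)}")
    grid = np.array([float(values[c]) for c in codes], dtype=float).reshape(3, 3)
    code_grid = tuple(tuple(codes[3 * r + c] for c in range(3)) for r in range(3))
    return SurfaceMatrix(values=grid, codes=code_grid, label=label)


def surface_matrix(card: PolicyScoreCard) -> SurfaceMatrix:
    """One policy's surface: scores placed row-major in schema order."""
    return _arrange({s.code: s.value for s in card.scores}, label=card.policy_id)


def average_surface(result: EvaluationResult) -> SurfaceMatrix:
    """Corpus surface built from the dimension averages."""
    if not result.scorecards:
        raise ValueError("empty evaluation result")
    return _arrange(dict(result.dimension_averages), label="Average")


def export_surface_grid(
    surface: SurfaceMatrix,
    resolution: int = 30,
    mode: str = "smooth",
    path: str | None = None,
    image_path: str | None = None,
) -> pd.DataFrame:
    """Interpolate the 3x3 control grid onto a resolution^2 height field.

    ``mode='smooth'`` uses tensor-product PCHIP: the field passes through
    the nine control values exactly and stays within [min, max] of the
    control grid.  ``mode='tile'`` repeats each control value over its
    nearest cells.  At ``resolution=3`` both return the control grid.
    Optionally writes the gridded field as CSV and/or a PNG/SVG surface
    plot; both outputs are deterministic for fixed inputs.
    """
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    nodes = np.array([0.0, 0.5, 1.0])
    t = np.linspace(0.0, 1.0, resolution)
    if resolution == 3:
        field = surface.values.copy()
    elif mode == "smooth":
        # interpolate along columns, then along rows of the intermediate field
        along_x = np.vstack([PchipInterpolator(nodes, row)(t) for row in surface.values])
        field = np.vstack(
            [PchipInterpolator(nodes, along_x[:, j])(t) for j in range(resolution)]
        ).T
    elif mode == "tile":
        idx = np.abs(t[:, None] - nodes[None, :]).argmin(axis=1)
        field = surface.values[np.ix_(idx, idx)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frame = pd.DataFrame(field, index=t, columns=t)
    if path:
        frame.to_csv(path, index_label="y")
    if image_path:
        _plot_surface(field, t, surface.label, image_path)
    return frame


def radar_data(
    result: EvaluationResult,
    threshold: float = 0.6,
    path: str | None = None,
    image_path: str | None = None,
) -> pd.DataFrame:
    """Ordered (dimension, average, flagged) rows; flags averages below threshold."""
    rows = [
        {
            "dimension": d,
            "value": round_half_up(v),
            "flagged": float(v) < threshold,
        }
        for d, v in result.dimension_averages.items()
    ]
    frame = pd.DataFrame(rows)
    if path:
        frame.to_csv(path, index=False)
    if image_path:
        _plot_radar(frame, image_path)
    return frame


def _plot_surface(field: np.ndarray, t: np.ndarray, label: str, image_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    xx, yy = np.meshgrid(t, t)
    ax.plot_surface(xx, yy, field, cmap="viridis", linewidth=0)
    ax.set_zlim(0, 1)
    ax.set_title(f"PMC surface {label}".strip())
    fig.savefig(image_path, dpi=120)
    plt.close(fig)


def _plot_radar(frame: pd.DataFrame, image_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(frame)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    values = frame["value"].to_numpy()
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.plot(np.append(angles, angles[0]), np.append(values, values[0]))
    ax.fill(np.append(angles, angles[0]), np.append(values, values[0]), alpha=0.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(frame["dimension"])
    ax.set_ylim(0, 1)
    fig.savefig(image_path, dpi=120)
    plt.close(fig)
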