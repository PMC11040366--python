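"""Rectangular domains and cell-centered state grids.

All quantitative machinery operates in a 2-D reduced (embedding) space; grids
are cell-centered with half-open binning [edge_i, edge_{i+1}).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Rect", "StateGrid"]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned bounding rectangle in embedding units."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("bounds must be strictly increasing")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (
            (p[..., 0] >= self.x_min)
            & (p[..., 0] <= self.x_max)
            & (p[..., 1] >= self.y_min)
            & (p[..., 1] <= self.y_max)
        )

    def expand(self, margin_frac: float) -> "Rect":
        mx = margin_frac * self.width
        my = margin_frac * self.height
        return Rect(self.x_min - mx, self.x_max + mx, self.y_min - my, self.y_max + my)

    def clip(self, points: np.ndarray) -> np.ndarray:
        p = np.array(points, float)
        p[..., 0] = np.clip(p[..., 0], self.x_min, self.x_max)
        p[..., 1] = np.clip(p[..., 1], self.y_min, self.y_max)
        return p


@dataclass(frozen=True)
class StateGrid:
    """Cell-centered grid over a rectangle; fields are (ny, nx) arrays
    indexed [iy, ix] with x varying along axis 1."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 cells per axis")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("bounds must be strictly increasing")

    @classmethod
    def from_rect(cls, rect: Rect, nx: int, ny: int | None = None) -> "StateGrid":
        return cls(rect.x_min, rect.x_max, rect.y_min, rect.y_max, nx, ny or nx)

    @property
    def rect(self) -> Rect:
        return Rect(self.x_min, self.x_max, self.y_min, self.y_max)

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def dy(self) -> float:
        return (self.y_max - self.y_min) / self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def x_edges(self) -> np.ndarray:
        return self.x_min + np.arange(self.nx + 1) * self.dx

    @property
    def y_edges(self) -> np.ndarray:
        return self.y_min + np.arange(self.ny + 1) * self.dy

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers)

    def centers_flat(self) -> np.ndarray:
        xx, yy = self.meshgrid()
        return np.column_stack([xx.ravel(), yy.ravel()])

    def refine(self, factor: int = 2) -> "StateGrid":
        return StateGrid(
            self.x_min, self.x_max, self.y_min, self.y_max,
            self.nx * factor, self.ny * factor,
        )
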