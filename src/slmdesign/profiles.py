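"""Containers for quantities defined along the anterior-posterior (AP) axis.

The modelled region spans 35.5-92.5% embryo length; the default grid has one
bin per percent (58 bins at 35.5, 36.5, ..., 92.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEFAULT_AP_GRID", "TfProfile", "ExpressionProfile"]

DEFAULT_AP_GRID = np.arange(35.5, 92.5 + 0.5, 1.0)


def _as_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("AP grid must be a nonempty 1-D array")
    if np.any(np.diff(g) <= 0):
        raise ValueError("AP grid must be strictly increasing")
    return g


@dataclass(frozen=True)
class TfProfile:
    """Concentration of one transcription factor per AP bin (arbitrary units)."""

    factor_name: str
    grid: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        g = _as_grid(self.grid)
        c = np.asarray(self.concentrations, dtype=float)
        if c.shape != g.shape:
            raise ValueError(
                f"{self.factor_name}: {c.size} concentrations for {g.size} bins"
            )
        if np.any(c < 0):
            raise ValueError(f"{self.factor_name}: concentrations must be >= 0")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class ExpressionProfile:
    """Expression per AP bin on the 0-255 display scale (model output or data)."""

    name: str
    grid: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        g = _as_grid(self.grid)
        v = np.asarray(self.values, dtype=float)
        if v.shape != g.shape:
            raise ValueError(f"{self.name}: {v.size} values for {g.size} bins")
        if np.any(v < 0):
            raise ValueError(f"{self.name}: expression values must be >= 0")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def peak_position(self) -> float:
        return float(self.grid[int(self.values.argmax())])

    def same_grid(self, other: "ExpressionProfile | TfProfile") -> bool:
        return self.grid.shape == other.grid.shape and bool(
            np.allclose(self.grid, other.grid)
        )
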