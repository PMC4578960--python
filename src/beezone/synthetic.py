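"""Synthetic landscapes with known optima.

The validation landscape is a 200×200 suitability surface built from five
Gaussian bumps: one tall central peak and four lower peaks at the grid
corners.  Because the surface is radially decreasing around the center
and the corner peaks stay below the central peak's value at radius 20,
the best 1250 cells by value form (almost exactly) the disk of radius 20
around the center — a known optimum any zoning optimizer should recover,
while the corner peaks act as local-optimum traps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .model import SuitabilityGrid

__all__ = [
    "MultiPeakSpec",
    "gauss_multipeak_surface",
    "circle_mask",
    "random_instance",
    "validation_instance",
]


@dataclass(frozen=True)
class MultiPeakSpec:
    """Parameters of the multi-peak Gaussian validation surface.

    Defaults are calibrated so that the top-1250 cells by value coincide
    with the central disk of radius 20 on a 200×200 grid: the central
    peak's value at radius 20 is exp(-400 / (2·25²)) ≈ 0.726, safely above
    the corner amplitude of 0.5, so no corner cell enters the top set.
    """

    n_rows: int = 200
    n_cols: int = 200
    center_amplitude: float = 1.0
    center_sigma: float = 25.0
    corner_amplitude: float = 0.5
    corner_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ConfigurationError(f"grid too small: {self.n_rows}×{self.n_cols}")
        if not (self.center_amplitude > self.corner_amplitude > 0):
            raise ConfigurationError(
                "need center_amplitude > corner_amplitude > 0, got "
                f"{self.center_amplitude} / {self.corner_amplitude}")
        if self.center_sigma <= 0 or self.corner_sigma <= 0:
            raise ConfigurationError("sigmas must be positive")

    @property
    def center(self) -> tuple[int, int]:
        return (self.n_rows // 2, self.n_cols // 2)


def _gauss_bump(rows: np.ndarray, cols: np.ndarray, at: tuple[float, float],
                amplitude: float, sigma: float) -> np.ndarray:
    d2 = (rows - at[0]) ** 2 + (cols - at[1]) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def gauss_multipeak_surface(spec: MultiPeakSpec = MultiPeakSpec()) -> SuitabilityGrid:
    """Build the validation instance from a multi-peak Gaussian surface.

    The eco layer is the normalized sum of the five bumps (maximum 1.0 at
    the central peak cell); the development layer is zero everywhere and
    every cell is configurable, so the site part of the objective reduces
    to the surface itself.
    """
    rows, cols = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols),
                             indexing="ij")
    rows = rows.astype(np.float64)
    cols = cols.astype(np.float64)
    surface = _gauss_bump(rows, cols, spec.center, spec.center_amplitude,
                          spec.center_sigma)
    corners = [(0, 0), (0, spec.n_cols - 1),
               (spec.n_rows - 1, 0), (spec.n_rows - 1, spec.n_cols - 1)]
    for corner in corners:
        surface += _gauss_bump(rows, cols, corner, spec.corner_amplitude,
                               spec.corner_sigma)
    surface /= surface.max()
    return SuitabilityGrid(eco=surface, dev=np.zeros(surface.shape))


def circle_mask(n_rows: int, n_cols: int, center: tuple[float, float],
                radius: float) -> np.ndarray:
    """Boolean mask of cells whose center lies within ``radius`` (Euclidean)
    of ``center``."""
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    d2 = (rows - center[0]) ** 2.0 + (cols - center[1]) ** 2.0
    return d2 <= radius ** 2


def validation_instance(spec: MultiPeakSpec = MultiPeakSpec(),
                        radius: float = 20.0) -> tuple[SuitabilityGrid, np.ndarray]:
    """The validation surface together with its known-optimum disk mask."""
    grid = gauss_multipeak_surface(spec)
    return grid, circle_mask(spec.n_rows, spec.n_cols, spec.center, radius)


def random_instance(n_rows: int, n_cols: int, rng: np.random.Generator,
                    blocked_fraction: float = 0.1) -> SuitabilityGrid:
    """Random instance for property tests: eco and dev i.i.d. uniform on
    [0, 1]; a ``blocked_fraction`` of cells is made non-configurable."""
    eco = rng.random((n_rows, n_cols))
    dev = rng.random((n_rows, n_cols))
    configurable = rng.random((n_rows, n_cols)) >= blocked_fraction
    if not configurable.any():
        configurable.ravel()[0] = True
    return SuitabilityGrid(eco=eco, dev=dev, configurable=configurable)
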