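"""Shared raster data types: complex object waves and unwrapped phase maps.

Conventions used throughout the package
---------------------------------------
* Rasters are ``(ny, nx)`` arrays; ``x`` runs along columns, ``y`` along rows.
* Lengths in the sample plane are micrometres; ``pixel_pitch_um`` is the
  (square) pixel size.
* Spatial frequencies are cycles per pixel.
* The grid centre used for radial coordinates is the pixel ``(ny // 2,
  nx // 2)`` — the same pixel that ``numpy.fft.fftshift`` moves DC to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import ConfigError

__all__ = ["ComplexField", "PhaseMap", "centered_coords", "radius_sq"]


def centered_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(y, x)`` pixel coordinate grids centred on ``(ny//2, nx//2)``."""
    ny, nx = shape
    y = np.arange(ny, dtype=float) - ny // 2
    x = np.arange(nx, dtype=float) - nx // 2
    return y[:, None], x[None, :]


def radius_sq(shape: tuple[int, int]) -> np.ndarray:
    """Squared pixel radius from the grid centre."""
    y, x = centered_coords(shape)
    return y * y + x * x


@dataclass
class ComplexField:
    """A complex object wave sampled on the camera grid."""

    values: np.ndarray
    pixel_pitch_um: float
    wavelength_um: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ConfigError("ComplexField expects a 2-D raster")
        if self.pixel_pitch_um <= 0:
            raise ConfigError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in ``(-pi, pi]`` computed with atan2."""
        return np.angle(self.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def conj(self) -> "ComplexField":
        return replace(self, values=np.conj(self.values))


@dataclass
class PhaseMap:
    """An unwrapped real-valued phase raster (radians) over the FOV."""

    values: np.ndarray
    pixel_pitch_um: float
    wavelength_um: float | None = None
    background_corrected: bool = False
    time_h: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("PhaseMap expects a 2-D raster")
        if self.pixel_pitch_um <= 0:
            raise ConfigError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def fov_area_um2(self) -> float:
        """FOV area implied by the raster geometry (pixels x pitch^2)."""
        ny, nx = self.shape
        return ny * nx * self.pixel_pitch_um**2

    def same_geometry(self, other: "PhaseMap") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_pitch_um, other.pixel_pitch_um
        )
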