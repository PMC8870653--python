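"""Synthetic cell populations as phase objects with closed-form dry mass.

Cells are rotationally symmetric thickness profiles (paraboloid cap by
default) with a uniform refractive index; the induced phase per pixel is

    phase(x, y) = (2*pi / lambda) * d(x, y) * (n_cell - n_medium)

summed over overlapping cells.  Because each profile has a closed-form
volume, the scene's dry mass is known analytically:

    dm = (n_cell - n_medium) * V / alpha

(per cell, alpha the specific refractive increment in mL/g = um^3/pg),
which is exactly what the phase-integral formulation yields once the
wavelength cancels.  Scripted 24-h scenarios (exponential or linear
growth, arrest, lysis with debris, delayed toxicity) rescale cell
thicknesses so the scene follows a prescribed mass law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import PhaseMap
from .errors import ConfigError

__all__ = [
    "PhantomCell",
    "Scene",
    "ScenarioSpec",
    "SCENARIO_KINDS",
    "PROFILES",
    "render_phase",
    "analytic_dry_mass",
    "scenario_mass",
    "evolve",
    "random_scene",
]

PROFILES = ("truncated-paraboloid", "hemisphere", "flat-disc")

#: volume of a profile with footprint radius R and max thickness d, as a
#: multiple of pi * R^2 * d
_VOLUME_FACTOR = {
    "truncated-paraboloid": 0.5,
    "hemisphere": 2.0 / 3.0,
    "flat-disc": 1.0,
}


@dataclass(frozen=True)
class PhantomCell:
    """One synthetic cell: a radial thickness profile with uniform index."""

    center_um: tuple[float, float]  #: (x, y) position in the sample plane
    footprint_radius_um: float
    max_thickness_um: float
    n_cell: float
    profile: str = "truncated-paraboloid"

    def __post_init__(self) -> None:
        if self.footprint_radius_um <= 0:
            raise ConfigError("footprint radius must be > 0")
        if self.max_thickness_um < 0:
            raise ConfigError("cell thickness must be >= 0")
        if self.profile not in PROFILES:
            raise ConfigError(f"unknown thickness profile {self.profile!r}")

    def thickness(self, rho_um: np.ndarray) -> np.ndarray:
        """Thickness (um) at radial distance ``rho_um`` from the centre."""
        u = np.clip(1.0 - (rho_um / self.footprint_radius_um) ** 2, 0.0, None)
        if self.profile == "truncated-paraboloid":
            prof = u
        elif self.profile == "hemisphere":
            prof = np.sqrt(u)
        else:  # flat-disc
            prof = (u > 0).astype(float)
        return self.max_thickness_um * prof

    @property
    def volume_um3(self) -> float:
        return (
            _VOLUME_FACTOR[self.profile]
            * math.pi
            * self.footprint_radius_um**2
            * self.max_thickness_um
        )


@dataclass
class Scene:
    """A synthetic cell population on a raster grid.

    ``shape`` is ``(ny, nx)`` pixels; the FOV spans ``nx * pitch`` by
    ``ny * pitch`` micrometres with the origin at the top-left corner.
    """

    cells: list[PhantomCell]
    n_medium: float = 1.337
    shape: tuple[int, int] = (384, 512)
    pixel_pitch_um: float = 0.879
    debris: list[PhantomCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        ny, nx = self.shape
        if ny < 64 or nx < 64:
            raise ConfigError("grid must be at least 64x64 pixels")
        if self.pixel_pitch_um <= 0:
            raise ConfigError("pixel pitch must be > 0")
        w, h = nx * self.pixel_pitch_um, ny * self.pixel_pitch_um
        for c in list(self.cells) + list(self.debris):
            cx, cy = c.center_um
            if not (0.0 <= cx <= w and 0.0 <= cy <= h):
                raise ConfigError(f"cell centre {c.center_um} outside the FOV")
            if c.n_cell < self.n_medium:
                raise ConfigError("n_cell must be >= n_medium")

    @property
    def fov_um(self) -> tuple[float, float]:
        ny, nx = self.shape
        return nx * self.pixel_pitch_um, ny * self.pixel_pitch_um

    def all_objects(self) -> list[PhantomCell]:
        return list(self.cells) + list(self.debris)

    def to_dict(self) -> dict:
        def cell_d(c: PhantomCell) -> dict:
            return {
                "center_um": list(c.center_um),
                "footprint_radius_um": c.footprint_radius_um,
                "max_thickness_um": c.max_thickness_um,
                "n_cell": c.n_cell,
                "profile": c.profile,
            }

        return {
            "cells": [cell_d(c) for c in self.cells],
            "debris": [cell_d(c) for c in self.debris],
            "n_medium": self.n_medium,
            "shape": list(self.shape),
            "pixel_pitch_um": self.pixel_pitch_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        def cell(c: dict) -> PhantomCell:
            return PhantomCell(
                center_um=tuple(c["center_um"]),
                footprint_radius_um=c["footprint_radius_um"],
                max_thickness_um=c["max_thickness_um"],
                n_cell=c["n_cell"],
                profile=c.get("profile", "truncated-paraboloid"),
            )

        return cls(
            cells=[cell(c) for c in d["cells"]],
            debris=[cell(c) for c in d.get("debris", [])],
            n_medium=d.get("n_medium", 1.337),
            shape=tuple(d.get("shape", (384, 512))),
            pixel_pitch_um=d.get("pixel_pitch_um", 0.879),
        )


SCENARIO_KINDS = (
    "control-exponential",
    "control-linear",
    "arrest",
    "lysis",
    "delayed-toxicity",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A scripted 24-h dry-mass law for a condition arm."""

    kind: str = "control-exponential"
    doubling_time_h: float = 12.0
    linear_slope_ng_per_h: float = 0.05
    onset_h: float = 10.0
    decline_rate_per_h: float = 0.15
    debris_mass_fraction: float = 0.25
    n_debris: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        if self.kind in ("control-exponential", "delayed-toxicity"):
            if self.doubling_time_h <= 0:
                raise ConfigError("doubling time must be > 0")
        if self.kind == "control-linear" and self.linear_slope_ng_per_h <= 0:
            raise ConfigError("linear slope must be > 0 for a control arm")
        if not 0.0 <= self.onset_h <= 24.0:
            raise ConfigError("decline onset must lie within [0, 24] h")
        if not 0.0 <= self.debris_mass_fraction <= 1.0:
            raise ConfigError("debris mass fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "doubling_time_h": self.doubling_time_h,
            "linear_slope_ng_per_h": self.linear_slope_ng_per_h,
            "onset_h": self.onset_h,
            "decline_rate_per_h": self.decline_rate_per_h,
            "debris_mass_fraction": self.debris_mass_fraction,
            "n_debris": self.n_debris,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)


def render_phase(scene: Scene, wavelength_um: float) -> PhaseMap:
    """Rasterize the scene's phase shift at the given wavelength.

    Phase contributions of overlapping cells add; the result is
    non-negative for valid scenes (``n_cell >= n_medium``).  Pixels are
    sampled at their centres.
    """
    if wavelength_um <= 0:
        raise ConfigError("wavelength must be > 0")
    ny, nx = scene.shape
    p = scene.pixel_pitch_um
    out = np.zeros((ny, nx), dtype=float)
    k = 2.0 * math.pi / wavelength_um
    for c in scene.all_objects():
        cx, cy = c.center_um
        r = c.footprint_radius_um
        # bounding box in pixel indices (pixel centres at (i + 0.5) * p)
        ix0 = max(0, int((cx - r) / p - 1))
        ix1 = min(nx, int((cx + r) / p + 2))
        iy0 = max(0, int((cy - r) / p - 1))
        iy1 = min(ny, int((cy + r) / p + 2))
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        xs = (np.arange(ix0, ix1) + 0.5) * p - cx
        ys = (np.arange(iy0, iy1) + 0.5) * p - cy
        rho = np.hypot(ys[:, None], xs[None, :])
        out[iy0:iy1, ix0:ix1] += k * (c.n_cell - scene.n_medium) * c.thickness(rho)
    return PhaseMap(out, pixel_pitch_um=p, wavelength_um=wavelength_um)


def analytic_dry_mass(
    scene: Scene, wavelength_um: float = 0.532, alpha_ml_per_g: float = 0.19
) -> float:
    """Closed-form scene dry mass in ng.

    Evaluates lambda/(2*pi*alpha) times the continuous phase integral
    from the cells' analytic volumes; the wavelength cancels, leaving
    ``sum((n_cell - n_medium) * V) / alpha`` in pg (alpha in mL/g equals
    alpha in um^3/pg numerically).
    """
    if wavelength_um <= 0:
        raise ConfigError("wavelength must be > 0")
    if alpha_ml_per_g <= 0:
        raise ConfigError("alpha must be > 0")
    pg = sum(
        (c.n_cell - scene.n_medium) * c.volume_um3 for c in scene.all_objects()
    ) / alpha_ml_per_g
    return pg / 1000.0  # pg -> ng


def scenario_mass(spec: ScenarioSpec, t_h: float, m0_ng: float) -> tuple[float, float]:
    """Evaluate the scenario law: returns ``(attached_ng, debris_ng)`` at ``t_h``."""
    if not 0.0 <= t_h <= 24.0:
        raise ConfigError("t must lie within [0, 24] h")
    if spec.kind == "control-exponential":
        return m0_ng * 2.0 ** (t_h / spec.doubling_time_h), 0.0
    if spec.kind == "control-linear":
        return m0_ng + spec.linear_slope_ng_per_h * t_h, 0.0
    if spec.kind == "arrest":
        return m0_ng, 0.0
    if spec.kind == "lysis":
        attached = m0_ng * math.exp(-spec.decline_rate_per_h * t_h)
        debris = spec.debris_mass_fraction * (m0_ng - attached)
        return attached, debris
    # delayed-toxicity: grow until onset, then exponential decline
    if t_h <= spec.onset_h:
        return m0_ng * 2.0 ** (t_h / spec.doubling_time_h), 0.0
    m_onset = m0_ng * 2.0 ** (spec.onset_h / spec.doubling_time_h)
    return m_onset * math.exp(-spec.decline_rate_per_h * (t_h - spec.onset_h)), 0.0


def _make_debris(
    spec: ScenarioSpec,
    scene: Scene,
    total_mass_ng: float,
    alpha_ml_per_g: float,
) -> list[PhantomCell]:
    if total_mass_ng <= 0 or spec.n_debris <= 0:
        return []
    rng = np.random.default_rng(spec.seed)
    w, h = scene.fov_um
    delta_n = 0.04
    frags: list[PhantomCell] = []
    share_pg = total_mass_ng * 1000.0 / spec.n_debris
    for _ in range(spec.n_debris):
        cx = rng.uniform(0.02 * w, 0.98 * w)
        cy = rng.uniform(0.02 * h, 0.98 * h)
        radius = rng.uniform(5.0, 9.0)
        volume = share_pg * alpha_ml_per_g / delta_n  # um^3
        d = volume / (_VOLUME_FACTOR["truncated-paraboloid"] * math.pi * radius**2)
        frags.append(
            PhantomCell(
                center_um=(cx, cy),
                footprint_radius_um=radius,
                max_thickness_um=d,
                n_cell=scene.n_medium + delta_n,
            )
        )
    return frags


def evolve(
    scene: Scene,
    scenario: ScenarioSpec,
    t_h: float,
    alpha_ml_per_g: float = 0.19,
) -> Scene:
    """Return a new scene whose analytic dry mass follows the scenario law.

    Cell thicknesses are rescaled uniformly (mass is linear in thickness);
    in the lysis scenario, seeded debris fragments carry a configurable
    fraction of the lysed mass.  Pure function of (scene, scenario, t).
    """
    m0 = analytic_dry_mass(scene, alpha_ml_per_g=alpha_ml_per_g)
    attached_ng, debris_ng = scenario_mass(scenario, t_h, m0)
    scale = 0.0 if m0 == 0 else max(attached_ng / m0, 0.0)

    # mass is proportional to R^2 * d; distribute growth between footprint
    # and thickness (s = s_R^2 * s_d) so phase stays moderate as cells grow
    s_r = scale**0.35
    s_d = scale**0.30

    def _scaled(c: PhantomCell) -> PhantomCell:
        return replace(
            c,
            footprint_radius_um=c.footprint_radius_um * s_r,
            max_thickness_um=c.max_thickness_um * s_d,
        )

    cells = [_scaled(c) for c in scene.cells]
    debris = [_scaled(c) for c in scene.debris]
    debris += _make_debris(scenario, scene, debris_ng, alpha_ml_per_g)
    return Scene(
        cells=cells,
        n_medium=scene.n_medium,
        shape=scene.shape,
        pixel_pitch_um=scene.pixel_pitch_um,
        debris=debris,
    )


def random_scene(
    seed: int | np.random.Generator = 0,
    n_cells: int = 12,
    shape: tuple[int, int] = (384, 512),
    pixel_pitch_um: float = 0.879,
    n_medium: float = 1.337,
    n_cell_range: tuple[float, float] = (1.36, 1.38),
    radius_range_um: tuple[float, float] = (8.0, 14.0),
    thickness_range_um: tuple[float, float] = (2.0, 4.0),
    profile: str = "truncated-paraboloid",
    margin_um: float = 20.0,
) -> Scene:
    """Draw a random subconfluent population (defaults keep peak phase < pi)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ny, nx = shape
    w, h = nx * pixel_pitch_um, ny * pixel_pitch_um
    cells = []
    for _ in range(n_cells):
        cells.append(
            PhantomCell(
                center_um=(
                    rng.uniform(margin_um, w - margin_um),
                    rng.uniform(margin_um, h - margin_um),
                ),
                footprint_radius_um=rng.uniform(*radius_range_um),
                max_thickness_um=rng.uniform(*thickness_range_um),
                n_cell=rng.uniform(*n_cell_range),
                profile=profile,
            )
        )
    return Scene(
        cells=cells, n_medium=n_medium, shape=shape, pixel_pitch_um=pixel_pitch_um
    )
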