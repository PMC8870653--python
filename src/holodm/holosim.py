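"""Off-axis hologram forward model.

Turns a ground-truth phase map into intensity frames

    I = | O * exp(i eta) + R |^2

with a tilted plane-wave reference ``R = A_r exp(2 pi i (fx x + fy y))``
(carrier in cycles/pixel, both components below Nyquist), optional
quadratic (spherical) phase aberration and defocus on the object wave,
per-frame decorrelated smooth coherent-noise phase screens ``eta`` and
additive detector noise.  Everything is a pure function of
(scene, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ComplexField, PhaseMap, radius_sq
from .errors import AliasingError, ConfigError
from .phantom import Scene, render_phase
from .propagation import angular_spectrum_propagate

__all__ = ["OpticalConfig", "Hologram", "object_wave", "interfere", "acquire_timepoint"]


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry and noise model for the virtual microscope."""

    wavelength_nm: float = 532.0
    pixel_pitch_um: float = 0.879
    shape: tuple[int, int] = (384, 512)  #: (ny, nx)
    carrier_cyc_per_px: tuple[float, float] = (0.25, 0.25)  #: (fx, fy)
    reference_amplitude: float = 1.0
    object_amplitude: float = 1.0
    aberration_coeff_rad_per_px2: float = 0.0
    defocus_um: float = 0.0
    coherent_sigma_rad: float = 0.0
    coherent_corr_px: float = 8.0
    detector_sigma: float = 0.0
    frames_per_timepoint: int = 15
    quantize_8bit: bool = False

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.pixel_pitch_um <= 0:
            raise ConfigError("wavelength and pixel pitch must be > 0")
        if self.reference_amplitude <= 0 or self.object_amplitude < 0:
            raise ConfigError("amplitudes must be positive (object may be 0)")
        if self.frames_per_timepoint < 1:
            raise ConfigError("frames_per_timepoint must be >= 1")
        fx, fy = self.carrier_cyc_per_px
        if abs(fx) >= 0.5 or abs(fy) >= 0.5:
            raise AliasingError(
                f"carrier {self.carrier_cyc_per_px} at or above Nyquist (0.5 cyc/px)"
            )
        if fx == 0.0 and fy == 0.0:
            raise ConfigError("carrier must be non-zero for off-axis holography")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / 1000.0

    def to_dict(self) -> dict[str, Any]:
        d = self.__dict__.copy()
        d["shape"] = list(self.shape)
        d["carrier_cyc_per_px"] = list(self.carrier_cyc_per_px)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "OpticalConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "carrier_cyc_per_px" in d:
            d["carrier_cyc_per_px"] = tuple(d["carrier_cyc_per_px"])
        return cls(**d)


@dataclass
class Hologram:
    """One recorded off-axis intensity frame plus acquisition metadata."""

    intensity: np.ndarray
    config: OpticalConfig
    time_h: float = 0.0
    frame_index: int = 0
    seed: int | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.config.shape:
            raise ConfigError("hologram dimensions do not match the config grid")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise ConfigError("hologram intensities must be finite and >= 0")


def object_wave(phase: PhaseMap, config: OpticalConfig) -> ComplexField:
    """Object wave ``A_o exp(i phase)`` with aberration and defocus applied."""
    if phase.shape != config.shape:
        raise ConfigError(
            f"phase grid {phase.shape} does not match config grid {config.shape}"
        )
    values = config.object_amplitude * np.exp(1j * phase.values)
    a = config.aberration_coeff_rad_per_px2
    if a != 0.0:
        values = values * np.exp(1j * a * radius_sq(config.shape))
    if config.defocus_um != 0.0:
        values = angular_spectrum_propagate(
            values, config.wavelength_um, config.pixel_pitch_um, config.defocus_um
        )
    return ComplexField(values, config.pixel_pitch_um, config.wavelength_um)


def _reference_wave(config: OpticalConfig) -> np.ndarray:
    ny, nx = config.shape
    fx, fy = config.carrier_cyc_per_px
    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    return config.reference_amplitude * np.exp(2j * np.pi * (fx * x + fy * y))


def coherent_phase_screen(
    shape: tuple[int, int], sigma_rad: float, corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random phase screen: low-pass-filtered white noise at exact std."""
    screen = gaussian_filter(rng.standard_normal(shape), corr_px, mode="wrap")
    sd = screen.std()
    if sd == 0:
        return np.zeros(shape)
    return screen * (sigma_rad / sd)


def interfere(obj: ComplexField, config: OpticalConfig, seed: int = 0) -> Hologram:
    """Record one hologram frame of the object wave against the tilted reference."""
    if obj.shape != config.shape:
        raise ConfigError("object wave grid does not match the config grid")
    fx, fy = config.carrier_cyc_per_px
    if abs(fx) >= 0.5 or abs(fy) >= 0.5:
        raise AliasingError("carrier at or above Nyquist")
    rng = np.random.default_rng(seed)
    values = obj.values
    if config.coherent_sigma_rad > 0:
        eta = coherent_phase_screen(
            config.shape, config.coherent_sigma_rad, config.coherent_corr_px, rng
        )
        values = values * np.exp(1j * eta)
    intensity = np.abs(values + _reference_wave(config)) ** 2
    if config.detector_sigma > 0:
        intensity = intensity + config.detector_sigma * rng.standard_normal(config.shape)
    intensity = np.clip(intensity, 0.0, None)
    if config.quantize_8bit:
        peak = intensity.max()
        if peak > 0:
            intensity = np.round(intensity / peak * 255.0) / 255.0 * peak
    return Hologram(intensity, config, frame_index=0, seed=seed)


def frame_seed(seed: int, t_h: float, frame: int) -> int:
    """Deterministic per-frame seed derived from (seed, timepoint, frame)."""
    ss = np.random.SeedSequence((int(seed), int(round(t_h * 3600.0)), int(frame)))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def acquire_timepoint(
    scene: Scene, config: OpticalConfig, t_h: float = 0.0, seed: int = 0
) -> list[Hologram]:
    """Record ``frames_per_timepoint`` frames with independent noise realizations.

    The scene phase is rendered once; each frame gets its own coherent-noise
    and detector-noise draw from a seed stream derived from (seed, t, frame).
    """
    phase = render_phase(scene, config.wavelength_um)
    obj = object_wave(phase, config)
    frames = []
    for i in range(config.frames_per_timepoint):
        holo = interfere(obj, config, seed=frame_seed(seed, t_h, i))
        holo.time_h = t_h
        holo.frame_index = i
        frames.append(holo)
    return frames


def verify_carrier_separation(config: OpticalConfig, sideband_radius: float) -> bool:
    """True when DC and the +/-1 orders cannot overlap in the spectrum."""
    fx, fy = config.carrier_cyc_per_px
    return float(np.hypot(fx, fy)) > 2.0 * sideband_radius
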