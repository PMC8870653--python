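"""Rolling-ball phase background subtraction.

The background is the grayscale morphological opening of the phase
raster by a non-flat spherical-cap structuring element ("rolling the
ball under the surface"); cells — features narrower than the ball — are
excluded from the estimate and therefore preserved in the output
``input - background``.  The cap height is expressed in radians
(``ball_height_rad``, analogous to ImageJ's intensity scaling of the
ball): it must be small enough that the ball cannot climb into
cell-scale bumps (tip curvature ``height / radius^2`` well below the
cells' peak curvature) yet large enough to track the slowly varying
well-bottom background.  The default 0.65 rad at 80 px radius loses
< 2% of the mass of isolated cells narrower than the ball while still
following 0.3-rad background undulations.

For large radii an ImageJ-style speed-up is used: block-min downscale,
opening with the correspondingly scaled cap, bilinear upsample, and a
pixelwise minimum with the input (which keeps the background estimate
anti-extensive).  The exact opening is used for small radii and is what
the test-suite oracle checks against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_dilation, grey_erosion
from skimage.transform import resize

from .core import PhaseMap
from .errors import ConfigError

__all__ = [
    "BackgroundParams",
    "ball_structure",
    "grey_opening_ball",
    "rolling_ball_background",
    "rolling_ball_subtract",
]


@dataclass(frozen=True)
class BackgroundParams:
    """Rolling-ball settings, held fixed across all experiments."""

    ball_radius_px: int = 80
    ball_height_rad: float = 0.65
    light_background: bool = False  #: cells are phase maxima by default
    downscale: int | str = "auto"

    def __post_init__(self) -> None:
        if self.ball_radius_px < 1:
            raise ConfigError("ball radius must be >= 1 pixel")
        if self.ball_height_rad <= 0:
            raise ConfigError("ball height must be > 0")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundParams":
        return cls(**d)


def ball_structure(
    radius_px: int, scale: int = 1, height_rad: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Footprint mask and cap heights for a ball of ``radius_px`` at ``scale``.

    ``height_rad`` vertically rescales the cap (defaults to the radius,
    the unscaled geometric ball).  ``scale > 1`` builds the element on a
    grid whose pixels are ``scale`` original pixels wide while keeping
    the vertical (radian) geometry of the full-size ball.
    """
    h = float(radius_px) if height_rad is None else float(height_rad)
    rw = max(1, int(round(radius_px / scale)))
    y, x = np.mgrid[-rw : rw + 1, -rw : rw + 1]
    rho_sq = ((scale * x) ** 2 + (scale * y) ** 2).astype(float)
    footprint = rho_sq <= radius_px**2
    heights = (h / radius_px) * np.sqrt(np.clip(radius_px**2 - rho_sq, 0.0, None))
    return footprint, heights


def grey_opening_ball(
    values: np.ndarray,
    radius_px: int,
    scale: int = 1,
    height_rad: float | None = None,
) -> np.ndarray:
    """Exact grayscale opening with the spherical-cap structuring element."""
    footprint, structure = ball_structure(radius_px, scale, height_rad)
    eroded = grey_erosion(values, footprint=footprint, structure=structure, mode="nearest")
    return grey_dilation(eroded, footprint=footprint, structure=structure, mode="nearest")


def _auto_scale(radius_px: int) -> int:
    return max(1, min(8, radius_px // 12))


def rolling_ball_background(
    values: np.ndarray,
    radius_px: int,
    downscale: int | str = "auto",
    height_rad: float | None = None,
) -> np.ndarray:
    """Estimate the slowly varying background under the phase surface."""
    ny, nx = values.shape
    if radius_px >= min(ny, nx):
        raise ConfigError(
            f"ball radius {radius_px} px is not smaller than the image {values.shape}"
        )
    scale = _auto_scale(radius_px) if downscale == "auto" else int(downscale)
    if scale <= 1:
        return grey_opening_ball(values, radius_px, height_rad=height_rad)
    # block-mean downscale (unbiased on smooth backgrounds; the final
    # pixelwise minimum keeps the estimate anti-extensive)
    pad_y = (-ny) % scale
    pad_x = (-nx) % scale
    padded = np.pad(values, ((0, pad_y), (0, pad_x)), mode="edge")
    py, px = padded.shape
    small = padded.reshape(py // scale, scale, px // scale, scale).mean(axis=(1, 3))
    bg_small = grey_opening_ball(small, radius_px, scale=scale, height_rad=height_rad)
    bg = resize(bg_small, padded.shape, order=1, mode="edge", anti_aliasing=False)
    bg = bg[:ny, :nx]
    return np.minimum(bg, values)


def _background_mode(values: np.ndarray) -> float:
    """Level of the dominant (background) pixel population.

    Coarse histogram peak, refined by the median of the pixels falling
    in the peak bin and its neighbours.  Zero for an exactly flat
    background; for noisy maps this measures the residual offset left by
    the opening riding the noise's lower envelope.
    """
    flat = values.ravel()
    counts, edges = np.histogram(flat, bins=256)
    k = int(np.argmax(counts))
    lo, hi = edges[max(0, k - 1)], edges[min(len(edges) - 1, k + 2)]
    sel = flat[(flat >= lo) & (flat <= hi)]
    return float(np.median(sel)) if sel.size else 0.0


def rolling_ball_subtract(phase: PhaseMap, params: BackgroundParams) -> PhaseMap:
    """Subtract the rolling-ball background from an unwrapped phase map.

    Background regions end up near zero; cellular phase is preserved for
    features narrower than the ball.  Because the opening rides the
    lower envelope of any residual noise, the subtracted map is finally
    re-zeroed on its background mode (enforcing the ``background ~ 0``
    contract without biasing the cell mass).  With ``light_background``
    the closing is used instead (cells as minima).
    """
    values = phase.values
    if params.light_background:
        bg = -rolling_ball_background(
            -values, params.ball_radius_px, params.downscale, params.ball_height_rad
        )
    else:
        bg = rolling_ball_background(
            values, params.ball_radius_px, params.downscale, params.ball_height_rad
        )
    out = values - bg
    out = out - _background_mode(out)
    return PhaseMap(
        out,
        pixel_pitch_um=phase.pixel_pitch_um,
        wavelength_um=phase.wavelength_um,
        background_corrected=True,
        time_h=phase.time_h,
        meta=dict(phase.meta, ball_radius_px=params.ball_radius_px),
    )
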