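"""Angular-spectrum free-space propagation (convolution approach).

The transfer function applied to the field spectrum for distance ``z`` is

    H(fx, fy) = exp( 2 pi i z sqrt(1/lambda^2 - fx^2 - fy^2) )

with spatial frequencies in 1/um.  Frequencies beyond 1/lambda are
evanescent and are zeroed (documented contract); on the propagating modes
|H| = 1, so propagation is unitary and ``z`` then ``-z`` is an exact
inverse.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError

__all__ = ["angular_spectrum_propagate"]


def angular_spectrum_propagate(
    values: np.ndarray, wavelength_um: float, pixel_pitch_um: float, z_um: float
) -> np.ndarray:
    """Propagate a complex field raster by ``z_um`` along the optical axis."""
    if wavelength_um <= 0 or pixel_pitch_um <= 0:
        raise ConfigError("wavelength and pixel pitch must be > 0")
    if z_um == 0.0:
        return np.array(values, dtype=complex)
    ny, nx = values.shape
    fx = np.fft.fftfreq(nx, d=pixel_pitch_um)[None, :]
    fy = np.fft.fftfreq(ny, d=pixel_pitch_um)[:, None]
    arg = 1.0 / wavelength_um**2 - fx**2 - fy**2
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    kernel = np.where(propagating, np.exp(2j * np.pi * z_um * kz), 0.0)
    return np.fft.ifft2(np.fft.fft2(values) * kernel)
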