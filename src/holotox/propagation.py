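"""Angular-spectrum (convolution) propagation of complex optical fields.

Free-space propagation over a distance ``z`` multiplies the field's spatial
spectrum by the transfer function

    H(fx, fy; z) = exp( i 2 pi z sqrt(1/lambda^2 - fx^2 - fy^2) ),

which is exact scalar diffraction for band-limited fields.  Distances are
signed: propagating by ``+z`` then ``-z`` restores the field (the kernel is
unitary on propagating components; evanescent components, which do not occur
at the pixel pitches used here, are suppressed).
"""

from __future__ import annotations

import numpy as np


def angular_spectrum_transfer(
    shape: tuple[int, int],
    distance_um: float,
    wavelength_um: float,
    pitch_x_um: float,
    pitch_y_um: float,
) -> np.ndarray:
    ny, nx = shape
    fx = np.fft.fftfreq(nx, d=pitch_x_um)
    fy = np.fft.fftfreq(ny, d=pitch_y_um)
    fxx, fyy = np.meshgrid(fx, fy)
    arg = 1.0 / wavelength_um**2 - fxx**2 - fyy**2
    kz = np.sqrt(np.maximum(arg, 0.0))
    h = np.exp(2j * np.pi * distance_um * kz)
    h[arg < 0] = 0.0  # evanescent cutoff
    return h


def propagate_angular_spectrum(
    field: np.ndarray,
    distance_um: float,
    wavelength_um: float,
    pitch_x_um: float,
    pitch_y_um: float,
) -> np.ndarray:
    """Propagate a complex field by a signed distance in micrometres."""
    if distance_um == 0.0:
        return field.copy()
    h = angular_spectrum_transfer(
        field.shape, distance_um, wavelength_um, pitch_x_um, pitch_y_um
    )
    return np.fft.ifft2(np.fft.fft2(field) * h)
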