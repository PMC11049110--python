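"""Optical configuration of the off-axis DHM setup.

All downstream phase-to-mass conversion is driven by this object: the laser
wavelength, the calibrated field of view, the off-axis carrier frequency of
the interferogram, and the refractive-index increment that relates optical
path delay to non-aqueous (dry) cellular mass.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator


class OpticalConfig(BaseModel):
    """Parameters of the holographic imaging system.

    Parameters
    ----------
    wavelength_nm : float
        Illumination wavelength in nanometres (frequency-doubled Nd:YAG,
        532 nm by default).
    pixel_count_x, pixel_count_y : int
        Detector grid size; ``x`` runs along array columns, ``y`` along rows.
    fov_x_um, fov_y_um : float
        Physical field of view in micrometres.  The default 405 x 538 um
        corresponds to a 20x objective on a standard camera sensor.  Pixel
        pitch may be anisotropic.
    carrier_frequency : tuple of float
        Spatial frequency of the off-axis fringe carrier in cycles/pixel,
        ``(fx, fy)``; each component must lie strictly inside the Nyquist
        band and the carrier must be nonzero.
    refractive_increment_ml_per_g : float
        Specific refractive-index increment alpha relating solute
        concentration to refractive index.  0.19 mL/g (= 0.19 um^3/pg) is
        the standard value for cellular protein.
    frames_per_stack : int
        Number of hologram frames recorded per field of view; frames carry
        independent coherence-noise realizations and are averaged after
        reconstruction.
    """

    wavelength_nm: float = 532.0
    pixel_count_x: int = 512
    pixel_count_y: int = 512
    fov_x_um: float = 405.0
    fov_y_um: float = 538.0
    carrier_frequency: tuple[float, float] = (0.25, 0.15)
    refractive_increment_ml_per_g: float = 0.19
    frames_per_stack: int = 10

    @model_validator(mode="after")
    def _check(self) -> "OpticalConfig":
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.fov_x_um <= 0 or self.fov_y_um <= 0:
            raise ValueError("field-of-view dimensions must be positive")
        if self.pixel_count_x < 8 or self.pixel_count_y < 8:
            raise ValueError("pixel counts must be at least 8")
        fx, fy = self.carrier_frequency
        for f in (fx, fy):
            if not (abs(f) < 0.5):
                raise ValueError(
                    "carrier frequency components must lie in (-0.5, 0.5) cycles/pixel"
                )
        if fx == 0.0 and fy == 0.0:
            raise ValueError("carrier frequency must be nonzero")
        if self.refractive_increment_ml_per_g <= 0:
            raise ValueError("refractive increment alpha must be positive")
        if self.frames_per_stack < 1:
            raise ValueError("frames_per_stack must be >= 1")
        return self

    # -- derived geometry ---------------------------------------------------

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def pixel_pitch_x_um(self) -> float:
        return self.fov_x_um / self.pixel_count_x

    @property
    def pixel_pitch_y_um(self) -> float:
        return self.fov_y_um / self.pixel_count_y

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_x_um * self.pixel_pitch_y_um

    @property
    def fov_area_um2(self) -> float:
        return self.fov_x_um * self.fov_y_um

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of images produced under this config."""
        return (self.pixel_count_y, self.pixel_count_x)

    @property
    def carrier_magnitude(self) -> float:
        fx, fy = self.carrier_frequency
        return float(np.hypot(fx, fy))
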