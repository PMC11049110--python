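"""Off-axis hologram forward model.

A hologram frame is the interference intensity ``I = |O + R|^2`` of the
object wave ``O = exp(i phi)`` with a tilted plane reference ``R`` whose
tilt puts the object spectrum on a fringe carrier.  The reference is
``R = exp(-i 2 pi (fx x + fy y))`` so that the sideband located at the
*positive* carrier frequency carries the object phase with positive sign —
the convention the reconstruction module assumes.

Noise model (all optional, all seeded):

* per-frame coherence speckle — Gaussian-filtered white noise added to the
  object phase, decorrelated between the frames of a stack (emulating the
  wavefront diversity introduced by the tunable-lens modulation), which is
  what makes stack averaging effective;
* additive Gaussian detector noise on the intensity, with optional Poisson
  shot noise;
* a dose-dependent scattering background — a smooth random phase field
  *common to all frames* whose amplitude grows with particle concentration,
  emulating the raised phase-background noise seen at high particle doses
  (it survives averaging, as in the real instrument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel
from scipy.ndimage import gaussian_filter

from .optics import OpticalConfig
from .propagation import propagate_angular_spectrum
from .scenes import PhaseScene


class NoiseSpec(BaseModel):
    """Noise configuration for hologram synthesis (see module docstring)."""

    speckle_sigma_rad: float = 0.1
    speckle_corr_px: float = 8.0
    detector_sigma_rel: float = 0.01
    poisson: bool = False
    scatter_dose_ug_ml: float = 0.0
    scatter_sigma_at_512_rad: float = 0.15
    scatter_corr_px: float = 16.0

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(speckle_sigma_rad=0.0, detector_sigma_rel=0.0, poisson=False)

    @property
    def scatter_sigma_rad(self) -> float:
        """Scatter phase-background std at the configured dose.

        Scales with the square root of concentration (scatterer-count
        statistics), pinned at ``scatter_sigma_at_512_rad`` for 512 ug/mL.
        """
        if self.scatter_dose_ug_ml <= 0:
            return 0.0
        return self.scatter_sigma_at_512_rad * float(
            np.sqrt(self.scatter_dose_ug_ml / 512.0)
        )


@dataclass
class HologramStack:
    """Recorded interferogram frames with their optics metadata."""

    frames: np.ndarray  # (n_frames, ny, nx) float intensity
    config: OpticalConfig
    defocus_um: float = 0.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if self.frames.shape[1:] != self.config.shape:
            raise ValueError("frame geometry does not match optics config")


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, corr_px: float
) -> np.ndarray:
    """Gaussian-filtered white noise renormalized to std ``sigma``."""
    if sigma <= 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.standard_normal(shape), corr_px, mode="wrap")
    std = raw.std()
    if std == 0:
        return np.zeros(shape)
    return sigma / std * (raw - raw.mean())


def _carrier_ramp(config: OpticalConfig) -> np.ndarray:
    ny, nx = config.shape
    fx, fy = config.carrier_frequency
    yy, xx = np.mgrid[0:ny, 0:nx]
    return 2.0 * np.pi * (fx * xx + fy * yy)


def synthesize_hologram_stack(
    scene: PhaseScene,
    config: OpticalConfig,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    defocus_um: float = 0.0,
    min_carrier_cpp: float | None = None,
) -> HologramStack:
    """Render a stack of off-axis interferograms of the scene.

    Each frame is ``I = |O_k + R|^2`` where ``O_k`` carries the scene phase
    plus that frame's coherence-noise realization (and the common scatter
    background), optionally numerically defocused by ``defocus_um`` before
    interference.  Intensities are scaled to a mean level of 0.5 on a 0..1
    detector range.
    """
    if scene.phase_map.shape != config.shape:
        raise ValueError("scene dimensions do not match optics config")
    noise = noise if noise is not None else NoiseSpec()
    if min_carrier_cpp is None:
        min_carrier_cpp = 6.0 / max(config.shape)
    if config.carrier_magnitude < 2.0 * min_carrier_cpp:
        raise ValueError(
            "carrier too close to DC: sidebands would overlap the "
            f"zero-order term (|carrier| = {config.carrier_magnitude:.4f} c/px)"
        )
    rng = np.random.default_rng(seed)
    ramp = _carrier_ramp(config)
    scatter = _smooth_noise(
        rng, config.shape, noise.scatter_sigma_rad, noise.scatter_corr_px
    )
    frames = np.empty((config.frames_per_stack,) + config.shape)
    for k in range(config.frames_per_stack):
        speckle = _smooth_noise(
            rng, config.shape, noise.speckle_sigma_rad, noise.speckle_corr_px
        )
        obj = np.exp(1j * (scene.phase_map + scatter + speckle))
        if defocus_um != 0.0:
            obj = propagate_angular_spectrum(
                obj,
                defocus_um,
                config.wavelength_um,
                config.pixel_pitch_x_um,
                config.pixel_pitch_y_um,
            )
        intensity = np.abs(obj + np.exp(-1j * ramp)) ** 2
        intensity /= 8.0  # |O + R|^2 <= 4 for unit waves; mean level 0.25..0.5
        if noise.poisson:
            photons = 2000.0
            intensity = rng.poisson(np.maximum(intensity, 0) * photons) / photons
        if noise.detector_sigma_rel > 0:
            intensity = intensity + noise.detector_sigma_rel * float(
                intensity.mean()
            ) * rng.standard_normal(config.shape)
        frames[k] = intensity
    return HologramStack(frames=frames, config=config, defocus_um=defocus_um)
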