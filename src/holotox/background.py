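"""Rolling-ball background subtraction and the population mean phase shift.

The slowly varying phase background of a reconstructed QPI image (residual
reference-wave curvature, medium inhomogeneity, particle scattering haze) is
estimated as the grayscale *opening* of the image with a ball (spherical
cap) structuring element: the surface traced by a ball of the given radius
rolling under the phase relief.  Subtracting it leaves the compact
cell-induced phase on a flat zero background.

The opening is computed exactly (erosion then dilation with the non-flat
ball element on a reflect-padded image); no shrink/scale approximation is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

from .reconstruction import QPIImage


DEFAULT_HEIGHT_SCALE = 0.01  # radians of ball height per pixel of ball radius


def ball_structuring_element(
    radius: float, height_scale: float = DEFAULT_HEIGHT_SCALE
) -> tuple[np.ndarray, np.ndarray]:
    """Heights of a spherical cap of the given radius on the pixel grid.

    Returns ``(structure, footprint)``: the height profile
    ``h = height_scale * sqrt(r^2 - d^2)`` over the disk ``d <= r`` and its
    boolean support.  ``height_scale`` converts the ball's vertical extent
    from pixels to the image's intensity units (here radians of phase): the
    ball must be much flatter than a cell (so it rolls *under* the cells
    rather than into them) while still curved enough to track the slow
    background relief.
    """
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (xx**2 + yy**2).astype(float)
    footprint = d2 <= radius**2
    structure = np.zeros_like(d2)
    structure[footprint] = height_scale * np.sqrt(radius**2 - d2[footprint])
    return structure, footprint


def rolling_ball_background(
    image: np.ndarray, radius: float, height_scale: float = DEFAULT_HEIGHT_SCALE
) -> np.ndarray:
    """Exact grayscale opening of ``image`` with a ball element.

    The image is reflect-padded by the kernel radius so border behaviour is
    defined by the image content, then eroded and dilated with the non-flat
    spherical-cap structuring element.
    """
    if radius < 1:
        raise ValueError("rolling-ball radius must be >= 1 pixel")
    ny, nx = image.shape
    r = int(np.ceil(radius))
    if r > max(ny, nx):
        raise ValueError(
            f"rolling-ball radius {radius} exceeds image extent {image.shape}"
        )
    structure, footprint = ball_structuring_element(radius, height_scale)
    # erosion-then-dilation needs 2r of valid support around every output
    # pixel; padding by 2r makes the result exactly the opening of the
    # reflect-extended image (and hence idempotent, borders included)
    pad = 2 * r
    padded = np.pad(image, pad, mode="reflect")
    eroded = ndi.grey_erosion(padded, structure=structure, footprint=footprint)
    opened = ndi.grey_dilation(eroded, structure=structure, footprint=footprint)
    return opened[pad : pad + ny, pad : pad + nx]


@dataclass
class BackgroundModel:
    method: str
    radius_px: float
    background_map: np.ndarray


def subtract_rolling_ball(
    qpi: QPIImage | np.ndarray,
    radius: float = 50.0,
    height_scale: float = DEFAULT_HEIGHT_SCALE,
) -> tuple[QPIImage, BackgroundModel]:
    """Background-correct a phase image; returns (corrected, model).

    The corrected image is ``phase - opening``; it is non-negative wherever
    the opening lies below the image (opening is anti-extensive) and exactly
    zero on flat regions.
    """
    if isinstance(qpi, QPIImage):
        phase = qpi.phase
        pixel_area = qpi.pixel_area_um2
        n_frames = qpi.n_frames_averaged
        provenance = dict(qpi.provenance)
    else:
        phase = np.asarray(qpi, dtype=float)
        pixel_area = 1.0
        n_frames = 1
        provenance = {}
    bg = rolling_ball_background(phase, radius, height_scale)
    provenance["rolling_ball_radius_px"] = radius
    corrected = QPIImage(
        phase=phase - bg,
        pixel_area_um2=pixel_area,
        n_frames_averaged=n_frames,
        provenance=provenance,
    )
    return corrected, BackgroundModel("rolling_ball", radius, bg)


def mean_phase_shift(corrected: QPIImage | np.ndarray) -> float:
    """Cell-induced mean phase shift: arithmetic mean over the full FOV."""
    phase = corrected.phase if isinstance(corrected, QPIImage) else np.asarray(corrected)
    if not np.all(np.isfinite(phase)):
        raise ValueError("corrected phase image must be finite")
    return float(phase.mean())


class RollingBallBackground(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying rolling-ball background removal.

    ``transform`` accepts a single 2D image or a stack of images and
    subtracts each image's ball opening; the background of the last image
    processed is kept in ``background_map_``.
    """

    def __init__(self, radius: float = 50.0, height_scale: float = DEFAULT_HEIGHT_SCALE):
        self.radius = radius
        self.height_scale = height_scale

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        single = arr.ndim == 2
        stack = arr[None] if single else arr
        out = np.empty_like(stack)
        for i, img in enumerate(stack):
            bg = rolling_ball_background(img, self.radius, self.height_scale)
            self.background_map_ = bg
            out[i] = img - bg
        return out[0] if single else out
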