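"""Quantitative phase reconstruction of off-axis hologram stacks.

The inverse path mirrors the forward model in :mod:`holotox.holography`:

1. locate the fringe carrier as the strongest spectral peak outside a DC
   exclusion disk (sub-pixel refined by local centroid);
2. demodulate: multiply the hologram by the conjugate carrier ramp, which
   shifts the object sideband exactly to DC, then isolate it with a
   soft-edged circular low-pass and inverse-transform to a complex field;
3. flatten residual reference tilt/offset estimated from cell-free pixels
   (wrap-safe, via mean conjugate-product phase gradients);
4. unwrap the phase (reliability-sorted 2D unwrapping);
5. optionally refocus by angular-spectrum propagation with an autofocus
   search (phase-object criterion: the in-focus plane minimizes amplitude
   contrast, scored by the Tamura coefficient);
6. average the unwrapped frames of a stack after per-frame constant-offset
   removal, averaging down the frame-decorrelated coherence noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import unwrap_phase as _skimage_unwrap
from sklearn.base import BaseEstimator, TransformerMixin

from .holography import HologramStack
from .optics import OpticalConfig
from .propagation import propagate_angular_spectrum


class NoSidebandError(ValueError):
    """Raised when no off-axis fringe carrier can be located."""


@dataclass
class ComplexField:
    """Reconstructed object wave with its sampling metadata."""

    values: np.ndarray
    pixel_pitch_x_um: float
    pixel_pitch_y_um: float
    wavelength_um: float
    focus_offset_um: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("complex field must be finite")


@dataclass
class QPIImage:
    """Unwrapped, averaged quantitative phase image (radians)."""

    phase: np.ndarray
    pixel_area_um2: float
    n_frames_averaged: int = 1
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# carrier detection
# ---------------------------------------------------------------------------

def _refine_carrier(
    hologram: np.ndarray, carrier: tuple[float, float], iterations: int = 2
) -> tuple[float, float]:
    """Fine-tune a carrier estimate to sub-bin precision.

    Demodulates with the current estimate and measures the residual tilt as
    the amplitude-weighted mean phase step of the low-passed field (the
    integrated phase gradient of compact cell signal is ~zero, so the mean
    step isolates the carrier error), then folds it back into the estimate.
    """
    cx, cy = carrier
    ny, nx = hologram.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _ in range(iterations):
        cmag = float(np.hypot(cx, cy))
        demod = hologram * np.exp(-2j * np.pi * (cx * xx + cy * yy))
        spec = np.fft.fft2(demod)
        spec *= _soft_disk_mask(hologram.shape, 0.45 * cmag)
        u = np.fft.ifft2(spec)
        dx = float(np.angle(np.sum(u[:, 1:] * np.conj(u[:, :-1]))))
        dy = float(np.angle(np.sum(u[1:, :] * np.conj(u[:-1, :]))))
        cx += dx / (2.0 * np.pi)
        cy += dy / (2.0 * np.pi)
    return (cx, cy)


def locate_carrier(
    hologram: np.ndarray,
    dc_exclusion_radius: float = 0.03,
    prominence: float = 8.0,
    refine_iterations: int = 2,
) -> tuple[float, float]:
    """Estimate the fringe carrier frequency in cycles/pixel.

    Returns the sub-pixel location of the strongest spectral magnitude peak
    outside the DC exclusion disk, refined first by a local magnitude
    centroid and then by demodulation residual-tilt feedback, mapped to the
    half-plane ``fx > 0`` (or ``fx == 0, fy > 0``); the conjugate sideband
    of the real-valued hologram sits at the mirrored position.  Raises
    :class:`NoSidebandError` when the peak does not stand out by
    ``prominence`` over the median spectral background.
    """
    if hologram.ndim != 2:
        raise ValueError("hologram must be a 2D real-valued image")
    ny, nx = hologram.shape
    spec = np.fft.fftshift(np.fft.fft2(hologram - hologram.mean()))
    mag = np.abs(spec)
    fx = np.fft.fftshift(np.fft.fftfreq(nx))
    fy = np.fft.fftshift(np.fft.fftfreq(ny))
    fxx, fyy = np.meshgrid(fx, fy)
    outside = np.hypot(fxx, fyy) > dc_exclusion_radius
    if not outside.any():
        raise NoSidebandError("DC exclusion disk covers the whole spectrum")
    search = np.where(outside, mag, 0.0)
    iy, ix = np.unravel_index(int(np.argmax(search)), search.shape)
    peak = search[iy, ix]
    background = float(np.median(mag[outside]))
    if peak <= prominence * max(background, np.finfo(float).tiny) or peak == 0.0:
        raise NoSidebandError(
            "no sideband found: strongest off-DC spectral peak "
            f"({peak:.3g}) does not exceed {prominence} x background ({background:.3g})"
        )
    # sub-pixel refinement: magnitude centroid over the 3x3 neighbourhood
    y0, y1 = max(iy - 1, 0), min(iy + 2, ny)
    x0, x1 = max(ix - 1, 0), min(ix + 2, nx)
    w = mag[y0:y1, x0:x1]
    cy = float((w * fyy[y0:y1, x0:x1]).sum() / w.sum())
    cx = float((w * fxx[y0:y1, x0:x1]).sum() / w.sum())
    if cx < 0 or (cx == 0 and cy < 0):
        cx, cy = -cx, -cy
    if refine_iterations > 0:
        cx, cy = _refine_carrier(hologram, (cx, cy), refine_iterations)
    return (cx, cy)


# ---------------------------------------------------------------------------
# demodulation
# ---------------------------------------------------------------------------

def _soft_disk_mask(
    shape: tuple[int, int], radius_cpp: float, taper_fraction: float = 0.3
) -> np.ndarray:
    """Raised-cosine tapered circular low-pass, DC-centered (unshifted)."""
    ny, nx = shape
    fx = np.fft.fftfreq(nx)
    fy = np.fft.fftfreq(ny)
    fxx, fyy = np.meshgrid(fx, fy)
    r = np.hypot(fxx, fyy)
    r_in = radius_cpp * (1.0 - taper_fraction)
    mask = np.zeros(shape)
    mask[r <= r_in] = 1.0
    ramp = (r > r_in) & (r < radius_cpp)
    mask[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - r_in) / (radius_cpp - r_in)))
    return mask


def _cell_free_mask(wrapped_or_field: np.ndarray, fraction: float = 0.4) -> np.ndarray:
    """Pixels with the lowest local phase activity (likely background).

    Local activity is the smoothed magnitude of the wrap-safe phase gradient.
    Falls back to a 16-pixel border frame if the mask degenerates.
    """
    from scipy.ndimage import uniform_filter

    u = wrapped_or_field
    if not np.iscomplexobj(u):
        u = np.exp(1j * u)
    gx = np.zeros(u.shape)
    gy = np.zeros(u.shape)
    gx[:, :-1] = np.abs(np.angle(u[:, 1:] * np.conj(u[:, :-1])))
    gy[:-1, :] = np.abs(np.angle(u[1:, :] * np.conj(u[:-1, :])))
    activity = uniform_filter(gx + gy, size=9)
    thresh = np.quantile(activity, fraction)
    mask = activity <= thresh
    if mask.sum() < 0.05 * mask.size:
        mask = np.zeros(u.shape, dtype=bool)
        mask[:16, :] = mask[-16:, :] = True
        mask[:, :16] = mask[:, -16:] = True
    return mask


def _flatten_reference(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove residual tilt and piston, estimated wrap-safely on ``mask``."""
    ny, nx = values.shape
    # mean phase gradients over background pixels via conjugate products
    px = values[:, 1:] * np.conj(values[:, :-1])
    py = values[1:, :] * np.conj(values[:-1, :])
    mx = mask[:, 1:] & mask[:, :-1]
    my = mask[1:, :] & mask[:-1, :]
    tx = float(np.angle(px[mx].sum())) if mx.any() else 0.0
    ty = float(np.angle(py[my].sum())) if my.any() else 0.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    flat = values * np.exp(-1j * (tx * xx + ty * yy))
    piston = np.angle(flat[mask].sum()) if mask.any() else 0.0
    return flat * np.exp(-1j * piston)


def remove_background_plane(phase: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the least-squares plane fit over cell-free pixels.

    Residual reference tilt left by a sub-bin carrier-estimate error is a
    clean plane across the whole field; fitting it on the unwrapped phase
    uses the full spatial lever arm and is far more precise than local
    gradient averaging.  The plane is anchored on cell-free pixels so the
    cell signal does not bias it.
    """
    if mask is None:
        mask = _cell_free_mask(phase)
    ny, nx = phase.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    a = np.column_stack(
        [np.ones(int(mask.sum())), xx[mask].ravel(), yy[mask].ravel()]
    )
    coef, *_ = np.linalg.lstsq(a, phase[mask].ravel(), rcond=None)
    return phase - (coef[0] + coef[1] * xx + coef[2] * yy)


def demodulate_to_phase(
    hologram: np.ndarray,
    carrier: tuple[float, float],
    filter_radius: float | None = None,
    config: OpticalConfig | None = None,
    flatten: bool = True,
) -> tuple[ComplexField, np.ndarray]:
    """Isolate the object sideband and return (complex field, wrapped phase).

    ``filter_radius`` (cycles/pixel) defaults to 0.45 x |carrier| and must
    stay below |carrier| so the low-pass cannot reach the zero-order (DC)
    term.
    """
    cx, cy = carrier
    cmag = float(np.hypot(cx, cy))
    if cmag == 0:
        raise ValueError("carrier must be nonzero")
    if filter_radius is None:
        filter_radius = 0.45 * cmag
    if filter_radius >= cmag:
        raise ValueError(
            f"filter radius {filter_radius:.4f} c/px overlaps the DC term "
            f"(|carrier| = {cmag:.4f} c/px)"
        )
    ny, nx = hologram.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    demod = hologram * np.exp(-2j * np.pi * (cx * xx + cy * yy))
    spec = np.fft.fft2(demod)
    spec *= _soft_disk_mask(hologram.shape, filter_radius)
    values = np.fft.ifft2(spec)
    if flatten:
        mask = _cell_free_mask(values)
        values = _flatten_reference(values, mask)
    if config is not None:
        fieldobj = ComplexField(
            values=values,
            pixel_pitch_x_um=config.pixel_pitch_x_um,
            pixel_pitch_y_um=config.pixel_pitch_y_um,
            wavelength_um=config.wavelength_um,
        )
    else:
        fieldobj = ComplexField(
            values=values, pixel_pitch_x_um=1.0, pixel_pitch_y_um=1.0, wavelength_um=0.532
        )
    return fieldobj, np.angle(values)


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """2D phase unwrapping (reliability-sorted / quality-guided).

    On wrap-free inputs this is the identity up to a constant multiple of
    2 pi.
    """
    return np.asarray(_skimage_unwrap(wrapped), dtype=float)


# ---------------------------------------------------------------------------
# autofocus
# ---------------------------------------------------------------------------

def tamura_coefficient(amplitude: np.ndarray) -> float:
    """Tamura coefficient sqrt(std/mean) of the amplitude image."""
    m = float(amplitude.mean())
    if m <= 0:
        return 0.0
    return float(np.sqrt(amplitude.std() / m))


def refocus_autofocus(
    fieldobj: ComplexField,
    search_range_um: tuple[float, float] = (-100.0, 100.0),
    steps: int = 41,
    criterion=None,
) -> tuple[ComplexField, float, bool]:
    """Propagate over candidate distances and pick the best focus.

    The default score is the *negated* Tamura coefficient of the amplitude:
    a pure phase object shows minimal amplitude contrast in focus, so the
    argmax of the score is the focus plane.  Returns ``(refocused field,
    chosen distance, tie_flag)``; ties are broken toward the smallest
    absolute distance and flagged.
    """
    if steps < 3:
        raise ValueError("need at least 3 search steps")
    lo, hi = search_range_um
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError("search range must be a finite nonempty interval")
    if criterion is None:
        criterion = lambda amp: -tamura_coefficient(amp)  # noqa: E731
    distances = np.linspace(lo, hi, steps)
    scores = np.empty(steps)
    for i, d in enumerate(distances):
        prop = propagate_angular_spectrum(
            fieldobj.values,
            float(d),
            fieldobj.wavelength_um,
            fieldobj.pixel_pitch_x_um,
            fieldobj.pixel_pitch_y_um,
        )
        scores[i] = criterion(np.abs(prop))
    best = scores.max()
    ties = np.isclose(scores, best, rtol=0, atol=1e-12)
    tie_flag = int(ties.sum()) > 1
    candidates = distances[ties]
    chosen = float(candidates[np.argmin(np.abs(candidates))])
    refocused = propagate_angular_spectrum(
        fieldobj.values,
        chosen,
        fieldobj.wavelength_um,
        fieldobj.pixel_pitch_x_um,
        fieldobj.pixel_pitch_y_um,
    )
    out = ComplexField(
        values=refocused,
        pixel_pitch_x_um=fieldobj.pixel_pitch_x_um,
        pixel_pitch_y_um=fieldobj.pixel_pitch_y_um,
        wavelength_um=fieldobj.wavelength_um,
        focus_offset_um=fieldobj.focus_offset_um + chosen,
    )
    return out, chosen, tie_flag


# ---------------------------------------------------------------------------
# stack averaging
# ---------------------------------------------------------------------------

def average_phase_stack(
    phases: np.ndarray | list[np.ndarray],
    pixel_area_um2: float = 1.0,
    provenance: dict | None = None,
) -> QPIImage:
    """Average unwrapped phase frames after per-frame offset removal.

    The per-frame constant offset (piston, e.g. a 2 pi branch picked by the
    unwrapper or inter-frame reference drift) is the median over cell-free
    pixels, identified on the pixel-wise median frame; frames are then
    averaged pixel-wise.
    """
    stack = np.asarray(phases, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("need a nonempty stack of 2D phase maps")
    ref = np.median(stack, axis=0)
    mask = _cell_free_mask(ref)
    aligned = stack - np.median(stack[:, mask], axis=1)[:, None, None]
    return QPIImage(
        phase=aligned.mean(axis=0),
        pixel_area_um2=pixel_area_um2,
        n_frames_averaged=stack.shape[0],
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# full stack reconstruction
# ---------------------------------------------------------------------------

def reconstruct_stack(
    stack: HologramStack,
    dc_exclusion_radius: float = 0.03,
    filter_radius: float | None = None,
    autofocus: bool = False,
    search_range_um: tuple[float, float] = (-100.0, 100.0),
    steps: int = 41,
) -> QPIImage:
    """Carrier detection, demodulation, (optional) refocus, unwrap, average."""
    config = stack.config
    carrier = locate_carrier(stack.frames[0], dc_exclusion_radius)
    focus_um = 0.0
    if autofocus:
        f0, _ = demodulate_to_phase(stack.frames[0], carrier, filter_radius, config)
        _, focus_um, _ = refocus_autofocus(f0, search_range_um, steps)
    unwrapped = []
    for frame in stack.frames:
        fieldobj, _ = demodulate_to_phase(frame, carrier, filter_radius, config)
        if focus_um != 0.0:
            fieldobj = ComplexField(
                values=propagate_angular_spectrum(
                    fieldobj.values,
                    focus_um,
                    config.wavelength_um,
                    config.pixel_pitch_x_um,
                    config.pixel_pitch_y_um,
                ),
                pixel_pitch_x_um=config.pixel_pitch_x_um,
                pixel_pitch_y_um=config.pixel_pitch_y_um,
                wavelength_um=config.wavelength_um,
                focus_offset_um=focus_um,
            )
        u = unwrap_phase(np.angle(fieldobj.values))
        unwrapped.append(remove_background_plane(u))
    return average_phase_stack(
        unwrapped,
        pixel_area_um2=config.pixel_area_um2,
        provenance={
            "carrier_cpp": list(carrier),
            "filter_radius_cpp": filter_radius,
            "autofocus_um": focus_um,
        },
    )


class HologramReconstructor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: hologram stack -> averaged phase map.

    ``fit`` estimates the fringe carrier from the first frame; ``transform``
    demodulates, unwraps and averages a ``(n_frames, ny, nx)`` stack into a
    single 2D phase map (radians).

    Parameters
    ----------
    config : OpticalConfig
        Imaging geometry; required for calibrated output.
    dc_exclusion_radius : float
        DC exclusion disk radius for carrier search, cycles/pixel.
    filter_radius : float or None
        Sideband low-pass radius; None = 0.45 x |carrier|.
    autofocus : bool
        Run the angular-spectrum autofocus before unwrapping.
    """

    def __init__(
        self,
        config: OpticalConfig | None = None,
        dc_exclusion_radius: float = 0.03,
        filter_radius: float | None = None,
        autofocus: bool = False,
        search_range_um: tuple[float, float] = (-100.0, 100.0),
        steps: int = 41,
    ):
        self.config = config
        self.dc_exclusion_radius = dc_exclusion_radius
        self.filter_radius = filter_radius
        self.autofocus = autofocus
        self.search_range_um = search_range_um
        self.steps = steps

    def fit(self, X, y=None):
        frames = np.asarray(X, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError("X must be a (n_frames, ny, nx) hologram stack")
        self.carrier_ = locate_carrier(frames[0], self.dc_exclusion_radius)
        self.n_frames_ = frames.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "carrier_"):
            raise RuntimeError("HologramReconstructor is not fitted")
        frames = np.asarray(X, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        config = self.config if self.config is not None else OpticalConfig(
            pixel_count_y=frames.shape[1], pixel_count_x=frames.shape[2]
        )
        stack = HologramStack(frames=frames, config=config)
        qpi = reconstruct_stack(
            stack,
            dc_exclusion_radius=self.dc_exclusion_radius,
            filter_radius=self.filter_radius,
            autofocus=self.autofocus,
            search_range_um=self.search_range_um,
            steps=self.steps,
        )
        self.qpi_ = qpi
        return qpi.phase
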