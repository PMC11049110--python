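"""Synthetic quantitative-phase scenes of adherent cell populations.

A scene is a 2D map of optical phase delay (radians) over the calibrated
field of view, with an exactly known total dry mass.  Cells are rendered as
smooth compact phase bumps (raised-cosine radial profiles) whose integrated
phase encodes their dry mass through the standard QPI relation

    dm = lambda / (2 pi alpha) * sum(phase) * pixel_area,

so every scene is self-consistent by construction: evaluating that relation
on the rendered map reproduces ``true_total_dry_mass`` to float precision.

The 24 h evolution of a population under nanoparticle exposure is modelled
as a dose-dependent growth factor interpolating between the medium-control
growth (doubling by default) and a net-loss floor, through the 4PL
ground-truth curve; strong effects render part of the lost population as
low-mass debris fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drymass import mass_from_phase_sum, phase_sum_from_mass
from .optics import OpticalConfig
from .truth import DoseEffectTruth, NonMonotoneDoseEffect

# unit-peak raised-cosine bump integrates to ~0.9343 R^2 over the plane
_BUMP_SUM_COEFF = 2.0 * np.pi * (0.25 - 1.0 / np.pi**2)


@dataclass
class CellSpec:
    """One rendered cell: center (pixels), radius (pixels), peak phase (rad)."""

    cy: float
    cx: float
    radius_px: float
    peak_rad: float
    is_debris: bool = False


@dataclass
class PhaseScene:
    """Ground-truth phase map with exact dry-mass bookkeeping."""

    phase_map: np.ndarray
    pixel_area_um2: float
    true_total_dry_mass_pg: float
    cell_count: int
    timestamp_h: float = 0.0
    cells: list[CellSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase_map)):
            raise ValueError("phase map must be finite")
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")


def _render_bump(shape: tuple[int, int], cell: CellSpec) -> np.ndarray:
    """Raised-cosine bump: peak * cos^2(pi r / (2 R)) inside r < R."""
    ny, nx = shape
    r = cell.radius_px
    y0 = max(0, int(np.floor(cell.cy - r)) - 1)
    y1 = min(ny, int(np.ceil(cell.cy + r)) + 2)
    x0 = max(0, int(np.floor(cell.cx - r)) - 1)
    x1 = min(nx, int(np.ceil(cell.cx + r)) + 2)
    out = np.zeros(shape)
    if y1 <= y0 or x1 <= x0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.hypot(yy - cell.cy, xx - cell.cx)
    inside = rr < r
    patch = np.zeros_like(rr, dtype=float)
    patch[inside] = cell.peak_rad * np.cos(np.pi * rr[inside] / (2.0 * r)) ** 2
    out[y0:y1, x0:x1] = patch
    return out


def _render_cells(shape: tuple[int, int], cells: list[CellSpec]) -> np.ndarray:
    phase = np.zeros(shape)
    for c in cells:
        phase += _render_bump(shape, c)
    return phase


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: np.ndarray,
    overlap_budget: float,
    max_tries: int = 80,
) -> list[tuple[float, float]]:
    """Place cell centers with bounded pairwise overlap, or raise."""
    ny, nx = shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r, ny - r) if ny > 2 * r else rng.uniform(0, ny)
            cx = rng.uniform(r, nx - r) if nx > 2 * r else rng.uniform(0, nx)
            # accept if no prior cell center closer than (1 - budget)*(r_i + r_j)
            good = True
            for (py, px), pr in zip(centers, placed_r):
                if np.hypot(cy - py, cx - px) < (1.0 - overlap_budget) * (r + pr):
                    good = False
                    break
            if good:
                centers.append((cy, cx))
                placed_r.append(float(r))
                ok = True
                break
        if not ok:
            raise ValueError(
                "cell density too high: could not place cells within the "
                f"configured overlap budget ({overlap_budget:.2f})"
            )
    return centers


def generate_phase_scene(
    config: OpticalConfig,
    n_cells: int,
    mean_cell_mass_pg: float = 300.0,
    seed: int = 0,
    mass_dispersion: float = 0.15,
    peak_phase_rad: float = 2.0,
    overlap_budget: float = 0.35,
    timestamp_h: float = 0.0,
) -> PhaseScene:
    """Render a population of ``n_cells`` cells with known total dry mass.

    Per-cell dry mass is drawn from a truncated normal around
    ``mean_cell_mass_pg`` with coefficient of variation ``mass_dispersion``
    (0 gives identical cells).  Cell radii are chosen so the peak phase sits
    near ``peak_phase_rad`` (kept modest so a single cell never spans more
    than one 2 pi interval), then the rendered map is integrated to record
    the exact total mass.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if mean_cell_mass_pg <= 0:
        raise ValueError("mean_cell_mass_pg must be positive")
    rng = np.random.default_rng(seed)
    shape = config.shape
    if n_cells == 0:
        return PhaseScene(
            phase_map=np.zeros(shape),
            pixel_area_um2=config.pixel_area_um2,
            true_total_dry_mass_pg=0.0,
            cell_count=0,
            timestamp_h=timestamp_h,
        )
    masses = mean_cell_mass_pg * (1.0 + mass_dispersion * rng.standard_normal(n_cells))
    masses = np.clip(masses, 0.2 * mean_cell_mass_pg, None)
    # per-cell integrated phase (rad * pixels) and bump geometry
    phase_sums = phase_sum_from_mass(masses, config)
    radii = np.sqrt(phase_sums / (_BUMP_SUM_COEFF * peak_phase_rad))
    radii = np.maximum(radii, 2.0)
    centers = _place_cells(rng, shape, radii, overlap_budget)
    cells = []
    for (cy, cx), r, psum in zip(centers, radii, phase_sums):
        unit = CellSpec(cy=cy, cx=cx, radius_px=float(r), peak_rad=1.0)
        rendered_sum = _render_bump(shape, unit).sum()
        # scale peak so the discretely rendered bump carries exactly psum
        cells.append(
            CellSpec(cy=cy, cx=cx, radius_px=float(r), peak_rad=float(psum / rendered_sum))
        )
    phase = _render_cells(shape, cells)
    mass = mass_from_phase_sum(float(phase.sum()), config)
    return PhaseScene(
        phase_map=phase,
        pixel_area_um2=config.pixel_area_um2,
        true_total_dry_mass_pg=mass,
        cell_count=n_cells,
        timestamp_h=timestamp_h,
        cells=cells,
    )


def growth_factor(
    dose: float,
    truth: DoseEffectTruth | NonMonotoneDoseEffect,
    control_growth: float = 2.0,
    floor_growth: float = 0.5,
) -> float:
    """Population mass multiplier over 24 h at the given dose.

    The truth's response fraction f interpolates linearly between the
    net-loss floor (f = 0) and the medium-control growth (f = 1):
    ``g = floor + f * (control - floor)``.
    """
    f = float(truth.response(dose))
    return floor_growth + f * (control_growth - floor_growth)


def apply_dose_response_truth(
    scene_t0: PhaseScene,
    dose: float,
    truth: DoseEffectTruth | NonMonotoneDoseEffect,
    duration_h: float = 24.0,
    seed: int = 0,
    config: OpticalConfig | None = None,
    control_growth: float = 2.0,
    floor_growth: float = 0.5,
    debris_mass_pg: float = 12.0,
) -> PhaseScene:
    """Evolve a t=0 scene to ``duration_h`` under the dose-effect truth.

    The target population mass is ``g * mass(t0)`` with ``g`` from
    :func:`growth_factor` (compounded for durations other than 24 h).  Net
    growth adds new cells drawn like the originals; net loss removes cells
    and renders part of the lost mass as sub-cellular debris fragments.  A
    final exact rescale pins the rendered total mass to the target.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if config is None:
        config = OpticalConfig(
            pixel_count_y=scene_t0.phase_map.shape[0],
            pixel_count_x=scene_t0.phase_map.shape[1],
        )
    rng = np.random.default_rng(seed)
    shape = scene_t0.phase_map.shape
    g24 = growth_factor(dose, truth, control_growth, floor_growth)
    g = float(g24 ** (duration_h / 24.0))
    target_mass = g * scene_t0.true_total_dry_mass_pg
    if scene_t0.true_total_dry_mass_pg == 0.0 or not scene_t0.cells:
        return PhaseScene(
            phase_map=np.zeros(shape),
            pixel_area_um2=scene_t0.pixel_area_um2,
            true_total_dry_mass_pg=0.0,
            cell_count=0,
            timestamp_h=scene_t0.timestamp_h + duration_h,
        )

    cells = [CellSpec(**vars(c)) for c in scene_t0.cells if not c.is_debris]
    per_cell_sums = np.array(
        [_render_bump(shape, c).sum() for c in cells]
    )
    target_sum = phase_sum_from_mass(target_mass, config)

    if g >= 1.0:
        # divide: add new cells of typical size until the target is reached
        extra = target_sum - per_cell_sums.sum()
        mean_sum = float(per_cell_sums.mean())
        n_new = int(np.floor(extra / mean_sum))
        new_specs: list[CellSpec] = []
        for _ in range(n_new):
            proto = cells[rng.integers(len(cells))]
            r = proto.radius_px * rng.uniform(0.9, 1.1)
            cy = rng.uniform(r, shape[0] - r)
            cx = rng.uniform(r, shape[1] - r)
            new_specs.append(CellSpec(cy=cy, cx=cx, radius_px=r, peak_rad=proto.peak_rad))
        cells = cells + new_specs
    else:
        # attrition: when the effect is strong, a fixed share of the surviving
        # mass is debris; whole cells (shuffled) fill the rest of the target
        f_resp = float(truth.response(dose))
        debris_share = 0.3 if f_resp < 0.2 else 0.0
        cell_budget = (1.0 - debris_share) * target_sum
        order = rng.permutation(len(cells))
        kept: list[CellSpec] = []
        acc = 0.0
        for i in order:
            if acc + per_cell_sums[i] <= cell_budget or not kept:
                kept.append(cells[i])
                acc += per_cell_sums[i]
                if acc > cell_budget:
                    break
        cells = kept
        deficit_mass = target_mass - mass_from_phase_sum(acc, config)
        if deficit_mass > debris_mass_pg / 2:
            n_frag = max(1, int(round(deficit_mass / debris_mass_pg)))
            frag_sum = phase_sum_from_mass(debris_mass_pg, config)
            # radius keeping fragment peak phase near 2 rad (no wrapping)
            r_base = max(1.2, float(np.sqrt(frag_sum / (_BUMP_SUM_COEFF * 2.0))))
            for _ in range(min(n_frag, 400)):
                r = r_base * rng.uniform(0.8, 1.25)
                cy = rng.uniform(r, shape[0] - r)
                cx = rng.uniform(r, shape[1] - r)
                unit = CellSpec(cy=cy, cx=cx, radius_px=float(r), peak_rad=1.0)
                s = _render_bump(shape, unit).sum()
                cells.append(
                    CellSpec(
                        cy=cy, cx=cx, radius_px=float(r),
                        peak_rad=float(frag_sum / s), is_debris=True,
                    )
                )

    phase = _render_cells(shape, cells)
    total = phase.sum()
    if total > 0:
        scale = target_sum / total
        phase = phase * scale
        cells = [
            CellSpec(c.cy, c.cx, c.radius_px, c.peak_rad * scale, c.is_debris) for c in cells
        ]
    mass = mass_from_phase_sum(float(phase.sum()), config)
    return PhaseScene(
        phase_map=phase,
        pixel_area_um2=scene_t0.pixel_area_um2,
        true_total_dry_mass_pg=mass,
        cell_count=sum(1 for c in cells if not c.is_debris),
        timestamp_h=scene_t0.timestamp_h + duration_h,
        cells=cells,
    )
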