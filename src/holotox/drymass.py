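"""Population dry mass from quantitative phase.

The non-aqueous (dry) mass of the cell population in a field of view follows
from the mean phase shift it induces:

    dm = lambda / (2 pi alpha) * mean_phase * S_FOV

with ``lambda`` the illumination wavelength, ``alpha`` the refractive-index
increment of cellular protein (0.19 mL/g = 0.19 um^3/pg by default) and
``S_FOV`` the field-of-view area.  The mean is taken over the full field —
cells and background alike — which makes the product ``mean_phase * S_FOV``
equal to the integrated phase times the pixel area, so the relation is
linear in phase and independent of any segmentation.

The 24 h proliferation readout is the dry mass increment (DMI)

    DMI = dm(t=24h) - dm(t=0),

normalized within an experiment to the maximal (control) increment to give
relative proliferation in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optics import OpticalConfig


def _mass_coeff_pg_per_rad_um2(config: OpticalConfig) -> float:
    """lambda / (2 pi alpha) in pg / (rad * um^2)."""
    return config.wavelength_um / (2.0 * np.pi * config.refractive_increment_ml_per_g)


def dry_mass_from_phase(mean_phase_rad: float, config: OpticalConfig) -> float:
    """Population dry mass in picograms from the FOV-mean phase shift."""
    if not np.isfinite(mean_phase_rad):
        raise ValueError("mean phase shift must be finite")
    return _mass_coeff_pg_per_rad_um2(config) * mean_phase_rad * config.fov_area_um2


def mass_from_phase_sum(phase_sum_rad: float | np.ndarray, config: OpticalConfig):
    """Dry mass (pg) from integrated phase (rad * pixels)."""
    return _mass_coeff_pg_per_rad_um2(config) * phase_sum_rad * config.pixel_area_um2


def phase_sum_from_mass(mass_pg: float | np.ndarray, config: OpticalConfig):
    """Integrated phase (rad * pixels) carrying the given dry mass."""
    return mass_pg / (_mass_coeff_pg_per_rad_um2(config) * config.pixel_area_um2)


def dry_mass_increment(dm_t0_pg: float, dm_t24_pg: float) -> float:
    """DMI = dm(t24) - dm(t0); negative values mean net mass loss."""
    if not (np.isfinite(dm_t0_pg) and np.isfinite(dm_t24_pg)):
        raise ValueError("dry mass values must be finite")
    return dm_t24_pg - dm_t0_pg


@dataclass
class DryMassRecord:
    """Per-FOV dry-mass measurement over the 24 h window."""

    well_id: str
    fov_id: str
    dm_t0_pg: float
    dm_t24_pg: float
    condition: str = ""
    concentration: float = 0.0
    relative_proliferation_pct: float | None = None

    @property
    def dmi_pg(self) -> float:
        return dry_mass_increment(self.dm_t0_pg, self.dm_t24_pg)


def normalize_increments(
    df: pd.DataFrame,
    group_cols: tuple[str, ...] = ("cell_line", "experiment"),
    reference: str = "max",
) -> pd.DataFrame:
    """Add ``relative_proliferation_pct`` within each group.

    Expects a ``dmi_pg`` column.  Within each group, per-concentration mean
    DMIs are computed and the reference is their maximum (``reference="max"``,
    in practice the medium control) or the zero-dose mean
    (``reference="control"``).  Each row is then expressed as a percentage of
    that reference; the reference maps to exactly 100%.  Groups whose
    reference is <= 0 are flagged ``no_growth_reference`` and left
    unnormalized (NaN).
    """
    if "dmi_pg" not in df.columns:
        raise ValueError("expected a 'dmi_pg' column")
    df = df.copy()
    cols = [c for c in group_cols if c in df.columns]
    df["relative_proliferation_pct"] = np.nan
    df["no_growth_reference"] = False
    groups = df.groupby(list(cols)) if cols else [((), df)]
    for _, sub in groups:
        if "concentration" in sub.columns:
            per_dose = sub.groupby("concentration")["dmi_pg"].mean()
        else:
            per_dose = sub["dmi_pg"]
        if reference == "control":
            if "concentration" not in sub.columns or 0.0 not in per_dose.index:
                raise ValueError("reference='control' requires concentration 0 rows")
            ref = float(per_dose.loc[0.0])
        else:
            ref = float(per_dose.max())
        if ref <= 0:
            df.loc[sub.index, "no_growth_reference"] = True
            continue
        df.loc[sub.index, "relative_proliferation_pct"] = 100.0 * (sub["dmi_pg"] / ref)
    return df
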