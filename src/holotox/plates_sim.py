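"""Synthetic plate-reader data for the WST-8 and LDH assays.

The simulator produces the raw absorbance tables the assay normalizations
consume, with the per-well ground truth entering linearly:

* WST-8 endpoint: OD450 carries the formazan signal proportional to the
  well's true viability fraction above a medium/reagent background; OD620
  carries turbidity (cells plus a dose-proportional particle term) that is
  common to both channels and cancels in the 450-620 difference.
* LDH kinetics: OD492 rises linearly in time with a slope interpolating
  between the negative-control slope (0% death) and the digitonin
  positive-control slope (100% death); an optional late-time plateau
  (substrate exhaustion) exercises linear-range detection.

Noise is multiplicative on every optical density reading.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .layout import PlateLayout, Well, WellRole
from .truth import DoseEffectTruth, NonMonotoneDoseEffect

TruthLike = DoseEffectTruth | NonMonotoneDoseEffect


class PlateNoise(BaseModel):
    """Multiplicative OD noise levels (relative standard deviations)."""

    wst8_sigma_rel: float = 0.02
    ldh_sigma_rel: float = 0.005

    @classmethod
    def off(cls) -> "PlateNoise":
        return cls(wst8_sigma_rel=0.0, ldh_sigma_rel=0.0)


# absorbance model constants (typical plate-reader magnitudes)
WST8_BACKGROUND_OD450 = 0.15
WST8_BACKGROUND_OD620 = 0.05
WST8_CELL_TURBIDITY_OD = 0.05
WST8_SIGNAL_OD = 1.30
PARTICLE_TURBIDITY_OD_PER_UG_ML = 2e-4
LDH_OD_AT_T0 = 0.10
LDH_SLOPE_NEGATIVE = 0.002  # OD/min, spontaneous LDH of viable cultures
LDH_SLOPE_POSITIVE = 0.020  # OD/min, digitonin full lysis


def _well_fractions(
    well: Well,
    viability_truth: TruthLike,
    death_truth: TruthLike,
) -> tuple[float, float]:
    """(viability fraction, death fraction) for one well."""
    if well.role is WellRole.background:
        return 0.0, 0.0
    if well.role is WellRole.negative_control:
        return 1.0, 0.0
    if well.role is WellRole.positive_control:
        return 0.0, 1.0
    v = float(viability_truth.response(well.concentration))
    d = float(death_truth.response(well.concentration))
    return v, d


def simulate_absorbance_plate(
    layout: PlateLayout,
    viability_truth: TruthLike,
    death_truth: TruthLike,
    noise: PlateNoise | None = None,
    seed: int = 0,
    n_minutes: int = 30,
    ldh_plateau_start_min: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one plate; returns ``(wst8_table, ldh_table)``.

    ``wst8_table`` is wide (one row per well, ``od450``/``od620`` columns);
    ``ldh_table`` is long (one row per well and minute, 0..``n_minutes``).
    The layout must provide digitonin positive-control wells for the LDH
    branch.
    """
    layout.require_positive_control()
    noise = noise if noise is not None else PlateNoise()
    rng = np.random.default_rng(seed)
    minutes = np.arange(n_minutes + 1, dtype=float)

    wst8_rows = []
    ldh_rows = []
    for well in layout.wells:
        v, d = _well_fractions(well, viability_truth, death_truth)
        turbidity = PARTICLE_TURBIDITY_OD_PER_UG_ML * well.concentration
        has_cells = well.role is not WellRole.background
        cell_turb = WST8_CELL_TURBIDITY_OD if has_cells else 0.0
        od620 = WST8_BACKGROUND_OD620 + cell_turb + turbidity
        od450 = WST8_BACKGROUND_OD450 + cell_turb + turbidity + WST8_SIGNAL_OD * v
        if noise.wst8_sigma_rel > 0:
            od450 *= 1.0 + noise.wst8_sigma_rel * rng.standard_normal()
            od620 *= 1.0 + noise.wst8_sigma_rel * rng.standard_normal()
        wst8_rows.append(
            {
                "well_id": well.well_id,
                "role": well.role.value,
                "condition_label": well.condition_label,
                "concentration": well.concentration,
                "replicate_index": well.replicate_index,
                "od450": od450,
                "od620": od620,
            }
        )

        slope = LDH_SLOPE_NEGATIVE + d * (LDH_SLOPE_POSITIVE - LDH_SLOPE_NEGATIVE)
        if not has_cells:
            slope = 0.0
        t_eff = minutes
        if ldh_plateau_start_min is not None:
            t_eff = np.minimum(minutes, ldh_plateau_start_min)
        series = LDH_OD_AT_T0 + slope * t_eff
        if noise.ldh_sigma_rel > 0:
            series = series * (
                1.0 + noise.ldh_sigma_rel * rng.standard_normal(series.shape)
            )
        for t, od in zip(minutes, series):
            ldh_rows.append(
                {
                    "well_id": well.well_id,
                    "role": well.role.value,
                    "condition_label": well.condition_label,
                    "concentration": well.concentration,
                    "replicate_index": well.replicate_index,
                    "minute": t,
                    "od492": od,
                }
            )
    return pd.DataFrame(wst8_rows), pd.DataFrame(ldh_rows)
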