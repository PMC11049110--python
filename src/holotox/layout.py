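"""96-well plate layout: well roles, conditions and dose series.

The layout maps wells to their role in the assay normalizations:

* ``sample`` wells carry cells dosed with nanoparticles;
* ``negative_control`` wells carry cells in plain medium (100% viability,
  0% LDH release reference);
* ``positive_control`` wells carry digitonin-lysed cells (100% LDH release
  reference; digitonin at 75 ug/mL);
* ``background`` wells contain medium and reagent but no cells (WST-8
  blank).
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable

import pandas as pd
from pydantic import BaseModel, model_validator

DIGITONIN_UG_PER_ML = 75.0


class WellRole(str, Enum):
    sample = "sample"
    negative_control = "negative_control"
    positive_control = "positive_control"
    background = "background"


class Well(BaseModel):
    well_id: str
    role: WellRole
    condition_label: str = ""
    concentration: float = 0.0
    replicate_index: int = 0

    @model_validator(mode="after")
    def _check(self) -> "Well":
        if self.concentration < 0:
            raise ValueError(f"well {self.well_id}: concentration must be >= 0")
        return self


class PlateLayout(BaseModel):
    wells: list[Well]

    @model_validator(mode="after")
    def _check(self) -> "PlateLayout":
        ids = [w.well_id for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate well ids in layout")
        roles = {w.role for w in self.wells}
        if WellRole.negative_control not in roles:
            raise ValueError("layout requires at least one negative_control well")
        if WellRole.background not in roles:
            raise ValueError("layout requires at least one background well")
        return self

    def require_positive_control(self) -> None:
        """LDH normalization needs digitonin wells; raise if absent."""
        if not any(w.role is WellRole.positive_control for w in self.wells):
            raise ValueError(
                "LDH release normalization requires positive_control (digitonin) wells"
            )

    def wells_by_role(self, role: WellRole) -> list[Well]:
        return [w for w in self.wells if w.role is role]

    def sample_conditions(self) -> dict[str, list[Well]]:
        out: dict[str, list[Well]] = {}
        for w in self.wells_by_role(WellRole.sample):
            out.setdefault(w.condition_label, []).append(w)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([w.model_dump() for w in self.wells])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        required = {"well_id", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"layout table missing columns: {sorted(missing)}")
        wells = []
        for _, row in df.iterrows():
            wells.append(
                Well(
                    well_id=str(row["well_id"]),
                    role=WellRole(row["role"]),
                    condition_label=str(row.get("condition_label", "") or ""),
                    concentration=float(row.get("concentration", 0.0) or 0.0),
                    replicate_index=int(row.get("replicate_index", 0) or 0),
                )
            )
        return cls(wells=wells)


def make_dose_layout(
    doses: Iterable[float],
    condition: str = "PACA",
    n_replicates: int = 4,
    n_negative: int = 4,
    n_positive: int = 4,
    n_background: int = 4,
) -> PlateLayout:
    """Standard layout: a dose series with replicate sample wells plus the
    three control groups needed by the WST-8 and LDH normalizations."""
    wells: list[Well] = []
    idx = 0

    def wid() -> str:
        nonlocal idx
        row, col = divmod(idx, 12)
        idx += 1
        return f"{chr(ord('A') + row)}{col + 1}"

    for rep in range(n_background):
        wells.append(Well(well_id=wid(), role=WellRole.background, replicate_index=rep))
    for rep in range(n_negative):
        wells.append(
            Well(
                well_id=wid(),
                role=WellRole.negative_control,
                condition_label="medium",
                replicate_index=rep,
            )
        )
    for rep in range(n_positive):
        wells.append(
            Well(
                well_id=wid(),
                role=WellRole.positive_control,
                condition_label="digitonin",
                concentration=DIGITONIN_UG_PER_ML,
                replicate_index=rep,
            )
        )
    for dose in doses:
        if dose <= 0:
            raise ValueError("sample doses must be positive; dose 0 is the negative control")
        for rep in range(n_replicates):
            wells.append(
                Well(
                    well_id=wid(),
                    role=WellRole.sample,
                    condition_label=condition,
                    concentration=float(dose),
                    replicate_index=rep,
                )
            )
    return PlateLayout(wells=wells)
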