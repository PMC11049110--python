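"""File interfaces: TIFF image stacks, phase maps, plate CSVs, layout YAML.

Hologram stacks are written as multi-page 16-bit grayscale TIFF with a JSON
sidecar carrying the optics metadata; reconstructed phase maps as 32-bit
float TIFF with a provenance sidecar.  Plate tables are plain CSV (wide for
WST-8, long well x minute for LDH) and layouts are a small YAML dialect:

    wells:
      - {well_id: A1, role: background}
      - {well_id: B1, role: sample, condition_label: PACA,
         concentration: 8.0, replicate_index: 0}
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .holography import HologramStack
from .layout import PlateLayout
from .optics import OpticalConfig
from .reconstruction import QPIImage

_DETECTOR_FULL_SCALE = 1.0  # hologram intensities are modelled on a 0..1 range


def save_hologram_stack(stack: HologramStack, path: str | Path) -> int:
    """Write a multi-page 16-bit TIFF plus ``<path>.json`` sidecar.

    Intensities above the detector full scale are clipped; the number of
    saturated pixels is returned and reported as a warning.
    """
    path = Path(path)
    frames = stack.frames
    saturated = int(np.count_nonzero(frames > _DETECTOR_FULL_SCALE))
    if saturated:
        warnings.warn(
            f"{saturated} saturated pixels clipped while writing {path.name}",
            stacklevel=2,
        )
    digitized = np.clip(frames / _DETECTOR_FULL_SCALE, 0.0, 1.0)
    digitized = np.round(digitized * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, digitized, photometric="minisblack")
    sidecar = {
        "optics": stack.config.model_dump(),
        "defocus_um": stack.defocus_um,
        "full_scale": _DETECTOR_FULL_SCALE,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return saturated


def load_hologram_stack(path: str | Path) -> HologramStack:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    config = OpticalConfig(**sidecar["optics"])
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    frames = arr / 65535.0 * sidecar.get("full_scale", _DETECTOR_FULL_SCALE)
    return HologramStack(
        frames=frames, config=config, defocus_um=sidecar.get("defocus_um", 0.0)
    )


def save_phase_tiff(qpi: QPIImage, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, qpi.phase.astype(np.float32), photometric="minisblack")
    sidecar = {
        "pixel_area_um2": qpi.pixel_area_um2,
        "n_frames_averaged": qpi.n_frames_averaged,
        "provenance": qpi.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_phase_tiff(path: str | Path) -> QPIImage:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    phase = tifffile.imread(path).astype(float)
    return QPIImage(
        phase=phase,
        pixel_area_um2=meta.get("pixel_area_um2", 1.0),
        n_frames_averaged=meta.get("n_frames_averaged", 1),
        provenance=meta.get("provenance", {}),
    )


_WST8_COLUMNS = {"well_id", "role", "od450", "od620"}
_LDH_COLUMNS = {"well_id", "minute", "od492"}


def write_plate_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_wst8_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = _WST8_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: WST-8 table missing columns {sorted(missing)}")
    return df


def read_ldh_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = _LDH_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: LDH table missing columns {sorted(missing)}")
    for well_id, sub in df.groupby("well_id"):
        t = sub["minute"].to_numpy()
        if np.any(np.diff(np.sort(t)) == 0):
            raise ValueError(f"{path}: duplicate time stamps for well {well_id}")
    return df


def layout_to_yaml(layout: PlateLayout, path: str | Path) -> None:
    data = {"wells": [w.model_dump(mode="json") for w in layout.wells]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def layout_from_yaml(path: str | Path) -> PlateLayout:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "wells" not in data:
        raise ValueError(f"{path}: layout file must contain a top-level 'wells' list")
    return PlateLayout(wells=data["wells"])
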