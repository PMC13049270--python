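"""NIfTI, table and configuration handling.

All volumes travel as a `Volume` (data + affine); the affine is carried
through untouched and any grid mismatch inside a series raises before
computation — there is no implicit resampling anywhere in the package.
Configs are YAML (JSON accepted) with units encoded in key names
(…_ms, _uT, _ppm, _s1); every pipeline run writes its resolved config
next to its outputs so a run can be reproduced bit-identically from the
output directory alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .signal_model import MISLModelParams, SaturationCurve, SaturationScheme

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "load_config",
    "save_config",
    "scheme_from_config",
    "params_from_config",
    "scheme_to_config",
    "params_to_config",
    "read_saturation_curve",
    "write_saturation_curve",
    "write_region_table",
    "RunConfig",
]


@dataclass
class Volume:
    """An intensity volume with its NIfTI affine."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def voxel_size_mm(self) -> tuple[float, ...]:
        return tuple(float(v) for v in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    def same_grid_as(self, other: "Volume") -> bool:
        return self.data.shape[:3] == other.data.shape[:3] and np.allclose(
            self.affine, other.affine
        )


def read_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    return Volume(data=np.asarray(img.dataobj, dtype=float), affine=img.affine.copy())


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def assert_same_grid(*volumes: Volume) -> None:
    """Raise with both grids printed when volumes disagree."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid_as(v):
            raise ValueError(
                "grid mismatch between volumes:\n"
                f"  shape {ref.data.shape[:3]} affine\n{ref.affine}\n"
                f"  vs shape {v.data.shape[:3]} affine\n{v.affine}"
            )


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(_clean(config), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(_clean(config), sort_keys=False))


def scheme_from_config(cfg: dict) -> SaturationScheme:
    return SaturationScheme(
        n_pulses=cfg.get("n_pulses", 50),
        pulse_width_ms=cfg.get("pulse_width_ms", 50.0),
        interpulse_delay_ms=cfg.get("interpulse_delay_ms", 25.0),
        peak_b1_uT=cfg.get("peak_b1_uT", 3.0),
        offset_ppm=cfg.get("offset_ppm", -10.0),
        shape_name=cfg.get("shape_name", "sincgauss"),
    )


def scheme_to_config(scheme: SaturationScheme) -> dict:
    return asdict(scheme)


def params_from_config(cfg: dict) -> MISLModelParams:
    return MISLModelParams(
        alpha=cfg.get("alpha", 0.42),
        r1rho_tissue_s1=cfg.get("r1rho_tissue_s1", 1.72),
        r1_csf_s1=cfg.get("r1_csf_s1", 0.23),
    )


def params_to_config(params: MISLModelParams) -> dict:
    return asdict(params)


def read_saturation_curve(path: str | Path) -> SaturationCurve:
    """Two-column delimited text (t_sat_s, delta_z); '#' comments allowed."""
    arr = np.loadtxt(str(path), comments="#", delimiter=None)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected two columns (t_sat_s, delta_z) in {path}")
    return SaturationCurve(arr[:, 0], arr[:, 1])


def write_saturation_curve(curve: SaturationCurve, path: str | Path) -> None:
    arr = np.column_stack([curve.t_sat_values_s, curve.delta_z_values])
    np.savetxt(str(path), arr, header="t_sat_s delta_z")


def write_region_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run, serialized next to its outputs."""

    scheme: dict = field(default_factory=lambda: scheme_to_config(SaturationScheme()))
    params: dict = field(default_factory=lambda: params_to_config(MISLModelParams()))
    csf_threshold: float | str = "otsu"
    pvs_threshold: float | str = "otsu"
    max_pvs_component: int = 300
    connectivity: int = 3
    dilation_radius: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return _clean(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})
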