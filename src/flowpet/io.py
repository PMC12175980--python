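"""Reading and writing of TAC/AIF tables, grid configs, and NIfTI volumes.

Text formats are tab-separated with explicit unit-bearing column names:
TAC tables carry ``frame_start_s``, ``frame_end_s``, ``value_kBq_per_mL``
and an optional ``region`` column (long format); AIF tables carry ``time_s``
and ``value_kBq_per_mL``.  Volumes use NIfTI with the frame schedule in a
JSON sidecar (NIfTI itself has no frame-timing field).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ArterialInput, FrameSchedule, TimeActivityCurve
from .estimation import GridConfig
from .imaging import DynamicImage, ParametricMaps

__all__ = [
    "write_tac_table", "read_tac_table", "write_aif", "read_aif",
    "grid_config_to_dict", "grid_config_from_dict", "load_grid_config",
    "save_grid_config", "save_dynamic_image", "load_dynamic_image",
    "save_labels", "load_labels", "write_parametric_maps",
]

PathLike = Union[str, Path]


# -- TAC / AIF tables -----------------------------------------------------

def write_tac_table(path: PathLike, tacs) -> None:
    """Write one TAC or a list of labeled TACs as a long-format TSV."""
    if isinstance(tacs, TimeActivityCurve):
        tacs = [tacs]
    frames = []
    for tac in tacs:
        frames.append(pd.DataFrame({
            "region": tac.label or "tac",
            "frame_start_s": tac.schedule.starts,
            "frame_end_s": tac.schedule.ends,
            "value_kBq_per_mL": tac.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_tac_table(path: PathLike) -> dict[str, TimeActivityCurve]:
    """Read a (long-format) TAC table into a dict keyed by region label."""
    df = pd.read_csv(path, sep="\t")
    required = {"frame_start_s", "frame_end_s", "value_kBq_per_mL"}
    if not required.issubset(df.columns):
        raise ValueError(f"TAC table must have columns {sorted(required)}")
    if "region" not in df.columns:
        df["region"] = "tac"
    out = {}
    for region, sub in df.groupby("region", sort=False):
        schedule = FrameSchedule(sub["frame_start_s"].to_numpy(),
                                 sub["frame_end_s"].to_numpy())
        out[str(region)] = TimeActivityCurve(
            schedule, sub["value_kBq_per_mL"].to_numpy(), str(region))
    return out


def write_aif(path: PathLike, aif: ArterialInput) -> None:
    pd.DataFrame({"time_s": aif.times,
                  "value_kBq_per_mL": aif.values}).to_csv(path, sep="\t",
                                                          index=False)


def read_aif(path: PathLike) -> ArterialInput:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "value_kBq_per_mL"}.issubset(df.columns):
        raise ValueError("AIF table must have columns time_s, value_kBq_per_mL")
    return ArterialInput(df["time_s"].to_numpy(),
                         df["value_kBq_per_mL"].to_numpy())


# -- grid configuration ---------------------------------------------------

def grid_config_to_dict(grid: GridConfig) -> dict:
    return {
        "k2": {"values": [float(v) for v in grid.k2]},
        "tc": {"values": [float(v) for v in grid.tc]},
        "td": {"values": [float(v) for v in grid.td]},
        "weighting": grid.weighting,
        "nonneg": grid.nonneg,
    }


def _axis_values(axis: dict, geometric: bool) -> np.ndarray:
    if "values" in axis:
        return np.asarray(axis["values"], dtype=float)
    lo, hi = float(axis["min"]), float(axis["max"])
    if geometric:
        return np.geomspace(lo, hi, int(axis["num"]))
    step = float(axis["step"])
    return np.arange(lo, hi + 1e-9, step)


def grid_config_from_dict(d: dict) -> GridConfig:
    """Build a GridConfig from a mapping; axes accept either explicit
    ``values`` or ``min``/``max`` with ``num`` (k2, geometric) or ``step``
    (Tc/td, linear)."""
    return GridConfig(
        k2=_axis_values(d["k2"], geometric=True),
        tc=_axis_values(d.get("tc", {"values": [0.0]}), geometric=False),
        td=_axis_values(d.get("td", {"values": [0.0]}), geometric=False),
        weighting=d.get("weighting", "frame_duration"),
        nonneg=bool(d.get("nonneg", True)),
    )


def load_grid_config(path: PathLike) -> GridConfig:
    with open(path) as fh:
        return grid_config_from_dict(yaml.safe_load(fh))


def save_grid_config(path: PathLike, grid: GridConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(grid_config_to_dict(grid), fh)


# -- volumes --------------------------------------------------------------

def _sidecar_path(nii_path: PathLike) -> Path:
    p = Path(nii_path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def save_dynamic_image(img: DynamicImage, path: PathLike) -> None:
    """Write a 4D NIfTI plus a JSON sidecar with the frame schedule."""
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), img.affine),
             str(path))
    meta = {"frame_starts_s": img.schedule.starts.tolist(),
            "frame_ends_s": img.schedule.ends.tolist(),
            "voxel_size_mm": img.voxel_size_mm}
    _sidecar_path(path).write_text(json.dumps(meta))


def load_dynamic_image(path: PathLike,
                       schedule_path: PathLike | None = None,
                       mask: np.ndarray | None = None) -> DynamicImage:
    nii = nib.load(str(path))
    meta = json.loads(Path(schedule_path or _sidecar_path(path)).read_text())
    schedule = FrameSchedule(np.asarray(meta["frame_starts_s"]),
                             np.asarray(meta["frame_ends_s"]))
    return DynamicImage(np.asarray(nii.dataobj, dtype=float), schedule,
                        voxel_size_mm=float(meta.get("voxel_size_mm", 4.0)),
                        mask=mask)


def save_labels(labels: np.ndarray, path: PathLike,
                voxel_size_mm: float = 4.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def load_labels(path: PathLike) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_parametric_maps(maps: ParametricMaps, outdir: PathLike,
                          prefix: str = "param") -> list[Path]:
    """One NIfTI per parameter, filename-suffixed by the parameter name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([maps.voxel_size_mm] * 3 + [1.0])
    written = []
    for name in maps.keys():
        p = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(maps[name].astype(np.float32), affine), str(p))
        written.append(p)
    return written
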