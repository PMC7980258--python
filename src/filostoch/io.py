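"""File round-trips: trajectory CSV, FLS record CSV, FRAP CSV, YAML configs,
TIFF stacks and the supplementary spreadsheet loader."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frap import FrapTrace
from .model import GrowthModelParams, LengthTrajectory

__all__ = [
    "trajectories_to_frame",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "read_records_csv",
    "write_records_csv",
    "read_frap_csv",
    "load_params_yaml",
    "save_params_yaml",
    "write_tiff",
    "read_tiff",
    "load_supplementary_dataset",
]

FRAP_COLUMNS = [
    "time_s",
    "bleached",
    "unbleached",
    "background_bleached",
    "background_unbleached",
]


def trajectories_to_frame(trajectories: list[LengthTrajectory]) -> pd.DataFrame:
    frames = []
    for tr in trajectories:
        vel = tr.velocities()
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": tr.id,
                    "t_min": tr.times,
                    "length_um": tr.lengths,
                    "velocity_um_per_min": vel,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trajectories_csv(trajectories: list[LengthTrajectory], path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_trajectories_csv(path, source: str = "measured") -> list[LengthTrajectory]:
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("trajectory_id", sort=False):
        out.append(
            LengthTrajectory(
                id=str(tid),
                times=g["t_min"].to_numpy(float),
                lengths=g["length_um"].to_numpy(float),
                source=source,
            )
        )
    return out


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_frap_csv(path) -> FrapTrace:
    df = pd.read_csv(path)
    missing = set(FRAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"FRAP CSV missing columns: {sorted(missing)}")
    return FrapTrace(
        time_s=df["time_s"].to_numpy(float),
        bleached=df["bleached"].to_numpy(float),
        unbleached=df["unbleached"].to_numpy(float),
        background_bleached=df["background_bleached"].to_numpy(float),
        background_unbleached=df["background_unbleached"].to_numpy(float),
    )


def load_params_yaml(path) -> GrowthModelParams:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "baselines" in cfg and cfg["baselines"] is not None:
        cfg["baselines"] = np.asarray(cfg["baselines"], dtype=float)
    return GrowthModelParams(**cfg)


def save_params_yaml(params: GrowthModelParams, path) -> None:
    cfg = {
        "M": params.M,
        "N": params.N,
        "theta": params.theta,
        "eta": params.eta,
        "baselines": None if params.baselines is None else list(map(float, params.baselines)),
        "dt": params.dt,
        "duration": params.duration,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)


def write_tiff(stack: np.ndarray, path) -> None:
    """Write a grayscale 16-bit multi-page TIFF."""
    import tifffile

    arr = np.asarray(stack)
    arr = np.clip(arr, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def load_supplementary_dataset(path, dataset: int) -> pd.DataFrame:
    """Load one tab of the supplementary multi-tab spreadsheet by number.

    Tabs are named ``Dataset <n>`` (falling back to positional order when
    the names differ).  Requires the optional spreadsheet file; nothing in
    the package depends on it being present.
    """
    import openpyxl  # noqa: F401  (engine)

    xls = pd.ExcelFile(path)
    name = f"Dataset {dataset}"
    if name in xls.sheet_names:
        return xls.parse(name)
    if 1 <= dataset <= len(xls.sheet_names):
        return xls.parse(xls.sheet_names[dataset - 1])
    raise ValueError(f"dataset {dataset} not found in {path}")
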