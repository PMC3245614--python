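"""TIFF / CSV / YAML interchange.

One nucleus is one TIFF: axis 0 is the channel (0 = DAPI, 1 = probe), so a
2D scene is stored as (2, rows, cols) and a z-stack as
(2, planes, rows, cols).  Tabular outputs are CSV with unit-bearing column
names; configurations travel as YAML (JSON is a YAML subset and is accepted
transparently).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ConfigurationError
from .shells import ShellProfile
from .synthetic import NucleusImage, SceneConfig

__all__ = [
    "save_nucleus",
    "load_nucleus",
    "save_config",
    "load_config",
    "ground_truth_frame",
    "profiles_frame",
    "profiles_from_frame",
]


def save_nucleus(image: NucleusImage, path) -> None:
    """Write a nucleus as a channel-first TIFF."""
    stack = np.stack([image.dapi, image.probe]).astype(np.float32)
    tifffile.imwrite(str(path), stack)


def load_nucleus(path, pixel_size_xy: float, z_step: float | None = None,
                 nucleus_id: int = 0) -> NucleusImage:
    """Read a channel-first TIFF back into a :class:`NucleusImage`."""
    stack = tifffile.imread(str(path))
    if stack.ndim not in (3, 4) or stack.shape[0] != 2:
        raise ConfigurationError(
            f"{path}: expected a (2, ...) channel-first TIFF, got shape {stack.shape}"
        )
    if stack.ndim == 4:
        if z_step is None:
            raise ConfigurationError(f"{path}: z-stack input requires z_step")
        spacing = (float(z_step), float(pixel_size_xy), float(pixel_size_xy))
    else:
        spacing = (float(pixel_size_xy), float(pixel_size_xy))
    return NucleusImage(
        dapi=np.asarray(stack[0], dtype=np.float32),
        probe=np.asarray(stack[1], dtype=np.float32),
        spacing=spacing,
        nucleus_id=nucleus_id,
    )


def save_config(config: SceneConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["image_shape"] = list(d["image_shape"])
    d["nucleus_axes"] = list(d["nucleus_axes"])
    if not isinstance(d["radial_law"], str):
        d["radial_law"] = list(d["radial_law"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> SceneConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(SceneConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    if isinstance(raw.get("radial_law"), list):
        raw["radial_law"] = tuple(raw["radial_law"])
    return SceneConfig(**raw)


def ground_truth_frame(images: list[NucleusImage]) -> pd.DataFrame:
    """Tabulate generator ground truth (centers in μm, true r)."""
    rows = []
    for img in images:
        for gt in img.ground_truth or []:
            center = dict(zip(["center_z_um", "center_y_um", "center_x_um"][-len(gt.center_um):],
                              gt.center_um))
            rows.append({"nucleus_id": img.nucleus_id, "territory_id": gt.territory_id,
                         **center, "true_r": gt.r})
    return pd.DataFrame(rows)


def profiles_frame(profiles: list[ShellProfile]) -> pd.DataFrame:
    """Long-format shell profile table (one row per nucleus and shell)."""
    rows = []
    for p in profiles:
        for k in range(len(p.normalized)):
            rows.append(
                {
                    "nucleus_id": p.nucleus_id,
                    "shell": k + 1,
                    "dapi_pct": p.dapi_pct[k],
                    "probe_pct": p.probe_pct[k],
                    "normalized": p.normalized[k],
                }
            )
    return pd.DataFrame(rows)


def profiles_from_frame(frame: pd.DataFrame) -> list[ShellProfile]:
    """Rebuild per-nucleus profiles from a long-format table."""
    required = {"nucleus_id", "shell", "dapi_pct", "probe_pct", "normalized"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"profile table is missing columns {sorted(missing)}")
    profiles = []
    for nucleus_id, grp in frame.groupby("nucleus_id", sort=True):
        grp = grp.sort_values("shell")
        profiles.append(
            ShellProfile(
                nucleus_id=int(nucleus_id),
                dapi_pct=grp["dapi_pct"].to_numpy(float),
                probe_pct=grp["probe_pct"].to_numpy(float),
                normalized=grp["normalized"].to_numpy(float),
            )
        )
    return profiles
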