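"""Readers and writers: TIFF image sets with manifests, tables, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import ChannelImage, ImageSet

__all__ = [
    "write_image_set",
    "read_image_set",
    "read_config",
    "write_localizations",
    "read_localizations",
]

MANIFEST_COLUMNS = ["file", "channel", "round", "well", "image_id", "pixel_size_nm"]


def write_image_set(image_set: ImageSet, out_dir: str | Path) -> Path:
    """Write each plane as TIFF plus a manifest CSV mapping file -> metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(image_set.images):
        name = f"{im.well}_r{im.round_id}_{im.channel}_{i}.tif"
        tifffile.imwrite(out / name, im.data.astype(np.float32))
        rows.append(
            {
                "file": name,
                "channel": im.channel,
                "round": im.round_id,
                "well": im.well,
                "image_id": im.image_id,
                "pixel_size_nm": image_set.pixel_size_nm,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_image_set(manifest: str | Path) -> ImageSet:
    """Load an image set from a manifest CSV (file, channel, round, well, ...)."""
    manifest = Path(manifest)
    tab = pd.read_csv(manifest, dtype={"round": str, "image_id": str, "well": str})
    missing = [c for c in ("file", "channel") if c not in tab.columns]
    if missing:
        raise ValueError(f"manifest lacks required columns: {missing}")
    px = tab["pixel_size_nm"].unique() if "pixel_size_nm" in tab.columns else [187.0]
    if len(px) > 1:
        raise ValueError(f"mixed pixel sizes in one image set: {sorted(px)}")
    images = []
    for _, row in tab.iterrows():
        path = manifest.parent / row["file"]
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file: {path}")
        images.append(
            ChannelImage(
                data=tifffile.imread(path).astype(float),
                channel=str(row["channel"]),
                round_id=str(row.get("round", "0")),
                well=str(row.get("well", "A1")),
                image_id=str(row.get("image_id", "0")),
            )
        )
    return ImageSet(images=images, pixel_size_nm=float(px[0]))


def read_config(path: str | Path) -> dict:
    """Read a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    locs.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    required = {"frame", "x_nm", "y_nm"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"localization table lacks columns: {sorted(missing)}")
    if not np.isfinite(tab[["x_nm", "y_nm"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in localization table")
    if (tab["frame"] < 0).any():
        raise ValueError("negative frame indices in localization table")
    return tab
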