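"""Readers and writers: TIFF galleries, manifest/feature/truth CSV, YAML config.

The interchange format for object imagery is one single-page grayscale
TIFF per object plus a manifest CSV (``object_id, file, pixel_area_um2,
channel``); proprietary instrument containers are out of scope and are
expected to be exported to TIFF upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, GalleryReadError, InvalidInputError
from .gating import GateConfig, PopulationSummary
from .masking import BinaryMask, ObjectImage

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = ["object_id", "file", "pixel_area_um2", "channel"]


def write_gallery(
    images: list[ObjectImage], out_dir: str | Path, *, manifest_name: str = MANIFEST_NAME
) -> Path:
    """Write one uint8 TIFF per object plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        fname = f"{img.object_id}.tif"
        data = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
        tifffile.imwrite(out / fname, data)
        rows.append(
            {
                "object_id": img.object_id,
                "file": fname,
                "pixel_area_um2": img.pixel_area,
                "channel": img.channel,
            }
        )
    manifest = out / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_gallery(manifest_path: str | Path) -> list[ObjectImage]:
    """Read a gallery back in manifest order.

    Rows referencing unreadable files are collected and reported together
    in a single :class:`GalleryReadError` naming each offending row.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except Exception as exc:  # noqa: BLE001 - reported as a parse error
        raise GalleryReadError(f"cannot parse manifest {manifest_path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS[:3] if c not in manifest.columns]
    if missing:
        raise GalleryReadError(f"manifest missing column(s): {missing}")
    if manifest["object_id"].duplicated().any():
        dupes = manifest.loc[manifest["object_id"].duplicated(), "object_id"].tolist()
        raise GalleryReadError(f"duplicate object_id(s) in manifest: {dupes}")

    base = manifest_path.parent
    images: list[ObjectImage] = []
    errors: list[str] = []
    for i, row in manifest.iterrows():
        path = base / str(row["file"])
        try:
            pixels = tifffile.imread(path).astype(float)
            images.append(
                ObjectImage(
                    pixels,
                    float(row["pixel_area_um2"]),
                    str(row["object_id"]),
                    str(row.get("channel", "polarised")),
                )
            )
        except Exception as exc:  # noqa: BLE001 - collected per row
            errors.append(f"row {i} (object_id={row['object_id']!r}): {exc}")
    if errors:
        raise GalleryReadError(
            "failed to read {} gallery row(s):\n  {}".format(
                len(errors), "\n  ".join(errors)
            )
        )
    return images


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Serialise a mask as a single-page binary (0/255) TIFF."""
    tifffile.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def read_mask(path: str | Path, kind: str = "object_tight") -> BinaryMask:
    return BinaryMask(tifffile.imread(Path(path)) > 0, kind)


def load_config(path: str | Path | None = None) -> GateConfig:
    """Load a YAML/JSON gate configuration; unset fields take the defaults.

    ``None`` or an empty file yields the default (field-template) config.
    """
    if path is None:
        return GateConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return GateConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return GateConfig.from_dict(data)


def save_config(config: GateConfig, path: str | Path) -> None:
    """Write a fully materialised gate configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    if "object_id" not in table.columns:
        raise InvalidInputError("feature table missing 'object_id' column")
    return table


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(Path(path), index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_summary(summary: PopulationSummary, path: str | Path) -> None:
    Path(path).write_text(summary.to_json(indent=2, sort_keys=True) + "\n")


def read_calibration_pairs(path: str | Path) -> pd.DataFrame:
    """Read (species, coccosphere_d_um, cell_d_um) pairs from CSV."""
    pairs = pd.read_csv(Path(path))
    missing = [c for c in ("coccosphere_d_um", "cell_d_um") if c not in pairs.columns]
    if missing:
        raise InvalidInputError(f"calibration CSV missing column(s): {missing}")
    return pairs


def write_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")
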