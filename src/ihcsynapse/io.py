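"""File I/O: OME-TIFF stacks, label masks, CSV tables, YAML configs.

Stacks are written as OME-TIFF with channel names and physical voxel sizes
in the metadata; cell delineations travel as a companion 16-bit label TIFF.
Reading refuses to proceed without voxel spacing (from metadata or an
explicit override), because every volume downstream would be wrong.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .stack import CHANNEL_ROLES, ImageStack

log = logging.getLogger(__name__)

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth",
    "read_truth",
    "MissingSpacingError",
    "ChannelMapError",
]


class MissingSpacingError(ValueError):
    """No physical voxel spacing in metadata and no override given."""


class ChannelMapError(ValueError):
    """Channel count and channel-role map do not agree."""


def _mask_path(path: Path) -> Path:
    return path.with_name(path.stem + "_labels.tif")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as OME-TIFF (+ companion label TIFF if masks exist).

    Channel order follows :data:`CHANNEL_ROLES` for roles present.
    """
    path = Path(path)
    roles = [r for r in CHANNEL_ROLES if r in stack.channels]
    roles += [r for r in stack.channels if r not in roles]
    data = np.stack([stack.channels[r] for r in roles], axis=0)  # (C, Z, Y, X)
    dz, dy, dx = stack.spacing_um
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": roles},
        },
    )
    if stack.cell_masks is not None:
        tifffile.imwrite(
            _mask_path(path),
            stack.cell_masks.astype(np.uint16),
            ome=True,
            photometric="minisblack",
            metadata={
                "axes": "ZYX",
                "PhysicalSizeX": dx,
                "PhysicalSizeY": dy,
                "PhysicalSizeZ": dz,
            },
        )
    return path


def _spacing_from_ome(tf: tifffile.TiffFile) -> Optional[Tuple[float, float, float]]:
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        px = meta["OME"]["Image"]
        if isinstance(px, list):
            px = px[0]
        px = px["Pixels"]
        return (
            float(px["PhysicalSizeZ"]),
            float(px["PhysicalSizeY"]),
            float(px["PhysicalSizeX"]),
        )
    except (TypeError, KeyError, ValueError):
        return None


def _channel_names_from_ome(tf: tifffile.TiffFile) -> Optional[List[str]]:
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        px = meta["OME"]["Image"]
        if isinstance(px, list):
            px = px[0]
        chans = px["Pixels"]["Channel"]
        if isinstance(chans, dict):
            chans = [chans]
        names = [c.get("Name") for c in chans]
        if all(names):
            return [str(n) for n in names]
    except (TypeError, KeyError):
        pass
    return None


def read_stack(
    path,
    channel_map: Optional[Sequence[str]] = None,
    spacing_override: Optional[Tuple[float, float, float]] = None,
    masks_path=None,
    stack_id: Optional[str] = None,
) -> ImageStack:
    """Read an OME-TIFF stack.

    ``channel_map`` lists the role of each channel in order; if omitted,
    channel names are taken from the OME metadata and must match the
    canonical roles.  Spacing comes from metadata unless
    ``spacing_override`` (dz, dy, dx in µm) is given; stacks without
    either are rejected.  A companion ``*_labels.tif`` is loaded as cell
    masks when present (or pass ``masks_path``).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = spacing_override or _spacing_from_ome(tf)
        names = channel_map or _channel_names_from_ome(tf)
    if spacing is None:
        raise MissingSpacingError(
            f"{path}: no physical voxel spacing in metadata; pass "
            "spacing_override=(dz, dy, dx) — volumes would be wrong otherwise"
        )
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a (C, Z, Y, X) stack, got {data.shape}")
    if names is None:
        raise ChannelMapError(
            f"{path}: no channel names in metadata; pass channel_map"
        )
    if len(names) != data.shape[0]:
        raise ChannelMapError(
            f"{path}: {data.shape[0]} channel(s) but {len(names)} role(s) mapped"
        )
    channels = {str(n): data[i].astype(np.float32) for i, n in enumerate(names)}
    masks = None
    mp = Path(masks_path) if masks_path else _mask_path(path)
    if mp.exists():
        masks = tifffile.imread(mp).astype(np.uint16)
        if masks.shape != data.shape[1:]:
            raise ValueError(
                f"{mp}: mask shape {masks.shape} != stack shape {data.shape[1:]}"
            )
    return ImageStack(
        channels=channels,
        spacing_um=tuple(float(s) for s in spacing),
        cell_masks=masks,
        stack_id=stack_id or path.stem,
    )


def write_truth(truth: pd.DataFrame, path) -> Path:
    """Ground truth as CSV with the documented column order."""
    path = Path(path)
    truth.to_csv(path, index=False)
    return path


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
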