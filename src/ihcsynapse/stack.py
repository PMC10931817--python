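"""Core in-memory containers: multichannel image stacks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = ["CHANNEL_ROLES", "ImageStack"]

#: Canonical channel roles: presynaptic ribbons (CtBP2-like), postsynaptic
#: receptor patches (GluR2-like) and the hair-cell body marker.
CHANNEL_ROLES = ("presynaptic", "postsynaptic", "haircell")


@dataclass
class ImageStack:
    """A 3-channel confocal stack with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping from channel role to a float array with axes (z, y, x).
    spacing_um
        Voxel spacing (dz, dy, dx) in µm; strictly positive.
    cell_masks
        Integer label volume of per-cell delineations (0 = background);
        labels are disjoint by construction of a label image.
    stack_id
        Identifier carried into every downstream table row.
    meta
        Free-form provenance (animal id, location, age group, generator
        profile, frame metadata, ...).
    """

    channels: Dict[str, np.ndarray]
    spacing_um: Tuple[float, float, float]
    cell_masks: Optional[np.ndarray] = None
    stack_id: str = "stack"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three strictly positive values")
        shapes = {role: arr.shape for role, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.cell_masks is not None:
            first = next(iter(self.channels.values()), None)
            if first is not None and self.cell_masks.shape != first.shape:
                raise ValueError("cell_masks shape differs from channel shape")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(
                f"stack {self.stack_id!r} has no {role!r} channel "
                f"(present: {sorted(self.channels)})"
            )
        return self.channels[role]

    def cell_ids(self):
        if self.cell_masks is None:
            return []
        ids = np.unique(self.cell_masks)
        return [int(i) for i in ids if i != 0]
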