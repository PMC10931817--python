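"""Per-hair-cell anatomical coordinate frames and side classification.

Each inner hair cell (IHC) gets its own orthonormal frame spanned by three
anatomical axes: apex→base along the cell row (``a``), modiolar→pillar
(``m``) and top→bottom (``t``).  Synapse positions are expressed as
fractions of the cell's extent along ``m`` and ``t`` ("normalized
position"), and the modiolar/pillar side label is simply which half of the
modiolar–pillar extent the synapse centre falls into.

All vectors live in physical µm space with (z, y, x) component order,
matching the voxel array axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "HairCellFrame",
    "NormalizedPosition",
    "FrameError",
    "fit_cell_frame",
    "normalize_position",
    "classify_side",
    "frame_coords",
    "frame_point",
]

MODIOLAR = "modiolar"
PILLAR = "pillar"


class FrameError(ValueError):
    """Raised when a cell mask cannot support a well-defined frame."""


@dataclass
class HairCellFrame:
    """Anatomical frame of one IHC.

    ``origin`` sits at the apex-most / modiolar-most / top-most corner so
    that frame coordinates run from 0 to ``extent`` along each axis.
    """

    cell_id: int
    origin_um: np.ndarray          # (z, y, x) µm
    axis_apexbase: np.ndarray      # unit, apex -> base
    axis_modpil: np.ndarray        # unit, modiolar -> pillar
    axis_topbottom: np.ndarray     # unit, top -> bottom (basolateral at 1)
    extent_um: Tuple[float, float, float]  # along (a, m, t)

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        self.axis_apexbase = np.asarray(self.axis_apexbase, dtype=float)
        self.axis_modpil = np.asarray(self.axis_modpil, dtype=float)
        self.axis_topbottom = np.asarray(self.axis_topbottom, dtype=float)
        A = np.stack([self.axis_apexbase, self.axis_modpil, self.axis_topbottom])
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise FrameError(f"cell {self.cell_id}: axes are not orthonormal")
        if any(e <= 0 for e in self.extent_um):
            raise FrameError(f"cell {self.cell_id}: extents must be positive")

    @property
    def center_um(self) -> np.ndarray:
        ea, em, et = self.extent_um
        return (
            self.origin_um
            + 0.5 * ea * self.axis_apexbase
            + 0.5 * em * self.axis_modpil
            + 0.5 * et * self.axis_topbottom
        )


@dataclass
class NormalizedPosition:
    """Position as fractions of the cell extent (0..1, clamped)."""

    u_mp: float   # 0 = modiolar extreme, 1 = pillar extreme
    u_tb: float   # 0 = top, 1 = bottom (basolateral)
    clamped: bool = False


def frame_coords(point_um, frame: HairCellFrame) -> np.ndarray:
    """Unclamped frame coordinates (u_a, u_mp, u_tb) of a physical point."""
    d = np.asarray(point_um, dtype=float) - frame.origin_um
    ea, em, et = frame.extent_um
    return np.array(
        [
            float(d @ frame.axis_apexbase) / ea,
            float(d @ frame.axis_modpil) / em,
            float(d @ frame.axis_topbottom) / et,
        ]
    )


def frame_point(u, frame: HairCellFrame) -> np.ndarray:
    """Inverse of :func:`frame_coords`: physical point from (u_a, u_mp, u_tb)."""
    ua, ump, utb = u
    ea, em, et = frame.extent_um
    return (
        frame.origin_um
        + ua * ea * frame.axis_apexbase
        + ump * em * frame.axis_modpil
        + utb * et * frame.axis_topbottom
    )


def normalize_position(point_um, frame: HairCellFrame) -> NormalizedPosition:
    """Normalize a physical point to the cell's modiolar–pillar and
    top–bottom extents, clamping to [0, 1] (clamping is flagged/logged)."""
    _, u_mp, u_tb = frame_coords(point_um, frame)
    clamped = not (0.0 <= u_mp <= 1.0 and 0.0 <= u_tb <= 1.0)
    if clamped:
        log.debug(
            "cell %d: normalized position (%.3f, %.3f) clamped to [0,1]",
            frame.cell_id, u_mp, u_tb,
        )
    return NormalizedPosition(
        u_mp=float(min(1.0, max(0.0, u_mp))),
        u_tb=float(min(1.0, max(0.0, u_tb))),
        clamped=clamped,
    )


def classify_side(pos: NormalizedPosition) -> str:
    """Modiolar vs pillar half of the cell.

    The boundary sits at the midpoint of the modiolar–pillar extent;
    a centre exactly on the boundary is labelled pillar (fixed,
    documented tie-break — a probability-zero event on continuous data).
    """
    return MODIOLAR if pos.u_mp < 0.5 else PILLAR


def fit_cell_frame(
    cell_mask: np.ndarray,
    spacing_um,
    row_direction_hint=(0.0, 0.0, 1.0),
    basal_direction_hint=(0.0, 1.0, 0.0),
    modiolar_direction_hint: Optional[Tuple[float, float, float]] = None,
    cell_id: int = 0,
) -> HairCellFrame:
    """Fit an anatomical frame to a delineated cell mask.

    The top→bottom axis is the principal axis of the mask's voxel cloud
    (IHCs are elongated along it), oriented so the basolateral,
    synapse-bearing end maps to coordinate 1 using ``basal_direction_hint``.
    The apex→base axis is the row direction hint (e.g. the direction
    through neighbouring cell centroids) orthogonalised against the
    principal axis; the modiolar→pillar axis completes the right-handed
    triad and is sign-fixed by ``modiolar_direction_hint``, a vector
    pointing toward the modiolus (the axis itself points modiolar→pillar,
    i.e. away from the hint).  Sign conventions cannot be recovered from a
    bare mask, hence the hints.

    Extents are the mask's span along each axis.
    """
    spacing = np.asarray(spacing_um, dtype=float)
    idx = np.argwhere(cell_mask)
    if idx.shape[0] < 8:
        raise FrameError(f"cell {cell_id}: mask too small to fit a frame")
    pts = idx * spacing
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise FrameError(f"cell {cell_id}: degenerate (collinear/coplanar) mask")
    t = evecs[:, 2]  # principal axis (largest eigenvalue)
    basal = np.asarray(basal_direction_hint, dtype=float)
    if t @ basal < 0:
        t = -t
    hint = np.asarray(row_direction_hint, dtype=float)
    a = hint - (hint @ t) * t
    na = np.linalg.norm(a)
    if na < 1e-9:
        raise FrameError(
            f"cell {cell_id}: row direction hint is parallel to the cell axis"
        )
    a = a / na
    m = np.cross(t, a)
    m /= np.linalg.norm(m)
    if modiolar_direction_hint is not None:
        d = np.asarray(modiolar_direction_hint, dtype=float)
        if m @ d > 0:  # m must point away from the modiolus
            m = -m
            # keep handedness consistent by flipping a as well
            a = -a
    proj = (pts - center) @ np.stack([a, m, t]).T
    span = proj.max(axis=0) - proj.min(axis=0)
    extent = tuple(float(s) for s in span)
    origin = (
        center
        + proj.min(axis=0)[0] * a
        + proj.min(axis=0)[1] * m
        + proj.min(axis=0)[2] * t
    )
    return HairCellFrame(
        cell_id=cell_id,
        origin_um=origin,
        axis_apexbase=a,
        axis_modpil=m,
        axis_topbottom=t,
        extent_um=extent,
    )
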