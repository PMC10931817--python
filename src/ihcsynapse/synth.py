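"""Synthetic cochlear confocal stacks with planted ground truth.

The study's microscopy data are not deposited, so every pipeline stage is
exercised against simulated specimens instead: rows of ellipsoidal inner
hair cells along the apex–base axis, paired pre/postsynaptic puncta planted
on the basolateral third of each cell's surface with per-side count and
volume laws, rendered into a three-channel voxel volume with Gaussian PSF
blur, background and photon-counting noise, and (for aged profiles)
broad-spectrum lipofuscin-like distractor blobs.

Ground truth (cell assignment, side, normalized position, true volumes,
centre coordinates) is returned as a tidy table so that detection,
colocalization, side classification and cohort statistics can all be
validated end to end.

Hierarchy of randomness: a master seed spawns independent substreams per
animal and per stack (``numpy.random.SeedSequence``), so cohorts are
reproducible stack-by-stack.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import HairCellFrame, MODIOLAR, PILLAR, frame_point
from .profiles import GeneratorProfile
from .stack import ImageStack

log = logging.getLogger(__name__)

__all__ = [
    "make_cell_row",
    "plant_synapses",
    "render_stack",
    "simulate_stack",
    "generate_cohort",
    "iter_cohort",
    "simulate_cohort_counts",
    "SizingError",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "kind", "cell_id", "side", "u_mp", "u_tb",
    "pre_vol_um3", "post_vol_um3",
    "cz_um", "cy_um", "cx_um",
    "pre_cz_um", "pre_cy_um", "pre_cx_um",
    "post_cz_um", "post_cy_um", "post_cx_um",
]

# world axes in (z, y, x) vector components: the cell row runs along x,
# the cell's long (top->bottom) axis along y, modiolar->pillar along z
_AX_ROW = np.array([0.0, 0.0, 1.0])
_AX_TB = np.array([0.0, 1.0, 0.0])
_AX_MP = np.array([1.0, 0.0, 0.0])
#: vector pointing toward the modiolus in generated stacks (low z side)
MODIOLAR_DIRECTION = (-1.0, 0.0, 0.0)


class SizingError(ValueError):
    """Requested cell row does not fit the allowed stack geometry."""


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# cell row geometry


def required_shape(n_cells: int, profile: GeneratorProfile) -> Tuple[int, int, int]:
    """Voxel shape (z, y, x) needed for ``n_cells`` ellipsoidal cells."""
    dz, dy, dx = profile.spacing_um
    sz, sy, sx = profile.cell_semi_axes_um
    mz, my, mx = profile.margin_um
    ext_z = 2 * sz + 2 * mz
    ext_y = 2 * sy + 2 * my
    ext_x = n_cells * profile.cell_pitch_um + 2 * mx
    return (
        int(math.ceil(ext_z / dz)),
        int(math.ceil(ext_y / dy)),
        int(math.ceil(ext_x / dx)),
    )


def make_cell_row(
    n_cells: int,
    profile: GeneratorProfile,
    rng=None,
    max_shape: Optional[Tuple[int, int, int]] = None,
) -> Tuple[np.ndarray, List[HairCellFrame]]:
    """Build a row of ellipsoidal IHC masks along the apex–base axis.

    Returns a uint16 label volume (0 = background, cells labelled 1..n)
    and one anatomical frame per cell.  Cell semi-axes receive a small
    (±4 %) deterministic jitter so cells are not identical.

    Raises :class:`SizingError` if ``max_shape`` is given and the row
    does not fit, naming the limiting dimension.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(rng if rng is not None else profile.seed)
    shape = required_shape(n_cells, profile)
    if max_shape is not None:
        for axname, need, have in zip("zyx", shape, max_shape):
            if need > have:
                raise SizingError(
                    f"{n_cells} cells need {need} voxels along {axname}, "
                    f"only {have} available"
                )
    dz, dy, dx = profile.spacing_um
    spacing = np.array([dz, dy, dx])
    labels = np.zeros(shape, dtype=np.uint16)
    frames: List[HairCellFrame] = []
    mz, my, mx = profile.margin_um
    sz0, sy0, sx0 = profile.cell_semi_axes_um
    cz = mz + sz0
    cy = my + sy0
    for i in range(n_cells):
        jit = 1.0 + 0.04 * rng.uniform(-1, 1, size=3)
        sz, sy, sx = sz0 * jit[0], sy0 * jit[1], sx0 * jit[2]
        cx = mx + (i + 0.5) * profile.cell_pitch_um
        center = np.array([cz, cy, cx])
        semi = np.array([sz, sy, sx])
        lo = np.maximum(((center - semi) / spacing).astype(int) - 1, 0)
        hi = np.minimum(
            ((center + semi) / spacing).astype(int) + 2, np.array(shape)
        )
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        d2 = (
            ((zz * dz - center[0]) / sz) ** 2
            + ((yy * dy - center[1]) / sy) ** 2
            + ((xx * dx - center[2]) / sx) ** 2
        )
        inside = d2 <= 1.0
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if (sub[inside] != 0).any():
            raise SizingError("cells overlap; decrease semi-axes or raise pitch")
        sub[inside] = i + 1
        origin = center - sx * _AX_ROW - sz * _AX_MP - sy * _AX_TB
        frames.append(
            HairCellFrame(
                cell_id=i + 1,
                origin_um=origin,
                axis_apexbase=_AX_ROW.copy(),
                axis_modpil=_AX_MP.copy(),
                axis_topbottom=_AX_TB.copy(),
                extent_um=(2 * sx, 2 * sz, 2 * sy),
            )
        )
    return labels, frames


# ---------------------------------------------------------------------------
# synapse planting


def _truncated_lognormal(rng, median, sigma, floor, size):
    v = median * np.exp(sigma * rng.standard_normal(size))
    return np.maximum(v, floor)


def _correlated_volumes(rng, n, pre_median, post_median, sigma, rho_s, floor):
    """Lognormal pre/post volumes tied by a Gaussian copula.

    The normal-scores correlation is chosen so the *rank* correlation of
    the pair hits the requested Spearman target:
    rho_s = (6/pi) asin(rho_g / 2)  =>  rho_g = 2 sin(pi rho_s / 6).
    """
    if n == 0:
        return np.empty(0), np.empty(0)
    rho_g = 2.0 * math.sin(math.pi * rho_s / 6.0)
    g1 = rng.standard_normal(n)
    g2 = rho_g * g1 + math.sqrt(max(0.0, 1.0 - rho_g**2)) * rng.standard_normal(n)
    pre = np.maximum(pre_median * np.exp(sigma * g1), floor)
    post = np.maximum(post_median * np.exp(sigma * g2), floor)
    return pre, post


def _sample_surface_points(
    rng, frame: HairCellFrame, n, side, profile: GeneratorProfile,
    existing: List[np.ndarray],
):
    """Dart-throw ``n`` synapse sites on the basolateral band of one side.

    Points live on the cell's ellipsoid surface, restricted to the
    basolateral top→bottom band and to the requested modiolar/pillar
    band (with margins so the planted side is unambiguous), with a
    hard-core minimum separation against all previously placed sites of
    the same cell.  Returns surface points and outward unit normals.
    """
    lo_tb, hi_tb = profile.basolateral_band
    lo_s, hi_s = profile.side_band
    if side == MODIOLAR:
        lo_mp, hi_mp = lo_s, hi_s
    else:
        lo_mp, hi_mp = 1.0 - hi_s, 1.0 - lo_s
    ea, em, et = frame.extent_um
    semi = np.array([ea, em, et]) / 2.0
    center = frame.center_um
    A = np.stack([frame.axis_apexbase, frame.axis_modpil, frame.axis_topbottom])
    pts, normals, us = [], [], []
    kept = list(existing)
    min_sep = profile.min_separation_um
    attempts = 0
    while len(pts) < n and attempts < 200:
        attempts += 1
        xi = rng.standard_normal((256, 3))
        xi /= np.linalg.norm(xi, axis=1, keepdims=True)
        u_mp = (xi[:, 1] + 1) / 2
        u_tb = (xi[:, 2] + 1) / 2
        ok = (u_tb >= lo_tb) & (u_tb <= hi_tb) & (u_mp >= lo_mp) & (u_mp <= hi_mp)
        for j in np.flatnonzero(ok):
            if len(pts) >= n:
                break
            p = center + (xi[j] * semi) @ A
            if kept and min(
                float(np.linalg.norm(p - q)) for q in kept
            ) < min_sep:
                continue
            grad = (xi[j] / semi) @ A  # ellipsoid surface normal direction
            normal = grad / np.linalg.norm(grad)
            pts.append(p)
            normals.append(normal)
            us.append((float(u_mp[j]), float(u_tb[j])))
            kept.append(p)
    if len(pts) < n:
        log.warning(
            "cell %d/%s: placed %d of %d synapses (hard-core packing limit)",
            frame.cell_id, side, len(pts), n,
        )
    return pts, normals, us


def plant_synapses(
    frames: Sequence[HairCellFrame],
    profile: GeneratorProfile,
    rng=None,
    count_scale: float = 1.0,
) -> pd.DataFrame:
    """Plant paired pre/postsynaptic elements on each cell and record truth.

    Per cell, modiolar and pillar counts are Poisson draws around the
    profile expectations (optionally scaled by an animal-level frailty
    ``count_scale``).  Each pair sits on the basolateral third of the
    cell surface: the presynaptic ribbon 0.20 µm inside the membrane and
    the postsynaptic patch 0.05 µm outside, i.e. centres 0.25 µm apart,
    forcing zero-gap colocalization of true pairs.  Volumes follow the
    profile's right-skewed law with the requested pre/post rank
    correlation.  Lipofuscin-like distractors are planted inside the cell
    body at ``lipofuscin_rate`` per cell with volumes above the synaptic
    range.

    Returns a ground-truth table with one row per planted element pair
    (kind ``synapse``) or distractor (kind ``lipofuscin``).
    """
    rng = _rng(rng if rng is not None else profile.seed)
    rows = []
    rho = profile.pre_post_volume_correlation
    for frame in frames:
        placed: List[np.ndarray] = []
        for side in (MODIOLAR, PILLAR):
            lam = count_scale * (
                profile.expected_count_modiolar
                if side == MODIOLAR
                else profile.expected_count_pillar
            )
            k = int(rng.poisson(lam)) if lam > 0 else 0
            if k == 0:
                continue
            pts, normals, us = _sample_surface_points(
                rng, frame, k, side, profile, placed
            )
            placed.extend(pts)
            med_pre = (
                profile.pre_volume_median_modiolar
                if side == MODIOLAR
                else profile.pre_volume_median_pillar
            )
            med_post = (
                profile.post_volume_median_modiolar
                if side == MODIOLAR
                else profile.post_volume_median_pillar
            )
            pre_v, post_v = _correlated_volumes(
                rng, len(pts), med_pre, med_post,
                profile.volume_log_sigma, rho, profile.min_volume_um3,
            )
            for i, (p, nrm, (u_mp, u_tb)) in enumerate(zip(pts, normals, us)):
                pre_c = p - 0.20 * nrm
                post_c = p + 0.05 * nrm
                rows.append(
                    dict(
                        kind="synapse",
                        cell_id=frame.cell_id,
                        side=side,
                        u_mp=u_mp,
                        u_tb=u_tb,
                        pre_vol_um3=float(pre_v[i]),
                        post_vol_um3=float(post_v[i]),
                        cz_um=p[0], cy_um=p[1], cx_um=p[2],
                        pre_cz_um=pre_c[0], pre_cy_um=pre_c[1], pre_cx_um=pre_c[2],
                        post_cz_um=post_c[0], post_cy_um=post_c[1], post_cx_um=post_c[2],
                    )
                )
        # lipofuscin-like broad-spectrum distractors inside the cell body
        if profile.lipofuscin_rate > 0:
            n_lip = int(rng.poisson(profile.lipofuscin_rate))
            for _ in range(n_lip):
                u = rng.uniform(0.25, 0.75, size=3)  # interior, away from surface
                p = frame_point(u, frame)
                vol = float(
                    _truncated_lognormal(
                        rng,
                        profile.lipofuscin_volume_median,
                        profile.lipofuscin_log_sigma,
                        profile.lipofuscin_volume_floor,
                        1,
                    )[0]
                )
                rows.append(
                    dict(
                        kind="lipofuscin",
                        cell_id=frame.cell_id,
                        side="",
                        u_mp=float(u[1]),
                        u_tb=float(u[2]),
                        pre_vol_um3=vol,
                        post_vol_um3=vol,
                        cz_um=p[0], cy_um=p[1], cx_um=p[2],
                        pre_cz_um=p[0], pre_cy_um=p[1], pre_cx_um=p[2],
                        post_cz_um=p[0], post_cy_um=p[1], post_cx_um=p[2],
                    )
                )
    if not rows:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# rendering


#: PSF-edge calibration: a Gaussian-blurred step falls to the detection
#: floor roughly this many sigma outside the kernel boundary, so kernels
#: are pre-shrunk per axis to make the *suprathreshold* extent after blur
#: match the planted true volume.
EDGE_SIGMA = 1.7


def _render_kernel(channel, center_um, volume_um3, spacing, amplitude, shrink_um):
    """Add a compact kernel whose blurred suprathreshold extent matches
    the requested true volume.

    The kernel is an ellipsoid of nominal radius r = (3V/4π)^{1/3},
    shrunk along each axis by the PSF edge extension (the blur restores
    the extent when the channel is later thresholded).  A kernel whose
    voxelised extent would be empty is clamped to the single nearest
    voxel with a warning.
    """
    dz, dy, dx = spacing
    r = (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    semi = np.array(
        [max(r - s, 0.35 * sp) for s, sp in zip(shrink_um, spacing)]
    )
    shape = channel.shape
    lo = [max(0, int((c - a) / s) - 1) for c, a, s in zip(center_um, semi, spacing)]
    hi = [
        min(n, int((c + a) / s) + 2)
        for c, a, s, n in zip(center_um, semi, spacing, shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]) * dz,
        np.arange(lo[1], hi[1]) * dy,
        np.arange(lo[2], hi[2]) * dx,
        indexing="ij",
    )
    d2 = (
        ((zz - center_um[0]) / semi[0]) ** 2
        + ((yy - center_um[1]) / semi[1]) ** 2
        + ((xx - center_um[2]) / semi[2]) ** 2
    )
    inside = d2 <= 1.0
    if not inside.any():
        if volume_um3 < float(np.prod(spacing)):
            warnings.warn(
                f"planted volume {volume_um3:.4f} um^3 smaller than one "
                "voxel; clamped to the nearest voxel",
                stacklevel=2,
            )
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        inside[idx] = True
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][inside] += amplitude


def render_stack(
    truth: pd.DataFrame,
    masks: np.ndarray,
    profile: GeneratorProfile,
    rng=None,
    frames: Optional[Sequence[HairCellFrame]] = None,
    stack_id: str = "stack",
    meta: Optional[dict] = None,
) -> ImageStack:
    """Render planted truth into a noisy three-channel stack.

    Each element becomes a solid intensity sphere of its true volume,
    blurred with an anisotropic Gaussian PSF; background is added and
    photon-counting (Poisson) noise applied.  Lipofuscin distractors are
    rendered into all three channels (broad-spectrum autofluorescence).
    Deterministic given the random state.
    """
    rng = _rng(rng if rng is not None else profile.seed)
    spacing = profile.spacing_um
    shape = masks.shape
    pre = np.zeros(shape, dtype=np.float32)
    post = np.zeros(shape, dtype=np.float32)
    hc = np.zeros(shape, dtype=np.float32)
    hc[masks > 0] = profile.haircell_intensity
    amp = profile.peak_intensity
    # shrink kernels laterally by the PSF edge extension so thresholded
    # extents track true volumes; the axial grid is too coarse to shrink
    # without losing monotonicity of measured volume in true volume
    shrink = (0.0, EDGE_SIGMA * profile.psf_sigma_um[1],
              EDGE_SIGMA * profile.psf_sigma_um[2])
    for row in truth.itertuples(index=False):
        if row.kind == "synapse":
            _render_kernel(
                pre, (row.pre_cz_um, row.pre_cy_um, row.pre_cx_um),
                row.pre_vol_um3, spacing, amp, shrink,
            )
            _render_kernel(
                post, (row.post_cz_um, row.post_cy_um, row.post_cx_um),
                row.post_vol_um3, spacing, amp, shrink,
            )
        else:  # broad-spectrum distractor
            c = (row.cz_um, row.cy_um, row.cx_um)
            for ch in (pre, post, hc):
                _render_kernel(ch, c, row.pre_vol_um3, spacing, 0.7 * amp, shrink)
    sigma_vox = [s / d for s, d in zip(profile.psf_sigma_um, spacing)]
    for ch in (pre, post, hc):
        ndimage.gaussian_filter(ch, sigma=sigma_vox, output=ch, truncate=3.0)
    channels = {}
    s = profile.photon_noise_scale
    for role, ch in (("presynaptic", pre), ("postsynaptic", post), ("haircell", hc)):
        img = ch + profile.background_level
        if s > 0:
            img = rng.poisson(img * s).astype(np.float32) / s
        channels[role] = img.astype(np.float32)
    meta = dict(meta or {})
    meta.setdefault("profile", profile.name)
    meta.setdefault("modiolar_direction", list(MODIOLAR_DIRECTION))
    if frames is not None:
        meta["true_frames"] = frames
    return ImageStack(
        channels=channels,
        spacing_um=spacing,
        cell_masks=masks,
        stack_id=stack_id,
        meta=meta,
    )


def simulate_stack(
    profile: GeneratorProfile,
    n_cells: int,
    rng=None,
    count_scale: float = 1.0,
    stack_id: str = "stack",
    meta: Optional[dict] = None,
) -> Tuple[ImageStack, pd.DataFrame]:
    """Convenience: cell row + planting + rendering with one stream."""
    rng = _rng(rng if rng is not None else profile.seed)
    masks, frames = make_cell_row(n_cells, profile, rng=rng)
    truth = plant_synapses(frames, profile, rng=rng, count_scale=count_scale)
    stack = render_stack(
        truth, masks, profile, rng=rng, frames=frames,
        stack_id=stack_id, meta=meta,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts


def iter_cohort(
    profiles: Sequence[GeneratorProfile],
    n_animals_per_group: int,
    cells_per_animal: int,
    seed: int = 0,
) -> Iterator[Tuple[ImageStack, pd.DataFrame]]:
    """Yield one (stack, truth) per animal × location.

    Hierarchical design: animals belong to an age group and are imaged at
    every location of that group (a repeated-measures structure); each
    animal carries a lognormal multiplicative frailty on expected counts,
    shared across its locations and sides.  Per-stack random substreams
    are spawned from the master seed.
    """
    if n_animals_per_group < 1:
        raise ValueError("n_animals_per_group must be >= 1")
    groups: Dict[str, List[GeneratorProfile]] = {}
    for p in profiles:
        groups.setdefault(p.age_group, []).append(p)
    ss = np.random.SeedSequence(seed)
    group_streams = ss.spawn(len(groups))
    for g_i, (age_group, plist) in enumerate(sorted(groups.items())):
        animal_ss = group_streams[g_i].spawn(n_animals_per_group)
        for a_i in range(n_animals_per_group):
            animal_id = f"{age_group[:1].upper()}{a_i + 1:02d}"
            a_ss = animal_ss[a_i]
            frailty_rng = np.random.default_rng(a_ss)
            sigma = plist[0].count_noise
            frailty = float(
                np.exp(sigma * frailty_rng.standard_normal() - 0.5 * sigma**2)
            )
            stack_ss = a_ss.spawn(len(plist))
            for p_i, prof in enumerate(sorted(plist, key=lambda p: p.name)):
                rng = np.random.default_rng(stack_ss[p_i])
                stack_id = f"{animal_id}_{prof.location_label}"
                meta = dict(
                    animal_id=animal_id,
                    age_group=age_group,
                    location=prof.location_label,
                    frailty=frailty,
                    n_cells=cells_per_animal,
                    median_cells_per_animal=cells_per_animal,
                )
                stack, truth = simulate_stack(
                    prof, cells_per_animal, rng=rng,
                    count_scale=frailty, stack_id=stack_id, meta=meta,
                )
                yield stack, truth


def generate_cohort(
    profiles: Sequence[GeneratorProfile],
    n_animals_per_group: int,
    cells_per_animal: int,
    seed: int = 0,
) -> Tuple[List[ImageStack], List[pd.DataFrame]]:
    """Materialised version of :func:`iter_cohort` (memory permitting)."""
    stacks, truths = [], []
    for stack, truth in iter_cohort(
        profiles, n_animals_per_group, cells_per_animal, seed
    ):
        stacks.append(stack)
        truths.append(truth)
    return stacks, truths


def simulate_cohort_counts(
    profiles: Sequence[GeneratorProfile],
    n_animals_per_group: int,
    cells_per_animal: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Count-model-only cohort simulation (no image rendering).

    Draws the same hierarchical count model as :func:`iter_cohort`
    (per-animal lognormal frailty, per-cell Poisson per side) and returns
    a per-cell table with columns ``animal_id, age_group, location,
    cell_id, n_modiolar, n_pillar, n_total``.  Used for statistical
    calibration studies where rendering images would add nothing.
    """
    groups: Dict[str, List[GeneratorProfile]] = {}
    for p in profiles:
        groups.setdefault(p.age_group, []).append(p)
    ss = np.random.SeedSequence(seed)
    rows = []
    group_streams = ss.spawn(len(groups))
    for g_i, (age_group, plist) in enumerate(sorted(groups.items())):
        animal_ss = group_streams[g_i].spawn(n_animals_per_group)
        for a_i in range(n_animals_per_group):
            rng = np.random.default_rng(animal_ss[a_i])
            animal_id = f"{age_group[:1].upper()}{a_i + 1:02d}"
            sigma = plist[0].count_noise
            frailty = float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2))
            for prof in sorted(plist, key=lambda p: p.name):
                n_mod = rng.poisson(
                    frailty * prof.expected_count_modiolar, size=cells_per_animal
                )
                n_pil = rng.poisson(
                    frailty * prof.expected_count_pillar, size=cells_per_animal
                )
                for c in range(cells_per_animal):
                    rows.append(
                        dict(
                            animal_id=animal_id,
                            age_group=age_group,
                            location=prof.location_label,
                            cell_id=c + 1,
                            n_modiolar=int(n_mod[c]),
                            n_pillar=int(n_pil[c]),
                            n_total=int(n_mod[c] + n_pil[c]),
                        )
                    )
    return pd.DataFrame(rows)
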