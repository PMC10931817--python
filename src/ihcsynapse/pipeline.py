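"""End-to-end pipeline: detection → colocalization → classification → volumes.

`process_stack` runs every image-level stage on one stack and returns tidy
tables; `run_cohort` maps it over a simulated cohort and aggregates the
per-animal summaries that feed the statistics stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import synth
from .coloc import ColocalizationResult, colocalize
from .detect import DetectionConfig, Punctum, detect_channel
from .geometry import (
    HairCellFrame,
    classify_side,
    fit_cell_frame,
    frame_coords,
    normalize_position,
)
from .profiles import GeneratorProfile
from .stack import ImageStack
from .stats import summarize_cohort
from .volumetry import normalize_volumes

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StackResult",
    "process_stack",
    "run_cohort",
    "annotate_pairs_df",
    "normalize_pairs_df",
]


@dataclass
class PipelineConfig:
    """Image-level pipeline options.

    ``modiolar_direction`` is a (z, y, x) vector pointing toward the
    modiolus; it cannot be inferred from masks alone.  For generated
    stacks it defaults to the generator's convention.
    """

    detection: DetectionConfig = field(default_factory=lambda: DetectionConfig(
        max_volume_um3=1.5
    ))
    max_gap_um: float = 0.0
    refit_frames: bool = True
    row_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    basal_direction: Tuple[float, float, float] = (0.0, 1.0, 0.0)
    modiolar_direction: Optional[Tuple[float, float, float]] = None
    #: drop pairs whose centre lies further outside every cell than this
    max_cell_distance_um: float = 1.0

    def to_dict(self) -> dict:
        d = dict(
            detection=vars(self.detection).copy(),
            max_gap_um=self.max_gap_um,
            refit_frames=self.refit_frames,
            row_direction=list(self.row_direction),
            basal_direction=list(self.basal_direction),
            modiolar_direction=(
                list(self.modiolar_direction)
                if self.modiolar_direction is not None else None
            ),
            max_cell_distance_um=self.max_cell_distance_um,
        )
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StackResult:
    stack_id: str
    puncta: pd.DataFrame
    pairs: pd.DataFrame
    cells: pd.DataFrame
    provenance: dict


def _cell_frames(stack: ImageStack, config: PipelineConfig) -> List[HairCellFrame]:
    if not config.refit_frames and "true_frames" in stack.meta:
        return list(stack.meta["true_frames"])
    if stack.cell_masks is None:
        raise ValueError(f"stack {stack.stack_id!r} has no cell masks")
    mod_dir = config.modiolar_direction
    if mod_dir is None:
        mod_dir = stack.meta.get("modiolar_direction")
    if mod_dir is None:
        raise ValueError(
            "modiolar_direction must be configured (it cannot be inferred "
            "from a mask alone)"
        )
    frames = []
    for cid in stack.cell_ids():
        frames.append(
            fit_cell_frame(
                stack.cell_masks == cid,
                stack.spacing_um,
                row_direction_hint=config.row_direction,
                basal_direction_hint=config.basal_direction,
                modiolar_direction_hint=mod_dir,
                cell_id=cid,
            )
        )
    return frames


def _assign_cell(center_um, frames: Sequence[HairCellFrame], max_outside_um: float):
    """Nearest cell in normalized ellipsoidal metric; None if too far."""
    best, best_r = None, np.inf
    for f in frames:
        u = frame_coords(center_um, f)
        r = float(np.linalg.norm(2.0 * (u - 0.5)))
        if r < best_r:
            best, best_r = f, r
    if best is None:
        return None
    min_semi = min(best.extent_um) / 2.0
    if (best_r - 1.0) * min_semi > max_outside_um:
        return None
    return best


def _puncta_table(stack_id: str, puncta: Sequence[Punctum]) -> pd.DataFrame:
    rows = [
        dict(
            stack_id=stack_id,
            channel_role=p.channel_role,
            punctum_id=p.id,
            voxel_count=p.voxel_count,
            volume_um3=p.volume_um3,
            cz_um=float(p.centroid_um[0]),
            cy_um=float(p.centroid_um[1]),
            cx_um=float(p.centroid_um[2]),
        )
        for p in puncta
    ]
    return pd.DataFrame(rows)


def process_stack(
    stack: ImageStack, config: Optional[PipelineConfig] = None
) -> StackResult:
    """Run detection, pairing, side classification and volume
    normalization on one stack.

    Pairs are assigned to the nearest delineated cell (in each cell's
    own normalized ellipsoidal metric); pairs farther than
    ``max_cell_distance_um`` outside every cell are dropped and logged.
    Per-cell counts include cells with zero pairs.
    """
    config = config or PipelineConfig()
    meta = stack.meta
    pre, info_pre = detect_channel(stack, "presynaptic", config.detection)
    post, info_post = detect_channel(stack, "postsynaptic", config.detection)
    result: ColocalizationResult = colocalize(
        pre, post, stack.spacing_um, max_gap_um=config.max_gap_um
    )
    pairs = result.pairs
    frames = _cell_frames(stack, config)
    n_dropped = 0
    kept = []
    for pair in pairs:
        frame = _assign_cell(pair.center_um, frames, config.max_cell_distance_um)
        if frame is None:
            n_dropped += 1
            continue
        pair.cell_id = frame.cell_id
        pos = normalize_position(pair.center_um, frame)
        pair.u_mp, pair.u_tb = pos.u_mp, pos.u_tb
        pair.side = classify_side(pos)
        kept.append(pair)
    if n_dropped:
        log.info(
            "stack %s: dropped %d pair(s) not attributable to a cell",
            stack.stack_id, n_dropped,
        )
    medians = normalize_volumes(kept, stack_id=stack.stack_id) if kept else {}
    pair_rows = [
        dict(
            stack_id=stack.stack_id,
            animal_id=meta.get("animal_id", ""),
            age_group=meta.get("age_group", ""),
            location=meta.get("location", ""),
            cell_id=p.cell_id,
            side=p.side,
            u_mp=p.u_mp,
            u_tb=p.u_tb,
            gap_um=p.gap_um,
            pre_id=p.pre_id,
            post_id=p.post_id,
            pre_volume_um3=p.pre_volume_um3,
            post_volume_um3=p.post_volume_um3,
            pre_norm_volume=p.pre_norm_volume,
            post_norm_volume=p.post_norm_volume,
        )
        for p in kept
    ]
    pairs_df = pd.DataFrame(pair_rows)
    cell_rows = []
    for f in frames:
        sub = [p for p in kept if p.cell_id == f.cell_id]
        n_mod = sum(1 for p in sub if p.side == "modiolar")
        n_pil = sum(1 for p in sub if p.side == "pillar")
        cell_rows.append(
            dict(
                stack_id=stack.stack_id,
                animal_id=meta.get("animal_id", ""),
                age_group=meta.get("age_group", ""),
                location=meta.get("location", ""),
                cell_id=f.cell_id,
                n_modiolar=n_mod,
                n_pillar=n_pil,
                n_total=n_mod + n_pil,
            )
        )
    cells_df = pd.DataFrame(cell_rows)
    provenance = dict(
        stack_id=stack.stack_id,
        config_hash=config.config_hash(),
        thresholds=[info_pre, info_post],
        n_pre=len(pre),
        n_post=len(post),
        n_pairs=len(kept),
        n_orphan_pre=len(result.orphan_pre),
        n_orphan_post=len(result.orphan_post),
        n_dropped_pairs=n_dropped,
        volume_medians=medians,
    )
    puncta_df = pd.concat(
        [_puncta_table(stack.stack_id, pre), _puncta_table(stack.stack_id, post)],
        ignore_index=True,
    )
    return StackResult(
        stack_id=stack.stack_id,
        puncta=puncta_df,
        pairs=pairs_df,
        cells=cells_df,
        provenance=provenance,
    )


def annotate_pairs_df(
    pairs_df: pd.DataFrame, stack: ImageStack, config: Optional[PipelineConfig] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Cell assignment + side classification on a pair table (stage restarts).

    ``pairs_df`` needs centre columns ``cz_um, cy_um, cx_um``; rows not
    attributable to a cell are dropped.  Returns the annotated pair table
    and the per-cell count table (including zero-pair cells).
    """
    config = config or PipelineConfig()
    frames = _cell_frames(stack, config)
    meta = stack.meta
    rows = []
    for r in pairs_df.to_dict(orient="records"):
        center = np.array([r["cz_um"], r["cy_um"], r["cx_um"]])
        frame = _assign_cell(center, frames, config.max_cell_distance_um)
        if frame is None:
            continue
        pos = normalize_position(center, frame)
        r.update(
            cell_id=frame.cell_id,
            u_mp=pos.u_mp,
            u_tb=pos.u_tb,
            side=classify_side(pos),
        )
        rows.append(r)
    annotated = pd.DataFrame(rows)
    cell_rows = []
    for f in frames:
        sub = annotated[annotated["cell_id"] == f.cell_id] if len(annotated) else []
        n_mod = int((sub["side"] == "modiolar").sum()) if len(sub) else 0
        n_pil = int((sub["side"] == "pillar").sum()) if len(sub) else 0
        cell_rows.append(
            dict(
                stack_id=stack.stack_id,
                animal_id=meta.get("animal_id", ""),
                age_group=meta.get("age_group", ""),
                location=meta.get("location", ""),
                cell_id=f.cell_id,
                n_modiolar=n_mod,
                n_pillar=n_pil,
                n_total=n_mod + n_pil,
            )
        )
    return annotated, pd.DataFrame(cell_rows)


def normalize_pairs_df(pairs_df: pd.DataFrame) -> pd.DataFrame:
    """Per-stack median normalization on a pair table (stage restarts)."""
    if not len(pairs_df):
        return pairs_df
    out = pairs_df.copy()
    for sid, sub in out.groupby("stack_id"):
        med_pre = sub["pre_volume_um3"].median()
        med_post = sub["post_volume_um3"].median()
        out.loc[sub.index, "pre_norm_volume"] = sub["pre_volume_um3"] / med_pre
        out.loc[sub.index, "post_norm_volume"] = sub["post_volume_um3"] / med_post
    return out


def run_cohort(
    profiles: Sequence[GeneratorProfile],
    n_animals_per_group: int,
    cells_per_animal: int,
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
    keep_truth: bool = False,
):
    """Simulate a cohort and push every stack through the full pipeline.

    Returns ``(cells, pairs, cohort, provenance)`` where ``cells`` is the
    per-cell count table, ``pairs`` the per-pair table, ``cohort`` the
    per-animal summary (one row per animal × location × side) and
    ``provenance`` the per-stack processing records.  With
    ``keep_truth=True`` the concatenated ground-truth tables are appended
    as a fifth element.
    """
    config = config or PipelineConfig()
    all_cells, all_pairs, prov, truths = [], [], [], []
    for stack, truth in synth.iter_cohort(
        profiles, n_animals_per_group, cells_per_animal, seed
    ):
        res = process_stack(stack, config)
        all_cells.append(res.cells)
        if len(res.pairs):
            all_pairs.append(res.pairs)
        prov.append(res.provenance)
        if keep_truth:
            t = truth.copy()
            t["stack_id"] = stack.stack_id
            t["animal_id"] = stack.meta.get("animal_id", "")
            t["age_group"] = stack.meta.get("age_group", "")
            t["location"] = stack.meta.get("location", "")
            truths.append(t)
    cells = pd.concat(all_cells, ignore_index=True)
    pairs = (
        pd.concat(all_pairs, ignore_index=True) if all_pairs else pd.DataFrame()
    )
    cohort = summarize_cohort(cells, pairs if len(pairs) else None)
    out = (cells, pairs, cohort, prov)
    if keep_truth:
        out = out + (
            pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(),
        )
    return out
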