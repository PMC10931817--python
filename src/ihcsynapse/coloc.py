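"""Object-based colocalization of pre- and postsynaptic puncta.

A functional synapse is defined by colocalization of a presynaptic ribbon
with a postsynaptic receptor patch: the two binarised components must
overlap or at least touch at their nearest points, i.e. have a minimal
distance of zero, in 3D.  On a voxel grid, "touching" is operationalised
as sharing a voxel or being 26-adjacent (sharing a face, edge or corner).

Matching is one-to-one: candidate (pre, post) pairs within the gap
tolerance are accepted greedily in ascending gap order with deterministic
id tie-breaks, so no ribbon is double-counted against two patches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .detect import Punctum

__all__ = ["SynapsePair", "component_gap", "colocalize", "ColocalizationResult"]


@dataclass
class SynapsePair:
    """A colocalized pre/post pair; spatial and volumetric annotations are
    filled in by the geometry and volumetry stages."""

    pre_id: int
    post_id: int
    gap_um: float
    pre_volume_um3: float
    post_volume_um3: float
    center_um: np.ndarray  # volume-weighted mean of the two centroids
    cell_id: Optional[int] = None
    side: Optional[str] = None
    u_mp: Optional[float] = None
    u_tb: Optional[float] = None
    pre_norm_volume: Optional[float] = None
    post_norm_volume: Optional[float] = None


@dataclass
class ColocalizationResult:
    pairs: List[SynapsePair]
    orphan_pre: List[int]
    orphan_post: List[int]


def component_gap(p: Punctum, q: Punctum, spacing_um) -> float:
    """Minimal distance between two components in µm.

    Zero if the voxel sets overlap or are 26-adjacent; otherwise the
    minimum Euclidean distance between member voxel centres in physical
    units.  Symmetric in its arguments.
    """
    spacing = np.asarray(spacing_um, dtype=float)
    a, b = (p, q) if len(p.voxels) <= len(q.voxels) else (q, p)
    tree_idx = cKDTree(b.voxels)
    cheb, _ = tree_idx.query(a.voxels, k=1, p=np.inf)
    if cheb.min() <= 1.0:  # shared voxel or 26-neighbourhood contact
        return 0.0
    tree_phys = cKDTree(b.voxels * spacing)
    d, _ = tree_phys.query(a.voxels * spacing, k=1)
    return float(d.min())


def colocalize(
    pre: Sequence[Punctum],
    post: Sequence[Punctum],
    spacing_um,
    max_gap_um: float = 0.0,
) -> ColocalizationResult:
    """One-to-one pre/post matching under the zero-distance criterion.

    All (pre, post) pairs with component gap <= ``max_gap_um`` (default 0:
    overlap or touch) are candidates; they are accepted greedily in
    ascending gap order, ties broken by smaller pre id then post id.
    Unmatched puncta are reported as orphans per channel.
    """
    spacing = np.asarray(spacing_um, dtype=float)
    candidates: List[Tuple[float, int, int, int, int]] = []
    if pre and post:
        centers = np.array([q.centroid_um for q in post])
        radii = np.array([q.radius_um for q in post])
        tree = cKDTree(centers)
        max_r_post = radii.max() if len(radii) else 0.0
        slack = float(np.linalg.norm(spacing))  # adjacency allowance
        for i, p in enumerate(pre):
            reach = p.radius_um + max_r_post + max_gap_um + slack
            for j in tree.query_ball_point(p.centroid_um, r=reach):
                gap = component_gap(p, post[j], spacing)
                if gap <= max_gap_um:
                    candidates.append((gap, p.id, post[j].id, i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_pre, used_post = set(), set()
    pairs: List[SynapsePair] = []
    for gap, pid, qid, i, j in candidates:
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        p, q = pre[i], post[j]
        wtot = p.volume_um3 + q.volume_um3
        center = (
            p.centroid_um * p.volume_um3 + q.centroid_um * q.volume_um3
        ) / wtot
        pairs.append(
            SynapsePair(
                pre_id=pid,
                post_id=qid,
                gap_um=float(gap),
                pre_volume_um3=p.volume_um3,
                post_volume_um3=q.volume_um3,
                center_um=center,
            )
        )
    orphan_pre = [p.id for i, p in enumerate(pre) if i not in used_pre]
    orphan_post = [q.id for j, q in enumerate(post) if j not in used_post]
    return ColocalizationResult(pairs, orphan_pre, orphan_post)
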