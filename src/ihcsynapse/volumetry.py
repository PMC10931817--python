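"""Median-normalized volumes and pre/post volume correlation.

Absolute immunofluorescence volumes are not comparable across specimens or
observers (threshold liberality scales every volume in a stack); dividing
each element's volume by the median volume of colocalized elements of the
same channel within the same stack removes that scale.  Only colocalized
elements contribute to the median, and pre- and postsynaptic channels are
normalized separately.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import SynapsePair

__all__ = [
    "NormalizationError",
    "normalize_volumes",
    "volume_correlation",
    "spearman_pre_post",
]


class NormalizationError(ValueError):
    """No colocalized elements available to define the per-stack median."""


def normalize_volumes(
    pairs: Sequence[SynapsePair], stack_id: str = "stack"
) -> Dict[str, float]:
    """Fill normalized volumes on each pair, in place.

    Each presynaptic element's normalized volume is its raw volume over
    the median raw volume of colocalized presynaptic elements of this
    stack; postsynaptic elements are normalized to their own median.
    Returns the two medians.  By construction the median of normalized
    volumes within the stack is 1 per channel.
    """
    if len(pairs) == 0:
        raise NormalizationError(
            f"stack {stack_id!r}: no colocalized elements; "
            "per-stack median undefined"
        )
    pre = np.array([p.pre_volume_um3 for p in pairs], dtype=float)
    post = np.array([p.post_volume_um3 for p in pairs], dtype=float)
    med_pre = float(np.median(pre))
    med_post = float(np.median(post))
    if med_pre <= 0 or med_post <= 0:
        raise NormalizationError(
            f"stack {stack_id!r}: nonpositive median volume"
        )
    for p in pairs:
        p.pre_norm_volume = p.pre_volume_um3 / med_pre
        p.post_norm_volume = p.post_volume_um3 / med_post
    return {"median_pre_um3": med_pre, "median_post_um3": med_post}


def spearman_pre_post(
    pre: Iterable[float], post: Iterable[float]
) -> Tuple[float, float]:
    """Spearman's rho (two-sided p) between pre and post volumes."""
    pre = np.asarray(list(pre), dtype=float)
    post = np.asarray(list(post), dtype=float)
    if len(pre) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(pre) == 0 or np.ptp(post) == 0:
        raise ValueError("constant volumes: rank correlation undefined")
    res = stats.spearmanr(pre, post)
    return float(res.statistic), float(res.pvalue)


def volume_correlation(
    pair_table: pd.DataFrame,
    groupby: Optional[List[str]] = None,
    pre_col: str = "pre_norm_volume",
    post_col: str = "post_norm_volume",
) -> pd.DataFrame:
    """Spearman correlation of pre vs post normalized volumes.

    Computed pooled and, if ``groupby`` columns are given (e.g.
    ``["age_group", "location", "side"]``), per subgroup.  Subgroups with
    fewer than 3 pairs are skipped.
    """
    rows = []
    rho, p = spearman_pre_post(pair_table[pre_col], pair_table[post_col])
    rows.append(dict(group="pooled", n=len(pair_table), rho=rho, p=p))
    if groupby:
        for key, sub in pair_table.groupby(groupby, sort=True):
            if len(sub) < 3:
                continue
            try:
                rho, p = spearman_pre_post(sub[pre_col], sub[post_col])
            except ValueError:
                continue
            name = key if isinstance(key, str) else "/".join(str(k) for k in key)
            rows.append(dict(group=name, n=len(sub), rho=rho, p=p))
    return pd.DataFrame(rows)
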