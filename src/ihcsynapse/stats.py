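"""Cohort aggregation and mixed-design ANOVA on per-animal summaries.

Individual synapses and cells are not independent samples: the animal is
the experimental unit, locations and sides within an animal form a
repeated-measures structure, and age group varies between animals.  The
statistics stage therefore consumes only one row per animal × location ×
side — per-animal *means* of per-cell synapse counts and per-animal
*medians* of normalized volumes (volumes are strongly right-skewed, so the
median is the appropriate per-animal summary).

The ANOVA is the classical mixed-design (split-plot) analysis: the
between-subject factor (age group) is tested against subjects-within-
groups, and each within-subject term (location, side, and their
interactions with age) is tested against its own subject-interaction error
stratum, built from orthonormal within-subject contrasts.  For a single
between factor, the between-effect F reduces exactly to the one-way ANOVA
on per-animal means.  Under the generator's compound-symmetric error
structure these F tests are exact.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "summarize_cohort",
    "mixed_anova",
    "count_anova",
    "volume_anova",
    "pairwise_posthoc",
    "DesignError",
    "PseudoreplicationError",
]


class DesignError(ValueError):
    """The factorial design is incomplete or rank-deficient."""


class PseudoreplicationError(ValueError):
    """Sub-animal rows reached the statistics stage."""


# ---------------------------------------------------------------------------
# aggregation


def summarize_cohort(
    cells: pd.DataFrame,
    pairs: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Aggregate per-cell results into one row per animal × location × side.

    Parameters
    ----------
    cells
        Per-cell table with columns ``animal_id, age_group, location,
        cell_id, n_modiolar, n_pillar`` (and optionally ``n_total``).
    pairs
        Optional per-pair table with ``animal_id, location, side,
        pre_norm_volume, post_norm_volume`` used for the per-animal
        volume medians.

    Returns the cohort table with columns ``animal_id, age_group,
    location, side, mean_count, median_norm_pre, median_norm_post,
    n_cells``.  Animals with zero evaluated cells at a location are
    omitted with a warning (they produce no rows to aggregate).
    """
    required = {"animal_id", "age_group", "location", "cell_id"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table lacks columns: {sorted(missing)}")
    rows = []
    for (animal, age, loc), sub in cells.groupby(
        ["animal_id", "age_group", "location"], sort=True
    ):
        n_cells = len(sub)
        if n_cells == 0:  # pragma: no cover - groupby never yields empty
            continue
        for side, col in (("modiolar", "n_modiolar"), ("pillar", "n_pillar")):
            row = dict(
                animal_id=animal,
                age_group=age,
                location=loc,
                side=side,
                mean_count=float(sub[col].mean()),
                median_norm_pre=np.nan,
                median_norm_post=np.nan,
                n_cells=n_cells,
            )
            if pairs is not None and len(pairs):
                sel = pairs[
                    (pairs["animal_id"] == animal)
                    & (pairs["location"] == loc)
                    & (pairs["side"] == side)
                ]
                if len(sel):
                    row["median_norm_pre"] = float(sel["pre_norm_volume"].median())
                    row["median_norm_post"] = float(sel["post_norm_volume"].median())
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split-plot ANOVA engine


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the contrast space."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis.T)
    # first k-1 columns of q span the contrast space (orthogonal to 1)
    Q = q[:, : k - 1].T
    # guard: rows orthogonal to the unit vector
    assert np.allclose(Q @ np.ones(k), 0, atol=1e-10)
    return Q


def _guard_unique(table, subject, within):
    key = [subject] + list(within)
    if table.duplicated(subset=key).any():
        raise PseudoreplicationError(
            "multiple rows per " + " x ".join(key) + ": aggregate to one row "
            "per animal and condition before running the ANOVA "
            "(per-cell or per-synapse rows inflate test power)"
        )


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "animal_id",
    between: Optional[str] = "age_group",
    within: Sequence[str] = ("location", "side"),
) -> pd.DataFrame:
    """Mixed-design (split-plot) ANOVA with the subject as the unit.

    Requires a complete within-subject design: every subject must have
    exactly one observation of ``dv`` in every within-cell.  Missing
    cells raise :class:`DesignError` listing them.

    Returns an effect table with columns ``effect, ss, df1, df2, F, p``.
    """
    within = [w for w in within if w is not None]
    _guard_unique(table, subject, within)
    data = table.dropna(subset=[dv])
    factors = {w: sorted(data[w].unique()) for w in within}
    for w, levels in factors.items():
        if len(levels) < 2:
            raise DesignError(f"within factor {w!r} has fewer than 2 levels")
    cells = list(itertools.product(*(factors[w] for w in within)))
    wide = data.pivot_table(
        index=[subject] + ([between] if between else []),
        columns=within,
        values=dv,
        aggfunc="first",
    )
    if wide.isna().any().any():
        holes = [
            (str(idx), str(col))
            for idx, col in zip(*np.where(wide.isna().values))
        ]
        raise DesignError(
            f"incomplete within-subject design; {int(wide.isna().sum().sum())} "
            f"missing subject x cell combinations (first: {holes[:5]})"
        )
    # order columns canonically (itertools.product order over within levels)
    if len(within) > 1:
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells))
    else:
        wide = wide.reindex(columns=[c[0] for c in cells])
    Y = wide.values
    n_subj = Y.shape[0]
    if between:
        group_labels = np.array(
            [idx[1] for idx in wide.index] if wide.index.nlevels > 1
            else list(wide.index)
        )
        groups = sorted(set(group_labels))
        if len(groups) < 2:
            raise DesignError(f"between factor {between!r} has fewer than 2 levels")
    else:
        group_labels = np.array(["_all_"] * n_subj)
        groups = ["_all_"]
    a = len(groups)
    if n_subj - a < 1:
        raise DesignError("no residual degrees of freedom (too few subjects)")

    dims = [len(factors[w]) for w in within]
    ncell = int(np.prod(dims))

    # orthonormal within-space projectors per term
    H = {w: _orthonormal_contrasts(len(factors[w])) for w in within}
    ones = {w: np.full((1, len(factors[w])), 1.0 / np.sqrt(len(factors[w]))) for w in within}

    def term_matrix(term: Tuple[str, ...]) -> np.ndarray:
        mats = [H[w] if w in term else ones[w] for w in within]
        Q = mats[0]
        for m in mats[1:]:
            Q = np.kron(Q, m)
        return Q  # (q_T, ncell)

    results = []

    # between-subject stratum: subject means scaled to the cell metric
    s = Y.mean(axis=1) * np.sqrt(ncell)
    gmeans = {g: s[group_labels == g].mean() for g in groups}
    grand = s.mean()
    ss_err_b = sum(
        ((s[group_labels == g] - gmeans[g]) ** 2).sum() for g in groups
    )
    df_err_b = n_subj - a
    if between:
        ss_a = sum(
            (group_labels == g).sum() * (gmeans[g] - grand) ** 2 for g in groups
        )
        F = (ss_a / (a - 1)) / (ss_err_b / df_err_b)
        p = float(sps.f.sf(F, a - 1, df_err_b))
        results.append(
            dict(effect=between, ss=float(ss_a), df1=a - 1, df2=df_err_b,
                 F=float(F), p=p)
        )

    # within-subject strata
    terms: List[Tuple[str, ...]] = []
    for r in range(1, len(within) + 1):
        terms.extend(itertools.combinations(within, r))
    for term in terms:
        Q = term_matrix(term)
        Z = Y @ Q.T  # (n_subj, q_T)
        q_T = Z.shape[1]
        zbar_g = {g: Z[group_labels == g].mean(axis=0) for g in groups}
        ng = {g: int((group_labels == g).sum()) for g in groups}
        zbar = sum(ng[g] * zbar_g[g] for g in groups) / n_subj
        ss_err = sum(
            ((Z[group_labels == g] - zbar_g[g]) ** 2).sum() for g in groups
        )
        df_err = q_T * (n_subj - a)
        ms_err = ss_err / df_err
        ss_t = n_subj * float(zbar @ zbar)
        F = (ss_t / q_T) / ms_err
        name = "*".join(term)
        results.append(
            dict(effect=name, ss=float(ss_t), df1=q_T, df2=df_err,
                 F=float(F), p=float(sps.f.sf(F, q_T, df_err)))
        )
        if between:
            ss_int = sum(
                ng[g] * float((zbar_g[g] - zbar) @ (zbar_g[g] - zbar))
                for g in groups
            )
            df_int = q_T * (a - 1)
            F = (ss_int / df_int) / ms_err
            results.append(
                dict(effect=f"{between}*{name}", ss=float(ss_int),
                     df1=df_int, df2=df_err, F=float(F),
                     p=float(sps.f.sf(F, df_int, df_err)))
            )
    out = pd.DataFrame(results)
    bad = out[(out["F"] < 0) | (out["p"] <= 0) | (out["p"] > 1)]
    assert bad.empty, "invalid F/p in effect table"
    return out


# ---------------------------------------------------------------------------
# post-hoc


def pairwise_posthoc(
    table: pd.DataFrame,
    dv: str,
    compare: str = "age_group",
    by: Sequence[str] = ("location", "side"),
    subject: str = "animal_id",
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise Welch t-tests on per-animal values within each cell of
    ``by``, with multiplicity correction (bonferroni, holm, or none)."""
    by = list(by)
    rows = []
    grouped = table.groupby(by, sort=True) if by else [((), table)]
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        levels = sorted(sub[compare].unique())
        for l1, l2 in itertools.combinations(levels, 2):
            x = sub.loc[sub[compare] == l1, dv].dropna().values
            y = sub.loc[sub[compare] == l2, dv].dropna().values
            if len(x) < 2 or len(y) < 2:
                continue
            t, p = sps.ttest_ind(x, y, equal_var=False)
            rows.append(
                dict(
                    cell="/".join(str(k) for k in key) if key else "all",
                    level_a=l1, level_b=l2,
                    mean_a=float(np.mean(x)), mean_b=float(np.mean(y)),
                    t=float(t), p_raw=float(p),
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        if method == "none":
            out["p_corr"] = out["p_raw"]
        else:
            out["p_corr"] = multipletests(out["p_raw"], method=method)[1]
    return out


# ---------------------------------------------------------------------------
# the study's two batteries


def count_anova(
    table: pd.DataFrame,
    between: Optional[str] = "age_group",
    within: Sequence[str] = ("location", "side"),
    posthoc_method: str = "bonferroni",
) -> Dict[str, pd.DataFrame]:
    """Mixed-design ANOVA on per-animal mean synapse counts.

    ``table`` is a cohort table (one row per animal × location × side).
    Returns the effect table and Bonferroni-corrected pairwise post-hoc
    comparisons of the between factor within each within-cell.
    """
    effects = mixed_anova(
        table, dv="mean_count", between=between, within=within
    )
    post = (
        pairwise_posthoc(
            table, "mean_count", compare=between, by=list(within),
            method=posthoc_method,
        )
        if between
        else pd.DataFrame()
    )
    return {"effects": effects, "posthoc": post}


def volume_anova(
    table: pd.DataFrame,
    channel_role: str = "presynaptic",
    between: Optional[str] = "age_group",
    within: Sequence[str] = ("location", "side"),
    posthoc_method: str = "bonferroni",
) -> Dict[str, pd.DataFrame]:
    """Mixed-design ANOVA on per-animal median normalized volumes.

    Separate analyses for the presynaptic and postsynaptic channels, as
    the two element classes are normalized to their own medians.
    """
    dv = {
        "presynaptic": "median_norm_pre",
        "postsynaptic": "median_norm_post",
    }.get(channel_role)
    if dv is None:
        raise ValueError("channel_role must be presynaptic or postsynaptic")
    effects = mixed_anova(table, dv=dv, between=between, within=within)
    post = (
        pairwise_posthoc(
            table, dv, compare=between, by=list(within), method=posthoc_method
        )
        if between
        else pd.DataFrame()
    )
    return {"effects": effects, "posthoc": post}
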