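"""Cohort aggregation and the mixed-design ANOVA battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ihcsynapse.profiles import get_profile
from ihcsynapse.stats import (
    DesignError,
    PseudoreplicationError,
    count_anova,
    mixed_anova,
    pairwise_posthoc,
    summarize_cohort,
    volume_anova,
)
from ihcsynapse.synth import simulate_cohort_counts


def _cells(counts, animal="A1", age="young_adult", loc="16kHz"):
    return pd.DataFrame(
        [
            dict(
                animal_id=animal, age_group=age, location=loc, cell_id=i + 1,
                n_modiolar=c, n_pillar=0, n_total=c,
            )
            for i, c in enumerate(counts)
        ]
    )


def test_per_animal_mean_of_cell_counts():
    cohort = summarize_cohort(_cells([20, 22, 24]))
    row = cohort[cohort.side == "modiolar"].iloc[0]
    assert row.mean_count == 22.0
    assert row.n_cells == 3


def test_cohort_has_one_row_per_animal_location_side():
    young = [get_profile(f"gerbil_{l}_young") for l in ("1k", "2k", "16k")]
    aged = [get_profile(f"gerbil_{l}_aged") for l in ("1k", "2k", "16k")]
    cells = simulate_cohort_counts(young + aged, 4, 6, seed=0)
    cohort = summarize_cohort(cells)
    assert len(cohort) == 8 * 3 * 2  # animals x locations x sides
    assert not cohort.duplicated(["animal_id", "location", "side"]).any()


def test_between_factor_f_equals_squared_t():
    rng = np.random.default_rng(0)
    rows = []
    for g in ("young_adult", "quiet_aged"):
        for i in range(7):
            for s in ("modiolar", "pillar"):
                rows.append(
                    dict(
                        animal_id=f"{g}{i}", age_group=g, location="16kHz",
                        side=s,
                        mean_count=rng.normal(10 + (g == "quiet_aged"), 2),
                    )
                )
    df = pd.DataFrame(rows)
    eff = mixed_anova(df, dv="mean_count", within=["side"])
    means = df.groupby(["animal_id", "age_group"]).mean_count.mean().reset_index()
    t, _ = sps.ttest_ind(
        means.loc[means.age_group == "young_adult", "mean_count"],
        means.loc[means.age_group == "quiet_aged", "mean_count"],
    )
    F = eff.loc[eff.effect == "age_group", "F"].iloc[0]
    assert F == pytest.approx(t * t)


def test_pseudoreplication_guard():
    """Per-cell rows must never reach the model."""
    cells = simulate_cohort_counts([get_profile("gerbil_16k_young")], 4, 6, seed=1)
    cells = cells.rename(columns={"n_total": "mean_count"})
    cells["side"] = "modiolar"
    with pytest.raises(PseudoreplicationError):
        mixed_anova(cells, dv="mean_count", within=["side"])


def test_incomplete_design_is_reported():
    rng = np.random.default_rng(1)
    rows = []
    for g in ("a", "b"):
        for i in range(4):
            for s in ("modiolar", "pillar"):
                rows.append(
                    dict(animal_id=f"{g}{i}", age_group=g, location="1kHz",
                         side=s, mean_count=rng.normal())
                )
    df = pd.DataFrame(rows).drop(index=0)  # puncture one cell
    with pytest.raises(DesignError, match="missing"):
        mixed_anova(df, dv="mean_count", within=["side"])


def test_f_nonnegative_p_in_unit_interval():
    young = [get_profile(f"gerbil_{l}_young") for l in ("1k", "2k", "16k")]
    aged = [get_profile(f"gerbil_{l}_aged") for l in ("1k", "2k", "16k")]
    cohort = summarize_cohort(simulate_cohort_counts(young + aged, 6, 9, seed=2))
    eff = count_anova(cohort)["effects"]
    assert (eff.F >= 0).all()
    assert ((eff.p > 0) & (eff.p <= 1)).all()
    # full factorial effect list: age, 2 within mains + interactions
    assert set(eff.effect) == {
        "age_group", "location", "side", "location*side",
        "age_group*location", "age_group*side", "age_group*location*side",
    }


def test_identical_tables_give_identical_effects():
    young = [get_profile(f"gerbil_{l}_young") for l in ("1k", "2k", "16k")]
    aged = [get_profile(f"gerbil_{l}_aged") for l in ("1k", "2k", "16k")]
    cells = simulate_cohort_counts(young + aged, 5, 8, seed=3)
    cohort = summarize_cohort(cells)
    rng = np.random.default_rng(4)
    vols = rng.lognormal(size=len(cohort))
    cohort["median_norm_pre"] = vols
    cohort["median_norm_post"] = vols  # same dependent variable
    pre = volume_anova(cohort, "presynaptic")["effects"]
    post = volume_anova(cohort, "postsynaptic")["effects"]
    pd.testing.assert_frame_equal(pre, post)


def test_permuted_side_labels_yield_uniform_p():
    """With side labels shuffled within animals the side effect is null;
    its p-values across replicates are uniform (KS check)."""
    prof = get_profile("gerbil_16k_young")
    ps = []
    for rep in range(120):
        cells = simulate_cohort_counts([prof], 8, 9, seed=9000 + rep)
        cohort = summarize_cohort(cells)
        rng = np.random.default_rng(rep)
        # permute side labels within each animal
        for a in cohort.animal_id.unique():
            idx = cohort.index[cohort.animal_id == a]
            cohort.loc[idx, "side"] = rng.permutation(cohort.loc[idx, "side"].values)
        eff = mixed_anova(cohort, dv="mean_count", between=None, within=["side"])
        ps.append(float(eff.loc[eff.effect == "side", "p"].iloc[0]))
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_posthoc_correction_orders_p_values():
    young = [get_profile(f"gerbil_{l}_young") for l in ("1k", "2k", "16k")]
    aged = [get_profile(f"gerbil_{l}_aged") for l in ("1k", "2k", "16k")]
    cohort = summarize_cohort(simulate_cohort_counts(young + aged, 6, 9, seed=5))
    post = pairwise_posthoc(cohort, "mean_count")
    assert (post.p_corr >= post.p_raw - 1e-12).all()
    holm = pairwise_posthoc(cohort, "mean_count", method="holm")
    assert (holm.p_corr <= post.p_corr + 1e-12).all()
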