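"""Generator contracts: determinism, geometry, count/volume laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from ihcsynapse.profiles import get_profile
from ihcsynapse.synth import (
    SizingError,
    generate_cohort,
    iter_cohort,
    make_cell_row,
    plant_synapses,
    render_stack,
    simulate_stack,
)


@pytest.fixture(scope="module")
def profile():
    return get_profile("gerbil_16k_young")


def test_single_cell_frame_orthonormal(profile):
    _, frames = make_cell_row(1, profile)
    f = frames[0]
    for u, v in [
        (f.axis_apexbase, f.axis_modpil),
        (f.axis_apexbase, f.axis_topbottom),
        (f.axis_modpil, f.axis_topbottom),
    ]:
        assert abs(u @ v) < 1e-12
        assert abs(np.linalg.norm(u) - 1) < 1e-12


def test_cell_masks_disjoint_and_counted(profile):
    labels, frames = make_cell_row(8, profile)
    assert len(frames) == 8
    # voxelwise: each voxel carries at most one label by construction;
    # verify every cell is non-empty and cells do not touch/overlap when
    # masks are taken independently
    ids = [int(i) for i in np.unique(labels) if i]
    assert ids == list(range(1, 9))
    total = sum(int((labels == i).sum()) for i in ids)
    assert total == int((labels > 0).sum())


def test_eleven_cell_field_of_view(profile):
    labels, frames = make_cell_row(11, profile)
    assert len(frames) == 11
    assert len([i for i in np.unique(labels) if i]) == 11


def test_sizing_error_names_dimension(profile):
    with pytest.raises(SizingError, match="along x"):
        make_cell_row(8, profile, max_shape=(100, 500, 100))


def test_zero_expectation_plants_nothing(profile):
    _, frames = make_cell_row(2, profile)
    empty = profile.replace(
        expected_count_modiolar=0.0, expected_count_pillar=0.0
    )
    truth = plant_synapses(frames, empty, rng=np.random.default_rng(0))
    assert len(truth) == 0


def test_count_law_calibration(profile):
    """Over many cells the empirical per-side means match the profile
    expectations within 3 standard errors (law of large numbers)."""
    _, frames = make_cell_row(3, profile)
    rng = np.random.default_rng(7)
    mod, pil = [], []
    n_cells = 0
    for _ in range(200):  # 600 cells total
        truth = plant_synapses(frames, profile, rng=rng)
        syn = truth[truth.kind == "synapse"]
        for f in frames:
            sub = syn[syn.cell_id == f.cell_id]
            mod.append((sub.side == "modiolar").sum())
            pil.append((sub.side == "pillar").sum())
            n_cells += 1
    assert n_cells >= 500
    for vals, expect in ((mod, 13.7), (pil, 8.3)):
        vals = np.asarray(vals, dtype=float)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) < 3 * se + 1e-9, (
            vals.mean(), expect, se)


def test_planted_volumes_right_skewed(profile):
    _, frames = make_cell_row(3, profile)
    rng = np.random.default_rng(3)
    truth = pd.concat(
        [plant_synapses(frames, profile, rng=rng) for _ in range(30)]
    )
    syn = truth[truth.kind == "synapse"]
    assert stats.skew(syn.pre_vol_um3) > 0
    assert stats.skew(syn.post_vol_um3) > 0


def test_planted_centers_inside_dilated_mask(profile):
    labels, frames = make_cell_row(2, profile)
    truth = plant_synapses(frames, profile, rng=np.random.default_rng(5))
    dilated = ndimage.binary_dilation(labels > 0)
    spacing = np.array(profile.spacing_um)
    syn = truth[truth.kind == "synapse"]
    centers = syn[["cz_um", "cy_um", "cx_um"]].values
    idx = np.round(centers / spacing).astype(int)
    idx = np.clip(idx, 0, np.array(labels.shape) - 1)
    assert dilated[tuple(idx.T)].all()


def test_volume_gradient_direction(profile):
    """Requested modiolar>pillar gradient holds in planted medians."""
    _, frames = make_cell_row(3, profile)
    rng = np.random.default_rng(11)
    truth = pd.concat(
        [plant_synapses(frames, profile, rng=rng) for _ in range(20)]
    )
    syn = truth[truth.kind == "synapse"]
    med = syn.groupby("side")[["pre_vol_um3", "post_vol_um3"]].median()
    assert med.loc["modiolar", "pre_vol_um3"] > med.loc["pillar", "pre_vol_um3"]
    assert med.loc["modiolar", "post_vol_um3"] > med.loc["pillar", "post_vol_um3"]


def test_render_determinism(profile):
    a, ta = simulate_stack(profile, 1, rng=np.random.default_rng(9))
    b, tb = simulate_stack(profile, 1, rng=np.random.default_rng(9))
    pd.testing.assert_frame_equal(ta, tb)
    for role in a.channels:
        np.testing.assert_array_equal(a.channels[role], b.channels[role])


def test_noise_free_single_synapse_renders_two_components(profile):
    clean = profile.replace(
        photon_noise_scale=0.0, background_level=0.0,
        expected_count_modiolar=1.0, expected_count_pillar=0.0,
    )
    labels, frames = make_cell_row(1, clean)
    rng = np.random.default_rng(1)
    truth = plant_synapses(frames, clean, rng=rng)
    while (truth.kind == "synapse").sum() != 1:  # Poisson draw until exactly 1
        truth = plant_synapses(frames, clean, rng=rng)
    stack = render_stack(truth, labels, clean, rng=rng)
    for role in ("presynaptic", "postsynaptic"):
        n = ndimage.label(stack.channels[role] > 0)[1]
        assert n == 1  # one suprathreshold component per synaptic channel


def test_cohort_structure(profile):
    stacks, truths = generate_cohort([profile], 1, 4, seed=0)
    assert len(stacks) == 1
    assert sorted(truths[0].cell_id.unique()) == [1, 2, 3, 4]
    assert stacks[0].meta["median_cells_per_animal"] == 4


def test_cohort_metadata_median_cells(profile):
    stack, _ = next(iter(iter_cohort([profile], 1, 9, seed=1)))
    assert stack.meta["median_cells_per_animal"] == 9
    assert stack.meta["animal_id"] == "Y01"
    assert stack.meta["location"] == "16kHz"
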