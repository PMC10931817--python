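"""Detection: thresholding, component extraction, splitting."""

import numpy as np
import pytest
from scipy import ndimage

from ihcsynapse.detect import (
    DetectionConfig,
    extract_puncta,
    labels_from_puncta,
    puncta_from_labels,
    split_merged,
    threshold_channel,
)
from ihcsynapse.stack import ImageStack

SPACING = (0.3, 0.08, 0.08)


def _stack(arr, spacing=SPACING):
    return ImageStack(channels={"presynaptic": arr.astype(np.float32)},
                      spacing_um=spacing)


def flood_fill_components(mask, connectivity=26):
    """Independent brute-force component oracle (BFS over voxel sets)."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    todo = {tuple(v) for v in np.argwhere(mask)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def test_constant_zero_channel_gives_empty_mask():
    stack = _stack(np.zeros((4, 8, 8)))
    with pytest.warns(UserWarning, match="constant"):
        mask, info = threshold_channel(
            stack, "presynaptic", DetectionConfig(threshold_mode="otsu")
        )
    assert not mask.any()
    assert info["threshold"] is None


def test_otsu_separates_two_level_image():
    arr = np.full((4, 10, 10), 10.0)
    arr[2, 4:7, 4:7] = 100.0
    mask, info = threshold_channel(
        _stack(arr), "presynaptic", DetectionConfig(threshold_mode="otsu")
    )
    np.testing.assert_array_equal(mask, arr >= 100.0)
    assert 10 < info["threshold"] <= 100


def test_mask_is_threshold_geq():
    arr = np.arange(27, dtype=float).reshape(3, 3, 3)
    mask, _ = threshold_channel(
        _stack(arr), "presynaptic",
        DetectionConfig(threshold_mode="fixed", threshold_value=13.0),
    )
    np.testing.assert_array_equal(mask, arr >= 13.0)


def test_min_voxel_rule_discards_small_components():
    mask = np.zeros((5, 8, 8), dtype=bool)
    mask[2, 2, 2:6] = True  # 4 voxels < 5
    assert extract_puncta(mask, SPACING, DetectionConfig()) == []
    mask[2, 3, 2] = True  # now 5 voxels
    puncta = extract_puncta(mask, SPACING, DetectionConfig())
    assert len(puncta) == 1
    assert puncta[0].voxel_count == 5
    assert puncta[0].volume_um3 == pytest.approx(5 * 0.3 * 0.08 * 0.08)
    assert puncta[0].volume_um3 == pytest.approx(0.0096)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_components_match_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(0)
    for _ in range(10):
        mask = rng.random((24, 24, 24)) < 0.08
        cfg = DetectionConfig(
            min_voxels=1, connectivity=connectivity, split_enabled=False
        )
        puncta = extract_puncta(mask, SPACING, cfg)
        got = {frozenset(map(tuple, p.voxels)) for p in puncta}
        expected = flood_fill_components(mask, connectivity)
        assert got == expected


def test_threshold_monotonicity():
    rng = np.random.default_rng(1)
    arr = rng.poisson(5, size=(8, 16, 16)).astype(float)
    counts = []
    for thr in (2.0, 4.0, 6.0, 9.0):
        mask, _ = threshold_channel(
            _stack(arr), "presynaptic",
            DetectionConfig(threshold_mode="fixed", threshold_value=thr),
        )
        counts.append(int(mask.sum()))
    assert counts == sorted(counts, reverse=True)


def test_min_voxel_filter_monotonicity():
    rng = np.random.default_rng(2)
    mask = rng.random((20, 20, 20)) < 0.1
    ns = []
    for mv in (1, 3, 5, 9):
        cfg = DetectionConfig(min_voxels=mv, split_enabled=False)
        ns.append(len(extract_puncta(mask, SPACING, cfg)))
    assert ns == sorted(ns, reverse=True)


def _ball_mask(shape, center, r, spacing):
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    return (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= r * r


def test_split_leaves_single_sphere_alone():
    shape = (12, 40, 40)
    mask = _ball_mask(shape, (1.8, 1.6, 1.6), 0.5, SPACING)
    cfg = DetectionConfig(min_voxels=1)
    (p,) = extract_puncta(mask, SPACING, cfg, apply_max_volume=False)
    frags = split_merged(p, SPACING, cfg)
    assert len(frags) == 1
    assert frags[0].voxel_count == p.voxel_count


def test_split_dumbbell_partitions_voxels():
    shape = (12, 60, 40)
    c1, c2 = (1.8, 1.4, 1.6), (1.8, 2.8, 1.6)  # 1.4 µm apart in y
    mask = _ball_mask(shape, c1, 0.45, SPACING) | _ball_mask(
        shape, c2, 0.45, SPACING
    )
    # thin bridge between the spheres
    mask[6, 18:35, 20] = True
    cfg = DetectionConfig(min_voxels=5, split_min_separation_um=0.6)
    (p,) = extract_puncta(mask, SPACING, cfg, apply_max_volume=False)
    frags = split_merged(p, SPACING, cfg)
    assert len(frags) == 2
    voxels = [set(map(tuple, f.voxels)) for f in frags]
    assert voxels[0].isdisjoint(voxels[1])
    assert voxels[0] | voxels[1] == set(map(tuple, p.voxels))


def test_split_conserves_voxel_count_on_random_blobs():
    rng = np.random.default_rng(3)
    cfg = DetectionConfig(min_voxels=5)
    for _ in range(10):
        mask = ndimage.binary_dilation(
            rng.random((10, 24, 24)) < 0.02, iterations=2
        )
        for p in extract_puncta(mask, SPACING, cfg, apply_max_volume=False):
            frags = split_merged(p, SPACING, cfg)
            assert sum(f.voxel_count for f in frags) == p.voxel_count
            assert all(f.voxel_count >= cfg.min_voxels for f in frags)


def test_label_round_trip():
    rng = np.random.default_rng(4)
    mask = rng.random((12, 20, 20)) < 0.05
    cfg = DetectionConfig(min_voxels=1, split_enabled=False)
    puncta = extract_puncta(mask, SPACING, cfg)
    labels = labels_from_puncta(puncta, mask.shape)
    back = puncta_from_labels(labels, SPACING, "presynaptic")
    got = {frozenset(map(tuple, p.voxels)) for p in back}
    expected = {frozenset(map(tuple, p.voxels)) for p in puncta}
    assert got == expected


def test_fixed_mode_requires_value():
    with pytest.raises(ValueError):
        DetectionConfig(threshold_mode="fixed")
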