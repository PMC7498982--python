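"""Volumetric extraction: label propagation, erosion, masking rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptapls.regions import REGION_LABELS, REGIONS, WM_REGIONS
from ptapls.roi import (
    EmptyRegionError,
    VolumeSet,
    assign_wm_to_nearest_label,
    build_region_masks,
    erode_mask,
    extract_regional_metrics,
    load_volume_set,
    save_volume_set,
)
from ptapls.synthetic import default_volume_config, generate_volume_set


def _brute_force_nearest(wm_mask, labels, voxel_size):
    """Per-voxel scan over all labeled voxels; lowest label wins ties."""
    out = labels.copy()
    lab_pos = {
        int(l): np.argwhere(labels == l) for l in np.unique(labels) if l != 0
    }
    vs = np.asarray(voxel_size, dtype=float)
    for idx in np.argwhere(wm_mask):
        best = (np.inf, None)
        for lab in sorted(lab_pos):
            d = np.min(np.sum(((lab_pos[lab] - idx) * vs) ** 2, axis=1))
            if d < best[0] - 1e-12:
                best = (d, lab)
        out[tuple(idx)] = best[1]
    return out


class TestNearestLabelAssignment:
    def test_single_label_everywhere(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 3
        wm = np.ones_like(labels, dtype=bool)
        wm[0, 0, 0] = False
        out = assign_wm_to_nearest_label(wm, labels)
        assert (out[wm] == 3).all()

    def test_matches_brute_force_two_corner_labels(self):
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[0, 0, 0] = 1
        labels[4, 4, 4] = 2
        wm = labels == 0
        out = assign_wm_to_nearest_label(wm, labels, (1.0, 1.0, 1.0))
        ref = _brute_force_nearest(wm, labels, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out, ref)

    def test_matches_brute_force_random_anisotropic(self, rng):
        labels = np.zeros((6, 5, 4), dtype=int)
        for lab in (1, 2, 3):
            i = tuple(rng.integers(0, s) for s in labels.shape)
            labels[i] = lab
        wm = (labels == 0) & (rng.random(labels.shape) < 0.5)
        vs = (1.0, 0.7, 1.2)
        out = assign_wm_to_nearest_label(wm, labels, vs)
        ref = _brute_force_nearest(wm, labels, vs)
        np.testing.assert_array_equal(out, ref)

    def test_exact_tie_goes_to_lowest_label(self):
        labels = np.zeros((5, 1, 1), dtype=int)
        labels[0, 0, 0] = 2
        labels[4, 0, 0] = 1
        wm = np.zeros_like(labels, dtype=bool)
        wm[2, 0, 0] = True  # exactly 2 voxels from both labels
        out = assign_wm_to_nearest_label(wm, labels)
        assert out[2, 0, 0] == 1

    def test_no_labels_is_an_error(self):
        with pytest.raises(ValueError, match="no labeled voxel"):
            assign_wm_to_nearest_label(
                np.ones((3, 3, 3), bool), np.zeros((3, 3, 3), int)
            )


class TestErosion:
    def test_solid_cube_leaves_center(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        out = erode_mask(mask)
        assert out.sum() == 1 and out[2, 2, 2]

    def test_empty_mask_identity(self):
        assert erode_mask(np.zeros((4, 4, 4), bool)).sum() == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_neighborhood_scan(self, seed):
        mask = np.random.default_rng(seed).random((8, 8, 8)) < 0.6
        out = erode_mask(mask)
        ref = np.zeros_like(mask)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    if 0 < i < 7 and 0 < j < 7 and 0 < k < 7:
                        ref[i, j, k] = mask[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2].all()
        np.testing.assert_array_equal(out, ref)


def _simple_volume(fa_value=0.5, lesion=None):
    """One 5×5×5 block per region along x, constant FA."""
    shape = (27, 7, 7)
    labels = np.zeros(shape, dtype=int)
    for i, r in enumerate(REGIONS):
        labels[1 + 5 * i : 6 + 5 * i, 1:6, 1:6] = REGION_LABELS[r]
    fa = np.full(shape, fa_value)
    excl = np.zeros(shape, bool)
    if lesion is not None:
        excl[lesion] = True
    return VolumeSet(
        label_volume=labels, metric_volumes={"FA": fa}, exclusion_mask=excl
    )


class TestBuildRegionMasks:
    def test_threshold_never_binds_at_high_fa(self):
        vs = _simple_volume(fa_value=0.5)
        masks = build_region_masks(vs)
        for r in REGIONS:
            expected = erode_mask(vs.label_volume == REGION_LABELS[r])
            np.testing.assert_array_equal(masks[r], expected)

    def test_boundary_fa_is_excluded_strictly(self):
        vs = _simple_volume(fa_value=0.3)
        masks = build_region_masks(vs, fa_threshold=0.3)
        for r in WM_REGIONS:
            assert masks[r].sum() == 0
        assert masks["BT"].sum() > 0  # BT takes no FA threshold

    def test_lesion_removed_by_set_difference(self):
        lesion = (slice(12, 14), slice(2, 4), slice(2, 4))  # inside CC
        vs = _simple_volume(lesion=lesion)
        masks = build_region_masks(vs)
        clean = _simple_volume()
        expected = erode_mask(clean.label_volume == REGION_LABELS["CC"])
        expected[lesion] = False
        np.testing.assert_array_equal(masks["CC"], expected)

    def test_masks_are_nested(self):
        vs = _simple_volume(lesion=(slice(2, 4), slice(2, 4), slice(2, 4)))
        masks = build_region_masks(vs)
        for r in REGIONS:
            label_mask = vs.label_volume == REGION_LABELS[r]
            eroded = erode_mask(label_mask)
            assert (masks[r] <= eroded).all()
            assert (eroded <= label_mask).all()

    def test_exclusion_monotonicity(self, rng):
        """A larger exclusion mask never increases any region's voxel count."""
        vs = _simple_volume()
        small = rng.random(vs.label_volume.shape) < 0.1
        big = small | (rng.random(vs.label_volume.shape) < 0.1)
        vs_small = VolumeSet(
            label_volume=vs.label_volume,
            metric_volumes=dict(vs.metric_volumes),
            exclusion_mask=small,
        )
        vs_big = VolumeSet(
            label_volume=vs.label_volume,
            metric_volumes=dict(vs.metric_volumes),
            exclusion_mask=big,
        )
        m_small = build_region_masks(vs_small)
        m_big = build_region_masks(vs_big)
        for r in REGIONS:
            assert m_big[r].sum() <= m_small[r].sum()


class TestExtraction:
    def test_constant_metric_gives_constant_means(self):
        vs = _simple_volume(fa_value=0.5)
        table = extract_regional_metrics(vs, subject_id="s")
        assert (table["mean"] == 0.5).all()
        assert (table["n_voxels"] > 0).all()
        assert len(table) == 5

    def test_three_voxel_hand_mean(self):
        """A 3-voxel BT region with values 0.2/0.4/0.6 averages to 0.4."""
        labels = np.zeros((9, 3, 3), dtype=int)
        labels[1:4, 1, 1] = REGION_LABELS["BT"]
        for i, r in enumerate(WM_REGIONS):  # one voxel each so no region is empty
            labels[5 + i, i % 3, 1] = REGION_LABELS[r]
        fa = np.full(labels.shape, 0.9)
        fa[1, 1, 1], fa[2, 1, 1], fa[3, 1, 1] = 0.2, 0.4, 0.6
        vs = VolumeSet(label_volume=labels, metric_volumes={"FA": fa})
        table = extract_regional_metrics(vs, erode=False)
        bt = table[(table.region == "BT") & (table.metric == "FA")]
        assert bt["mean"].iloc[0] == pytest.approx(0.4)
        assert bt["n_voxels"].iloc[0] == 3

    def test_generator_truth_reproduced_without_noise(self):
        vols, truth = generate_volume_set(default_volume_config())
        table = extract_regional_metrics(vols, subject_id="s")
        merged = table.merge(truth, on=["region", "metric"])
        assert len(merged) == 10
        np.testing.assert_array_equal(
            merged["mean"].to_numpy(), merged["mean_post"].to_numpy()
        )
        np.testing.assert_array_equal(
            merged["n_voxels"].to_numpy(), merged["n_post"].to_numpy()
        )

    def test_empty_region_raises_with_name(self):
        vs = _simple_volume(fa_value=0.2)  # below threshold: WM regions empty
        with pytest.raises(EmptyRegionError, match="FT"):
            extract_regional_metrics(vs)

    def test_non_finite_voxels_are_dropped(self):
        vs = _simple_volume(fa_value=0.5)
        fa = vs.metric_volumes["FA"]
        masks = build_region_masks(vs)
        idx = tuple(np.argwhere(masks["BT"])[0])
        fa[idx] = np.nan
        n_bt = masks["BT"].sum()
        table = extract_regional_metrics(vs)
        bt = table[table.region == "BT"]
        assert bt["n_voxels"].iloc[0] == n_bt - 1
        assert np.isfinite(bt["mean"].iloc[0])

    def test_mean_invariant_to_background_padding(self):
        vs = _simple_volume(fa_value=0.5)
        t1 = extract_regional_metrics(vs)
        padded = VolumeSet(
            label_volume=np.pad(vs.label_volume, 2),
            metric_volumes={"FA": np.pad(vs.metric_volumes["FA"], 2)},
            exclusion_mask=np.pad(vs.exclusion_mask, 2),
        )
        t2 = extract_regional_metrics(padded)
        pd.testing.assert_frame_equal(t1, t2)


class TestVolumeSetValidation:
    def test_fa_out_of_range_rejected(self):
        labels = np.zeros((3, 3, 3), int)
        labels[1, 1, 1] = 1
        with pytest.raises(ValueError, match="FA"):
            VolumeSet(label_volume=labels, metric_volumes={"FA": np.full((3, 3, 3), 1.5)})

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            VolumeSet(
                label_volume=np.zeros((3, 3, 3), int),
                metric_volumes={"FA": np.zeros((4, 3, 3))},
            )

    def test_undeclared_labels_rejected(self):
        labels = np.zeros((3, 3, 3), int)
        labels[0, 0, 0] = 9
        with pytest.raises(ValueError, match="undeclared"):
            VolumeSet(label_volume=labels)


def test_nifti_roundtrip(tmp_path):
    vols, _ = generate_volume_set(default_volume_config())
    paths = save_volume_set(vols, tmp_path)
    back = load_volume_set(
        paths["labels"], {"FA": paths["FA"], "MD": paths["MD"]}, paths["exclusion"]
    )
    np.testing.assert_array_equal(back.label_volume, vols.label_volume)
    np.testing.assert_allclose(
        back.metric_volumes["FA"], vols.metric_volumes["FA"], atol=1e-6
    )
    np.testing.assert_array_equal(back.exclusion_mask, vols.exclusion_mask)
    assert back.voxel_size == vols.voxel_size
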