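"""Cortical classifier: kernels, segmentation passes, classification logic."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from ermorph.cortical import (
    ChannelMasks,
    ClassifierParams,
    assign_to_cells,
    classify,
    classify_cortical_field,
    feature_segment,
    preprocess_brightfield,
    ring_kernel,
    rolling_ball_background,
    segment_cells_from_brightfield,
    segment_channel,
    summarize_population,
)

from conftest import small_cortical
from ermorph.synth import render_cortical_field
from ermorph.synth.fields import NoiseModel

PARAMS = ClassifierParams()


class TestRollingBall:
    def test_constant_image_to_zero(self):
        out = rolling_ball_background(np.full((40, 40), 7.0), radius=10)
        assert np.allclose(out, 0.0)

    def test_gradient_plus_spots_recovered(self):
        rr, cc = np.mgrid[0:80, 0:80]
        gradient = 0.4 + 0.004 * rr + 0.003 * cc
        img = gradient.copy()
        spots = []
        for r0, c0 in [(20, 20), (60, 50)]:
            spot = np.hypot(rr - r0, cc - c0) <= 3
            img[spot] += 1.0
            spots.append(spot)
        out = rolling_ball_background(img, radius=20)
        for spot in spots:
            assert out[spot].max() == pytest.approx(1.0, rel=0.05)

    def test_output_non_negative(self, rng):
        img = rng.normal(0, 1, (50, 50))
        assert (rolling_ball_background(img, radius=10) >= 0).all()


class TestBrightfield:
    def test_constant_image_zero_output(self):
        out = preprocess_brightfield(np.full((64, 64), 2.0))
        assert np.allclose(out, 0.0)

    def test_shape_preserved(self):
        out = preprocess_brightfield(np.zeros((63, 61)))
        assert out.shape == (63, 61)

    def test_outlines_land_in_top_decile(self, cortical_field):
        bf = cortical_field.channels["bf"][0]
        out = preprocess_brightfield(bf)
        tc = cortical_field.truth_cells > 0
        outline = tc ^ ndi.binary_erosion(tc, iterations=2)
        cutoff = np.percentile(out, 90)
        assert out[outline].mean() > cutoff


class TestRingKernel:
    def test_radius_one_contains_eight_neighborhood(self):
        k = ring_kernel(1)
        c = k.shape[0] // 2
        ring = k > 0
        assert not ring[c, c]
        assert ring[c - 1 : c + 2, c - 1 : c + 2].sum() == 8
        vals = k[ring]
        assert np.allclose(vals, vals[0])

    @pytest.mark.parametrize("r", [1, 2, 3.5, 6, 10])
    def test_kernel_sums_to_one(self, r):
        assert ring_kernel(r).sum() == pytest.approx(1.0)

    def test_constant_image_reproduced_by_convolution(self):
        img = np.full((30, 30), 0.37)
        out = ndi.convolve(img, ring_kernel(3), mode="reflect")
        assert np.allclose(out, 0.37)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            ring_kernel(0.5)


class TestFeatureSegment:
    def test_constant_image_empty_with_warning(self):
        with pytest.warns(UserWarning):
            mask = feature_segment(np.full((32, 32), 0.5), 2, 0.02, 1.0)
        assert not mask.any()

    def test_bright_ridge_segmented(self):
        img = np.zeros((40, 40))
        img[18:20, 5:35] = 1.0
        mask = feature_segment(img, radius=2, strength=0.01, bg_multiplier=1.0)
        assert mask[18:20, 10:30].mean() > 0.9
        assert mask[~ndi.binary_dilation(img > 0, iterations=3)].sum() == 0

    def test_bg_multiplier_monotone(self, cortical_field):
        img = cortical_field.channels["sec63"][0]
        masks = [
            feature_segment(img, 2, 0.02, bg) for bg in (0.6, 1.0, 1.5, 2.0)
        ]
        for a, b in zip(masks, masks[1:]):
            assert not (b & ~a).any()  # raising bg only shrinks the mask


class TestSegmentChannel:
    def test_blank_channel_empty(self):
        with pytest.warns(UserWarning):
            m = segment_channel(np.zeros((32, 32)), PARAMS, "general")
        assert not m.total_mask.any()

    def test_union_property(self, cortical_field):
        img = cortical_field.channels["sec63"][0]
        m = segment_channel(img, PARAMS, "general")
        assert np.array_equal(m.total_mask, m.small_feature_mask | m.large_feature_mask)

    def test_tubule_only_field_mostly_small_pass(self):
        """Without sheets, the large-feature pass adds little beyond the
        small-feature pass (checked on the unblurred field; PSF blur adds a
        dim halo around tubules that only the far ring can see)."""
        f = render_cortical_field(
            small_cortical(
                31,
                target_sheet_fraction=0.0,
                target_tubule_fraction=0.2,
                psf_sigma=0.0,
                noise_model=NoiseModel(gaussian_sd=0.0, poisson_scale=0.0),
            )
        )
        m = segment_channel(f.channels["sec63"][0], PARAMS, "general")
        exclusive_large = m.large_feature_mask & ~m.small_feature_mask
        assert exclusive_large.sum() < 0.10 * max(m.total_mask.sum(), 1)

    def test_bad_role_rejected(self):
        with pytest.raises(ValueError):
            segment_channel(np.zeros((8, 8)), PARAMS, "nonsense")


class TestClassify:
    def test_empty_rtn_masks_keep_provisional_sheets(self):
        sec = np.zeros((50, 50), dtype=bool)
        sec[10:40, 10:40] = True  # one big sheet-like block
        sec_masks = ChannelMasks(np.zeros_like(sec), sec)
        rtn_masks = ChannelMasks(np.zeros_like(sec), np.zeros_like(sec))
        cls = classify(sec_masks, rtn_masks, trimming_factor=3)
        assert not cls.cluster_mask.any()
        assert cls.sheet_mask.sum() > 0.9 * sec.sum()

    def test_partition_and_disjointness(self, cortical_field):
        sec = cortical_field.channels["sec63"][0]
        rtn = cortical_field.channels["rtn1"][0]
        sm = segment_channel(sec, PARAMS, "general")
        rm = segment_channel(rtn, PARAMS, "curvature")
        cls = classify(sm, rm, PARAMS.trimming_factor)
        assert not (cls.tubule_mask & cls.sheet_mask).any()
        assert np.array_equal(cls.tubule_mask | cls.sheet_mask, sm.total_mask)
        assert not (cls.cluster_mask & ~cls.tubule_mask).any()

    def test_sheet_with_rim_stays_sheet_cluster_becomes_tubule(self):
        """A Sec63 patch with only an Rtn1 rim is a sheet; a patch filled with
        Rtn1 is reclassified as tubules via the cluster rule."""
        f = render_cortical_field(
            small_cortical(
                37,
                image_size=(160, 160),
                n_cells=2,
                target_sheet_fraction=0.25,
                target_tubule_fraction=0.05,
                target_cluster_fraction=0.0,
            )
        )
        f2 = render_cortical_field(
            small_cortical(
                37,
                image_size=(160, 160),
                n_cells=2,
                target_sheet_fraction=0.0,
                target_tubule_fraction=0.05,
                target_cluster_fraction=0.25,
            )
        )
        cls1, pc1, _ = classify_cortical_field(
            f.channels["sec63"][0], f.channels["rtn1"][0],
            cell_labels=f.truth_cells, background_subtract=False,
        )
        cls2, pc2, _ = classify_cortical_field(
            f2.channels["sec63"][0], f2.channels["rtn1"][0],
            cell_labels=f2.truth_cells, background_subtract=False,
        )
        # rim-only sheets retained as sheets
        assert (cls1.sheet_mask & f.truth_sheets).sum() > 0.6 * f.truth_sheets.sum()
        # rtn1-filled patches mostly absorbed into tubules
        assert (cls2.sheet_mask & f2.truth_clusters).sum() < 0.3 * f2.truth_clusters.sum()
        assert (cls2.tubule_mask & f2.truth_clusters).sum() > 0.6 * f2.truth_clusters.sum()

    def test_trimming_factor_monotone(self, cortical_field):
        sec = cortical_field.channels["sec63"][0]
        rtn = cortical_field.channels["rtn1"][0]
        sm = segment_channel(sec, PARAMS, "general")
        rm = segment_channel(rtn, PARAMS, "curvature")
        prev = None
        for tf in (0, 1, 2, 3, 5, 8):
            cls = classify(sm, rm, tf)
            prov = cls.sheet_mask | (cls.cluster_mask & cls.tubule_mask)
            area = prov.sum()
            if prev is not None:
                assert area <= prev
            prev = area


class TestAssignAndSummarize:
    def test_no_cells_empty_table(self, cortical_field):
        sec = cortical_field.channels["sec63"][0]
        sm = segment_channel(sec, PARAMS, "general")
        cls = classify(sm, ChannelMasks(np.zeros_like(sm.total_mask), np.zeros_like(sm.total_mask)), 3)
        table = assign_to_cells(cls, np.zeros_like(cortical_field.truth_cells))
        assert len(table) == 0

    def test_per_cell_partition_exact(self, cortical_field):
        sec = cortical_field.channels["sec63"][0]
        rtn = cortical_field.channels["rtn1"][0]
        sm = segment_channel(sec, PARAMS, "general")
        rm = segment_channel(rtn, PARAMS, "curvature")
        cls = classify(sm, rm, PARAMS.trimming_factor)
        table = assign_to_cells(cls, cortical_field.truth_cells)
        for row in table.itertuples():
            cell = cortical_field.truth_cells == row.cell
            sec_total = (sm.total_mask & cell).sum()
            assert row.tubule_area_px + row.sheet_area_px == sec_total
            assert row.tubule_fraction == pytest.approx(
                row.tubule_area_px / row.cortex_area_px
            )

    def test_median_summaries(self):
        import pandas as pd

        one = pd.DataFrame(
            {
                "tubule_fraction": [0.2],
                "sheet_fraction": [0.1],
                "cluster_area_px": [5],
            }
        )
        s = summarize_population(one)
        assert s["median_tubule_fraction"] == 0.2
        two = pd.concat([one, one.assign(tubule_fraction=0.4, sheet_fraction=0.3)])
        s2 = summarize_population(two)
        assert s2["median_tubule_fraction"] == pytest.approx(0.3)
        s4 = summarize_population(pd.concat([two, two]))
        assert s4 == {**s2, "n_cells": 4}

    def test_empty_population_raises(self):
        import pandas as pd

        with pytest.raises(ValueError):
            summarize_population(pd.DataFrame())


def test_intensity_scale_near_invariance(cortical_field):
    """Multiplying both channels by a constant changes per-cell fractions by
    less than one percentage point (all thresholds are Otsu-relative)."""
    sec = cortical_field.channels["sec63"][0]
    rtn = cortical_field.channels["rtn1"][0]
    _, pc1, _ = classify_cortical_field(
        sec, rtn, cell_labels=cortical_field.truth_cells, background_subtract=False
    )
    _, pc2, _ = classify_cortical_field(
        sec * 7.3, rtn * 7.3, cell_labels=cortical_field.truth_cells,
        background_subtract=False,
    )
    for col in ("tubule_fraction", "sheet_fraction"):
        assert np.abs(pc1[col].to_numpy() - pc2[col].to_numpy()).max() < 0.01


def test_fallback_brightfield_segmenter_finds_cells(cortical_field):
    labels = segment_cells_from_brightfield(cortical_field.channels["bf"][0])
    n_true = cortical_field.truth_cells.max()
    assert labels.max() >= 0.5 * n_true
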