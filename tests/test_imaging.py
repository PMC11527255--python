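"""Segmentation, feature extraction and FISH spot counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.measure import label as cc_label

from rarecell import imaging, synth
from rarecell.imaging import SegmentationConfig, equivalent_diameter

from conftest import match_to_truth


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "area,expected",
        [(np.pi, 2.0), (4 * np.pi, 4.0), (225 * np.pi, 30.0)],
    )
    def test_analytic_values(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected, rel=1e-12)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e6), st.floats(min_value=1.01, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_area(self, area, factor):
        assert equivalent_diameter(area * factor) > equivalent_diameter(area)


class TestSegmentChannel:
    def test_constant_image_empty_mask(self):
        cfg = SegmentationConfig(offset=1.0)
        mask = imaging.segment_channel(np.full((100, 100), 42.0), cfg)
        assert not mask.any()

    def test_disk_area_recovered(self, flat_disk_slide):
        img, disk = flat_disk_slide
        cfg = SegmentationConfig(offset=50.0)
        mask = imaging.segment_channel(img, cfg)
        assert mask.sum() == pytest.approx(disk.sum(), rel=0.05)

    def test_two_separated_disks_two_components(self):
        img = np.full((300, 300), 100.0)
        for center in ((80, 80), (220, 220)):
            rr, cc = np.mgrid[0:300, 0:300]
            img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= 15**2] = 1000.0
        mask = imaging.segment_channel(img, SegmentationConfig(offset=50.0))
        assert cc_label(mask, connectivity=2).max() == 2

    def test_block_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="block"):
            imaging.segment_channel(np.zeros((20, 20)), SegmentationConfig(block_size_px=51))

    def test_even_block_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConfig(block_size_px=50)


class TestBuildCellMask:
    def _slide(self, planes):
        return imaging.SlideImage(channels=planes, pixel_size_um=1.0)

    def test_single_channel_union_identity(self):
        img = np.full((120, 120), 100.0)
        rr, cc = np.mgrid[0:120, 0:120]
        img[(rr - 60) ** 2 + (cc - 60) ** 2 <= 10**2] = 900.0
        slide = self._slide({"DAPI": img})
        cfg = SegmentationConfig(offset=50.0, channels_for_cell_mask=("DAPI",))
        labeled = imaging.build_cell_mask(slide, cfg)
        np.testing.assert_array_equal(labeled > 0, imaging.segment_channel(img, cfg))

    def test_concentric_disks_merge_to_one_label(self):
        rr, cc = np.mgrid[0:150, 0:150]
        dapi = np.full((150, 150), 100.0)
        dapi[(rr - 75) ** 2 + (cc - 75) ** 2 <= 8**2] = 900.0
        epi = np.full((150, 150), 100.0)
        epi[(rr - 75) ** 2 + (cc - 75) ** 2 <= 20**2] = 900.0
        slide = self._slide({"DAPI": dapi, "EPI": epi})
        cfg = SegmentationConfig(offset=50.0, channels_for_cell_mask=("DAPI", "EPI"))
        labeled = imaging.build_cell_mask(slide, cfg)
        assert labeled.max() == 1
        assert (labeled > 0).sum() >= (epi > 500).sum()

    def test_channel_order_irrelevant(self):
        rr, cc = np.mgrid[0:150, 0:150]
        a = np.full((150, 150), 100.0)
        a[(rr - 40) ** 2 + (cc - 40) ** 2 <= 10**2] = 900.0
        b = np.full((150, 150), 100.0)
        b[(rr - 110) ** 2 + (cc - 110) ** 2 <= 10**2] = 900.0
        slide = self._slide({"A": a, "B": b})
        m1 = imaging.build_cell_mask(
            slide, SegmentationConfig(offset=50.0, channels_for_cell_mask=("A", "B"))
        )
        m2 = imaging.build_cell_mask(
            slide, SegmentationConfig(offset=50.0, channels_for_cell_mask=("B", "A"))
        )
        np.testing.assert_array_equal(m1 > 0, m2 > 0)
        assert m1.max() == 2

    def test_empty_channel_subset_errors(self):
        slide = self._slide({"DAPI": np.zeros((60, 60))})
        with pytest.raises(ValueError, match="empty"):
            imaging.build_cell_mask(slide, SegmentationConfig(channels_for_cell_mask=()))


class TestExtractCells:
    def test_uniform_intensity_statistics(self):
        rr, cc = np.mgrid[0:120, 0:120]
        disk = (rr - 60) ** 2 + (cc - 60) ** 2 <= 12**2
        img = np.where(disk, 500.0, 10.0)
        slide = imaging.SlideImage(channels={"DAPI": img}, pixel_size_um=1.0)
        cfg = SegmentationConfig(offset=50.0, channels_for_cell_mask=("DAPI",))
        cell_mask = imaging.build_cell_mask(slide, cfg)
        recs = imaging.extract_cells(slide, cell_mask, cell_mask > 0, cfg)
        assert len(recs) == 1
        r = recs[0]
        assert r.channel_stats["DAPI_cell_mean"] == pytest.approx(500.0)
        assert r.channel_stats["DAPI_cell_median"] == pytest.approx(500.0)
        assert r.channel_stats["DAPI_cell_max"] == pytest.approx(500.0)
        assert r.channel_stats["DAPI_cell_total"] == pytest.approx(500.0 * r.cell_area_px)

    def test_cell_without_nucleus_reported_not_dropped(self):
        rr, cc = np.mgrid[0:120, 0:120]
        epi = np.where((rr - 60) ** 2 + (cc - 60) ** 2 <= 12**2, 900.0, 100.0)
        slide = imaging.SlideImage(
            channels={"EPI": epi, "DAPI": np.full((120, 120), 100.0)}, pixel_size_um=1.0
        )
        cfg = SegmentationConfig(offset=50.0, channels_for_cell_mask=("EPI",))
        cell_mask = imaging.build_cell_mask(slide, cfg)
        dapi_mask = imaging.segment_channel(slide["DAPI"], cfg)
        recs = imaging.extract_cells(slide, cell_mask, dapi_mask, cfg)
        assert len(recs) == 1
        assert recs[0].n_nuclei == 0
        assert np.isnan(recs[0].nucleus_equivalent_diameter_um)

    def test_generated_slide_diameters_match_truth(self, segmented_slide):
        spec, slide, truth, records, _, _ = segmented_slide
        pairs = match_to_truth(records, truth)
        matched = [(t, r) for t, r in pairs if r is not None]
        assert len(matched) / len(truth) >= 0.95
        for t, r in matched:
            err_px = abs(t.nucleus_diameter_um - r.nucleus_equivalent_diameter_um)
            assert err_px <= 1.5 * spec.pixel_size_um


class TestSlideIO:
    def test_tiff_roundtrip(self, tmp_path):
        spec = synth.SlideSpec(width_px=300, height_px=300, n_wbc=3, n_ctc=2, n_igc=0, seed=2)
        slide, _ = synth.generate_slide(spec)
        path = tmp_path / "s.tiff"
        imaging.write_slide_tiff(slide, path)
        back = imaging.read_slide_tiff(path)
        assert list(back.channels) == list(slide.channels)
        assert back.pixel_size_um == slide.pixel_size_um
        # 16-bit quantization only
        for ch in slide.channels:
            assert np.abs(back[ch] - np.clip(slide[ch], 0, 65535)).max() <= 1.0


class TestFishSpots:
    def _nucleus_mask(self):
        rr, cc = np.mgrid[0:200, 0:200]
        m = np.zeros((200, 200), dtype=int)
        m[(rr - 60) ** 2 + (cc - 60) ** 2 <= 25**2] = 1
        m[(rr - 140) ** 2 + (cc - 140) ** 2 <= 25**2] = 2
        return m

    def test_three_rendered_puncta_counted(self):
        mask = self._nucleus_mask()
        spots = synth.add_spots(
            np.full((200, 200), 50.0), [(50, 50), (60, 70), (72, 55)], amplitude=2000.0
        )
        counts = imaging.count_fish_spots(mask, spots)
        assert counts[1] == 3
        assert counts[2] == 0

    def test_blank_channel_zero_everywhere(self):
        counts = imaging.count_fish_spots(self._nucleus_mask(), np.full((200, 200), 50.0))
        assert counts == {1: 0, 2: 0}

    def test_puncta_outside_nuclei_ignored(self):
        mask = self._nucleus_mask()
        spots = synth.add_spots(np.full((200, 200), 50.0), [(10, 190), (190, 10)])
        counts = imaging.count_fish_spots(mask, spots)
        assert counts == {1: 0, 2: 0}

    def test_ploidy_difference_recovered(self):
        # chromosome-1-like probe at 3 copies vs chromosome-10-like at 1 copy
        mask = self._nucleus_mask()
        chr1 = synth.add_spots(
            np.full((200, 200), 50.0), [(50, 52), (66, 68), (70, 48), (132, 140), (150, 148), (140, 128)]
        )
        chr10 = synth.add_spots(np.full((200, 200), 50.0), [(60, 60), (140, 140)])
        c1 = imaging.count_fish_spots(mask, chr1)
        c10 = imaging.count_fish_spots(mask, chr10)
        assert c1 == {1: 3, 2: 3}
        assert c10 == {1: 1, 2: 1}
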