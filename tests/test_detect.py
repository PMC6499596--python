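import warnings

import numpy as np
import pytest

import focikit as fk
from focikit import detect as det
from tests.conftest import match_detected_to_planted


def disk_image(centers, radius=15, level=2000.0, shape=(256, 256)):
    img = np.zeros(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2] = level
    return img


class TestSegmentNuclei:
    def test_separated_disks_counted_with_centroids(self):
        centers = [(40, 40), (40, 120), (40, 200), (140, 60), (180, 180)]
        img = disk_image(centers)
        mask, rec = det.segment_nuclei(img, fk.DetectionParams())
        assert len(rec) == 5
        found = sorted((round(r.centroid_row), round(r.centroid_col))
                       for r in rec.itertuples())
        for (fr, fc), (er, ec) in zip(found, sorted(centers)):
            assert abs(fr - er) <= 0.5 and abs(fc - ec) <= 0.5

    def test_all_zero_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask, rec = det.segment_nuclei(np.zeros((64, 64)),
                                           fk.DetectionParams())
        assert rec.empty and mask.max() == 0

    def test_planted_field_component_count(self, small_course):
        """On a seeded synthetic field at default SNR the number of retained
        nuclei equals the planted count (distractors filtered out)."""
        layout, images, gt = small_course
        p = fk.DetectionParams()
        mask, rec = det.segment_nuclei(images[0], p)
        rec, mask = det.filter_nuclei(rec, mask, p)
        assert len(rec) == layout.n_nuclei


class TestFilterNuclei:
    def test_distractors_removed(self, small_course):
        layout, images, gt = small_course
        p = fk.DetectionParams()
        mask, rec = det.segment_nuclei(images[0], p)
        kept, _ = det.filter_nuclei(rec, mask, p)
        # raw segmentation sees the saturated blobs; filtering removes them
        assert len(rec) > len(kept) >= layout.n_nuclei
        assert (kept["saturated_frac"] <= p.saturation_fraction_max).all()

    def test_small_speck_removed(self):
        img = disk_image([(100, 100)], radius=15)
        img += disk_image([(30, 30)], radius=3, level=4000.0)
        p = fk.DetectionParams()
        mask, rec = det.segment_nuclei(img, p)
        kept, m2 = det.filter_nuclei(rec, mask, p)
        assert len(kept) == 1
        assert m2.max() == 1  # relabeled consecutively

    def test_no_removals_is_identity(self):
        img = disk_image([(60, 60), (180, 180)])
        p = fk.DetectionParams()
        mask, rec = det.segment_nuclei(img, p)
        kept, m2 = det.filter_nuclei(rec, mask, p)
        assert len(kept) == len(rec)
        assert np.array_equal(m2 > 0, mask > 0)


class TestBandpass:
    def test_constant_image_gives_zero(self):
        img = np.full((64, 64), 500.0)
        enh = det.bandpass_enhance(img, fk.DetectionParams())
        assert np.abs(enh).max() < 1e-9 * 500.0

    def test_target_size_spot_peaks_at_center(self):
        p = fk.DetectionParams()
        sigma = p.focus_diameter_px / 2.355
        rr, cc = np.mgrid[0:101, 0:101]
        img = 100.0 + 50.0 * np.exp(-((rr - 50) ** 2 + (cc - 50) ** 2)
                                    / (2 * sigma ** 2))
        enh = det.bandpass_enhance(img, p)
        assert np.unravel_index(np.argmax(enh), enh.shape) == (50, 50)

    def test_oversized_spot_enhanced_less(self):
        """A blob 4x the target diameter yields a strictly lower band-pass
        peak than a target-size blob of equal amplitude."""
        p = fk.DetectionParams()
        rr, cc = np.mgrid[0:201, 0:201]

        def spot(sigma):
            img = 50.0 * np.exp(-((rr - 100) ** 2 + (cc - 100) ** 2)
                                / (2 * sigma ** 2))
            return det.bandpass_enhance(img, p).max()

        s_target = p.focus_diameter_px / 2.355
        assert spot(s_target) > spot(4 * s_target)


class TestDetectFoci:
    def test_counts_exact_on_noiseless_field(self, noiseless_course):
        layout, images, gt = noiseless_course
        p = fk.DetectionParams()
        for t, img in zip((45, 120), images):
            res = det.quantify_field(img, p, timepoint_min=t)
            lab2cell = match_detected_to_planted(res["records"], gt.cells)
            planted = gt.counts_at(t)
            for row in res["table"].itertuples():
                assert row.focus_count == planted[lab2cell[row.nucleus_label]]

    def test_empty_noiseless_nucleus_gives_zero(self):
        img = disk_image([(100, 100)], radius=18)
        res = det.quantify_field(img, fk.DetectionParams())
        assert len(res["foci"]) == 0

    def test_close_maxima_merged(self):
        """Two planted spots closer than the minimum separation collapse to
        one reported focus."""
        p = fk.DetectionParams(min_separation_px=5.0)
        img = disk_image([(100, 100)], radius=20)
        sigma = p.focus_diameter_px / 2.355
        rr, cc = np.mgrid[0:256, 0:256]
        for dc in (0, 3):  # 3 px apart < min separation 5
            img += 3000.0 * np.exp(-((rr - 100) ** 2 + (cc - 97 - dc) ** 2)
                                   / (2 * sigma ** 2))
        res = det.quantify_field(img, p)
        assert len(res["foci"]) == 1

    def test_no_focus_outside_retained_nucleus(self, small_course):
        _, images, _ = small_course
        p = fk.DetectionParams()
        res = det.quantify_field(images[0], p)
        mask = res["mask"]
        for f in res["foci"].itertuples():
            assert mask[int(f.row), int(f.col)] == f.nucleus_label

    def test_tiny_nucleus_warns_zero_foci(self):
        p = fk.DetectionParams()
        enhanced = np.random.default_rng(0).normal(size=(32, 32))
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[10:12, 10:13] = 1  # 6 px
        import pandas as pd
        rec = pd.DataFrame([{"label": 1, "centroid_row": 10.5,
                             "centroid_col": 11, "area_px": 6.0,
                             "mean_intensity": 100.0, "max_intensity": 120.0,
                             "solidity": 1.0, "saturated_frac": 0.0,
                             "on_border": False, "passed_filters": True}])
        with pytest.warns(UserWarning):
            foci = det.detect_foci(enhanced, mask, rec, p, image=enhanced)
        assert foci.empty

    def test_scale_equivariance_of_focus_calls(self, small_course):
        """Multiplying the image by a positive constant leaves focus calls
        unchanged (all thresholds are equivariant; x2 is exact in floats)."""
        _, images, _ = small_course
        p = fk.DetectionParams()
        img = images[0].astype(float)
        a = det.quantify_field(img, p)["foci"]
        b = det.quantify_field(img * 2.0, p)["foci"]
        assert set(map(tuple, a[["nucleus_label", "row", "col"]].to_numpy())) \
            == set(map(tuple, b[["nucleus_label", "row", "col"]].to_numpy()))


class TestCountTable:
    def test_zero_focus_nuclei_included(self):
        img = disk_image([(60, 60), (180, 180)])
        res = det.quantify_field(img, fk.DetectionParams())
        assert len(res["table"]) == 2
        assert (res["table"]["focus_count"] == 0).all()

    def test_inconsistent_focus_label_raises(self):
        import pandas as pd
        foci = pd.DataFrame([{"nucleus_label": 99, "row": 1, "col": 1,
                              "enhanced_intensity": 1.0}])
        rec = pd.DataFrame([{"label": 1, "mean_intensity": 10.0}])
        with pytest.raises(ValueError, match="filtered-out"):
            det.count_table(foci, rec, "f", 45)

    def test_detected_total_tracks_planted_total(self, small_course):
        layout, images, gt = small_course
        res = det.quantify_field(images[0], fk.DetectionParams(),
                                 timepoint_min=45)
        total = res["table"]["focus_count"].sum()
        planted = gt.counts_at(45).sum()
        assert abs(total - planted) / planted < 0.05
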