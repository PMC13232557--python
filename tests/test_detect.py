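"""Geometric detection, circularity, ring classification, video filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liposort import (
    DegenerateInputError,
    Detection,
    DetectionParams,
    ImagingConfig,
    InputError,
    circularity,
    classify_localization,
    detect_frame,
    render_frame,
    threshold_detect,
    video_filter,
)
from tests.conftest import make_liposome


def disks_image(diameters_um, px_um=0.25, size=512, level=400.0, offset=100.0):
    """Synthetic noiseless disk image with given equivalent diameters."""
    img = np.full((size, size), offset)
    ys, xs = np.mgrid[0:size, 0:size]
    n = len(diameters_um)
    for i, d in enumerate(diameters_um):
        cx = (i + 1) * size / (n + 1)
        cy = size / 2
        rho = np.hypot(xs - cx, ys - cy) * px_um
        img[rho <= d / 2] = offset + level
    return img


class TestThresholdDetect:
    def test_blank_image_empty(self, rng):
        img = rng.normal(100, 5, size=(512, 512))
        assert threshold_detect(img, DetectionParams()) == []

    def test_saturated_image_rejected(self):
        img = np.full((64, 64), 1000.0)
        img[0, 0] = 0.0
        with pytest.raises(DegenerateInputError):
            threshold_detect(img, DetectionParams(threshold_value=10.0))

    def test_size_gate_keeps_only_in_range_disks(self):
        """Disks of 3, 8, 15 and 25 um: only 8 and 15 pass the 3.5-20 um gate."""
        img = disks_image([3.0, 8.0, 15.0, 25.0])
        dets = threshold_detect(img, DetectionParams(threshold_value=200.0))
        found = sorted(d.equiv_diameter_um for d in dets)
        assert len(found) == 2
        assert found[0] == pytest.approx(8.0, abs=0.5)
        assert found[1] == pytest.approx(15.0, abs=0.5)

    def test_border_touching_components_removed(self):
        img = np.full((512, 512), 100.0)
        img[0:40, 100:140] = 500.0  # touches the top border
        assert threshold_detect(img, DetectionParams(threshold_value=200.0)) == []

    def test_centroid_in_physical_units(self):
        img = disks_image([8.0])
        det = threshold_detect(img, DetectionParams(threshold_value=200.0))[0]
        assert det.centroid_um[0] == pytest.approx(256.5 * 0.25, abs=0.3)
        assert det.centroid_um[1] == pytest.approx(256.5 * 0.25, abs=0.3)


class TestCircularity:
    def test_analytic_circle_is_one(self):
        r = 3.7
        assert circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_closed_form(self):
        s = 5.0
        assert circularity(s * s, 4 * s) == pytest.approx(math.pi / 4, abs=1e-12)

    def test_two_to_one_ellipse_ramanujan_oracle(self):
        a, b = 8.0, 4.0
        area = math.pi * a * b
        perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
        expected = 4 * math.pi * area / perim**2  # ~0.84
        assert circularity(area, perim) == pytest.approx(expected)
        assert expected == pytest.approx(0.84, abs=0.01)

    def test_nonpositive_perimeter_rejected(self):
        with pytest.raises(InputError):
            circularity(10.0, 0.0)

    @given(st.floats(0.5, 50), st.floats(min_value=1.01, max_value=5))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, r, k):
        """Scaling a region by k leaves the statistic unchanged."""
        area, perim = math.pi * r**2 * 1.3, 2 * math.pi * r * 1.21
        assert abs(circularity(area, perim) -
                   circularity(area * k**2, perim * k)) < 1e-9


class TestClassifyLocalization:
    def _detection_at(self, x_um, y_um, r_um):
        return Detection(bbox_px=(0, 0, 1, 1), centroid_um=(x_um, y_um),
                         area_um2=math.pi * r_um**2, perimeter_um=2 * math.pi * r_um,
                         circularity=1.0, equiv_diameter_um=2 * r_um, aspect_ratio=1.0)

    def test_uniform_signal_scores_one_and_class_one(self):
        img = np.full((256, 256), 500.0)
        det = self._detection_at(32.0, 32.0, 4.0)
        cls, score, _ = classify_localization(img, img, det, DetectionParams())
        assert score == pytest.approx(1.0)
        assert cls == 1

    def test_membrane_mode_scores_high(self, imaging):
        lp = make_liposome(64.0, 64.0, diameter=10.0, mode="static_membrane",
                           phenotype="membrane")
        mem = render_frame([lp], imaging, "membrane", 0.0, rng=None)
        prot = render_frame([lp], imaging, "protein", 0.0, rng=None)
        det = self._detection_at(64.0, 64.0, 5.0)
        cls, score, conf = classify_localization(mem, prot, det, DetectionParams())
        assert score >= 3.0
        assert cls == 2 and conf > 0.5

    def test_lumen_mode_scores_low(self, imaging):
        lp = make_liposome(64.0, 64.0, diameter=10.0, mode="static_lumen",
                           phenotype="lumen")
        mem = render_frame([lp], imaging, "membrane", 0.0, rng=None)
        prot = render_frame([lp], imaging, "protein", 0.0, rng=None)
        det = self._detection_at(64.0, 64.0, 5.0)
        cls, score, _ = classify_localization(mem, prot, det, DetectionParams())
        assert cls == 1
        assert score < 1.5

    def test_border_clipped_detection_flagged_skipped(self):
        img = np.full((256, 256), 100.0)
        det = self._detection_at(1.0, 32.0, 4.0)
        cls, score, conf = classify_localization(img, img, det, DetectionParams())
        assert cls is None and det.skipped
        assert math.isnan(score)

    def test_invariant_to_gain_and_offset(self, imaging, rng):
        """The ring score survives a global affine intensity change (<=1%)."""
        lp = make_liposome(64.0, 64.0, diameter=10.0, mode="static_membrane",
                           phenotype="membrane")
        mem = render_frame([lp], imaging, "membrane", 0.0, rng)
        prot = render_frame([lp], imaging, "protein", 0.0, rng).astype(float)
        det1 = self._detection_at(64.0, 64.0, 5.0)
        det2 = self._detection_at(64.0, 64.0, 5.0)
        _, s1, _ = classify_localization(mem, prot, det1, DetectionParams())
        _, s2, _ = classify_localization(mem, prot * 2.5 + 300.0, det2, DetectionParams())
        assert s2 == pytest.approx(s1, rel=0.01)


class TestVideoFilter:
    @pytest.mark.parametrize("aspect,area,kept", [
        (0.6, 100.0, False),   # too elongated in x/y
        (1.4, 100.0, False),
        (1.0, 36.0, False),    # below the 37 um^2 area floor
        (1.0, 50.0, True),
        (0.7, 37.0, True),     # boundary values are inclusive
    ])
    def test_aspect_and_area_gates(self, aspect, area, kept):
        d = Detection(bbox_px=(0, 0, 10, 10), centroid_um=(5, 5), area_um2=area,
                      perimeter_um=20.0, circularity=0.9, equiv_diameter_um=7.0,
                      aspect_ratio=aspect)
        assert (video_filter([d]) == [d]) is kept


class TestDetectFrame:
    def test_blank_frames_empty(self, imaging, rng):
        blank = render_frame([], imaging, "membrane", 0.0, rng)
        assert detect_frame(blank, blank, DetectionParams()) == []

    def test_mixed_grid_detected_and_classified(self, imaging, rng, grid_population):
        mem = render_frame(grid_population, imaging, "membrane", 0.0, rng)
        prot = render_frame(grid_population, imaging, "protein", 0.0, rng)
        dets = detect_frame(mem, prot, DetectionParams(), classify=True)
        assert len(dets) == 16
        assert sum(d.cls == 2 for d in dets) == 8

    def test_count_never_exceeds_truth(self, imaging, rng, grid_population):
        mem = render_frame(grid_population, imaging, "membrane", 0.0, rng)
        prot = render_frame(grid_population, imaging, "protein", 0.0, rng)
        dets = detect_frame(mem, prot, DetectionParams())
        assert len(dets) <= len(grid_population)


class TestSparsePrecisionRecall:
    def test_precision_and_recall_at_least_95_percent(self):
        """Sparse, well-separated FOVs: detection matches ground truth >=95%."""
        from liposort import GenotypeSpec, PopulationConfig, sample_population

        imaging = ImagingConfig()
        g = GenotypeSpec(name="m", phenotype="membrane")
        cfg = PopulationConfig(components=[(g, 1.0)], p_expression=1.0,
                               liposomes_per_fov=(25, 25), min_gap_um=2.0,
                               diameter_lognormal=(8.0, 0.3),
                               diameter_range_um=(5.0, 15.0), n_fov=6, seed=99)
        rng = np.random.default_rng(99)
        tp = fp = fn = 0
        for pop in sample_population(cfg, rng):
            mem = render_frame(pop, imaging, "membrane", 0.0, rng)
            dets = detect_frame(mem, mem, DetectionParams(), classify=False)
            centers = np.array([lp.center_um for lp in pop])
            # truth restricted to objects the size gate is meant to keep
            eligible = np.array([
                5.0 <= lp.diameter_um <= 18.0
                and 10.0 <= lp.center_um[0] <= 118.0
                and 10.0 <= lp.center_um[1] <= 118.0
                for lp in pop
            ])
            matched = np.zeros(len(pop), dtype=bool)
            for d in dets:
                dist = np.hypot(centers[:, 0] - d.centroid_um[0],
                                centers[:, 1] - d.centroid_um[1])
                j = int(np.argmin(dist))
                if dist[j] < 2.0 and not matched[j]:
                    matched[j] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((eligible & ~matched).sum())
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95
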