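"""Ratio series, global/local features, areas, and feature invariances."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from arterymetrics.contour import ArteryAnnotation, Contour
from arterymetrics.features import (
    FEATURE_NAMES,
    PeakConfig,
    area_features,
    extract_features,
    find_peaks_circular,
    global_features,
    local_features,
    ratio_series,
)
from arterymetrics.measurement import measure_profile
from arterymetrics.signal import CircularSeries, condition
from arterymetrics.simulate import make_artery, make_cohort_artery

from conftest import circle_contour, star_annotation


def _bump_annotation(amplitude, bump_deg=120.0, seed=0):
    """Nested circles with a focal intimal bump (lumen dented inward)."""
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    d = np.angle(np.exp(1j * (theta - np.deg2rad(bump_deg))))
    r_l = 40.0 - amplitude * np.exp(-0.5 * (d / np.deg2rad(20)) ** 2)
    lumen = Contour(np.column_stack([r_l * np.cos(theta), r_l * np.sin(theta)]))
    return ArteryAnnotation(
        media=circle_contour((0, 0), 100),
        intimas=[circle_contour((0, 0), 70)],
        lumens=[lumen],
        artery_id=f"bump-{amplitude}",
    )


class TestRatioSeries:
    def test_equal_thickness_gives_half(self, annulus):
        conditioned = condition(measure_profile(annulus.annotation))
        r = ratio_series(conditioned)
        assert np.allclose(r.values[np.isfinite(r.values)], 0.5, atol=1e-6)

    def test_annuli_width_ratio(self):
        artery = make_artery("nested", radii=(100, 80, 40), canvas=256)
        conditioned = condition(measure_profile(artery.annotation))
        r = ratio_series(conditioned)
        assert np.allclose(r.values[np.isfinite(r.values)], 40 / 60, atol=1e-3)

    def test_bounded_zero_one(self):
        conditioned = condition(measure_profile(star_annotation(3)))
        vals = ratio_series(conditioned).values
        vals = vals[np.isfinite(vals)]
        assert np.all(vals >= 0) and np.all(vals <= 1)

    def test_role_swap_complement(self, annulus):
        """Swapping media and intima roles maps the ratio to 1 - ratio."""
        conditioned = condition(measure_profile(annulus.annotation))
        r = ratio_series(conditioned)
        swapped = conditioned.copy()
        swapped.media, swapped.intima = conditioned.intima.copy(), conditioned.media.copy()
        r2 = ratio_series(swapped)
        ok = np.isfinite(r.values)
        assert np.allclose(r.values[ok] + r2.values[ok], 1.0, atol=1e-9)


class TestGlobalFeatures:
    def test_constant(self):
        avg, med, var = global_features(CircularSeries(np.full(10, 3.3)))
        assert (avg, med, var) == (pytest.approx(3.3), pytest.approx(3.3), pytest.approx(0.0))

    def test_two_point_population_variance(self):
        avg, med, var = global_features(CircularSeries(np.array([0.0, 1.0])))
        assert (avg, med, var) == (0.5, 0.5, 0.25)

    def test_matches_direct_sums(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(2, 4, 1000)
        avg, med, var = global_features(CircularSeries(vals))
        assert np.isclose(avg, vals.sum() / len(vals))
        assert np.isclose(med, np.sort(vals)[499:501].mean())
        assert np.isclose(var, ((vals - vals.mean()) ** 2).sum() / len(vals))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            global_features(CircularSeries(np.full(5, np.nan)))


class TestCircularPeaks:
    def test_constant_has_no_peaks(self):
        assert find_peaks_circular(CircularSeries(np.full(360, 1.0))) == []

    def test_single_gaussian_bump(self):
        x = np.arange(360.0)
        vals = np.exp(-0.5 * ((x - 180) / 25) ** 2)
        peaks = find_peaks_circular(CircularSeries(vals), PeakConfig(theta_w=10))
        assert len(peaks) == 1
        assert peaks[0].location_idx == 180
        assert peaks[0].height == pytest.approx(1.0)
        assert peaks[0].prominence == pytest.approx(1.0, abs=1e-6)

    def test_bump_straddling_wraparound_found_once(self):
        """A bump across 0/359 is one peak, and matches the detector run
        on the half-turn-rotated series."""
        x = np.arange(360.0)
        d = np.angle(np.exp(1j * np.deg2rad(x)))
        vals = np.exp(-0.5 * (d / np.deg2rad(15)) ** 2)
        peaks = find_peaks_circular(CircularSeries(vals), PeakConfig(theta_w=10))
        assert len(peaks) == 1
        rotated = find_peaks_circular(CircularSeries(np.roll(vals, 180)), PeakConfig(theta_w=10))
        assert len(rotated) == 1
        assert (peaks[0].location_idx + 180) % 360 == rotated[0].location_idx
        assert peaks[0].prominence == pytest.approx(rotated[0].prominence, rel=1e-6)

    def test_narrow_peak_rejected_by_width(self):
        vals = np.zeros(360)
        vals[100:103] = [0.5, 1.0, 0.5]
        assert find_peaks_circular(CircularSeries(vals), PeakConfig(theta_w=10)) == []


class TestLocalFeatures:
    def test_max_over_peaks_independently(self):
        from arterymetrics.features import Peak

        peaks = [
            Peak(0, 0, height=2, prominence=1, width=12),
            Peak(10, 10, height=5, prominence=4, width=12),
            Peak(20, 20, height=3, prominence=2, width=12),
        ]
        assert local_features(peaks) == (5, 4)

    def test_empty_sentinel_zero(self):
        assert local_features([]) == (0.0, 0.0)


class TestAreaFeatures:
    def test_nested_circles_analytic(self, annulus_annotation):
        media_a, intima_a, ratio = area_features(annulus_annotation, physical_units=False)
        assert media_a == pytest.approx(np.pi * (100**2 - 70**2), rel=0.01)
        assert intima_a == pytest.approx(np.pi * (70**2 - 40**2), rel=0.01)
        assert ratio == pytest.approx((100**2 - 70**2) ** -1 * (70**2 - 40**2), rel=0.02)

    def test_square_annotation_exact_shoelace(self):
        sq = lambda h: Contour(np.array([[-h, -h], [h, -h], [h, h], [-h, h]], dtype=float))
        ann = ArteryAnnotation(media=sq(30), intimas=[sq(20)], lumens=[sq(10)])
        media_a, intima_a, ratio = area_features(ann, physical_units=False)
        assert media_a == 60**2 - 40**2
        assert intima_a == 40**2 - 20**2
        assert ratio == (40**2 - 20**2) / (60**2 - 40**2)

    def test_scaling_homogeneity(self, annulus_annotation):
        base = area_features(annulus_annotation, physical_units=False)
        scaled = area_features(annulus_annotation.transformed(lambda p: p * 2), physical_units=False)
        assert scaled[0] == pytest.approx(4 * base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(4 * base[1], rel=1e-9)
        assert scaled[2] == pytest.approx(base[2], rel=1e-9)


class TestExtractFeatures:
    def test_annulus_feature_vector(self, annulus_annotation):
        row = extract_features(annulus_annotation)
        assert set(FEATURE_NAMES) <= set(row)
        assert row["media_average"] == pytest.approx(0.5, abs=1e-6)
        assert row["intima_average"] == pytest.approx(0.5, abs=1e-6)
        assert row["ratio_average"] == pytest.approx(0.5, abs=1e-6)
        for s in ("media", "intima", "ratio"):
            assert row[f"{s}_variance"] < 1e-8
            assert row[f"{s}_peak_height"] == 0.0  # constant: no peaks

    def test_focal_bump_raises_intima_peak(self):
        row = extract_features(_bump_annotation(20.0, bump_deg=120.0))
        assert row["intima_peak_height"] > row["intima_average"]
        # peak sits near the bump angle, allowing filter lag
        conditioned = condition(measure_profile(_bump_annotation(20.0, bump_deg=120.0)))
        peaks = find_peaks_circular(
            CircularSeries(np.where(conditioned.valid, conditioned.intima, np.nan), "intima")
        )
        best = max(peaks, key=lambda p: p.height)
        assert abs(best.location_deg - 120.0) <= 10.0

    def test_peak_height_monotone_in_bump_amplitude(self):
        """Across simulated arteries the intima peak height grows with
        the ground-truth focal thickening amplitude."""
        amplitudes = np.linspace(2, 30, 24)
        heights = [
            extract_features(_bump_annotation(a))["intima_peak_height"] for a in amplitudes
        ]
        rho = spearmanr(amplitudes, heights).statistic
        assert rho > 0.95

    def test_rotation_invariance_of_features(self):
        ann = star_annotation(21)
        base = extract_features(ann)
        phi = np.deg2rad(73.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        c = np.array([128.0, 128.0])
        rotated = extract_features(ann.transformed(lambda p: (p - c) @ rot.T + c))
        for s in ("media", "intima", "ratio"):
            for stat in ("average", "median", "variance"):
                assert rotated[f"{s}_{stat}"] == pytest.approx(base[f"{s}_{stat}"], abs=2e-3)

    def test_scale_invariance_of_thickness_features(self):
        ann = star_annotation(22)
        base = extract_features(ann)
        scaled = extract_features(ann.transformed(lambda p: p * 1.7))
        for s in ("media", "intima", "ratio"):
            assert scaled[f"{s}_average"] == pytest.approx(base[f"{s}_average"], abs=1e-3)
        assert scaled["ratio_intima_media_area"] == pytest.approx(
            base["ratio_intima_media_area"], rel=1e-6
        )

    def test_cohort_artery_has_complete_features(self):
        rng = np.random.default_rng(3)
        row = extract_features(make_cohort_artery(rng, score=2, artery_id="x"))
        assert all(np.isfinite(row[name]) for name in FEATURE_NAMES)
        assert row["score"] == 2
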