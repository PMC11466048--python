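"""Radial thickness measurement: annulus recovery, pair selection,
appearance flagging, and equivariance."""

import numpy as np
import pytest

from arterymetrics.contour import ArteryAnnotation, Contour
from arterymetrics.geometry import center_of_mass
from arterymetrics.measurement import (
    EXCL_CROSS,
    EXCL_CROSS_WINDOW,
    EXCL_MISSING,
    EXCL_NONE,
    EXCL_OPEN,
    EXCL_OPEN_WINDOW,
    MeasurementConfig,
    flag_open_lumen,
    measure_profile,
    select_primary_lumen_intima,
)
from arterymetrics.simulate import make_artery

from conftest import circle_contour, star_annotation


class TestSelectPrimaryPair:
    def test_singleton(self, annulus_annotation):
        lumen, intima, others = select_primary_lumen_intima(annulus_annotation)
        assert lumen is annulus_annotation.lumens[0]
        assert intima is annulus_annotation.intimas[0]
        assert others == []

    def test_largest_combined_area_wins(self):
        """Two candidate pairs with areas (100 + 50) vs (90 + 70): the
        second pair (sum 160) must be selected; enumeration oracle."""
        def disc(cx, r):
            return circle_contour((cx, 0), r, n=256)

        r_for = lambda a: np.sqrt(a / np.pi)
        intima_a, lumen_a = disc(-300, r_for(10000)), disc(-300, r_for(5000))
        intima_b, lumen_b = disc(300, r_for(9000)), disc(300, r_for(7000))
        media = Contour(np.array([[-500.0, -500.0], [500.0, -500.0], [500.0, 500.0], [-500.0, 500.0]]))
        ann = ArteryAnnotation(media=media, intimas=[intima_a, intima_b], lumens=[lumen_a, lumen_b])
        lumen, intima, others = select_primary_lumen_intima(ann)
        # exhaustive oracle over containment-consistent pairs
        best = max(
            [(intima_a, lumen_a), (intima_b, lumen_b)],
            key=lambda pair: pair[0].area + pair[1].area,
        )
        assert intima is best[0] and lumen is best[1]
        assert len(others) == 2

    def test_no_lumen_raises(self, annulus_annotation):
        ann = ArteryAnnotation(
            media=annulus_annotation.media, intimas=annulus_annotation.intimas, lumens=[]
        )
        with pytest.raises(ValueError, match="lumen"):
            select_primary_lumen_intima(ann)

    def test_no_containment_consistent_pair_raises(self):
        intima = circle_contour((0, 0), 50, n=128)
        lumen = circle_contour((200, 0), 20, n=128)  # outside the intima
        media = circle_contour((0, 0), 80, n=128)
        ann = ArteryAnnotation(media=media, intimas=[intima], lumens=[lumen])
        with pytest.raises(ValueError, match="containment"):
            select_primary_lumen_intima(ann)


class TestAnnulusRecovery:
    def test_thickness_equals_radius_differences(self, annulus):
        profile = measure_profile(annulus.annotation)
        assert profile.n == 360
        assert profile.valid.all()
        assert np.abs(profile.media - 30.0).max() < 0.1
        assert np.abs(profile.intima - 30.0).max() < 0.1

    def test_off_center_lumen_asymmetry(self):
        """Shifting the lumen +20 px in x thins the intima at 0 deg and
        thickens it at 180 deg."""
        media = circle_contour((0, 0), 100)
        intima = circle_contour((0, 0), 70)
        lumen = circle_contour((20, 0), 40)
        ann = ArteryAnnotation(media=media, intimas=[intima], lumens=[lumen])
        profile = measure_profile(ann)
        assert profile.intima[0] < profile.intima[180]

    def test_missing_samples_recorded_not_zero(self):
        """When the measurement line passes beside a small eccentric
        lumen, the sample is recorded as missing rather than zero."""
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ell = lambda a, b: Contour(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))
        media, intima = ell(110, 80), ell(80, 50)
        lumen = Contour(np.column_stack([30 + 8 * np.cos(theta), 20 + 8 * np.sin(theta)]))
        ann = ArteryAnnotation(media=media, intimas=[intima], lumens=[lumen])
        profile = measure_profile(ann)
        missing = profile.exclusion_reason == EXCL_MISSING
        assert missing.any()
        assert not profile.valid[missing].any()
        assert np.isnan(profile.intima[missing]).all()
        assert not np.any(profile.intima[profile.valid] == 0)


class TestOpenLumenFlagging:
    def test_semicircle_open_arc_flagged(self):
        artery = make_artery("open_lumen")
        profile = measure_profile(artery.annotation)
        truth = artery.truth["open_arc"]
        flagged = ~profile.valid
        recall = (flagged & truth).sum() / truth.sum()
        assert recall >= 0.99
        margin = MeasurementConfig().window_size
        assert (flagged & ~truth).sum() <= 2 * margin

    def test_complete_artery_unchanged(self, annulus):
        profile = measure_profile(annulus.annotation)
        flagged = flag_open_lumen(profile, MeasurementConfig())
        assert flagged.valid.all()
        assert (flagged.exclusion_reason == EXCL_NONE).all()

    def test_window_discards_neighborhoods(self):
        """A run of open-lumen samples contaminates every window that
        holds more than the count limit."""
        cfg = MeasurementConfig(window_size=5, window_count_limit=1)
        n = cfg.n_angles
        profile = measure_profile(make_artery("nested", radii=(100, 70, 40), canvas=256).annotation)
        profile.media[100:104] = 0.5
        profile.intima[100:104] = 0.5
        out = flag_open_lumen(profile, cfg)
        assert set(np.nonzero(out.exclusion_reason == EXCL_OPEN)[0]) == {100, 101, 102, 103}
        window_flagged = np.nonzero(out.exclusion_reason == EXCL_OPEN_WINDOW)[0]
        assert len(window_flagged) > 0
        assert window_flagged.min() >= 100 - cfg.window_size
        assert window_flagged.max() <= 103 + cfg.window_size
        assert not out.valid[98:106].any()


class TestCrossIntersectionFlagging:
    def test_single_lumen_unchanged(self, annulus):
        profile = measure_profile(annulus.annotation)
        assert not np.isin(profile.exclusion_reason, [EXCL_CROSS, EXCL_CROSS_WINDOW]).any()

    def test_secondary_lumen_arc_excluded(self):
        """Every angle whose ray provably crosses the secondary lumen
        (closed-form angular extent) is flagged."""
        artery = make_artery("multi_lumen")
        profile = measure_profile(artery.annotation)
        truth = artery.truth["cross_arc"]
        cross = np.isin(profile.exclusion_reason, [EXCL_CROSS, EXCL_CROSS_WINDOW])
        assert (truth & ~cross).sum() == 0
        # windowed exclusion stays within the closed-form arc plus margin
        margin = MeasurementConfig().window_size
        assert cross.sum() <= truth.sum() + 2 * margin
        # the arc center (angle 280) is excluded
        assert not profile.valid[280]


class TestEquivariance:
    @pytest.mark.parametrize("phi", [30.0, 90.0, 217.0])
    def test_rotation_shifts_profile(self, phi):
        ann = star_annotation(11)
        base = measure_profile(ann)
        c = np.asarray(center_of_mass(ann.lumens[0]))
        rad = np.deg2rad(phi)
        rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        rotated = ann.transformed(lambda pts: (pts - c) @ rot.T + c)
        shifted = measure_profile(rotated)
        k = int(round(phi))
        for name in ("media", "intima"):
            a = np.roll(getattr(base, name), k)
            b = getattr(shifted, name)
            ok = np.isfinite(a) & np.isfinite(b)
            assert ok.mean() > 0.98
            assert np.abs(a[ok] - b[ok]).max() < 0.5

    def test_scale_equivariance(self):
        ann = star_annotation(5)
        base = measure_profile(ann)
        s = 2.5
        scaled_ann = ann.transformed(lambda pts: pts * s)
        scaled = measure_profile(scaled_ann)
        ok = base.valid & scaled.valid
        rel = np.abs(scaled.media[ok] - s * base.media[ok]) / (s * base.media[ok])
        assert rel.max() < 1e-3
        rel_i = np.abs(scaled.intima[ok] - s * base.intima[ok]) / (s * base.intima[ok])
        assert rel_i.max() < 1e-3


class TestProfileContainer:
    def test_frame_round_trip(self, annulus):
        profile = measure_profile(annulus.annotation)
        back = type(profile).from_frame(profile.to_frame())
        assert np.allclose(back.media, profile.media, equal_nan=True)
        assert np.array_equal(back.valid, profile.valid)
        assert np.array_equal(back.exclusion_reason, profile.exclusion_reason)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MeasurementConfig(window_size=4)
        with pytest.raises(ValueError):
            MeasurementConfig(beta_deg=95)
        with pytest.raises(ValueError):
            MeasurementConfig(n_angles=4)
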