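"""Feature definitions against closed-form and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mkflow.event_model import DEFAULT_PANEL, EventImage, EventSet, PanelConfig
from mkflow.morphometry import (
    InvalidMaskError,
    Mask,
    aspect_ratio,
    compute_features,
    compute_mask,
    diameter,
    gradient_rms,
    intensity,
    raw_max_pixel,
)
from mkflow.synthgen import SyntheticConfig, render_event


def _disc_mask(n: int, r: float) -> Mask:
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2  # pixel-centred disc
    return Mask(((yy - c) ** 2 + (xx - c) ** 2) <= r**2, "Ch01")


def _event(raster: np.ndarray, channel: str = "Ch01") -> EventImage:
    return EventImage(0, 0.0, {channel: raster.astype(np.uint16)})


class TestDiameter:
    def test_circular_mask_radius20_at_half_micron(self):
        d = diameter(_disc_mask(64, 20.0), 0.5)
        assert d == pytest.approx(20.0, abs=0.01)  # pixelation only

    def test_square_mask_closed_form(self):
        mask = Mask(np.ones((10, 10), bool), "Ch01")
        assert diameter(mask, 1.0) == pytest.approx(2 * np.sqrt(100 / np.pi), abs=1e-12)

    def test_diameter_area_identity_is_exact(self, default200):
        _, _, features = default200
        ok = features["mask_valid_bf"] == 1.0
        d, a = features.loc[ok, "diameter_bf"], features.loc[ok, "area_bf"]
        np.testing.assert_allclose(d**2 * np.pi / 4, a, rtol=1e-12)

    def test_rendered_mk_diameter_close_to_truth(self):
        rng = np.random.default_rng(11)
        ev = render_event("mk", rng, diameter_um=22.5)
        mask = compute_mask(ev, DEFAULT_PANEL.channel("bf"), "morphology")
        assert 21.0 <= diameter(mask, 0.5) <= 24.0

    def test_invalid_mask_rejected(self):
        bad = Mask(np.zeros((5, 5), bool), "Ch01", valid=False)
        with pytest.raises(InvalidMaskError):
            diameter(bad, 0.5)


class TestAspectRatio:
    def test_circle_is_round(self):
        assert aspect_ratio(_disc_mask(64, 20.0)) == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        yy, xx = np.mgrid[0:80, 0:80]
        mask = Mask(((yy - 40) / 15.0) ** 2 + ((xx - 40) / 30.0) ** 2 <= 1, "Ch01")
        assert aspect_ratio(mask) == pytest.approx(0.5, abs=0.02)

    def test_touching_disc_doublet_is_elongated(self):
        yy, xx = np.mgrid[0:100, 0:100]
        left = (yy - 50) ** 2 + (xx - 35) ** 2 <= 15**2
        right = (yy - 50) ** 2 + (xx - 65) ** 2 <= 15**2
        assert aspect_ratio(Mask(left | right, "Ch01")) < 0.6

    def test_single_pixel_mask_degenerate(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(InvalidMaskError):
            aspect_ratio(Mask(m, "Ch01"))


class TestRawMaxPixel:
    @pytest.mark.parametrize(
        "raster,expected",
        [(np.full((4, 4), 7), 7), (np.eye(4) * 4095, 4095)],
    )
    def test_maximum_over_frame(self, raster, expected):
        assert raw_max_pixel(_event(raster), "Ch01") == expected

    def test_saturated_events_flagged_consistently(self, default200):
        events, truth, features = default200
        cols = [c for c in features.columns if c.startswith("raw_max_pixel_")]
        computed = (features[cols] >= 4030).any(axis=1)
        assert (computed == truth["is_saturated"]).all()


class TestGradientRms:
    def test_constant_raster_scores_zero(self):
        mask = Mask(np.ones((8, 8), bool), "Ch01")
        assert gradient_rms(_event(np.full((8, 8), 1000)), "Ch01", mask) == 0.0

    def test_step_edge_matches_brute_force(self):
        """Independent oracle: explicit nested-loop central differences on a
        vertical 0→4095 step."""
        raster = np.zeros((5, 5))
        raster[:, 3:] = 4095
        mask = Mask(np.ones((5, 5), bool), "Ch01")
        got = gradient_rms(_event(raster), "Ch01", mask)

        norm = raster * 100.0 / 4095
        sq = []
        for i in range(5):
            for j in range(5):
                gy = (
                    (norm[min(i + 1, 4), j] - norm[max(i - 1, 0), j])
                    / (2 if 0 < i < 4 else 1)
                )
                gx = (
                    (norm[i, min(j + 1, 4)] - norm[i, max(j - 1, 0)])
                    / (2 if 0 < j < 4 else 1)
                )
                sq.append(gx**2 + gy**2)
        assert got == pytest.approx(np.sqrt(np.mean(sq)), rel=1e-12)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(2)
        base = rng.integers(500, 1500, size=(16, 16))
        mask = Mask(np.ones((16, 16), bool), "Ch01")
        a = gradient_rms(_event(base), "Ch01", mask)
        b = gradient_rms(_event(base + 700), "Ch01", mask)
        assert a == pytest.approx(b, rel=1e-12)

    def test_tiny_mask_rejected(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True  # 4 px < 9
        with pytest.raises(InvalidMaskError):
            gradient_rms(_event(np.ones((5, 5))), "Ch01", Mask(m, "Ch01"))


class TestIntensity:
    def test_uniform_foreground_closed_form(self):
        raster = np.full((40, 40), 10.0)
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:15] = True  # 50 px
        raster[mask] = 100.0
        got = intensity(_event(raster), "Ch01", Mask(mask, "Ch01"))
        assert got == pytest.approx(50 * (100 - 10), abs=1e-9)

    def test_empty_signal_channel_floors_at_zero(self):
        raster = np.full((30, 30), 20.0)
        mask = np.zeros((30, 30), bool)
        mask[5:10, 5:10] = True
        assert intensity(_event(raster), "Ch01", Mask(mask, "Ch01")) == 0.0

    def test_lymphocytes_brighter_than_mks_on_cd45(self, default200):
        _, truth, features = default200
        lymph = features.loc[truth["label"] == "lymphocyte", "intensity_cd45"]
        mk = features.loc[truth["label"] == "mk", "intensity_cd45"]
        assert lymph.median() > mk.median()


class TestComputeMask:
    def test_all_background_raster_is_invalid(self):
        rng = np.random.default_rng(1)
        raster = rng.poisson(30, size=(60, 60)).astype(np.uint16)
        mask = compute_mask(_event(raster), "Ch01")
        assert not mask.valid

    def test_doublet_becomes_single_component(self):
        rng = np.random.default_rng(9)
        ev = render_event("doublet", rng)
        mask = compute_mask(ev, DEFAULT_PANEL.channel("bf"))
        assert mask.valid
        from scipy import ndimage

        _, n = ndimage.label(mask.pixels)
        assert n == 1

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            compute_mask(_event(np.ones((8, 8))), "Ch01", kind="fancy")


class TestComputeFeatures:
    def test_one_row_per_event_and_deterministic(self, tiny_event_set):
        a = compute_features(tiny_event_set)
        b = compute_features(tiny_event_set)
        assert len(a) == 10
        assert a.equals(b)

    def test_order_equivariance(self, tiny_event_set):
        reversed_set = EventSet(
            panel=tiny_event_set.panel,
            events=list(reversed(tiny_event_set.events)),
        )
        a = compute_features(tiny_event_set)
        b = compute_features(reversed_set)
        assert a.sort_index().equals(b.sort_index())
        assert list(b.index) == list(reversed(a.index.tolist()))

    def test_invalid_mask_yields_sentinels_not_crash(self):
        rng = np.random.default_rng(1)
        blank = {
            ch: rng.poisson(30, size=(120, 120)).astype(np.uint16)
            for ch in DEFAULT_PANEL.channel_map.values()
        }
        events = EventSet(
            panel=DEFAULT_PANEL, events=[EventImage(0, 0.0, blank)]
        )
        table = compute_features(events)
        assert table.loc[0, "mask_valid_bf"] == 0.0
        assert np.isnan(table.loc[0, "diameter_bf"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_features(EventSet(panel=DEFAULT_PANEL, events=[]))
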