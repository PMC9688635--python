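"""Band-difference statistics, classification and trend checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stainsight as ss
from stainsight.color import (
    BandDifferences,
    ClassificationRule,
    DEFAULT_RULE,
    concentration_trend,
    mobile_relative_change,
)
from stainsight.errors import ConfigurationError, SampleSizeError
from stainsight.segmentation import BackgroundEstimate, SegmentedObject
from stainsight.synthetic import STAIN_PROFILES, STAINED_CLASSES


def _obj(mean_rgb, label=1):
    return SegmentedObject(
        label=label, area_px=100, centroid=(0.0, 0.0), mean_rgb=mean_rgb,
        bbox=(0, 0, 10, 10),
    )


BG225 = BackgroundEstimate((225.0, 225.0, 225.0), (0.0, 0.0, 0.0))


class TestBandDifferences:
    @pytest.mark.parametrize(
        "obj_mean, expected",
        [
            ((175.0, 185.0, 185.0), (50.0, 40.0, 40.0)),  # trypan blue cell
            ((225.0, 225.0, 225.0), (0.0, 0.0, 0.0)),
            ((100.0, 105.0, 85.0), (125.0, 120.0, 140.0)),  # bead
        ],
    )
    def test_exact_subtraction(self, obj_mean, expected):
        d = ss.band_differences(_obj(obj_mean), BG225)
        assert d.d_rgb == expected

    def test_signed_not_clamped(self):
        d = ss.band_differences(_obj((230.0, 225.0, 225.0)), BG225)
        assert d.d_rgb[0] == -5.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        d0=st.tuples(*[st.floats(1, 200)] * 3),
        k=st.floats(0.1, 1.0),
    )
    def test_linearity_scaling_deficits_scales_differences(self, d0, k):
        """d is affine in the object mean: scaling deficits by k scales d by k."""
        mean = tuple(225.0 - k * x for x in d0)
        d = ss.band_differences(_obj(mean), BG225)
        np.testing.assert_allclose(d.d, [k * x for x in d0], atol=1e-9)


class TestDominantBand:
    @pytest.mark.parametrize(
        "d, band",
        [((25.0, 135.0, 100.0), "R"), ((100.0, 115.0, 30.0), "B")],
    )
    def test_brightest_band_is_the_dyes_color(self, d, band):
        got, tie = ss.dominant_band(BandDifferences(d))
        assert got == band and not tie

    def test_tie_breaks_to_red_and_flags(self):
        got, tie = ss.dominant_band(BandDifferences((10.0, 10.0, 10.0)))
        assert got == "R" and tie

    @pytest.mark.parametrize("name", sorted(STAINED_CLASSES))
    def test_profile_dominant_band_has_smallest_deficit(self, name):
        p = STAIN_PROFILES[name]
        i = ("R", "G", "B").index(p.dominant_band)
        assert p.deficit_rgb[i] == min(p.deficit_rgb)


class TestClassify:
    @pytest.mark.parametrize(
        "d, expected",
        [
            ((125.0, 120.0, 140.0), "bead"),
            ((15.0, 15.0, 30.0), "unstained"),
            ((100.0, 100.0, 45.0), "MB"),
            ((5.0, 80.0, 80.0), "background"),  # below the stage-1 gate
            ((200.0, 12.0, 12.0), "unknown"),  # matches no class intervals
        ],
    )
    def test_two_stage_rule(self, d, expected):
        assert ss.classify_object(BandDifferences(d), DEFAULT_RULE) == expected

    @pytest.mark.parametrize("name", sorted(STAIN_PROFILES))
    def test_round_trip_every_bundled_profile(self, name):
        d = BandDifferences(STAIN_PROFILES[name].deficit_rgb)
        assert ss.classify_object(d, DEFAULT_RULE) == name

    def test_accuracy_on_noisy_objects(self, noisy_class_recovery):
        """>=99% correct over the segmented noisy recovery fixtures."""
        total = correct = 0
        for name, data in noisy_class_recovery.items():
            for d in data["diffs"]:
                total += 1
                correct += ss.classify_object(d, DEFAULT_RULE) == name
        assert total >= 590
        assert correct / total >= 0.99

    def test_ambiguous_rule_table_rejected(self):
        dup = {
            "a": ss.StainProfile("a", (50.0, 50.0, 50.0)),
            "b": ss.StainProfile("b", (50.0, 50.0, 50.0)),
        }
        with pytest.raises(ConfigurationError):
            ClassificationRule.from_profiles(dup)


class TestSummarize:
    def test_table_rows_overall_range_is_25_to_135(self):
        labeled = [
            (name, BandDifferences(STAIN_PROFILES[name].deficit_rgb))
            for name in STAINED_CLASSES
        ]
        s = ss.summarize_differences(labeled, allow_fewer=True)
        assert s.overall_min == 25.0
        assert s.overall_max == 135.0

    def test_identical_objects_have_zero_sd(self):
        labeled = [("TB", BandDifferences((50.0, 40.0, 40.0)))] * 25
        s = ss.summarize_differences(labeled)
        row = s.table.loc["TB"]
        assert (row[["sd_R", "sd_G", "sd_B"]] == 0.0).all()

    def test_too_few_stained_objects_raises(self):
        labeled = [("TB", BandDifferences((50.0, 40.0, 40.0)))] * 5
        with pytest.raises(SampleSizeError, match="5 stained"):
            ss.summarize_differences(labeled)

    def test_noisy_tb_recovery_within_3(self, noisy_class_recovery):
        mean_d = noisy_class_recovery["TB"]["mean_d"]
        np.testing.assert_allclose(mean_d, (50.0, 40.0, 40.0), atol=3.0)


class TestRelativeChange:
    def test_identical_means_give_zero(self):
        rc = ss.relative_change((200.0, 200.0, 200.0), (200.0, 200.0, 200.0))
        assert rc.pct_rgb == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        rc = ss.relative_change((200.0, 200.0, 200.0), (160.0, 180.0, 198.0))
        np.testing.assert_allclose(rc.pct, (20.0, 10.0, 1.0))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.relative_change((0.0, 200.0, 200.0), (10.0, 10.0, 10.0))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(d=st.tuples(*[st.floats(0, 224)] * 3))
    def test_agrees_with_band_differences_against_background(self, d):
        """When the reference is the background, change/100 == d/background."""
        obj = _obj(tuple(225.0 - x for x in d))
        diffs = ss.band_differences(obj, BG225)
        rc = ss.relative_change(BG225.mean_rgb, obj.mean_rgb)
        np.testing.assert_allclose(rc.pct / 100.0, diffs.d / 225.0, atol=1e-12)


class TestConcentrationTrend:
    def test_decreasing_deficits_with_dilution_are_monotone(self):
        series = [
            (0.1, BandDifferences((50.0, 40.0, 38.0))),
            (0.05, BandDifferences((35.0, 30.0, 34.0))),
            (0.01, BandDifferences((20.0, 22.0, 30.0))),
        ]
        v = concentration_trend(series)
        assert v.is_monotone and not v.is_flat
        assert v.greatest_change_band == "R"

    def test_constant_deficits_are_flat_not_monotone(self):
        series = [
            (c, BandDifferences((40.0, 40.0, 40.0))) for c in (0.1, 0.05, 0.01)
        ]
        v = concentration_trend(series)
        assert v.is_flat and not v.is_monotone

    def test_generated_decreasing_profiles_are_monotone_in_every_band(self):
        """Series rendered with strictly decreasing deficit profiles come out
        monotone through the full measurement pipeline."""
        from conftest import NOISELESS, segment_scene

        series = []
        for conc, scale in ((0.1, 1.0), (0.05, 0.7), (0.01, 0.4)):
            profile = ss.StainProfile(
                "TB", tuple(scale * d for d in (50.0, 40.0, 40.0))
            )
            spec = ss.SceneSpec(
                optics=NOISELESS,
                counts={"TB": 5},
                stain_overrides={"TB": profile},
                seed=17,
            )
            image, _ = ss.render_scene(spec)
            bg, objects = segment_scene(image, 2.0)
            d = np.mean([ss.band_differences(o, bg).d for o in objects], axis=0)
            series.append((conc, BandDifferences(tuple(d))))
        v = concentration_trend(series)
        assert v.is_monotone
        assert all(v.monotone_bands.values())
        assert v.greatest_change_band == "R"

    def test_single_point_rejected(self):
        with pytest.raises(ConfigurationError):
            concentration_trend([(0.1, BandDifferences((1.0, 1.0, 1.0)))])


def test_mobile_relative_change_red_dominates():
    ref, sam = ss.make_mobile_pair(seed=1)
    rc = mobile_relative_change(ref, sam)
    assert rc.pct_rgb[0] == max(rc.pct_rgb)
    assert rc.pct_rgb[2] == min(rc.pct_rgb)
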