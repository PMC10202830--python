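"""Tests for junction morphometrics: zigzag, RFI, linescans, puncta, PLA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctomech.morphometry import (
    JunctionTrace,
    LinescanProfile,
    PunctaTrain,
    ROICounts,
    RegionIntensity,
    filament_dimensions,
    linescan_peak_positions,
    pla_junctional_count,
    puncta_from_profile,
    puncta_metrics,
    relative_intensity,
    zigzag_index,
)
from junctomech.synthdata import gen_linescans, gen_puncta_trains


class TestZigzagIndex:
    def test_straight_trace_is_one(self):
        t = JunctionTrace(points=[(0, 0), (3, 4)])
        assert zigzag_index(t) == pytest.approx(1.0)

    def test_right_angle_toy_trace(self):
        t = JunctionTrace(points=[(0, 0), (1, 0), (1, 1)])
        assert zigzag_index(t) == pytest.approx(np.sqrt(2))

    def test_closed_loop_rejected(self):
        t = JunctionTrace(points=[(0, 0), (1, 0), (0, 0.0)])
        with pytest.raises(ZeroDivisionError):
            zigzag_index(t)

    def test_invariance_under_rigid_motion_and_scaling(self, rng):
        pts = np.cumsum(rng.normal(size=(20, 2)), axis=0)
        zi = zigzag_index(JunctionTrace(points=pts))
        for theta, shift, scale in [(0.7, (3, -2), 2.5), (2.0, (-10, 4), 0.1)]:
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            moved = scale * pts @ rot.T + shift
            assert zigzag_index(JunctionTrace(points=moved)) == pytest.approx(zi)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=15,
        )
    )
    def test_arc_length_never_below_chord(self, pts):
        arr = np.asarray(pts, float)
        if np.any(np.all(np.diff(arr, axis=0) == 0, axis=1)):
            return  # degenerate consecutive duplicates are rejected by the type
        if np.allclose(arr[0], arr[-1]):
            return
        assert zigzag_index(JunctionTrace(points=arr)) >= 1.0 - 1e-9

    def test_collinear_refinement_is_inert(self):
        t1 = JunctionTrace(points=[(0, 0), (2, 0), (2, 2)])
        t2 = JunctionTrace(points=[(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)])
        assert zigzag_index(t2) == pytest.approx(zigzag_index(t1))


class TestRelativeIntensity:
    def test_signal_equals_reference(self):
        rfi, flag = relative_intensity(RegionIntensity(50, 50, 10))
        assert rfi == pytest.approx(1.0) and not flag

    def test_signal_equals_background(self):
        rfi, _ = relative_intensity(RegionIntensity(10, 50, 10))
        assert rfi == 0.0

    def test_midpoint_arithmetic(self):
        rfi, _ = relative_intensity(RegionIntensity(30, 50, 10))
        assert rfi == pytest.approx(0.5)

    def test_negative_numerator_clipped_and_flagged(self):
        rfi, flag = relative_intensity(RegionIntensity(5, 50, 10))
        assert rfi == 0.0 and flag

    def test_reference_below_background_rejected(self):
        with pytest.raises(ValueError):
            relative_intensity(RegionIntensity(30, 10, 20))


class TestLinescan:
    def test_noise_free_offsets_recovered_exactly(self):
        profiles, _ = gen_linescans(seed=0, n=1, noise_sd=0.0)
        _, dist = linescan_peak_positions(profiles[0], "ZO1")
        assert dist["CGN"] == pytest.approx(64.6, abs=1e-6)
        assert dist["NM2B"] == pytest.approx(117.13, abs=1e-6)

    def test_flat_channel_flagged(self):
        pos = np.linspace(-500, 500, 101)
        prof = LinescanProfile(
            positions=pos,
            channels={"ZO1": np.exp(-0.5 * (pos / 34) ** 2), "flat": np.ones_like(pos)},
        )
        fits, dist = linescan_peak_positions(prof, "ZO1")
        assert not fits["flat"].ok
        assert np.isnan(dist["flat"])

    def test_small_recovery_bias_at_high_snr(self):
        # mean absolute offset error below 5% of the true offset
        profiles, _ = gen_linescans(seed=3, n=40)
        d = np.array(
            [linescan_peak_positions(p, "ZO1")[1]["CGN"] for p in profiles]
        )
        assert abs(d.mean() / 64.6 - 1) < 0.05

    def test_two_peak_channel_mean_absolute_offset(self):
        pos = np.linspace(-500, 500, 101)
        mid = np.exp(-0.5 * (pos / 34) ** 2)
        flank = np.exp(-0.5 * ((pos - 120) / 34) ** 2) + np.exp(
            -0.5 * ((pos + 120) / 34) ** 2
        )
        prof = LinescanProfile(positions=pos, channels={"ZO1": mid, "NM2B": flank})
        _, dist = linescan_peak_positions(prof, "ZO1", two_peak_channels=("NM2B",))
        assert dist["NM2B"] == pytest.approx(120.0, rel=1e-3)


class TestPuncta:
    def test_density_per_ten_microns(self):
        train = PunctaTrain(
            junction_length=100.0,
            puncta=[(10 * k + 1.0, 10 * k + 1.3) for k in range(10)],
        )
        assert puncta_metrics(train).count_per_10um == pytest.approx(1.0)

    def test_periodic_train_spacings(self):
        train = PunctaTrain(
            junction_length=10.0,
            puncta=[(0.93 * k, 0.93 * k + 0.27) for k in range(10)],
        )
        m = puncta_metrics(train)
        assert np.allclose(m.punctum_lengths, 0.27)
        assert np.allclose(m.gaps, 0.66)
        assert np.allclose(m.inter_puncta_distances, 0.93)

    def test_empty_train(self):
        m = puncta_metrics(PunctaTrain(junction_length=10.0, puncta=[]))
        assert m.count_per_10um == 0.0
        assert m.gaps.size == 0 and m.inter_puncta_distances.size == 0

    def test_length_conservation(self):
        trains, _ = gen_puncta_trains(seed=1, n=10)
        for t in trains:
            m = puncta_metrics(t)
            starts = [p[0] for p in t.puncta]
            ends = [p[1] for p in t.puncta]
            margins = starts[0] + (t.junction_length - ends[-1])
            total = m.punctum_lengths.sum() + m.gaps.sum() + margins
            assert total == pytest.approx(t.junction_length)

    def test_reversal_invariance(self):
        trains, _ = gen_puncta_trains(seed=2, n=5)
        for t in trains:
            rev = PunctaTrain(
                junction_length=t.junction_length,
                puncta=[
                    (t.junction_length - b, t.junction_length - a)
                    for a, b in t.puncta
                ],
            )
            m, mr = puncta_metrics(t), puncta_metrics(rev)
            assert m.count_per_10um == mr.count_per_10um
            assert np.allclose(np.sort(m.gaps), np.sort(mr.gaps))
            assert np.allclose(
                np.sort(m.inter_puncta_distances),
                np.sort(mr.inter_puncta_distances),
            )

    def test_overlapping_puncta_rejected(self):
        with pytest.raises(ValueError):
            PunctaTrain(junction_length=5.0, puncta=[(0.0, 1.0), (0.5, 2.0)])

    def test_profile_thresholding_roundtrip(self):
        pos = np.linspace(0, 10, 1001)
        intensity = np.where((pos % 0.93) < 0.27, 1.0, 0.05)
        train = puncta_from_profile(pos, intensity)
        m = puncta_metrics(train)
        assert np.allclose(m.inter_puncta_distances, 0.93, atol=0.02)


class TestPLA:
    @pytest.mark.parametrize("cell,cyto,expected,flag", [
        (50, 20, 30, False), (7, 7, 0, False), (10, 15, -5, True),
    ])
    def test_subtraction_and_flag(self, cell, cyto, expected, flag):
        value, flagged = pla_junctional_count(ROICounts(cell, cyto))
        assert value == expected and flagged == flag


class TestFilamentDimensions:
    def test_identical_tiny_groups_p_is_one(self):
        df = pd.DataFrame({"length_nm": [300.0, 310, 290], "width_nm": [11.0, 12, 10]})
        _, pvals = filament_dimensions({"a": df, "b": df.copy()})
        # with every value tied across groups, no table is more extreme
        constant = pd.DataFrame(
            {"length_nm": [300.0] * 3, "width_nm": [11.0] * 3}
        )
        _, pvals_const = filament_dimensions({"a": constant, "b": constant.copy()})
        assert pvals_const["length_nm"] == 1.0
        assert pvals["length_nm"] > 0.5

    def test_large_shift_detected(self, rng):
        a = pd.DataFrame(
            {
                "length_nm": rng.normal(300, 30, 200),
                "width_nm": rng.normal(11, 1.5, 200),
            }
        )
        b = pd.DataFrame(
            {
                "length_nm": rng.normal(600, 30, 200),
                "width_nm": rng.normal(11, 1.5, 200),
            }
        )
        summary, pvals = filament_dimensions({"plain": a, "decorated": b})
        assert pvals["length_nm"] < 1e-4
        assert pvals["width_nm"] > 0.001
        assert set(summary["group"]) == {"plain", "decorated"}

    def test_single_group_summary_only(self):
        df = pd.DataFrame({"length_nm": [1.0, 2], "width_nm": [3.0, 4]})
        summary, pvals = filament_dimensions({"only": df})
        assert pvals == {}
        assert len(summary) == 2
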