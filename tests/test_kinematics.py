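"""Midline fitting, arc length and the contraction measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafseal.errors import ConfigError, DataError
from leafseal.kinematics import (
    DEFAULT_SEGMENTS,
    ContractionSeries,
    MARKER_NAMES,
    MarkerTrack,
    SegmentDefinition,
    absolute_contraction,
    arc_length,
    endpoint_summary,
    fit_midline,
    relative_contraction,
    segment_lengths,
)
from leafseal.synthetic import LeafSimConfig, expected_contraction, simulate_leaf

PARABOLA_ARC_01 = (2 * math.sqrt(5) + math.asinh(2)) / 4  # integral closed form


def _vertical_track(y_by_marker, n_frames=2):
    """Straight vertical leaf: x = 0, given y per marker, static in time."""
    pos = np.zeros((n_frames, 17, 2))
    for j, m in enumerate(MARKER_NAMES):
        pos[:, j, 1] = y_by_marker(m)
    return MarkerTrack(times_s=np.arange(n_frames) * 6.0, positions=pos)


class TestFitMidline:
    def test_collinear_points_zero_residuals(self):
        t = np.linspace(0, 10, 17)
        pts = np.column_stack([t, 2 * t + 1])
        fit = fit_midline(pts, degree=1)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_exact_parabola_coefficients(self):
        x = np.linspace(-1, 1, 17)
        pts = np.column_stack([x, x**2])
        fit = fit_midline(pts, degree=2)
        assert np.allclose(fit.coef, [0.0, 0.0, 1.0], atol=1e-9)

    def test_noisy_parabola_residual_rms_bounded(self, rng):
        x = np.linspace(-1, 1, 17)
        pts = np.column_stack([x, x**2 + rng.normal(0, 0.05, 17)])
        fit = fit_midline(pts, degree=2, align=False)
        assert fit.residual_rms < 2 * 0.05

    def test_rank_deficient_raises(self):
        pts = np.column_stack([np.zeros(5), np.linspace(0, 1, 5)])
        with pytest.raises(DataError):
            fit_midline(pts, degree=2, align=False)

    def test_too_few_points_raises(self):
        with pytest.raises(DataError):
            fit_midline(np.random.default_rng(0).normal(size=(3, 2)),
                        degree=3)

    def test_principal_axis_handles_vertical_cloud(self):
        # a vertical leaf is unfittable as y(x) but fine after rotation
        y = np.linspace(0, 40, 17)
        pts = np.column_stack([np.zeros(17), y])
        fit = fit_midline(pts, degree=3)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)


class TestArcLength:
    def test_flat_line(self):
        pts = np.column_stack([np.linspace(0, 10, 17), np.zeros(17)])
        fit = fit_midline(pts, degree=1, align=False)
        assert arc_length(fit, 0, 10) == pytest.approx(10.0, rel=1e-10)

    def test_parabola_closed_form(self):
        x = np.linspace(0, 1, 17)
        fit = fit_midline(np.column_stack([x, x**2]), degree=2, align=False)
        assert arc_length(fit, 0, 1) == pytest.approx(PARABOLA_ARC_01,
                                                      abs=1e-8)

    def test_symmetric_in_bounds(self):
        x = np.linspace(0, 1, 17)
        fit = fit_midline(np.column_stack([x, x**2]), degree=2, align=False)
        assert arc_length(fit, 1, 0) == arc_length(fit, 0, 1)

    def test_out_of_domain_raises(self):
        x = np.linspace(0, 1, 17)
        fit = fit_midline(np.column_stack([x, x**2]), degree=2, align=False)
        with pytest.raises(DataError):
            arc_length(fit, -0.5, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=2, max_size=5),
           st.floats(0.05, 1.0), st.floats(0.0, 0.9))
    def test_arc_never_shorter_than_chord(self, coefs, span, frac):
        x = np.linspace(0, 5, 17)
        y = np.polynomial.polynomial.polyval(x, np.array(coefs))
        fit = fit_midline(np.column_stack([x, y]), degree=len(coefs) - 1,
                          align=False)
        a = frac * (5 - span)
        b = a + span
        chord = math.hypot(b - a, float(fit(b) - fit(a)))
        assert arc_length(fit, a, b) >= chord - 1e-10


class TestSegmentLengths:
    def test_y_spacing_direct(self):
        y_map = {"p1": 40.0, "p5": 30.0, "p9": 20.0, "p13": 10.0,
                 "p17": 0.0}

        def y_of(m):
            i = int(m[1:])
            anchors = sorted((int(k[1:]), v) for k, v in y_map.items())
            for (i0, y0), (i1, y1) in zip(anchors, anchors[1:]):
                if i0 <= i <= i1:
                    return y0 + (y1 - y0) * (i - i0) / (i1 - i0)
            raise AssertionError

        track = _vertical_track(y_of)
        L = segment_lengths(track, mode="y_spacing")
        assert L["incision"][0] == pytest.approx(10.0)
        assert L["apex"][0] == pytest.approx(10.0)
        assert L["base"][0] == pytest.approx(20.0)

    def test_arc_equals_y_spacing_on_straight_leaf(
        self, straight_leaf_noiseless
    ):
        _, track = straight_leaf_noiseless
        La = segment_lengths(track, mode="arc", degree=1)
        Ly = segment_lengths(track, mode="y_spacing")
        for sid in La:
            assert np.allclose(La[sid], Ly[sid], atol=1e-9)

    def test_recurved_lengths_match_generator_closed_form(
        self, recurved_leaf_noiseless
    ):
        cfg, track = recurved_leaf_noiseless
        L = segment_lengths(track, mode="arc", degree=5)
        t_min = track.times_s / 60.0
        L_inc = cfg.leaf_length_mm * 2 / 3 + 2.0
        s0 = {"apex": cfg.leaf_length_mm - L_inc,
              "incision": 4.0,
              "base": cfg.leaf_length_mm * 2 / 3 - 2.0}
        for sid, L0 in s0.items():
            factor = 1 + cfg.segment_plateaus[sid] * (
                1 - np.exp(-t_min / cfg.tau_min))
            truth = L0 * factor
            rel = np.max(np.abs(L[sid] - truth) / truth)
            assert rel < 1e-6

    def test_missing_marker_error_names_frame_and_marker(self):
        import pandas as pd

        track = _vertical_track(lambda m: float(int(m[1:])))
        df = track.to_frame()
        df = df[~((df["frame"] == 1) & (df["marker"] == "p9"))]
        with pytest.raises(DataError, match="p9.*frame 1|frame 1.*p9"):
            MarkerTrack.from_frame(df)

    def test_noncontiguous_segments_rejected(self):
        with pytest.raises(ConfigError):
            SegmentDefinition((("apex", "p1", "p5"), ("base", "p9", "p17")))


class TestContractionMeasures:
    @pytest.mark.parametrize("L, expected", [
        ([10.0, 10.0], 0.0),
        ([10.0, 9.0], -0.10),
        ([10.0, 10.5], 0.05),
    ])
    def test_absolute_contraction_arithmetic(self, L, expected):
        eps = absolute_contraction(np.array(L))
        assert eps[0] == 0.0
        assert eps[1] == pytest.approx(expected)

    def test_zero_initial_length_raises(self):
        with pytest.raises(DataError):
            absolute_contraction(np.array([0.0, 1.0]))

    def test_relative_contraction_arithmetic(self):
        out = relative_contraction(np.array([-0.10]), np.array([9.0]),
                                   np.array([30.0]))
        assert out[0] == pytest.approx(-0.03)

    def test_single_segment_relative_equals_absolute(self):
        eps = np.array([0.0, -0.04, -0.07])
        L = np.array([20.0, 19.2, 18.6])
        assert np.allclose(relative_contraction(eps, L, L), eps)

    def test_zero_eps_gives_zero_relative(self):
        assert relative_contraction(np.zeros(3), np.ones(3),
                                    np.full(3, 4.0)).tolist() == [0, 0, 0]

    def test_relative_never_exceeds_absolute(self, straight_leaf_noiseless):
        _, track = straight_leaf_noiseless
        series = ContractionSeries.from_track(track, mode="y_spacing")
        for sid in series.segments:
            assert np.all(np.abs(series.eps_rel[sid])
                          <= np.abs(series.eps_abs[sid]) + 1e-15)

    def test_scale_invariance(self, recurved_leaf_noiseless):
        _, track = recurved_leaf_noiseless
        scaled = MarkerTrack(times_s=track.times_s,
                             positions=track.positions * 3.7,
                             markers=track.markers)
        for mode, deg in (("y_spacing", 1), ("arc", 3)):
            e1 = ContractionSeries.from_track(track, mode=mode,
                                              degree=deg).eps_abs
            e2 = ContractionSeries.from_track(scaled, mode=mode,
                                              degree=deg).eps_abs
            for sid in e1:
                assert np.max(np.abs(e1[sid] - e2[sid])) < 1e-12

    def test_eps_zero_at_t0_for_every_segment(self, recurved_leaf_noiseless):
        _, track = recurved_leaf_noiseless
        series = ContractionSeries.from_track(track, mode="arc")
        for sid in series.segments:
            assert series.eps_abs[sid][0] == 0.0

    def test_total_length_is_sum_of_segments(self, straight_leaf_noiseless):
        _, track = straight_leaf_noiseless
        series = ContractionSeries.from_track(track, mode="y_spacing")
        summed = sum(series.lengths[s] for s in series.segments)
        assert np.allclose(series.total_length, summed, rtol=1e-14)


class TestEndpointSummary:
    def test_constant_series_any_window(self, straight_leaf_noiseless):
        _, track = straight_leaf_noiseless
        series = ContractionSeries.from_track(track, mode="y_spacing")
        flat = ContractionSeries(
            times_s=series.times_s,
            lengths={s: np.full_like(series.lengths[s], 10.0)
                     for s in series.segments},
        )
        for w in (1, 5, 50):
            assert endpoint_summary(flat, w) == {
                s: 0.0 for s in series.segments}

    def test_window_one_is_final_value(self, straight_leaf_noiseless):
        cfg, track = straight_leaf_noiseless
        series = ContractionSeries.from_track(track, mode="y_spacing")
        out = endpoint_summary(series, window_frames=1)
        for sid, plateau in cfg.segment_plateaus.items():
            assert out[sid] == pytest.approx(
                expected_contraction(plateau, cfg.tau_min, cfg.duration_min),
                abs=1e-10,
            )

    def test_wider_window_reduces_variance(self):
        # across seeds, the 5-frame median endpoint is less variable
        # than the single final frame
        est = {1: [], 5: []}
        for seed in range(40):
            cfg = LeafSimConfig(
                shape_profile="straight", noise_sd_mm=0.05, seed=seed,
                segment_plateaus={"apex": -0.03, "incision": -0.08,
                                  "base": -0.04},
                duration_min=10.0,
            )
            series = ContractionSeries.from_track(simulate_leaf(cfg),
                                                  mode="y_spacing")
            for w in est:
                est[w].append(endpoint_summary(series, w)["incision"])
        assert np.var(est[5]) < np.var(est[1])

    def test_invalid_window_raises(self, straight_leaf_noiseless):
        _, track = straight_leaf_noiseless
        series = ContractionSeries.from_track(track, mode="y_spacing")
        with pytest.raises(ConfigError):
            endpoint_summary(series, 0)
        with pytest.raises(ConfigError):
            endpoint_summary(series, len(series.times_s) + 1)
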