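"""Nictation metrics, batch normalization, Dunnett comparisons, track speeds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neuropep.behavior import (
    BoutTrack,
    LocomotionTrack,
    NictationComparison,
    bouts_to_frame,
    dunnett_compare,
    frame_to_tracks,
    max_abs_dunnett_cdf,
    metrics_frame,
    nictation_metrics,
    normalize_batches,
    speeds_frame,
    track_speed,
)


def _track(bouts, t_total=90.0, **kw):
    defaults = dict(individual="w1", group="control", batch="b1")
    defaults.update(kw)
    return BoutTrack(t_total=t_total, bouts=bouts, **defaults)


@st.composite
def bout_tracks(draw):
    t_total = draw(st.floats(30.0, 120.0))
    n = draw(st.integers(0, 6))
    points = sorted(
        draw(
            st.lists(
                st.floats(0.0, 1.0, exclude_max=False),
                min_size=2 * n, max_size=2 * n, unique=True,
            )
        )
    )
    bouts = [
        (points[2 * i] * t_total, points[2 * i + 1] * t_total) for i in range(n)
    ]
    bouts = [(s, e) for s, e in bouts if e > s]
    return _track(bouts, t_total=t_total)


class TestNictationMetrics:
    def test_worked_example(self):
        m = nictation_metrics(_track([(10, 25), (40, 55)], t_total=90))
        assert m.t_nict == 30
        assert m.nictation_ratio == pytest.approx(1 / 3)
        assert m.initiation_index == pytest.approx(2 / 60)
        assert m.average_duration == pytest.approx(15.0)

    def test_no_bouts(self):
        m = nictation_metrics(_track([]))
        assert m.nictation_ratio == 0
        assert m.initiation_index == 0
        assert math.isnan(m.average_duration)

    def test_full_window_nictation(self):
        m = nictation_metrics(_track([(0, 90)], t_total=90))
        assert m.nictation_ratio == 1.0
        assert math.isnan(m.initiation_index)
        assert m.average_duration == 90.0

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _track([(10, 30), (20, 40)])

    def test_bout_outside_window_rejected(self):
        with pytest.raises(ValueError):
            _track([(80, 95)], t_total=90)

    @settings(derandomize=True, max_examples=150)
    @given(track=bout_tracks())
    def test_algebraic_identity(self, track):
        """initiation_index × average_duration = ratio / (1 − ratio)
        whenever all three are defined."""
        m = nictation_metrics(track)
        if m.n_nict > 0 and m.nictation_ratio < 1:
            lhs = m.initiation_index * m.average_duration
            rhs = m.nictation_ratio / (1 - m.nictation_ratio)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_ratio_invariant_to_bout_splitting(self):
        whole = nictation_metrics(_track([(10, 30)], t_total=90))
        split = nictation_metrics(_track([(10, 20), (20, 30)], t_total=90))
        assert split.nictation_ratio == whole.nictation_ratio
        assert split.n_nict == whole.n_nict + 1
        assert split.initiation_index > whole.initiation_index

    def test_frame_round_trip(self):
        tracks = [
            _track([(1, 5), (10, 20)], individual="a"),
            _track([], individual="b"),
        ]
        back = frame_to_tracks(bouts_to_frame(tracks))
        assert [t.bouts for t in back] == [t.bouts for t in tracks]


class TestBatchNormalization:
    def _data(self, batches):
        rows = []
        for batch, groups in batches.items():
            for group, values in groups.items():
                for i, v in enumerate(values):
                    rows.append(
                        {"individual": f"{batch}{group}{i}", "group": group,
                         "batch": batch, "nictation_ratio": v}
                    )
        return pd.DataFrame(rows)

    def test_single_batch_identity(self):
        data = self._data({"b1": {"control": [0.3, 0.4, 0.5], "mut": [0.6, 0.7]}})
        norm = normalize_batches(data, control="control")
        assert np.allclose(norm, data["nictation_ratio"])

    def test_control_medians_aligned_across_batches(self):
        data = self._data(
            {"b1": {"control": [0.2, 0.3, 0.4], "mut": [0.5, 0.6]},
             "b2": {"control": [0.5, 0.6, 0.7], "mut": [0.8, 0.9]}}
        )
        grand = data.loc[data["group"] == "control", "nictation_ratio"].median()
        data = data.assign(norm=normalize_batches(data, control="control"))
        med = data[data["group"] == "control"].groupby("batch")["norm"].median()
        # batch control medians coincide with the grand control median
        assert np.allclose(med, grand)

    def test_whole_batch_scaling_invariance(self):
        # the grand control median is robust to rescaling batch b3 (its
        # control values stay above the pooled median), so normalization
        # must undo the batch-level scale exactly
        data = self._data(
            {"b1": {"control": [0.2, 0.3, 0.4], "mut": [0.5, 0.6]},
             "b2": {"control": [0.25, 0.35, 0.45], "mut": [0.55, 0.65]},
             "b3": {"control": [0.5, 0.52, 0.55], "mut": [0.6]}}
        )
        n1 = normalize_batches(data, control="control")
        scaled = data.copy()
        scaled.loc[scaled["batch"] == "b3", "nictation_ratio"] *= 1.7
        n2 = normalize_batches(scaled, control="control")
        assert np.allclose(n1, n2)

    def test_missing_control_batch_rejected(self):
        data = self._data(
            {"b1": {"control": [0.2, 0.3], "mut": [0.5]},
             "b2": {"mut": [0.8, 0.9]}}
        )
        with pytest.raises(ValueError, match="b2"):
            normalize_batches(data, control="control")

    def test_ratios_clipped_to_unit_interval(self):
        data = self._data(
            {"b1": {"control": [0.1, 0.2, 0.3], "mut": [0.9, 0.95]},
             "b2": {"control": [0.05, 0.06, 0.07], "mut": [0.5]}}
        )
        norm = normalize_batches(data, control="control")
        assert norm.between(0, 1).all()


def _groups_frame(groups: dict) -> pd.DataFrame:
    rows = [
        {"individual": f"{g}{i}", "group": g, "value": v}
        for g, values in groups.items()
        for i, v in enumerate(values)
    ]
    return pd.DataFrame(rows)


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self):
        data = _groups_frame(
            {"control": [0.30, 0.35, 0.40, 0.38, 0.33],
             "mut": [0.50, 0.55, 0.48, 0.52]}
        )
        res = dunnett_compare(data, "value", control="control")
        row = res.table.set_index("group").loc["mut"]
        t, p = stats.ttest_ind(
            data.loc[data["group"] == "mut", "value"],
            data.loc[data["group"] == "control", "value"],
            equal_var=True,
        )
        assert row["t"] == pytest.approx(t, abs=1e-12)
        assert row["p_adjusted"] == pytest.approx(p, abs=1e-9)

    def test_treatment_equal_to_control_p_near_one(self):
        vals = [0.3, 0.35, 0.4, 0.32, 0.38]
        data = _groups_frame({"control": vals, "m1": vals, "m2": [0.6] * 5})
        res = dunnett_compare(data, "value", control="control")
        assert res.table.set_index("group").loc["m1", "p_adjusted"] > 0.99

    def test_adjusted_p_geq_unadjusted_for_multiple_comparisons(self, rng):
        data = _groups_frame(
            {g: list(rng.normal(0.4, 0.1, 6)) for g in
             ["control", "m1", "m2", "m3"]}
        )
        res = dunnett_compare(data, "value", control="control")
        sub = res.table[res.table["group"] != "control"]
        assert (sub["p_adjusted"] >= sub["p_unadjusted"] - 1e-12).all()

    def test_quadrature_matches_monte_carlo_oracle(self):
        """Fixed toy data, 3 balanced groups: the quadrature-adjusted p
        matches a seeded Monte-Carlo estimate of the max-|t| null
        distribution within 0.005."""
        data = _groups_frame(
            {"control": [0.30, 0.35, 0.40, 0.38],
             "m1": [0.45, 0.50, 0.42, 0.47],
             "m2": [0.33, 0.36, 0.31, 0.39]}
        )
        res = dunnett_compare(data, "value", control="control")
        ns = data.groupby("group")["value"].count()
        df = int(ns.sum() - 3)
        lam = np.sqrt(np.array([4.0, 4.0]) / (np.array([4.0, 4.0]) + 4.0))
        rng = np.random.default_rng(12345)
        n_mc = 400_000
        z0 = rng.standard_normal(n_mc)
        zi = rng.standard_normal((n_mc, 2))
        chi = np.sqrt(rng.chisquare(df, n_mc) / df)
        T = (lam * z0[:, None] + np.sqrt(1 - lam**2) * zi) / chi[:, None]
        max_abs = np.abs(T).max(axis=1)
        for grp in ("m1", "m2"):
            row = res.table.set_index("group").loc[grp]
            p_mc = float(np.mean(max_abs >= abs(row["t"])))
            assert row["p_adjusted"] == pytest.approx(p_mc, abs=0.005)

    def test_quadrature_matches_scipy_dunnett(self):
        """Independent cross-check against SciPy's Dunnett implementation."""
        rng = np.random.default_rng(7)
        control = rng.normal(0.35, 0.08, 8)
        m1 = rng.normal(0.45, 0.08, 6)
        m2 = rng.normal(0.36, 0.08, 7)
        data = _groups_frame(
            {"control": list(control), "m1": list(m1), "m2": list(m2)}
        )
        res = dunnett_compare(data, "value", control="control")
        sp = stats.dunnett(m1, m2, control=control, random_state=1)
        ours = res.table.set_index("group").loc[["m1", "m2"], "p_adjusted"].values
        assert np.allclose(ours, sp.pvalue, atol=2e-3)

    def test_mc_method_agrees_with_quadrature(self):
        data = _groups_frame(
            {"control": [0.30, 0.35, 0.40, 0.38],
             "m1": [0.45, 0.50, 0.42, 0.47],
             "m2": [0.33, 0.36, 0.31, 0.39]}
        )
        q = dunnett_compare(data, "value", control="control")
        mc = dunnett_compare(
            data, "value", control="control", method="mc",
            mc_samples=400_000, mc_seed=3,
        )
        assert np.allclose(
            q.table["p_adjusted"], mc.table["p_adjusted"], atol=0.005
        )

    def test_cdf_sane_limits(self):
        lam = np.array([0.7, 0.7])
        assert max_abs_dunnett_cdf(0.0, 10, lam) == 0.0
        assert max_abs_dunnett_cdf(50.0, 10, lam) == pytest.approx(1.0, abs=1e-6)

    def test_control_row_convention(self):
        data = _groups_frame(
            {"control": [0.3, 0.4, 0.35], "m1": [0.5, 0.6, 0.55]}
        )
        res = dunnett_compare(data, "value", control="control")
        row = res.table.set_index("group").loc["control"]
        assert row["p_adjusted"] == 1.0
        assert "Dunnett" in res.summary()

    def test_undersized_group_rejected(self):
        data = _groups_frame({"control": [0.3, 0.4], "m1": [0.5]})
        with pytest.raises(ValueError, match="fewer than 2"):
            NictationComparison(data, "value", control="control")


class TestTrackSpeed:
    def test_straight_line_arithmetic(self):
        # 100 px over 10 s at 2 um/px -> 20 um/s; pad to pass the 30 s rule
        times = np.arange(0, 41.0, 1.0)
        x = 10.0 * times  # 10 px/s
        track = LocomotionTrack("t1", "g", times, x, np.zeros_like(x),
                                pixel_to_micrometer=2.0)
        assert track_speed(track) == pytest.approx(20.0)

    def test_short_track_excluded(self):
        times = np.arange(0, 29.5, 0.5)
        track = LocomotionTrack("t1", "g", times, times, times)
        assert track_speed(track) is None
        df = speeds_frame([track])
        assert not df["included"].iloc[0]

    def test_boundary_thirty_seconds_included(self):
        times = np.arange(0, 30.5, 0.5)
        track = LocomotionTrack("t1", "g", times, times, np.zeros_like(times))
        assert track_speed(track) is not None

    def test_circular_path_speed(self):
        # fine sampling of a circle: mean speed -> circumference / period
        period, radius = 60.0, 50.0
        times = np.linspace(0, period, 6001)
        theta = 2 * np.pi * times / period
        track = LocomotionTrack(
            "t1", "g", times, radius * np.cos(theta), radius * np.sin(theta),
            pixel_to_micrometer=1.5,
        )
        expected = 1.5 * 2 * np.pi * radius / period
        assert track_speed(track) == pytest.approx(expected, rel=1e-4)

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            LocomotionTrack("t1", "g", [0, 1, 1], [0, 1, 2], [0, 0, 0])


class TestMetricsFrame:
    def test_columns_and_values(self):
        tracks = [
            _track([(0, 30)], individual="a", group="wt"),
            _track([], individual="b", group="wt"),
        ]
        df = metrics_frame(tracks)
        assert list(df["individual"]) == ["a", "b"]
        assert df.loc[0, "nictation_ratio"] == pytest.approx(1 / 3)
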