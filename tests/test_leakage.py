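"""Compartmental MFI, Vascular Leakage and Leakage Index statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fadf import (
    ChannelFrame,
    CompartmentMasks,
    KineticParams,
    MFIMeasurement,
    aggregate_longitudinal,
    leakage_index,
    measure_mfi,
    vascular_leakage,
)
from conftest import render_variant


def _masks(vessel, evs, channel="green"):
    return CompartmentMasks(vessel, evs, channel, 4.0, 0.0)


def _meas(t, r, channel="green"):
    """Measurement with out/in ratio exactly r."""
    return MFIMeasurement(t, channel, mfi_in=1.0, mfi_out=r, n_in=10, n_out=10)


def brute_force_median(values):
    s = sorted(float(v) for v in values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


class TestMeasureMFI:
    def test_hand_computed_medians(self):
        px = np.zeros((2, 3))
        px[0] = [10, 20, 30]
        px[1] = [1, 2, 3]
        vessel = np.zeros((2, 3), bool)
        vessel[0] = True
        evs = ~vessel
        frame = ChannelFrame(px, "green", 0.0)
        m = measure_mfi(frame, _masks(vessel, evs))
        assert m.mfi_in == 20 and m.mfi_out == 2
        assert m.n_in == 3 and m.n_out == 3

    def test_uniform_image_equal_compartments(self):
        px = np.full((4, 4), 7.0)
        vessel = np.zeros((4, 4), bool)
        vessel[:2] = True
        m = measure_mfi(ChannelFrame(px, "green", 0.0), _masks(vessel, ~vessel))
        assert m.mfi_in == m.mfi_out == 7.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_median_oracle(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.uniform(0, 1000, (64, 64))
        vessel = rng.random((64, 64)) < 0.3
        if not vessel.any() or vessel.all():
            return
        frame = ChannelFrame(px, "green", 0.0)
        m = measure_mfi(frame, _masks(vessel, ~vessel))
        assert m.mfi_in == brute_force_median(px[vessel])
        assert m.mfi_out == brute_force_median(px[~vessel])

    def test_mean_statistic(self):
        px = np.zeros((1, 4))
        px[0] = [1, 2, 3, 10]
        vessel = np.array([[True, True, True, False]])
        m = measure_mfi(ChannelFrame(px, "green", 0.0), _masks(vessel, ~vessel), "mean")
        assert m.mfi_in == pytest.approx(2.0)

    def test_empty_masks_error(self):
        px = np.ones((4, 4))
        frame = ChannelFrame(px, "green", 5.0)
        empty = np.zeros((4, 4), bool)
        with pytest.raises(ValueError, match="no vessels detected at t=5"):
            measure_mfi(frame, _masks(empty, ~empty))
        with pytest.raises(ValueError, match="extravascular"):
            measure_mfi(frame, _masks(~empty, empty))


class TestVascularLeakage:
    def test_no_leak_series_is_unity(self):
        vl = vascular_leakage([_meas(t, 0.2) for t in (0, 5, 10)])
        assert np.allclose(vl["vl"], 1.0)
        assert vl["vl"].iloc[0] == 1.0

    def test_ratio_relative_to_baseline(self):
        vl = vascular_leakage([_meas(0, 0.1), _meas(30, 0.3)])
        assert vl["vl"].iloc[-1] == pytest.approx(3.0)

    def test_difference_mode(self):
        vl = vascular_leakage([_meas(0, 0.1), _meas(30, 0.3)], mode="difference")
        assert vl["vl"].iloc[0] == 0.0
        assert vl["vl"].iloc[-1] == pytest.approx(0.2)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            vascular_leakage([_meas(5, 0.1), _meas(10, 0.2)])

    def test_zero_mfi_in_rejected(self):
        bad = MFIMeasurement(0.0, "green", 0.0, 0.5, 5, 5)
        with pytest.raises(ValueError, match="mfi_in"):
            vascular_leakage([bad, _meas(5, 0.1)])

    def test_zero_baseline_ratio_rejected(self):
        with pytest.raises(ValueError, match=r"R\(0\)"):
            vascular_leakage([_meas(0, 0.0), _meas(5, 0.1)])

    def test_mixed_channels_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            vascular_leakage([_meas(0, 0.1), _meas(5, 0.1, channel="red")])

    @given(c=st.floats(0.05, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_channel_scale_invariance(self, c):
        # scaling a whole channel cancels in the baseline normalization
        ms = [_meas(t, 0.1 + 0.02 * t) for t in (0, 5, 10, 15)]
        scaled = [
            MFIMeasurement(m.time_min, m.channel, c * m.mfi_in, c * m.mfi_out, m.n_in, m.n_out)
            for m in ms
        ]
        np.testing.assert_allclose(
            vascular_leakage(ms)["vl"], vascular_leakage(scaled)["vl"], rtol=1e-12
        )


class TestLeakageIndex:
    def test_ratio_of_channel_leakages(self):
        vg = vascular_leakage([_meas(0, 0.1), _meas(30, 0.3)])
        vr = vascular_leakage([_meas(0, 0.2, "red"), _meas(30, 0.2, "red")])
        series = leakage_index(vg, vr)
        assert series.table["li"].iloc[0] == 1.0
        assert series.li_30 == pytest.approx(3.0)
        assert series.endpoint_min == 30.0

    def test_mismatched_grids_rejected(self):
        vg = vascular_leakage([_meas(0, 0.1), _meas(30, 0.3)])
        vr = vascular_leakage([_meas(0, 0.2, "red"), _meas(25, 0.2, "red")])
        with pytest.raises(ValueError, match="mismatched time grids"):
            leakage_index(vg, vr)

    def test_endpoint_fallback_warns(self):
        vg = vascular_leakage([_meas(0, 0.1), _meas(20, 0.2)])
        vr = vascular_leakage([_meas(0, 0.2, "red"), _meas(20, 0.2, "red")])
        with pytest.warns(UserWarning, match="last time point"):
            series = leakage_index(vg, vr, endpoint_min=30.0)
        assert series.endpoint_min == 20.0

    @given(
        gains=st.lists(st.floats(0.1, 5.0), min_size=4, max_size=4),
    )
    @settings(max_examples=25, deadline=None)
    def test_shared_gain_profile_cancels(self, gains):
        # a per-time-point gain applied to both channels leaves LI untouched
        times = (0, 10, 20, 30)
        base_g = [_meas(t, 0.1 + 0.01 * t) for t in times]
        base_r = [_meas(t, 0.2, "red") for t in times]

        def drifted(ms):
            return [
                MFIMeasurement(
                    m.time_min, m.channel, g * m.mfi_in, g * m.mfi_out, m.n_in, m.n_out
                )
                for g, m in zip(gains, ms)
            ]

        li0 = leakage_index(vascular_leakage(base_g), vascular_leakage(base_r)).table["li"]
        li1 = leakage_index(
            vascular_leakage(drifted(base_g)), vascular_leakage(drifted(base_r))
        ).table["li"]
        np.testing.assert_allclose(li0, li1, rtol=1e-10)

    def test_vl_matches_analytic_kinetics_through_renderer(self, default_tree):
        # noiseless render measured under ground-truth masks reproduces the
        # closed-form (baseline + gain*dilution*c_ev)/(baseline + gain*c_in)
        kin = KineticParams(0.2, 0.05)
        session, truth = render_variant(default_tree, kin_det=kin, noise_sd=0.0)
        masks = CompartmentMasks(truth.vessel_mask, truth.evs_mask, "green", 4.0, 0.0)
        ms = [measure_mfi(g, masks) for _, g, _ in session.frames]
        vl = vascular_leakage(ms)["vl"].to_numpy()

        cfg = truth.config
        ci = truth.curves["c_in_green"].to_numpy()
        ce = truth.curves["c_ev_green"].to_numpy()
        r = (cfg.baseline + cfg.gain * cfg.evs_dilution * ce) / (cfg.baseline + cfg.gain * ci)
        np.testing.assert_allclose(vl, r / r[0], atol=1e-6)


class TestAggregateLongitudinal:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows, columns=["subject", "session", "li_30"])

    def test_single_subject_normalization(self):
        records = self._records([("m1", 90, 2.0), ("m1", 258, 4.0)])
        per_subject, cohort = aggregate_longitudinal(records, 90)
        assert per_subject["normalized"].tolist() == [1.0, 2.0]
        assert cohort.loc[cohort["session"] == 258, "mean_normalized"].iloc[0] == 2.0

    def test_identical_sessions_have_zero_sem(self):
        rows = [(f"m{i}", day, 3.0) for i in range(3) for day in (90, 180)]
        _, cohort = aggregate_longitudinal(self._records(rows), 90)
        assert np.allclose(cohort["mean_normalized"], 1.0)
        assert np.allclose(cohort["sem"], 0.0)

    def test_missing_reference_rejected(self):
        records = self._records([("m1", 90, 2.0)])
        with pytest.raises(ValueError, match="reference session"):
            aggregate_longitudinal(records, 40)

    def test_simulated_cohort_recovers_rising_trend(self):
        rng = np.random.default_rng(0)
        days = [90, 150, 210, 258]
        trend = {90: 1.5, 150: 2.0, 210: 3.0, 258: 4.5}
        rows = [
            (f"m{i}", d, trend[d] * rng.lognormal(0.0, 0.08))
            for i in range(12)
            for d in days
        ]
        _, cohort = aggregate_longitudinal(self._records(rows), 90)
        for d in days:
            row = cohort[cohort["session"] == d].iloc[0]
            assert abs(row["mean"] - trend[d]) <= 2 * row["sem"] + 1e-9 * trend[d]
        means = cohort.sort_values("session")["mean_normalized"].to_numpy()
        assert (np.diff(means) > 0).all()
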