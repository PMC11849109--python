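"""Kinetic forward model and voxel-wise CBF/ATT estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mroximetry import (AcquisitionSchedule, KineticConstants, fit_volume,
                        fit_voxel, pcasl_signal, t1_blood_from_hct,
                        territory_median)
from mroximetry.errors import EmptyRegionError


def bolus_integral_oracle(cbf, att, tau, w, constants, m0=1.0, step_ms=1.0):
    """Independent 1-ms midpoint integration of labelled-bolus delivery.

    A blood element labelled at time s in [0, tau] arrives at the voxel at
    s + att and decays at the T1 of blood from the moment of labelling; the
    measured signal at t = tau + w sums the surviving magnetisation of all
    arrived elements, i.e. those with s <= min(tau, t - att). Integrating
    over exactly that support keeps the midpoint rule's error quadratic in
    the step instead of being dominated by the arrival cutoff.
    """
    t = (tau + w) / 1000.0
    t1b = constants.t1_blood / 1000.0
    f = cbf / 6000.0
    upper = min(tau, tau + w - att) / 1000.0
    if upper <= 0.0:
        return 0.0
    n = max(1, int(np.ceil(upper / (step_ms / 1000.0))))
    edges = np.linspace(0.0, upper, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    integral = np.sum(np.exp(-(t - mids) / t1b) * widths)
    return 2.0 * constants.alpha * (m0 / constants.lam) * f * integral


class TestT1Blood:
    @pytest.mark.parametrize("hct,expected_ms", [(0.42, 1671.1), (0.35, 1779.4)])
    def test_linear_relaxivity_relation(self, hct, expected_ms):
        assert t1_blood_from_hct(hct) == pytest.approx(expected_ms, abs=0.1)

    def test_monotone_decreasing_in_hct(self):
        hcts = np.linspace(0.2, 0.6, 9)
        t1s = [t1_blood_from_hct(h) for h in hcts]
        assert np.all(np.diff(t1s) < 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_hct(self, bad):
        with pytest.raises(ValueError):
            t1_blood_from_hct(bad)


class TestForwardModel:
    def test_zero_before_arrival(self, constants):
        assert pcasl_signal(50.0, 1500.0, 573.0, 700.0, constants) == 0.0

    def test_zero_flow_gives_zero_signal(self, schedule, constants):
        sig = pcasl_signal(0.0, 1200.0, schedule.tau, schedule.pld, constants)
        assert np.all(sig == 0.0)

    def test_matches_numerical_bolus_integration(self, constants):
        """Closed form vs 1-ms integration of the delivery-and-decay integral."""
        val = pcasl_signal(50.0, 1200.0, 2024.0, 2024.0, constants, 1.0)
        oracle = bolus_integral_oracle(50.0, 1200.0, 2024.0, 2024.0, constants)
        assert val == pytest.approx(oracle, rel=1e-4)

    def test_continuous_at_piecewise_boundaries(self, constants):
        att, tau = 1300.0, 885.0
        for t_edge in (att, att + tau):  # arrival and end-of-bolus edges
            w_edge = t_edge - tau
            lo = pcasl_signal(50.0, att, tau, w_edge - 1e-6, constants)
            hi = pcasl_signal(50.0, att, tau, w_edge + 1e-6, constants)
            assert hi == pytest.approx(lo, abs=1e-8)

    def test_decays_to_zero_at_long_pld(self, constants):
        w = np.array([2000.0, 6000.0, 12000.0, 24000.0])
        sig = pcasl_signal(50.0, 1200.0, 885.0, w, constants)
        assert np.all(np.diff(sig) < 0)
        assert sig[-1] < 1e-5 * sig[0]

    def test_matches_single_pld_quantification_form(self, constants):
        """For t >= att+tau the model equals the standard single-PLD formula."""
        cbf, att, tau, w, m0 = 47.0, 900.0, 1800.0, 1800.0, 1.0
        t1b_s = constants.t1_blood / 1000.0
        dm = pcasl_signal(cbf, att, tau, w, constants, m0)
        # white-paper quantification solved for delta-M (ATT cancels)
        expected = (2 * constants.alpha * m0 * (cbf / 6000.0) * t1b_s
                    * (1 - np.exp(-tau / 1000.0 / t1b_s))
                    * np.exp(-w / 1000.0 / t1b_s) / constants.lam)
        assert dm == pytest.approx(expected, rel=1e-12)

    @given(cbf=st.floats(1.0, 150.0), scale=st.floats(0.1, 5.0))
    def test_linear_in_cbf_and_m0(self, cbf, scale):
        constants = KineticConstants()
        base = pcasl_signal(cbf, 1200.0, 885.0, 1573.0, constants, 1.0)
        assert pcasl_signal(cbf * scale, 1200.0, 885.0, 1573.0, constants, 1.0) \
            == pytest.approx(base * scale, rel=1e-12)
        assert pcasl_signal(cbf, 1200.0, 885.0, 1573.0, constants, scale) \
            == pytest.approx(base * scale, rel=1e-12)

    def test_rejects_negative_inputs(self, constants):
        with pytest.raises(ValueError):
            pcasl_signal(-1.0, 1200.0, 885.0, 1573.0, constants)
        with pytest.raises(ValueError):
            pcasl_signal(50.0, -5.0, 885.0, 1573.0, constants)


def grid_search_oracle(signals, schedule, constants,
                       cbf_step=1.0, att_step=10.0):
    """Exhaustive search over the bounded (CBF, ATT) grid."""
    cbfs = np.arange(0.0, 200.0 + cbf_step / 2, cbf_step)
    atts = np.arange(100.0, 3500.0 + att_step / 2, att_step)
    G = np.stack([pcasl_signal(1.0, a, schedule.tau, schedule.pld,
                               constants, 1.0) for a in atts])
    cost = np.sum((cbfs[:, None, None] * G[None, :, :]
                   - np.asarray(signals)[None, None, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    return cbfs[i], atts[j]


class TestFitVoxel:
    def test_noiseless_round_trip(self, schedule, constants):
        sig = pcasl_signal(50.0, 1400.0, schedule.tau, schedule.pld,
                           constants, 1000.0)
        fit = fit_voxel(sig, 1000.0, schedule, constants)
        assert fit.converged
        assert fit.cbf == pytest.approx(50.0, rel=1e-3)
        assert fit.att == pytest.approx(1400.0, rel=1e-3)

    def test_all_zero_signals_degenerate(self, schedule, constants):
        fit = fit_voxel(np.zeros(6), 1000.0, schedule, constants)
        assert fit.cbf == 0.0
        assert fit.att == 100.0  # lower bound; unidentifiable
        assert not fit.converged

    def test_matches_grid_search_oracle(self, schedule, constants, rng):
        """Optimizer solution within one grid cell of exhaustive search."""
        # ATT drawn above the 700 ms identifiability floor of the default
        # schedule (below it all points are post-bolus and ATT-free)
        for _ in range(5):
            cbf_t = float(rng.uniform(15.0, 90.0))
            att_t = float(rng.uniform(750.0, 2500.0))
            sig = pcasl_signal(cbf_t, att_t, schedule.tau, schedule.pld,
                               constants, 1.0)
            fit = fit_voxel(sig, 1.0, schedule, constants)
            cbf_g, att_g = grid_search_oracle(sig, schedule, constants)
            assert abs(fit.cbf - cbf_g) <= 1.0
            assert abs(fit.att - att_g) <= 10.0

    def test_rejects_bad_m0_and_short_signals(self, schedule, constants):
        with pytest.raises(ValueError):
            fit_voxel(np.ones(6), 0.0, schedule, constants)
        with pytest.raises(ValueError):
            fit_voxel(np.ones(2), 1.0,
                      AcquisitionSchedule((573.0, 885.0), (700.0, 1297.0)),
                      constants)


class TestFitVolume:
    def test_uniform_noiseless_phantom_recovers_truth(self, schedule):
        constants = KineticConstants.for_hct(0.42)
        shape = (3, 3, 2)
        sig = pcasl_signal(40.0, 1100.0, schedule.tau, schedule.pld,
                           constants, 500.0)
        asl = np.broadcast_to(sig, shape + (6,)).copy()
        m0 = np.full(shape, 500.0)
        mask = np.ones(shape, dtype=bool)
        mask[0, 0, 0] = False
        cbf, att = fit_volume(asl, m0, mask, schedule, hct=0.42)
        assert np.isnan(cbf[0, 0, 0]) and np.isnan(att[0, 0, 0])
        assert np.allclose(cbf[mask], 40.0, rtol=1e-3)
        assert np.allclose(att[mask], 1100.0, rtol=1e-3)

    def test_shape_mismatch_rejected(self, schedule):
        with pytest.raises(ValueError):
            fit_volume(np.zeros((2, 2, 2, 6)), np.ones((3, 2, 2)),
                       np.ones((2, 2, 2), bool), schedule, hct=0.42)


class TestTerritoryMedian:
    @pytest.mark.parametrize("values,expected", [
        ([42.0], 42.0),
        ([1, 2, 3, 4, 5], 3.0),
        ([10, 20, 30, 40], 25.0),  # even count: mean of central pair
    ])
    def test_median_conventions(self, values, expected):
        arr = np.asarray(values, dtype=float)
        assert territory_median(arr, np.ones_like(arr, bool)) == expected

    def test_ignores_missing_and_out_of_mask(self):
        arr = np.array([1.0, np.nan, 100.0, 3.0])
        mask = np.array([True, True, False, True])
        assert territory_median(arr, mask) == 2.0

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            territory_median(np.array([np.nan]), np.array([True]))


class TestScheduleAndModelObjects:
    def test_default_schedule_is_joint_six_point_grid(self, schedule):
        assert len(schedule) == 6
        assert schedule.label_durations == (573.0, 885.0, 2024.0,
                                            573.0, 885.0, 2024.0)
        assert schedule.post_label_delays == (700.0, 1297.0, 2158.0,
                                              1000.0, 1573.0, 2024.0)

    def test_rejects_duplicate_measurement_times(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule((500.0, 500.0), (700.0, 700.0))

    def test_csv_round_trip(self, tmp_path, schedule):
        path = tmp_path / "sched.csv"
        schedule.to_csv(path)
        assert AcquisitionSchedule.from_csv(path) == schedule

    def test_model_results_from_volumes(self, schedule, constants):
        from mroximetry import PerfusionModel

        shape = (2, 2, 2)
        sig = pcasl_signal(55.0, 900.0, schedule.tau, schedule.pld,
                           constants, 100.0)
        asl = np.broadcast_to(sig, shape + (6,)).copy()
        m0 = np.full(shape, 100.0)
        mask = np.ones(shape, bool)
        res = PerfusionModel.from_volumes(asl, m0, mask, schedule,
                                          constants).fit()
        cbf_map, att_map = res.maps()
        assert np.allclose(cbf_map, 55.0, rtol=1e-3)
        assert np.allclose(att_map, 900.0, rtol=1e-3)
        assert "CBF median" in res.summary()
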