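import numpy as np
import pandas as pd
import pytest

import pwspdt as pw
from pwspdt.metrics import ScenarioResult, Thresholds


def synthetic_result(scale=1.0, name="synthetic"):
    """Analytic stand-in series: quadratic wall dose, linear papillary rate."""
    t = np.arange(0.0, 2001.0, 10.0)
    wall_cum = scale * 1e-7 * t**2
    pap_rate = scale * 1e-7 * t
    pap_cum = scale * 0.5e-7 * t**2
    epi_cum = scale * 0.25e-7 * t**2
    return ScenarioResult(
        name=name,
        series=pd.DataFrame(
            {
                "t": t,
                "wall_ros_cum": wall_cum,
                "wall_ros_rate": 2e-7 * scale * t,
                "papillary_ros_rate": pap_rate,
                "papillary_ros_cum": pap_cum,
                "epidermis_ros_cum": epi_cum,
            }
        ),
    )


class TestCalibration:
    def test_thresholds_read_off_baseline_series(self):
        res = synthetic_result()
        th = pw.calibrate_thresholds(res)
        assert th.damage_threshold == pytest.approx(1e-7 * 1200**2)
        assert th.pain_threshold == pytest.approx(1e-7 * 600)

    def test_scaling_covariance(self):
        """Rescaling the ROS fields rescales thresholds, not crossing times."""
        th1 = pw.calibrate_thresholds(synthetic_result(1.0))
        th10 = pw.calibrate_thresholds(synthetic_result(10.0))
        assert th10.damage_threshold == pytest.approx(10 * th1.damage_threshold)
        assert th10.pain_threshold == pytest.approx(10 * th1.pain_threshold)
        t1 = pw.damage_time(synthetic_result(1.0), th1)
        t10 = pw.damage_time(synthetic_result(10.0), th10)
        assert t1 == pytest.approx(t10)

    def test_short_baseline_rejected(self):
        res = synthetic_result()
        res.series = res.series[res.series.t < 1000]
        with pytest.raises(ValueError):
            pw.calibrate_thresholds(res)


class TestCrossings:
    def test_damage_time_is_calibration_time_by_construction(self):
        res = synthetic_result()
        th = pw.calibrate_thresholds(res)
        assert pw.damage_time(res, th) == pytest.approx(1200.0)

    def test_pain_onset_and_duration_identity(self):
        res = synthetic_result()
        th = pw.calibrate_thresholds(res)
        onset, duration = pw.pain_onset_and_duration(res, th)
        assert onset == pytest.approx(600.0)
        assert duration == pytest.approx(pw.damage_time(res, th) - onset)

    def test_crossing_linearly_interpolated(self):
        res = synthetic_result()
        th = Thresholds(damage_threshold=1e-7 * 1205.0**2, pain_threshold=1e-7)
        t = pw.damage_time(res, th)
        # quadratic series sampled every 10 s: interpolated crossing within one sample
        assert 1200.0 < t < 1210.0

    def test_unreached_threshold_reported_absent(self):
        res = synthetic_result()
        th = Thresholds(damage_threshold=1e3, pain_threshold=1e-7)
        assert pw.damage_time(res, th) is None


class TestPSC:
    def test_identical_fields_give_unity(self):
        res = synthetic_result()
        res.series["papillary_ros_cum"] = res.series["wall_ros_cum"]
        th = pw.calibrate_thresholds(res)
        assert pw.psc(res, th) == pytest.approx(1.0)

    def test_psc_value_and_region_override(self):
        res = synthetic_result()
        th = pw.calibrate_thresholds(res)
        assert pw.psc(res, th) == pytest.approx(2.0)
        assert pw.psc(res, th, denominator_region="epidermis") == pytest.approx(4.0)

    def test_invariant_under_global_rescale_with_recalibration(self):
        for scale in (0.1, 10.0):
            res = synthetic_result(scale)
            th = pw.calibrate_thresholds(res)
            assert pw.psc(res, th) == pytest.approx(2.0)


class TestTherapeuticZone:
    def test_zero_field_empty_zone(self):
        th = Thresholds(damage_threshold=0.222, pain_threshold=1e-5)
        mask, vol = pw.therapeutic_zone(np.zeros((4, 4, 4)), th, voxel_volume=1000.0)
        assert not mask.any() and vol == 0.0

    def test_boundary_value_included(self):
        th = Thresholds(damage_threshold=0.222, pain_threshold=1e-5)
        field = np.full((3, 3, 3), 0.8 * 0.222)
        mask, vol = pw.therapeutic_zone(field, th, voxel_volume=125.0)
        assert mask.all() and vol == pytest.approx(27 * 125.0)


class TestEquilibration:
    def test_epidermal_catchup_time(self):
        res = synthetic_result()
        res.series["epidermis_ros_cum"] = 1e-7 * np.maximum(res.series.t - 500.0, 0) ** 2
        # epidermal quadratic (delayed, steeper) catches the wall when
        # (t-500)^2 = t^2 -> never; use a crossing variant instead
        res.series["epidermis_ros_cum"] = 2e-7 * np.maximum(res.series.t - 500.0, 0) ** 2
        t_eq = pw.equilibration_time(res)
        # 2(t-500)^2 = t^2 -> t = 500·(2+sqrt(2)) ≈ 1707.1
        assert t_eq == pytest.approx(500 * (2 + np.sqrt(2)), rel=0.01)

    def test_zero_epidermal_series_absent(self):
        res = synthetic_result()
        res.series["epidermis_ros_cum"] = 0.0
        assert pw.equilibration_time(res) is None


def test_percent_change_values():
    assert pw.percent_change(1.93, 1.31) == pytest.approx(47.3, abs=0.1)
    assert pw.percent_change(5.0, 5.0) == 0.0
    assert pw.percent_change(420.0, 600.0) == pytest.approx(-30.0)
    with pytest.raises(ZeroDivisionError):
        pw.percent_change(1.0, 0.0)
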