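import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaflux.physiology import (
    CalibrationCurve,
    InsufficientDataError,
    MonomerMassTable,
    Phase,
    PhysioTimeCourse,
    compute_growth_rate,
    mean_residual_biomass,
    microresp_percent_co2,
    pha_conc,
    relative_co2,
    residual_biomass,
    segment_phases,
    specific_rate,
)


def simple_course(times, residual, pha=None, ha=None, octanoate=None):
    times = np.asarray(times, float)
    residual = np.asarray(residual, float)
    pha = np.zeros_like(residual) if pha is None else np.asarray(pha, float)
    total = residual + pha
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * pha / total, 0.0)
    return PhysioTimeCourse(
        strain="test",
        times=times,
        total_biomass=total,
        pha_pct_cdw=pct,
        ha_conc=np.zeros_like(residual) if ha is None else np.asarray(ha, float),
        octanoate=(np.full_like(residual, 15.0) if octanoate is None
                   else np.asarray(octanoate, float)),
    )


class TestResidualBiomass:
    def test_wild_type_endpoint_partitioning(self):
        # 1.3 g/L at 71.7 %CDW -> 0.93 g/L polymer, 0.37 g/L residual,
        # matching the printed 1.0 +/- 0.1 and 0.4 +/- 0.0 within rounding
        assert pha_conc(1.3, 71.7) == pytest.approx(0.93, abs=0.005)
        assert residual_biomass(1.3, 71.7) == pytest.approx(0.37, abs=0.005)

    def test_no_polymer_case(self):
        assert residual_biomass(2.7, 0.0) == 2.7
        assert pha_conc(2.7, 0.0) == 0.0

    def test_even_split(self):
        assert residual_biomass(2.0, 50.0) == pytest.approx(1.0)
        assert pha_conc(2.0, 50.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("pct", [-0.1, 100.1])
    def test_out_of_range_pct_rejected(self, pct):
        with pytest.raises(ValueError):
            residual_biomass(1.0, pct)

    @given(
        total=st.floats(0, 100, allow_nan=False),
        pct=st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_sums_to_total_exactly(self, total, pct):
        assert residual_biomass(total, pct) + pha_conc(total, pct) == pytest.approx(
            total, rel=1e-12, abs=1e-12
        )


class TestGrowthRate:
    def test_flat_series_gives_zero(self):
        tc = simple_course([0, 1, 2, 3], [0.5, 0.5, 0.5, 0.5])
        assert compute_growth_rate(tc, Phase("I", 0, 4)) == pytest.approx(0.0)

    def test_recovers_exponential_rate(self):
        # ln-regression oracle: noiseless 0.08 * e^(0.31 t) must return 0.31
        t = np.arange(0, 6.0)
        tc = simple_course(t, 0.08 * np.exp(0.31 * t))
        mu = compute_growth_rate(tc, Phase("I", 0, 6))
        assert mu == pytest.approx(0.31, abs=1e-12)

    def test_insufficient_points_raise(self):
        tc = simple_course([0, 1, 2], [0.1, 0.2, 0.3])
        with pytest.raises(InsufficientDataError):
            compute_growth_rate(tc, Phase("II", 2.5, 5))

    def test_nonpositive_biomass_excluded_with_warning(self):
        tc = simple_course([0, 1, 2, 3], [0.0, 0.1, 0.2, 0.4])
        with pytest.warns(UserWarning, match="non-positive"):
            mu = compute_growth_rate(tc, Phase("I", 0, 4))
        assert mu == pytest.approx(math.log(2.0), abs=1e-9)

    @given(scale=st.floats(0.01, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_biomass_rescaling(self, scale):
        t = np.arange(0, 5.0)
        base = 0.1 * np.exp(0.25 * t)
        mu1 = compute_growth_rate(simple_course(t, base), Phase("I", 0, 5))
        mu2 = compute_growth_rate(simple_course(t, scale * base), Phase("I", 0, 5))
        assert mu1 == pytest.approx(mu2, rel=1e-9)


class TestSpecificRate:
    def test_zero_delta_is_zero(self):
        assert specific_rate(0.0, 5.0, 0.3, 0.16021) == 0.0

    def test_hand_calculation(self):
        # (0.5 / 0.16021) / (5 * 0.25) = 2.497 mmol gCDW^-1 h^-1
        assert specific_rate(0.5, 5.0, 0.25, 0.16021) == pytest.approx(
            (0.5 / 0.16021) / (5 * 0.25)
        )
        assert specific_rate(0.5, 5.0, 0.25, 0.16021) == pytest.approx(2.50, abs=0.01)

    def test_zero_biomass_raises(self):
        with pytest.raises(ZeroDivisionError):
            specific_rate(0.5, 5.0, 0.0, 0.16021)

    @given(
        delta=st.floats(-5, 5, allow_nan=False),
        k=st.floats(0.1, 10, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_linear_in_delta_and_inverse_in_interval_and_biomass(self, delta, k):
        base = specific_rate(delta, 2.0, 0.4, 0.1)
        assert specific_rate(k * delta, 2.0, 0.4, 0.1) == pytest.approx(
            k * base, rel=1e-9, abs=1e-12
        )
        assert specific_rate(delta, k * 2.0, 0.4, 0.1) == pytest.approx(
            base / k, rel=1e-9, abs=1e-12
        )
        assert specific_rate(delta, 2.0, k * 0.4, 0.1) == pytest.approx(
            base / k, rel=1e-9, abs=1e-12
        )


class TestPhaseSegmentation:
    def test_default_three_phases(self, wt_course):
        phases = segment_phases(wt_course)
        assert [p.label for p in phases] == ["I", "II", "III"]
        assert [(p.t_start, p.t_end) for p in phases] == [
            (0.0, 5.0), (5.0, 10.0), (10.0, 24.0)
        ]
        # every sample lands in exactly one phase
        for t in wt_course.times:
            assert sum(p.contains(t) for p in phases) == 1

    def test_short_course_collapses_to_phase_one(self):
        tc = simple_course([0, 1, 2, 3], [0.1, 0.12, 0.15, 0.2])
        phases = segment_phases(tc)
        assert len(phases) == 1 and phases[0].label == "I"

    def test_custom_boundaries_match_bucketing_oracle(self, wt_course):
        boundaries = (4.0, 12.0)
        phases = segment_phases(wt_course, boundaries)

        def oracle(t):  # brute-force bucket assignment
            if t < 4.0:
                return "I"
            if t < 12.0:
                return "II"
            return "III"

        for t in wt_course.times:
            assigned = [p.label for p in phases if p.contains(t)]
            assert assigned == [oracle(t)]

    def test_unsorted_boundaries_rejected(self, wt_course):
        with pytest.raises(ValueError, match="sorted"):
            segment_phases(wt_course, (10.0, 5.0))


class TestMeanResidualBiomass:
    def test_endpoint_mean_and_log_mean(self):
        t = np.arange(0, 6.0)
        tc = simple_course(t, 0.1 * np.exp(0.3 * t))
        phase = Phase("I", 0, 5)
        x0, x1 = 0.1, 0.1 * math.exp(1.5)
        assert mean_residual_biomass(tc, phase) == pytest.approx(0.5 * (x0 + x1))
        # log-mean equals time-average of an exponential exactly
        assert mean_residual_biomass(tc, phase, "log-mean") == pytest.approx(
            (x1 - x0) / math.log(x1 / x0)
        )


class TestMicroRespCalibration:
    def test_packaged_defaults(self):
        calib = CalibrationCurve()
        assert calib.A == 1.73 and calib.B == -0.13

    def test_direct_evaluation(self):
        # 1.73 * 0.26 / (0.26 - 0.13) = 3.46
        assert microresp_percent_co2(0.26, CalibrationCurve()) == pytest.approx(3.46)

    def test_asymptote_equals_A(self):
        calib = CalibrationCurve()
        assert microresp_percent_co2(1e6, calib) == pytest.approx(
            calib.A, abs=1e-6
        )

    def test_domain_error_left_of_asymptote(self):
        with pytest.raises(ValueError, match="asymptote"):
            microresp_percent_co2(0.10, CalibrationCurve())

    def test_monotone_decreasing_on_valid_domain(self):
        calib = CalibrationCurve()
        xs = np.linspace(0.14, 10.0, 200)
        ys = [microresp_percent_co2(x, calib) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))


class TestRelativeCo2:
    def test_direct_ratio(self):
        assert relative_co2({"wt": 2.0, "M4": 6.0}, "wt") == {
            "wt": 1.0, "M4": 3.0
        }

    def test_self_normalization(self):
        assert relative_co2({"wt": 5.2}, "wt") == {"wt": 1.0}

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_co2({"wt": 0.0, "M4": 3.0}, "wt")

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            relative_co2({"M4": 3.0}, "wt")


class TestCsvInterface:
    def test_round_trip_with_optional_columns(self, tmp_path, archetypes):
        from phaflux.synthetic_data import make_strain_timecourse

        tc = make_strain_timecourse(archetypes["KT2440"], seed=3)
        path = tmp_path / "wt.csv"
        tc.to_csv(str(path))
        back = PhysioTimeCourse.from_csv(str(path), strain="KT2440")
        np.testing.assert_allclose(back.times, tc.times)
        np.testing.assert_allclose(back.total_biomass, tc.total_biomass)
        np.testing.assert_allclose(back.viable_cells, tc.viable_cells)

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_h,total_biomass_gL\n0,0.1\n")
        with pytest.raises(ValueError, match="missing required"):
            PhysioTimeCourse.from_csv(str(path))

    def test_validation_of_ranges(self):
        with pytest.raises(ValueError, match="pha_pct"):
            simple_course([0, 1, 24], [1, 1, 1]).__class__(
                strain="x",
                times=[0, 1],
                total_biomass=[1, 1],
                pha_pct_cdw=[0, 120],
                ha_conc=[0, 0],
                octanoate=[15, 14],
            )
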