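"""Closed-form model: rate law, intensity, thresholds, waiting times, units."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gammaln

import tumorclock as tc
from tumorclock.core import EPSILON_B, ProgressionParams


class TestProgressionParams:
    def test_b_derived_from_s_and_a(self):
        p = ProgressionParams(mu0=2e-5, s=0.01, a=0.32)
        assert p.b == 0.01 * 0.32

    def test_from_b_backfills_missing_factor(self):
        p = ProgressionParams(mu0=1e-5, s=0.01, b=0.0032)
        assert p.a == pytest.approx(0.32)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu0": -1e-5, "b": 0.01},
            {"mu0": 1e-5, "s": -0.1, "a": 1.0},
            {"mu0": 1e-5, "b": -0.01},
            {"mu0": 1e-5},  # neither (s, a) nor b
            {"mu0": 1e-5, "b": 0.01, "generation_time_days": 0},
            {"mu0": 1e-5, "s": 0.01, "a": 0.32, "b": 0.999},  # inconsistent
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProgressionParams(**kwargs)


class TestMutationRate:
    def test_initial_rate_at_time_zero(self, mx34):
        assert tc.mutation_rate(0.0, mx34) == 2e-5

    def test_unit_exponent(self):
        p = ProgressionParams(mu0=1.0, b=0.25)
        assert tc.mutation_rate(1 / 0.25, p) == pytest.approx(math.e, rel=1e-12)

    def test_late_rate_and_derivative_of_intensity(self, mx34):
        # direct evaluation, cross-checked as d/dt of the cumulative intensity
        expected = 2e-5 * math.exp(3.2)
        assert tc.mutation_rate(1000.0, mx34) == pytest.approx(4.906e-4, rel=1e-3)
        h = 1e-3
        numeric = (
            tc.cumulative_intensity(1000 + h, mx34)
            - tc.cumulative_intensity(1000 - h, mx34)
        ) / (2 * h)
        assert numeric == pytest.approx(expected, rel=1e-8)

    def test_negative_time_rejected(self, mx34):
        with pytest.raises(ValueError):
            tc.mutation_rate(-1.0, mx34)


class TestCumulativeIntensity:
    def test_zero_at_origin(self, mx34):
        assert tc.cumulative_intensity(0.0, mx34) == 0.0

    def test_homogeneous_limit(self):
        p = ProgressionParams(mu0=1e-5, b=0.0)
        assert tc.cumulative_intensity(1e5, p) == pytest.approx(1.0, rel=1e-12)

    def test_matches_quadrature_of_rate(self, mx34):
        val = tc.cumulative_intensity(39.54, mx34)
        assert val == pytest.approx(8.43e-4, rel=1e-3)
        quadval, _ = quad(lambda x: tc.mutation_rate(x, mx34), 0, 39.54)
        assert val == pytest.approx(quadval, rel=1e-10)

    def test_continuity_across_small_b_switch(self):
        # b just above the switch vs exactly zero: 1e-6 relative agreement
        above = ProgressionParams(mu0=1e-5, b=1e-14)
        at_zero = ProgressionParams(mu0=1e-5, b=0.0)
        for t in (1.0, 1e3, 1e6):
            assert tc.cumulative_intensity(t, above) == pytest.approx(
                tc.cumulative_intensity(t, at_zero), rel=1e-6
            )
            assert tc.waiting_time(1e-3 * t, above) == pytest.approx(
                tc.waiting_time(1e-3 * t, at_zero), rel=1e-6
            )


class TestStageProbability:
    def test_all_cells_unmutated_at_origin(self, mx34):
        assert tc.stage_probability(0, 0.0, mx34) == 1.0

    def test_poisson_mass_at_unit_mean(self):
        p = ProgressionParams(mu0=1e-5, b=0.0)
        t = 1e5  # lambda = 1
        assert tc.stage_probability(2, t, p) == pytest.approx(
            math.exp(-1) / 2, rel=1e-12
        )

    def test_normalization_partial_sum(self, mx34):
        for t in (0.0, 100.0, 1500.0):
            lam = tc.cumulative_intensity(t, mx34)
            J = int(50 * (1 + lam))
            total = sum(tc.stage_probability(j, t, mx34) for j in range(J + 1))
            assert total > 1 - 1e-12

    def test_rejects_negative_or_fractional_j(self, mx34):
        with pytest.raises(ValueError):
            tc.stage_probability(-1, 1.0, mx34)
        with pytest.raises(ValueError):
            tc.stage_probability(1.5, 1.0, mx34)


class TestDetectionThreshold:
    def test_single_driver_is_reciprocal_pool_size(self):
        assert tc.detection_threshold_lambda(1, 1e10).lambda_k == pytest.approx(
            1e-10, rel=1e-12
        )

    def test_three_driver_threshold(self):
        res = tc.detection_threshold_lambda(3, 1e10, "linearized")
        assert res.lambda_k == pytest.approx(0.000843, rel=1e-3)

    def test_exact_root_solves_occupancy_equation(self):
        res = tc.detection_threshold_lambda(10, 1e10, "exact")
        assert res.lambda_k == pytest.approx(0.4749, rel=1e-3)
        lam = res.lambda_k
        recovered = math.exp(10 * math.log(lam) - lam - gammaln(11))
        assert recovered == pytest.approx(1e-10, rel=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 5, 10, 20, 30])
    @pytest.mark.parametrize("n_cells", [1e6, 1e9, 1e10])
    def test_exact_at_least_linearized(self, k, n_cells):
        exact = tc.detection_threshold_lambda(k, n_cells, "exact").lambda_k
        lin = tc.detection_threshold_lambda(k, n_cells, "linearized").lambda_k
        assert exact >= lin
        # linearized value plugged back in exceeds 1/N (exp(-lambda) dropped)
        occupancy = math.exp(k * math.log(lin) - lin - gammaln(k + 1))
        assert occupancy * n_cells <= 1.0 + 1e-12

    def test_monotone_in_k_and_pool_size(self):
        lams = [tc.detection_threshold_lambda(k, 1e9).lambda_k for k in range(1, 14)]
        assert all(b > a for a, b in zip(lams, lams[1:]))
        byN = [tc.detection_threshold_lambda(5, N).lambda_k for N in (1e6, 1e9, 1e12)]
        assert all(b < a for a, b in zip(byN, byN[1:]))

    def test_no_detection_solution_raises(self):
        # tiny pool: even the modal k-driver occupancy stays below 1/N
        with pytest.raises(tc.DetectionError):
            tc.detection_threshold_lambda(10, 2.0, "exact")

    @pytest.mark.parametrize("bad_k,bad_n", [(0, 1e9), (-1, 1e9), (3, 1.0)])
    def test_preconditions(self, bad_k, bad_n):
        with pytest.raises(ValueError):
            tc.detection_threshold_lambda(bad_k, bad_n)


class TestWaitingTime:
    def test_zero_threshold_means_zero_time(self, mx34):
        assert tc.waiting_time(0.0, mx34) == 0.0

    def test_homogeneous_limit(self):
        p = ProgressionParams(mu0=1e-5, b=0.0)
        assert tc.waiting_time(1.0, p) == pytest.approx(1e5, rel=1e-12)

    def test_three_driver_waiting_time(self, mx34):
        t = tc.waiting_time(0.000843, mx34)
        assert t == pytest.approx(39.5, rel=2e-3)
        assert tc.cumulative_intensity(t, mx34) == pytest.approx(0.000843, rel=1e-10)

    @given(st.floats(min_value=1e-12, max_value=10.0))
    def test_inverse_identity(self, lam):
        params = tc.MX34_PARAMS
        t = tc.waiting_time(lam, params)
        assert tc.cumulative_intensity(t, params) == pytest.approx(lam, rel=1e-9)


class TestWaitingTimeTable:
    def test_rows_and_roundtrip_identity(self, mx34):
        table = tc.waiting_time_table(mx34, 1e10, 16)
        df = table.to_frame()
        assert list(df["k"]) == list(range(1, 17))
        assert df["t_generations"].is_monotonic_increasing
        for _, row in df.iterrows():
            assert tc.cumulative_intensity(row["t_generations"], mx34) == pytest.approx(
                row["lambda_k"], rel=1e-10
            )
        assert df.loc[df["k"] == 3, "stage"].item() == "microadenoma"

    def test_single_row_table(self, mx34):
        df = tc.waiting_time_table(mx34, 1e10, 1).to_frame()
        assert len(df) == 1
        assert df["t_generations"].iloc[0] == pytest.approx(
            tc.waiting_time(1e-10, mx34), rel=1e-12
        )

    def test_infeasible_rows_marked_not_fatal(self, mx34):
        # N=5: exact threshold stops existing at large k; rows flagged, not dropped
        df = tc.waiting_time_table(mx34, 5.0, 12, method="exact").to_frame()
        assert len(df) == 12
        bad = df["lambda_k"].isna()
        assert bad.any() and not bad.all()
        assert df.loc[bad, "note"].str.contains("no detection solution").all()

    def test_k_max_validated(self, mx34):
        with pytest.raises(ValueError):
            tc.waiting_time_table(mx34, 1e10, 0)


class TestConvertTime:
    @pytest.mark.parametrize(
        "value,frm,to,expected",
        [
            (150, "generations", "days", 600.0),
            (158.2, "days", "years", 158.2 / 365),
            (7.3, "years", "years", 7.3),
            (365.0, "days", "generations", 91.25),
        ],
    )
    def test_conversions(self, value, frm, to, expected):
        assert tc.convert_time(value, frm, to) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_round_trip_identity(self, value):
        via_days = tc.convert_time(
            tc.convert_time(value, "years", "generations"), "generations", "years"
        )
        assert via_days == pytest.approx(value, rel=1e-12, abs=1e-300)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown time unit"):
            tc.convert_time(1.0, "fortnights", "days")


def test_wright_fisher_reduction():
    """With a=1 and mu0=u*d the rate law collapses to u*d*exp(s*t)."""
    u, d, s = 1e-7, 100, 0.01
    reduced = ProgressionParams(mu0=u * d, s=s, a=1.0)
    for t in (0.0, 10.0, 500.0):
        assert tc.mutation_rate(t, reduced) == pytest.approx(
            u * d * math.exp(s * t), rel=1e-12
        )


def test_small_b_is_below_any_physical_curvature():
    assert EPSILON_B < 1e-6  # switch never triggers for fitted patients
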