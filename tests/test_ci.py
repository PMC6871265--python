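import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from paleobracket import (
    AgeAxisMap,
    RecoveryCurve,
    ci_extant,
    ci_for_record,
    ci_nonuniform,
    ci_range,
    ci_transformed,
    ml_corrected_origin,
    unbiased_origin,
)

from .conftest import make_record


class TestCiExtant:
    def test_sand_dollar(self):
        # FAD 4.0 Ma, n = 10 localities -> bound ~5 Ma
        result = ci_extant(4.0, 10, 0.95)
        assert round(result.t_c, 2) == 5.40
        assert round(result.t_c) == 5

    def test_zero_confidence_is_identity(self):
        assert ci_extant(7.7, 3, 0.0).t_c == 7.7

    def test_single_locality(self):
        # FAD * 20 for n = 1, C = 0.95
        assert ci_extant(10.0, 1, 0.95).t_c == pytest.approx(200.0)

    def test_single_locality_coverage_oracle(self):
        # one find uniform on (0, T_true): P(T_true <= T_C) should be ~0.95
        rng = np.random.default_rng(7)
        reps = 20_000
        fad = rng.random(reps)  # T_true = 1
        covered = np.mean(fad * (1 - 0.95) ** (-1.0) >= 1.0)
        assert covered == pytest.approx(0.95, abs=3 * math.sqrt(0.95 * 0.05 / reps))
        assert ci_extant(0.5, 1, 0.95).t_c == pytest.approx(0.5 * 20)

    @pytest.mark.parametrize("fad,n,c", [(0.0, 3, 0.5), (4.0, 0, 0.5), (4.0, 3, 1.0)])
    def test_invalid_inputs(self, fad, n, c):
        with pytest.raises(ValueError):
            ci_extant(fad, n, c)


class TestCiRange:
    def test_hominin_older_endpoint(self):
        assert round(ci_range(7.5, 3.1, 4, 0.95).t_c, 1) == 12.8

    def test_hominin_younger_endpoint(self):
        assert round(ci_range(6.5, 2.1, 4, 0.95).t_c, 1) == 10.1

    def test_closed_form_n2(self):
        # R[(1-C)^(-1) - 1] + FAD = 1*[2-1] + 10 = 11
        assert ci_range(10.0, 1.0, 2, 0.5).t_c == pytest.approx(11.0)

    def test_dirichlet_gap_simulation_oracle(self):
        # n uniform finds on (origin, extinction): empirical 50% quantile of
        # the origin matches the C=0.5 bound on average
        rng = np.random.default_rng(11)
        reps, n, c = 40_000, 2, 0.5
        finds = rng.random((reps, n))
        fad, lad = finds.max(axis=1), finds.min(axis=1)
        t_c = (fad - lad) * ((1 - c) ** (-1.0 / (n - 1)) - 1.0) + fad
        coverage = np.mean(t_c >= 1.0)
        assert coverage == pytest.approx(c, abs=3 * math.sqrt(c * (1 - c) / reps))

    @pytest.mark.parametrize("fad,r,n,c", [(5.0, 1.0, 1, 0.5), (5.0, 0.0, 3, 0.5),
                                           (5.0, 1.0, 3, 1.0)])
    def test_invalid_inputs(self, fad, r, n, c):
        with pytest.raises(ValueError):
            ci_range(fad, r, n, c)


class TestUnbiasedOrigin:
    def test_hominin_envelope(self, hominin_record):
        assert round(unbiased_origin(hominin_record, endpoint="older",
                                     basis="range"), 1) == 8.5
        assert round(unbiased_origin(hominin_record, endpoint="younger",
                                     basis="range"), 1) == 7.2

    def test_extant_average_gap(self):
        record = make_record([4.0, 3.9, 3.8, 3.7, 3.6, 3.5, 3.4, 3.3, 3.2, 3.1],
                             extant=True)
        assert record.n == 10
        assert unbiased_origin(record) == pytest.approx(4.0 + 4.0 / 10)

    def test_extant_mean_gap_simulation_oracle(self):
        # mean of (T_true - FAD) under n uniform finds is T_true / (n + 1),
        # estimated by FAD/n
        rng = np.random.default_rng(3)
        n, reps = 10, 50_000
        fad = rng.random((reps, n)).max(axis=1)
        gap_hat = fad / n
        assert np.mean(1.0 - fad) == pytest.approx(np.mean(gap_hat), rel=0.02)

    def test_extinct_needs_two_localities(self):
        record = make_record([4.0], extant=False)
        with pytest.raises(ValueError):
            unbiased_origin(record)


class TestMlCorrectedOrigin:
    def test_arithmetic(self):
        assert ml_corrected_origin(7.0, 7) == pytest.approx(8.0)

    def test_large_n_limit(self):
        assert ml_corrected_origin(4.0, 10_000_000) == pytest.approx(4.0, rel=1e-6)

    def test_equals_extant_unbiased(self):
        record = make_record(
            [4.0, 3.9, 3.8, 3.7, 3.6, 3.5, 3.4, 3.3, 3.2, 3.1], extant=True)
        assert ml_corrected_origin(4.0, 10) == pytest.approx(
            unbiased_origin(record))
        assert ml_corrected_origin(4.0, 10) == pytest.approx(4.4)


class TestCiTransformed:
    def test_identity_map_exact(self):
        record = make_record([4.0, 3.0, 2.0, 1.0], extant=True)
        plain = ci_for_record(record, 0.95)
        transformed = ci_transformed(record, 0.95, axis_map=AgeAxisMap.identity())
        assert transformed.t_c == plain.t_c  # exact

    def test_thick_old_unit_deepens_bound(self):
        # formations: ages [0,5] hold 5 axis units, [5,6] hold 10 (a 1-Myr
        # unit with ~half the section), beyond 6 the section thins to 1/Myr.
        axis_map = AgeAxisMap([(0.0, 0.0), (5.0, 5.0), (6.0, 15.0), (8.0, 17.0)])
        record = make_record([6.0, 5.5, 5.0, 3.0, 1.0], extant=True)
        n, c = 5, 0.95
        result = ci_transformed(record, c, axis_map=axis_map)
        # hand computation on the piecewise map
        fad_axis = 15.0
        bound_axis = fad_axis * (1 - c) ** (-1.0 / n)
        expected = 8.0 + (bound_axis - 17.0) / 1.0
        assert result.t_c == pytest.approx(expected)
        assert result.t_c > ci_for_record(record, c).t_c

    def test_map_from_record_axis_positions(self):
        record = make_record([3.0, 2.0, 1.0], extant=True,
                             axis_positions=[30.0, 20.0, 10.0])
        result = ci_transformed(record, 0.5)
        # axis = 10 * age, so the transform is linear: same answer as time CI
        assert result.t_c == pytest.approx(ci_for_record(record, 0.5).t_c)

    def test_non_monotone_mapping_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            AgeAxisMap([(0.0, 0.0), (1.0, 5.0), (2.0, 3.0)])

    def test_missing_axis_position_rejected(self):
        record = make_record([3.0, 2.0], extant=True)
        with pytest.raises(ValueError, match="axis_position"):
            AgeAxisMap.from_record(record)


class TestCiNonuniform:
    def test_constant_curve_reduces_to_extant(self):
        record = make_record([4.0, 3.0, 2.0], extant=True)
        curve = RecoveryCurve.constant(1000.0, rate=2.5)
        uniform = ci_for_record(record, 0.95)
        nonuniform = ci_nonuniform(record, curve, 0.95)
        assert nonuniform.t_c == pytest.approx(uniform.t_c, abs=1e-9)

    def test_step_curve_against_bisection_oracle(self):
        record = make_record([10.0, 8.0, 6.0, 4.0, 2.0], extant=True)
        assert record.n == 5
        curve = RecoveryCurve([0.0, 12.0, 200.0], [1.0, 0.2])
        c = 0.95
        result = ci_nonuniform(record, curve, c)
        g_fad = curve.cumulative(10.0)
        oracle = brentq(
            lambda t: (g_fad / curve.cumulative(t)) ** 5 - (1 - c),
            10.0, 200.0, xtol=1e-12,
        )
        assert result.t_c == pytest.approx(oracle, abs=1e-6)

    def test_drop_deepens_bound(self):
        # recovery drops 10x older than 66 Ma: the bound must be strictly
        # deeper than under constant recovery
        record = make_record([70.0, 69.0, 68.0], extant=True)
        dropped = RecoveryCurve([0.0, 66.0, 500.0], [1.0, 0.1])
        constant = RecoveryCurve.constant(500.0)
        assert (ci_nonuniform(record, dropped, 0.95).t_c
                > ci_nonuniform(record, constant, 0.95).t_c)

    def test_unbounded_reported_not_raised(self):
        record = make_record([10.0, 9.0], extant=True)
        curve = RecoveryCurve([0.0, 11.0], [1.0])  # ends just above the FAD
        result = ci_nonuniform(record, curve, 0.95)
        assert not result.bounded
        assert result.t_c == math.inf

    def test_range_basis_uniform_limit(self):
        record = make_record([10.0, 8.0, 6.0, 4.0], extant=False)
        curve = RecoveryCurve.constant(1000.0)
        assert ci_nonuniform(record, curve, 0.9).t_c == pytest.approx(
            ci_for_record(record, 0.9).t_c, abs=1e-9)


class TestMonotonicity:
    @settings(max_examples=100, deadline=None)
    @given(
        fad=st.floats(min_value=0.1, max_value=1000.0),
        n=st.integers(min_value=1, max_value=100),
        c1=st.floats(min_value=0.0, max_value=0.99),
        c2=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_extant_nondecreasing_in_c(self, fad, n, c1, c2):
        lo, hi = sorted([c1, c2])
        assert ci_extant(fad, n, hi).t_c >= ci_extant(fad, n, lo).t_c

    @settings(max_examples=100, deadline=None)
    @given(
        fad=st.floats(min_value=0.1, max_value=1000.0),
        n=st.integers(min_value=1, max_value=100),
        c=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_extant_nonincreasing_in_n(self, fad, n, c):
        assert ci_extant(fad, n + 1, c).t_c <= ci_extant(fad, n, c).t_c

    @settings(max_examples=100, deadline=None)
    @given(
        fad=st.floats(min_value=0.1, max_value=1000.0),
        r1=st.floats(min_value=0.01, max_value=100.0),
        r2=st.floats(min_value=0.01, max_value=100.0),
        n=st.integers(min_value=2, max_value=100),
        c=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_range_nondecreasing_in_r(self, fad, r1, r2, n, c):
        lo, hi = sorted([r1, r2])
        assert ci_range(fad, hi, n, c).t_c >= ci_range(fad, lo, n, c).t_c

    @settings(max_examples=100, deadline=None)
    @given(
        fad=st.floats(min_value=0.1, max_value=1000.0),
        n=st.integers(min_value=1, max_value=50),
        c=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_bound_never_below_fad(self, fad, n, c):
        assert ci_extant(fad, n, c).t_c >= fad
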