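"""Statistics layer: dose-response OLS vs normal-equations oracle,
Bland–Altman arithmetic, release formula, photobleaching deltas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mesofluor import pipeline, simgen
from mesofluor.dosestat import (
    DoseResponseFit,
    ReleaseMeasurement,
    compare_platforms,
    fit_dose_response,
    fold_change,
    photobleaching_delta,
    release_fraction,
)
from mesofluor.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    PairingError,
    ProvenanceError,
    UndefinedFoldChangeError,
    UndefinedReleaseError,
)
from mesofluor.segquant import WellMeasurement


def meas(conc, signal, *, well="W", channel="dox", tp="post_activation",
         threshold=10.0, background=0.0):
    return WellMeasurement(
        well_id=well, channel=channel, timepoint=tp, concentration=conc,
        mean_signal=signal, n_pixels=100, threshold_used=threshold,
        background_level=background,
    )


def normal_equations(x, y):
    """Independent least-squares oracle: solve X'X beta = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    return beta[1], beta[0], r2


class TestFitDoseResponse:
    def test_exact_line(self):
        ms = [meas(x, 2.0 * x + 1.0, well=f"W{x}") for x in (1.0, 3.0, 6.0, 9.0)]
        fit = fit_dose_response(ms)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_reports_zero_r_squared(self):
        ms = [meas(x, 5.0, well=f"W{x}") for x in (1.0, 3.0, 6.0)]
        fit = fit_dose_response(ms)
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = np.array([1.0, 3.0, 6.0, 9.0])
        for _ in range(50):
            y = rng.normal(3.0, 1.0) * x + rng.normal(0.0, 2.0, size=4)
            fit = fit_dose_response([meas(c, v, well=f"W{c}") for c, v in zip(x, y)])
            slope, intercept, r2 = normal_equations(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-9)
            assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_worked_example_against_oracle(self):
        x = np.array([1.0, 3.0, 6.0, 9.0])
        y = np.array([3.1, 6.9, 13.2, 18.8])
        fit = fit_dose_response([meas(c, v, well=f"W{c}") for c, v in zip(x, y)])
        slope, intercept, r2 = normal_equations(x, y)
        assert (fit.slope, fit.intercept, fit.r_squared) == (
            pytest.approx(slope), pytest.approx(intercept), pytest.approx(r2),
        )

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_dose_response([meas(1.0, 1.0), meas(3.0, 2.0)])

    def test_degenerate_design(self):
        ms = [meas(2.0, v, well=f"W{i}") for i, v in enumerate((1.0, 2.0, 3.0))]
        with pytest.raises((DegenerateDesignError, InsufficientDataError)):
            fit_dose_response(ms)


class TestFoldChange:
    def test_four_fold(self):
        fit = DoseResponseFit([1.0, 9.0], [100.0, 400.0], 0, 0, 1.0)
        assert fold_change(fit) == pytest.approx(4.0)

    def test_equal_means_is_unity(self):
        fit = DoseResponseFit([1.0, 9.0], [70.0, 70.0], 0, 0, 1.0)
        assert fold_change(fit) == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self):
        fit = DoseResponseFit([1.0, 9.0], [0.0, 400.0], 0, 0, 1.0)
        with pytest.raises(UndefinedFoldChangeError):
            fold_change(fit)

    def test_noiseless_defaults_give_concentration_ratio(self):
        # zero media offset, shared geometry, uniform leakage: the quantified
        # means are proportional to concentration, so the 9:1 design gives 9.0
        shape = (128, 128)
        optics = simgen.OpticsParams(leakage_pattern=np.full(shape, 400.0))
        b = simgen.generate_dose_response_experiment(
            [1.0, 3.0, 6.0, 9.0], "compact", optics, simgen.NOISELESS, 0,
            shared_field_seed=5, media_background=0.0,
        )
        res = pipeline.analyze_frames(
            b.all_frames(), b.calibration, b.concentration_map(), roles=b.role_map()
        )
        assert res.fold_changes["dox"] == pytest.approx(9.0, rel=1e-9)


class TestComparePlatforms:
    def test_identical_series(self):
        r = compare_platforms([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0 and r.sd_diff == 0.0 and r.loa_width == 0.0
        assert r.regression_r_squared == pytest.approx(1.0)

    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0])
        r = compare_platforms(a, a + 5.0)
        assert r.bias == pytest.approx(-5.0)
        assert r.loa_width == pytest.approx(0.0, abs=1e-12)

    def test_four_pair_hand_oracle(self):
        # a = {10,20,30,40}, b = {12,19,33,41}: d = {-2, 1, -3, -1}
        # bias = -1.25; sample SD = sqrt(8.75/3) = 1.70783; LoA = bias ± 1.96 SD
        r = compare_platforms([10.0, 20.0, 30.0, 40.0], [12.0, 19.0, 33.0, 41.0])
        sd = np.sqrt(8.75 / 3.0)
        assert r.n_pairs == 4
        assert r.bias == pytest.approx(-1.25)
        assert r.sd_diff == pytest.approx(sd, rel=1e-12)
        assert r.loa_lower == pytest.approx(-1.25 - 1.96 * sd, rel=1e-12)
        assert r.loa_upper == pytest.approx(-1.25 + 1.96 * sd, rel=1e-12)
        assert r.loa_width == pytest.approx(2 * 1.96 * sd, rel=1e-12)
        # grand mean of pairwise means = 25.625
        assert r.percent_bias == pytest.approx(100 * -1.25 / 25.625, rel=1e-12)
        # bias CI via t(0.975, 3) = 3.182446...
        from scipy import stats

        tq = stats.t.ppf(0.975, 3)
        assert r.bias_ci == pytest.approx(
            (-1.25 - tq * sd / 2.0, -1.25 + tq * sd / 2.0), rel=1e-9
        )
        se_loa = np.sqrt(sd**2 * (1 / 4 + 1.96**2 / (2 * 3)))
        assert r.loa_ci_lower[0] == pytest.approx(r.loa_lower - tq * se_loa, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            compare_platforms([1.0, 2.0], [1.0])
        with pytest.raises(InsufficientDataError):
            compare_platforms([1.0], [2.0])

    @given(
        d=st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        shift=st.floats(-100, 100),
        scale=st.floats(0.1, 10),
    )
    def test_symmetry_shift_and_scale_invariances(self, d, shift, scale):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 100, size=len(d))
        a = b + np.asarray(d)
        fwd = compare_platforms(a, b)
        rev = compare_platforms(b, a)
        assert fwd.bias == pytest.approx(-rev.bias, abs=1e-9)
        assert fwd.loa_width == pytest.approx(rev.loa_width, abs=1e-9)
        shifted = compare_platforms(a + shift, b + shift)
        assert shifted.bias == pytest.approx(fwd.bias, abs=1e-7)
        assert shifted.loa_width == pytest.approx(fwd.loa_width, abs=1e-7)
        scaled = compare_platforms(scale * a, scale * b)
        assert scaled.bias == pytest.approx(scale * fwd.bias, rel=1e-7, abs=1e-7)
        assert scaled.loa_width == pytest.approx(scale * fwd.loa_width, rel=1e-7, abs=1e-7)


class TestPhotobleaching:
    def pre_post(self, factor, *, background=0.0):
        pre = [
            meas(c, 1000.0 * c + background, well=f"W{c}", channel="pop",
                 tp="pre_activation", background=background)
            for c in (1.0, 3.0, 6.0, 9.0)
        ]
        post = [
            meas(c, factor * 1000.0 * c + background, well=f"W{c}", channel="pop",
                 tp="post_activation", background=background)
            for c in (1.0, 3.0, 6.0, 9.0)
        ]
        return pre, post

    def test_no_change_gives_zero_deltas(self):
        pre, post = self.pre_post(1.0)
        for d in photobleaching_delta(pre, post):
            assert d.fractional_decrease == pytest.approx(0.0)

    def test_ninety_percent_factor(self):
        pre, post = self.pre_post(0.9)
        for d in photobleaching_delta(pre, post):
            assert d.fractional_decrease == pytest.approx(0.1, rel=1e-12)

    def test_background_referencing_undoes_dilution(self):
        # an unbleached additive background leaves the absolute decrease
        # intact and, once referenced, the fractional decrease too
        pre, post = self.pre_post(0.9, background=500.0)
        for d in photobleaching_delta(pre, post):
            assert d.fractional_decrease == pytest.approx(0.1, rel=1e-12)

    def test_unmatched_wells_raise(self):
        pre, post = self.pre_post(0.9)
        with pytest.raises(PairingError):
            photobleaching_delta(pre, post[:-1])

    def test_threshold_mismatch_raises(self):
        pre, post = self.pre_post(0.9)
        post[0].threshold_used = 11.0
        with pytest.raises(ProvenanceError):
            photobleaching_delta(pre, post)

    def test_planted_factor_recovered_through_pipeline(self):
        vals = []
        for seed in (0, 1, 2):
            b = simgen.generate_dose_response_experiment(
                [1.0, 3.0, 6.0, 9.0], "compact", simgen.OpticsParams(),
                simgen.NoiseParams(), seed, bleach_factor=0.85,
            )
            res = pipeline.analyze_frames(
                b.all_frames(), b.calibration, b.concentration_map(), roles=b.role_map()
            )
            vals += [d.fractional_decrease for d in res.bleaching]
        assert np.mean(vals) == pytest.approx(0.15, abs=0.02)


class TestReleaseFraction:
    @pytest.mark.parametrize(
        "initial, final, triton, expected",
        [(10.0, 10.0, 110.0, 0.0), (10.0, 110.0, 110.0, 100.0), (10.0, 60.0, 110.0, 50.0)],
    )
    def test_endpoint_and_midpoint_cases(self, initial, final, triton, expected):
        m = ReleaseMeasurement(f_initial=initial, f_final=final, f_triton=triton)
        assert release_fraction(m) == pytest.approx(expected)

    def test_undefined_when_triton_equals_initial(self):
        with pytest.raises(UndefinedReleaseError):
            release_fraction(ReleaseMeasurement(10.0, 50.0, 10.0))

    def test_out_of_range_warns_but_returns(self):
        with pytest.warns(UserWarning):
            pct = release_fraction(ReleaseMeasurement(10.0, 200.0, 110.0))
        assert pct == pytest.approx(190.0)

    @given(
        shift=st.floats(-1e4, 1e4),
        initial=st.floats(0, 100),
        span=st.floats(1, 1000),
        frac=st.floats(0, 1),
    )
    def test_affine_invariance(self, shift, initial, span, frac):
        triton = initial + span
        final = initial + frac * span
        base = release_fraction(ReleaseMeasurement(initial, final, triton))
        shifted = release_fraction(
            ReleaseMeasurement(initial + shift, final + shift, triton + shift)
        )
        assert shifted == pytest.approx(base, abs=1e-6)
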