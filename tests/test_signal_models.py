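"""Forward models, WLSL initialisation and the simplex fitting contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adapts import (
    CARDIAC_PROTOCOL,
    DecaySignal,
    EchoProtocol,
    InvalidSignalError,
    MonoExpParams,
    NoiseCorrectedParams,
    OffsetModelParams,
    UnderdeterminedFitError,
    fit_model,
    predict_monoexp,
    predict_offset,
    predict_second_moment,
    wlsl_fit,
)

from .conftest import monoexp_signal


class TestForwardModels:
    def test_monoexp_point_values(self):
        prot = EchoProtocol((10.0, 20.0))
        pred = predict_monoexp(MonoExpParams(100.0, 10.0), prot)
        assert pred[0] == pytest.approx(100.0 * np.exp(-1.0), abs=1e-10)
        # value at TE -> 0 approaches PD
        assert predict_monoexp(MonoExpParams(100.0, 10.0), EchoProtocol((1e-9, 1.0)))[
            0
        ] == pytest.approx(100.0, rel=1e-8)

    def test_monoexp_matches_high_precision_oracle(self):
        # arbitrary-precision evaluation via sympy, frozen to 30 digits
        import sympy

        pred = predict_monoexp(MonoExpParams(100.0, 20.0), CARDIAC_PROTOCOL)
        for te, got in zip(CARDIAC_PROTOCOL.tes, pred):
            exact = float(
                (100 * sympy.exp(-sympy.Rational(str(te)) / 20)).evalf(30)
            )
            assert got == pytest.approx(exact, rel=1e-10)

    def test_monoexp_strictly_decreasing(self):
        pred = predict_monoexp(MonoExpParams(50.0, 7.0), CARDIAC_PROTOCOL)
        assert np.all(np.diff(pred) < 0)

    def test_offset_reduces_to_monoexp_and_adds_constant(self):
        mono = predict_monoexp(MonoExpParams(100.0, 10.0), CARDIAC_PROTOCOL)
        off0 = predict_offset(OffsetModelParams(100.0, 10.0, 0.0), CARDIAC_PROTOCOL)
        off5 = predict_offset(OffsetModelParams(100.0, 10.0, 5.0), CARDIAC_PROTOCOL)
        np.testing.assert_allclose(off0, mono, rtol=0, atol=0)
        np.testing.assert_allclose(off5, mono + 5.0, rtol=1e-15)
        assert off5[3] == pytest.approx(100.0 * np.exp(-1.0) + 5.0, abs=1e-4)

    def test_second_moment_values(self):
        sq = predict_second_moment(
            NoiseCorrectedParams(100.0, 10.0, 0.0), CARDIAC_PROTOCOL
        )
        mono = predict_monoexp(MonoExpParams(100.0, 10.0), CARDIAC_PROTOCOL)
        np.testing.assert_allclose(sq, mono**2, rtol=1e-15)
        sq300 = predict_second_moment(
            NoiseCorrectedParams(100.0, 10.0, 300.0), CARDIAC_PROTOCOL
        )
        # at TE = 10 ms: (100 e^-1)^2 + 300
        assert sq300[3] == pytest.approx(36.7879441**2 + 300.0, abs=1e-3)

    def test_param_invariants_rejected(self):
        with pytest.raises(ValueError):
            MonoExpParams(0.0, 10.0)
        with pytest.raises(ValueError):
            OffsetModelParams(100.0, 10.0, -1.0)
        with pytest.raises(ValueError):
            NoiseCorrectedParams(100.0, -1.0, 0.0)


class TestWlsl:
    def test_exact_on_noiseless_data(self):
        fit = wlsl_fit(monoexp_signal(CARDIAC_PROTOCOL, 100.0, 10.0))
        assert fit.pd == pytest.approx(100.0, rel=1e-9)
        assert fit.t2 == pytest.approx(10.0, rel=1e-9)

    def test_two_points_determine_the_line(self):
        sig = DecaySignal(EchoProtocol((2.5, 5.0)), np.array([77.8801, 60.6531]))
        fit = wlsl_fit(sig)
        assert fit.pd == pytest.approx(100.0, rel=1e-4)
        assert fit.t2 == pytest.approx(10.0, rel=1e-4)

    def test_matches_weighted_normal_equations(self, rng):
        # independent oracle: solve the 2x2 weighted normal equations
        # for ln(S) ~ a + b TE with weights S^2 directly
        te = CARDIAC_PROTOCOL.te_array
        y = 80.0 * np.exp(-te / 12.0) * np.exp(rng.normal(0, 0.05, te.size))
        w = y**2
        X = np.column_stack([np.ones_like(te), te])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * np.log(y)))
        fit = wlsl_fit(DecaySignal(CARDIAC_PROTOCOL, y))
        assert fit.pd == pytest.approx(np.exp(beta[0]), rel=1e-10)
        assert fit.t2 == pytest.approx(-1.0 / beta[1], rel=1e-10)

    def test_rejects_non_positive_values(self):
        sig = DecaySignal(EchoProtocol((1.0, 2.0, 3.0)), np.array([5.0, 0.0, 1.0]))
        with pytest.raises(InvalidSignalError):
            wlsl_fit(sig)

    def test_non_decaying_signal_clamped_to_ceiling(self):
        sig = DecaySignal(CARDIAC_PROTOCOL, np.full(10, 42.0))
        fit = wlsl_fit(sig)
        assert fit.t2 == pytest.approx(10 * 25.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        pd=st.floats(1.0, 1e4),
        t2=st.floats(0.5, 100.0),
    )
    def test_exact_recovery_property(self, pd, t2):
        fit = wlsl_fit(monoexp_signal(CARDIAC_PROTOCOL, pd, t2))
        assert fit.t2 == pytest.approx(min(t2, 250.0), rel=1e-8)


class TestFitModel:
    def test_noiseless_monoexp_recovery(self):
        params, diag = fit_model("monoexp", monoexp_signal(CARDIAC_PROTOCOL, 100, 10))
        assert params.pd == pytest.approx(100.0, rel=1e-6)
        assert params.t2 == pytest.approx(10.0, rel=1e-6)
        assert diag.converged and diag.sse < 1e-8

    def test_noiseless_offset_recovery(self):
        truth = OffsetModelParams(100.0, 10.0, 8.0)
        sig = DecaySignal(CARDIAC_PROTOCOL, predict_offset(truth, CARDIAC_PROTOCOL))
        params, diag = fit_model("offset", sig)
        assert params.pd == pytest.approx(100.0, rel=1e-4)
        assert params.t2 == pytest.approx(10.0, rel=1e-4)
        assert params.c == pytest.approx(8.0, rel=1e-4)

    def test_noiseless_second_moment_recovery(self):
        truth = NoiseCorrectedParams(100.0, 10.0, 300.0)
        values = np.sqrt(predict_second_moment(truth, CARDIAC_PROTOCOL))
        params, _ = fit_model("second_moment", DecaySignal(CARDIAC_PROTOCOL, values))
        assert params.t2 == pytest.approx(10.0, rel=1e-4)
        assert params.k == pytest.approx(300.0, rel=1e-2)

    def test_fixed_noise_second_moment(self):
        truth = NoiseCorrectedParams(100.0, 10.0, 300.0)
        values = np.sqrt(predict_second_moment(truth, CARDIAC_PROTOCOL))
        params, _ = fit_model(
            "second_moment",
            DecaySignal(CARDIAC_PROTOCOL, values),
            fixed_noise=300.0,
        )
        assert params.k == 300.0
        assert params.t2 == pytest.approx(10.0, rel=1e-6)

    def test_idempotent_at_the_optimum(self):
        sig = monoexp_signal(CARDIAC_PROTOCOL, 100, 10)
        params, diag = fit_model("monoexp", sig, init=MonoExpParams(100.0, 10.0))
        assert diag.sse < 1e-8
        assert params.t2 == pytest.approx(10.0, rel=1e-6)

    def test_underdetermined_raises(self):
        sig = DecaySignal(EchoProtocol((1.0, 2.0)), np.array([10.0, 5.0]))
        with pytest.raises(UnderdeterminedFitError):
            fit_model("offset", sig)

    def test_non_finite_signal_rejected_at_construction(self):
        with pytest.raises(InvalidSignalError):
            DecaySignal(EchoProtocol((1.0, 2.0)), np.array([1.0, np.nan]))

    def test_sse_dominates_grid_search_monoexp(self, rng):
        # oracle: brute-force 100x100 grid spanning +/-50% around truth
        te = CARDIAC_PROTOCOL.te_array
        y = np.abs(100 * np.exp(-te / 10.0) + rng.normal(0, 3.0, te.size))
        sig = DecaySignal(CARDIAC_PROTOCOL, y)
        params, diag = fit_model("monoexp", sig)
        pds = np.linspace(50, 150, 100)
        t2s = np.linspace(5, 15, 100)
        pred = pds[:, None, None] * np.exp(-te[None, None, :] / t2s[None, :, None])
        grid_min = np.sum((y - pred) ** 2, axis=-1).min()
        assert diag.sse <= grid_min + 1e-9

    def test_sse_dominates_grid_search_offset(self, rng):
        te = CARDIAC_PROTOCOL.te_array
        y = np.abs(100 * np.exp(-te / 10.0) + 8.0 + rng.normal(0, 3.0, te.size))
        sig = DecaySignal(CARDIAC_PROTOCOL, y)
        params, diag = fit_model("offset", sig)
        pds = np.linspace(50, 150, 100)
        t2s = np.linspace(5, 15, 100)
        cs = np.linspace(0, 16, 100)
        best = np.inf
        for pd_val in pds:
            pred = (
                pd_val * np.exp(-te[None, None, :] / t2s[:, None, None])
                + cs[None, :, None]
            )
            best = min(best, np.sum((y - pred) ** 2, axis=-1).min())
        assert diag.sse <= best + 1e-9

    def test_matches_scipy_nelder_mead(self, rng):
        # independent route: scipy's simplex from the same start should
        # not find a better interior optimum
        from scipy.optimize import minimize

        te = CARDIAC_PROTOCOL.te_array
        y = np.abs(100 * np.exp(-te / 10.0) + rng.normal(0, 2.0, te.size))
        sig = DecaySignal(CARDIAC_PROTOCOL, y)
        init = wlsl_fit(sig)
        params, diag = fit_model("monoexp", sig, init=init)
        res = minimize(
            lambda x: np.sum((y - x[0] * np.exp(-te / x[1])) ** 2),
            [init.pd, init.t2],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        assert diag.sse == pytest.approx(res.fun, rel=1e-6, abs=1e-9)
        assert params.t2 == pytest.approx(res.x[1], rel=1e-4)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        pd0=st.floats(10.0, 300.0),
        t20=st.floats(1.0, 60.0),
    )
    def test_sse_never_exceeds_initialization(self, seed, pd0, t20):
        g = np.random.default_rng(seed)
        te = CARDIAC_PROTOCOL.te_array
        y = np.abs(100 * np.exp(-te / 8.0) + g.normal(0, 5.0, te.size))
        sig = DecaySignal(CARDIAC_PROTOCOL, y)
        init = MonoExpParams(pd0, t20)
        _, diag = fit_model("monoexp", sig, init=init)
        sse_init = float(np.sum((y - pd0 * np.exp(-te / t20)) ** 2))
        assert diag.sse <= sse_init + 1e-9
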