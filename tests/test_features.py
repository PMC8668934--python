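"""Phasor/lifetime features: closed-form oracles, invariances, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasornet.decay_sim import BiexpParams, DecayConfig, DecayHistogram, model_curve
from phasornet.exceptions import ConfigurationError, EmptyDecayError
from phasornet.features import (
    FeatureScaler,
    amplitude_weighted_lifetime,
    apply_scaler,
    closed_form_features,
    extract_features,
    extract_features_batch,
    fit_scaler,
    invert_scaler,
    irf_phasor,
    mean_lifetime,
    phasor_coordinates,
)


def noiseless_histogram(params, config, scale=1e9):
    """Deterministic 'decay' with counts proportional to the model curve."""
    c = np.rint(model_curve(params, config) * scale).astype(np.int64)
    return DecayHistogram(c, config)


def numeric_closed_form(params, omega, n=100_000, t_max=400.0):
    """Quadrature oracle for the infinite-window feature definitions."""
    t = np.linspace(0.0, t_max, n)
    I = params.a1 * np.exp(-t / params.tau1) + (1 - params.a1) * np.exp(
        -t / params.tau2
    )
    area = np.trapezoid(I, t)
    g = np.trapezoid(I * np.cos(omega * t), t) / area
    s = np.trapezoid(I * np.sin(omega * t), t) / area
    tau_m = np.trapezoid(I * t, t) / area
    return np.array([g, s, tau_m, area / I[0]])


class TestClosedForm:
    def test_slow_modulation_limit(self):
        f = closed_form_features(BiexpParams(1.0, 2.0, 2.0), omega=1e-9)
        assert f.as_array() == pytest.approx([1.0, 0.0, 2.0, 2.0], abs=1e-6)

    def test_omega_tau_one(self):
        tau = 1.0
        f = closed_form_features(BiexpParams(1.0, tau, tau), omega=1.0)
        assert (f.g, f.s) == pytest.approx((0.5, 0.5))

    def test_matches_quadrature(self):
        p = BiexpParams(0.5, 1.0, 2.5)
        omega = DecayConfig().omega
        assert closed_form_features(p, omega).as_array() == pytest.approx(
            numeric_closed_form(p, omega), rel=1e-4
        )


class TestPhasorCoordinates:
    def test_delta_at_origin(self, delta_irf_config):
        c = np.zeros(256, dtype=np.int64)
        c[0] = 1000
        g, s = phasor_coordinates(DecayHistogram(c, delta_irf_config))
        assert g == pytest.approx(1.0, abs=1e-3)
        assert s == pytest.approx(0.0, abs=0.02)

    def test_biexp_matches_closed_form(self, delta_irf_config):
        p = BiexpParams(0.5, 1.0, 2.5)
        h = noiseless_histogram(p, delta_irf_config)
        g, s = phasor_coordinates(h)
        cf = closed_form_features(p, delta_irf_config.omega)
        assert g == pytest.approx(cf.g, abs=0.01)
        assert s == pytest.approx(cf.s, abs=0.01)

    def test_empty_decay_raises(self, delta_irf_config):
        with pytest.raises(EmptyDecayError):
            phasor_coordinates(DecayHistogram(np.zeros(256, int), delta_irf_config))

    def test_monotone_in_tau_for_monoexp(self, delta_irf_config):
        taus = np.linspace(0.2, 3.0, 15)
        gs = []
        for tau in taus:
            h = noiseless_histogram(BiexpParams(1.0, tau, tau), delta_irf_config)
            gs.append(phasor_coordinates(h))
        g = np.array([v[0] for v in gs])
        s = np.array([v[1] for v in gs])
        assert np.all(np.diff(g) < 0)  # g decreases with tau
        # s rises to a maximum near omega*tau = 1 then falls
        peak = np.argmax(s)
        assert np.all(np.diff(s[: peak + 1]) > 0)
        assert np.all(np.diff(s[peak:]) < 0)
        assert abs(taus[peak] - 1.0 / delta_irf_config.omega) < 0.35


class TestLifetimes:
    def test_point_mass_mean(self, delta_irf_config):
        c = np.zeros(256, dtype=np.int64)
        c[10] = 500
        t10 = delta_irf_config.channel_centers()[10]
        assert mean_lifetime(
            DecayHistogram(c, delta_irf_config), window_correction=False
        ) == pytest.approx(t10)

    def test_monoexp_short_lifetime(self, delta_irf_config):
        h = noiseless_histogram(BiexpParams(1.0, 0.5, 0.5), delta_irf_config)
        assert mean_lifetime(h) == pytest.approx(0.5, rel=2e-3)

    def test_biexp_mean_lifetime_near_moment_identity(self, delta_irf_config):
        h = noiseless_histogram(BiexpParams(0.5, 1.0, 2.5), delta_irf_config)
        assert mean_lifetime(h) == pytest.approx(2.0714, rel=0.02)

    def test_amplitude_weighted_monoexp(self, delta_irf_config):
        h = noiseless_histogram(BiexpParams(1.0, 1.0, 1.0), delta_irf_config)
        assert amplitude_weighted_lifetime(h) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize(
        "params, expect",
        [((0.5, 1.16, 2.35), 1.755), ((0.5, 1.0, 2.5), 1.75)],
    )
    def test_amplitude_weighted_biexp(self, delta_irf_config, params, expect):
        h = noiseless_histogram(BiexpParams(*params), delta_irf_config)
        assert amplitude_weighted_lifetime(h) == pytest.approx(expect, rel=0.02)


class TestFeatureAccuracy:
    def test_monoexp_features_within_one_percent_of_closed_forms(
        self, delta_irf_config
    ):
        """Noiseless monoexponentials across the training lifetime range."""
        omega = delta_irf_config.omega
        for tau in np.linspace(0.2, 3.0, 15):
            p = BiexpParams(1.0, tau, tau)
            f = extract_features_batch(
                model_curve(p, delta_irf_config)[None, :] * 1e9, delta_irf_config
            )[0]
            cf = closed_form_features(p, omega).as_array()
            assert np.all(np.abs(f - cf) / np.abs(cf) < 0.01), f"tau={tau}"

    def test_scale_invariance(self, delta_irf_config):
        h = noiseless_histogram(BiexpParams(0.4, 0.8, 2.2), delta_irf_config)
        f1 = extract_features(h).as_array()
        f2 = extract_features(
            DecayHistogram(h.counts * 7, delta_irf_config)
        ).as_array()
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_background_correction_cancels_exactly(self, delta_irf_config):
        h = noiseless_histogram(BiexpParams(0.5, 1.0, 2.5), delta_irf_config, 1e6)
        with_bg = DecayHistogram(h.counts + 50, delta_irf_config)
        f_raw = extract_features(h).as_array()
        f_corr = extract_features(with_bg, background=50.0).as_array()
        assert f_corr == pytest.approx(f_raw, abs=1e-12)

    def test_irf_phasor_printed_values(self):
        g32, _ = irf_phasor(32.0)
        g150, _ = irf_phasor(150.0)
        assert round(g32, 3) == 1.000
        assert round(g150, 3) == 0.999


class TestScaler:
    def test_two_point_standardization(self):
        sc = fit_scaler(np.array([[1.0], [3.0]]))
        assert apply_scaler(np.array([[1.0], [3.0]]), sc).ravel() == pytest.approx(
            [-1.0, 1.0]
        )

    def test_roundtrip_identity(self, rng):
        X = rng.normal(size=(50, 4))
        sc = fit_scaler(X)
        assert np.allclose(invert_scaler(apply_scaler(X, sc), sc), X, atol=1e-12)

    def test_training_features_standardized(self, rng):
        X = rng.gamma(2.0, 1.0, size=(500, 4))
        sc = fit_scaler(X)
        Z = apply_scaler(X, sc)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert Z.std(axis=0) == pytest.approx(np.ones(4))

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_scaler(np.ones((10, 4)))

    def test_holdout_mean_near_but_not_exactly_zero(self, rng):
        train = rng.normal(1.0, 2.0, size=(4000, 4))
        test = rng.normal(1.0, 2.0, size=(4000, 4))
        z = apply_scaler(test, fit_scaler(train))
        assert np.abs(z.mean(axis=0)).max() < 0.1
        assert np.abs(z.mean(axis=0)).max() > 1e-8


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    a1=st.floats(0.1, 0.9),
    tau1=st.floats(0.25, 2.9),
    ratio=st.floats(1.0, 3.0),
    scale=st.integers(2, 50),
)
def test_feature_count_rescaling_property(a1, tau1, ratio, scale):
    """g, s, tau_m are exactly invariant and <tau> invariant by construction
    under uniform count rescaling."""
    cfg = DecayConfig(irf_fwhm=0.0)
    tau2 = min(tau1 * ratio, 3.0)
    c = np.rint(model_curve(BiexpParams(a1, tau1, tau2), cfg) * 1e7).astype(np.int64)
    f1 = extract_features_batch(c[None, :], cfg)[0]
    f2 = extract_features_batch(c[None, :] * scale, cfg)[0]
    assert np.allclose(f1, f2, rtol=1e-10)
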