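"""Simulator: model curves against independent oracles, sampling statistics."""

import numpy as np
import pytest
from scipy import stats

from phasornet.decay_sim import (
    BiexpParams,
    DecayConfig,
    DecayHistogram,
    draw_biexp_params,
    generate_eval_set,
    generate_training_set,
    load_dataset,
    model_curve,
    model_curves,
    sample_decay,
    save_dataset,
)
from phasornet.decay_sim import _FWHM_SIGMA
from phasornet.exceptions import (
    ConfigurationError,
    InvalidParameterError,
)


def quadrature_model_curve(params, config, m=20, n_irf=4001):
    """Independent oracle: trapezoid quadrature of the continuous convolution
    integral of a Gaussian pulse with the biexponential, binned to channels."""
    n = config.n_channels * m
    tf = (np.arange(n) + 0.5) * config.period / n
    sig = config.irf_fwhm * 1e-3 / _FWHM_SIGMA
    ug = np.linspace(config.irf_center - 10 * sig, config.irf_center + 10 * sig, n_irf)
    gauss = np.exp(-0.5 * ((ug - config.irf_center) / sig) ** 2)
    conv = np.zeros(n)
    for a, tau in ((params.a1, params.tau1), (1 - params.a1, params.tau2)):
        lag = np.clip(tf[:, None] - ug[None, :], 0.0, None)
        e = np.where(tf[:, None] >= ug[None, :], np.exp(-lag / tau), 0.0)
        conv += a * np.trapezoid(gauss[None, :] * e, ug, axis=1)
    o = conv.reshape(config.n_channels, m).mean(axis=1)
    return o / o.sum()


class TestDecayConfig:
    def test_derived_quantities(self, default_config):
        assert default_config.omega * default_config.period == pytest.approx(
            2 * np.pi, abs=1e-14
        )
        assert default_config.dt == pytest.approx(12.5 / 256)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_channels": 1},
            {"period": 0.0},
            {"irf_fwhm": -1.0},
            {"irf_shape": "boxcar"},
            {"irf_shape": "tabulated"},  # missing table
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            DecayConfig(**kwargs)

    def test_irf_kernel_normalized_and_peaked_at_center(self):
        cfg = DecayConfig(irf_fwhm=150.0, irf_center=6.0)
        k = cfg.irf_kernel()
        assert k.sum() == pytest.approx(1.0)
        assert abs(cfg.channel_centers()[np.argmax(k)] - 6.0) < cfg.dt

    def test_json_roundtrip(self, tmp_path):
        cfg = DecayConfig(n_channels=128, period=50.0, irf_fwhm=150.0)
        cfg.to_json(tmp_path / "c.json")
        assert DecayConfig.from_json(tmp_path / "c.json") == cfg


class TestBiexpParams:
    def test_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            BiexpParams(0.5, 2.5, 1.0)

    def test_ordered_constructor_complements_a1(self):
        p = BiexpParams.ordered(0.3, 2.5, 1.0)
        assert (p.a1, p.tau1, p.tau2) == (0.7, 1.0, 2.5)

    @pytest.mark.parametrize("a1", [0.0, -0.1, 1.5])
    def test_bad_fraction_rejected(self, a1):
        with pytest.raises(InvalidParameterError):
            BiexpParams(a1, 1.0, 2.0)


class TestModelCurve:
    def test_default_length_and_normalization(self, default_config):
        c = model_curve(BiexpParams(0.5, 1.0, 2.5), default_config)
        assert c.shape == (256,)
        assert c.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(c >= 0)

    def test_monoexponential_no_irf_matches_exponential(self, delta_irf_config):
        c = model_curve(BiexpParams(1.0, 1.0, 1.0), delta_irf_config)
        t = delta_irf_config.channel_centers()
        expect = np.exp(-t)
        expect /= expect.sum()
        assert np.allclose(c, expect, rtol=1e-3)

    def test_matches_fine_grid_quadrature_oracle(self, default_config):
        p = BiexpParams(0.5, 1.0, 2.5)
        oracle = quadrature_model_curve(p, default_config)
        mine = model_curve(p, default_config)
        assert np.max(np.abs(mine - oracle) / oracle) < 1e-3

    def test_underflow_lifetime_raises(self, delta_irf_config):
        with pytest.raises(InvalidParameterError):
            model_curve(BiexpParams(1.0, 1e-9, 1e-9), delta_irf_config)

    def test_tabulated_irf_curve_normalized(self):
        table = [0.0] * 256
        table[3] = 1.0
        cfg = DecayConfig(irf_shape="tabulated", irf_table=tuple(table))
        c = model_curve(BiexpParams(0.5, 1.0, 2.5), cfg)
        assert c.sum() == pytest.approx(1.0)
        # pulse mass spread within channel 3 puts the curve maximum at the
        # rise (channel 3) or the first fully-developed channel (4)
        assert np.argmax(c) in (3, 4)
        assert np.all(c[:3] < 1e-6)


class TestSampleDecay:
    def test_reproducible_and_seed_sensitive(self, default_config):
        p = BiexpParams(0.5, 1.0, 2.5)
        a = sample_decay(p, default_config, 1e4, seed=5)
        b = sample_decay(p, default_config, 1e4, seed=5)
        c = sample_decay(p, default_config, 1e4, seed=6)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_total_mean(self, default_config):
        rng = np.random.default_rng(0)
        totals = [
            sample_decay(BiexpParams(0.5, 1.0, 2.5), default_config, 1000.0, rng).total
            for _ in range(300)
        ]
        se = np.sqrt(1000.0 / 300)
        assert abs(np.mean(totals) - 1000.0) < 3 * se

    def test_snr_definition(self, default_config):
        h = sample_decay(BiexpParams(0.5, 1.0, 2.5), default_config, 1e5, seed=0)
        assert h.snr == pytest.approx(np.sqrt(h.total))

    def test_monoexp_mean_arrival_matches_truncated_exponential(
        self, delta_irf_config
    ):
        tau, T = 0.5, delta_irf_config.period
        h = sample_decay(BiexpParams(1.0, tau, tau), delta_irf_config, 1e6, seed=2)
        t = delta_irf_config.channel_centers()
        emp = (h.counts * t).sum() / h.total
        expect = tau - T * np.exp(-T / tau) / (1 - np.exp(-T / tau))
        sd = np.sqrt(((h.counts * (t - emp) ** 2).sum() / h.total) / h.total)
        assert abs(emp - expect) < 3 * sd + delta_irf_config.dt**2 / (6 * tau)

    def test_multinomial_equals_per_photon_sampling(self, delta_irf_config, rng):
        """Chi-square homogeneity between the two sampling routes at N=1e4."""
        p = BiexpParams(0.5, 1.0, 2.5)
        curve = model_curve(p, delta_irf_config)
        n = 10_000
        a = rng.multinomial(n, curve)
        # per-photon inverse-CDF route
        cdf = np.cumsum(curve)
        channels = np.searchsorted(cdf, rng.uniform(size=n), side="right")
        b = np.bincount(channels, minlength=curve.size)
        # pool low-expectation bins, then two-sample chi-square
        order = np.argsort(-curve)
        pooled_a, pooled_b, ca, cb = [], [], 0, 0
        for k in order:
            ca += a[k]
            cb += b[k]
            if (ca + cb) >= 20:
                pooled_a.append(ca)
                pooled_b.append(cb)
                ca = cb = 0
        pooled_a.append(ca)
        pooled_b.append(cb)
        table = np.array([pooled_a, pooled_b])
        table = table[:, table.sum(axis=0) > 0]
        _, pval, _, _ = stats.chi2_contingency(table)
        assert pval > 0.01


class TestDatasets:
    def test_training_set_ranges_and_ordering(self):
        ds = generate_training_set(n_samples=300, seed=1)
        assert len(ds) == 300
        assert np.all(ds.params[:, 1] <= ds.params[:, 2])
        assert np.all((ds.params[:, 1:] >= 0.2) & (ds.params[:, 1:] <= 3.0))
        assert np.all((ds.params[:, 0] >= 0.1) & (ds.params[:, 0] <= 0.9))

    def test_deterministic_under_seed(self):
        a = generate_training_set(n_samples=10, seed=7)
        b = generate_training_set(n_samples=10, seed=7)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.params, b.params)

    def test_a1_uniformity_ks(self):
        params = draw_biexp_params(50_000, rng=np.random.default_rng(3))
        stat = stats.kstest(params[:, 0], stats.uniform(0.1, 0.8).cdf)
        assert stat.pvalue > 0.01

    def test_eval_set_photon_budget(self):
        ds = generate_eval_set(params=(0.5, 1.0, 2.5), n_reps=200, snr=31.0, seed=4)
        totals = ds.counts.sum(axis=1)
        assert abs(totals.mean() - 961.0) < 3 * np.sqrt(961.0 / 200)

    def test_eval_set_rejects_empty_request(self):
        with pytest.raises(ConfigurationError):
            generate_eval_set(params=(0.5, 1.0, 2.5), n_reps=0)

    def test_tau_range_outside_period_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_training_set(n_samples=5, tau_range=(0.2, 20.0))

    def test_csv_roundtrip(self, tmp_path):
        ds = generate_training_set(n_samples=8, seed=11)
        save_dataset(ds, tmp_path / "d")
        back = load_dataset(tmp_path / "d")
        assert np.array_equal(back.counts, ds.counts)
        assert np.allclose(back.params, ds.params)
        assert back.config == ds.config

    def test_histogram_shape_validated(self, default_config):
        with pytest.raises(ConfigurationError):
            DecayHistogram(np.ones(10, dtype=int), default_config)
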