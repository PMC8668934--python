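"""Reduction of decay histograms to the 4-vector (g, s, tau_m, <tau>).

The four features are the phasor coordinates at the laser repetition
frequency,

    g = sum_k c_k cos(w t_k) / sum_k c_k,
    s = sum_k c_k sin(w t_k) / sum_k c_k,

the mean (first-moment) lifetime tau_m = sum_k c_k t_k / sum_k c_k, and the
amplitude-weighted lifetime <tau> = integral of the amplitude-normalized
decay.  Times are measured from the IRF peak.  For a multiexponential with
fractions a_i and lifetimes tau_i the infinite-window values are

    g = [sum a_i tau_i / (1 + (w tau_i)^2)] / sum a_i tau_i
    s = [sum a_i w tau_i^2 / (1 + (w tau_i)^2)] / sum a_i tau_i
    tau_m = sum a_i tau_i^2 / sum a_i tau_i
    <tau>  = sum a_i tau_i

(see :func:`closed_form_features`).  Because the acquisition window spans
exactly one repetition period, the truncated Fourier ratios g and s equal
their infinite-window counterparts; the moment-based lifetimes do not, so
by default they are de-biased with a single-exponential finite-window
correction that is exact for monoexponential decays (``window_correction``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .decay_sim import DecayConfig, DecayHistogram, BiexpParams
from .exceptions import ConfigurationError, DegenerateDecayError, EmptyDecayError

__all__ = [
    "PhasorFeatures",
    "FeatureScaler",
    "phasor_coordinates",
    "mean_lifetime",
    "amplitude_weighted_lifetime",
    "extract_features",
    "extract_features_batch",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "closed_form_features",
    "irf_phasor",
    "time_origin",
]


@dataclass(frozen=True)
class PhasorFeatures:
    """The network's 4-vector input: (g, s, tau_m, tau_amp), lifetimes in ns."""

    g: float
    s: float
    tau_m: float
    tau_amp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.s, self.tau_m, self.tau_amp], dtype=float)


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature standardization (zero mean, unit variance) parameters."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float).ravel()
        s = np.asarray(self.std, dtype=float).ravel()
        if m.shape != s.shape:
            raise ConfigurationError("mean and std must have the same shape")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ConfigurationError("scaler std must be positive and finite")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "std", s)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


# ---------------------------------------------------------------------------
# Conventions: time origin and peak channel


def time_origin(config: DecayConfig) -> float:
    """Time origin for the feature integrals, in ns from the window start.

    The continuous IRF peak position for a Gaussian IRF; the center of the
    kernel's maximum channel for a tabulated IRF.
    """
    if config.irf_shape == "gaussian":
        return float(config.irf_center)
    kernel = config.irf_kernel()
    return float(config.channel_centers()[int(np.argmax(kernel))])


def _peak_channel(config: DecayConfig) -> int:
    """Channel expected to hold the decay maximum: the IRF kernel argmax."""
    return int(np.argmax(config.irf_kernel()))


# ---------------------------------------------------------------------------
# Finite-window (truncation) de-biasing

# For a monoexponential observed on a window of length T the first moment is
# m(tau) = tau - T e^{-T/tau} / (1 - e^{-T/tau}), monotone in tau with
# supremum T/2.  The inverse is tabulated once per period and interpolated.


@lru_cache(maxsize=8)
def _trunc_mean_table(period: float) -> tuple[np.ndarray, np.ndarray]:
    tau = np.geomspace(1e-4 * period, 40.0 * period, 8000)
    x = period / tau
    with np.errstate(over="ignore"):
        m = tau - period * np.exp(-x) / (-np.expm1(-x))
    return m, tau


def _invert_trunc_mean(m_raw: np.ndarray, period: float) -> np.ndarray:
    m, tau = _trunc_mean_table(period)
    return np.interp(np.clip(m_raw, m[0], m[-1]), m, tau)


# ---------------------------------------------------------------------------
# Batch feature extraction (single-decay operations are thin wrappers)


def extract_features_batch(
    counts,
    config: DecayConfig,
    background: np.ndarray | float | None = None,
    window_correction: bool = True,
    on_invalid: str = "raise",
    with_amplitude: bool = True,
) -> np.ndarray:
    """Features (g, s, tau_m, tau_amp) for each row of a counts matrix.

    ``background`` (scalar or per-channel) is subtracted first and negative
    channels are clamped to zero.  With ``on_invalid="nan"`` rows that are
    empty or degenerate yield NaN features instead of raising; this is what
    the per-pixel image pipeline uses.
    """
    C = np.atleast_2d(np.asarray(counts, dtype=float))
    if C.shape[1] != config.n_channels:
        raise ConfigurationError("counts row length must equal n_channels")
    if background is not None:
        C = C - background
        np.clip(C, 0.0, None, out=C)

    tot = C.sum(axis=1)
    empty = tot <= 0
    if np.any(empty) and on_invalid == "raise":
        raise EmptyDecayError("decay has zero total counts after background correction")
    tot = np.where(empty, np.nan, tot)

    t = config.channel_centers() - time_origin(config)
    w = config.omega
    g = (C @ np.cos(w * t)) / tot
    s = (C @ np.sin(w * t)) / tot
    tau_m_raw = (C @ t) / tot

    if window_correction:
        tau_m = _invert_trunc_mean(tau_m_raw, config.period)
        tau_m = np.where(np.isnan(tau_m_raw), np.nan, tau_m)
    else:
        tau_m = tau_m_raw

    if not with_amplitude:
        return np.column_stack([g, s, tau_m, np.full_like(tau_m, np.nan)])

    # Amplitude-weighted lifetime: area / amplitude at t = 0.  The amplitude
    # is taken from the peak channel with a local single-exponential
    # bin-integral correction.  The local decay constant comes from the
    # one-channel-lag ratio of sums over the few channels after the peak
    # (for exact exponential bin integrals that ratio is e^{-dt/tau}
    # regardless of the span, and summing tames Poisson noise).
    dt = config.dt
    p = _peak_channel(config)
    if p >= config.n_channels - 1:
        raise DegenerateDecayError("IRF peak in the last channel; no decay to integrate")
    cp = C[:, p]
    bad_peak = cp <= 0
    if np.any(bad_peak & ~empty) and on_invalid == "raise":
        raise DegenerateDecayError("zero counts in the peak channel")
    cp = np.where(bad_peak, np.nan, cp)
    span = min(8, config.n_channels - 1 - p)
    lead = C[:, p : p + span].sum(axis=1)
    lag = C[:, p + 1 : p + 1 + span].sum(axis=1)
    ratio = np.clip(lag / np.where(lead > 0, lead, np.nan), 1e-12, 1.0 - 1e-9)
    tau_loc = np.clip(-dt / np.log(ratio), dt / 20.0, 20.0 * config.period)
    amplitude = cp / (tau_loc * -np.expm1(-dt / tau_loc))
    tau_amp = tot / amplitude
    if window_correction:
        tau_amp = tau_amp / -np.expm1(-config.period / np.where(tau_m > 0, tau_m, np.inf))

    return np.column_stack([g, s, tau_m, tau_amp])


def _single(
    decay: DecayHistogram, background=None, window_correction=True, with_amplitude=True
) -> np.ndarray:
    return extract_features_batch(
        decay.counts[None, :],
        decay.config,
        background,
        window_correction,
        with_amplitude=with_amplitude,
    )[0]


def phasor_coordinates(decay: DecayHistogram) -> tuple[float, float]:
    """Phasor (g, s) of one histogram at the laser repetition frequency."""
    f = _single(decay, with_amplitude=False)
    return float(f[0]), float(f[1])


def mean_lifetime(decay: DecayHistogram, window_correction: bool = True) -> float:
    """First-moment lifetime tau_m in ns (optionally truncation-corrected)."""
    return float(
        _single(decay, window_correction=window_correction, with_amplitude=False)[2]
    )


def amplitude_weighted_lifetime(
    decay: DecayHistogram, window_correction: bool = True
) -> float:
    """Amplitude-weighted lifetime <tau> = area / t=0 amplitude, in ns."""
    return float(_single(decay, window_correction=window_correction)[3])


def extract_features(
    decay: DecayHistogram,
    background: np.ndarray | float | None = None,
    window_correction: bool = True,
) -> PhasorFeatures:
    """Background-correct one histogram and reduce it to its 4 features."""
    f = _single(decay, background, window_correction)
    return PhasorFeatures(*map(float, f))


# ---------------------------------------------------------------------------
# Standardization


def fit_scaler(features: np.ndarray) -> FeatureScaler:
    """Per-feature mean/std estimated from a training feature matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] < 2:
        raise ConfigurationError("need at least 2 samples to fit a scaler")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if np.any(std <= 0):
        raise ConfigurationError("a feature has zero variance; cannot standardize")
    return FeatureScaler(mean, std)


def apply_scaler(features: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    return (np.asarray(features, dtype=float) - scaler.mean) / scaler.std


def invert_scaler(standardized: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    return np.asarray(standardized, dtype=float) * scaler.std + scaler.mean


# ---------------------------------------------------------------------------
# Analytic references


def closed_form_features(
    params: BiexpParams, omega: float | None = None
) -> PhasorFeatures:
    """Infinite-window analytic features of a noiseless biexponential.

    Used as a test oracle and for documentation; ``omega`` defaults to the
    80 MHz value 2*pi/12.5 rad/ns.
    """
    if omega is None:
        omega = DecayConfig().omega
    a = np.array([params.a1, 1.0 - params.a1])
    tau = np.array([params.tau1, params.tau2])
    atau = a * tau
    denom = atau.sum()
    g = float((atau / (1.0 + (omega * tau) ** 2)).sum() / denom)
    s = float((atau * omega * tau / (1.0 + (omega * tau) ** 2)).sum() / denom)
    tau_m = float((a * tau**2).sum() / denom)
    tau_amp = float(denom)
    return PhasorFeatures(g, s, tau_m, tau_amp)


def irf_phasor(
    fwhm_ps: float, config: DecayConfig | None = None
) -> tuple[float, float]:
    """Phasor (g, s) of a Gaussian IRF discretized on the channel grid.

    The pulse is placed on the mid-window channel center so the grid
    samples it fully (as a measured IRF would sit inside the window), and
    the phasor time origin is the kernel's peak channel.
    """
    base = config or DecayConfig()
    center = float(base.channel_centers()[base.n_channels // 2])
    cfg = DecayConfig(
        n_channels=base.n_channels,
        period=base.period,
        irf_fwhm=fwhm_ps,
        irf_center=center,
        irf_shape="gaussian",
    )
    kernel = cfg.irf_kernel()
    t = cfg.channel_centers() - cfg.channel_centers()[int(np.argmax(kernel))]
    g = float(kernel @ np.cos(cfg.omega * t))
    s = float(kernel @ np.sin(cfg.omega * t))
    return g, s
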