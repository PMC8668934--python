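"""Monte Carlo simulation of TCSPC biexponential fluorescence decays.

Time-correlated single-photon counting records, for every detected photon,
its arrival time relative to the laser pulse; accumulating many photons
yields a decay histogram over ``n_channels`` temporal bins spanning one
laser repetition period.  The photophysical model is a biexponential

    I(t) = IRF(t) * [a1 exp(-t/tau1) + (1 - a1) exp(-t/tau2)]

convolved with the instrument response function (IRF).  Under Poisson
photon statistics the signal-to-noise ratio of a histogram equals the
square root of its total photon count.

Sampling is done as Poisson(total) + multinomial over the discretized
model curve, which is exactly equivalent in distribution to drawing each
photon's arrival time from the normalized curve but tractable for tens of
thousands of histograms with up to 10^6 photons each.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft
from scipy.special import erf as scipy_erf
from scipy.special import erfcx as scipy_erfcx

from .exceptions import ConfigurationError, FormatError, InvalidParameterError

__all__ = [
    "DecayConfig",
    "BiexpParams",
    "DecayHistogram",
    "LabeledDataset",
    "model_curve",
    "model_curves",
    "sample_decay",
    "draw_biexp_params",
    "generate_training_set",
    "generate_eval_set",
    "save_dataset",
    "load_dataset",
    "DEFAULT_OVERSAMPLE",
]

#: FWHM of a Gaussian = _FWHM_SIGMA * sigma
_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Fine-grid oversampling factor used when discretizing the convolved model.
DEFAULT_OVERSAMPLE = 25


@dataclass(frozen=True)
class DecayConfig:
    """Acquisition geometry of a TCSPC channel.

    Parameters
    ----------
    n_channels
        Number of temporal bins the repetition period is divided into.
    period
        Laser repetition period in ns (12.5 ns corresponds to 80 MHz).
    irf_fwhm
        Full width at half maximum of the instrument response, in **ps**.
    irf_center
        Position of the IRF peak in ns relative to the window start.
    irf_shape
        ``"gaussian"`` or ``"tabulated"``; the latter reads a per-channel
        kernel from ``irf_table``.
    irf_table
        Per-channel IRF samples (length ``n_channels``), only for the
        tabulated shape.  Renormalized internally.
    """

    n_channels: int = 256
    period: float = 12.5
    irf_fwhm: float = 32.0
    irf_center: float = 0.0
    irf_shape: str = "gaussian"
    irf_table: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if not (self.period > 0 and np.isfinite(self.period)):
            raise ConfigurationError("period must be a positive finite number of ns")
        if self.irf_fwhm < 0:
            raise ConfigurationError("irf_fwhm must be >= 0 ps")
        if self.irf_shape not in ("gaussian", "tabulated"):
            raise ConfigurationError(f"unknown irf_shape {self.irf_shape!r}")
        if self.irf_shape == "tabulated":
            if self.irf_table is None or len(self.irf_table) != self.n_channels:
                raise ConfigurationError(
                    "tabulated IRF requires irf_table of length n_channels"
                )
            if min(self.irf_table) < 0 or sum(self.irf_table) <= 0:
                raise ConfigurationError("irf_table must be non-negative with positive sum")
        if self.irf_table is not None and not isinstance(self.irf_table, tuple):
            object.__setattr__(self, "irf_table", tuple(float(v) for v in self.irf_table))

    @property
    def omega(self) -> float:
        """Laser angular repetition frequency 2*pi/period in rad/ns."""
        return 2.0 * np.pi / self.period

    @property
    def dt(self) -> float:
        """Channel width in ns."""
        return self.period / self.n_channels

    def channel_centers(self, oversample: int = 1) -> np.ndarray:
        """Bin-center times t_k = (k + 1/2) * dt / oversample, in ns."""
        n = self.n_channels * oversample
        return (np.arange(n) + 0.5) * (self.period / n)

    def irf_kernel(self, oversample: int = 1) -> np.ndarray:
        """IRF discretized on the (optionally oversampled) channel grid, sum 1.

        Gaussian kernels carry the exact pulse mass per bin (erf
        differences), so a pulse truncated by the window edge discretizes
        consistently at any oversampling.  A zero-width Gaussian
        degenerates to a delta on the grid point nearest ``irf_center``.
        """
        t = self.channel_centers(oversample)
        if self.irf_shape == "tabulated":
            w = np.repeat(np.asarray(self.irf_table, dtype=float), oversample)
        else:
            sigma = self.irf_fwhm * 1e-3 / _FWHM_SIGMA  # ps -> ns
            if sigma <= 0:
                w = np.zeros(t.size)
                w[int(np.argmin(np.abs(t - self.irf_center)))] = 1.0
            else:
                edges = np.linspace(0.0, self.period, t.size + 1)
                z = (edges - self.irf_center) / (sigma * np.sqrt(2.0))
                w = np.diff(scipy_erf(z))
                if w.sum() <= 0:  # pulse entirely outside the window
                    w = np.zeros(t.size)
                    w[int(np.argmin(np.abs(t - self.irf_center)))] = 1.0
        return w / w.sum()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecayConfig":
        d = json.loads(Path(path).read_text())
        if d.get("irf_table") is not None:
            d["irf_table"] = tuple(d["irf_table"])
        return cls(**d)


@dataclass(frozen=True)
class BiexpParams:
    """Biexponential decay parameters (a1, tau1, tau2), lifetimes in ns.

    ``a1`` is the fraction of the first (shorter-lived) component; the
    complementary fraction ``1 - a1`` belongs to ``tau2``.  Ordering
    ``tau1 <= tau2`` is enforced at construction.
    """

    a1: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a1 <= 1.0):
            raise InvalidParameterError(f"a1 must be in (0, 1], got {self.a1}")
        if not (self.tau1 > 0 and np.isfinite(self.tau1)):
            raise InvalidParameterError(f"tau1 must be positive, got {self.tau1}")
        if not (self.tau2 >= self.tau1 and np.isfinite(self.tau2)):
            raise InvalidParameterError(
                f"require tau2 >= tau1 > 0, got tau1={self.tau1}, tau2={self.tau2}"
            )

    @classmethod
    def ordered(cls, a1: float, tau1: float, tau2: float) -> "BiexpParams":
        """Build with the lifetimes sorted; swapping slots complements a1."""
        if tau1 > tau2:
            a1, tau1, tau2 = 1.0 - a1, tau2, tau1
        return cls(a1, tau1, tau2)

    @property
    def a2(self) -> float:
        return 1.0 - self.a1

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.tau1, self.tau2], dtype=float)


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per temporal channel together with the acquisition config."""

    counts: np.ndarray
    config: DecayConfig

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size != self.config.n_channels:
            raise ConfigurationError(
                f"counts must be 1-D of length {self.config.n_channels}, got shape {c.shape}"
            )
        if np.any(c < 0):
            raise ConfigurationError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def snr(self) -> float:
        """Poisson signal-to-noise ratio sqrt(N)."""
        return float(np.sqrt(self.total))


# ---------------------------------------------------------------------------
# Model curve


@lru_cache(maxsize=32)
def _kernel_fft(config: DecayConfig, oversample: int) -> tuple[np.ndarray, int, int]:
    """rfft of the fine-grid IRF kernel, padded for linear convolution."""
    n = config.n_channels * oversample
    nfft = next_fast_len(2 * n - 1)
    return rfft(config.irf_kernel(oversample), nfft), nfft, n


def _biexp_fine(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a1 = params[:, 0:1]
    with np.errstate(under="ignore"):
        return a1 * np.exp(-t / params[:, 1:2]) + (1.0 - a1) * np.exp(
            -t / params[:, 2:3]
        )


def _emg(t: np.ndarray, tau: np.ndarray, sigma: float, center: float) -> np.ndarray:
    """Gaussian (x) exponential convolution density, numerically stable.

    The exponentially modified Gaussian
        0.5 * exp(sigma^2/(2 tau^2) - (t-c)/tau) * erfc(z),
        z = (sigma/tau - (t-c)/sigma) / sqrt(2),
    evaluated as exp(-(t-c)^2/(2 sigma^2)) * erfcx(z) / 2 where erfcx would
    not overflow, and by its asymptotic tail form (erfc -> 2) deep in the
    decay tail where it would.
    """
    u = t - center
    z = (sigma / tau - u / sigma) / np.sqrt(2.0)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        body = 0.5 * np.exp(-0.5 * (u / sigma) ** 2) * scipy_erfcx(z)
        tail = np.exp(sigma**2 / (2.0 * tau**2) - u / tau)
    return np.where(z < -6.0, tail, body)


def model_curves(
    params: np.ndarray,
    config: DecayConfig | None = None,
    oversample: int = DEFAULT_OVERSAMPLE,
    chunk: int = 1024,
) -> np.ndarray:
    """Normalized model decay curves for a batch of parameter triples.

    Each row of ``params`` is (a1, tau1, tau2).  For the Gaussian IRF the
    convolution is evaluated in closed form (exponentially modified
    Gaussian); a tabulated IRF is convolved discretely.  Either way the
    curve is sampled on a grid oversampled ``oversample``-fold, integrated
    over each channel, truncated to the acquisition window and
    renormalized to sum 1.

    Returns an array of shape ``(n, n_channels)``.
    """
    config = config or DecayConfig()
    P = np.atleast_2d(np.asarray(params, dtype=float))
    if P.shape[1] != 3:
        raise InvalidParameterError("params must have three columns (a1, tau1, tau2)")
    if not np.all(np.isfinite(P)):
        raise InvalidParameterError("non-finite decay parameters")
    if np.any(P[:, 0] <= 0) or np.any(P[:, 0] > 1) or np.any(P[:, 1:] <= 0):
        raise InvalidParameterError("require 0 < a1 <= 1 and lifetimes > 0")

    t = config.channel_centers(oversample)
    sigma = config.irf_fwhm * 1e-3 / _FWHM_SIGMA
    gaussian = config.irf_shape == "gaussian" and sigma > 0
    if not gaussian and config.irf_shape == "tabulated":
        kfft, nfft, nf = _kernel_fft(config, oversample)

    out = np.empty((P.shape[0], config.n_channels))
    for lo in range(0, P.shape[0], chunk):
        block = P[lo : lo + chunk]
        if gaussian:
            a1 = block[:, 0:1]
            fine = a1 * _emg(t, block[:, 1:2], sigma, config.irf_center) + (
                1.0 - a1
            ) * _emg(t, block[:, 2:3], sigma, config.irf_center)
        elif config.irf_shape == "tabulated":
            fine = _biexp_fine(block, t)
            fine = irfft(rfft(fine, nfft, axis=-1) * kfft, nfft, axis=-1)[..., :nf]
        else:  # zero-width pulse at irf_center
            shifted = np.maximum(t - config.irf_center, 0.0)
            fine = _biexp_fine(block, shifted) * (t >= config.irf_center)
        curves = fine.reshape(block.shape[0], config.n_channels, oversample).sum(-1)
        np.clip(curves, 0.0, None, out=curves)
        norm = curves.sum(axis=-1, keepdims=True)
        if not np.all(np.isfinite(norm)) or np.any(norm <= 0):
            raise InvalidParameterError(
                "model curve underflowed to zero (lifetime too small for the grid)"
            )
        out[lo : lo + chunk] = curves / norm
    return out


def model_curve(
    params: BiexpParams,
    config: DecayConfig | None = None,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> np.ndarray:
    """Normalized per-channel probabilities of the IRF-convolved biexponential."""
    return model_curves(params.as_array()[None, :], config, oversample)[0]


# ---------------------------------------------------------------------------
# Sampling


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_decay(
    params: BiexpParams,
    config: DecayConfig | None = None,
    mean_photons: float = 1e5,
    seed=None,
) -> DecayHistogram:
    """Draw one Poisson/multinomial decay histogram.

    The total photon number is Poisson(``mean_photons``); arrival channels
    are multinomial over the model curve, which matches per-photon
    inverse-CDF sampling in distribution.
    """
    if not (mean_photons > 0):
        raise ConfigurationError("mean_photons must be positive")
    config = config or DecayConfig()
    rng = _as_rng(seed)
    curve = model_curve(params, config)
    total = rng.poisson(mean_photons)
    counts = rng.multinomial(total, curve)
    return DecayHistogram(counts, config)


@dataclass(frozen=True)
class LabeledDataset:
    """Ground-truth parameter triples paired with simulated histograms.

    ``params`` has shape (n, 3) with columns (a1, tau1, tau2); ``counts``
    has shape (n, n_channels).  All records share one :class:`DecayConfig`.
    """

    params: np.ndarray
    counts: np.ndarray
    config: DecayConfig
    seed: int
    snr_nominal: float

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        c = np.asarray(self.counts)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] == 0:
            raise ConfigurationError("params must be a non-empty (n, 3) array")
        if c.shape != (p.shape[0], self.config.n_channels):
            raise ConfigurationError("counts shape must be (n, n_channels)")
        object.__setattr__(self, "params", p)
        object.__setattr__(self, "counts", c.astype(np.int64))

    def __len__(self) -> int:
        return self.params.shape[0]

    def record(self, i: int) -> tuple[BiexpParams, DecayHistogram]:
        a1, t1, t2 = self.params[i]
        return BiexpParams(a1, t1, t2), DecayHistogram(self.counts[i], self.config)

    @property
    def records(self):
        return (self.record(i) for i in range(len(self)))


def draw_biexp_params(
    n: int,
    a1_range: tuple[float, float] = (0.1, 0.9),
    tau_range: tuple[float, float] = (0.2, 3.0),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Uniform random (a1, tau1, tau2) with the two lifetimes sorted ascending."""
    rng = _as_rng(rng)
    a1 = rng.uniform(*a1_range, size=n)
    taus = np.sort(rng.uniform(*tau_range, size=(n, 2)), axis=1)
    return np.column_stack([a1, taus])


def _validate_ranges(config, a1_range, tau_range):
    if not (0.0 <= a1_range[0] < a1_range[1] <= 1.0):
        raise ConfigurationError(f"a1_range must be inside [0, 1], got {a1_range}")
    if not (0.0 < tau_range[0] < tau_range[1] < config.period):
        raise ConfigurationError(
            f"tau_range must lie inside (0, period={config.period}), got {tau_range}"
        )


def generate_training_set(
    config: DecayConfig | None = None,
    n_samples: int = 50_000,
    a1_range: tuple[float, float] = (0.1, 0.9),
    tau_range: tuple[float, float] = (0.2, 3.0),
    snr: float = 316.0,
    seed: int = 0,
) -> LabeledDataset:
    """Simulate a training set of biexponential decays at one nominal SNR.

    Defaults follow the training protocol: 50,000 decays, a1 uniform on
    [0.1, 0.9], lifetimes uniform on [0.2, 3.0] ns (sorted), mean photon
    number snr**2 with snr = 316.
    """
    config = config or DecayConfig()
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    if not (snr > 0):
        raise ConfigurationError("snr must be positive")
    _validate_ranges(config, a1_range, tau_range)
    ss = np.random.SeedSequence(seed)
    param_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    params = draw_biexp_params(n_samples, a1_range, tau_range, param_rng)
    curves = model_curves(params, config)
    totals = noise_rng.poisson(snr**2, size=n_samples)
    counts = noise_rng.multinomial(totals, curves)
    return LabeledDataset(params, counts, config, seed, float(snr))


def generate_eval_set(
    config: DecayConfig | None = None,
    params: BiexpParams | tuple[float, float, float] = (0.5, 1.0, 2.5),
    n_reps: int = 1000,
    snr: float = 316.0,
    seed: int = 0,
) -> LabeledDataset:
    """Simulate ``n_reps`` i.i.d. decays at one fixed parameter triple."""
    config = config or DecayConfig()
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    if not (snr > 0):
        raise ConfigurationError("snr must be positive")
    if not isinstance(params, BiexpParams):
        params = BiexpParams(*params)
    if not (0 < params.tau1 and params.tau2 < config.period):
        raise ConfigurationError("lifetimes must lie inside (0, period)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    curve = model_curve(params, config)
    totals = rng.poisson(snr**2, size=n_reps)
    counts = rng.multinomial(totals, curve)
    P = np.tile(params.as_array(), (n_reps, 1))
    return LabeledDataset(P, counts, config, seed, float(snr))


# ---------------------------------------------------------------------------
# Serialization (delimited text + JSON config)


def save_dataset(ds: LabeledDataset, directory: str | Path) -> None:
    """Write params.csv, counts.csv and config.json into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tab = pd.DataFrame(
        {
            "id": np.arange(len(ds)),
            "a1": ds.params[:, 0],
            "tau1_ns": ds.params[:, 1],
            "tau2_ns": ds.params[:, 2],
            "total_photons": ds.counts.sum(axis=1),
            "seed": ds.seed,
        }
    )
    tab.to_csv(d / "params.csv", index=False)
    np.savetxt(d / "counts.csv", ds.counts, fmt="%d", delimiter=",")
    meta = dataclasses.asdict(ds.config)
    meta.update(seed=ds.seed, snr_nominal=ds.snr_nominal)
    (d / "config.json").write_text(json.dumps(meta, indent=1))


def load_dataset(directory: str | Path) -> LabeledDataset:
    d = Path(directory)
    try:
        meta = json.loads((d / "config.json").read_text())
        seed = int(meta.pop("seed"))
        snr = float(meta.pop("snr_nominal"))
        if meta.get("irf_table") is not None:
            meta["irf_table"] = tuple(meta["irf_table"])
        config = DecayConfig(**meta)
        tab = pd.read_csv(d / "params.csv")
        counts = np.loadtxt(d / "counts.csv", dtype=np.int64, delimiter=",", ndmin=2)
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"cannot load dataset from {d}: {exc}") from exc
    params = tab[["a1", "tau1_ns", "tau2_ns"]].to_numpy()
    return LabeledDataset(params, counts, config, seed, snr)
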