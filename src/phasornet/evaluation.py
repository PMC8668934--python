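"""Evaluation statistics and the three simulation studies.

Estimator accuracy is summarized per condition by box statistics of the
1000-replicate (configurable) predicted parameters: median, quartiles by
linear interpolation, Tukey whiskers at 1.5 x IQR clipped to the data
range.  Bias is reported both absolutely and as the relative error of the
median,

    err = |X_m - X_t| / X_t,

where X_m is the median estimate and X_t the true value.  The three
canonical sweeps vary the signal-to-noise ratio, the first (FRET-shortened
donor) lifetime, and the proportion a1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .decay_sim import BiexpParams, DecayConfig, generate_eval_set
from .exceptions import ConfigurationError
from .features import extract_features_batch
from .knn_baseline import KNNModel, knn_predict
from .mlfit import DEFAULT_BOUNDS, fit_decays
from .phasor_net import TrainedModel, predict

__all__ = [
    "BoxStats",
    "boxplot_stats",
    "relative_error",
    "fret_efficiency",
    "make_phasor_net_estimator",
    "make_knn_estimator",
    "make_mlfit_estimator",
    "run_sweep",
    "run_snr_sweep",
    "run_tau1_sweep",
    "run_a1_sweep",
]

#: An estimator maps a counts matrix + config to an (n, 3) parameter array.
Estimator = Callable[[np.ndarray, DecayConfig], np.ndarray]

PARAM_NAMES = ("a1", "tau1", "tau2")


@dataclass(frozen=True)
class BoxStats:
    """Median, quartiles and 1.5-IQR whiskers of one sample."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


def boxplot_stats(samples) -> BoxStats:
    """Box summary with linearly interpolated quartiles and Tukey whiskers."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ConfigurationError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(max(x.min(), q1 - 1.5 * iqr)),
        whisker_high=float(min(x.max(), q3 + 1.5 * iqr)),
        n=int(x.size),
    )


def relative_error(estimated_median: float, truth: float) -> float:
    """err = |X_m - X_t| / X_t, as a fraction."""
    if truth == 0:
        raise ConfigurationError("relative error undefined for a zero truth")
    return abs(estimated_median - truth) / abs(truth)


def fret_efficiency(tau1: float, tau2: float) -> float:
    """FRET efficiency E = 1 - tau1/tau2 (tau1: donor with acceptor, tau2: donor)."""
    if not (tau2 > 0):
        raise ConfigurationError("tau2 must be positive")
    e = 1.0 - tau1 / tau2
    if e < 0:
        warnings.warn("tau1 > tau2 gives a negative FRET efficiency")
    return e


# ---------------------------------------------------------------------------
# Estimator adapters


def make_phasor_net_estimator(model: TrainedModel) -> Estimator:
    def estimator(counts, config):
        return predict(model, extract_features_batch(counts, config))

    return estimator


def make_knn_estimator(model: KNNModel) -> Estimator:
    def estimator(counts, config):
        return knn_predict(model, extract_features_batch(counts, config))

    return estimator


def make_mlfit_estimator(bounds=DEFAULT_BOUNDS, max_iter: int = 6000) -> Estimator:
    def estimator(counts, config):
        params, _ = fit_decays(counts, config, bounds, max_iter=max_iter)
        return params

    return estimator


# ---------------------------------------------------------------------------
# Experiment runners


def run_sweep(
    estimator: Estimator,
    conditions: Sequence[tuple[BiexpParams, float]],
    sweep_name: str,
    condition_values: Sequence[float],
    config: DecayConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Generic runner: one evaluation set per (params, snr) condition.

    Returns one row per condition x parameter with box statistics and the
    absolute/relative errors of the median.  Deterministic per seed.
    """
    config = config or DecayConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(conditions))]
    rows = []
    for (params, snr), value, cseed in zip(conditions, condition_values, child_seeds):
        ds = generate_eval_set(config, params, n_reps=n_reps, snr=snr, seed=cseed)
        est = estimator(ds.counts, config)
        truth = params.as_array()
        for j, name in enumerate(PARAM_NAMES):
            bs = boxplot_stats(est[:, j])
            rows.append(
                {
                    "sweep": sweep_name,
                    "condition": value,
                    "snr": snr,
                    "parameter": name,
                    "truth": truth[j],
                    "median": bs.median,
                    "q1": bs.q1,
                    "q3": bs.q3,
                    "whisker_low": bs.whisker_low,
                    "whisker_high": bs.whisker_high,
                    "n": bs.n,
                    "abs_error": abs(bs.median - truth[j]),
                    "rel_error": relative_error(bs.median, truth[j]),
                }
            )
    return pd.DataFrame(rows)


def run_snr_sweep(
    estimator: Estimator,
    snr_list: Sequence[float] = (31.0, 100.0, 316.0, 1000.0),
    params: BiexpParams | tuple = (0.5, 1.0, 2.5),
    config: DecayConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed (a1, tau1, tau2), swept signal-to-noise ratio."""
    if not isinstance(params, BiexpParams):
        params = BiexpParams(*params)
    conditions = [(params, float(snr)) for snr in snr_list]
    return run_sweep(estimator, conditions, "snr", list(snr_list), config, n_reps, seed)


def run_tau1_sweep(
    estimator: Estimator,
    tau1_list: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    a1: float = 0.5,
    tau2: float = 2.5,
    snr: float = 100.0,
    config: DecayConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Swept donor-with-acceptor lifetime tau1 at fixed a1, tau2 and SNR."""
    conditions = [(BiexpParams(a1, t1, tau2), snr) for t1 in tau1_list]
    return run_sweep(estimator, conditions, "tau1", list(tau1_list), config, n_reps, seed)


def run_a1_sweep(
    estimator: Estimator,
    a1_list: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    tau1: float = 1.0,
    tau2: float = 2.5,
    snr: float = 100.0,
    config: DecayConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Swept proportion a1 at fixed lifetimes and SNR."""
    conditions = [(BiexpParams(a, tau1, tau2), snr) for a in a1_list]
    return run_sweep(estimator, conditions, "a1", list(a1_list), config, n_reps, seed)
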