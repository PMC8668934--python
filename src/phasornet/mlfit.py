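"""Maximum-likelihood biexponential fitting of single decays (the MLfit baseline).

Each histogram is fit with the IRF-convolved biexponential model by
minimizing the Poisson deviance

    D(params) = 2 sum_k [ mu_k - c_k - c_k ln(mu_k / c_k) ]

(terms with c_k = 0 reduce to 2 mu_k), where mu_k = N * model_curve_k.
This is the maximum-likelihood weighted quadratic criterion appropriate
for photon-counting noise; it is non-negative and zero iff mu == c.
Optimization uses the Nelder-Mead simplex on a logistic bound transform
of (a1, tau1, tau2) with an iteration cap of 6000 and tolerance 1e-12.
Bounds default to the network training ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit as scipy_expit

from .decay_sim import (
    DEFAULT_OVERSAMPLE,
    BiexpParams,
    DecayConfig,
    DecayHistogram,
    model_curves,
)
from .exceptions import EmptyDecayError
from .features import extract_features_batch

__all__ = [
    "FitResult",
    "DEFAULT_BOUNDS",
    "auto_initial_guess",
    "fit_decay_mle",
    "fit_decays",
    "poisson_deviance",
]

#: (a1, tau1, tau2) box constraints; lifetimes and a1 restricted to the
#: same ranges as the network training data.
DEFAULT_BOUNDS = ((0.1, 0.9), (0.2, 3.0), (0.2, 3.0))


@dataclass(frozen=True)
class FitResult:
    params: BiexpParams
    objective: float
    iterations: int
    converged: bool
    init: BiexpParams


def poisson_deviance(mu: np.ndarray, counts: np.ndarray) -> float:
    """Poisson deviance 2*sum(mu - c - c*ln(mu/c)); zero-count terms give 2*mu."""
    mu = np.clip(np.asarray(mu, dtype=float), 1e-300, None)
    c = np.asarray(counts, dtype=float)
    pos = c > 0
    dev = 2.0 * float((mu - c).sum())
    dev += 2.0 * float((c[pos] * np.log(c[pos] / mu[pos])).sum())
    return dev


def _sigmoid(z):
    return scipy_expit(z)


def _to_bounded(z, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * _sigmoid(z)


def _from_bounded(theta, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    frac = np.clip((np.asarray(theta) - lo) / (hi - lo), 1e-4, 1.0 - 1e-4)
    return np.log(frac / (1.0 - frac))


def auto_initial_guess(
    decay: DecayHistogram, bounds=DEFAULT_BOUNDS
) -> BiexpParams:
    """Moment-based starting point with a1 = 0.5.

    From the measured tau_m and <tau>, an equal-fraction split
    tau1 + tau2 = 2<tau>, tau1^2 + tau2^2 = 2 tau_m <tau> is solved; the
    two roots bracket the component lifetimes and are spread by +/-10%
    before clipping into the bounds.  Degenerate decays fall back to the
    bound midpoints.
    """
    try:
        f = extract_features_batch(decay.counts[None, :], decay.config)[0]
        tau_m, tau_amp = float(f[2]), float(f[3])
        s = 2.0 * tau_amp
        q = tau_m * s
        disc = 2.0 * q - s * s
        if disc > 0:
            x1 = 0.5 * (s - np.sqrt(disc))
            x2 = 0.5 * (s + np.sqrt(disc))
        else:
            x1 = x2 = tau_amp
        t1, t2 = 0.9 * x1, 1.1 * x2
    except Exception:
        t1 = t2 = 0.5 * (bounds[1][0] + bounds[1][1])
    pad1 = 1e-3 * (bounds[1][1] - bounds[1][0])
    pad2 = 1e-3 * (bounds[2][1] - bounds[2][0])
    t1 = float(np.clip(t1, bounds[1][0] + pad1, bounds[1][1] - pad1))
    t2 = float(np.clip(t2, bounds[2][0] + pad2, bounds[2][1] - pad2))
    if t1 > t2:
        t1, t2 = t2, t1
    return BiexpParams(0.5, t1, t2)


def fit_decay_mle(
    decay: DecayHistogram,
    bounds=DEFAULT_BOUNDS,
    init: BiexpParams | None = None,
    max_iter: int = 6000,
    tol: float = 1e-12,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> FitResult:
    """Fit one histogram by Poisson-deviance Nelder-Mead within bounds.

    The three parameters are mapped to the real line by a logistic
    reparameterization so the simplex search is unconstrained.  Lifetimes
    in the result are sorted ascending (a1 complemented on swap).  If the
    iteration cap is reached the best point found is still returned with
    ``converged=False``.
    """
    total = decay.total
    if total <= 0:
        raise EmptyDecayError("cannot fit an all-zero decay")
    config = decay.config
    counts = decay.counts.astype(float)
    if init is None:
        init = auto_initial_guess(decay, bounds)
    z0 = _from_bounded(init.as_array(), bounds)

    def objective(z):
        theta = _to_bounded(z, bounds)
        mu = total * model_curves(theta[None, :], config, oversample)[0]
        return poisson_deviance(mu, counts)

    res = minimize(
        objective,
        z0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "maxfev": 2 * max_iter,
            "xatol": tol,
            "fatol": tol,
        },
    )
    theta = _to_bounded(res.x, bounds)
    params = BiexpParams.ordered(*theta)
    return FitResult(
        params=params,
        objective=float(res.fun),
        iterations=int(res.nit),
        converged=bool(res.success),
        init=init,
    )


def fit_decays(
    counts: np.ndarray,
    config: DecayConfig,
    bounds=DEFAULT_BOUNDS,
    max_iter: int = 6000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit every row of a counts matrix; returns (params (n,3), converged (n,))."""
    C = np.atleast_2d(np.asarray(counts))
    out = np.empty((C.shape[0], 3))
    ok = np.zeros(C.shape[0], dtype=bool)
    for i in range(C.shape[0]):
        r = fit_decay_mle(
            DecayHistogram(C[i], config), bounds, max_iter=max_iter, tol=tol
        )
        out[i] = r.params.as_array()
        ok[i] = r.converged
    return out, ok
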