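# phasornet

Phasor-feature neural-network analysis of TCSPC fluorescence lifetime
(FLIM) decays.

## The problem

In time-correlated single-photon counting FLIM, every pixel carries a
histogram `I(t)` of photon arrival times over one laser period.  For
FRET experiments the decay is biexponential,

    I(t) = IRF(t) * [ a1 e^(-t/tau1) + (1 - a1) e^(-t/tau2) ],   tau1 <= tau2,

and the biology lives in the three parameters: `a1` is the fraction of
donor molecules quenched by an acceptor, `tau1` their shortened lifetime,
`tau2` the unquenched donor lifetime (FRET efficiency `E = 1 - tau1/tau2`).
Per-pixel nonlinear fitting is slow and collapses at the photon counts
live-cell imaging allows (SNR = sqrt(N) with N photons).

`phasornet` instead reduces each decay to four physical features —
the phasor coordinates

    g = ∫ I(t) cos(wt) dt / ∫ I(t) dt,    s = ∫ I(t) sin(wt) dt / ∫ I(t) dt

at the laser angular frequency `w = 2*pi/period`, the mean lifetime
`tau_m = ∫ t I(t) dt / ∫ I(t) dt` and the amplitude-weighted lifetime
`<tau> = Σ a_i tau_i` — and regresses `(a1, tau1, tau2)` with a small
fully connected network (4 inputs → 11 hidden layers × 6 neurons → 3
outputs).  The package also provides the Monte Carlo decay simulator used
for training, a per-decay maximum-likelihood fitting baseline, a k-NN
baseline on the same features, the evaluation protocol (SNR / tau1 / a1
sweeps with box statistics), and a per-pixel FLIM-image pipeline
(binning, background subtraction, thresholding, parameter maps).

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

```python
import numpy as np
from phasornet import (
    DecayConfig, NetConfig, TrainConfig, generate_training_set,
    generate_eval_set, extract_features_batch, train, predict,
)

# 1. Simulate a training set: 10,000 biexponential decays, 256 channels
#    over 12.5 ns (80 MHz), Gaussian IRF of 32 ps FWHM, 100,000 photons
#    each (SNR 316), a1 ~ U(0.1, 0.9), lifetimes ~ U(0.2, 3.0) ns.
ds = generate_training_set(n_samples=10_000, snr=316.0, seed=1)

# 2. Train the 4 -> 6x11 -> 3 network (two restarts here for speed).
model = train(ds, NetConfig(), TrainConfig(n_restarts=2, seed=1))
print(f"validation relative squared error: {model.metadata['validation_rse']:.3f}")

# 3. Evaluate on unseen decays mimicking a FRET pair: a1 = 0.5,
#    tau1 = 1.0 ns (donor with acceptor), tau2 = 2.5 ns (donor), SNR 100.
ev = generate_eval_set(params=(0.5, 1.0, 2.5), n_reps=250, snr=100.0, seed=2)
est = predict(model, extract_features_batch(ev.counts, ev.config))
print("median (a1, tau1, tau2):", np.median(est, axis=0).round(3))
```

Output from this exact script:

```
validation relative squared error: 0.175
median (a1, tau1, tau2): [0.493 0.96  2.513]
```

The validation relative squared error, `mean(((yhat - y)/y)^2)` on the
15% held-out split, is dominated by training draws with `tau1 ≈ tau2`
where `a1` is fundamentally unidentifiable, so values of this order are
expected.  What matters is the recovery: the medians over 250 noisy
decays land within a few percent of the truth (0.5, 1.0, 2.5) at a
photon budget (10,000 per decay) where per-decay fitting is already
noisy.  FRET efficiency follows as `E = 1 - 0.96/2.513 = 0.62`
(truth 0.60).

The same model applies per pixel to an image cube:

```sh
phasornet image --in cube.tif --model model.json --bin 4 \
    --min-photons 1240 --background auto --out maps/
```

All CLI entry points: `phasornet simulate | features | train | predict |
mlfit | knn | evaluate | image` (see `--help`).

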