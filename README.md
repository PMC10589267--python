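# parashim

Automated B0 shimming of a **parallel two-channel NMR probehead**, virtualized
end to end: a spherical-harmonic shim field model over the sample volume, a
forward spectrometer that turns field maps into 1D spectra, and the full
deep-regression shimming pipeline — dataset construction, preprocessing and
augmentation, a convolutional-recurrent shim regressor, the
random-then-predictive shimming episode, and classical derivative-free
baselines with exact acquisition accounting.

## The problem

Parallel NMR detection puts several miniature detectors in one magnet bore.
Each detection site must be shimmed to ppb field uniformity, but the local
shim sets of neighbouring cells overlap and are mutually non-orthogonal, so
per-coil iterative optimization becomes slow and unreliable.  The approach
implemented here learns the inverse mapping instead: a deep network
`F_theta` maps a short sequence of observed spectra and shim actions to the
underlying shim distortion.

Formally, with `m` channels and `n` shim coils per channel, a training pair
is a sequence

    x = [ (u(0), 0), (u(a_1), a_1), ..., (u(a_t), a_t) ],    y = S in R^(m*n)

where `u(a)` is the spectrum pair acquired after commanding shim offsets `a`
from the unshimmed state and `S` is the distortion w.r.t. the reference shim
currents `Ref` (drawn per component from `N(0, (Ref_i/3)^2)` during data
collection).  Shimming an unknown distortion is an episode of
`t = r + p + 1` acquisitions: the unshimmed spectrum, `r` random Gaussian
probe steps, then `p` predictive steps with `a_t = y_hat_{t-1}`.  With
`r = 5, p = 4` the whole procedure costs 10 acquisitions, against a
theoretical minimum of 48 for per-shim parabolic interpolation and 13
spectra for mere Nelder-Mead initialization at `m = 2, n = 6`.

Quality metrics: linewidth (FWHM, with a Voigt fit when the peak splits),
normalized MAE, the direction ratio DiR (fraction of components whose
predicted sign matches the target) and the success rate SR (fraction of
episodes in which the peak intensity rose on both channels).

## Worked example

```python
import numpy as np
from parashim import build_spectrometer, fwhm, estimate_convergence_order
from parashim.presets import reduced_run_config
from parashim.dataset import draw_distortion

cfg = reduced_run_config(seed=1)          # 2 channels x 2 zonal shims (Z, Z2)
spect = build_spectrometer(cfg.world, seed=1)
ref = [fwhm(s) for s in spect.reference_spectra()]
print(f"reference linewidths: {ref[0]:.2f} Hz / {ref[1]:.2f} Hz")

rng = np.random.default_rng(0)
S = draw_distortion(spect.ref_ma.ravel(), rng)        # sigma = Ref/3 per coil
pair = spect.acquire(spect.make_state(S.values.reshape(2, 2)), rng=rng)
print(f"unshimmed linewidths: {fwhm(pair[0]):.1f} Hz / {fwhm(pair[1]):.1f} Hz")

pair = spect.acquire(spect.make_state(S.values.reshape(2, 2),
                                      action=S.values.reshape(2, 2)), rng=rng)
print(f"after the exact correction a = S: {fwhm(pair[0]):.2f} Hz / {fwhm(pair[1]):.2f} Hz")
print(f"acquisitions used: {spect.acquisitions}")

res = estimate_convergence_order(lambda x: x*x + 0.3*x**3, (-0.5, 0.3, 1.0),
                                 true_min=0.0)
print(f"SPI empirical convergence order: {res.order:.4f}")
```

prints

```
reference linewidths: 6.29 Hz / 6.29 Hz
unshimmed linewidths: 9.5 Hz / 39.6 Hz
after the exact correction a = S: 6.28 Hz / 6.29 Hz
acquisitions used: 2
SPI empirical convergence order: 1.3251
```

The distorted lines broaden according to the random shim offsets; applying
the action equal to the distortion restores the natural linewidth exactly
(this identity `a = S  =>  reference spectrum` is what makes `S` a
well-defined regression target), and every spectrum pair costs exactly one
acquisition on the internal counter.  The last line is the measured
superlinear convergence order of successive parabolic interpolation — the
classical one-dimensional shimming primitive — on a smooth non-quadratic
objective, matching its theoretical order (the real root of
`q^3 = q + 1 ~ 1.3247`).

## Command line

```bash
parashim simulate-world --seed 1 --out runs/world      # field maps + spectra
parashim make-dataset --seed 1 --out runs/dataset      # HDF5 + manifest.json
parashim train --dataset runs/dataset --out runs/model
parashim shim --model runs/model --seed 7              # one 10-acquisition episode
parashim benchmark --model runs/model --episodes 20    # PeDR vs parabola vs simplex
```

All commands accept `--config PATH` (YAML, validated, unknown keys
rejected) and `--seed`; identical seeds reproduce identical datasets,
training runs and benchmark CSVs byte for byte.

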