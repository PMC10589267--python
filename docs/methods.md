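# Methods

`parashim` simulates automated B0 shimming of a parallel (two-channel) NMR
probehead and implements the full deep-regression shimming pipeline on top
of the simulation: dataset construction, preprocessing, augmentation, a
convolutional-recurrent shim regressor, the random-then-predictive shimming
episode, and classical derivative-free baselines with exact acquisition
accounting.  This note records the model, its assumptions, the tunable
parameters that matter, and the design choices that were genuinely open.

## Field model

Each detection cell sees a static-field inhomogeneity expressed directly as
a frequency offset (Hz) over a cylindrical sample volume (default 1 mm OD x
8 mm, matching a miniaturized stripline detector's region of interest).
The local shim set comprises up to six coils named after the real solid
harmonic each approximates: X, Y, Z, Z2, Z3, Z4.  Profiles are the textbook
real solid harmonics evaluated on normalized coordinates (u, v, w) =
(x/R, y/R, z/(L/2)):

    X: u        Z:  w          Z3: w^3 - (3/2) w rho^2
    Y: v        Z2: w^2 - rho^2/2   Z4: w^4 - 3 w^2 rho^2 + (3/8) rho^4

scaled so that the profile value at the reference coordinate (sample edge
on the relevant axis) equals the configured per-coil gain in Hz/mA.
Hardware winding details (turn counts, PCB layout) are deliberately not
simulated; the gains subsume them.  Profiles are linear in current by
construction, so the total field is affine in the commanded currents.

Cross-channel non-orthogonality — the reason simple per-coil optimization
struggles on a parallel probe — is modelled by a constant coupling matrix
C (m*n x m*n): effective basis amplitudes are C @ currents, with unit
diagonal and seeded random off-diagonal entries bounded by a configurable
epsilon (default 0.1).  The identity recovers fully decoupled channels.

The quadrature grid places `n_axial` planes uniformly along z and, for
`n_radial > 1`, `n_radial` equi-azimuthal points on the ring of RMS radius
R/sqrt(2) per plane (one on-axis point per plane for `n_radial = 1`).  The
single-ring rule reproduces the second radial moment of a uniform disc —
sufficient for profiles that are at most quadratic transversally — and
keeps the X/Y/Z Gram matrix exactly diagonal on the symmetric grid.  The
default 4 x 64 grid resolves the quartic zonal profiles with well under 1%
quadrature error.

Two construction modes tie the intrinsic (sample- and
susceptibility-induced) background field to the reference shim currents:

* `derived`: a random low-order polynomial background is sampled (defaults:
  3000 Hz span along z, 500 Hz transversally, emulating the simulated field
  maps of a high-aspect-ratio sample at 15.2 T) and the reference currents
  are the weighted least-squares shim solution.  A residual inhomogeneity
  remains at reference, as after manual shimming of real hardware.
* `explicit`: reference currents are given (default 30 mA per coil) and the
  intrinsic field is constructed to cancel them exactly, so the reference
  condition reaches the natural linewidth.  This mode gives full control
  over the Ref values that the sigma = Ref/3 distortion law depends on and
  is the default for dataset generation.

## Virtual spectrometer

Absorption-mode spectra are synthesized directly in the frequency domain:
every grid point contributes a unit-area Lorentzian at its local offset,
weighted by its quadrature weight.  No FID/FFT stage is simulated — the
model consumes 1D real spectra, and time-domain simulation would add
nothing testable.  Inhomogeneous broadening therefore emerges from the
field distribution itself: a linear z-gradient yields a box (x) Lorentzian
profile, a z^2 term yields the skewed distribution with the characteristic
sqrt-edge of a quadratic field, and so on.  The synthesis is verified
against a naive double-loop implementation and against a brute-force
numerical convolution oracle in the tests.

Receiver non-idealities, applied in order: inter-channel RF leakage
(convex mixing of the two channels' clean spectra, a knob standing in for
the coupled components real synchronized excitation produces), a carrier
(z0) bin shift, first-order phase error applied in the complex domain via
Hilbert-transform complexification, and additive white Gaussian noise.
"SNR 30" is interpreted as the linear peak-amplitude-to-noise-std ratio by
default (a dB interpretation is config-switchable, since the units are a
genuinely open question).

`acquire()` returns one spectrum per channel and increments the
acquisition counter by exactly 1 — the unit cost by which all shimming
methods are compared.  The state convention is `effective currents =
Ref - S + a`, so the commanded action a = S nulls the distortion S exactly
and y = S is the regression target.

## Dataset and sequences

A sample is the unshimmed spectrum pair recorded under a distortion S
drawn per component from N(0, (Ref_i/3)^2).  Splits are 80/10/10 with
floor rounding for val/test and the remainder assigned to train; split
assignment is a seeded permutation.  Training sequences are mined online:
every request draws fresh Gaussian random actions (offsets w.r.t. the
initial unshimmed state, same sigma policy as the distortions) and
re-synthesizes the corresponding spectra on demand.  Only the unshimmed
pairs, targets and world parameters are persisted (HDF5 + JSON manifest);
this keeps the container small and matches the online-mining protocol.

## Preprocessing and augmentation

Spectra are cut to a centred ROI (default 4096 of 8192 bins) and
downsampled by adjacent-bin averaging (default factor 2).  A sequence is
normalized by its first entity's spectrum pair: the common minimum is
subtracted and everything is divided by the brighter spectrum's range, so
later spectra may exceed 1.  Targets and actions are normalized to [-1, 1]
by a per-component bound of 2x|Ref| — evaluation distortions reach 2x the
reference values, and the tanh output head must be able to express them.

Augmentation (per training sequence): one integer circular shift in
[-4, 4] bins shared by all spectra of the sequence; uniform label noise of
half-width 0.1 on the normalized target; "shim interaction noise" of 0.1,
implemented as a uniform multiplicative perturbation of the non-zero
actions (the term "shim interaction noise" comes with a single number and
no formula, so this is one defensible reading, recorded as such);
first-order phase error uniform in +-0.5 radians across the ROI (radians
vs cycles is config-switchable); and fresh AWGN at SNR 30.

## Network and training

The regressor is sequence-to-vector: at each step the two channel-spectra
enter a shared convolutional block as two input channels (joint processing
is required for cross-channel coupling), default 3 layers of
(64 filters, kernel 41, stride 2) with ReLU, dropout and max-pooling of 2;
the flattened features are fused with the step's action by concatenation
and layer normalization; one LSTM cell (default hidden width 256) carries
the shimming history; the head applies layer norm, a dense+ReLU+dropout
layer, and a final dense+tanh layer of width m*n.  Predictions therefore
live in (-1, 1)^(m*n), and the same parameters process sequences of any
length.  Hidden width, dropout rate and pooling kind/size are free
parameters (max-pooling of 2 by default); all are checkpoint-recorded.

The network, backpropagation (including through time), Adam, and the Huber
loss (delta = 1) are implemented in NumPy; gradients are verified against
central-difference numerical differentiation in the test suite, and the
step-by-step recurrent path is verified to match the batched unroll.

Training minimizes the Huber loss over all steps of each sequence with the
target broadcast to every step.  Per-step losses are weighted linearly
with step index by default: before the probe history accumulates, the
target is only partially identifiable (see "Sign identifiability" below),
so early-step predictions carry less trainable signal.  The sequence
length follows a curriculum from 4 to 10, +2 every 25 epochs over 100
epochs by default; learning rate 1e-4 with reduce-on-plateau (factor 0.5,
patience 5); batch size 256.  Model selection is best-on-validation with a
fixed validation protocol.

## Shimming episodes and metrics

An episode acquires the unshimmed pair, performs r random Gaussian probe
steps (each observation and its action evolve the model's hidden state),
then p predictive steps with the commanded action equal to the last
prediction mapped back to mA — r + p + 1 acquisitions in total, asserted
against the spectrometer counter.  Default r = 5, p = 4 (the 10-acquisition
budget; the random phase matters more than the predictive phase, so the
split favours probing).  The final setting is the last step's by default;
best-observed-step retention is available as a flag and is enabled in the
reduced study condition.  Retention quality is the worst-channel peak
improvement ratio (peak height relative to the unshimmed acquisition,
minimized over channels) — peak height is the canonical single-scan shim
quality measure, and taking the worst channel reflects that a parallel
probe is only as good as its weakest cell; a summed-FWHM criterion is the
config alternative.  Retention matters in closed loop for two structural
reasons: the predictive phase feeds the model states (actions near the
true distortion) that are rare in the random training sequences, so late
predictions can drift from the best one; and under uniform +-2 Ref
evaluation draws some episodes start with one channel already
near-shimmed, where the last step's residual can lose to a better
intermediate acquisition.

Metrics: FWHM by linear interpolation of the half-maximum crossings around
the global peak, with a Voigt fit (measured numerically on the fitted
profile) when a splitting heuristic triggers (a second local maximum above
50% of the global one within +-10 widths, after light smoothing); the
direction ratio DiR = fraction of components with matching prediction/
target sign, where sign(0) matches only sign(0); success rate SR = fraction
of episodes in which the peak intensity increased on both channels;
normalized MAE on the [-1, 1] target scale.

## Classical baselines

Parabolic interpolation: shims are optimized one at a time in
channel-major order — 3 bracket acquisitions, jump to the fitted parabola's
vertex (clamped to the bracket; colinear/non-convex brackets leave the
shim unchanged and are logged), then 1 verification acquisition.  For
m = 2, n = 6 this is exactly 4 * 12 = 48 acquisitions, the theoretical
minimum of the method.  Nelder-Mead operates on the joint 12-dimensional
shim space with the standard reflection/expansion/contraction/shrink
coefficients; initialization alone consumes (m*n) + 1 = 13 acquisitions.
Both use the summed FWHM of the two channels as their objective (the
baseline objective is not dictated by the method; the choice is logged in
the report).  The Nelder-Mead loop is hand-rolled so that acquisitions can
be accounted phase by phase; it is cross-checked against
scipy.optimize.minimize on a quadratic objective in the tests.

Successive parabolic interpolation keeps the three most recent points and
jumps to the vertex of the parabola through them.  Its asymptotic
convergence order is the real root of q^3 = q + 1 (~1.3247), *provided*
f'' > 0 and f''' != 0 at the minimizer.  The package estimates the order
empirically as the least-squares slope of log e_{k+1} vs log e_k over the
superlinear regime (errors between ~0.5 and the float64 stagnation floor).
Two degenerate cases are documented and tested: an exactly quadratic
objective is solved by the first fit (flagged, no order estimate), and an
objective with f'''(x*) = 0 — cosh is one — converges *faster* than the
generic order, so the generic estimate does not apply to it.  The
acceptance experiment therefore measures the order on
f(x) = x^2 + 0.3 x^3 from brackets (-0.5, 0.3, 1.0): f''' != 0 at the
minimizer and the minimum value is 0, so float64 tracks the error sequence
deep into the asymptotic regime; the estimate is 1.3251.

## Sign identifiability, and what the synthetic world does not emulate

On a perfectly z-symmetric sample grid the zonal odd shims (Z, Z3) leave
the spectrum invariant under sign flips of their coefficient: the field
distribution of c*w and -c*w over w in [-1, 1] is identical.  The sign of
an odd-shim distortion is therefore *not identifiable from a single
spectrum* — only the probe steps reveal it, by correlating known random
actions with the induced linewidth changes.  This makes the synthetic task
strictly harder than a hardware task in this respect (real probes always
carry geometric and B1-sensitivity asymmetries that leak sign information
into single spectra), and it bounds the direction ratio any regressor can
reach on this world: the sign of a small odd-shim component whose probe
responses drown in the even-shim broadening is irreducibly uncertain.

Conversely, the synthetic world omits: drift between acquisitions
(exposed as an optional config, default 0), sample-dependent multi-line
spectra, radiation damping and temperature effects, and any RF-pulse
physics.  Passing tests therefore demonstrate that the pipeline recovers
shim distortions under the stated forward model, not that it matches any
particular instrument's linewidths.

## The reduced (desk-scale) study condition

`presets.reduced_run_config` defines the validation condition used by the
acceptance experiments: two channels with two zonal shims each (Z, Z2),
identity coupling, SNR 1000, single line per channel (natural FWHM 6 Hz),
512-bin spectra over a 1 kHz sweep (ROI 512, downsample 2 -> 256 input
bins), axis-only grid of 33 points, Ref = 30 mA per coil, 2000 samples,
and a 32-filter / 128-hidden network trained for 20 epochs with batch 32,
lr 1e-3, dropout 0, curriculum 4 -> 10 advancing every 5 epochs.

The shim gains of this condition (3 and 2 Hz/mA for Z and Z2) set the
conversion between shim-current error and residual linewidth, and are
calibrated to two design targets: sigma = Ref/3 distortions broaden the
line to roughly 10x the natural width (the distortion is clearly resolved),
and a correction at the precision this class of regressor attains on the
normalized scale (MAE of a few hundredths) lands within about 2x the
natural width, so shimmed and unshimmed distributions separate cleanly.
With much steeper gains the same normalized error would translate into
residual widths many times the natural linewidth and the episode success
criterion would measure the gain choice, not the method.  Episode
evaluation draws distortions uniformly in [-2 Ref, 2 Ref] (the Gaussian
in-distribution alternative is config-exposed).

## Numerical choices

* float64 throughout; conv/LSTM verified by gradient checks at 1e-4
  relative tolerance.
* FWHM requires a peak at least 5x above the noise floor (estimated from
  the outer 10% of bins); degenerate spectra raise instead of returning a
  number.
* Voigt fits fall back to the direct half-max width on fit failure.
* Parabola-vertex updates are clamped to the bracket; denominators below
  1e-12 count as colinear.
* The 80/10/10 split uses floor for val/test (8799 -> 7041/879/879).
* All randomness flows through numpy Generators seeded from
  (global seed, crc32(module name)) SeedSequences; identical seeds give
  bit-identical datasets, training batches and episodes.

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; the default
  full-scale configuration (8192-bin spectra, 64-filter network, 100
  epochs) is sized for a GPU-era workflow and is not expected to be run to
  convergence on one CPU.  The reduced condition exists for exactly this
  reason.
* Episode success (peak increase on both channels) is sensitive to the
  lineshape pathologies of polynomial fields: a quadratic zonal field
  produces a sqrt-edge spike whose FWHM stays narrow even under large
  distortions, which depresses SR relative to instruments with gentler
  lineshapes.
* The coupling model is a constant linear matrix; real cross-talk is
  geometry- and current-dependent.
* Predictions are bounded by the tanh head: distortions beyond the
  normalization bound (2x Ref) cannot be fully corrected in one step.
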