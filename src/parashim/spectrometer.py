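"""Virtual two-channel NMR spectrometer.

Turns per-channel field maps into 1D absorption-mode spectra: every grid
point contributes a Lorentzian at its local frequency offset, weighted by
its quadrature weight, so field inhomogeneity broadens and distorts the
line exactly as a static-field distribution does.  Receiver non-idealities
(white noise, first-order phase, carrier shift, inter-channel RF leakage)
are applied on top.  The :class:`VirtualSpectrometer` exposes the
``acquire()`` contract consumed by the dataset builder and the shimming
loop, and counts every acquisition — the unit by which shimming methods
are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import hilbert

from .config import WorldConfig
from .fields import (
    CouplingMatrix,
    FieldMap,
    SampleGrid,
    ShimBasis,
    build_coupling_matrix,
    build_sample_grid,
    build_sh_basis,
    sample_intrinsic_distortion,
    total_field,
)

__all__ = [
    "Spectrum",
    "LineModel",
    "SpectrometerState",
    "VirtualSpectrometer",
    "synthesize_spectrum",
    "apply_receiver_effects",
    "build_spectrometer",
]


@dataclass
class Spectrum:
    """A 1D real spectrum with a uniform frequency axis (Hz)."""

    intensities: np.ndarray
    axis_hz: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.axis_hz = np.asarray(self.axis_hz, dtype=float)
        if self.intensities.shape != self.axis_hz.shape:
            raise ValueError("intensities and axis must have equal length")

    @property
    def bin_hz(self) -> float:
        return float(self.axis_hz[1] - self.axis_hz[0])

    def copy(self) -> "Spectrum":
        return Spectrum(self.intensities.copy(), self.axis_hz.copy(), dict(self.meta))


@dataclass
class LineModel:
    """Line list of one channel's sample: positions, amplitudes, natural width."""

    positions_hz: np.ndarray
    amplitudes: np.ndarray
    natural_fwhm_hz: float

    def __post_init__(self) -> None:
        self.positions_hz = np.atleast_1d(np.asarray(self.positions_hz, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if np.any(self.amplitudes <= 0):
            raise ValueError("line amplitudes must be positive")
        if self.natural_fwhm_hz <= 0:
            raise ValueError("natural linewidth must be positive")


@dataclass
class SpectrometerState:
    """Shim state of one acquisition.

    Effective coil currents are ``ref - distortion + action``: the field
    model sees the effective distortion (S - a), so ``action == distortion``
    nulls it exactly and restores the reference condition.
    """

    ref: np.ndarray          # (m, n) reference currents, mA
    distortion: np.ndarray   # (m, n) applied distortion S, mA
    action: np.ndarray       # (m, n) commanded offset a_t, mA

    def effective_currents(self) -> np.ndarray:
        return self.ref - self.distortion + self.action


def synthesize_spectrum(
    field: FieldMap,
    lines: LineModel,
    L: int,
    sweep_hz: float,
    weights: np.ndarray | None = None,
) -> Spectrum:
    """Forward model: weighted sum of Lorentzians over the field distribution.

    intensity(f) = sum_p w_p * sum_k amp_k * Lor(f - pos_k - offset_p; fwhm)
    with unit-area Lorentzians, so the spectral area equals the total line
    amplitude whenever the sweep contains the lineshape.  A sweep holding
    less than 99% of the mass is recorded as a warning in ``meta``.
    """
    if L < 64:
        raise ValueError("L must be >= 64")
    offsets = field.offsets
    if weights is None:
        weights = np.full(offsets.shape[0], 1.0 / offsets.shape[0])
    axis = (np.arange(L) - L / 2.0) * (sweep_hz / L)
    hw = lines.natural_fwhm_hz / 2.0
    centers = lines.positions_hz[:, None] + offsets[None, :]      # (K, P)
    w_amp = lines.amplitudes[:, None] * weights[None, :]          # (K, P)
    d = axis[None, None, :] - centers[:, :, None]                 # (K, P, L)
    intens = np.einsum("kp,kpl->l", w_amp, (hw / np.pi) / (d * d + hw * hw))
    meta: dict = {"channel": field.channel_id}
    mass = intens.sum() * (sweep_hz / L)
    total_amp = float(lines.amplitudes.sum())
    if mass < 0.99 * total_amp:
        meta["warnings"] = [f"sweep contains only {mass / total_amp:.1%} of spectral mass"]
    return Spectrum(intensities=intens, axis_hz=axis, meta=meta)


def apply_receiver_effects(
    spec: Spectrum,
    snr: float | None = None,
    phase1: float = 0.0,
    z0_shift: int = 0,
    leak_from: Spectrum | None = None,
    leak_coeff: float = 0.0,
    rng: np.random.Generator | None = None,
    snr_is_db: bool = False,
    phase1_in_cycles: bool = False,
) -> Spectrum:
    """Receiver chain: leakage mix, carrier shift, first-order phase, AWGN.

    ``phase1`` is the phase ramp half-span across the spectrum: the applied
    phase runs linearly from -phase1 at the first bin to +phase1 at the
    last (radians by default, cycles if ``phase1_in_cycles``).  ``snr`` is
    the linear peak-amplitude-to-noise-std ratio (dB if ``snr_is_db``);
    None disables noise.
    """
    if not 0.0 <= leak_coeff < 1.0:
        raise ValueError("leak_coeff must be in [0, 1)")
    y = spec.intensities
    if leak_coeff > 0.0:
        if leak_from is None:
            raise ValueError("leak_coeff > 0 requires leak_from")
        y = (1.0 - leak_coeff) * y + leak_coeff * leak_from.intensities
    if z0_shift:
        y = np.roll(y, int(z0_shift))
    if phase1 != 0.0:
        L = y.size
        ramp = phase1 * (2.0 * np.arange(L) / (L - 1) - 1.0)
        if phase1_in_cycles:
            ramp = ramp * 2.0 * np.pi
        y = np.real(hilbert(y) * np.exp(1j * ramp))
    if snr is not None and np.isfinite(snr):
        if rng is None:
            raise ValueError("snr set but no rng provided")
        snr_lin = 10.0 ** (snr / 20.0) if snr_is_db else snr
        if snr_lin <= 0:
            raise ValueError("snr must be positive")
        sigma = float(np.max(np.abs(y))) / snr_lin
        y = y + rng.normal(0.0, sigma, size=y.shape)
    return Spectrum(intensities=y, axis_hz=spec.axis_hz.copy(), meta=dict(spec.meta))


class VirtualSpectrometer:
    """The virtual probehead: field model + line model + receiver + counter."""

    def __init__(
        self,
        grid: SampleGrid,
        bases: list[ShimBasis],
        coupling: CouplingMatrix,
        intrinsic: list[FieldMap],
        lines: list[LineModel],
        ref_ma: np.ndarray,
        L: int,
        sweep_hz: float,
        receiver: dict | None = None,
    ):
        m = len(bases)
        if not (len(intrinsic) == len(lines) == m):
            raise ValueError("bases, intrinsic and lines must have one entry per channel")
        self.grid = grid
        self.bases = bases
        self.coupling = coupling
        self.intrinsic = intrinsic
        self.lines = lines
        self.ref_ma = np.asarray(ref_ma, dtype=float).reshape(m, bases[0].n_coils)
        self.L = int(L)
        self.sweep_hz = float(sweep_hz)
        self.receiver = receiver or {}
        self.acquisitions = 0

    @property
    def m(self) -> int:
        return len(self.bases)

    @property
    def n(self) -> int:
        return self.bases[0].n_coils

    def make_state(self, distortion: np.ndarray, action: np.ndarray | None = None) -> SpectrometerState:
        distortion = np.asarray(distortion, dtype=float).reshape(self.m, self.n)
        if action is None:
            action = np.zeros_like(distortion)
        action = np.asarray(action, dtype=float).reshape(self.m, self.n)
        return SpectrometerState(ref=self.ref_ma.copy(), distortion=distortion, action=action)

    def fields_for(self, state: SpectrometerState) -> list[FieldMap]:
        cur = state.effective_currents()
        if cur.shape != (self.m, self.n):
            raise ValueError(f"state currents must have shape ({self.m}, {self.n})")
        return total_field(self.bases, cur, self.coupling, self.intrinsic)

    def acquire(
        self,
        state: SpectrometerState,
        rng: np.random.Generator | None = None,
        noiseless: bool = False,
    ) -> tuple[Spectrum, ...]:
        """Acquire one spectrum per channel; costs exactly one acquisition."""
        fields = self.fields_for(state)
        clean = [
            synthesize_spectrum(f, self.lines[ch], self.L, self.sweep_hz, self.grid.weights)
            for ch, f in enumerate(fields)
        ]
        self.acquisitions += 1
        if noiseless:
            out = clean
        else:
            rcv = self.receiver
            drift = rcv.get("z0_drift_bins_per_acq", 0.0)
            shift = int(round(drift * self.acquisitions))
            out = []
            for ch, spec in enumerate(clean):
                other = clean[1 - ch] if self.m == 2 else None
                out.append(
                    apply_receiver_effects(
                        spec,
                        snr=rcv.get("snr"),
                        phase1=rcv.get("phase1", 0.0),
                        z0_shift=shift,
                        leak_from=other,
                        leak_coeff=rcv.get("leak_coeff", 0.0) if other is not None else 0.0,
                        rng=rng,
                        snr_is_db=rcv.get("snr_is_db", False),
                    )
                )
        for ch, spec in enumerate(out):
            spec.meta.update(channel=ch, acq_index=self.acquisitions)
        return tuple(out)

    def reference_spectra(self) -> tuple[Spectrum, ...]:
        """Noiseless spectra at the reference condition (no distortion)."""
        state = self.make_state(np.zeros((self.m, self.n)))
        specs = self.acquire(state, noiseless=True)
        self.acquisitions -= 1  # bookkeeping only; not a counted acquisition
        return specs


def build_spectrometer(cfg: WorldConfig, seed: int = 0) -> VirtualSpectrometer:
    """Construct the virtual probehead described by a :class:`WorldConfig`.

    In ``derived`` mode the per-channel intrinsic distortion is sampled and
    the reference currents are the weighted least-squares shim solution, so
    a small residual inhomogeneity remains at reference (as after manual
    shimming).  In ``explicit`` mode the given reference currents are taken
    as ground truth and the intrinsic field is constructed to cancel them
    exactly, so the reference condition reaches the natural linewidth.
    """
    grid = build_sample_grid(
        cfg.grid.diameter_mm, cfg.grid.length_mm, cfg.grid.n_radial, cfg.grid.n_axial
    )
    gains = np.asarray(cfg.shims.gains_hz_per_ma, dtype=float)
    if gains.size != cfg.n or len(cfg.shims.coils) != cfg.n:
        raise ValueError(f"expected {cfg.n} shim coils/gains, got {gains.size}")
    basis = build_sh_basis(grid, gains, tuple(cfg.shims.coils))
    bases = [basis] * cfg.m
    coupling = build_coupling_matrix(cfg.m, cfg.n, cfg.coupling.epsilon, cfg.coupling.seed)
    lines = [
        LineModel(np.asarray(lc.positions_hz), np.asarray(lc.amplitudes), lc.natural_fwhm_hz)
        for lc in cfg.lines
    ]
    if len(lines) != cfg.m:
        raise ValueError("one line model per channel required")
    m, n, P = cfg.m, cfg.n, grid.n_points
    if cfg.ref_mode == "explicit":
        if cfg.ref_ma is None:
            raise ValueError("ref_mode='explicit' requires ref_ma")
        ref = np.asarray(cfg.ref_ma, dtype=float).reshape(m, n)
        shim_at_ref = total_field(
            bases, ref, coupling, [FieldMap(np.zeros(P), ch) for ch in range(m)]
        )
        intrinsic = [FieldMap(-fm.offsets, ch) for ch, fm in enumerate(shim_at_ref)]
    else:
        intrinsic = [
            sample_intrinsic_distortion(
                grid,
                cfg.distortion.z_span_hz,
                cfg.distortion.xy_span_hz,
                seed=seed * 1000 + ch,
                channel_id=ch,
            )
            for ch in range(m)
        ]
        # design matrix: column j = stacked field response to unit current on coil j
        A = np.zeros((m * P, m * n))
        for j in range(m * n):
            amps = coupling.entries[:, j].reshape(m, n)
            for ch in range(m):
                A[ch * P : (ch + 1) * P, j] = amps[ch] @ bases[ch].profiles
        b = np.concatenate([fm.offsets for fm in intrinsic])
        sw = np.sqrt(np.tile(grid.weights, m))
        ref_vec, *_ = np.linalg.lstsq(A * sw[:, None], -b * sw, rcond=None)
        ref = ref_vec.reshape(m, n)
    receiver = cfg.receiver.model_dump()
    return VirtualSpectrometer(
        grid, bases, coupling, intrinsic, lines, ref, cfg.L, cfg.sweep_hz, receiver
    )
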