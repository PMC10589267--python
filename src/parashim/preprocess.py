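"""Normalization and augmentation of shimming sequences.

Spectra are cut to a region of interest and downsampled; a sequence's
intensities are normalized by the brightest spectrum of its first entity;
regression targets are mapped to [-1, 1].  Augmentation adds the receiver
variability the model must be robust to: a common carrier-bin shift,
uniform label noise, action ("shim interaction") noise, first-order phase
error, and fresh white noise.
"""

from __future__ import annotations

import numpy as np

from .config import AugmentConfig, PreprocessConfig
from .dataset import DistortionVector, SequenceEntity, ShimSequence
from .spectrometer import Spectrum, apply_receiver_effects

__all__ = [
    "crop_and_downsample",
    "normalize_sequence",
    "normalize_targets",
    "denormalize_targets",
    "augment",
    "default_target_bound",
    "prepare_sequence",
]


def crop_and_downsample(spec: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Cut to the ROI around the carrier bin, then block-average adjacent bins."""
    L = spec.intensities.size
    roi = cfg.roi_size
    if roi > L:
        raise ValueError(f"roi_size {roi} exceeds raw length {L}")
    if cfg.downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    if roi % cfg.downsample_factor:
        raise ValueError("roi_size must be divisible by downsample_factor")
    center = cfg.roi_center_bin if cfg.roi_center_bin is not None else L // 2
    start = center - roi // 2
    if start < 0 or start + roi > L:
        raise ValueError("ROI does not fit inside the raw spectrum")
    y = spec.intensities[start : start + roi]
    ax = spec.axis_hz[start : start + roi]
    f = cfg.downsample_factor
    if f > 1:
        y = y.reshape(-1, f).mean(axis=1)
        ax = ax.reshape(-1, f).mean(axis=1)
    return Spectrum(y, ax, dict(spec.meta))


def _seq_map(seq: ShimSequence, fn) -> ShimSequence:
    entities = [
        SequenceEntity(tuple(fn(s) for s in e.spectra), e.action.copy())
        for e in seq.entities
    ]
    return ShimSequence(entities=entities, target=DistortionVector(seq.target.values.copy()))


def normalize_sequence(seq: ShimSequence) -> ShimSequence:
    """Scale the whole sequence by the first entity's brightest spectrum.

    The two channel-spectra of the first entity are mapped to [0, 1] using
    their common minimum and the maximum of the brighter one; all later
    spectra use the same affine map, so their values may exceed 1.
    """
    first = seq.entities[0].spectra
    lo = min(float(s.intensities.min()) for s in first)
    hi = max(float(s.intensities.max()) for s in first)
    if hi - lo <= 0.0:
        raise ValueError("degenerate sequence: first-entity spectra have zero range")
    scale = hi - lo
    return _seq_map(
        seq, lambda s: Spectrum((s.intensities - lo) / scale, s.axis_hz.copy(), dict(s.meta))
    )


def default_target_bound(ref: np.ndarray) -> np.ndarray:
    """Per-component normalization bound 2*|Ref| (evaluation distortions reach 2x Ref)."""
    bound = 2.0 * np.abs(np.asarray(ref, dtype=float).ravel())
    if np.any(bound <= 0):
        raise ValueError("target bound requires nonzero reference currents")
    return bound


def normalize_targets(y: np.ndarray, bound: np.ndarray) -> np.ndarray:
    """Map shim values to [-1, 1] (clipped); exact inverse below the bound."""
    bound = np.asarray(bound, dtype=float).ravel()
    if np.any(bound <= 0):
        raise ValueError("bound must be positive per component")
    return np.clip(np.asarray(y, dtype=float).ravel() / bound, -1.0, 1.0)


def denormalize_targets(y_norm: np.ndarray, bound: np.ndarray) -> np.ndarray:
    return np.asarray(y_norm, dtype=float).ravel() * np.asarray(bound, dtype=float).ravel()


def augment(
    seq: ShimSequence,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    target_bound: np.ndarray | None = None,
) -> ShimSequence:
    """Randomized augmentation of a normalized sequence.

    Applies, independently per call: one integer circular shift shared by
    all spectra; uniform additive noise on the normalized target; uniform
    multiplicative perturbation of the (nonzero) actions; a random
    first-order phase ramp; and fresh AWGN.  Sequence length and the zero
    first action are never altered.
    """
    shift = int(rng.integers(-cfg.z0_shift_range, cfg.z0_shift_range + 1)) if cfg.z0_shift_range else 0
    phase1 = float(rng.uniform(-cfg.phase1_range, cfg.phase1_range)) if cfg.phase1_range else 0.0
    entities = []
    for k, e in enumerate(seq.entities):
        new_specs = []
        for s in e.spectra:
            out = apply_receiver_effects(
                s,
                snr=cfg.awgn_snr,
                phase1=phase1,
                z0_shift=shift,
                rng=rng if cfg.awgn_snr is not None else None,
                phase1_in_cycles=cfg.phase1_in_cycles,
            )
            new_specs.append(out)
        action = e.action.copy()
        if k > 0 and cfg.interaction_noise:
            action = action * (
                1.0 + rng.uniform(-cfg.interaction_noise, cfg.interaction_noise, size=action.shape)
            )
        entities.append(SequenceEntity(tuple(new_specs), action))
    target = seq.target.values.copy()
    if cfg.label_noise:
        bound = (
            np.asarray(target_bound, dtype=float).ravel()
            if target_bound is not None
            else np.ones_like(target)
        )
        target = target + bound * rng.uniform(-cfg.label_noise, cfg.label_noise, size=target.shape)
    return ShimSequence(entities=entities, target=DistortionVector(target))


def prepare_sequence(
    seq: ShimSequence,
    pre_cfg: PreprocessConfig,
    target_bound: np.ndarray,
    aug_cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full input pipeline: crop/downsample, normalize, (augment,) tensorize.

    Returns ``(spectra, actions, target)`` with shapes (T, m, L'), (T, m*n)
    and (m*n,); actions and target are on the normalized [-1, 1] scale.
    """
    cropped = _seq_map(seq, lambda s: crop_and_downsample(s, pre_cfg))
    norm = normalize_sequence(cropped)
    if aug_cfg is not None:
        if rng is None:
            raise ValueError("augmentation requires an rng")
        norm = augment(norm, aug_cfg, rng, target_bound)
    T = len(norm)
    m = len(norm.entities[0].spectra)
    Lp = norm.entities[0].spectra[0].intensities.size
    spectra = np.empty((T, m, Lp))
    actions = np.empty((T, norm.target.values.size))
    for k, e in enumerate(norm.entities):
        for ch in range(m):
            spectra[k, ch] = e.spectra[ch].intensities
        actions[k] = normalize_targets(e.action, target_bound)
    target = normalize_targets(norm.target.values, target_bound)
    return spectra, actions, target
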