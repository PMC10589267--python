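"""Spectral-quality and prediction metrics: FWHM, direction ratio, success rate."""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelmax
from scipy.special import voigt_profile

from .spectrometer import Spectrum

__all__ = ["fwhm", "direction_ratio", "success_rate", "peak_height"]


def peak_height(spec: Spectrum) -> float:
    return float(spec.intensities.max())


def _noise_std(y: np.ndarray) -> float:
    """Noise estimate from the outer 10% of bins on each side."""
    k = max(8, y.size // 10)
    edges = np.concatenate([y[:k], y[-k:]])
    return float(np.std(edges))


def _halfmax_width(axis: np.ndarray, y: np.ndarray) -> float:
    """Width of the half-maximum crossings around the global peak, by linear
    interpolation between bins."""
    ip = int(np.argmax(y))
    half = y[ip] / 2.0
    if half <= 0:
        raise ValueError("degenerate profile: non-positive maximum")
    # walk left
    i = ip
    while i > 0 and y[i] > half:
        i -= 1
    if y[i] > half or i >= ip:
        raise ValueError("half-maximum not reached on the left edge")
    fl = axis[i] + (axis[i + 1] - axis[i]) * (half - y[i]) / (y[i + 1] - y[i])
    # walk right
    j = ip
    while j < y.size - 1 and y[j] > half:
        j += 1
    if y[j] > half or j <= ip:
        raise ValueError("half-maximum not reached on the right edge")
    fr = axis[j - 1] + (axis[j] - axis[j - 1]) * (half - y[j - 1]) / (y[j] - y[j - 1])
    return float(fr - fl)


def _is_split(axis: np.ndarray, y: np.ndarray, width_hint: float) -> bool:
    """Splitting heuristic: a second local maximum above 50% of the global
    maximum within +-10 widths of the peak."""
    ip = int(np.argmax(y))
    window = 10.0 * max(width_hint, axis[1] - axis[0])
    mask = np.abs(axis - axis[ip]) <= window
    sub = y[mask]
    if sub.size >= 9:  # light smoothing so receiver noise does not mimic splitting
        kern = np.ones(5) / 5.0
        sub = np.convolve(sub, kern, mode="same")
    locmax = argrelmax(sub, order=3)[0]
    strong = [k for k in locmax if sub[k] >= 0.5 * sub.max()]
    return len(strong) >= 2


def _voigt_fwhm_fit(axis: np.ndarray, y: np.ndarray, width_hint: float) -> float:
    """Fit a Voigt profile around the peak and measure its width numerically."""
    ip = int(np.argmax(y))
    window = 10.0 * max(width_hint, axis[1] - axis[0])
    mask = np.abs(axis - axis[ip]) <= window
    x, yy = axis[mask], y[mask]

    def model(f, amp, f0, sigma, gamma, base):
        return amp * voigt_profile(f - f0, abs(sigma) + 1e-9, abs(gamma) + 1e-9) + base

    p0 = [yy.max() * width_hint, axis[ip], width_hint / 4.0, width_hint / 4.0, float(yy.min())]
    popt, _ = curve_fit(model, x, yy, p0=p0, maxfev=20000)
    fine = np.linspace(x[0], x[-1], 20001)
    curve = model(fine, *popt) - popt[4]
    return _halfmax_width(fine, curve)


def fwhm(spec: Spectrum, allow_voigt: bool = True) -> float:
    """Linewidth (Hz) at half maximum.

    Default: linear-interpolated half-maximum crossings around the global
    peak.  If the peak shows splitting (a second local maximum above 50% of
    the global one nearby), a Voigt profile is fitted and its width
    reported.  Raises if no peak stands at least 5x above the noise floor.
    """
    y = spec.intensities
    axis = spec.axis_hz
    noise = _noise_std(y)
    peak = float(y.max())
    if noise > 0 and peak < 5.0 * noise:
        raise ValueError("no detectable peak above the noise floor")
    width = _halfmax_width(axis, y)
    if allow_voigt and _is_split(axis, y, width):
        try:
            return _voigt_fwhm_fit(axis, y, width)
        except (RuntimeError, ValueError):  # fit failure: fall back to the direct width
            return width
    return width


def direction_ratio(pred: np.ndarray, target: np.ndarray) -> float:
    """Fraction of components whose predicted sign matches the target sign.

    Convention for zeros: sign(0) matches only sign(0) — a zero prediction
    counts as a match only when the target component is exactly zero.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.shape != target.shape:
        raise ValueError("pred and target must have equal length")
    return float(np.mean(np.sign(pred) == np.sign(target)))


def success_rate(episodes) -> float:
    """Fraction of episodes in which the peak intensity increased on BOTH channels."""
    if not len(episodes):
        return 0.0
    succ = [float(ep.success()) for ep in episodes]
    return float(np.mean(succ))
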