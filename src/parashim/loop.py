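"""Shimming episodes, classical baselines, and acquisition accounting.

A PeDR episode acquires the unshimmed spectrum pair, applies ``r`` random
probe steps to build the model's shimming history, then ``p`` predictive
steps where the commanded action is the model's last (denormalized)
prediction — exactly ``r + p + 1`` acquisitions in total.  The classical
competitors (per-shim parabolic interpolation and Nelder-Mead simplex on
the joint shim space) are run against the same virtual spectrometer with
every acquisition counted, which is the unit of comparison throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger("parashim.loop")

from .config import DatasetConfig, EpisodeConfig, PreprocessConfig
from .dataset import draw_action
from .metrics import direction_ratio, fwhm, peak_height
from .model import LstmState, PedrNet
from .preprocess import crop_and_downsample, denormalize_targets, normalize_targets
from .spectrometer import Spectrum, VirtualSpectrometer

__all__ = [
    "EpisodeResult",
    "BaselineReport",
    "run_pedr_episode",
    "draw_eval_distortion",
    "run_parabola_baseline",
    "run_simplex_baseline",
    "SpiResult",
    "estimate_convergence_order",
]


@dataclass
class EpisodeResult:
    """Trace of one shimming run."""

    actions: list[np.ndarray]
    predictions: list[np.ndarray]
    fwhm_per_step: list[tuple[float, ...]]
    peak_per_step: list[tuple[float, ...]]
    initial_spectra: tuple[Spectrum, ...]
    final_spectra: tuple[Spectrum, ...]
    target: np.ndarray
    final_prediction: np.ndarray
    acquisitions: int
    metrics: dict = dc_field(default_factory=dict)

    def success(self) -> bool:
        """Peak intensity increased on both channels."""
        first = self.peak_per_step[0]
        last = self.peak_per_step[-1]
        return all(l > f for f, l in zip(first, last))

    @property
    def initial_fwhm(self) -> tuple[float, ...]:
        return self.fwhm_per_step[0]

    @property
    def final_fwhm(self) -> tuple[float, ...]:
        return self.fwhm_per_step[-1]


@dataclass
class BaselineReport:
    """Outcome of one classical shimming run with acquisition accounting."""

    method: str
    acquisitions: int
    theoretical_min_acquisitions: int
    best_fwhm: tuple[float, ...]
    initial_fwhm: tuple[float, ...]
    best_currents: np.ndarray
    events: list[str] = dc_field(default_factory=list)


def _safe_fwhm(spec: Spectrum) -> float:
    try:
        return fwhm(spec)
    except ValueError:
        return float("nan")


def draw_eval_distortion(
    ref: np.ndarray, cfg: EpisodeConfig, rng: np.random.Generator,
    dataset_cfg: DatasetConfig | None = None,
) -> np.ndarray:
    """Evaluation distortion: uniform in [-2 Ref, 2 Ref] per component (default)
    or Gaussian with the dataset's sigma policy."""
    ref = np.asarray(ref, dtype=float).ravel()
    if cfg.eval_distortion == "uniform_2ref":
        return rng.uniform(-2.0 * np.abs(ref), 2.0 * np.abs(ref))
    return draw_action(ref, rng, dataset_cfg or DatasetConfig())


def run_pedr_episode(
    spect: VirtualSpectrometer,
    net: PedrNet,
    episode_cfg: EpisodeConfig,
    pre_cfg: PreprocessConfig,
    target_bound: np.ndarray,
    rng: np.random.Generator,
    distortion: np.ndarray | None = None,
    dataset_cfg: DatasetConfig | None = None,
) -> EpisodeResult:
    """One shimming episode: 1 unshimmed + r random + p predictive acquisitions.

    The model's hidden state is fresh at episode start and evolves with
    every observed (spectrum pair, action) entity; during predictive steps
    the commanded action is the last prediction mapped back to mA.
    """
    r, p = episode_cfg.r, episode_cfg.p
    if r < 1 or p < 1:
        raise ValueError("episode requires r >= 1 and p >= 1")
    m, n = spect.m, spect.n
    if net.out_dim != m * n:
        raise ValueError("model output dimension does not match the spectrometer")
    bound = np.asarray(target_bound, dtype=float).ravel()
    if distortion is None:
        distortion = draw_eval_distortion(spect.ref_ma.ravel(), episode_cfg, rng, dataset_cfg)
    S = np.asarray(distortion, dtype=float).ravel()
    acq_start = spect.acquisitions

    norm_lo = norm_scale = None

    def observe(action_vec: np.ndarray):
        nonlocal norm_lo, norm_scale
        state = spect.make_state(S.reshape(m, n), action_vec.reshape(m, n))
        pair = spect.acquire(state, rng=rng)
        pre = [crop_and_downsample(s, pre_cfg) for s in pair]
        if norm_lo is None:
            norm_lo = min(float(s.intensities.min()) for s in pre)
            hi = max(float(s.intensities.max()) for s in pre)
            norm_scale = hi - norm_lo
            if norm_scale <= 0:
                raise ValueError("degenerate initial spectra: zero intensity range")
        x = np.stack([(s.intensities - norm_lo) / norm_scale for s in pre])
        return pair, x

    actions: list[np.ndarray] = []
    predictions: list[np.ndarray] = []
    widths: list[tuple[float, ...]] = []
    peaks: list[tuple[float, ...]] = []
    state = None

    def step(action_vec: np.ndarray):
        nonlocal state
        pair, x = observe(action_vec)
        a_norm = normalize_targets(action_vec, bound)
        yhat, state = net.forward_step(x, a_norm, state)
        actions.append(action_vec.copy())
        predictions.append(yhat.copy())
        widths.append(tuple(_safe_fwhm(s) for s in pair))
        peaks.append(tuple(peak_height(s) for s in pair))
        logger.debug("acquisition %d: action=%s fwhm=%s",
                     spect.acquisitions, np.round(action_vec, 3), widths[-1])
        return pair, yhat

    first_pair, yhat = step(np.zeros(m * n))
    for _ in range(r):
        a = draw_action(spect.ref_ma.ravel(), rng, dataset_cfg or DatasetConfig())
        _, yhat = step(a)
    final_pair = first_pair
    for _ in range(p):
        a = denormalize_targets(yhat, bound)
        final_pair, yhat = step(a)

    if episode_cfg.keep_best_step:
        # retain the best observed shim setting (any step with a commanded
        # action, i.e. excluding the initial unshimmed acquisition); quality
        # criterion: the worst-channel peak height ("peak", the standard
        # single-scan shim quality measure) or the summed linewidth ("fwhm")
        if episode_cfg.best_step_criterion == "peak":
            p0 = np.asarray(peaks[0], dtype=float)
            quality = [float(np.min(np.asarray(p) / p0)) for p in peaks[1:]]
            k = 1 + int(np.argmax(quality))
        else:
            sums = [np.nansum(w) if not all(np.isnan(w)) else np.inf for w in widths[1:]]
            k = 1 + int(np.argmin(sums))
        widths.append(widths[k])
        peaks.append(peaks[k])

    acq = spect.acquisitions - acq_start
    assert acq == r + p + 1, "episode acquisition accounting violated"
    final_pred = predictions[-1]
    y_norm = normalize_targets(S, bound)
    result = EpisodeResult(
        actions=actions,
        predictions=predictions,
        fwhm_per_step=widths,
        peak_per_step=peaks,
        initial_spectra=first_pair,
        final_spectra=final_pair,
        target=S,
        final_prediction=final_pred,
        acquisitions=acq,
        metrics={
            "mae": float(np.mean(np.abs(final_pred - y_norm))),
            "dir": direction_ratio(final_pred, y_norm),
        },
    )
    logger.info(
        "episode done: %d acquisitions, fwhm %s -> %s, success=%s",
        acq, np.round(result.initial_fwhm, 1), np.round(result.final_fwhm, 1),
        result.success(),
    )
    return result


# --------------------------------------------------------------------- baselines

def _objective(spect: VirtualSpectrometer, S: np.ndarray, a: np.ndarray,
               rng: np.random.Generator | None) -> tuple[float, tuple[float, ...]]:
    """Summed FWHM of both channels at action ``a`` (one acquisition)."""
    state = spect.make_state(S.reshape(spect.m, spect.n), a.reshape(spect.m, spect.n))
    pair = spect.acquire(state, rng=rng)
    widths = tuple(_safe_fwhm(s) for s in pair)
    total = float(np.nansum(widths)) if not all(np.isnan(widths)) else float("inf")
    return total, widths


def run_parabola_baseline(
    spect: VirtualSpectrometer,
    distortion: np.ndarray,
    bracket_ma: float | np.ndarray = 10.0,
    rng: np.random.Generator | None = None,
    colinear_tol: float = 1e-12,
) -> BaselineReport:
    """Sequential per-shim parabolic interpolation, channel-major order.

    For every coil: 3 bracket acquisitions, set the fitted parabola's
    minimum (clamped to the bracket), then 1 verification acquisition —
    4 per shim, m*n*4 in total (48 for m=2, n=6).  Colinear bracket values
    leave the shim unchanged and log the event.
    """
    m, n = spect.m, spect.n
    S = np.asarray(distortion, dtype=float).ravel()
    brackets = np.broadcast_to(np.asarray(bracket_ma, dtype=float), (m * n,))
    acq_start = spect.acquisitions
    events: list[str] = []
    a = np.zeros(m * n)
    initial_widths: tuple[float, ...] | None = None
    best_widths: tuple[float, ...] | None = None
    for j in range(m * n):
        d = brackets[j]
        ys = []
        for offs in (-d, 0.0, d):
            trial = a.copy()
            trial[j] += offs
            total, widths = _objective(spect, S, trial, rng)
            if initial_widths is None and offs == 0.0 and j == 0:
                initial_widths = widths
            ys.append(total)
        y0, y1, y2 = ys
        denom = y0 - 2.0 * y1 + y2
        if abs(denom) < colinear_tol or denom <= 0:
            events.append(f"shim {j}: colinear/non-convex bracket, left unchanged")
        else:
            vertex = 0.5 * d * (y0 - y2) / denom
            a[j] += float(np.clip(vertex, -d, d))
        _, best_widths = _objective(spect, S, a, rng)  # verification acquisition
    acq = spect.acquisitions - acq_start
    return BaselineReport(
        method="parabola",
        acquisitions=acq,
        theoretical_min_acquisitions=4 * m * n,
        best_fwhm=best_widths,
        initial_fwhm=initial_widths,
        best_currents=a,
        events=events,
    )


def run_simplex_baseline(
    spect: VirtualSpectrometer,
    distortion: np.ndarray,
    init_vertices: np.ndarray,
    rng: np.random.Generator | None = None,
    max_acquisitions: int = 200,
    xtol: float = 1e-8,
) -> BaselineReport:
    """Nelder-Mead on the joint m*n shim space, objective = summed FWHM.

    Initialization evaluates the (m*n)+1 vertices (13 acquisitions for the
    two-channel, six-shim probe); each iteration then costs acquisitions as
    incurred.  A zero-volume initial polytope is flagged and makes no
    progress.
    """
    m, n = spect.m, spect.n
    dim = m * n
    S = np.asarray(distortion, dtype=float).ravel()
    V = np.asarray(init_vertices, dtype=float).reshape(-1, dim).copy()
    if V.shape[0] != dim + 1:
        raise ValueError(f"need {dim + 1} initial vertices, got {V.shape[0]}")
    acq_start = spect.acquisitions
    events: list[str] = []

    def f(a: np.ndarray) -> float:
        return _objective(spect, S, a, rng)[0]

    fv = np.array([f(v) for v in V])  # initialization: dim+1 acquisitions
    initial_widths = None  # widths at zero action not separately acquired here
    degenerate = np.linalg.matrix_rank(V[1:] - V[0], tol=1e-12) < dim
    if degenerate:
        events.append("degenerate initial polytope: zero volume, no progress possible")
    alpha, gamma, rho, sigma = 1.0, 2.0, 0.5, 0.5
    while not degenerate and spect.acquisitions - acq_start < max_acquisitions:
        order = np.argsort(fv)
        V, fv = V[order], fv[order]
        if np.max(np.abs(V[1:] - V[0])) < xtol:
            break
        centroid = V[:-1].mean(axis=0)
        xr = centroid + alpha * (centroid - V[-1])
        fr = f(xr)
        if fr < fv[0]:
            xe = centroid + gamma * (xr - centroid)
            fe = f(xe)
            if fe < fr:
                V[-1], fv[-1] = xe, fe
            else:
                V[-1], fv[-1] = xr, fr
        elif fr < fv[-2]:
            V[-1], fv[-1] = xr, fr
        else:
            xc = centroid + rho * (V[-1] - centroid)
            fc = f(xc)
            if fc < fv[-1]:
                V[-1], fv[-1] = xc, fc
            else:
                for i in range(1, dim + 1):
                    V[i] = V[0] + sigma * (V[i] - V[0])
                    fv[i] = f(V[i])
    best = V[int(np.argmin(fv))]
    _, best_widths = _objective(spect, S, best, rng)
    acq = spect.acquisitions - acq_start
    return BaselineReport(
        method="simplex",
        acquisitions=acq,
        theoretical_min_acquisitions=dim + 1,
        best_fwhm=best_widths,
        initial_fwhm=initial_widths,
        best_currents=best,
        events=events,
    )


# ------------------------------------------------- successive parabolic interpolation

@dataclass
class SpiResult:
    order: float | None
    iterates: list[float]
    errors: list[float]
    exact_quadratic: bool = False


def estimate_convergence_order(
    objective,
    brackets: tuple[float, float, float],
    true_min: float | None = None,
    max_iter: int = 60,
) -> SpiResult:
    """Run successive parabolic interpolation and fit its convergence order.

    The minimizer keeps the three most recent points and jumps to the
    vertex of the parabola through them; its asymptotic order is the real
    root of q^3 = q + 1 (~1.3247).  The order is fitted as the slope of
    log e_{k+1} against log e_k over the superlinear regime, i.e. before
    floating-point stagnation.  An exactly quadratic objective is solved by
    the first fit and flagged instead of fitted.
    """
    pts = [(float(x), float(objective(x))) for x in brackets]
    iterates: list[float] = []
    for it in range(max_iter):
        (x0, f0), (x1, f1), (x2, f2) = pts[-3:]
        if max(x0, x1, x2) - min(x0, x1, x2) < 1e-14:  # converged to one point
            break
        denom = (x0 - x1) * (f0 - f2) - (x0 - x2) * (f0 - f1)
        if denom == 0.0:
            fspread = max(f0, f1, f2) - min(f0, f1, f2)
            if fspread <= 4.0 * np.finfo(float).eps * max(abs(f0), abs(f1), abs(f2), 1.0):
                break  # floating-point stagnation: function differences lost
            raise RuntimeError(f"successive parabolic interpolation stalled at iteration {it}: colinear points")
        num = (x0 - x1) ** 2 * (f0 - f2) - (x0 - x2) ** 2 * (f0 - f1)
        x_new = x0 - 0.5 * num / denom
        iterates.append(x_new)
        if iterates[-1:] and len(iterates) >= 2 and abs(iterates[-1] - iterates[-2]) < 1e-15:
            break
        pts.append((x_new, float(objective(x_new))))
    if len(iterates) >= 2 and abs(iterates[1] - iterates[0]) < 1e-13:
        return SpiResult(order=None, iterates=iterates, errors=[], exact_quadratic=True)
    if true_min is None:
        lo, hi = min(b for b in brackets), max(b for b in brackets)
        res = minimize_scalar(objective, bounds=(lo - 1.0, hi + 1.0), method="bounded",
                              options={"xatol": 1e-14})
        true_min = float(res.x)
    errors = [abs(x - true_min) for x in iterates]
    logpairs = [
        (np.log(e0), np.log(e1))
        for e0, e1 in zip(errors[:-1], errors[1:])
        if 1e-13 < e1 < e0 < 0.5
    ]
    if len(logpairs) < 2:
        raise RuntimeError("too few superlinear iterations to estimate an order")
    lx = np.array([p[0] for p in logpairs])
    ly = np.array([p[1] for p in logpairs])
    q = float(np.polyfit(lx, ly, 1)[0])
    return SpiResult(order=q, iterates=iterates, errors=errors)
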