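"""Spherical-harmonic shim field model over a cylindrical sample region.

Each detection cell carries a local set of six shim coils named after the
real solid harmonic their field profile approximates: X, Y, Z, Z2, Z3, Z4.
Frequency offsets are expressed in Hz (offset = gamma_bar * delta_B0); coil
profiles are stored at unit current (Hz/mA) and are linear in current by
construction.  Coordinates are millimetres, z along the bore, origin at the
sample centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COIL_NAMES: tuple[str, ...] = ("X", "Y", "Z", "Z2", "Z3", "Z4")

__all__ = [
    "COIL_NAMES",
    "SampleGrid",
    "ShimBasis",
    "CouplingMatrix",
    "FieldMap",
    "build_sample_grid",
    "build_sh_basis",
    "build_coupling_matrix",
    "sample_intrinsic_distortion",
    "total_field",
]


@dataclass(frozen=True)
class SampleGrid:
    """Quadrature points filling a cylindrical sample volume.

    ``points`` has shape (P, 3) in mm; ``weights`` (P,) are non-negative and
    sum to 1.  The default layout is symmetric under z -> -z.
    """

    points: np.ndarray
    weights: np.ndarray
    diameter_mm: float
    length_mm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass(frozen=True)
class ShimBasis:
    """Per-coil frequency-offset profiles at unit current.

    ``profiles`` has shape (n_coils, P) in Hz/mA; ``scale`` is the per-coil
    gain at the reference coordinate (Hz/mA).
    """

    profiles: np.ndarray
    coil_names: tuple[str, ...]
    scale: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class CouplingMatrix:
    """Linear map from commanded shim currents to effective basis amplitudes.

    Shape (m*n, m*n), channel-major ordering.  The identity recovers fully
    orthogonal, decoupled channels.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.allclose(np.diag(e), 1.0):
            raise ValueError("coupling matrix diagonal must be 1")
        object.__setattr__(self, "entries", e)

    @property
    def dim(self) -> int:
        return self.entries.shape[0]


@dataclass
class FieldMap:
    """Per-grid-point frequency offsets (Hz) of one detection cell."""

    offsets: np.ndarray
    channel_id: int = 0

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        if not np.all(np.isfinite(off)):
            raise ValueError("field map offsets must be finite")
        self.offsets = off


def build_sample_grid(
    diameter_mm: float = 1.0,
    length_mm: float = 8.0,
    n_radial: int = 4,
    n_axial: int = 64,
) -> SampleGrid:
    """Build a z-symmetric quadrature grid for a cylindrical sample.

    ``n_axial`` planes are spaced uniformly over [-L/2, +L/2].  With
    ``n_radial == 1`` all points sit on the z-axis; otherwise each plane
    carries ``n_radial`` points equi-spaced in azimuth on the ring of
    root-mean-square radius R/sqrt(2), which reproduces the second radial
    moment of a uniform disc and keeps the {X, Y} profiles orthogonal.
    All weights are equal and sum to 1.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("grid dimensions must be positive")
    if n_radial < 1:
        raise ValueError("n_radial must be >= 1")
    if n_axial < 3:
        raise ValueError("n_axial must be >= 3")
    zs = np.linspace(-length_mm / 2.0, length_mm / 2.0, n_axial)
    if n_radial == 1:
        xy = np.zeros((1, 2))
    else:
        r = diameter_mm / 2.0 / np.sqrt(2.0)
        theta = 2.0 * np.pi * np.arange(n_radial) / n_radial
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pts = np.empty((n_axial * n_radial, 3))
    for i, z in enumerate(zs):
        sl = slice(i * n_radial, (i + 1) * n_radial)
        pts[sl, :2] = xy
        pts[sl, 2] = z
    w = np.full(pts.shape[0], 1.0 / pts.shape[0])
    return SampleGrid(points=pts, weights=w, diameter_mm=diameter_mm, length_mm=length_mm)


def _normalized_coords(grid: SampleGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = grid.points[:, 0] / (grid.diameter_mm / 2.0)
    v = grid.points[:, 1] / (grid.diameter_mm / 2.0)
    w = grid.points[:, 2] / (grid.length_mm / 2.0)
    return u, v, w


def _sh_profiles(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Real solid harmonics on normalized coordinates, one row per coil.

    Each polynomial equals 1 at its reference coordinate: (1,0,0) for X,
    (0,1,0) for Y and (0,0,1) for the zonal terms.
    """
    rho2 = u * u + v * v
    return np.stack(
        [
            u,
            v,
            w,
            w * w - 0.5 * rho2,
            w**3 - 1.5 * w * rho2,
            w**4 - 3.0 * w * w * rho2 + 0.375 * rho2 * rho2,
        ]
    )


def build_sh_basis(grid: SampleGrid, gains_hz_per_ma, coil_names=COIL_NAMES) -> ShimBasis:
    """Evaluate shim profiles on ``grid`` scaled to per-coil gains.

    ``gains_hz_per_ma`` gives, for each coil, the offset in Hz produced at
    the reference coordinate by 1 mA of current.  The full six-coil set is
    the default; ``coil_names`` may select a subset (reduced probes).
    """
    gains = np.asarray(gains_hz_per_ma, dtype=float)
    if gains.shape != (len(coil_names),):
        raise ValueError(f"expected {len(coil_names)} gains, got shape {gains.shape}")
    unknown = set(coil_names) - set(COIL_NAMES)
    if unknown:
        raise ValueError(f"unknown coil names: {sorted(unknown)}")
    if grid.n_points == 0:
        raise ValueError("empty sample grid")
    u, v, w = _normalized_coords(grid)
    full = _sh_profiles(u, v, w)
    rows = [COIL_NAMES.index(name) for name in coil_names]
    profiles = full[rows] * gains[:, None]
    return ShimBasis(profiles=profiles, coil_names=tuple(coil_names), scale=gains)


def build_coupling_matrix(m: int, n: int, epsilon: float = 0.1, seed: int = 0) -> CouplingMatrix:
    """Random cross-channel coupling: unit diagonal, off-diagonals ~ U(-eps, eps)."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    dim = m * n
    rng = np.random.default_rng(seed)
    entries = rng.uniform(-epsilon, epsilon, size=(dim, dim))
    np.fill_diagonal(entries, 1.0)
    return CouplingMatrix(entries=entries)


def sample_intrinsic_distortion(
    grid: SampleGrid,
    z_span_hz: float,
    xy_span_hz: float,
    seed: int,
    channel_id: int = 0,
) -> FieldMap:
    """Draw a random low-order polynomial background field.

    The zonal part is a random polynomial of orders 1..4 in the normalized
    axial coordinate, rescaled so its max-minus-min along the z-axis equals
    ``z_span_hz`` exactly; the transverse part is linear in x and y with a
    span of ``xy_span_hz`` across the full sample diameter (hence <= that
    over the interior grid ring).
    """
    if z_span_hz < 0 or xy_span_hz < 0:
        raise ValueError("spans must be non-negative")
    rng = np.random.default_rng(seed)
    u, v, w = _normalized_coords(grid)
    cz = rng.uniform(-1.0, 1.0, size=4)
    cxy = rng.uniform(-1.0, 1.0, size=2)
    # span of the zonal polynomial along the grid's own z-axis column (u = v = 0)
    w_axis = np.unique(w)
    axis_vals = sum(c * w_axis ** (k + 1) for k, c in enumerate(cz))
    span = float(np.max(axis_vals) - np.min(axis_vals))
    if z_span_hz == 0.0 or span == 0.0:
        cz[:] = 0.0
    else:
        cz *= z_span_hz / span
    norm_xy = np.hypot(cxy[0], cxy[1])
    if xy_span_hz == 0.0 or norm_xy == 0.0:
        cxy[:] = 0.0
    else:
        cxy *= xy_span_hz / (2.0 * norm_xy)
    offsets = sum(c * w ** (k + 1) for k, c in enumerate(cz)) + cxy[0] * u + cxy[1] * v
    return FieldMap(offsets=np.asarray(offsets, dtype=float), channel_id=channel_id)


def total_field(
    basis_per_channel: list[ShimBasis],
    currents: np.ndarray,
    coupling: CouplingMatrix,
    intrinsic: list[FieldMap],
) -> list[FieldMap]:
    """Combine shim currents and background field into per-channel field maps.

    ``currents`` has shape (m, n), channel-major.  Effective basis amplitudes
    are ``coupling.entries @ currents.ravel()``; each channel's offsets are
    its intrinsic field plus the amplitude-weighted sum of its profiles, so
    the result is affine in the commanded currents.
    """
    m = len(basis_per_channel)
    currents = np.asarray(currents, dtype=float)
    if len(intrinsic) != m:
        raise ValueError("one intrinsic field map per channel required")
    n = basis_per_channel[0].n_coils
    if currents.shape != (m, n):
        raise ValueError(f"currents must have shape ({m}, {n}), got {currents.shape}")
    if coupling.dim != m * n:
        raise ValueError("coupling matrix dimension mismatch")
    amplitudes = (coupling.entries @ currents.ravel()).reshape(m, n)
    out = []
    for ch in range(m):
        offsets = intrinsic[ch].offsets + amplitudes[ch] @ basis_per_channel[ch].profiles
        out.append(FieldMap(offsets=offsets, channel_id=ch))
    return out
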