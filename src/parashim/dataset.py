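"""Dataset construction for learned shimming.

A sample is an unshimmed two-channel spectrum pair recorded under a random
shim distortion S drawn per component from N(0, (Ref_i/3)^2); S is the
regression target.  Training sequences are mined online: fresh random
actions (offsets from the unshimmed state) are drawn every time a sequence
is requested, and the corresponding spectra are synthesized on demand by
the virtual spectrometer, so the stored container stays small.

Persistence uses an HDF5 container with a sidecar ``manifest.json``:
groups /spectra (n_samples, m, L), /targets (n_samples, m*n), /ref (m*n)
plus the world configuration needed to rebuild the spectrometer exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np

from .config import DatasetConfig, WorldConfig
from .spectrometer import Spectrum, VirtualSpectrometer, build_spectrometer

__all__ = [
    "DistortionVector",
    "SequenceEntity",
    "ShimSequence",
    "ShimDataset",
    "draw_distortion",
    "draw_action",
    "split_sizes",
    "generate_dataset",
    "build_training_sequence",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class DistortionVector:
    """Channel-major shim-current offsets (mA), length m*n."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("distortion values must be finite")
        object.__setattr__(self, "values", v)


@dataclass
class SequenceEntity:
    """One (spectrum pair, action) element of a shimming sequence."""

    spectra: tuple[Spectrum, ...]
    action: np.ndarray  # (m*n,) offset w.r.t. the initial unshimmed state


@dataclass
class ShimSequence:
    """Ordered entities plus the regression target (the distortion S)."""

    entities: list[SequenceEntity]
    target: DistortionVector

    def __post_init__(self) -> None:
        if not self.entities:
            raise ValueError("sequence must contain at least one entity")
        if np.any(self.entities[0].action != 0.0):
            raise ValueError("first entity's action must be the zero vector")

    def __len__(self) -> int:
        return len(self.entities)


@dataclass
class ShimDataset:
    """Stored samples (unshimmed pair + target) with split labels and world."""

    spectra: np.ndarray       # (n_samples, m, L)
    axis_hz: np.ndarray       # (L,)
    targets: np.ndarray       # (n_samples, m*n)
    ref: np.ndarray           # (m*n,)
    splits: dict[str, np.ndarray]
    world_config: WorldConfig
    dataset_config: DatasetConfig
    seed: int
    spectrometer: VirtualSpectrometer | None = None
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    def indices(self, split: str) -> np.ndarray:
        return self.splits[split]

    def get_spectra(self, i: int) -> tuple[Spectrum, ...]:
        return tuple(
            Spectrum(self.spectra[i, ch].copy(), self.axis_hz.copy(), {"channel": ch})
            for ch in range(self.spectra.shape[1])
        )

    def attach_spectrometer(self) -> VirtualSpectrometer:
        if self.spectrometer is None:
            self.spectrometer = build_spectrometer(self.world_config, seed=self.seed)
        return self.spectrometer


def _component_sigma(ref: np.ndarray, cfg: DatasetConfig) -> np.ndarray:
    ref = np.asarray(ref, dtype=float).ravel()
    if cfg.sigma_policy == "absolute":
        if cfg.sigma_ma is None:
            raise ValueError("sigma_policy='absolute' requires sigma_ma")
        return np.full(ref.shape, float(cfg.sigma_ma))
    return np.abs(ref) / 3.0


def draw_distortion(
    ref: np.ndarray, rng: np.random.Generator, cfg: DatasetConfig | None = None
) -> DistortionVector:
    """Component-wise Gaussian distortion with sigma = Ref_i / 3 (default)."""
    cfg = cfg or DatasetConfig()
    sigma = _component_sigma(ref, cfg)
    return DistortionVector(rng.normal(0.0, sigma))


def draw_action(
    ref: np.ndarray, rng: np.random.Generator, cfg: DatasetConfig | None = None
) -> np.ndarray:
    """Random probe action, same sigma policy as the distortions."""
    cfg = cfg or DatasetConfig()
    sigma = _component_sigma(ref, cfg)
    return rng.normal(0.0, sigma)


def split_sizes(n: int, ratios=(0.8, 0.1, 0.1)) -> tuple[int, int, int]:
    """80/10/10 split with floor for val/test and the remainder to train."""
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(
    n_samples: int,
    world_cfg: WorldConfig,
    seed: int,
    dataset_cfg: DatasetConfig | None = None,
    spectrometer: VirtualSpectrometer | None = None,
) -> ShimDataset:
    """Synthesize a dataset of unshimmed spectrum pairs under random distortions."""
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    dataset_cfg = dataset_cfg or DatasetConfig()
    spect = spectrometer or build_spectrometer(world_cfg, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    m, n = spect.m, spect.n
    ref = spect.ref_ma.ravel()
    spectra = np.empty((n_samples, m, spect.L))
    targets = np.empty((n_samples, m * n))
    axis = None
    for i in range(n_samples):
        S = draw_distortion(ref, rng, dataset_cfg)
        state = spect.make_state(S.values.reshape(m, n))
        pair = spect.acquire(state, rng=rng)
        for ch in range(m):
            spectra[i, ch] = pair[ch].intensities
        targets[i] = S.values
        axis = pair[0].axis_hz
    n_train, n_val, n_test = split_sizes(n_samples, dataset_cfg.split_ratios)
    perm = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2,))
    ).permutation(n_samples)
    splits = {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }
    return ShimDataset(
        spectra=spectra,
        axis_hz=axis,
        targets=targets,
        ref=ref,
        splits=splits,
        world_config=world_cfg,
        dataset_config=dataset_cfg,
        seed=seed,
        spectrometer=spect,
        meta={"n_samples": n_samples},
    )


def build_training_sequence(
    dataset: ShimDataset,
    index: int,
    t: int,
    rng: np.random.Generator,
    spectrometer: VirtualSpectrometer | None = None,
) -> ShimSequence:
    """Mine one online training sequence for sample ``index``.

    The first entity is the stored unshimmed pair with the zero action;
    the following ``t`` entities carry fresh Gaussian random actions (same
    sigma policy as the distortions) with spectra synthesized on the fly.
    The target is always the sample's stored distortion.
    """
    if t < 0 or t > dataset.dataset_config.max_seq_len:
        raise ValueError(
            f"t must be in [0, {dataset.dataset_config.max_seq_len}], got {t}"
        )
    spect = spectrometer or dataset.attach_spectrometer()
    m, n = spect.m, spect.n
    S = dataset.targets[index]
    entities = [SequenceEntity(dataset.get_spectra(index), np.zeros(m * n))]
    for _ in range(t):
        a = draw_action(dataset.ref, rng, dataset.dataset_config)
        state = spect.make_state(S.reshape(m, n), a.reshape(m, n))
        pair = spect.acquire(state, rng=rng)
        entities.append(SequenceEntity(pair, a))
    return ShimSequence(entities=entities, target=DistortionVector(S))


_MANIFEST_KEYS = ("n_samples", "L", "m", "n", "seed", "sigma_policy", "sweep_hz")


def save_dataset(dataset: ShimDataset, path: str | Path) -> None:
    """Write the HDF5 container and its ``manifest.json`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    world = dataset.world_config.model_dump(mode="json")
    manifest = {
        "n_samples": dataset.n_samples,
        "L": int(dataset.spectra.shape[2]),
        "m": int(dataset.spectra.shape[1]),
        "n": int(dataset.targets.shape[1] // dataset.spectra.shape[1]),
        "seed": int(dataset.seed),
        "sigma_policy": dataset.dataset_config.sigma_policy,
        "sweep_hz": float(dataset.world_config.sweep_hz),
        "world_config": world,
        "dataset_config": dataset.dataset_config.model_dump(mode="json"),
    }
    with h5py.File(path / "shimdata.h5", "w") as f:
        f.create_dataset("spectra", data=dataset.spectra)
        f.create_dataset("axis_hz", data=dataset.axis_hz)
        f.create_dataset("targets", data=dataset.targets)
        f.create_dataset("ref", data=dataset.ref)
        grp = f.create_group("splits")
        for name, idx in dataset.splits.items():
            grp.create_dataset(name, data=idx)
        for key in _MANIFEST_KEYS:
            f.attrs[key] = manifest[key]
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_dataset(path: str | Path) -> ShimDataset:
    """Load a saved container; raises a format error naming any missing key."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json found in {path}")
    manifest = json.loads(manifest_path.read_text())
    for key in _MANIFEST_KEYS + ("world_config", "dataset_config"):
        if key not in manifest:
            raise KeyError(f"manifest is missing required key '{key}'")
    world_cfg = WorldConfig.model_validate(manifest["world_config"])
    dataset_cfg = DatasetConfig.model_validate(manifest["dataset_config"])
    with h5py.File(path / "shimdata.h5", "r") as f:
        spectra = f["spectra"][...]
        axis = f["axis_hz"][...]
        targets = f["targets"][...]
        ref = f["ref"][...]
        splits = {name: f["splits"][name][...] for name in f["splits"]}
    return ShimDataset(
        spectra=spectra,
        axis_hz=axis,
        targets=targets,
        ref=ref,
        splits=splits,
        world_config=world_cfg,
        dataset_config=dataset_cfg,
        seed=int(manifest["seed"]),
        meta={"n_samples": int(manifest["n_samples"])},
    )


def export_targets_csv(dataset: ShimDataset, path: str | Path) -> None:
    """Inspection export: one row per sample, one column per shim component."""
    import pandas as pd

    m = dataset.spectra.shape[1]
    n = dataset.targets.shape[1] // m
    cols = [f"ch{ch}_{coil}" for ch in range(m) for coil in range(n)]
    pd.DataFrame(dataset.targets, columns=cols).to_csv(path, index_label="sample")
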