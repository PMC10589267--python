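"""Validated run configuration and deterministic per-module random streams.

Every tunable of the virtual spectrometer, dataset builder, preprocessing,
network and episode loop lives in one nested, fully serializable
:class:`RunConfig`.  Unknown keys are rejected so that typos in a YAML file
fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridConfig(_Section):
    diameter_mm: float = 1.0
    length_mm: float = 8.0
    n_radial: int = 4
    n_axial: int = 64


class ShimsConfig(_Section):
    #: active shim coils per channel (subset of X, Y, Z, Z2, Z3, Z4)
    coils: list[str] = Field(default_factory=lambda: ["X", "Y", "Z", "Z2", "Z3", "Z4"])
    #: offset (Hz) at the reference coordinate per mA, one per active coil;
    #: calibrated so sigma = Ref/3 distortions broaden the line to ~90 Hz mean
    gains_hz_per_ma: list[float] = Field(
        default_factory=lambda: [2.0, 2.0, 8.0, 6.0, 4.0, 3.0]
    )


class CouplingConfig(_Section):
    epsilon: float = 0.1
    seed: int = 0


class DistortionConfig(_Section):
    z_span_hz: float = 3000.0
    xy_span_hz: float = 500.0


class LinesConfig(_Section):
    positions_hz: list[float] = Field(default_factory=lambda: [0.0])
    amplitudes: list[float] = Field(default_factory=lambda: [1.0])
    natural_fwhm_hz: float = 3.0

    @field_validator("amplitudes")
    @classmethod
    def _positive(cls, v):
        if any(a <= 0 for a in v):
            raise ValueError("line amplitudes must be positive")
        return v


class ReceiverConfig(_Section):
    snr: float | None = 30.0          # None disables noise
    snr_is_db: bool = False
    phase1: float = 0.0               # radians across the spectrum
    z0_drift_bins_per_acq: float = 0.0
    leak_coeff: float = 0.0           # inter-channel RF leakage fraction


class WorldConfig(_Section):
    m: int = 2                        # parallel channels
    n: int = 6                        # shim coils per channel
    L: int = 8192                     # raw spectrum length (bins)
    sweep_hz: float = 4000.0
    grid: GridConfig = Field(default_factory=GridConfig)
    shims: ShimsConfig = Field(default_factory=ShimsConfig)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    distortion: DistortionConfig = Field(default_factory=DistortionConfig)
    lines: list[LinesConfig] = Field(default_factory=lambda: [LinesConfig(), LinesConfig()])
    receiver: ReceiverConfig = Field(default_factory=ReceiverConfig)
    #: "derived": reference currents solved by least squares against the
    #: sampled intrinsic field; "explicit": reference currents given and the
    #: intrinsic field constructed to cancel them exactly at a = S.
    ref_mode: str = "explicit"
    ref_ma: list[float] | None = Field(default_factory=lambda: [30.0] * 12)

    @field_validator("ref_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("derived", "explicit"):
            raise ValueError("ref_mode must be 'derived' or 'explicit'")
        return v


class DatasetConfig(_Section):
    n_samples: int = 2000
    #: "ref/3" draws each component from N(0, (Ref_i/3)^2); "absolute" uses sigma_ma
    sigma_policy: str = "ref/3"
    sigma_ma: float | None = None
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    max_seq_len: int = 10

    @field_validator("sigma_policy")
    @classmethod
    def _policy(cls, v):
        if v not in ("ref/3", "absolute"):
            raise ValueError("sigma_policy must be 'ref/3' or 'absolute'")
        return v


class PreprocessConfig(_Section):
    roi_size: int = 4096
    downsample_factor: int = 2
    roi_center_bin: int | None = None   # default: centre of the raw axis
    #: per-component scale mapping targets to [-1, 1]; None -> 2 x Ref
    target_norm_bound: list[float] | None = None


class AugmentConfig(_Section):
    z0_shift_range: int = 4           # uniform integer circular shift in bins
    label_noise: float = 0.1          # uniform half-width on normalized targets
    interaction_noise: float = 0.1    # uniform multiplicative half-width on actions
    phase1_range: float = 0.5         # uniform half-width; radians across ROI
    phase1_in_cycles: bool = False
    awgn_snr: float | None = 30.0


class ModelConfig(_Section):
    n_filters: int = 64
    kernel_size: int = 41
    stride: int = 2
    n_conv_layers: int = 3
    pool_size: int = 2
    hidden_size: int = 256
    head_hidden: int = 64
    dropout: float = 0.2


class TrainConfig(_Section):
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 256
    huber_delta: float = 1.0
    #: sequence length schedule: start at curriculum_min, +2 every
    #: curriculum_period epochs up to curriculum_max
    curriculum_min: int = 4
    curriculum_max: int = 10
    curriculum_period: int = 25
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    #: per-step loss weighting: "uniform", or "linear" which emphasizes late
    #: steps (early-step targets are only partially identifiable before the
    #: probe history accumulates)
    step_loss_weighting: str = "linear"

    @field_validator("step_loss_weighting")
    @classmethod
    def _slw(cls, v):
        if v not in ("uniform", "linear"):
            raise ValueError("step_loss_weighting must be 'uniform' or 'linear'")
        return v


class EpisodeConfig(_Section):
    r: int = 5                        # random probe steps
    p: int = 4                        # predictive steps
    #: distortion draw for evaluation episodes: "uniform_2ref" (U[-2Ref, 2Ref])
    #: or "gaussian" (same sigma policy as the dataset)
    eval_distortion: str = "uniform_2ref"
    #: retain the best observed setting of the episode instead of the last
    keep_best_step: bool = False
    #: retention quality measure: worst-channel peak height or summed FWHM
    best_step_criterion: str = "peak"

    @field_validator("eval_distortion")
    @classmethod
    def _dist(cls, v):
        if v not in ("uniform_2ref", "gaussian"):
            raise ValueError("eval_distortion must be 'uniform_2ref' or 'gaussian'")
        return v

    @field_validator("best_step_criterion")
    @classmethod
    def _crit(cls, v):
        if v not in ("peak", "fwhm"):
            raise ValueError("best_step_criterion must be 'peak' or 'fwhm'")
        return v


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "runs"
    world: WorldConfig = Field(default_factory=WorldConfig)
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    augment: AugmentConfig = Field(default_factory=AugmentConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    episode: EpisodeConfig = Field(default_factory=EpisodeConfig)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file -> defaults."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))


class RngTree:
    """Named, independent random streams derived from one global seed.

    Each module name maps to a :class:`numpy.random.Generator` seeded by
    (global_seed, crc32(name)); consuming draws from one stream never
    perturbs another.
    """

    def __init__(self, global_seed: int):
        self.global_seed = int(global_seed)

    def get(self, name: str) -> np.random.Generator:
        key = zlib.crc32(name.encode())
        ss = np.random.SeedSequence(entropy=self.global_seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    def child_seed(self, name: str) -> int:
        """A plain integer seed (< 2**31) derived for ``name``."""
        key = zlib.crc32(name.encode())
        ss = np.random.SeedSequence(entropy=self.global_seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31))


def seeded_rng_tree(global_seed: int) -> RngTree:
    return RngTree(global_seed)
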