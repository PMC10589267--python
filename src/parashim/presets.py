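"""Ready-made run configurations.

``default_run_config`` is the full two-channel, six-shim study condition.
``reduced_run_config`` is the desk-scale learning condition used for
validation experiments: a decoupled, noise-reduced world with two zonal
shims (Z, Z2) per channel, short spectra, a small network and a pinned
curriculum, sized so that training completes in minutes on one CPU while
keeping every stage of the pipeline identical to the full condition.
"""

from __future__ import annotations

from .config import (
    AugmentConfig,
    CouplingConfig,
    DatasetConfig,
    EpisodeConfig,
    GridConfig,
    LinesConfig,
    ModelConfig,
    PreprocessConfig,
    ReceiverConfig,
    RunConfig,
    ShimsConfig,
    TrainConfig,
    WorldConfig,
)

__all__ = ["default_run_config", "reduced_run_config"]


def default_run_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def reduced_run_config(seed: int = 0, n_samples: int = 2000) -> RunConfig:
    """Scaled-down learning condition: 2 zonal shims/channel, 512-bin spectra."""
    world = WorldConfig(
        m=2,
        n=2,
        L=512,
        sweep_hz=1000.0,
        grid=GridConfig(diameter_mm=1.0, length_mm=8.0, n_radial=1, n_axial=33),
        shims=ShimsConfig(coils=["Z", "Z2"], gains_hz_per_ma=[3.0, 2.0]),
        coupling=CouplingConfig(epsilon=0.0, seed=0),
        lines=[
            LinesConfig(positions_hz=[0.0], amplitudes=[1.0], natural_fwhm_hz=6.0),
            LinesConfig(positions_hz=[0.0], amplitudes=[1.0], natural_fwhm_hz=6.0),
        ],
        receiver=ReceiverConfig(snr=1000.0, phase1=0.0, leak_coeff=0.0),
        ref_mode="explicit",
        ref_ma=[30.0, 30.0, 30.0, 30.0],
    )
    return RunConfig(
        seed=seed,
        world=world,
        dataset=DatasetConfig(n_samples=n_samples),
        preprocess=PreprocessConfig(roi_size=512, downsample_factor=2),
        augment=AugmentConfig(
            z0_shift_range=0, label_noise=0.0, interaction_noise=0.0,
            phase1_range=0.0, awgn_snr=None,
        ),
        model=ModelConfig(
            n_filters=32, kernel_size=21, stride=2, n_conv_layers=2,
            pool_size=2, hidden_size=128, head_hidden=32, dropout=0.0,
        ),
        train=TrainConfig(
            epochs=20, learning_rate=1e-3, batch_size=32,
            curriculum_min=4, curriculum_max=10, curriculum_period=5,
        ),
        episode=EpisodeConfig(r=5, p=4, eval_distortion="uniform_2ref",
                              keep_best_step=True),
    )
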