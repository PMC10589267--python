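"""The shimming regression network and its training procedure.

Architecture (i2f -> fusion -> recurrent -> f2o): a convolutional block
extracts features from the two channel-spectra at each time step, the
flattened features are fused with the step's action by concatenation and
layer normalization, an LSTM cell carries the shimming history, and the
output head (layer norm, dense + ReLU + dropout, dense + tanh) emits the
normalized shim-correction vector in (-1, 1)^(m*n).

Training minimizes the Huber loss with Adam under a sequence-length
curriculum (4 -> 10, +2 every 25 epochs by default) with
reduce-on-plateau learning-rate decay, all on a fixed seed tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import AugmentConfig, ModelConfig, PreprocessConfig, TrainConfig
from .dataset import ShimDataset, build_training_sequence
from .metrics import direction_ratio
from .preprocess import default_target_bound, prepare_sequence

__all__ = [
    "PedrNet",
    "curriculum_length",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


def _feature_length(L: int, cfg: ModelConfig) -> int:
    for _ in range(cfg.n_conv_layers):
        L = nn.conv_output_length(L, cfg.kernel_size, cfg.stride)
        if cfg.pool_size > 1:
            L //= cfg.pool_size
        if L < 1:
            raise ValueError("spectrum too short for the configured conv stack")
    return L


@dataclass
class LstmState:
    h: np.ndarray
    c: np.ndarray


class PedrNet:
    """Sequence-to-vector shim regressor with an explicit recurrent state.

    The hidden state is opaque to callers: it is carried between steps
    within a shimming episode and reset between episodes.
    """

    def __init__(self, model_cfg: ModelConfig, input_length: int, m: int, out_dim: int, seed: int = 0):
        self.cfg = model_cfg
        self.input_length = int(input_length)
        self.m = int(m)
        self.out_dim = int(out_dim)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c = model_cfg
        self.params: dict[str, np.ndarray] = {}
        cin = m
        for i in range(c.n_conv_layers):
            fan_in = cin * c.kernel_size
            self.params[f"conv{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c.n_filters, cin, c.kernel_size)
            )
            self.params[f"conv{i}_b"] = np.zeros(c.n_filters)
            cin = c.n_filters
        feat_len = _feature_length(input_length, c)
        self.flat_dim = c.n_filters * feat_len
        self.fused_dim = self.flat_dim + out_dim
        H = c.hidden_size
        self.params["ln_fuse_g"] = np.ones(self.fused_dim)
        self.params["ln_fuse_b"] = np.zeros(self.fused_dim)
        k = 1.0 / np.sqrt(H)
        self.params["lstm_Wx"] = rng.uniform(-k, k, size=(self.fused_dim, 4 * H))
        self.params["lstm_Wh"] = rng.uniform(-k, k, size=(H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.params["lstm_b"] = b
        self.params["ln_head_g"] = np.ones(H)
        self.params["ln_head_b"] = np.zeros(H)
        self.params["head1_W"] = rng.normal(0.0, np.sqrt(2.0 / H), size=(H, c.head_hidden))
        self.params["head1_b"] = np.zeros(c.head_hidden)
        self.params["head2_W"] = rng.normal(0.0, np.sqrt(1.0 / c.head_hidden), size=(c.head_hidden, out_dim))
        self.params["head2_b"] = np.zeros(out_dim)

    # ------------------------------------------------------------------ forward
    def init_state(self, batch: int = 1) -> LstmState:
        H = self.cfg.hidden_size
        return LstmState(h=np.zeros((batch, H)), c=np.zeros((batch, H)))

    def forward(
        self,
        spectra: np.ndarray,
        actions: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        state: LstmState | None = None,
    ):
        """spectra: (B, T, m, L), actions: (B, T, out_dim).

        Returns (preds (B, T, out_dim), final LstmState, caches).
        """
        p = self.params
        c = self.cfg
        B, T, m, L = spectra.shape
        if m != self.m or L != self.input_length:
            raise ValueError(
                f"expected spectra (B, T, {self.m}, {self.input_length}), got {spectra.shape}"
            )
        if actions.shape != (B, T, self.out_dim):
            raise ValueError("actions shape mismatch")
        if train and rng is None:
            raise ValueError("training mode requires an rng for dropout")
        x = spectra.reshape(B * T, m, L)
        conv_caches = []
        for i in range(c.n_conv_layers):
            x, cc = nn.conv1d_forward(x, p[f"conv{i}_W"], p[f"conv{i}_b"], c.stride)
            x, rm = nn.relu_forward(x)
            x, dm = nn.dropout_forward(x, c.dropout, rng, train)
            x, pc = nn.maxpool1d_forward(x, c.pool_size)
            conv_caches.append((cc, rm, dm, pc))
        flat = x.reshape(B * T, -1)
        fused = np.concatenate([flat, actions.reshape(B * T, self.out_dim)], axis=1)
        fused_n, ln_fuse_cache = nn.layernorm_forward(fused, p["ln_fuse_g"], p["ln_fuse_b"])
        seq = fused_n.reshape(B, T, self.fused_dim)
        st = state or self.init_state(B)
        h, cst = st.h, st.c
        lstm_caches = []
        hs = np.empty((B, T, c.hidden_size))
        for t in range(T):
            h, cst, lc = nn.lstm_step_forward(seq[:, t], h, cst, p["lstm_Wx"], p["lstm_Wh"], p["lstm_b"])
            hs[:, t] = h
            lstm_caches.append(lc)
        hh = hs.reshape(B * T, c.hidden_size)
        hn, ln_head_cache = nn.layernorm_forward(hh, p["ln_head_g"], p["ln_head_b"])
        z1, d1c = nn.dense_forward(hn, p["head1_W"], p["head1_b"])
        a1, rm1 = nn.relu_forward(z1)
        a1d, dm1 = nn.dropout_forward(a1, c.dropout, rng, train)
        z2, d2c = nn.dense_forward(a1d, p["head2_W"], p["head2_b"])
        preds = np.tanh(z2).reshape(B, T, self.out_dim)
        caches = {
            "shape": (B, T),
            "conv": conv_caches,
            "conv_out_shape": x.shape,
            "ln_fuse": ln_fuse_cache,
            "lstm": lstm_caches,
            "ln_head": ln_head_cache,
            "d1": d1c,
            "rm1": rm1,
            "dm1": dm1,
            "d2": d2c,
            "tanh": preds.reshape(B * T, self.out_dim),
        }
        return preds, LstmState(h=h, c=cst), caches

    # ----------------------------------------------------------------- backward
    def backward(self, dpreds: np.ndarray, caches) -> dict[str, np.ndarray]:
        p = self.params
        c = self.cfg
        B, T = caches["shape"]
        g: dict[str, np.ndarray] = {}
        dz2 = dpreds.reshape(B * T, self.out_dim) * (1.0 - caches["tanh"] ** 2)
        da1d, g["head2_W"], g["head2_b"] = nn.dense_backward(dz2, caches["d2"])
        da1 = nn.dropout_backward(da1d, caches["dm1"])
        dz1 = nn.relu_backward(da1, caches["rm1"])
        dhn, g["head1_W"], g["head1_b"] = nn.dense_backward(dz1, caches["d1"])
        dhh, g["ln_head_g"], g["ln_head_b"] = nn.layernorm_backward(dhn, caches["ln_head"])
        dhs = dhh.reshape(B, T, c.hidden_size)
        H = c.hidden_size
        g["lstm_Wx"] = np.zeros_like(p["lstm_Wx"])
        g["lstm_Wh"] = np.zeros_like(p["lstm_Wh"])
        g["lstm_b"] = np.zeros_like(p["lstm_b"])
        dseq = np.empty((B, T, self.fused_dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dx, dh_next, dc_next, dWx, dWh, db = nn.lstm_step_backward(
                dhs[:, t] + dh_next, dc_next, caches["lstm"][t]
            )
            dseq[:, t] = dx
            g["lstm_Wx"] += dWx
            g["lstm_Wh"] += dWh
            g["lstm_b"] += db
        dfused_n = dseq.reshape(B * T, self.fused_dim)
        dfused, g["ln_fuse_g"], g["ln_fuse_b"] = nn.layernorm_backward(dfused_n, caches["ln_fuse"])
        dflat = dfused[:, : self.flat_dim]
        dx = dflat.reshape(caches["conv_out_shape"])
        for i in range(c.n_conv_layers - 1, -1, -1):
            cc, rm, dm, pc = caches["conv"][i]
            dx = nn.maxpool1d_backward(dx, pc)
            dx = nn.dropout_backward(dx, dm)
            dx = nn.relu_backward(dx, rm)
            dx, g[f"conv{i}_W"], g[f"conv{i}_b"] = nn.conv1d_backward(dx, cc)
        return g

    # --------------------------------------------------------------- inference
    def forward_step(
        self,
        spectra_pair: np.ndarray,
        last_action: np.ndarray,
        state: LstmState | None = None,
    ) -> tuple[np.ndarray, LstmState]:
        """Single-step inference: one (m, L) spectrum pair plus the last
        normalized action; returns (prediction, evolved hidden state)."""
        spectra = np.asarray(spectra_pair, dtype=float)[None, None, :, :]
        actions = np.asarray(last_action, dtype=float)[None, None, :]
        preds, new_state, _ = self.forward(spectra, actions, train=False, state=state)
        return preds[0, 0], new_state

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


def curriculum_length(epoch: int, cfg: TrainConfig) -> int:
    """Sequence length for a 1-based epoch: +2 every period, capped."""
    return min(
        cfg.curriculum_min + 2 * ((epoch - 1) // cfg.curriculum_period),
        cfg.curriculum_max,
    )


def _batch_arrays(dataset, indices, t, rng, pre_cfg, bound, aug_cfg, aug_rng):
    xs, acts, ys = [], [], []
    for idx in indices:
        seq = build_training_sequence(dataset, int(idx), t, rng)
        x, a, y = prepare_sequence(seq, pre_cfg, bound, aug_cfg, aug_rng)
        xs.append(x)
        acts.append(a)
        ys.append(y)
    return np.stack(xs), np.stack(acts), np.stack(ys)


def train(
    dataset: ShimDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    pre_cfg: PreprocessConfig,
    aug_cfg: AugmentConfig | None,
    seed: int,
) -> tuple[PedrNet, list[dict]]:
    """Train on the dataset's train split; model selection on validation loss.

    Sequences are mined online and fresh each epoch.  Returns the network
    with the best-on-validation parameters restored, plus a history with
    per-epoch train/validation loss, curriculum length and learning rate.
    """
    for split in ("train", "val"):
        if len(dataset.indices(split)) == 0:
            raise ValueError(f"dataset has an empty '{split}' split")
    m = dataset.spectra.shape[1]
    out_dim = dataset.targets.shape[1]
    in_len = pre_cfg.roi_size // pre_cfg.downsample_factor
    net = PedrNet(model_cfg, in_len, m, out_dim, seed=seed)
    bound = (
        np.asarray(pre_cfg.target_norm_bound, dtype=float)
        if pre_cfg.target_norm_bound is not None
        else default_target_bound(dataset.ref)
    )
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(7,))
    rng_seq, rng_aug, rng_drop, rng_shuffle = [np.random.default_rng(s) for s in ss.spawn(4)]
    opt = nn.Adam(net.params, lr=train_cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_params = net.clone_params()
    stall = 0
    train_idx = dataset.indices("train")
    val_idx = dataset.indices("val")
    def step_weights(T: int) -> np.ndarray | None:
        if train_cfg.step_loss_weighting == "uniform":
            return None
        w = np.arange(1, T + 1, dtype=float)
        return (w / w.mean())[None, :, None]

    for epoch in range(1, train_cfg.epochs + 1):
        t = curriculum_length(epoch, train_cfg)
        order = rng_shuffle.permutation(train_idx)
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start : start + train_cfg.batch_size]
            x, a, y = _batch_arrays(dataset, batch, t, rng_seq, pre_cfg, bound, aug_cfg, rng_aug)
            preds, _, caches = net.forward(x, a, train=True, rng=rng_drop)
            target = np.broadcast_to(y[:, None, :], preds.shape)
            loss, dpreds = nn.huber_loss(
                preds, target, train_cfg.huber_delta, weights=step_weights(preds.shape[1])
            )
            grads = net.backward(dpreds, caches)
            opt.step(net.params, grads)
            losses.append(loss)
        # validation with a fixed per-epoch-independent seed so epochs compare
        val_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(8,)))
        vx, va, vy = _batch_arrays(dataset, val_idx, t, val_rng, pre_cfg, bound, None, None)
        vpreds, _, _ = net.forward(vx, va, train=False)
        vtarget = np.broadcast_to(vy[:, None, :], vpreds.shape)
        val_loss, _ = nn.huber_loss(vpreds, vtarget, train_cfg.huber_delta)
        history.append(
            {
                "epoch": epoch,
                "seq_len": t,
                "train_loss": float(np.mean(losses)),
                "val_loss": float(val_loss),
                "lr": opt.lr,
            }
        )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = net.clone_params()
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.plateau_patience:
                opt.lr *= train_cfg.plateau_factor
                stall = 0
    net.set_params(best_params)
    return net, history


def evaluate(
    net: PedrNet,
    dataset: ShimDataset,
    split: str,
    pre_cfg: PreprocessConfig,
    seed: int = 0,
    t: int = 4,
) -> dict[str, float]:
    """Offline metrics on a split: normalized MAE (in [0, 1]) and DiR.

    Sequences are constructed with a fixed evaluation seed and the final
    step's prediction is scored against the normalized target.
    """
    idx = dataset.indices(split)
    if len(idx) == 0:
        raise ValueError(f"empty split '{split}'")
    bound = (
        np.asarray(pre_cfg.target_norm_bound, dtype=float)
        if pre_cfg.target_norm_bound is not None
        else default_target_bound(dataset.ref)
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    x, a, y = _batch_arrays(dataset, idx, t, rng, pre_cfg, bound, None, None)
    preds, _, _ = net.forward(x, a, train=False)
    final = preds[:, -1, :]
    mae = float(np.mean(np.abs(final - y)))
    dirs = [direction_ratio(final[i], y[i]) for i in range(final.shape[0])]
    return {"mae": mae, "dir": float(np.mean(dirs))}


def save_checkpoint(
    net: PedrNet,
    path: str | Path,
    pre_cfg: PreprocessConfig | None = None,
    train_cfg: TrainConfig | None = None,
    extra: dict | None = None,
) -> None:
    """Bundle weights plus every config needed to reproduce inference."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **net.params)
    meta = {
        "model_config": net.cfg.model_dump(mode="json"),
        "input_length": net.input_length,
        "m": net.m,
        "out_dim": net.out_dim,
        "seed": net.seed,
        "preprocess_config": pre_cfg.model_dump(mode="json") if pre_cfg else None,
        "train_config": train_cfg.model_dump(mode="json") if train_cfg else None,
        "extra": extra or {},
    }
    (path / "checkpoint.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> tuple[PedrNet, dict]:
    path = Path(path)
    meta = json.loads((path / "checkpoint.json").read_text())
    cfg = ModelConfig.model_validate(meta["model_config"])
    net = PedrNet(cfg, meta["input_length"], meta["m"], meta["out_dim"], seed=meta["seed"])
    with np.load(path / "weights.npz") as data:
        net.set_params({k: data[k] for k in data.files})
    return net, meta
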