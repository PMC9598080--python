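"""Hierarchical multi-output CNN for dual-echo water-fat mapping.

The model is an encoder-decoder with convolutional down/upsampling,
densely connected local shortcuts inside each level (every block sees
the concatenation of all earlier block outputs, and a 1x1 projection
fuses the level back to its channel width), U-Net-style global
shortcuts between matching encoder/decoder levels, and two parallel 1x1
output heads producing water and fat magnitude images.  Inputs are six
channels: normalized magnitudes of both echoes, wrapped phases divided
by pi, and two constant maps carrying the echo times.

Two presets are provided: the full-scale configuration (five levels,
16/32/64/128/256 channels) and a desk-scale configuration (three
levels, 8/16/32 channels) with identical topology, used for training
on synthetic phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import nn
from .core import DualEchoImage, WaterFatResult
from .metrics import evaluate_pair  # noqa: F401  (re-exported convenience)

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TNet",
    "assemble_input_stack",
    "fit_normalization",
    "build_network",
    "train_model",
    "predict_water_fat",
    "full_config",
    "desk_config",
]

TE_SCALE_MS = 10.0  # TE channels are TE / 10 ms, so clinical TEs fall in ~[0.1, 0.5]


@dataclass(frozen=True)
class NetworkConfig:
    n_levels: int = 3
    channels_per_level: tuple[int, ...] = (8, 16, 32)
    blocks_per_level: int = 3
    kernel_size: int = 3
    down_up_kernel: int = 2
    activation: str = "prelu"
    n_input_channels: int = 6
    n_outputs: int = 2
    dense_local_shortcuts: bool = True
    global_shortcuts: bool = True

    def __post_init__(self) -> None:
        if len(self.channels_per_level) != self.n_levels:
            raise ValueError(
                f"channels_per_level has {len(self.channels_per_level)} entries "
                f"for {self.n_levels} levels"
            )
        if self.activation != "prelu":
            raise ValueError(f"unsupported activation {self.activation!r}")


def full_config() -> NetworkConfig:
    """Full-scale preset: five levels with 16..256 channels."""
    return NetworkConfig(n_levels=5, channels_per_level=(16, 32, 64, 128, 256))


def desk_config() -> NetworkConfig:
    """Reduced-capacity preset with the same topology (three levels)."""
    return NetworkConfig(n_levels=3, channels_per_level=(8, 16, 32))


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    loss: str = "l1"
    init: str = "he"
    epochs: int = 20
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "l1":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.init != "he":
            raise ValueError(f"unsupported init {self.init!r}")


class _DenseLevel(nn.Module):
    """blocks_per_level 3x3+PReLU blocks with dense concatenative shortcuts,
    fused back to the level width by a linear 1x1 projection."""

    def __init__(self, cin: int, ch: int, n_blocks: int, k: int, dense: bool, rng):
        self.dense = dense
        self.blocks: list[tuple[nn.Conv2d, nn.PReLU]] = []
        width = cin
        for _ in range(n_blocks):
            conv = nn.Conv2d(width, ch, k, stride=1, pad=k // 2, rng=rng)
            self.blocks.append((conv, nn.PReLU(ch)))
            width = (width + ch) if dense else ch
        fuse_in = width if dense else ch
        self.fuse = nn.Conv2d(fuse_in, ch, 1, rng=rng)
        self._splits: list[int] | None = None

    def params(self):
        out = []
        for conv, act in self.blocks:
            out += conv.params() + act.params()
        return out + self.fuse.params()

    def forward(self, x, train=True):
        outs = [x]
        for conv, act in self.blocks:
            inp = np.concatenate(outs, axis=1) if self.dense else outs[-1]
            outs.append(act.forward(conv.forward(inp, train), train))
        cat = np.concatenate(outs, axis=1) if self.dense else outs[-1]
        if train:
            self._splits = [o.shape[1] for o in outs]
        return self.fuse.forward(cat, train)

    def backward(self, dy):
        splits = self._splits
        assert splits is not None
        dcat = self.fuse.backward(dy)
        if self.dense:
            bounds = np.cumsum(splits)[:-1]
            grads = list(np.split(dcat, bounds, axis=1))
        else:
            grads = [np.zeros((dcat.shape[0], splits[0]) + dcat.shape[2:], dtype=dcat.dtype)]
            grads += [np.zeros((dcat.shape[0], s) + dcat.shape[2:], dtype=dcat.dtype)
                      for s in splits[1:-1]]
            grads.append(dcat)
        for bi in range(len(self.blocks) - 1, -1, -1):
            conv, act = self.blocks[bi]
            g = grads[bi + 1]
            dinp = conv.backward(act.backward(g))
            if self.dense:
                bounds = np.cumsum(splits[: bi + 1])[:-1]
                for gi, piece in enumerate(np.split(dinp, bounds, axis=1)):
                    grads[gi] = grads[gi] + piece
            else:
                grads[bi] = grads[bi] + dinp
        self._splits = None
        return grads[0]


class TNet(nn.Module):
    """Encoder-decoder with dense local and global shortcuts, two 1x1 heads."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.channels_per_level
        L = cfg.n_levels
        k, dk = cfg.kernel_size, cfg.down_up_kernel
        self.enc = []
        self.down = []
        width = cfg.n_input_channels
        for lvl in range(L):
            if lvl > 0:
                conv = nn.Conv2d(ch[lvl - 1], ch[lvl], dk, stride=dk, rng=rng)
                self.down.append((conv, nn.PReLU(ch[lvl])))
                width = ch[lvl]
            self.enc.append(
                _DenseLevel(width, ch[lvl], cfg.blocks_per_level, k,
                            cfg.dense_local_shortcuts, rng)
            )
            width = ch[lvl]
        self.up = []
        self.dec = []
        for lvl in range(L - 2, -1, -1):
            self.up.append((nn.ConvTranspose2d(ch[lvl + 1], ch[lvl], dk, rng=rng),
                            nn.PReLU(ch[lvl])))
            dec_in = 2 * ch[lvl] if cfg.global_shortcuts else ch[lvl]
            self.dec.append(
                _DenseLevel(dec_in, ch[lvl], cfg.blocks_per_level, k,
                            cfg.dense_local_shortcuts, rng)
            )
        self.heads = [nn.Conv2d(ch[0], 1, 1, rng=rng) for _ in range(cfg.n_outputs)]

    # ---- parameters -------------------------------------------------
    def params(self):
        out = []
        for lvl in self.enc:
            out += lvl.params()
        for conv, act in self.down:
            out += conv.params() + act.params()
        for conv, act in self.up:
            out += conv.params() + act.params()
        for lvl in self.dec:
            out += lvl.params()
        for h in self.heads:
            out += h.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    @property
    def divisor(self) -> int:
        return self.cfg.down_up_kernel ** (self.cfg.n_levels - 1)

    # ---- forward / backward -----------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cfg = self.cfg
        enc_out = []
        h = x.astype(np.float32)
        for lvl in range(cfg.n_levels):
            if lvl > 0:
                conv, act = self.down[lvl - 1]
                h = act.forward(conv.forward(h, train), train)
            h = self.enc[lvl].forward(h, train)
            enc_out.append(h)
        h = enc_out[-1]
        for di, lvl in enumerate(range(cfg.n_levels - 2, -1, -1)):
            conv, act = self.up[di]
            h = act.forward(conv.forward(h, train), train)
            if cfg.global_shortcuts:
                h = np.concatenate([h, enc_out[lvl]], axis=1)
            h = self.dec[di].forward(h, train)
        outs = [head.forward(h, train) for head in self.heads]
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        L = cfg.n_levels
        ch = cfg.channels_per_level
        dh = None
        for oi, head in enumerate(self.heads):
            g = head.backward(dout[:, oi : oi + 1])
            dh = g if dh is None else dh + g
        d_enc = [None] * L
        # decoder ran di = 0..L-2 over levels L-2..0; reverse it
        for di in range(L - 2, -1, -1):
            lvl = L - 2 - di
            g = self.dec[di].backward(dh)
            if cfg.global_shortcuts:
                g_up, g_skip = g[:, : ch[lvl]], g[:, ch[lvl] :]
                d_enc[lvl] = g_skip if d_enc[lvl] is None else d_enc[lvl] + g_skip
            else:
                g_up = g
            conv, act = self.up[di]
            dh = conv.backward(act.backward(g_up))
        d_enc[L - 1] = dh if d_enc[L - 1] is None else d_enc[L - 1] + dh
        g = None
        for lvl in range(L - 1, -1, -1):
            if d_enc[lvl] is not None:
                g = d_enc[lvl] if g is None else g + d_enc[lvl]
            g = self.enc[lvl].backward(g)
            if lvl > 0:
                conv, act = self.down[lvl - 1]
                g = conv.backward(act.backward(g))
        return g


def build_network(cfg: NetworkConfig, seed: int = 0) -> tuple[TNet, int]:
    """Construct a network from a config; returns (model, parameter count)."""
    rng = np.random.default_rng(seed)
    model = TNet(cfg, rng)
    return model, model.n_parameters


# ---- input normalization --------------------------------------------


def fit_normalization(images: Sequence[DualEchoImage]) -> dict:
    """Fit the magnitude scale m (99th percentile of |S1| over the set)."""
    mags = np.concatenate([np.abs(im.s1).ravel() for im in images])
    m = float(np.percentile(mags, 99))
    if m <= 0:
        raise ValueError("blank images: 99th-percentile magnitude is zero")
    return {"m": m, "te_scale_ms": TE_SCALE_MS}


def assemble_input_stack(
    img: DualEchoImage, norm: dict | str = "fit"
) -> tuple[np.ndarray, dict]:
    """Build the 6-channel network input for one image.

    Channels: [|S1|/m, |S2|/m, arg(S1)/pi, arg(S2)/pi, TE1/10ms, TE2/10ms].
    With ``norm="fit"`` the scale m is fit on this image alone; pass a
    stored record for consistent training/inference scaling.  The
    inverse transform for network outputs is multiplication by m.
    """
    if norm == "fit":
        norm = fit_normalization([img])
    elif not isinstance(norm, dict):
        raise ValueError("norm must be 'fit' or a normalization record")
    m = norm["m"]
    h, w = img.shape
    stack = np.empty((6, h, w), dtype=np.float32)
    stack[0] = np.abs(img.s1) / m
    stack[1] = np.abs(img.s2) / m
    stack[2] = np.angle(img.s1) / np.pi
    stack[3] = np.angle(img.s2) / np.pi
    stack[4] = img.params.te1_ms / TE_SCALE_MS
    stack[5] = img.params.te2_ms / TE_SCALE_MS
    return stack, norm


def make_target(water: np.ndarray, fat: np.ndarray, norm: dict) -> np.ndarray:
    """Stack normalized (water, fat) reference channels."""
    return np.stack([water, fat]).astype(np.float32) / np.float32(norm["m"])


def phantom_dataset(
    n_cases: int,
    spec=None,
    seed: int = 0,
    noise_sigma: float = 0.03,
    norm: dict | None = None,
):
    """Simulate a seeded set of phantom acquisitions as training pairs.

    Returns (pairs, norm, raw) where ``pairs`` are (input stack, target)
    tuples, ``norm`` the magnitude normalization (fit on this set when
    not supplied), and ``raw`` the underlying (DualEchoImage,
    PhantomTruth) tuples for image-level evaluation.  The default noise
    level gives roughly 30 dB peak SNR on tissue.
    """
    from .phantom import generate_phantom, simulate_acquisition, smooth_spec

    if spec is None:
        spec = smooth_spec()
    raw = []
    for k in range(n_cases):
        truth = generate_phantom(spec, seed=seed + k)
        img = simulate_acquisition(truth, noise_sigma=noise_sigma, seed=seed + k)
        raw.append((img, truth))
    if norm is None:
        norm = fit_normalization([img for img, _ in raw])
    pairs = [
        (assemble_input_stack(img, norm)[0], make_target(t.water, t.fat, norm))
        for img, t in raw
    ]
    return pairs, norm, raw


# ---- training --------------------------------------------------------


def train_model(
    train_set: Sequence[tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    verbose: bool = False,
) -> tuple[TNet, dict]:
    """Train on (input stack, target water/fat stack) pairs; seeded end to end.

    Minimizes mean absolute error with Adam; history records per-epoch
    mean training loss and validation loss.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    shapes = {x.shape for x, _ in train_set}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent input shapes in training set: {shapes}")

    model, _ = build_network(net_cfg, seed=train_cfg.seed)
    opt = nn.Adam(model.params(), lr=train_cfg.lr, beta1=train_cfg.beta1,
                  beta2=train_cfg.beta2, eps=train_cfg.epsilon)
    rng = np.random.default_rng(train_cfg.seed + 1)

    xs = np.stack([x for x, _ in train_set]).astype(np.float32)
    ys = np.stack([y for _, y in train_set]).astype(np.float32)
    history: dict = {"train_loss": [], "val_loss": []}
    n = len(train_set)
    bs = min(train_cfg.batch_size, n)
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            opt.zero_grad()
            pred = model.forward(xs[idx], train=True)
            loss, grad = nn.l1_loss(pred, ys[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(evaluate_loss(model, val_set))
        if verbose:
            print(
                f"epoch {_epoch + 1:3d}  train l1 {history['train_loss'][-1]:.4f}"
                f"  val l1 {history['val_loss'][-1]:.4f}"
            )
    return model, history


def evaluate_loss(model: TNet, dataset: Sequence[tuple[np.ndarray, np.ndarray]],
                  batch_size: int = 16) -> float:
    """Mean l1 loss of a model over a dataset (no gradients)."""
    if len(dataset) == 0:
        return float("nan")
    losses = []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        x = np.stack([c[0] for c in chunk]).astype(np.float32)
        y = np.stack([c[1] for c in chunk]).astype(np.float32)
        pred = model.forward(x, train=False)
        losses.append(np.mean(np.abs(pred - y)) * x.shape[0])
    return float(np.sum(losses) / len(dataset))


def predict_water_fat(model: TNet, img: DualEchoImage, norm: dict) -> WaterFatResult:
    """Network inference on one image; pads to the divisibility constraint.

    Outputs are de-normalized to the input's amplitude units; negative
    raw predictions are clamped to zero and the clamped fraction is
    reported in the result metadata.  The phasor map and selection
    labels are not produced by the network and are left empty.
    """
    stack, _ = assemble_input_stack(img, norm)
    h, w = img.shape
    div = model.divisor
    ph = (-h) % div
    pw = (-w) % div
    x = np.pad(stack, ((0, 0), (0, ph), (0, pw)), mode="edge")[None]
    raw = model.forward(x, train=False)[0, :, :h, :w]
    clamped = float((raw < 0).mean())
    out = np.maximum(raw, 0.0) * norm["m"]
    return WaterFatResult(
        water=out[0].astype(float),
        fat=out[1].astype(float),
        phasor=np.ones(img.shape, dtype=complex),
        selection=np.zeros(img.shape, dtype=np.int64),
        meta={
            "method": "network",
            "config": asdict(model.cfg),
            "normalization": dict(norm),
            "clamped_fraction": clamped,
        },
    )
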