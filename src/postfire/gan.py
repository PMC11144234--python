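"""Recovery mapping with an adaptive conditional GAN, plus its metrics.

The model learns the mapping from a post-fire vegetation-index composite at
time t to the composite at t+Delta, so a trained generator turns a single
post-fire image into a *recovery map* — the network's estimate of the
recovered vegetation state.

Generator: encoder-decoder.  ``n_down`` stride-2 convolutions double the
channel count while halving the grid; a gated-residual self-attention block
(scalar gate initialized at 0, so the network starts as a plain
encoder-decoder) sits after the third downsampling stage by default;
mirrored nearest-neighbour-upsample + conv stages restore resolution with
*summation* skip connections from matching encoder stages, dropout in every
decoding stage, and a tanh-activated output convolution, so outputs live
strictly in (-1, 1).

Discriminator: PatchGAN — three stride-2 leaky-ReLU convolutions (batch
normalization after the first, instance normalization after the second and
third) followed by a stride-1 convolution to a 1-channel grid of patch
logits; each logit judges one local patch of the (input, candidate) pair.

Training alternates discriminator and generator steps with the
non-saturating adversarial loss plus ``rec_weight`` * L1 reconstruction,
and L2 weight regularization on all convolution kernels of both networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from . import nn
from .errors import ConfigError, InputError, TrainingError
from .raster import ClassScheme, IndexRaster, classify_ndvi

RECOVERY_LEVELS = ("regressed", "stable", "recovering", "recovered")


@dataclass
class GANConfig:
    image_size: int = 32
    base_channels: int = 16
    n_down: int = 3
    attention_after: int = 3
    dropout_rate: float = 0.3
    l2_weight: float = 1e-5
    rec_weight: float = 50.0
    epochs: int = 30
    batch: int = 16
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    seed: int = 0

    def __post_init__(self):
        s = self.image_size
        if s < 2 or s & (s - 1):
            raise ConfigError("image_size must be a power of 2")
        if self.n_down < 3:
            raise ConfigError("need at least 3 downsampling stages")
        if s % (1 << self.n_down):
            raise ConfigError(
                f"image_size {s} not divisible by 2^{self.n_down}")
        if not 1 <= self.attention_after <= self.n_down:
            raise ConfigError("attention_after must be within 1..n_down")
        if s < 8:
            raise ConfigError("image smaller than the discriminator receptive field")


class Generator:
    """Encoder-decoder generator with summation skips and gated attention."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = [1] + [cfg.base_channels * (1 << i) for i in range(cfg.n_down)]
        self.enc_convs = [nn.Conv2d(ch[i], ch[i + 1], 4, 2, 1, rng)
                          for i in range(cfg.n_down)]
        self.enc_acts = [nn.ReLU() for _ in range(cfg.n_down)]
        self.attn = nn.SelfAttention2d(ch[cfg.attention_after], rng)
        # decoder stage for encoder level i (n_down..1): upsample, conv to the
        # previous level's width, summation skip where a matching encoder
        # output exists (levels n_down-1..1), ReLU, dropout
        self.dec = []
        for i in range(cfg.n_down, 0, -1):
            c_out = ch[i - 1] if i > 1 else cfg.base_channels
            skip = i - 2 if i >= 2 else None  # index into encoder outputs
            self.dec.append((nn.Upsample2x(),
                             nn.Conv2d(ch[i], c_out, 3, 1, 1, rng),
                             nn.ReLU(),
                             nn.Dropout(cfg.dropout_rate, rng),
                             skip))
        self.out_conv = nn.Conv2d(cfg.base_channels, 1, 3, 1, 1, rng)
        self.tanh = nn.Tanh()

    def params(self) -> list[nn.Param]:
        ps = []
        for c in self.enc_convs:
            ps += c.params()
        ps += self.attn.params()
        for _, conv, _, _, _ in self.dec:
            ps += conv.params()
        ps += self.out_conv.params()
        return ps

    def conv_kernels(self) -> list[nn.Param]:
        ks = [c.W for c in self.enc_convs]
        ks += [conv.W for _, conv, _, _, _ in self.dec]
        ks.append(self.out_conv.W)
        return ks

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cfg = self.cfg
        outs = []
        h = x
        for i in range(cfg.n_down):
            h = self.enc_acts[i].forward(self.enc_convs[i].forward(h))
            if i + 1 == cfg.attention_after:
                h = self.attn.forward(h)
            outs.append(h)
        self._outs = outs
        for up, conv, act, drop, skip in self.dec:
            h = conv.forward(up.forward(h))
            if skip is not None:
                h = h + outs[skip]
            h = drop.forward(act.forward(h), train=train)
        return self.tanh.forward(self.out_conv.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        dh = self.out_conv.backward(self.tanh.backward(dy))
        dskips: dict[int, np.ndarray] = {}
        for up, conv, act, drop, skip in reversed(self.dec):
            dh = act.backward(drop.backward(dh))
            if skip is not None:
                dskips[skip] = dskips.get(skip, 0) + dh
            dh = up.backward(conv.backward(dh))
        for i in reversed(range(cfg.n_down)):
            if i in dskips:
                dh = dh + dskips[i]
            if i + 1 == cfg.attention_after:
                dh = self.attn.backward(dh)
            dh = self.enc_convs[i].backward(self.enc_acts[i].backward(dh))
        return dh


class Discriminator:
    """Conditional PatchGAN over (input, candidate) channel pairs."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        b = cfg.base_channels
        self.net = nn.Sequential([
            nn.Conv2d(2, b, 4, 2, 1, rng), nn.BatchNorm2d(b), nn.LeakyReLU(0.2),
            nn.Conv2d(b, 2 * b, 4, 2, 1, rng), nn.InstanceNorm2d(2 * b), nn.LeakyReLU(0.2),
            nn.Conv2d(2 * b, 4 * b, 4, 2, 1, rng), nn.InstanceNorm2d(4 * b), nn.LeakyReLU(0.2),
            nn.Conv2d(4 * b, 1, 3, 1, 1, rng),
        ])

    def params(self):
        return self.net.params()

    def conv_kernels(self):
        return [l.W for l in self.net.layers if isinstance(l, nn.Conv2d)]

    def forward(self, x, train=True):
        return self.net.forward(x, train=train)

    def backward(self, dy):
        return self.net.backward(dy)

    @staticmethod
    def patch_map_shape(image_size: int) -> tuple[int, int]:
        """Closed-form output grid: three stride-2 halvings, stride-1 head."""
        s = image_size
        for _ in range(3):
            s = (s + 2 - 4) // 2 + 1
        return (s, s)


@dataclass
class AdaptiGAN:
    cfg: GANConfig
    generator: Generator
    discriminator: Discriminator
    loss_log: list[dict] = field(default_factory=list)

    @classmethod
    def build(cls, cfg: GANConfig) -> "AdaptiGAN":
        rng = np.random.default_rng(cfg.seed)
        return cls(cfg, Generator(cfg, rng), Discriminator(cfg, rng))


def build_generator(cfg: GANConfig) -> Generator:
    return Generator(cfg, np.random.default_rng(cfg.seed))


def build_discriminator(cfg: GANConfig) -> Discriminator:
    return Discriminator(cfg, np.random.default_rng(cfg.seed + 1))


def _as_batch(images, size: int) -> np.ndarray:
    arrs = []
    for im in images:
        a = im.values if isinstance(im, IndexRaster) else np.asarray(im, float)
        if a.shape != (size, size):
            raise InputError(f"expected {size}x{size} images, got {a.shape}")
        arrs.append(a)
    return np.asarray(arrs)[:, None, :, :]


def train_adaptigan(pairs, cfg: GANConfig | None = None) -> AdaptiGAN:
    """Alternating adversarial training on (composite_t, composite_t+Delta) pairs.

    Per batch: one discriminator step (real pair vs. generated pair, binary
    cross-entropy) then one generator step (non-saturating adversarial loss
    plus ``rec_weight`` * L1 to the target).  Both losses include
    ``l2_weight`` * sum ||W||^2 over convolution kernels.  Per-epoch means
    are appended to ``model.loss_log``.
    """
    cfg = cfg or GANConfig()
    if len(pairs) < 1:
        raise InputError("need at least one training pair")
    x = _as_batch([p[0] for p in pairs], cfg.image_size)
    y = _as_batch([p[1] for p in pairs], cfg.image_size)
    model = AdaptiGAN.build(cfg)
    G, D = model.generator, model.discriminator
    opt_g = nn.Adam(G.params(), lr=cfg.lr_g, beta1=0.5,
                    weight_decay=cfg.l2_weight, decay_params=G.conv_kernels())
    opt_d = nn.Adam(D.params(), lr=cfg.lr_d, beta1=0.5,
                    weight_decay=cfg.l2_weight, decay_params=D.conv_kernels())
    rng = np.random.default_rng(cfg.seed + 2)
    n = x.shape[0]
    bs = min(cfg.batch, n)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {"d_loss": [], "g_adv": [], "g_l1": [], "g_loss": []}
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x[idx], y[idx]
            # --- discriminator step
            fake = G.forward(xb, train=True)
            opt_d.zero_grad()
            z_real = D.forward(np.concatenate([xb, yb], axis=1))
            l_real, dz = nn.bce_with_logits(z_real, 1.0)
            D.backward(dz)
            z_fake = D.forward(np.concatenate([xb, fake], axis=1))
            l_fake, dz = nn.bce_with_logits(z_fake, 0.0)
            D.backward(dz)
            opt_d.step()
            d_l2 = cfg.l2_weight * nn.l2_penalty(D.conv_kernels())
            # --- generator step (non-saturating: maximize log D(fake))
            fake = G.forward(xb, train=True)
            z = D.forward(np.concatenate([xb, fake], axis=1))
            g_adv, dz = nn.bce_with_logits(z, 1.0)
            g_l1, dl1 = nn.l1_loss(fake, yb)
            opt_g.zero_grad()
            dcat = D.backward(dz)  # D grads are stale until its next zero_grad
            G.backward(dcat[:, 1:2] + cfg.rec_weight * dl1)
            opt_g.step()
            g_l2 = cfg.l2_weight * nn.l2_penalty(G.conv_kernels())
            ep["d_loss"].append(l_real + l_fake + d_l2)
            ep["g_adv"].append(g_adv)
            ep["g_l1"].append(g_l1)
            ep["g_loss"].append(g_adv + cfg.rec_weight * g_l1 + g_l2)
        entry = {k: float(np.mean(v)) for k, v in ep.items()}
        entry["epoch"] = epoch
        if not all(np.isfinite(v) for v in entry.values()):
            raise TrainingError(f"non-finite loss at epoch {epoch}: {entry}")
        model.loss_log.append(entry)
    return model


# ----------------------------------------------------------- inference -----

@dataclass
class RecoveryMap:
    values: np.ndarray          # generated recovery-state index, in [-1, 1]
    source: IndexRaster
    nodata_mask: np.ndarray
    level_map: np.ndarray | None = None  # codes into RECOVERY_LEVELS


def generate_recovery_map(model: AdaptiGAN, post_fire: IndexRaster,
                          with_levels: bool = True) -> RecoveryMap:
    """Run the generator over a post-fire raster (tiled with overlap if larger).

    Inference is deterministic (dropout disabled).  The optional level map
    buckets the per-pixel vegetation-class shift between the generated and
    the input raster into {regressed, stable, recovering, recovered}.
    """
    s = model.cfg.image_size
    vals = post_fire.values.copy()
    vals[post_fire.nodata_mask] = 0.0
    h, w = vals.shape
    if h < s or w < s:
        raise InputError(f"raster {vals.shape} smaller than model tile {s}")
    out = np.zeros((h, w))
    weight = np.zeros((h, w))
    step = max(1, s // 2)
    rows = sorted({min(r, h - s) for r in range(0, h, step) if r <= h - s} | {h - s})
    cols = sorted({min(c, w - s) for c in range(0, w, step) if c <= w - s} | {w - s})
    for r in rows:
        for c in cols:
            tile = vals[r:r + s, c:c + s]
            if np.all(post_fire.nodata_mask[r:r + s, c:c + s]):
                continue
            gen = model.generator.forward(tile[None, None], train=False)[0, 0]
            out[r:r + s, c:c + s] += gen
            weight[r:r + s, c:c + s] += 1.0
    covered = weight > 0
    out[covered] /= weight[covered]
    mask = post_fire.nodata_mask | ~covered
    level = None
    if with_levels:
        scheme = ClassScheme()
        gen_cls = classify_ndvi(IndexRaster(np.clip(out, -1, 1), nodata_mask=mask,
                                            pixel_size_m=post_fire.pixel_size_m), scheme)
        in_cls = classify_ndvi(IndexRaster(post_fire.values, nodata_mask=mask,
                                           pixel_size_m=post_fire.pixel_size_m,
                                           index_name="NDVI"), scheme)
        diff = gen_cls.labels.astype(int) - in_cls.labels.astype(int)
        level = np.select([diff < 0, diff == 0, diff == 1], [0, 1, 2], default=3)
        level[mask] = -1
    return RecoveryMap(values=np.clip(out, -1, 1), source=post_fire,
                       nodata_mask=mask, level_map=level)


# ------------------------------------------------------------- metrics -----

@dataclass
class MetricsReport:
    mae: float
    mse: float
    msle: float
    rmse: float
    huber: float
    delta: float
    residuals: np.ndarray

    def to_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mse": self.mse, "msle": self.msle,
                "rmse": self.rmse, "huber": self.huber, "delta": self.delta}


def huber_loss(residuals: np.ndarray, delta: float) -> float:
    """Mean Huber loss: 1/2 r^2 inside |r| <= delta, delta(|r| - delta/2) beyond."""
    r = np.abs(np.asarray(residuals, float))
    quad = 0.5 * r**2
    lin = delta * (r - 0.5 * delta)
    return float(np.mean(np.where(r <= delta, quad, lin)))


def regression_metrics(y, y_hat, delta: float = 1.0,
                       mask: np.ndarray | None = None) -> MetricsReport:
    """MAE/MSE/MSLE/RMSE/Huber over unmasked pixels.

    MSLE shifts both grids by +1 so logarithms stay defined on [-1, 1] data.
    """
    ya = y.values if isinstance(y, IndexRaster) else np.asarray(y, float)
    pa = y_hat.values if isinstance(y_hat, IndexRaster) else np.asarray(y_hat, float)
    if ya.shape != pa.shape:
        raise InputError("y and y_hat shapes differ")
    if mask is None:
        m_y = y.nodata_mask if isinstance(y, IndexRaster) else np.zeros(ya.shape, bool)
        m_p = y_hat.nodata_mask if isinstance(y_hat, IndexRaster) else np.zeros(pa.shape, bool)
        mask = m_y | m_p
    yv, pv = ya[~mask], pa[~mask]
    res = yv - pv
    mse = float(np.mean(res**2))
    tiny = 1e-9  # keep log defined at exactly -1 after the +1 shift
    msle = float(np.mean((np.log1p(np.clip(yv, -1 + tiny, None))
                          - np.log1p(np.clip(pv, -1 + tiny, None)))**2))
    return MetricsReport(
        mae=float(np.mean(np.abs(res))), mse=mse, msle=msle,
        rmse=float(np.sqrt(mse)), huber=huber_loss(res, delta),
        delta=delta, residuals=res,
    )


def homoscedasticity_check(residuals: np.ndarray, fitted: np.ndarray,
                           plot_path: str | None = None) -> dict:
    """Breusch-Pagan test: regress squared residuals on fitted values.

    The statistic is n*R^2, chi-square with 1 df; the verdict is
    "homoscedastic" when p > 0.05.  Constant fitted values make the
    auxiliary regression undefined -> verdict "degenerate".
    """
    residuals = np.asarray(residuals, float).ravel()
    fitted = np.asarray(fitted, float).ravel()
    if residuals.size != fitted.size:
        raise InputError("residuals and fitted lengths differ")
    if residuals.size < 30:
        raise InputError("homoscedasticity check needs >= 30 observations")
    if np.ptp(fitted) == 0:
        return {"statistic": float("nan"), "p_value": float("nan"),
                "verdict": "degenerate"}
    exog = sm.add_constant(fitted)
    stat, p_value, _, _ = het_breuschpagan(residuals, exog)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(fitted, residuals, s=4, alpha=0.5)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("fitted")
        ax.set_ylabel("residual")
        ax.set_title("Residuals vs. fitted")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    verdict = "homoscedastic" if p_value > 0.05 else "heteroscedastic"
    return {"statistic": float(stat), "p_value": float(p_value), "verdict": verdict}


# ----------------------------------------------------------- persistence ---

def save_gan(model: AdaptiGAN, path: str) -> None:
    arrays = {f"g{i}": p.value for i, p in enumerate(model.generator.params())}
    arrays |= {f"d{i}": p.value for i, p in enumerate(model.discriminator.params())}
    cfg = model.cfg
    manifest = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    np.savez(path, manifest=np.array(json.dumps(manifest)), **arrays)


def load_gan(path: str) -> AdaptiGAN:
    data = np.load(path, allow_pickle=False)
    cfg = GANConfig(**json.loads(str(data["manifest"])))
    model = AdaptiGAN.build(cfg)
    for i, p in enumerate(model.generator.params()):
        p.value[...] = data[f"g{i}"]
    for i, p in enumerate(model.discriminator.params()):
        p.value[...] = data[f"d{i}"]
    return model
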