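"""Bi-temporal vegetation change detection: sparse autoencoder + DEC.

The detector classifies the pre- and post-fire NDVI rasters into the five
vegetation classes, turns every unmasked pixel into a patch feature over the
class map, and clusters the features of *both* epochs with one shared Deep
Embedded Clustering model (k = 5, one cluster per vegetation class).  A
pixel is flagged as changed when its pre- and post-fire cluster labels
disagree; the binary map can be alpha-blended over the pre-fire image.

Sparse autoencoder.  The encoder is a stack of sigmoid dense layers; the
training loss is the mean-squared reconstruction error plus a sparsity
penalty on the bottleneck activations, either

* L1: lambda * sum_i |a_i| (per-sample average over the batch), or
* KL: kl_weight * sum_j KL(rho || rho_hat_j), the Bernoulli KL between the
  target activation rate rho and the batch-mean activation rho_hat_j of
  each bottleneck unit.

Deep Embedded Clustering.  Soft assignments use the Student-t kernel
q_ij proportional to (1 + ||z_i - mu_j||^2 / alpha)^(-(alpha+1)/2) with
alpha = 1; the auxiliary target p_ij = (q_ij^2/f_j) / sum_j'(q_ij'^2/f_j')
with cluster frequencies f_j = sum_i q_ij sharpens high-confidence
assignments.  Training alternates target updates with gradient steps on
KL(P||Q) over both the encoder weights and the centroids, and stops when
fewer than ``tol`` of the points change hard assignment between target
updates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .errors import InputError, TrainingError
from .raster import ClassMap, IndexRaster, ClassScheme, classify_ndvi, rasters_aligned

logger = logging.getLogger(__name__)

_EPS = 1e-7


# ----------------------------------------------------------- configuration

@dataclass
class SparseAEConfig:
    """Sparse-autoencoder hyper-parameters.

    ``layer_widths`` are the encoder widths; the last entry is the
    bottleneck and the decoder mirrors the stack.  ``sparsity_mode`` picks
    the penalty: "l1" (weight ``lam``) or "kl" (target rate ``rho``,
    weight ``kl_weight``).
    """

    layer_widths: tuple[int, ...] = (16, 4)
    sparsity_mode: str = "kl"
    lam: float = 1e-4
    rho: float = 0.1
    kl_weight: float = 0.05
    epochs: int = 150
    learning_rate: float = 1e-2
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0 or self.kl_weight < 0:
            raise InputError("sparsity weights must be non-negative")
        if not 0.0 < self.rho < 1.0:
            raise InputError("rho must lie in (0, 1)")
        if self.sparsity_mode not in ("l1", "kl"):
            raise InputError("sparsity_mode must be 'l1' or 'kl'")


@dataclass
class DECConfig:
    """DEC training schedule on top of the sparse-AE initialization."""

    ae: SparseAEConfig = field(default_factory=SparseAEConfig)
    alpha: float = 1.0
    learning_rate: float = 1e-2
    max_epochs: int = 150
    update_interval: int = 30
    tol: float = 1e-3

    def __post_init__(self):
        if self.alpha <= 0:
            raise InputError("alpha must be positive")


@dataclass
class ChangeDetectConfig:
    patch: int = 3
    k: int = 5
    dec: DECConfig = field(default_factory=DECConfig)
    max_train: int = 4096  # training subsample; assignment always covers all pixels
    scheme: ClassScheme = field(default_factory=ClassScheme)


@dataclass
class ChangeMap:
    binary: np.ndarray
    pre_labels: ClassMap
    post_labels: ClassMap
    nodata_mask: np.ndarray
    pixel_size_m: float

    def __post_init__(self):
        self.binary = np.asarray(self.binary, dtype=bool)
        if np.any(self.binary & self.nodata_mask):
            raise InputError("changed pixels must be unmasked")

    @property
    def shape(self):
        return self.binary.shape


# ------------------------------------------------------------- features ----

def extract_patches(source: IndexRaster | ClassMap, patch: int = 3,
                    scale: float | None = None) -> np.ndarray:
    """Featureize each unmasked pixel as its patch x patch neighbourhood.

    Borders are reflect-padded.  Returns an (n_unmasked, patch^2) matrix in
    raster scan order of the unmasked pixels; ``scale`` divides the values
    (class maps use scale=4 so codes land in [0, 1]).
    """
    if patch < 1 or patch % 2 == 0:
        raise InputError("patch size must be odd and >= 1")
    if isinstance(source, ClassMap):
        grid = source.labels.astype(np.float64)
        mask = source.nodata_mask
        scale = 4.0 if scale is None else scale
    else:
        grid = source.values
        mask = source.nodata_mask
        scale = 1.0 if scale is None else scale
    if min(grid.shape) < patch:
        raise InputError("raster smaller than the patch")
    pad = patch // 2
    padded = np.pad(grid / scale, pad, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(padded, (patch, patch))
    feats = win.reshape(grid.shape[0], grid.shape[1], patch * patch)
    return feats[~mask]


# ----------------------------------------------------- sparse autoencoder --

def _bernoulli_kl(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    rho_hat = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    return rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))


def sparse_ae_loss(x: np.ndarray, x_hat: np.ndarray, activations: np.ndarray,
                   cfg: SparseAEConfig) -> float:
    """Reconstruction MSE plus the configured sparsity penalty.

    ``activations`` are the designated hidden layer's outputs, shaped
    (batch, units) or (units,) for a single sample.
    """
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise InputError("x and x_hat shapes differ")
    a = np.atleast_2d(np.asarray(activations, float))
    recon = float(np.mean((x - x_hat) ** 2))
    if cfg.sparsity_mode == "l1":
        return recon + cfg.lam * float(np.abs(a).sum(axis=1).mean())
    rho_hat = a.mean(axis=0)
    if np.any(rho_hat <= 0) or np.any(rho_hat >= 1):
        logger.warning("mean activations outside (0,1); clamping to [%g, %g]",
                       _EPS, 1 - _EPS)
    return recon + cfg.kl_weight * float(_bernoulli_kl(cfg.rho, rho_hat).sum())


class SparseAutoencoder:
    """Dense autoencoder with sigmoid hidden layers and a sparsity penalty."""

    def __init__(self, n_in: int, cfg: SparseAEConfig):
        if cfg.layer_widths[-1] >= n_in:
            raise InputError("bottleneck width must be smaller than the input width")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [n_in, *cfg.layer_widths]
        enc: list[nn.Layer] = []
        for a, b in zip(widths[:-1], widths[1:]):
            enc += [nn.Dense(a, b, rng), nn.Sigmoid()]
        dec: list[nn.Layer] = []
        rev = widths[::-1]
        for i, (a, b) in enumerate(zip(rev[:-1], rev[1:])):
            dec.append(nn.Dense(a, b, rng))
            if i < len(rev) - 2:
                dec.append(nn.Sigmoid())
        self.encoder = nn.Sequential(enc)
        self.decoder = nn.Sequential(dec)
        self.loss_history: list[float] = []

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(np.asarray(x, float), train=False)

    def _step(self, xb: np.ndarray, opt: nn.Adam) -> float:
        cfg = self.cfg
        z = self.encoder.forward(xb)
        x_hat = self.decoder.forward(z)
        recon, drecon = nn.mse_loss(x_hat, xb)
        n = xb.shape[0]
        if cfg.sparsity_mode == "l1":
            pen = cfg.lam * float(np.abs(z).sum() / n)
            dz_pen = cfg.lam * np.sign(z) / n
        else:
            rho_hat = np.clip(z.mean(axis=0), _EPS, 1 - _EPS)
            pen = cfg.kl_weight * float(_bernoulli_kl(cfg.rho, rho_hat).sum())
            dkl = -cfg.rho / rho_hat + (1 - cfg.rho) / (1 - rho_hat)
            dz_pen = cfg.kl_weight * dkl[None, :] / n
        opt.zero_grad()
        dz = self.decoder.backward(drecon) + dz_pen
        self.encoder.backward(dz)
        opt.step()
        return recon + pen

    def fit(self, x: np.ndarray) -> "SparseAutoencoder":
        cfg = self.cfg
        x = np.asarray(x, float)
        if x.shape[0] < 1:
            raise InputError("no training samples")
        rng = np.random.default_rng(cfg.seed + 1)
        params = self.encoder.params() + self.decoder.params()
        opt = nn.Adam(params, lr=cfg.learning_rate)
        bs = min(cfg.batch_size, x.shape[0])
        for _ in range(cfg.epochs):
            order = rng.permutation(x.shape[0])
            losses = [self._step(x[order[i:i + bs]], opt)
                      for i in range(0, x.shape[0], bs)]
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise TrainingError(
                    f"sparse AE diverged at epoch {len(self.loss_history)}: "
                    f"loss={epoch_loss}")
            self.loss_history.append(epoch_loss)
        return self


def train_sparse_ae(features: np.ndarray, cfg: SparseAEConfig) -> SparseAutoencoder:
    features = np.asarray(features, float)
    ae = SparseAutoencoder(features.shape[1], cfg)
    return ae.fit(features)


# ------------------------------------------------------------------ DEC ----

def soft_assignment(z: np.ndarray, mu: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student-t kernel soft assignment Q (rows sum to 1)."""
    mu = np.atleast_2d(mu)
    if mu.shape[0] < 1:
        raise InputError("need at least one centroid")
    d2 = np.sum((z[:, None, :] - mu[None, :, :]) ** 2, axis=2)
    q = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return q / q.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target P = (q^2/f) normalized per row."""
    f = np.maximum(q.sum(axis=0), _EPS)
    w = q**2 / f
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class DECState:
    encoder: SparseAutoencoder
    centroids: np.ndarray
    soft_assign: np.ndarray
    target: np.ndarray
    alpha: float
    k: int
    kl_history: list[float] = field(default_factory=list)
    # embedding standardization frozen at initialization, so the
    # unit-bandwidth t-kernel sees pairwise distances of order 1 regardless
    # of how tightly the sparsity penalty compresses the codes
    embed_center: np.ndarray | None = None
    embed_scale: float = 1.0

    def embed(self, features: np.ndarray) -> np.ndarray:
        z = self.encoder.encode(features)
        if self.embed_center is not None:
            z = (z - self.embed_center) / self.embed_scale
        return z

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Hard cluster labels for arbitrary feature rows."""
        q = soft_assignment(self.embed(features), self.centroids, self.alpha)
        return np.argmax(q, axis=1)

    def final_kl(self) -> float:
        return self.kl_history[-1] if self.kl_history else float("nan")


def _kl_pq(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * (np.log(np.maximum(p, _EPS)) - np.log(np.maximum(q, _EPS)))))


def dec_gradients(z: np.ndarray, mu: np.ndarray, p: np.ndarray, q: np.ndarray,
                  alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form gradients of KL(P||Q) w.r.t. embeddings and centroids."""
    diff = z[:, None, :] - mu[None, :, :]
    w = (1.0 + np.sum(diff**2, axis=2) / alpha) ** -1
    coef = (alpha + 1.0) / alpha * w * (p - q)
    dz = np.einsum("ij,ijd->id", coef, diff)
    dmu = -np.einsum("ij,ijd->jd", coef, diff)
    return dz, dmu


def _init_centroids(z: np.ndarray, k: int, seed: int) -> np.ndarray:
    """K-means centroids; degenerate data with < k distinct embeddings gets
    one centroid per distinct point (so identical epochs cluster identically
    instead of failing)."""
    if z.shape[0] < 1:
        raise InputError("no samples to cluster")
    distinct = np.unique(z, axis=0)
    if distinct.shape[0] <= k:
        return distinct
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    for attempt in range(5):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt).fit(z)
        if np.all(np.bincount(km.labels_, minlength=k) > 0):
            return km.cluster_centers_
        logger.warning("empty cluster after k-means init, re-seeding (%d)", attempt)
    raise TrainingError("k-means produced an empty cluster in 5 attempts")


def train_dec(features: np.ndarray, k: int, cfg: DECConfig | None = None) -> DECState:
    """Pretrain the sparse AE, k-means-init the centroids, refine by KL(P||Q).

    The target distribution P is recomputed every ``update_interval``
    epochs; training stops when fewer than ``tol`` of the points change
    hard assignment between consecutive target updates.
    """
    cfg = cfg or DECConfig()
    features = np.asarray(features, float)
    ae = train_sparse_ae(features, cfg.ae)
    z0 = ae.encode(features)
    center = z0.mean(axis=0)
    scale = float(z0.std())
    if not np.isfinite(scale) or scale < _EPS:
        scale = 1.0
    z = (z0 - center) / scale
    mu = nn.Param(_init_centroids(z, k, cfg.ae.seed))
    k = mu.value.shape[0]  # degenerate data may support fewer clusters
    if features.shape[0] <= k:
        # one centroid per point: assignment is already optimal, nothing to refine
        q = soft_assignment(z, mu.value, cfg.alpha)
        p = target_distribution(q)
        return DECState(encoder=ae, centroids=mu.value, soft_assign=q,
                        target=p, alpha=cfg.alpha, k=k,
                        kl_history=[_kl_pq(p, q)],
                        embed_center=center, embed_scale=scale)
    opt = nn.Adam(ae.encoder.params() + [mu], lr=cfg.learning_rate)
    q = soft_assignment(z, mu.value, cfg.alpha)
    p = target_distribution(q)
    prev_hard = np.argmax(q, axis=1)
    kl_history: list[float] = []
    for epoch in range(cfg.max_epochs):
        if epoch > 0 and epoch % cfg.update_interval == 0:
            hard = np.argmax(q, axis=1)
            changed = float(np.mean(hard != prev_hard))
            p = target_distribution(q)
            if changed < cfg.tol:
                logger.info("DEC converged at epoch %d (%.4f changed)", epoch, changed)
                break
            prev_hard = hard
        z = (ae.encoder.forward(features) - center) / scale
        q = soft_assignment(z, mu.value, cfg.alpha)
        kl_history.append(_kl_pq(p, q))
        dz, dmu = dec_gradients(z, mu.value, p, q, cfg.alpha)
        opt.zero_grad()
        ae.encoder.backward(dz / scale)
        mu.grad += dmu
        opt.step()
    z = (ae.encode(features) - center) / scale
    q = soft_assignment(z, mu.value, cfg.alpha)
    kl_history.append(_kl_pq(p, q))
    return DECState(encoder=ae, centroids=mu.value, soft_assign=q,
                    target=p, alpha=cfg.alpha, k=k, kl_history=kl_history,
                    embed_center=center, embed_scale=scale)


# ------------------------------------------------------- change detection --

def detect_change(pre: IndexRaster, post: IndexRaster,
                  cfg: ChangeDetectConfig | None = None) -> ChangeMap:
    """Cluster both epochs with one shared DEC model; change = label disagreement.

    Both rasters are thresholded into the five NDVI classes, each unmasked
    pixel becomes a patch feature over its class map, and one DEC model
    (k = 5) assigns every pixel of both epochs a cluster; a pixel changed
    iff its two labels differ.  Swapping pre and post yields the identical
    binary map: the training rows are canonicalized by lexicographic sort,
    so the fitted model does not depend on epoch order.
    """
    cfg = cfg or ChangeDetectConfig()
    rasters_aligned(pre, post)
    valid = pre.valid & post.valid
    cm_pre = classify_ndvi(pre, cfg.scheme)
    cm_post = classify_ndvi(post, cfg.scheme)
    joint_mask = ~valid
    pre_cm = ClassMap(cm_pre.labels, joint_mask, pre.pixel_size_m, cfg.scheme)
    post_cm = ClassMap(cm_post.labels, joint_mask, post.pixel_size_m, cfg.scheme)
    feats_pre = extract_patches(pre_cm, cfg.patch)
    feats_post = extract_patches(post_cm, cfg.patch)
    if feats_pre.shape[0] == 0:
        return ChangeMap(np.zeros(pre.shape, bool), pre_cm, post_cm,
                         joint_mask, pre.pixel_size_m)
    both = np.vstack([feats_pre, feats_post])
    train_rows = both[np.lexsort(both.T[::-1])]  # epoch-order invariant
    if train_rows.shape[0] > cfg.max_train:
        rng = np.random.default_rng(cfg.dec.ae.seed)
        sel = rng.choice(train_rows.shape[0], cfg.max_train, replace=False)
        train_rows = train_rows[np.sort(sel)]
    state = train_dec(train_rows, cfg.k, cfg.dec)
    lab_pre = state.assign(feats_pre)
    lab_post = state.assign(feats_post)
    binary = np.zeros(pre.shape, dtype=bool)
    binary[valid] = lab_pre != lab_post
    return ChangeMap(binary, pre_cm, post_cm, joint_mask, pre.pixel_size_m)


def overlay_change(pre: IndexRaster, cm: ChangeMap,
                   color: tuple[int, int, int] = (255, 0, 0),
                   alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend the change mask over a grayscale render of the pre image."""
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must lie in [0, 1]")
    if cm.shape != pre.shape:
        raise InputError("change map and raster shapes differ")
    gray = np.clip((pre.values + 1.0) * 127.5, 0, 255)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    col = np.asarray(color, dtype=np.float64)
    rgb[cm.binary] = (1.0 - alpha) * rgb[cm.binary] + alpha * col
    return np.round(rgb).astype(np.uint8)


def binary_map_metrics(pred: np.ndarray, truth: np.ndarray,
                       valid: np.ndarray | None = None) -> dict[str, float]:
    """Precision/recall/F1/accuracy/IoU of a binary map against ground truth."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth shapes differ")
    if valid is not None:
        pred, truth = pred[valid], truth[valid]
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    tn = float(np.sum(~pred & ~truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy, "iou": iou}


# ----------------------------------------------------------- persistence ---

def save_dec(state: DECState, path: str) -> None:
    """Archive the DEC model (encoder weights, centroids) with a manifest."""
    arrays = {f"w{i}": p.value for i, p in enumerate(state.encoder.encoder.params())}
    manifest = {
        "k": state.k, "alpha": state.alpha,
        "layer_widths": list(state.encoder.cfg.layer_widths),
        "seed": state.encoder.cfg.seed,
        "n_in": state.encoder.encoder.layers[0].W.value.shape[0],
        "sparsity_mode": state.encoder.cfg.sparsity_mode,
    }
    manifest["embed_scale"] = state.embed_scale
    center = state.embed_center if state.embed_center is not None else \
        np.zeros(state.centroids.shape[1])
    np.savez(path, centroids=state.centroids, embed_center=center,
             manifest=np.array(json.dumps(manifest)), **arrays)


def load_dec(path: str) -> DECState:
    data = np.load(path, allow_pickle=False)
    manifest = json.loads(str(data["manifest"]))
    cfg = SparseAEConfig(layer_widths=tuple(manifest["layer_widths"]),
                         seed=manifest["seed"],
                         sparsity_mode=manifest["sparsity_mode"])
    ae = SparseAutoencoder(manifest["n_in"], cfg)
    for i, p in enumerate(ae.encoder.params()):
        p.value[...] = data[f"w{i}"]
    centroids = data["centroids"]
    q = np.full((1, manifest["k"]), 1.0 / manifest["k"])
    return DECState(encoder=ae, centroids=centroids, soft_assign=q,
                    target=q.copy(), alpha=manifest["alpha"], k=manifest["k"],
                    embed_center=data["embed_center"],
                    embed_scale=manifest.get("embed_scale", 1.0))
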