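"""Deep per-pixel features from a small encoder-decoder network.

A compact U-shaped segmentation network (two resolution levels, skip
connections, a 16-channel final decoder layer and a 1-channel sigmoid head)
is trained on synthetic image/mask pairs with the Generalized Dice loss.
After training, the 16 activation maps of the final decoder layer are
extracted at input resolution and appended to the filter-based features.

The network is implemented directly on numpy (im2col convolutions, manual
backpropagation, Adam) so it is fully deterministic under a seed and
CPU-trainable at desk scale.  Only the contract matters downstream: a
16-channel final decoder layer at input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import affine_transform

GD_EPS = 1e-8  # epsilon inside the class weights of the Generalized Dice loss


# ---------------------------------------------------------------------------
# Generalized Dice loss


def gd_loss(G: np.ndarray, M: np.ndarray) -> float:
    """Generalized Dice loss between per-class truth G and prediction M.

    GD = 1 - 2 * sum_c w_c sum_p G_cp M_cp / sum_c w_c sum_p (G_cp + M_cp),
    with class weights w_c = ((sum_p G_cp / t)^2 + eps)^(-1), t the number
    of classes.  G is binary, M lies in [0,1]; both are (t, ...) arrays.
    """
    G = np.asarray(G, dtype=float)
    M = np.asarray(M, dtype=float)
    if G.shape != M.shape:
        raise ValueError("G and M must share shape (t, n)")
    t = G.shape[0]
    Gf = G.reshape(t, -1)
    Mf = M.reshape(t, -1)
    w = 1.0 / ((Gf.sum(axis=1) / t) ** 2 + GD_EPS)
    num = (w * (Gf * Mf).sum(axis=1)).sum()
    den = (w * (Gf + Mf).sum(axis=1)).sum()
    return float(1.0 - 2.0 * num / den)


def _gd_loss_grad_sigmoid(G1: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    """GD loss and its gradient w.r.t. the sigmoid output s.

    Two classes: vessel map M1 = s, background map M0 = 1 - s, with
    G0 = 1 - G1.  Returns (loss, dLoss/ds) with ds the same shape as s.
    """
    t = 2
    G = np.stack([1.0 - G1, G1]).reshape(t, -1)
    M = np.stack([1.0 - s, s]).reshape(t, -1)
    w = 1.0 / ((G.sum(axis=1) / t) ** 2 + GD_EPS)
    num = (w * (G * M).sum(axis=1)).sum()
    den = (w * (G + M).sum(axis=1)).sum()
    loss = 1.0 - 2.0 * num / den
    # dGD/dM_cp = -2 (w_c G_cp den - num w_c) / den^2
    dM = -2.0 * (w[:, None] * G * den - num * w[:, None]) / den**2
    ds = (dM[1] - dM[0]).reshape(s.shape)
    return float(loss), ds


# ---------------------------------------------------------------------------
# augmentation


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    prob: float = 0.7,
    max_rotation_deg: float = 20.0,
    max_shift_frac: float = 0.10,
    max_zoom_frac: float = 0.10,
    force: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random affine augmentation applied identically to image and mask.

    With probability ``prob`` a single affine combining a rotation in
    [-20, 20] degrees, a per-axis shift of 0-10% of the size and a zoom of
    up to 10% is applied; otherwise both inputs pass through unchanged.
    ``force`` overrides the coin flip (used in tests).
    """
    apply = rng.random() < prob if force is None else force
    if not apply:
        return image.copy(), mask.copy()
    ang = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    zoom = 1.0 + rng.uniform(-max_zoom_frac, max_zoom_frac)
    shift = rng.uniform(-max_shift_frac, max_shift_frac, size=2) * np.array(image.shape)
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s], [s, c]]) / zoom
    center = (np.array(image.shape) - 1) / 2.0
    offset = center - rot @ center - shift
    img_out = affine_transform(image, rot, offset=offset, order=1, mode="reflect")
    mask_out = (
        affine_transform(mask.astype(float), rot, offset=offset, order=0, mode="constant")
        > 0.5
    )
    return img_out, mask_out


def rotate_pair(image, mask, degrees):
    """Deterministic rotation about the image center (mask nearest-neighbor)."""
    ang = np.deg2rad(degrees)
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s], [s, c]])
    center = (np.array(image.shape) - 1) / 2.0
    offset = center - rot @ center
    img_out = affine_transform(image, rot, offset=offset, order=1, mode="reflect")
    mask_out = (
        affine_transform(mask.astype(float), rot, offset=offset, order=0, mode="constant")
        > 0.5
    )
    return img_out, mask_out


# ---------------------------------------------------------------------------
# numpy layers


def _conv_forward(x, W, b):
    """3x3 same convolution. x: (N,C,H,W); W: (Cout, C, 3, 3); b: (Cout,)."""
    N, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * Wd, C * 9)
    Wm = W.reshape(W.shape[0], -1).T  # (C*9, Cout)
    y = cols @ Wm + b
    y = y.reshape(N, H, Wd, -1).transpose(0, 3, 1, 2)
    return y, cols


def _conv_backward(dy, cols, W, x_shape):
    N, C, H, Wd = x_shape
    Cout = W.shape[0]
    dyf = dy.transpose(0, 2, 3, 1).reshape(N * H * Wd, Cout)
    dWm = cols.T @ dyf  # (C*9, Cout)
    dW = dWm.T.reshape(W.shape)
    db = dyf.sum(axis=0)
    dcols = dyf @ W.reshape(Cout, -1)  # (N*H*W, C*9)
    dcols = dcols.reshape(N, H, Wd, C, 3, 3)
    dxp = np.zeros((N, C, H + 2, Wd + 2))
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + H, dj : dj + Wd] += dcols[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _pool2(x):
    N, C, H, W = x.shape
    v = x.reshape(N, C, H // 2, 2, W // 2, 2)
    y = v.max(axis=(3, 5))
    mask = v == y[:, :, :, None, :, None]
    # break ties: keep only the first max in each 2x2 block
    flat = mask.reshape(N, C, H // 2, W // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(mask.shape)
    return y, mask


def _pool2_backward(dy, mask):
    return (mask * dy[:, :, :, None, :, None]).reshape(
        mask.shape[0], mask.shape[1], mask.shape[2] * 2, mask.shape[4] * 2
    )


def _up2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dy):
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the network


@dataclass
class TrainConfig:
    """Training schedule for the deep feature extractor."""

    lr: float = 1e-3
    batch: int = 8
    max_epochs: int = 100
    patience: int = 15
    augment_prob: float = 0.7
    rotation_deg: float = 20.0
    shift_frac: float = 0.10
    zoom_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


#: (name, C_in, C_out) of every 3x3 conv; "head" is 1x1
_ARCH = [
    ("enc1a", 1, 8),
    ("enc1b", 8, 8),
    ("enc2a", 8, 16),
    ("enc2b", 16, 16),
    ("bott", 16, 16),
    ("dec2", 32, 16),
    ("dec1", 24, 16),  # final decoder layer: its 16 ReLU maps are the deep features
]


@dataclass
class Checkpoint:
    """Trained network parameters plus provenance metadata."""

    params: dict
    seed: int
    epochs_run: int
    best_val_loss: float
    history: list = field(default_factory=list)

    def save(self, path):
        path = Path(path)
        arrays = {k: v for k, v in self.params.items()}
        meta = np.array(
            [self.seed, self.epochs_run, self.best_val_loss], dtype=float
        )
        np.savez(path, __meta__=meta, **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(path)
        meta = data["__meta__"]
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            params=params,
            seed=int(meta[0]),
            epochs_run=int(meta[1]),
            best_val_loss=float(meta[2]),
        )


def _init_params(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    params = {}
    for name, cin, cout in _ARCH:
        scale = np.sqrt(2.0 / (cin * 9))
        params[f"{name}.W"] = rng.normal(0, scale, size=(cout, cin, 3, 3))
        params[f"{name}.b"] = np.zeros(cout)
    params["head.W"] = rng.normal(0, np.sqrt(2.0 / 16), size=(1, 16, 1, 1))
    params["head.b"] = np.zeros(1)
    return params


def _forward(params, x, want_grad=False):
    """Forward pass; x is (N,1,H,W) with H,W divisible by 4."""
    cache = {}

    def conv(name, inp):
        y, cols = _conv_forward(inp, params[f"{name}.W"], params[f"{name}.b"])
        r = np.maximum(y, 0)
        if want_grad:
            cache[name] = (cols, y > 0, inp.shape)
        return r

    e1 = conv("enc1b", conv("enc1a", x))
    p1, m1 = _pool2(e1)
    e2 = conv("enc2b", conv("enc2a", p1))
    p2, m2 = _pool2(e2)
    bt = conv("bott", p2)
    u2 = np.concatenate([_up2(bt), e2], axis=1)
    d2 = conv("dec2", u2)
    u1 = np.concatenate([_up2(d2), e1], axis=1)
    d1 = conv("dec1", u1)  # (N,16,H,W) — the deep feature maps
    logits = (
        np.einsum("nchw,oc->nohw", d1, params["head.W"][:, :, 0, 0]) + params["head.b"]
    )
    s = 1.0 / (1.0 + np.exp(-logits))
    if want_grad:
        cache["pools"] = (m1, m2)
        cache["acts"] = (e1, e2, bt, d2, d1, s)
    return s[:, 0], d1, cache


def _backward(params, cache, ds):
    """Backprop from dLoss/ds (N,H,W) to parameter gradients."""
    m1, m2 = cache["pools"]
    e1, e2, bt, d2, d1, s = cache["acts"]
    grads = {}
    dlogit = (ds * s[:, 0] * (1 - s[:, 0]))[:, None]
    grads["head.W"] = np.einsum("nohw,nchw->oc", dlogit, d1)[:, :, None, None]
    grads["head.b"] = dlogit.sum(axis=(0, 2, 3))
    dd1 = np.einsum("nohw,oc->nchw", dlogit, params["head.W"][:, :, 0, 0])

    def conv_back(name, dout):
        cols, relu_mask, x_shape = cache[name]
        dy = dout * relu_mask
        dx, dW, db = _conv_backward(dy, cols, params[f"{name}.W"], x_shape)
        grads[f"{name}.W"] = dW
        grads[f"{name}.b"] = db
        return dx

    du1 = conv_back("dec1", dd1)
    dd2 = _up2_backward(du1[:, :16])
    de1 = du1[:, 16:]
    du2 = conv_back("dec2", dd2)
    dbt = _up2_backward(du2[:, :16])
    de2 = du2[:, 16:]
    dp2 = conv_back("bott", dbt)
    de2 = de2 + _pool2_backward(dp2, m2)
    dp1 = conv_back("enc2a", conv_back("enc2b", de2))
    de1 = de1 + _pool2_backward(dp1, m1)
    conv_back("enc1a", conv_back("enc1b", de1))
    return grads


def _pad_to_multiple(img: np.ndarray, mult: int = 4):
    h, w = img.shape
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def minmax_normalize(img: np.ndarray) -> np.ndarray:
    """Per-image min/max normalization to [0,1]."""
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


def train_network(
    train_pairs: list,
    val_pairs: list,
    config: TrainConfig | None = None,
) -> Checkpoint:
    """Train the encoder-decoder on (Angiogram, VesselMask) pairs.

    Adam at the configured learning rate, mini-batches of ``batch`` frames,
    Generalized Dice loss, early stop when validation loss has not improved
    for ``patience`` epochs (cap ``max_epochs``); the checkpoint with the
    lowest validation loss is returned.  Fully deterministic under the seed.
    """
    cfg = config or TrainConfig()
    if not train_pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg.seed)

    def prep(pairs):
        out = []
        for angio, mask in pairs:
            img = minmax_normalize(np.asarray(angio.pixels if hasattr(angio, "pixels") else angio, dtype=float))
            lab = np.asarray(mask.labels if hasattr(mask, "labels") else mask, dtype=float)
            img, _ = _pad_to_multiple(img)
            lab, _ = _pad_to_multiple(lab)
            out.append((img, lab))
        return out

    train = prep(train_pairs)
    val = prep(val_pairs) if val_pairs else []

    mstate = {k: np.zeros_like(v) for k, v in params.items()}
    vstate = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    b1, b2, eps = 0.9, 0.999, 1e-8

    def val_loss(p):
        if not val:
            return np.nan
        losses = []
        for img, lab in val:
            s, _, _ = _forward(p, img[None, None])
            losses.append(gd_loss(np.stack([1 - lab, lab]), np.stack([1 - s[0], s[0]])))
        return float(np.mean(losses))

    best = {k: v.copy() for k, v in params.items()}
    best_loss = val_loss(params) if val else np.inf
    best_epoch = 0
    history = []

    epochs_run = 0
    for epoch in range(cfg.max_epochs):
        epochs_run = epoch + 1
        order = rng.permutation(len(train))
        epoch_losses = []
        for start in range(0, len(train), cfg.batch):
            idx = order[start : start + cfg.batch]
            imgs, labs = [], []
            for i in idx:
                im, la = augment(
                    train[i][0],
                    train[i][1].astype(bool),
                    rng,
                    prob=cfg.augment_prob,
                    max_rotation_deg=cfg.rotation_deg,
                    max_shift_frac=cfg.shift_frac,
                    max_zoom_frac=cfg.zoom_frac,
                )
                imgs.append(im)
                labs.append(la.astype(float))
            x = np.stack(imgs)[:, None]
            y = np.stack(labs)
            s, _, cache = _forward(params, x, want_grad=True)
            loss, ds = _gd_loss_grad_sigmoid(y, s)
            epoch_losses.append(loss)
            grads = _backward(params, cache, ds)
            step += 1
            for k in params:
                g = grads[k]
                mstate[k] = b1 * mstate[k] + (1 - b1) * g
                vstate[k] = b2 * vstate[k] + (1 - b2) * g * g
                mh = mstate[k] / (1 - b1**step)
                vh = vstate[k] / (1 - b2**step)
                params[k] -= cfg.lr * mh / (np.sqrt(vh) + eps)
        vloss = val_loss(params)
        history.append((float(np.mean(epoch_losses)), vloss))
        ref = vloss if val else float(np.mean(epoch_losses))
        if ref < best_loss - 1e-9:
            best_loss = ref
            best = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
        elif val and epoch - best_epoch >= cfg.patience:
            break

    return Checkpoint(
        params=best,
        seed=cfg.seed,
        epochs_run=epochs_run,
        best_val_loss=float(best_loss),
        history=history,
    )


def predict_proba_map(checkpoint: Checkpoint, image: np.ndarray) -> np.ndarray:
    """Sigmoid vessel probability map from the trained network."""
    img = minmax_normalize(np.asarray(image, dtype=float))
    img, (h, w) = _pad_to_multiple(img)
    s, _, _ = _forward(checkpoint.params, img[None, None])
    return s[0][:h, :w]


def extract_deep_features(checkpoint: Checkpoint, image: np.ndarray) -> np.ndarray:
    """The 16 final-decoder activation maps at input resolution.

    Pure inference: no parameter updates.  Inputs whose shape is not
    divisible by the network's downsampling factor are padded reflectively
    and cropped on output.
    """
    img = minmax_normalize(np.asarray(image, dtype=float))
    img, (h, w) = _pad_to_multiple(img)
    _, d1, _ = _forward(checkpoint.params, img[None, None])
    return d1[0][:, :h, :w]
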