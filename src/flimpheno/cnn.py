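"""LeNet-style CNN on per-cell lifetime-component image stacks.

Each segmented cell becomes a 40x40 multi-channel image (NAD(P)H tau1, tau2,
alpha1, tau_m, intensity and FAD intensity are the available channels);
lifetime channels are scaled by fixed physical ranges (tau: 0-5 ns -> 0-1,
alpha: identity) and intensity channels per-image to [0, 1], so stored models
remain applicable to new scenes.  The network is the classical LeNet-5
layout — two 5x5 convolution + 2x2 max-pool blocks (6 and 16 filters), dense
120 -> 84 -> 2 — trained with softmax cross-entropy and Adam.  The layers are
implemented directly on numpy (im2col convolutions), which keeps training
reproducible and single-threaded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .fitting import FLIMImage
from .features import mean_lifetime_map
from .segmentation import SegmentationLabels

logger = logging.getLogger(__name__)

INPUT_SIZE = 40
TAU_SCALE = 5.0   # ns mapped to [0, 1]

#: channels available for stacking, in canonical order
CHANNEL_ORDER = ["nadh_t1", "nadh_t2", "nadh_a1", "nadh_tm",
                 "nadh_intensity", "fad_intensity"]
#: default channel sets
CHANNEL_SETS = {
    "nadh_all": ["nadh_t1", "nadh_t2", "nadh_a1", "nadh_tm", "nadh_intensity"],
    "nadh_intensity": ["nadh_intensity"],
    "intensities": ["nadh_intensity", "fad_intensity"],
}


@dataclass
class CellImageStack:
    cell_id: int
    label: str
    image: np.ndarray          # (k, 40, 40)
    channels: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.channels)
        if self.image.shape != (k, INPUT_SIZE, INPUT_SIZE):
            raise ValueError(f"stack must be ({k}, 40, 40)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    epochs: int = 80
    batch_size: int = 32
    patience: int = 10           # early stop on validation loss
    val_fraction: float = 0.15
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# --------------------------------------------------------------------------
# cell-image extraction


def _scale_channel(img, name):
    if name.endswith("intensity"):
        m = img.max()
        return img / m if m > 0 else img
    if name.endswith("a1"):
        return img
    return np.clip(img / TAU_SCALE, 0.0, 1.0)


def _fit_to_box(img: np.ndarray) -> np.ndarray:
    """Rescale longest side to 40 preserving aspect, center-pad to 40x40."""
    h, w = img.shape
    s = INPUT_SIZE / max(h, w)
    nh, nw = max(int(round(h * s)), 1), max(int(round(w * s)), 1)
    if (nh, nw) != (h, w):
        img = resize(img, (nh, nw), order=1, preserve_range=True,
                     anti_aliasing=nh < h)
    out = np.zeros((INPUT_SIZE, INPUT_SIZE))
    r0 = (INPUT_SIZE - nh) // 2
    c0 = (INPUT_SIZE - nw) // 2
    out[r0:r0 + nh, c0:c0 + nw] = img
    return out


def channel_maps(nadh: FLIMImage, fad: FLIMImage) -> dict:
    return {"nadh_t1": nadh.tau1, "nadh_t2": nadh.tau2,
            "nadh_a1": nadh.alpha1, "nadh_tm": mean_lifetime_map(nadh),
            "nadh_intensity": nadh.intensity, "fad_intensity": fad.intensity}


def extract_cell_images(nadh: FLIMImage, fad: FLIMImage,
                        labels: SegmentationLabels, channels,
                        groups: dict | None = None,
                        max_bbox: int = 120) -> list:
    """Crop, mask, rescale and channel-scale every segmented cell.

    ``groups`` maps cell id -> phenotype label (defaults to "unknown").
    Cells whose bounding box exceeds ``max_bbox`` pixels on a side are skipped.
    """
    unknown = set(channels) - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    maps = channel_maps(nadh, fad)
    stacks = []
    for cid, (r0, c0, r1, c1) in labels.bboxes.items():
        if max(r1 - r0, c1 - c0) > max_bbox:
            logger.warning("cell %d bbox exceeds %d px; skipped", cid, max_bbox)
            continue
        mask = (labels.cells[r0:r1, c0:c1] == cid)
        planes = []
        for name in channels:
            crop = np.nan_to_num(maps[name][r0:r1, c0:c1], nan=0.0) * mask
            planes.append(_fit_to_box(_scale_channel(crop, name)))
        stacks.append(CellImageStack(
            cell_id=int(cid),
            label="unknown" if groups is None else groups.get(int(cid), "unknown"),
            image=np.stack(planes), channels=list(channels),
            provenance={"bbox": (r0, c0, r1, c1)}))
    return stacks


def stacks_from_arrays(images: np.ndarray, labels, channel_names,
                       channels) -> list:
    """Build CellImageStack objects from raw (n, 6, h, w) parameter images.

    Applies the same fixed channel scaling and 40x40 fitting as
    :func:`extract_cell_images`; used with the simulator's per-cell fast path.
    """
    idx = [channel_names.index(c) for c in channels]
    out = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        planes = [_fit_to_box(_scale_channel(img[j], channel_names[j]))
                  for j in idx]
        out.append(CellImageStack(cell_id=i, label=str(lab),
                                  image=np.stack(planes),
                                  channels=list(channels)))
    return out


# --------------------------------------------------------------------------
# numpy LeNet


def _im2col(x, kh, kw):
    # x: (n, c, h, w) -> (n, out_h*out_w, c*kh*kw)
    n, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, oh, ow, kh, kw), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw), oh, ow


class _Conv:
    def __init__(self, cin, cout, k, rng):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0, scale, (cout, cin, k, k))
        self.b = np.zeros(cout)
        self.k = k

    def forward(self, x):
        self.x = x
        cols, oh, ow = _im2col(x, self.k, self.k)
        self.cols, self.oh, self.ow = cols, oh, ow
        Wf = self.W.reshape(self.W.shape[0], -1)
        out = cols @ Wf.T + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], -1, oh, ow)

    def backward(self, g):
        n, cout, oh, ow = g.shape
        gf = g.reshape(n, cout, oh * ow).transpose(0, 2, 1)  # (n, P, cout)
        Wf = self.W.reshape(cout, -1)
        self.dW = np.einsum("npc,npk->ck", gf, self.cols).reshape(self.W.shape)
        self.db = gf.sum(axis=(0, 1))
        dcols = gf @ Wf                                      # (n, P, c*k*k)
        # fold columns back onto the input
        cin, k = self.x.shape[1], self.k
        dx = np.zeros_like(self.x)
        dcols = dcols.reshape(n, oh, ow, cin, k, k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        x = x[:, :, :h - h % 2, :w - w % 2]
        v = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self.shape = x.shape
        out = v.max(axis=(3, 5))
        self.mask = v == out[:, :, :, None, :, None]
        return out

    def backward(self, g):
        g6 = self.mask * g[:, :, :, None, :, None]
        return g6.reshape(self.shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, fin, fout, rng):
        self.W = rng.normal(0, np.sqrt(2.0 / fin), (fin, fout))
        self.b = np.zeros(fout)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self.x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _Flatten:
    def forward(self, x):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.shape)

    def params(self):
        return []


class LeNet:
    """LeNet-5-sized network for (k, 40, 40) inputs, 2-way softmax output."""

    def __init__(self, input_channels: int, seed: int = 0):
        if input_channels < 1:
            raise ValueError("need at least one input channel")
        rng = np.random.default_rng(seed)
        # 40 -> conv5 -> 36 -> pool -> 18 -> conv5 -> 14 -> pool -> 7
        self.layers = [
            _Conv(input_channels, 6, 5, rng), _ReLU(), _MaxPool2(),
            _Conv(6, 16, 5, rng), _ReLU(), _MaxPool2(),
            _Flatten(),
            _Dense(16 * 7 * 7, 120, rng), _ReLU(),
            _Dense(120, 84, rng), _ReLU(),
            _Dense(84, 2, rng),
        ]
        self.input_channels = input_channels

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x, batch_size: int = 256):
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size])
            out.append(_softmax(logits))
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, x):
        return self.predict_proba(x).argmax(axis=1)


def build_lenet(input_channels: int, seed: int = 0) -> LeNet:
    """Construct the two-conv-block LeNet for 40x40 k-channel cell images."""
    return LeNet(input_channels, seed=seed)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs, y):
    """Mean two-class cross-entropy of predicted probabilities vs labels."""
    p = np.clip(probs[np.arange(y.size), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.state = {}
        self.t = 0
        self.layers = layers

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for pi, (p, gname) in enumerate(layer.params()):
                g = getattr(layer, gname)
                key = (li, pi)
                m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[key] = (m, v)
                mh = m / (1 - self.b1 ** self.t)
                vh = v / (1 - self.b2 ** self.t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _augment(x, rng):
    """Random flips and 90-degree rotations, per sample."""
    out = x.copy()
    for i in range(x.shape[0]):
        if rng.random() < 0.5:
            out[i] = out[i, :, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1, :]
        k = rng.integers(0, 4)
        if k:
            out[i] = np.rot90(out[i], k, axes=(1, 2))
    return out


def stacks_to_arrays(stacks, positive: str):
    X = np.stack([s.image for s in stacks]).astype(np.float64)
    y = np.array([1 if s.label == positive else 0 for s in stacks])
    return X, y


def train_cnn(stacks, config: TrainConfig = TrainConfig(),
              positive: str = "oxphos_inhibited"):
    """Train a LeNet on cell stacks with an internal validation split.

    Cells are partitioned (by cell, no leakage) into train/validation; early
    stopping restores the weights of the best validation-loss epoch.  Returns
    ``(model, history)`` where history is a per-epoch record of losses and
    accuracies.
    """
    X, y = stacks_to_arrays(stacks, positive)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train")
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = (max(int(round(config.val_fraction * n)), 1)
             if config.val_fraction > 0 and n > 5 else 0)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    model = build_lenet(X.shape[1], seed=config.seed)
    opt = _Adam(model.layers, config.learning_rate)
    history = {"epoch": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": []}
    best = (np.inf, None, 0)

    for epoch in range(config.epochs):
        order = rng.permutation(Xtr.shape[0])
        losses = []
        for i in range(0, order.size, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = _augment(Xtr[idx], rng) if config.augment else Xtr[idx]
            with np.errstate(over="ignore", invalid="ignore"):
                logits = model.forward(xb)
            probs = _softmax(logits)
            loss = cross_entropy(probs, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss at epoch {epoch})")
            losses.append(loss)
            g = probs.copy()
            g[np.arange(idx.size), ytr[idx]] -= 1.0
            model.backward(g / idx.size)
            opt.step()
        tr_probs = model.predict_proba(Xtr)
        tr_loss = cross_entropy(tr_probs, ytr)
        tr_acc = float((tr_probs.argmax(1) == ytr).mean())
        if n_val:
            va_probs = model.predict_proba(Xval)
            va_loss = cross_entropy(va_probs, yval)
            va_acc = float((va_probs.argmax(1) == yval).mean())
        else:
            va_loss, va_acc = tr_loss, tr_acc
        history["epoch"].append(epoch)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        logger.info("epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                    epoch, tr_loss, tr_acc, va_loss, va_acc)
        if va_loss < best[0] - 1e-5:
            best = (va_loss, _snapshot(model), epoch)
        elif epoch - best[2] >= config.patience:
            break
    if best[1] is not None:
        _restore(model, best[1])
    return model, history


def _snapshot(model):
    return [[p.copy() for p, _ in layer.params()] for layer in model.layers]


def _restore(model, snap):
    for layer, saved in zip(model.layers, snap):
        for (p, _), s in zip(layer.params(), saved):
            p[...] = s


def evaluate_cnn(model: LeNet, stacks, positive: str = "oxphos_inhibited"):
    """Test-set report (accuracy, AUC from the positive-class probability,
    precision and recall with positive = OXPHOS-inhibited)."""
    from sklearn.metrics import roc_auc_score

    X, y = stacks_to_arrays(stacks, positive)
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / y.size
    report = {
        "accuracy": float(acc),
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        "confusion": [[tn, fp], [fn, tp]],
        "auc": float("nan"),
        "auc_defined": len(np.unique(y)) > 1,
    }
    if report["auc_defined"]:
        report["auc"] = float(roc_auc_score(y, probs[:, 1]))
    return report
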