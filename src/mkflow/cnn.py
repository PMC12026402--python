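"""Two-class CNN separating true CD41⁺ membranes from adherent platelets.

A candidate megakaryocyte that survived the gating cascade is either a
cell with genuine CD41 membrane signal (many spots along the perimeter)
or a CD41⁻ cell carrying a few bright adherent-platelet spots.  The two
patterns are distinguished from the brightfield + CD41 image pair alone.

The network is deliberately small — it trains on hundreds of crops on a
single CPU in minutes:

    input 64×64×2
    → [conv 3×3 (16) + ReLU + maxpool 2×2]
    → [conv 3×3 (32) + ReLU + maxpool 2×2]
    → [conv 3×3 (64) + ReLU + maxpool 2×2]
    → global average pool → dense 2 → softmax

Crops are resampled to 64×64 with aspect-preserving padding and
per-channel min-max normalization: cell *size* is handled by the
morphometry features, the CNN judges signal pattern.  Flip and 90°
rotation augmentation is on by default (flow-cell orientation is
physically arbitrary).  Forward and backward passes are plain NumPy
(im2col convolutions, Adam); training is a pure function of
(data, spec, seed).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .event_model import EventImage, EventSet, PanelConfig

__all__ = [
    "TruthSet",
    "SplitSpec",
    "CnnModelSpec",
    "CnnModel",
    "crop_event",
    "split_truth_set",
    "realized_split_fractions",
    "train_cnn",
    "predict",
    "synthetic_truth_set",
]

POSITIVE = "cd41_pos"
NEGATIVE = "cd41_neg"
CLASS_ORDER = (POSITIVE, NEGATIVE)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Labeled BF+CD41 crops: (N, 2, S, S) float32 in [0, 1]."""

    crops: np.ndarray
    labels: np.ndarray
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.crops = np.asarray(self.crops, np.float32)
        self.labels = np.asarray(self.labels, object)
        if self.crops.ndim != 4 or self.crops.shape[1] != 2:
            raise ValueError("crops must be (N, 2 channels, S, S)")
        if len(self.labels) != len(self.crops):
            raise ValueError("labels must cover every crop")
        unknown = set(self.labels) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.crops)

    @property
    def y(self) -> np.ndarray:
        """Integer labels: 0 = positive class, 1 = negative class."""
        return np.array([CLASS_ORDER.index(l) for l in self.labels])

    def subset(self, idx) -> "TruthSet":
        prov = [self.provenance[i] for i in idx] if self.provenance else None
        return TruthSet(self.crops[idx], self.labels[idx], prov)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test partition specification."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r < 0 for r in self.ratios):
            raise ValueError("split ratios must be non-negative")


@dataclass(frozen=True)
class CnnModelSpec:
    """Architecture + training hyperparameters; deterministic given seed."""

    input_size: int = 64
    in_channels: int = 2
    conv_filters: tuple[int, ...] = (16, 32, 64)
    kernel: int = 3
    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 25
    min_epochs: int = 10
    patience: int = 5
    convergence_gap: float = 0.02
    augment: bool = True
    class_weighted: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# Crop extraction
# ---------------------------------------------------------------------------


def crop_event(
    event: EventImage, panel: PanelConfig, size: int = 64
) -> np.ndarray:
    """BF+CD41 crop: aspect-preserving pad to square, resize, min-max norm."""
    chans = []
    for marker in ("bf", "cd41"):
        r = event.channel(panel.channel(marker)).astype(np.float32)
        h, w = r.shape
        if h != w:
            s = max(h, w)
            pad_h, pad_w = s - h, s - w
            r = np.pad(
                r,
                (
                    (pad_h // 2, pad_h - pad_h // 2),
                    (pad_w // 2, pad_w - pad_w // 2),
                ),
                mode="edge",
            )
        if r.shape[0] != size:
            r = resize(r, (size, size), anti_aliasing=True, preserve_range=True)
        lo, hi = float(r.min()), float(r.max())
        r = (r - lo) / (hi - lo) if hi > lo else np.zeros_like(r)
        chans.append(r.astype(np.float32))
    return np.stack(chans)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    rem = n - sum(counts)
    order = np.argsort([c - e for c, e in zip(counts, exact)])  # largest frac first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def split_truth_set(
    truth: TruthSet, spec: SplitSpec = SplitSpec()
) -> tuple[TruthSet, TruthSet, TruthSet]:
    """Stratified random partition with largest-remainder per-class counts."""
    for cls in CLASS_ORDER:
        if int((truth.labels == cls).sum()) < 10:
            raise ValueError(f"class {cls} has < 10 events; cannot split")
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        groups = [np.flatnonzero(truth.labels == cls) for cls in CLASS_ORDER]
    else:
        groups = [np.arange(len(truth))]
    for idx in groups:
        idx = rng.permutation(idx)
        counts = _largest_remainder(len(idx), spec.ratios)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(idx[start : start + c].tolist())
            start += c
    return tuple(truth.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


def realized_split_fractions(counts, decimals: int = 1) -> tuple[float, ...]:
    """Partition sizes → realized percentages at the stated precision."""
    from .metrics import round_half_up

    total = sum(counts)
    return tuple(round_half_up(100.0 * c / total, decimals) for c in counts)


# ---------------------------------------------------------------------------
# NumPy CNN
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) → (N·H·W, C·9) patches for a same-padded 3×3 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


def _col2im(dcol: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    d = dcol.reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
    out = np.zeros((n, c, h + 2, w + 2), dcol.dtype)
    for di in range(3):
        for dj in range(3):
            out[:, :, di : di + h, dj : dj + w] += d[:, :, :, :, di, dj]
    return out[:, :, 1 : 1 + h, 1 : 1 + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0, scale, size=(c_in * 9, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col(x)
        out = (col @ self.w + self.b).reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (col, x.shape)
        return out

    def backward(self, dout: np.ndarray):
        col, xshape = self._cache
        n, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dw = col.T @ dflat
        self.db = dflat.sum(axis=0)
        return _col2im(dflat @ self.w.T, xshape)

    params = property(lambda self: [("w", self), ("b", self)])


def _maxpool_forward(x: np.ndarray):
    n, f, h, w = x.shape
    xr = x.reshape(n, f, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, f, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, in_shape):
    n, f, h, w = in_shape
    dflat = np.zeros((n, f, h // 2, w // 2, 4), dout.dtype)
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    return (
        dflat.reshape(n, f, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, f, h, w)
    )


class CnnModel:
    """Fitted network; use :func:`predict` or :meth:`predict_proba`."""

    def __init__(self, spec: CnnModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.convs: list[_Conv] = []
        c_in = spec.in_channels
        for c_out in spec.conv_filters:
            self.convs.append(_Conv(c_in, c_out, rng))
            c_in = c_out
        scale = np.sqrt(2.0 / c_in)
        self.wd = rng.normal(0, scale, size=(c_in, 2)).astype(np.float32)
        self.bd = np.zeros(2, np.float32)

    # ---- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._caches = []
        a = x.astype(np.float32)
        for conv in self.convs:
            z = conv.forward(a, train=train)
            relu_mask = z > 0
            z = z * relu_mask
            pooled, idx = _maxpool_forward(z)
            if train:
                self._caches.append((relu_mask, idx, z.shape))
            a = pooled
        self._gap_in_shape = a.shape
        g = a.mean(axis=(2, 3))
        if train:
            self._gap_input = g
        logits = g @ self.wd + self.bd
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        g = self._gap_input
        self.dwd = g.T @ dlogits
        self.dbd = dlogits.sum(axis=0)
        da = dlogits @ self.wd.T
        n, f, h, w = self._gap_in_shape
        da = np.broadcast_to(
            da[:, :, None, None] / (h * w), self._gap_in_shape
        ).astype(np.float32)
        for conv, (relu_mask, idx, zshape) in zip(
            reversed(self.convs), reversed(self._caches)
        ):
            dz = _maxpool_backward(da, idx, zshape)
            dz = dz * relu_mask
            da = conv.backward(dz)

    def predict_proba(self, crops: np.ndarray, batch: int = 256) -> np.ndarray:
        crops = np.asarray(crops, np.float32)
        if crops.ndim != 4 or crops.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"crops must be (N, {self.spec.in_channels}, S, S); got {crops.shape}"
            )
        out = []
        for i in range(0, len(crops), batch):
            logits = self.forward(crops[i : i + batch], train=False)
            out.append(_softmax(logits))
        return np.vstack(out) if out else np.empty((0, 2))

    # ---- parameter plumbing -------------------------------------------

    def _param_list(self):
        params = []
        for i, conv in enumerate(self.convs):
            params.append((f"conv{i}_w", conv, "w", "dw"))
            params.append((f"conv{i}_b", conv, "b", "db"))
        params.append(("dense_w", self, "wd", "dwd"))
        params.append(("dense_b", self, "bd", "dbd"))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(obj, attr).copy() for name, obj, attr, _ in self._param_list()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, obj, attr, _ in self._param_list():
            setattr(obj, attr, state[name].copy())

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name, obj, attr, _ in self._param_list():
            h.update(name.encode())
            h.update(np.ascontiguousarray(getattr(obj, attr)).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        state["_spec_json"] = np.frombuffer(
            json.dumps(asdict(self.spec)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "CnnModel":
        with np.load(path) as data:
            spec_d = json.loads(bytes(data["_spec_json"].tobytes()).decode())
            spec_d["conv_filters"] = tuple(spec_d["conv_filters"])
            spec = CnnModelSpec(**spec_d)
            model = cls(spec)
            model.load_state({k: data[k] for k in data.files if k != "_spec_json"})
        return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, model: CnnModel, lr: float):
        self.model, self.lr, self.t = model, lr, 0
        self.m = {n: np.zeros_like(getattr(o, a)) for n, o, a, _ in model._param_list()}
        self.v = {n: np.zeros_like(getattr(o, a)) for n, o, a, _ in model._param_list()}

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, obj, attr, gattr in self.model._param_list():
            g = getattr(obj, gattr)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            setattr(
                obj,
                attr,
                getattr(obj, attr) - self.lr * mhat / (np.sqrt(vhat) + eps),
            )


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random per-sample 90° rotation and flip (8 orientation group)."""
    codes = rng.integers(0, 8, size=len(x))
    out = x.copy()
    for code in np.unique(codes):
        sel = codes == code
        sub = x[sel]
        k, flip = int(code) % 4, int(code) // 4
        if k:
            sub = np.rot90(sub, k, axes=(2, 3))
        if flip:
            sub = sub[:, :, ::-1, :]
        out[sel] = sub
    return out


def _accuracy_of(model: CnnModel, crops: np.ndarray, y: np.ndarray) -> float:
    proba = model.predict_proba(crops)
    return float((proba.argmax(axis=1) == y).mean())


def train_cnn(
    train: TruthSet, validation: TruthSet, spec: CnnModelSpec = CnnModelSpec()
) -> tuple[CnnModel, pd.DataFrame]:
    """Train the CNN; returns the fitted model and per-epoch accuracy curves.

    Training stops once (after ``min_epochs``) either the train and
    validation accuracy curves have stayed within ``convergence_gap`` of
    each other for ``patience`` consecutive epochs, or validation
    accuracy has not improved for ``patience`` epochs — whichever comes
    first.  The returned model carries the best-validation-epoch weights.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    y_train, y_val = train.y, validation.y
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    model = CnnModel(spec)
    opt = _Adam(model, spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)

    if spec.class_weighted:
        freq = np.bincount(y_train, minlength=2) / len(y_train)
        class_w = (1.0 / np.maximum(freq, 1e-12)).astype(np.float32)
        class_w /= class_w.mean()
    else:
        class_w = np.ones(2, np.float32)

    history = []
    best_val, best_state, best_epoch = -1.0, None, -1
    converged_run, stall = 0, 0
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(train))
        for i in range(0, len(order), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            xb = train.crops[idx]
            if spec.augment:
                xb = _augment_batch(xb, rng)
            yb = y_train[idx]
            logits = model.forward(xb, train=True)
            proba = _softmax(logits)
            w = class_w[yb]
            grad = proba.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad *= (w / w.sum())[:, None]
            model.backward(grad.astype(np.float32))
            opt.step()

        train_acc = _accuracy_of(model, train.crops, y_train)
        val_acc = _accuracy_of(model, validation.crops, y_val)
        history.append({"epoch": epoch, "train_acc": train_acc, "val_acc": val_acc})

        if val_acc > best_val + 1e-12:
            best_val, best_state, best_epoch = val_acc, model.state_dict(), epoch
            stall = 0
        else:
            stall += 1
        converged_run = (
            converged_run + 1
            if abs(train_acc - val_acc) < spec.convergence_gap
            else 0
        )
        if epoch >= spec.min_epochs and (
            converged_run >= spec.patience or stall >= spec.patience
        ):
            break

    if best_state is not None:
        model.load_state(best_state)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


def predict(model: CnnModel, crops: np.ndarray) -> pd.DataFrame:
    """Per-event predicted label and class probabilities."""
    proba = model.predict_proba(crops)
    labels = [CLASS_ORDER[i] for i in proba.argmax(axis=1)]
    return pd.DataFrame(
        {
            "label": labels,
            f"p_{POSITIVE}": proba[:, 0],
            f"p_{NEGATIVE}": proba[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# Synthetic truth-set construction
# ---------------------------------------------------------------------------


def synthetic_truth_set(
    n_pos: int = 412,
    n_neg: int = 382,
    seed: int = 1,
    config=None,
    size: int = 64,
    micro_mk_fraction: float = 0.15,
    defocus_fraction: float = 0.05,
) -> TruthSet:
    """Render a labeled crop set for CNN training/evaluation.

    Positives are MK-class events (a configurable fraction rendered as
    micro-MKs), negatives are platelet-adherent events; a small fraction
    of both classes is rendered slightly defocused, as happens in real
    acquisitions that pass a permissive focus gate.
    """
    from .event_model import DEFAULT_PANEL
    from .synthgen import SyntheticConfig, render_event

    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        if positive:
            label_cls = "micro_mk" if rng.random() < micro_mk_fraction else "mk"
        else:
            label_cls = "platelet_adherent"
        sigma = 1.5 if rng.random() < defocus_fraction else 0.0
        ev = render_event(
            label_cls, rng, config=cfg, panel=DEFAULT_PANEL, object_id=i,
            defocus_sigma=sigma,
        )
        crops.append(crop_event(ev, DEFAULT_PANEL, size=size))
        labels.append(POSITIVE if positive else NEGATIVE)
    return TruthSet(np.stack(crops), np.array(labels, object), provenance=None)
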