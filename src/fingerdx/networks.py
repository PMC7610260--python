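"""Locally connected neural classifiers for spectral fingerprints.

The fingerprint classifier ("SN") is a small feed-forward network with

1. a stack of locally connected 1D layers — convolution-like sliding windows
   whose weights are NOT shared across positions, so each m/z region learns
   its own filter (appropriate for spectra, where the identity of a position
   carries meaning, unlike natural images);
2. a stack of fully connected "feature interaction" layers with rectifier
   activations and dropout, modeling nonlinear dependencies among the
   extracted features; and
3. a softmax layer producing the two class probabilities.

The multi-modal variant ("CSN") concatenates a per-sample clinical-index
vector with the flattened locally connected output at the entry of the
feature-interaction stack, so both modalities influence all downstream
layers.

Everything — forward pass, backpropagation, Adam updates, dropout, early
stopping, and the input-gradient computation used for saliency maps — is
implemented here on NumPy arrays.  All randomness (initialization, batch
shuffling, dropout masks, holdout split) flows from a single integer seed,
and inference is deterministic (dropout disabled), so refitting with the same
seed and data reproduces identical weights and scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ArchitectureError(ValueError):
    """Raised when an architecture specification is internally inconsistent."""


class TrainingError(ValueError):
    """Raised on invalid training inputs (single class, misaligned rows)."""


@dataclass(frozen=True)
class LCBlock:
    """One locally connected 1D block: unshared weights per output position."""

    kernel_width: int = 9
    stride: int = 3
    channels: int = 8
    activation: str = "relu"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Network layout for the SN (clinical_width=0) or CSN (clinical_width>0).

    ``fusion_point`` indexes the fully connected layer whose input is
    concatenated with the clinical vector; 0 (the default) fuses at the entry
    of the feature-interaction stack.  ``lc_layers`` may be empty, giving a
    plain MLP — used for narrow inputs such as a clinical-indexes-only model,
    where a sliding window would be wider than the input itself.
    """

    input_width: int
    # kernel widths chosen so each layer's windows tile its input exactly
    # (881 -> 291 -> 95 -> 29 -> 7): no bin falls outside every receptive field
    lc_layers: tuple[LCBlock, ...] = (
        LCBlock(11, 3, 8), LCBlock(9, 3, 8), LCBlock(11, 3, 16), LCBlock(11, 3, 16))
    fc_layers: tuple[int, ...] = (64, 16)
    dropout_rate: float = 0.5
    input_dropout_rate: float = 0.25
    n_classes: int = 2
    clinical_width: int = 0
    fusion_point: int = 0

    def __post_init__(self) -> None:
        if self.input_width < 1:
            raise ArchitectureError("input_width must be >= 1")
        if not 0 <= self.dropout_rate < 1 or not 0 <= self.input_dropout_rate < 1:
            raise ArchitectureError("dropout rates must be in [0, 1)")
        if self.clinical_width > 0 and not 0 <= self.fusion_point <= len(self.fc_layers):
            raise ArchitectureError("fusion_point must index a fully connected layer")
        width = self.input_width
        for i, blk in enumerate(self.lc_layers):
            if blk.kernel_width > width:
                raise ArchitectureError(
                    f"lc layer {i}: kernel_width {blk.kernel_width} exceeds input width {width}")
            if blk.stride < 1 or blk.kernel_width < 1 or blk.channels < 1:
                raise ArchitectureError(f"lc layer {i}: kernel, stride and channels must be >= 1")
            width = (width - blk.kernel_width) // blk.stride + 1

    def lc_output_widths(self) -> list[int]:
        widths, w = [], self.input_width
        for blk in self.lc_layers:
            w = (w - blk.kernel_width) // blk.stride + 1
            widths.append(w)
        return widths

    @property
    def flat_width(self) -> int:
        if not self.lc_layers:
            return self.input_width
        return self.lc_output_widths()[-1] * self.lc_layers[-1].channels


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _LocallyConnected1D:
    """Weights W[p, c_out, c_in, k], bias b[p, c_out]; no weight sharing."""

    def __init__(self, in_width: int, in_channels: int, blk: LCBlock, rng: np.random.Generator):
        self.blk = blk
        self.out_positions = (in_width - blk.kernel_width) // blk.stride + 1
        fan_in = blk.kernel_width * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale,
                            size=(self.out_positions, blk.channels, in_channels, blk.kernel_width))
        self.b = np.zeros((self.out_positions, blk.channels))
        self.in_width = in_width
        self.in_channels = in_channels

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        # x: (B, C_in, W_in) -> windows (B, C_in, P, K)
        win = sliding_window_view(x, self.blk.kernel_width, axis=2)[:, :, ::self.blk.stride, :]
        z = np.einsum("bipk,pcik->bcp", win, self.W, optimize=True) + self.b.T[None]
        return z, (x, win)

    def backward(self, dz: np.ndarray, cache: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, win = cache
        dW = np.einsum("bcp,bipk->pcik", dz, win, optimize=True)
        db = np.einsum("bcp->pc", dz)
        dwin = np.einsum("bcp,pcik->bipk", dz, self.W, optimize=True)
        dx = np.zeros_like(x)
        k, s = self.blk.kernel_width, self.blk.stride
        for p in range(self.out_positions):
            dx[:, :, p * s:p * s + k] += dwin[:, :, p, :]
        return dx, dW, db


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x @ self.W + self.b, x

    def backward(self, dz: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return dz @ self.W.T, x.T @ dz, dz.sum(axis=0)


@dataclass
class TrainConfig:
    """Optimization settings; all stochastic elements derive from ``seed``.

    The default schedule trains for the full 80-epoch cap (patience equals
    the cap, so the early-stop rule cannot fire before it) while still
    restoring the weights that minimized holdout cross-entropy — an 80-epoch
    stop with best-epoch restoration.  Set a smaller
    ``early_stop_patience`` to stop as soon as the monitor stalls.
    """

    max_epochs: int = 80
    batch_size: int = 32
    learning_rate: float = 3e-3
    weight_decay: float = 1.0
    early_stop_patience: int = 80
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("early_stop_patience must be <= max_epochs")
        if not 0 <= self.holdout_fraction < 0.5:
            raise ValueError("holdout_fraction must be in [0, 0.5)")


class SNClassifier:
    """A (possibly multi-modal) locally connected softmax classifier.

    Build with :func:`build_model` or :func:`build_csn`; fit with
    :meth:`fit`; score with :meth:`predict_scores`.  ``input_gradient``
    exposes the gradient of the case-class logit with respect to the inputs,
    the primitive behind saliency maps.
    """

    def __init__(self, arch: ArchitectureSpec, init_seed: int = 0):
        self.arch = arch
        self._build(init_seed)
        self.history: list[dict] = []
        self.fitted = False
        self._x_mean = None
        self._x_sd = None
        self._x_median = None
        self._c_mean = None
        self._c_sd = None
        self._c_median = None

    def _build(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.lc = []
        width, channels = self.arch.input_width, 1
        for blk in self.arch.lc_layers:
            layer = _LocallyConnected1D(width, channels, blk, rng)
            self.lc.append(layer)
            width, channels = layer.out_positions, blk.channels
        self.fc = []
        n_in = self.arch.flat_width
        fusion = self.arch.fusion_point if self.arch.clinical_width > 0 else None
        for i, units in enumerate(self.arch.fc_layers):
            if fusion == i:
                n_in += self.arch.clinical_width
            self.fc.append(_Dense(n_in, units, rng))
            n_in = units
        if fusion == len(self.arch.fc_layers):
            n_in += self.arch.clinical_width
        self.out = _Dense(n_in, self.arch.n_classes, rng)

    # ---- parameter plumbing -------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        ps = []
        for layer in [*self.lc, *self.fc, self.out]:
            ps.extend([layer.W, layer.b])
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self._params())

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, clinical: np.ndarray | None,
                 dropout_rng: np.random.Generator | None = None):
        """Returns (logits, caches). Dropout active only when a rng is given."""
        caches = {"lc": [], "fc": [], "drop": []}
        fusion = self.arch.fusion_point if self.arch.clinical_width > 0 else None
        if dropout_rng is not None and self.arch.input_dropout_rate > 0:
            # dropout on the input bins forces redundant use of informative
            # features instead of a minimal subset
            keep = 1.0 - self.arch.input_dropout_rate
            X = X * ((dropout_rng.random(X.shape) < keep) / keep)
        if self.lc:
            h = X[:, None, :]  # (B, 1, W)
            for layer in self.lc:
                z, cache = layer.forward(h)
                caches["lc"].append((cache, z))
                h = _relu(z)
            flat = h.reshape(h.shape[0], -1)
            caches["flat_shape"] = h.shape
        else:
            flat = X
            caches["flat_shape"] = None
        h = flat
        for i, layer in enumerate(self.fc):
            if fusion == i:
                caches["fuse_at"] = (i, h.shape[1])
                h = np.concatenate([h, clinical], axis=1)
            z, x_in = layer.forward(h)
            a = _relu(z)
            if dropout_rng is not None and self.arch.dropout_rate > 0:
                keep = 1.0 - self.arch.dropout_rate
                mask = (dropout_rng.random(a.shape) < keep) / keep
                a = a * mask
            else:
                mask = None
            caches["fc"].append((x_in, z, mask))
            h = a
        if fusion == len(self.fc):
            caches["fuse_at"] = (len(self.fc), h.shape[1])
            h = np.concatenate([h, clinical], axis=1)
        logits, x_in = self.out.forward(h)
        caches["out"] = x_in
        return logits, caches

    def _backward(self, dlogits: np.ndarray, caches,
                  want_param_grads: bool = True):
        """Backprop ``dlogits`` to inputs; returns (dX, dclinical, grads)."""
        grads = []
        fuse = caches.get("fuse_at")
        dclin = None
        dh, dW, db = self.out.backward(dlogits, caches["out"])
        if want_param_grads:
            grads[:0] = [dW, db]
        if fuse is not None and fuse[0] == len(self.fc):
            dh, dclin = dh[:, :fuse[1]], dh[:, fuse[1]:]
        for i in range(len(self.fc) - 1, -1, -1):
            x_in, z, mask = caches["fc"][i]
            if mask is not None:
                dh = dh * mask
            dz = dh * (z > 0)
            dh, dW, db = self.fc[i].backward(dz, x_in)
            if want_param_grads:
                grads[:0] = [dW, db]
            if fuse is not None and fuse[0] == i:
                dh, dclin = dh[:, :fuse[1]], dh[:, fuse[1]:]
        if self.lc:
            dh = dh.reshape(caches["flat_shape"])
            for i in range(len(self.lc) - 1, -1, -1):
                cache, z = caches["lc"][i]
                dz = dh * (z > 0)
                dh, dW, db = self.lc[i].backward(dz, cache)
                if want_param_grads:
                    grads[:0] = [dW, db]
            dX = dh[:, 0, :]
        else:
            dX = dh
        return dX, dclin, grads

    # ---- preprocessing ------------------------------------------------------

    def _fit_scalers(self, X: np.ndarray, clinical: np.ndarray | None) -> None:
        # median imputation handles NaN (e.g. a clinical table fed as the
        # primary input); fingerprints are normally complete and unaffected
        self._x_median = np.nanmedian(X, axis=0)
        self._x_median = np.where(np.isnan(self._x_median), 0.0, self._x_median)
        filled = np.where(np.isnan(X), self._x_median, X)
        self._x_mean = filled.mean(axis=0)
        sd = filled.std(axis=0)
        self._x_sd = np.where(sd > 0, sd, 1.0)
        if clinical is not None:
            self._c_median = np.nanmedian(clinical, axis=0)
            self._c_median = np.where(np.isnan(self._c_median), 0.0, self._c_median)
            filled = np.where(np.isnan(clinical), self._c_median, clinical)
            self._c_mean = filled.mean(axis=0)
            csd = filled.std(axis=0)
            self._c_sd = np.where(csd > 0, csd, 1.0)

    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        X = np.where(np.isnan(X), self._x_median, X)
        return (X - self._x_mean) / self._x_sd

    def _scale_clinical(self, clinical: np.ndarray | None) -> np.ndarray | None:
        if clinical is None:
            return None
        filled = np.where(np.isnan(clinical), self._c_median, clinical)
        return (filled - self._c_mean) / self._c_sd

    def _check_inputs(self, X, clinical, fitted_ok=False):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.arch.input_width:
            raise TrainingError(
                f"expected fingerprint width {self.arch.input_width}, got {X.shape}")
        if self.arch.clinical_width > 0:
            if clinical is None:
                raise TrainingError("this model fuses clinical indexes; clinical block required")
            clinical = np.asarray(clinical, dtype=float)
            if clinical.shape != (X.shape[0], self.arch.clinical_width):
                raise TrainingError(
                    f"expected clinical width {self.arch.clinical_width}, got {clinical.shape}")
        elif clinical is not None:
            raise TrainingError("model has no clinical block but clinical data given")
        return X, clinical

    # ---- training -----------------------------------------------------------

    def fit(self, X, y, clinical=None, cfg: TrainConfig | None = None) -> "SNClassifier":
        """Mini-batch Adam on softmax cross-entropy with dropout and early stop.

        A stratified ``holdout_fraction`` of the data monitors cross-entropy;
        training stops at ``max_epochs`` or after ``early_stop_patience``
        epochs without improvement, whichever comes first, and the best
        weights seen on the monitor are restored.  The per-feature
        standardization (fingerprints: mean/sd; clinical: median-impute then
        z-score) is estimated on the training rows only and stored for
        inference.
        """
        cfg = cfg or TrainConfig()
        X, clinical = self._check_inputs(X, clinical)
        y = np.asarray(y, dtype=int)
        if y.shape != (X.shape[0],):
            raise TrainingError("labels misaligned with inputs")
        if np.unique(y).size < 2:
            raise TrainingError("training labels contain a single class")

        self._build(cfg.seed)
        rng = np.random.default_rng(cfg.seed)
        self._fit_scalers(X, clinical)
        Xs = self._scale_X(X)
        Cs = self._scale_clinical(clinical)

        n = y.size
        n_hold = int(round(n * cfg.holdout_fraction))
        if n_hold >= 2:
            # stratified holdout for the early-stop monitor
            hold = []
            for cls in np.unique(y):
                idx = rng.permutation(np.flatnonzero(y == cls))
                k = max(1, int(round(idx.size * cfg.holdout_fraction)))
                hold.append(idx[:k])
            hold = np.sort(np.concatenate(hold))
        else:
            hold = np.array([], dtype=int)
        train = np.setdiff1d(np.arange(n), hold)

        # Adam state
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        self.history = []
        best_monitor, best_weights, since_best = np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(train)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                xb = Xs[batch]
                cb = Cs[batch] if Cs is not None else None
                yb = y[batch]
                logits, caches = self._forward(xb, cb, dropout_rng=rng)
                probs = _softmax(logits)
                onehot = np.eye(self.arch.n_classes)[yb]
                loss = -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1))
                ep_loss += loss * batch.size
                ep_correct += int(np.sum(probs.argmax(axis=1) == yb))
                dlogits = (probs - onehot) / batch.size
                _, _, grads = self._backward(dlogits, caches)
                t += 1
                params = self._params()
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1 ** t)
                    vhat = v[j] / (1 - beta2 ** t)
                    # decoupled weight decay; biases (odd slots) exempt
                    if cfg.weight_decay and j % 2 == 0:
                        p -= cfg.learning_rate * cfg.weight_decay * p
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            entry = {"epoch": epoch, "train_loss": ep_loss / order.size,
                     "train_acc": ep_correct / order.size}
            if hold.size:
                logits, _ = self._forward(Xs[hold], Cs[hold] if Cs is not None else None)
                probs = _softmax(logits)
                onehot = np.eye(self.arch.n_classes)[y[hold]]
                entry["holdout_loss"] = float(
                    -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))
                entry["holdout_acc"] = float(np.mean(probs.argmax(axis=1) == y[hold]))
                monitor = entry["holdout_loss"]
            else:
                monitor = entry["train_loss"]
            self.history.append(entry)
            if monitor < best_monitor - 1e-6:
                best_monitor = monitor
                best_weights = [p.copy() for p in self._params()]
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
        if best_weights is not None:
            for p, w in zip(self._params(), best_weights):
                p[...] = w
        self.fitted = True
        self.train_config = cfg
        return self

    # ---- inference ----------------------------------------------------------

    def predict_scores(self, X, clinical=None) -> np.ndarray:
        """Case-class softmax probability per sample; dropout inactive."""
        if not self.fitted:
            raise TrainingError("model is not fitted")
        X, clinical = self._check_inputs(X, clinical)
        logits, _ = self._forward(self._scale_X(X), self._scale_clinical(clinical))
        return _softmax(logits)[:, 1]

    def case_logit(self, X, clinical=None) -> np.ndarray:
        """Pre-softmax score of the case class (the saliency target)."""
        if not self.fitted:
            raise TrainingError("model is not fitted")
        X, clinical = self._check_inputs(X, clinical)
        logits, _ = self._forward(self._scale_X(X), self._scale_clinical(clinical))
        return logits[:, 1]

    def input_gradient(self, X, clinical=None,
                       target_class: int = 1) -> tuple[np.ndarray, np.ndarray | None]:
        """Gradient of the target-class logit w.r.t. each raw input feature.

        Computed with dropout disabled and chained through the stored
        standardization, so it is the derivative of ``case_logit`` with
        respect to the inputs as supplied.
        """
        if not self.fitted:
            raise TrainingError("model is not fitted")
        X, clinical = self._check_inputs(X, clinical)
        logits, caches = self._forward(self._scale_X(X), self._scale_clinical(clinical))
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        dX, dclin, _ = self._backward(dlogits, caches, want_param_grads=False)
        dX = dX / self._x_sd  # chain rule through standardization
        if dclin is not None:
            dclin = dclin / self._c_sd
        return dX, dclin

    # ---- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing JSON archive: architecture + scalers + weights."""
        state = {
            "arch": {**asdict(self.arch),
                     "lc_layers": [asdict(b) for b in self.arch.lc_layers]},
            "fitted": self.fitted,
            "history": self.history,
            "scalers": {k: (getattr(self, k).tolist() if getattr(self, k) is not None else None)
                        for k in ("_x_mean", "_x_sd", "_x_median",
                                  "_c_mean", "_c_sd", "_c_median")},
            "weights": [p.tolist() for p in self._params()],
        }
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def load(cls, path) -> "SNClassifier":
        with open(path) as fh:
            state = json.load(fh)
        arch_d = dict(state["arch"])
        arch_d["lc_layers"] = tuple(LCBlock(**b) for b in arch_d["lc_layers"])
        arch_d["fc_layers"] = tuple(arch_d["fc_layers"])
        model = cls(ArchitectureSpec(**arch_d))
        for p, w in zip(model._params(), state["weights"]):
            p[...] = np.asarray(w, dtype=float)
        for k, val in state["scalers"].items():
            setattr(model, k, np.asarray(val, dtype=float) if val is not None else None)
        model.history = state["history"]
        model.fitted = state["fitted"]
        return model


def build_model(arch: ArchitectureSpec) -> SNClassifier:
    """Untrained SN shell (fingerprints only)."""
    if arch.clinical_width > 0:
        raise ArchitectureError("clinical_width > 0: use build_csn for the multi-modal variant")
    return SNClassifier(arch)


def build_csn(arch: ArchitectureSpec) -> SNClassifier:
    """Untrained CSN shell (fingerprints + clinical fusion)."""
    if arch.clinical_width < 1:
        raise ArchitectureError("clinical_width must be >= 1 for a CSN; use build_model")
    return SNClassifier(arch)


def default_arch(input_width: int = 881, clinical_width: int = 0) -> ArchitectureSpec:
    """The default SN/CSN layout for 881-bin fingerprints."""
    return ArchitectureSpec(input_width=input_width, clinical_width=clinical_width)


def mlp_arch(input_width: int, fc_layers: tuple[int, ...] = (16, 8),
             dropout_rate: float = 0.25) -> ArchitectureSpec:
    """A locally-connected-free layout for narrow inputs (e.g. clinical-only)."""
    return ArchitectureSpec(input_width=input_width, lc_layers=(),
                            fc_layers=fc_layers, dropout_rate=dropout_rate)


def arch_for_width(input_width: int, clinical_width: int = 0,
                   base_kernel: int = 9, stride: int = 3,
                   channel_plan: tuple[int, ...] = (8, 8, 16, 16)) -> ArchitectureSpec:
    """Locally connected stack sized for ``input_width`` with full coverage.

    Per layer the kernel is widened to ``base_kernel + (w - base_kernel) % stride``
    so that the strided windows tile the layer's input exactly — every bin
    lies inside at least one receptive field, so no input can have an
    identically-zero gradient by construction.  Blocks are added (up to four)
    while the running width supports a kernel; narrower inputs get a pure
    MLP.  At 881 bins this reproduces the default four-block layout
    (kernels 11/9/11/11, widths 881 -> 291 -> 95 -> 29 -> 7).
    """
    blocks = []
    width = input_width
    for ch in channel_plan:
        if width < base_kernel + stride:
            break
        kernel = base_kernel + (width - base_kernel) % stride
        blocks.append(LCBlock(kernel, stride, ch))
        width = (width - kernel) // stride + 1
    if not blocks:
        return ArchitectureSpec(input_width=input_width, lc_layers=(),
                                fc_layers=(16, 8), dropout_rate=0.25,
                                clinical_width=clinical_width)
    return ArchitectureSpec(input_width=input_width, lc_layers=tuple(blocks),
                            clinical_width=clinical_width)
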