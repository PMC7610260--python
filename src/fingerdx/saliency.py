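"""Gradient-saliency feature selection on spectral fingerprints.

A fingerprint lives on a fixed m/z grid, so — like an image on its pixel
grid — it supports saliency maps: the magnitude of the gradient of the
case-class pre-softmax score with respect to each input bin, evaluated per
sample with dropout disabled.  Averaging the per-sample maps over the
discovery cohort scores every bin's importance to the trained classifier;
the top-k bins form the selected metabolite-feature panel, each labelled
up- or down-regulated from the case/control mean intensities.

For visualization the 1-D fingerprint is reshaped onto the smallest square
2-D grid (row-major, zero-padded).  The layout is presentation only: the
network consumes the same 1-D inputs, so the reshape cannot change any
saliency value, and padded cells are flagged and excluded from aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridLayout:
    """Row-major square embedding of n_bins into rows x cols cells."""

    n_bins: int
    rows: int
    cols: int

    @property
    def n_padded(self) -> int:
        return self.rows * self.cols - self.n_bins

    def to_grid(self, vec: np.ndarray) -> np.ndarray:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_bins,):
            raise ValueError(f"expected length {self.n_bins}, got {vec.shape}")
        out = np.zeros(self.rows * self.cols)
        out[: self.n_bins] = vec
        return out.reshape(self.rows, self.cols)

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if grid.shape != (self.rows, self.cols):
            raise ValueError(f"expected shape {(self.rows, self.cols)}, got {grid.shape}")
        return grid.ravel()[: self.n_bins]

    def padded_mask(self) -> np.ndarray:
        mask = np.zeros(self.rows * self.cols, dtype=bool)
        mask[self.n_bins:] = True
        return mask.reshape(self.rows, self.cols)


def make_layout(n_bins: int) -> GridLayout:
    """Smallest square grid holding n_bins cells: rows = cols = ceil(sqrt(n))."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    side = math.isqrt(n_bins)
    if side * side < n_bins:
        side += 1
    return GridLayout(n_bins, side, side)


class LinearScorer:
    """Degenerate depth-0 scorer ``score = w·x + b`` with exact gradient w.

    Implements the same scoring protocol as the trained networks; used to
    validate the saliency machinery analytically (saliency must equal |w|
    for every sample).
    """

    def __init__(self, w: np.ndarray, b: float = 0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)
        self.fitted = True

    def case_logit(self, X, clinical=None) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def input_gradient(self, X, clinical=None, target_class: int = 1):
        X = np.asarray(X, dtype=float)
        return np.tile(self.w, (X.shape[0], 1)), None


def saliency_map(model, X, clinical=None) -> np.ndarray:
    """Per-sample, per-bin saliency: |d case_logit / d input bin|.

    ``model`` is any scorer exposing ``input_gradient`` (a trained SN/CSN or
    a :class:`LinearScorer`).  Clinical-input gradients, when present, are
    not mixed into the fingerprint map; use ``clinical_saliency`` for those.
    """
    if not getattr(model, "fitted", False):
        raise ValueError("model must be trained before computing saliency")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grad, _ = model.input_gradient(X, clinical)
    return np.abs(grad)


def clinical_saliency(model, X, clinical) -> np.ndarray:
    """|gradient| of the case logit w.r.t. each clinical index, per sample."""
    if not getattr(model, "fitted", False):
        raise ValueError("model must be trained before computing saliency")
    _, gclin = model.input_gradient(np.atleast_2d(X), clinical)
    if gclin is None:
        raise ValueError("model has no clinical block")
    return np.abs(gclin)


def aggregate_saliency(maps: np.ndarray) -> np.ndarray:
    """Arithmetic mean saliency per bin over a set of per-sample maps."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.size == 0:
        raise ValueError("cannot aggregate an empty set of saliency maps")
    return maps.mean(axis=0)


@dataclass(frozen=True)
class PanelEntry:
    bin_index: int
    bin_center_mz: float
    aggregate_score: float
    direction: str       # "up" if case mean > control mean on discovery
    fold_change: float   # case mean / control mean


@dataclass(frozen=True)
class FeaturePanel:
    entries: tuple[PanelEntry, ...]

    @property
    def bin_indices(self) -> np.ndarray:
        return np.array([e.bin_index for e in self.entries], dtype=int)

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_index,mz,score,direction,fold_change\n")
            for e in self.entries:
                fh.write(f"{e.bin_index},{e.bin_center_mz:.6f},{e.aggregate_score!r},"
                         f"{e.direction},{e.fold_change!r}\n")


def select_panel(aggregate: np.ndarray, k: int, values: np.ndarray, labels,
                 bin_centers: np.ndarray | None = None) -> FeaturePanel:
    """Top-k bins by aggregate saliency, with regulation direction.

    Ties in the aggregate score break toward the lower bin index.  Direction
    and fold change come from the case/control mean intensities of ``values``
    (the discovery fingerprints on the scale fed to the model, typically
    TIC-normalized).
    """
    aggregate = np.asarray(aggregate, dtype=float)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_bins = aggregate.size
    if k > n_bins:
        raise ValueError(f"k={k} exceeds n_bins={n_bins}")
    if values.shape[1] != n_bins:
        raise ValueError("values width must equal aggregate length")
    if bin_centers is None:
        bin_centers = np.arange(n_bins, dtype=float)
    # stable sort on (-score, index): deterministic tie-break toward low index
    order = np.lexsort((np.arange(n_bins), -aggregate))
    chosen = order[:k]
    case_mean = values[labels == 1].mean(axis=0)
    ctrl_mean = values[labels == 0].mean(axis=0)
    entries = []
    for b in chosen:
        fc = case_mean[b] / ctrl_mean[b] if ctrl_mean[b] > 0 else np.inf
        entries.append(PanelEntry(int(b), float(bin_centers[b]), float(aggregate[b]),
                                  "up" if case_mean[b] > ctrl_mean[b] else "down",
                                  float(fc)))
    return FeaturePanel(tuple(entries))


def panel_recovery(panel: FeaturePanel, truth: list[tuple[int, str]]) -> float:
    """Fraction of planted bins recovered in the selected panel."""
    if not truth:
        raise ValueError("no planted bins to recover")
    planted = {b for b, _ in truth}
    return len(planted & set(panel.bin_indices.tolist())) / len(planted)


def refit_on_panel(panel: FeaturePanel, X_discovery, y_discovery,
                   X_validation, y_validation, seed: int = 0,
                   max_epochs: int = 80):
    """Train a fresh network restricted to the panel's bins and evaluate it.

    Returns a dict with discovery/validation AUC, the discovery Youden
    threshold, and validation sensitivity/specificity at that threshold.
    The check that a selected panel retains most of the discriminative
    signal of the full fingerprint.
    """
    from .evaluation import auc, confusion_at, youden_threshold
    from .networks import SNClassifier, TrainConfig, arch_for_width

    if len(panel) == 0:
        raise ValueError("panel is empty")
    bins = panel.bin_indices
    Xd = np.asarray(X_discovery, dtype=float)[:, bins]
    Xv = np.asarray(X_validation, dtype=float)[:, bins]
    model = SNClassifier(arch_for_width(len(bins)))
    model.fit(Xd, np.asarray(y_discovery, int),
              cfg=TrainConfig(seed=seed, max_epochs=max_epochs,
                              early_stop_patience=max_epochs))
    sd = model.predict_scores(Xd)
    sv = model.predict_scores(Xv)
    thr = youden_threshold(sd, y_discovery)
    sens, spec = confusion_at(sv, y_validation, thr)
    return {
        "model": model,
        "discovery_auc": auc(sd, y_discovery),
        "validation_auc": auc(sv, y_validation),
        "threshold": thr,
        "validation_sensitivity": sens,
        "validation_specificity": spec,
    }
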