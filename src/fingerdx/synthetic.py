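"""Synthetic case-control fingerprint cohorts with planted discriminative bins.

No public data accompany the diagnostic study this package reproduces, so
every downstream stage is exercised on simulated cohorts.  The generator
emulates the shape of a serum-metabolic-fingerprint study: per-sample
fingerprints of 881 m/z bins with log-normal baseline intensities, a
configurable set of planted up/down-regulated bins whose case-group mean is
shifted multiplicatively (additively on the log scale), an optional shared
per-sample scale factor emulating total-ion-current drift, and a matched
clinical-index table with configurable group mean shifts and missing values
injected completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprints import FingerprintMatrix, MzGrid


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates an invariant."""


class SplitError(ValueError):
    """Raised when a cohort cannot be stratified-split."""


@dataclass(frozen=True)
class PlantedBin:
    """One discriminative bin: case log-intensity shifted by +/- log(effect_size)."""

    bin_index: int
    direction: str  # "up" or "down"
    effect_size: float  # multiplicative fold change on the intensity scale, > 0


@dataclass(frozen=True)
class ClinicalIndexSpec:
    """One clinical column: normal with class-specific means, shared sd."""

    name: str
    control_mean: float
    case_mean: float
    sd: float


# Default clinical panel loosely shaped after routine serum chemistry indexes
# (gamma-glutamyl transferase, albumin, albumin/globulin ratio).
DEFAULT_CLINICAL = (
    ClinicalIndexSpec("ggt", 30.0, 45.0, 15.0),
    ClinicalIndexSpec("albumin", 45.0, 43.0, 4.0),
    ClinicalIndexSpec("ag_ratio", 1.6, 1.5, 0.3),
)


def default_planted_bins(n: int = 20, n_bins: int = 881, effect_size: float = 2.0,
                         seed: int = 0) -> tuple[PlantedBin, ...]:
    """A reproducible panel of ``n`` planted bins, alternating up/down."""
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_bins, size=n, replace=False))
    return tuple(
        PlantedBin(int(b), "up" if i % 2 == 0 else "down", effect_size)
        for i, b in enumerate(idx)
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; every draw flows from ``seed``."""

    n_controls: int = 172
    n_cases: int = 172
    n_bins: int = 881
    mz_min: float = 100.0
    mz_max: float = 1000.0
    planted_bins: tuple[PlantedBin, ...] = ()
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 0.5
    tic_log_sd: float = 0.0  # per-sample multiplicative scale drift; 0 disables
    clinical_spec: tuple[ClinicalIndexSpec, ...] = DEFAULT_CLINICAL
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_cases < 1:
            raise CohortConfigError("n_controls and n_cases must be >= 1")
        if self.n_bins < 1:
            raise CohortConfigError("n_bins must be >= 1")
        idx = [p.bin_index for p in self.planted_bins]
        if len(set(idx)) != len(idx):
            raise CohortConfigError("planted_bins: bin indices must be unique")
        for p in self.planted_bins:
            if not 0 <= p.bin_index < self.n_bins:
                raise CohortConfigError(f"planted_bins: index {p.bin_index} out of range")
            if p.effect_size <= 0:
                raise CohortConfigError("planted_bins: effect_size must be > 0")
            if p.direction not in ("up", "down"):
                raise CohortConfigError(f"planted_bins: bad direction {p.direction!r}")
        if not 0 <= self.missing_rate < 1:
            raise CohortConfigError("missing_rate must be in [0, 1)")
        if self.baseline_log_sd <= 0:
            raise CohortConfigError("baseline_log_sd must be > 0")
        if self.tic_log_sd < 0:
            raise CohortConfigError("tic_log_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_controls + self.n_cases

    @property
    def grid(self) -> MzGrid:
        return MzGrid(self.mz_min, self.mz_max, self.n_bins)


@dataclass
class SyntheticCohort:
    """Generated fingerprints, aligned clinical table, labels, and ground truth."""

    fingerprints: FingerprintMatrix
    clinical: pd.DataFrame
    labels: np.ndarray  # 0 = control, 1 = case
    truth: list[tuple[int, str]]
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.fingerprints.n_samples
        if not (len(self.clinical) == n == self.labels.size):
            raise ValueError("fingerprints, clinical and labels must have equal row counts")
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("labels must contain both classes")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint, exhaustive discovery/validation index sets, stratified by label."""

    discovery_indices: np.ndarray
    validation_indices: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.discovery_indices, dtype=int)
        v = np.asarray(self.validation_indices, dtype=int)
        if np.intersect1d(d, v).size:
            raise ValueError("discovery and validation indices overlap")
        object.__setattr__(self, "discovery_indices", d)
        object.__setattr__(self, "validation_indices", v)


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Draw one cohort.

    Per-bin log-intensity is N(baseline_log_mean, baseline_log_sd), independent
    across bins; case rows add +/- log(effect_size) on the planted bins.  When
    ``tic_log_sd > 0`` each sample is additionally scaled by a shared
    log-normal factor, making TIC normalization non-trivial.  Deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_bins
    labels = np.concatenate([np.zeros(cfg.n_controls, int), np.ones(cfg.n_cases, int)])

    log_int = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=(n, p))
    for pb in cfg.planted_bins:
        shift = np.log(pb.effect_size) * (1.0 if pb.direction == "up" else -1.0)
        log_int[labels == 1, pb.bin_index] += shift
    if cfg.tic_log_sd > 0:
        log_int += rng.normal(0.0, cfg.tic_log_sd, size=(n, 1))
    values = np.exp(log_int)

    sample_ids = [f"{'ctrl' if l == 0 else 'case'}{i:04d}" for i, l in enumerate(labels)]
    fp = FingerprintMatrix(values, cfg.grid.bin_centers, sample_ids)

    cols = {}
    for spec in cfg.clinical_spec:
        means = np.where(labels == 1, spec.case_mean, spec.control_mean)
        cols[spec.name] = rng.normal(means, spec.sd)
    clinical = pd.DataFrame(cols, index=sample_ids)
    if cfg.missing_rate > 0 and len(cfg.clinical_spec):
        mask = rng.random(clinical.shape) < cfg.missing_rate
        clinical = clinical.mask(mask)

    truth = [(pb.bin_index, pb.direction) for pb in cfg.planted_bins]
    return SyntheticCohort(fp, clinical, labels, truth, cfg)


def default_interaction_bins(n_pairs: int = 10, n_bins: int = 881,
                             seed: int = 0) -> tuple[PlantedBin, ...]:
    """``n_pairs`` adjacent bin pairs (b, b+1) with no overlap between pairs.

    Adjacent placement puts each interacting pair inside shared locally
    connected windows, mirroring how neighboring peaks co-vary in real
    spectra.
    """
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice((n_bins - 1) // 2, size=n_pairs, replace=False)) * 2
    bins = np.sort(np.concatenate([starts, starts + 1]))
    return tuple(PlantedBin(int(b), "up", 1.0) for b in bins)


def generate_interaction_cohort(cfg: CohortConfig, pair_correlation: float = 0.8,
                                ) -> SyntheticCohort:
    """Cohort whose class signal lives in pairwise products of planted bins.

    Consecutive planted bins are paired; within each pair the two log
    intensities are drawn bivariate-normal with correlation
    ``+pair_correlation`` for cases and ``-pair_correlation`` for controls.
    Every bin's marginal distribution is identical across classes, so linear
    classifiers on the bins see no signal — only models sensitive to feature
    interactions (products) can discriminate.  Any ``effect_size`` on the
    planted bins is additionally applied as a mean shift, allowing mixed
    linear + interaction designs.
    """
    if len(cfg.planted_bins) < 2:
        raise CohortConfigError("interaction cohort needs >= 2 planted bins")
    if not 0 < pair_correlation < 1:
        raise CohortConfigError("pair_correlation must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_bins
    labels = np.concatenate([np.zeros(cfg.n_controls, int), np.ones(cfg.n_cases, int)])
    log_int = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=(n, p))

    planted_idx = [pb.bin_index for pb in cfg.planted_bins]
    pairs = [(planted_idx[i], planted_idx[i + 1])
             for i in range(0, len(planted_idx) - 1, 2)]
    sd = cfg.baseline_log_sd
    for b1, b2 in pairs:
        # redraw the pair with class-dependent correlation sign
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        rho = np.where(labels == 1, pair_correlation, -pair_correlation)
        corr = rho * z1 + np.sqrt(1 - rho ** 2) * z2
        log_int[:, b1] = cfg.baseline_log_mean + sd * z1
        log_int[:, b2] = cfg.baseline_log_mean + sd * corr
    for pb in cfg.planted_bins:
        if pb.effect_size != 1.0:
            shift = np.log(pb.effect_size) * (1.0 if pb.direction == "up" else -1.0)
            log_int[labels == 1, pb.bin_index] += shift
    if cfg.tic_log_sd > 0:
        log_int += rng.normal(0.0, cfg.tic_log_sd, size=(n, 1))
    values = np.exp(log_int)

    sample_ids = [f"{'ctrl' if l == 0 else 'case'}{i:04d}" for i, l in enumerate(labels)]
    fp = FingerprintMatrix(values, cfg.grid.bin_centers, sample_ids)
    cols = {}
    for spec in cfg.clinical_spec:
        means = np.where(labels == 1, spec.case_mean, spec.control_mean)
        cols[spec.name] = rng.normal(means, spec.sd)
    clinical = pd.DataFrame(cols, index=sample_ids)
    if cfg.missing_rate > 0 and len(cfg.clinical_spec):
        mask = rng.random(clinical.shape) < cfg.missing_rate
        clinical = clinical.mask(mask)
    truth = [(pb.bin_index, pb.direction) for pb in cfg.planted_bins]
    return SyntheticCohort(fp, clinical, labels, truth, cfg)


def split_cohort(cohort: SyntheticCohort, validation_fraction: float = 0.2,
                 seed: int = 0) -> CohortSplit:
    """Stratified discovery/validation split.

    The validation size is ``round(n * validation_fraction)`` overall,
    apportioned across classes by largest fractional remainder (ties toward
    the control class).  A balanced 172/172 cohort at fraction 0.2 therefore
    yields the 275/69 discovery/validation shape with per-class validation
    counts 35 controls / 34 cases and discovery counts 137 / 138.
    """
    if not 0 < validation_fraction < 1:
        raise SplitError("validation_fraction must be in (0, 1)")
    labels = cohort.labels
    rng = np.random.default_rng(seed)
    classes = [np.flatnonzero(labels == cls) for cls in (0, 1)]
    for cls, idx in enumerate(classes):
        if idx.size < 2:
            raise SplitError(f"class {cls} has fewer than 2 members")
    n_val_total = int(round(labels.size * validation_fraction))
    n_val_total = min(max(n_val_total, 2), labels.size - 2)
    exact = [idx.size * validation_fraction for idx in classes]
    n_val = [int(np.floor(e)) for e in exact]
    # largest-remainder apportionment; ties resolved toward class 0
    order = sorted(range(2), key=lambda c: (-(exact[c] - n_val[c]), c))
    for c in order:
        if sum(n_val) >= n_val_total:
            break
        n_val[c] += 1
    val_parts, disc_parts = [], []
    for cls, idx in enumerate(classes):
        k = min(max(n_val[cls], 1), idx.size - 1)
        perm = rng.permutation(idx)
        val_parts.append(np.sort(perm[:k]))
        disc_parts.append(np.sort(perm[k:]))
    return CohortSplit(np.sort(np.concatenate(disc_parts)),
                       np.sort(np.concatenate(val_parts)))


def ground_truth(cohort: SyntheticCohort) -> list[tuple[int, str]]:
    """The planted (bin_index, direction) panel, exactly as configured."""
    return list(cohort.truth)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write fingerprints (TSV), clinical (CSV), labels (CSV), truth (CSV)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    cohort.fingerprints.to_tsv(os.path.join(out_dir, "fingerprints.tsv"))
    cohort.clinical.to_csv(os.path.join(out_dir, "clinical.csv"), index_label="sample_id")
    pd.DataFrame({"sample_id": cohort.fingerprints.sample_ids,
                  "label": cohort.labels}).to_csv(
        os.path.join(out_dir, "labels.csv"), index=False)
    pd.DataFrame(cohort.truth, columns=["bin_index", "direction"]).to_csv(
        os.path.join(out_dir, "truth.csv"), index=False)
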