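"""Spectral binning onto a fixed m/z grid.

A serum metabolic fingerprint (SMF) is the vector of ion intensities of one
sample's mass spectrum accumulated onto a fixed grid of m/z bins.  The default
grid covers 100-1000 Da in 881 uniform bins, so every sample is represented by
the same 881 features regardless of which peaks its spectrum happens to
contain.  This module reads peak lists (two-column text or centroided mzML),
bins them, applies total-ion-current normalization, and computes the cosine
similarity used for acquisition-reproducibility checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class SpectrumParseError(ValueError):
    """Raised when a peak-list file cannot be parsed."""


class NormalizationError(ValueError):
    """Raised when a fingerprint cannot be normalized (zero total intensity)."""


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list: strictly increasing m/z with nonnegative intensity."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class MzGrid:
    """Uniform partition of [mz_min, mz_max] into n_bins half-open intervals.

    Bin ``i`` covers ``[mz_min + i*w, mz_min + (i+1)*w)`` with
    ``w = (mz_max - mz_min) / n_bins``; the last bin is closed at ``mz_max`` so
    a peak exactly at the upper edge is kept.
    """

    mz_min: float = 100.0
    mz_max: float = 1000.0
    n_bins: int = 881

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def bin_width(self) -> float:
        return (self.mz_max - self.mz_min) / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        w = self.bin_width
        return self.mz_min + w * (np.arange(self.n_bins) + 0.5)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.mz_min, self.mz_max, self.n_bins + 1)

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per m/z; -1 for values outside [mz_min, mz_max]."""
        mz = np.asarray(mz, dtype=float)
        idx = np.floor((mz - self.mz_min) / self.bin_width).astype(int)
        idx = np.where(np.isclose(mz, self.mz_max), self.n_bins - 1, idx)
        outside = (mz < self.mz_min) | (mz > self.mz_max)
        return np.where(outside, -1, idx)


@dataclass
class FingerprintMatrix:
    """Samples x bins intensity matrix on a fixed grid."""

    values: np.ndarray
    bin_centers: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bins)")
        if self.values.shape[1] != self.bin_centers.size:
            raise ValueError("column count must equal number of bin centers")
        if np.any(self.values < 0):
            raise ValueError("fingerprint intensities must be nonnegative")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids must match number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | os.PathLike) -> None:
        header = "sample_id\t" + "\t".join(f"{c:.6f}" for c in self.bin_centers)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FingerprintMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            centers = np.array([float(c) for c in header[1:]])
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(np.array(rows, dtype=float), centers, ids)


def load_spectrum(path: str | os.PathLike, dialect: str = "two_column_text",
                  sample_id: str | None = None) -> Spectrum:
    """Read a peak list from disk.

    ``two_column_text`` expects whitespace- or tab-separated ``m/z intensity``
    lines (blank lines and ``#`` comments ignored); ``mzml`` reads the first
    centroided spectrum of an mzML file via pyteomics.  Peaks are returned
    sorted by m/z with duplicate m/z entries merged by intensity sum.
    """
    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    if dialect == "two_column_text":
        mzs, intens = [], []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
                try:
                    mz, inten = float(parts[0]), float(parts[1])
                except ValueError as exc:
                    raise SpectrumParseError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
                if inten < 0:
                    raise SpectrumParseError(f"{path}:{lineno}: negative intensity {inten}")
                mzs.append(mz)
                intens.append(inten)
        mz_arr = np.array(mzs, dtype=float)
        in_arr = np.array(intens, dtype=float)
    elif dialect == "mzml":
        mz_arr, in_arr = _read_mzml_first_spectrum(path)
        if np.any(in_arr < 0):
            raise SpectrumParseError(f"{path}: negative intensity in mzML spectrum")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'two_column_text' or 'mzml'")

    if mz_arr.size == 0:
        return Spectrum(np.array([]), np.array([]), sid)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, in_arr = mz_arr[order], in_arr[order]
    # merge exact-duplicate m/z by summing intensity
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, in_arr)
    return Spectrum(uniq, summed, sid)


def _read_mzml_first_spectrum(path) -> tuple[np.ndarray, np.ndarray]:
    """Decode the first spectrum of a centroided mzML file.

    Supports the common encodings: 64/32-bit float binary arrays, plain or
    zlib-compressed.  Only the m/z and intensity arrays are read.
    """
    import base64
    import zlib as _zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = etree.parse(os.fspath(path))
    spectrum = tree.find(f".//{ns}spectrum")
    if spectrum is None:
        return np.array([]), np.array([])
    arrays: dict[str, np.ndarray] = {}
    for bda in spectrum.iter(f"{ns}binaryDataArray"):
        accessions = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
        dtype = np.float64 if "MS:1000523" in accessions else np.float32
        which = ("mz" if "MS:1000514" in accessions
                 else "intensity" if "MS:1000515" in accessions else None)
        if which is None:
            continue
        binary = bda.find(f"{ns}binary")
        raw = base64.b64decode((binary.text or "").strip())
        if "MS:1000574" in accessions:  # zlib compression
            raw = _zlib.decompress(raw)
        arrays[which] = np.frombuffer(raw, dtype=dtype).astype(float)
    if "mz" not in arrays or "intensity" not in arrays:
        raise SpectrumParseError(f"{path}: mzML spectrum lacks m/z or intensity array")
    if arrays["mz"].size != arrays["intensity"].size:
        raise SpectrumParseError(f"{path}: mzML array length mismatch")
    return arrays["mz"], arrays["intensity"]


def bin_spectrum(spectrum: Spectrum, grid: MzGrid) -> tuple[np.ndarray, int]:
    """Accumulate peak intensities onto the grid.

    Returns ``(vector, n_dropped)`` where peaks outside ``[mz_min, mz_max]``
    are dropped and tallied.  Intensity is conserved: ``vector.sum()`` plus the
    dropped intensity equals the spectrum's total.
    """
    vec = np.zeros(grid.n_bins, dtype=float)
    if len(spectrum) == 0:
        return vec, 0
    idx = grid.bin_index(spectrum.mz)
    inside = idx >= 0
    np.add.at(vec, idx[inside], spectrum.intensity[inside])
    return vec, int(np.count_nonzero(~inside))


def bin_spectra(spectra: list[Spectrum], grid: MzGrid, normalize: bool = False) -> FingerprintMatrix:
    """Bin a list of spectra into a FingerprintMatrix (optionally TIC-normalized)."""
    rows = []
    for s in spectra:
        vec, _ = bin_spectrum(s, grid)
        if normalize:
            vec = tic_normalize(vec)
        rows.append(vec)
    ids = [s.sample_id or f"S{i}" for i, s in enumerate(spectra)]
    return FingerprintMatrix(np.vstack(rows), grid.bin_centers, ids)


def tic_normalize(vec: np.ndarray) -> np.ndarray:
    """Scale a nonnegative fingerprint to unit sum (total-ion-current normalization)."""
    vec = np.asarray(vec, dtype=float)
    if np.any(vec < 0):
        raise ValueError("fingerprint must be nonnegative")
    total = vec.sum()
    if total <= 0:
        raise NormalizationError("cannot TIC-normalize an all-zero fingerprint")
    return vec / total


def tic_normalize_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise TIC normalization of a samples x bins matrix."""
    values = np.asarray(values, dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise NormalizationError("cannot TIC-normalize rows with zero total intensity")
    return values / totals


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two fingerprints, in [0, 1] for nonnegative input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.dot(a, b) / (na * nb))
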