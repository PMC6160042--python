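"""Discrete-wavelet feature extraction for FAIMS dispersion grids.

The pipeline compresses each linearised sample either with a 1-D DWT of
the whole vector, or — preferred — by reshaping the vector back into its
dispersion grid (compensation-voltage rows × both polarities' dispersion
columns side by side, 512 × 102 at instrument defaults), zero-padding to
a dyadic square and applying a full-depth separable 2-D DWT.

Wavelet family is Daubechies' least-asymmetric ("symlet") family with a
configurable number of vanishing moments (default 10, i.e. ``sym10``),
with periodic boundary handling on the already zero-padded dyadic array.

2-D feature convention
----------------------
For a 2^L × 2^L input the feature vector concatenates, for each scale
``j = L-1`` down to ``0``, the four coefficient sub-grids at that scale
(smooth, horizontal, vertical, diagonal; each 2^j × 2^j, row-major),
followed by the final scale-0 smooth constant.  The smooth band is
recorded at every scale even though it is further decomposed, so the
total length is ``4 * (4^L - 1) / 3 + 1``: 349,525 for 512×512, 87,381
for 256×256 and 21,845 for 128×128.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .io import DEFAULT_COLS, DEFAULT_ROWS, FeatureTable

__all__ = [
    "WaveletSpec",
    "reshape_to_grid",
    "crop_and_pad",
    "dwt2_features",
    "dwt2_feature_ids",
    "dwt2_feature_count",
    "dwt2_inverse",
    "dwt1_features",
    "feature_support",
    "transform_table",
]

_BANDS = ("s", "h", "v", "d")


@dataclass(frozen=True)
class WaveletSpec:
    """Configuration of the wavelet stage.

    mode
        ``none`` (raw features pass through), ``dwt1`` or ``dwt2``.
    crop_rows
        Number of contiguous compensation-voltage rows retained before
        padding to a dyadic square; 512 (no crop), 256 or 128.
    crop_offset
        First retained row; defaults to 0.
    vanishing_moments
        Symlet order; ``sym10`` by default.
    """

    mode: str = "dwt2"
    crop_rows: int = 512
    crop_offset: int = 0
    vanishing_moments: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("none", "dwt1", "dwt2"):
            raise ValueError(f"mode must be none/dwt1/dwt2, got {self.mode!r}")
        if self.crop_rows < 1 or self.crop_rows & (self.crop_rows - 1):
            raise ValueError(f"crop_rows must be a power of two, got {self.crop_rows}")
        if self.vanishing_moments < 1:
            raise ValueError("vanishing_moments must be >= 1")
        if self.crop_offset < 0:
            raise ValueError("crop_offset must be >= 0")

    @property
    def wavelet(self) -> str:
        return f"sym{self.vanishing_moments}"


def reshape_to_grid(vector: np.ndarray, rows: int = DEFAULT_ROWS, cols: int = DEFAULT_COLS) -> np.ndarray:
    """Invert linearisation: vector -> rows × (2*cols) dispersion grid.

    The positive polarity occupies columns ``[0, cols)``, the negative
    polarity columns ``[cols, 2*cols)``; rows are compensation-voltage
    steps.  A 52,224-length vector becomes the 512 × 102 grid.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size != 2 * rows * cols:
        raise ValueError(
            f"vector of length {vector.size} does not factor as 2 x {rows} x {cols}"
        )
    pos = vector[: rows * cols].reshape(rows, cols)
    neg = vector[rows * cols :].reshape(rows, cols)
    return np.hstack([pos, neg])


def crop_and_pad(grid: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Retain ``crop_rows`` contiguous rows, zero-pad to a dyadic square.

    All columns are kept; zeros are appended on the high side so the
    result is the smallest 2^n square covering both dimensions:
    512×512, 256×256 or 128×128 at instrument defaults.
    """
    grid = np.asarray(grid, dtype=float)
    rows, cols = grid.shape
    lo, hi = spec.crop_offset, spec.crop_offset + spec.crop_rows
    if hi > rows:
        raise ValueError(f"crop window [{lo}, {hi}) exceeds grid rows {rows}")
    window = grid[lo:hi]
    side = 1
    while side < max(spec.crop_rows, cols):
        side *= 2
    out = np.zeros((side, side))
    out[: window.shape[0], :cols] = window
    return out


def dwt2_feature_count(side: int) -> int:
    """Closed-form length of the 2-D feature vector for a 2^L side."""
    L = int(np.log2(side))
    return 4 * (4**L - 1) // 3 + 1


def _check_dyadic_square(square: np.ndarray) -> int:
    square = np.asarray(square)
    if square.ndim != 2 or square.shape[0] != square.shape[1]:
        raise ValueError(f"input must be square, got shape {square.shape}")
    side = square.shape[0]
    if side < 2 or side & (side - 1):
        raise ValueError(f"side must be a power of two >= 2, got {side}")
    return side


def dwt2_features(square: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Full-depth separable 2-D DWT feature vector (see module docstring)."""
    side = _check_dyadic_square(square)
    approx = np.asarray(square, dtype=float)
    pieces: list[np.ndarray] = []
    while approx.shape[0] > 1:
        approx, (ch, cv, cd) = pywt.dwt2(approx, spec.wavelet, mode="periodization")
        pieces.extend([approx.ravel(), ch.ravel(), cv.ravel(), cd.ravel()])
    pieces.append(approx.ravel())  # scale-0 smooth constant
    out = np.concatenate(pieces)
    assert out.size == dwt2_feature_count(side)
    return out


def dwt2_feature_ids(side: int) -> list[str]:
    """Identifiers aligned with :func:`dwt2_features` ordering.

    ``d2:j<scale>:<band>:r<row>:c<col>`` with band in s/h/v/d, plus the
    trailing ``d2:final``.
    """
    L = int(np.log2(side))
    ids: list[str] = []
    for j in range(L - 1, -1, -1):
        n = 2**j
        for band in _BANDS:
            prefix = f"d2:j{j}:{band}:"
            ids.extend(f"{prefix}r{r}:c{c}" for r in range(n) for c in range(n))
    ids.append("d2:final")
    return ids


def dwt1_features(vector: np.ndarray, spec: WaveletSpec = WaveletSpec(mode="dwt1")) -> np.ndarray:
    """Full-depth 1-D DWT of the zero-padded vector.

    The input is zero-padded to the next power of two 2^J and decomposed
    to depth J with periodic boundaries; the output concatenates the
    final smooth coefficient and the detail coefficients from coarsest
    to finest, total length 2^J (65,536 for a 52,224-length input).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size == 0:
        raise ValueError("dwt1_features needs a non-empty 1-D vector")
    n = 1
    while n < vector.size:
        n *= 2
    padded = np.zeros(n)
    padded[: vector.size] = vector
    level = int(np.log2(n))
    with warnings.catch_warnings():
        # full-depth decomposition is intentional; pywt warns that the
        # coarsest levels are shorter than the filter
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(padded, spec.wavelet, mode="periodization", level=level)
    return np.concatenate(coeffs)


def dwt2_inverse(features: np.ndarray, side: int, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Reconstruct the padded square from a 2-D feature vector.

    Only the non-redundant subset of the feature vector — the three
    detail subbands at every scale plus the final smooth constant, which
    together form the orthonormal transform — is used; the intermediate
    smooth bands are recomputed implicitly by the inverse transform.
    """
    features = np.asarray(features, dtype=float)
    if features.size != dwt2_feature_count(side):
        raise ValueError(
            f"feature vector of length {features.size} does not match side {side}"
        )
    L = int(np.log2(side))
    details = []
    pos = 0
    for j in range(L - 1, -1, -1):
        n = 2**j
        block = n * n
        pos += block  # skip the redundant smooth band
        triple = tuple(
            features[pos + t * block : pos + (t + 1) * block].reshape(n, n)
            for t in range(3)
        )
        pos += 3 * block
        details.append(triple)
    approx = features[pos:].reshape(1, 1)
    return pywt.waverec2([approx, *details[::-1]], spec.wavelet, mode="periodization")


def _parse_dwt2_id(feature_id: str, side: int) -> tuple[int, str, int, int]:
    L = int(np.log2(side))
    if feature_id == "d2:final":
        return 0, "s", 0, 0
    parts = feature_id.split(":")
    if len(parts) != 5 or parts[0] != "d2":
        raise ValueError(f"not a 2-D wavelet feature id: {feature_id!r}")
    j = int(parts[1][1:])
    band = parts[2]
    r = int(parts[3][1:])
    c = int(parts[4][1:])
    if band not in _BANDS or not (0 <= j < L) or not (0 <= r < 2**j and 0 <= c < 2**j):
        raise ValueError(f"malformed 2-D wavelet feature id: {feature_id!r}")
    return j, band, r, c


def feature_support(
    feature_id: str,
    side: int,
    spec: WaveletSpec = WaveletSpec(),
    rel_threshold: float = 0.01,
) -> np.ndarray:
    """Effective spatial support of one 2-D wavelet coefficient.

    Inverse-transforms an impulse at that coefficient and keeps the grid
    cells whose reconstructed magnitude exceeds ``rel_threshold`` of the
    maximum — the region the coefficient meaningfully responds to.  Used
    to relate selected wavelet features back to dispersion-plot regions.
    """
    j, band, r, c = _parse_dwt2_id(feature_id, side)
    L = int(np.log2(side))
    depth = L - j
    n = 2**j
    approx = np.zeros((n, n))
    details = []
    for jj in range(j, L):
        m = 2**jj
        details.append(tuple(np.zeros((m, m)) for _ in range(3)))
    if band == "s":
        approx[r, c] = 1.0
    else:
        target = dict(h=0, v=1, d=2)[band]
        details[0][target][r, c] = 1.0
    rec = pywt.waverec2([approx, *details], spec.wavelet, mode="periodization")
    assert rec.shape == (side, side) and depth == len(details)
    return np.abs(rec) > rel_threshold * np.abs(rec).max()


def transform_table(
    table: FeatureTable,
    spec: WaveletSpec,
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
) -> FeatureTable:
    """Apply the configured wavelet stage to every sample of a raw table."""
    if spec.mode == "none":
        return table
    if spec.mode == "dwt1":
        values = np.stack([dwt1_features(row, spec) for row in table.values])
        ids = [f"d1:{i}" for i in range(values.shape[1])]
        return FeatureTable(table.sample_ids, ids, values, "dwt1", _validated=True)
    first = crop_and_pad(reshape_to_grid(table.values[0], rows, cols), spec)
    side = first.shape[0]
    out = np.empty((table.n_samples, dwt2_feature_count(side)))
    out[0] = dwt2_features(first, spec)
    for i in range(1, table.n_samples):
        square = crop_and_pad(reshape_to_grid(table.values[i], rows, cols), spec)
        out[i] = dwt2_features(square, spec)
    return FeatureTable(table.sample_ids, dwt2_feature_ids(side), out, "dwt2", _validated=True)
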