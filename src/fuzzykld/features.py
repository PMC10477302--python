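"""HOG and LBP texture descriptors and feature-profile pre-processing.

Gradients use central differences with replicate border padding,

    G_x = I(x+1, y) − I(x−1, y),   G_y = I(x, y+1) − I(x, y−1),

magnitude √(G_x² + G_y²) and unsigned orientation atan2(G_y, G_x) folded
to [0°, 180°).  HOG accumulates magnitude-weighted orientation votes
with linear bin interpolation into 8×8-pixel cells, then normalizes
2×2-cell blocks (L2).  LBP thresholds the 8 square neighbours of each
interior pixel against the centre (difference ≥ 0 → bit 1, so a constant
image codes 255 everywhere), with bit i = 2^i assigned clockwise from
the top-left neighbour, and reports the normalized 256-bin code
histogram.

Two whole-class summaries of sorted descriptor vectors are provided:
the position-wise average profile, and the position-wise (min, max)
envelope that turns a set of vectors into fuzzy intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureVector",
    "FuzzyProfile",
    "to_gray",
    "image_gradients",
    "hog_descriptor",
    "lbp_descriptor",
    "concat_features",
    "sorted_average_profile",
    "fuzzy_interval_profile",
]


@dataclass(frozen=True)
class FeatureVector:
    """An ordered descriptor with a provenance tag (hog | lbp | hog+lbp)."""

    values: np.ndarray
    kind: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("feature values must be a non-empty 1-D vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FuzzyProfile:
    """Position-wise lower/upper envelope of sorted feature vectors."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if lo.shape != up.shape:
            raise ValueError("lower and upper must share a shape")
        if np.any(lo > up + 1e-12):
            raise ValueError("lower must not exceed upper")

    def to_dict(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyProfile":
        return cls(np.asarray(d["lower"]), np.asarray(d["upper"]))


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance conversion 0.299 R + 0.587 G + 0.114 B; pass-through for 2-D."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return (0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2])
    raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")


def image_gradients(img: np.ndarray):
    """Central-difference gradients, magnitude and unsigned orientation.

    Returns (G_x, G_y, magnitude, orientation_deg) with orientation in
    [0°, 180°) and 0 where both gradients vanish.  Borders replicate.
    """
    I = np.asarray(img, dtype=float)
    if I.ndim != 2 or I.shape[0] < 3 or I.shape[1] < 3:
        raise ValueError("image_gradients needs a 2-D image of size >= 3x3")
    P = np.pad(I, 1, mode="edge")
    gx = P[1:-1, 2:] - P[1:-1, :-2]   # I(x+1,y) - I(x-1,y), x = column
    gy = P[2:, 1:-1] - P[:-2, 1:-1]   # I(x,y+1) - I(x,y-1), y = row
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx))
    ang = np.mod(ang, 180.0)          # unsigned orientation
    ang[(gx == 0) & (gy == 0)] = 0.0
    return gx, gy, mag, ang


def hog_descriptor(img: np.ndarray, cell: int = 8, bins: int = 9,
                   block: int = 2, norm: str = "L2") -> FeatureVector:
    """Histogram-of-oriented-gradients descriptor.

    Per 8×8 cell, each pixel votes its gradient magnitude into the two
    orientation bins bracketing its angle (linear interpolation on the
    unsigned 180° circle); 2×2-cell blocks are flattened and L2 (or L1)
    normalized.  Length = n_blocks_y · n_blocks_x · block² · bins.
    """
    I = np.asarray(img, dtype=float)
    if I.ndim != 2 or I.shape[0] < cell or I.shape[1] < cell:
        raise ValueError("image smaller than one cell")
    _, _, mag, ang = image_gradients(I)
    ny, nx = I.shape[0] // cell, I.shape[1] // cell
    mag = mag[: ny * cell, : nx * cell]
    ang = ang[: ny * cell, : nx * cell]

    bin_width = 180.0 / bins
    pos = ang / bin_width                  # bin centres at 0°, 20°, ...
    b0 = np.floor(pos).astype(int)
    w1 = pos - b0
    b1 = np.mod(b0 + 1, bins)
    b0 = np.mod(b0, bins)

    cy = np.arange(ny * cell) // cell
    cx = np.arange(nx * cell) // cell
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    hist = np.zeros((ny, nx, bins))
    np.add.at(hist, (cyy, cxx, b0), mag * (1.0 - w1))
    np.add.at(hist, (cyy, cxx, b1), mag * w1)

    nby, nbx = ny - block + 1, nx - block + 1
    if nby < 1 or nbx < 1:
        raise ValueError("image too small for one block")
    out = np.empty((nby, nbx, block * block * bins))
    for by in range(nby):
        for bx in range(nbx):
            v = hist[by:by + block, bx:bx + block].ravel()
            if norm == "L2":
                nrm = np.sqrt((v ** 2).sum())
            elif norm == "L1":
                nrm = np.abs(v).sum()
            else:
                raise ValueError("norm must be 'L2' or 'L1'")
            out[by, bx] = v / nrm if nrm > 0 else v
    return FeatureVector(out.ravel(), "hog")


#: 8-neighbour offsets (row, col), clockwise from the top-left; bit i = 2^i
LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_codes(img: np.ndarray) -> np.ndarray:
    """Per-interior-pixel 8-bit local binary pattern codes."""
    I = np.asarray(img, dtype=float)
    if I.ndim != 2 or I.shape[0] < 3 or I.shape[1] < 3:
        raise ValueError("lbp needs a 2-D image of size >= 3x3")
    centre = I[1:-1, 1:-1]
    codes = np.zeros_like(centre, dtype=np.int64)
    for i, (dr, dc) in enumerate(LBP_OFFSETS):
        nb = I[1 + dr: I.shape[0] - 1 + dr, 1 + dc: I.shape[1] - 1 + dc]
        codes |= ((nb - centre) >= 0).astype(np.int64) << i
    return codes


def lbp_descriptor(img: np.ndarray) -> FeatureVector:
    """Normalized 256-bin histogram of LBP codes (sums to 1)."""
    codes = lbp_codes(img)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return FeatureVector(hist / hist.sum(), "lbp")


def concat_features(hog: FeatureVector, lbp: FeatureVector) -> FeatureVector:
    """HOG followed by LBP; lengths add."""
    if len(hog) == 0 or len(lbp) == 0:
        raise ValueError("cannot concatenate empty feature vectors")
    return FeatureVector(np.concatenate([hog.values, lbp.values]), "hog+lbp")


def _sorted_matrix(vectors) -> np.ndarray:
    vecs = [np.sort(np.asarray(v.values if isinstance(v, FeatureVector) else v,
                               dtype=float)) for v in vectors]
    if len(vecs) == 0:
        raise ValueError("need at least one feature vector")
    L = len(vecs[0])
    if any(len(v) != L for v in vecs):
        raise ValueError("feature vectors must share a length")
    return np.stack(vecs)


def sorted_average_profile(vectors) -> FeatureVector:
    """Position-wise mean of ascending-sorted vectors (itself ascending)."""
    return FeatureVector(_sorted_matrix(vectors).mean(axis=0), "profile")


def fuzzy_interval_profile(vectors) -> FuzzyProfile:
    """Position-wise (min, max) envelope of ascending-sorted vectors."""
    m = _sorted_matrix(vectors)
    return FuzzyProfile(m.min(axis=0), m.max(axis=0))
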