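"""The 178-feature texture signature of a masked liver slice.

Pipeline: the masked intensities are discretized to nine integer gray
levels 0..8 by equal-width binning over the region's min-max range; on
those levels we compute first-order statistics and the gray-level
co-occurrence (GLCM), run-length (GLRLM) and size-zone (GLSZM) matrices.
GLCM and GLRLM are evaluated along the four in-plane directions 0, 45, 90
and 135 degrees at pixel distance 1; the GLSZM is direction-free
(8-connected zones).  Separately, a rotation-invariant uniform local
binary pattern histogram (P = 24 neighbours, radius 3, 26 bins) is taken
on the *raw* intensities.  Pairs, runs and zones never cross the mask
boundary.

Conventions that the formulas below pin down:

* coordinates are row-major, origin top-left; the direction offsets
  (drow, dcol) are 0 deg -> (0, 1), 45 deg -> (-1, 1), 90 deg -> (-1, 0),
  135 deg -> (-1, -1);
* GLCMs are symmetrized (transpose added) then normalized to
  probabilities;
* run lengths and zone sizes are 1-based; gray levels are weighted as
  (level + 1) in the low/high gray-level emphases so that level 0
  contributes a finite weight;
* features that are undefined on a degenerate input (no valid pixel pair,
  zero variance) are the NaN sentinel, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern

from .io import FeatureVector, MaskedImage
from .manifest import (
    DIRECTIONS,
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    MANIFEST_VERSION,
)

__all__ = [
    "TextureConfig",
    "DiscretizedROI",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "LBPHistogram",
    "discretize",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "glszm",
    "glszm_features",
    "first_order_features",
    "lbp_histogram",
    "extract_features",
]

#: (drow, dcol) unit offsets per direction, row-major with origin top-left.
OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class TextureConfig:
    """Tunable knobs of the texture stage (defaults reproduce the manifest)."""

    n_levels: int = 9          # gray levels 0 .. n_levels-1
    glcm_distance: int = 1     # pixel offset of co-occurring pairs
    lbp_P: int = 24            # circular neighbours -> P + 2 histogram bins
    lbp_R: float = 3.0         # sampling radius (pixels)
    first_order_on_raw: bool = False  # first-order stats on raw intensities


DEFAULT_CONFIG = TextureConfig()


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels (0..n_levels-1), defined where the mask is true."""

    levels: np.ndarray  # int array; values outside the mask are undefined
    mask: np.ndarray
    n_levels: int = 9

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    p: np.ndarray          # n_levels x n_levels joint probabilities
    direction: int
    distance: int
    n_pairs: int           # valid in-mask pixel pairs before symmetrization

    @property
    def flagged(self) -> bool:
        """True when no valid pixel pair exists in this direction."""
        return self.n_pairs == 0


@dataclass(frozen=True)
class RunLengthMatrix:
    R: np.ndarray          # n_levels x Lmax integer run counts; col j = length j+1
    direction: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.R.sum())


@dataclass(frozen=True)
class SizeZoneMatrix:
    S: np.ndarray          # n_levels x Smax integer zone counts; col s = size s+1
    n_pixels: int

    @property
    def n_zones(self) -> int:
        return int(self.S.sum())


@dataclass(frozen=True)
class LBPHistogram:
    bins: np.ndarray       # 26 frequencies summing to 1
    labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(f"LBM {i}" for i in range(26))
    )


NAN = float("nan")


# ---------------------------------------------------------------------------
# discretization


def discretize(img: MaskedImage, n_levels: int = 9) -> DiscretizedROI:
    """Equal-width binning of masked intensities into ``n_levels`` levels.

    level(x) = min(n_levels - 1, floor(n_levels * (x - min) / (max - min)));
    a constant region maps wholly to level 0.
    """
    if img.n_masked < 2:
        raise ValueError("texture analysis needs at least 2 masked pixels")
    values = img.masked_values
    lo, hi = float(values.min()), float(values.max())
    levels = np.zeros(img.pixels.shape, dtype=np.int64)
    if hi > lo:
        scaled = np.floor(n_levels * (img.pixels - lo) / (hi - lo))
        levels = np.clip(scaled, 0, n_levels - 1).astype(np.int64)
        levels[~img.mask] = 0
    return DiscretizedROI(levels=levels, mask=img.mask.copy(), n_levels=n_levels)


# ---------------------------------------------------------------------------
# GLCM


def glcm(
    roi: DiscretizedROI, direction: int, distance: int = 1
) -> CooccurrenceMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix.

    Counts ordered level pairs (a, b) at the direction's offset with both
    pixels inside the mask, adds the transpose, and normalizes.
    """
    if direction not in OFFSETS:
        raise ValueError(f"direction must be one of {sorted(OFFSETS)}")
    dr, dc = (o * distance for o in OFFSETS[direction])
    lv, m = roi.levels, roi.mask
    H, W = lv.shape
    src_r = slice(max(0, -dr), min(H, H - dr))
    src_c = slice(max(0, -dc), min(W, W - dc))
    dst_r = slice(max(0, dr), min(H, H + dr))
    dst_c = slice(max(0, dc), min(W, W + dc))
    a = lv[src_r, src_c]
    b = lv[dst_r, dst_c]
    valid = m[src_r, src_c] & m[dst_r, dst_c]
    L = roi.n_levels
    counts = np.zeros((L, L), dtype=np.int64)
    np.add.at(counts, (a[valid], b[valid]), 1)
    n_pairs = int(valid.sum())
    sym = (counts + counts.T).astype(float)
    p = sym / sym.sum() if n_pairs else sym
    return CooccurrenceMatrix(
        p=p, direction=direction, distance=distance, n_pairs=n_pairs
    )


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The 21 Haralick-style co-occurrence features of the manifest."""
    if m.flagged:
        return {name: NAN for name in GLCM_NAMES}
    p = m.p
    L = p.shape[0]
    i = np.arange(L)[:, None].astype(float)
    j = np.arange(L)[None, :].astype(float)
    px = p.sum(axis=1)
    mu_x = float((np.arange(L) * px).sum())
    mu_y = mu_x  # symmetric matrix
    var_x = float(((np.arange(L) - mu_x) ** 2 * px).sum())
    sd_x = np.sqrt(var_x)

    diff = i - j
    absdiff = np.abs(diff)
    # distributions of i+j and |i-j|
    ks_sum = np.arange(0, 2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    for k in ks_sum:
        p_sum[k] = p[(i + j) == k].sum()
    ks_diff = np.arange(L)
    p_diff = np.zeros(L)
    for k in ks_diff:
        p_diff[k] = p[absdiff == k].sum()

    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    nz_sum = p_sum > 0
    sum_entropy = float(-(p_sum[nz_sum] * np.log2(p_sum[nz_sum])).sum())
    nz_diff = p_diff > 0
    diff_entropy = float(-(p_diff[nz_diff] * np.log2(p_diff[nz_diff])).sum())

    sum_average = float((ks_sum * p_sum).sum())
    sum_variance = float(((ks_sum - sum_average) ** 2 * p_sum).sum())

    off = diff != 0
    inverse_variance = float((p[off] / (diff[off] ** 2)).sum())

    if sd_x > 0:
        correlation = float(
            (((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_x)
        )
    else:
        correlation = NAN

    feats = {
        "autocorrelation": float((i * j * p).sum()),
        "cluster prominence": float(((i + j - mu_x - mu_y) ** 4 * p).sum()),
        "cluster shade": float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
        "cluster tendency": float(((i + j - mu_x - mu_y) ** 2 * p).sum()),
        "contrast": float((diff**2 * p).sum()),
        "correlation": correlation,
        "difference entropy": diff_entropy,
        "dissimilarity": float((absdiff * p).sum()),
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "homogeneity": float((p / (1.0 + absdiff)).sum()),
        "inverse difference moment": float((p / (1.0 + diff**2)).sum()),
        "inverse difference moment normalized": float(
            (p / (1.0 + (diff / L) ** 2)).sum()
        ),
        "inverse difference normalized": float(
            (p / (1.0 + absdiff / L)).sum()
        ),
        "inverse variance": inverse_variance,
        "max probability": float(p.max()),
        "mean": mu_x,
        "sum average": sum_average,
        "sum entropy": sum_entropy,
        "sum variance": sum_variance,
        "variance": float((((i - mu_x) ** 2) * p).sum()),
    }
    assert tuple(feats) == GLCM_NAMES
    return feats


# ---------------------------------------------------------------------------
# GLRLM


def _lines(roi: DiscretizedROI, direction: int):
    """Yield (levels, mask) 1D lines along the direction's axis."""
    lv, m = roi.levels, roi.mask
    if direction == 0:
        for r in range(lv.shape[0]):
            yield lv[r, :], m[r, :]
    elif direction == 90:
        for c in range(lv.shape[1]):
            yield lv[:, c], m[:, c]
    elif direction == 45:
        # direction (-1, +1): anti-diagonals == diagonals of the left-right flip
        flv, fm = lv[:, ::-1], m[:, ::-1]
        H, W = lv.shape
        for d in range(-(H - 1), W):
            yield np.diagonal(flv, d), np.diagonal(fm, d)
    elif direction == 135:
        H, W = lv.shape
        for d in range(-(H - 1), W):
            yield np.diagonal(lv, d), np.diagonal(m, d)
    else:
        raise ValueError(f"direction must be one of {sorted(OFFSETS)}")


def glrlm(roi: DiscretizedROI, direction: int) -> RunLengthMatrix:
    """Gray-level run-length matrix: maximal constant-level collinear runs.

    Runs are broken by the mask boundary and the image edge; every masked
    pixel belongs to exactly one run per direction.
    """
    L = roi.n_levels
    counts: dict[tuple[int, int], int] = {}
    max_len = 1
    for levels, mask in _lines(roi, direction):
        run_level, run_len = -1, 0
        for value, inside in zip(levels, mask):
            if not inside:
                if run_len:
                    key = (run_level, run_len)
                    counts[key] = counts.get(key, 0) + 1
                    max_len = max(max_len, run_len)
                run_level, run_len = -1, 0
            elif value == run_level:
                run_len += 1
            else:
                if run_len:
                    key = (run_level, run_len)
                    counts[key] = counts.get(key, 0) + 1
                    max_len = max(max_len, run_len)
                run_level, run_len = int(value), 1
        if run_len:
            key = (run_level, run_len)
            counts[key] = counts.get(key, 0) + 1
            max_len = max(max_len, run_len)
    R = np.zeros((L, max_len), dtype=np.int64)
    for (lvl, ln), c in counts.items():
        R[lvl, ln - 1] = c
    return RunLengthMatrix(R=R, direction=direction, n_pixels=roi.n_pixels)


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length features of the manifest.

    Run lengths j are 1-based; gray levels are weighted (level + 1) in the
    low/high gray-level emphases.
    """
    if m.n_runs == 0:
        return {name: NAN for name in GLRLM_NAMES}
    R = m.R.astype(float)
    n_r = R.sum()
    j = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]
    g = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]
    r_g = R.sum(axis=1)  # per gray level
    r_j = R.sum(axis=0)  # per run length
    feats = {
        "GLNU": float((r_g**2).sum() / n_r),
        "RLN": float((r_j**2).sum() / n_r),
        "run percentage": float(n_r / m.n_pixels),
        "short run emphasis": float((R / j**2).sum() / n_r),
        "long run emphasis": float((R * j**2).sum() / n_r),
        "low gray level run emphasis": float((R / g**2).sum() / n_r),
        "high gray level run emphasis": float((R * g**2).sum() / n_r),
        "short run low gray level emphasis": float(
            (R / (g**2 * j**2)).sum() / n_r
        ),
        "short run high gray level emphasis": float(
            (R * g**2 / j**2).sum() / n_r
        ),
        "long run low gray level emphasis": float(
            (R * j**2 / g**2).sum() / n_r
        ),
        "long run high gray level emphasis": float(
            (R * g**2 * j**2).sum() / n_r
        ),
    }
    assert tuple(feats) == GLRLM_NAMES
    return feats


# ---------------------------------------------------------------------------
# GLSZM


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def glszm(roi: DiscretizedROI) -> SizeZoneMatrix:
    """Gray-level size-zone matrix: maximal 8-connected constant-level zones."""
    L = roi.n_levels
    sizes_per_level: dict[int, np.ndarray] = {}
    max_size = 1
    for lvl in range(L):
        blob = (roi.levels == lvl) & roi.mask
        if not blob.any():
            continue
        labelled, n = ndimage.label(blob, structure=_EIGHT_CONNECTED)
        sizes = np.bincount(labelled.ravel())[1:]
        sizes_per_level[lvl] = sizes
        max_size = max(max_size, int(sizes.max()))
    S = np.zeros((L, max_size), dtype=np.int64)
    for lvl, sizes in sizes_per_level.items():
        for s in sizes:
            S[lvl, int(s) - 1] += 1
    return SizeZoneMatrix(S=S, n_pixels=roi.n_pixels)


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    """The 11 size-zone features; sizes 1-based, intensity weighted (level+1)."""
    if m.n_zones == 0:
        return {name: NAN for name in GLSZM_NAMES}
    S = m.S.astype(float)
    n_z = S.sum()
    s = np.arange(1, S.shape[1] + 1, dtype=float)[None, :]
    g = np.arange(1, S.shape[0] + 1, dtype=float)[:, None]
    z_g = S.sum(axis=1)
    z_s = S.sum(axis=0)
    feats = {
        "Small area emphasis": float((S / s**2).sum() / n_z),
        "Large area emphasis": float((S * s**2).sum() / n_z),
        "Intensity variability": float((z_g**2).sum() / n_z),
        "Size zone variability": float((z_s**2).sum() / n_z),
        "Zone percentage": float(n_z / m.n_pixels),
        "Low intensity emphasis": float((S / g**2).sum() / n_z),
        "High intensity emphasis": float((S * g**2).sum() / n_z),
        "Small area low intensity emphasis": float(
            (S / (g**2 * s**2)).sum() / n_z
        ),
        "Small area high intensity emphasis": float(
            (S * g**2 / s**2).sum() / n_z
        ),
        "Large area low intensity emphasis": float(
            (S * s**2 / g**2).sum() / n_z
        ),
        "Large area high intensity emphasis": float(
            (S * g**2 * s**2).sum() / n_z
        ),
    }
    assert tuple(feats) == GLSZM_NAMES
    return feats


# ---------------------------------------------------------------------------
# first-order statistics


def first_order_features(
    roi: DiscretizedROI, raw_values: np.ndarray | None = None
) -> dict[str, float]:
    """The 13 first-order features, on discretized levels by default.

    Pass ``raw_values`` to compute on raw masked intensities instead
    (the ``first_order_on_raw`` config flag).  Skewness and kurtosis use
    population moments; kurtosis is Pearson (non-excess).  Entropy (base 2)
    and uniformity are taken over the empirical value distribution.
    """
    x = (
        np.asarray(raw_values, dtype=float)
        if raw_values is not None
        else roi.masked_levels.astype(float)
    )
    n = x.size
    if n < 2:
        raise ValueError("first-order statistics need at least 2 pixels")
    mu = float(x.mean())
    var = float(((x - mu) ** 2).mean())
    sd = float(np.sqrt(var))
    if sd > 0:
        skew = float((((x - mu) / sd) ** 3).mean())
        kurt = float((((x - mu) / sd) ** 4).mean())
    else:
        skew, kurt = NAN, NAN
    _, counts = np.unique(x, return_counts=True)
    pk = counts / n
    feats = {
        "Energy": float((x**2).sum()),
        "Entropy": float(-(pk * np.log2(pk)).sum()),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mu,
        "Mean deviation": float(np.abs(x - mu).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "RMS": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Standard deviation": sd,
        "Uniformity": float((pk**2).sum()),
        "Variance": var,
    }
    assert tuple(feats) == FIRST_ORDER_NAMES
    return feats


# ---------------------------------------------------------------------------
# local binary patterns


def lbp_histogram(
    img: MaskedImage, P: int = 24, R: float = 3.0
) -> LBPHistogram:
    """Rotation-invariant uniform LBP histogram over the masked interior.

    Codes come from ``skimage.feature.local_binary_pattern`` with
    ``method="uniform"`` (P + 2 = 26 labels) on raw intensities; only
    masked centers whose full sampling circle stays inside the image are
    histogrammed; frequencies sum to 1.
    """
    pixels = img.pixels
    if np.all(pixels == np.rint(pixels)):
        pixels = pixels.astype(np.int64)  # integer path avoids float-tie artifacts
    codes = local_binary_pattern(pixels, P, R, method="uniform")
    margin = int(np.ceil(R))
    H, W = img.pixels.shape
    eligible = np.zeros((H, W), dtype=bool)
    if H > 2 * margin and W > 2 * margin:
        eligible[margin : H - margin, margin : W - margin] = True
    sel = img.mask & eligible
    if not sel.any():
        raise ValueError(
            "no masked pixel has a full LBP sampling circle inside the image"
        )
    hist = np.bincount(codes[sel].astype(int), minlength=P + 2).astype(float)
    bins = hist / hist.sum()
    return LBPHistogram(
        bins=bins, labels=tuple(f"LBM {i}" for i in range(P + 2))
    )


# ---------------------------------------------------------------------------
# full signature


def extract_features(
    img: MaskedImage, config: TextureConfig = DEFAULT_CONFIG,
    subject_id: str = "",
) -> FeatureVector:
    """Compute the full ordered 178-feature texture signature of one image."""
    roi = discretize(img, n_levels=config.n_levels)
    values: dict[str, float] = {}

    raw = img.masked_values if config.first_order_on_raw else None
    values.update(first_order_features(roi, raw_values=raw))

    for d in DIRECTIONS:
        feats = glcm_features(glcm(roi, d, distance=config.glcm_distance))
        values.update({f"{d} {k}": v for k, v in feats.items()})
    for d in DIRECTIONS:
        feats = glrlm_features(glrlm(roi, d))
        values.update({f"{d} {k}": v for k, v in feats.items()})
    values.update(glszm_features(glszm(roi)))

    hist = lbp_histogram(img, P=config.lbp_P, R=config.lbp_R)
    values.update(dict(zip(hist.labels, hist.bins.tolist())))

    return FeatureVector(
        values=values, subject_id=subject_id, manifest_version=MANIFEST_VERSION
    )
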