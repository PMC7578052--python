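"""Canonical manifest of the 178 liver texture features.

The signature of one subject is the ordered concatenation of five feature
families computed on a masked axial liver slice:

* 13 first-order statistics of the discretized gray levels,
* 21 gray-level co-occurrence (GLCM) features for each of the four
  in-plane directions 0, 45, 90 and 135 degrees (84 values),
* 11 gray-level run-length (GLRLM) features per direction (44 values),
* 11 gray-level size-zone (GLSZM) features (direction-free),
* 26 bins of the rotation-invariant uniform local binary pattern
  histogram ("LBM 0" ... "LBM 25", P = 24 neighbours).

13 + 84 + 44 + 11 + 26 = 178.  Directional names carry the direction as a
prefix, e.g. ``"45 RLN"`` or ``"135 cluster tendency"``; first-order and
GLSZM names are capitalised, e.g. ``"Mean deviation"``,
``"Size zone variability"``.
"""

from __future__ import annotations

from typing import NamedTuple

MANIFEST_VERSION = "1.0"

#: GLCM/GLRLM offsets are evaluated along these in-plane directions (degrees).
DIRECTIONS: tuple[int, ...] = (0, 45, 90, 135)

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "Energy",
    "Entropy",
    "Kurtosis",
    "Maximum",
    "Mean",
    "Mean deviation",
    "Median",
    "Minimum",
    "RMS",
    "Skewness",
    "Standard deviation",
    "Uniformity",
    "Variance",
)

GLCM_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster prominence",
    "cluster shade",
    "cluster tendency",
    "contrast",
    "correlation",
    "difference entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse difference moment",
    "inverse difference moment normalized",
    "inverse difference normalized",
    "inverse variance",
    "max probability",
    "mean",
    "sum average",
    "sum entropy",
    "sum variance",
    "variance",
)

GLRLM_NAMES: tuple[str, ...] = (
    "GLNU",
    "RLN",
    "run percentage",
    "short run emphasis",
    "long run emphasis",
    "low gray level run emphasis",
    "high gray level run emphasis",
    "short run low gray level emphasis",
    "short run high gray level emphasis",
    "long run low gray level emphasis",
    "long run high gray level emphasis",
)

GLSZM_NAMES: tuple[str, ...] = (
    "Small area emphasis",
    "Large area emphasis",
    "Intensity variability",
    "Size zone variability",
    "Zone percentage",
    "Low intensity emphasis",
    "High intensity emphasis",
    "Small area low intensity emphasis",
    "Small area high intensity emphasis",
    "Large area low intensity emphasis",
    "Large area high intensity emphasis",
)

LBM_NAMES: tuple[str, ...] = tuple(f"LBM {i}" for i in range(26))


class ManifestEntry(NamedTuple):
    """One feature of the canonical manifest."""

    name: str       # canonical column name, e.g. "45 RLN"
    family: str     # first_order | glcm | glrlm | glszm | lbm
    direction: int | None  # degrees, None for direction-free families
    base: str       # family-local feature name, e.g. "RLN"


def build_manifest() -> tuple[ManifestEntry, ...]:
    entries: list[ManifestEntry] = []
    for n in FIRST_ORDER_NAMES:
        entries.append(ManifestEntry(n, "first_order", None, n))
    for d in DIRECTIONS:
        for n in GLCM_NAMES:
            entries.append(ManifestEntry(f"{d} {n}", "glcm", d, n))
    for d in DIRECTIONS:
        for n in GLRLM_NAMES:
            entries.append(ManifestEntry(f"{d} {n}", "glrlm", d, n))
    for n in GLSZM_NAMES:
        entries.append(ManifestEntry(n, "glszm", None, n))
    for n in LBM_NAMES:
        entries.append(ManifestEntry(n, "lbm", None, n))
    return tuple(entries)


MANIFEST: tuple[ManifestEntry, ...] = build_manifest()

#: The 178 canonical feature names in canonical order.
FEATURE_NAMES: tuple[str, ...] = tuple(e.name for e in MANIFEST)

N_FEATURES: int = len(FEATURE_NAMES)


def manifest_records() -> list[dict]:
    """Machine-readable manifest (for the ``hepatex manifest`` command)."""
    return [
        {
            "index": i,
            "name": e.name,
            "family": e.family,
            "direction": e.direction,
            "base": e.base,
            "version": MANIFEST_VERSION,
        }
        for i, e in enumerate(MANIFEST)
    ]
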