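"""Reading and writing of the pipeline's external artifacts.

Canonical formats: 8/16-bit grayscale PNG for images and binary region
masks, RFC-4180 CSV for clinical and feature tables, JSON for reports.
A single-frame DICOM reader is available when pydicom is installed.
Clinical ingest is strict: every subject must carry the full set of 13
predictors (missing values are an error, never imputed) and the diagnosis
label must be the literal string ``"AAH"`` or ``"control"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .manifest import FEATURE_NAMES, MANIFEST_VERSION

__all__ = [
    "MaskedImage",
    "ClinicalRecord",
    "FeatureVector",
    "CLINICAL_PREDICTORS",
    "CATEGORY_VOCABULARIES",
    "read_masked_image",
    "read_dicom_image",
    "write_masked_image",
    "read_clinical_table",
    "write_clinical_table",
    "clinical_frame",
    "read_feature_table",
    "write_feature_table",
]

#: The 13 clinical predictors, in canonical column order.
CLINICAL_PREDICTORS: tuple[str, ...] = (
    "age_years",
    "race",
    "sex",
    "wbc",
    "bun",
    "creatinine",
    "total_bilirubin",
    "albumin",
    "ast",
    "alt",
    "platelet_count",
    "meld",
    "cirrhosis",
)

#: Allowed values for categorical predictors and the label column.
CATEGORY_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "race": ("White", "Black", "Hispanic", "Asian", "Other"),
    "sex": ("F", "M"),
    "label": ("AAH", "control"),
}

_NUMERIC_PREDICTORS = tuple(
    c for c in CLINICAL_PREDICTORS if c not in ("race", "sex")
)

_GRAYSCALE_MODES = {"L", "I", "I;16", "I;16B", "F", "1"}


@dataclass(frozen=True)
class MaskedImage:
    """A 2D grayscale slice plus a same-shape binary region-of-interest mask.

    Intensities are arbitrary non-negative units (HU-like); ``pixel_spacing``
    is carried as metadata only and never enters any feature formula.
    """

    pixels: np.ndarray
    mask: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.mask) != 0
        if pixels.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {pixels.shape}")
        if pixels.shape != mask.shape:
            raise ValueError(
                f"image shape {pixels.shape} != mask shape {mask.shape}"
            )
        if not np.all(np.isfinite(pixels)):
            raise ValueError("image intensities must be finite")
        if not mask.any():
            raise ValueError("empty mask")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "mask", mask)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's 13 clinical predictors plus the binary diagnosis label."""

    subject_id: str
    label: str  # "AAH" (positive class) or "control"
    age_years: float
    race: str
    sex: str
    wbc: float
    bun: float
    creatinine: float
    total_bilirubin: float
    albumin: float
    ast: float
    alt: float
    platelet_count: float
    meld: float
    cirrhosis: int

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_VOCABULARIES["label"]:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown label {self.label!r} "
                "(expected 'AAH' or 'control')"
            )
        for field in ("race", "sex"):
            value = getattr(self, field)
            if value not in CATEGORY_VOCABULARIES[field]:
                raise ValueError(
                    f"subject {self.subject_id!r}: unknown {field} category "
                    f"{value!r}"
                )
        for field in _NUMERIC_PREDICTORS:
            value = getattr(self, field)
            if value is None or not np.isfinite(float(value)):
                raise ValueError(
                    f"subject {self.subject_id!r}: predictor {field!r} is "
                    "missing or non-finite"
                )
        if int(self.cirrhosis) not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: cirrhosis must be 0 or 1"
            )


@dataclass(frozen=True)
class FeatureVector:
    """The ordered, named texture signature of one subject."""

    values: dict[str, float]
    subject_id: str = ""
    manifest_version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# images


def _load_grayscale(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in _GRAYSCALE_MODES:
            raise ValueError(
                f"{path}: expected a single-channel grayscale image, "
                f"got mode {im.mode!r}"
            )
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    return arr


def read_masked_image(
    image_path: str | Path, mask_path: str | Path
) -> MaskedImage:
    """Read a grayscale PNG image and a same-shape binary mask PNG.

    Any nonzero mask pixel counts as inside the region.  Integer
    intensities are preserved exactly.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    pixels = _load_grayscale(image_path).astype(float)
    mask = _load_grayscale(mask_path)
    if pixels.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: {image_path} is {pixels.shape} but "
            f"{mask_path} is {mask.shape}"
        )
    if not (mask != 0).any():
        raise ValueError(f"{mask_path}: empty mask")
    return MaskedImage(pixels=pixels, mask=mask != 0)


def read_dicom_image(
    dicom_path: str | Path, mask_path: str | Path
) -> MaskedImage:
    """Read a single-frame DICOM slice (rescale slope/intercept applied)
    plus a PNG mask.  Requires the optional pydicom dependency."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "DICOM support requires pydicom (pip install hepatex[dicom])"
        ) from exc
    ds = pydicom.dcmread(str(dicom_path))
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{dicom_path}: expected a single-frame 2D slice")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    arr = arr - arr.min() if arr.min() < 0 else arr  # keep intensities >= 0
    mask = _load_grayscale(Path(mask_path))
    if arr.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: {dicom_path} is {arr.shape} but "
            f"{mask_path} is {mask.shape}"
        )
    if not (mask != 0).any():
        raise ValueError(f"{mask_path}: empty mask")
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    return MaskedImage(pixels=arr, mask=mask != 0, pixel_spacing=spacing)


def write_masked_image(
    img: MaskedImage, image_path: str | Path, mask_path: str | Path
) -> None:
    """Write image and mask as 16-bit / 8-bit grayscale PNGs."""
    pixels = np.asarray(img.pixels)
    if pixels.min() < 0 or pixels.max() > 65535:
        raise ValueError("intensities outside the 16-bit PNG range [0, 65535]")
    out = np.rint(pixels).astype(np.uint16)
    Image.fromarray(out).save(str(image_path))
    Image.fromarray(
        (img.mask.astype(np.uint8) * 255), mode="L"
    ).save(str(mask_path))


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV: subject_id, label and the 13 predictors.

    Strict complete-case ingest: a missing column, an unparseable number,
    an empty cell or an unknown category label raises immediately.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["subject_id", "label", *CLINICAL_PREDICTORS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records: list[ClinicalRecord] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        kwargs: dict = {"subject_id": sid, "label": row["label"]}
        for col in CLINICAL_PREDICTORS:
            raw = row[col]
            if col in ("race", "sex"):
                kwargs[col] = raw
                continue
            if pd.isna(raw) or str(raw).strip() == "":
                raise ValueError(
                    f"{path}: subject {sid!r}: missing value for {col!r}"
                )
            try:
                value = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: subject {sid!r}: unparseable numeric "
                    f"{col!r} = {raw!r}"
                ) from exc
            kwargs[col] = int(value) if col == "cirrhosis" else value
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical_table(
    records: Sequence[ClinicalRecord], path: str | Path
) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=["subject_id", "label", *CLINICAL_PREDICTORS])
    df.to_csv(path, index=False)


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by subject_id."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("subject_id")


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(
    vectors: Iterable[FeatureVector], path: str | Path
) -> None:
    """Write one row per subject: subject_id plus the 178 feature columns.

    All vectors must share the same name manifest in the same order; values
    round-trip through the CSV at full double precision.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError(
                f"inconsistent feature manifests: subject {v.subject_id!r} "
                "does not match the first vector"
            )
    df = pd.DataFrame(
        [[v.subject_id, *v.as_array()] for v in vectors],
        columns=["subject_id", *names],
    )
    # %.17g round-trips any IEEE double exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame indexed by subject_id."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing 'subject_id' column")
    return df.set_index("subject_id")


def default_feature_columns() -> tuple[str, ...]:
    return FEATURE_NAMES
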