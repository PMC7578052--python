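"""Synthetic phantom cohort: liver-like textured slices plus linked labs.

A phantom slice is an elliptical region filled with a stationary Gaussian
random field (white noise smoothed by a Gaussian kernel whose scale is
the *correlation length*, then rescaled to a target contrast), with a few
darker elliptical inclusions standing in for vessels.  Spatial
heterogeneity is controlled by one number per subject — the latent
heterogeneity h = 1 / correlation_length (+ noise) — which is also the
single bridge to the clinical table: each laboratory value is log-linear
in h around its class median, with correlated noise across labs to
emulate the multicollinearity of real chemistries.  Class medians default
to the AAH / trauma-control values (AST 153 / 32.5 U/L, total bilirubin
12.0 / 0.5 mg/dL, ALT 48 / 28 U/L); the AAH class additionally has its
correlation length multiplied by ``class_effect`` (< 1 means rougher AAH
texture).  Ground truth (class, per-subject correlation length and h) is
retained so every downstream stage can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    ClinicalRecord,
    MaskedImage,
    write_clinical_table,
    write_masked_image,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SyntheticCohort",
    "make_phantom",
    "make_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one phantom slice."""

    image_size: int = 128          # square image side (pixels)
    mask_axes: tuple[float, float] = (48.0, 38.0)  # ellipse semi-axes (px)
    correlation_length: float = 3.0  # Gaussian kernel scale (px)
    contrast_sd: float = 12.0        # intensity SD inside the ROI
    inclusion_rate: float = 3.0      # expected dark blobs per ROI
    base_intensity: float = 120.0    # mean ROI level (arbitrary units)

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        area = np.pi * self.mask_axes[0] * self.mask_axes[1]
        if area < 100:
            raise ValueError("mask ellipse area must be >= 100 pixels")


#: Per-class lab medians: (control, AAH).  AST/ALT/bilirubin follow the
#: published cohort; the remaining labs are typical for trauma controls vs
#: moderate-severe alcohol-associated hepatitis.
DEFAULT_LAB_MEDIANS: dict[str, tuple[float, float]] = {
    "wbc": (7.0, 12.5),            # 10^9/L
    "bun": (12.0, 18.0),           # mg/dL
    "creatinine": (0.9, 1.0),      # mg/dL
    "total_bilirubin": (0.5, 12.0),  # mg/dL
    "albumin": (4.2, 2.8),         # g/dL
    "ast": (32.5, 153.0),          # U/L
    "alt": (28.0, 48.0),           # U/L
    "platelet_count": (250.0, 150.0),  # 10^9/L
    "meld": (7.0, 24.0),
}

#: Log-scale slope of each lab on centred latent heterogeneity h.
#: AST carries the strongest (negative) link by design.
DEFAULT_CLINICAL_LINKS: dict[str, float] = {
    "ast": -8.0,
    "wbc": 2.0,
    "total_bilirubin": 3.0,
    "bun": 1.0,
}

#: Physiologic floors applied after generation.
LAB_FLOORS: dict[str, float] = {
    "wbc": 1.0,
    "bun": 2.0,
    "creatinine": 0.2,
    "total_bilirubin": 0.1,
    "albumin": 1.0,
    "ast": 5.0,
    "alt": 5.0,
    "platelet_count": 20.0,
    "meld": 6.0,
}

RACE_PROBS = {
    "White": 0.30, "Black": 0.12, "Hispanic": 0.43,
    "Asian": 0.07, "Other": 0.08,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort."""

    n_aah: int = 34
    n_control: int = 35
    image_size: int = 128
    mask_axes: tuple[float, float] = (48.0, 38.0)
    base_intensity: float = 120.0
    contrast_sd: float = 12.0
    inclusion_rate: float = 3.0
    correlation_length: float = 3.0   # control-class kernel scale
    class_effect: float = 0.6         # AAH correlation_length multiplier
    cl_jitter_sd: float = 0.2         # lognormal per-subject jitter (log sd)
    h_noise_sd: float = 0.02          # additive noise on h
    clinical_links: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_LINKS)
    )
    lab_medians: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LAB_MEDIANS)
    )
    lab_noise_sd: float = 0.15        # log-scale noise SD per lab
    lab_noise_corr: float = 0.3       # common pairwise noise correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_aah, self.n_control) < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.lab_noise_sd < 0 or self.h_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 < self.class_effect:
            raise ValueError("class_effect must be positive")
        unknown = set(self.clinical_links) - set(DEFAULT_LAB_MEDIANS)
        if unknown:
            raise ValueError(f"clinical_links for unknown lab(s) {unknown}")


@dataclass
class SyntheticCohort:
    images: list[MaskedImage]
    clinical: list[ClinicalRecord]
    ground_truth: dict


def _elliptical_mask(size: int, axes: tuple[float, float]) -> np.ndarray:
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    return ((rr - c) / axes[0]) ** 2 + ((cc - c) / axes[1]) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec, seed: int) -> MaskedImage:
    """One deterministic phantom slice for the given spec and seed."""
    rng = np.random.default_rng(seed)
    size = spec.image_size
    mask = _elliptical_mask(size, spec.mask_axes)
    noise = rng.standard_normal((size, size))
    fld = ndimage.gaussian_filter(noise, sigma=spec.correlation_length)
    sd = fld[mask].std()
    if sd > 0 and spec.contrast_sd > 0:
        fld = (fld - fld[mask].mean()) / sd * spec.contrast_sd
    else:
        fld = np.zeros_like(fld)
    pixels = spec.base_intensity + fld

    n_incl = rng.poisson(spec.inclusion_rate)
    depth = 0.8 * spec.contrast_sd     # vanishes with contrast, so
    for _ in range(n_incl):            # contrast_sd = 0 stays constant
        r0, c0 = rng.uniform(0.25 * size, 0.75 * size, size=2)
        a, b = rng.uniform(2.0, 6.0, size=2)
        theta = rng.uniform(0, np.pi)
        rr, cc = np.mgrid[0:size, 0:size]
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        pixels = np.where(blob, pixels - depth, pixels)

    pixels = np.clip(np.rint(pixels), 0, 65535)
    return MaskedImage(pixels=pixels, mask=mask)


def _lab_noise(rng, n_labs: int, sd: float, rho: float) -> np.ndarray:
    """One draw of correlated log-scale lab noise (equicorrelation rho)."""
    cov = sd**2 * ((1 - rho) * np.eye(n_labs) + rho * np.ones((n_labs, n_labs)))
    return rng.multivariate_normal(np.zeros(n_labs), cov, method="cholesky")


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full phantom cohort with linked clinical chemistry."""
    rng = np.random.default_rng(spec.seed)
    img_seeds = np.random.SeedSequence(spec.seed).spawn(1)[0].spawn(
        spec.n_aah + spec.n_control
    )
    labs = sorted(spec.lab_medians)
    images: list[MaskedImage] = []
    records: list[ClinicalRecord] = []
    truth_subjects: list[dict] = []

    classes = ["AAH"] * spec.n_aah + ["control"] * spec.n_control
    for k, label in enumerate(classes):
        sid = f"S{k + 1:03d}"
        is_aah = label == "AAH"
        cl_class = spec.correlation_length * (
            spec.class_effect if is_aah else 1.0
        )
        cl_subj = cl_class * float(np.exp(rng.normal(0.0, spec.cl_jitter_sd)))
        phantom = make_phantom(
            PhantomSpec(
                image_size=spec.image_size,
                mask_axes=spec.mask_axes,
                correlation_length=cl_subj,
                contrast_sd=spec.contrast_sd,
                inclusion_rate=spec.inclusion_rate,
                base_intensity=spec.base_intensity,
            ),
            seed=int(img_seeds[k].generate_state(1)[0] % (2**31)),
        )
        images.append(phantom)

        h = 1.0 / cl_subj + float(rng.normal(0.0, spec.h_noise_sd))
        h_center = 1.0 / cl_class
        eps = _lab_noise(rng, len(labs), spec.lab_noise_sd, spec.lab_noise_corr)
        lab_values: dict[str, float] = {}
        for lab, e in zip(labs, eps):
            median = spec.lab_medians[lab][1 if is_aah else 0]
            slope = spec.clinical_links.get(lab, 0.0)
            value = median * float(np.exp(slope * (h - h_center) + e))
            lab_values[lab] = max(value, LAB_FLOORS[lab])

        sex = "M" if rng.random() < (0.853 if is_aah else 0.667) else "F"
        race = str(
            rng.choice(list(RACE_PROBS), p=list(RACE_PROBS.values()))
        )
        age = float(np.clip(rng.normal(44.0, 10.0), 18.0, 90.0))
        cirrhosis = int(rng.random() < (0.45 if is_aah else 0.05))
        records.append(
            ClinicalRecord(
                subject_id=sid,
                label=label,
                age_years=round(age, 1),
                race=race,
                sex=sex,
                cirrhosis=cirrhosis,
                **{lab: round(v, 3) for lab, v in lab_values.items()},
            )
        )
        truth_subjects.append(
            {
                "subject_id": sid,
                "label": label,
                "correlation_length": cl_subj,
                "heterogeneity": h,
            }
        )

    ground_truth = {
        "spec": {
            **{
                k: v
                for k, v in dataclasses.asdict(spec).items()
                if not isinstance(v, dict)
            },
            "clinical_links": dict(spec.clinical_links),
        },
        "subjects": truth_subjects,
    }
    return SyntheticCohort(
        images=images, clinical=records, ground_truth=ground_truth
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write PNG images/masks, clinical CSV, ground truth and a manifest."""
    import json

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for img, rec in zip(cohort.images, cohort.clinical):
        ipath = out / "images" / f"{rec.subject_id}.png"
        mpath = out / "masks" / f"{rec.subject_id}.png"
        write_masked_image(img, ipath, mpath)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "image": str(ipath.relative_to(out)),
                "mask": str(mpath.relative_to(out)),
            }
        )
    write_clinical_table(cohort.clinical, out / "clinical.csv")
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=2)
    )
    (out / "cohort_manifest.json").write_text(
        json.dumps({"subjects": entries, "clinical": "clinical.csv"}, indent=2)
    )
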