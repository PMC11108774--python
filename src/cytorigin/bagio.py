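"""Image tiling, patch quality control, taxonomy mapping and manifest I/O.

Turns cytology smear frames plus clinical records into labeled bags of
224 x 224 patches — the unit of classification.  One saved microscope frame
(typically ~2,797 x 1,757 px at x200 or x400) combined with its clinical
record is one case; a patient with several frames contributes several cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import (
    DimensionError,
    ExcludedSubgroupError,
    IntegrityError,
    SchemaError,
    UnknownLabelError,
    UnsupportedInputError,
)

PATCH_SIZE = 224

CATEGORIES = ("digestive", "female_reproductive", "respiratory", "blood_lymphatic", "benign")
SEXES = ("male", "female")
SITES = ("hydrothorax", "ascites")
SPLITS = ("train", "val", "test")
CERTAINTY_TIERS = ("high", "low", "uncertainty")

MANIFEST_COLUMNS = (
    "case_id", "image_path", "age", "sex", "site",
    "fine_label", "coarse_label", "certainty", "split",
)

# Organ -> fine subgroup.  Cavity and secretory digestive organs are distinct
# subgroups that both collapse into the digestive category; breast sits with
# the female genital system by clinical convention.
_ORGAN_TO_SUBGROUP = {
    "esophagus": "cavity_digestive", "stomach": "cavity_digestive",
    "duodenum": "cavity_digestive", "intestine": "cavity_digestive",
    "appendix": "cavity_digestive", "colon": "cavity_digestive",
    "rectum": "cavity_digestive", "colon_rectum": "cavity_digestive",
    "liver": "secretory_digestive", "gallbladder": "secretory_digestive",
    "pancreas": "secretory_digestive",
    "ovary": "female_genital", "fallopian_tube": "female_genital",
    "corpus_uteri": "female_genital", "cervix_uteri": "female_genital",
    "uterus": "female_genital", "vagina": "female_genital",
    "breast": "female_genital",
    "lung": "respiratory_tract", "trachea": "respiratory_tract",
    "upper_respiratory_tract": "respiratory_tract",
    "leukemia": "blood_lymphatic_system", "lymphoma": "blood_lymphatic_system",
    "kidney": "urinary", "ureter": "urinary", "bladder": "urinary",
    "urethra": "urinary", "prostate": "urinary", "testicle": "urinary",
    "seminal_vesicle": "urinary",
    "benign": "benign",
}

_SUBGROUP_TO_CATEGORY = {
    "cavity_digestive": "digestive",
    "secretory_digestive": "digestive",
    "female_genital": "female_reproductive",
    "respiratory_tract": "respiratory",
    "blood_lymphatic_system": "blood_lymphatic",
    "benign": "benign",
}

# Recognized but deliberately outside the model's scope: these systems rarely
# metastasize to the thoracoabdominal serous cavities, so images are too
# scarce to train on.
_EXCLUDED_SUBGROUPS = frozenset({
    "urinary", "head_and_neck", "nervous_system", "bone_soft_tissue",
    "melanoma", "mesothelioma", "thymoma",
})


@dataclass
class CytologyImage:
    """One saved smear frame.  ``pixels`` is (H, W) or (H, W, 3) uint8."""

    pixels: np.ndarray
    case_id: str = ""
    magnification: str = "unknown"  # "x200" | "x400" | "unknown"; metadata only

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise DimensionError("pixels must be a 2-D grayscale or 3-channel raster")
        if self.height < 1 or self.width < 1:
            raise DimensionError("image must have positive height and width")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_file(cls, path, case_id: str = "", magnification: str = "unknown"):
        arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(arr, case_id=case_id or Path(path).stem, magnification=magnification)


@dataclass
class PatchBag:
    """Ordered set of patches (rasters and/or a feature matrix) for one case.

    ``patches`` is (n, p, p[, 3]); ``features`` is (n, d).  ``coords`` carries
    the 0-based (row, col) grid position of each patch so attention heatmaps
    can be re-anchored on the source frame.
    """

    patches: Optional[np.ndarray] = None
    features: Optional[np.ndarray] = None
    coords: Sequence[tuple] = field(default_factory=list)
    case_id: str = ""
    empty: bool = False

    @property
    def n(self) -> int:
        if self.patches is not None:
            return len(self.patches)
        if self.features is not None:
            return len(self.features)
        return 0

    @property
    def has_rasters(self) -> bool:
        return self.patches is not None


@dataclass(frozen=True)
class ClinicalCovariates:
    """Per-case clinical record: age (years), sex, specimen sampling site."""

    age: Optional[int]
    sex: Optional[str]
    site: Optional[str]

    def __post_init__(self):
        if self.age is not None and not (0 <= int(self.age) <= 120):
            raise ValueError(f"age {self.age} outside [0, 120]")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.site is not None and self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")

    @property
    def complete(self) -> bool:
        return self.age is not None and self.sex is not None and self.site is not None


@dataclass(frozen=True)
class OriginLabel:
    """Ground-truth origin: fine subgroup, coarse category, certainty tier."""

    fine: str
    coarse: Optional[str] = None
    certainty: str = "high"

    def __post_init__(self):
        if self.certainty not in CERTAINTY_TIERS:
            raise ValueError(f"certainty must be one of {CERTAINTY_TIERS}")
        if self.certainty == "uncertainty":
            object.__setattr__(self, "coarse", None)
        elif self.coarse is None:
            object.__setattr__(self, "coarse", map_taxonomy(self.fine))


def tile_image(image: CytologyImage, patch_size: int = PATCH_SIZE) -> PatchBag:
    """Non-overlapping row-major grid tiling, top-left anchored.

    Partial edge tiles are dropped, so ``n = (H // p) * (W // p)``.
    """
    h, w = image.height, image.width
    if h < patch_size:
        raise DimensionError(f"image height {h} < patch size {patch_size}")
    if w < patch_size:
        raise DimensionError(f"image width {w} < patch size {patch_size}")
    rows, cols = h // patch_size, w // patch_size
    patches, coords = [], []
    for r in range(rows):
        for c in range(cols):
            patches.append(image.pixels[r * patch_size:(r + 1) * patch_size,
                                        c * patch_size:(c + 1) * patch_size])
            coords.append((r, c))
    return PatchBag(patches=np.stack(patches), coords=coords, case_id=image.case_id)


def _to_gray(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(np.float64)
    if p.ndim == 3:
        p = p @ np.array([0.299, 0.587, 0.114])
    return p


def qc_filter_patches(bag: PatchBag, blank_threshold: float = 10.0,
                      focus_threshold: float = 5.0) -> PatchBag:
    """Drop blank and out-of-focus patches.

    A patch is blank if its grayscale intensity variance is below
    ``blank_threshold`` and unfocused if the variance of its Laplacian is
    below ``focus_threshold``.  Thresholds of 0 keep everything.  The returned
    bag carries ``empty=True`` when no patch survives.  Idempotent.
    """
    if not bag.has_rasters:
        raise UnsupportedInputError("qc_filter_patches requires raster patches, not features")
    keep, kept_coords = [], []
    for patch, coord in zip(bag.patches, bag.coords):
        gray = _to_gray(patch)
        if gray.var() < blank_threshold:
            continue
        if ndimage.laplace(gray).var() < focus_threshold:
            continue
        keep.append(patch)
        kept_coords.append(coord)
    if not keep:
        return PatchBag(patches=np.empty((0,) + bag.patches.shape[1:]),
                        coords=[], case_id=bag.case_id, empty=True)
    return PatchBag(patches=np.stack(keep), coords=kept_coords, case_id=bag.case_id)


def map_taxonomy(fine_subgroup: str) -> str:
    """Map an organ or fine subgroup to one of the five coarse categories.

    Deterministic and total over the in-scope subgroups; recognized but
    out-of-scope subgroups raise :class:`ExcludedSubgroupError`, anything
    else :class:`UnknownLabelError`.
    """
    key = str(fine_subgroup).strip().lower().replace(" ", "_").replace("-", "_")
    subgroup = _ORGAN_TO_SUBGROUP.get(key, key)
    if subgroup in _EXCLUDED_SUBGROUPS:
        raise ExcludedSubgroupError(
            f"subgroup {fine_subgroup!r} is out of the model's scope "
            "(rare thoracoabdominal metastasis)")
    if subgroup not in _SUBGROUP_TO_CATEGORY:
        raise UnknownLabelError(f"unknown fine subgroup {fine_subgroup!r}")
    return _SUBGROUP_TO_CATEGORY[subgroup]


@dataclass
class DatasetManifest:
    """Tabular index of cases: image paths, covariates, labels, split."""

    table: pd.DataFrame

    def __post_init__(self):
        validate_manifest(self.table)

    def __len__(self):
        return len(self.table)

    def rows(self):
        return self.table.itertuples(index=False)


def validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing required column(s): {', '.join(missing)}")
    dup = df["case_id"][df["case_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate case id(s): {sorted(set(dup))}")
    bad_rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        problems = []
        if not pd.isna(row.age) and not (0 <= float(row.age) <= 120):
            problems.append("age outside [0, 120]")
        if not pd.isna(row.sex) and row.sex not in SEXES:
            problems.append(f"invalid sex {row.sex!r}")
        if not pd.isna(row.site) and row.site not in SITES:
            problems.append(f"invalid site {row.site!r}")
        if row.certainty not in CERTAINTY_TIERS:
            problems.append(f"invalid certainty {row.certainty!r}")
        if row.split not in SPLITS:
            problems.append(f"invalid split {row.split!r}")
        if not pd.isna(row.coarse_label) and row.coarse_label not in CATEGORIES:
            problems.append(f"invalid coarse label {row.coarse_label!r}")
        if problems:
            bad_rows.append(f"row {i}: " + "; ".join(problems))
    if bad_rows:
        raise SchemaError("schema violations:\n" + "\n".join(bad_rows))


def read_manifest(path) -> DatasetManifest:
    df = pd.read_csv(path, dtype={"case_id": str, "image_path": str,
                                  "sex": str, "site": str, "fine_label": str,
                                  "coarse_label": str, "certainty": str, "split": str})
    return DatasetManifest(df)


def write_manifest(manifest: DatasetManifest, path) -> None:
    validate_manifest(manifest.table)
    manifest.table.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))
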