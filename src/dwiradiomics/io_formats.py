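"""Reading and writing of images, ROI masks, cohort manifests and feature tables.

Images and masks travel as NIfTI (``.nii``/``.nii.gz``), 16-bit grayscale PNG,
or plain CSV grids; feature tables as CSV; manifests, configs and reports as
JSON.  Everything on disk is plain text or a standard imaging format so that a
cohort can be inspected with ordinary tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image as PILImage
from scipy import ndimage

from .errors import (
    AmbiguityError,
    CongruenceError,
    FormatError,
    InvalidRoiError,
    SchemaError,
)

#: Default in-plane pixel size (mm) when a file format carries no spacing.
#: Chosen for a 256 reconstruction matrix over a ~36 cm field of view.
DEFAULT_SPACING = (1.4, 1.4)

#: Smallest analyzable ROI, in pixels.  A 2-level co-occurrence matrix and one
#: Haar scale are defined on 16 pixels; smaller regions are rejected outright.
MIN_ROI_PIXELS = 16

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


class Modality:
    """String tags for the image modalities handled by the pipeline."""

    ADC = "ADC"
    DWI_HIGH_B = "DWI_HIGH_B"
    B0 = "B0"

    ALL = (ADC, DWI_HIGH_B, B0)


@dataclass(frozen=True)
class AnnotatedImage:
    """A single 2-D slice with physical pixel spacing and a modality tag.

    ``pixels`` is a finite float array of shape ``(rows, cols)``; ``spacing``
    is the (row, col) pixel size in mm.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = DEFAULT_SPACING
    modality: str = Modality.ADC
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise FormatError(f"image must be 2-D and at least 2x2, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError("image contains non-finite values")
        sp = (float(self.spacing[0]), float(self.spacing[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise FormatError(f"pixel spacing must be positive, got {sp}")
        if self.modality not in Modality.ALL:
            raise FormatError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiMask:
    """A binary lesion mask congruent with its image grid.

    The true pixels must form one 8-connected component of at least
    ``MIN_ROI_PIXELS`` pixels.
    """

    mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise InvalidRoiError(f"mask must be 2-D, got shape {m.shape}")
        n = int(m.sum())
        if n < MIN_ROI_PIXELS:
            raise InvalidRoiError(f"ROI has {n} pixels, below the minimum of {MIN_ROI_PIXELS}")
        _, n_comp = ndimage.label(m, structure=_EIGHT_CONN)
        if n_comp != 1:
            raise InvalidRoiError(f"ROI must be a single 8-connected component, found {n_comp}")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _load_grid(path: Path, slice_index: int | None = None):
    """Load a 2-D numeric grid and, where available, its pixel spacing.

    Returns ``(array, spacing_or_None)``.
    """
    suffixes = "".join(path.suffixes[-2:]).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
            zooms = img.header.get_zooms()
        except Exception as exc:  # nibabel raises a zoo of errors
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        axes = [a for a in range(data.ndim) if data.shape[a] > 1]
        if len(axes) > 3:
            raise FormatError(f"{path}: more than 3 non-singleton dimensions")
        if len(axes) == 3:
            if slice_index is None:
                raise AmbiguityError(
                    f"{path} is a multi-slice volume; pass a slice index to select one slice"
                )
            data = data[..., slice_index]
            zooms = zooms[:2]
        # squeeze singleton dimensions, keeping the zooms of the kept axes
        keep = [a for a in range(data.ndim) if data.shape[a] > 1]
        if len(keep) != 2:
            raise FormatError(f"{path}: cannot reduce shape {data.shape} to a 2-D slice")
        spacing = (float(zooms[keep[0]]), float(zooms[keep[1]])) if len(zooms) >= 2 else None
        data = data.reshape([data.shape[a] for a in keep])
        return np.asarray(data, dtype=float), spacing
    if suffixes.endswith(".png"):
        try:
            with PILImage.open(path) as im:
                data = np.asarray(im, dtype=float)
        except Exception as exc:
            raise FormatError(f"cannot read PNG file {path}: {exc}") from exc
        if data.ndim != 2:
            raise FormatError(f"{path}: PNG must be single-channel grayscale")
        return data, None
    if suffixes.endswith((".csv", ".txt")):
        try:
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        except Exception as exc:
            raise FormatError(f"cannot read CSV grid {path}: {exc}") from exc
        return np.asarray(data, dtype=float), None
    raise FormatError(f"unsupported image format: {path}")


def read_image(
    path,
    modality: str = Modality.ADC,
    *,
    spacing: tuple[float, float] | None = None,
    slice_index: int | None = None,
    id: str = "",
) -> AnnotatedImage:
    """Read a 2-D image from NIfTI, 16-bit PNG or CSV.

    A 3-D NIfTI with a single non-singleton slice dimension is squeezed to
    2-D; a genuinely multi-slice volume requires ``slice_index``.  Spacing
    comes from the NIfTI header when present, else from ``spacing``, else the
    package default of 1.4 mm isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    data, file_spacing = _load_grid(path, slice_index=slice_index)
    sp = spacing or file_spacing or DEFAULT_SPACING
    return AnnotatedImage(pixels=data, spacing=tuple(sp), modality=modality, id=id or path.stem)


def write_image(image: AnnotatedImage, path) -> None:
    """Write an image as NIfTI, 16-bit PNG, or CSV, chosen by file suffix."""
    path = Path(path)
    suffixes = "".join(path.suffixes[-2:]).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float64), affine), str(path))
    elif suffixes.endswith(".png"):
        px = image.pixels
        if np.any(px < 0) or np.any(px > 65535) or not np.allclose(px, np.round(px)):
            raise FormatError("PNG output requires integer pixel values in [0, 65535]")
        PILImage.fromarray(px.astype(np.uint16)).save(path)
    elif suffixes.endswith((".csv", ".txt")):
        np.savetxt(path, image.pixels, delimiter=",", fmt="%.17g")
    else:
        raise FormatError(f"unsupported image format: {path}")


def read_mask(path, image: AnnotatedImage, *, id: str = "") -> RoiMask:
    """Read a binary mask (nonzero means inside) and validate it against an image."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    data, _ = _load_grid(path)
    if data.shape != image.shape:
        raise CongruenceError(
            f"mask shape {data.shape} does not match image shape {image.shape}"
        )
    return RoiMask(mask=data != 0, id=id or path.stem)


def write_mask(mask: RoiMask, path, spacing: tuple[float, float] = DEFAULT_SPACING) -> None:
    """Write a mask as NIfTI (uint8), PNG or CSV of 0/1."""
    as_img = AnnotatedImage(
        pixels=mask.mask.astype(float), spacing=spacing, modality=Modality.ADC, id=mask.id
    )
    path = Path(path)
    if "".join(path.suffixes[-2:]).lower().endswith((".nii", ".nii.gz")):
        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))
    else:
        write_image(as_img, path)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

LABEL_COLUMN = "class_label"
ID_COLUMN = "lesion_id"


@dataclass
class FeatureTable:
    """Lesions x features matrix with one class label per lesion.

    Backed by a :class:`pandas.DataFrame` indexed by lesion id, with the label
    in ``class_label`` and features in canonical catalogue order after it.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if LABEL_COLUMN not in self.data.columns:
            raise SchemaError(f"feature table lacks a {LABEL_COLUMN!r} column")
        names = list(self.data.columns)
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in table")
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate lesion ids in table")

    @classmethod
    def from_records(
        cls, lesion_ids: Sequence[str], labels: Sequence[str], features: Mapping[str, Sequence[float]]
    ) -> "FeatureTable":
        df = pd.DataFrame(dict(features), index=pd.Index(lesion_ids, name=ID_COLUMN))
        df.insert(0, LABEL_COLUMN, list(labels))
        return cls(df)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != LABEL_COLUMN]

    @property
    def labels(self) -> np.ndarray:
        return self.data[LABEL_COLUMN].to_numpy()

    @property
    def lesion_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def matrix(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    def subset(self, row_mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.data.loc[np.asarray(row_mask, dtype=bool)])

    def __len__(self) -> int:
        return len(self.data)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV (floats at 17 significant digits, NaN empty)."""
    if len(table) == 0:
        raise SchemaError("refusing to write an empty feature table")
    table.data.to_csv(path, float_format="%.17g", index_label=ID_COLUMN)


def read_feature_table(path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, index_col=ID_COLUMN)
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

#: Names of the two segmentation variants a manifest may carry per lesion.
MASK_ADC = "ADC_MASK"   # lesion delineated directly on the ADC map
MASK_DWI = "DWI_MASK"   # lesion delineated on high-b DWI and propagated (wider)
MASK_VARIANTS = (MASK_ADC, MASK_DWI)


@dataclass(frozen=True)
class ManifestEntry:
    lesion_id: str
    image_path: str
    mask_paths: Mapping[str, str]  # variant -> path
    label: str


@dataclass
class CohortManifest:
    """Maps lesion ids to image/mask files and class labels.

    ``contrasts`` optionally declares extra binary groupings derived from the
    labels (e.g. hormone-receptor-positive = {luminal_A, luminal_B}), which the
    classifier enumerates as group-vs-rest tasks.
    """

    entries: list[ManifestEntry]
    classes: tuple[str, ...]
    contrasts: dict[str, tuple[str, ...]] = field(default_factory=dict)
    base_dir: Path | None = None

    def __post_init__(self) -> None:
        ids = [e.lesion_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate lesion ids in manifest")
        known = set(self.classes)
        for e in self.entries:
            if e.label not in known:
                raise SchemaError(f"lesion {e.lesion_id}: label {e.label!r} not in class set")
        for name, labels in self.contrasts.items():
            if not set(labels) <= known:
                raise SchemaError(f"contrast {name!r} references unknown labels")

    def _resolve(self, p: str) -> Path:
        path = Path(p)
        if not path.is_absolute() and self.base_dir is not None:
            path = self.base_dir / path
        return path

    def to_json(self, path) -> None:
        doc = {
            "classes": list(self.classes),
            "contrasts": {k: list(v) for k, v in self.contrasts.items()},
            "entries": [
                {
                    "lesion_id": e.lesion_id,
                    "image": e.image_path,
                    "masks": dict(e.mask_paths),
                    "label": e.label,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "CohortManifest":
        path = Path(path)
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"manifest {path} is not valid JSON: {exc}") from exc
        entries = [
            ManifestEntry(
                lesion_id=str(e["lesion_id"]),
                image_path=str(e["image"]),
                mask_paths={str(k): str(v) for k, v in e["masks"].items()},
                label=str(e["label"]),
            )
            for e in doc["entries"]
        ]
        manifest = cls(
            entries=entries,
            classes=tuple(doc["classes"]),
            contrasts={str(k): tuple(v) for k, v in doc.get("contrasts", {}).items()},
            base_dir=path.parent,
        )
        for e in entries:
            if not manifest._resolve(e.image_path).exists():
                raise FormatError(f"manifest references missing image {e.image_path}")
            for mp in e.mask_paths.values():
                if not manifest._resolve(mp).exists():
                    raise FormatError(f"manifest references missing mask {mp}")
        return manifest


@dataclass
class LesionRecord:
    """One lesion held in memory: its ADC image, its masks and its label."""

    lesion_id: str
    image: AnnotatedImage
    masks: dict[str, RoiMask]
    label: str


def load_cohort(manifest: CohortManifest) -> list[LesionRecord]:
    """Load every lesion of a manifest, preserving manifest order."""
    records = []
    for e in manifest.entries:
        image = read_image(manifest._resolve(e.image_path), Modality.ADC, id=e.lesion_id)
        masks = {
            variant: read_mask(manifest._resolve(p), image, id=f"{e.lesion_id}_{variant}")
            for variant, p in e.mask_paths.items()
        }
        records.append(LesionRecord(e.lesion_id, image, masks, e.label))
    return records
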