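"""ROI statistics on 4D dynamic CT: label-map overlay and TIC extraction.

The segmentation of a single timepoint (produced upstream by a deep-learning
model and reviewed by a radiologist; both outside this package) is overlaid
on every acquisition of the perfusion sequence, and the mean attenuation of
each region of interest per timepoint forms its time-intensity curve.
Inputs are assumed co-registered; residual motion is exercised by the
synthetic phantom's rigid-jitter option rather than corrected here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .curve import TimeIntensityCurve
from .errors import SegmentationError

#: Anatomical structures of the segmentation schema.  Integer codes are a
#: package convention (editable via YAML); names are fixed.
DEFAULT_LABELS: dict[str, int] = {
    "background": 0,
    "pancreas": 1,
    "tumor": 2,
    "portomesenteric_splenic_veins": 3,
    "abdominal_aorta": 4,
    "celiac_trunk": 5,
    "hepatic_artery": 6,
    "splenic_artery": 7,
    "superior_mesenteric_artery": 8,
    "pancreatic_duct": 9,
    "common_bile_duct": 10,
    "stent": 11,
}

VESSEL_LABELS = (
    "portomesenteric_splenic_veins",
    "abdominal_aorta",
    "celiac_trunk",
    "hepatic_artery",
    "splenic_artery",
    "superior_mesenteric_artery",
)

#: Structures removed from the tumor ROI before averaging, to keep vascular
#: and stent artifacts out of the tumor curve.
DEFAULT_TUMOR_EXCLUSIONS = VESSEL_LABELS + ("stent",)

MANDATORY_LABELS = ("tumor", "pancreas")


@dataclass(frozen=True)
class LabelSchema:
    """Mapping from anatomical structure name to integer label code."""

    labels: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        codes = list(self.labels.values())
        if len(set(codes)) != len(codes):
            raise SegmentationError("label codes must be unique")
        for name in MANDATORY_LABELS:
            if name not in self.labels:
                raise SegmentationError(f"schema must define label '{name}'")

    def __getitem__(self, name: str) -> int:
        try:
            return self.labels[name]
        except KeyError:
            raise SegmentationError(f"unknown label name '{name}'") from None

    def codes(self, names) -> list[int]:
        return [self[n] for n in names]

    @property
    def vessel_names(self) -> tuple[str, ...]:
        return tuple(n for n in VESSEL_LABELS if n in self.labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelSchema":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        return cls({str(k): int(v) for k, v in mapping.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.labels, fh, sort_keys=False)


@dataclass(frozen=True)
class DynamicSeries:
    """A 4D dynamic CT series: T stacked 3D volumes in HU plus times.

    ``volumes`` has shape (T, Z, Y, X); ``acquisition_times`` is strictly
    increasing, length T >= 8; ``voxel_spacing`` is the (z, y, x) spacing
    in mm.
    """

    volumes: np.ndarray
    acquisition_times: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        t = np.asarray(self.acquisition_times, dtype=float)
        if v.ndim != 4:
            raise SegmentationError(f"volumes must be 4D (T,Z,Y,X), got {v.shape}")
        if v.shape[0] != t.size:
            raise SegmentationError(
                f"{v.shape[0]} volumes but {t.size} acquisition times"
            )
        if t.size < 8:
            raise SegmentationError("dynamic series needs >= 8 timepoints")
        if np.any(np.diff(t) <= 0):
            raise SegmentationError("acquisition times must be strictly increasing")
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "acquisition_times", t)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    @classmethod
    def from_nifti(cls, paths, acquisition_times) -> "DynamicSeries":
        """Load from one 4D NIfTI file or a sequence of 3D NIfTI files."""
        if isinstance(paths, (str, Path)):
            img = nib.load(str(paths))
            data = np.asanyarray(img.dataobj)
            if data.ndim != 4:
                raise SegmentationError(
                    f"{paths}: expected a 4D image, got shape {data.shape}"
                )
            vols = np.moveaxis(data, -1, 0)  # NIfTI stores time last
            zooms = img.header.get_zooms()[:3]
        else:
            imgs = [nib.load(str(p)) for p in paths]
            arrs = [np.asanyarray(i.dataobj) for i in imgs]
            shapes = {a.shape for a in arrs}
            if len(shapes) != 1:
                raise SegmentationError(
                    f"inconsistent spatial shapes across timepoints: {shapes}"
                )
            vols = np.stack(arrs, axis=0)
            zooms = imgs[0].header.get_zooms()[:3]
        return cls(vols, np.asarray(acquisition_times, float),
                   tuple(float(z) for z in zooms))


def load_label_map(path: str | Path) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    return np.rint(arr).astype(np.int32)


def load_acquisition_times(path: str | Path) -> np.ndarray:
    """Acquisition times from a sidecar JSON (``{"times_s": [...]}``) or a
    one-column CSV with header ``time_s``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return np.asarray(json.load(fh)["times_s"], dtype=float)
    import pandas as pd

    return pd.read_csv(path)["time_s"].to_numpy(float)


def extract_tic_from_mask(series: DynamicSeries, roi_mask: np.ndarray,
                          exclude_mask: np.ndarray | None = None,
                          roi_name: str = "roi") -> TimeIntensityCurve:
    """Mean attenuation over a voxel mask at every timepoint.

    Excluded voxels are removed from the ROI *before* averaging, so their
    values can never leak into the curve.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != series.spatial_shape:
        raise SegmentationError(
            f"mask shape {roi_mask.shape} does not match series spatial "
            f"shape {series.spatial_shape}"
        )
    if exclude_mask is not None:
        roi_mask = roi_mask & ~np.asarray(exclude_mask, dtype=bool)
    n_vox = int(roi_mask.sum())
    if n_vox == 0:
        raise SegmentationError("ROI is empty after exclusion")
    values = series.volumes[:, roi_mask].mean(axis=1)
    return TimeIntensityCurve(series.acquisition_times, values,
                              roi_name=roi_name, n_voxels=n_vox)


def extract_tic(series: DynamicSeries, labels: np.ndarray, schema: LabelSchema,
                roi: str, exclude: tuple[str, ...] = ()) -> TimeIntensityCurve:
    """Overlay the label map on every timepoint and average the ROI.

    Parameters
    ----------
    roi : str
        Structure name in the schema defining the ROI.
    exclude : tuple of str
        Structures whose voxels are removed from the ROI before averaging
        (e.g. vessels and stents crossing a tumor ROI).
    """
    labels = np.asarray(labels)
    if labels.shape != series.spatial_shape:
        raise SegmentationError(
            f"label map shape {labels.shape} does not match series spatial "
            f"shape {series.spatial_shape}"
        )
    roi_mask = labels == schema[roi]
    exclude_mask = None
    if exclude:
        exclude_mask = np.isin(labels, schema.codes(exclude))
    return extract_tic_from_mask(series, roi_mask, exclude_mask, roi_name=roi)


def extract_tumor_tic(series: DynamicSeries, labels: np.ndarray,
                      schema: LabelSchema) -> TimeIntensityCurve:
    """Tumor TIC with the default vessel/stent exclusion applied."""
    exclude = tuple(n for n in DEFAULT_TUMOR_EXCLUSIONS if n in schema.labels)
    return extract_tic(series, labels, schema, "tumor", exclude=exclude)


@dataclass(frozen=True)
class SegmentationReport:
    """Structural sanity report for a label map (report-only, no errors)."""

    voxel_counts: dict[str, int]
    flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_segmentation(labels: np.ndarray, schema: LabelSchema
                          ) -> SegmentationReport:
    """Per-label voxel counts plus flags for empty mandatory labels and
    tumor components disconnected from the pancreas region."""
    labels = np.asarray(labels)
    code_to_name = {v: k for k, v in schema.labels.items()}
    codes, counts = np.unique(labels, return_counts=True)
    count_map = dict(zip(codes.tolist(), counts.tolist()))
    voxel_counts = {name: int(count_map.get(code, 0))
                    for name, code in schema.labels.items()}
    for code, cnt in count_map.items():
        if code not in code_to_name:
            voxel_counts[f"unknown_{code}"] = int(cnt)

    flags: list[str] = []
    for name in MANDATORY_LABELS:
        if voxel_counts.get(name, 0) == 0:
            flags.append(f"missing mandatory label: {name}")

    tumor_mask = labels == schema["tumor"]
    panc_mask = labels == schema["pancreas"]
    if tumor_mask.any() and panc_mask.any():
        panc_bbox = ndimage.find_objects(panc_mask.astype(np.int8))[0]
        # pad the pancreas bounding region by one voxel on each side
        padded = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in panc_bbox)
        comp, n_comp = ndimage.label(tumor_mask)
        inside = np.zeros_like(tumor_mask)
        inside[padded] = True
        for i in range(1, n_comp + 1):
            if not np.any((comp == i) & inside):
                flags.append(
                    f"tumor component {i} disconnected from pancreas region"
                )
    return SegmentationReport(voxel_counts=voxel_counts, flags=tuple(flags))
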