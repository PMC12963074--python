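"""Trabecular ROI extraction from vertebral label masks.

Given a CT volume and a co-registered integer label mask (one positive
label per vertebral body, conventionally 1..4 for L1..L4), the trabecular
region of interest for a vertebra is built as:

1. an axis-aligned box centred at the label's centroid, spanning a
   configurable fraction (default 0.5) of the label's bounding extent on
   every axis — this realises centring on the left-right,
   anterior-posterior and superior-inferior centres of the vertebral body;
2. intersected with the label mask, so the ROI can never leave the
   vertebra;
3. eroded by a configurable margin (default 1 voxel) to keep clear of the
   high-attenuation cortical rim.

From the ROI the mean and median trabecular HU are extracted together
with the voxel count and physical volume.  Failures on a single vertebra
(empty label, ROI eroded away) are recorded per vertebra and do not stop
the remaining levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

DEFAULT_LABELS = {1: "L1", 2: "L2", 3: "L3", 4: "L4"}
AGGREGATE_LEVEL = "L1L4"


class RoiError(ValueError):
    """A per-vertebra extraction failure (empty label, degenerate ROI)."""


@dataclass(frozen=True)
class RoiParams:
    """Geometry of the trabecular ROI.

    fraction : float
        Fraction of the label's bounding extent spanned by the central
        box on each axis, in (0, 1].
    erosion_margin : int
        Number of binary-erosion iterations applied to box ∩ label.
    """

    fraction: float = 0.5
    erosion_margin: int = 1

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.erosion_margin < 0:
            raise ValueError("erosion_margin must be >= 0")


@dataclass
class LabeledVolume:
    """A CT image grid with a co-registered integer label mask.

    ``image`` holds HU values (already rescaled per the volume header);
    ``mask`` shares the exact grid — a shape or spacing mismatch is an
    error, never silently resampled.
    """

    image: np.ndarray
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    axis_meaning: tuple[str, str, str] = ("LR", "AP", "SI")

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} grids differ"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))


@dataclass(frozen=True)
class TrabecularMeasurement:
    """Per patient × phase × level trabecular HU statistics and ROI volume."""

    patient_id: str
    phase: str
    level: str
    mean_hu: float
    median_hu: float
    voxel_count: int
    roi_volume_ml: float
    #: raw ROI voxel HU values; kept for pooled aggregation, not serialized
    values: np.ndarray | None = field(default=None, repr=False, compare=False)

    def as_row(self) -> dict:
        return dict(
            patient_id=self.patient_id,
            phase=self.phase,
            level=self.level,
            mean_hu=self.mean_hu,
            median_hu=self.median_hu,
            voxel_count=self.voxel_count,
            roi_volume_ml=self.roi_volume_ml,
        )


def load_labeled_volume(image_path, mask_path) -> LabeledVolume:
    """Read a NIfTI image/mask pair into a :class:`LabeledVolume`.

    HU rescaling (scl_slope / scl_inter) is applied by the reader; the
    mask must share the image grid exactly.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise ValueError(f"image grid {img.shape} != mask grid {msk.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    mzooms = tuple(float(z) for z in msk.header.get_zooms()[:3])
    if not np.allclose(zooms, mzooms):
        raise ValueError(f"image spacing {zooms} != mask spacing {mzooms}")
    axcodes = nib.aff2axcodes(img.affine)
    meaning = tuple(
        {"L": "LR", "R": "LR", "A": "AP", "P": "AP", "S": "SI", "I": "SI"}[c]
        for c in axcodes
    )
    return LabeledVolume(
        image=np.asarray(img.get_fdata(), dtype=float),
        mask=np.asarray(np.rint(msk.get_fdata()), dtype=int),
        voxel_spacing=zooms,
        axis_meaning=meaning,  # type: ignore[arg-type]
    )


def trabecular_roi(
    vol: LabeledVolume, label: int, params: RoiParams = RoiParams()
) -> np.ndarray:
    """Boolean trabecular ROI for one vertebral label.

    Centred box (fraction of the label's bounding extent per axis) ∩
    label, then eroded.  Raises :class:`RoiError` for an empty label or an
    ROI that erodes away (e.g. a one-voxel label).
    """
    inside = vol.mask == label
    if not inside.any():
        raise RoiError(f"label {label} is empty in mask")

    idx = np.nonzero(inside)
    centroid = np.array([c.mean() for c in idx])
    lo = np.array([c.min() for c in idx], dtype=float)
    hi = np.array([c.max() for c in idx], dtype=float)
    half = np.maximum((hi - lo + 1) * params.fraction / 2.0, 0.5)

    box = np.ones_like(inside)
    for ax in range(inside.ndim):
        coords = np.arange(inside.shape[ax], dtype=float)
        sel = np.abs(coords - centroid[ax]) <= half[ax]
        shape = [1] * inside.ndim
        shape[ax] = -1
        box &= sel.reshape(shape)

    roi = box & inside
    if params.erosion_margin > 0 and roi.any():
        roi = ndimage.binary_erosion(roi, iterations=params.erosion_margin)
    if not roi.any():
        raise RoiError(
            f"label {label}: ROI empty after fraction={params.fraction}, "
            f"erosion={params.erosion_margin}"
        )
    return roi


def roi_statistics(
    vol: LabeledVolume, roi: np.ndarray, patient_id: str, phase: str, level: str
) -> TrabecularMeasurement:
    """Mean / median HU, voxel count and volume over the ROI voxels."""
    if not roi.any():
        raise RoiError(f"{patient_id}/{phase}/{level}: empty ROI")
    values = vol.image[roi]
    return TrabecularMeasurement(
        patient_id=patient_id,
        phase=phase,
        level=level,
        mean_hu=float(values.mean()),
        median_hu=float(np.median(values)),
        voxel_count=int(values.size),
        roi_volume_ml=values.size * vol.voxel_volume_mm3 / 1000.0,
        values=values,
    )


def aggregate_levels(
    per_vertebra: list[TrabecularMeasurement], mode: str = "pooled"
) -> TrabecularMeasurement:
    """Aggregate L1..L4 measurements into a single L1–L4 measurement.

    ``pooled`` (default) computes statistics over the union of all ROI
    voxels and sums voxel counts; ``per-vertebra-mean`` takes the
    unweighted mean of the per-vertebra statistics.
    """
    if not per_vertebra:
        raise RoiError("no usable vertebrae to aggregate")
    first = per_vertebra[0]
    total_voxels = sum(m.voxel_count for m in per_vertebra)
    total_volume = sum(m.roi_volume_ml for m in per_vertebra)
    if mode == "pooled":
        if any(m.values is None for m in per_vertebra):
            raise ValueError("pooled aggregation requires raw ROI voxel values")
        pooled = np.concatenate([m.values for m in per_vertebra])
        mean_hu = float(pooled.mean())
        median_hu = float(np.median(pooled))
        values = pooled
    elif mode == "per-vertebra-mean":
        mean_hu = float(np.mean([m.mean_hu for m in per_vertebra]))
        median_hu = float(np.mean([m.median_hu for m in per_vertebra]))
        values = None
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return TrabecularMeasurement(
        patient_id=first.patient_id,
        phase=first.phase,
        level=AGGREGATE_LEVEL,
        mean_hu=mean_hu,
        median_hu=median_hu,
        voxel_count=total_voxels,
        roi_volume_ml=total_volume,
        values=values,
    )


def extract_measurements(
    vol: LabeledVolume,
    patient_id: str,
    phase: str,
    labels: dict[int, str] = DEFAULT_LABELS,
    params: RoiParams = RoiParams(),
    aggregate: str = "pooled",
) -> tuple[list[TrabecularMeasurement], list[str]]:
    """Per-vertebra measurements plus the L1–L4 aggregate for one volume.

    Returns ``(measurements, failures)``; a failed vertebra contributes a
    human-readable failure string instead of aborting the volume.
    """
    out: list[TrabecularMeasurement] = []
    failures: list[str] = []
    for label, level in sorted(labels.items()):
        try:
            roi = trabecular_roi(vol, label, params)
            out.append(roi_statistics(vol, roi, patient_id, phase, level))
        except RoiError as e:
            failures.append(f"{patient_id}/{phase}/{level}: {e}")
    if out:
        agg = aggregate_levels(out, mode=aggregate)
        out = [replace(m, values=None) for m in out]  # drop voxel payloads
        out.append(replace(agg, values=None))
    else:
        failures.append(f"{patient_id}/{phase}/{AGGREGATE_LEVEL}: no usable vertebrae")
    return out, failures
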