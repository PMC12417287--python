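"""Lesion subregion segmentation (reduced scope).

Pipeline: the post-contrast T1 image is intensity-normalized to [0, 1] over a
local reference region (the user-supplied lesion contour dilated by 10 mm),
the CE (contrast-enhancing) mask keeps contour voxels surviving a 0.7
threshold, the whole-lesion mask is a morphological closing of the CE mask
(dilate -> fill holes -> erode, 6-connected 3x3x3 cross, one iteration each),
and the central non-CE mask is the whole-lesion mask minus the CE mask.
Volumes and per-subregion ADC summaries are extracted on the shared grid.

No registration or resampling is performed: all images must share one voxel
grid, and the lesion contour is a required input (contouring is manual
upstream). An optional override mask replaces the automatic closing, standing
in for the manual-adjustment step.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError, NormalizationError

CE_THRESHOLD = 0.7
NORM_MARGIN_MM = 10.0

#: 6-connected 3x3x3 cross, the cited closing chain's default connectivity
STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationMasks:
    """CE / whole-lesion / central non-CE binary masks on one voxel grid."""

    ce_mask: np.ndarray
    whole_mask: np.ndarray
    nonce_mask: np.ndarray
    voxel_volume: float      # mm^3

    def __post_init__(self) -> None:
        if not (self.ce_mask.shape == self.whole_mask.shape == self.nonce_mask.shape):
            raise GeometryError("masks must share one grid")
        if np.any(self.ce_mask & ~self.whole_mask):
            raise ValueError("ce_mask must be a subset of whole_mask")
        if np.any(self.nonce_mask != (self.whole_mask & ~self.ce_mask)):
            raise ValueError("nonce_mask must equal whole_mask AND NOT ce_mask")

    @classmethod
    def from_ce_and_whole(cls, ce, whole, voxel_volume) -> "SegmentationMasks":
        whole = whole | ce
        return cls(ce, whole, whole & ~ce, voxel_volume)

    def volume_cc(self, subregion: str) -> float:
        mask = getattr(self, f"{subregion}_mask")
        return float(mask.sum()) * self.voxel_volume / 1000.0


def normalize_t1post(image: np.ndarray, reference_region: np.ndarray) -> np.ndarray:
    """Affine rescale so the reference region spans [0, 1]; clipped outside.

    The reference region is local (contour + margin) rather than whole-brain,
    which keeps the fixed 0.7 threshold meaningful on cropped images and
    phantoms.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise NormalizationError("image must be finite-valued")
    if not reference_region.any():
        raise NormalizationError("reference region is empty")
    ref = image[reference_region.astype(bool)]
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        raise NormalizationError("constant image over the reference region")
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def reference_region_from_contour(
    contour: np.ndarray, voxel_size, margin_mm: float = NORM_MARGIN_MM
) -> np.ndarray:
    """Lesion contour dilated by ``margin_mm`` of Euclidean distance."""
    contour = contour.astype(bool)
    if not contour.any():
        raise NormalizationError("contour mask is empty")
    dist = ndimage.distance_transform_edt(~contour, sampling=voxel_size)
    return dist <= margin_mm


def segment_ce(
    normalized: np.ndarray, contour: np.ndarray, threshold: float = CE_THRESHOLD
) -> np.ndarray:
    """Contour voxels whose normalized intensity survives the threshold."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.min() < 0.0 or normalized.max() > 1.0:
        raise NormalizationError("segment_ce expects a [0, 1]-normalized image")
    return contour.astype(bool) & (normalized >= threshold)


def close_whole_lesion(ce_mask: np.ndarray) -> np.ndarray:
    """Morphological closing: dilate, fill holes, erode (one iteration each)."""
    ce_mask = ce_mask.astype(bool)
    out = ndimage.binary_dilation(ce_mask, structure=STRUCT)
    out = ndimage.binary_fill_holes(out, structure=STRUCT)
    out = ndimage.binary_erosion(out, structure=STRUCT)
    return out


def extract_measurements(masks: SegmentationMasks, adc: np.ndarray) -> dict:
    """Per-subregion volume [cc] and ADC median/mean [1e-6 mm^2/s].

    Empty subregions get volume 0 and NaN ADC summaries (e.g. absence of a
    central non-CE component), which downstream analyses exclude pairwise.
    """
    adc = np.asarray(adc, dtype=float)
    if adc.shape != masks.ce_mask.shape:
        raise GeometryError("ADC image does not share the masks' grid")
    out = {}
    for sub in ("ce", "whole", "nonce"):
        mask = getattr(masks, f"{sub}_mask")
        vals = adc[mask]
        out[sub] = {
            "volume_cc": masks.volume_cc(sub),
            "adc_median": float(np.median(vals)) if vals.size else float("nan"),
            "adc_mean": float(np.mean(vals)) if vals.size else float("nan"),
        }
    return out


def segment_lesion(
    t1_img: nib.Nifti1Image,
    adc_img: nib.Nifti1Image,
    contour_img: nib.Nifti1Image,
    threshold: float = CE_THRESHOLD,
    norm_margin_mm: float = NORM_MARGIN_MM,
    override_whole: np.ndarray | None = None,
) -> tuple[SegmentationMasks, dict]:
    """Full front end: NIfTI inputs in, masks plus measurements out."""
    shapes = {t1_img.shape, adc_img.shape, contour_img.shape}
    if len(shapes) != 1:
        raise GeometryError("T1, ADC and contour must share one grid")
    voxel_size = t1_img.header.get_zooms()[:3]
    contour = np.asanyarray(contour_img.dataobj).astype(bool)
    reference = reference_region_from_contour(contour, voxel_size, norm_margin_mm)
    normalized = normalize_t1post(np.asanyarray(t1_img.dataobj), reference)
    ce = segment_ce(normalized, contour, threshold)
    whole = override_whole.astype(bool) if override_whole is not None \
        else close_whole_lesion(ce)
    # confine to the contour's closed hull
    hull = ndimage.binary_fill_holes(contour, structure=STRUCT)
    whole = whole & hull
    masks = SegmentationMasks.from_ce_and_whole(
        ce, whole, float(np.prod(voxel_size))
    )
    return masks, extract_measurements(masks, np.asanyarray(adc_img.dataobj))
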