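"""Nuclear, plasma-membrane, and tissue compartment segmentation.

The nuclear stain (DAPI) channel yields the nuclear mask and a nucleus
count; the plasma-membrane marker channel (Na+/K+-ATPase) yields the
membrane mask; the tissue mask — the denominator region for area-per-cell —
is the union of the dilated nuclear mask with the membrane mask.

Thresholding is strict (intensity > cutoff) throughout, matching the
positivity convention of :mod:`mifquant.thresholding`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk
from skimage.segmentation import watershed

from .image_io import ChannelStack
from .thresholding import PositivityThreshold


class SegmentationError(ValueError):
    """Missing channels, degenerate images, or inconsistent parameters."""


@dataclass
class SegmentationParams:
    """Tunable segmentation settings.

    Defaults: Otsu thresholds (parameter-free and reproducible; the source
    assay's vendor-software thresholds are unpublished), 8-neighbour
    connectivity for nuclear blob labelling, 10 um^2 minimum nucleus area
    for debris rejection, no declumping, and a 5 um nuclear dilation when
    building the tissue mask.
    """

    nuclear_threshold_method: Literal["otsu", "fixed"] = "otsu"
    nuclear_fixed_threshold: Optional[float] = None
    min_nucleus_area_um2: float = 10.0
    split_touching_nuclei: bool = False
    membrane_threshold_method: Literal["otsu", "fixed", "control_derived"] = "otsu"
    membrane_fixed_threshold: Optional[float] = None
    connectivity: Literal[4, 8] = 8
    tissue_dilation_um: float = 5.0

    def __post_init__(self) -> None:
        if self.nuclear_threshold_method == "fixed" and self.nuclear_fixed_threshold is None:
            raise SegmentationError("nuclear_fixed_threshold required with method 'fixed'")
        if self.membrane_threshold_method == "fixed" and self.membrane_fixed_threshold is None:
            raise SegmentationError("membrane_fixed_threshold required with method 'fixed'")
        if self.min_nucleus_area_um2 < 0:
            raise SegmentationError("min_nucleus_area_um2 must be >= 0")
        if self.connectivity not in (4, 8):
            raise SegmentationError("connectivity must be 4 or 8")
        if self.tissue_dilation_um < 0:
            raise SegmentationError("tissue_dilation_um must be >= 0")

    @property
    def skimage_connectivity(self) -> int:
        # skimage: 1 = 4-neighbour, 2 = 8-neighbour
        return 1 if self.connectivity == 4 else 2


@dataclass
class CompartmentMasks:
    """Boolean compartment masks for one field, all sharing the source shape."""

    nuclear: np.ndarray
    membrane: np.ndarray
    tissue: np.ndarray
    nucleus_count: int
    field_id: str

    def __post_init__(self) -> None:
        shapes = {self.nuclear.shape, self.membrane.shape, self.tissue.shape}
        if len(shapes) != 1:
            raise SegmentationError(f"mask shapes differ: {sorted(shapes)}")
        if self.nucleus_count < 0:
            raise SegmentationError("nucleus_count must be >= 0")
        if np.any(self.nuclear & ~self.tissue):
            raise SegmentationError("nuclear mask must be a subset of the tissue mask")


def _otsu_or_fail(img: np.ndarray, what: str) -> float:
    if img.min() == img.max():
        raise SegmentationError(
            f"degenerate image: constant-intensity {what} channel cannot be Otsu-thresholded"
        )
    return float(threshold_otsu(img))


def segment_nuclei(
    stack: ChannelStack, params: SegmentationParams | None = None
) -> tuple[np.ndarray, int]:
    """Segment DAPI-positive nuclei; return (binary mask, nucleus count).

    Pipeline: threshold (Otsu or fixed, strict '>'), fill holes, drop
    components below ``min_nucleus_area_um2``, optionally split touching
    nuclei by distance-transform watershed, then count connected components
    under ``params.connectivity``.
    """
    params = params or SegmentationParams()
    img = stack.channel("nuclear_stain")
    if params.nuclear_threshold_method == "otsu":
        thr = _otsu_or_fail(img, "nuclear-stain")
    else:
        thr = float(params.nuclear_fixed_threshold)  # type: ignore[arg-type]
    mask = img > thr
    mask = ndi.binary_fill_holes(mask)

    min_area_px = params.min_nucleus_area_um2 / stack.pixel_size_um**2
    lab = label(mask, connectivity=params.skimage_connectivity)
    if lab.max() > 0:
        areas = np.bincount(lab.ravel())
        keep = np.flatnonzero(areas >= min_area_px)
        keep = keep[keep > 0]
        mask = np.isin(lab, keep)

    if params.split_touching_nuclei and mask.any():
        count = _watershed_count(mask, min_area_px, params.skimage_connectivity)
    else:
        _, count = _label_count(mask, params.skimage_connectivity)
    return mask, count


def _label_count(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    lab, n = label(mask, connectivity=connectivity, return_num=True)
    return lab, int(n)


def _watershed_count(mask: np.ndarray, min_area_px: float, connectivity: int) -> int:
    distance = ndi.distance_transform_edt(mask)
    # peak separation scaled to the radius of the smallest admissible nucleus
    min_dist = max(2, int(round(np.sqrt(max(min_area_px, 4.0) / np.pi))))
    lab, _ = _label_count(mask, connectivity)
    coords = peak_local_max(distance, labels=lab, min_distance=min_dist, exclude_border=False)
    if len(coords) == 0:
        return int(lab.max() > 0)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(markers > 0)
    ws = watershed(-distance, markers, mask=mask)
    return int(len(np.unique(ws)) - (0 in ws))


def segment_membrane(
    stack: ChannelStack,
    params: SegmentationParams | None = None,
    threshold: PositivityThreshold | None = None,
) -> np.ndarray:
    """Binary mask of membrane-marker-positive pixels (Na+/K+-ATPase)."""
    params = params or SegmentationParams()
    img = stack.channel("membrane_marker")
    method = params.membrane_threshold_method
    if method == "otsu":
        thr = _otsu_or_fail(img, "membrane-marker")
    elif method == "fixed":
        thr = float(params.membrane_fixed_threshold)  # type: ignore[arg-type]
    else:  # control_derived
        if threshold is None:
            raise SegmentationError(
                "membrane method 'control_derived' requires a PositivityThreshold"
            )
        thr = float(threshold.cutoff)
    return img > thr


def build_tissue_mask(
    stack: ChannelStack,
    params: SegmentationParams | None = None,
    nuclear_mask: np.ndarray | None = None,
    membrane_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Tissue (tumour-cell region) mask: dilated nuclei united with membrane.

    Dilation radius ``tissue_dilation_um`` approximates the cytoplasmic
    extent around each nucleus; the result is always a superset of the
    nuclear mask (dilation radius 0 leaves it equal when no membrane signal
    exists).
    """
    params = params or SegmentationParams()
    if nuclear_mask is None:
        nuclear_mask, _ = segment_nuclei(stack, params)
    radius_px = int(round(params.tissue_dilation_um / stack.pixel_size_um))
    if radius_px > 0 and nuclear_mask.any():
        tissue = ndi.binary_dilation(nuclear_mask, structure=disk(radius_px))
    else:
        tissue = nuclear_mask.copy()
    if membrane_mask is not None:
        tissue = tissue | membrane_mask
    return tissue


def segment_field(
    stack: ChannelStack,
    params: SegmentationParams | None = None,
    membrane_threshold: PositivityThreshold | None = None,
) -> CompartmentMasks:
    """Run all three segmentations for one field."""
    params = params or SegmentationParams()
    nuclear, count = segment_nuclei(stack, params)
    membrane = segment_membrane(stack, params, membrane_threshold)
    tissue = build_tissue_mask(stack, params, nuclear_mask=nuclear, membrane_mask=membrane)
    return CompartmentMasks(
        nuclear=nuclear,
        membrane=membrane,
        tissue=tissue,
        nucleus_count=count,
        field_id=stack.field_id,
    )
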