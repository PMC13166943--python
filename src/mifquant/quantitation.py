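"""Endpoint metrics per field/ROI.

The assay's readouts are binary-area fractions, not intensity averages:

* marker area positive per cell — marker-positive tumour-cell area (um^2)
  divided by the number of nuclei in the same field;
* %MAP — percent of the plasma-membrane mask positive for a marker, and the
  dual variant for pixels positive for two markers simultaneously
  (membrane-colocalised total MET & phospho-MET);
* %NAP — percent of the nuclear mask positive for a marker;
* phospho/total ratio — ratio of the two area-per-cell values.

Undefined values (empty denominator, zero nuclei) are carried as missing
(None / NaN) with a QC note, never as 0: zero-filling would bias
treated-group means downward.

Areas are physical: pixel_count * pixel_size_um^2.  Percent metrics are
therefore pixel-size-invariant while area-per-cell scales with the squared
pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .image_io import ChannelStack
from .segmentation import CompartmentMasks
from .thresholding import PositivityThreshold, apply_threshold

#: markers quantified per record
MARKERS = ("total_met", "phospho_met")

#: per-specimen evaluability rule: biopsy sections must together contain at
#: least this many viable tumour cells (nuclei)
DEFAULT_MIN_CELLS = 3000


class QuantitationError(ValueError):
    pass


@dataclass
class ROIQuantRecord:
    """The per-field/ROI endpoint row."""

    field_id: str
    roi_id: str
    specimen_id: str = ""
    group: str = ""
    nucleus_count: int = 0
    tissue_area_um2: float = 0.0
    membrane_area_um2: float = 0.0
    nuclear_area_um2: float = 0.0
    total_met_positive_area_um2: Optional[float] = None
    total_met_area_per_cell_um2: Optional[float] = None
    total_met_pct_map: Optional[float] = None
    total_met_pct_nap: Optional[float] = None
    phospho_met_positive_area_um2: Optional[float] = None
    phospho_met_area_per_cell_um2: Optional[float] = None
    phospho_met_pct_map: Optional[float] = None
    phospho_met_pct_nap: Optional[float] = None
    pct_map_dual: Optional[float] = None
    phospho_total_ratio: Optional[float] = None
    evaluable: bool = True
    qc_notes: str = ""

    def note(self, msg: str) -> None:
        self.qc_notes = f"{self.qc_notes}; {msg}" if self.qc_notes else msg


def _check_shapes(*masks: np.ndarray) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise QuantitationError(f"mask shapes differ: {sorted(shapes)}")


def marker_area_per_cell(
    positive: np.ndarray,
    tissue: np.ndarray,
    nucleus_count: int,
    pixel_size_um: float,
) -> Optional[float]:
    """Marker-positive tumour-cell area (um^2) divided by the field's nuclei.

    Returns None when ``nucleus_count`` is 0 (no evaluable cells).
    """
    _check_shapes(positive, tissue)
    if nucleus_count == 0:
        return None
    area_um2 = int(np.count_nonzero(positive & tissue)) * pixel_size_um**2
    return area_um2 / nucleus_count


def percent_membrane_area_positive(
    positive: np.ndarray, membrane: np.ndarray
) -> Optional[float]:
    """100 * |positive ∩ membrane| / |membrane|; None when membrane is empty."""
    _check_shapes(positive, membrane)
    denom = int(np.count_nonzero(membrane))
    if denom == 0:
        return None
    return 100.0 * int(np.count_nonzero(positive & membrane)) / denom


def percent_membrane_area_dual_positive(
    pos_a: np.ndarray, pos_b: np.ndarray, membrane: np.ndarray
) -> Optional[float]:
    """%MAP of pixels positive for both markers (colocalisation)."""
    _check_shapes(pos_a, pos_b, membrane)
    denom = int(np.count_nonzero(membrane))
    if denom == 0:
        return None
    return 100.0 * int(np.count_nonzero(pos_a & pos_b & membrane)) / denom


def percent_nuclear_area_positive(
    positive: np.ndarray, nuclear: np.ndarray
) -> Optional[float]:
    """100 * |positive ∩ nuclear| / |nuclear|; None when no nuclear pixels."""
    _check_shapes(positive, nuclear)
    denom = int(np.count_nonzero(nuclear))
    if denom == 0:
        return None
    return 100.0 * int(np.count_nonzero(positive & nuclear)) / denom


def phospho_total_ratio(
    phospho_apc: Optional[float], total_apc: Optional[float]
) -> Optional[float]:
    """phospho / total area-per-cell ratio; None when total is 0 or missing."""
    if phospho_apc is None or total_apc is None:
        return None
    if total_apc == 0:
        return None
    return phospho_apc / total_apc


def quantify_roi(
    stack: ChannelStack,
    masks: CompartmentMasks,
    thresholds: Mapping[str, PositivityThreshold],
    roi: Optional[tuple[int, int, int, int]] = None,
    roi_id: str = "full",
    specimen_id: str = "",
    group: str = "",
) -> ROIQuantRecord:
    """Compute every endpoint metric for one rectangular ROI of a field.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixels, or None
    for the whole field.  ``thresholds`` must cover both quantified markers.
    """
    px = stack.pixel_size_um
    sl = (slice(None), slice(None)) if roi is None else (
        slice(roi[0], roi[1]), slice(roi[2], roi[3])
    )
    nuclear = masks.nuclear[sl]
    membrane = masks.membrane[sl]
    tissue = masks.tissue[sl]
    if roi is None:
        count = masks.nucleus_count
    else:
        # nuclei are counted as components intersecting the ROI window
        from skimage.measure import label

        count = int(label(nuclear, connectivity=2, return_num=True)[1])

    rec = ROIQuantRecord(
        field_id=masks.field_id,
        roi_id=roi_id,
        specimen_id=specimen_id,
        group=group,
        nucleus_count=count,
        tissue_area_um2=int(np.count_nonzero(tissue)) * px**2,
        membrane_area_um2=int(np.count_nonzero(membrane)) * px**2,
        nuclear_area_um2=int(np.count_nonzero(nuclear)) * px**2,
    )

    pos: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        if marker not in thresholds:
            raise QuantitationError(f"no threshold supplied for marker {marker!r}")
        pos[marker] = apply_threshold(stack.channel(marker)[sl], marker, thresholds[marker])
        area = int(np.count_nonzero(pos[marker] & tissue)) * px**2
        setattr(rec, f"{marker}_positive_area_um2", area)
        apc = marker_area_per_cell(pos[marker], tissue, count, px)
        setattr(rec, f"{marker}_area_per_cell_um2", apc)
        setattr(rec, f"{marker}_pct_map", percent_membrane_area_positive(pos[marker], membrane))
        setattr(rec, f"{marker}_pct_nap", percent_nuclear_area_positive(pos[marker], nuclear))

    rec.pct_map_dual = percent_membrane_area_dual_positive(
        pos["total_met"], pos["phospho_met"], membrane
    )
    rec.phospho_total_ratio = phospho_total_ratio(
        rec.phospho_met_area_per_cell_um2, rec.total_met_area_per_cell_um2
    )

    if count == 0:
        rec.evaluable = False
        rec.note("no evaluable cells (nucleus_count = 0)")
    if rec.membrane_area_um2 == 0:
        rec.note("empty membrane mask: %MAP undefined")
    if rec.nuclear_area_um2 == 0:
        rec.note("empty nuclear mask: %NAP undefined")
    if rec.phospho_total_ratio is None and rec.total_met_area_per_cell_um2 == 0:
        rec.note("no total-MET signal: ratio undefined")
    return rec


def assess_evaluability(
    records: Sequence[ROIQuantRecord],
    min_cells: int = DEFAULT_MIN_CELLS,
    specimen_key: Optional[Callable[[ROIQuantRecord], str]] = None,
) -> dict[str, bool]:
    """Flag specimens whose summed nucleus count falls below ``min_cells``.

    Nuclei are summed over all ROIs/sections of a specimen; the flag is
    propagated to every record of that specimen.  Returns the per-specimen
    verdicts.
    """
    if min_cells < 0:
        raise QuantitationError("min_cells must be >= 0")
    key = specimen_key or (lambda r: r.specimen_id or r.field_id)
    totals: dict[str, int] = {}
    for r in records:
        totals[key(r)] = totals.get(key(r), 0) + r.nucleus_count
    verdicts = {s: n >= min_cells for s, n in totals.items()}
    for r in records:
        if not verdicts[key(r)]:
            r.evaluable = False
            r.note(f"specimen below {min_cells}-cell evaluability minimum")
    return verdicts
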