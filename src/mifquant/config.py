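"""Pipeline configuration: a single human-readable YAML document.

The config is the full, diffable record of an analysis run: input manifest
(field -> file(s), channel map, group, specimen), segmentation parameters,
threshold specifications per marker, ROI definitions, the evaluability
minimum, and the statistical contrasts.  ``schema_version`` guards future
format changes.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .quantitation import DEFAULT_MIN_CELLS


class ThresholdSpec(BaseModel):
    """How to obtain one marker's positivity cutoff.

    ``fixed`` takes the cutoff directly from ``parameter``; the derived
    methods need a ``control`` image (isotype or negative cell line) whose
    pixels define the background distribution.
    """

    method: Literal["mean_plus_k_sd", "percentile", "fixed"] = "mean_plus_k_sd"
    parameter: float = 3.0
    control: Optional[Union[str, Dict[str, str]]] = None
    control_channel_map: Optional[Dict[str, int]] = None

    @model_validator(mode="after")
    def _needs_control(self):
        if self.method != "fixed" and self.control is None:
            raise ValueError(f"method {self.method!r} requires a control image")
        return self


class SegmentationConfig(BaseModel):
    nuclear_threshold_method: Literal["otsu", "fixed"] = "otsu"
    nuclear_fixed_threshold: Optional[float] = None
    min_nucleus_area_um2: float = 10.0
    split_touching_nuclei: bool = False
    membrane_threshold_method: Literal["otsu", "fixed", "control_derived"] = "otsu"
    membrane_fixed_threshold: Optional[float] = None
    connectivity: Literal[4, 8] = 8
    tissue_dilation_um: float = 5.0


class FieldEntry(BaseModel):
    """One image field of the input manifest."""

    field_id: str
    path: Union[str, Dict[str, str]]  # one multichannel TIFF or role -> file
    channel_map: Dict[str, int]
    group: str = Field(min_length=1)
    specimen: str = ""
    rois: Optional[List[Tuple[int, int, int, int]]] = None  # (r0, r1, c0, c1)


class PipelineConfig(BaseModel):
    schema_version: int = 1
    pixel_size_um: float = Field(gt=0)
    output_dir: str = "results"
    min_cells: int = DEFAULT_MIN_CELLS
    segmentation: SegmentationConfig = SegmentationConfig()
    thresholds: Dict[str, ThresholdSpec]
    reference_group: Optional[str] = None
    contrasts: Optional[List[Tuple[str, str]]] = None
    stats_metrics: List[str] = Field(
        default_factory=lambda: [
            "total_met_area_per_cell_um2",
            "phospho_met_area_per_cell_um2",
            "total_met_pct_map",
            "phospho_met_pct_map",
            "pct_map_dual",
            "total_met_pct_nap",
            "phospho_met_pct_nap",
            "phospho_total_ratio",
        ]
    )
    unit_of_analysis: Literal["roi", "specimen"] = "roi"
    export_masks: bool = False
    fields: List[FieldEntry] = Field(min_length=1)

    @field_validator("thresholds")
    @classmethod
    def _markers_covered(cls, v):
        for marker in ("total_met", "phospho_met"):
            if marker not in v:
                raise ValueError(f"thresholds must cover marker {marker!r}")
        return v

    @model_validator(mode="after")
    def _reference_exists(self):
        groups = {f.group for f in self.fields}
        if self.reference_group is not None and self.reference_group not in groups:
            raise ValueError(
                f"reference_group {self.reference_group!r} not among field groups {sorted(groups)}"
            )
        return self

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
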