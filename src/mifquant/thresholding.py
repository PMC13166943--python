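"""Positivity thresholds derived from isotype-control or control-line images.

A marker pixel is called positive when its intensity strictly exceeds the
cutoff.  Cutoffs are derived once from a control (isotype-stained section or
a biologically negative cell line) and then applied uniformly — there is no
per-field adaptive thresholding, mirroring calibrated-assay practice.

Conventions, chosen to be oracle-checkable:

* ``mean_plus_k_sd`` uses the population (1/N) standard deviation; the
  default is k = 3, a conventional Gaussian background-exclusion rule.
* ``percentile`` uses the nearest-rank rule: the value at sorted index
  ceil(p/100 * N) (1-based).
* positivity is strict ``>``, so a zero-noise control thresholded at its own
  mean is exactly 0% positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Literal, Optional

import numpy as np


class ThresholdError(ValueError):
    pass


@dataclass
class PositivityThreshold:
    """A per-marker intensity cutoff with its derivation provenance."""

    marker: str
    cutoff: float
    method: Literal["mean_plus_k_sd", "percentile", "fixed"]
    k_or_percentile: float
    control_id: str = ""

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ThresholdError(f"cutoff must be >= 0, got {self.cutoff}")
        if self.method == "percentile" and not 0 < self.k_or_percentile <= 100:
            raise ThresholdError("percentile must lie in (0, 100]")
        if self.method == "mean_plus_k_sd" and self.k_or_percentile < 0:
            raise ThresholdError("k must be >= 0")

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "cutoff": float(self.cutoff),
            "method": self.method,
            "k_or_percentile": float(self.k_or_percentile),
            "control_id": self.control_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PositivityThreshold":
        return cls(**d)


def _control_pixels(control, marker: str) -> np.ndarray:
    # ChannelStack-like (has .channel) or a bare pixel sample
    if hasattr(control, "channel"):
        return np.asarray(control.channel(marker), dtype=float).ravel()
    return np.asarray(control, dtype=float).ravel()


def derive_threshold(
    control,
    marker: str,
    method: Literal["mean_plus_k_sd", "percentile", "fixed"] = "mean_plus_k_sd",
    parameter: float = 3.0,
    control_id: str = "",
) -> PositivityThreshold:
    """Derive a positivity cutoff from control pixels.

    ``control`` is a ChannelStack containing the marker channel, or any
    array-like pixel sample.  ``parameter`` is k for ``mean_plus_k_sd``
    (>= 0), the percentile in (0, 100] for ``percentile``, or the cutoff
    itself for ``fixed``.
    """
    if method == "fixed":
        return PositivityThreshold(marker, float(parameter), "fixed", float(parameter), control_id)
    px = _control_pixels(control, marker)
    if px.size == 0:
        raise ThresholdError("empty control sample")
    if method == "mean_plus_k_sd":
        if parameter < 0:
            raise ThresholdError("k must be >= 0")
        cutoff = float(px.mean() + parameter * px.std(ddof=0))
    elif method == "percentile":
        if not 0 < parameter <= 100:
            raise ThresholdError(f"percentile out of range: {parameter}")
        ordered = np.sort(px)
        rank = ceil(parameter / 100.0 * px.size)  # nearest-rank, 1-based
        cutoff = float(ordered[rank - 1])
    else:
        raise ThresholdError(f"unknown method {method!r}")
    return PositivityThreshold(marker, cutoff, method, float(parameter), control_id)


def apply_threshold(
    stack,
    marker: str,
    threshold: PositivityThreshold,
    within: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Boolean mask of pixels with intensity strictly above the cutoff,
    intersected with ``within`` when given."""
    if threshold.marker != marker:
        raise ThresholdError(
            f"threshold derived for {threshold.marker!r} applied to {marker!r}"
        )
    img = stack.channel(marker) if hasattr(stack, "channel") else np.asarray(stack)
    mask = img > threshold.cutoff
    if within is not None:
        mask = mask & np.asarray(within, bool)
    return mask
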