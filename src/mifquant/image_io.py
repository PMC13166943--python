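"""Reading multichannel microscopy images and writing result tables.

The canonical in-memory representation is a :class:`ChannelStack`: one
registered image field whose channels are addressed by biological role
(nuclear stain, plasma-membrane marker, total MET, phospho-MET, isotype
control) rather than by acquisition order.  Raster layout is row-major with
(row=0, col=0) at top-left; every mask produced downstream shares it.

Channels may arrive either as pages of a single multi-page TIFF or as one
single-page TIFF per channel; both dialects are mapped onto roles through a
:class:`ChannelMap`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Channel roles the pipeline understands.
CHANNEL_ROLES = (
    "nuclear_stain",
    "membrane_marker",
    "total_met",
    "phospho_met",
    "isotype_control",
)

#: Token written for undefined metric values (never 0).
MISSING_TOKEN = "NA"


class ImageIOError(ValueError):
    """Raised for unreadable files, bad channel maps, or invalid stacks."""


@dataclass
class ChannelMap:
    """Maps channel roles to channel indices in the source file(s).

    ``entries`` gives, for each role, the page/channel index inside its
    source TIFF.  ``pixel_size_um`` is the physical edge length of one pixel
    in micrometres; there is no default because acquisition calibration must
    be supplied explicitly.
    """

    entries: dict[str, int]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ImageIOError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for role in self.entries:
            if role not in CHANNEL_ROLES:
                raise ImageIOError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
        # index uniqueness applies when all roles share one file; it is
        # checked in read_multichannel_image for the single-file dialect


@dataclass
class ChannelStack:
    """One registered multichannel image field.

    channels : mapping from role to a 2-D non-negative intensity raster;
        all rasters share one (height, width).
    pixel_size_um : physical pixel edge in micrometres (> 0).
    bit_depth : nominal unsigned bit depth of the source data (8 or 16).
    """

    field_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageIOError("ChannelStack requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ImageIOError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ImageIOError(f"unknown channel role {role!r}")
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ImageIOError(f"channel {role!r} is not a 2-D raster")
            if np.any(arr < 0):
                raise ImageIOError(f"channel {role!r} has negative intensities")
            self.channels[role] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ImageIOError(f"mismatched channel shapes: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> tuple[str, ...]:
        # canonical role order, independent of source file order
        return tuple(r for r in CHANNEL_ROLES if r in self.channels)

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise ImageIOError(
                f"field {self.field_id!r} has no {role!r} channel "
                f"(available: {self.roles})"
            ) from None


def read_multichannel_image(
    path: str | os.PathLike | Mapping[str, str | os.PathLike],
    cmap: ChannelMap,
    field_id: str | None = None,
) -> ChannelStack:
    """Read a TIFF (or one TIFF per channel) into a :class:`ChannelStack`.

    Parameters
    ----------
    path
        Either a single multi-page/multichannel TIFF containing every mapped
        channel, or a mapping from role to a per-channel TIFF path (each
        file's page selected by the same :class:`ChannelMap` index, which is
        typically 0 for single-page exports).
    cmap
        Role-to-index map plus the physical pixel size.
    field_id
        Identifier for the field; defaults to the file stem.
    """
    channels: dict[str, np.ndarray] = {}
    if isinstance(path, Mapping):
        for role, idx in cmap.entries.items():
            if role not in path:
                raise ImageIOError(f"no file supplied for mapped role {role!r}")
            channels[role] = _read_channel(path[role], idx)
        if field_id is None:
            any_path = next(iter(path.values()))
            field_id = os.path.splitext(os.path.basename(os.fspath(any_path)))[0]
    else:
        indices = list(cmap.entries.values())
        if len(set(indices)) != len(indices):
            raise ImageIOError(f"channel indices must be unique, got {indices}")
        arr = _read_stack_array(path)
        n_channels = arr.shape[0]
        for role, idx in cmap.entries.items():
            if not 0 <= idx < n_channels:
                raise ImageIOError(
                    f"channel index out of range: {idx} for role {role!r} "
                    f"(file has {n_channels} channels)"
                )
            channels[role] = arr[idx]
        if field_id is None:
            field_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    bit_depth = max(_bit_depth(arr) for arr in channels.values())
    return ChannelStack(
        field_id=field_id,
        channels=channels,
        pixel_size_um=cmap.pixel_size_um,
        bit_depth=bit_depth,
    )


def write_multichannel_image(stack: ChannelStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF, pages in canonical role order."""
    arr = np.stack([stack.channel(r) for r in stack.roles])
    tifffile.imwrite(os.fspath(path), arr, photometric="minisblack")


def write_mask_tiff(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Export a boolean mask as an 8-bit 0/255 TIFF for visual QC."""
    tifffile.imwrite(os.fspath(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def _read_stack_array(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(os.fspath(path)):
        raise ImageIOError(f"missing file: {path}")
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ImageIOError(f"unsupported TIFF dimensionality {arr.shape} in {path}")
    return arr


def _read_channel(path: str | os.PathLike, idx: int) -> np.ndarray:
    arr = _read_stack_array(path)
    if not 0 <= idx < arr.shape[0]:
        raise ImageIOError(
            f"channel index out of range: {idx} (file {path} has {arr.shape[0]} channels)"
        )
    return arr[idx]


def _bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    return 16


# ---------------------------------------------------------------------------
# result tables


def quant_records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert ROIQuantRecord-like dataclasses to a DataFrame in documented
    column order, with undefined metrics as pandas NA."""
    from dataclasses import asdict

    if len(records) == 0:
        raise ImageIOError("no records to tabulate")
    rows = [asdict(r) if not isinstance(r, dict) else dict(r) for r in records]
    cols = list(rows[0].keys())
    for row in rows[1:]:
        if list(row.keys()) != cols:
            raise ImageIOError("heterogeneous record columns")
    df = pd.DataFrame(rows, columns=cols)
    return df


def write_quant_table(records: Sequence, path: str | os.PathLike) -> None:
    """Write one row per field/ROI as CSV.

    Undefined values (e.g. %MAP on a field with no membrane pixels) are
    rendered as ``NA``, never as 0.  Floats use the shortest round-trip
    representation, so re-reading reproduces every numeric value exactly,
    and identical inputs yield byte-identical files (no timestamps).
    """
    df = quant_records_to_frame(records)
    df.to_csv(
        os.fspath(path), index=False, na_rep=MISSING_TOKEN, lineterminator="\n",
        float_format=lambda x: repr(float(x)),  # shortest round-trip representation
    )


def read_quant_table(path: str | os.PathLike) -> pd.DataFrame:
    """Parse back a table written by :func:`write_quant_table`."""
    return pd.read_csv(
        os.fspath(path), na_values=[MISSING_TOKEN], keep_default_na=False,
        float_precision="round_trip",
    )
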