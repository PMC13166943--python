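"""Synthetic multichannel immunofluorescence scenes with exact ground truth.

Each scene is a field of non-overlapping disk-shaped cells: an interior
disk-shaped nucleus (bright in the nuclear-stain channel), an annular
plasma membrane (bright in the membrane-marker channel), and cytoplasm in
between.  Marker positivity (total MET, phospho-MET) is painted onto an
exact pixel subset of each compartment — floor(fraction * compartment size)
pixels chosen by the seeded generator — so ground-truth area fractions are
known exactly, then additive zero-mean Gaussian noise (clipped at 0) is
applied.

Presets span the expression tiers seen across gastric/colorectal carcinoma
lines: "negligible" (SNU-1-like, no MET), "moderate" (HT29-like), and
"high" (GTL-16-like, MET-amplified with constitutive activation), plus
nuclear-accumulation presets emulating ligand-driven nuclear phospho-MET.

A dose-response series rescales the phospho fractions by the Hill
inhibition factor 1 / (1 + (dose/IC50)^hill) while leaving total MET
unchanged — the pharmacodynamic signature of a selective MET kinase
inhibitor such as crizotinib.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .image_io import ChannelStack

COMPARTMENTS = ("background", "cytoplasm", "membrane", "nucleus")
MARKER_ROLES = ("total_met", "phospho_met")

#: baseline per-channel compartment intensity means (16-bit scale)
DEFAULT_INTENSITY: dict[str, dict[str, float]] = {
    "nuclear_stain": {"background": 100.0, "cytoplasm": 300.0, "membrane": 300.0, "nucleus": 3000.0},
    "membrane_marker": {"background": 100.0, "cytoplasm": 200.0, "membrane": 3000.0, "nucleus": 200.0},
    "total_met": {"background": 100.0, "cytoplasm": 100.0, "membrane": 100.0, "nucleus": 100.0},
    "phospho_met": {"background": 100.0, "cytoplasm": 100.0, "membrane": 100.0, "nucleus": 100.0},
}

#: intensity given to painted marker-positive pixels
DEFAULT_POSITIVE_MEAN = 2500.0

#: rejection-sampling attempts per cell before declaring the geometry unplaceable
PLACEMENT_ATTEMPTS = 500


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSceneSpec:
    """Generative parameters for one field.

    ``positive_fraction`` maps (marker, compartment) to the fraction of that
    compartment's pixels painted positive, e.g. ``{("phospho_met",
    "membrane"): 0.3}``.  The default geometry (256x256 px at 0.5 um/px,
    20 cells of radius 6-9 um, 1 um membrane, nucleus at 0.55 of the cell
    radius) and noise (SD 50 on a 16-bit scale with ~2400-count contrast)
    emulate a well-stained, moderately noisy 20x field.
    """

    height: int = 256
    width: int = 256
    pixel_size_um: float = 0.5
    n_cells: int = 20
    cell_radius_um: tuple[float, float] = (6.0, 9.0)
    membrane_thickness_um: float = 1.0
    nucleus_radius_fraction: float = 0.55
    intensity: dict[str, dict[str, float]] = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_INTENSITY.items()}
    )
    positive_mean: float = DEFAULT_POSITIVE_MEAN
    positive_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 50.0
    allow_touching: bool = False
    seed: int = 0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0 or self.pixel_size_um <= 0:
            raise SyntheticError("geometric parameters must be positive")
        if self.n_cells < 0:
            raise SyntheticError("n_cells must be >= 0")
        lo, hi = self.cell_radius_um
        if lo <= 0 or hi < lo:
            raise SyntheticError(f"invalid cell radius range {self.cell_radius_um}")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise SyntheticError("nucleus_radius_fraction must lie in (0, 1)")
        if self.membrane_thickness_um <= 0:
            raise SyntheticError("membrane_thickness_um must be positive")
        if self.nucleus_radius_fraction * lo >= lo - self.membrane_thickness_um:
            raise SyntheticError("nucleus does not fit inside the membrane annulus")
        for key, f in self.positive_fraction.items():
            marker, comp = key
            if marker not in MARKER_ROLES or comp not in COMPARTMENTS:
                raise SyntheticError(f"unknown (marker, compartment) {key}")
            if not 0 <= f <= 1:
                raise SyntheticError(f"positive fraction out of [0, 1]: {key} = {f}")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth for one generated scene."""

    cell_mask: np.ndarray
    nuclear_mask: np.ndarray
    membrane_mask: np.ndarray
    nucleus_count: int
    positive_masks: dict[tuple[str, str], np.ndarray]
    true_fraction: dict[tuple[str, str], float]  # achieved (painted/size), exact
    true_area_per_cell_um2: dict[str, float]

    def summary(self) -> dict:
        """JSON-serialisable sidecar content (masks regenerate from the seed)."""
        return {
            "nucleus_count": self.nucleus_count,
            "true_fraction": {f"{m}:{c}": v for (m, c), v in self.true_fraction.items()},
            "true_area_per_cell_um2": dict(self.true_area_per_cell_um2),
        }


def _place_cells(spec: SyntheticSceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk centres; radii in pixels."""
    lo_px = spec.cell_radius_um[0] / spec.pixel_size_um
    hi_px = spec.cell_radius_um[1] / spec.pixel_size_um
    cells: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    for i in range(spec.n_cells):
        for attempt in range(PLACEMENT_ATTEMPTS):
            r = rng.uniform(lo_px, hi_px)
            row = rng.uniform(r, spec.height - r)
            col = rng.uniform(r, spec.width - r)
            if spec.allow_touching or all(
                (row - cr) ** 2 + (col - cc) ** 2 > (r + pr + 1.0) ** 2
                for cr, cc, pr in cells
            ):
                cells.append((row, col, r))
                break
        else:
            raise SyntheticError(
                f"unplaceable geometry: cell {i + 1}/{spec.n_cells} not placed "
                f"after {PLACEMENT_ATTEMPTS} attempts"
            )
    return cells


def _disk_mask(shape, row, col, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def generate_scene(spec: SyntheticSceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render one field; deterministic given ``spec.seed``.

    Geometry, positive-pixel painting, and noise use three independent
    child streams of the seed, so an isotype control generated from the
    same spec (painting suppressed) shares bit-identical geometry channels.
    """
    geom_rng, paint_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )
    shape = (spec.height, spec.width)
    cells = _place_cells(spec, geom_rng)

    cell_mask = np.zeros(shape, bool)
    membrane_mask = np.zeros(shape, bool)
    nuclear_mask = np.zeros(shape, bool)
    thick_px = spec.membrane_thickness_um / spec.pixel_size_um
    for row, col, r in cells:
        cdisk = _disk_mask(shape, row, col, r)
        inner = _disk_mask(shape, row, col, r - thick_px)
        ndisk = _disk_mask(shape, row, col, r * spec.nucleus_radius_fraction)
        cell_mask |= cdisk
        membrane_mask |= cdisk & ~inner
        nuclear_mask |= ndisk
    cytoplasm_mask = cell_mask & ~membrane_mask & ~nuclear_mask
    comp_masks = {
        "background": ~cell_mask,
        "cytoplasm": cytoplasm_mask,
        "membrane": membrane_mask,
        "nucleus": nuclear_mask,
    }

    images: dict[str, np.ndarray] = {}
    for role, levels in spec.intensity.items():
        img = np.zeros(shape, float)
        for comp, mean in levels.items():
            img[comp_masks[comp]] = mean
        images[role] = img

    # paint exact positive-pixel subsets; iteration order fixed for determinism
    positive_masks: dict[tuple[str, str], np.ndarray] = {}
    true_fraction: dict[tuple[str, str], float] = {}
    for marker in MARKER_ROLES:
        for comp in COMPARTMENTS:
            f = spec.positive_fraction.get((marker, comp), 0.0)
            comp_idx = np.flatnonzero(comp_masks[comp])
            k = int(np.floor(f * comp_idx.size))
            pmask = np.zeros(shape, bool)
            if k > 0:
                chosen = paint_rng.choice(comp_idx, size=k, replace=False)
                pmask.flat[chosen] = True
                images[marker].flat[chosen] = spec.positive_mean
            positive_masks[(marker, comp)] = pmask
            true_fraction[(marker, comp)] = k / comp_idx.size if comp_idx.size else 0.0

    true_apc: dict[str, float] = {}
    for marker in MARKER_ROLES:
        painted = np.zeros(shape, bool)
        for comp in ("cytoplasm", "membrane", "nucleus"):
            painted |= positive_masks[(marker, comp)]
        area = int(painted.sum()) * spec.pixel_size_um**2
        true_apc[marker] = area / len(cells) if cells else 0.0

    max_val = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    channels: dict[str, np.ndarray] = {}
    for role in ("nuclear_stain", "membrane_marker", "total_met", "phospho_met"):
        img = images[role]
        if spec.noise_sd > 0:
            img = img + noise_rng.normal(0.0, spec.noise_sd, size=shape)
        channels[role] = np.clip(np.rint(img), 0, max_val).astype(dtype)

    stack = ChannelStack(
        field_id=f"scene_seed{spec.seed}",
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        bit_depth=spec.bit_depth,
    )
    truth = GroundTruth(
        cell_mask=cell_mask,
        nuclear_mask=nuclear_mask,
        membrane_mask=membrane_mask,
        nucleus_count=len(cells),
        positive_masks=positive_masks,
        true_fraction=true_fraction,
        true_area_per_cell_um2=true_apc,
    )
    return stack, truth


def generate_isotype_control(spec: SyntheticSceneSpec) -> ChannelStack:
    """Same geometry and seed, but marker channels carry background + noise
    only (every positive fraction forced to 0), emulating an isotype-stained
    serial section for threshold derivation."""
    ctrl_spec = replace(spec, positive_fraction={})
    stack, _ = generate_scene(ctrl_spec)
    stack.field_id = f"isotype_seed{spec.seed}"
    return stack


def hill_inhibition(dose: float, ic50: float, hill: float) -> float:
    """Fraction of baseline phospho signal remaining at ``dose``."""
    if ic50 <= 0:
        raise SyntheticError("ic50 must be > 0")
    if dose < 0:
        raise SyntheticError("dose must be >= 0")
    return 1.0 / (1.0 + (dose / ic50) ** hill)


@dataclass
class DoseScene:
    dose: float
    replicate: int
    stack: ChannelStack
    truth: GroundTruth


def generate_dose_response_series(
    base: SyntheticSceneSpec,
    doses: Iterable[float],
    ic50: float,
    hill: float = 1.0,
    n_reps: int = 4,
    seed: int = 0,
) -> list[DoseScene]:
    """Scenes for each (dose, replicate): phospho positive fractions scaled
    by the Hill factor, total MET untouched; replicate seeds derived
    deterministically as seed + running replicate index."""
    if n_reps < 1:
        raise SyntheticError("n_reps must be >= 1")
    out: list[DoseScene] = []
    idx = 0
    for dose in doses:
        scale = hill_inhibition(dose, ic50, hill)
        fractions = {
            key: (f * scale if key[0] == "phospho_met" else f)
            for key, f in base.positive_fraction.items()
        }
        for rep in range(n_reps):
            spec = replace(base, positive_fraction=fractions, seed=seed + idx)
            stack, truth = generate_scene(spec)
            stack.field_id = f"dose{dose:g}_rep{rep}"
            out.append(DoseScene(dose=float(dose), replicate=rep, stack=stack, truth=truth))
            idx += 1
    return out


# ---------------------------------------------------------------------------
# expression-tier and localisation presets

#: (marker, compartment) fractions per tier.  "negligible" mirrors a
#: MET-null line (SNU-1-like); "moderate" a line with intermediate MET
#: expression and activation (HT29-like); "high" a MET-amplified line with
#: constitutive, ligand-independent signalling (GTL-16/SNU-5-like).
PRESET_FRACTIONS: dict[str, dict[tuple[str, str], float]] = {
    "negligible": {},
    "moderate": {
        ("total_met", "membrane"): 0.35,
        ("total_met", "cytoplasm"): 0.15,
        ("phospho_met", "membrane"): 0.15,
        ("phospho_met", "cytoplasm"): 0.05,
    },
    "high": {
        ("total_met", "membrane"): 0.70,
        ("total_met", "cytoplasm"): 0.40,
        ("phospho_met", "membrane"): 0.55,
        ("phospho_met", "cytoplasm"): 0.25,
    },
    # ligand-driven nuclear accumulation of activated MET (HGF knock-in
    # pattern): wildtype ~30% nuclear phospho, HGF-overexpressing ~60%
    "nuclear_low": {
        ("total_met", "membrane"): 0.40,
        ("phospho_met", "membrane"): 0.20,
        ("phospho_met", "nucleus"): 0.30,
    },
    "nuclear_high": {
        ("total_met", "membrane"): 0.40,
        ("phospho_met", "membrane"): 0.20,
        ("phospho_met", "nucleus"): 0.60,
    },
}


def preset_spec(name: str, seed: int = 0, **overrides) -> SyntheticSceneSpec:
    """A scene spec for a named expression tier or localisation preset."""
    if name not in PRESET_FRACTIONS:
        raise SyntheticError(f"unknown preset {name!r}; known: {sorted(PRESET_FRACTIONS)}")
    return SyntheticSceneSpec(
        positive_fraction=dict(PRESET_FRACTIONS[name]), seed=seed, **overrides
    )
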