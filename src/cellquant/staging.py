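"""Cell volume from 2D masks, bud-ratio cell-cycle staging, and per-cell
mRNA concentration.

Budding yeast cells are close to solids of revolution around their major
axis, so a 3D volume can be reconstructed from a single 2D segmentation
mask: the mask is rotated so its major axis is horizontal and each 1-pixel
column of height h contributes a cylindrical slab π·(h/2)².  Cell-cycle
stage follows from bud presence, the bud-to-mother volume ratio (S below
0.3, G2/M at or above), and the nucleus count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CellRecord",
    "StageCall",
    "estimate_volume_from_mask",
    "classify_stage",
    "mrna_concentration",
    "stage_table",
]

#: Bud-to-mother volume ratio separating S from G2/M.
BUD_RATIO_THRESHOLD = 0.3

Stage = Literal["G1", "S", "G2M", "ambiguous"]


@dataclass
class CellRecord:
    """One segmented cell and what staging needs to know about it."""

    label: int
    volume_fl: float
    nuclei_count: int = 1
    bud_label: int | None = None
    bud_volume_fl: float | None = None
    bud_to_mother_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.volume_fl <= 0:
            raise ValueError("cell volume must be positive")
        if self.nuclei_count < 0:
            raise ValueError("nuclei_count must be >= 0")
        if self.bud_to_mother_ratio is None and self.bud_volume_fl is not None:
            self.bud_to_mother_ratio = self.bud_volume_fl / self.volume_fl
        if self.bud_to_mother_ratio is not None and self.bud_to_mother_ratio < 0:
            raise ValueError("bud-to-mother ratio must be >= 0")

    @property
    def budded(self) -> bool:
        return self.bud_label is not None


@dataclass(frozen=True)
class StageCall:
    """A cell-cycle stage with the rule that produced it."""

    stage: Stage
    rationale: str


def estimate_volume_from_mask(mask2d: np.ndarray, pixel_size_xy: float) -> float:
    """Cell volume (fL) from a 2D mask by solid-of-revolution reconstruction.

    The mask is rotated so its major axis is horizontal; every 1-pixel-wide
    column of height h_i then contributes π·(h_i/2)² voxel units, and the sum
    is converted to fL with the cubed pixel size (1 µm³ = 1 fL).  The
    estimate is rotation- and translation-invariant up to discretization.
    """
    mask2d = np.asarray(mask2d).astype(bool)
    if pixel_size_xy <= 0:
        raise ValueError("pixel size must be positive")
    if not mask2d.any():
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask2d)
    coords = np.stack([ys, xs], axis=1).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T) if centered.shape[0] > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]  # (dy, dx) of major axis
    angle_deg = float(np.degrees(np.arctan2(major[0], major[1])))
    rotated = ndimage.rotate(mask2d.astype(np.uint8), angle_deg, reshape=True, order=0)
    heights = rotated.astype(bool).sum(axis=0)
    heights = heights[heights > 0]
    volume_vox = float(np.pi * np.sum((heights / 2.0) ** 2))
    return volume_vox * pixel_size_xy**3


def classify_stage(cell: CellRecord) -> StageCall:
    """Assign G1 / S / G2M / ambiguous from bud state and nucleus count.

    Unbudded cells with one nucleus are G1.  Budded cells with two nuclei
    are G2/M regardless of the ratio; otherwise the bud-to-mother volume
    ratio decides: below 0.3 is S-phase, at or above 0.3 is G2/M (the exact
    boundary value is assigned to G2/M).  Unbudded cells with a nucleus
    count other than one cannot be staged automatically and are flagged
    ambiguous for visual inspection.
    """
    if not cell.budded:
        if cell.nuclei_count == 1:
            return StageCall("G1", "unbudded with one nucleus")
        return StageCall(
            "ambiguous",
            f"unbudded with {cell.nuclei_count} nuclei: needs visual inspection",
        )
    if cell.nuclei_count == 2:
        return StageCall("G2M", "budded with two nuclei")
    if cell.bud_to_mother_ratio is None:
        raise ValueError(
            f"cell {cell.label} is budded but has no bud volume or ratio"
        )
    if cell.bud_to_mother_ratio < BUD_RATIO_THRESHOLD:
        return StageCall(
            "S", f"bud-to-mother ratio {cell.bud_to_mother_ratio:.3f} < 0.3"
        )
    return StageCall(
        "G2M", f"bud-to-mother ratio {cell.bud_to_mother_ratio:.3f} >= 0.3"
    )


def mrna_concentration(spot_count: float, volume_fl: float) -> float:
    """mRNA concentration as spots per fL: count divided by cell volume."""
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    return spot_count / volume_fl


def stage_table(
    cells: list[CellRecord],
    spot_counts: dict[int, int] | None = None,
    include_bud_spots: bool = True,
) -> pd.DataFrame:
    """Stage a list of cells and tabulate volume, ratio, stage and spots.

    Spots detected in a bud's footprint are credited to the mother row when
    ``include_bud_spots`` is true, since the bud is part of the mother's
    cell cycle until division; the bud itself then gets no row of its own.
    """
    spot_counts = spot_counts or {}
    bud_labels = {c.bud_label for c in cells if c.bud_label is not None}
    rows = []
    for cell in cells:
        if cell.label in bud_labels:
            continue  # buds are reported with their mothers
        call = classify_stage(cell)
        n_spots = spot_counts.get(cell.label, 0)
        volume = cell.volume_fl
        if cell.budded:
            if include_bud_spots:
                n_spots += spot_counts.get(cell.bud_label, 0)
            if cell.bud_volume_fl is not None:
                volume += cell.bud_volume_fl
        rows.append(
            {
                "cell_id": cell.label,
                "volume_fl": volume,
                "ratio": cell.bud_to_mother_ratio,
                "nuclei": cell.nuclei_count,
                "stage": call.stage,
                "rationale": call.rationale,
                "n_spots": n_spots,
                "conc_per_fl": mrna_concentration(n_spots, volume),
            }
        )
    return pd.DataFrame(rows)
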