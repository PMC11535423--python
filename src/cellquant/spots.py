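"""3D smFISH spot calling with resolution-limited merging and iterative
effect-size filtering.

Single mRNA molecules imaged by smFISH appear as diffraction-limited spots in
a widefield z-stack.  The caller proceeds in five steps:

1. mild 3D Gaussian prefilter of the stack;
2. global automatic thresholding (triangle / Li / Otsu) to segment candidate
   spot signal;
3. 3D local-maxima detection restricted to the segmented signal;
4. merging of peaks that fall within a single resolution-limited spheroid
   (lateral radius set by the optical resolution, axial radius ~1 µm) —
   only the brightest peak of such a group can be a distinct molecule;
5. iterative filtering on Glass' delta, the effect size of each peak's
   intensity against the background of its own cell; peaks below a threshold
   are discarded, their voxels rejoin the background, and the filter repeats
   until the peak count is stable.

Coordinates are 0-based voxel indices in (z, y, x) order; physical distances
are in µm.  Cell segmentation masks are 2D label images (0 = background)
shared by all z-planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_li, threshold_otsu, threshold_triangle

__all__ = [
    "ImageStack",
    "SpheroidRadii",
    "SpotCallingConfig",
    "SpotCandidate",
    "Spot",
    "resolution_spheroid_radii",
    "prefilter",
    "segment_spot_signal",
    "find_local_maxima",
    "merge_resolution_limited",
    "glass_delta",
    "iterative_effect_size_filter",
    "call_spots",
    "count_spots_per_cell",
]

_THRESHOLD_FUNCS = {
    "triangle": threshold_triangle,
    "li": threshold_li,
    "otsu": threshold_otsu,
}


@dataclass(frozen=True)
class ImageStack:
    """A 3D fluorescence stack with its physical voxel sizes.

    Parameters
    ----------
    data
        Intensities, shape ``(z, y, x)``, arbitrary units.
    voxel_size_z
        Axial step between planes, µm.
    pixel_size_xy
        Lateral pixel size, µm.
    """

    data: np.ndarray
    voxel_size_z: float
    pixel_size_xy: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {data.shape}")
        if min(data.shape) < 1:
            raise ValueError("stack dimensions must be positive")
        if self.voxel_size_z <= 0 or self.pixel_size_xy <= 0:
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class SpheroidRadii:
    """Radii of the resolution-limited spheroid, in µm and in voxels."""

    r_xy_um: float
    r_z_um: float
    r_xy_vox: float
    r_z_vox: float

    def __post_init__(self) -> None:
        if min(self.r_xy_um, self.r_z_um, self.r_xy_vox, self.r_z_vox) <= 0:
            raise ValueError("spheroid radii must be positive")


@dataclass
class SpotCallingConfig:
    """Parameters of the five-step spot caller.

    ``effect_size_threshold`` (τ) is the Glass'-delta cutoff; in practice it
    is chosen per experiment by inspecting images, typically in [0.2, 1.0].
    ``lateral_coefficient`` is the prefactor of the lateral resolution limit
    r_xy = coeff · λ / NA; the default 0.61 reproduces the conventional
    resolution-limit radius for a 1.4 NA objective.
    """

    numerical_aperture: float = 1.4
    emission_wavelength_nm: float = 668.0
    prefilter_sigma: float = 0.75
    threshold_method: Literal["triangle", "li", "otsu"] = "triangle"
    effect_size_threshold: float = 0.5
    z_radius_um: float = 1.0
    lateral_coefficient: float = 0.61
    max_iterations: int | None = None
    intensity_source: Literal["filtered", "raw"] = "filtered"

    def __post_init__(self) -> None:
        if self.effect_size_threshold <= 0:
            raise ValueError("effect_size_threshold must be > 0")
        if self.numerical_aperture <= 0 or self.emission_wavelength_nm <= 0:
            raise ValueError("NA and wavelength must be > 0")
        if self.z_radius_um <= 0:
            raise ValueError("z_radius_um must be > 0")


@dataclass(frozen=True)
class SpotCandidate:
    """A local intensity maximum, prior to effect-size filtering."""

    center: tuple[int, int, int]  # (z, y, x) voxel
    intensity: float
    cell_label: int = 0


@dataclass(frozen=True)
class Spot(SpotCandidate):
    """A candidate that survived the iterative effect-size filter."""

    glass_delta: float = np.nan


def resolution_spheroid_radii(
    numerical_aperture: float,
    emission_wavelength_nm: float,
    z_radius_um: float = 1.0,
    voxel_size_z: float = 0.240,
    pixel_size_xy: float = 0.103,
    lateral_coefficient: float = 0.61,
) -> SpheroidRadii:
    """Radii of the spheroid within which two peaks cannot be resolved.

    The lateral radius is the optical resolution limit
    ``lateral_coefficient * wavelength / NA`` (0.61 λ/NA by default, i.e. the
    Rayleigh-criterion radius); the axial radius is set directly because the
    axial extent of the widefield PSF is far larger than the z-sampling and
    is treated as a fixed 1 µm scale.

    Examples
    --------
    >>> r = resolution_spheroid_radii(1.4, 668.0)
    >>> round(r.r_xy_um, 3)
    0.291
    """
    if numerical_aperture <= 0:
        raise ValueError("numerical aperture must be > 0")
    if emission_wavelength_nm <= 0:
        raise ValueError("emission wavelength must be > 0")
    if z_radius_um <= 0 or voxel_size_z <= 0 or pixel_size_xy <= 0:
        raise ValueError("radii and voxel sizes must be > 0")
    r_xy_um = lateral_coefficient * (emission_wavelength_nm / 1000.0) / numerical_aperture
    return SpheroidRadii(
        r_xy_um=r_xy_um,
        r_z_um=z_radius_um,
        r_xy_vox=r_xy_um / pixel_size_xy,
        r_z_vox=z_radius_um / voxel_size_z,
    )


def prefilter(data: np.ndarray, sigma_voxels: float = 0.75) -> np.ndarray:
    """Isotropic (in voxel units) 3D Gaussian smoothing; ``sigma=0`` is the
    identity."""
    if sigma_voxels < 0:
        raise ValueError("sigma must be >= 0")
    data = np.asarray(data, dtype=float)
    if sigma_voxels == 0:
        return data.copy()
    return ndimage.gaussian_filter(data, sigma=sigma_voxels)


def segment_spot_signal(filtered: np.ndarray, method: str = "triangle") -> np.ndarray:
    """Global automatic threshold of the filtered stack.

    Returns a boolean mask of voxels strictly above the threshold.  A
    constant image has no spot signal: an empty mask is returned with a
    warning rather than an error.
    """
    try:
        func = _THRESHOLD_FUNCS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; choose from "
            f"{sorted(_THRESHOLD_FUNCS)}"
        ) from None
    filtered = np.asarray(filtered, dtype=float)
    if np.ptp(filtered) == 0:
        warnings.warn("constant image: no spot signal segmented", stacklevel=2)
        return np.zeros(filtered.shape, dtype=bool)
    return filtered > func(filtered)


def find_local_maxima(filtered: np.ndarray, spot_mask: np.ndarray) -> list[SpotCandidate]:
    """3D local maxima (26-connectivity) restricted to the segmented signal.

    A voxel is a candidate iff it lies inside ``spot_mask`` and its value is
    ≥ all of its 26 neighbours.  A connected plateau of equal-valued maxima
    collapses to a single candidate at its lexicographically smallest
    (z, y, x) voxel, so flat-topped spots are not double counted.
    """
    filtered = np.asarray(filtered, dtype=float)
    spot_mask = np.asarray(spot_mask, dtype=bool)
    if spot_mask.shape != filtered.shape:
        raise ValueError("mask shape must match stack shape")
    if not spot_mask.any():
        return []
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = filtered >= ndimage.maximum_filter(filtered, footprint=footprint, mode="nearest")
    local_max &= spot_mask
    if not local_max.any():
        return []
    # collapse connected plateaus of equal value to one representative
    labels, n = ndimage.label(local_max, structure=footprint)
    candidates: list[SpotCandidate] = []
    for idx_arrays in _component_indices(labels, n):
        coords = np.stack(idx_arrays, axis=1)
        # lexicographic minimum over (z, y, x)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        z, y, x = (int(v) for v in coords[order[0]])
        candidates.append(SpotCandidate(center=(z, y, x), intensity=float(filtered[z, y, x])))
    candidates.sort(key=lambda c: c.center)
    return candidates


def _component_indices(labels: np.ndarray, n: int):
    objs = ndimage.find_objects(labels)
    for lab, sl in zip(range(1, n + 1), objs):
        sub = labels[sl] == lab
        idx = np.nonzero(sub)
        yield tuple(ix + s.start for ix, s in zip(idx, sl))


def _spheroid_offsets(radii: SpheroidRadii) -> np.ndarray:
    """Integer (dz, dy, dx) offsets inside the resolution-limited spheroid."""
    nz = int(np.floor(radii.r_z_vox))
    nxy = int(np.floor(radii.r_xy_vox))
    dz, dy, dx = np.mgrid[-nz : nz + 1, -nxy : nxy + 1, -nxy : nxy + 1]
    inside = (dz / radii.r_z_vox) ** 2 + (dy / radii.r_xy_vox) ** 2 + (
        dx / radii.r_xy_vox
    ) ** 2 <= 1.0
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def _within_spheroid(
    a: tuple[int, int, int], b: tuple[int, int, int], radii: SpheroidRadii
) -> bool:
    dz = (a[0] - b[0]) / radii.r_z_vox
    dy = (a[1] - b[1]) / radii.r_xy_vox
    dx = (a[2] - b[2]) / radii.r_xy_vox
    return dz * dz + dy * dy + dx * dx <= 1.0


def merge_resolution_limited(
    candidates: Sequence[SpotCandidate], radii: SpheroidRadii
) -> list[SpotCandidate]:
    """Discard peaks that cannot be distinct molecules.

    Greedy by decreasing intensity (ties broken by lexicographic center): a
    candidate is dropped iff it lies within the spheroid of an
    already-retained brighter candidate.  After merging, no retained peak
    lies inside another retained peak's spheroid.
    """
    ordered = sorted(candidates, key=lambda c: (-c.intensity, c.center))
    retained: list[SpotCandidate] = []
    for cand in ordered:
        if not any(_within_spheroid(cand.center, kept.center, radii) for kept in retained):
            retained.append(cand)
    retained.sort(key=lambda c: c.center)
    return retained


def _peak_voxels(
    center: tuple[int, int, int],
    offsets: np.ndarray,
    shape: tuple[int, int, int],
    cell_footprint: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices of a peak's spheroid, clipped to the stack and,
    optionally, to the (y, x) footprint of the peak's cell."""
    pts = offsets + np.asarray(center)
    ok = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < shape[1])
        & (pts[:, 2] >= 0)
        & (pts[:, 2] < shape[2])
    )
    pts = pts[ok]
    if cell_footprint is not None:
        pts = pts[cell_footprint[pts[:, 1], pts[:, 2]]]
    return pts[:, 0], pts[:, 1], pts[:, 2]


def glass_delta(
    data: np.ndarray,
    center: tuple[int, int, int],
    cell_footprint: np.ndarray,
    all_peaks_mask: np.ndarray,
    radii: SpheroidRadii,
) -> float:
    """Glass' delta of one peak against its cell's background.

    Δ = (mean of peak voxels − mean of background voxels) / sd of background
    voxels, with the population (n-denominator) standard deviation.  Peak
    voxels are those inside the resolution-limited spheroid around
    ``center``, clipped to the stack and to the cell's (y, x) footprint.
    Background voxels lie inside the cell footprint (all z-planes) but
    outside every detected peak's spheroid (``all_peaks_mask``).

    Raises
    ------
    ValueError
        If the background is empty or has zero spread.
    """
    data = np.asarray(data, dtype=float)
    cell_footprint = np.asarray(cell_footprint, dtype=bool)
    offsets = _spheroid_offsets(radii)
    zz, yy, xx = _peak_voxels(center, offsets, data.shape, cell_footprint)
    if zz.size == 0:
        raise ValueError("peak spheroid contains no voxels inside the cell")
    cell3d = np.broadcast_to(cell_footprint, data.shape)
    bg = cell3d & ~all_peaks_mask
    bg_values = data[bg]
    if bg_values.size == 0:
        raise ValueError("empty background: cell is fully covered by peaks")
    sd = float(bg_values.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate background (zero standard deviation)")
    return float((data[zz, yy, xx].mean() - bg_values.mean()) / sd)


def _peaks_mask(
    shape: tuple[int, int, int],
    centers: Sequence[tuple[int, int, int]],
    offsets: np.ndarray,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for center in centers:
        zz, yy, xx = _peak_voxels(center, offsets, shape, None)
        mask[zz, yy, xx] = True
    return mask


def iterative_effect_size_filter(
    data: np.ndarray,
    candidates: Sequence[SpotCandidate],
    cell_labels: np.ndarray,
    radii: SpheroidRadii,
    effect_size_threshold: float,
    max_iterations: int | None = None,
) -> list[Spot]:
    """Iteratively discard peaks whose Glass' delta falls below τ.

    Each round recomputes every surviving peak's Δ — voxels of peaks
    discarded in earlier rounds rejoin the background — and removes peaks
    with Δ < τ.  The loop stops when the peak count no longer changes; since
    the count is strictly decreasing until the fixed point, at most
    ``len(candidates) + 1`` rounds are needed.
    """
    if effect_size_threshold <= 0:
        raise ValueError("effect_size_threshold must be > 0")
    data = np.asarray(data, dtype=float)
    cell_labels = np.asarray(cell_labels)
    if cell_labels.shape != data.shape[1:]:
        raise ValueError("cell label mask must match the stack's (y, x) shape")
    offsets = _spheroid_offsets(radii)
    footprints = {
        int(lab): cell_labels == lab for lab in np.unique(cell_labels) if lab != 0
    }
    surviving = [
        c for c in candidates if int(cell_labels[c.center[1], c.center[2]]) != 0
    ]
    limit = max_iterations if max_iterations is not None else len(surviving) + 1
    deltas: dict[tuple[int, int, int], float] = {}
    for _ in range(limit + 1):
        mask = _peaks_mask(data.shape, [c.center for c in surviving], offsets)
        deltas = {}
        for cand in surviving:
            lab = int(cell_labels[cand.center[1], cand.center[2]])
            deltas[cand.center] = glass_delta(
                data, cand.center, footprints[lab], mask, radii
            )
        kept = [c for c in surviving if deltas[c.center] >= effect_size_threshold]
        if len(kept) == len(surviving):
            return [
                Spot(
                    center=c.center,
                    intensity=c.intensity,
                    cell_label=int(cell_labels[c.center[1], c.center[2]]),
                    glass_delta=deltas[c.center],
                )
                for c in kept
            ]
        surviving = kept
    raise RuntimeError("effect-size filter did not reach a fixed point")


def call_spots(
    stack: ImageStack,
    cell_labels: np.ndarray,
    nuclei_labels: np.ndarray | None = None,
    config: SpotCallingConfig | None = None,
) -> pd.DataFrame:
    """Run the full five-step spot caller on one stack.

    Parameters
    ----------
    stack
        The smFISH channel with voxel sizes.
    cell_labels
        2D cell segmentation label image (0 = background), aligned with the
        stack's (y, x) axes.
    nuclei_labels
        Optional 2D nuclei label image; unused by the caller itself but
        validated for alignment so downstream staging can rely on it.
    config
        Spot-calling parameters; defaults are used when omitted.

    Returns
    -------
    pandas.DataFrame
        One row per called spot: ``cell_id, z_vox, y_vox, x_vox, z_um,
        y_um, x_um, intensity, glass_delta``.
    """
    if config is None:
        config = SpotCallingConfig()
    cell_labels = np.asarray(cell_labels)
    if cell_labels.ndim != 2 or cell_labels.shape != stack.shape[1:]:
        raise ValueError(
            "cell label mask must be 2D and match the stack's (y, x) shape"
        )
    if nuclei_labels is not None:
        nuclei_labels = np.asarray(nuclei_labels)
        if nuclei_labels.shape != cell_labels.shape:
            raise ValueError("nuclei mask must match the cell mask shape")

    radii = resolution_spheroid_radii(
        config.numerical_aperture,
        config.emission_wavelength_nm,
        z_radius_um=config.z_radius_um,
        voxel_size_z=stack.voxel_size_z,
        pixel_size_xy=stack.pixel_size_xy,
        lateral_coefficient=config.lateral_coefficient,
    )
    filtered = prefilter(stack.data, config.prefilter_sigma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # blank stacks are a valid input here
        mask = segment_spot_signal(filtered, config.threshold_method)
    candidates = find_local_maxima(filtered, mask)
    if config.intensity_source == "raw":
        candidates = [
            SpotCandidate(center=c.center, intensity=float(stack.data[c.center]))
            for c in candidates
        ]
    merged = merge_resolution_limited(candidates, radii)
    spots = iterative_effect_size_filter(
        stack.data,
        merged,
        cell_labels,
        radii,
        config.effect_size_threshold,
        config.max_iterations,
    )
    rows = [
        {
            "cell_id": s.cell_label,
            "z_vox": s.center[0],
            "y_vox": s.center[1],
            "x_vox": s.center[2],
            "z_um": s.center[0] * stack.voxel_size_z,
            "y_um": s.center[1] * stack.pixel_size_xy,
            "x_um": s.center[2] * stack.pixel_size_xy,
            "intensity": s.intensity,
            "glass_delta": s.glass_delta,
        }
        for s in spots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "z_vox",
            "y_vox",
            "x_vox",
            "z_um",
            "y_um",
            "x_um",
            "intensity",
            "glass_delta",
        ],
    )


def count_spots_per_cell(
    spot_table: pd.DataFrame, cell_labels: np.ndarray
) -> pd.DataFrame:
    """Per-cell spot counts, including zero counts for spot-free cells."""
    cell_labels = np.asarray(cell_labels)
    cells = [int(lab) for lab in np.unique(cell_labels) if lab != 0]
    counts = spot_table.groupby("cell_id").size() if len(spot_table) else pd.Series(dtype=int)
    return pd.DataFrame(
        {"cell_id": cells, "n_spots": [int(counts.get(c, 0)) for c in cells]}
    )
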