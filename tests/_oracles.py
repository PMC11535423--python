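"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written as plain Python loops over voxels,
sharing no code path with the package internals, so agreement is evidence of
correctness rather than of shared bugs.  Only intended for small arrays.
"""

from __future__ import annotations

import numpy as np


def brute_glass_delta(
    data: np.ndarray,
    center: tuple[int, int, int],
    cell_footprint: np.ndarray,
    peak_centers: list[tuple[int, int, int]],
    r_z_vox: float,
    r_xy_vox: float,
) -> float:
    """Glass' delta by looping over every voxel of the stack."""

    def in_spheroid(z, y, x, c):
        return ((z - c[0]) / r_z_vox) ** 2 + ((y - c[1]) / r_xy_vox) ** 2 + (
            (x - c[2]) / r_xy_vox
        ) ** 2 <= 1.0

    peak_vals, bg_vals = [], []
    nz, ny, nx = data.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not cell_footprint[y, x]:
                    continue
                if in_spheroid(z, y, x, center):
                    peak_vals.append(data[z, y, x])
                if not any(in_spheroid(z, y, x, c) for c in peak_centers):
                    bg_vals.append(data[z, y, x])
    peak_vals = np.array(peak_vals)
    bg_vals = np.array(bg_vals)
    return float((peak_vals.mean() - bg_vals.mean()) / bg_vals.std(ddof=0))


def brute_otsu_mask(image: np.ndarray) -> np.ndarray:
    """Otsu foreground by exhaustive search over candidate thresholds,
    maximizing the between-class variance of the split."""
    flat = image.ravel().astype(float)
    levels = np.unique(flat)
    best_t, best_var = None, -1.0
    for i in range(len(levels) - 1):
        t = (levels[i] + levels[i + 1]) / 2.0
        lo, hi = flat[flat <= t], flat[flat > t]
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return image > best_t


def brute_local_maxima(
    data: np.ndarray, mask: np.ndarray
) -> list[tuple[int, int, int]]:
    """26-neighbour local maxima inside a mask, with connected equal-valued
    plateaus collapsed to their lexicographically smallest voxel."""
    nz, ny, nx = data.shape
    is_max = np.zeros_like(mask, dtype=bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                ok = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                if data[zz, yy, xx] > data[z, y, x]:
                                    ok = False
                if ok:
                    is_max[z, y, x] = True
    # group connected maxima (26-connectivity) by flood fill
    seen = np.zeros_like(is_max)
    reps = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not is_max[z, y, x] or seen[z, y, x]:
                    continue
                stack_, comp = [(z, y, x)], []
                seen[z, y, x] = True
                while stack_:
                    cz, cy, cx = stack_.pop()
                    comp.append((cz, cy, cx))
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                zz, yy, xx = cz + dz, cy + dy, cx + dx
                                if (
                                    0 <= zz < nz
                                    and 0 <= yy < ny
                                    and 0 <= xx < nx
                                    and is_max[zz, yy, xx]
                                    and not seen[zz, yy, xx]
                                ):
                                    seen[zz, yy, xx] = True
                                    stack_.append((zz, yy, xx))
                reps.append(min(comp))
    return sorted(reps)


def brute_iterative_filter(
    data: np.ndarray,
    centers: list[tuple[int, int, int]],
    cell_labels: np.ndarray,
    r_z_vox: float,
    r_xy_vox: float,
    tau: float,
) -> tuple[list[tuple[int, int, int]], list[list[tuple[int, int, int]]]]:
    """Fixed point of the effect-size filter by plain re-iteration.

    Returns the surviving centers and the history of per-round discards.
    """
    surviving = list(centers)
    history = []
    while True:
        deltas = {}
        for c in surviving:
            lab = cell_labels[c[1], c[2]]
            foot = cell_labels == lab
            deltas[c] = brute_glass_delta(
                data, c, foot, surviving, r_z_vox, r_xy_vox
            )
        discarded = [c for c in surviving if deltas[c] < tau]
        history.append(discarded)
        if not discarded:
            return surviving, history
        surviving = [c for c in surviving if c not in discarded]
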