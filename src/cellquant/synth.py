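"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the data types the analysis consumes: smFISH z-stacks
of diffraction-limited spots on cellular backgrounds, single-cell reporter
production traces, transcription-shut-off mRNA decay series, cell populations
with volume-dependent transcript counts, and qPCR Cq tables.  Every generator
is driven by an explicit integer seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spots import ImageStack
from .traces import Trace

__all__ = [
    "StackSimParams",
    "TraceSimParams",
    "DecaySimParams",
    "PopulationSimParams",
    "generate_smfish_stack",
    "generate_trace",
    "generate_decay_series",
    "generate_population",
    "generate_cq_table",
]


@dataclass
class StackSimParams:
    """Geometry, optics and noise of a simulated smFISH acquisition.

    Defaults mirror a typical widefield setup for budding yeast: 20 z-planes
    at a 240 nm axial step, ~0.1 µm lateral pixels, and a diffraction-limited
    spot modelled as a separable 3D Gaussian (σ_xy ≈ 0.10 µm, σ_z ≈ 0.35 µm).
    """

    shape: tuple[int, int, int] = (20, 128, 128)
    voxel_size_z: float = 0.240
    pixel_size_xy: float = 0.103
    psf_sigma_xy: float = 0.10
    psf_sigma_z: float = 0.35
    n_spots: int = 10
    spot_amplitude: float = 50.0
    cell_background: float = 10.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    n_cells: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("stack shape must be positive")
        if self.voxel_size_z <= 0 or self.pixel_size_xy <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("PSF sigmas must be positive")
        if self.spot_amplitude < 0 or self.cell_background < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.n_spots < 0 or self.n_cells < 1:
            raise ValueError("n_spots >= 0 and n_cells >= 1 required")


@dataclass
class TraceSimParams:
    """Plateau–rise–plateau reporter production trace.

    The noiseless profile is a first plateau at ``p_g1``, a linear rise of
    height ``produced_amount`` over ``rise_duration`` starting at
    ``rise_start``, and a second plateau at ``p_g1 + produced_amount`` —
    the canonical shape of a histone-reporter amount during one cell cycle.
    """

    p_g1: float = 100.0
    produced_amount: float = 100.0
    rise_start: float = 30.0
    rise_duration: float = 30.0
    sampling_interval: float = 3.0
    total_duration: float = 120.0
    noise_sd: float = 0.0
    autofluor_alpha: float = 0.0
    autofluor_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0 or self.total_duration <= 0:
            raise ValueError("sampling interval and duration must be positive")
        if self.rise_start < 0 or self.rise_duration < 0:
            raise ValueError("rise window must be non-negative")
        if self.rise_start + self.rise_duration > self.total_duration:
            raise ValueError("rise window must lie within the trace")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def p_g2(self) -> float:
        return self.p_g1 + self.produced_amount


@dataclass
class DecaySimParams:
    """Single-exponential mRNA decay after transcription shut-off.

    Samples follow ``exp(-ln2 · t / half_life) · (1 + ε)`` with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.  The default
    time points span the 0–60 min window of a shut-off time course.
    """

    half_life: float = 20.0
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0)
    n_replicates: int = 4
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        if len(self.timepoints) < 2 or self.timepoints[0] != 0:
            raise ValueError("timepoints must start at 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class PopulationSimParams:
    """A population of cells with volume-dependent transcript counts.

    Volumes are lognormal around ``volume_median_fl``; the expected count at
    volume V is ``c · V**scaling_exponent``.  ``scaling_exponent = 1`` gives
    volume-proportional amounts (constant concentration, 'scaling' genes);
    ``scaling_exponent = 0`` gives constant amounts per cell (histone-like).
    """

    n_cells: int = 2000
    volume_median_fl: float = 55.0
    volume_sigma: float = 0.25
    scaling_exponent: float = 1.0
    c: float = 1.0
    poisson_noise: bool = True
    condition: str = "YPD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.volume_median_fl <= 0 or self.volume_sigma < 0:
            raise ValueError("volume parameters must be positive")
        if self.c < 0:
            raise ValueError("c must be >= 0")


def _cell_layout(
    shape: tuple[int, int, int], n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Lay out ``n_cells`` elliptical cells on a grid; nuclei are concentric
    smaller ellipses.  Returns (cell labels, nuclei labels), both 2D."""
    _, ny, nx = shape
    ncols = math.ceil(math.sqrt(n_cells))
    nrows = math.ceil(n_cells / ncols)
    tile_y, tile_x = ny / nrows, nx / ncols
    yy, xx = np.mgrid[0:ny, 0:nx]
    cells = np.zeros((ny, nx), dtype=np.int32)
    nuclei = np.zeros((ny, nx), dtype=np.int32)
    for k in range(n_cells):
        r, c = divmod(k, ncols)
        cy, cx = (r + 0.5) * tile_y, (c + 0.5) * tile_x
        ry = 0.40 * tile_y * rng.uniform(0.9, 1.0)
        rx = 0.34 * tile_x * rng.uniform(0.9, 1.0)
        ell = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        cells[ell] = k + 1
        nuc = ((yy - cy) / (0.4 * ry)) ** 2 + ((xx - cx) / (0.4 * rx)) ** 2 <= 1.0
        nuclei[nuc] = k + 1
    return cells, nuclei


def _add_gaussian_spot(
    stack: np.ndarray,
    center: tuple[float, float, float],
    amplitude: float,
    sigma_vox: tuple[float, float, float],
) -> None:
    """Add a separable 3D Gaussian in place, evaluated on a ±5σ window."""
    lo, hi = [], []
    for c, s, n in zip(center, sigma_vox, stack.shape):
        lo.append(max(0, int(np.floor(c - 5 * s))))
        hi.append(min(n, int(np.ceil(c + 5 * s)) + 1))
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    g = amplitude * np.exp(
        -((zz - center[0]) ** 2) / (2 * sigma_vox[0] ** 2)
        - ((yy - center[1]) ** 2) / (2 * sigma_vox[1] ** 2)
        - ((xx - center[2]) ** 2) / (2 * sigma_vox[2] ** 2)
    )
    stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += g


def generate_smfish_stack(
    params: StackSimParams,
) -> tuple[ImageStack, np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate an smFISH z-stack with cells, nuclei and known spots.

    Returns
    -------
    stack : ImageStack
        Noisy float stack: per-cell background plus Gaussian spots, with
        optional Poisson noise on (signal + background) followed by additive
        Gaussian read noise, clipped at 0.
    cells, nuclei : ndarray
        2D label images (0 = outside).
    ground_truth : pandas.DataFrame
        One row per simulated spot: ``spot_id, cell_label, z, y, x,
        amplitude`` with sub-voxel (float) centers.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    cells, nuclei = _cell_layout(params.shape, params.n_cells, rng)

    sigma_vox = (
        params.psf_sigma_z / params.voxel_size_z,
        params.psf_sigma_xy / params.pixel_size_xy,
        params.psf_sigma_xy / params.pixel_size_xy,
    )
    clean = np.zeros(params.shape, dtype=float)
    clean += params.cell_background * (cells > 0)[None, :, :]

    records = []
    z_lo, z_hi = 0.15 * nz, 0.85 * nz  # keep spots away from stack faces
    # minimum center-to-center separation keeps simulated molecules resolvable
    min_sep_vox = 4.0
    for lab in range(1, params.n_cells + 1):
        ys, xs = np.nonzero(cells == lab)
        if params.n_spots > 0 and ys.size < params.n_spots:
            raise ValueError(
                f"cell {lab} has {ys.size} pixels, cannot place {params.n_spots} spots"
            )
        placed: list[tuple[float, float, float]] = []
        attempts = 0
        while len(placed) < params.n_spots:
            attempts += 1
            if attempts > 1000 * max(params.n_spots, 1):
                raise ValueError(
                    f"could not place {params.n_spots} separated spots in cell {lab}"
                )
            i = rng.integers(ys.size)
            pos = (
                float(rng.uniform(z_lo, z_hi)),
                float(ys[i] + rng.uniform(-0.5, 0.5)),
                float(xs[i] + rng.uniform(-0.5, 0.5)),
            )
            if any(
                (pos[0] - q[0]) ** 2 + (pos[1] - q[1]) ** 2 + (pos[2] - q[2]) ** 2
                < min_sep_vox**2
                for q in placed
            ):
                continue
            placed.append(pos)
        for pos in placed:
            _add_gaussian_spot(clean, pos, params.spot_amplitude, sigma_vox)
            records.append(
                {
                    "spot_id": len(records),
                    "cell_label": lab,
                    "z": pos[0],
                    "y": pos[1],
                    "x": pos[2],
                    "amplitude": params.spot_amplitude,
                }
            )

    noisy = rng.poisson(clean).astype(float) if params.poisson_noise else clean.copy()
    if params.read_noise_sd > 0:
        noisy += rng.normal(0.0, params.read_noise_sd, size=noisy.shape)
    np.clip(noisy, 0.0, None, out=noisy)

    stack = ImageStack(noisy, params.voxel_size_z, params.pixel_size_xy)
    ground_truth = pd.DataFrame(
        records, columns=["spot_id", "cell_label", "z", "y", "x", "amplitude"]
    )
    return stack, cells, nuclei, ground_truth


def generate_trace(
    params: TraceSimParams, volume_trace: np.ndarray | None = None
) -> Trace:
    """Simulate one plateau–rise–plateau production trace.

    If ``volume_trace`` is given (fL per time point), a volume-dependent
    autofluorescence ``alpha + beta · V`` is added on top of the signal,
    emulating the background a reporter measurement must be corrected for.
    """
    times = np.arange(0.0, params.total_duration + params.sampling_interval / 2,
                      params.sampling_interval)
    rise_end = params.rise_start + params.rise_duration
    if params.rise_duration > 0:
        frac = np.clip((times - params.rise_start) / params.rise_duration, 0.0, 1.0)
    else:
        frac = (times >= rise_end).astype(float)
    clean = params.p_g1 + params.produced_amount * frac
    rng = np.random.default_rng(params.seed)
    intensities = clean + rng.normal(0.0, params.noise_sd, size=times.size) \
        if params.noise_sd > 0 else clean.copy()
    volumes = None
    if volume_trace is not None:
        volumes = np.asarray(volume_trace, dtype=float)
        if volumes.shape != times.shape:
            raise ValueError("volume_trace length must match the sampled times")
        intensities = intensities + params.autofluor_alpha + params.autofluor_beta * volumes
    elif params.autofluor_alpha != 0 or params.autofluor_beta != 0:
        if params.autofluor_beta != 0:
            raise ValueError("volume_trace required for volume-dependent autofluorescence")
        intensities = intensities + params.autofluor_alpha
    return Trace(times=times, intensities=intensities, volumes=volumes)


def generate_decay_series(params: DecaySimParams) -> pd.DataFrame:
    """Simulate a transcription-shut-off decay time course.

    Returns a long-format table ``time_min, replicate, rel_conc`` where the
    noiseless value at time t is ``exp(-ln2 · t / half_life)`` (1.0 at t=0).
    """
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.timepoints, dtype=float)
    rows = []
    for rep in range(params.n_replicates):
        clean = np.exp(-np.log(2.0) * t / params.half_life)
        noisy = clean * (1.0 + rng.normal(0.0, params.noise_cv, size=t.size))
        noisy = np.clip(noisy, 1e-9, None)
        for ti, vi in zip(t, noisy):
            rows.append({"time_min": ti, "replicate": rep, "rel_conc": vi})
    return pd.DataFrame(rows)


def generate_population(params: PopulationSimParams) -> pd.DataFrame:
    """Simulate single cells with volumes and mRNA counts.

    Returns ``cell_id, volume_fl, mrna_count, condition``.  With Poisson
    noise the counts are integers drawn with mean ``c · V**a``; without
    noise the exact expectation is stored (possibly non-integer), which is
    the right input for exact-recovery checks.
    """
    rng = np.random.default_rng(params.seed)
    volumes = params.volume_median_fl * np.exp(
        rng.normal(0.0, params.volume_sigma, size=params.n_cells)
    )
    mean_counts = params.c * volumes**params.scaling_exponent
    counts = rng.poisson(mean_counts).astype(float) if params.poisson_noise else mean_counts
    return pd.DataFrame(
        {
            "cell_id": np.arange(params.n_cells),
            "volume_fl": volumes,
            "mrna_count": counts,
            "condition": params.condition,
        }
    )


def generate_cq_table(
    genes: list[str],
    conditions: list[str],
    true_log2_rel: dict[tuple[str, str], float],
    cq_ref: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_biological: int = 4,
    n_technical: int = 3,
    technical_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate a qPCR Cq table with technical triplicates.

    The noiseless gene Cq is ``cq_ref - log2(relative concentration)``;
    biological noise (sd ``noise_sd``) is shared by a sample's technical
    replicates, technical noise (sd ``technical_noise_sd``) is per well.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for cond in conditions:
            log2_rel = true_log2_rel[(gene, cond)]
            for bio in range(n_biological):
                bio_noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                for tech in range(n_technical):
                    tech_noise = (
                        rng.normal(0.0, technical_noise_sd)
                        if technical_noise_sd > 0
                        else 0.0
                    )
                    rows.append(
                        {
                            "gene": gene,
                            "condition": cond,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "cq": cq_ref - log2_rel + bio_noise + tech_noise,
                            "cq_ref": cq_ref,
                        }
                    )
    return pd.DataFrame(rows)
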