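"""Single-cell fluorescence trace quantification.

A trace is the total reporter fluorescence of one cell sampled at regular
intervals (3 min by default) over one cell cycle.  For a cell-cycle gene
expressed in a burst, the profile is a plateau (P_G1), a roughly linear rise
during the production phase, and a second plateau (P_G2).  This module fits
and subtracts volume-dependent autofluorescence, computes the amount produced
during the cycle (difference of 4-point end medians), and delimits the
production phase by 10% threshold crossings of the two plateau levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Trace",
    "ProductionSummary",
    "AutofluorModel",
    "fit_autofluorescence",
    "correct_autofluorescence",
    "produced_amount",
    "production_phase",
]


@dataclass(frozen=True)
class Trace:
    """A single-cell fluorescence time series.

    ``times`` are minutes and must be strictly increasing with at least 8
    samples, so that the two non-overlapping 4-point end medians used for
    the produced amount are defined.  ``volumes`` (fL, optional) are needed
    for volume-dependent autofluorescence correction.
    """

    times: np.ndarray
    intensities: np.ndarray
    cell_id: int | None = None
    volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if times.ndim != 1 or times.shape != intensities.shape:
            raise ValueError("times and intensities must be matching 1D arrays")
        if times.size < 8:
            raise ValueError("a trace needs at least 8 time points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if self.volumes is not None:
            volumes = np.asarray(self.volumes, dtype=float)
            if volumes.shape != times.shape:
                raise ValueError("volumes must match times in length")
            object.__setattr__(self, "volumes", volumes)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ProductionSummary:
    """Produced amount and production-phase timing of one trace.

    ``t_start`` is the last sampled time still below 1.1·P_G1 and ``t_end``
    the first sampled time above 0.9·P_G2; ``duration = t_end - t_start``.
    """

    produced_amount: float
    p_g1: float
    p_g2: float
    t_start: float
    t_end: float
    duration: float


@dataclass(frozen=True)
class AutofluorModel:
    """Linear autofluorescence model ``alpha + beta · V`` fitted from cells
    that express no fluorescent protein, per nutrient condition."""

    alpha: float
    beta: float
    condition: str = ""


def fit_autofluorescence(
    volumes: np.ndarray, intensities: np.ndarray, condition: str = ""
) -> AutofluorModel:
    """Least-squares line through control-cell (volume, intensity) pairs.

    With fewer than 3 cells the fit is refused; if all volumes coincide the
    slope is unidentifiable and a constant model (beta = 0, alpha = mean
    intensity) is returned.
    """
    volumes = np.asarray(volumes, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if volumes.shape != intensities.shape or volumes.ndim != 1:
        raise ValueError("volumes and intensities must be matching 1D arrays")
    if volumes.size < 3:
        raise ValueError("need at least 3 control cells")
    if np.ptp(volumes) == 0:
        return AutofluorModel(alpha=float(intensities.mean()), beta=0.0,
                              condition=condition)
    beta, alpha = np.polyfit(volumes, intensities, 1)
    return AutofluorModel(alpha=float(alpha), beta=float(beta), condition=condition)


def correct_autofluorescence(trace: Trace, model: AutofluorModel) -> Trace:
    """Subtract ``alpha + beta · V_t`` from a trace.

    Negative corrected values are retained: clipping would bias the 4-point
    medians of dim traces.  A volume series is required whenever beta ≠ 0.
    """
    if model.beta != 0:
        if trace.volumes is None:
            raise ValueError(
                "trace has no volume series but the autofluorescence model is "
                "volume-dependent (beta != 0)"
            )
        af = model.alpha + model.beta * trace.volumes
    else:
        af = model.alpha
    return Trace(
        times=trace.times,
        intensities=trace.intensities - af,
        cell_id=trace.cell_id,
        volumes=trace.volumes,
    )


def produced_amount(trace: Trace) -> float:
    """Amount produced over the cycle: median of the last four samples minus
    median of the first four samples."""
    if len(trace) < 8:
        raise ValueError("need at least 8 time points")
    first = float(np.median(trace.intensities[:4]))
    last = float(np.median(trace.intensities[-4:]))
    return last - first


def production_phase(trace: Trace, k_plateau: int = 4) -> ProductionSummary:
    """Delimit the production phase by 10% plateau-threshold crossings.

    The plateau levels are the means of the first and last ``k_plateau``
    samples (P_G1, P_G2).  The production phase runs from the last sampled
    time with intensity < 1.1·P_G1 to the first sampled time with intensity
    > 0.9·P_G2 (strict inequalities).  The caller must supply a trace whose
    first/last ``k_plateau`` samples are plateau-only.

    Raises
    ------
    ValueError
        If either threshold is never crossed, or the crossings are out of
        order (e.g. a flat trace, where 0.9·P_G2 < 1.1·P_G1).
    """
    if k_plateau < 1:
        raise ValueError("k_plateau must be >= 1")
    if len(trace) < 2 * k_plateau:
        raise ValueError("trace too short for the requested plateau extent")
    intens = trace.intensities
    p_g1 = float(intens[:k_plateau].mean())
    p_g2 = float(intens[-k_plateau:].mean())
    lo, hi = 1.1 * p_g1, 0.9 * p_g2
    # strict inequalities: a sample exactly at a threshold does not satisfy
    # the condition, including when the equality is only broken by float
    # round-off of the 1.1/0.9 factors
    below = np.nonzero((intens < lo) & ~np.isclose(intens, lo, rtol=1e-9, atol=0))[0]
    above = np.nonzero((intens > hi) & ~np.isclose(intens, hi, rtol=1e-9, atol=0))[0]
    if below.size == 0 or above.size == 0:
        raise ValueError("degenerate plateaus: threshold never crossed")
    t_start = float(trace.times[below[-1]])
    t_end = float(trace.times[above[0]])
    if t_end < t_start:
        raise ValueError("degenerate plateaus: crossings out of order")
    return ProductionSummary(
        produced_amount=produced_amount(trace),
        p_g1=p_g1,
        p_g2=p_g2,
        t_start=t_start,
        t_end=t_end,
        duration=t_end - t_start,
    )
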