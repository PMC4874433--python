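"""Spatio-temporal statistics of growth fronts.

These functions link generation number (time) to tissue depth or radius
(space).  For the bounded diffusive-Eden strip the depth distribution of a
generation reaches a stationary shape whose variance matches the tissue
width ``N`` — the genealogical face of the KPZ roughness law
``W_sat ~ N^(1/2)`` — whereas unbounded radial growth has no stationary
deviation distribution: the spread of a generation keeps increasing with
its label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .eden import EdenResult

__all__ = [
    "GenerationDepthStats",
    "FrontWidthSeries",
    "generation_depth_stats",
    "deviation_distribution",
    "front_width_series",
    "radial_stats",
]


@dataclass
class GenerationDepthStats:
    """Per-replicate depth (or radius) statistics of one generation label."""

    generation: int
    means: np.ndarray      # per-replicate mean depth of generation-g cells
    variances: np.ndarray  # per-replicate variance of that depth
    mean_of_means: float
    mean_of_variances: float

    @property
    def n_replicates(self) -> int:
        return int(self.means.size)


@dataclass
class FrontWidthSeries:
    """Front width (std of boundary depth) sampled along a run."""

    widths: np.ndarray
    events_per_sample: int
    w_sat: float  # mean width over the second half of the run


def _axis_values(result: EdenResult, g: int, radial: bool) -> np.ndarray:
    cells = result.genealogy.cells_of_generation(g)
    if cells.size == 0:
        raise ValueError(f"generation {g} absent from replicate")
    coords = result.genealogy.coords[cells]
    if radial:
        return np.sqrt((coords.astype(np.float64) ** 2).sum(axis=1))
    return coords[:, 0].astype(np.float64)


def _stats(ensemble: Sequence[EdenResult], g: int, radial: bool) -> GenerationDepthStats:
    means, variances = [], []
    for res in ensemble:
        v = _axis_values(res, g, radial)
        means.append(v.mean())
        variances.append(v.var())
    means = np.asarray(means)
    variances = np.asarray(variances)
    return GenerationDepthStats(
        generation=g,
        means=means,
        variances=variances,
        mean_of_means=float(means.mean()),
        mean_of_variances=float(variances.mean()),
    )


def generation_depth_stats(ensemble: Sequence[EdenResult], g: int) -> GenerationDepthStats:
    """Mean and variance of tissue depth of generation-``g`` cells.

    Within each replicate the ``N_g`` cells carrying label ``g`` are pooled
    and their depth mean/variance computed; the ensemble summaries are the
    mean of means and the mean of variances.  Every replicate must contain
    generation ``g`` (run with ``complete=g`` so membership is final).
    """
    return _stats(ensemble, g, radial=False)


def radial_stats(ensemble: Sequence[EdenResult], g: int) -> GenerationDepthStats:
    """Same statistics on the Euclidean radius from the founder (unbounded)."""
    return _stats(ensemble, g, radial=True)


def deviation_distribution(ensemble: Sequence[EdenResult], g: int,
                           radial: bool = False) -> np.ndarray:
    """Pooled deviations of generation-``g`` positions from replicate means.

    For the bounded diffusive-Eden strip these deviations are stationary in
    ``g`` with variance approximately equal to the tissue width ``N``; for
    unbounded growth their variance increases without bound.
    """
    out = []
    for res in ensemble:
        v = _axis_values(res, g, radial)
        out.append(v - v.mean())
    return np.concatenate(out)


def front_width_series(result: EdenResult) -> FrontWidthSeries:
    """Front-width series of a bounded run and its saturated value.

    The width is the standard deviation of the boundary cells' depths,
    sampled every ``params.width_every`` growth events by the simulator.
    ``w_sat`` averages the second half of the series, discarding the
    growth transient.
    """
    w = np.asarray(result.widths, dtype=np.float64)
    if w.size == 0:
        raise ValueError("run was not recorded with width_every > 0")
    half = w.size // 2
    return FrontWidthSeries(
        widths=w,
        events_per_sample=result.params.width_every,
        w_sat=float(w[half:].mean()),
    )
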