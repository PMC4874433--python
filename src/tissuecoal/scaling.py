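"""Scaling fits connecting coalescence times to KPZ growth exponents.

The central empirical facts this module quantifies:

* the mean time to the MRCA of a bounded Eden strip grows as ``N^z`` with
  the KPZ dynamic exponent (``z = 3/2`` in (1+1) dimensions, ``~1.61`` in
  (2+1)), so an Eden tissue of width ``N`` behaves like a neutral
  Wright-Fisher population of *effective* size ``N_e = N^z``;
* for unbounded (tumour-like) growth the fraction of lineages surviving
  ``h`` generations back decays as ``h^-alpha`` with
  ``alpha = (d - 1)/z`` (2/3 for the two-dimensional colony), while
  neutral reproduction on a linearly growing population has ``alpha = 1``;
  raising the surviving fraction to ``1/alpha`` maps one law onto the
  other (the effective-lineage transform).

All exponent estimates are unweighted ordinary least squares on log-log
transformed means.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy import stats

__all__ = [
    "ScalingFit",
    "SurvivalFit",
    "fit_dynamic_exponent",
    "effective_population",
    "effective_population_from_fit",
    "rescale_and_overlap",
    "fit_survival_exponent",
    "effective_lineage_transform",
]


@dataclass
class ScalingFit:
    """Log-log OLS of a response (e.g. mean TMRCA, W_sat) against width."""

    widths: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    stderr: float

    def predict(self, widths) -> np.ndarray:
        return np.exp(self.intercept) * np.asarray(widths, float) ** self.slope

    def to_json(self) -> str:
        d = asdict(self)
        d["widths"] = list(map(float, self.widths))
        d["responses"] = list(map(float, self.responses))
        return json.dumps(d)


@dataclass
class SurvivalFit:
    """Power-law fit of fractional lineage survival versus look-back height."""

    heights: np.ndarray
    fractions: np.ndarray
    alpha: float      # magnitude of the decay exponent
    intercept: float
    stderr: float


def fit_dynamic_exponent(widths, responses) -> ScalingFit:
    """OLS of ``log(response)`` on ``log(width)``; the slope estimates ``z``.

    ``responses`` are typically ensemble-mean TMRCAs, one per width;
    at least three distinct positive widths are required.
    """
    widths = np.asarray(widths, dtype=np.float64)
    responses = np.asarray(responses, dtype=np.float64)
    if np.unique(widths).size < 3:
        raise ValueError("need at least three distinct widths")
    if np.any(responses <= 0) or np.any(widths <= 0):
        raise ValueError("widths and responses must be positive")
    res = stats.linregress(np.log(widths), np.log(responses))
    return ScalingFit(
        widths=widths,
        responses=responses,
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
    )


def effective_population(N: int, z: float = 1.5) -> float:
    """Wright-Fisher population size equivalent to an Eden strip of width N.

    ``N_e = N**z``: rescaling Eden look-back time by ``1/N_e`` aligns its
    coalescence-probability curve with the neutral model's ``t/N`` curve.
    ``z = 1`` recovers the Wright-Fisher identity ``N_e = N``.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if z <= 0:
        raise ValueError("z must be positive")
    return float(N) ** z


def effective_population_from_fit(fit: ScalingFit, N: int) -> float:
    """Effective population dictated by a fitted TMRCA-scaling regression.

    The neutral model's mean whole-population TMRCA is ``2 N_e``, so the
    Wright-Fisher size whose coalescent time scale matches an Eden strip of
    width ``N`` is half the regression's predicted mean TMRCA,
    ``N_e = exp(intercept) * N**slope / 2``.  The amplitude of the TMRCA
    law is not universal (it depends on the growth micro-rules), so using
    the full regression rather than the bare ``N**z`` keeps the time
    rescaling aligned across models.
    """
    return float(fit.predict(N) / 2.0)


def rescale_and_overlap(curve_a, timescale_a, curve_b, timescale_b) -> float:
    """Sup-norm distance between two curves on a common rescaled-time grid.

    Each curve is indexed by look-back generation; generation ``t`` maps to
    rescaled time ``t / timescale``.  Both are linearly interpolated onto a
    grid covering the intersection of their rescaled supports.  Used to
    quantify the visual collapse of coalescence-probability and normalized
    lineage curves.
    """
    a = np.asarray(curve_a, dtype=np.float64)
    b = np.asarray(curve_b, dtype=np.float64)
    ta = np.arange(a.size) / float(timescale_a)
    tb = np.arange(b.size) / float(timescale_b)
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if hi <= lo:
        raise ValueError("curves have no overlapping rescaled-time support")
    grid = np.linspace(lo, hi, 2048)
    return float(np.abs(np.interp(grid, ta, a) - np.interp(grid, tb, b)).max())


def fit_survival_exponent(n_lineages, n_total=None, h_min: int = 5,
                          h_max: int | None = None) -> SurvivalFit:
    """Fit the lineage-survival exponent ``alpha``.

    ``n_lineages[h]`` is the (mean) number of distinct ancestral lineages
    ``h`` generations back of the sampled final generation; the fractional
    survival ``N_h`` is ``n_lineages[h] / n_lineages[0]`` (the fraction of
    the sampled lineages that survive to height ``h``).  The fit is OLS of
    ``log(N_h)`` on ``log(h)`` over the intermediate window
    ``h_min <= h <= h_max`` (default ``h_max`` is a third of the recorded
    look-back time): below ``h_min`` the decay is distorted by
    multiple-merger transients, and in the last two thirds of the history
    the shrinking total population forces coalescence and breaks the pure
    power law.  ``alpha`` is reported as the magnitude of the decay
    exponent.

    ``n_total`` (the population ``h`` generations before sampling) is only
    validated here; it enters the companion
    :func:`effective_lineage_transform`.
    """
    n_lin = np.asarray(n_lineages, dtype=np.float64)
    if n_total is not None:
        n_tot = np.asarray(n_total, dtype=np.float64)
        if n_lin.shape != n_tot.shape:
            raise ValueError("lineage and total arrays must have equal length")
        if np.any(n_lin > n_tot):
            raise ValueError("lineage counts cannot exceed population totals")
    h = np.arange(n_lin.size)
    if h_max is None:
        h_max = (n_lin.size - 1) // 3
    sel = (h >= h_min) & (h <= h_max) & (n_lin > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than three usable heights in fit range")
    frac = n_lin[sel] / n_lin[0]
    res = stats.linregress(np.log(h[sel]), np.log(frac))
    return SurvivalFit(
        heights=h[sel],
        fractions=frac,
        alpha=float(-res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
    )


def effective_lineage_transform(n_lineages, n_total, alpha: float) -> np.ndarray:
    """Map an ``h^-alpha`` survival law onto the neutral ``h^-1`` law.

    Returns ``N_T * (N_lin / N_T) ** (1/alpha)``: the lineage count an
    equivalent neutral (``alpha = 1``) process would show.  With
    ``alpha = 1`` this is the identity.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_lin = np.asarray(n_lineages, dtype=np.float64)
    n_tot = np.asarray(n_total, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n_tot * (n_lin / n_tot) ** (1.0 / alpha)
    return out
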