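"""Ensemble experiment drivers reproducing the study's scaling analyses.

Each function runs many replicates of one growth model, traces the
genealogies backwards and reduces them to the quantity of interest
(mean TMRCA per width, coalescence-probability curves, lineage-survival
curves, front statistics).  Replicate seeds are derived from a master seed
through :func:`replicate_seeds` so every experiment is reproducible and
replicates are independent.

Default problem sizes are chosen so a full sweep runs in minutes on a
single core while leaving the fitted exponents' statistical errors well
below the tolerances quoted for them; they can be scaled up freely.
"""

from __future__ import annotations

import numpy as np

from .eden import EdenParams, EdenResult, LatticeConfig, simulate_eden
from .genealogy import trace_lineages
from .neutral import GrowthSchedule, WFParams, simulate_wf, wf_tmrca_ensemble
from .scaling import ScalingFit, fit_dynamic_exponent

__all__ = [
    "replicate_seeds",
    "DIFFUSION_RATE",
    "eden_horizon",
    "diffusive_eden_params",
    "eden_tmrca_sample",
    "tmrca_scaling",
    "eden_coalescence_curve",
    "wf_coalescence_curve",
    "linear_growth_lineage_curves",
    "unbounded_lineage_curves",
    "unbounded_generation_count",
    "saturated_widths",
    "diffusive_ensemble",
]

#: calibrated hop rate of the diffusive-Eden model: one hop attempt per
#: growth event on average (cells move and reproduce at equal rates)
DIFFUSION_RATE = 1.0


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent replicate seeds from a master seed.

    Uses ``numpy.random.SeedSequence(master_seed).spawn`` and reduces each
    child to a 31-bit integer accepted by every simulator in the package.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return np.array(
        [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)], dtype=np.int64
    )


def eden_horizon(width: int, dimension: int = 2) -> int:
    """Simulation depth used for TMRCA measurements of a bounded strip.

    Mean TMRCA grows like ``N^z``; the horizon is a fixed multiple of that
    scale, deep enough that non-coalescence is negligible (well under 1%
    of replicates at every width used here).
    """
    if dimension == 2:
        return int(3 * width ** 1.5) + 40
    return int(15 * width ** 1.61) + 60


def diffusive_eden_params(width: int, G: int, seed: int, **kw) -> EdenParams:
    """Bounded diffusive-Eden strip at the calibrated diffusion rate."""
    return EdenParams(
        lattice=LatticeConfig("bounded", 2, width),
        G=G, seed=seed, p_move=DIFFUSION_RATE, complete=G, **kw,
    )


def eden_tmrca_sample(width: int, reps: int, seed: int, *, dimension: int = 2,
                      p_move: float = 0.0, G: int | None = None) -> np.ndarray:
    """TMRCAs of the completed final generation for ``reps`` Eden replicates.

    Entries are -1 where the sample did not coalesce within the horizon.
    """
    if G is None:
        G = eden_horizon(width, dimension)
    seeds = replicate_seeds(seed, reps)
    out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        res = simulate_eden(EdenParams(
            lattice=LatticeConfig("bounded", dimension, width),
            G=G, seed=int(seeds[r]), p_move=p_move, complete=G,
        ))
        t = trace_lineages(res.genealogy, G).tmrca
        out[r] = -1 if t is None else t
    return out


def tmrca_scaling(widths, reps: int, seed: int, *, dimension: int = 2,
                  p_move: float = 0.0) -> tuple[ScalingFit, dict]:
    """Mean-TMRCA-versus-width regression for a family of bounded strips.

    Replicates that fail to coalesce within the horizon are excluded from
    the per-width means and counted in the returned summary.
    """
    means, info = [], {"widths": list(widths), "n_not_coalesced": [],
                       "reps": reps, "mean_tmrca": []}
    for i, N in enumerate(widths):
        ts = eden_tmrca_sample(N, reps, seed + i, dimension=dimension,
                               p_move=p_move)
        ok = ts[ts >= 0]
        info["n_not_coalesced"].append(int((ts < 0).sum()))
        info["mean_tmrca"].append(float(ok.mean()))
        means.append(ok.mean())
    fit = fit_dynamic_exponent(widths, means)
    return fit, info


def _tmrca_ecdf(tmrcas: np.ndarray, tmax: int) -> np.ndarray:
    """P(coalesced by t) for t = 0..tmax from a TMRCA sample (-1 = never)."""
    c = np.zeros(tmax + 1)
    valid = tmrcas[(tmrcas >= 0) & (tmrcas <= tmax)]
    np.add.at(c, valid, 1)
    return np.cumsum(c) / tmrcas.size


def eden_coalescence_curve(width: int, reps: int, seed: int, *,
                           p_move: float = DIFFUSION_RATE) -> np.ndarray:
    """Coalescence-probability curve of a bounded (diffusive) Eden strip."""
    G = eden_horizon(width)
    ts = eden_tmrca_sample(width, reps, seed, p_move=p_move, G=G)
    return _tmrca_ecdf(ts, G)


def wf_coalescence_curve(N: int, reps: int, seed: int,
                         G: int | None = None) -> np.ndarray:
    """Coalescence-probability curve of the constant-``N`` layer model."""
    if G is None:
        G = 20 * N
    ts = wf_tmrca_ensemble(N, G, reps, seed)
    return _tmrca_ecdf(ts, G)


def linear_growth_lineage_curves(G: int, lam: float, reps: int, seed: int,
                                 N0: float = 1.0):
    """Mean lineage curve and totals for the linear-growth neutral model.

    Returns ``(mean_lineages, totals)`` where ``mean_lineages[h]`` is the
    ensemble-mean number of distinct ancestors ``h`` generations back of
    the final generation and ``totals[h]`` the population size ``h``
    generations before sampling.
    """
    sched = GrowthSchedule(kind="linear", N0=N0, lam=lam)
    seeds = replicate_seeds(seed, reps)
    acc = np.zeros(G + 1)
    for r in range(reps):
        gen = simulate_wf(WFParams(schedule=sched, G=G, seed=int(seeds[r])))
        acc += trace_lineages(gen, G).counts
    totals = sched.sizes(G)[::-1].astype(np.float64)
    return acc / reps, totals


def unbounded_lineage_curves(G: int, reps: int, seed: int):
    """Mean lineage curve and totals for the unbounded Eden colony.

    The colony is grown until generation ``G`` is complete, all
    generation-``G`` cells are traced back to the founder, and the mean
    per-generation population (``totals[h]`` = cells labelled ``G - h``)
    is returned alongside.
    """
    seeds = replicate_seeds(seed, reps)
    lin = np.zeros(G + 1)
    tot = np.zeros(G + 1)
    for r in range(reps):
        res = simulate_eden(EdenParams(
            lattice=LatticeConfig("unbounded", 2), G=G, seed=int(seeds[r]),
            init="single-seed", complete=G,
        ))
        lin += trace_lineages(res.genealogy, G).counts
        tot += res.genealogy.generation_counts()[:G + 1][::-1]
    return lin / reps, tot / reps


def unbounded_generation_count(G: int, reps: int, seed: int) -> np.ndarray:
    """Final cell count of generation ``G`` in the unbounded colony."""
    seeds = replicate_seeds(seed, reps)
    out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        res = simulate_eden(EdenParams(
            lattice=LatticeConfig("unbounded", 2), G=G, seed=int(seeds[r]),
            init="single-seed", complete=G,
        ))
        out[r] = res.genealogy.generation_counts()[G]
    return out


def saturated_widths(widths, reps: int, seed: int, *,
                     horizon_factor: float = 12.0) -> list[float]:
    """Mean saturated front width ``W_sat`` per strip width (plain Eden)."""
    out = []
    for i, N in enumerate(widths):
        G = int(horizon_factor * N ** 1.5) + 50
        seeds = replicate_seeds(seed + i, reps)
        vals = []
        for r in range(reps):
            res = simulate_eden(EdenParams(
                lattice=LatticeConfig("bounded", 2, N), G=G,
                seed=int(seeds[r]), width_every=N,
            ))
            w = res.widths
            vals.append(float(w[w.size // 2:].mean()))
        out.append(float(np.mean(vals)))
    return out


def diffusive_ensemble(N: int, G: int, reps: int, seed: int) -> list[EdenResult]:
    """Completed diffusive-Eden replicates for front statistics."""
    seeds = replicate_seeds(seed, reps)
    return [simulate_eden(diffusive_eden_params(N, G, int(s))) for s in seeds]
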