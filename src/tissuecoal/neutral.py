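"""Layer-by-layer neutral growth (Wright-Fisher) and exact-coalescent theory.

The layer model treats a bounded, unidirectionally growing tissue as a
sequence of layers of fixed width ``N``: every cell of layer ``t`` picks
its parent uniformly at random among the ``N`` cells of layer ``t - 1``.
This is exactly the haploid Wright-Fisher model with tissue depth playing
the role of forward time, so classical coalescent results apply: the
expected whole-population time to the MRCA approaches ``2N`` generations
and essentially all replicates coalesce within ``5N`` generations.

A linearly growing schedule (``N_t = round(N0 + lambda * t)``) models
neutral reproduction in an expanding population; traced backwards from the
final generation its genealogies are star-like, with a lineage-survival
law close to ``h^-1``.

Closed-form quantities use the haploid convention (pairwise coalescence
probability ``1/N`` per generation).  ``exact_ancestor_chain`` implements
the exact whole-population coalescent, in which several lineages may merge
in a single generation; its ancestor-count Markov chain serves as an
independent oracle for the simulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import stirling2

from .genealogy import Genealogy, trace_lineages

__all__ = [
    "GrowthSchedule",
    "WFParams",
    "simulate_wf",
    "simulate_linear_growth_wf",
    "kingman_expected_tmrca",
    "exact_ancestor_chain",
    "exact_expected_tmrca",
    "wf_tmrca_ensemble",
    "wf_lineage_curves",
]


@dataclass(frozen=True)
class GrowthSchedule:
    """Population size over forward time: constant ``N`` or ``N0 + lambda*t``.

    The default linear rate 2.78 cells per generation reproduces the
    growth of the unbounded Eden colony (about 1250 generation-450 cells,
    2500 at 900, 5000 at 1800); linear sizes are rounded to the nearest
    integer and floored at 1.
    """

    kind: str = "constant"  # "constant" | "linear"
    N: int = 100
    N0: float = 1.0
    lam: float = 2.78

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "constant" and self.N < 1:
            raise ValueError("N must be >= 1")
        if self.kind == "linear" and self.N0 < 1:
            raise ValueError("N0 must be >= 1")

    def sizes(self, G: int) -> np.ndarray:
        """Layer sizes for generations 0..G inclusive."""
        t = np.arange(G + 1)
        if self.kind == "constant":
            return np.full(G + 1, self.N, dtype=np.int64)
        s = np.rint(self.N0 + self.lam * t).astype(np.int64)
        return np.maximum(s, 1)


@dataclass(frozen=True)
class WFParams:
    schedule: GrowthSchedule
    G: int
    seed: int

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")


def simulate_wf(params: WFParams) -> Genealogy:
    """Simulate layer-by-layer neutral growth, returning the full genealogy.

    Generation ``t`` holds ``schedule.sizes(G)[t]`` cells at depth ``t``;
    each child's parent is drawn independently and uniformly from the
    previous layer.  Reproducible for a fixed seed.
    """
    sizes = params.schedule.sizes(params.G)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    total = int(offsets[-1])
    rng = np.random.default_rng(params.seed)

    parent = np.empty(total, dtype=np.int32)
    parent[: sizes[0]] = -1
    if np.all(sizes == sizes[0]):
        # constant width: a single vectorized draw for all generations
        n = int(sizes[0])
        draws = rng.integers(0, n, size=(params.G, n), dtype=np.int32)
        parent[n:] = (draws + offsets[:-2, None]).ravel()
    else:
        for t in range(1, params.G + 1):
            draws = rng.integers(0, sizes[t - 1], size=sizes[t], dtype=np.int32)
            parent[offsets[t]:offsets[t + 1]] = draws + offsets[t - 1]

    generation = np.repeat(np.arange(params.G + 1, dtype=np.int32), sizes)
    within = np.arange(total, dtype=np.int32) - offsets[:-1].astype(np.int32).repeat(sizes)
    coords = np.column_stack((generation, within))
    return Genealogy(parent=parent, generation=generation, coords=coords)


def simulate_linear_growth_wf(params: WFParams) -> Genealogy:
    """Neutral reproduction on a linearly growing population.

    With ``lam = 0`` the schedule is constant and this reduces exactly to
    :func:`simulate_wf` (identical output for identical seeds).
    """
    if params.schedule.kind != "linear":
        raise ValueError("simulate_linear_growth_wf requires a linear schedule")
    return simulate_wf(params)


def kingman_expected_tmrca(n: int, N: int) -> float:
    """Kingman-coalescent expected TMRCA of an ``n``-sample: ``2N(1 - 1/n)``.

    Haploid time scale: pairwise lineages coalesce at rate ``1/N`` per
    generation, so the exponential epochs with ``k`` lineages have mean
    ``2N / (k(k-1))`` and their sum telescopes to ``2N(1 - 1/n)``; for the
    whole population (``n = N``, large) this approaches the classical
    ``2N``-generation fixation time.
    """
    if n < 2:
        raise ValueError("need at least two lineages")
    if n > N:
        raise ValueError("sample cannot exceed population size")
    return 2.0 * N * (1.0 - 1.0 / n)


def exact_ancestor_chain(N: int) -> np.ndarray:
    """Ancestor-count transition matrix of the exact whole-population coalescent.

    Entry ``P[j, k]`` is the probability that ``j`` lineages have exactly
    ``k`` distinct parents one generation back in a population of constant
    size ``N``:

        P(k | j) = S(j, k) * N (N-1) ... (N-k+1) / N**j

    with ``S`` the Stirling number of the second kind.  Multiple mergers
    occur with positive probability, unlike in the Kingman limit.  Row 0 is
    unused (identity); rows 1..N are stochastic.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = 1.0
    for j in range(1, N + 1):
        denom = N ** j  # exact integer arithmetic, then one float division
        ff = 1
        for k in range(1, j + 1):
            ff *= N - k + 1
            if ff == 0:
                break
            P[j, k] = float(stirling2(j, k, exact=True) * ff) / float(denom)
    return P


def exact_expected_tmrca(N: int) -> float:
    """Expected whole-population TMRCA from the exact coalescent chain.

    Solves the absorbing Markov chain over ancestor counts (absorbing
    state 1) for the expected number of generations starting from ``N``
    lineages.
    """
    if N < 2:
        return 0.0
    P = exact_ancestor_chain(N)
    # transient states 2..N
    Q = P[2:, 2:]
    t = np.linalg.solve(np.eye(N - 1) - Q, np.ones(N - 1))
    return float(t[-1])


# ---------------------------------------------------------------------------
# fast ensemble helpers (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _wf_backward_tmrca(N, G, reps, seed):  # pragma: no cover - numba
    """TMRCA of the full final generation, by direct backward simulation.

    Tracing a constant-``N`` layer model backwards is itself a sequence of
    uniform parent draws, so the backward pass samples the identical
    distribution without materializing the forward table.  Returns -1 for
    replicates that do not coalesce within ``G`` generations.
    """
    np.random.seed(seed)
    out = np.empty(reps, np.int64)
    hit = np.zeros(N, np.uint8)
    for r in range(reps):
        k = N
        t = 0
        while k > 1 and t < G:
            kk = 0
            for _ in range(k):
                p = np.random.randint(0, N)
                if hit[p] == 0:
                    hit[p] = 1
                    kk += 1
            # reset flags
            for i in range(N):
                hit[i] = 0
            k = kk
            t += 1
        out[r] = t if k == 1 else -1
    return out


def wf_tmrca_ensemble(N: int, G: int, reps: int, seed: int) -> np.ndarray:
    """Whole-population TMRCA for ``reps`` constant-``N`` replicates.

    Uses the exact backward representation of the layer model (each of the
    ``k`` current lineages draws its parent uniformly among the ``N`` cells
    of the previous layer).  Entries are -1 where no MRCA was found within
    ``G`` generations.
    """
    return _wf_backward_tmrca(N, G, reps, int(seed) % 2**31)


def wf_lineage_curves(N: int, G: int, reps: int, seed: int) -> np.ndarray:
    """Matrix (reps, G+1) of distinct-lineage counts for the final generation.

    Runs the forward simulator and traces every replicate; replicate seeds
    are ``seed + r``.
    """
    sched = GrowthSchedule(kind="constant", N=N)
    mat = np.empty((reps, G + 1), dtype=np.int64)
    for r in range(reps):
        gen = simulate_wf(WFParams(schedule=sched, G=G, seed=seed + r))
        mat[r] = trace_lineages(gen, G).counts
    return mat
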