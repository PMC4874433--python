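"""Eden growth models on a square lattice, with full genealogy recording.

Two geometries are supported:

* **bounded** — a strip (1+1 dimensional) or slab (2+1 dimensional) of
  transverse width ``N`` with periodic transverse boundaries and unbounded
  depth; growth advances in the +depth direction from a full founder layer
  (or from a single seed).  This models unidirectional, width-limited
  tissue growth and belongs to the KPZ universality class.
* **unbounded** — radial growth from a single founder at the origin, the
  classical Eden model of a tumour or bacterial colony.

Growth rule (default, ``variant="bond"``): one (occupied, empty) von-Neumann
neighbour pair is chosen uniformly among all such pairs — so boundary cells
reproduce in proportion to their free sites, and the parent of a new cell
is uniform among its occupied neighbours.  Alternative micro-rules are
selectable: ``"site"`` picks the empty perimeter site uniformly first and
``"cell"`` picks a reproducing boundary cell uniformly first; all three
share the KPZ universality class but differ in non-universal amplitudes
and in corrections to scaling at small widths.  The child's generation
label is always the parent's plus one.  With diffusion enabled, each
growth event is
followed by a random number of hop attempts with mean ``p_move`` (the
diffusion-to-growth rate ratio): a uniformly chosen boundary cell moves
into a uniformly chosen empty neighbour, subject to a local connectivity
guard; the cell's id and generation travel with it.

Two implementations are provided: :func:`simulate_eden` drives a compiled
event loop for production ensembles, and :class:`SimState` with
:func:`step_growth` / :func:`step_diffusion` is a transparent step-by-step
reference used for inspection and invariant checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .genealogy import Genealogy

__all__ = [
    "LatticeConfig",
    "EdenParams",
    "EdenResult",
    "simulate_eden",
    "SimState",
    "step_growth",
    "step_diffusion",
    "run_state",
    "complete_generation",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Square-lattice geometry for an Eden run.

    ``dimension`` counts growth plus transverse axes: 2 means (1+1), a
    width-``N`` strip; 3 means (2+1), layers of ``N x N`` cells.  Bounded
    strips have periodic transverse boundaries and unbounded depth; the
    unbounded geometry ignores ``width``.
    """

    geometry: str = "bounded"  # "bounded" | "unbounded"
    dimension: int = 2
    width: int | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("bounded", "unbounded"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.geometry == "bounded":
            if self.width is None or self.width < 2:
                raise ValueError("bounded lattices need width >= 2")
        if self.geometry == "unbounded" and self.dimension != 2:
            raise ValueError("unbounded growth is implemented in 2 dimensions")


@dataclass(frozen=True)
class EdenParams:
    """Parameters of one Eden realization.

    ``G`` is the stop generation: the run ends when the first cell of
    generation ``G`` is born, or — if ``complete`` is set — once no
    boundary cell has a generation below ``complete``, which makes the
    membership of every generation up to ``complete`` final (needed for
    counting and sampling whole generations).
    """

    lattice: LatticeConfig
    G: int
    seed: int
    init: str = "full-layer"  # "full-layer" | "single-seed"
    p_move: float = 0.0
    complete: int | None = None
    width_every: int = 0  # record front width every this many growth events
    variant: str = "bond"  # "site" | "bond" | "cell" growth-site selection

    def __post_init__(self) -> None:
        if self.variant not in ("site", "bond", "cell"):
            raise ValueError(f"unknown growth variant {self.variant!r}")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.p_move < 0.0:
            raise ValueError("p_move must be non-negative")
        if self.init not in ("full-layer", "single-seed"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.complete is not None and not 0 <= self.complete <= self.G:
            raise ValueError("complete must be in [0, G]")
        if self.p_move > 0 and self.lattice.dimension != 2:
            raise ValueError("diffusion is implemented for 2-dimensional "
                             "lattices only")


@dataclass
class EdenResult:
    """Output of :func:`simulate_eden`."""

    params: EdenParams
    genealogy: Genealogy
    occupied: np.ndarray        # (n_occupied, ndim) coordinates, end of run
    occupied_ids: np.ndarray    # matching cell ids
    boundary: np.ndarray        # (n_boundary, ndim) boundary coordinates
    widths: np.ndarray          # front-width series (if width_every > 0)
    n_events: int

    def boundary_depths(self) -> np.ndarray:
        return self.boundary[:, 0]


# ---------------------------------------------------------------------------
# lattice tables for the kernel
# ---------------------------------------------------------------------------

def _bounded_tables(N: int, dim: int, D: int):
    """Neighbour tables for a depth-D strip/slab with periodic width N."""
    layer = N if dim == 2 else N * N
    nsites = D * layer
    s = np.arange(nsites, dtype=np.int64)
    d = s // layer
    nbr = np.empty((nsites, 2 * (dim - 1) + 2), dtype=np.int32)
    diag = np.full((nsites, 4), -1, dtype=np.int32)
    nbr[:, 0] = np.where(d + 1 < D, s + layer, -1)
    nbr[:, 1] = np.where(d > 0, s - layer, -1)
    if dim == 2:
        y = s % N
        nbr[:, 2] = d * layer + (y + 1) % N
        nbr[:, 3] = d * layer + (y - 1) % N
        up = (y + 1) % N
        dn = (y - 1) % N
        diag[:, 0] = np.where(d + 1 < D, (d + 1) * layer + up, -1)  # NE
        diag[:, 1] = np.where(d > 0, (d - 1) * layer + up, -1)      # NW
        diag[:, 2] = np.where(d > 0, (d - 1) * layer + dn, -1)      # SW
        diag[:, 3] = np.where(d + 1 < D, (d + 1) * layer + dn, -1)  # SE
    else:
        r = (s % layer) // N
        c = s % N
        nbr[:, 2] = d * layer + ((r + 1) % N) * N + c
        nbr[:, 3] = d * layer + ((r - 1) % N) * N + c
        nbr[:, 4] = d * layer + r * N + (c + 1) % N
        nbr[:, 5] = d * layer + r * N + (c - 1) % N
    depth = d.astype(np.int32)
    is_edge = (d == D - 1).astype(np.uint8)
    return nbr, diag, depth, is_edge


def _unbounded_tables(H: int):
    """Neighbour tables for a (2H+1)^2 open grid centred on the founder."""
    S = 2 * H + 1
    nsites = S * S
    s = np.arange(nsites, dtype=np.int64)
    r = s // S
    c = s % S
    nbr = np.empty((nsites, 4), dtype=np.int32)
    nbr[:, 0] = np.where(r + 1 < S, s + S, -1)
    nbr[:, 1] = np.where(r > 0, s - S, -1)
    nbr[:, 2] = np.where(c + 1 < S, s + 1, -1)
    nbr[:, 3] = np.where(c > 0, s - 1, -1)
    diag = np.full((nsites, 4), -1, dtype=np.int32)
    in_n = r + 1 < S
    in_s = r > 0
    in_e = c + 1 < S
    in_w = c > 0
    diag[:, 0] = np.where(in_n & in_e, s + S + 1, -1)  # NE
    diag[:, 1] = np.where(in_s & in_e, s - S + 1, -1)  # NW
    diag[:, 2] = np.where(in_s & in_w, s - S - 1, -1)  # SW
    diag[:, 3] = np.where(in_n & in_w, s + S - 1, -1)  # SE
    depth = (r - H).astype(np.int32)  # unused for width recording
    edge = (r == 0) | (r == S - 1) | (c == 0) | (c == S - 1)
    return nbr, diag, depth, edge.astype(np.uint8)


def _decode_coords(sites: np.ndarray, params: EdenParams, D: int, H: int) -> np.ndarray:
    lat = params.lattice
    if lat.geometry == "unbounded":
        S = 2 * H + 1
        return np.column_stack((sites // S - H, sites % S - H)).astype(np.int32)
    N = lat.width
    layer = N if lat.dimension == 2 else N * N
    d = sites // layer
    if lat.dimension == 2:
        return np.column_stack((d, sites % N)).astype(np.int32)
    rem = sites % layer
    return np.column_stack((d, rem // N, rem % N)).astype(np.int32)


def simulate_eden(params: EdenParams) -> EdenResult:
    """Simulate one Eden realization and return its genealogy and state.

    Growth events (interleaved with diffusion hops at rate ``p_move`` per
    event when enabled) continue until the first cell of generation ``G``
    is created, or until generation ``params.complete`` is final.  The
    run is bit-reproducible for a fixed seed.  Lattice storage is sized
    from ``G`` and grown automatically in the (rare) event the cluster
    reaches the allocated edge.
    """
    lat = params.lattice
    depth_cap = params.G + (256 if params.complete is not None else 2)
    radius_cap = min(int(0.85 * params.G) + 32, params.G + 2)

    for attempt in range(6):
        if lat.geometry == "bounded":
            N = lat.width
            D, H = depth_cap, 0
            nbr, diag, depth, is_edge = _bounded_tables(N, lat.dimension, D)
            layer = N if lat.dimension == 2 else N * N
            if params.init == "full-layer":
                founders = np.arange(layer, dtype=np.int32)
            else:
                mid = (N // 2) * N + N // 2 if lat.dimension == 3 else N // 2
                founders = np.array([mid], dtype=np.int32)
        else:
            D, H = 0, radius_cap
            nbr, diag, depth, is_edge = _unbounded_tables(H)
            S = 2 * H + 1
            founders = np.array([H * S + H], dtype=np.int32)

        complete_target = -1 if params.complete is None else params.complete
        status, parent, generation, site_of, occ, widths, n_events = _kernels.run_eden(
            nbr, diag, depth, is_edge, founders, float(params.p_move),
            np.int64(params.G), np.int64(complete_target),
            np.int64(params.width_every), np.int64(int(params.seed) % 2**31),
            np.int64(nbr.shape[0]),
            np.int64({"site": 0, "bond": 1, "cell": 2}[params.variant]),
        )
        if status == _kernels.OK:
            break
        # enlarge and replay (the RNG stream is identical, so any events
        # simulated before hitting the guard edge are reproduced exactly)
        depth_cap = int(depth_cap * 1.5) + 64
        radius_cap = int(radius_cap * 1.4) + 64
    else:
        raise RuntimeError("Eden lattice could not be sized to contain the run")

    occ_sites = np.flatnonzero(occ >= 0)
    bnd_mask = np.zeros(occ.size, dtype=bool)
    empty = occ < 0
    for t in range(nbr.shape[1]):
        col = nbr[occ_sites, t]
        valid = col >= 0
        bnd_mask[occ_sites[valid]] |= empty[col[valid]]
    bnd_sites = np.flatnonzero(bnd_mask)

    genealogy = Genealogy(
        parent=parent,
        generation=generation,
        coords=_decode_coords(site_of.astype(np.int64), params, D, H),
    )
    return EdenResult(
        params=params,
        genealogy=genealogy,
        occupied=_decode_coords(occ_sites, params, D, H),
        occupied_ids=occ[occ_sites].astype(np.int32),
        boundary=_decode_coords(bnd_sites, params, D, H),
        widths=widths,
        n_events=int(n_events),
    )


# ---------------------------------------------------------------------------
# step-by-step reference implementation
# ---------------------------------------------------------------------------

class _RandomSet:
    """Set with O(1) uniform sampling (list + position map)."""

    def __init__(self) -> None:
        self._items: list = []
        self._pos: dict = {}

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, x) -> bool:
        return x in self._pos

    def __iter__(self):
        return iter(self._items)

    def add(self, x) -> None:
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def discard(self, x) -> None:
        i = self._pos.pop(x, None)
        if i is None:
            return
        last = self._items.pop()
        if i < len(self._items):
            self._items[i] = last
            self._pos[last] = i

    def sample(self, rng: np.random.Generator):
        return self._items[rng.integers(len(self._items))]


class SimState:
    """Mutable state of a running Eden simulation (reference implementation).

    Holds the sparse occupancy map (site -> cell id), the boundary set
    (occupied sites with at least one empty neighbour), the growth-candidate
    set (empty sites adjacent to the cluster), the genealogy-in-progress and
    an event counter.  Sites are coordinate tuples: ``(depth, y[, x])`` for
    bounded strips (transverse axes periodic), ``(x, y)`` offsets from the
    founder for unbounded growth.
    """

    def __init__(self, params: EdenParams, rng: np.random.Generator | None = None):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.occ: dict[tuple, int] = {}
        self.boundary = _RandomSet()
        self.candidates = _RandomSet()
        self.parent: list[int] = []
        self.generation: list[int] = []
        self.site_of: list[tuple] = []
        self.n_events = 0
        self._max_gen = 0

        lat = params.lattice
        if lat.geometry == "bounded":
            if params.init == "full-layer":
                if lat.dimension == 2:
                    sites = [(0, y) for y in range(lat.width)]
                else:
                    sites = [(0, y, x) for y in range(lat.width)
                             for x in range(lat.width)]
            else:
                sites = [(0,) + (lat.width // 2,) * (lat.dimension - 1)]
        else:
            sites = [(0, 0)]
        for s in sites:
            self._occupy(s, self._new_cell(-1, 0, s))

    # -- geometry ------------------------------------------------------
    def neighbours(self, site: tuple) -> list[tuple]:
        lat = self.params.lattice
        if lat.geometry == "unbounded":
            x, y = site
            return [(x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)]
        N = lat.width
        out = []
        d = site[0]
        if lat.dimension == 2:
            y = site[1]
            out = [(d + 1, y), (d - 1, y), (d, (y + 1) % N), (d, (y - 1) % N)]
        else:
            y, x = site[1], site[2]
            out = [(d + 1, y, x), (d - 1, y, x),
                   (d, (y + 1) % N, x), (d, (y - 1) % N, x),
                   (d, y, (x + 1) % N), (d, y, (x - 1) % N)]
        return [s for s in out if s[0] >= 0]

    # -- bookkeeping ---------------------------------------------------
    def _new_cell(self, parent: int, generation: int, site: tuple) -> int:
        self.parent.append(parent)
        self.generation.append(generation)
        self.site_of.append(site)
        if generation > self._max_gen:
            self._max_gen = generation
        return len(self.parent) - 1

    def _occupy(self, site: tuple, cid: int) -> None:
        self.occ[site] = cid
        self.candidates.discard(site)
        has_empty = False
        for nb in self.neighbours(site):
            if nb not in self.occ:
                has_empty = True
                self.candidates.add(nb)
            elif nb in self.boundary and not any(
                    m not in self.occ for m in self.neighbours(nb)):
                self.boundary.discard(nb)
        if has_empty:
            self.boundary.add(site)

    def _vacate(self, site: tuple) -> None:
        del self.occ[site]
        self.boundary.discard(site)
        for nb in self.neighbours(site):
            if nb in self.occ:
                self.boundary.add(nb)
            elif nb in self.candidates and not any(
                    m in self.occ for m in self.neighbours(nb)):
                self.candidates.discard(nb)
        if any(m in self.occ for m in self.neighbours(site)):
            self.candidates.add(site)

    # -- views ----------------------------------------------------------
    def to_genealogy(self) -> Genealogy:
        return Genealogy(
            parent=np.array(self.parent, dtype=np.int32),
            generation=np.array(self.generation, dtype=np.int32),
            coords=np.array(self.site_of, dtype=np.int32),
        )

    @property
    def max_generation(self) -> int:
        return self._max_gen


def step_growth(state: SimState) -> SimState:
    """Perform one growth event in place (and return the state).

    Site/parent selection follows ``params.variant``: ``"bond"`` (default)
    draws a uniform (occupied, empty) neighbour pair, ``"site"`` draws the
    empty perimeter site uniformly, ``"cell"`` draws a reproducing
    boundary cell uniformly; the parent is always uniform among the grown
    site's occupied neighbours (for ``"cell"`` it is the drawn cell).
    """
    if len(state.candidates) == 0:
        raise RuntimeError("no growth site available")
    variant = state.params.variant
    rng = state.rng
    max_nbr = 2 * state.params.lattice.dimension
    if variant == "cell":
        cell_site = state.boundary.sample(rng)
        empties = [nb for nb in state.neighbours(cell_site)
                   if nb not in state.occ]
        site = empties[rng.integers(len(empties))]
        pid = state.occ[cell_site]
    else:
        while True:
            site = state.candidates.sample(rng)
            occ_nb = [nb for nb in state.neighbours(site) if nb in state.occ]
            if variant == "site" or rng.integers(max_nbr) < len(occ_nb):
                break
        pid = state.occ[occ_nb[rng.integers(len(occ_nb))]]
    cid = state._new_cell(pid, state.generation[pid] + 1, site)
    state._occupy(site, cid)
    state.n_events += 1
    return state


def step_diffusion(state: SimState) -> SimState:
    """Attempt one diffusion hop in place (rejected moves are no-ops).

    A uniformly chosen boundary cell attempts to move into a uniformly
    chosen empty neighbour.  The move is accepted only if (a) the
    destination has an occupied neighbour besides the mover and (b) the
    origin is a *simple point* once the mover sits at the destination: its
    occupied von-Neumann neighbours form a single arc around it (two
    consecutive edge neighbours count as linked iff the diagonal between
    them is occupied).  Vacating a simple point cannot split the cluster,
    so the occupied set stays connected after every accepted hop.  Id and
    generation travel with the cell.
    """
    if state.params.lattice.dimension != 2:
        raise ValueError("diffusion is implemented for 2-dimensional lattices")
    if len(state.boundary) == 0:
        return state
    origin = state.boundary.sample(state.rng)
    empties = [nb for nb in state.neighbours(origin) if nb not in state.occ]
    if not empties:
        return state
    dest = empties[state.rng.integers(len(empties))]
    if not any(nb != origin and nb in state.occ
               for nb in state.neighbours(dest)):
        return state

    def occupied_after(site) -> bool:
        if site is None:
            return False
        return site == dest or site in state.occ

    edges, diags = _ring(state, origin)
    e = [occupied_after(s) for s in edges]
    d = [occupied_after(s) for s in diags]
    arcs = sum(1 for i in range(4) if e[i] and not (d[i] and e[(i + 1) % 4]))
    if arcs <= 1:
        cid = state.occ[origin]
        state._vacate(origin)
        state._occupy(dest, cid)
        state.site_of[cid] = dest
    return state


def _ring(state: SimState, site: tuple):
    """Edge and diagonal neighbours of ``site`` in cyclic order."""
    lat = state.params.lattice
    if lat.geometry == "unbounded":
        x, y = site
        edges = [(x + 1, y), (x, y + 1), (x - 1, y), (x, y - 1)]
        diags = [(x + 1, y + 1), (x - 1, y + 1), (x - 1, y - 1), (x + 1, y - 1)]
        return edges, diags
    N = lat.width
    d0, y = site
    up, dn = (y + 1) % N, (y - 1) % N
    edges = [(d0 + 1, y), (d0, up), (d0 - 1, y), (d0, dn)]
    diags = [(d0 + 1, up), (d0 - 1, up), (d0 - 1, dn), (d0 + 1, dn)]
    edges = [s if s[0] >= 0 else None for s in edges]
    diags = [s if s[0] >= 0 else None for s in diags]
    return edges, diags


def _run_until(state: SimState, done) -> SimState:
    p = state.params.p_move
    while not done(state):
        step_growth(state)
        if p > 0.0:
            n_hops = int(p)
            if state.rng.random() < p - n_hops:
                n_hops += 1
            for _ in range(n_hops):
                step_diffusion(state)
    return state


def run_state(params: EdenParams) -> SimState:
    """Drive a :class:`SimState` to the same stop condition as the kernel."""
    state = SimState(params)
    if params.complete is not None:
        return complete_generation(state, params.complete)
    return _run_until(state, lambda s: s.max_generation >= params.G)


def complete_generation(state: SimState, g: int) -> SimState:
    """Continue events until no boundary cell has generation below ``g``.

    Afterwards no new cell with generation label <= ``g`` can ever appear,
    so the set of generation-``g`` cells is final; re-running with a longer
    horizon cannot change it.
    """
    def done(s: SimState) -> bool:
        return all(s.generation[s.occ[b]] >= g for b in s.boundary)
    return _run_until(state, done)
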