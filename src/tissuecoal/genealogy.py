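"""Parent-pointer genealogies and backward lineage tracing.

Every growth model in this package (layer-by-layer neutral reproduction,
bounded and unbounded Eden growth) records its full genealogy as an
append-only table of cells: each cell has an integer id, a parent id
(absent for founders), a generation label, and a lattice site.  Tracing a
sampled generation backwards through the parent pointers yields the number
of distinct ancestral lineages as a function of generations back in time;
the time to the most recent common ancestor (MRCA) is the first look-back
depth at which a single ancestor remains.

Conventions
-----------
* Generations back are counted as differences of generation labels: a
  sample taken at generation 200 whose MRCA lives in generation 96 has
  ``tmrca = 104``.
* The sample is *all* cells carrying a given generation label, regardless
  of spatial position.
* Ancestors are identified by cell id, never by lattice site (cells may
  move when diffusion is enabled).
* A sample that does not reach a single ancestor within the recorded
  history is "not coalesced"; this is an ordinary return value (``None``),
  not an error, because unbounded growth routinely produces star-like
  genealogies whose lineages survive all the way back to the founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "CellRecord",
    "Genealogy",
    "LineageCurve",
    "trace_lineages",
    "tmrca",
    "excess_lineages",
    "coalescence_probability",
    "coalescence_probability_curve",
    "mean_lineage_curve",
    "to_newick",
    "read_genealogy_csv",
    "write_genealogy_csv",
]


@dataclass(frozen=True)
class CellRecord:
    """A single cell: one row of a genealogy table."""

    id: int
    parent_id: int | None
    generation: int
    site: tuple[int, ...]


@dataclass
class Genealogy:
    """Append-only genealogy of a simulated tissue.

    Cells are stored in topological birth order, so row ``i`` is cell id
    ``i`` and every parent id is smaller than its child's id.  Founders
    have ``parent = -1`` and generation 0.
    """

    parent: np.ndarray      # (n,) int32, -1 for founders
    generation: np.ndarray  # (n,) int32
    coords: np.ndarray      # (n, ndim) int32 lattice coordinates

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int32)
        self.generation = np.asarray(self.generation, dtype=np.int32)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int32))
        if not (len(self.parent) == len(self.generation) == len(self.coords)):
            raise ValueError("parent, generation and coords must have equal length")

    # -- basic queries -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return int(self.parent.size)

    @property
    def ndim(self) -> int:
        return int(self.coords.shape[1])

    @property
    def max_generation(self) -> int:
        return int(self.generation.max(initial=0))

    def generation_counts(self) -> np.ndarray:
        """Number of cells per generation label, index = generation."""
        return np.bincount(self.generation, minlength=self.max_generation + 1)

    def cells_of_generation(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.generation == g).astype(np.int32)

    def record(self, cell_id: int) -> CellRecord:
        p = int(self.parent[cell_id])
        return CellRecord(
            id=int(cell_id),
            parent_id=None if p < 0 else p,
            generation=int(self.generation[cell_id]),
            site=tuple(int(c) for c in self.coords[cell_id]),
        )

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        n = self.n_cells
        if n == 0:
            raise ValueError("empty genealogy")
        founders = self.parent < 0
        if not np.all(self.generation[founders] == 0):
            raise ValueError("founders must have generation 0")
        ids = np.arange(n)
        child = ~founders
        if np.any(self.parent[child] >= ids[child]):
            raise ValueError("parent ids must precede child ids (birth order)")
        if np.any(self.generation[child] != self.generation[self.parent[child]] + 1):
            raise ValueError("child generation must equal parent generation + 1")


@dataclass
class LineageCurve:
    """Distinct ancestral lineages of a sampled generation, per look-back depth.

    ``counts[g]`` is the number of distinct ancestors *g* generations back
    of all cells sampled at ``sample_generation``; ``counts[0]`` is the
    sample size and the array is non-increasing.
    """

    sample_generation: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size == 0 or self.counts.size > self.sample_generation + 1:
            raise ValueError("counts length must be in [1, sample_generation + 1]")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("lineage counts must be non-increasing")
        if self.counts[-1] < 1:
            raise ValueError("lineage counts must stay >= 1")

    @property
    def sample_size(self) -> int:
        return int(self.counts[0])

    @property
    def tmrca(self) -> int | None:
        """First look-back depth with a single ancestor, or None."""
        hit = np.flatnonzero(self.counts == 1)
        return int(hit[0]) if hit.size else None

    @property
    def coalesced(self) -> bool:
        return self.tmrca is not None


@njit(cache=True)
def _trace_counts(parent, sample, steps):  # pragma: no cover - numba
    counts = np.empty(steps + 1, np.int64)
    cur = sample.copy()
    k = cur.size
    counts[0] = k
    for g in range(1, steps + 1):
        for i in range(k):
            cur[i] = parent[cur[i]]
        sub = np.sort(cur[:k])
        k2 = 0
        prev = np.int32(-2)
        for i in range(k):
            if sub[i] != prev:
                prev = sub[i]
                cur[k2] = prev
                k2 += 1
        k = k2
        counts[g] = k
        if k == 1:
            counts[g + 1:] = 1
            break
    return counts


def trace_lineages(genealogy: Genealogy, sample_generation: int) -> LineageCurve:
    """Trace all cells of one generation back to their distinct ancestors.

    Returns the full curve of length ``sample_generation + 1``; entry ``g``
    is the number of distinct ancestors ``g`` generations back.  Raises
    ``ValueError`` if no cell carries the requested generation label.
    """
    if genealogy.n_cells == 0:
        raise ValueError("empty genealogy")
    if not 0 <= sample_generation <= genealogy.max_generation:
        raise ValueError(
            f"sample generation {sample_generation} outside recorded history "
            f"[0, {genealogy.max_generation}]"
        )
    sample = genealogy.cells_of_generation(sample_generation)
    if sample.size == 0:
        raise ValueError(f"no cells in generation {sample_generation}")
    counts = _trace_counts(genealogy.parent, sample, sample_generation)
    return LineageCurve(sample_generation=sample_generation, counts=counts)


def tmrca(genealogy: Genealogy, sample_generation: int) -> int | None:
    """Generations back to the sample's MRCA; ``None`` if it never coalesces."""
    return trace_lineages(genealogy, sample_generation).tmrca


def excess_lineages(curve: LineageCurve) -> np.ndarray:
    """Lineages in excess of the single common ancestor: ``counts - 1``."""
    return curve.counts - 1


def _coalesced_by(curve: LineageCurve, g: int) -> bool:
    t = curve.tmrca
    return t is not None and t <= g


def coalescence_probability(curves: Sequence[LineageCurve], g: int) -> float:
    """Fraction of replicate curves that have coalesced by look-back depth ``g``.

    Replicates whose recorded history ends before ``g`` without coalescing
    count as not coalesced.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("empty ensemble")
    s = curves[0].sample_generation
    if any(c.sample_generation != s for c in curves):
        raise ValueError("all curves must share the same sample generation")
    return sum(_coalesced_by(c, g) for c in curves) / len(curves)


def coalescence_probability_curve(curves: Sequence[LineageCurve]) -> np.ndarray:
    """Coalescence probability at every look-back depth 0..sample_generation."""
    curves = list(curves)
    if not curves:
        raise ValueError("empty ensemble")
    s = curves[0].sample_generation
    mat = np.stack([np.pad(c.counts, (0, s + 1 - c.counts.size),
                           constant_values=c.counts[-1]) for c in curves])
    return (mat == 1).mean(axis=0)


def mean_lineage_curve(curves: Sequence[LineageCurve]) -> np.ndarray:
    """Mean number of distinct lineages at every look-back depth."""
    curves = list(curves)
    if not curves:
        raise ValueError("empty ensemble")
    s = curves[0].sample_generation
    mat = np.stack([np.pad(c.counts, (0, s + 1 - c.counts.size),
                           constant_values=c.counts[-1]) for c in curves])
    return mat.mean(axis=0)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def to_newick(genealogy: Genealogy, sample_generation: int) -> str:
    """Serialize the genealogical tree of a sampled generation as Newick.

    Leaves are labelled ``c<id>`` and branch lengths are measured in
    generations.  If the sample coalesces, a single tree rooted at the MRCA
    is returned and every root-to-leaf path length equals the TMRCA.  If it
    does not, one tree per surviving root lineage is emitted (a forest,
    newline-separated), each rooted at a distinct deepest ancestor.
    """
    sample = genealogy.cells_of_generation(sample_generation)
    if sample.size == 0:
        raise ValueError(f"no cells in generation {sample_generation}")
    parent = genealogy.parent
    gen = genealogy.generation

    curve = trace_lineages(genealogy, sample_generation)
    depth = curve.tmrca if curve.coalesced else sample_generation

    # climb each leaf `depth` steps, recording the child sets of every
    # ancestor on a path
    children: dict[int, set[int]] = {}
    roots: set[int] = set()
    for leaf in sample:
        node = int(leaf)
        for _ in range(depth):
            p = int(parent[node])
            children.setdefault(p, set()).add(node)
            node = p
        roots.add(node)

    leaves = set(int(c) for c in sample)

    def emit(node: int) -> str:
        kids = children.get(node)
        if not kids:  # a sampled leaf
            return f"c{node}"
        parts = []
        for k in sorted(kids):
            # collapse unary chains into one branch
            cur = k
            while cur not in leaves and len(children.get(cur, ())) == 1:
                (cur,) = children[cur]
            parts.append(f"{emit(cur)}:{int(gen[cur]) - int(gen[node])}")
        return "(" + ",".join(parts) + ")"

    trees = []
    for r in sorted(roots):
        if r in leaves and r not in children:
            trees.append(f"c{r};")  # single-cell sample: zero-length tree
        else:
            trees.append(emit(r) + ";")
    return "\n".join(trees)


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

_COORD_NAMES = ("x", "y", "z")


def write_genealogy_csv(genealogy: Genealogy, path) -> None:
    """Write the genealogy table as CSV (id,parent_id,generation,x,y[,z]).

    ``parent_id`` is empty for founders; coordinates are 0-based integers.
    """
    cols = {
        "id": np.arange(genealogy.n_cells, dtype=np.int64),
        "parent_id": pd.array(
            np.where(genealogy.parent < 0, None, genealogy.parent), dtype="Int64"
        ),
        "generation": genealogy.generation,
    }
    for d in range(genealogy.ndim):
        cols[_COORD_NAMES[d]] = genealogy.coords[:, d]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_genealogy_csv(path) -> Genealogy:
    df = pd.read_csv(path, dtype={"parent_id": "Int64"})
    coord_cols = [c for c in _COORD_NAMES if c in df.columns]
    parent = df["parent_id"].fillna(-1).to_numpy(dtype=np.int32)
    g = Genealogy(
        parent=parent,
        generation=df["generation"].to_numpy(dtype=np.int32),
        coords=df[coord_cols].to_numpy(dtype=np.int32),
    )
    if not np.array_equal(df["id"].to_numpy(), np.arange(g.n_cells)):
        raise ValueError("genealogy CSV ids must be consecutive from 0")
    return g
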