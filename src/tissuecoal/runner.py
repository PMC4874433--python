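"""Run configuration, deterministic seeding, output files and fixtures.

A :class:`RunConfig` names one of the five growth models, its parameters,
a replicate count and a master seed.  :func:`run_simulation` executes the
replicates (seeds derived deterministically from the master seed via
``numpy.random.SeedSequence``), writes one genealogy CSV per replicate, a
lineage-curve CSV (look-back generation, mean lineages, coalescence
probability) and a summary JSON, and is byte-reproducible: identical
configs produce identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eden import EdenParams, LatticeConfig, simulate_eden
from .experiments import DIFFUSION_RATE, replicate_seeds
from .genealogy import (
    Genealogy,
    coalescence_probability_curve,
    mean_lineage_curve,
    to_newick,
    trace_lineages,
    write_genealogy_csv,
)
from .neutral import GrowthSchedule, WFParams, simulate_wf

__all__ = ["RunConfig", "run_simulation", "make_fixture", "FIXTURES"]

MODELS = ("wf", "wf-linear", "eden-bounded", "eden-diffusive", "eden-unbounded")


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of a simulation run."""

    model: str
    generations: int
    seed: int = 0
    replicates: int = 1
    # neutral-model parameters
    N: int = 100
    N0: float = 1.0
    lam: float = 2.78
    # Eden parameters
    width: int = 50
    dimension: int = 2
    init: str = "full-layer"
    p_move: float | None = None
    complete: int | None = None
    variant: str = "bond"
    out: str = "."

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.model in ("wf", "wf-linear") and self.p_move is not None:
            raise ValueError("p_move is an Eden parameter; not valid for "
                             f"model {self.model!r}")
        if self.model.startswith("eden") and self.model != "eden-unbounded":
            if self.width < 2:
                raise ValueError("width must be >= 2 for bounded Eden growth")
        if self.model == "wf" and self.N < 1:
            raise ValueError("N must be >= 1")

    # -- (de)serialization ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _simulate_one(config: RunConfig, seed: int) -> Genealogy:
    g = config.generations
    if config.model == "wf":
        sched = GrowthSchedule(kind="constant", N=config.N)
        return simulate_wf(WFParams(schedule=sched, G=g, seed=seed))
    if config.model == "wf-linear":
        sched = GrowthSchedule(kind="linear", N0=config.N0, lam=config.lam)
        return simulate_wf(WFParams(schedule=sched, G=g, seed=seed))
    if config.model == "eden-unbounded":
        lattice = LatticeConfig("unbounded", 2)
        init = "single-seed"
    else:
        lattice = LatticeConfig("bounded", config.dimension, config.width)
        init = config.init
    p_move = config.p_move
    if p_move is None:
        p_move = DIFFUSION_RATE if config.model == "eden-diffusive" else 0.0
    if config.model == "eden-bounded" and p_move > 0:
        raise ValueError("p_move must be 0 for eden-bounded; use eden-diffusive")
    complete = config.complete if config.complete is not None else g
    params = EdenParams(lattice=lattice, G=g, seed=seed, init=init,
                        p_move=p_move, complete=complete,
                        variant=config.variant)
    return simulate_eden(params).genealogy


def run_simulation(config: RunConfig) -> dict:
    """Run all replicates of a config and write output files.

    Writes ``genealogy_<r>.csv`` per replicate, ``lineage_curves.csv``
    (g, mean_lineages, prob_coalesced) for the final-generation sample and
    ``summary.json``; returns the summary dictionary.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = replicate_seeds(config.seed, config.replicates)

    curves = []
    for r in range(config.replicates):
        genealogy = _simulate_one(config, int(seeds[r]))
        write_genealogy_csv(genealogy, outdir / f"genealogy_{r}.csv")
        curves.append(trace_lineages(genealogy, config.generations))

    mean_curve = mean_lineage_curve(curves)
    prob_curve = coalescence_probability_curve(curves)
    pd.DataFrame({
        "g": np.arange(mean_curve.size),
        "mean_lineages": mean_curve,
        "prob_coalesced": prob_curve,
    }).to_csv(outdir / "lineage_curves.csv", index=False)

    tmrcas = [c.tmrca for c in curves]
    cfg = dataclasses.asdict(config)
    cfg.pop("out")  # the output location is not part of the run identity
    summary = {
        "model": config.model,
        "config": cfg,
        "replicate_seeds": [int(s) for s in seeds],
        "n_replicates": config.replicates,
        "n_not_coalesced": sum(t is None for t in tmrcas),
        "mean_tmrca": (float(np.mean([t for t in tmrcas if t is not None]))
                       if any(t is not None for t in tmrcas) else None),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("chain", "star", "wf-tiny", "eden-tiny")


def make_fixture(name: str) -> Genealogy:
    """Small deterministic genealogies with known curves, used in tests.

    * ``chain`` — 10 generations of a single cell each; a sample from any
      generation is a single lineage (all lineage counts 1, TMRCA 0: a
      one-cell sample is its own most recent common ancestor).
    * ``star`` — one founder with five generation-1 children; counts
      [5, 1], TMRCA 1.
    * ``wf-tiny`` — layer model, N=4, G=20, fixed seed.
    * ``eden-tiny`` — bounded strip, N=4, G=12, fixed seed.
    """
    if name == "chain":
        n = 11
        return Genealogy(
            parent=np.arange(-1, n - 1, dtype=np.int32),
            generation=np.arange(n, dtype=np.int32),
            coords=np.column_stack((np.arange(n), np.zeros(n, int))),
        )
    if name == "star":
        return Genealogy(
            parent=np.array([-1, 0, 0, 0, 0, 0], dtype=np.int32),
            generation=np.array([0, 1, 1, 1, 1, 1], dtype=np.int32),
            coords=np.column_stack((np.array([0, 1, 1, 1, 1, 1]),
                                    np.arange(6))),
        )
    if name == "wf-tiny":
        sched = GrowthSchedule(kind="constant", N=4)
        return simulate_wf(WFParams(schedule=sched, G=20, seed=20240917))
    if name == "eden-tiny":
        params = EdenParams(lattice=LatticeConfig("bounded", 2, 4), G=12,
                            seed=20240917)
        return simulate_eden(params).genealogy
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
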