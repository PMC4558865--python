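"""Deterministic toy populations and scripted genealogies for fast tests.

Everything here is fully explicit — no random draws — so that life-cycle
operations and statistics can be exercised in milliseconds against known
ground truth, without running a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import Genome
from .population import MUTATION_TYPES, Population
from .statistics import LineageForest

__all__ = [
    "ToySpec",
    "ScriptedCell",
    "GenealogySpec",
    "make_toy_population",
    "make_scripted_genealogy",
    "fig1_style_genome",
]


@dataclass(frozen=True)
class ToySpec:
    """Explicit description of a toy population.

    genes : per-cell lists of (c, A) pairs (may be empty for an empty
        genome).
    resources : per-cell internal resource balances.
    R_env : total resource of the closed system; must cover the cells'
        holdings, the remainder becomes the free pool.
    alpha : area constant shared by all genes.
    lineages : optional per-cell founder labels (defaults to one lineage
        per cell).
    """

    genes: tuple[tuple[tuple[float, float], ...], ...]
    resources: tuple[float, ...]
    R_env: float
    alpha: float = 0.2
    lineages: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        genes = tuple(tuple(tuple(float(v) for v in g) for g in cell) for cell in self.genes)
        res = tuple(float(r) for r in self.resources)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "resources", res)
        if len(genes) != len(res):
            raise ValueError("need one resource balance per cell")
        if self.lineages is not None and len(self.lineages) != len(res):
            raise ValueError("need one lineage label per cell")
        if sum(res) > self.R_env * (1 + 1e-9):
            raise ValueError("declared cell resources exceed R_env")


def make_toy_population(spec: ToySpec) -> Population:
    """Build the exact population declared by ``spec``; resource
    conservation holds by construction.  Founder genes receive sequential
    variant ids."""
    genomes = []
    next_vid = 0
    for cell_genes in spec.genes:
        if not cell_genes:
            genomes.append(Genome.empty(spec.alpha))
            continue
        c = [g[0] for g in cell_genes]
        A = [g[1] for g in cell_genes]
        origin = list(range(next_vid, next_vid + len(cell_genes)))
        next_vid += len(cell_genes)
        genomes.append(Genome(c, A, spec.alpha, origin))
    return Population(
        genomes,
        np.asarray(spec.resources),
        R_env=spec.R_env,
        lineage_id=spec.lineages,
        alpha=spec.alpha,
    )


def fig1_style_genome(alpha: float = 0.2) -> Genome:
    """A three-gene genotype with well-separated peaks of distinct heights,
    whose uptake envelope has three local maxima."""
    return Genome(
        c=[-0.6, 0.0, 0.7],
        A=[0.5, 0.9, 0.7],
        alpha=alpha,
        origin=[0, 1, 2],
    )


# ---------------------------------------------------------------------------
# Scripted genealogies


@dataclass(frozen=True)
class ScriptedCell:
    """One cell in a scripted genealogy.

    ``parent`` is the label of the cell it budded from (None for a
    founder); ``events`` is the ordered list of its own mutation events as
    ``(step, type)`` pairs appended to the inherited trail."""

    label: str
    parent: Optional[str] = None
    events: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class GenealogySpec:
    """A small genealogy with a declared set of extant cells, from which the
    ground-truth fixed/unfixed status of every event is knowable by hand."""

    cells: tuple[ScriptedCell, ...]
    extant: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.cells]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate cell labels")
        known = set(labels)
        for c in self.cells:
            if c.parent is not None and c.parent not in known:
                raise ValueError(f"orphan cell {c.label!r}: unknown parent {c.parent!r}")
            for _, ev_type in c.events:
                if ev_type not in MUTATION_TYPES:
                    raise ValueError(f"unknown mutation type {ev_type!r}")
        for label in self.extant:
            if label not in known:
                raise ValueError(f"extant label {label!r} not declared")


def make_scripted_genealogy(spec: GenealogySpec) -> LineageForest:
    """Build a ``LineageForest`` from an explicit genealogy script.

    Cells must be declared parents-before-children.  Each cell's trail is
    its parent's trail plus its own events (timestamps must be
    non-decreasing along every trail); each founder starts its own lineage.
    Returns the forest restricted to the declared extant cells.
    """
    type_code = {name: i for i, name in enumerate(MUTATION_TYPES)}
    chain_parent: list[int] = []
    types: list[int] = []
    steps: list[int] = []
    depth: list[int] = []
    tip_of: dict[str, int] = {}
    lineage_of: dict[str, int] = {}
    last_step_of: dict[str, int] = {}
    next_lineage = 0
    for cell in spec.cells:
        if cell.parent is None:
            tip, lineage, last_step = -1, next_lineage, -1
            next_lineage += 1
        else:
            if cell.parent not in tip_of:
                raise ValueError(
                    f"cell {cell.label!r} declared before its parent {cell.parent!r}"
                )
            tip = tip_of[cell.parent]
            lineage = lineage_of[cell.parent]
            last_step = last_step_of[cell.parent]
        for ev_step, ev_type in cell.events:
            if ev_step < last_step:
                raise ValueError(
                    f"event timestamps out of order on trail of {cell.label!r}"
                )
            pos = len(chain_parent)
            chain_parent.append(tip)
            types.append(type_code[ev_type])
            steps.append(int(ev_step))
            depth.append(0 if tip < 0 else depth[tip] + 1)
            tip = pos
            last_step = ev_step
        tip_of[cell.label] = tip
        lineage_of[cell.label] = lineage
        last_step_of[cell.label] = last_step
    tips = np.asarray([tip_of[l] for l in spec.extant], dtype=np.int64)
    lineages = np.asarray([lineage_of[l] for l in spec.extant], dtype=np.int64)
    return LineageForest(
        np.asarray(chain_parent, dtype=np.int64),
        np.asarray(types, dtype=np.int8),
        np.asarray(steps, dtype=np.int64),
        np.asarray(depth, dtype=np.int64),
        tips,
        lineages,
    )
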