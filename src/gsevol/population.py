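"""Population state and the cell life cycle.

The population is a well-mixed collection of haploid clonal cells competing
for a single finite resource pool.  Total resource is strictly conserved::

    free_pool + sum_i r_i == R_env      (the model's master invariant)

Every sub-operation below moves resource between cells and the free pool but
never creates or destroys it.

One full time step applies, in order:

1. ``pay_or_die`` — each cell independently dies with probability ``delta``
   (returning its whole internal resource to the pool) or pays its genome
   cost ``K(n)`` into the pool.  A cell that cannot cover the full cost pays
   what it has and is left to the starvation check.
2. ``cull_starved`` — cells whose internal resource fell strictly below
   ``r_min`` die and return their resource to the pool.
3. ``feed`` — cells are queued in uniformly random order; each receives its
   uptake ``U_i(x)`` at the current condition ``x`` from the pool until the
   pool is depleted (the cell at the front when it runs dry receives the
   remainder; everyone behind goes unfed).
4. a second ``cull_starved`` — removes cells that were already below the
   starvation threshold and went unfed.
5. ``reproduce`` — each cell whose resource strictly exceeds ``r_rep``
   splits into two clonal daughters with half the resource each; each
   daughter independently undergoes each of the three mutation types
   (duplication, deletion, modification, applied in that canonical order)
   with probability ``mu`` per type.

The double starvation cull keeps dead cells from feeding and prevents
negative balances.  Paying costs before feeding mirrors the cells "returning"
resources ahead of uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    SQRT_2PI,
    CostParams,
    Genome,
    MutationInfo,
    mutate_deletion,
    mutate_duplication,
    mutate_modification,
)

__all__ = [
    "LifeCycleParams",
    "Cell",
    "Population",
    "EventLog",
    "StepStats",
    "pay_or_die",
    "feed",
    "cull_starved",
    "reproduce",
    "step",
    "CONSERVATION_RTOL",
    "DEFAULT_SUBSTEP_ORDER",
]

CONSERVATION_RTOL = 1e-6

#: Canonical sub-step order of one time step.
DEFAULT_SUBSTEP_ORDER = ("pay_or_die", "cull_starved", "feed", "cull_starved", "reproduce")

MUTATION_TYPES = ("duplication", "deletion", "modification")
_TYPE_CODE = {name: i for i, name in enumerate(MUTATION_TYPES)}


@dataclass(frozen=True)
class LifeCycleParams:
    """Parameters of the cell life cycle.

    cost : genome cost model (gamma, kappa) and the area constant alpha.
    delta : per-step probability of random (non-starvation) death.
    mu : per-type, per-daughter mutation probability at reproduction.
    r_min : starvation threshold — a cell dies when its resource drops
        strictly below this.
    r_rep : reproduction threshold — a cell divides when its resource
        strictly exceeds this.
    m_c, m_A : half-widths of the uniform modification perturbation applied
        to a gene's centre and peak efficiency.
    """

    cost: CostParams
    delta: float
    mu: float
    r_min: float
    r_rep: float
    m_c: float = 0.1
    m_A: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not self.r_min > 0:
            raise ValueError("r_min must be positive")
        if not self.r_rep > self.r_min:
            raise ValueError("r_rep must exceed r_min")


@dataclass(frozen=True)
class Cell:
    """Read-only view of one cell (convenience for tests and inspection)."""

    genome: Genome
    r: float
    cell_id: int
    lineage_id: int
    birth_step: int
    trail_tip: int


class EventLog:
    """Append-only log of mutation events with genealogy structure.

    Each event knows the event preceding it on its cell's mutation trail
    (``chain_parent``, a position in this log, or -1 for the trail root).
    Trails are therefore paths in a forest, and "fixed in a lineage" reduces
    to: ancestors of the lowest common ancestor of all extant trail tips.

    Event ids are ``start_id + position`` so they can share a namespace with
    founder gene variant ids.
    """

    def __init__(self, start_id: int = 0):
        self.start_id = int(start_id)
        self.chain_parent: list[int] = []
        self.type_code: list[int] = []
        self.step: list[int] = []
        self.depth: list[int] = []
        self._records: list[tuple] = []

    def __len__(self) -> int:
        return len(self.chain_parent)

    def append(
        self,
        *,
        step: int,
        cell_id: int,
        parent_cell_id: int,
        lineage_id: int,
        chain_parent: int,
        info: MutationInfo,
    ) -> int:
        """Record one mutation event; returns its globally unique event id."""
        pos = len(self.chain_parent)
        self.chain_parent.append(int(chain_parent))
        self.type_code.append(_TYPE_CODE[info.type])
        self.step.append(int(step))
        self.depth.append(0 if chain_parent < 0 else self.depth[chain_parent] + 1)
        event_id = self.start_id + pos
        self._records.append(
            (
                event_id,
                int(step),
                int(cell_id),
                int(parent_cell_id),
                int(lineage_id),
                info.type,
                int(info.gene_index),
                info.old_c,
                info.old_A,
                info.new_c,
                info.new_A,
                int(info.new_origin_id),
            )
        )
        return event_id

    def next_id(self) -> int:
        return self.start_id + len(self.chain_parent)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._records,
            columns=[
                "event_id",
                "step",
                "cell_id",
                "parent_cell_id",
                "lineage_id",
                "type",
                "gene_index",
                "old_c",
                "old_A",
                "new_c",
                "new_A",
                "new_origin_id",
            ],
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(chain_parent, type_code, step, depth) as numpy arrays."""
        return (
            np.asarray(self.chain_parent, dtype=np.int64),
            np.asarray(self.type_code, dtype=np.int8),
            np.asarray(self.step, dtype=np.int64),
            np.asarray(self.depth, dtype=np.int64),
        )


class Population:
    """All living cells plus the free resource pool.

    Cell state is held in parallel arrays (internal resource, ids, lineage
    labels, trail tips) and a list of ``Genome`` objects.  Genomes are
    immutable, so clonal daughters share their parent's object until a
    mutation replaces it.
    """

    def __init__(
        self,
        genomes: Sequence[Genome],
        r,
        R_env: float,
        free_pool: Optional[float] = None,
        *,
        lineage_id=None,
        cell_id=None,
        birth_step=None,
        trail_tip=None,
        alpha: Optional[float] = None,
        enforce_conservation: bool = True,
    ):
        self.genomes: list[Genome] = list(genomes)
        self.r = np.asarray(r, dtype=float).copy()
        if self.r.ndim != 1 or len(self.genomes) != self.r.size:
            raise ValueError("need one resource balance per genome")
        if np.any(self.r < 0):
            raise ValueError("internal resources must be non-negative")
        n = self.r.size
        self.R_env = float(R_env)
        held = float(self.r.sum())
        if free_pool is None:
            free_pool = self.R_env - held
        self.free_pool = float(free_pool)
        if self.free_pool < -CONSERVATION_RTOL * max(1.0, self.R_env):
            raise ValueError("cells hold more resource than R_env provides")
        self.free_pool = max(self.free_pool, 0.0)
        if enforce_conservation and abs(
            self.free_pool + held - self.R_env
        ) > CONSERVATION_RTOL * max(1.0, self.R_env):
            raise ValueError("free_pool + held resources must equal R_env")

        def _arr(v, default, dtype=np.int64):
            if v is None:
                return np.asarray(default, dtype=dtype)
            a = np.asarray(v, dtype=dtype).copy()
            if a.size != n:
                raise ValueError("per-cell array has wrong length")
            return a

        self.cell_id = _arr(cell_id, np.arange(n))
        self.lineage_id = _arr(lineage_id, np.arange(n))
        self.birth_step = _arr(birth_step, np.zeros(n))
        self.trail_tip = _arr(trail_tip, np.full(n, -1))
        if alpha is None:
            alpha = self.genomes[0].alpha if self.genomes else 1.0
        self.alpha = float(alpha)
        self._rebuild_caches()
        self._next_cell_id = int(self.cell_id.max()) + 1 if n else 0
        top = max((int(g.origin.max()) for g in self.genomes if g.n), default=-1)
        self._next_variant_id = top + 1

    # -- basic queries ------------------------------------------------------

    @property
    def size(self) -> int:
        return self.r.size

    @property
    def extinct(self) -> bool:
        return self.size == 0

    def _rebuild_caches(self) -> None:
        # flat per-gene arrays (cells in order) and per-cell gene counts;
        # kept in sync by remove()/reproduce(), which only append or mask
        self._n = np.fromiter(
            (g.n for g in self.genomes), dtype=np.int64, count=len(self.genomes)
        )
        if self._n.sum():
            self._flat_c = np.concatenate([g.c for g in self.genomes])
            self._flat_A = np.concatenate([g.A for g in self.genomes])
            self._flat_origin = np.concatenate([g.origin for g in self.genomes])
        else:
            self._flat_c = np.empty(0)
            self._flat_A = np.empty(0)
            self._flat_origin = np.empty(0, dtype=np.int64)

    def gene_counts(self) -> np.ndarray:
        return self._n

    def total_resource(self) -> float:
        return self.free_pool + float(self.r.sum())

    def conservation_error(self) -> float:
        """Relative deviation of total resource from R_env."""
        return abs(self.total_resource() - self.R_env) / max(1.0, self.R_env)

    def check_conservation(self, rtol: float = CONSERVATION_RTOL) -> None:
        err = self.conservation_error()
        if err > rtol:
            raise AssertionError(f"resource conservation violated: rel err {err:.3e}")

    def cells(self) -> list[Cell]:
        return [
            Cell(
                self.genomes[i],
                float(self.r[i]),
                int(self.cell_id[i]),
                int(self.lineage_id[i]),
                int(self.birth_step[i]),
                int(self.trail_tip[i]),
            )
            for i in range(self.size)
        ]

    def uptake_at(self, x: float) -> np.ndarray:
        """Vector of U_i(x) for every living cell (0 for empty genomes)."""
        N = self.size
        U = np.zeros(N)
        if N == 0:
            return U
        lens = self._n
        if self._flat_A.size == 0:
            return U
        flat_c = self._flat_c
        flat_A = self._flat_A
        sig = self.alpha / (flat_A * SQRT_2PI)
        u = flat_A * np.exp(-((x - flat_c) ** 2) / (2.0 * sig * sig))
        nz = lens > 0
        offsets = np.zeros(N, dtype=np.int64)
        np.cumsum(lens[:-1], out=offsets[1:])
        U[nz] = np.maximum.reduceat(u, offsets[nz])
        return U

    def costs(self, cost: CostParams) -> np.ndarray:
        ns = self._n
        return cost.gamma * (ns + ns * ns) + cost.kappa

    # -- structural edits ---------------------------------------------------

    def remove(self, dead_mask: np.ndarray) -> None:
        """Drop cells flagged in ``dead_mask`` (their r must already have
        been returned to the pool by the caller)."""
        if not dead_mask.any():
            return
        keep = ~dead_mask
        self.genomes = [g for g, k in zip(self.genomes, keep) if k]
        self.r = self.r[keep]
        self.cell_id = self.cell_id[keep]
        self.lineage_id = self.lineage_id[keep]
        self.birth_step = self.birth_step[keep]
        self.trail_tip = self.trail_tip[keep]
        gene_keep = np.repeat(keep, self._n)
        self._flat_c = self._flat_c[gene_keep]
        self._flat_A = self._flat_A[gene_keep]
        self._flat_origin = self._flat_origin[gene_keep]
        self._n = self._n[keep]

    def new_cell_id(self) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        return cid

    def new_variant_id(self) -> int:
        vid = self._next_variant_id
        self._next_variant_id += 1
        return vid

    def copy(self) -> "Population":
        pop = Population(
            [g.copy() for g in self.genomes],
            self.r,
            self.R_env,
            self.free_pool,
            lineage_id=self.lineage_id,
            cell_id=self.cell_id,
            birth_step=self.birth_step,
            trail_tip=self.trail_tip,
            alpha=self.alpha,
            enforce_conservation=False,
        )
        pop._next_cell_id = self._next_cell_id
        pop._next_variant_id = self._next_variant_id
        return pop

    def __repr__(self) -> str:  # pragma: no cover
        return f"Population(size={self.size}, free_pool={self.free_pool:.3f}, R_env={self.R_env})"


@dataclass
class StepStats:
    """Per-step bookkeeping emitted by ``step`` (one time-series row)."""

    x: float = np.nan
    census: int = 0
    free_pool: float = 0.0
    mean_n: float = np.nan
    var_n: float = np.nan
    mean_uptake: float = np.nan
    births: int = 0
    deaths_random: int = 0
    deaths_starved: int = 0
    mutation_events: int = 0
    extinct: bool = False


# ---------------------------------------------------------------------------
# Life-cycle sub-operations.  Each mutates `pop` in place, conserves total
# resource, and reports what happened through `stats`.


def pay_or_die(
    pop: Population,
    params: LifeCycleParams,
    rng: np.random.Generator,
    stats: Optional[StepStats] = None,
) -> Population:
    """Random death with probability delta; survivors pay min(K, r) into the
    free pool."""
    if pop.size == 0:
        return pop
    dead = (
        rng.random(pop.size) < params.delta
        if params.delta > 0
        else np.zeros(pop.size, dtype=bool)
    )
    if params.delta >= 1.0:
        dead[:] = True
    K = pop.costs(params.cost)
    pay = np.minimum(K, pop.r)
    pay[dead] = 0.0
    returned = float(pay.sum()) + float(pop.r[dead].sum())
    pop.r -= pay
    pop.r[dead] = 0.0
    pop.free_pool += returned
    pop.remove(dead)
    if stats is not None:
        stats.deaths_random += int(dead.sum())
    return pop


def feed(
    pop: Population,
    x: float,
    rng: np.random.Generator,
    stats: Optional[StepStats] = None,
) -> Population:
    """Feed cells one by one in uniformly random order.

    Each visited cell receives ``min(U_i(x), remaining pool)``; once the pool
    is exhausted the rest of the queue goes unfed.
    """
    if abs(x) > 1.0:
        raise ValueError("environmental condition x must lie in [-1, 1]")
    if pop.size == 0:
        return pop
    U = pop.uptake_at(x)
    if stats is not None:
        stats.mean_uptake = float(U.mean())
    if pop.free_pool <= 0.0:
        return pop
    order = rng.permutation(pop.size)
    u_ord = U[order]
    cum = np.cumsum(u_ord)
    pool = pop.free_pool
    # First queue position at which the cumulative demand exceeds the pool.
    k = int(np.searchsorted(cum, pool, side="left"))
    alloc = np.zeros(pop.size)
    alloc[:k] = u_ord[:k]
    if k < pop.size:
        prev = cum[k - 1] if k > 0 else 0.0
        alloc[k] = min(u_ord[k], pool - prev)
    total = float(alloc.sum())
    pop.r[order] += alloc
    pop.free_pool = max(pop.free_pool - total, 0.0)
    return pop


def cull_starved(
    pop: Population,
    r_min: float,
    stats: Optional[StepStats] = None,
) -> Population:
    """Remove every cell whose resource fell strictly below ``r_min``."""
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    if pop.size == 0:
        return pop
    dead = pop.r < r_min
    if dead.any():
        pop.free_pool += float(pop.r[dead].sum())
        pop.r[dead] = 0.0
        if stats is not None:
            stats.deaths_starved += int(dead.sum())
        pop.remove(dead)
    return pop


def reproduce(
    pop: Population,
    params: LifeCycleParams,
    rng: np.random.Generator,
    stats: Optional[StepStats] = None,
    *,
    step_idx: int = 0,
    log: Optional[EventLog] = None,
) -> Population:
    """Clonal fission of every cell with ``r > r_rep`` (strict).

    The parent is replaced by two daughters carrying ``r / 2`` each and the
    parent's lineage label and mutation trail; each daughter then mutates
    independently.  Mutations cost no resource, so conservation is untouched.
    """
    if pop.size == 0:
        return pop
    idx = np.flatnonzero(pop.r > params.r_rep)
    if idx.size == 0:
        return pop
    child_genomes: list[Genome] = []
    child_r: list[float] = []
    child_ids: list[int] = []
    child_lineage: list[int] = []
    child_tip: list[int] = []
    n_events = 0
    for i in idx:
        half = float(pop.r[i]) / 2.0
        parent_genome = pop.genomes[i]
        parent_id = int(pop.cell_id[i])
        lineage = int(pop.lineage_id[i])
        parent_tip = int(pop.trail_tip[i])
        for _ in range(2):
            child_id = pop.new_cell_id()
            genome, tip = parent_genome, parent_tip
            fire = rng.random(3) < params.mu
            if fire.any():
                for code in range(3):
                    if not fire[code]:
                        continue
                    if code == 0:
                        genome, info = mutate_duplication(genome, rng)
                    elif code == 1:
                        genome, info = mutate_deletion(genome, rng)
                    else:
                        new_vid = (
                            log.next_id() if log is not None else pop.new_variant_id()
                        )
                        genome, info = mutate_modification(
                            genome, rng, params.m_c, params.m_A, new_origin_id=new_vid
                        )
                    if info is None:
                        continue
                    n_events += 1
                    if log is not None:
                        new_tip = len(log)
                        log.append(
                            step=step_idx,
                            cell_id=child_id,
                            parent_cell_id=parent_id,
                            lineage_id=lineage,
                            chain_parent=tip,
                            info=info,
                        )
                        tip = new_tip
            child_genomes.append(genome)
            child_r.append(half)
            child_ids.append(child_id)
            child_lineage.append(lineage)
            child_tip.append(tip)
    keep = np.ones(pop.size, dtype=bool)
    keep[idx] = False
    gene_keep = np.repeat(keep, pop._n)
    child_ns = np.fromiter((g.n for g in child_genomes), dtype=np.int64, count=len(child_genomes))
    child_parts = [g for g in child_genomes if g.n]
    pop._flat_c = np.concatenate([pop._flat_c[gene_keep]] + [g.c for g in child_parts])
    pop._flat_A = np.concatenate([pop._flat_A[gene_keep]] + [g.A for g in child_parts])
    pop._flat_origin = np.concatenate(
        [pop._flat_origin[gene_keep]] + [g.origin for g in child_parts]
    )
    pop._n = np.concatenate([pop._n[keep], child_ns])
    pop.genomes = [g for g, k in zip(pop.genomes, keep) if k] + child_genomes
    pop.r = np.concatenate([pop.r[keep], np.asarray(child_r)])
    pop.cell_id = np.concatenate([pop.cell_id[keep], np.asarray(child_ids, dtype=np.int64)])
    pop.lineage_id = np.concatenate(
        [pop.lineage_id[keep], np.asarray(child_lineage, dtype=np.int64)]
    )
    pop.birth_step = np.concatenate(
        [pop.birth_step[keep], np.full(len(child_ids), step_idx, dtype=np.int64)]
    )
    pop.trail_tip = np.concatenate(
        [pop.trail_tip[keep], np.asarray(child_tip, dtype=np.int64)]
    )
    if stats is not None:
        stats.births += int(idx.size)  # net gain: each fission adds one cell
        stats.mutation_events += n_events
    return pop


def step(
    pop: Population,
    env,
    params: LifeCycleParams,
    rng: np.random.Generator,
    *,
    step_idx: int = 0,
    log: Optional[EventLog] = None,
    substep_order: Sequence[str] = DEFAULT_SUBSTEP_ORDER,
) -> StepStats:
    """One full life-cycle step at environmental condition ``env``.

    ``env`` may be an ``EnvironmentState`` or a plain condition value x.
    Returns the per-step statistics; an empty population is a legal terminal
    state and is reported with ``extinct=True``.
    """
    x = float(getattr(env, "x", env))
    stats = StepStats(x=x)
    for op in substep_order:
        if op == "pay_or_die":
            pay_or_die(pop, params, rng, stats)
        elif op == "cull_starved":
            cull_starved(pop, params.r_min, stats)
        elif op == "feed":
            feed(pop, x, rng, stats)
        elif op == "reproduce":
            reproduce(pop, params, rng, stats, step_idx=step_idx, log=log)
        else:
            raise ValueError(f"unknown sub-step {op!r}")
    stats.census = pop.size
    stats.free_pool = pop.free_pool
    if pop.size:
        ns = pop.gene_counts()
        stats.mean_n = float(ns.mean())
        stats.var_n = float(ns.var())
    stats.extinct = pop.size == 0
    return stats
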