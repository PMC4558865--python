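"""Summary statistics over simulation records.

The statistics mirror the quantities used to characterise genome-size
evolution in this model:

* ``grand_mean_genes`` — the per-step mean gene count per cell, averaged
  over a post-stabilisation window (by default the final half of the run).
* ``fixed_mutations_per_lineage`` — the rate of adaptive evolution: how many
  mutation events became *fixed* in each clonal lineage, by mutation type.
  A clonal lineage is the set of all extant descendants of one founder cell;
  an event is fixed when it is carried in the mutation trail of every extant
  member.  Because trails are append-only paths in the event forest, the
  fixed events of a lineage are exactly the ancestors of the lowest common
  ancestor (LCA) of the extant trail tips.
* ``strain_count`` — the number of distinct extant genotypes, where a
  genotype is identified by its multiset of gene variant ids (exact
  comparison, no floating-point tolerance).
* ``mean_uptake_heatmap`` — the population-mean uptake envelope U(x) over
  time, from the stored genotype snapshots.
* ``crash_frequency`` — the fraction of replicate runs that went extinct
  before their configured horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import SQRT_2PI
from .population import MUTATION_TYPES, EventLog, Population

__all__ = [
    "UndefinedStatisticError",
    "LineageForest",
    "grand_mean_genes",
    "fixed_mutations_per_lineage",
    "fixed_mutations_per_strain",
    "strain_count",
    "mean_uptake_heatmap",
    "crash_frequency",
    "summarize_run",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested for a state where it has no
    value (empty window, extinct population, no extant lineages)."""


@dataclass
class LineageForest:
    """Mutation-event genealogy plus the extant cells that anchor it.

    ``chain_parent[i]`` is the position of the event preceding event ``i``
    on its cell's trail (-1 at the trail root), ``type_code[i]`` indexes
    ``MUTATION_TYPES``, ``step[i]`` is the birth step of the event.
    ``tips``/``lineages`` give, for every extant cell, its trail tip
    position (-1 if it never mutated) and its founder lineage.
    """

    chain_parent: np.ndarray
    type_code: np.ndarray
    step: np.ndarray
    depth: np.ndarray
    tips: np.ndarray
    lineages: np.ndarray

    @classmethod
    def from_population(cls, pop: Population, log: EventLog) -> "LineageForest":
        chain_parent, type_code, step, depth = log.arrays()
        return cls(
            chain_parent,
            type_code,
            step,
            depth,
            pop.trail_tip.copy(),
            pop.lineage_id.copy(),
        )

    @classmethod
    def from_record(cls, record) -> "LineageForest":
        if record.event_log is None:
            raise ValueError("record has no event log")
        if record.final_population is not None:
            return cls.from_population(record.final_population, record.event_log)
        snap = record.snapshots[-1]
        chain_parent, type_code, step, depth = record.event_log.arrays()
        return cls(
            chain_parent,
            type_code,
            step,
            depth,
            snap.cells["trail_tip"].to_numpy(np.int64),
            snap.cells["lineage_id"].to_numpy(np.int64),
        )

    @property
    def n_extant(self) -> int:
        return self.tips.size

    def trail(self, tip: int) -> list[int]:
        """Event positions on the path from the trail root to ``tip``."""
        path = []
        node = int(tip)
        while node != -1:
            path.append(node)
            node = int(self.chain_parent[node])
        return path[::-1]

    def _lca(self, a: int, b: int) -> int:
        parent, depth = self.chain_parent, self.depth
        while a != b:
            if a == -1 or b == -1:
                return -1
            if depth[a] >= depth[b]:
                a = int(parent[a])
            else:
                b = int(parent[b])
        return a

    def fixed_events(self, tips: Iterable[int]) -> list[int]:
        """Events carried by every one of the given trail tips: the path
        from the root to the tips' LCA (inclusive)."""
        tips = list(tips)
        if not tips:
            return []
        node = tips[0]
        for t in tips[1:]:
            node = self._lca(node, int(t))
            if node == -1:
                return []
        return self.trail(node)


def _resolve_window(record, window) -> tuple[int, int]:
    steps = record.timeseries["step"].to_numpy()
    last = int(steps.max()) if steps.size else 0
    if window is None:
        start = (last + 1) // 2
        return start, last
    start, end = int(window[0]), int(window[1])
    if start > end:
        raise UndefinedStatisticError("empty window")
    if end > last:
        raise UndefinedStatisticError(f"window end {end} beyond run end {last}")
    return start, end


def grand_mean_genes(record, window: Optional[tuple[int, int]] = None) -> float:
    """Grand mean gene number: the per-step mean gene count per cell,
    averaged over the steps of ``window`` (inclusive; default the final half
    of the run).  Undefined if the population is extinct anywhere in the
    window."""
    start, end = _resolve_window(record, window)
    ts = record.timeseries
    sel = ts[(ts["step"] >= start) & (ts["step"] <= end)]
    if not len(sel):
        raise UndefinedStatisticError("no steps in window")
    if (sel["census"] == 0).any():
        raise UndefinedStatisticError("population extinct inside the window")
    return float(sel["mean_n"].mean())


def fixed_mutations_per_lineage(
    forest_or_record,
    window: Optional[tuple[int, int]] = None,
) -> dict[str, float]:
    """Mean number of fixed mutation events per extant clonal lineage, by
    mutation type.

    An event counts when (a) it is present in the mutation trail of every
    extant cell of its lineage and (b) its birth step lies in ``window``
    (inclusive; default: all steps).  Raises if there are no extant
    lineages."""
    if isinstance(forest_or_record, LineageForest):
        forest = forest_or_record
        lo, hi = (
            (int(window[0]), int(window[1]))
            if window is not None
            else (0, np.iinfo(np.int64).max)
        )
    else:
        forest = LineageForest.from_record(forest_or_record)
        lo, hi = _resolve_window(forest_or_record, window) if window is not None else (
            0,
            np.iinfo(np.int64).max,
        )
    if forest.n_extant == 0:
        raise UndefinedStatisticError("no extant lineages")
    totals = np.zeros(len(MUTATION_TYPES))
    lineage_ids = np.unique(forest.lineages)
    for lid in lineage_ids:
        tips = forest.tips[forest.lineages == lid]
        for ev in forest.fixed_events(tips):
            s = forest.step[ev]
            if lo <= s <= hi:
                totals[forest.type_code[ev]] += 1
    means = totals / lineage_ids.size
    return {name: float(means[i]) for i, name in enumerate(MUTATION_TYPES)}


def fixed_mutations_per_strain(
    record,
    window: Optional[tuple[int, int]] = None,
) -> dict[str, float]:
    """Mean number of fixed mutation events per extant clonal strain, by type.

    A clonal strain is a set of extant cells with identical genotypes
    (same variant-id multiset).  An event is fixed in a strain when every
    member carries it; counting is restricted to events born inside
    ``window`` (inclusive; default: all steps).  Because strains are finer
    groupings than founder lineages, strain-level counts include recently
    arisen events that have not yet sorted across the whole lineage, so
    their type composition sits closer to the raw mutational supply.
    """
    forest = LineageForest.from_record(record)
    if forest.n_extant == 0:
        raise UndefinedStatisticError("no extant lineages")
    lo, hi = (
        _resolve_window(record, window)
        if window is not None
        else (0, np.iinfo(np.int64).max)
    )
    pop = record.final_population
    if pop is not None:
        keys = [g.strain_key() for g in pop.genomes]
    else:
        keys = _strain_keys_from_snapshot(record.snapshots[-1])
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    totals = np.zeros(len(MUTATION_TYPES))
    for members in groups.values():
        tips = forest.tips[members]
        for ev in forest.fixed_events(tips):
            s = forest.step[ev]
            if lo <= s <= hi:
                totals[forest.type_code[ev]] += 1
    means = totals / len(groups)
    return {name: float(means[i]) for i, name in enumerate(MUTATION_TYPES)}


def _strain_keys_from_snapshot(snapshot) -> list[tuple]:
    keys = {int(cid): () for cid in snapshot.cells["cell_id"]}
    if len(snapshot.genes):
        for cid, grp in snapshot.genes.groupby("cell_id", sort=False):
            keys[int(cid)] = tuple(sorted(int(o) for o in grp["origin_id"]))
    return list(keys.values())


def strain_count(snapshot_or_population) -> int:
    """Number of distinct extant genotypes (clonal strains).

    Genotypes compare as multisets of gene variant ids, so two cells belong
    to the same strain iff their genomes descend from the same variants with
    the same copy numbers."""
    obj = snapshot_or_population
    if isinstance(obj, Population):
        if obj.size == 0:
            raise UndefinedStatisticError("empty population has no strains")
        return len({g.strain_key() for g in obj.genomes})
    if not len(obj.cells):
        raise UndefinedStatisticError("empty snapshot has no strains")
    return len(set(_strain_keys_from_snapshot(obj)))


def _mean_uptake_profile(snapshot, alpha: float, x_grid: np.ndarray) -> np.ndarray:
    """Population mean of the per-cell uptake envelope on ``x_grid``."""
    n_cells = len(snapshot.cells)
    if n_cells == 0:
        return np.zeros(x_grid.size)
    genes = snapshot.genes
    if not len(genes):
        return np.zeros(x_grid.size)
    c = genes["c"].to_numpy()
    A = genes["A"].to_numpy()
    sig = alpha / (A * SQRT_2PI)
    u = A[:, None] * np.exp(
        -((x_grid[None, :] - c[:, None]) ** 2) / (2.0 * sig[:, None] ** 2)
    )
    # segment max per cell; cells without genes contribute a zero envelope
    cell_ids = genes["cell_id"].to_numpy()
    order = np.argsort(cell_ids, kind="stable")
    u = u[order]
    cell_ids = cell_ids[order]
    boundaries = np.flatnonzero(np.r_[True, cell_ids[1:] != cell_ids[:-1]])
    env = np.maximum.reduceat(u, boundaries, axis=0)
    return env.sum(axis=0) / n_cells


def mean_uptake_heatmap(
    record,
    x_grid: Optional[np.ndarray] = None,
    t_stride: int = 1,
) -> pd.DataFrame:
    """Heatmap of the population-mean uptake envelope over time.

    Rows are snapshot steps (every ``t_stride``-th stored snapshot), columns
    the environmental grid; entry (t, x) is the mean over cells of U(x).
    All values lie in [0, 1]."""
    if t_stride < 1:
        raise ValueError("t_stride must be positive")
    if x_grid is None:
        x_grid = np.linspace(-1.0, 1.0, 201)
    x_grid = np.asarray(x_grid, dtype=float)
    alpha = record.config.alpha
    snaps = record.snapshots[::t_stride]
    data = np.vstack(
        [_mean_uptake_profile(s, alpha, x_grid) for s in snaps]
    ) if snaps else np.zeros((0, x_grid.size))
    return pd.DataFrame(data, index=[s.step for s in snaps], columns=x_grid)


def crash_frequency(records: Sequence) -> float:
    """Fraction of replicate runs that ended in extinction before their
    configured horizon."""
    records = list(records)
    if not records:
        raise UndefinedStatisticError("need at least one record")
    return sum(1 for r in records if r.extinct) / len(records)


def summarize_run(record, window: Optional[tuple[int, int]] = None) -> dict:
    """One-stop report for a single run (used by the ``stats`` CLI)."""
    report: dict = {
        "status": record.status,
        "extinct_step": record.extinct_step,
        "final_census": int(record.timeseries["census"].iloc[-1]),
        "steps": int(record.timeseries["step"].iloc[-1]),
    }
    try:
        report["grand_mean_genes"] = grand_mean_genes(record, window)
    except UndefinedStatisticError:
        report["grand_mean_genes"] = None
    try:
        fixed = fixed_mutations_per_lineage(record, window)
        report["fixed_mutations_per_lineage"] = fixed
    except (UndefinedStatisticError, ValueError):
        report["fixed_mutations_per_lineage"] = None
    try:
        report["strain_count"] = strain_count(record.snapshots[-1])
    except UndefinedStatisticError:
        report["strain_count"] = None
    return report
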