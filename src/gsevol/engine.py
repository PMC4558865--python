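"""Seeded, configurable simulation runs.

``SimConfig`` collects every model parameter; ``run`` wires the bounded
random-walk environment to the population life cycle and produces a
``SimulationRecord`` holding the per-step time series, periodic genotype
snapshots, the mutation-event log, and the final population.  Runs are fully
deterministic given ``(config, seed)``: the master seed is split into four
independent sub-streams (initialisation, environment, life cycle, mutation)
so that, e.g., changing the mutation rate does not perturb the environmental
trajectory.

The default parameter values are the package's calibrated baseline (see
``docs/methods.md``): they are chosen so that populations in a constant
environment (T = 0) streamline to a grand mean of about two genes per
genome, while turbulent environments select for substantially larger
genomes.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .environment import (
    BOUNDARY_MODES,
    EnvironmentState,
    TurbulenceSchedule,
    step_environment,
)
from .genome import CostParams, Genome, sigma_of
from .population import (
    DEFAULT_SUBSTEP_ORDER,
    EventLog,
    LifeCycleParams,
    Population,
    StepStats,
    step,
)

__all__ = [
    "SimConfig",
    "Snapshot",
    "SimulationRecord",
    "initialize",
    "run",
    "resume",
    "run_replicates",
]

_TIMESERIES_COLUMNS = [
    "step",
    "x",
    "T",
    "census",
    "free_pool",
    "mean_n",
    "var_n",
    "mean_uptake",
    "births",
    "deaths_random",
    "deaths_starved",
    "mutation_events",
]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulation run.

    Resource and cost parameters are in the model's abstract resource units;
    one time step is the unit of time.  ``T_schedule`` accepts a scalar
    turbulence, a ``TurbulenceSchedule``, or a list of ``{start_step, T}``
    segments.
    """

    T_schedule: object = 0.0
    R_env: float = 2000.0
    gamma: float = 1.1e-4
    kappa: float = 0.002
    alpha: float = 0.04
    delta: float = 0.01
    mu: float = 0.015
    r_min: float = 0.5
    r_rep: float = 8.0
    init_pop_size: int = 300
    eta0_range: tuple[int, int] = (1, 10)
    init_resource: Optional[float] = None  # default: (r_min + r_rep) / 2
    steps: int = 50_000
    seed: int = 0
    snapshot_every: int = 1000
    boundary_mode: str = "resample"
    substep_order: tuple[str, ...] = DEFAULT_SUBSTEP_ORDER
    m_c: float = 0.15
    m_A: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "T_schedule", TurbulenceSchedule.from_value(self.T_schedule)
        )
        object.__setattr__(self, "eta0_range", tuple(int(v) for v in self.eta0_range))
        object.__setattr__(self, "substep_order", tuple(self.substep_order))
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if not (0 < self.r_min < self.r_rep):
            raise ValueError("need r_rep > r_min > 0")
        lo, hi = self.eta0_range
        if lo < 0 or lo > hi:
            raise ValueError("eta0_range must satisfy 0 <= lo <= hi")
        if self.init_pop_size < 1:
            raise ValueError("init_pop_size must be positive")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be positive")
        if self.init_pop_size * self.initial_resource_per_cell() > self.R_env * (
            1 + 1e-9
        ):
            raise ValueError(
                "infeasible config: initial cells would hold more than R_env"
            )
        # Validate shared-parameter constraints eagerly.
        self.life_cycle_params()

    def initial_resource_per_cell(self) -> float:
        return (
            float(self.init_resource)
            if self.init_resource is not None
            else 0.5 * (self.r_min + self.r_rep)
        )

    def cost_params(self) -> CostParams:
        return CostParams(gamma=self.gamma, kappa=self.kappa, alpha=self.alpha)

    def life_cycle_params(self) -> LifeCycleParams:
        return LifeCycleParams(
            cost=self.cost_params(),
            delta=self.delta,
            mu=self.mu,
            r_min=self.r_min,
            r_rep=self.r_rep,
            m_c=self.m_c,
            m_A=self.m_A,
        )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["T_schedule"] = self.T_schedule.to_jsonable()
        d["eta0_range"] = list(self.eta0_range)
        d["substep_order"] = list(self.substep_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "eta0_range" in d:
            d["eta0_range"] = tuple(d["eta0_range"])
        if "substep_order" in d:
            d["substep_order"] = tuple(d["substep_order"])
        return cls(**d)


@dataclass
class Snapshot:
    """Full-population genotype snapshot at one step.

    ``cells``: one row per cell (cell_id, lineage_id, r, birth_step,
    trail_tip, n).  ``genes``: one row per gene (cell_id, lineage_id, c, A,
    sigma, origin_id).
    """

    step: int
    cells: pd.DataFrame
    genes: pd.DataFrame

    @classmethod
    def from_population(cls, pop: Population, step_idx: int) -> "Snapshot":
        ns = pop.gene_counts()
        cells = pd.DataFrame(
            {
                "cell_id": pop.cell_id,
                "lineage_id": pop.lineage_id,
                "r": pop.r,
                "birth_step": pop.birth_step,
                "trail_tip": pop.trail_tip,
                "n": ns,
            }
        )
        if pop.size and ns.sum():
            flat_c = np.concatenate([g.c for g in pop.genomes])
            flat_A = np.concatenate([g.A for g in pop.genomes])
            flat_o = np.concatenate([g.origin for g in pop.genomes])
            genes = pd.DataFrame(
                {
                    "cell_id": np.repeat(pop.cell_id, ns),
                    "lineage_id": np.repeat(pop.lineage_id, ns),
                    "c": flat_c,
                    "A": flat_A,
                    "sigma": sigma_of(flat_A, pop.alpha)
                    if flat_A.size
                    else flat_A,
                    "origin_id": flat_o,
                }
            )
        else:
            genes = pd.DataFrame(
                columns=["cell_id", "lineage_id", "c", "A", "sigma", "origin_id"]
            )
        return cls(step=step_idx, cells=cells, genes=genes)

    def genomes(self, alpha: float) -> dict[int, Genome]:
        """Reconstruct per-cell genomes (cell_id -> Genome)."""
        out: dict[int, Genome] = {}
        for cid in self.cells["cell_id"]:
            out[int(cid)] = Genome.empty(alpha)
        if len(self.genes):
            for cid, grp in self.genes.groupby("cell_id", sort=False):
                out[int(cid)] = Genome(
                    grp["c"].to_numpy(),
                    grp["A"].to_numpy(),
                    alpha,
                    grp["origin_id"].to_numpy(),
                )
        return out


@dataclass
class _Checkpoint:
    """Complete engine state, sufficient to continue a run bit-identically."""

    step: int
    population: Population
    env_state: EnvironmentState
    env_rng_state: dict
    life_rng_state: dict
    mut_rng_state: dict
    event_log: EventLog
    rows: list
    snapshots: list


@dataclass
class SimulationRecord:
    """Everything a run produced; sufficient to compute every statistic
    without re-running."""

    config: SimConfig
    seed: int
    timeseries: pd.DataFrame
    snapshots: list[Snapshot]
    events: pd.DataFrame
    status: str  # "completed" | "extinct"
    extinct_step: Optional[int]
    final_population: Optional[Population] = None
    event_log: Optional[EventLog] = None
    checkpoint: Optional[_Checkpoint] = None

    @property
    def extinct(self) -> bool:
        return self.status == "extinct"

    def snapshot_at(self, step_idx: int) -> Snapshot:
        for snap in self.snapshots:
            if snap.step == step_idx:
                return snap
        raise KeyError(f"no snapshot stored at step {step_idx}")

    # -- persistence --------------------------------------------------------

    def to_dir(self, path) -> Path:
        """Write timeseries.tsv, events.tsv, snapshots/*.tsv and meta.json."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.timeseries.to_csv(out / "timeseries.tsv", sep="\t", index=False)
        self.events.to_csv(out / "events.tsv", sep="\t", index=False)
        snapdir = out / "snapshots"
        snapdir.mkdir(exist_ok=True)
        for snap in self.snapshots:
            snap.cells.to_csv(
                snapdir / f"step_{snap.step:08d}_cells.tsv", sep="\t", index=False
            )
            snap.genes.to_csv(
                snapdir / f"step_{snap.step:08d}_genes.tsv", sep="\t", index=False
            )
        meta = {
            "format": "gsevol-run",
            "version": __version__,
            "seed": self.seed,
            "status": self.status,
            "extinct_step": self.extinct_step,
            "event_log_start_id": self.event_log.start_id if self.event_log else 0,
            "config": self.config.to_jsonable(),
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
        return out

    @classmethod
    def from_dir(cls, path) -> "SimulationRecord":
        src = Path(path)
        meta = json.loads((src / "meta.json").read_text())
        config = SimConfig.from_dict(meta["config"])
        ts = pd.read_csv(src / "timeseries.tsv", sep="\t")
        events = pd.read_csv(src / "events.tsv", sep="\t")
        snaps = []
        snapdir = src / "snapshots"
        for cells_path in sorted(snapdir.glob("step_*_cells.tsv")):
            step_idx = int(cells_path.name.split("_")[1])
            genes_path = snapdir / f"step_{step_idx:08d}_genes.tsv"
            snaps.append(
                Snapshot(
                    step=step_idx,
                    cells=pd.read_csv(cells_path, sep="\t"),
                    genes=pd.read_csv(genes_path, sep="\t"),
                )
            )
        log = EventLog(start_id=int(meta.get("event_log_start_id", 0)))
        if len(events):
            for row in events.itertuples(index=False):
                log.chain_parent.append(int(row.chain_parent))
                log.type_code.append(int(row.type_code))
                log.step.append(int(row.step))
                log.depth.append(int(row.depth))
        return cls(
            config=config,
            seed=int(meta["seed"]),
            timeseries=ts,
            snapshots=snaps,
            events=events,
            status=meta["status"],
            extinct_step=meta["extinct_step"],
            final_population=None,
            event_log=log,
        )


def _spawn_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    """(init, environment, life-cycle, mutation) generator streams."""
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(child) for child in ss.spawn(4))


def initialize(config: SimConfig, rng: np.random.Generator) -> Population:
    """Found a population from the configured initial-genome-size range.

    Each founder cell receives a gene count drawn uniformly from
    ``eta0_range`` (inclusive); every founder gene gets a uniform centre on
    [-1, 1], a uniform peak efficiency on (0, 1], a globally unique variant
    id, and sigma from the area constraint.  Each founder is its own lineage;
    the remainder of ``R_env`` forms the free pool.
    """
    lo, hi = config.eta0_range
    n_cells = config.init_pop_size
    r0 = config.initial_resource_per_cell()
    counts = rng.integers(lo, hi + 1, size=n_cells)
    genomes = []
    next_variant = 0
    for n in counts:
        n = int(n)
        if n == 0:
            genomes.append(Genome.empty(config.alpha))
            continue
        c = rng.uniform(-1.0, 1.0, size=n)
        A = 1.0 - rng.random(n)  # uniform on (0, 1]
        origin = np.arange(next_variant, next_variant + n, dtype=np.int64)
        next_variant += n
        genomes.append(Genome(c, A, config.alpha, origin))
    pop = Population(
        genomes,
        np.full(n_cells, r0),
        R_env=config.R_env,
        alpha=config.alpha,
    )
    pop._next_variant_id = next_variant
    return pop


def _stats_row(t: int, T: float, stats: StepStats) -> tuple:
    return (
        t,
        stats.x,
        T,
        stats.census,
        stats.free_pool,
        stats.mean_n,
        stats.var_n,
        stats.mean_uptake,
        stats.births,
        stats.deaths_random,
        stats.deaths_starved,
        stats.mutation_events,
    )


def _observe(pop: Population, x: float) -> StepStats:
    """Time-series row for a state without running a life-cycle step."""
    stats = StepStats(x=x, census=pop.size, free_pool=pop.free_pool)
    if pop.size:
        ns = pop.gene_counts()
        stats.mean_n = float(ns.mean())
        stats.var_n = float(ns.var())
        stats.mean_uptake = float(pop.uptake_at(x).mean())
    stats.extinct = pop.size == 0
    return stats


def run(
    config: SimConfig,
    seed: Optional[int] = None,
    *,
    keep_checkpoint: bool = True,
) -> SimulationRecord:
    """Execute a full simulation run.

    ``seed`` overrides ``config.seed``.  The returned record carries the
    final engine state as an in-memory checkpoint so the run can be resumed
    (see ``resume``); on-disk output is written separately via
    ``SimulationRecord.to_dir``.
    """
    seed = config.seed if seed is None else int(seed)
    init_rng, env_rng, life_rng, mut_rng = _spawn_rngs(seed)
    pop = initialize(config, init_rng)
    founder_variants = pop._next_variant_id
    log = EventLog(start_id=founder_variants)
    env = EnvironmentState()
    schedule = config.T_schedule
    rows = [_stats_row(0, schedule.at(0), _observe(pop, env.x))]
    snapshots = [Snapshot.from_population(pop, 0)]
    state = _Checkpoint(
        step=0,
        population=pop,
        env_state=env,
        env_rng_state=env_rng.bit_generator.state,
        life_rng_state=life_rng.bit_generator.state,
        mut_rng_state=mut_rng.bit_generator.state,
        event_log=log,
        rows=rows,
        snapshots=snapshots,
    )
    return _run_loop(config, seed, state, env_rng, life_rng, mut_rng, keep_checkpoint)


def resume(
    record: SimulationRecord,
    steps: int,
    *,
    keep_checkpoint: bool = True,
) -> SimulationRecord:
    """Continue a run from its stored checkpoint up to step ``steps``.

    Resuming reproduces the uninterrupted run exactly: all four RNG streams
    are restored, so ``run(config with steps=N)`` and
    ``resume(run(config with steps=M), N)`` emit identical time series.
    """
    if record.checkpoint is None:
        raise ValueError("record carries no checkpoint; rerun with keep_checkpoint")
    ck = record.checkpoint
    if steps < ck.step:
        raise ValueError("cannot resume backwards")
    config = replace(record.config, steps=int(steps))
    env_rng = np.random.default_rng()
    life_rng = np.random.default_rng()
    mut_rng = np.random.default_rng()
    env_rng.bit_generator.state = copy.deepcopy(ck.env_rng_state)
    life_rng.bit_generator.state = copy.deepcopy(ck.life_rng_state)
    mut_rng.bit_generator.state = copy.deepcopy(ck.mut_rng_state)
    log = EventLog(start_id=ck.event_log.start_id)
    log.chain_parent = list(ck.event_log.chain_parent)
    log.type_code = list(ck.event_log.type_code)
    log.step = list(ck.event_log.step)
    log.depth = list(ck.event_log.depth)
    log._records = list(ck.event_log._records)
    state = _Checkpoint(
        step=ck.step,
        population=ck.population.copy(),
        env_state=ck.env_state,
        env_rng_state=ck.env_rng_state,
        life_rng_state=ck.life_rng_state,
        mut_rng_state=ck.mut_rng_state,
        event_log=log,
        rows=list(ck.rows),
        snapshots=list(ck.snapshots),
    )
    return _run_loop(
        config, record.seed, state, env_rng, life_rng, mut_rng, keep_checkpoint
    )


def _run_loop(
    config: SimConfig,
    seed: int,
    state: _Checkpoint,
    env_rng: np.random.Generator,
    life_rng: np.random.Generator,
    mut_rng: np.random.Generator,
    keep_checkpoint: bool,
) -> SimulationRecord:
    pop = state.population
    env = state.env_state
    log = state.event_log
    rows = state.rows
    snapshots = state.snapshots
    params = config.life_cycle_params()
    schedule = config.T_schedule
    status, extinct_step = "completed", None
    if pop.size == 0:
        status, extinct_step = "extinct", state.step
    t = state.step
    while t < config.steps and pop.size > 0:
        T = schedule.at(t)
        env = step_environment(env, T, env_rng, config.boundary_mode)
        t = env.t
        stats = _step_with_streams(pop, env.x, params, life_rng, mut_rng, t, log, config)
        rows.append(_stats_row(t, T, stats))
        if t % config.snapshot_every == 0 or t == config.steps:
            snapshots.append(Snapshot.from_population(pop, t))
        if pop.size == 0:
            status, extinct_step = "extinct", t
            if snapshots[-1].step != t:
                snapshots.append(Snapshot.from_population(pop, t))
            break
    timeseries = pd.DataFrame(rows, columns=_TIMESERIES_COLUMNS)
    events = _events_frame(log)
    checkpoint = None
    if keep_checkpoint:
        checkpoint = _Checkpoint(
            step=t,
            population=pop.copy(),
            env_state=env,
            env_rng_state=copy.deepcopy(env_rng.bit_generator.state),
            life_rng_state=copy.deepcopy(life_rng.bit_generator.state),
            mut_rng_state=copy.deepcopy(mut_rng.bit_generator.state),
            event_log=log,
            rows=list(rows),
            snapshots=list(snapshots),
        )
    return SimulationRecord(
        config=config,
        seed=seed,
        timeseries=timeseries,
        snapshots=snapshots,
        events=events,
        status=status,
        extinct_step=extinct_step,
        final_population=pop,
        event_log=log,
        checkpoint=checkpoint,
    )


def _step_with_streams(
    pop: Population,
    x: float,
    params: LifeCycleParams,
    life_rng: np.random.Generator,
    mut_rng: np.random.Generator,
    step_idx: int,
    log: EventLog,
    config: SimConfig,
) -> StepStats:
    """One life-cycle step with the life-cycle and mutation RNG streams
    kept separate (death/feeding-order draws vs mutation draws)."""
    from . import population as P

    stats = StepStats(x=x)
    for op in config.substep_order:
        if op == "pay_or_die":
            P.pay_or_die(pop, params, life_rng, stats)
        elif op == "cull_starved":
            P.cull_starved(pop, params.r_min, stats)
        elif op == "feed":
            P.feed(pop, x, life_rng, stats)
        elif op == "reproduce":
            P.reproduce(pop, params, mut_rng, stats, step_idx=step_idx, log=log)
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


def _events_frame(log: EventLog) -> pd.DataFrame:
    frame = log.to_frame()
    chain_parent, type_code, ev_step, depth = log.arrays()
    frame["chain_parent"] = chain_parent
    frame["type_code"] = type_code
    frame["depth"] = depth
    return frame


def run_replicates(
    config: SimConfig,
    seeds: Iterable[int],
    *,
    keep_checkpoint: bool = False,
) -> list[SimulationRecord]:
    """Run one independent replicate per seed.

    Replicates differ only in their pseudo-random seed; results do not
    depend on execution order.
    """
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("need at least one seed")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: replicates will be identical", stacklevel=2)
    return [run(config, seed=s, keep_checkpoint=keep_checkpoint) for s in seeds]
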