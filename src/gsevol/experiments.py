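"""Canned study designs for the model's headline analyses.

Each function runs a complete, seeded experiment on the calibrated baseline
(`SimConfig()` defaults) at a reduced scale — populations of a few hundred
cells and runs of tens of thousands of steps — and returns plain-dict
results.  They are used both by the acceptance test suite and by
``scripts/acceptance.py``; the scales here are the package's documented
study conditions (see ``docs/methods.md``).

Experiments
-----------
constant_environment_anchor
    Replicate runs at T = 0; the population should streamline to a grand
    mean of about two genes per genome.
turbulence_plateau
    Replicates at T = 0.05, 0.2 and 0.4; gene numbers rise steeply up to
    T ≈ 0.05 and change little beyond (the plateau).  Replicates that
    crash — a real feature of low-to-medium turbulence — are excluded from
    the surviving-run means but reported.
mutation_spectrum
    Replicates at T = 0.02; pooled counts of mutation events fixed in
    extant clonal strains (and founder lineages) over the stabilised second
    half of each run, by type.
modulated_turbulence
    A single long run founded with 40-60 genes per genome under a
    low/high/low turbulence schedule; reports the mean gene number over the
    tail of each epoch.  Because populations frequently crash at low
    turbulence and right after a low-to-high switch, the protocol attempts
    a fixed number of replicate seeds and reports the first run that
    survives all three epochs.
crash_profile
    Extinction frequency over replicates at constant T, for stable
    (T = 0), low-to-medium (T = 0.02) and high (T = 0.2) turbulence at a
    common horizon.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .engine import SimConfig, run
from .statistics import (
    fixed_mutations_per_lineage,
    fixed_mutations_per_strain,
    grand_mean_genes,
)

__all__ = [
    "derive_seeds",
    "constant_environment_anchor",
    "turbulence_plateau",
    "mutation_spectrum",
    "modulated_turbulence",
    "crash_profile",
]


def derive_seeds(seed: int, label: str, n: int) -> list[int]:
    """Deterministic per-experiment replicate seeds below 2**31."""
    import zlib

    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode()) % (2**31)])
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


def _gmg_or_none(record) -> Optional[float]:
    if record.extinct:
        return None
    return grand_mean_genes(record)


def constant_environment_anchor(
    seed: int, n_reps: int = 4, steps: int = 50_000
) -> dict:
    """Grand mean gene number of replicate runs in a constant environment."""
    cfg = SimConfig(T_schedule=0.0, steps=steps)
    means, crashed = [], 0
    for s in derive_seeds(seed, "anchor-T0", n_reps):
        rec = run(replace(cfg, seed=s), keep_checkpoint=False)
        m = _gmg_or_none(rec)
        if m is None:
            crashed += 1
        else:
            means.append(m)
    return {
        "replicate_means": means,
        "crashed": crashed,
        "grand_mean": float(np.mean(means)) if means else None,
        "n_reps": n_reps,
        "steps": steps,
    }


def turbulence_plateau(
    seed: int,
    reps_at_low: int = 6,
    reps_at_high: int = 3,
    steps: int = 50_000,
) -> dict:
    """Grand mean gene number at T = 0.05 and beyond (0.2, 0.4).

    More replicates are run at T = 0.05 because runs there crash often;
    the means are over surviving replicates."""
    out: dict = {"steps": steps}
    for T, n_reps in ((0.05, reps_at_low), (0.2, reps_at_high), (0.4, reps_at_high)):
        cfg = SimConfig(T_schedule=T, steps=steps)
        means, crashed = [], 0
        for s in derive_seeds(seed, f"plateau-T{T}", n_reps):
            rec = run(replace(cfg, seed=s), keep_checkpoint=False)
            m = _gmg_or_none(rec)
            if m is None:
                crashed += 1
            else:
                means.append(m)
        out[T] = {
            "replicate_means": means,
            "crashed": crashed,
            "mean": float(np.mean(means)) if means else None,
            "sd": float(np.std(means, ddof=1)) if len(means) > 1 else None,
        }
    return out


def mutation_spectrum(
    seed: int, n_reps: int = 8, steps: int = 30_000, T: float = 0.02
) -> dict:
    """Pooled fixed-mutation counts by type at low-to-medium turbulence.

    Counts events born in the second half of each surviving run that are
    fixed by run end, summed over replicates; reported both per clonal
    strain and per founder lineage."""
    cfg = SimConfig(T_schedule=T, steps=steps)
    window = (steps // 2, steps)
    strain_tot = {"duplication": 0.0, "deletion": 0.0, "modification": 0.0}
    lineage_tot = dict(strain_tot)
    survivors = 0
    for s in derive_seeds(seed, "spectrum", n_reps):
        rec = run(replace(cfg, seed=s), keep_checkpoint=False)
        if rec.extinct:
            continue
        survivors += 1
        for k, v in fixed_mutations_per_strain(rec, window).items():
            strain_tot[k] += v
        for k, v in fixed_mutations_per_lineage(rec, window).items():
            lineage_tot[k] += v
    def ratio(d):
        return d["modification"] / d["duplication"] if d["duplication"] else None
    return {
        "survivors": survivors,
        "n_reps": n_reps,
        "steps": steps,
        "per_strain": strain_tot,
        "per_lineage": lineage_tot,
        "mod_dup_ratio_strain": ratio(strain_tot),
        "mod_dup_ratio_lineage": ratio(lineage_tot),
    }


def modulated_turbulence(
    seed: int,
    max_attempts: int = 8,
    epochs: Sequence[tuple[int, float]] = ((120_000, 0.005), (40_000, 0.2), (40_000, 0.005)),
) -> dict:
    """Genome-size response to a low/high/low turbulence schedule.

    Founded with 40-60 genes per genome.  Reports, for the first replicate
    seed whose population survives the whole schedule, the mean gene number
    over the final third of each epoch; failed attempts (extinctions, which
    concentrate at low T and just after the low-to-high switch) are counted.
    """
    bounds = np.cumsum([0] + [length for length, _ in epochs])
    schedule = []
    start = 0
    for length, T in epochs:
        schedule.append((start, T))
        start += length
    total = int(bounds[-1])
    cfg = SimConfig(
        T_schedule=schedule,
        steps=total,
        eta0_range=(40, 60),
        init_resource=7.0,
        R_env=4000.0,
        init_pop_size=100,
    )
    attempts = 0
    for s in derive_seeds(seed, "modulated", max_attempts):
        attempts += 1
        rec = run(replace(cfg, seed=s), keep_checkpoint=False)
        if rec.extinct:
            continue
        ts = rec.timeseries
        tail_means = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            tail = ts[(ts["step"] > lo + (hi - lo) * 2 // 3) & (ts["step"] <= hi)]
            tail_means.append(float(tail["mean_n"].mean()))
        return {
            "completed": True,
            "attempts": attempts,
            "epoch_tail_means": tail_means,
            "epochs": [list(e) for e in epochs],
        }
    return {
        "completed": False,
        "attempts": attempts,
        "epoch_tail_means": None,
        "epochs": [list(e) for e in epochs],
    }


def crash_profile(
    seed: int,
    n_reps: int = 8,
    horizon: int = 30_000,
    T_values: Sequence[float] = (0.0, 0.02, 0.2),
) -> dict:
    """Extinction frequency by turbulence level at a common horizon."""
    out: dict = {"horizon": horizon, "n_reps": n_reps}
    for T in T_values:
        cfg = SimConfig(T_schedule=T, steps=horizon)
        crashed = 0
        for s in derive_seeds(seed, f"crash-T{T}", n_reps):
            rec = run(replace(cfg, seed=s), keep_checkpoint=False)
            crashed += int(rec.extinct)
        out[T] = crashed / n_reps
    return out
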