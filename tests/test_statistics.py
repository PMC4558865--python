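"""Summary statistics: grand mean gene number, fixation per lineage/strain,
strain counts, uptake heatmaps, crash frequency."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from gsevol.engine import SimConfig, Snapshot, run
from gsevol.fixtures import (
    GenealogySpec,
    ScriptedCell,
    ToySpec,
    make_scripted_genealogy,
    make_toy_population,
)
from gsevol.genome import Genome, genotype_uptake
from gsevol.population import MUTATION_TYPES, Population
from gsevol.statistics import (
    LineageForest,
    UndefinedStatisticError,
    crash_frequency,
    fixed_mutations_per_lineage,
    grand_mean_genes,
    mean_uptake_heatmap,
    strain_count,
)


def fake_record(mean_n, census=None):
    steps = np.arange(len(mean_n))
    census = np.full(len(mean_n), 5) if census is None else np.asarray(census)
    ts = pd.DataFrame({"step": steps, "mean_n": mean_n, "census": census})
    return SimpleNamespace(timeseries=ts)


class TestGrandMeanGenes:
    def test_constant_gene_count(self):
        rec = fake_record([3.0] * 10)
        assert grand_mean_genes(rec, (0, 9)) == pytest.approx(3.0)

    def test_two_step_window_average(self):
        rec = fake_record([9.0, 9.0, 2.0, 4.0])
        assert grand_mean_genes(rec, (2, 3)) == pytest.approx(3.0)

    def test_default_window_is_final_half(self):
        rec = fake_record([10.0] * 5 + [2.0] * 6)
        assert grand_mean_genes(rec) == pytest.approx(2.0)

    def test_extinct_window_is_undefined(self):
        rec = fake_record([2.0, 2.0, np.nan], census=[5, 5, 0])
        with pytest.raises(UndefinedStatisticError):
            grand_mean_genes(rec, (0, 2))

    def test_empty_or_overlong_window_rejected(self):
        rec = fake_record([1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            grand_mean_genes(rec, (2, 1))
        with pytest.raises(UndefinedStatisticError):
            grand_mean_genes(rec, (0, 99))

    def test_matches_recomputation_from_snapshots(self):
        cfg = SimConfig(
            R_env=60, init_pop_size=10, eta0_range=(1, 3), steps=100, snapshot_every=10
        )
        rec = run(cfg, seed=3, keep_checkpoint=False)
        for snap in rec.snapshots:
            row = rec.timeseries[rec.timeseries["step"] == snap.step].iloc[0]
            if row["census"]:
                assert snap.cells["n"].mean() == pytest.approx(row["mean_n"])


def brute_force_fixed(forest: LineageForest, window=None):
    """Oracle: explicit trail sets intersected per lineage."""
    lo, hi = window if window else (0, np.iinfo(np.int64).max)
    per_type = np.zeros(len(MUTATION_TYPES))
    lineages = np.unique(forest.lineages)
    for lid in lineages:
        trails = [
            set(forest.trail(int(tip)))
            for tip in forest.tips[forest.lineages == lid]
        ]
        common = set.intersection(*trails) if trails else set()
        for ev in common:
            if lo <= forest.step[ev] <= hi:
                per_type[forest.type_code[ev]] += 1
    return {
        name: per_type[i] / lineages.size for i, name in enumerate(MUTATION_TYPES)
    }


class TestFixedMutations:
    def test_single_extant_cell_fixes_whole_trail(self):
        spec = GenealogySpec(
            cells=(
                ScriptedCell("a", events=((1, "duplication"), (2, "modification"))),
                ScriptedCell("b", parent="a", events=((3, "modification"),)),
            ),
            extant=("b",),
        )
        forest = make_scripted_genealogy(spec)
        fixed = fixed_mutations_per_lineage(forest)
        assert fixed == {"duplication": 1.0, "deletion": 0.0, "modification": 2.0}

    def test_event_missing_from_one_branch_is_not_fixed(self):
        spec = GenealogySpec(
            cells=(
                ScriptedCell("root", events=((1, "duplication"),)),
                ScriptedCell("left", parent="root", events=((2, "modification"),)),
                ScriptedCell("right", parent="root"),
                ScriptedCell("left2", parent="left"),
            ),
            extant=("left", "left2", "right"),
        )
        forest = make_scripted_genealogy(spec)
        fixed = fixed_mutations_per_lineage(forest)
        # duplication is ancestral to everyone; the modification is not
        assert fixed["duplication"] == 1.0
        assert fixed["modification"] == 0.0

    def test_window_filters_by_event_birth_step(self):
        spec = GenealogySpec(
            cells=(
                ScriptedCell(
                    "a", events=((1, "duplication"), (50, "modification"))
                ),
            ),
            extant=("a",),
        )
        forest = make_scripted_genealogy(spec)
        fixed = fixed_mutations_per_lineage(forest, window=(40, 60))
        assert fixed["modification"] == 1.0
        assert fixed["duplication"] == 0.0

    def test_streaming_tracker_matches_brute_force_on_random_forests(self):
        rng = np.random.default_rng(99)
        for trial in range(30):
            n_cells = int(rng.integers(2, 40))
            cells = [ScriptedCell("c0")]
            labels = ["c0"]
            t = 0
            for i in range(1, n_cells):
                parent = labels[int(rng.integers(len(labels)))]
                n_ev = int(rng.integers(0, 4))
                events = []
                for _ in range(n_ev):
                    t += 1
                    events.append(
                        (t, MUTATION_TYPES[int(rng.integers(3))])
                    )
                label = f"c{i}"
                cells.append(ScriptedCell(label, parent=parent, events=tuple(events)))
                labels.append(label)
            n_extant = int(rng.integers(1, len(labels) + 1))
            extant = tuple(
                np.random.default_rng(trial).choice(labels, n_extant, replace=False)
            )
            forest = make_scripted_genealogy(
                GenealogySpec(cells=tuple(cells), extant=extant)
            )
            assert fixed_mutations_per_lineage(forest) == brute_force_fixed(forest)

    def test_no_mutation_run_fixes_nothing(self):
        cfg = SimConfig(R_env=60, init_pop_size=10, eta0_range=(1, 2), steps=120, mu=0.0)
        rec = run(cfg, seed=5, keep_checkpoint=False)
        fixed = fixed_mutations_per_lineage(rec)
        assert all(v == 0.0 for v in fixed.values())

    def test_no_extant_lineages_is_undefined(self):
        forest = make_scripted_genealogy(
            GenealogySpec(cells=(ScriptedCell("a"),), extant=("a",))
        )
        forest.tips = forest.tips[:0]
        forest.lineages = forest.lineages[:0]
        with pytest.raises(UndefinedStatisticError):
            fixed_mutations_per_lineage(forest)


class TestStrainCount:
    def _pop(self, genomes):
        return Population(
            genomes, np.ones(len(genomes)), R_env=100.0, alpha=0.2
        )

    def test_identical_cells_form_one_strain(self):
        g = Genome([0.0], [0.5], alpha=0.2, origin=[1])
        assert strain_count(self._pop([g, g, g.copy()])) == 1

    def test_mutant_forms_second_strain(self):
        g = Genome([0.0], [0.5], alpha=0.2, origin=[1])
        m = Genome([0.0], [0.5], alpha=0.2, origin=[2])  # modified variant
        assert strain_count(self._pop([g, g, m])) == 2

    def test_duplicate_copy_number_distinguishes_strains(self):
        g = Genome([0.0], [0.5], alpha=0.2, origin=[1])
        gg = Genome([0.0, 0.0], [0.5, 0.5], alpha=0.2, origin=[1, 1])
        assert strain_count(self._pop([g, gg])) == 2

    def test_matches_pairwise_oracle_on_random_snapshots(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            keys = [
                tuple(sorted(rng.integers(0, 5, size=rng.integers(0, 4)).tolist()))
                for _ in range(15)
            ]
            genomes = [
                Genome(
                    np.zeros(len(k)), np.full(len(k), 0.5), 0.2, np.asarray(k)
                )
                if k
                else Genome.empty(0.2)
                for k in keys
            ]
            pop = self._pop(genomes)
            # O(N^2) oracle
            distinct = 0
            seen = []
            for k in keys:
                if not any(k == s for s in seen):
                    distinct += 1
                    seen.append(k)
            assert strain_count(pop) == distinct

    def test_snapshot_and_population_agree(self):
        g = Genome([0.0], [0.5], alpha=0.2, origin=[1])
        m = Genome([0.1], [0.4], alpha=0.2, origin=[2])
        pop = self._pop([g, g, m])
        snap = Snapshot.from_population(pop, 0)
        assert strain_count(snap) == strain_count(pop) == 2

    def test_empty_population_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            strain_count(self._pop([]))


class TestHeatmap:
    def _record_from_pops(self, pops, alpha=0.2):
        snaps = [Snapshot.from_population(p, i * 10) for i, p in enumerate(pops)]
        return SimpleNamespace(snapshots=snaps, config=SimpleNamespace(alpha=alpha))

    def test_single_cell_single_gene_row_is_its_gaussian(self):
        g = Genome([0.3], [0.8], alpha=0.2, origin=[0])
        pop = Population([g], [1.0], R_env=10.0, alpha=0.2)
        rec = self._record_from_pops([pop])
        grid = np.linspace(-1, 1, 101)
        hm = mean_uptake_heatmap(rec, grid)
        np.testing.assert_allclose(hm.iloc[0].to_numpy(), genotype_uptake(g, grid))

    def test_values_bounded_in_unit_interval(self):
        cfg = SimConfig(
            R_env=60, init_pop_size=10, eta0_range=(1, 4), steps=100, snapshot_every=20
        )
        rec = run(cfg, seed=8, keep_checkpoint=False)
        hm = mean_uptake_heatmap(rec)
        assert (hm.to_numpy() >= 0).all() and (hm.to_numpy() <= 1).all()

    def test_two_cell_average(self):
        a = Genome([0.0], [0.8], alpha=0.2, origin=[0])
        b = Genome([0.5], [0.4], alpha=0.2, origin=[1])
        pop = Population([a, b], [1.0, 1.0], R_env=10.0, alpha=0.2)
        rec = self._record_from_pops([pop])
        grid = np.linspace(-1, 1, 51)
        hm = mean_uptake_heatmap(rec, grid)
        expected = 0.5 * (genotype_uptake(a, grid) + genotype_uptake(b, grid))
        np.testing.assert_allclose(hm.iloc[0].to_numpy(), expected)

    def test_stride_subsamples_rows_consistently(self):
        g = Genome([0.0], [0.8], alpha=0.2, origin=[0])
        pops = [Population([g], [1.0], R_env=10.0, alpha=0.2) for _ in range(4)]
        rec = self._record_from_pops(pops)
        full = mean_uptake_heatmap(rec)
        strided = mean_uptake_heatmap(rec, t_stride=2)
        np.testing.assert_allclose(
            strided.to_numpy(), full.iloc[::2].to_numpy()
        )

    def test_empty_genome_cells_drag_mean_down(self):
        a = Genome([0.0], [0.8], alpha=0.2, origin=[0])
        pop = Population(
            [a, Genome.empty(0.2)], [1.0, 1.0], R_env=10.0, alpha=0.2
        )
        rec = self._record_from_pops([pop])
        grid = np.asarray([0.0])
        hm = mean_uptake_heatmap(rec, grid)
        assert hm.iloc[0, 0] == pytest.approx(0.4)


class TestCrashFrequency:
    def test_fractions(self):
        recs = [SimpleNamespace(extinct=False)] * 7 + [SimpleNamespace(extinct=True)] * 3
        assert crash_frequency(recs) == pytest.approx(0.3)
        assert crash_frequency([SimpleNamespace(extinct=False)]) == 0.0

    def test_certain_death_crashes(self):
        cfg = SimConfig(R_env=60, init_pop_size=10, eta0_range=(1, 2), steps=20, delta=1.0)
        recs = [run(cfg, seed=s, keep_checkpoint=False) for s in (1, 2)]
        assert crash_frequency(recs) == 1.0

    def test_requires_records(self):
        with pytest.raises(UndefinedStatisticError):
            crash_frequency([])
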