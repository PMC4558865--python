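# gsevol — genome-size evolution in stable and fluctuating environments

`gsevol` is an individual-based simulator for studying how environmental
variability shapes prokaryotic genome size. It models a resource-limited,
well-mixed population of haploid clonal cells adapting to a single abiotic
condition *x* ∈ [−1, 1] (think temperature, pH or irradiance) that performs
a bounded random walk,

    x(t+1) = x(t) + RND[−T, T],    |x(t+1)| ≤ 1,

where the *turbulence* T ∈ [0, 0.5] sets how unpredictable the environment
is. Each metabolic gene is represented purely by its phenotype: a Gaussian
resource-uptake kernel

    u(x) = A · exp(−(x − c)² / 2σ²),

whose area is pinned to a constant α (so σ = α / (A√2π)): a gene is either
a narrow specialist (high A) or a broad generalist (low A), never both. A
genome is a multiset of such genes; its uptake U(x) is the pointwise
maximum over its genes, and carrying n genes costs

    K(n) = γ(n + n²) + κ

per time step — the linear term for the metabolic genes, the quadratic term
for the regulatory apparatus (regulatory gene numbers scale roughly with
the square of genome size), κ a flat cost of living. Cells feed from a
finite, strictly conserved resource pool, die of starvation or by chance
(probability δ per step), and divide once their reserve exceeds a
threshold; at division each daughter independently undergoes gene deletion,
duplication and modification, each with probability µ. Genome size is thus
a freely evolving trait, shaped by the tension between covering the
environmental axis and paying the regulatory bill.

The simulator reproduces the signature phenomena of this model class:
genome streamlining down to ~2 genes in constant environments, a rise to a
plateau of ~12–16 genes once T ≳ 0.05, genome-size re-optimisation when the
turbulence level switches, a fixed-mutation spectrum dominated by gene
modifications, and an extinction-risk peak at *low-to-medium* turbulence —
populations that evolved in nearly stable environments are the most fragile
under change.

## Worked example

```python
import gsevol as g

# replicate runs at moderate turbulence on the calibrated baseline
cfg = g.SimConfig(T_schedule=0.05, steps=50_000)
records = g.run_replicates(cfg, seeds=range(6))

for rec in records:
    if rec.extinct:
        print(f"seed {rec.seed}: population crashed at step {rec.extinct_step}")
    else:
        print(f"seed {rec.seed}: grand mean genes = {g.grand_mean_genes(rec):.2f}")
```

Output:

```
seed 0: population crashed at step 21086
seed 1: population crashed at step 8280
seed 2: population crashed at step 13479
seed 3: population crashed at step 12928
seed 4: grand mean genes = 11.22
seed 5: population crashed at step 27547
```

Two things are visible at once: surviving populations at T = 0.05 carry an
order of magnitude more genes than the ~2 genes/genome that evolve at
T = 0 (run the same with `T_schedule=0.0`), and a large fraction of
replicates at low-to-medium turbulence go extinct — both are headline
behaviours of the model, not artefacts. Statistics beyond the grand mean:

```python
g.fixed_mutations_per_lineage(rec)       # fixed events per founder lineage, by type
g.strain_count(rec.snapshots[-1])        # number of distinct extant genotypes
g.mean_uptake_heatmap(rec)               # population-mean U(x) over time
```

The same workflows are available from a shell:

```
gsevol simulate --config cfg.yaml --seed 42 --out run/
gsevol sweep --param T_schedule --values 0,0.05,0.2 --reps 10 --out sweep/
gsevol stats --run run/
```

Runs are written as plain TSV/JSON (time series, genotype snapshots,
mutation-event log, metadata) and are bit-reproducible given a seed.

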