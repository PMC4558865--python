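# Model and methods

## The model

`gsevol` simulates a closed, well-mixed system: a fixed total resource
`R_env` is split at every instant between the internal reserves of living
cells and a free pool, and every operation of the life cycle moves resource
between the two without creating or destroying any. This conservation law
is the model's master invariant and is asserted continuously in the test
suite (relative tolerance 1e-6).

**Environment.** One abiotic condition x ∈ [−1, 1] follows a bounded random
walk with uniform increments on [−T, T]; the turbulence T ∈ [0, 0.5] is the
only knob of environmental unpredictability, and may follow a
piecewise-constant schedule within a run. The boundary constraint can be
enforced three ways; the default, *rejection resampling* of the increment,
keeps the walk a proper bounded walk without placing probability atoms at
±1 (clipping would). `clip` and `reflect` are available as config options
and recorded in run metadata.

**Genes and genomes.** A gene is a Gaussian uptake kernel u(x) =
A·exp(−(x−c)²/2σ²) with peak position c ∈ [−1, 1] and peak efficiency
A ∈ (0, 1]. The area under every kernel equals a global constant α, which
forces σ = α/(A√2π): peak efficiency trades off against niche width
(specialist vs generalist). A genome is an ordered multiset of genes; its
uptake is the envelope U(x) = max_i u_i(x), so an exact duplicate adds cost
but no uptake. The per-step cost of n genes is K(n) = γ(n+n²) + κ — the
quadratic term models the regulatory burden, whose size scales roughly
quadratically with the number of regulated genes, and κ is a flat cost of
living. Empty genomes are representable: deletion of the last gene leaves a
cell with U ≡ 0 that still pays κ and is removed by selection, not by fiat.

**Life cycle.** One time step applies, in order: (1) *pay or die* — each
cell dies with probability δ (its whole reserve returns to the pool) or
pays min(K, r) into the pool; (2) *starvation cull* — cells with r
strictly below r_min die and return their reserve; (3) *feeding* — cells
are queued in uniformly random order and each receives min(U_i(x),
remaining pool) until the pool is dry, the cell at the front receiving the
remainder and everyone behind going unfed; (4) a second *starvation cull*;
(5) *reproduction* — every cell with r strictly above r_rep is replaced by
two daughters with r/2 each; each daughter independently suffers each of
{duplication, deletion, modification} with probability µ, applied in that
canonical order when several fire. The substep order is a design choice
(the narrative description of the life cycle does not pin one down): paying
costs before feeding matches the idea that cells return resources ahead of
uptake, and the double cull prevents dead cells from feeding and keeps
balances non-negative. The order is configurable (`substep_order`) and
recorded in run metadata.

**Mutations.** The modification kernel perturbs c by a uniform draw on
[−m_c, m_c] and A on [−m_A, m_A], clamps c to [−1, 1] and A to [1e−6, 1]
(the floor keeps σ finite), and recomputes σ from the area constraint —
the smallest-assumption local "change of shape" consistent with the
constraint. Targets of all three mutation types are chosen uniformly over
genes, duplicates counted separately. Every mutation event carries a
globally unique id; a gene carries the id of the event that created its
variant, and exact duplicates share their template's id until modified.
This id scheme makes genotype identity (strain membership) an exact integer
comparison rather than a floating-point one.

**Determinism.** The master seed is split into four independent
`numpy` Generator streams — initialisation, environment, life cycle
(death and feeding order), mutation — so a run is bit-reproducible and
parameter changes perturb only the draws they logically own. Records carry
an in-memory checkpoint (population, RNG states, event log), and
`resume()` provably continues a run identically to an uninterrupted one
(asserted in the suite).

## Fixation statistics

A *clonal lineage* is all extant descendants of one founder cell; a
*clonal strain* is a set of extant cells with identical genotypes. Each
cell's mutation trail is a path in the event forest (append-only down a
lineage), so "fixed in a group" — present in the trail of every member —
reduces to the ancestors of the lowest common ancestor of the group's
trail tips. `fixed_mutations_per_lineage` groups by founder,
`fixed_mutations_per_strain` by genotype; both count events born inside a
step window, averaged over groups. Lineage-level counts isolate deeply
sorted (swept) events and are dominated by adaptive modifications;
strain-level counts also include recent, not-yet-sorted events, so their
type composition sits closer to the 1:1:1 mutational supply. The
fixed-mutation spectrum experiments report both.

The *grand mean gene number* is the per-step mean gene count per cell
averaged over a post-stabilisation window, by default the final half of the
run (mirroring measuring over the last half of a run after the system has
stabilised). An optional plateau check on the window is available but not
applied by default.

## The calibrated baseline

The quantitative behaviour of the model depends on a parameter set that is
not derivable from the model structure; the package ships one calibrated
baseline (the `SimConfig` defaults) chosen so that the canonical anchors
hold at the reduced scale the package targets:

| parameter | value | meaning |
|---|---|---|
| R_env | 2000 | total resource; sets census ≈ 300–450 cells |
| α | 0.04 | kernel area; sets how many genes full-axis coverage takes |
| γ | 1.1e−4 | gene/regulatory cost scale |
| κ | 0.002 | cost of living (famine drain floor) |
| δ | 0.01 | random death probability per step |
| µ | 0.015 | per-type, per-daughter mutation probability |
| r_min, r_rep | 0.5, 8.0 | starvation and division thresholds |
| m_c, m_A | 0.15, 0.1 | modification step half-widths |
| η₀ | U{1..10} | founder genes per genome |
| init r | (r_min+r_rep)/2 | founder reserve |
| steps | 50 000 | default horizon |

The calibration logic: α sets the number of narrow kernels needed to tile
the axis (full coverage at evolved heights takes ~12–16 genes); γ against
the per-capita resource throughput sets the strength of streamlining
selection, and µ against that selection sets the mutation–selection balance
that keeps constant-environment genomes near two genes; κ, δ and r_rep
control how long a cell survives an unfed famine (~300 steps at small
genome sizes), which decides whether populations ride out environmental
excursions into uncovered territory. These couplings are antagonistic —
raising µ speeds adaptation but inflates streamlined genomes; raising costs
sharpens streamlining but shortens famine survival — and the shipped values
are the compromise that reproduces all anchors at this scale.

At this baseline, on runs of 5×10⁴ steps: T = 0 replicates settle at a
grand mean of ~2.5–3 genes; surviving runs at T = 0.05 reach ~11–13 genes
with little further change at T = 0.2–0.4 (the plateau); extinction
frequency peaks sharply at T ≈ 0.005–0.05 and is near zero at T = 0 and
T ≥ 0.2.

## Study designs and scales

The experiments in `gsevol.experiments` (used by the acceptance tests and
`scripts/acceptance.py`) run at a deliberately reduced scale so that the
full battery completes in minutes on one CPU: populations of a few hundred
cells (R_env = 2000, census ≈ 300–450) instead of the much larger
populations such models are usually run with, and horizons of 3–20 × 10⁴
steps. Replicate counts: 4 at T = 0; 6/3/3 at T = 0.05/0.2/0.4; 8 at
T = 0.02 for the spectrum (means over surviving replicates); 8 per
turbulence level for the crash profile at a 3×10⁴-step horizon. The
modulated-turbulence design founds 100 cells with η₀ ∈ [40, 60] genes on
R_env = 4000 and runs epochs of 120/40/40 × 10³ steps at T =
0.005/0.2/0.005; because extinctions concentrate at low T and immediately
after the low→high switch, the protocol attempts up to eight replicate
seeds and reports the first that survives the whole schedule (attempt
counts are reported alongside; with a per-seed completion probability of
roughly one in eight at this scale, the protocol yields a measurable run in
about two of three invocations).

## What the synthetic conditions do and do not show

All data is generated by the model itself; there is no external input. The
environment is a single scalar condition with uniform, memoryless
increments — no seasonality, autocorrelation, or multivariate structure.
Genes have no sequence, no linkage, no expression regulation; horizontal
gene transfer, genomic islands and noncoding DNA are deliberately outside
the model. Passing tests therefore show that the implemented dynamics
produce the claimed evolutionary phenomena under these idealisations; they
say nothing about any particular organism.

## Numerical choices and edge cases

- Resource conservation is maintained to ≤1e−6 relative error; the final
  feeding allocation is truncated to the remaining pool, and the pool is
  floored at exactly 0 after feeding.
- Strict inequalities: starvation at r < r_min, division at r > r_rep
  (boundary cells survive / do not divide).
- Cost payment is min(K, r): a cell that cannot cover its cost pays what
  it has and faces the starvation cull; reserves never go negative.
- A is clamped to ≥1e−6 under modification so σ stays finite; c is clamped
  to the axis.
- Empty populations are legal terminal states; statistics on them raise
  `UndefinedStatisticError` rather than returning NaNs.
- The event log stores trail-parent pointers and depths; LCA computation is
  iterative pointer-walking (event chains are short relative to run
  lengths).

## Known limitations

- Crash frequencies at low-to-medium turbulence are high at this reduced
  scale (small populations buffer famines poorly), so surviving-replicate
  statistics there carry survivorship conditioning — reported explicitly
  wherever used.
- The plateau level is still drifting upward slowly at the 5×10⁴-step
  horizon; longer runs give slightly larger plateau means.
- The modulated-turbulence ordering (streamline → expand → streamline)
  needs the first epoch long enough to approach the low-T optimum from a
  40–60-gene start; at this scale that takes most of the run and the
  completion probability per seed is well below one.
- Feeding is sequential-random with full-demand allocation; no partial
  fair-share scheme is implemented (the depletion rule terminates the
  queue).
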