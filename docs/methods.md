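# Methods

## The model

An individual is a linear hierarchy of `f = P_e / C` *functional systems*,
each a block of `C` binary phenotypic elements. Development assembles the
systems strictly in order and stops at the first system with a missing
element; only the resulting unbroken prefix of complete systems counts, so
fitness is

```
n_FS(i) = length of the maximal prefix of systems whose elements are all present.
```

Elements become present in two ways:

* **Inheritance.** A genotype of `L` loci with `A` alleles per locus maps
  onto elements through a fixed genotype-phenotype map: each of the
  `L x A` (locus, allele) pairs is assigned one target element uniformly at
  random, once per run. Expression is a logical OR over loci — an element
  is inherited-present iff at least one locus carries an allele targeting
  it — so several genetic variants can encode the same element
  (redundancy requires `L*A >= P_e`; all presets use `L*A > P_e`).
* **Plasticity.** Each lifetime, an individual gets `t` all-or-nothing
  trials on its *terminal* system — the first system incomplete under the
  union of inherited and already-acquired elements. A trial facing `m`
  missing elements succeeds with probability `p_e^m` (every missing
  element must fill independently); on success all `m` elements are
  acquired at once and development resumes, passing for free through any
  subsequent systems that happen to be fully inherited; on failure
  nothing is kept, so partial fills never persist and the per-trial law
  is exactly `p_e^m`. Acquired elements are phenotypic only: they are
  never written back to the genome (no Lamarckian inheritance).

Reproduction is asexual with non-overlapping generations. Each of the `N`
offspring copies the genome of a parent drawn by fitness-proportional
rejection sampling (draw a uniform candidate, accept with probability
`fitness/max_fitness`; the marginal law is `fitness/sum(fitness)`), then
every locus mutates independently with probability `mu` to a uniform draw
from the other `A - 1` alleles. Fitness includes plasticity-completed
systems, which is what lets plastic adaptation confer a selective
advantage and drive genetic assimilation of the underlying elements.

For a randomly initialized genome the probability that a given element is
inherited-present is

```
p_rnd = 1 - (1 - 1/P_e)^L            (~0.865 for L = 4000, P_e = 2000)
```

and an incomplete system misses `m = C (1 - p_rnd)` elements in
expectation; `p_rnd` is a marginal over random maps and genomes — a fixed
map has element-specific deviations, which is why the Monte-Carlo checks
redraw the map per sample.

## Parameters

| name | meaning | default | note |
|------|---------|---------|------|
| `N`   | population size | 500 | constant, non-overlapping generations |
| `n_g` | generations | 25 000 | trajectories have `n_g + 1` points |
| `L`   | loci | 4000 | `L/P_e = 2` fixes `p_rnd ~ 0.865` |
| `A`   | alleles per locus | 5 | |
| `P_e` | phenotypic elements | 2000 | must be a multiple of `C` |
| `C`   | elements per system | 10 / 20 / 40 | the complexity knob |
| `mu`  | per-locus mutation prob. | 1e-6 – 1e-3 | per reproduction |
| `p_e` | per-element fill prob. | 0.5 | during one plasticity trial |
| `t`   | plasticity trials | 0 / 1 / 5 / 10 | 0 disables plasticity |

## Numerical and design choices

* **Trial draw.** A trial is decided by a single uniform variate compared
  against `p_e^m` rather than `m` separate Bernoulli draws — the same
  distribution, one draw per trial, which keeps the RNG stream layout
  independent of the phenotype and lets a loop-based oracle reproduce a
  vectorized run bit for bit.
* **All-zero fitness.** The division-by-max selection rule is undefined
  when every fitness is 0 (common early at high `C`); parents are then
  drawn uniformly. Any fitness-blind rule is equivalent.
* **Mutation target.** Mutation excludes the current allele (uniform over
  the `A - 1` alternatives), so `mu` is exactly the per-locus change
  probability; with `A = 1` mutation is a no-op.
* **RNG protocol.** One master seed spawns named `SeedSequence`
  substreams (map, initialization, one per generation); within a
  generation the draw order is fixed: N scalar selection draws, one
  mutation mask plus row-major shift vector, one uniform vector per
  plasticity trial. Identical `(params, seed)` give bit-identical output;
  replicate seeds are derived from a hash of `(condition, replicate)` so
  they do not depend on grid ordering.
* **Waiting-time grid.** `acceleration_ratio` averages, over every
  integer threshold `k` reached by both conditions strictly after
  generation 0, the ratio of first crossing times of the ensemble-mean
  population-max inherited-system trajectories. Thresholds already
  reached at initialization measure no evolution and would contribute
  0/0, so they are excluded.
* **Confidence limits.** 95% limits are the normal approximation
  `mean ± 1.96 SE` over replicates.
* **Headline counts.** Both the inherited-only (`max_inherited`) and the
  plasticity-inclusive (`max_total`) complete-system counts of the best
  individual are recorded every generation. `max_total` is the quantity
  fitness and selection act on; `max_inherited` isolates genetic
  assimilation and is the input to the waiting-time statistics.

## Desk-scale presets and what they show

The full presets (`fig2`, `fig3a`, `fig3b`, `fig4`) use the table above
and take tens of minutes per run on one core. The desk-scale presets
(`fig2-mini`: N=100, n_g=2000, L=400, P_e=200, C=10, 3 replicates;
`fig3a-mini`: the same base with C in {5, 10, 20}) preserve the
locus-to-element ratio `L/P_e = 2` — hence `p_rnd` and the expected
per-system deficit `m = C(1-p_rnd)` at a given `C` — and run in about
half a minute per condition. The test suite and the acceptance script
use these presets.

Shrinking `P_e` at fixed `t` changes one thing qualitatively: the system
cap `f = P_e/C` drops (20 at C=10 instead of 100 at full scale), and the
per-system deficit at C=10 (`m ~ 1.35`, per-trial success ~0.4) makes
plastic repair of mutational damage cheap. Two consequences, both
visible in the shipped ensembles:

* The plastic population's *total* count climbs rapidly and saturates
  the cap, while its *inherited* count stays near mutation-drift balance
  — the shadowing effect: cheap plasticity buffers the fitness cost of
  losing inherited elements, so selection for assimilation nearly
  vanishes. At this scale the inherited-count comparison between plastic
  and non-plastic conditions therefore measures shadowing, not
  acceleration.
* At C=20 of the desk-scale grid (`m ~ 2.7`, per-trial success ~0.15)
  repair is expensive, assimilation pressure survives, and the plastic
  condition accelerates the inherited count several-fold — the same
  regime as the full-scale parameterization, where the deficit per
  system is 2.7–5.4 elements.

Passing desk-scale tests therefore demonstrate the mechanism (selection
law, trial law, assimilation at sufficient complexity, shadowing at low
complexity) rather than the full-scale magnitudes; the full presets are
provided for reproducing those magnitudes offline.

What the generator does not emulate: real genetic architecture
(recombination, diploidy, pleiotropy beyond the many-to-one map),
environmental change, costs of plasticity, or any tree-structured system
hierarchy — systems grow along a single line of descent.

## Known limitations

* Selection is fitness-proportional only through the rejection scheme's
  marginal law; with all fitnesses equal it degenerates to drift, so
  saturated populations (everyone at the cap `f`) evolve neutrally.
* `max_inherited` is a prefix statistic: losing a single element of an
  early system collapses it even when all downstream systems remain
  fully assimilated genetically. In plastic populations — where such a
  gap is cheap to bridge phenotypically and hence weakly selected
  against — the inherited prefix systematically understates the amount
  of assimilated genetic material; `max_total` and the element-level
  `inherited_proportion_profile` are the complementary views.
* `generations_to_k` reports the first crossing of an ensemble-mean
  trajectory; for non-monotone (drifting) trajectories the crossing time
  is an optimistic lower bound of a stable attainment time.
* Ensembles of 3 replicates (desk scale) give acceleration-ratio
  estimates with large variance when the true ratio is near 1.
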