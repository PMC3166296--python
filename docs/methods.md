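# Methods

## Model and procedure

The pipeline treats a multi-tissue aging study as a grid of *conditions*
(tissue, age), with ages on an ordered ladder and one or more replicate
measurements per condition.  Analysis proceeds in four stages.

**Pre-filtering.**  Probes missing in strictly more than a configurable
fraction of samples (default 0.80) are removed; a probe missing in exactly
80% of samples survives the default cut.  When several probes map to one
gene, the probe with the most samples showing presented expression is kept —
Present detection calls when a detection table is attached, non-missing
values otherwise — with ties broken to the lowest input row, so the result
is deterministic and order-stable.  The loader never transforms values: a
`scale` flag (`log2`, `linear`, `zscore`) travels with the dataset and the
fold-change logic interprets it.  Missing values are an explicit mask
(`NaN` internally, `NA` in files), never a magic number.

**Directional change calling.**  For each tissue and each consecutive age
phase, genes are assigned to an up set, a down set, or neither.  Replicates
are aggregated by arithmetic mean on the stored scale before fold-changes
are computed.  The criteria:

- *Fold-change*: |fold-change| >= `fc_threshold` (default 2), inclusive —
  on log2 data this is |Δlog2| >= 1.  Non-positive linear signals and genes
  missing at either age are unusable and called in neither direction.
  Fold-changes are refused on z-scored (scale-free) data.
- *Z test*: z = (mean_to − mean_from)/sqrt(s²_to/n_to + s²_from/n_from)
  with per-gene, per-group sample variances (n−1 denominators, unpooled —
  the conservative reading for replicate-to-replicate variation) against
  standard-normal tails; one-sided calls at `z_alpha` per tail (default
  0.01; 0.001 is the convention for intervention-style designs).  Genes with
  fewer than two usable replicates in a group are skipped and counted, as is
  the degenerate zero-spread/equal-means case; zero spread with unequal
  means is an infinitely confident call.  Note the finite-replicate level:
  with n replicates per group the statistic's true null is approximately
  t with 2n−2 df, so at n = 5 the realised per-tail rate at nominal 0.01 is
  ≈ P(t₈ > z₀.₀₁) ≈ 0.024, converging to the nominal level as n grows.
  The test suite asserts this realised behaviour.
- *Composite MAS5-style rule*: externally supplied change p-values
  (< 0.0025 for increase, 1 − p < 0.0025 for decrease) AND fold-change >= 2
  AND every compared sample detected Present.  The probe-level change
  algorithm is proprietary and is consumed, never computed; without a
  detection table the presence filter is skipped with a logged warning.
- *Consensus*: fold-change calls intersected across two datasets measuring
  the same process, same direction required in both; mismatched gene
  universes are restricted to the intersection with a logged loss.

Phase labels follow `<to><unit>v<from><unit>` (later age first), and node
names `<tissue-code>_<label>_<direction>`, e.g. `A_10Mv4M_up`.  Endpoint
(first-to-last) contrasts are available behind an explicit flag, default
off: the networks use consecutive phases, while the endpoint contrast
exists to demonstrate what two-point designs conceal.

**Overlap significance.**  Two directional sets of sizes M and K from a
universe of N genes overlapping in x genes are scored with the
hypergeometric upper tail P(X >= x), computed via `scipy`'s survival
function; the test-suite oracle re-derives it by exact integer-arithmetic
summation (all N <= 25) and by exhaustive enumeration of draws.  P(X >= 0)
is exactly 1; extreme tails are floored at the smallest positive double
rather than underflowing to 0.  The universe N defaults to the genes that
survive filtering in the dataset under analysis — only those genes can
appear in any set — with the pre-filter count available by configuration
for sensitivity checks.  Thresholds are strict (<) and deliberately raw:
no multiple-testing correction is applied across pairs, matching the
method's use of per-figure fixed thresholds (0.005/0.001 per-phase,
0.0001/0.0005 for 4D); the threshold is always an explicit, recorded knob.

**Networks.**  Per phase, all four directional combinations of every
cross-tissue node pair are tested; the up and down sets of one tissue-phase
are disjoint by construction and never tested against each other (a forced
p = 1 edge would be noise).  Empty sets are carried but untested, so they
surface as isolated — *stochastic* — nodes.  The 4D network applies the
same rule to all unordered node pairs across tissues and phases and labels
each edge same-tissue cross-phase, cross-tissue same-phase, or cross-tissue
cross-phase; restricting the 4D edge set to same-phase pairs reproduces the
per-phase networks exactly, which the suite asserts edge-for-edge and
p-for-p.  Node categories are derived from incident edge classes with this
precedence: no edges → `specific`; any cross-tissue cross-phase edge, or
same-tissue plus cross-tissue edges together → `spatio-temporal-associated`;
only same-tissue edges → `tissue-specific-temporal`; remaining connected
nodes (cross-tissue within a single phase only) → `temporal-associated`.
The four published categories do not fully pin down a partition of all edge
combinations, so the precedence above is this package's explicit choice.

## Synthetic data

The generator draws baseline log2 gene means from Normal(8, 1) — the
magnitude range of MAS5-style signals, though any location/scale would do
since overlap statistics are scale-free after calling — adds per-replicate
Normal(0, `noise_sd`) noise, and applies uniform MCAR missingness.  Planted
*blocks* shift disjoint gene modules by ±`effect_size` (default 1.5, a
robustly detectable change at the default `noise_sd` 0.2) in chosen tissues
from the end age of one phase onward; the step persists, so a module
planted in phase k is not re-called later.  A block's `overlap` fraction
controls how many module genes the tissues share: shared same-direction
shifts plant a true synchronous pair, opposite shifts a true asynchronous
pair.  All randomness derives from the single config seed; identical seeds
give bit-identical datasets.

What the generator does *not* emulate: probe-level array structure, batch
effects, correlated (non-MCAR) missingness, heavy-tailed or
intensity-dependent noise, and gene-gene correlation outside planted
modules.  Passing recovery tests therefore show that the pipeline detects
the designed kind of shared directional structure at realistic
signal-to-noise, not that real microarray noise is fully modelled.

## Study conditions used in the statistical checks

Problem sizes were chosen to give tight binomial error bars while keeping
the default suite fast: 10^4 genes, five tissues, a four-age ladder (three
consecutive phases).

- *Null calibration*: 200 no-structure simulations at `noise_sd` 0.5.  The
  elevated noise is what makes the check informative: a 2-fold call is a
  5-sigma event at noise 0.2, so essentially no genes are called and no
  pairs tested, whereas noise 0.5 yields a realistic few-percent call rate
  (set sizes ~800) under which the discrete tail p is nearly continuous and
  the edge rate at threshold 0.005 can be compared to its nominal level.
- *Planted recovery*: 100 simulations, 200-gene modules, overlap 0.5,
  effect 1.5, noise 0.2, threshold 0.005; synchronous and asynchronous
  recall are scored separately.
- *Trajectory*: 100 seeded runs of a three-phase plan (two synchronous
  blocks, then two asynchronous blocks, then nothing), scored for the
  sync > async, async > sync, edgeless signature.  The quiet phase can
  occasionally acquire a chance edge between tiny background sets (two
  ~4-gene sets overlapping in one gene give p ≈ MK/N ≈ 0.0016 < 0.005),
  which bounds the attainable success rate slightly below 1.

## Numerical and degenerate-input choices

- Tail p floored at the smallest positive double; survival-function
  evaluation throughout the pipeline, exact summation only in oracles.
- Fold-change thresholds are inclusive; network thresholds strict.
- Duplicate-probe ties break to the lowest input row; sample order follows
  the matrix header.
- Reversed phase endpoints are representable so the antisymmetry property
  (swapping endpoints swaps up and down) is directly testable.
- Empty gene sets, empty datasets and edgeless networks are all legal and
  produce empty-but-well-formed outputs.

## Known limitations

- The Z test's finite-replicate anticonservatism (above) is inherent to the
  plug-in variance statistic; with ≥ 10 replicates the realised level is
  within ~30% of nominal, at 3–5 replicates it is 2–4x nominal.
- Raw (uncorrected) pair thresholds mean the number of edges grows with the
  number of tested pairs under the null; cross-study comparisons should fix
  both the threshold and the design.
- The MAS5 composite path depends entirely on externally supplied change
  p-values and detection calls; no attempt is made to validate their
  provenance.
- GraphML export carries attributes only; layout and rendering are left to
  external viewers.
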