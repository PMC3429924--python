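# Methods

## The assay and its accounting

A wing-disc cell that loses the rescuing *mwh⁺Y* chromosome during mitosis
produces one labeled (*mwh* homozygous) daughter; that daughter's
descendants stay together and appear on the adult wing as a mosaic spot of
multiple-trichome cells. The package's statistics rest on three standard
assumptions:

1. **One labeled daughter per event.** The loss affects exactly one of the
   two daughters, so a clone of average size *m* represents a mother-cell
   lineage of 2*m* final cells. The screened area of *C* cells per wing
   therefore corresponds to *C*/(2*m*) exposed target cells, and *N* wings
   to *N C*/(2*m*) targets.
2. **Constant per-division loss rate.** If the loss probability is the
   same in every round, earlier-founded (larger) clones are rarer in
   proportion to the number of unlabeled divisions available in their
   founding round. Since division counts double each round, class counts
   should halve from each size class to the next ("halve-by-half"), and
   clone counts per wing should be Poisson.
3. **Equal contribution.** All disc lineages contribute equally to the
   blade, so clone size maps deterministically onto founding round.

Size class *k* covers clones of 2^(k−2)+1 … 2^(k−1) cells (1, 2, 3–4,
5–8, …): the minimum number of divisions between the loss event and the
end of proliferation. The scalar rule is `class(s) = 1` for `s = 1`, else
`ceil(log2 s) + 1`, implemented with integer bit-length so powers of two
are exact; clones above 128 cells continue the same rule (class 9, 10, …).

The induction frequency per cell division is the published estimator

    f = 2 n m / (N C),

reported on the 1e-4 scale rounded to one decimal (round half away from
zero), the convention of the published summary tables. All internal
computation is unrounded; rounding happens only at the reporting boundary.

### The average clone size m

The source tables derive *m* from a log-linear interpolation whose inputs
(within-class average sizes) are not printed, so it cannot be recomputed
from class counts alone. The package uses the mean size-class index
rounded to one decimal — classes I and II contain exactly 1 and 2 cells,
so the index tracks the cell count closely for the small clones that
dominate — and accepts a published *m* as an explicit override
(`m_override`) when exact table reproduction is wanted. On the eleven
published rows the rule lands within ±0.1 of the printed value for all
but one treatment (colchicine, where oversized regeneration clones stretch
the class–size relation; the printed 2.8 is then supplied as an override).

## Goodness-of-fit machinery

* **Halve-by-half expectation**: expected counts
  `n · 2^(1−i) / Σ_j 2^(1−j)` over classes i = 1..K; sums to n exactly.
* **Poisson wing counts**: ν = n/N unrounded, expected wings
  `N · ν^i e^(−ν)/i!` for i = 0..i_max; the truncated tail mass
  `N·(1 − CDF(i_max))` is reported, not silently dropped.
* **Chi-square**: Pearson statistic with tail pooling — trailing bins with
  expected count below `pool_below` (default 1.0) are merged into their
  lower neighbour *for the test statistic only*; reported expectation
  tables stay unpooled. df = bins − 1, with an optional extra −1 when the
  Poisson rate was estimated from the same data (off by default; the
  published non-significance conclusions hold either way).
* **Homogeneity across cohorts**: under a common clones-per-wing rate,
  group *i* expects `Σn · N_i / ΣN` clones; chi-square on
  `len(groups) − 1` df. Degenerate all-zero input returns p = 1 with a
  warning rather than an error.

Degenerate inputs are flagged, not raised, where a field workflow needs
it: an empty group yields n = 0, f = 0 and NaN *m*; a single wing yields a
point estimate without a bootstrap interval.

## The simulator

`simulate_disc` grows `n0` unlabeled cells (default 5,500, the
mid-third-instar disc size at treatment) through `rounds` synchronous
division rounds (default 3, the divisions left before proliferation
ceases). Each unlabeled division converts one daughter into a labeled
clone founder with probability `p_loss` (default 1.7e-4, the spontaneous
rate); labeled cells divide normally but cannot lose the chromosome again,
so a clone founded in round r ends at 2^(R−r) cells — the size-class
bookkeeping holds by construction. Divisions are modelled as synchronous
rounds; the real ~10 h cycles are not explicitly asynchronous anywhere in
the accounting, and synchrony is what makes founding round and size class
interchangeable.

**Regeneration mode** (cytotoxic treatments): `death_fraction` of
treatment-time cells is removed and every survivor — labeled cells
included — performs `extra_rounds` compensatory divisions, producing the
class V–VIII oversized clones seen after X-rays or colchicine. The
per-division loss rate stays active during compensatory rounds (the
constant-rate assumption is extended rather than suspended).

`embed_wing` samples `blade_fraction` (default 0.5) of the final
population uniformly without replacement, truncates or pads with plain
unlabeled cells to exactly `screened_cells` (default 30,000), assigns each
surviving clone wholly to the dorsal or ventral surface, and places it as
a connected square patch on the surface lattice. Patches sit on a slot
grid sized `max_patch_side + clone_gap` (default gap 5 intervening cells,
comfortably beyond the 3-cell merge rule), so ground-truth clones can
never merge spuriously; over-dense configurations raise a placement error
rather than silently overlapping. The treatment-time count, blade
fraction and screened count are deliberately independent knobs — the
field's round numbers (5–6k cells, "about half", 30k screened) are only
approximately consistent with each other, and forcing one to derive from
the others would misstate all three.

`render_trichomes` gives wild-type cells one trichome in one of eight 45°
orientation sectors; labeled cells draw 2–5 trichomes (uniform) with the
second forced into a different sector, so every labeled cell satisfies
the divergent-orientation calling rule. `noise_rate` renders a fraction of
wild-type cells with two *same-sector* trichomes — a doubled hair that a
correct caller must reject.

A single seeded generator drives every draw in a fixed order
(growth → sampling → surface assignment → placement → rendering), so one
config + seed reproduces a wing bit for bit; cohorts spawn one child
stream per wing from a seed sequence.

### What the generator does and does not emulate

It reproduces the assay's statistical structure: event counts and founding
rounds under constant-rate branching, clone-size geometry under blade
sampling, contiguous same-surface spots, the mwh trichome phenotype and a
benign doublet confounder. It does not attempt wing geometry, veins,
cell-shape or density gradients, asynchronous cycling, position-dependent
proliferation, or clone fragmentation by cell mixing — so passing tests
demonstrate correctness of the scoring and estimation machinery on data
that obey the model's assumptions, not robustness to every way real wings
violate them (a real clone split by a vein, for instance, would be called
as two).

## Clone calling choices

* "Trichomes pointing into different directions" is operationalised as
  distinct 45° sectors (0–7): discrete, testable, and free of an arbitrary
  angular threshold. Cells with ≥3 trichomes are called regardless of
  orientation (the orientation clause qualifies only two-trichome single
  cells).
* The "no more than three normal cells between them" merge rule is read as
  a Chebyshev gap `max(|Δx|, |Δy|) − 1 ≤ 3` on the lattice — the
  permissive reading, stated exactly so the boundary cases are sharp: 3
  intervening cells merge, 4 do not. Merging is the transitive closure
  (disjoint-set union over KD-tree candidate pairs); the partition is
  order-invariant, and coarsens monotonically in the gap parameter.
* Clones never span surfaces. The hinge mask (an x-threshold or arbitrary
  coordinate predicate) removes cells before calling, and the screened
  count C reported downstream is the unmasked count.

## Loss-rate recovery and calibration

The estimator f = 2nm/(NC) is the field's published quantity, and the
package reports it with a wing-level bootstrap interval (resampling whole
wings preserves the within-wing clustering of clone counts). But f is not
numerically the per-division loss probability: it counts loss events from
*every* division round while normalising by a single effective target
count, so under constant-rate branching with R rounds and full blade
retention its expectation is close to R·p, and blade thinning shifts the
factor further (≈2.2 at the default geometry). `recover_loss_rate`
therefore also inverts the branching model: a dynamic program computes the
exact expectation of f under the generator's growth-sampling-scoring
chain — expected unlabeled divisions `n0(2−p)^(r−1)` per round, clone
cohorts of final size 2^(R−r), binomial thinning at retention
`min(blade_fraction, C/population)`, conditional observed-size
distributions, the resulting mean class index — and a monotone root-find
returns the p whose expected f matches the observed one. The bootstrap
interval maps through the same inverse. Parameter-recovery tests check
coverage of this calibrated estimate; the raw f is reported unchanged as
the published-scale quantity.

One consequence documented rather than hidden: the halve-by-half law holds
exactly for clone sizes at the end of proliferation, but binomial blade
thinning moves clones across class boundaries, so the simulator's
class-distribution test runs at full blade retention
(`blade_fraction = 1`, screened count equal to the final population)
where the law is mathematically expected — this follows from the thinning
arithmetic, not from tuning.

## Problem sizes used in the test suite

Unit tests use small discs (n0 = 100–500) at elevated loss rates so every
code path sees events; the end-to-end checks use the full default geometry
(n0 = 5,500, C = 30,000) with 30 single-disc replicates for the class
distribution law and 4 × 60-wing cohorts per rate for bootstrap-coverage
checks at p ∈ {1e-4, 1e-3} — sizes chosen to make the Monte-Carlo noise
small relative to the tested effects while keeping the default suite quick
to run.

## Package shape

The public surface follows the model/results idiom of statistical
packages: `CloneFrequencyModel` (from a tidy clone table, scored wing
records, or transcribed class counts) with `fit()` returning
`CloneFrequencyResults` carrying summaries, intervals, diagnostics and a
`summary()` table; the simulator and the pipeline/CLI hang off the same
dataclasses. Known limitations: no dose–response modelling, no
multiple-testing correction across treatment panels, no image-level
scoring — inputs are cell tables, not micrographs.
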