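# Methods

This note records the models, conventions, and design choices behind the
package, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and data model

All coordinates are 0-based, half-open (BED convention). A chromosome of
length *L* at resolution *r* has `ceil(L/r)` bins; bin *k* covers
`[k·r, (k+1)·r)` and a trailing partial bin is kept. Contact matrices are
per-chromosome, symmetric, with a zero diagonal by convention and a
valid-bin mask; they move through the states raw → normalized →
observed-over-expected, and each operation checks the state it needs.
Intra-chromosomal analysis only; trans contacts are out of scope.

## Synthetic generative model

The generator exists so that every downstream statistic can be validated by
parameter recovery. For bins *i* < *j* the expected contact count is

    E[i,j] = A · (j−i)^(−α) · (1 + c·σ_i·σ_j) · Π_{i ≤ b < j} f_b

with Poisson counts scaled so the expected upper-triangle total equals the
target depth. The three factors are:

* **distance decay** `(j−i)^(−α)`, default α = 1, the leading-order
  behaviour of polymer contact maps at this scale;
* **compartments**: a rank-1 checkerboard with per-bin signs σ ∈ {−1,+1}
  alternating in blocks and strength c ∈ [0,1);
* **boundaries**: each boundary "at bin b" separates bins ≤ b from bins
  > b and multiplies every crossing contact by its insulation factor
  f ∈ (0,1] (f = 1 ⇒ no boundary). Attenuation compounds across multiple
  boundaries.

Mutant genotypes derive from the wildtype layout by removing boundaries
(strict loss, f → 1, the boundary is absent from the mutant layout) or
weakening them (partial loss, f → f^γ, default γ = 0.5 — weakened but
present, which is what partial factor dependency looks like in insulation
terms).

**What the model emulates and what it does not.** It reproduces the
features the pipeline's statistics respond to: decay, counting noise at a
chosen depth, sharply positioned boundaries of graded strength, plaid
compartment structure, and coverage heterogeneity (boundary bins genuinely
lose total coverage). It does **not** model restriction-fragment structure,
mappability or copy-number artifacts, loops/corner peaks, nested domains,
or trans contacts. One consequence of multiplicative compounding deserves
note: with many strong boundaries planted, long-range contacts are
attenuated by large products, which erases the compartment plaid at long
range. Compartment recovery is therefore validated on boundary-free
checkerboard scenarios; in the mixed default pipeline scenario the
eigenvector is reported but dominated by domain structure. Passing recovery
tests shows the estimators work under this model's assumptions — not that
real-data artifacts are handled.

**Scenario conditions** (chosen once, on realism grounds):

* Recovery scenario: 500-bin (1 Mb) chromosome, 10 boundaries,
  f ∈ (0.2, 0.4), pairwise spacing ≥ 15 bins, depth 5 × 10⁶. The depth is
  of the order of the per-Mb contact density of a deeply sequenced fly
  experiment.
* Two-genotype scenario: 20 boundaries (5 strict, 3 partial), spacing
  ≥ 10 bins (20 kb). Contact domains below ~20 kb are essentially absent
  from fly maps at this resolution, and two boundaries within a 20-kb
  insulation window are below the caller's positional resolution.
* Boundaries are planted ≥ 40 bins (half the largest window) from
  chromosome ends, where truncated insulation windows make calls
  unreliable — the real analysis likewise excludes pericentromeric ends.
* ChIP scenario: 20-bp windows at 10-bp spacing over 20,000 windows,
  background mean 20, NB dispersion 0.05, 2 replicates per condition.
  Wildtype peaks at 16× background; partial peaks retain 6× in the mutant
  (16/6 > 2-fold reduction, and (6+1)/2 > 3× background keeps them
  detectable in the mutant-vs-knockout comparison); peak density ~1% of
  windows, so the mean-based background estimate is not inflated by peaks.
* Random number contract: every simulation call takes a named integer
  seed; replicate streams are spawned deterministically from it. Identical
  (parameters, seed) pairs give byte-identical outputs.

## Hi-C processing

**Low-coverage filter.** Bins with zero total contacts are masked, plus the
`floor(frac · n_nonzero)` lowest-total nonzero bins (default frac = 0.02),
with ties broken deterministically by bin index. The count-based rule (mask
exactly that many bins) is used rather than an inclusive value-threshold
rule, which would mask *every* bin when totals are tied (e.g. uniform
coverage). The quantile is genome-wide by default (per-chromosome filtering
is a parameter).

**ICE balancing.** The bias vector *b* making per-bin coverage equal over
valid bins (`out = D·M·D`, `D = diag(1/b)`) is found by solving the
log-bias equal-coverage equations with Newton–Krylov, falling back to the
classic fixed-point iteration (divide by coverage relative to the valid-bin
mean; convergence = coverage CV ≤ tol, default 10⁻⁸). The fixed point is
solved well past the CV tolerance because a loosely balanced matrix differs
cell-wise from the exact solution by more than the coverage CV suggests.
`D·M·D` has a free global scale; it is anchored so the valid-cell total
equals the raw valid-cell total. Masked rows/columns are NaN in the output.

**Observed-over-expected.** Expected value at distance *d* is the mean of
normalized values over valid pairs at *d*; by construction the per-distance
mean of O/E over valid pairs is exactly 1. Distances with no valid pairs
are NaN.

**Downsampling** draws without replacement (multivariate hypergeometric
over upper-triangle cells), matching fixed-total semantics exactly;
**replicate correlation** is the Pearson r over valid upper-triangle cells
at genomic distance < 1 Mb.

## Insulation and boundary calling

`binSignal_i` is the mean over the rectangle rows `i−w+1..i` × columns
`i+1..i+w` (valid cells only; truncated at chromosome ends). The insulation
score divides `binSignal_i` by the **sum** of `binSignal_j` over strictly
`i − w/2 < j < i + w/2`. The printed formula uses a sum while the
surrounding prose says local average; the sum is implemented. The
difference is a constant −log2(#terms) offset that cancels in every
difference the pipeline takes (between genotypes, between positions); the
strict bounds give w−1 terms for even w (9 at w = 10) and w terms for odd
w, which the constant-matrix analytic tests pin down.

The boundary caller is TopDom-compatible in structure but not bit-identical
(the reference algorithm's pruning internals are not fully specified):

1. candidates = local minima of binSignal (plateaus: leftmost bin);
2. pruning: one-sided Wilcoxon rank-sum that the w×w cross-rectangle values
   are lower than the flanking within-domain triangle values, at
   p < p_cut (default 0.05). The test runs on **observed/expected** values:
   on raw values cross cells sit at systematically larger distances than
   within cells, so a pure-decay null would be called anticonservatively.
3. an effect-size gate: mean(cross O/E) / mean(within O/E) ≤ max_ratio
   (default 0.8), which keeps the caller silent on null maps where rank
   noise alone would occasionally reach p < 0.05.

Per-window calls at 20/40/80/160 kb are merged as a union; the retained
score is the across-window mean insulation score at the bin. Because large
windows lose positional precision between closely spaced boundaries (their
rectangle spans both), the merged set is **sharpened**: a merged boundary
is kept only if it lies within one bin of a smallest-window call. Larger
windows corroborate and contribute to the score; the smallest window fixes
positions.

**2-kb merging.** Boundaries are whole bins, so "within 2 kb of each
other" is measured edge-to-edge between boundary bins: at 2-kb resolution,
bins one or two apart merge. Grouping is transitive (a–b and b–c within the
gap chain all three); each chain keeps the member with the lowest score
(leftmost on ties), so output boundaries are pairwise > 2 kb apart and the
operation is idempotent. The same chaining harmonizes genotypes: a chain
containing both genotypes is class `both` with score = mean of the two
genotypes' best scores; single-genotype chains are `wt_only`/`mutant_only`.
The insulation delta (mutant − wildtype, from the across-window average
tracks) is read at the representative bin; delta > +0.1 flags "visibly
weaker in mutant", < −0.1 "weaker in wildtype".

## Compartments

Per chromosome (arm), invalid bins and any configured exclusion mask are
dropped; the Pearson correlation matrix of the O/E matrix is formed and its
leading eigenvector (largest eigenvalue of the symmetric eigendecomposition)
is mean-centered and multiplied by the sign of its correlation with the
expressed-TSS density per bin ("expressed" = expression > 0 by default).
Positive bins are compartment A. A constant-row correlation matrix raises.
A gene's compartment is its TSS bin's label; genes in invalid bins are
unassigned and excluded from switch-fraction denominators.

## Windowed ChIP occupancy

Counting: a read increments every 20-bp window (10-bp spacing) it overlaps;
duplicates (chrom, start, end, strand) collapse when dedup is on. The
3-fold background filter estimates background as the median across samples
of the per-sample mean window count — a window-scale estimate of the
genome-wide per-2-kb average, valid because peaks occupy a negligible
genome fraction.

TMM factors are trimmed means of M-values (30% M-trim, 5% A-trim,
precision weights, reference = sample with upper quartile closest to the
mean upper quartile), anchored to product 1. The factors capture *relative
effective depth* — library size times composition — so doubling a library
doubles its factor. In one-sided comparisons (wildtype vs knockout) every
retained window is differential, so the pipeline computes factors on the
full background-dominated table, not the retained windows.

The per-window test replaces the quasi-likelihood GLM of the reference
toolchain with a documented simpler contract: a pooled NB dispersion
estimated by method of moments across windows
(φ̂ = Σ(v−m) / Σ(m²−v/r), clipped at 10⁻⁸), then an exact conditional NB
test on the per-condition sums (sum of outcome probabilities not exceeding
the observed one, the standard two-sided rule for discrete tests). With
2+2 replicates and 10⁴ windows the type-I rate at nominal 0.05 sits in the
requested [0.03, 0.07] band (slightly conservative, as discrete exact tests
are). log2FC = log2((mean_B + 0.5)/(mean_A + 0.5)) of normalized
per-replicate means; the 0.5 prior keeps identical counts at exactly 0.

Regions: retained windows within 100 bp (default; configurable) cluster;
region p = Simes over member windows; BH across regions; reported regions
satisfy FDR < 0.01 and |FC| > 2. Occupancy = best (smallest-p) window's
log2FC, ties broken by larger |log2FC| then leftmost; position = that
window's center.

Dependency classes from the three-way comparisons: wildtype-vs-knockout
peaks are split at the edges of overlapping mutant-vs-knockout and
reduced-in-mutant regions so each fragment is uniformly covered; a fragment
with no mutant-vs-knockout overlap is strictly dependent, with overlap plus
a reduced call partially dependent, otherwise independent. The exact
splitting rule of the reference analysis is not described; edge-splitting
is this package's own rule.

PWM scanning scores log2 odds against a uniform background on both strands
(N scores 0); strand symmetry score(s,+) = score(revcomp(s),−) is exact.
JASPAR-format matrices are read via Biopython with a 0.5 pseudocount.

## Association statistics

Distance profiles report, per signed 2-kb offset bin over ±20 kb (default),
the percentage of anchors with **at least one** feature in that bin — a
presence statistic, not a count. Direction-aware mode mirrors offsets at
minus-strand anchors. Random controls draw uniformly over valid bins;
matched controls draw, per 20-quantile bin of the matching covariate
(default expression), exactly as many pool members as there are cases,
failing loudly when a bin lacks pool. The central fold enrichment is the
case/control percentage ratio within ±1 kb of offset zero; a single control
draw is the default, an averaged multi-draw control is available. Fisher's
exact test (two-sided) and the Wilcoxon rank-sum test (exact for group
sizes ≤ 25, normal approximation with continuity correction above) wrap
scipy. Proximity counting keeps external intervals ≤ 4 kb and counts those
whose center is within 2 kb of a boundary. Reporter summaries take the
median of per-cell log2(mCherry/EGFP) per replicate (non-positive
intensities dropped) and average the medians.

## Pipeline, sizes, and determinism

`run_pipeline` chains simulate → filter/ICE → insulation/boundaries →
differential classification → compartments → windowed ChIP → association on
a single `RunConfig`, derives all stage seeds from one root seed, and
writes text outputs plus a JSON report. Thresholds default to the analysis
conventions (2-kb resolution; 20/40/80/160-kb windows; 2-kb merge gap;
±0.1 weak-delta flag; ChIP FDR < 0.01 and |FC| > 2; DE thresholds
padj < 0.05, |FC| > 1.5). The validation suite and the reproduction script
use the scenario sizes listed above — 500–750-bin chromosomes, depths of a
few 10⁶, 20 seeds per experiment — which keep each experiment in the
seconds-to-a-minute range while leaving the recovery rates stable to ~1%
across seeds.

## Known limitations

* The caller's positional accuracy degrades for boundary pairs closer than
  half the smallest window; such pairs are also rare in real maps at this
  resolution.
* The exact conditional NB test rounds normalized sums to integers; with
  very small counts it is conservative.
* Compartment calling assumes the plaid dominates the O/E correlation
  structure at long range; heavily domain-dominated matrices (or the
  synthetic model with many strong boundaries) violate this.
* The generator's Poisson counts have no overdispersion between Hi-C
  replicates; replicate-correlation numbers on synthetic data are
  optimistic relative to real libraries.
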