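# insulscope

Hi-C insulation analysis for chromosomes with architectural-protein-dependent
contact domains: matrix normalization, insulation scoring, contact-domain
(CD) boundary calling, two-genotype differential boundary classification,
A/B compartment calling, windowed differential ChIP occupancy, and the
association statistics that connect boundaries, binding sites, and gene
expression. A bundled synthetic-data generator with full ground truth makes
every step testable by parameter recovery.

The package targets the analysis design used for *Drosophila* CTCF studies:
wildtype versus factor-null Hi-C maps at 2-kb resolution, boundaries called
from insulation minima at several window sizes, and binding peaks classified
as strictly or partially dependent on the deleted factor.

## The core statistics

**Insulation score.** For a window of *w* bins, `binSignal_i` is the mean
normalized contact frequency of the *w* x *w* rectangle between the *w* bins
up to and including *i* and the *w* bins after *i* — the cross-boundary
"diamond". The physical insulation score is

```
score_i = log2( binSignal_i / sum_{i - w/2 < j < i + w/2} binSignal_j )
```

with strict bounds on *j* (9 denominator terms at *w* = 10), so a constant
matrix scores exactly −log2(9) ≈ −3.170 at every interior bin. Lower scores
mean stronger boundaries. Boundaries are local minima of `binSignal` pruned
by a one-sided rank-sum test on observed/expected contacts, called at window
sizes 20/40/80/160 kb, merged across windows, and collapsed within 2 kb
keeping the lowest-score member. Classification across genotypes compares
the per-genotype sets within 2 kb (`both` / `wt_only` / `mutant_only`) and
flags boundaries whose score difference (mutant − wildtype) exceeds +0.1 as
visibly weaker in the mutant.

**Compartments.** The leading eigenvector of the Pearson correlation matrix
of the observed-over-expected map, mean-centered, sign-oriented by the
density of expressed-gene TSSs per bin; positive values are compartment A.

**ChIP occupancy.** Counts in 20-bp windows spaced 10 bp, filtered at
3-fold over the between-sample median background, TMM-normalized, tested
per window with a pooled-dispersion negative-binomial exact test, combined
into regions by Simes with Benjamini–Hochberg across regions (FDR < 0.01,
|fold change| > 2). A region's occupancy is its best window's log2 fold
change (`best.log2FC`) and its position that window's center (`best.pos`).

**Synthetic truth.** Expected contacts follow
`E[i,j] = A·|i−j|^(−α) · (1 + c·σ_i σ_j) · Π f_b` — a power-law decay, a
rank-1 compartment plaid, and multiplicative attenuation `f ∈ (0,1]` per
boundary crossed — Poisson-sampled at a target depth. Mutants remove
boundaries (strict, `f→1`) or weaken them (partial, `f→f^γ`, default
γ = 0.5).

## Worked example

`python examples/01_boundaries_from_hic.py` simulates a 1-Mb chromosome
(2-kb bins, depth 5 × 10⁶ contacts) with ten planted boundaries, normalizes
it, and calls boundaries:

```
planted boundary bins: [50, 95, 141, 173, 230, 256, 340, 377, 425, 443]
insulation factors:    [0.35, 0.31, 0.27, 0.36, 0.26, 0.29, 0.23, 0.28, 0.24, 0.25]

called 10 boundaries:
 bin     score          windows
  50 -5.576416     (10, 20, 40)
  95 -5.611775     (10, 20, 40)
 142 -5.822805         (20, 40)
 173 -5.446016     (10, 20, 40)
 231 -5.877315         (10, 40)
 256 -5.668715 (10, 20, 40, 80)
 341 -5.997443     (10, 40, 80)
 377 -5.647967 (10, 20, 40, 80)
 424 -6.091293            (80,)
 444 -6.088035            (10,)
```

All ten planted boundaries are recovered within one bin, none spuriously.
The `score` column is the across-window mean insulation score (more
negative = more insulated) and `windows` lists the window sizes (in bins)
that called each boundary.

The other examples cover differential classification
(`02_differential_boundaries.py`), compartment recovery
(`03_compartments.py`), ChIP dependency classes (`04_chip_occupancy.py`),
and enrichment with matched controls (`05_enrichment_and_tests.py`).

A thin CLI wraps the pipeline: `insulscope simulate|boundaries|run`, e.g.

```
insulscope run --seed 1 --out runs/demo
```

writes boundary BED files, insulation and eigenvector bedGraphs, a gene
table, and a JSON run report.

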