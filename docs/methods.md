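# Methods

## Scope and data model

`cnegrn` reconstructs a developmental gene regulatory network from paired
expression and chromatin-accessibility matrices over a shared sample design
(tissue × stage × replicate, with batch labels), a catalog of conserved
non-coding elements with per-element conservation type and score, gene
models, TF motif models, and a transposable-element annotation.  Intervals
are held 0-based half-open internally; printed element identifiers of the
form `chr1:196579342-242` are treated as 1-based start plus *length* (the
`start-length` dialect) because catalog elements average ~80–300 bp — far
shorter than a start–end reading would imply.  The dialect is an explicit
parameter everywhere and is never guessed from the numbers.

## Model equations and conventions

- **Openness** `O[i,j] = (count[i,j]/length[i]) / (library[j]/G)`, the fold
  change of reads per base pair over the genome-wide background rate.  The
  effective genome size `G` is a required configuration value; openness is
  invariant to joint rescaling of all library sizes and `G`.  Pre-computed
  openness tables are ingested equivalently.
- **Specificity.** The JMS score is `med^(1/3) / max(JSD, ε)`.  Two
  deliberate numerical choices: (a) the Jensen–Shannon divergence is the
  standard base-2 form with mixture `M = (p+q)/2`, range [0, 1], rather
  than the shifted variant that omits the factor 2 inside the logarithms
  (that variant has a negative range and violates the divergence axioms);
  (b) the exponent on the median is the cube *root*, which keeps numerator
  and denominator on comparable magnitudes for FPKM-scale data.  Both are
  configurable (`jms_exponent`, and the floor `ε = 1e-6` that keeps the
  score finite for perfectly specific genes).
- **Upstream model.** One design column per nearby active element:
  elementwise (member-TF expression sum) × openness, fitted by ordinary
  least squares with a per-coefficient two-sided t-test at α = 0.05 and no
  within-TTF multiplicity correction (a family-wise option exists).  If
  the design would exceed `n_samples − 2` columns, terms are pre-screened
  by absolute marginal correlation and the reduction is logged; identically
  zero predictors are dropped with a warning.  Member TFs must carry a
  motif hit on the element *and* Spearman ρ > 0.6 with the TTF at BH
  q < 0.01 (family = all motif-bearing TFs tested for that TTF).
- **Downstream screen.** Predictor `sqrt(TTF·O)` per sample — the
  square-root (geometric-mean) coupling of regulator expression and element
  accessibility.  Correlations are computed on `log2(x+1)` scales by
  default (raw scale available); Spearman with average ranks; BH over the
  entire tested triplet family; retention requires γ strictly > 0.7 and
  q < 0.01.  Triplets with a constant predictor or response are flagged
  invalid and excluded from the BH family.  Samples are pooled across the
  focal tissue's stages and replicates.
- **Influence.** `R_k,t` multiplies openness, binding strength B, TTF and
  target expression (replicates of a time point averaged) and a gamma
  factor.  The gamma factor defaults to `2^γ`; a `2·γ` reading is available
  behind `gamma_transform="linear2"`.  Both are monotone in γ, so rankings
  are insensitive to the choice.  `R_k = max_t R_k,t` over the focal
  tissue's time points; `W = sqrt(R·C)`.  Type I conservation (PhastCons,
  bounded in [0,1]) and type II (PhyloP, unbounded) are different scales,
  so ranking is dense, descending and strictly within type; cross-type W
  values are reported but never cross-ranked.
- **Motif scanning.** Log-odds scores against a configurable background
  (uniform default) are discretized to an integer grid (10^-4 log2 units)
  and the null score distribution is obtained exactly by dynamic
  programming (per-position convolution).  Window scores use the same grid,
  so p-values are exact on the grid and monotone decreasing in score by
  construction.  Both strands are scanned; windows containing N are
  skipped; the default per-match threshold is p ≤ 1e-4.  Binding strength
  `B = Σ −log10 p` over a region's matches, with p = 0 capped at
  −log10 p = 10.  External hit tables (per-match `neglog10p` or
  pre-aggregated `B`) are ingested so an external scanner can substitute.
- **Reproducible peaks.** Peaks from all replicates of a condition are
  pooled and joined into connected components under ≥ 1 bp overlap; a
  component is kept iff every replicate contributed a peak.  The consensus
  span is the union of contributing peaks (an intersection-span variant is
  available).  Element activity requires ≥ 1 bp overlap with a consensus
  region by default (`min_overlap` configurable).
- **Differential layer.** Welch t-tests on `log2(FPKM+1)` with per-stage
  BH families approximate the moderated linear models often used for this
  step; externally computed p/FC tables are accepted verbatim
  (`calls_from_table`) for users who prefer limma/edgeR output.  Gene calls
  gate on focal-up `log2FC > 1`, peak calls on `|log2FC| > 1`, both at
  q < 0.05, all strict.  A stage with one replicate per group uses the
  plain rule FPKM > 2 and FC > 2 with ε = 0.01 guarding the ratio.
  Differential TTFs are the intersection of differentially expressed TFs
  and TFs motif-enriched in differentially accessible peaks
  (hypergeometric upper tail against the consensus background, strict
  −log10 P > 6).
- **TE summaries.** An element is TE-derived when ≥ 50% of its length is
  covered by the TE annotation (union coverage; fraction configurable with
  a 1 bp option).  Because fold comparisons appear in two conventions in
  the literature, both are always emitted with labels: the ratio
  `pct_A/pct_B` and the excess `(pct_A − pct_B)/pct_B`.

## Synthetic data generator

The generator emulates the motivating study design: two epithelial tissues
(focal organ and developmental predecessor) × five stages (E60, D1, D7,
D28, Y1) × three biological replicates (one at Y1), two library batches
with log-additive offsets (sd 0.3 log2 units), paired FPKM and openness
matrices, a two-chromosome 1 Mb-each toy genome, gene models, motif models
(8 bp consensus PFMs), and a TE annotation.  Planted structure:

- 3 toolkit TFs whose expression follows the upstream linear model with
  known coefficients (β ∈ [0.01, 0.05], noise sd = 10% of signal sd);
- 10 planted downstream triplets whose target log-expression is linear in
  `sqrt(log2(TTF+1)·log2(O+1))` with slope 3 and Gaussian noise sd 0.5
  log2 units — calibrated so the realized planted Spearman coupling is
  ≈ 0.9, the strength of coupling the screen is designed to call;
- 90 decoy triplets whose element carries a genuine TTF motif (inserted
  into the genome sequence, so scanning rediscovers it) but whose target is
  developmentally flat lognormal noise;
- 14 inactive elements with no peaks and no motifs.

Openness and regulator-TF profiles are random-walk stage profiles spanning
realistic dynamic ranges (openness 1–20, TF FPKM 5–50) with 0.2 log2 units
of replicate noise.  All draws come from one seeded generator in documented
order; a given seed reproduces the bundle exactly.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: read-level sampling noise, mappability and GC
artefacts, motif similarity within TF families (each synthetic TF has a
unique consensus), correlated decoy expression programs (real non-targets
share developmental trends, which inflates the tail of spurious
correlations relative to this null), linkage between neighbouring elements,
and genome-scale multiple-testing burdens.

## Problem sizes

The recovery experiments run at deliberately compact sizes chosen to
exercise every code path of the method: the upstream-recovery experiment
uses 100 replicates of 20 samples × 3 terms; the null calibration uses
10^4 independent triplets of 13 samples (the focal-tissue sample count of
the emulated design); the end-to-end recovery uses the default bundle
(10 planted vs 90 decoy triplets, 120 elements, 55 genes); brute-force
oracle comparisons run at ≤ 10^3 intervals.

## Known limitations

- The Welch t-test differential layer lacks the variance moderation of
  limma/edgeR; at small replicate counts it is conservative.
- The upstream OLS assumes additive, contemporaneous effects; no time lags
  or penalization.
- The motif scanner's exact p-values assume an i.i.d. background;
  dinucleotide backgrounds and ZOOPS-style scoring are out of scope.
- The downstream screen is correlational; retained triplets are hypotheses
  for functional validation, not causal claims.
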