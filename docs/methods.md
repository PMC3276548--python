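# Methods

## The analysis

`mirderep` quantifies transcriptome-wide derepression of microRNA targets in
a loss-of-function experiment: log2 expression profiles of the same cell
population from wild-type animals (miRNA active) and miRNA-deletion mutants,
with replicates per genotype.  The chain of inference is:

1. **Site detection.**  Canonical target sites are exact reverse-complementary
   matches on the 3'UTR sense strand to the miRNA seed: positions 2–8 (a 7-nt
   "seed7" site) or positions 2–7 (a 6-nt "seed6" site).  The seed7 match is
   implemented as a plain 7-nt complement to positions 2–8 with no requirement
   for an A opposite position 1; TargetScan-style "7mer-A1" counts will differ.
   A seed6 occurrence contained in a reported seed7 window is not reported
   again.  `N` never matches.  Non-canonical (seed-imperfect) sites are never
   called from sequence: they are imported from an external prediction table
   and retained only with a favourable score (mirSVR convention, score
   < −0.1; more negative = stronger predicted site).
2. **Conservation.**  A site is *well-conserved* under the default rule when
   at least 5 of the six-species melanogaster-group panel (D. sechellia,
   D. simulans, D. yakuba, D. erecta, D. ananassae, D. pseudoobscura) carry a
   gapless, base-identical copy of the reference site, and D. pseudoobscura
   is among them; otherwise *poorly-conserved*.  An alternative outgroup rule
   calls a site well-conserved when it is identical in at least one species
   outside the melanogaster group (pse, per, wil, moj, vir, gri).  Whether
   "identical" tolerates alignment gaps is an open choice; gapless identity
   was chosen, and a gap in a species' site columns counts as non-identical
   for that species.  Alignment rows are projected onto reference (ungapped)
   coordinates before classification.
3. **Gene-level collapse.**  Multiple sites per gene collapse under the
   precedence seed7 > seed6 > non-canonical; gene conservation is "well" if
   any site is well-conserved.  This precedence is a package decision (the
   field has no fixed convention) and is the natural one given the ordered
   repression strengths; it is isolated in `gene_site_summary` so sensitivity
   analyses can swap it.
4. **Differential expression.**  Per gene, log2 fold change =
   mean(mutant) − mean(wildtype); a two-sample t on log2 values (Welch by
   default, pooled-variance optional); Benjamini–Hochberg FDR across genes.
   Probe-level inputs collapse to the probe with the lowest adjusted p (ties:
   lexicographically lowest probe id).  Presence per genotype = median log2
   intensity above a threshold (default: 25th percentile of the whole
   matrix) — a deliberate, configurable stand-in for platform-specific
   detection calls.
5. **ECDF shifts.**  Genes are partitioned into mutually exclusive sets over
   the expressed universe (by site class, conservation, or any-site), with
   background = expressed genes bearing no site of any class (strictest
   mutual exclusion; a "no conserved site" background is available for
   sensitivity).  Each set is compared to background with the two-sample
   Kolmogorov–Smirnov test on log2 fold changes; D = sup |F_set − F_bg|,
   two-sided p.  Direction (up/down) is reported separately, from the sign of
   the median difference, because sidedness of the original test is not part
   of the statistic.  The same machinery runs on absolute levels (mean log2
   intensity within one genotype) and on progenitor/neuron signature sets.
6. **Motif regression.**  REDUCE-style iterative single-motif least squares:
   every width-7 motif observed in the UTRs is scored by the two-sided t
   p-value of the slope of the current residual fold changes on its
   occurrence *count* (count, not presence, is the classic convention);
   the best motif (ties: larger |slope|, then lexicographic) is accepted when
   its — optionally Bonferroni-corrected — p is ≤ 0.05, its fitted
   contribution subtracted, and the search repeated (cap: 20 motifs).
   Residual sum of squares strictly decreases at every acceptance.
   Discovered motifs are annotated as cognate-seed variants (Hamming ≤ 1 from
   the seed7 pattern, or an exact shifted 7-window over the reverse
   complement of miRNA positions 1–9), known motifs (default table: the
   Pumilio binding site UGUAAAU, transliterated U→T), or orphans.
7. **Enrichment.**  One-sided Fisher's exact test (hypergeometric upper tail,
   P(X ≥ a)) of a gene set against each annotation term within the expressed
   universe, Bonferroni-corrected over the terms tested; terms with fewer
   than 3 universe genes are skipped (stability guard).  Up/down cohorts
   require |fold change| > 30% with p < 0.05.  The *exclusion contrast*
   reports each term's enrichment among (i) all predicted targets and
   (ii) derepressed targets (targets ∩ up cohort), separating bioinformatic
   from functional mutual exclusion.

## Statistical and numerical choices

* **Welch vs moderated fits.**  Expression pipelines usually moderate
  per-gene variances across genes; this package deliberately uses plain
  two-sample t statistics, so gene lists near thresholds will differ from a
  moderated analysis.  Two consequences are documented rather than patched:
  (a) at 3+3 replicates Welch's t is conservative under the null (~3.7% of
  raw p < 0.05 instead of 5%, a known property of the Welch–Satterthwaite
  approximation; the pooled-variance option is exactly calibrated under
  homoscedastic noise), and (b) without moderation the BH-adjusted p of a
  3+3-replicate t-test essentially never reaches 0.05, so the ">30% and
  p<0.05" / ">2-fold and p<0.05" cohort filters default to raw p
  (`use_adjusted` switches them).  Both p columns are always written.
* **Variance floor.**  Within-group variances are floored at 1e-8 on the
  log2 scale so duplicated rows give t = 0, p = 1 rather than NaN.
* **KS flavour.**  Exact null enumeration when the smaller sample has ≤ 25
  values, the asymptotic Kolmogorov distribution otherwise — transcriptome-
  sized sets make exact enumeration pointless and slow.  ECDFs are
  right-continuous (ties counted with ≤).
* **Coordinates.**  0-based half-open everywhere internally; site-table files
  declare their convention in a `#coords=` header and 1-based-closed input is
  normalized on import.
* **Degenerate inputs.**  Constant fold-change vectors yield an empty motif
  model; zero-variance motif columns are skipped; empty gene sets are skipped
  with a warning in shift analyses and raise errors where a result would be
  meaningless (empty universe, empty background).

## The synthetic-data generator

The generator emulates the sorted-cell experiment end to end: 2000 genes,
two genotypes × 3 replicates, per-gene baseline ~ Normal(6, 2) on the log2
scale, additive replicate noise Normal(0, 0.5), 500-nt i.i.d.-uniform UTRs.
Planted structure and defaults:

| parameter | default | meaning |
|---|---|---|
| `frac_7mer`, `frac_6mer`, `frac_noncanonical` | 0.10 / 0.10 / 0.05 | gene fractions given one planted site of each class |
| `effect_7mer`, `effect_6mer`, `effect_nc` | 0.6 / 0.3 / 0.15 | mean log2 derepression added to mutant samples, ordered by class |
| `frac_conserved` | 0.5 | planted sites labelled well-conserved |
| `expr_mean_offset_targets` | +1.0 | log2 baseline offset of target genes (targets sit above average expression in both genotypes) |
| `frac_pumilio_down`, `pumilio_effect` | 0.05 / −0.4 | cohort carrying UGUAAAU with a negative shift |
| `noise_sd` | 0.5 | per-sample log2 replicate noise |
| `n_species` | 7 | alignment depth including the reference |

Effect sizes are study conditions, not estimates of any biology: the source
experiments report no per-class effect scale, so the defaults were chosen
once to be comfortably detectable at 3+3 replicates while keeping the class
ordering non-trivial, and are fully tunable.

Key generator decisions:

* **Effects follow realized site content.**  Background UTRs acquire
  accidental seed matches at an appreciable rate (~11% of 500-nt sequences
  contain a chance 6mer).  A real seed match represses regardless of how it
  arose, so genes with accidental matches receive the effect of their
  strongest realized class; the truth table records the match as
  `incidental` and keeps the original `designed_class`.  Decoupling the two
  (sites without effects) would break the mutual-exclusion structure the
  analysis assumes — measured concretely as the seed6 target set degrading
  toward the non-canonical set.
* **The Pumilio cohort is scrubbed** of canonical seed matches so its net
  planted effect is negative by construction.
* **Non-canonical planted sites** are the seed7 pattern with one mismatch at
  a seed position (never creating a canonical match), exported to an
  imported-style prediction table with scores ~ Uniform(−0.5, −0.1); the
  external scoring model itself is out of scope.
* **Alignments.**  Well-conserved sites are copied identically into ≥ 5
  non-reference species including the mandatory one; poorly-conserved sites
  are identical in ≤ 4 species or in exactly the 5 species lacking the
  mandatory one (so the mandatory-member clause is exercised); non-site
  columns mutate per-base at rate 0.2.
* **Determinism.**  One master seed spawns independent substreams per
  component (assignment, sequences, expression, alignments, annotations);
  identical configs give byte-identical datasets.
* **Scenarios.**  `default`, `null` (all effects zero, for calibration),
  `signature` (progenitor genes shift up, neuron genes down), `exclusion`
  (an "epidermis" term enriched among targets whose effects are zeroed).

What the generator does **not** model: probe-level microarray effects,
normalization artefacts, batch effects, cell-sorting impurity, heteroscedastic
or correlated noise, UTR length/composition biases, site context (AU-flank,
position within UTR), and conservation-dependent effect strength (well- and
poorly-conserved planted sites share the same class effect, so passing tests
say nothing about conservation-stratified effect *ordering* on real data —
only about correct partitioning and direction).

## Problem sizes in the standard runs

The calibration and recovery studies use: 2000 genes × 3+3 replicates;
2000 resampled-noise repeats for the null type-I-error rate of the
target-set KS test (one fixed null partition, fresh replicate noise each
repeat); 100 independently seeded datasets for the class-ordering and
motif-recovery rates (motif runs: one planted seed7 cohort at +0.5 per
occurrence, one TGTAAAT cohort at −0.5, residual fold-change noise sd 0.5,
realized as per-sample noise 0.5·√(3/2)); oracle-agreement checks use 1000
random 500-nt UTRs (scanner), 10⁴ random sample pairs (KS), 10⁴ random
contingency tables at N ≤ 500 (Fisher), and 10⁴ random p-vectors (BH).

## Known limitations

* No moderated variance estimation; underpowered at few replicates compared
  to limma-class pipelines, and conservative Welch p at n = 3.
* Conservation classification requires alignments projected to reference
  coordinates; there is no liftover, and CDS/5'UTR sites are out of scope.
* The motif search is fixed-width, count-coded, single-variable per step; no
  PWM refinement and no multi-motif joint fit.
* The printed statistics of the motivating experiments (genome-wide KS
  p-values, motif cohort sizes, signature cluster sizes) depend on the real
  microarray data, genome-wide UTR sets, and annotation-database versions,
  none of which ship with the package; the acceptance machinery therefore
  measures operating characteristics on synthetic data.
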